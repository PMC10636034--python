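"""Network multifractal spectrum via the sandbox method.

Sampled centers c yield masses M_c(r) = number of nodes within shortest
path distance r.  Mass exponents tau(q) are the log-log slopes of the
moment curves <(M(r)/N)^(q-1)>_c against r/d (d = diameter); the
Lipschitz-Holder exponents alpha(q) = d tau / d q and the spectrum
f(alpha) = q alpha - tau follow by numerical Legendre transform.  Spectrum
width (alpha_max - alpha_min) measures structural heterogeneity; height is
taken as max f(alpha).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph

from .netio import DirectedPattern

__all__ = [
    "MultifractalSpectrum",
    "SandboxMasses",
    "sandbox_masses",
    "spectrum",
    "width_height",
    "default_q_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SandboxMasses:
    """Mass table M_c(r) for sampled centers, on the largest component."""

    centers: np.ndarray  # (n_centers,) node ids within the component
    radii: np.ndarray  # (n_radii,)
    masses: np.ndarray  # (n_centers, n_radii)
    component_size: int
    diameter: int


@dataclass(frozen=True)
class MultifractalSpectrum:
    q_grid: np.ndarray
    tau: np.ndarray
    alpha_lh: np.ndarray
    f_alpha: np.ndarray
    width: float
    height: float
    r_squared: np.ndarray
    radii_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.q_grid,
                "tau": self.tau,
                "alpha": self.alpha_lh,
                "f": self.f_alpha,
                "r_squared": self.r_squared,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_json(self) -> str:
        return json.dumps({"width": self.width, "height": self.height})


def default_q_grid(lo: float = -5.0, hi: float = 5.0, step: float = 0.5):
    """q values from lo..hi excluding the neighborhood (0.9, 1.1) of q=1."""
    q = np.arange(lo, hi + step / 2, step)
    return q[(q <= 0.9) | (q >= 1.1)]


def _undirected_distances(pattern: DirectedPattern):
    """(component node ids, pairwise-ready adjacency, sizes) of the LCC."""
    adj = pattern.symmetrized().to_sparse()
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        logger.warning(
            "graph is disconnected (%d components); restricting to the "
            "largest connected component",
            n_comp,
        )
    largest = np.argmax(np.bincount(labels))
    nodes = np.flatnonzero(labels == largest)
    sub = adj[np.ix_(nodes, nodes)]
    return nodes, sub


def sandbox_masses(
    pattern: DirectedPattern,
    radii=None,
    n_centers: int = 50,
    seed: int = 0,
) -> SandboxMasses:
    """M_c(r) = nodes within distance r of center c (undirected distances).

    Centers are sampled uniformly without replacement from the largest
    connected component; `radii` defaults to 1..ceil(diameter/2).
    """
    nodes, sub = _undirected_distances(pattern)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    k = min(n_centers, n)
    centers_local = np.sort(rng.choice(n, size=k, replace=False))
    dist = csgraph.dijkstra(sub, directed=False, unweighted=True)
    diameter = int(dist[np.isfinite(dist)].max()) if n > 1 else 0
    if radii is None:
        # half the diameter, but never fewer than 3 radii when the graph
        # allows it (spectrum fitting needs >= 3 usable points)
        hi = min(max(diameter, 1), max(3, int(np.ceil(diameter / 2))))
        radii = np.arange(1, hi + 1)
    radii = np.asarray(radii, dtype=int)
    if radii.size and (radii.min() < 1 or (diameter and radii.max() > diameter)):
        raise ValueError(f"radii must lie in [1, diameter={diameter}]")
    dc = dist[centers_local]
    masses = np.array([(dc <= r).sum(axis=1) for r in radii]).T
    return SandboxMasses(
        centers=nodes[centers_local],
        radii=radii,
        masses=masses,
        component_size=n,
        diameter=diameter,
    )


def spectrum(
    pattern: DirectedPattern,
    q_grid=None,
    radii=None,
    n_centers: int = 50,
    seed: int = 0,
) -> MultifractalSpectrum:
    """Sandbox multifractal spectrum of the (symmetrized) network.

    The fit uses radii where the mean mass has not yet saturated at the
    component size; at least 3 usable radii are required.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any((q_grid > 0.9) & (q_grid < 1.1)):
        raise ValueError("q_grid must exclude the neighborhood (0.9, 1.1) of q=1")
    mass = sandbox_masses(pattern, radii=radii, n_centers=n_centers, seed=seed)
    N = mass.component_size
    d = max(mass.diameter, 1)
    mean_mass = mass.masses.mean(axis=0)
    usable = mean_mass < N  # strictly below the saturation plateau
    if usable.sum() < 3:
        raise ValueError(
            f"only {int(usable.sum())} usable radii below saturation; need >= 3"
        )
    r = mass.radii[usable].astype(float)
    frac = mass.masses[:, usable] / N  # (centers, radii)
    x = np.log(r / d)
    tau = np.empty(q_grid.size)
    r2 = np.empty(q_grid.size)
    for i, q in enumerate(q_grid):
        y = np.log(np.mean(frac ** (q - 1.0), axis=0))
        slope, intercept = np.polyfit(x, y, 1)
        tau[i] = slope
        resid = y - (slope * x + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2[i] = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    alpha = np.gradient(tau, q_grid)  # handles the gap at q=1
    f = q_grid * alpha - tau
    return MultifractalSpectrum(
        q_grid=q_grid,
        tau=tau,
        alpha_lh=alpha,
        f_alpha=f,
        width=float(alpha.max() - alpha.min()),
        height=float(f.max()),
        r_squared=r2,
        radii_used=mass.radii[usable],
    )


def width_height(s: MultifractalSpectrum) -> tuple[float, float]:
    """(alpha_max - alpha_min, max f(alpha)) recomputed from the arrays."""
    return (
        float(s.alpha_lh.max() - s.alpha_lh.min()),
        float(s.f_alpha.max()),
    )
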