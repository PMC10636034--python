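# fractrl

Structural controllability of discrete-time dynamical networks with
long-term power-law memory.

Networks whose state depends on the distant past (modeled with
Grünwald–Letnikov fractional-order differences) can be steered to any
target state with far fewer dedicated inputs than their memoryless
(Markov) counterparts on the same topology. `fractrl` computes, for any
directed network and any time-to-control horizon `T`:

- the **minimum driven-node set** (diagonal input matrix) achieving
  structural controllability in `T` steps, for Markov and for
  power-law-memory dynamics — the memory case reduces to the Markov
  problem on the self-loop-augmented pattern;
- the **generic rank** of the `T`-step structural controllability matrix,
  computed as a unit-capacity max flow on a time-expanded graph (with an
  independent numeric oracle for verification);
- **trajectory simulation** and numeric `T`-step reachability for
  fractional-order realizations;
- **comparison metrics** across the time-to-control sweep
  (`n_T`, `%D`, `% savings`, `% time-to-control`) and seeded ensemble
  experiments over Erdős–Rényi, Barabási–Albert and Watts–Strogatz
  topologies;
- the **sandbox multifractal spectrum** of a network (width/height as
  structural-heterogeneity indicators).

## Library quick start

```python
import fractrl as f

star = f.DirectedPattern(3, {(0, 1), (0, 2)})   # hub drives two leaves
f.min_driven(star, T=3, mode="markov").size       # 2
f.min_driven(star, T=3, mode="long_memory").size  # 1  (memory helps)

profile = f.control_profile(star, T_grid=[1, 2, 3])
profile.to_frame()          # T, pct_ttc, n_markov, n_longmem, n_T, pct_D, pct_savings
```

Arc convention: `(j, i)` means node `j` influences node `i` (entry
`(i, j)` of the state matrix is a free parameter).

## CLI

```sh
fractrl generate --family er --n 250 --m 300 --seed 1 --out er.tsv
fractrl mindriven --edgelist er.tsv --T 50 --mode long_memory --method heuristic
fractrl profile  --edgelist er.tsv --out profile.csv --summary summary.json
fractrl ensemble --family ba --n 50 --k 2 --reps 20 --seed 7 --out mean.csv
fractrl simulate --edgelist er.tsv --driven 0,1 --alpha 0.5 --steps 100 --seed 3 --out traj.csv
fractrl spectrum --edgelist er.tsv --undirected --out spec.csv --summary wh.json
```

Every stochastic subcommand takes an explicit `--seed` (default 0) and
records it in its outputs; identical config + seed gives byte-identical
CSVs.

## Package layout

| module | contents |
| --- | --- |
| `fractrl.netio` | `DirectedPattern`, edge-list / Matrix Market I/O, ER/BA/WS generators, source-SCC decomposition |
| `fractrl.fracdyn` | memory kernel `psi_weights`, expanded matrices, `simulate`, `reachability_matrix`, numeric controllability oracle |
| `fractrl.structctrl` | self-loop augmentation, time-expanded-graph generic rank (+ certificates), numeric generic-rank oracle |
| `fractrl.drivensel` | minimum driven sets: exact (N ≤ 14), lazy greedy, partition/source-SCC heuristic — all certificate-checked |
| `fractrl.experiments` | `control_profile`, ensemble experiments, real-network summaries |
| `fractrl.multifractal` | sandbox masses, spectrum, width/height |
| `fractrl.cli` | `fractrl` console entry point |
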