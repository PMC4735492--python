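# raidsim

An agent-based model of collective risky action ("raids") on friendship
networks. Each agent carries a strategy `s ∈ [0, 1]` — the probability of
joining a raid when asked. Every generation a leader recruits a raid
nucleus from within hop distance `r` (nucleation), nucleus members ask
their direct friends (expansion), the raid occurs if at least `m` agents
joined, coordination payoffs are assigned, and the whole population then
updates by pairwise imitation (copy a random peer's strategy iff that peer
scored strictly higher). The headline statistic is the **Mean Risk-taking
Ratio (MRR)**: mean strategy after convergence divided by the initial mean.

The package also implements two intervention regimes and their analysis:

* **attitude bias `α`** — non-leader initial strategies drawn from `[0, α]`;
* **control nodes** — "saints" (never join) and "devils" (always join),
  placed uniformly at random or on the highest-degree nodes;

plus replicate batch runners, parameter sweeps with bootstrap CIs and OLS
regression of mean MRR on control count, and grid calibration of the
nucleus size `n` and raid threshold `m` so that the baseline MRR is close
to one.

## Layout

| module | contents |
| --- | --- |
| `raidsim.network` | Watts-Strogatz generation, distance neighborhoods, top-degree selection, two-sample KS degree comparison, edge-list/GraphML/GML I/O, node-role CSVs |
| `raidsim.simcore` | the game itself: population init, nucleation, expansion, payoffs, imitation, convergence, `run_simulation` |
| `raidsim.interventions` | saint/devil placement, attitude-bias initialization |
| `raidsim.experiments` | replicate batches, sweeps, MRR regression, baseline calibration |
| `raidsim.fixtures` | seeded named (network, leader set) fixtures `ws91` … `ws500` |
| `raidsim.cli` | the `raidsim` command line |

## CLI

```sh
raidsim fixtures                        # list shipped fixtures
raidsim fixtures --name ws91 --out out/ # write edge list + roles CSV
raidsim gen-network --n 200 --neighbors 6 --rewire 0.75 --seed 1 --out net.edgelist
raidsim simulate --network fixture:ws91 --seed 7 --out run/
raidsim batch    --network fixture:ws91 --replicates 1000 --seed 7 --out batch/
raidsim sweep    --network fixture:ws91 --param saint_count --values 0,5,10 \
                 --placement top_degree --replicates 200 --seed 7 --out sweep/
raidsim calibrate --network fixture:ws91 --n-grid 3,4,5,6 --m-grid 7,8,9,10 \
                 --replicates 100 --seed 7 --out cal/
```

Networks are `fixture:<name>` or a file (edge list, GraphML, GML; format
inferred from the extension). Node roles (leader/saint/devil) travel in a
separate two-column CSV via `--roles`. Every command writes a
`provenance.json` sidecar with the fully resolved configuration and seeds;
any output is reproducible from its sidecar. Config precedence:
CLI flag > `--config` YAML file > shipped defaults.

## Reproducibility

All randomness flows through explicit seeds (`numpy.random.Generator`
seeded per replicate from `SeedSequence` entropy tuples). The same
network seed, run seed, and configuration reproduce every raid record,
trajectory, and aggregate bit-for-bit.
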