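# divnav

Diversity monitoring and adaptive constraints for string-based generative
molecular design.

Reinforcement-learning-driven generators (REINVENT-style RNNs over SMILES)
reliably *mode-collapse*: as the policy is optimized toward a property
score, the emitted molecules concentrate on a few structures, and the
collapse looks different depending on the representation you measure it in.
`divnav` gives computational chemists running such campaigns three things:

1. **Multi-metric diversity analysis** of each generation step's batch —
   structural (Morgan/Tanimoto mean pairwise similarity and distinct-cluster
   ratio at threshold 0.3), sequence-level (SMILES 10-gram unique fraction
   and frequent-gram count), fragment-level (BRICS distinct-fragment
   fraction and frequent-fragment count) and scaffold-level (Bemis–Murcko).
2. **Temporal monitoring** — per-step time series, collapse alerts, PCA /
   t-SNE / UMAP chemical-space projections, static HTML reports.
3. **Adaptive constraints** — three flagging algorithms (similarity
   clusters exceeding 10 molecules or 10% of a step; fragments > 8 heavy
   atoms in > 5% of molecules with ≥ 50 cumulative occurrences; 10-grams in
   > 3% of molecules with ≥ 100 cumulative occurrences) that emit
   per-molecule multiplicative penalties in [0, 1] for integration into an
   RL scoring function, plus strong/weak combined regimes.

A bundled synthetic campaign generator — a softmax-over-templates surrogate
with a rising inverse temperature and a closed penalty loop — reproduces
collapse and constraint response end to end with no external model or data,
and is what the test suite and acceptance script exercise. See
`docs/methods.md` for the model, parameter meanings and limitations.

## Worked example

Simulate a collapsing unconstrained campaign, analyze it, then stream it
through the combined constraint regime:

```console
$ divnav simulate --steps 40 --batch 100 --seed 7 --out run
wrote run/run_log.csv (4000 molecules)
$ divnav analyze --log run/run_log.csv --out analysis
wrote analysis/metrics.csv (40 steps)
$ divnav constrain --log run/run_log.csv --regime all --out constrained
wrote constrained/scoring.csv and constrained/flagged.csv (293 flags)
$ divnav report --metrics analysis/metrics.csv --flagged constrained/flagged.csv --out report.html
wrote report.html
```

Selected rows of `analysis/metrics.csv` (long format, pivoted):

```
metric  cluster_ratio  mean_tanimoto  ngram_unique_frac  ngram_frequent_n  frag_frequent_n  mean_score
step
0                0.91          0.123              0.800               0.0              6.0       0.490
20               0.22          0.219              0.293              54.0             14.0       0.944
39               0.10          0.368              0.169              48.0             12.0       0.946
```

Read: at step 0 the sampler is flat — 91 structural clusters per 100
molecules, 80% of 10-grams unique, no frequent gram, mean score ≈ the pool
average. By step 39 the score has been optimized to 0.95 at the cost of
diversity: 10 clusters per 100 molecules, frequent 10-grams up from 0 to ~50.
The constraint pass flags 257 redundant 10-grams, 32 cluster
representatives and 4 oversized fragments, and zeroes the score of 3369 of
the 4000 molecules in `constrained/scoring.csv` (columns `step, smiles,
score, multiplier, adjusted, reasons`) — the record an external RL scoring
function would consume.

Run the same campaign *with* the constraint loop closed
(`divnav simulate --regime all ...`) and the collapse largely disappears;
the n-gram regime alone preserves structural and fragment diversity too,
while the similarity regime does not — string-space penalties act in the
generator's own representation, fingerprint-space penalties do not.

## Library surface

```python
from divnav import (read_run_log, track_run, make_regime, process_log,
                    SimConfig, run_campaign)

log = read_run_log("run/run_log.csv")
series = track_run(log)                      # DiversityTimeSeries
table, state = process_log(log, make_regime("ngram"))  # penalties + flags
result = run_campaign(SimConfig(seed=1, regime="all"))  # closed loop
```

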