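# Methods

`divnav` monitors and steers the chemical diversity of a string-based
generative molecular design campaign. Its inputs are per-iteration batches of
SMILES strings with scores in [0, 1] — the stream a reinforcement-learning
(RL) loop around an autoregressive generator produces — and its outputs are
per-step diversity metrics, flagged redundant patterns, and per-molecule
penalty multipliers that an external RL scoring function can consume.

## Diversity metrics

Four metric families probe complementary representations of a batch. All of
them are computed on the batch's *valid* molecules only; the valid fraction
is itself a reported metric, and invalid SMILES are retained in the data
model (validity is data, not an error).

**Structural (fingerprint) metrics.** Molecules are fingerprinted with
hashed Morgan circular fingerprints (radius 2, 2048 bits by default; MACCS
keys available). Two scalars are reported per step: the mean Tanimoto
similarity over all unordered pairs, and the distinct-cluster ratio. The
cluster ratio uses single-pass *leader* clustering in batch order: a
molecule joins the first existing cluster whose representative it resembles
(Tanimoto > 0.3), otherwise it opens a new cluster. The 0.3 threshold
reflects the empirical fact that in broad organic chemical space pairwise
Morgan-Tanimoto above ~0.2 is rare, so 0.3 marks genuine structural
redundancy. Leader clustering is chosen over Butina-style complete
clustering because it is streaming, deterministic given batch order, and
cheap enough to run at every RL step; its memberships depend on order, but
the degenerate cases (all-identical, all-dissimilar) are order-free.

**Sequence (n-gram) metrics.** The SMILES strings themselves are scanned
for all contiguous substrings of length n = 10. Reported are the fraction of
unique grams (distinct grams / total gram occurrences) and the number of
grams present in more than 10% of the batch's molecules. By default grams
are taken from the *raw* generated string — the token stream the generator
actually emitted — because that is the representation in which an
autoregressive model becomes redundant; a config switch recomputes them on
canonical SMILES. The uniqueness denominator (total occurrences rather than
molecule count) is a convention choice; both appear in the literature and
the tables expose the raw counts either way.

**Fragment metrics.** Each molecule is cleaved at all BRICS
(retrosynthetic) bonds and the resulting leaf-fragment multiset is counted
(`BreakBRICSBonds` + connected components, so a fragment occurring twice in
one molecule counts twice). Attachment points left by cleavage are
normalized to the bare wildcard atom before canonicalization — the BRICS
link type is deliberately not part of a fragment's identity here — and do
not count as heavy atoms. A molecule with no cleavable bonds is its own
single fragment. Reported: distinct-fragment fraction and the number of
fragments in more than 10% of molecules. No size filter is applied at the
metric level; the size filter belongs to the fragment *constraint*.

**Scaffold metrics.** Bemis–Murcko frameworks (ring systems plus linkers).
Acyclic molecules have an empty framework and are binned under a dedicated
`acyclic` label rather than dropped, so the distinct-scaffold fraction stays
well defined on any batch.

Undefined metrics (mean similarity of a one-molecule batch, gram metrics
when no string reaches length n) are recorded as *missing*, never as zero.

## Adaptive constraints

Three constraint families watch the campaign cumulatively and flag patterns
that have become redundant. Flags are permanent (tallies and cluster sizes
only grow), and each family's frequency trigger is evaluated on the current
step while its occurrence floor is evaluated on the whole campaign — a
pattern must be both currently frequent and historically recurrent to be
flagged.

| family | flags | frequency trigger | cumulative floor | extra filter |
|---|---|---|---|---|
| similarity | cluster representatives | >10% of a step's molecules in one cluster | cluster size > 10 molecules | clusters persist across steps, Tanimoto > 0.3 to representative |
| fragment | BRICS fragments | >5% of molecules | ≥ 50 total occurrences | fragment > 8 heavy atoms |
| ngram | SMILES 10-grams | >3% of molecules | ≥ 100 total occurrences | — |

The relaxed ("weak") variants use 10% / 100 occurrences for fragments, 6% /
200 for n-grams, and 20% step fraction / 20 molecules for similarity. Named
regimes bundle these: `none`, one per family, `all` (all three, strict) and
`all_weak`.

A molecule is penalized by the similarity family when its similarity to any
flagged representative exceeds the threshold; by the fragment family when
any of its BRICS fragments is flagged; by the ngram family when its raw
string contains any flagged gram (this check needs no valid structure, so
it also covers syntactically invalid SMILES). Each violated family
contributes its multiplicative penalty factor (default 0.0, a hard veto —
the strongest and simplest choice, and configurable per rule); families
combine by taking the **minimum** factor, which makes the combined penalty
at least as strict as any single family and keeps the scoring adapter
monotone. The adjusted score is `raw_score x multiplier`, exported per
molecule together with the violation reasons so any external RL framework
can consume it. Within a step, rules are updated *before* penalties are
applied, so a pattern is penalized from the very step at which it first
qualifies.

Two readings of the occurrence floors were possible — per-step or
campaign-cumulative. The cumulative reading is used because the constraint
state is explicitly historical (clusters of molecules generated in previous
steps); a sliding window or decay would be a natural extension and the
bookkeeping supports adding one, but it is off by default.

## Monitoring

`track_run` evaluates every enabled metric per step plus the mean raw score
and (when present) the mean prior negative log-likelihood. Alert rules fire
when a metric sits on the wrong side of a threshold for `patience`
consecutive steps (default 5), at the last step of that window, at most once
per rule — a simple, order-stable collapse detector. 2D chemical-space
projections use an in-house PCA (mean-centering, eigendecomposition of the
covariance, top-2 components, sign fixed by making each component's
largest-magnitude loading positive, so the projection is deterministic and
order-independent); t-SNE and UMAP are available behind the same interface
with a fixed seed but are treated as exploratory, not assertable. Reports
are static, self-contained HTML with per-metric plots, the flagged-pattern
table and an optional projection panel; the numeric tables are exactly the
long-format metrics CSV.

## The synthetic campaign surrogate

Testing a diversity monitor requires a collapsing generator, so the package
bundles one. The RL loop (an RNN policy over SMILES tokens updated by
policy gradients) is replaced by a *softmax surrogate*: a fixed pool of
valid template molecules with latent scores, sampled with probability
proportional to `exp(beta * score * multiplier)`, where the inverse
temperature `beta` ramps linearly from 0 to `beta_max` over the campaign.
Rising beta concentrates sampling on the top-scoring templates, which
produces exactly the phenomena the monitor is built to detect: rising mean
similarity, collapsing cluster and unique-gram ratios, recurring fragments.
The loop is closed at template granularity — a template inherits the
penalty multiplier of its last emitted instance — so a hard veto redirects
probability mass on the next step, and the constraint engines can be tested
end to end.

Templates are assembled from part tables (two substituted ring systems
joined by a short linker) and admitted by a greedy MaxMin-style filter: a
candidate is kept only if its Morgan-Tanimoto to every already-kept
template is below 0.3, so pairwise dissimilarity holds for 100% of pairs by
construction. The parts are designed so that (a) no 10-gram is shared by
templates that share only a bare ring core (every literal run between
substitution points is under 10 characters), (b) small cores stay at ≤ 8
heavy atoms — *below* the fragment constraint's size filter — while fused
cores exceed it, giving the fragment constraint a realistic mixture of
flaggable and unflaggable redundancy, and (c) swapping one substituent
yields a valid near-neighbour (the mutation operator), emulating the local
exploration of a real generator.

Default conditions: 1000 templates, 200 steps x 100 molecules per step,
`beta_max` 400, mutation rate 0.1, score noise SD 0.02, latent scores
uniform on [0.05, 0.95]. The pool size keeps the step-0 batch nearly
duplicate-free (matching the near-100% distinct-cluster start of a real
campaign); `beta_max` is set so the final softmax resolves the ~1e-3 score
gaps between top templates, leaving an effective support of only a handful
of templates — deep collapse — by the end. 200 steps is the horizon over
which the unconstrained run visibly collapses; it also keeps a full
6-regime, 5-seed evaluation within desk-scale compute.

**What the surrogate does and does not emulate.** It reproduces
distribution-level phenomena: concentration under optimization pressure,
recurring substrings and fragments, penalty-driven redistribution, and the
representational-alignment effect (string-space penalties veto a whole
template family through its shared grams, while fingerprint-space penalties
veto only a similarity ball around the flagged representative, so n-gram
constraints preserve cross-metric diversity better than similarity
constraints — the ordering a real campaign shows). It does not emulate
token-by-token generation, syntactically invalid emissions (all templates
and mutants are valid by construction; invalid-SMILES handling is tested on
hand-made records), score landscapes with structure-activity correlation
(latent scores are i.i.d.), or the gradual policy drift of a real RL model.
Passing tests therefore demonstrate the correctness and closed-loop
behaviour of the metrics and constraints, not performance claims about any
particular generator.

## Numerical and convention choices

- Tanimoto of two all-zero fingerprints is defined as 1.0 (identical
  emptiness); this matters for tiny molecules under MACCS and must be fixed
  one way or the other.
- All tallies are exact integer counts; ratio metrics are exact quotients.
  Oracle tests compare against brute-force reimplementations at 1e-12.
- Frequency triggers are strict (`>`), occurrence floors inclusive (`≥`),
  matching the stated thresholds ("more than 5%", "minimum 50").
- Scores outside [0, 1] are clamped on ingestion with a warning.
- Ties among flagged patterns: a molecule within threshold of several
  flagged representatives reports all of them as reasons; the multiplier is
  unaffected (minimum of equal factors).
- Campaigns are bit-for-bit reproducible: one PCG64 generator seeded from
  the config drives sampling, mutation and noise; the template pool is a
  deterministic function of (size, seed) alone.

## Problem sizes used in the test suite

Unit and oracle tests run on batches of ≤ 50 molecules from a 64-template
pool. Campaign-level checks run the full default conditions (200 x 100) on
five fixed seeds for all six regimes, asserting each qualitative property
on at least 4 of the 5 seeds; determinism checks use a reduced 30 x 60
configuration. The acceptance script re-runs all six regimes at full
default size for its single given seed.

## Known limitations

- Leader clustering's memberships depend on batch order (documented and
  deliberate); only its degenerate cases are order-free.
- The n-gram machinery treats SMILES as raw character strings; multi-
  character tokens (`Cl`, `Br`, ring-closure digits) are not tokenized, so a
  10-gram is 10 characters, not 10 chemical tokens.
- Flags are permanent; there is no decay or unflagging, so a pattern that
  was briefly dominant early stays penalized forever.
- The similarity constraint stores cluster representatives only; violation
  is similarity-to-representative, not to all members (streaming cost).
- t-SNE/UMAP projections are smoke-tested only; their stochastic output is
  not asserted.
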