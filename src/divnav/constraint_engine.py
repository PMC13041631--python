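"""Adaptive diversity constraints: flag redundant patterns, penalize molecules.

Three complementary constraint families watch a campaign step by step and
flag patterns that have become redundant:

* **similarity** — molecules are assigned to a persistent set of structural
  clusters (leader scan, Tanimoto > 0.3 to the cluster representative).  A
  cluster is flagged once it exceeds 10 cumulative members or more than 10%
  of a single generation step.
* **fragment** — BRICS fragments larger than 8 heavy atoms are flagged when
  they appear in more than 5% of a step's molecules and have at least 50
  cumulative occurrences.  The size filter keeps ubiquitous small motifs
  (methyl, phenyl, ...) out of the penalty set.
* **ngram** — SMILES 10-grams occurring in more than 3% of a step's
  molecules with at least 100 cumulative occurrences.

Flags are cumulative (no unflagging).  A molecule matching any flagged
pattern receives that family's multiplicative penalty factor (default 0.0,
a hard veto); families combine by taking the minimum factor.  The adjusted
score ``raw_score x multiplier`` is what an external RL scoring function
should consume.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd
from rdkit import DataStructs

from .core_io import GenerationStep, MetricConfig, RunLog
from .diversity_metrics import (
    Fingerprint,
    compute_fingerprint,
    extract_ngrams,
    fragment_molecule,
    tanimoto,
)

__all__ = [
    "ConstraintRule",
    "ConstraintState",
    "PenaltyResult",
    "FlagInfo",
    "REGIME_NAMES",
    "make_regime",
    "update_similarity_rule",
    "update_fragment_rule",
    "update_ngram_rule",
    "update_all_rules",
    "apply_penalties",
    "scoring_adapter",
    "scoring_records",
    "process_log",
]

Family = Literal["similarity", "fragment", "ngram"]

REGIME_NAMES = ("none", "similarity", "fragment", "ngram", "all", "all_weak")


@dataclass
class FlagInfo:
    """Bookkeeping for one flagged pattern (for reports and flagged CSVs)."""

    first_step: int
    occurrences: int  # cumulative occurrences when flagged
    frequency: float  # step molecule-frequency when flagged


@dataclass
class ConstraintRule:
    """One constraint family's thresholds and its currently flagged patterns.

    ``freq_threshold`` is evaluated on the current step's molecule frequency
    (strict >); ``min_occurrences`` on the cumulative campaign tally (>=).
    Family-specific extras: similarity uses ``cluster_size_trigger`` /
    ``step_fraction_trigger`` / ``similarity_threshold``; fragment uses
    ``min_heavy_atoms``; ngram uses ``n``.
    """

    family: Family
    freq_threshold: float = 0.0
    min_occurrences: int = 0
    penalty_factor: float = 0.0
    # similarity extras
    cluster_size_trigger: int = 10
    step_fraction_trigger: float = 0.10
    similarity_threshold: float = 0.3
    # fragment extras
    min_heavy_atoms: int = 8
    # ngram extras
    n: int = 10
    flagged: dict[str, FlagInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.penalty_factor <= 1.0):
            raise ValueError(f"penalty_factor must be in [0,1], got {self.penalty_factor}")


def make_regime(name: str, penalty_factor: float = 0.0) -> list[ConstraintRule]:
    """Build the rule list for a named constraint regime.

    ``none`` applies no constraints; the single-family regimes and ``all``
    use the strong default thresholds; ``all_weak`` relaxes them to 10% / 100
    occurrences (fragment), 6% / 200 (ngram) and 20% step fraction / 20
    molecules (similarity).
    """
    if name not in REGIME_NAMES:
        raise ValueError(f"unknown regime {name!r}; valid regimes: {', '.join(REGIME_NAMES)}")
    strong = {
        "similarity": ConstraintRule(
            family="similarity", cluster_size_trigger=10, step_fraction_trigger=0.10,
            penalty_factor=penalty_factor,
        ),
        "fragment": ConstraintRule(
            family="fragment", freq_threshold=0.05, min_occurrences=50,
            min_heavy_atoms=8, penalty_factor=penalty_factor,
        ),
        "ngram": ConstraintRule(
            family="ngram", freq_threshold=0.03, min_occurrences=100, n=10,
            penalty_factor=penalty_factor,
        ),
    }
    if name == "none":
        return []
    if name in strong:
        return [strong[name]]
    if name == "all":
        return [strong["similarity"], strong["fragment"], strong["ngram"]]
    return [  # all_weak
        ConstraintRule(
            family="similarity", cluster_size_trigger=20, step_fraction_trigger=0.20,
            penalty_factor=penalty_factor,
        ),
        ConstraintRule(
            family="fragment", freq_threshold=0.10, min_occurrences=100,
            min_heavy_atoms=8, penalty_factor=penalty_factor,
        ),
        ConstraintRule(
            family="ngram", freq_threshold=0.06, min_occurrences=200, n=10,
            penalty_factor=penalty_factor,
        ),
    ]


@dataclass
class _PersistentCluster:
    representative: str
    rep_fp: Fingerprint
    cumulative_size: int = 0


@dataclass
class ConstraintState:
    """Cumulative campaign bookkeeping shared by all constraint rules.

    Clusters persist across steps (a cluster keeps growing over the whole
    campaign); fragment and n-gram tallies are cumulative totals.  Tallies
    never decrease and flags are never removed.
    """

    rules: list[ConstraintRule]
    config: MetricConfig = field(default_factory=MetricConfig)
    clusters: list[_PersistentCluster] = field(default_factory=list)
    fragment_totals: Counter = field(default_factory=Counter)
    fragment_heavy: dict[str, int] = field(default_factory=dict)
    ngram_totals: Counter = field(default_factory=Counter)
    last_step: int | None = None
    # Memoized leader-scan assignment: the cluster list only grows, so the
    # first cluster a given canonical SMILES matches can never change.
    _cluster_of: dict[str, int] = field(default_factory=dict)

    def rule(self, family: str) -> ConstraintRule | None:
        for r in self.rules:
            if r.family == family:
                return r
        return None

    def flagged_rows(self) -> list[dict]:
        """All flagged patterns as rows for the flagged-pattern CSV."""
        rows = []
        for r in self.rules:
            for pattern, info in sorted(r.flagged.items()):
                rows.append(
                    {
                        "pattern_type": r.family,
                        "pattern": pattern,
                        "first_step": info.first_step,
                        "occurrences": info.occurrences,
                        "frequency": info.frequency,
                    }
                )
        return rows


# ---------------------------------------------------------------------------
# Rule updates (flagging)
# ---------------------------------------------------------------------------


def update_similarity_rule(state: ConstraintState, step: GenerationStep) -> None:
    """Assign the step's molecules to the persistent clusters and flag.

    A cluster's representative is flagged when the cluster's cumulative size
    exceeds ``cluster_size_trigger`` or its membership within this step
    exceeds ``step_fraction_trigger`` of the step's valid count.
    """
    rule = state.rule("similarity")
    if rule is None:
        return
    valid = step.valid_records()
    if not valid:
        return
    step_counts: Counter[int] = Counter()
    for rec in valid:
        smi = rec.canonical_smiles
        placed = state._cluster_of.get(smi)
        if placed is None:
            fp = compute_fingerprint(smi, state.config)
            if state.clusters:
                if fp.bits.GetNumOnBits() == 0:  # all-zero convention path
                    sims = [tanimoto(fp, c.rep_fp) for c in state.clusters]
                else:
                    sims = DataStructs.BulkTanimotoSimilarity(
                        fp.bits, [c.rep_fp.bits for c in state.clusters]
                    )
                placed = next(
                    (ci for ci, s in enumerate(sims) if s > rule.similarity_threshold),
                    None,
                )
            if placed is None:
                state.clusters.append(_PersistentCluster(representative=smi, rep_fp=fp))
                placed = len(state.clusters) - 1
            state._cluster_of[smi] = placed
        state.clusters[placed].cumulative_size += 1
        step_counts[placed] += 1
    n_valid = len(valid)
    for ci, cluster in enumerate(state.clusters):
        if cluster.representative in rule.flagged:
            continue
        if (
            cluster.cumulative_size > rule.cluster_size_trigger
            or step_counts[ci] / n_valid > rule.step_fraction_trigger
        ):
            rule.flagged[cluster.representative] = FlagInfo(
                first_step=step.step,
                occurrences=cluster.cumulative_size,
                frequency=step_counts[ci] / n_valid,
            )


def update_fragment_rule(state: ConstraintState, step: GenerationStep) -> None:
    """Tally BRICS fragments and flag large, frequent, recurrent ones."""
    rule = state.rule("fragment")
    if rule is None:
        return
    valid = step.valid_records()
    if not valid:
        return
    containing: Counter[str] = Counter()
    for rec in valid:
        frags = fragment_molecule(rec.canonical_smiles)
        state.fragment_totals.update(f for f, _ in frags)
        containing.update({f for f, _ in frags})
        for f, h in frags:
            state.fragment_heavy[f] = h
    n_valid = len(valid)
    for frag, n_mols in containing.items():
        if frag in rule.flagged:
            continue
        if (
            state.fragment_heavy[frag] > rule.min_heavy_atoms
            and n_mols / n_valid > rule.freq_threshold
            and state.fragment_totals[frag] >= rule.min_occurrences
        ):
            rule.flagged[frag] = FlagInfo(
                first_step=step.step,
                occurrences=state.fragment_totals[frag],
                frequency=n_mols / n_valid,
            )


def update_ngram_rule(state: ConstraintState, step: GenerationStep) -> None:
    """Tally SMILES n-grams and flag frequent, recurrent ones.

    Grams come from the raw generated strings (the generator's own token
    stream) of all valid molecules, matching the metric-side default.
    """
    rule = state.rule("ngram")
    if rule is None:
        return
    valid = step.valid_records()
    if not valid:
        return
    containing: Counter[str] = Counter()
    for rec in valid:
        source = rec.canonical_smiles if state.config.ngram_on_canonical else rec.raw_smiles
        grams = extract_ngrams(source, rule.n)
        state.ngram_totals.update(grams)
        containing.update(set(grams))
    n_valid = len(valid)
    for gram, n_mols in containing.items():
        if gram in rule.flagged:
            continue
        if (
            n_mols / n_valid > rule.freq_threshold
            and state.ngram_totals[gram] >= rule.min_occurrences
        ):
            rule.flagged[gram] = FlagInfo(
                first_step=step.step,
                occurrences=state.ngram_totals[gram],
                frequency=n_mols / n_valid,
            )


def update_all_rules(state: ConstraintState, step: GenerationStep) -> None:
    """Run every enabled rule's update on one generation step, in order."""
    if state.last_step is not None and step.step <= state.last_step:
        raise ValueError(
            f"steps must be fed in increasing order (got {step.step} after {state.last_step})"
        )
    update_similarity_rule(state, step)
    update_fragment_rule(state, step)
    update_ngram_rule(state, step)
    state.last_step = step.step


# ---------------------------------------------------------------------------
# Penalty application
# ---------------------------------------------------------------------------


@dataclass
class PenaltyResult:
    """Per-molecule multipliers in [0, 1] with the violated (family, pattern) pairs."""

    multipliers: list[float]
    reasons: list[list[tuple[str, str]]]


def apply_penalties(step: GenerationStep, state: ConstraintState) -> PenaltyResult:
    """Compute per-molecule penalty multipliers against the current flag sets.

    A molecule violates the similarity family when its similarity to any
    flagged cluster representative exceeds the similarity threshold; the
    fragment family when any of its BRICS fragments is flagged; the ngram
    family when its raw string contains any flagged gram (this last check
    needs no valid structure, so it also applies to invalid SMILES).  The
    composite multiplier is the minimum of the violated families' penalty
    factors; molecules with no violation get 1.0.
    """
    sim_rule = state.rule("similarity")
    frag_rule = state.rule("fragment")
    gram_rule = state.rule("ngram")
    flagged_rep_fps: list[tuple[str, Fingerprint]] = []
    if sim_rule is not None and sim_rule.flagged:
        by_rep = {c.representative: c.rep_fp for c in state.clusters}
        flagged_rep_fps = [
            (rep, by_rep[rep]) for rep in sim_rule.flagged if rep in by_rep
        ]
    sim_hits_cache: dict[str, list[str]] = {}

    def _sim_hits(smi: str) -> list[str]:
        hits = sim_hits_cache.get(smi)
        if hits is None:
            fp = compute_fingerprint(smi, state.config)
            if fp.bits.GetNumOnBits() == 0:
                sims = [tanimoto(fp, rep_fp) for _, rep_fp in flagged_rep_fps]
            else:
                sims = DataStructs.BulkTanimotoSimilarity(
                    fp.bits, [rep_fp.bits for _, rep_fp in flagged_rep_fps]
                )
            hits = [
                rep
                for (rep, _), s in zip(flagged_rep_fps, sims)
                if s > sim_rule.similarity_threshold
            ]
            sim_hits_cache[smi] = hits
        return hits

    multipliers: list[float] = []
    reasons: list[list[tuple[str, str]]] = []
    for rec in step.records:
        why: list[tuple[str, str]] = []
        factors: list[float] = []
        if rec.valid and flagged_rep_fps:
            hits = _sim_hits(rec.canonical_smiles)
            if hits:
                why.extend(("similarity", rep) for rep in hits)
                factors.append(sim_rule.penalty_factor)
        if rec.valid and frag_rule is not None and frag_rule.flagged:
            hits = sorted(
                {f for f, _ in fragment_molecule(rec.canonical_smiles)}
                & frag_rule.flagged.keys()
            )
            if hits:
                why.extend(("fragment", f) for f in hits)
                factors.append(frag_rule.penalty_factor)
        if gram_rule is not None and gram_rule.flagged:
            source = (
                rec.canonical_smiles
                if state.config.ngram_on_canonical and rec.valid
                else rec.raw_smiles
            )
            hits = sorted(g for g in gram_rule.flagged if g in source)
            if hits:
                why.extend(("ngram", g) for g in hits)
                factors.append(gram_rule.penalty_factor)
        multipliers.append(min(factors) if factors else 1.0)
        reasons.append(why)
    return PenaltyResult(multipliers=multipliers, reasons=reasons)


def scoring_adapter(scores: list[float], penalties: PenaltyResult) -> list[float]:
    """Elementwise ``score x multiplier`` — the adjusted RL scores."""
    if len(scores) != len(penalties.multipliers):
        raise ValueError(
            f"length mismatch: {len(scores)} scores vs {len(penalties.multipliers)} multipliers"
        )
    return [s * m for s, m in zip(scores, penalties.multipliers)]


def scoring_records(step: GenerationStep, penalties: PenaltyResult) -> pd.DataFrame:
    """Generic scoring-component table an external RL framework can consume.

    Columns: step, smiles, score, multiplier, adjusted, reasons (semicolon-
    joined ``family:pattern``).  Missing raw scores propagate as NaN.
    """
    rows = []
    for rec, mult, why in zip(step.records, penalties.multipliers, penalties.reasons):
        raw = float("nan") if rec.score is None else rec.score
        rows.append(
            {
                "step": rec.step,
                "smiles": rec.raw_smiles,
                "score": raw,
                "multiplier": mult,
                "adjusted": raw * mult,
                "reasons": ";".join(f"{f}:{p}" for f, p in why),
            }
        )
    return pd.DataFrame(
        rows, columns=["step", "smiles", "score", "multiplier", "adjusted", "reasons"]
    )


def process_log(
    log: RunLog, rules: list[ConstraintRule], config: MetricConfig | None = None
) -> tuple[pd.DataFrame, ConstraintState]:
    """Stream a whole run log through the constraint engine.

    For each step, rules are updated first (so a pattern is flagged at the
    first step where it qualifies) and penalties are then applied to that
    same step.  Returns the concatenated scoring-component table and the
    final state.
    """
    state = ConstraintState(rules=rules, config=config or MetricConfig())
    frames = []
    for step in log:
        update_all_rules(state, step)
        penalties = apply_penalties(step, state)
        frames.append(scoring_records(step, penalties))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else scoring_records(GenerationStep(step=0, records=[]), PenaltyResult([], []))
    )
    return table, state
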