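"""A synthetic string-based generative campaign with controllable mode collapse.

Real reinforcement-learning campaigns (an RNN policy over SMILES tokens,
updated by policy gradients against a property score) are replaced by a
softmax surrogate: a fixed pool of valid template molecules with latent
scores in [0, 1] is sampled with probability proportional to
``exp(beta * score * multiplier)``, where ``beta`` is a per-step "inverse
temperature" that ramps up over the campaign.  Rising beta concentrates the
sampling distribution on the top-scoring templates — the same phenomenon
(structural, sequence and fragment redundancy) that diversity monitors see
in a real collapsing run — without any neural network.

The loop is closed: a template inherits the penalty multiplier of its last
emitted instance, so a hard veto (multiplier 0) on a template's molecules
redirects probability mass elsewhere on the next step, emulating penalty
integration into the RL scoring function.

Templates are two substituted ring systems joined by a short linker,
``coreA(subA)-linker-coreB(subB)``, assembled programmatically and admitted
to the pool by a greedy MaxMin-style diversity filter (a candidate is kept
only if its Morgan-Tanimoto to every already-kept template is below 0.3).
This gives (a) validity by construction plus a parse check, (b) a pairwise
dissimilarity guarantee stronger than the 95% floor that is verified at
build, (c) shared SMILES substrings and BRICS fragments among templates
sharing parts — exactly the pattern structure the n-gram and fragment
machinery is meant to detect, with small ring cores (<= 8 heavy atoms)
sitting below the fragment constraint's size filter and fused/large cores
above it — and (d) a validity-preserving mutation operator (swap one
substituent at its attachment point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from rdkit import Chem, DataStructs

from .constraint_engine import (
    ConstraintState,
    apply_penalties,
    make_regime,
    scoring_adapter,
    update_all_rules,
)
from .core_io import GenerationStep, MetricConfig, MoleculeRecord, RunLog
from .diversity_metrics import DiversityTimeSeries, compute_all, compute_fingerprint

logger = logging.getLogger("divnav")

__all__ = ["SimConfig", "TemplatePool", "build_template_pool", "sample_step", "run_campaign", "CampaignResult"]


# Building blocks.  Cores are ring systems with two substitution points
# ({R1}, {R2}); {R2} receives the linker + second ring.  Small cores stay at
# <= 8 heavy atoms (their BRICS fragments sit below the fragment
# constraint's size filter), fused/large cores exceed it.  Every literal run
# between substitution points is kept under 10 characters so no 10-gram is
# shared by templates that share only a bare core.  Substituents are 4-7
# heavy atoms with strong heteroatom variety so that no single shared part
# can push a template pair's Tanimoto above the 0.3 admission cutoff; ring
# closures inside substituents use digits 8/9 (cores use 1-4).
_SMALL_CORES = (
    "c1cc({R1})cc({R2})c1", "c1cc({R1})ccc1{R2}", "c1c({R1})sc({R2})c1",
    "c1c({R1})oc({R2})c1", "c1c({R1})cc({R2})o1", "c1c({R1})[nH]c({R2})c1",
    "c1c({R1})cnc({R2})c1", "c1nc({R1})cc({R2})c1", "c1nc({R1})cnc1{R2}",
    "c1nc({R1})nc({R2})c1", "c1c({R1})ncc({R2})n1", "c1c({R1})sc({R2})n1",
    "c1c({R1})oc({R2})n1", "c1c({R1})nc({R2})s1", "c1n({R1})cc({R2})n1",
    "c1c({R1})nn({R2})c1", "c1c({R1})cc({R2})nn1", "C1CC({R1})CC({R2})C1",
    "C1C({R1})CC({R2})C1", "C1CC({R1})N({R2})C1", "C1CC({R1})CN({R2})C1",
    "C1CC({R1})OC({R2})C1", "C1C({R1})OC({R2})C1", "C1CN({R1})CCN1{R2}",
    "c1c({R1})csc1{R2}", "c1c({R1})coc1{R2}", "c1c({R1})cc({R2})cn1",
    "c1c({R1})nc({R2})n1C", "C1C({R1})CC({R2})CN1C", "C1C({R1})SC({R2})C1",
    "C1OC({R1})OC1{R2}",
)
_LARGE_CORES = (
    "c1cc2cc({R1})ccc2c({R2})c1", "c1cc2nc({R1})ccc2c({R2})c1",
    "c1cc2cc({R1})cnc2c({R2})c1", "c1cc2sc({R1})cc2c({R2})c1",
    "c1cc2oc({R1})cc2c({R2})c1", "c1cc2nc({R1})cnc2c({R2})c1",
    "c1cc2ncc({R1})nc2c({R2})c1", "c1cc({R1})c2[nH]c({R2})cc2c1",
    "c1cc2sc({R1})nc2c({R2})c1", "c1cc2oc({R1})nc2c({R2})c1",
    "c1cc2nc({R1})[nH]c2c({R2})c1", "c1cc2c(c({R2})c1)CC({R1})C2",
    "c1cc2c(c({R2})c1)OC({R1})O2", "c1cc2c(c({R2})c1)CCC({R1})C2",
)
CORES: tuple[str, ...] = _SMALL_CORES + _LARGE_CORES
SUBSTITUENTS: tuple[str, ...] = (
    "CCCC", "CC(C)C", "CCCCC", "CC(C)CC", "CCC(C)C", "CCCCCC",
    "CCOC", "CCOCC", "COCC", "CCCOC", "OCCOC", "OCCCO",
    "CCNC", "CCN(C)C", "NCCC", "CNCCC", "NCCO", "OCCNC",
    "CCSC", "CSCC", "CCSCC", "CS(=O)CC",
    "CC(=O)C", "CCC(=O)C", "CC(=O)OC", "COC(=O)C", "CC(=O)NC", "CNC(=O)C",
    "CCC#N", "NC(=O)CC", "OC(=O)CC", "CCC(F)F", "OCC(F)F", "CC(F)CF",
    "C8CCC8", "C8CCCC8", "C8CCCCC8", "C8CCOC8", "C8CCNC8", "C8CCSC8",
    "OC8CCC8", "CC8CCC8", "N8CCCC8", "N8CCOCC8",
    "OCC#C", "CCC=C", "CN(C)C=O", "COCC#N", "CCOC=O", "NC(=O)NC", "SCC#N",
    "OCCSC", "CC(C)CO", "CCNC=O", "OCCC#N", "CSCC=O",
)
LINKERS: tuple[str, ...] = (
    "-", "C", "CC", "O", "C(=O)", "C=C", "C#C", "OC", "S", "N",
    "CO", "CN", "OCC", "C(C)", "CCC",
)


class SimConfig(BaseModel):
    """Conditions of a surrogate campaign.

    ``steps`` x ``batch`` mirrors a monitored RL campaign sampled 100
    molecules per generation step; the default 200 steps is the horizon over
    which an unconstrained run visibly collapses.  ``beta_schedule`` defaults
    to a linear ramp 0 -> ``beta_max``; with ~1000 templates and scores
    spread over [0.05, 0.95], beta_max = 400 leaves an effective support of
    only a handful of templates at the end (gap between adjacent top scores
    ~1e-3, so beta must reach several hundred for the softmax to resolve
    them).  ``n_templates`` = 1000 keeps the step-0 batch of 100 nearly
    duplicate-free, matching the near-100% distinct-cluster start of a real
    campaign.
    """

    n_templates: int = Field(default=1000, ge=2)
    steps: int = Field(default=200, ge=1)
    batch: int = Field(default=100, ge=2)
    beta_max: float = Field(default=400.0, ge=0.0)
    beta_schedule: tuple[float, ...] | None = None
    mutation_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    score_noise_sd: float = Field(default=0.02, ge=0.0)
    seed: int = 0
    regime: str = "none"
    penalty_factor: float = Field(default=0.0, ge=0.0, le=1.0)
    metric_config: MetricConfig = Field(default_factory=MetricConfig)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.beta_schedule is not None:
            if len(self.beta_schedule) < self.steps:
                raise ValueError(
                    f"beta_schedule has {len(self.beta_schedule)} entries for {self.steps} steps"
                )
            if any(b < a for a, b in zip(self.beta_schedule, self.beta_schedule[1:])):
                raise ValueError("beta_schedule must be non-decreasing")
            if any(b < 0 for b in self.beta_schedule):
                raise ValueError("beta_schedule must be non-negative")
        return self

    def schedule(self) -> np.ndarray:
        if self.beta_schedule is not None:
            return np.asarray(self.beta_schedule[: self.steps], dtype=float)
        return np.linspace(0.0, self.beta_max, self.steps)


@dataclass
class TemplatePool:
    """Fixed library of valid, mutually dissimilar template molecules.

    ``parts[i]`` is the recipe ``(core_a, sub_a, linker, core_b, sub_b)``
    (indices into CORES / SUBSTITUENTS / LINKERS) that assembles template i;
    mutation swaps one substituent index of the recipe.
    """

    raw_smiles: list[str]  # assembled strings, as the "generator" emits them
    canonical: list[str]
    scores: np.ndarray  # latent scores in [0, 1]
    parts: list[tuple[int, int, int, int, int]]
    diversity_threshold: float = 0.3

    def __len__(self) -> int:
        return len(self.raw_smiles)


def _branch(core: int, sub: str) -> str:
    """Second ring written as a substituent: drop its {R2} site, fill {R1},
    shift ring-closure digits 1/2 -> 3/4 to avoid colliding with the first
    ring's closures."""
    s = CORES[core].replace("({R2})", "").replace("{R2}", "")
    s = s.replace("{R1}", sub)
    return s.translate(str.maketrans("12", "34"))


def _assemble(core_a: int, sub_a: int, linker: int, core_b: int, sub_b: int) -> str:
    second = _branch(core_b, SUBSTITUENTS[sub_b])
    link = LINKERS[linker]
    attachment = "-" + second if link == "-" else link + second
    return CORES[core_a].replace("{R1}", SUBSTITUENTS[sub_a]).replace("{R2}", attachment)


def build_template_pool(
    n_templates: int = 1000,
    seed: int = 0,
    diversity_threshold: float = 0.3,
    max_attempts_per_template: int = 200,
) -> TemplatePool:
    """Assemble a diverse template pool deterministically from the part tables.

    Candidate recipes (core_a, sub_a, linker, core_b, sub_b) are drawn at
    random and admitted only if they parse, are new, and have Morgan-Tanimoto
    below ``diversity_threshold`` to *every* already-admitted template
    (greedy MaxMin-style selection) — so the pairwise dissimilarity guarantee
    holds for 100% of pairs by construction, verified as each candidate is
    admitted.  Latent scores are drawn uniformly from [0.05, 0.95].  Raises
    when the part space cannot supply ``n_templates`` mutually dissimilar
    molecules within the attempt budget.
    """
    if n_templates < 2:
        raise ValueError("n_templates must be >= 2")
    rng = np.random.default_rng(seed)
    config = MetricConfig()
    kept_parts: list[tuple[int, int, int, int, int]] = []
    raw_smiles: list[str] = []
    canonical: list[str] = []
    kept_bits = []
    seen: set[str] = set()
    budget = max_attempts_per_template * n_templates
    attempts = 0
    while len(kept_parts) < n_templates and attempts < budget:
        attempts += 1
        ca = int(rng.integers(len(CORES)))
        cb = int(rng.integers(len(CORES)))
        if ca == cb:
            continue
        sa = int(rng.integers(len(SUBSTITUENTS)))
        sb = int(rng.integers(len(SUBSTITUENTS)))
        li = int(rng.integers(len(LINKERS)))
        raw = _assemble(ca, sa, li, cb, sb)
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        fp = compute_fingerprint(can, config)
        if kept_bits:
            sims = DataStructs.BulkTanimotoSimilarity(fp.bits, kept_bits)
            if max(sims) >= diversity_threshold:
                continue
        seen.add(can)
        kept_parts.append((ca, sa, li, cb, sb))
        raw_smiles.append(raw)
        canonical.append(can)
        kept_bits.append(fp.bits)
    if len(kept_parts) < n_templates:
        raise RuntimeError(
            f"assembled only {len(kept_parts)} of {n_templates} mutually dissimilar "
            f"templates in {attempts} attempts; the part space is exhausted at this "
            f"diversity threshold ({diversity_threshold})"
        )
    scores = rng.uniform(0.05, 0.95, size=n_templates)
    return TemplatePool(
        raw_smiles=raw_smiles,
        canonical=canonical,
        scores=scores,
        parts=kept_parts,
        diversity_threshold=diversity_threshold,
    )


_POOL_CACHE: dict[tuple[int, int], TemplatePool] = {}
_CANONICAL_CACHE: dict[str, str | None] = {}


def _pooled(n_templates: int, seed: int) -> TemplatePool:
    key = (n_templates, seed)
    if key not in _POOL_CACHE:
        _POOL_CACHE[key] = build_template_pool(n_templates, seed)
    return _POOL_CACHE[key]


def sample_step(
    pool: TemplatePool,
    beta: float,
    multipliers: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
    batch: int,
    step_index: int,
    score_noise_sd: float = 0.02,
    warn_on_fallback: bool = True,
) -> tuple[GenerationStep, list[int]]:
    """Sample one generation step from the softmax surrogate policy.

    Template i is drawn with probability proportional to
    ``exp(beta * score_i * multiplier_i)``; each sampled molecule is then
    independently mutated with probability ``mutation_rate`` by swapping one
    of its two substituents for another from the vocabulary (validity is
    re-checked; a failed swap falls back to the unmutated template).
    Emitted scores are the template's latent score plus bounded Gaussian
    noise, clamped to [0, 1].  Returns the step and the source template
    index of each record.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    multipliers = np.asarray(multipliers, dtype=float)
    if np.all(multipliers == 0.0):
        logger.log(
            logging.WARNING if warn_on_fallback else logging.DEBUG,
            "step %d: all template multipliers are zero; sampling falls back to uniform",
            step_index,
        )
    logits = beta * pool.scores * multipliers
    logits -= logits.max()
    weights = np.exp(logits)
    probs = weights / weights.sum()
    picks = rng.choice(len(pool), size=batch, p=probs)
    mutate = rng.random(batch) < mutation_rate
    noise = rng.normal(0.0, score_noise_sd, size=batch)
    records: list[MoleculeRecord] = []
    sources: list[int] = []
    for j, t in enumerate(picks):
        t = int(t)
        raw = pool.raw_smiles[t]
        if mutate[j]:
            ca, sa, li, cb, sb = pool.parts[t]
            position = int(rng.integers(2))
            new_sub = int(rng.integers(len(SUBSTITUENTS)))
            recipe = (ca, new_sub, li, cb, sb) if position == 0 else (ca, sa, li, cb, new_sub)
            candidate = _assemble(*recipe)
            if candidate != raw and Chem.MolFromSmiles(candidate) is not None:
                raw = candidate
        score = float(np.clip(pool.scores[t] + noise[j], 0.0, 1.0))
        canonical = _CANONICAL_CACHE.get(raw)
        if canonical is None:
            mol = Chem.MolFromSmiles(raw)  # valid by construction; parse for canonical form
            canonical = Chem.MolToSmiles(mol) if mol is not None else None
            _CANONICAL_CACHE[raw] = canonical
        records.append(
            MoleculeRecord(
                step=step_index,
                raw_smiles=raw,
                canonical_smiles=canonical,
                valid=canonical is not None,
                score=score,
            )
        )
        sources.append(t)
    return GenerationStep(step=step_index, records=records), sources


@dataclass
class CampaignResult:
    """Everything a closed-loop surrogate campaign produced."""

    log: RunLog
    series: DiversityTimeSeries
    state: ConstraintState
    pool: TemplatePool


def run_campaign(config: SimConfig) -> CampaignResult:
    """Run the full closed loop: sample, analyze, flag, penalize, feed back.

    Per step: (1) sample a batch using each template's latest multiplier,
    (2) compute all diversity metrics plus mean raw/adjusted score, (3)
    update the constraint rules (flagging happens at the first qualifying
    step), (4) apply penalties to the step, and (5) write each record's
    multiplier back onto its source template for the next step.  Identical
    configs produce identical results bit for bit.
    """
    pool = _pooled(config.n_templates, config.seed)
    rng = np.random.default_rng(config.seed + 1)  # pool consumed part of the seed stream
    rules = make_regime(config.regime, penalty_factor=config.penalty_factor)
    state = ConstraintState(rules=rules, config=config.metric_config)
    schedule = config.schedule()
    template_multipliers = np.ones(len(pool))
    series = DiversityTimeSeries()
    steps: list[GenerationStep] = []
    warned_fallback = False
    for t in range(config.steps):
        all_vetoed = bool(np.all(template_multipliers == 0.0))
        step, sources = sample_step(
            pool,
            beta=float(schedule[t]),
            multipliers=template_multipliers,
            mutation_rate=config.mutation_rate,
            rng=rng,
            batch=config.batch,
            step_index=t,
            score_noise_sd=config.score_noise_sd,
            warn_on_fallback=not warned_fallback,
        )
        warned_fallback = warned_fallback or all_vetoed
        values = compute_all(step, config.metric_config)
        scores = [r.score for r in step.records]
        values["mean_score"] = float(np.mean(scores))
        update_all_rules(state, step)
        penalties = apply_penalties(step, state)
        adjusted = scoring_adapter(scores, penalties)
        values["mean_adjusted_score"] = float(np.mean(adjusted))
        values["flagged_total"] = float(sum(len(r.flagged) for r in state.rules))
        series.append(t, values)
        for j, src in enumerate(sources):
            template_multipliers[src] = penalties.multipliers[j]
        steps.append(step)
    log = RunLog(
        steps=steps,
        metadata={
            "generator": "softmax-template surrogate",
            "regime": config.regime,
            "seed": config.seed,
            "n_templates": config.n_templates,
        },
    )
    return CampaignResult(log=log, series=series, state=state, pool=pool)
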