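"""Domain types and file I/O for generative-campaign run logs.

A *run log* is the record of a string-based generative campaign: at each
reinforcement-learning iteration ("step") the model emits a batch of SMILES
strings with scores in [0, 1].  Everything downstream (diversity metrics,
constraint engines, monitors) consumes the types defined here.

Invalid SMILES are first-class data: generators routinely emit unparseable
strings, so records are kept (flagged ``valid=False``) and only excluded
from structure-based computations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator
from rdkit import Chem, RDLogger

if TYPE_CHECKING:  # pragma: no cover
    from .diversity_metrics import DiversityTimeSeries

# RDKit is chatty about every malformed SMILES; invalidity is data here.
RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("divnav")

__all__ = [
    "MoleculeRecord",
    "GenerationStep",
    "RunLog",
    "MetricConfig",
    "SchemaError",
    "RowError",
    "parse_and_canonicalize",
    "make_record",
    "read_run_log",
    "write_run_log",
    "write_metrics",
    "read_metrics",
    "write_flagged",
    "read_flagged",
]


class SchemaError(ValueError):
    """A run-log file does not have the required columns."""


class RowError(ValueError):
    """A run-log row cannot be interpreted (carries the 1-based line number)."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MoleculeRecord:
    """One generated SMILES with its step index, validity and score.

    ``valid`` is true iff ``canonical_smiles`` is present and parseable;
    canonicalization is idempotent, so a valid record's canonical form
    re-canonicalizes to itself.
    """

    step: int
    raw_smiles: str
    canonical_smiles: str | None
    valid: bool
    score: float | None = None
    nll: float | None = None


@dataclass
class GenerationStep:
    """One iteration's batch of molecule records.

    ``batch_size`` counts *all* records, valid or not — the invalid fraction
    is information, never silently dropped.
    """

    step: int
    records: list[MoleculeRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.step != self.step:
                raise ValueError(
                    f"record step {r.step} does not match batch step {self.step}"
                )

    @property
    def batch_size(self) -> int:
        return len(self.records)

    def valid_records(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.valid]

    @property
    def n_valid(self) -> int:
        return sum(1 for r in self.records if r.valid)

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.batch_size if self.records else 0.0


@dataclass
class RunLog:
    """An ordered sequence of generation steps plus free-form metadata."""

    steps: list[GenerationStep]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        indices = [s.step for s in self.steps]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(f"step indices must be strictly increasing, got {indices}")

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)


class MetricConfig(BaseModel):
    """Configuration shared by all diversity metrics.

    Parameters
    ----------
    fingerprint_kind:
        ``morgan`` (circular, hashed), ``ecfp`` (alias for Morgan — ECFP_{2r}
        is the Morgan fingerprint of radius r) or ``maccs`` (fixed 166-key).
    similarity_cluster_threshold:
        Tanimoto similarity above which two molecules belong to the same
        structural cluster (0.3: pairwise similarities above ~0.2 are rare in
        broad organic-electronics chemical space, so 0.3 marks genuine
        structural redundancy).
    ngram_n:
        Substring length for SMILES sequence analysis (10 characters).
    frequent_fraction:
        A pattern is "frequent" when it occurs in more than this fraction of
        the batch's valid molecules (0.10).
    ngram_on_canonical:
        N-grams are computed on the raw generated string by default — the
        token stream the generative model actually produced; set this to use
        canonical SMILES instead.
    enabled_families:
        Which metric families ``compute_all`` evaluates.
    """

    fingerprint_kind: Literal["morgan", "maccs", "ecfp"] = "morgan"
    morgan_radius: int = Field(default=2, ge=1)
    n_bits: int = Field(default=2048, ge=8)
    similarity_cluster_threshold: float = Field(default=0.3, gt=0.0, le=1.0)
    ngram_n: int = Field(default=10, ge=1)
    frequent_fraction: float = Field(default=0.10, gt=0.0, le=1.0)
    fragment_min_heavy_atoms: int = Field(default=8, ge=1)
    ngram_on_canonical: bool = False
    enabled_families: tuple[str, ...] = ("similarity", "ngram", "fragment", "scaffold")

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_families(self) -> "MetricConfig":
        known = {"similarity", "ngram", "fragment", "scaffold"}
        unknown = set(self.enabled_families) - known
        if unknown:
            raise ValueError(f"unknown metric families {sorted(unknown)}; known: {sorted(known)}")
        return self


# ---------------------------------------------------------------------------
# SMILES parsing
# ---------------------------------------------------------------------------


def parse_and_canonicalize(raw_smiles: str) -> tuple[bool, str | None]:
    """Parse a SMILES string, returning ``(valid, canonical_smiles)``.

    Never raises on malformed input — invalidity is data, not an error.
    """
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        return False, None
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return False, None
    return True, Chem.MolToSmiles(mol)


def make_record(
    step: int,
    raw_smiles: str,
    score: float | None = None,
    nll: float | None = None,
) -> MoleculeRecord:
    """Build a MoleculeRecord, canonicalizing and clamping the score to [0, 1]."""
    valid, canonical = parse_and_canonicalize(raw_smiles)
    if score is not None and not (0.0 <= score <= 1.0):
        clamped = min(max(score, 0.0), 1.0)
        logger.warning(
            "score %.4g outside [0,1] for %r at step %d; clamped to %.4g",
            score, raw_smiles, step, clamped,
        )
        score = clamped
    return MoleculeRecord(
        step=step, raw_smiles=raw_smiles, canonical_smiles=canonical,
        valid=valid, score=score, nll=nll,
    )


# ---------------------------------------------------------------------------
# Run-log readers / writers
# ---------------------------------------------------------------------------

_SMI_PATTERN = re.compile(r"step_(\d+)\.smi$")


def read_run_log(path: str | Path, dialect: Literal["csv", "smi_per_step"] = "csv") -> RunLog:
    """Read a campaign run log.

    ``csv``: a single file with header columns ``step,smiles[,score][,nll]``.
    ``smi_per_step``: a directory of ``step_<k>.smi`` files, one SMILES per
    line (an optional whitespace-separated name is ignored).
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv_log(path)
    if dialect == "smi_per_step":
        return _read_smi_dir(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'smi_per_step'")


def _read_csv_log(path: Path) -> RunLog:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    missing = {"step", "smiles"} - set(cols)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)}; found {cols}"
        )
    by_step: dict[int, list[MoleculeRecord]] = {}
    order: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        raw_step = getattr(row, "step")
        try:
            step = int(raw_step)
        except (TypeError, ValueError):
            raise RowError(line, f"non-integer step {raw_step!r}") from None
        score = _opt_float(getattr(row, "score", ""), line, "score")
        nll = _opt_float(getattr(row, "nll", ""), line, "nll")
        rec = make_record(step, getattr(row, "smiles"), score=score, nll=nll)
        if step not in by_step:
            by_step[step] = []
            order.append(step)
        by_step[step].append(rec)
    steps = [GenerationStep(step=k, records=by_step[k]) for k in sorted(order)]
    return RunLog(steps=steps, metadata={"source": str(path), "dialect": "csv"})


def _opt_float(value: object, line: int, column: str) -> float | None:
    text = str(value).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise RowError(line, f"non-numeric {column} {text!r}") from None


def _read_smi_dir(path: Path) -> RunLog:
    if not path.is_dir():
        raise SchemaError(f"{path}: smi_per_step dialect expects a directory")
    files: list[tuple[int, Path]] = []
    for f in path.iterdir():
        m = _SMI_PATTERN.search(f.name)
        if m:
            files.append((int(m.group(1)), f))
    steps = []
    for step, f in sorted(files):
        records = []
        for line in f.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            smiles = line.split()[0]
            records.append(make_record(step, smiles))
        steps.append(GenerationStep(step=step, records=records))
    return RunLog(steps=steps, metadata={"source": str(path), "dialect": "smi_per_step"})


def write_run_log(path: str | Path, log: RunLog) -> None:
    """Write a run log as the standard ``step,smiles,score[,nll]`` CSV."""
    rows = []
    has_nll = any(r.nll is not None for s in log for r in s.records)
    for s in log:
        for r in s.records:
            row = {
                "step": r.step,
                "smiles": r.raw_smiles,
                "score": "" if r.score is None else repr(float(r.score)),
            }
            if has_nll:
                row["nll"] = "" if r.nll is None else repr(float(r.nll))
            rows.append(row)
    cols = ["step", "smiles", "score"] + (["nll"] if has_nll else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Metric and flagged-pattern tables
# ---------------------------------------------------------------------------


def write_metrics(path: str | Path, series: "DiversityTimeSeries") -> None:
    """Write a diversity time series as long-format CSV (step, metric, value)."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_metrics(path: str | Path) -> "DiversityTimeSeries":
    """Read back a long-format metrics CSV into a DiversityTimeSeries."""
    from .diversity_metrics import DiversityTimeSeries

    df = pd.read_csv(path)
    missing = {"step", "metric", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return DiversityTimeSeries.from_frame(df)


_FLAGGED_COLUMNS = ["pattern_type", "pattern", "first_step", "occurrences", "frequency"]


def write_flagged(path: str | Path, rows: Iterable[dict]) -> None:
    """Write flagged patterns (one row per pattern) to CSV.

    Expected keys per row: pattern_type, pattern, first_step, occurrences,
    frequency.
    """
    df = pd.DataFrame(list(rows), columns=_FLAGGED_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_flagged(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_FLAGGED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return df
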