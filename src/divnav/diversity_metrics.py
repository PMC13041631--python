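"""Multi-representation diversity metrics for batches of generated molecules.

Four complementary families, each probing a different facet of chemical
diversity and each with a different sensitivity to generative-model collapse:

* **similarity** — Morgan/MACCS fingerprints with Tanimoto similarity: mean
  pairwise similarity of a batch, and the ratio of distinct structural
  clusters (leader clustering at a configurable threshold, default 0.3).
* **ngram** — syntactic diversity of the SMILES strings themselves via
  length-n substrings (default 10-grams): fraction of unique grams and the
  number of grams occurring in more than ``frequent_fraction`` of molecules.
* **fragment** — architectural diversity via retrosynthetic (BRICS) bond
  cleavage: fraction of distinct fragments and number of frequent fragments.
* **scaffold** — Bemis–Murcko framework diversity.

All metrics operate on the *valid* molecules of a batch; the valid fraction
is itself reported.  Registry names (``mean_tanimoto``, ``cluster_ratio``,
``ngram_unique_frac``, ``ngram_frequent_n``, ``frag_unique_frac``,
``frag_frequent_n``, ``scaffold_unique_frac``) are public contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import BRICS, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .core_io import GenerationStep, MetricConfig

__all__ = [
    "Fingerprint",
    "ClusterSet",
    "NGramTable",
    "FragmentTable",
    "DiversityTimeSeries",
    "compute_fingerprint",
    "tanimoto",
    "mean_pairwise_similarity",
    "cluster_molecules",
    "distinct_cluster_ratio",
    "extract_ngrams",
    "ngram_metrics",
    "fragment_molecule",
    "fragment_metrics",
    "murcko_scaffold",
    "scaffold_metrics",
    "compute_all",
    "METRIC_NAMES",
    "ACYCLIC_SCAFFOLD",
]

ACYCLIC_SCAFFOLD = "acyclic"

METRIC_NAMES = (
    "mean_tanimoto",
    "cluster_ratio",
    "ngram_unique_frac",
    "ngram_frequent_n",
    "frag_unique_frac",
    "frag_frequent_n",
    "scaffold_unique_frac",
)


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto similarity
# ---------------------------------------------------------------------------


@dataclass
class Fingerprint:
    """A bit-vector fingerprint tagged with the kind that produced it."""

    bits: DataStructs.ExplicitBitVect
    kind: str

    def __len__(self) -> int:
        return self.bits.GetNumBits()

    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())


_FP_CACHE: dict[tuple, Fingerprint] = {}
_MORGAN_GENERATORS: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _MORGAN_GENERATORS:
        _MORGAN_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _MORGAN_GENERATORS[key]


def compute_fingerprint(canonical_smiles: str, config: MetricConfig) -> Fingerprint:
    """Fingerprint a canonical SMILES; deterministic for a given config.

    ``ecfp`` is computed as the Morgan fingerprint (ECFP_{2r} == Morgan radius
    r); ``maccs`` ignores ``n_bits`` (fixed 167-bit key set).
    """
    key = (canonical_smiles, config.fingerprint_kind, config.morgan_radius, config.n_bits)
    fp = _FP_CACHE.get(key)
    if fp is not None:
        return fp
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {canonical_smiles!r}: pre-filter with parse_and_canonicalize")
    if config.fingerprint_kind in ("morgan", "ecfp"):
        bits = _morgan_generator(config.morgan_radius, config.n_bits).GetFingerprint(mol)
    else:  # maccs
        bits = MACCSkeys.GenMACCSKeys(mol)
    fp = Fingerprint(bits=bits, kind=config.fingerprint_kind)
    _FP_CACHE[key] = fp
    return fp


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| in [0, 1].

    Two all-zero fingerprints are defined to be identical (similarity 1.0) —
    the 0/0 case must be fixed, and it arises for tiny molecules under MACCS.
    """
    if a.kind != b.kind or len(a) != len(b):
        raise ValueError(f"fingerprint mismatch: {a.kind}/{len(a)} vs {b.kind}/{len(b)}")
    if a.bits.GetNumOnBits() == 0 and b.bits.GetNumOnBits() == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def _batch_fingerprints(step: GenerationStep, config: MetricConfig) -> list[Fingerprint]:
    return [compute_fingerprint(r.canonical_smiles, config) for r in step.valid_records()]


def mean_pairwise_similarity(step: GenerationStep, config: MetricConfig) -> float | None:
    """Mean Tanimoto over all unordered pairs of the batch's valid molecules.

    Returns None (undefined) for fewer than two valid molecules.
    """
    fps = _batch_fingerprints(step, config)
    n = len(fps)
    if n < 2:
        return None
    zero = [fp.bits.GetNumOnBits() == 0 for fp in fps]
    total = 0.0
    for i in range(n - 1):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i].bits, [f.bits for f in fps[i + 1:]])
        if zero[i]:  # RDKit returns 0 for 0/0; our convention is 1
            sims = [1.0 if zero[i + 1 + j] else s for j, s in enumerate(sims)]
        total += sum(sims)
    return total / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Leader clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """A partition of a batch's valid molecules into structural clusters.

    ``clusters`` holds ``(representative_smiles, member_indices)`` where the
    indices refer to positions in the batch's valid-molecule sequence.  Every
    member's similarity to its representative exceeds ``threshold`` (or the
    member is the representative itself).
    """

    clusters: list[tuple[str, list[int]]]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_molecules(step: GenerationStep, config: MetricConfig) -> ClusterSet:
    """Single-pass leader clustering in batch order.

    Each valid molecule joins the first existing cluster whose representative
    it resembles (Tanimoto > threshold), else it opens a new cluster as that
    cluster's representative.  Deterministic given the input order.
    """
    valid = step.valid_records()
    if not valid:
        raise ValueError("cluster_molecules requires at least one valid molecule")
    threshold = config.similarity_cluster_threshold
    fps = _batch_fingerprints(step, config)
    clusters: list[tuple[str, list[int]]] = []
    rep_fps: list[Fingerprint] = []
    for i, (rec, fp) in enumerate(zip(valid, fps)):
        placed = False
        for c, rep_fp in zip(clusters, rep_fps):
            if tanimoto(fp, rep_fp) > threshold:
                c[1].append(i)
                placed = True
                break
        if not placed:
            clusters.append((rec.canonical_smiles, [i]))
            rep_fps.append(fp)
    return ClusterSet(clusters=clusters, threshold=threshold)


def distinct_cluster_ratio(clusters: ClusterSet, n_valid: int) -> float:
    """Number of clusters over number of valid molecules, in (0, 1]."""
    if n_valid < 1:
        raise ValueError("n_valid must be >= 1")
    return clusters.n_clusters / n_valid


# ---------------------------------------------------------------------------
# SMILES n-grams
# ---------------------------------------------------------------------------


@dataclass
class NGramTable:
    """Occurrence counts for every length-n substring seen in a batch."""

    n: int
    counts: dict[str, tuple[int, int]]  # gram -> (total_occurrences, molecules_containing)
    batch_size: int


def extract_ngrams(smiles_text: str, n: int) -> list[str]:
    """All contiguous substrings of length n (stride 1), as a multiset.

    A string shorter than n yields no grams; otherwise exactly
    ``len(text) - n + 1`` grams.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return [smiles_text[i : i + n] for i in range(len(smiles_text) - n + 1)]


def _ngram_source(record, config: MetricConfig) -> str:
    return record.canonical_smiles if config.ngram_on_canonical else record.raw_smiles


def ngram_metrics(
    step: GenerationStep, config: MetricConfig
) -> tuple[float | None, int | None, NGramTable]:
    """Unique-gram fraction and frequent-gram count for one batch.

    ``unique_fraction`` = distinct grams / total gram occurrences.
    ``frequent_count`` = number of distinct grams present in more than
    ``frequent_fraction`` of the batch's valid molecules.  Both are None
    (undefined) when no valid string is long enough to bear a gram.
    """
    n = config.ngram_n
    valid = step.valid_records()
    totals: Counter[str] = Counter()
    containing: Counter[str] = Counter()
    for rec in valid:
        grams = extract_ngrams(_ngram_source(rec, config), n)
        totals.update(grams)
        containing.update(set(grams))
    table = NGramTable(
        n=n,
        counts={g: (totals[g], containing[g]) for g in totals},
        batch_size=step.batch_size,
    )
    total_occ = sum(totals.values())
    if total_occ == 0:
        return None, None, table
    n_valid = len(valid)
    unique_fraction = len(totals) / total_occ
    frequent = sum(1 for g in containing if containing[g] / n_valid > config.frequent_fraction)
    return unique_fraction, frequent, table


# ---------------------------------------------------------------------------
# BRICS fragmentation
# ---------------------------------------------------------------------------


@dataclass
class FragmentTable:
    """Occurrence counts for every BRICS fragment seen in a batch."""

    entries: dict[str, tuple[int, int, int]]  # frag -> (heavy_atoms, total_occ, mols_containing)


_FRAGMENT_CACHE: dict[str, list[tuple[str, int]]] = {}


def fragment_molecule(canonical_smiles: str) -> list[tuple[str, int]]:
    """Cleave a molecule at BRICS (retrosynthetic) bonds.

    Returns the multiset of leaf fragments as ``(canonical_smiles,
    heavy_atom_count)`` pairs.  Attachment points left by cleavage are
    normalized to the plain wildcard atom ``*`` before canonicalization (the
    BRICS link type is not part of a fragment's identity here) and do not
    count as heavy atoms.  A molecule with no cleavable bonds is its own
    single fragment.
    """
    cached = _FRAGMENT_CACHE.get(canonical_smiles)
    if cached is not None:
        return cached
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {canonical_smiles!r}")
    broken = BRICS.BreakBRICSBonds(mol)
    frags = []
    for frag in Chem.GetMolFrags(broken, asMols=True, sanitizeFrags=False):
        heavy = 0
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:  # dummy attachment point
                atom.SetIsotope(0)
                atom.SetAtomMapNum(0)
            elif atom.GetAtomicNum() > 1:
                heavy += 1
        frags.append((Chem.MolToSmiles(frag), heavy))
    _FRAGMENT_CACHE[canonical_smiles] = frags
    return frags


def fragment_metrics(
    step: GenerationStep, config: MetricConfig
) -> tuple[float | None, int | None, FragmentTable]:
    """Distinct-fragment fraction and frequent-fragment count for one batch.

    ``unique_fraction`` = distinct fragments / total fragment occurrences;
    ``frequent_count`` counts distinct fragments present in more than
    ``frequent_fraction`` of valid molecules.  No heavy-atom filter is
    applied here — that filter belongs to the fragment *constraint*, not the
    metric.
    """
    valid = step.valid_records()
    if not valid:
        return None, None, FragmentTable(entries={})
    totals: Counter[str] = Counter()
    containing: Counter[str] = Counter()
    heavy_of: dict[str, int] = {}
    for rec in valid:
        frags = fragment_molecule(rec.canonical_smiles)
        totals.update(f for f, _ in frags)
        containing.update({f for f, _ in frags})
        for f, h in frags:
            heavy_of[f] = h
    table = FragmentTable(
        entries={f: (heavy_of[f], totals[f], containing[f]) for f in totals}
    )
    total_occ = sum(totals.values())
    n_valid = len(valid)
    unique_fraction = len(totals) / total_occ
    frequent = sum(1 for f in containing if containing[f] / n_valid > config.frequent_fraction)
    return unique_fraction, frequent, table


# ---------------------------------------------------------------------------
# Murcko scaffolds
# ---------------------------------------------------------------------------

_SCAFFOLD_CACHE: dict[str, str] = {}


def murcko_scaffold(canonical_smiles: str) -> str:
    """Bemis–Murcko framework of a molecule (ring systems plus linkers).

    Acyclic molecules have an empty framework and are binned under the
    dedicated ``acyclic`` label rather than dropped.
    """
    cached = _SCAFFOLD_CACHE.get(canonical_smiles)
    if cached is not None:
        return cached
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(smiles=canonical_smiles)
    result = scaffold if scaffold else ACYCLIC_SCAFFOLD
    _SCAFFOLD_CACHE[canonical_smiles] = result
    return result


def scaffold_metrics(step: GenerationStep) -> tuple[float, list[tuple[str, int]]]:
    """Distinct-scaffold fraction and scaffolds ranked by frequency."""
    valid = step.valid_records()
    if not valid:
        raise ValueError("scaffold_metrics requires at least one valid molecule")
    counts = Counter(murcko_scaffold(r.canonical_smiles) for r in valid)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return len(counts) / len(valid), top


# ---------------------------------------------------------------------------
# Registry and time series
# ---------------------------------------------------------------------------


def _similarity_family(step: GenerationStep, config: MetricConfig) -> dict:
    out: dict = {}
    mps = mean_pairwise_similarity(step, config)
    if mps is not None:
        out["mean_tanimoto"] = mps
    if step.n_valid >= 1:
        clusters = cluster_molecules(step, config)
        out["cluster_ratio"] = distinct_cluster_ratio(clusters, step.n_valid)
    return out


def _ngram_family(step: GenerationStep, config: MetricConfig) -> dict:
    unique_frac, frequent, _ = ngram_metrics(step, config)
    if unique_frac is None:
        return {}
    return {"ngram_unique_frac": unique_frac, "ngram_frequent_n": frequent}


def _fragment_family(step: GenerationStep, config: MetricConfig) -> dict:
    unique_frac, frequent, _ = fragment_metrics(step, config)
    if unique_frac is None:
        return {}
    return {"frag_unique_frac": unique_frac, "frag_frequent_n": frequent}


def _scaffold_family(step: GenerationStep, config: MetricConfig) -> dict:
    if step.n_valid < 1:
        return {}
    frac, _ = scaffold_metrics(step)
    return {"scaffold_unique_frac": frac}


_FAMILY_REGISTRY = {
    "similarity": _similarity_family,
    "ngram": _ngram_family,
    "fragment": _fragment_family,
    "scaffold": _scaffold_family,
}


def compute_all(step: GenerationStep, config: MetricConfig) -> dict[str, float]:
    """One row of the diversity time series: every enabled metric on one batch.

    Undefined metrics (e.g. mean similarity of a single-molecule batch) are
    simply absent from the mapping — missing, never zero.
    """
    if step.batch_size == 0:
        raise ValueError("compute_all requires a non-empty step")
    values: dict[str, float] = {"valid_fraction": step.valid_fraction}
    for family in config.enabled_families:
        values.update(_FAMILY_REGISTRY[family](step, config))
    return values


@dataclass
class DiversityTimeSeries:
    """Per-step metric values for a campaign; appendable and serializable."""

    data: dict[int, dict[str, float]] = field(default_factory=dict)

    def append(self, step: int, values: dict[str, float]) -> None:
        if self.data and step <= max(self.data):
            raise ValueError(f"step {step} not greater than last step {max(self.data)}")
        self.data[step] = dict(values)

    def steps(self) -> list[int]:
        return sorted(self.data)

    def metric_names(self) -> list[str]:
        names: set[str] = set()
        for row in self.data.values():
            names.update(row)
        return sorted(names)

    def series(self, metric: str) -> tuple[list[int], list[float]]:
        """(steps, values) for one metric, restricted to steps where it is defined."""
        if metric not in self.metric_names():
            raise KeyError(f"unknown metric {metric!r}; have {self.metric_names()}")
        steps = [s for s in self.steps() if metric in self.data[s]]
        return steps, [self.data[s][metric] for s in steps]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": s, "metric": m, "value": v}
            for s in self.steps()
            for m, v in sorted(self.data[s].items())
        ]
        return pd.DataFrame(rows, columns=["step", "metric", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiversityTimeSeries":
        ts = cls()
        for s in sorted(df["step"].unique()):
            sub = df[df["step"] == s]
            ts.append(int(s), dict(zip(sub["metric"], sub["value"].astype(float))))
        return ts

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DiversityTimeSeries) and self.data == other.data
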