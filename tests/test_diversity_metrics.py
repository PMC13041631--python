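"""Diversity metrics against independent brute-force oracles and closed forms."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import BRICS
from rdkit.Chem.Scaffolds import MurckoScaffold

from divnav import (
    MetricConfig,
    cluster_molecules,
    compute_all,
    compute_fingerprint,
    distinct_cluster_ratio,
    extract_ngrams,
    fragment_metrics,
    fragment_molecule,
    mean_pairwise_similarity,
    murcko_scaffold,
    ngram_metrics,
    scaffold_metrics,
    tanimoto,
)
from divnav.diversity_metrics import ACYCLIC_SCAFFOLD
from helpers import make_step

CONFIG = MetricConfig()


# --- independent oracles (set arithmetic on on-bit indices, plain dicts) ---


def oracle_tanimoto(a, b) -> float:
    sa, sb = a.on_bits(), b.on_bits()
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def oracle_mean_pairwise(step, config=CONFIG) -> float:
    fps = [compute_fingerprint(r.canonical_smiles, config) for r in step.valid_records()]
    total, n_pairs = 0.0, 0
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            total += oracle_tanimoto(fps[i], fps[j])
            n_pairs += 1
    return total / n_pairs


def oracle_leader_scan(step, config=CONFIG):
    """Independent first-fit scan over the valid molecules, in batch order."""
    valid = step.valid_records()
    fps = [compute_fingerprint(r.canonical_smiles, config) for r in valid]
    clusters: list[list[int]] = []
    for i in range(len(valid)):
        for members in clusters:
            if oracle_tanimoto(fps[i], fps[members[0]]) > config.similarity_cluster_threshold:
                members.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def oracle_ngram_counts(step, n):
    totals, containing = Counter(), Counter()
    for rec in step.valid_records():
        text = rec.raw_smiles
        grams = [text[i : i + n] for i in range(len(text) - n + 1)]
        totals.update(grams)
        for g in set(grams):
            containing[g] += 1
    return totals, containing


# --------------------------------------------------------------------------


class TestFingerprintsAndTanimoto:
    def test_spelling_invariance_via_canonical_form(self):
        a = compute_fingerprint(Chem.CanonSmiles("OCC"), CONFIG)
        b = compute_fingerprint(Chem.CanonSmiles("CCO"), CONFIG)
        assert tanimoto(a, b) == 1.0

    def test_benzene_fingerprint_nonempty_and_differs_from_methane(self):
        benzene = compute_fingerprint("c1ccccc1", CONFIG)
        methane = compute_fingerprint("C", CONFIG)
        assert benzene.bits.GetNumOnBits() > 0
        assert tanimoto(benzene, methane) < 1.0

    def test_self_similarity_is_one(self, corpus):
        for _, canonical in corpus[:10]:
            fp = compute_fingerprint(canonical, CONFIG)
            assert tanimoto(fp, fp) == 1.0

    def test_kind_mismatch_rejected(self):
        a = compute_fingerprint("CCO", CONFIG)
        b = compute_fingerprint("CCO", MetricConfig(fingerprint_kind="maccs"))
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(a, b)

    def test_matches_set_arithmetic_oracle_on_corpus(self, corpus):
        fps = [compute_fingerprint(c, CONFIG) for _, c in corpus[:15]]
        for i in range(len(fps)):
            for j in range(i, len(fps)):
                assert tanimoto(fps[i], fps[j]) == pytest.approx(
                    oracle_tanimoto(fps[i], fps[j]), abs=1e-12
                )

    def test_invalid_smiles_is_an_error_here(self):
        with pytest.raises(ValueError, match="invalid SMILES"):
            compute_fingerprint("C1CC", CONFIG)


class TestMeanPairwiseSimilarity:
    def test_identical_batch_gives_one(self):
        assert mean_pairwise_similarity(make_step(["c1ccccc1"] * 5), CONFIG) == pytest.approx(1.0)

    def test_permutation_invariant(self, small_pool):
        smiles = small_pool.raw_smiles[:12]
        forward = mean_pairwise_similarity(make_step(smiles), CONFIG)
        backward = mean_pairwise_similarity(make_step(smiles[::-1]), CONFIG)
        assert forward == pytest.approx(backward, abs=1e-12)

    def test_single_valid_molecule_is_undefined(self):
        assert mean_pairwise_similarity(make_step(["CCO", "C1CC"]), CONFIG) is None

    def test_matches_double_loop_oracle(self, random_batches):
        for step in random_batches:
            assert mean_pairwise_similarity(step, CONFIG) == pytest.approx(
                oracle_mean_pairwise(step), abs=1e-12
            )


class TestClustering:
    def test_identical_batch_single_cluster(self):
        clusters = cluster_molecules(make_step(["c1ccccc1"] * 7), CONFIG)
        assert clusters.n_clusters == 1
        assert distinct_cluster_ratio(clusters, 7) == pytest.approx(1 / 7)

    def test_all_dissimilar_batch_one_cluster_each(self, small_pool):
        # pool admission guarantees pairwise similarity < 0.3
        step = make_step(small_pool.raw_smiles[:20])
        clusters = cluster_molecules(step, CONFIG)
        assert clusters.n_clusters == 20
        assert distinct_cluster_ratio(clusters, 20) == 1.0

    def test_partition_property(self, random_batches):
        for step in random_batches[:5]:
            clusters = cluster_molecules(step, CONFIG)
            members = sorted(i for _, ms in clusters.clusters for i in ms)
            assert members == list(range(step.n_valid))

    def test_members_similar_to_representative(self, random_batches):
        config = CONFIG
        for step in random_batches[:5]:
            valid = step.valid_records()
            clusters = cluster_molecules(step, config)
            for rep, members in clusters.clusters:
                rep_fp = compute_fingerprint(rep, config)
                for i in members:
                    fp = compute_fingerprint(valid[i].canonical_smiles, config)
                    sim = tanimoto(fp, rep_fp)
                    assert sim > config.similarity_cluster_threshold or valid[i].canonical_smiles == rep

    def test_matches_independent_leader_scan(self, random_batches):
        for step in random_batches:
            ours = cluster_molecules(step, CONFIG)
            theirs = oracle_leader_scan(step)
            assert [ms for _, ms in ours.clusters] == theirs

    def test_ratio_monotone_under_merging(self):
        # merging two clusters can only lower the count, hence the ratio
        step = make_step(["c1ccccc1", "CCO", "CCCCN"])
        clusters = cluster_molecules(step, CONFIG)
        assert distinct_cluster_ratio(clusters, 3) >= (clusters.n_clusters - 1) / 3


class TestNGrams:
    @pytest.mark.parametrize(
        "text,n,expected",
        [
            ("CCO", 10, []),
            ("abcdefghijkl", 10, ["abcdefghij", "bcdefghijk", "cdefghijkl"]),
            ("AAAA", 2, ["AA", "AA", "AA"]),
        ],
    )
    def test_extraction_examples(self, text, n, expected):
        assert extract_ngrams(text, n) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(min_size=0, max_size=40), st.integers(min_value=1, max_value=12))
    def test_gram_count_closed_form(self, text, n):
        assert len(extract_ngrams(text, n)) == max(0, len(text) - n + 1)

    def test_identical_batch_closed_form(self):
        smiles = "c1ccc(CCOCC)cc1"  # length 15 >= 10
        length = len(smiles)
        for batch in (2, 10):
            unique_frac, frequent, _ = ngram_metrics(make_step([smiles] * batch), CONFIG)
            assert unique_frac == pytest.approx(1 / batch)
            assert frequent == length - 10 + 1

    def test_no_gram_bearing_strings_undefined(self):
        unique_frac, frequent, table = ngram_metrics(make_step(["CCO", "CCN"]), CONFIG)
        assert unique_frac is None and frequent is None
        assert table.counts == {}

    def test_matches_dictionary_count_oracle(self, random_batches):
        for step in random_batches:
            unique_frac, frequent, table = ngram_metrics(step, CONFIG)
            totals, containing = oracle_ngram_counts(step, CONFIG.ngram_n)
            n_valid = step.n_valid
            assert dict(table.counts) == {
                g: (totals[g], containing[g]) for g in totals
            }
            if totals:
                assert unique_frac == pytest.approx(len(totals) / sum(totals.values()), abs=1e-12)
                assert frequent == sum(
                    1 for g in containing if containing[g] / n_valid > CONFIG.frequent_fraction
                )


class TestFragments:
    def test_uncleavable_molecule_is_its_own_fragment(self):
        frags = fragment_molecule("c1ccccc1")
        assert frags == [("c1ccccc1", 6)]

    def test_spelling_invariance(self):
        a = sorted(fragment_molecule(Chem.CanonSmiles("CCc1ccccc1")))
        b = sorted(fragment_molecule(Chem.CanonSmiles("c1ccccc1CC")))
        assert a == b

    def test_ethylbenzene_matches_reference_brics(self):
        ours = {f for f, _ in fragment_molecule("CCc1ccccc1")}
        reference = set()
        for frag in BRICS.BRICSDecompose(Chem.MolFromSmiles("CCc1ccccc1")):
            mol = Chem.MolFromSmiles(frag)
            for atom in mol.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetIsotope(0)
            reference.add(Chem.MolToSmiles(mol))
        assert ours == reference

    def test_attachment_points_do_not_count_as_heavy(self):
        frags = dict(fragment_molecule("CCc1ccccc1"))
        ring = next(f for f in frags if "1" in f)
        assert frags[ring] == 6  # benzene ring, dummy excluded

    def test_identical_single_fragment_batch_closed_form(self):
        step = make_step(["c1ccccc1"] * 10)
        unique_frac, frequent, _ = fragment_metrics(step, CONFIG)
        assert unique_frac == pytest.approx(1 / 10)
        assert frequent == 1

    def test_disjoint_fragment_sets_unique_fraction_one(self):
        step = make_step(["c1ccccc1", "C1CCCCC1", "c1ccncc1"])
        unique_frac, _, _ = fragment_metrics(step, CONFIG)
        assert unique_frac == 1.0

    def test_matches_count_oracle(self, random_batches):
        for step in random_batches[:10]:
            unique_frac, frequent, table = fragment_metrics(step, CONFIG)
            totals, containing = Counter(), Counter()
            for rec in step.valid_records():
                frags = [f for f, _ in fragment_molecule(rec.canonical_smiles)]
                totals.update(frags)
                for f in set(frags):
                    containing[f] += 1
            assert unique_frac == pytest.approx(len(totals) / sum(totals.values()), abs=1e-12)
            assert frequent == sum(
                1
                for f in containing
                if containing[f] / step.n_valid > CONFIG.frequent_fraction
            )


class TestScaffolds:
    def test_toluene_and_chlorobenzene_share_benzene_scaffold(self):
        benzene = MurckoScaffold.MurckoScaffoldSmiles(smiles="Cc1ccccc1")
        assert murcko_scaffold("Cc1ccccc1") == benzene
        assert murcko_scaffold("Clc1ccccc1") == benzene
        frac, top = scaffold_metrics(make_step(["Cc1ccccc1", "Clc1ccccc1"]))
        assert frac == 0.5
        assert top[0] == (benzene, 2)

    def test_acyclic_molecules_share_the_acyclic_bin(self):
        frac, top = scaffold_metrics(make_step(["CCO", "CCCN", "CC(C)=O"]))
        assert frac == pytest.approx(1 / 3)
        assert top == [(ACYCLIC_SCAFFOLD, 3)]

    def test_fraction_bounds(self, random_batches):
        for step in random_batches[:5]:
            frac, _ = scaffold_metrics(step)
            assert 0 < frac <= 1


class TestComputeAll:
    def test_default_registry_names_present(self, small_pool):
        values = compute_all(make_step(small_pool.raw_smiles[:10]), CONFIG)
        for name in (
            "mean_tanimoto", "cluster_ratio", "ngram_unique_frac", "ngram_frequent_n",
            "frag_unique_frac", "frag_frequent_n", "scaffold_unique_frac", "valid_fraction",
        ):
            assert name in values

    def test_disabled_family_keys_absent(self, small_pool):
        config = MetricConfig(enabled_families=("similarity", "ngram", "scaffold"))
        values = compute_all(make_step(small_pool.raw_smiles[:5]), config)
        assert "frag_unique_frac" not in values and "frag_frequent_n" not in values

    def test_undefined_metric_missing_not_zero(self):
        values = compute_all(make_step(["CCO"]), CONFIG)  # 1 molecule, 3 chars
        assert "mean_tanimoto" not in values
        assert "ngram_unique_frac" not in values
        assert values["cluster_ratio"] == 1.0

    def test_order_invariance_of_scalar_metrics(self, small_pool):
        smiles = small_pool.raw_smiles[:15]
        a = compute_all(make_step(smiles), CONFIG)
        b = compute_all(make_step(smiles[::-1]), CONFIG)
        assert a == pytest.approx(b)

    def test_ratio_metrics_within_bounds(self, random_batches):
        for step in random_batches:
            values = compute_all(step, CONFIG)
            for name in ("cluster_ratio", "ngram_unique_frac", "frag_unique_frac",
                         "scaffold_unique_frac", "valid_fraction"):
                if name in values:
                    assert 0 <= values[name] <= 1
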