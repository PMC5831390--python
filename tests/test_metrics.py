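import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germcore import (
    FrequencyTable,
    accession_divergence,
    accession_rarity,
    accession_scores,
    allele_specificity,
    mutual_information,
    relative_specificity,
)
from germcore.freqtable import ValidationError

from conftest import naive_scores, naive_specificity, random_table


class TestAlleleSpecificity:
    def test_table1_printed_values(self, table1):
        s = allele_specificity(table1)
        assert s[("Locus2", "Allele1")] == pytest.approx(2.0, abs=5e-4)
        assert s[("Locus2", "Allele2")] == pytest.approx(0.415, abs=5e-4)
        assert s[("Locus3", "Allele2")] == pytest.approx(0.478, abs=5e-4)

    def test_hand_derived_locus1(self, table1):
        # p = (1,0,1,0), p_i = 0.5: two accessions each contribute 1/2 * log2(2)
        assert s_abs(table1, "Locus1", "Allele1") == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_allele_scores_zero(self):
        t = FrequencyTable(
            ["X", "Y", "Z"],
            [("L", "a"), ("L", "b")],
            np.array([[0.3] * 3, [0.7] * 3]),
        )
        s = allele_specificity(t)
        assert s.specificity_abs == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_private_allele_hits_log2_n_bound(self):
        n = 8
        vals = np.zeros((2, n))
        vals[0, 0] = 0.4
        vals[1] = 1 - vals[0]
        t = FrequencyTable([f"A{j}" for j in range(n)], [("L", "a"), ("L", "b")], vals)
        s = allele_specificity(t)
        assert s.specificity_abs[0] == pytest.approx(math.log2(n), abs=1e-12)
        assert s.specificity_rel[0] == pytest.approx(1.0, abs=1e-12)

    def test_unobserved_allele_flagged_not_zero(self):
        t = FrequencyTable(
            ["X", "Y"],
            [("L", "a"), ("L", "b"), ("L", "c")],
            np.array([[0.0, 0.0], [0.4, 0.6], [0.6, 0.4]]),
        )
        s = allele_specificity(t)
        assert not s.defined[0] and np.isnan(s.specificity_abs[0])
        assert s.defined[1:].all()

    def test_single_accession_table_raises(self):
        t = FrequencyTable(["X"], [("L", "a"), ("L", "b")], np.array([[0.4], [0.6]]))
        with pytest.raises(ValidationError, match="single-accession"):
            allele_specificity(t)

    def test_missing_data_uses_available_accessions_only(self):
        vals = np.array(
            [[0.5, np.nan, 1.0], [0.5, np.nan, 0.0]]
        )
        t = FrequencyTable(["X", "Y", "Z"], [("L", "a"), ("L", "b")], vals)
        s = allele_specificity(t)
        assert (s.n_available == 2).all()
        # same as a 2-accession table without the missing column
        t2 = FrequencyTable(["X", "Z"], [("L", "a"), ("L", "b")], vals[:, [0, 2]])
        np.testing.assert_allclose(
            s.specificity_abs, allele_specificity(t2).specificity_abs
        )

    def test_specificity_bounded_by_log2_available(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 12, 6, missing_rate=0.15)
        s = allele_specificity(t)
        ok = s.defined
        assert (s.specificity_abs[ok] <= np.log2(s.n_available[ok]) + 1e-9).all()
        assert (s.specificity_abs[ok] >= -1e-12).all()


def s_abs(t, locus, allele):
    s = allele_specificity(t)
    return s[(locus, allele)]


class TestRelativeSpecificity:
    def test_table1_top_allele_is_one(self, table1):
        s = relative_specificity(allele_specificity(table1))
        idx = s.allele_index.index(("Locus2", "Allele1"))
        assert s.specificity_rel[idx] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_is_zero(self):
        t = FrequencyTable(
            ["X", "Y"], [("L", "a"), ("L", "b")], np.array([[0.5, 0.5], [0.5, 0.5]])
        )
        s = relative_specificity(allele_specificity(t))
        assert s.specificity_rel == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_private_allele_with_missing_data(self):
        # the relative score undoes the missing-data penalty on the ceiling
        n, masked = 40, 3
        vals = np.zeros((2, n))
        vals[0, 0] = 1.0
        vals[1] = 1 - vals[0]
        vals[:, -masked:] = np.nan
        t = FrequencyTable([f"A{j}" for j in range(n)], [("L", "a"), ("L", "b")], vals)
        s = allele_specificity(t)
        assert s.specificity_abs[0] == pytest.approx(math.log2(n - masked), abs=1e-12)
        assert s.specificity_rel[0] == pytest.approx(1.0, abs=1e-12)


class TestAccessionScores:
    def test_table1_printed_rarity(self, table1):
        r = accession_rarity(table1)
        assert r.rarity_of("A4") == pytest.approx(1.361, abs=5e-4)
        assert r.rarity_of("A1") == pytest.approx(0.732, abs=5e-4)
        assert r.rarity_of("A2") == pytest.approx(0.631, abs=5e-4)
        assert r.rarity_of("A3") == pytest.approx(0.631, abs=5e-4)

    def test_table1_printed_divergence(self, table1):
        d = accession_divergence(table1)
        assert d.divergence_of("A4") == pytest.approx(1.472, abs=5e-4)
        assert d.divergence_of("A1") == pytest.approx(0.487, abs=5e-4)

    def test_identical_accessions_have_zero_divergence(self):
        col = np.array([0.3, 0.7])
        t = FrequencyTable(
            ["X", "Y", "Z"], [("L", "a"), ("L", "b")], np.tile(col[:, None], 3)
        )
        d = accession_divergence(t)
        assert d.divergence == pytest.approx([0.0] * 3, abs=1e-12)

    def test_divergence_nonnegative(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 15, 8)
        assert (accession_divergence(t).divergence >= -1e-12).all()

    def test_all_missing_accession_flagged_unscored(self):
        vals = np.array([[0.5, np.nan], [0.5, np.nan]])
        t = FrequencyTable(["X", "Y"], [("L", "a"), ("L", "b")], vals)
        s = accession_scores(t)
        assert s.n_loci_used[1] == 0 and np.isnan(s.rarity[1])

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for missing in (0.0, 0.2):
            t = random_table(rng, 10, 10, missing_rate=missing)
            rarity, divergence = naive_scores(t)
            s = accession_scores(t)
            for j, acc in enumerate(t.accession_ids):
                assert s.rarity[j] == pytest.approx(rarity[acc], abs=1e-12)
                assert s.divergence[j] == pytest.approx(divergence[acc], abs=1e-12)
            spec = naive_specificity(t)
            prod = allele_specificity(t)
            for r, key in enumerate(t.allele_index):
                if spec[key] is None:
                    assert not prod.defined[r]
                else:
                    assert prod.specificity_abs[r] == pytest.approx(spec[key], abs=1e-12)


class TestMutualInformation:
    def test_table1_three_routes_agree(self, table1):
        mi = mutual_information(table1)
        assert mi.consistent
        # frozen from the naive-loop oracle on the printed table
        assert mi.value_from_divergence == pytest.approx(0.8385707091280326, abs=1e-12)

    def test_duplicated_accession_collection_is_zero(self):
        col = np.array([0.25, 0.75])
        t = FrequencyTable(
            ["X", "Y"], [("L", "a"), ("L", "b")], np.tile(col[:, None], 2)
        )
        mi = mutual_information(t)
        assert mi.value_from_divergence == pytest.approx(0.0, abs=1e-12)

    def test_fully_private_collection_reaches_log2_n(self):
        n = 6
        vals = np.eye(n)
        t = FrequencyTable(
            [f"A{j}" for j in range(n)], [("L", f"a{i}") for i in range(n)], vals
        )
        mi = mutual_information(t)
        assert mi.value_from_divergence == pytest.approx(math.log2(n), abs=1e-12)
        assert mi.consistent


class TestEquivariance:
    def test_column_permutation_permutes_scores(self):
        rng = np.random.default_rng(9)
        t = random_table(rng, 8, 5)
        perm = rng.permutation(8)
        tp = FrequencyTable(
            [t.accession_ids[j] for j in perm], list(t.allele_index), t.values[:, perm]
        )
        s, sp = accession_scores(t), accession_scores(tp)
        for j, acc in enumerate(tp.accession_ids):
            k = t.accession_ids.index(acc)
            assert sp.rarity[j] == pytest.approx(s.rarity[k], abs=1e-12)
            assert sp.divergence[j] == pytest.approx(s.divergence[k], abs=1e-12)
        np.testing.assert_allclose(
            np.sort(allele_specificity(t).specificity_abs),
            np.sort(allele_specificity(tp).specificity_abs),
        )

    def test_duplicating_every_accession_preserves_scores(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, 6, 4)
        t2 = FrequencyTable(
            t.accession_ids + [a + "_dup" for a in t.accession_ids],
            list(t.allele_index),
            np.hstack([t.values, t.values]),
        )
        np.testing.assert_allclose(
            allele_specificity(t2).specificity_abs,
            allele_specificity(t).specificity_abs,
            atol=1e-12,
        )
        s, s2 = accession_scores(t), accession_scores(t2)
        np.testing.assert_allclose(s2.rarity[: 6], s.rarity, atol=1e-12)
        np.testing.assert_allclose(s2.divergence[: 6], s.divergence, atol=1e-12)


@given(
    seed=st.integers(0, 10_000),
    n=st.integers(2, 20),
    n_loci=st.integers(1, 6),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_identity_mean_rarity_equals_mean_divergence(seed, n, n_loci):
    """On complete data, mean rarity, mean divergence and the locus-averaged
    frequency-weighted specificity sum are the same mutual information."""
    rng = np.random.default_rng(seed)
    t = random_table(rng, n, n_loci, max_alleles=5)
    mi = mutual_information(t)
    assert abs(mi.value_from_rarity - mi.value_from_divergence) < 1e-9
    assert abs(mi.value_from_specificity - mi.value_from_divergence) < 1e-9
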