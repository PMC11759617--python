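"""QC filters: boundary behaviour, hand enumerations, KING kinship on
constructed pedigrees, and the Hardy-Weinberg mid-p against an independent
enumeration oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from pcmatch import qc, simulate
from pcmatch.containers import GenotypeMatrix

from conftest import toy_genotypes


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

class TestMissingness:
    def _matrix_with_missing(self, n, counts):
        """counts[j] samples missing at variant j."""
        d = np.ones((n, len(counts)), dtype=np.int8)
        for j, c in enumerate(counts):
            d[:c, j] = -1
        return toy_genotypes(d)

    def test_variant_boundary(self):
        G = self._matrix_with_missing(100, [11, 10, 0])
        G2, rep = qc.filter_variant_missingness(G, 0.10)
        assert G2.n_variants == 2                      # 11% removed, 10% kept
        assert list(rep.removed_variants["reason"]) == ["missingness"]

    def test_variant_hand_enumeration(self):
        G = self._matrix_with_missing(20, [0, 1, 2, 3, 4])
        G2, _ = qc.filter_variant_missingness(G, 0.10)
        # 0/20, 1/20, 2/20 survive at 10%; 3/20 = 15% and 4/20 = 20% do not
        assert list(G2.variants["id"]) == list(G.variants["id"][:3])

    def test_sample_boundary_and_enumeration(self):
        d = np.ones((4, 20), dtype=np.int8)
        d[0, :1] = -1      # 5%  kept
        d[1, :2] = -1      # 10% removed
        d[2, :3] = -1      # 15% removed
        G = toy_genotypes(d, samples=["a", "b", "c", "d"])
        G2, rep = qc.filter_sample_missingness(G, 0.05)
        assert G2.samples == ["a", "d"]
        assert set(rep.removed_samples["sample_id"]) == {"b", "c"}

    def test_idempotence(self):
        G = self._matrix_with_missing(50, [0, 3, 6, 9])
        G1, _ = qc.filter_variant_missingness(G, 0.10)
        G2, rep = qc.filter_variant_missingness(G1, 0.10)
        np.testing.assert_array_equal(G1.dosages, G2.dosages)
        assert rep.removed_variants.empty


# ---------------------------------------------------------------------------
# HET/HOM outliers
# ---------------------------------------------------------------------------

class TestHetHom:
    def test_homogeneous_cohort_untouched(self, rng):
        d = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        G = toy_genotypes(d)
        G2, rep = qc.het_hom_outliers(G)
        assert G2.n_samples == 30
        assert rep.removed_samples.empty

    def test_constructed_outlier_removed(self, rng):
        d = rng.choice([0, 1, 2], p=[0.5, 0.25, 0.25],
                       size=(100, 400)).astype(np.int8)
        d[0] = 1                        # all-het sample: extreme ratio
        G = toy_genotypes(d)
        G2, rep = qc.het_hom_outliers(G, n_sd=6)
        assert G.samples[0] in set(rep.removed_samples["sample_id"])
        assert G2.n_samples == 99

    def test_matches_direct_computation(self, rng):
        d = rng.choice([0, 1, 2], p=[0.4, 0.4, 0.2],
                       size=(20, 300)).astype(np.int8)
        G = toy_genotypes(d)
        het = (d == 1).sum(axis=1)
        hom = np.maximum((d == 2).sum(axis=1), 1)
        ratio = het / hom
        expect = np.abs(ratio - ratio.mean()) > 2 * ratio.std()
        _, rep = qc.het_hom_outliers(G, n_sd=2)
        got = set(rep.removed_samples["sample_id"])
        want = {G.samples[i] for i in np.flatnonzero(expect)}
        assert got == want


# ---------------------------------------------------------------------------
# KING kinship
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def population_freqs():
    rng = np.random.default_rng(31)
    return rng.uniform(0.1, 0.5, size=4000)


class TestKing:
    def test_duplicate_sample(self, population_freqs, rng):
        g = rng.binomial(2, population_freqs).astype(np.int8)
        others = rng.binomial(2, population_freqs, size=(3, len(g))).astype(np.int8)
        G = toy_genotypes(np.vstack([g, g, others]),
                          samples=["dup1", "dup2", "x", "y", "z"])
        tab = qc.king_kinship(G)
        phi = tab.set_index(["id1", "id2"]).loc[("dup1", "dup2"), "phi"]
        assert abs(phi - 0.5) < 0.02

    def test_parent_offspring(self, population_freqs, rng):
        p = population_freqs
        father = rng.binomial(1, p) + rng.binomial(1, p)
        transmitted = rng.binomial(1, np.where(father == 1, 0.5, father / 2))
        child = transmitted + rng.binomial(1, p)
        G = toy_genotypes(np.vstack([father, child]).astype(np.int8),
                          samples=["dad", "kid"])
        tab = qc.king_kinship(G)
        assert abs(tab["phi"].iloc[0] - 0.25) < 0.03

    def test_unrelated_near_zero(self, population_freqs, rng):
        a = rng.binomial(2, population_freqs).astype(np.int8)
        b = rng.binomial(2, population_freqs).astype(np.int8)
        G = toy_genotypes(np.vstack([a, b]), samples=["u1", "u2"])
        tab = qc.king_kinship(G)
        assert abs(tab["phi"].iloc[0]) < 0.02

    def test_pair_list_matches_all_pairs(self, population_freqs, rng):
        d = rng.binomial(2, population_freqs, size=(4, len(population_freqs)))
        G = toy_genotypes(d.astype(np.int8), samples=list("abcd"))
        full = qc.king_kinship(G).set_index(["id1", "id2"])
        sub = qc.king_kinship(G, pairs=[("a", "c"), ("b", "d")])
        for r in sub.itertuples():
            assert abs(full.loc[(r.id1, r.id2), "phi"] - r.phi) < 1e-6

    def test_insufficient_overlap_skipped(self):
        d = np.full((2, 150), -1, dtype=np.int8)
        d[:, :50] = 1
        G = toy_genotypes(d, samples=["a", "b"])
        tab = qc.king_kinship(G, min_overlap=100)
        assert tab.empty


class TestRemoveRelated:
    def _table(self, pairs):
        return pd.DataFrame(pairs, columns=["id1", "id2", "phi"])

    def _geno(self, ids):
        return toy_genotypes(np.ones((len(ids), 10), dtype=np.int8),
                             samples=list(ids))

    def test_no_pairs_identity(self):
        G = self._geno("abc")
        G2, rep = qc.remove_related(self._table([("a", "b", 0.01)]), G)
        assert G2.samples == ["a", "b", "c"]
        assert rep.removed_samples.empty

    def test_duplicate_pair_removes_one(self):
        G = self._geno("abc")
        G2, _ = qc.remove_related(self._table([("a", "b", 0.5)]), G)
        assert len(G2.samples) == 2
        assert "c" in G2.samples

    def test_triangle_minimal_cover(self):
        # three mutually related: greedy must remove exactly two, and the
        # tie rule (equal degree, equal missingness) keeps the
        # lexicographically largest of the first two picks
        G = self._geno("abc")
        table = self._table([("a", "b", 0.3), ("a", "c", 0.3), ("b", "c", 0.3)])
        G2, rep = qc.remove_related(table, G)
        assert len(G2.samples) == 1
        assert set(rep.removed_samples["sample_id"]) == {"a", "b"}


# ---------------------------------------------------------------------------
# Hardy-Weinberg mid-p
# ---------------------------------------------------------------------------

def hwe_midp_oracle_distribution(n, n_minor):
    """Independent oracle: recurrence over heterozygote counts.

    Uses the ratio identity
    P(h+2) / P(h) = h_homA * h_homB * 4 / ((h+2)(h+1)) ... built strictly
    from successive factorial ratios, no log-gamma.
    """
    parity = n_minor % 2
    hs = list(range(parity, min(n_minor, 2 * n - n_minor) + 1, 2))
    probs = [1.0]
    for h in hs[:-1]:
        a = (n_minor - h) // 2          # minor homs at h
        b = n - h - a                   # major homs at h
        ratio = 4.0 * a * b / ((h + 2.0) * (h + 1.0))
        probs.append(probs[-1] * ratio)
    total = sum(probs)
    return hs, [p / total for p in probs]


def hwe_midp_oracle(n_AA, n_Aa, n_aa):
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    hs, probs = hwe_midp_oracle_distribution(n, n_minor)
    p_obs = probs[hs.index(n_Aa)]
    tol = 1e-12 * p_obs
    mid = sum(p for p in probs if p < p_obs - tol)
    mid += 0.5 * sum(p for p in probs if abs(p - p_obs) <= tol)
    return min(mid, 1.0)


class TestHweMidp:
    def test_monomorphic_is_one(self):
        assert qc.hwe_midp(0, 0, 100) == 1.0
        assert qc.hwe_midp(100, 0, 0) == 1.0

    def test_balanced_table_matches_oracle(self):
        assert abs(qc.hwe_midp(25, 50, 25) - hwe_midp_oracle(25, 50, 25)) < 1e-12

    def test_extreme_het_deficit_below_gate(self):
        # all-homozygote split: overwhelming HWE violation
        assert qc.hwe_midp(50, 0, 50) < 1e-15

    def test_matches_oracle_on_exhaustive_small_grid(self):
        for n in range(1, 61):
            for n_aa in range(n + 1):
                for n_Aa in range(n - n_aa + 1):
                    n_AA = n - n_aa - n_Aa
                    got = qc.hwe_midp(n_AA, n_Aa, n_aa)
                    want = hwe_midp_oracle(n_AA, n_Aa, n_aa)
                    assert abs(got - want) < 1e-9, (n_AA, n_Aa, n_aa)

    def test_midp_below_conventional_p(self):
        # mid-p correction halves the observed table's contribution
        for table in [(30, 20, 50), (10, 40, 50), (70, 25, 5)]:
            n = sum(table)
            n_minor = min(2 * table[2] + table[1],
                          2 * n - 2 * table[2] - table[1])
            hs, probs = hwe_midp_oracle_distribution(n, n_minor)
            p_obs = probs[hs.index(table[1])]
            conventional = sum(p for p in probs if p <= p_obs + 1e-15 * p_obs)
            assert qc.hwe_midp(*table) <= conventional + 1e-12


class TestHweFilter:
    def test_filters_only_violating_variants(self, rng):
        freqs = np.full(30, 0.3)
        d = rng.binomial(2, freqs, size=(200, 30)).astype(np.int8)
        d[:, 0] = np.where(np.arange(200) < 60, 2, 0)   # no hets at all
        G = toy_genotypes(d)
        G2, rep = qc.hwe_filter(G, min_midp=1e-15)
        assert list(rep.removed_variants["variant_id"]) == [G.variants["id"][0]]
        assert G2.n_variants == 29


# ---------------------------------------------------------------------------
# MAC / privacy
# ---------------------------------------------------------------------------

class TestMacPrivacy:
    def test_carrier_boundary(self):
        n = 200
        d = np.zeros((n, 2), dtype=np.int8)
        d[:19, 0] = 1                   # 19 carriers, MAC 19 -> removed
        d[:20, 1] = 1                   # 20 carriers, MAC 20 -> retained
        G = toy_genotypes(d)
        G2, rep = qc.mac_privacy_filter(G)
        assert list(G2.variants["id"]) == [G.variants["id"][1]]
        assert list(rep.removed_variants["reason"]) == ["mac"]

    def test_minor_allele_is_ref_when_alt_common(self):
        n = 100
        d = np.full((n, 1), 2, dtype=np.int8)
        d[:10, 0] = 1                   # minor (ref) allele: 10 copies
        G = toy_genotypes(d)
        G2, _ = qc.mac_privacy_filter(G)
        assert G2.n_variants == 0

    def test_hand_enumeration(self):
        n = 300
        cols = []
        # (carriers, copies-each): MACs 15, 40, 25(hom), 22
        for carriers, dose in [(15, 1), (40, 1), (25, 2), (11, 2)]:
            c = np.zeros(n, dtype=np.int8)
            c[:carriers] = dose
            cols.append(c)
        G = toy_genotypes(np.column_stack(cols))
        G2, rep = qc.mac_privacy_filter(G, min_carriers=20, min_mac=20)
        # v0: MAC 15 fails; v1: 40 carriers MAC 40 ok; v2: 25 carriers MAC 50
        # ok; v3: 11 carriers (MAC 22) fails the carrier rule
        assert list(G2.variants["id"]) == [G.variants["id"][1],
                                           G.variants["id"][2]]
        reasons = dict(zip(rep.removed_variants["variant_id"],
                           rep.removed_variants["reason"]))
        assert reasons[G.variants["id"][0]] == "mac"
        assert reasons[G.variants["id"][3]] == "privacy"


# ---------------------------------------------------------------------------
# PC outliers
# ---------------------------------------------------------------------------

class TestPcOutliers:
    def test_no_outliers_kept(self, rng):
        scores = rng.normal(size=(100, 10))
        assert qc.pc_outlier_mask(scores, n_sd=6).all()

    def test_planted_outlier_removed(self, rng):
        scores = rng.normal(size=(200, 10))
        scores[7, 3] = 50.0
        mask = qc.pc_outlier_mask(scores, n_sd=6)
        assert not mask[7]
        assert mask.sum() == 199

    def test_matches_direct_computation(self, rng):
        scores = rng.normal(size=(60, 12))
        mask = qc.pc_outlier_mask(scores, n_sd=2, n_pcs=10)
        S = scores[:, :10]
        want = (np.abs(S - S.mean(0)) <= 2 * S.std(0)).all(axis=1)
        np.testing.assert_array_equal(mask, want)
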