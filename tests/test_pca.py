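"""PC space: pruning, reference PCA, projection identity and shrinkage,
Jaccard PCs, nearest-centroid ancestry labels."""

import numpy as np
import pytest

from pcmatch import pca, simulate
from pcmatch.containers import GenotypeMatrix, default_variant_table

from conftest import toy_genotypes


@pytest.fixture(scope="module")
def two_pop_study():
    """Two well-separated populations, reference + held-out samples."""
    panel = simulate.draw_ancestral_frequencies(800, 2, 0.1, seed=41)
    admix = simulate.draw_admixture(500, [0.5, 0.5], seed=42)
    G = simulate.simulate_genotypes(panel, admix, seed=43)
    return panel, admix, G


class TestLdPrune:
    def test_independent_variants_mostly_retained(self):
        panel = simulate.draw_ancestral_frequencies(1000, 1, 0.0,
                                                    base_bounds=(0.1, 0.5),
                                                    seed=1)
        admix = simulate.draw_admixture(400, [1.0], seed=2)
        G = simulate.simulate_genotypes(panel, admix, seed=3)
        kept = pca.ld_prune(G, window_kb=100, r2_max=0.1, maf_min=0.01)
        assert len(kept) >= 950

    def test_duplicate_variant_pruned(self):
        panel = simulate.draw_ancestral_frequencies(50, 1, 0.0,
                                                    base_bounds=(0.2, 0.4),
                                                    seed=4)
        admix = simulate.draw_admixture(300, [1.0], seed=5)
        G = simulate.simulate_genotypes(panel, admix, seed=6)
        simulate.add_ld_copy(G, 10, 11, flip_prob=0.0)
        kept = pca.ld_prune(G, window_kb=100, r2_max=0.1)
        assert (10 in kept) != (11 in kept)

    def test_hand_computed_toy(self):
        # pairwise r2 of these printed dosages (hand/numpy-checked):
        #   r2(v0,v1) = 0.714, r2(v0,v2) = 0.360, r2(v1,v2) = 0.417;
        # MAFs 0.4 / 0.5 / 0.4.  Scan: v1 beats v0 (higher MAF), v2 then
        # conflicts with v1 and loses -> survivor set {v1}.
        v0 = np.array([0, 0, 1, 1, 2, 2, 0, 1, 0, 1], dtype=np.int8)
        v1 = v0.copy()
        v1[[0, 1]] = 1
        v2 = np.array([2, 0, 0, 2, 0, 0, 2, 0, 2, 0], dtype=np.int8)
        G = toy_genotypes(np.column_stack([v0, v1, v2]))
        kept = pca.ld_prune(G, window_kb=100, r2_max=0.1, maf_min=0.01)
        assert list(kept) == [1]

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        # independent quadratic-time implementation of the same stated rule
        def oracle(G, window, r2_max, maf_min):
            maf = G.maf()
            pos = G.variants["pos"].to_numpy()
            cand = [j for j in range(G.n_variants) if maf[j] >= maf_min]
            X = G.imputed_dosages()
            result = []
            for i in cand:
                alive = True
                for j in list(result):
                    if pos[i] - pos[j] > window * 1000:
                        continue
                    r = np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2
                    if r > r2_max:
                        if maf[i] <= maf[j]:
                            alive = False
                            break
                        result.remove(j)
                if alive:
                    result.append(i)
            return result

        for trial in range(5):
            panel = simulate.draw_ancestral_frequencies(
                12, 1, 0.0, base_bounds=(0.2, 0.5), seed=100 + trial)
            admix = simulate.draw_admixture(80, [1.0], seed=200 + trial)
            G = simulate.simulate_genotypes(panel, admix, seed=300 + trial)
            for src, dst in [(0, 1), (4, 6), (8, 9)]:
                simulate.add_ld_copy(G, src, dst, flip_prob=0.1,
                                     seed=400 + trial)
            G.variants["pos"] = 1 + 3000 * np.arange(12)   # some out of window
            kept = pca.ld_prune(G, window_kb=5, r2_max=0.1, maf_min=0.01)
            assert list(kept) == oracle(G, 5, 0.1, 0.01)


class TestReferencePca:
    def test_pc1_separates_populations(self):
        panel = simulate.draw_ancestral_frequencies(600, 2, 0.1, seed=11)
        Q = np.zeros((300, 2))
        Q[:150, 0] = 1.0
        Q[150:, 1] = 1.0
        admix = simulate.AdmixtureSpec(np.array([1.0, 1.0]), 300, Q)
        G = simulate.simulate_genotypes(panel, admix, seed=12)
        _, scores = pca.reference_pca(G, k=5)
        label = Q[:, 0]
        r = np.corrcoef(scores.scores[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_sample_permutation_equivariance(self, two_pop_study):
        _, _, G = two_pop_study
        _, s1 = pca.reference_pca(G, k=4)
        perm = np.random.default_rng(1).permutation(G.n_samples)
        _, s2 = pca.reference_pca(G.subset(sample_idx=perm), k=4)
        np.testing.assert_allclose(s1.scores[perm], s2.scores, atol=1e-6)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        d[:, d.std(axis=0) == 0] = rng.integers(0, 3, size=d.shape[0])[:, None]
        G = toy_genotypes(d)
        k = min(G.n_samples, G.n_variants) - 1
        model, scores = pca.reference_pca(G, k=k)
        Z = (G.dosages - 2 * model.freqs) / np.sqrt(
            2 * model.freqs * (1 - model.freqs))
        recon = scores.scores @ model.loadings.T
        # k = rank-1 captures all but a negligible tail of the spectrum
        resid = np.linalg.norm(Z - recon) / np.linalg.norm(Z)
        assert resid < 0.2

    def test_loadings_orthonormal(self, two_pop_study):
        _, _, G = two_pop_study
        model, _ = pca.reference_pca(G, k=6)
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(6), atol=1e-8)

    def test_model_round_trip(self, tmp_path, two_pop_study):
        _, _, G = two_pop_study
        model, _ = pca.reference_pca(G, k=3)
        model.save(tmp_path / "pc")
        back = pca.PCModel.load(tmp_path / "pc")
        np.testing.assert_allclose(model.loadings, back.loadings, atol=1e-12)
        np.testing.assert_allclose(model.freqs, back.freqs, atol=1e-12)


class TestProjection:
    def test_projection_identity_on_reference(self, two_pop_study):
        _, _, G = two_pop_study
        model, scores = pca.reference_pca(G, k=5)
        proj = pca.project(model, G)
        np.testing.assert_allclose(proj.scores, scores.scores, atol=1e-8)
        assert proj.provenance == "projected"

    def test_heldout_scores_match_joint_pca(self):
        panel = simulate.draw_ancestral_frequencies(800, 2, 0.15, seed=21)
        admix = simulate.draw_admixture(900, [1.0, 1.0], seed=22)
        G = simulate.simulate_genotypes(panel, admix, seed=23)
        ref_idx = np.arange(600)
        out_idx = np.arange(600, 900)
        model, _ = pca.reference_pca(G.subset(sample_idx=ref_idx), k=2)
        proj = pca.project(model, G.subset(sample_idx=out_idx))
        _, joint = pca.reference_pca(G, k=2)
        r = np.corrcoef(proj.scores[:, 0], joint.scores[out_idx, 0])[0, 1]
        assert abs(r) > 0.9

    def test_standardization_uses_reference_frequencies(self, two_pop_study):
        # identical target genotypes, different target cohort frequencies:
        # scores must be identical because standardization comes from the
        # model, not from the target cohort
        _, _, G = two_pop_study
        model, _ = pca.reference_pca(G, k=3)
        target = G.subset(sample_idx=np.arange(50))
        skewed = G.subset(sample_idx=np.concatenate(
            [np.arange(50), np.repeat(60, 200)]))   # wildly different freqs
        p1 = pca.project(model, target).scores
        p2 = pca.project(model, skewed).scores[:50]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_absent_variants_hard_error(self, two_pop_study):
        _, _, G = two_pop_study
        model, _ = pca.reference_pca(G, k=3)
        few = G.subset(variant_idx=np.arange(100))   # 12.5% coverage
        with pytest.raises(pca.ProjectionSpaceError):
            pca.project(model, few)

    def test_unseen_population_falls_outside_reference_range(self):
        panel = simulate.draw_ancestral_frequencies(1000, 3, 0.15, seed=31)
        Q_ref = np.zeros((300, 3))
        Q_ref[:150, 0] = 1.0
        Q_ref[150:, 1] = 1.0
        Q_new = np.zeros((100, 3))
        Q_new[:, 2] = 1.0
        G_ref = simulate.simulate_genotypes(
            panel, simulate.AdmixtureSpec(np.ones(3), 300, Q_ref), seed=32)
        G_new = simulate.simulate_genotypes(
            panel, simulate.AdmixtureSpec(np.ones(3), 100, Q_new), seed=33)
        model, ref_scores = pca.reference_pca(G_ref, k=3)
        proj = pca.project(model, G_new)
        # the unseen population forms its own cluster: every projected
        # sample sits farther from both reference-population centroids
        # than the typical within-cluster spread of the reference
        R = ref_scores.scores
        c0, c1 = R[:150].mean(axis=0), R[150:].mean(axis=0)
        within = np.linalg.norm(R[:150] - c0, axis=1).mean()
        d0 = np.linalg.norm(proj.scores - c0, axis=1)
        d1 = np.linalg.norm(proj.scores - c1, axis=1)
        assert np.minimum(d0, d1).min() > 2 * within


class TestShrinkage:
    def test_none_is_identity(self, two_pop_study):
        _, _, G = two_pop_study
        f = pca.estimate_shrinkage(G, k=4, method="none")
        np.testing.assert_array_equal(f, np.ones(4))

    def test_factors_at_least_one(self, two_pop_study):
        _, _, G = two_pop_study
        f = pca.estimate_shrinkage(G, k=4, method="jackknife", seed=0)
        assert np.all(f >= 1 - 1e-6)

    def test_factors_shrink_toward_one_with_n(self):
        panel = simulate.draw_ancestral_frequencies(400, 2, 0.2, seed=51)
        lead = []
        for n in (150, 600):
            admix = simulate.draw_admixture(n, [1.0, 1.0], seed=52)
            G = simulate.simulate_genotypes(panel, admix, seed=53)
            f = pca.estimate_shrinkage(G, k=1, method="jackknife", seed=0)
            lead.append(f[0])
        assert lead[1] <= lead[0] + 0.02


class TestJaccard:
    def test_identical_and_disjoint_profiles(self):
        n = 60
        rng = np.random.default_rng(61)
        # background rare variants so MAF < 0.01 threshold has content
        d = np.zeros((n, 300), dtype=np.int8)
        carriers = rng.integers(0, n, size=300)
        d[carriers, np.arange(300)] = 1
        d[0] = d[1]                      # identical profiles
        d[2] = 0                         # carries nothing
        G = toy_genotypes(d)
        J = pca.jaccard_matrix(G, rare_maf_max=0.05)
        assert J[0, 1] == pytest.approx(1.0)
        assert np.all(J[2, np.arange(n) != 2] == 0)

    def test_eigenvectors_match_dense_oracle(self):
        rng = np.random.default_rng(62)
        d = (rng.random((40, 500)) < 0.004).astype(np.int8)
        G = toy_genotypes(d)
        scores = pca.jaccard_pcs(G, rare_maf_max=0.05, k=3)
        J = pca.jaccard_matrix(G, rare_maf_max=0.05)
        row = J.mean(axis=1, keepdims=True)
        Jc = J - row - row.T + J.mean()
        w, V = np.linalg.eigh(Jc)
        top = V[:, np.argsort(w)[::-1][:3]]
        for j in range(3):
            c = abs(np.corrcoef(scores.scores[:, j], top[:, j])[0, 1])
            assert c > 1 - 1e-8
        np.testing.assert_allclose(scores.scores.std(axis=0), 1.0, atol=1e-8)


class TestAssignAncestry:
    def test_exact_centroid_and_tie(self):
        scores = pca.ScoreMatrix(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.0]]),
                                 ["a", "b", "c"])
        cents = {"P1": [0.0, 0.0], "P2": [1.0, 0.0]}
        labels = pca.assign_ancestry(scores, cents)
        assert labels == ["P1", "P2", "P1"]   # equidistant -> first label

    def test_simulation_recovers_populations(self):
        panel = simulate.draw_ancestral_frequencies(800, 3, 0.15, seed=71)
        Q = np.zeros((300, 3))
        for j in range(3):
            Q[j * 100:(j + 1) * 100, j] = 1.0
        G = simulate.simulate_genotypes(
            panel, simulate.AdmixtureSpec(np.ones(3), 300, Q), seed=72)
        _, scores = pca.reference_pca(G, k=2)
        truth = np.repeat([0, 1, 2], 100)
        cents = {str(j): scores.scores[truth == j].mean(axis=0)
                 for j in range(3)}
        labels = np.array([int(l) for l in
                           pca.assign_ancestry(scores, cents)])
        assert (labels == truth).mean() >= 0.95
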