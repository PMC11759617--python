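"""End-to-end study scenarios on synthetic two-cohort data.

These functions wire the full method together at realistic (but
single-machine) problem sizes: simulate two admixed cohorts with different
ancestry mixtures, build the reference PC space on the disease cohort,
project the biobank cohort into it, match by propensity-score
subclassification on the projected PCs, and run the covariate-adjusted
logistic scan.  They are the basis of the null-calibration and
stratification-control checks, and of the demonstration pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, matching, pca, qc, simulate
from .containers import GenotypeMatrix


@dataclass
class TwoCohortStudy:
    G_ref: GenotypeMatrix
    G_target: GenotypeMatrix
    sheet_ref: pd.DataFrame
    sheet_target: pd.DataFrame
    admix_ref: simulate.AdmixtureSpec
    admix_target: simulate.AdmixtureSpec
    panel: simulate.AncestralPanel
    pc_model: pca.PCModel = None
    scores_ref: pca.ScoreMatrix = None
    scores_target: pca.ScoreMatrix = None
    pruned: np.ndarray = None
    extras: dict = field(default_factory=dict)


def simulate_two_cohorts(seed: int, n_ref: int = 4000, n_target: int = 20000,
                         m: int = 50000, k_pops: int = 3, fst: float = 0.1,
                         alpha_ref=(8.0, 1.0, 1.0), alpha_target=(2.0, 5.0, 5.0),
                         target_ref_like_frac: float = 0.25,
                         phen_ref: simulate.PhenotypeSpec | None = None,
                         phen_target: simulate.PhenotypeSpec | None = None,
                         missing_rate: float = 0.0) -> TwoCohortStudy:
    """Two cohorts drawn from overlapping mixtures of the same ancestral
    populations, with divergent Dirichlet admixture parameters.

    The reference (disease) cohort leans toward the first ancestral
    population.  The target (biobank) cohort is a two-component mixture:
    a ``target_ref_like_frac`` subgroup drawn from the reference's
    admixture distribution — the subpopulation genetic matching is meant
    to recover — embedded in a majority dominated by the other ancestral
    populations.  This recreates a heterogeneous biobank that contains,
    but is not composed of, participants genetically similar to the
    disease cohort.
    """
    rng = np.random.default_rng(seed)
    panel = simulate.draw_ancestral_frequencies(m, k_pops, fst, seed=rng)
    admix_ref = simulate.draw_admixture(n_ref, alpha_ref[:k_pops], seed=rng)
    admix_target = simulate.draw_admixture(n_target, alpha_target[:k_pops], seed=rng)
    if target_ref_like_frac > 0:
        n_like = int(round(target_ref_like_frac * n_target))
        like = simulate.draw_admixture(n_like, alpha_ref[:k_pops], seed=rng)
        which = rng.permutation(n_target)[:n_like]
        admix_target.Q[which] = like.Q
    G_ref = simulate.simulate_genotypes(panel, admix_ref, missing_rate, seed=rng)
    G_target = simulate.simulate_genotypes(panel, admix_target, missing_rate, seed=rng)
    G_ref.samples = [f"R{i:06d}" for i in range(n_ref)]
    G_target.samples = [f"T{i:06d}" for i in range(n_target)]

    phen_ref = phen_ref or simulate.PhenotypeSpec()
    phen_target = phen_target or simulate.PhenotypeSpec()
    sheet_ref = simulate.simulate_phenotypes(G_ref, admix_ref, phen_ref,
                                             seed=rng, cohort="reference")
    sheet_target = simulate.simulate_phenotypes(G_target, admix_target,
                                                phen_target, seed=rng,
                                                cohort="target")
    return TwoCohortStudy(G_ref, G_target, sheet_ref, sheet_target,
                          admix_ref, admix_target, panel)


def build_pc_space(study: TwoCohortStudy, k: int = 20,
                   shrinkage: str = "jackknife",
                   prune_window_kb: float = 100.0, prune_r2: float = 0.1,
                   seed: int = 0) -> TwoCohortStudy:
    """Reference PCA on LD-pruned common variants; project the target."""
    pruned = pca.ld_prune(study.G_ref, window_kb=prune_window_kb,
                          r2_max=prune_r2, maf_min=0.01)
    model, scores_ref = pca.reference_pca(study.G_ref, pruned, k=k)
    model.shrinkage = pca.estimate_shrinkage(
        study.G_ref, pruned, k=model.k, method=shrinkage, seed=seed)
    scores_target = pca.project(model, study.G_target)
    study.pruned = pruned
    study.pc_model = model
    study.scores_ref = scores_ref
    study.scores_target = scores_target
    return study


def match_cohorts(study: TwoCohortStudy, include_age_sex: bool = False,
                  n_subclasses: int = 500,
                  weight_threshold: float = 1.0) -> matching.MatchResult:
    sheet = pd.concat([study.sheet_ref, study.sheet_target], ignore_index=True)
    scores = np.vstack([study.scores_ref.scores, study.scores_target.scores])
    return matching.run_matching(scores, sheet, "reference",
                                 include_age_sex=include_age_sex,
                                 n_subclasses=n_subclasses,
                                 weight_threshold=weight_threshold)


def matched_target_indices(study: TwoCohortStudy,
                           result: matching.MatchResult) -> np.ndarray:
    n_ref = study.G_ref.n_samples
    return np.flatnonzero(result.matched[n_ref:])


def scan_lambda(G: GenotypeMatrix, y: np.ndarray, covars: np.ndarray | None,
                min_mac: int = 20, firth: bool = True) -> tuple[float, pd.DataFrame]:
    """MAC-filter, logistic scan with Firth fallback, genomic lambda."""
    Gf, _ = qc.mac_privacy_filter(G, min_carriers=min_mac, min_mac=min_mac)
    rec = assoc.logistic_scan(Gf, y, covars)
    if firth:
        rec = assoc.firth_fallback_policy(rec, Gf, y, covars, min_mac=min_mac)
    p = rec.loc[rec["converged"], "p"].to_numpy()
    lam = assoc.genomic_lambda(p).lam
    return lam, rec


def null_calibration(seed: int, n_ref: int = 4000, n_target: int = 20000,
                     m: int = 50000, k_pcs: int = 20,
                     n_subclasses: int = 500) -> dict:
    """Null-phenotype calibration of the matched-cohort GWAS.

    Simulates the divergent two-cohort scenario with no true associations
    and no ancestry confounding, matches the target cohort to the
    reference on projected PCs, and scans the matched cohort with the PCs
    as covariates.  A well-calibrated pipeline gives lambda ~ 1.00.
    """
    study = simulate_two_cohorts(seed, n_ref=n_ref, n_target=n_target, m=m)
    build_pc_space(study, k=k_pcs, seed=seed)
    result = match_cohorts(study, n_subclasses=n_subclasses)
    idx = matched_target_indices(study, result)
    G_m = study.G_target.subset(sample_idx=idx)
    y = study.sheet_target["status"].to_numpy()[idx]
    covars = study.scores_target.scores[idx, :]
    lam, rec = scan_lambda(G_m, y, covars)
    return {
        "lambda": lam,
        "n_matched": int(len(idx)),
        "n_cases": int(y.sum()),
        "n_variants": int((rec["converged"]).sum()),
        "records": rec,
        "study": study,
        "match": result,
    }


def stratification_contrast(seed: int, n_ref: int = 4000,
                            n_target: int = 20000, m: int = 50000,
                            k_pcs: int = 20, n_subclasses: int = 500,
                            confound=(0.0, 1.0, -0.6)) -> dict:
    """Ancestry-confounded phenotype: pooled unmatched vs matched GWAS.

    The phenotype baseline risk differs by ancestral population
    (``confound`` log-odds through the admixture proportions) with no
    causal variants, so any association signal is pure stratification.
    The pooled two-cohort scan without ancestry adjustment should inflate
    (lambda > 1.05); matching plus PC adjustment should restore
    calibration.
    """
    phen = simulate.PhenotypeSpec(ancestry_confound=confound)
    study = simulate_two_cohorts(seed, n_ref=n_ref, n_target=n_target, m=m,
                                 phen_ref=phen, phen_target=phen)
    build_pc_space(study, k=k_pcs, seed=seed)

    # pooled, unmatched, no ancestry adjustment
    G_pool = GenotypeMatrix(
        np.vstack([study.G_ref.dosages, study.G_target.dosages]),
        study.G_ref.samples + study.G_target.samples,
        study.G_ref.variants)
    sheet = pd.concat([study.sheet_ref, study.sheet_target], ignore_index=True)
    y_pool = sheet["status"].to_numpy()
    base_covars = sheet[["age", "sex"]].to_numpy(dtype=float)
    lam_pooled, _ = scan_lambda(G_pool, y_pool, base_covars, firth=False)

    # matched target, PC-adjusted
    result = match_cohorts(study, n_subclasses=n_subclasses)
    idx = matched_target_indices(study, result)
    G_m = study.G_target.subset(sample_idx=idx)
    y_m = study.sheet_target["status"].to_numpy()[idx]
    covars_m = study.scores_target.scores[idx, :]
    lam_matched, _ = scan_lambda(G_m, y_m, covars_m)
    return {
        "lambda_pooled_unmatched": lam_pooled,
        "lambda_matched_adjusted": lam_matched,
        "n_matched": int(len(idx)),
    }
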