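"""Synthetic admixed case-control cohorts.

The generator produces the statistical structure the downstream analysis
assumes: K ancestral populations whose allele frequencies diverge from a
shared base frequency under the Balding-Nichols model, per-sample admixture
proportions drawn from cohort-specific Dirichlet distributions, binomial
genotypes from the admixed individual allele probabilities, and a
logistic-liability disease phenotype whose baseline risk may be confounded
with ancestry.  A noisy "by-proxy" affection status is modelled as symmetric
misclassification of the clinical status.

Variants are simulated independent (no linkage disequilibrium) by default;
:func:`add_ld_copy` duplicates a variant's draw with a small flip
probability to create crude LD for prune/clump testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import GenotypeMatrix, default_variant_table, new_sample_sheet

_EPS = 1e-4


class InvalidParameterError(ValueError):
    pass


class ModelInfeasibleError(RuntimeError):
    pass


@dataclass
class AncestralPanel:
    """Per-population allele frequencies around a shared base frequency."""

    n_pops: int
    base_freqs: np.ndarray          # (m,)
    fst: np.ndarray                 # (K,)
    pop_freqs: np.ndarray           # (K, m)


@dataclass
class AdmixtureSpec:
    """Admixture proportions for one cohort; rows of Q lie on the simplex."""

    dirichlet_alpha: np.ndarray
    n_samples: int
    Q: np.ndarray                   # (n, K)


@dataclass
class PhenotypeSpec:
    """Logistic-liability phenotype model.

    ``causal_variants`` maps variant index -> per-allele log-odds.
    ``ancestry_confound`` holds one log-odds offset per ancestral population,
    applied through the admixture proportions, which is what creates
    stratification when cohorts differ in admixture.  Proxy status applies
    ``proxy_sensitivity``/``proxy_specificity`` to the clinical label.
    """

    prevalence: float = 0.111
    causal_variants: dict = field(default_factory=dict)
    ancestry_confound: Sequence[float] | None = None
    age_effect: float = 0.0
    sex_effect: float = 0.0
    proxy_sensitivity: float = 1.0
    proxy_specificity: float = 1.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_ancestral_frequencies(m: int, k: int, fst, base_bounds=(0.05, 0.5),
                               seed=None) -> AncestralPanel:
    """Balding-Nichols differentiated allele frequencies.

    Base frequencies are Uniform(*base_bounds*); population ``j`` with
    differentiation ``F`` draws each variant frequency from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that ``E = p`` and
    ``Var = F p (1-p)``.  ``F = 0`` copies the base frequencies exactly.
    """
    if m < 1 or k < 1:
        raise InvalidParameterError("m and k must be >= 1")
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (k,)).copy()
    if np.any(fst < 0) or np.any(fst >= 1):
        raise InvalidParameterError("each fst must lie in [0, 1)")
    lo, hi = base_bounds
    if not (0 < lo < hi < 1):
        raise InvalidParameterError("base frequency bounds must lie inside (0, 1)")
    rng = _as_rng(seed)
    base = rng.uniform(lo, hi, size=m)
    pop = np.empty((k, m))
    for j in range(k):
        F = fst[j]
        if F == 0:
            pop[j] = base
        else:
            a = base * (1 - F) / F
            b = (1 - base) * (1 - F) / F
            pop[j] = rng.beta(a, b)
    np.clip(pop, _EPS, 1 - _EPS, out=pop)
    return AncestralPanel(n_pops=k, base_freqs=base, fst=fst, pop_freqs=pop)


def draw_admixture(n: int, alpha, seed=None) -> AdmixtureSpec:
    """Rows i.i.d. Dirichlet(alpha); every row sums to one."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise InvalidParameterError("Dirichlet parameters must be positive")
    rng = _as_rng(seed)
    Q = rng.dirichlet(alpha, size=n)
    return AdmixtureSpec(dirichlet_alpha=alpha, n_samples=n, Q=Q)


def simulate_genotypes(panel: AncestralPanel, admix: AdmixtureSpec,
                       missing_rate: float = 0.0, seed=None,
                       chunk: int = 2048) -> GenotypeMatrix:
    """Binomial(2, p_ij) dosages with p_ij = sum_k Q[i,k] pop_freqs[k,j]."""
    if admix.Q.shape[1] != panel.n_pops:
        raise InvalidParameterError("admixture and panel disagree on K")
    if not (0 <= missing_rate < 1):
        raise InvalidParameterError("missing_rate must lie in [0, 1)")
    rng = _as_rng(seed)
    n, m = admix.n_samples, panel.pop_freqs.shape[1]
    G = np.empty((n, m), dtype=np.int8)
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        P = admix.Q @ panel.pop_freqs[:, j0:j1]
        G[:, j0:j1] = rng.binomial(2, P).astype(np.int8)
        if missing_rate > 0:
            miss = rng.random((n, j1 - j0)) < missing_rate
            G[:, j0:j1][miss] = -1
    return GenotypeMatrix(G, variants=default_variant_table(m))


def add_ld_copy(G: GenotypeMatrix, src: int, dst: int, flip_prob: float = 0.0,
                seed=None) -> None:
    """Overwrite variant ``dst`` with a noisy copy of ``src`` (crude LD).

    Each allele of the copied genotype is flipped with probability
    ``flip_prob``; ``flip_prob = 0`` gives r^2 = 1.
    """
    rng = _as_rng(seed)
    g = G.dosages[:, src].astype(np.int16)
    if flip_prob > 0:
        flips = rng.binomial(1, flip_prob, size=(len(g), 2))
        up = (g < 2) & (flips[:, 0] == 1)
        down = (g > 0) & (flips[:, 1] == 1)
        g = g + up.astype(np.int16) - down.astype(np.int16)
    g[G.dosages[:, src] == -1] = -1
    G.dosages[:, dst] = np.clip(g, -1, 2).astype(np.int8)


def _liability(G: GenotypeMatrix, admix: AdmixtureSpec, spec: PhenotypeSpec,
               age_std: np.ndarray, sex: np.ndarray) -> np.ndarray:
    eta = np.zeros(G.n_samples)
    if spec.causal_variants:
        idx = np.array(sorted(spec.causal_variants), dtype=int)
        if idx.min() < 0 or idx.max() >= G.n_variants:
            raise InvalidParameterError("causal variant index out of range")
        betas = np.array([spec.causal_variants[i] for i in idx])
        D = G.subset(variant_idx=idx).imputed_dosages()
        eta += D @ betas
    if spec.ancestry_confound is not None:
        conf = np.asarray(spec.ancestry_confound, dtype=float)
        eta += admix.Q @ conf
    eta += spec.age_effect * age_std + spec.sex_effect * sex
    return eta


def simulate_phenotypes(G: GenotypeMatrix, admix: AdmixtureSpec,
                        spec: PhenotypeSpec, age_bounds=(55.0, 90.0),
                        seed=None, cohort: str = "cohort") -> pd.DataFrame:
    """Sample sheet with clinical and proxy affection status.

    The intercept of the liability is solved numerically so that the
    marginal case probability equals ``spec.prevalence``.
    """
    rng = _as_rng(seed)
    n = G.n_samples
    age = rng.uniform(age_bounds[0], age_bounds[1], size=n)
    sex = rng.integers(0, 2, size=n)
    sd = age.std()
    age_std = (age - age.mean()) / (sd if sd > 0 else 1.0)
    eta = _liability(G, admix, spec, age_std, sex)

    def marginal(b0):
        return expit(b0 + eta).mean() - spec.prevalence

    lo, hi = -50.0, 50.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ModelInfeasibleError("no intercept in [-50, 50] attains the prevalence")
    b0 = brentq(marginal, lo, hi, xtol=1e-12)
    p_case = expit(b0 + eta)
    clinical = (rng.random(n) < p_case).astype(int)

    sens, specif = spec.proxy_sensitivity, spec.proxy_specificity
    if not (0 < sens <= 1 and 0 < specif <= 1):
        raise InvalidParameterError("proxy sensitivity/specificity must lie in (0, 1]")
    u = rng.random(n)
    proxy = np.where(clinical == 1, (u < sens).astype(int),
                     (u >= specif).astype(int))

    sheet = new_sample_sheet(G.samples, cohort, clinical, "clinical", age, sex,
                             Q=admix.Q)
    sheet["proxy_status"] = proxy
    return sheet


# ---------------------------------------------------------------------------
# round-trip I/O: VCF v4.2 (GT only) + tab-delimited sample sheet
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_cohort(G: GenotypeMatrix, sheet: pd.DataFrame, vcf_path, sheet_path) -> None:
    """Write genotypes as uncompressed VCF v4.2 (GT field only) + TSV sheet."""
    var = G.variants
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pcmatch-simulate\n")
        for chrom in pd.unique(var["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        codes = np.array([_GT_CODE[0], _GT_CODE[1], _GT_CODE[2], _GT_CODE[-1]])
        idx = np.where(G.dosages < 0, 3, G.dosages)
        chroms = var["chrom"].astype(str).to_numpy()
        poss = var["pos"].to_numpy()
        ids = var["id"].astype(str).to_numpy()
        refs = var["ref"].astype(str).to_numpy()
        alts = var["alt"].astype(str).to_numpy()
        for j in range(G.n_variants):
            gts = "\t".join(codes[idx[:, j]])
            fh.write(f"{chroms[j]}\t{poss[j]}\t{ids[j]}\t{refs[j]}\t{alts[j]}"
                     f"\t.\t.\t.\tGT\t{gts}\n")
    sheet.to_csv(sheet_path, sep="\t", index=False)


def read_cohort(vcf_path, sheet_path):
    """Read a cohort back; rows are aligned to the sample-sheet order by id."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    rows = []
    meta = {"chrom": [], "pos": [], "id": [], "ref": [], "alt": []}
    for v in vcf:
        gt = np.asarray(v.genotype.array())[:, :2]
        dos = np.where((gt < 0).any(axis=1), -1, gt.clip(min=0).sum(axis=1))
        rows.append(dos.astype(np.int8))
        meta["chrom"].append(v.CHROM)
        meta["pos"].append(v.POS)
        meta["id"].append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        meta["ref"].append(v.REF)
        meta["alt"].append(v.ALT[0] if v.ALT else ".")
    vcf.close()
    if not rows:
        raise ValueError(f"{vcf_path}: no variant records")
    dosages = np.vstack(rows).T  # samples x variants
    variants = pd.DataFrame(meta)

    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str})
    missing = set(sheet["sample_id"]) - set(vcf_samples)
    if missing:
        raise ValueError(f"sample sheet ids absent from VCF: {sorted(missing)[:5]}")
    order = [vcf_samples.index(s) for s in sheet["sample_id"]]
    G = GenotypeMatrix(dosages[order, :], list(sheet["sample_id"]), variants)
    return G, sheet
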