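"""Sample- and variant-level quality control.

The filter cascade mirrors the order used in large sequencing studies:
technical replicates -> sample missingness -> HET/HOM-ratio outliers ->
relatedness (KING-robust kinship) -> PC outliers -> variant missingness ->
minor-allele-count / carrier ("privacy") filters -> Hardy-Weinberg exact
mid-p.  Each removal carries exactly one primary reason code and is logged
in a :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix

SAMPLE_REASONS = ("replicate", "missingness", "het_hom", "related", "pc_outlier")
VARIANT_REASONS = ("missingness", "mac", "privacy", "hwe")


@dataclass
class QCReport:
    removed_samples: pd.DataFrame = None
    removed_variants: pd.DataFrame = None
    thresholds: dict = field(default_factory=dict)
    order: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if self.removed_samples is None:
            self.removed_samples = pd.DataFrame(columns=["sample_id", "reason"])
        if self.removed_variants is None:
            self.removed_variants = pd.DataFrame(columns=["variant_id", "reason"])

    def log_samples(self, ids, reason):
        if len(ids):
            add = pd.DataFrame({"sample_id": list(ids), "reason": reason})
            self.removed_samples = pd.concat(
                [self.removed_samples, add], ignore_index=True)
        self.order.append(f"sample:{reason}")

    def log_variants(self, ids, reason):
        if len(ids):
            add = pd.DataFrame({"variant_id": list(ids), "reason": reason})
            self.removed_variants = pd.concat(
                [self.removed_variants, add], ignore_index=True)
        self.order.append(f"variant:{reason}")

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            pd.concat([self.removed_samples, other.removed_samples],
                      ignore_index=True),
            pd.concat([self.removed_variants, other.removed_variants],
                      ignore_index=True),
            {**self.thresholds, **other.thresholds},
            self.order + other.order,
            self.notes + other.notes,
        )

    def to_tsv(self, path):
        rows = [
            {"axis": "sample", "id": r.sample_id, "reason": r.reason}
            for r in self.removed_samples.itertuples()
        ] + [
            {"axis": "variant", "id": r.variant_id, "reason": r.reason}
            for r in self.removed_variants.itertuples()
        ]
        pd.DataFrame(rows, columns=["axis", "id", "reason"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# missingness filters (strict inequality: exactly-at-threshold is retained)
# ---------------------------------------------------------------------------

def filter_variant_missingness(G: GenotypeMatrix, max_miss: float = 0.10):
    if not (0 <= max_miss < 1):
        raise ValueError("max_miss must lie in [0, 1)")
    frac = G.missing_mask().mean(axis=0)
    drop = frac > max_miss
    rep = QCReport(thresholds={"variant_max_miss": max_miss})
    rep.log_variants(G.variants.loc[drop, "id"], "missingness")
    return G.subset(variant_idx=np.flatnonzero(~drop)), rep


def filter_sample_missingness(G: GenotypeMatrix, max_miss: float = 0.05):
    if not (0 <= max_miss < 1):
        raise ValueError("max_miss must lie in [0, 1)")
    frac = G.missing_mask().mean(axis=1)
    drop = frac > max_miss
    rep = QCReport(thresholds={"sample_max_miss": max_miss})
    rep.log_samples([G.samples[i] for i in np.flatnonzero(drop)], "missingness")
    return G.subset(sample_idx=np.flatnonzero(~drop)), rep


def drop_replicates(G: GenotypeMatrix, replicate_of: dict):
    """Keep, within each replicate group, the sample with fewest missing calls.

    ``replicate_of`` maps sample_id -> group key; samples absent from the map
    are singletons.  Replicate identity is metadata accepted as input, not
    inferred from genotypes.
    """
    miss = G.missing_mask().sum(axis=1)
    groups: dict = {}
    for i, s in enumerate(G.samples):
        groups.setdefault(replicate_of.get(s, s), []).append(i)
    keep = []
    for members in groups.values():
        best = min(members, key=lambda i: (miss[i], G.samples[i]))
        keep.append(best)
    keep = sorted(keep)
    dropped = sorted(set(range(G.n_samples)) - set(keep))
    rep = QCReport()
    rep.log_samples([G.samples[i] for i in dropped], "replicate")
    return G.subset(sample_idx=keep), rep


# ---------------------------------------------------------------------------
# HET/HOM outliers
# ---------------------------------------------------------------------------

def het_hom_outliers(G: GenotypeMatrix, n_sd: float = 6.0):
    """Remove samples whose het / non-ref-hom call ratio is > n_sd SDs from
    the cohort mean.  A denominator floor of one call avoids division by
    zero; all-homozygous-reference samples are flagged in the report."""
    if G.n_samples < 3:
        raise ValueError("need at least 3 samples")
    het = (G.dosages == 1).sum(axis=1)
    hom_alt = (G.dosages == 2).sum(axis=1)
    ratio = het / np.maximum(hom_alt, 1)
    mu, sd = ratio.mean(), ratio.std()
    drop = np.abs(ratio - mu) > n_sd * sd if sd > 0 else np.zeros(len(ratio), bool)
    rep = QCReport(thresholds={"het_hom_n_sd": n_sd})
    floored = np.flatnonzero(hom_alt == 0)
    if len(floored):
        rep.notes.append(
            f"{len(floored)} samples with zero non-reference homozygous calls; "
            "ratio denominator floored at 1")
    rep.log_samples([G.samples[i] for i in np.flatnonzero(drop)], "het_hom")
    return G.subset(sample_idx=np.flatnonzero(~drop)), rep


# ---------------------------------------------------------------------------
# KING-robust kinship and relatedness pruning
# ---------------------------------------------------------------------------

def king_kinship(G: GenotypeMatrix, pairs=None, min_overlap: int = 100) -> pd.DataFrame:
    """KING-robust between-family kinship estimates.

    For samples i, j over mutually non-missing variants, with N_Aa,Aa the
    double-heterozygote count, N_AA,aa the opposite-homozygote count and
    N_Aa^(i) sample i's heterozygote count on the shared sites,

        phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa^(i) + N_Aa^(j)).

    Duplicates give phi ~ 0.5, parent-offspring ~ 0.25, unrelated ~ 0.
    Pairs with fewer than ``min_overlap`` shared calls are skipped.
    """
    D = G.dosages
    H = (D == 1)
    A = (D == 2)
    R = (D == 0)
    V = (D != -1)
    Hf = H.astype(np.float32)
    if pairs is None:
        # all pairs via matrix products
        opp = R.astype(np.float32) @ A.astype(np.float32).T
        opp = opp + opp.T
        hethet = Hf @ Hf.T
        het_shared = Hf @ V.astype(np.float32).T   # [i, j] = i's hets valid in j
        overlap = V.astype(np.float32) @ V.astype(np.float32).T
        rows = []
        n = G.n_samples
        for i in range(n):
            for j in range(i + 1, n):
                if overlap[i, j] < min_overlap:
                    continue
                denom = het_shared[i, j] + het_shared[j, i]
                phi = (hethet[i, j] - 2 * opp[i, j]) / denom if denom > 0 else 0.0
                rows.append((G.samples[i], G.samples[j], float(phi),
                             int(overlap[i, j])))
        return pd.DataFrame(rows, columns=["id1", "id2", "phi", "n_overlap"])
    rows = []
    index = {s: i for i, s in enumerate(G.samples)}
    for a, b in pairs:
        i, j = index[a], index[b]
        shared = V[i] & V[j]
        if shared.sum() < min_overlap:
            continue
        hh = np.count_nonzero(H[i] & H[j] & shared)
        oo = np.count_nonzero((R[i] & A[j] & shared) | (A[i] & R[j] & shared))
        hi = np.count_nonzero(H[i] & shared)
        hj = np.count_nonzero(H[j] & shared)
        denom = hi + hj
        phi = (hh - 2 * oo) / denom if denom > 0 else 0.0
        rows.append((a, b, float(phi), int(shared.sum())))
    return pd.DataFrame(rows, columns=["id1", "id2", "phi", "n_overlap"])


def remove_related(table: pd.DataFrame, G: GenotypeMatrix,
                   threshold: float = 0.0884):
    """Greedy cover of the relatedness graph at ``phi >= threshold``.

    Iteratively drop the sample in the most remaining related pairs; ties
    are broken by higher genotype missingness, then lexicographic id.  The
    default threshold 0.0884 (= 2^-3.5) is the conventional boundary for
    second-degree relatives.
    """
    edges = table[table["phi"] >= threshold][["id1", "id2"]].values.tolist()
    miss = dict(zip(G.samples, G.missing_mask().mean(axis=1)))
    removed = []
    while edges:
        degree: dict = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        worst = max(degree,
                    key=lambda s: (degree[s], miss.get(s, 0.0), [-ord(c) for c in s]))
        # tie-break: max degree, then max missingness, then smallest id
        removed.append(worst)
        edges = [e for e in edges if worst not in e]
    rep = QCReport(thresholds={"kinship_threshold": threshold})
    rep.log_samples(removed, "related")
    keep = [i for i, s in enumerate(G.samples) if s not in set(removed)]
    return G.subset(sample_idx=keep), rep


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test with mid-p correction
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _het_distribution(n: int, n_minor: int):
    """Exact probabilities of every heterozygote count compatible with
    ``n`` diploid genotypes carrying ``n_minor`` minor alleles.

    Computed directly from the log-gamma form of the conditional
    distribution P(n_het | n, n_minor) under Hardy-Weinberg.
    """
    parity = n_minor % 2
    h = np.arange(parity, min(n_minor, 2 * n - n_minor) + 1, 2)
    n_hom_minor = (n_minor - h) // 2
    n_hom_major = n - h - n_hom_minor
    n_major = 2 * n - n_minor
    logp = (
        gammaln(n + 1)
        - gammaln(h + 1) - gammaln(n_hom_minor + 1) - gammaln(n_hom_major + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1)
    )
    p = np.exp(logp)
    return h, p / p.sum()


def hwe_midp(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test mid-p value.

    Enumerates every heterozygote count compatible with the observed allele
    counts; the mid-p value sums the probabilities of strictly less probable
    tables plus half the probability of equally probable tables (the
    observed one included).  Monomorphic variants return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("counts must be nonnegative with positive total")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    h, p = _het_distribution(n, n_minor)
    p_obs = p[np.searchsorted(h, n_Aa)]
    tol = 1e-12 * p_obs
    midp = p[p < p_obs - tol].sum() + 0.5 * p[np.abs(p - p_obs) <= tol].sum()
    return float(min(midp, 1.0))


def hwe_filter(G: GenotypeMatrix, min_midp: float = 1e-15):
    """Drop variants whose HWE mid-p is <= ``min_midp``."""
    drop = []
    for j in range(G.n_variants):
        col = G.dosages[:, j]
        n_AA = int(np.count_nonzero(col == 0))
        n_Aa = int(np.count_nonzero(col == 1))
        n_aa = int(np.count_nonzero(col == 2))
        if n_AA + n_Aa + n_aa == 0:
            continue
        if hwe_midp(n_AA, n_Aa, n_aa) <= min_midp:
            drop.append(j)
    rep = QCReport(thresholds={"hwe_min_midp": min_midp})
    rep.log_variants(G.variants.iloc[drop]["id"], "hwe")
    keep = sorted(set(range(G.n_variants)) - set(drop))
    return G.subset(variant_idx=keep), rep


# ---------------------------------------------------------------------------
# MAC / carrier-count ("privacy") filter
# ---------------------------------------------------------------------------

def mac_privacy_filter(G: GenotypeMatrix, min_carriers: int = 20,
                       min_mac: int = 20):
    """Drop variants carried by fewer than ``min_carriers`` individuals or
    with minor-allele count below ``min_mac`` (both inclusive keeps)."""
    ok = G.dosages != -1
    alt = np.where(ok, G.dosages, 0)
    freq = G.alt_allele_freq()
    minor_is_alt = np.nan_to_num(freq, nan=0.0) <= 0.5
    carriers_alt = (alt >= 1).sum(axis=0)
    carriers_ref = ((G.dosages <= 1) & ok).sum(axis=0)
    carriers = np.where(minor_is_alt, carriers_alt, carriers_ref)
    mac = G.minor_allele_count()
    drop_mac = mac < min_mac
    drop_priv = (carriers < min_carriers) & ~drop_mac
    rep = QCReport(thresholds={"min_carriers": min_carriers, "min_mac": min_mac})
    rep.log_variants(G.variants.loc[drop_mac, "id"], "mac")
    rep.log_variants(G.variants.loc[drop_priv, "id"], "privacy")
    keep = np.flatnonzero(~(drop_mac | drop_priv))
    return G.subset(variant_idx=keep), rep


# ---------------------------------------------------------------------------
# PC outliers
# ---------------------------------------------------------------------------

def pc_outlier_mask(scores: np.ndarray, n_sd: float = 6.0,
                    n_pcs: int = 10) -> np.ndarray:
    """True for samples to KEEP: within n_sd SDs of the mean on every one of
    the top ``n_pcs`` components."""
    S = np.asarray(scores)[:, : n_pcs]
    mu = S.mean(axis=0)
    sd = S.std(axis=0)
    sd[sd == 0] = np.inf
    return (np.abs(S - mu) <= n_sd * sd).all(axis=1)


def pc_outlier_filter(G: GenotypeMatrix, scores: np.ndarray, n_sd: float = 6.0,
                      n_pcs: int = 10):
    keep = pc_outlier_mask(scores, n_sd=n_sd, n_pcs=n_pcs)
    rep = QCReport(thresholds={"pc_n_sd": n_sd, "pc_n_pcs": n_pcs})
    rep.log_samples([G.samples[i] for i in np.flatnonzero(~keep)], "pc_outlier")
    return G.subset(sample_idx=np.flatnonzero(keep)), rep
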