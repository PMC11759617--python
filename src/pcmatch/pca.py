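"""Reference-cohort PCA and projection of external cohorts.

The reference cohort defines the coordinate system: dosages are
standardized as ``(g - 2 p_j) / sqrt(2 p_j (1 - p_j))`` with allele
frequencies ``p_j`` estimated in the reference, a truncated SVD yields
loadings and singular values, and a second cohort is placed in the same
space by least-squares projection of its dosages standardized *with the
reference frequencies*.  Out-of-sample projection contracts scores toward
the origin; per-component jackknife factors estimated on held-out
reference samples correct that shrinkage.

Also here: sliding-window LD pruning, principal components of the rare-
variant Jaccard similarity matrix, and nearest-centroid ancestry labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

from .containers import GenotypeMatrix


class ProjectionSpaceError(RuntimeError):
    """Target cohort does not cover enough of the model's variant list."""


@dataclass
class PCModel:
    variants: pd.DataFrame          # chrom, pos, id of the pruned common set
    freqs: np.ndarray               # reference standardization frequencies p_j
    loadings: np.ndarray            # (m, k), orthonormal columns
    singular_values: np.ndarray     # (k,)
    shrinkage: np.ndarray = None    # (k,), >= 1
    k: int = 20

    def __post_init__(self):
        if self.shrinkage is None:
            self.shrinkage = np.ones(self.k)

    # serialization: a directory of text files
    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tab = self.variants.copy()
        tab["freq"] = self.freqs
        for j in range(self.k):
            tab[f"loading{j + 1}"] = self.loadings[:, j]
        tab.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        meta = {
            "k": int(self.k),
            "singular_values": self.singular_values.tolist(),
            "shrinkage": self.shrinkage.tolist(),
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, indir):
        indir = Path(indir)
        tab = pd.read_csv(indir / "variants.tsv", sep="\t")
        meta = json.loads((indir / "meta.json").read_text())
        k = meta["k"]
        cols = [f"loading{j + 1}" for j in range(k)]
        return cls(
            variants=tab[["chrom", "pos", "id"]].copy(),
            freqs=tab["freq"].to_numpy(),
            loadings=tab[cols].to_numpy(),
            singular_values=np.array(meta["singular_values"]),
            shrinkage=np.array(meta["shrinkage"]),
            k=k,
        )


@dataclass
class ScoreMatrix:
    scores: np.ndarray              # (n, k)
    samples: list
    provenance: str = "reference"   # or "projected"

    @property
    def k(self):
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{j + 1}" for j in range(self.k)])
        df.insert(0, "sample_id", self.samples)
        return df


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(G: GenotypeMatrix, window_kb: float = 100.0, r2_max: float = 0.1,
             maf_min: float = 0.01) -> np.ndarray:
    """Greedy left-to-right sliding-window prune.

    Variants below ``maf_min`` are excluded up front.  Scanning by position,
    each candidate is compared with the already-kept variants inside the
    window; any pair with squared dosage correlation above ``r2_max`` loses
    its lower-MAF member.  Returns the kept variant indices (into G).
    """
    maf = G.maf()
    pos = G.variants["pos"].to_numpy()
    if not np.all(np.diff(pos) >= 0):
        raise ValueError("variants must be sorted by position")
    cand = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    if len(cand) == 0:
        return cand
    X = G.subset(variant_idx=cand).imputed_dosages(dtype=np.float32)
    X -= X.mean(axis=0)
    norms = np.sqrt((X ** 2).sum(axis=0))
    norms[norms == 0] = np.inf
    X /= norms
    window = window_kb * 1000.0
    cpos = pos[cand].astype(float)

    # pass 1: all conflicting pairs (r^2 > r2_max within the window),
    # found with blocked matrix products
    conflicts: dict[int, list[int]] = {}
    nc = len(cand)
    block = 512
    for a in range(0, nc, block):
        b = min(a + block, nc)
        hi = int(np.searchsorted(cpos, cpos[b - 1] + window, side="right"))
        R2 = (X[:, a:b].T @ X[:, a:hi]) ** 2
        ii, jj = np.nonzero(R2 > r2_max)
        jj = jj + a
        ii = ii + a
        ok = (jj > ii) & (cpos[jj] - cpos[ii] <= window)
        for i, j in zip(ii[ok], jj[ok]):
            conflicts.setdefault(int(j), []).append(int(i))

    # pass 2: deterministic left-to-right greedy on the conflict graph;
    # the lower-MAF member of a pair loses, the earlier variant wins ties
    alive_mask = np.ones(nc, dtype=bool)
    for i in range(nc):
        for j in conflicts.get(i, ()):
            if not alive_mask[j]:
                continue
            if maf[cand[i]] <= maf[cand[j]]:
                alive_mask[i] = False
                break
            alive_mask[j] = False
    # removing an earlier keeper cannot resurrect variants already dropped
    # against it; the scan is single-pass and deterministic.
    return cand[alive_mask]


# ---------------------------------------------------------------------------
# reference PCA and projection
# ---------------------------------------------------------------------------

def _standardize(dosages_f: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Center to 2p and scale by sqrt(2 p (1-p)), IN PLACE (the input is
    always a freshly materialized float matrix)."""
    freqs = freqs.astype(dosages_f.dtype, copy=False)
    dosages_f -= 2.0 * freqs
    dosages_f /= np.sqrt(2.0 * freqs * (1.0 - freqs))
    return dosages_f


def _fix_signs(loadings: np.ndarray):
    """Largest-magnitude loading of each component is made positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs, signs


def reference_pca(G_ref: GenotypeMatrix, variant_idx=None, k: int = 20):
    """Fit the reference PC model and return (PCModel, ScoreMatrix).

    When variants outnumber samples (the usual case) the truncated SVD is
    obtained from the sample-by-sample Gram matrix ``Z Z^T``: its top
    eigenpairs give the scores directly and the loadings follow as
    ``Z^T U / s``, which costs one dense symmetric product instead of a
    long Lanczos iteration over the genotype matrix.
    """
    if variant_idx is not None:
        G_ref = G_ref.subset(variant_idx=variant_idx)
    n, m = G_ref.n_samples, G_ref.n_variants
    if n < k + 1:
        raise ValueError("need at least k+1 reference samples")
    freqs = np.clip(G_ref.alt_allele_freq(), 1e-6, 1 - 1e-6)
    Z = _standardize(G_ref.imputed_dosages(), freqs)
    k_eff = min(k, min(n, m) - 1)
    if m >= n:
        from scipy.linalg import eigh as dense_eigh
        K = Z @ Z.T
        K = (K + K.T) / 2
        w, U = dense_eigh(K, subset_by_index=[n - k_eff, n - 1])
        order = np.argsort(w)[::-1]
        s = np.sqrt(np.maximum(w[order], 1e-30))
        U = U[:, order]
        V = (Z.T @ U) / s
    else:
        v0 = np.full(min(Z.shape), 1.0 / np.sqrt(min(Z.shape)))
        U, s, Vt = svds(Z, k=k_eff, v0=v0)
        order = np.argsort(s)[::-1]
        s = s[order]
        V = Vt[order].T
    V, signs = _fix_signs(V)
    model = PCModel(
        variants=G_ref.variants[["chrom", "pos", "id"]].copy(),
        freqs=freqs, loadings=V, singular_values=s, k=k_eff)
    scores = Z @ V
    return model, ScoreMatrix(scores, list(G_ref.samples), "reference")


def project(model: PCModel, G_target: GenotypeMatrix,
            max_absent: float = 0.20, chunk: int = 1024) -> ScoreMatrix:
    """Least-squares projection of a target cohort into the reference space.

    Target dosages are standardized with the *model's* reference
    frequencies; variants absent from the target (or missing calls) are
    imputed to the reference mean dosage ``2 p_j`` and therefore contribute
    zero in standardized space.  Scores are scaled per component by the
    model's shrinkage factors.
    """
    id_to_col = {v: i for i, v in enumerate(G_target.variants["id"])}
    cols = np.array([id_to_col.get(v, -1) for v in model.variants["id"]])
    absent = cols < 0
    if absent.mean() > max_absent:
        raise ProjectionSpaceError(
            f"{absent.mean():.0%} of model variants absent from target "
            f"(limit {max_absent:.0%}); PC space not comparable")
    n = G_target.n_samples
    k = model.k
    scores = np.zeros((n, k))
    present = np.flatnonzero(~absent)
    mean = 2.0 * model.freqs[present]
    denom = np.sqrt(2.0 * model.freqs[present]
                    * (1.0 - model.freqs[present]))
    loadings = model.loadings[present, :]
    take = cols[present]
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        D = G_target.dosages[i0:i1].take(take, axis=1).astype(np.float64)
        miss = D < 0
        if miss.any():
            D[miss] = np.broadcast_to(mean, D.shape)[miss]
        Z = (D - mean) / denom
        scores[i0:i1] = Z @ loadings
    scores *= model.shrinkage
    return ScoreMatrix(scores, list(G_target.samples), "projected")


def estimate_shrinkage(G_ref: GenotypeMatrix, variant_idx=None, k: int = 20,
                       method: str = "jackknife", n_folds: int = 10,
                       seed: int = 0) -> np.ndarray:
    """Per-component projection-shrinkage correction factors.

    ``none`` returns ones.  ``jackknife`` splits the reference cohort into
    folds; each fold is projected with a model fit on the remaining
    samples, and the factor for a component is the ratio of the mean
    in-sample score magnitude (full-reference model) to the mean projected
    magnitude over held-out samples, pooled over folds and floored at 1.

    Implementation note: everything is derived from the sample-by-sample
    Gram matrix of the standardized dosages, so the fold models cost a
    dense eigendecomposition each instead of a fresh pass over genotypes.
    Held-out projections onto a fold model are
    ``K[held, train] @ U_train / s_train``.
    """
    if method == "none":
        return np.ones(k)
    if method != "jackknife":
        raise ValueError(f"unknown shrinkage method {method!r}")
    if variant_idx is not None:
        G_ref = G_ref.subset(variant_idx=variant_idx)
    n = G_ref.n_samples
    freqs = np.clip(G_ref.alt_allele_freq(), 1e-6, 1 - 1e-6)
    Z = _standardize(G_ref.imputed_dosages(dtype=np.float32), freqs)
    K = (Z @ Z.T).astype(np.float64)
    del Z
    K = (K + K.T) / 2

    from scipy.linalg import eigh as dense_eigh

    def top_eig(Kmat, kk):
        nn = Kmat.shape[0]
        w, U = dense_eigh(Kmat, subset_by_index=[nn - kk, nn - 1])
        order = np.argsort(w)[::-1]
        return np.sqrt(np.maximum(w[order], 1e-12)), U[:, order]

    s_full, U_full = top_eig(K, min(k, n - 1))
    k = len(s_full)
    full_scores = U_full * s_full            # in-sample scores

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    num = np.zeros(k)
    den = np.zeros(k)
    for fold in folds:
        if len(fold) == 0:
            continue
        train = np.setdiff1d(np.arange(n), fold)
        s_t, U_t = top_eig(K[np.ix_(train, train)], k)
        if len(s_t) < k:
            continue
        proj = K[np.ix_(fold, train)] @ U_t / s_t
        # align fold components to full components via train-sample scores
        C = U_t.T @ U_full[train, :]
        aligned = np.zeros((len(fold), k))
        for j in range(k):
            src = int(np.argmax(np.abs(C[:, j])))
            aligned[:, j] = np.sign(C[src, j]) * proj[:, src]
        num += np.abs(full_scores[fold, :]).sum(axis=0)
        den += np.abs(aligned).sum(axis=0)
    den[den == 0] = np.inf
    factors = num / den
    return np.maximum(factors, 1.0)


# ---------------------------------------------------------------------------
# Jaccard PCs on rare variants
# ---------------------------------------------------------------------------

def jaccard_matrix(G: GenotypeMatrix, rare_maf_max: float = 0.01) -> np.ndarray:
    """Pairwise Jaccard similarity of rare-minor-allele carrier profiles."""
    maf = np.nan_to_num(G.maf())
    rare = np.flatnonzero((maf > 0) & (maf < rare_maf_max))
    if len(rare) == 0:
        raise ValueError("no rare variants below the MAF threshold")
    sub = G.subset(variant_idx=rare)
    freq = np.nan_to_num(sub.alt_allele_freq())
    minor_is_alt = freq <= 0.5
    d = sub.dosages
    carrier = np.where(minor_is_alt, (d >= 1) & (d != -1), d <= 1)
    C = carrier.astype(np.float32)
    inter = C @ C.T
    counts = C.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union == 0, 1, union), 0.0)
    np.fill_diagonal(J, 1.0)
    return J


def jaccard_pcs(G: GenotypeMatrix, rare_maf_max: float = 0.01,
                k: int = 5) -> ScoreMatrix:
    """Top-k eigenvectors of the double-centered Jaccard matrix, scaled to
    unit variance."""
    J = jaccard_matrix(G, rare_maf_max)
    n = J.shape[0]
    row = J.mean(axis=1, keepdims=True)
    Jc = J - row - row.T + J.mean()
    w, V = np.linalg.eigh(Jc.astype(np.float64))
    order = np.argsort(w)[::-1][:k]
    V = V[:, order]
    V, _ = _fix_signs(V)
    sd = V.std(axis=0)
    sd[sd == 0] = 1.0
    return ScoreMatrix(V / sd, list(G.samples), "reference")


# ---------------------------------------------------------------------------
# nearest-centroid ancestry labels
# ---------------------------------------------------------------------------

def assign_ancestry(scores: ScoreMatrix, centroids: dict) -> list:
    """Euclidean nearest-centroid label per sample.

    ``centroids`` maps label -> k-vector; distance ties go to the label
    listed first.
    """
    labels = list(centroids)
    M = np.array([np.asarray(centroids[l], dtype=float) for l in labels])
    if M.shape[1] != scores.k:
        raise ValueError("centroid dimension does not match score dimension")
    d2 = ((scores.scores[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)   # argmin takes the first minimum: tie rule
    return [labels[i] for i in best]
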