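"""Core in-memory containers shared by every pipeline stage.

Genotypes are kept as a dense ``samples x variants`` dosage matrix of the
alternate-allele count {0, 1, 2}, with -1 marking a missing call.  Variant
metadata travels alongside as a :class:`pandas.DataFrame`; sample phenotype
metadata is a plain DataFrame (the "sample sheet") keyed by ``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns every sample sheet carries
SHEET_COLUMNS = ["sample_id", "cohort", "status", "status_type", "age", "sex"]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` int8 array of alternate-allele counts,
        ``-1`` for missing.
    samples
        Sample identifiers, one per row.
    variants
        DataFrame with at least ``chrom, pos, id, ref, alt``.
    """

    dosages: np.ndarray
    samples: list = field(default_factory=list)
    variants: pd.DataFrame = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.variants is None:
            m = self.dosages.shape[1]
            self.variants = default_variant_table(m)
        self.samples = list(self.samples) or [
            f"S{i:06d}" for i in range(self.dosages.shape[0])
        ]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample count does not match dosage rows")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant count does not match dosage columns")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    # -- per-variant summaries ------------------------------------------
    def call_counts(self) -> np.ndarray:
        """Number of non-missing calls per variant."""
        return (self.dosages != MISSING).sum(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        ok = self.dosages != MISSING
        alt = np.where(ok, self.dosages, 0).sum(axis=0, dtype=np.int64)
        n = 2 * ok.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def minor_allele_count(self) -> np.ndarray:
        ok = self.dosages != MISSING
        alt = np.where(ok, self.dosages, 0).sum(axis=0, dtype=np.int64)
        tot = 2 * ok.sum(axis=0, dtype=np.int64)
        return np.minimum(alt, tot - alt)

    # -- transformations ------------------------------------------------
    def imputed_dosages(self, dtype=np.float64) -> np.ndarray:
        """Float dosage matrix with missing entries set to the variant mean."""
        ok = self.dosages != MISSING
        X = self.dosages.astype(dtype)
        freq = self.alt_allele_freq()
        mean = 2.0 * np.nan_to_num(freq, nan=0.0)
        miss_r, miss_c = np.nonzero(~ok)
        X[miss_r, miss_c] = mean[miss_c]
        return X

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            variants = variants.iloc[variant_idx].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), samples, variants.copy())

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample id {e} not present in genotype matrix")


def default_variant_table(m: int, chrom: str = "1", spacing: int = 1000,
                          start: int = 1) -> pd.DataFrame:
    """Synthetic variant metadata: one chromosome, fixed spacing, 1-based."""
    pos = start + spacing * np.arange(m)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"var{i:07d}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )


def new_sample_sheet(sample_ids, cohort, status, status_type, age, sex,
                     Q=None) -> pd.DataFrame:
    sheet = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "cohort": cohort,
            "status": np.asarray(status, dtype=int),
            "status_type": status_type,
            "age": np.asarray(age, dtype=float),
            "sex": np.asarray(sex, dtype=int),
        }
    )
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        for k in range(Q.shape[1]):
            sheet[f"Q{k + 1}"] = Q[:, k]
    return sheet
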