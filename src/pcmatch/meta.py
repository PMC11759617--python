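"""Fixed-effect inverse-variance meta-analysis with post-filters and clumping.

Per-study summary statistics are harmonized on variant id and effect
allele (flipping sign and frequency when alleles are swapped), combined
with inverse-squared-standard-error weights, and annotated with a
direction string, the cross-study degrees of freedom (number of
contributing studies minus one) and the allele-frequency amplitude
``max_eaf - min_eaf`` used to flag harmonization problems.  Post-filters
reproduce a conservative biobank meta-analysis: amplitude strictly below
0.4, variants present in every cohort (df = 1 for two studies), and a
per-population Hardy-Weinberg mid-p gate.  Significant variants are
grouped into loci by greedy LD clumping around lead (lowest-p) variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .qc import hwe_midp

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _harmonize(study: pd.DataFrame, ref_alleles: pd.DataFrame,
               ambiguous_policy: str = "freq") -> pd.DataFrame:
    """Align one study's records to reference effect/other alleles.

    Swapped alleles flip ``beta`` and ``eaf``.  Strand-ambiguous pairs
    (A/T, C/G) are kept only when the frequency clearly identifies the
    allele (|eaf - 0.5| > 0.1 in both the study and the reference record);
    unresolvable rows are dropped.
    """
    s = study.merge(ref_alleles, on="id", suffixes=("", "_ref"))
    ea = s["effect_allele"].str.upper()
    oa = s["other_allele"].str.upper()
    ea_r = s["effect_allele_ref"].str.upper()
    oa_r = s["other_allele_ref"].str.upper()
    same = (ea == ea_r) & (oa == oa_r)
    swapped = (ea == oa_r) & (oa == ea_r)
    ambiguous = [
        (a, b) in _AMBIGUOUS for a, b in zip(ea, oa)
    ]
    ambiguous = pd.Series(ambiguous, index=s.index)
    keep = (same | swapped) & ~ambiguous
    if ambiguous_policy == "freq":
        informative = ((s["eaf"] - 0.5).abs() > 0.1) & \
            ((s["eaf_ref"] - 0.5).abs() > 0.1)
        # frequency-resolvable ambiguous rows: orientation chosen so the
        # frequencies agree
        amb_ok = ambiguous & informative
        amb_same = amb_ok & ~(((s["eaf"] > 0.5) ^ (s["eaf_ref"] > 0.5)))
        amb_swap = amb_ok & (((s["eaf"] > 0.5) ^ (s["eaf_ref"] > 0.5)))
        same = same & ~ambiguous | amb_same
        swapped = swapped & ~ambiguous | amb_swap
        keep = same | swapped
    out = s[keep].copy()
    flip = swapped[keep]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    out["effect_allele"] = out["effect_allele_ref"]
    out["other_allele"] = out["other_allele_ref"]
    return out.drop(columns=[c for c in out.columns if c.endswith("_ref")])


def ivw_meta(studies: list[pd.DataFrame], ambiguous_policy: str = "freq") -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    Records are aligned on variant id with the first study carrying a
    variant defining the reference alleles.  Output columns: id, chrom,
    pos, effect_allele, other_allele, beta, se, p, direction, df,
    avg_eaf, min_eaf, max_eaf, freq_amplitude, n.
    """
    if not studies:
        raise ValueError("need at least one study")
    allele_cols = ["id", "effect_allele", "other_allele"]
    ref_table = pd.concat(
        [s[allele_cols + ["eaf"]] for s in studies]
    ).drop_duplicates("id", keep="first")
    ref_alleles = ref_table[allele_cols]
    aligned = []
    for s in studies:
        a = _harmonize(s, ref_table, ambiguous_policy)
        a = a[np.isfinite(a["beta"]) & np.isfinite(a["se"]) & (a["se"] > 0)]
        aligned.append(a.set_index("id"))
    ids = sorted(set().union(*[set(a.index) for a in aligned]))

    k = len(studies)
    beta = np.full((len(ids), k), np.nan)
    se = np.full((len(ids), k), np.nan)
    eaf = np.full((len(ids), k), np.nan)
    nn = np.zeros((len(ids), k))
    for j, a in enumerate(aligned):
        loc = a.reindex(ids)
        beta[:, j] = loc["beta"].to_numpy()
        se[:, j] = loc["se"].to_numpy()
        eaf[:, j] = loc["eaf"].to_numpy()
        nn[:, j] = loc["n"].fillna(0).to_numpy() if "n" in loc else 0

    present = np.isfinite(beta) & np.isfinite(se)
    w = np.where(present, 1.0 / np.where(present, se, 1.0) ** 2, 0.0)
    wsum = w.sum(axis=1)
    mbeta = (w * np.nan_to_num(beta)).sum(axis=1) / wsum
    mse = wsum ** -0.5
    z = mbeta / mse
    p = 2.0 * stats.norm.sf(np.abs(z))
    direction = [
        "".join("?" if not present[i, j] else ("+" if beta[i, j] >= 0 else "-")
                for j in range(k))
        for i in range(len(ids))
    ]
    df = present.sum(axis=1) - 1
    w_n = np.where(present & (nn > 0), nn, 0.0)
    w_n_sum = w_n.sum(axis=1)
    avg_eaf = np.where(
        w_n_sum > 0,
        (w_n * np.nan_to_num(eaf)).sum(axis=1) / np.maximum(w_n_sum, 1),
        np.nanmean(np.where(present, eaf, np.nan), axis=1),
    )
    min_eaf = np.nanmin(np.where(present, eaf, np.nan), axis=1)
    max_eaf = np.nanmax(np.where(present, eaf, np.nan), axis=1)

    meta_pos = pd.concat(
        [s[["id", "chrom", "pos"]] for s in studies]).drop_duplicates("id")
    out = pd.DataFrame({"id": ids})
    out = out.merge(meta_pos, on="id", how="left")
    out = out.merge(ref_alleles, on="id", how="left")
    out["beta"] = mbeta
    out["se"] = mse
    out["p"] = p
    out["direction"] = direction
    out["df"] = df
    out["avg_eaf"] = avg_eaf
    out["min_eaf"] = min_eaf
    out["max_eaf"] = max_eaf
    out["freq_amplitude"] = max_eaf - min_eaf
    out["n"] = w_n_sum
    return out.sort_values(["chrom", "pos", "id"]).reset_index(drop=True)


def meta_filters(records: pd.DataFrame, max_amplitude: float = 0.4,
                 require_df: int = 1, hwe_gate: float = 1e-15,
                 hwe_tables: dict | None = None) -> pd.DataFrame:
    """Post-meta filters: frequency amplitude strictly below
    ``max_amplitude``, degrees of freedom exactly ``require_df``, and —
    when per-population genotype tables are supplied as
    ``{variant_id: {pop: (n_AA, n_Aa, n_aa)}}`` — HWE mid-p strictly above
    ``hwe_gate`` in every population."""
    keep = (records["freq_amplitude"] < max_amplitude) & \
        (records["df"] == require_df)
    if hwe_tables is not None:
        hwe_ok = []
        for vid in records["id"]:
            tables = hwe_tables.get(vid, {})
            ok = all(hwe_midp(*t) > hwe_gate for t in tables.values())
            hwe_ok.append(ok)
        keep &= pd.Series(hwe_ok, index=records.index)
    return records[keep].reset_index(drop=True)


def clump(records: pd.DataFrame, G: GenotypeMatrix | None = None,
          r2_min: float = 0.01, window_kb: float = 1000.0,
          p_threshold: float = 5e-8) -> pd.DataFrame:
    """Greedy LD clumping of significant variants.

    Significant variants are sorted by ascending p (id tie-break); the
    best unassigned variant seeds a clump and absorbs every unassigned
    significant variant within the window whose dosage r^2 with the seed
    exceeds ``r2_min``.  Seeds are lead variants.  Variants absent from
    the LD genotypes become flagged singleton clumps.
    """
    out = records.copy()
    out["clump"] = -1
    out["lead"] = False
    out["ld_missing"] = False
    sig = out[(out["p"] < p_threshold) & np.isfinite(out["p"])]
    sig = sig.sort_values(["p", "id"])
    if len(sig) == 0:
        return out

    geno = {}
    if G is not None:
        id_to_col = {v: j for j, v in enumerate(G.variants["id"])}
        for vid in sig["id"]:
            j = id_to_col.get(vid)
            if j is not None:
                g = G.dosages[:, j].astype(float)
                g[g < 0] = np.nan
                geno[vid] = g

    unassigned = list(sig.index)
    clump_id = 0
    while unassigned:
        seed_idx = unassigned.pop(0)
        clump_id += 1
        out.loc[seed_idx, ["clump", "lead"]] = clump_id, True
        seed = out.loc[seed_idx]
        if seed["id"] not in geno and G is not None:
            out.loc[seed_idx, "ld_missing"] = True
            continue
        absorbed = []
        for idx in unassigned:
            row = out.loc[idx]
            if row["chrom"] != seed["chrom"]:
                continue
            if abs(row["pos"] - seed["pos"]) > window_kb * 1000.0:
                continue
            if row["id"] not in geno:
                continue
            r2 = _dosage_r2(geno[seed["id"]], geno[row["id"]])
            if r2 > r2_min:
                out.loc[idx, "clump"] = clump_id
                absorbed.append(idx)
        unassigned = [i for i in unassigned if i not in absorbed]
    return out


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return 0.0
    aa, bb = a[ok], b[ok]
    sa, sb = aa.std(), bb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(aa, bb)[0, 1] ** 2)


def write_meta(records: pd.DataFrame, path) -> None:
    """METAL-like tab-delimited output."""
    out = pd.DataFrame({
        "MarkerName": records["id"],
        "Allele1": records["effect_allele"],
        "Allele2": records["other_allele"],
        "Freq1": records["avg_eaf"],
        "FreqAmplitude": records["freq_amplitude"],
        "Effect": records["beta"],
        "StdErr": records["se"],
        "P-value": records["p"],
        "Direction": records["direction"],
        "df": records["df"],
    })
    for c in ("clump", "lead"):
        if c in records:
            out[c] = records[c]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
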