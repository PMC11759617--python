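"""Pipeline orchestration: configuration, staged runs, resumability.

A run directory is populated stage by stage (simulate -> qc -> pca ->
match -> gwas -> power), with a JSON manifest recording parameters,
output hashes and row counts.  Re-running with an unchanged configuration
skips stages whose outputs exist and still hash-match; corrupting an
intermediate file triggers recomputation of that stage and everything
after it.
"""

from __future__ import annotations

import copy
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, matching, pca, power, qc, scenarios, simulate

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_ref": 600,
        "n_target": 3000,
        "m": 4000,
        "k_pops": 3,
        "fst": 0.1,
        "alpha_ref": [8.0, 1.0, 1.0],
        "alpha_target": [2.0, 5.0, 5.0],
        "prevalence": 0.111,
        "missing_rate": 0.01,
        "ancestry_confound": None,
        "proxy_sensitivity": 1.0,
        "proxy_specificity": 1.0,
        "age_min": 55.0,
        "age_max": 90.0,
    },
    "qc": {
        "variant_max_miss": 0.10,
        "sample_max_miss": 0.05,
        "het_hom_n_sd": 6.0,
        "kinship_threshold": 0.0884,
        "run_kinship": False,
        "pc_outlier_n_sd": 6.0,
        "min_carriers": 20,
        "min_mac": 20,
        "hwe_min_midp": 1e-15,
    },
    "pca": {
        "k": 20,
        "prune_window_kb": 100.0,
        "prune_r2": 0.1,
        "maf_min": 0.01,
        "shrinkage": "jackknife",
    },
    "match": {
        "include_age_sex": False,
        "n_subclasses": 500,
        "weight_threshold": 1.0,
    },
    "gwas": {
        "firth_p": 0.01,
        "min_mac": 20,
    },
    "power": {
        "prevalence": 0.111,
        "alpha": 5e-8,
        "target": 0.80,
        "mafs": [0.001, 0.003, 0.005],
    },
}

STAGES = ["simulate", "qc", "pca", "match", "gwas", "power"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        data = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in raw.items():
            if key == "seed":
                data["seed"] = int(val)
                continue
            if key not in data:
                raise ConfigError(f"unknown config section {key!r}")
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, v in val.items():
                if sub not in data[key]:
                    raise ConfigError(f"unknown key {key}.{sub}")
                data[key][sub] = v
        return cls(data)

    def show(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for blk in iter(lambda: fh.read(1 << 20), b""):
            h.update(blk)
    return h.hexdigest()


def _log(stage: str, msg: str):
    print(f"[{stage}] {msg}", file=sys.stderr)


class PipelineRun:
    """Executes the staged pipeline inside a run directory."""

    def __init__(self, config: PipelineConfig, outdir):
        self.cfg = config.data
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {"stages": {}, "seed": self.cfg["seed"]}
        if self.manifest_path.exists():
            try:
                self.manifest = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                pass

    # -- manifest helpers ------------------------------------------------
    def _params_hash(self, stage: str) -> str:
        blob = json.dumps({"seed": self.cfg["seed"],
                           stage: self.cfg.get(stage, {})}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def _stage_fresh(self, stage: str, outputs: list[Path]) -> bool:
        entry = self.manifest["stages"].get(stage)
        if entry is None or entry.get("params") != self._params_hash(stage):
            return False
        for f in outputs:
            rec = entry.get("outputs", {}).get(f.name)
            if rec is None or not f.exists() or _sha256(f) != rec:
                return False
        return True

    def _record(self, stage: str, outputs: list[Path], counts: dict):
        self.manifest["stages"][stage] = {
            "params": self._params_hash(stage),
            "outputs": {f.name: _sha256(f) for f in outputs},
            "counts": counts,
            "time": time.time(),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    # -- stages ----------------------------------------------------------
    def run(self, upto: str = "power") -> Path:
        last = STAGES.index(upto)
        stale = False
        for stage in STAGES[: last + 1]:
            fn = getattr(self, f"stage_{stage}")
            outputs = fn(dry=True)
            if not stale and self._stage_fresh(stage, outputs):
                _log(stage, "outputs up to date; skipped")
                continue
            stale = True
            _log(stage, "running")
            try:
                counts = fn(dry=False)
            except Exception as e:
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            self._record(stage, outputs, counts)
        return self.outdir

    # each stage function doubles as an output lister (dry=True)
    def stage_simulate(self, dry=False):
        out = [self.outdir / f for f in
               ("ref.vcf", "ref.sheet.tsv", "target.vcf", "target.sheet.tsv")]
        if dry:
            return out
        p = self.cfg["simulate"]
        phen = simulate.PhenotypeSpec(
            prevalence=p["prevalence"],
            ancestry_confound=p["ancestry_confound"],
            proxy_sensitivity=p["proxy_sensitivity"],
            proxy_specificity=p["proxy_specificity"])
        study = scenarios.simulate_two_cohorts(
            self.cfg["seed"], n_ref=p["n_ref"], n_target=p["n_target"],
            m=p["m"], k_pops=p["k_pops"], fst=p["fst"],
            alpha_ref=tuple(p["alpha_ref"]), alpha_target=tuple(p["alpha_target"]),
            phen_ref=phen, phen_target=phen, missing_rate=p["missing_rate"])
        study.sheet_target["status_type"] = "proxy"
        study.sheet_target["status"] = study.sheet_target["proxy_status"]
        simulate.write_cohort(study.G_ref, study.sheet_ref, out[0], out[1])
        simulate.write_cohort(study.G_target, study.sheet_target, out[2], out[3])
        return {"n_ref": p["n_ref"], "n_target": p["n_target"], "m": p["m"]}

    def stage_qc(self, dry=False):
        out = [self.outdir / f for f in
               ("ref.qc.vcf", "ref.qc.sheet.tsv", "target.qc.vcf",
                "target.qc.sheet.tsv", "qc_report.tsv")]
        if dry:
            return out
        p = self.cfg["qc"]
        counts = {}
        reports = []
        for tag, vcf, sheet_f in (("ref", "ref.vcf", "ref.sheet.tsv"),
                                  ("target", "target.vcf", "target.sheet.tsv")):
            G, sheet = simulate.read_cohort(self.outdir / vcf,
                                            self.outdir / sheet_f)
            G, r1 = qc.filter_sample_missingness(G, p["sample_max_miss"])
            G, r2 = qc.het_hom_outliers(G, p["het_hom_n_sd"])
            if p["run_kinship"]:
                kin = qc.king_kinship(G)
                G, r3 = qc.remove_related(kin, G, p["kinship_threshold"])
            else:
                r3 = qc.QCReport()
            G, r4 = qc.filter_variant_missingness(G, p["variant_max_miss"])
            G, r5 = qc.mac_privacy_filter(G, p["min_carriers"], p["min_mac"])
            rep = r1.merge(r2).merge(r3).merge(r4).merge(r5)
            keep = sheet["sample_id"].isin(G.samples)
            sheet = sheet[keep].reset_index(drop=True)
            simulate.write_cohort(G, sheet, self.outdir / f"{tag}.qc.vcf",
                                  self.outdir / f"{tag}.qc.sheet.tsv")
            counts[f"{tag}_samples"] = G.n_samples
            counts[f"{tag}_variants"] = G.n_variants
            reports.append(rep)
        reports[0].merge(reports[1]).to_tsv(out[4])
        return counts

    def _load_qc(self):
        G_ref, sheet_ref = simulate.read_cohort(
            self.outdir / "ref.qc.vcf", self.outdir / "ref.qc.sheet.tsv")
        G_tgt, sheet_tgt = simulate.read_cohort(
            self.outdir / "target.qc.vcf", self.outdir / "target.qc.sheet.tsv")
        return G_ref, sheet_ref, G_tgt, sheet_tgt

    def stage_pca(self, dry=False):
        out = [self.outdir / "pcmodel" / "variants.tsv",
               self.outdir / "pcmodel" / "meta.json",
               self.outdir / "scores.ref.tsv", self.outdir / "scores.target.tsv"]
        if dry:
            return out
        p = self.cfg["pca"]
        G_ref, _, G_tgt, _ = self._load_qc()
        pruned = pca.ld_prune(G_ref, window_kb=p["prune_window_kb"],
                              r2_max=p["prune_r2"], maf_min=p["maf_min"])
        model, scores_ref = pca.reference_pca(G_ref, pruned, k=p["k"])
        model.shrinkage = pca.estimate_shrinkage(
            G_ref, pruned, k=model.k, method=p["shrinkage"],
            seed=self.cfg["seed"])
        scores_tgt = pca.project(model, G_tgt)
        model.save(self.outdir / "pcmodel")
        scores_ref.to_frame().to_csv(out[2], sep="\t", index=False)
        scores_tgt.to_frame().to_csv(out[3], sep="\t", index=False)
        return {"pruned_variants": int(len(pruned)), "k": int(model.k)}

    def stage_match(self, dry=False):
        out = [self.outdir / "weights.tsv", self.outdir / "matched_ids.txt",
               self.outdir / "balance.tsv"]
        if dry:
            return out
        p = self.cfg["match"]
        _, sheet_ref, _, sheet_tgt = self._load_qc()
        s_ref = pd.read_csv(self.outdir / "scores.ref.tsv", sep="\t")
        s_tgt = pd.read_csv(self.outdir / "scores.target.tsv", sep="\t")
        sheet = pd.concat([sheet_ref, sheet_tgt], ignore_index=True)
        scores = np.vstack([s_ref.iloc[:, 1:].to_numpy(),
                            s_tgt.iloc[:, 1:].to_numpy()])
        result = matching.run_matching(
            scores, sheet, "reference", include_age_sex=p["include_age_sex"],
            n_subclasses=p["n_subclasses"],
            weight_threshold=p["weight_threshold"])
        wt = pd.DataFrame({"sample_id": sheet["sample_id"],
                           "cohort": sheet["cohort"],
                           "subclass": result.subclass,
                           "weight": result.weights,
                           "matched": result.matched})
        wt.to_csv(out[0], sep="\t", index=False)
        matched_ids = sheet.loc[result.matched, "sample_id"]
        out[1].write_text("\n".join(matched_ids) + "\n")
        matching.balance_report(scores, sheet, result.is_reference,
                                result.matched).to_csv(out[2], sep="\t",
                                                       index=False)
        return {"n_matched": int(result.matched.sum()),
                "n_subclasses": int(result.n_subclasses)}

    def stage_gwas(self, dry=False):
        out = [self.outdir / "gwas.matched.tsv", self.outdir / "gwas.lambda.json"]
        if dry:
            return out
        p = self.cfg["gwas"]
        _, _, G_tgt, sheet_tgt = self._load_qc()
        matched_ids = set(
            (self.outdir / "matched_ids.txt").read_text().split())
        idx = np.flatnonzero(sheet_tgt["sample_id"].isin(matched_ids))
        s_tgt = pd.read_csv(self.outdir / "scores.target.tsv", sep="\t")
        G_m = G_tgt.subset(sample_idx=idx)
        y = sheet_tgt["status"].to_numpy()[idx]
        covars = s_tgt.iloc[idx, 1:].to_numpy()
        rec = assoc.logistic_scan(G_m, y, covars)
        rec = assoc.firth_fallback_policy(rec, G_m, y, covars,
                                          threshold_p=p["firth_p"],
                                          min_mac=p["min_mac"])
        assoc.write_sumstats(rec, out[0])
        lam = assoc.genomic_lambda(rec.loc[rec["converged"], "p"])
        out[1].write_text(json.dumps(
            {"lambda": lam.lam, "n_variants": lam.n_variants}, indent=1))
        return {"n_samples": int(len(idx)), "lambda": round(lam.lam, 4)}

    def stage_power(self, dry=False):
        out = [self.outdir / "power.tsv"]
        if dry:
            return out
        p = self.cfg["power"]
        _, _, _, sheet_tgt = self._load_qc()
        matched_ids = set(
            (self.outdir / "matched_ids.txt").read_text().split())
        sheet_ref = pd.read_csv(self.outdir / "ref.qc.sheet.tsv", sep="\t")
        tgt = sheet_tgt[sheet_tgt["sample_id"].isin(matched_ids)]
        n_cases = int(sheet_ref["status"].sum() + tgt["status"].sum())
        n_controls = int((1 - sheet_ref["status"]).sum()
                         + (1 - tgt["status"]).sum())
        rows = []
        for maf in p["mafs"]:
            grr = power.min_grr_for_power(
                maf, n_cases, n_controls, prevalence=p["prevalence"],
                alpha=p["alpha"], target=p["target"])
            rows.append({"maf": maf, "n_cases": n_cases,
                         "n_controls": n_controls, "min_grr": grr})
        pd.DataFrame(rows).to_csv(out[0], sep="\t", index=False)
        return {"n_cases": n_cases, "n_controls": n_controls}


def run_pipeline(config: PipelineConfig, outdir, upto: str = "power") -> Path:
    return PipelineRun(config, outdir).run(upto)


def two_scenario_demo(seed: int = 1, n_ref: int = 600, n_target: int = 3000,
                      m: int = 4000) -> dict:
    """Match with PCs only vs PCs + age + sex on one simulated dataset.

    Adding age and sex to the propensity model should pull the matched
    target cohort's age distribution toward the reference (smaller age
    SMD) while both matched GWAS stay calibrated.
    """
    phen = simulate.PhenotypeSpec()
    study = scenarios.simulate_two_cohorts(seed, n_ref=n_ref,
                                           n_target=n_target, m=m)
    # give the target cohort a different age distribution
    rng = np.random.default_rng(seed + 1)
    study.sheet_target["age"] = rng.uniform(40.0, 75.0, n_target)
    scenarios.build_pc_space(study, k=min(20, n_ref - 1), seed=seed)
    report = {}
    sheet = pd.concat([study.sheet_ref, study.sheet_target], ignore_index=True)
    scores = np.vstack([study.scores_ref.scores, study.scores_target.scores])
    for label, flag in (("pcs_only", False), ("pcs_age_sex", True)):
        res = matching.run_matching(scores, sheet, "reference",
                                    include_age_sex=flag,
                                    n_subclasses=min(500, n_ref))
        bal = matching.balance_report(scores, sheet, res.is_reference,
                                      res.matched)
        idx = scenarios.matched_target_indices(study, res)
        G_m = study.G_target.subset(sample_idx=idx)
        y = study.sheet_target["status"].to_numpy()[idx]
        covars = study.scores_target.scores[idx, :]
        lam, _ = scenarios.scan_lambda(G_m, y, covars, firth=False)
        report[label] = {
            "n_matched": int(res.matched.sum()),
            "age_smd": float(abs(
                bal.loc[bal["covariate"] == "age", "smd_matched"].iloc[0])),
            "lambda": lam,
        }
    return report
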