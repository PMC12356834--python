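"""End-to-end orchestration: simulate (optional) -> QC -> qualifying/
collapse -> association -> secondary analyses -> reports.

Every stage writes its artifact plus a machine-readable count line
(JSON-lines) and a timestamped text log; reruns with identical config and
seed are bit-identical.  Phenotype is only consulted where the method
requires it (differential missingness and the association itself).
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as rio
from .association import (
    AdjustedModelSpec,
    adjusted_burden_model,
    carrier_pc_projection,
    gene_burden_scan,
    secondary_analyses,
)
from .collapse import (
    QualifyingRule,
    collapse_carriers,
    exome_variant_count,
    group_maf,
    select_qualifying,
    stratum_tables,
)
from .model import ALPHA_EXOME, MISSING
from .qc import QCThresholds, compute_pca, ld_prune, sample_qc, variant_qc
from .synthetic import SimulationConfig, simulate_study


@dataclass
class PipelineConfig:
    vcf: Optional[str] = None
    samples: Optional[str] = None
    annotations: Optional[str] = None
    out_dir: str = "rareburden_out"
    seed: int = 0
    alpha_exome: float = ALPHA_EXOME
    stratify_by: str = "cohort"
    common_af_min: float = 0.05  # variants at or above this AF feed the PCA
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    rule: QualifyingRule = field(default_factory=QualifyingRule)
    adjusted: AdjustedModelSpec = field(default_factory=AdjustedModelSpec)
    simulate: Optional[SimulationConfig] = None
    config_path: Optional[str] = None  # original TOML, copied verbatim

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(config_path=path)
        for key in ("vcf", "samples", "annotations", "out_dir", "seed",
                    "alpha_exome", "stratify_by", "common_af_min"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "thresholds" in raw:
            cfg.thresholds = QCThresholds(**raw["thresholds"])
        if "rule" in raw:
            kw = dict(raw["rule"])
            if "ptv_classes" in kw:
                kw["ptv_classes"] = frozenset(kw["ptv_classes"])
            cfg.rule = QualifyingRule(**kw)
        if "adjusted" in raw:
            cfg.adjusted = AdjustedModelSpec(**raw["adjusted"])
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            if "strata_spec" in sim:
                sim["strata_spec"] = [tuple(x) for x in sim["strata_spec"]]
            if "risk_genes" in sim:
                from .synthetic import RiskGeneSpec

                sim["risk_genes"] = [
                    RiskGeneSpec(**r) for r in sim["risk_genes"]
                ]
            cfg.simulate = SimulationConfig(**sim)
        return cfg


class _StageLog:
    def __init__(self, out_dir: Path):
        self.text_path = out_dir / "pipeline.log"
        self.json_path = out_dir / "stage_counts.jsonl"
        self.text = open(self.text_path, "a")
        self.jsonl = open(self.json_path, "a")

    def stage(self, name: str, **counts) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        self.text.write(f"[{stamp}] {name}: {counts}\n")
        self.text.flush()
        self.jsonl.write(json.dumps({"stage": name, **counts}) + "\n")
        self.jsonl.flush()

    def close(self) -> None:
        self.text.close()
        self.jsonl.close()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def coverage_profile_report(gm, samples) -> pd.DataFrame:
    """Per-phenotype-group summary of exome-wide variant counts.

    Quantiles of per-sample non-reference counts plus a two-sample
    Mann-Whitney location test of each case group against controls
    (report-only: used to spot batch-differential artifacts)."""
    counts = exome_variant_count(gm)
    by_id = {s.sample_id: s for s in samples}
    groups: dict[str, list] = {}
    for sid, cnt in counts.items():
        s = by_id.get(sid)
        if s is None:
            continue
        groups.setdefault(s.phenotype, []).append(cnt)
    controls = groups.get("control", [])
    rows = []
    for pheno in sorted(groups):
        vals = np.array(groups[pheno])
        q = np.quantile(vals, [0.05, 0.25, 0.5, 0.75, 0.95])
        p = np.nan
        if pheno != "control" and len(controls) >= 2 and len(vals) >= 2:
            _, p = sps.mannwhitneyu(vals, controls,
                                    alternative="two-sided")
        rows.append({
            "phenotype": pheno, "n": len(vals),
            "q05": q[0], "q25": q[1], "median": q[2],
            "q75": q[3], "q95": q[4],
            "p_vs_controls": p,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the full analysis; returns the output directory.

    Stage order is fixed; any stage failure aborts with the stage name,
    preserving partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out)
    if config.config_path:
        shutil.copy(config.config_path, out / "config.toml")
    else:
        (out / "config.json").write_text(
            json.dumps(_config_dict(config), indent=2, default=str)
        )

    try:
        stage = "simulate"
        if config.simulate is not None:
            paths = simulate_study(config.simulate, str(out / "simulated"))
            config.vcf = paths["vcf"]
            config.samples = paths["samples"]
            config.annotations = paths["annotations"]
            log.stage(stage, vcf=paths["vcf"])

        stage = "read_inputs"
        variants, gm = rio.read_vcf(config.vcf)
        samples = rio.read_samples(config.samples)
        annotations = rio.read_annotations(
            config.annotations,
            known_variant_ids=set(gm.variant_ids),
        )
        log.stage(stage, n_variants=len(variants),
                  n_samples=len(samples), n_annotations=len(annotations))

        stage = "variant_qc"
        vreport, gm_v = variant_qc(variants, gm, samples, config.thresholds)
        log.stage(stage, n_in=len(variants),
                  n_out=gm_v.n_variants,
                  steps=dict(vreport.step_counts))

        stage = "sample_qc"
        af = _overall_af(gm_v)
        common_ids = [gm_v.variant_ids[j] for j in
                      np.flatnonzero(np.minimum(af, 1 - af)
                                     >= config.common_af_min)]
        common_gm = gm_v.subset_variants(common_ids) if common_ids else None
        sreport = sample_qc(samples, gm_v, config.thresholds, common_gm)
        keep = sreport.passed_samples
        gm_s = gm_v.subset_samples(keep)
        samples_kept = [s for s in samples if s.sample_id in set(keep)]
        log.stage(stage, n_in=len(samples), n_out=len(keep),
                  steps=dict(sreport.step_counts))

        stage = "qualify_collapse"
        mafs = group_maf(gm_s, samples_kept)
        qualifying = select_qualifying(annotations, mafs, config.rule)
        gene_map = {a.variant_id: a.gene for a in annotations}
        carriers = collapse_carriers(gm_s, qualifying, gene_map)
        tables = stratum_tables(carriers, samples_kept, config.stratify_by)
        log.stage(stage, n_qualifying=len(qualifying),
                  n_genes=len(carriers.genes))

        stage = "association"
        results = gene_burden_scan(tables, config.alpha_exome)
        evc = exome_variant_count(gm_s)
        pcs = {}
        if common_gm is not None:
            pruned = ld_prune(common_gm, config.thresholds.ld_r2_max)
            pruned = common_gm.subset_variants(pruned)
            if pruned.n_variants >= config.thresholds.n_pcs:
                scores, _ = compute_pca(pruned, config.thresholds.n_pcs)
                pcs = {sid: scores[i] for i, sid in
                       enumerate(common_gm.sample_ids)}
        # covariate-adjusted model for every exome-wide-significant gene
        for res in results:
            if not res.exome_wide_significant or not pcs:
                continue
            status = carriers.carrier_status(res.gene)
            ids = [s.sample_id for s in samples_kept
                   if status.get(s.sample_id) is not None
                   and s.sample_id in pcs]
            carrier_vec = np.array([status[i] for i in ids], dtype=float)
            case_vec = np.array(
                [s.is_case for s in samples_kept if s.sample_id in set(ids)],
                dtype=float)
            cov = np.array([
                np.concatenate([pcs[i][:config.thresholds.n_pcs],
                                [evc.get(i, 0)]]) for i in ids])
            fit = adjusted_burden_model(carrier_vec, case_vec, cov,
                                        config.adjusted)
            res.p_adjusted = fit.p_value
        rio.write_results(results, str(out / "summary_stats.tsv"))
        log.stage(stage, n_genes=len(results),
                  n_significant=sum(r.exome_wide_significant
                                    for r in results))

        stage = "secondary"
        if results:
            top = results[0]
            status = carriers.carrier_status(top.gene) \
                if top.gene in carriers.genes else {}
            sec = secondary_analyses(status, samples_kept)
            sec_rows = []
            for name, r in sec.items():
                sec_rows.append({
                    "analysis": name, "or_mh": r["or_mh"],
                    "ci_low": r["ci95"][0], "ci_high": r["ci95"][1],
                    "p_cmh": r["p_cmh"],
                })
            pd.DataFrame(sec_rows).to_csv(
                out / "secondary_analyses.tsv", sep="\t", index=False)
            if pcs:
                proj = carrier_pc_projection(status, pcs)
                pd.DataFrame({
                    "PC1_p": [proj["location_test_p"]["PC1"]],
                    "PC2_p": [proj["location_test_p"]["PC2"]],
                }).to_csv(out / "carrier_pc_check.tsv", sep="\t",
                          index=False)
            log.stage(stage, top_gene=top.gene)

        stage = "reports"
        coverage_profile_report(gm_s, samples_kept).to_csv(
            out / "variant_count_profile.tsv", sep="\t", index=False)
        log.stage(stage, done=True)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        log.stage("FAILED", stage=stage, error=str(exc))
        log.close()
        raise StageFailure(stage, exc) from exc
    log.close()
    return str(out)


def _overall_af(gm) -> np.ndarray:
    called = gm.dosage != MISSING
    n = called.sum(axis=0)
    ac = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, ac / (2.0 * n), 0.0)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    rule = d.get("rule")
    if rule and isinstance(rule.get("ptv_classes"), frozenset):
        rule["ptv_classes"] = sorted(rule["ptv_classes"])
    return d
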