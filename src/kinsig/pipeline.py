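"""End-to-end orchestration: simulate -> correlate -> select -> survival ->
qPCR -> combination indices, under one seeded configuration.

`run_pipeline` writes every stage output plus a JSON manifest (parameter
echo, seed, per-stage output checksums); rerunning with the same
configuration reproduces the checksums bit-for-bit. `report` renders a
manifest into a human-readable summary of the selection funnel, hazard
ratios, emergence sets, qPCR contrasts and CI tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bicor import build_consensus, correlate_collection, select_stage1, select_stage2
from .dose_response import MedianEffectModel
from .qpcr import stage_comparison
from .survival import SignatureSurvivalModel, four_way_emergence, multivariate_cox
from .synthetic import (
    SyntheticConfig,
    generate_dose_response,
    generate_expression_collection,
    generate_qpcr_table,
    generate_survival_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "report"]

log = logging.getLogger("kinsig")


@dataclass
class PipelineConfig:
    """One configuration for a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "kinsig_out"
    anchor: str = "ZAP70"
    threshold: float = 0.5
    min_datasets: int = 5
    min_other_kinases: int = 2
    top_k: int = 8
    endpoints: tuple[str, ...] = ("ttt", "os")
    multivariate_gene: str = "DNPEP"
    skip_qpcr: bool = False
    skip_ci: bool = False
    skip_survival: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.min_datasets < 1 or self.top_k < 1:
            raise ValueError("min_datasets and top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        syn = raw.pop("synthetic", {})
        if isinstance(syn, dict):
            for key in ("samples_per_dataset", "rai_sizes", "kinase_panel"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            if "drugs" in syn:
                syn["drugs"] = {k: tuple(v) for k, v in syn["drugs"].items()}
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    # insertion order preserved so that report() renders identically
    # from the in-memory manifest and from the file
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    manifest: dict = {
        "kinsig_version": __version__,
        "seed": syn.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str = "completed", **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}
        log.info("stage %s: %s %s", stage, status, info or "")

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t" if name.endswith(".tsv") else ",", index=False)
        manifest["outputs"][name] = _sha256(path)

    try:
        # --- correlation screen -------------------------------------------
        datasets, truth = generate_expression_collection(syn)
        record(
            "simulate_expression",
            n_datasets=len(datasets),
            n_genes=syn.n_genes,
            n_planted=len(truth.positive_genes),
        )
        records = correlate_collection(datasets, syn.kinase_panel)
        save("correlations.tsv", records)
        record("correlate", n_records=len(records))
        counts = build_consensus(records, threshold=config.threshold)
        stage1 = select_stage1(
            counts, anchor=config.anchor, min_datasets=config.min_datasets
        )
        selection = select_stage2(
            counts,
            stage1_genes=stage1,
            anchor=config.anchor,
            min_other_kinases=config.min_other_kinases,
            min_datasets=config.min_datasets,
        )
        _write_json(selection.to_dict(), out / "selection.json")
        manifest["outputs"]["selection.json"] = _sha256(out / "selection.json")
        planted = set(truth.positive_genes)
        selected = set(selection.stage2_genes)
        negatives = syn.n_genes - len(planted)
        recovery = {
            "sensitivity": len(planted & selected) / len(planted) if planted else None,
            "specificity": 1.0 - len(selected - planted) / negatives
            if negatives
            else None,
        }
        record(
            "select",
            n_stage1=len(stage1),
            n_stage2=len(selection.stage2_genes),
            **{k: v for k, v in recovery.items() if v is not None},
        )
        manifest["selection_recovery"] = recovery

        # --- survival -----------------------------------------------------
        if config.skip_survival:
            record("survival", status="skipped")
        else:
            cohort, struth = generate_survival_cohort(syn)
            cohort.to_csv(out / "cohort.csv")
            manifest["outputs"]["cohort.csv"] = _sha256(out / "cohort.csv")
            genes = cohort.genes
            surv: dict = {}
            for ep in config.endpoints:
                res = SignatureSurvivalModel(cohort, genes, ep).fit(k=config.top_k)
                anchor_analog = sorted(struth.true_betas.get(ep, {}))[:1]
                surv[ep] = {
                    "combined_hr": res.hr,
                    "combined_hr_ci": res.stratification.hr_ci,
                    "logrank_p": res.stratification.logrank_p,
                    "individual_hr": res.individual_hr.to_dict("records"),
                    "top_k": res.top_genes(),
                    "loo_top_k": res.contributions["gene"].head(config.top_k).tolist()
                    if res.contributions is not None
                    else [],
                }
                record(f"survival_{ep}", combined_hr=res.hr)
            # effect-driven list length (see four_way_emergence docstring)
            emergence = four_way_emergence(cohort, genes, k=None)
            surv["emergence"] = emergence
            try:
                mv = multivariate_cox(cohort, "ttt", gene=config.multivariate_gene)
                surv["multivariate_ttt_p"] = mv["p_values"]
            except (KeyError, ValueError) as exc:
                surv["multivariate_ttt_p"] = {"error": str(exc)}
            _write_json(surv, out / "survival.json")
            manifest["outputs"]["survival.json"] = _sha256(out / "survival.json")
            manifest["survival"] = {
                ep: {"combined_hr": surv[ep]["combined_hr"]}
                for ep in config.endpoints
            }
            manifest["emergence_common"] = emergence["common"]

        # --- qPCR ---------------------------------------------------------
        if config.skip_qpcr:
            record("qpcr", status="skipped")
        else:
            ct = generate_qpcr_table(syn)
            save("qpcr_ct.csv", ct)
            contrasts = pd.concat(
                [
                    stage_comparison(ct, "rai", syn.qpcr_target, syn.qpcr_reference),
                    stage_comparison(ct, "binet", syn.qpcr_target, syn.qpcr_reference),
                ],
                ignore_index=True,
            )
            save("qpcr_contrasts.tsv", contrasts)
            record("qpcr", n_samples=syn.qpcr_n)
            manifest["qpcr_p"] = {
                f"{r.staging}:{r.contrast}": r.p for r in contrasts.itertuples()
            }

        # --- combination indices -------------------------------------------
        if config.skip_ci:
            record("combination", status="skipped")
        else:
            single, combos, dtruth = generate_dose_response(syn)
            save("dose_single.csv", single)
            save("dose_combo.csv", combos)
            results = MedianEffectModel(single).fit()
            ci = results.combination_indices(combos)
            save("combination_index.tsv", ci)
            record("combination", n_points=len(ci))
            manifest["ci_mean"] = float(ci["ci"].mean()) if len(ci) else None
            manifest["true_synergy_factor"] = dtruth.synergy_factor
    except Exception as exc:
        stage = next(
            (s for s, v in manifest["stages"].items() if v["status"] != "completed"),
            "unknown",
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable run summary from a manifest (dict or path)."""
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = json.load(fh)
    if "stages" not in manifest:
        raise ValueError("incomplete manifest: no stage records")
    lines = [
        f"kinsig run (version {manifest.get('kinsig_version')}, "
        f"seed {manifest.get('seed')})",
        "stages:",
    ]
    for stage, info in manifest["stages"].items():
        extra = {k: v for k, v in info.items() if k != "status"}
        lines.append(f"  {stage}: {info['status']} {extra if extra else ''}".rstrip())
    sel = manifest["stages"].get("select", {})
    if sel.get("status") == "completed":
        if sel.get("n_stage2", 0) == 0:
            lines.append("selection: no genes passed the consensus thresholds")
        else:
            lines.append(
                f"selection funnel: {sel.get('n_stage1')} stage-1 genes -> "
                f"{sel.get('n_stage2')} signature genes"
            )
    for ep, res in manifest.get("survival", {}).items():
        lines.append(f"combined {ep.upper()} hazard ratio: {res['combined_hr']:.3f}")
    if manifest.get("emergence_common") is not None:
        lines.append(
            "common across the four analyses: "
            + (", ".join(manifest["emergence_common"]) or "(none)")
        )
    for contrast, p in manifest.get("qpcr_p", {}).items():
        lines.append(f"qPCR {contrast}: p = {p:.4g}")
    if manifest.get("ci_mean") is not None:
        lines.append(
            f"mean combination index: {manifest['ci_mean']:.3f} "
            f"(true synergy factor {manifest.get('true_synergy_factor')})"
        )
    return "\n".join(lines)
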