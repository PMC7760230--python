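"""End-to-end orchestration: simulate/read -> QC -> normalize -> DE ->
cluster -> survival, from one config, with a reproducibility manifest.

Every stage writes plain tab-delimited files so any stage can be audited
or rerun from the previous stage's outputs; the manifest records input
hashes, all effective parameters (defaults included), seeds, per-stage
record counts and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import diffexp, io as dsp_io
from . import qc as qc_mod
from . import survival as surv_mod
from . import synth
from .normalize import (
    DEFAULT_HK_PROBES,
    NORMALIZATION_METHODS,
    assess_normalizers,
    build_factor_table,
    normalize_counts,
    normalize_hk,
    normalize_within_groups,
)

logger = logging.getLogger("dspforge")

STAGES = ("inputs", "qc", "normalize", "diffexp", "correlation",
          "cluster", "survival")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run (defaults echoed to the
    manifest)."""

    out_dir: str = "dspforge_out"
    # either file inputs ...
    counts_path: str | None = None
    roi_path: str | None = None
    panel_path: str | None = None
    survival_path: str | None = None
    # ... or a simulation
    simulate: dict[str, Any] | None = None
    # qc
    snr_summary: str = "median"
    snr_threshold: float = 1.0
    flag_threshold: float = 50.0
    drop_flagged: bool = False
    # normalization
    normalization: str = "hk_mean"
    normalize_within_compartments: bool = False
    hk_probes: tuple[str, ...] = DEFAULT_HK_PROBES
    hk_mean: str = "arithmetic"
    pseudo_count: float = 1.0
    # differential expression
    comparisons: list[dict[str, str]] = field(default_factory=lambda: [
        {"comparison": "TME_vs_Tumour", "design": "paired"},
        {"comparison": "NAT_vs_TME", "design": "paired"},
        {"comparison": "NAT_vs_TME", "design": "unpaired"},
        {"comparison": "TME_vs_Tumour", "design": "unpaired"},
    ])
    correlation_alpha: float = 0.001
    # clustering
    cluster_k: int = 3
    cluster_seed: int = 0
    cluster_restarts: int = 10
    # survival
    survival_compartments: tuple[str, ...] = ("Tumour", "TME")
    dichotomize: bool = False
    survival_adjust: bool = False

    def validate(self) -> None:
        if self.normalization not in NORMALIZATION_METHODS:
            raise ConfigError(
                f"unknown normalization method {self.normalization!r}; "
                f"allowed: {list(NORMALIZATION_METHODS)}")
        if self.snr_summary not in qc_mod.SUMMARY_METHODS:
            raise ConfigError(
                f"unknown snr summary {self.snr_summary!r}; "
                f"allowed: {list(qc_mod.SUMMARY_METHODS)}")
        if self.snr_threshold <= 0:
            raise ConfigError("snr_threshold must be > 0")
        if self.cluster_k < 2:
            raise ConfigError("cluster_k must be >= 2")
        for spec in self.comparisons:
            diffexp.parse_comparison(spec["comparison"])
            if spec.get("design", "paired") not in ("paired", "unpaired"):
                raise ConfigError(f"unknown design in comparison {spec!r}")
        if self.simulate is None and (self.counts_path is None
                                      or self.roi_path is None
                                      or self.panel_path is None):
            raise ConfigError(
                "config must give either a 'simulate' block or counts/roi/panel paths")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_design(spec: dict[str, Any]) -> synth.SimulationDesign:
    spec = dict(spec or {})
    seed = int(spec.pop("seed", 0))
    n_pairs = spec.pop("n_pairs", None)
    compartments = tuple(spec.pop("compartments", ("Tumour", "TME")))
    if n_pairs is not None:
        return synth.paired_design(int(n_pairs), compartments=compartments,
                                   seed=seed, **spec)
    return synth.default_design(seed=seed, **spec)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns (and writes) the manifest."""
    config.validate()
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    manifest: dict[str, Any] = {
        "parameters": _jsonable(asdict(config)),
        "stages": {},
        "input_hashes": {},
        "warnings": [],
    }
    current = "inputs"
    try:
        # ------------------------------------------------------ inputs
        if config.simulate is not None:
            design = _build_design(config.simulate)
            counts, roi_table, truth = synth.simulate_counts(design)
            survival = synth.simulate_survival(truth, design)
            sim_dir = os.path.join(out_dir, "simulated")
            paths = synth.write_simulation(sim_dir, counts, roi_table,
                                           design.panel, truth, survival)
            panel = design.panel
            manifest["stages"]["inputs"] = {
                "source": "simulated", "seed": design.seed,
                "n_rois": len(counts), "n_probes": counts.shape[1],
                "outputs": sorted(paths.values()),
            }
        else:
            counts = dsp_io.read_counts(config.counts_path)
            roi_table = dsp_io.read_roi_table(config.roi_path)
            panel = dsp_io.read_panel(config.panel_path)
            survival = (dsp_io.read_survival(config.survival_path)
                        if config.survival_path else None)
            for key in ("counts_path", "roi_path", "panel_path", "survival_path"):
                path = getattr(config, key)
                if path:
                    manifest["input_hashes"][key] = _sha256(path)
            manifest["stages"]["inputs"] = {
                "source": "files", "n_rois": len(counts),
                "n_probes": counts.shape[1], "outputs": [],
            }
        panel.validate_for_pipeline()
        dsp_io.check_consistency(counts, roi_table, panel, survival)

        # ---------------------------------------------------------- qc
        current = "qc"
        report = qc_mod.roi_median_counts(counts, config.flag_threshold)
        snr_table = qc_mod.snr(counts, panel, summary_method=config.snr_summary,
                               threshold=config.snr_threshold)
        robust = qc_mod.filter_probes(snr_table, panel)
        if config.drop_flagged:
            keep_rois = report.medians.index[~report.low_count_flag]
            counts = counts.loc[keep_rois]
        qc_paths = dsp_io.write_results({
            "roi_qc": report.frame(),
            "snr_table": snr_table.frame(),
        }, out_dir)
        robust_path = os.path.join(out_dir, "robust_probes.txt")
        with open(robust_path, "w") as fh:
            fh.write("\n".join(robust) + "\n")
        manifest["stages"]["qc"] = {
            "n_flagged_rois": int(report.low_count_flag.sum()),
            "n_robust_probes": len(robust),
            "outputs": qc_paths + [robust_path],
        }
        robust_targets = [p for p in robust if panel.probe_class(p) == "target"]
        kept = counts[[p for p in robust if p in counts.columns]]

        # --------------------------------------------------- normalize
        current = "normalize"
        factors = build_factor_table(counts, panel, roi_table)
        assessment = assess_normalizers(factors)
        hk_kwargs = ({"probes": config.hk_probes, "mean": config.hk_mean}
                     if config.normalization == "hk_mean" else {})
        if config.normalize_within_compartments:
            comp = roi_table.set_index("roi_id")["compartment"]
            nm = normalize_within_groups(kept, panel, comp,
                                         method=config.normalization,
                                         **hk_kwargs)
        elif config.normalization == "hk_mean":
            nm = normalize_hk(kept, panel, probes=config.hk_probes,
                              mean=config.hk_mean)
        else:
            nm = normalize_counts(kept, panel, method=config.normalization)
        norm_paths = dsp_io.write_results({
            "normalizer_assessment": assessment.correlations.rename_axis("factor"),
            "factors": nm.factors.rename("factor").rename_axis("roi_id").to_frame(),
        }, out_dir)
        normalized_path = os.path.join(out_dir, "normalized.tsv")
        dsp_io.write_counts(nm.values, normalized_path)
        manifest["stages"]["normalize"] = {
            "method": nm.method, "recommended_factor": assessment.recommended,
            "n_rois": len(nm.values),
            "outputs": norm_paths + [normalized_path],
        }

        # ----------------------------------------------------- diffexp
        current = "diffexp"
        de_paths = []
        n_de = 0
        for spec in config.comparisons:
            design_kind = spec.get("design", "paired")
            result = diffexp.run_comparison(nm, roi_table, spec["comparison"],
                                            design=design_kind,
                                            probes=robust_targets)
            label = f"de_{spec['comparison']}_{design_kind}"
            de_paths += dsp_io.write_results({label: result}, out_dir)
            n_de += len(result)
        manifest["stages"]["diffexp"] = {"n_tests": n_de, "outputs": de_paths}

        # ------------------------------------------------- correlation
        current = "correlation"
        corr_paths = []
        for comp in dsp_io.COMPARTMENTS:
            n_comp = int((roi_table["compartment"] == comp).sum())
            if n_comp < 3:
                continue
            cm = diffexp.correlation_matrix(nm, roi_table, comp,
                                            probes=robust_targets,
                                            alpha=config.correlation_alpha)
            corr_paths += dsp_io.write_results(
                {f"corr_{comp}": cm.r.rename_axis("probe_id")}, out_dir)
        manifest["stages"]["correlation"] = {"outputs": corr_paths}

        # ----------------------------------------------------- cluster
        current = "cluster"
        est = cluster_mod.ExpressionClustering(
            k=config.cluster_k, seed=config.cluster_seed,
            restarts=config.cluster_restarts).fit(nm)
        res = est.result()
        ordered = res.scaled.iloc[res.order]
        clusters = pd.DataFrame({
            "roi_id": res.labels.index,
            "kmeans_class": res.labels.to_numpy(),
            "compartment": roi_table.set_index("roi_id").reindex(
                res.labels.index)["compartment"].to_numpy(),
        })
        cl_paths = dsp_io.write_results({
            "linkage": cluster_mod.linkage_frame(res.linkage),
            "clusters": clusters,
        }, out_dir)
        heatmap_path = os.path.join(out_dir, "heatmap_matrix.tsv")
        dsp_io.write_counts(ordered, heatmap_path)
        manifest["stages"]["cluster"] = {
            "k": config.cluster_k, "outputs": cl_paths + [heatmap_path]}

        # ---------------------------------------------------- survival
        current = "survival"
        sv_paths = []
        n_fits = 0
        if survival is not None:
            for comp in config.survival_compartments:
                table = surv_mod.screen_compartment(
                    nm, roi_table, survival, comp, probes=robust_targets,
                    dichotomize=config.dichotomize,
                    adjust=config.survival_adjust)
                sv_paths += dsp_io.write_results({f"cox_{comp}": table}, out_dir)
                n_fits += len(table)
        manifest["stages"]["survival"] = {"n_fits": n_fits, "outputs": sv_paths}
    except (dsp_io.ValidationError, ConfigError):
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(collector)

    manifest["warnings"] = collector.messages
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
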