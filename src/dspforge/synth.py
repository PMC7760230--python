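"""Synthetic DSP experiment generator with a ground-truth ledger.

Emulates the count structure of an antibody-barcode spatial profiling run
on a tumour tissue microarray: per-ROI capture-efficiency size factors,
negative-binomial probe counts, isotype-IgG background in the 50-150 count
range, ROI median counts between 1e2 and 1e3, systematically depressed
normal-adjacent-tissue (NAT) signal, patient-matched compartment pairs, and
survival times whose log-hazard depends on chosen marker expression.

Every draw is governed by one master seed split into named sub-streams, so
counts and survival are independently reproducible.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as dsp_io
from .panel import ProbePanel, make_default_panel

_STREAMS = ("patient_effects", "counts", "roi_covariates", "survival", "censoring")

#: deterministic baseline abundances (expected raw counts at unit size factor)
ABUNDANT_TARGETS = {
    "SMA": 3000.0, "Fibronectin": 2500.0, "PanCk": 2200.0, "Beta-2M": 1800.0,
    "CD44": 1200.0, "CD45": 1100.0, "HLA-DR": 1000.0, "CD68": 900.0,
    "B7-H3": 850.0,
}
FEATURED_TARGETS = {
    "EpCAM": 420.0, "PTEN": 320.0, "CD3": 260.0, "CD34": 240.0, "CD4": 220.0,
    "CD45RO": 180.0, "CD163": 160.0, "Ki-67": 150.0, "CD27": 140.0,
    "ICOS": 130.0, "VISTA": 120.0, "ARG1": 115.0, "IDO1": 110.0,
    "LAG3": 105.0, "PD-L1": 60.0,
}
HOUSEKEEPER_MEANS = {"Histone H3": 1500.0, "S6": 1200.0, "GAPDH": 800.0}

#: default compartment log2 enrichments, mirroring an immune-infiltrated TME
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    **{p: {"TME": 1.5} for p in
       ("CD27", "CD3", "CD4", "CD44", "CD45", "CD45RO", "CD68", "CD163", "VISTA")},
    **{p: {"Tumour": 1.5} for p in ("Ki-67", "EpCAM", "PanCk")},
    **{p: {"NAT": 1.0} for p in
       ("CD34", "Fibronectin", "IDO1", "LAG3", "ARG1", "PTEN")},
}

#: default protective markers (log-hazard per log2 expression unit)
DEFAULT_SURVIVAL_BETAS = {
    "CD3": math.log(0.5), "CD34": math.log(0.53), "ICOS": math.log(0.6),
}


class DesignError(ValueError):
    """Raised for invalid simulation designs."""


def _baseline_means(panel: ProbePanel, lo: float = 45.0, hi: float = 500.0) -> dict[str, float]:
    """Deterministic per-probe baselines: named markers fixed, the rest
    log-spaced over [lo, hi] in panel order (a subset lands below the IgG
    background, as real panels do)."""
    means: dict[str, float] = {}
    rest = [p for p in panel.targets
            if p not in ABUNDANT_TARGETS and p not in FEATURED_TARGETS]
    for i, p in enumerate(rest):
        frac = i / max(len(rest) - 1, 1)
        means[p] = lo * (hi / lo) ** frac
    means.update({p: v for p, v in ABUNDANT_TARGETS.items() if p in panel})
    means.update({p: v for p, v in FEATURED_TARGETS.items() if p in panel})
    for p, v in HOUSEKEEPER_MEANS.items():
        if p in panel:
            means[p] = v
    return means


@dataclass
class SimulationDesign:
    """Data-generating assumptions for one synthetic experiment.

    ``patients`` maps patient_id -> tuple of compartments profiled for that
    patient; each (patient, compartment) yields one ROI unless
    ``rois_per_patient_compartment`` > 1.
    """

    panel: ProbePanel = field(repr=False)
    patients: dict[str, tuple[str, ...]] = field(repr=False)
    background_mean: float = 100.0
    roi_size_factor_sd: float = 0.2
    nat_depression: float = 0.7
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)
    dispersion: float = 0.008
    patient_effect_sd: float = 0.4
    gapdh_extra_sd: float = 0.35
    survival_betas: dict[str, float] = field(default_factory=dict)
    base_rate: float = 0.02
    censor_rate: float = 0.3
    survival_compartment: str = "Tumour"
    rois_per_patient_compartment: int = 1
    area_scale: float = 160_000.0
    area_max: float = 282_743.0
    nuclei_scale: float = 400.0
    baseline_means: dict[str, float] | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patients:
            raise DesignError("design requires at least one patient")
        if len(self.panel) == 0:
            raise DesignError("design requires a non-empty panel")
        if not 0.0 < self.nat_depression <= 1.0:
            raise DesignError("nat_depression must be in (0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise DesignError("censor_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise DesignError("dispersion must be > 0")
        known = set(self.panel.probe_ids)
        for name, mapping in (("effect_table", self.effect_table),
                              ("survival_betas", self.survival_betas)):
            unknown = set(mapping) - known
            if unknown:
                raise DesignError(f"{name} references unknown probe(s): {sorted(unknown)}")
        for comp_set in self.patients.values():
            for c in comp_set:
                if c not in dsp_io.COMPARTMENTS:
                    raise DesignError(
                        f"unknown compartment {c!r}; allowed: {list(dsp_io.COMPARTMENTS)}"
                    )
        if self.baseline_means is None:
            self.baseline_means = _baseline_means(self.panel)

    @property
    def n_patients(self) -> int:
        return len(self.patients)


@dataclass
class GroundTruth:
    """Truth ledger: everything needed for parameter-recovery tests."""

    size_factors: pd.Series = field(repr=False)          # per ROI
    compartment_means: pd.DataFrame = field(repr=False)  # probe x compartment E[count]
    patient_effects: pd.DataFrame = field(repr=False)    # patient x target multipliers
    patient_log2_expression: pd.DataFrame = field(repr=False)  # patient x beta-probes
    log_hazard: pd.Series = field(repr=False)            # per patient (centred)
    seed: int = 0


# ---------------------------------------------------------------------------
# canned designs

def default_patient_pattern() -> dict[str, tuple[str, ...]]:
    """62 patients whose compartment sets reproduce a 96-ROI TMA layout:
    45 tumour, 32 TME and 19 NAT ROIs with 18 tumour-TME, 14 NAT-tumour and
    8 TME-NAT matched pairs."""
    groups = [
        (("Tumour", "TME", "NAT"), 6),
        (("Tumour", "TME"), 12),
        (("Tumour", "NAT"), 8),
        (("TME", "NAT"), 2),
        (("Tumour",), 19),
        (("TME",), 12),
        (("NAT",), 3),
    ]
    patients: dict[str, tuple[str, ...]] = {}
    i = 1
    for comps, n in groups:
        for _ in range(n):
            patients[f"P{i:03d}"] = comps
            i += 1
    return patients


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """The reference study conditions used throughout the test-suite."""
    kwargs = dict(
        panel=make_default_panel(),
        patients=default_patient_pattern(),
        effect_table={p: dict(v) for p, v in DEFAULT_EFFECTS.items()},
        survival_betas=dict(DEFAULT_SURVIVAL_BETAS),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


def paired_design(n_pairs: int, compartments: tuple[str, str] = ("Tumour", "TME"),
                  seed: int = 0, **overrides) -> SimulationDesign:
    """A fully matched two-compartment design with ``n_pairs`` patients."""
    patients = {f"P{i + 1:03d}": tuple(compartments) for i in range(n_pairs)}
    kwargs = dict(
        panel=make_default_panel(),
        patients=patients,
        effect_table={},
        survival_betas={},
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


# ---------------------------------------------------------------------------
# simulation

def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with Var = mu + alpha * mu^2 (gamma-Poisson mixture)."""
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def _expected_mean(design: SimulationDesign, probe: str, cls: str, comp: str) -> float:
    """Expected count at unit size factor for (probe, compartment)."""
    if cls == "igg_control":
        return design.background_mean
    base = design.baseline_means[probe]
    if cls == "housekeeper":
        return base
    eff = design.effect_table.get(probe, {}).get(comp, 0.0)
    nat = design.nat_depression if comp == "NAT" else 1.0
    return base * 2.0 ** eff * nat


def simulate_counts(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic experiment.

    Returns ``(counts, roi_table, truth)`` where counts is ROIs x probes,
    roi_table carries compartment/pairing/area/nuclei metadata and truth is
    the :class:`GroundTruth` ledger.
    """
    rngs = _streams(design.seed)
    panel = design.panel
    probes = panel.probe_ids
    classes = {p: panel.probe_class(p) for p in probes}
    targets = panel.targets
    patients = list(design.patients)

    # per-patient biological multipliers on target probes (mean 1)
    sd_b = design.patient_effect_sd
    if sd_b > 0 and targets:
        b = rngs["patient_effects"].lognormal(
            -0.5 * sd_b ** 2, sd_b, size=(len(patients), len(targets)))
    else:
        b = np.ones((len(patients), len(targets)))
    patient_effects = pd.DataFrame(b, index=patients, columns=targets)

    # ROI layout
    rows = []
    for pt in patients:
        for comp in design.patients[pt]:
            for _ in range(design.rois_per_patient_compartment):
                rows.append((pt, comp))
    roi_ids = [f"ROI{i + 1:03d}" for i in range(len(rows))]

    rng_c = rngs["counts"]
    sd_s = design.roi_size_factor_sd
    s = (rng_c.lognormal(0.0, sd_s, size=len(roi_ids))
         if sd_s > 0 else np.ones(len(roi_ids)))
    size_factors = pd.Series(s, index=roi_ids, name="size_factor")

    # expected mean matrix
    mean = np.empty((len(roi_ids), len(probes)))
    tgt_col = {p: j for j, p in enumerate(targets)}
    pt_row = {pt: i for i, pt in enumerate(patients)}
    for i, ((pt, comp), _) in enumerate(zip(rows, roi_ids)):
        pi = pt_row[pt]
        for j, p in enumerate(probes):
            m = _expected_mean(design, p, classes[p], comp)
            if classes[p] == "target":
                m *= b[pi, tgt_col[p]]
            mean[i, j] = m * s[i]
    # GAPDH tracks abundance only loosely in real runs; give it extra noise
    if "GAPDH" in probes and design.gapdh_extra_sd > 0:
        g = design.gapdh_extra_sd
        j = probes.index("GAPDH")
        mean[:, j] *= rng_c.lognormal(-0.5 * g ** 2, g, size=len(roi_ids))

    counts = pd.DataFrame(
        _nb_draw(rng_c, mean, design.dispersion), index=roi_ids, columns=probes)
    counts.index.name = "roi_id"

    # ROI covariates: noisy monotone transforms of the size factor
    rng_r = rngs["roi_covariates"]
    area = design.area_scale * s * rng_r.lognormal(0.0, 0.15, size=len(roi_ids))
    area = np.minimum(area, design.area_max)
    nuclei = rng_r.poisson(design.nuclei_scale * s
                           * rng_r.lognormal(0.0, 0.10, size=len(roi_ids)))
    roi_table = pd.DataFrame({
        "roi_id": roi_ids,
        "patient_id": [pt for pt, _ in rows],
        "compartment": [comp for _, comp in rows],
        "area": area,
        "nuclei": nuclei,
        "shape": "geometric",
    })

    # truth ledger
    es = math.exp(0.5 * sd_s ** 2)  # E[size factor]
    comp_means = pd.DataFrame(
        {c: [_expected_mean(design, p, classes[p], c) * es for p in probes]
         for c in dsp_io.COMPARTMENTS},
        index=pd.Index(probes, name="probe_id"),
    )

    beta_probes = list(design.survival_betas)
    x = np.zeros((len(patients), len(beta_probes)))
    for j, p in enumerate(beta_probes):
        mu = _expected_mean(design, p, classes[p], design.survival_compartment)
        pe = (patient_effects[p].to_numpy()
              if p in patient_effects.columns else np.ones(len(patients)))
        x[:, j] = np.log2(mu * pe)
    patient_log2 = pd.DataFrame(x, index=patients, columns=beta_probes)
    if beta_probes:
        centred = x - x.mean(axis=0, keepdims=True)
        lp = centred @ np.array([design.survival_betas[p] for p in beta_probes])
    else:
        lp = np.zeros(len(patients))
    log_hazard = pd.Series(lp, index=patients, name="log_hazard")

    truth = GroundTruth(
        size_factors=size_factors,
        compartment_means=comp_means,
        patient_effects=patient_effects,
        patient_log2_expression=patient_log2,
        log_hazard=log_hazard,
        seed=design.seed,
    )
    return counts, roi_table, truth


def simulate_survival(truth: GroundTruth, design: SimulationDesign) -> pd.DataFrame:
    """Draw per-patient follow-up: exponential event times with rate
    ``base_rate * exp(log_hazard)`` and independent exponential censoring
    calibrated so a ``censor_rate`` fraction of baseline records is censored.
    """
    if truth.seed != design.seed:
        raise DesignError("truth ledger and design come from different runs")
    if set(truth.log_hazard.index) != set(design.patients):
        raise DesignError("truth ledger patient set does not match design")
    rngs = _streams(design.seed)
    patients = list(truth.log_hazard.index)
    rate = design.base_rate * np.exp(truth.log_hazard.to_numpy())
    t_event = rngs["survival"].exponential(1.0 / rate)
    if design.censor_rate > 0:
        c = design.censor_rate
        rate_c = design.base_rate * c / (1.0 - c)
        t_cens = rngs["censoring"].exponential(1.0 / rate_c, size=len(patients))
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
    else:
        time, event = t_event, np.ones(len(patients), dtype=bool)
    return pd.DataFrame({"patient_id": patients, "time": time, "event": event})


def write_simulation(
    out_dir: str | os.PathLike,
    counts: pd.DataFrame,
    roi_table: pd.DataFrame,
    panel: ProbePanel,
    truth: GroundTruth,
    survival: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Emit the generated experiment in the formats the io module reads,
    plus the truth ledger (size factors and compartment means)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["counts"] = os.path.join(out_dir, "counts.tsv")
    dsp_io.write_counts(counts, paths["counts"])
    paths["rois"] = os.path.join(out_dir, "rois.tsv")
    dsp_io.write_table(roi_table, paths["rois"])
    paths["panel"] = os.path.join(out_dir, "panel.tsv")
    dsp_io.write_table(panel.table, paths["panel"])
    if survival is not None:
        paths["survival"] = os.path.join(out_dir, "survival.tsv")
        out = survival.copy()
        out["event"] = out["event"].astype(int)
        dsp_io.write_table(out, paths["survival"])
    ledger = truth.size_factors.rename_axis("roi_id").reset_index()
    paths["truth_size_factors"] = os.path.join(out_dir, "truth_size_factors.tsv")
    dsp_io.write_table(ledger, paths["truth_size_factors"])
    paths["truth_means"] = os.path.join(out_dir, "truth_compartment_means.tsv")
    dsp_io.write_table(truth.compartment_means, paths["truth_means"], index=True)
    return paths


def replace_design(design: SimulationDesign, **changes) -> SimulationDesign:
    """Functional update of a design (re-validates invariants)."""
    return replace(design, **changes)
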