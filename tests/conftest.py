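import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dspforge as dsp
from dspforge.panel import ProbePanel

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> ProbePanel:
    return dsp.make_default_panel()


@pytest.fixture(scope="session")
def default_sim():
    """One default 96-ROI experiment shared across tests (seed fixed)."""
    design = dsp.default_design(seed=7)
    counts, rois, truth = dsp.simulate_counts(design)
    return design, counts, rois, truth


@pytest.fixture()
def tiny_panel() -> ProbePanel:
    return ProbePanel(pd.DataFrame({
        "probe_id": ["A", "B", "Rb IgG", "Ms IgG1", "Histone H3", "S6"],
        "probe_class": ["target", "target", "igg_control", "igg_control",
                        "housekeeper", "housekeeper"],
        "module": ["M1", "M1", "Controls", "Controls", "Controls", "Controls"],
    }))


@pytest.fixture()
def tiny_counts(tiny_panel) -> pd.DataFrame:
    # hand-checkable 3-ROI instance
    return pd.DataFrame(
        {
            "A": [100.0, 200.0, 50.0],
            "B": [50.0, 100.0, 25.0],
            "Rb IgG": [80.0, 160.0, 40.0],
            "Ms IgG1": [120.0, 240.0, 60.0],
            "Histone H3": [200.0, 400.0, 100.0],
            "S6": [400.0, 800.0, 200.0],
        },
        index=pd.Index(["R1", "R2", "R3"], name="roi_id"),
    )


@pytest.fixture()
def tiny_rois() -> pd.DataFrame:
    return pd.DataFrame({
        "roi_id": ["R1", "R2", "R3"],
        "patient_id": ["P1", "P1", "P2"],
        "compartment": ["Tumour", "TME", "NAT"],
        "area": [1000.0, 2000.0, 500.0],
        "nuclei": [100, 200, 50],
        "shape": ["geometric"] * 3,
    })


def nb_small_panel(n_targets: int = 30) -> ProbePanel:
    """Reduced panel for replicate-heavy simulations."""
    full = dsp.make_default_panel()
    targets = full.targets[:n_targets]
    keep = targets + full.igg_controls + ["Histone H3", "S6"]
    return full.subset(keep)
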