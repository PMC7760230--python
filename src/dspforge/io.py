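"""Reading, writing and cross-file validation of the tabular artifacts.

All files are tab-delimited UTF-8 with a header row and '.' decimal point.
Compartment labels are case-insensitive on input and canonicalized to
``Tumour`` / ``TME`` / ``NAT`` on output.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import ProbePanel

logger = logging.getLogger("dspforge")

COMPARTMENTS = ("Tumour", "TME", "NAT")
_CANON = {c.lower(): c for c in COMPARTMENTS}
ROI_SHAPES = ("geometric", "custom")

#: significant digits used by every writer
FLOAT_FORMAT = "%.6g"


class ValidationError(ValueError):
    """A malformed or inconsistent input file."""


def canonical_compartment(label: str) -> str:
    try:
        return _CANON[str(label).strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown compartment {label!r}; allowed values: {list(COMPARTMENTS)}"
        ) from None


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read an ROIs x probes count matrix.

    First column is ``roi_id``; remaining columns are probe ids. Returns a
    DataFrame indexed by roi_id with float values.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected roi_id column plus >=1 probe column")
    first = df.columns[0]
    if first != "roi_id":
        raise ValidationError(f"{path}: missing required column(s): ['roi_id']")
    if df["roi_id"].duplicated().any():
        dup = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValidationError(f"{path}: duplicate roi_id(s): {dup}")
    counts = df.set_index("roi_id")
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count value ({exc})") from None
    if not np.isfinite(counts.to_numpy()).all():
        bad = counts.index[~np.isfinite(counts).all(axis=1)].tolist()
        raise ValidationError(f"{path}: non-finite counts in ROI(s) {bad}")
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)].tolist()
        raise ValidationError(f"{path}: negative counts in ROI(s) {bad}")
    return counts


def read_roi_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read ROI metadata: roi_id, patient_id, compartment, area, nuclei, shape."""
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str, "patient_id": str})
    _require_columns(df, ["roi_id", "compartment"], str(path))
    if df["roi_id"].duplicated().any():
        dup = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValidationError(f"{path}: duplicate roi_id(s): {dup}")
    df["compartment"] = df["compartment"].map(canonical_compartment)
    for col, default in (("patient_id", None), ("area", np.nan),
                         ("nuclei", np.nan), ("shape", "geometric")):
        if col not in df.columns:
            df[col] = default
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].replace({"": None})
    area = pd.to_numeric(df["area"], errors="coerce")
    if ((area <= 0) & area.notna()).any():
        bad = df.loc[(area <= 0) & area.notna(), "roi_id"].tolist()
        raise ValidationError(f"{path}: non-positive area for ROI(s) {bad}")
    df["area"] = area
    df["nuclei"] = pd.to_numeric(df["nuclei"], errors="coerce")
    bad_shape = set(df["shape"].dropna()) - set(ROI_SHAPES)
    if bad_shape:
        raise ValidationError(
            f"{path}: unknown ROI shape {sorted(bad_shape)}; allowed: {list(ROI_SHAPES)}"
        )
    return df.reset_index(drop=True)


def read_panel(path: str | os.PathLike) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["probe_id", "probe_class", "module"], str(path))
    return ProbePanel(df)


def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    """Read patient survival: patient_id, time (months), event (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, ["patient_id", "time", "event"], str(path))
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"{path}: duplicate patient_id(s): {dup}")
    df["time"] = pd.to_numeric(df["time"])
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "patient_id"].tolist()
        raise ValidationError(f"{path}: non-positive time for patient(s) {bad}")
    ev = df["event"]
    if not set(pd.unique(ev.astype(int))) <= {0, 1}:
        raise ValidationError(f"{path}: event must be 0/1")
    df["event"] = ev.astype(int).astype(bool)
    return df.reset_index(drop=True)


def check_consistency(
    counts: pd.DataFrame,
    roi_table: pd.DataFrame,
    panel: ProbePanel,
    survival: pd.DataFrame | None = None,
) -> None:
    """Cross-file invariants: ROI and probe identifiers must all resolve."""
    roi_ids = set(roi_table["roi_id"])
    missing_rois = [r for r in counts.index if r not in roi_ids]
    if missing_rois:
        raise ValidationError(
            f"counts reference roi_id(s) absent from ROI table: {missing_rois[:5]}"
        )
    known = set(panel.probe_ids)
    missing_probes = [p for p in counts.columns if p not in known]
    if missing_probes:
        raise ValidationError(
            f"counts reference probe_id(s) absent from panel: {missing_probes[:5]}"
        )
    if survival is not None:
        pts = set(survival["patient_id"])
        linked = roi_table["patient_id"].dropna()
        unmatched = sorted(set(linked) - pts)
        if unmatched:
            logger.warning(
                "%d patient id(s) in ROI table have no survival record: %s",
                len(unmatched), unmatched[:5],
            )


# ---------------------------------------------------------------------------
# writers

def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    out = counts.copy()
    out.index.name = "roi_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_results(results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> list[str]:
    """Write one TSV per named result table; returns the paths written."""
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out_dir}: {exc}")
    if not os.access(out_dir, os.W_OK):
        raise ValidationError(f"output directory not writable: {out_dir}")
    paths = []
    for name, df in results.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        indexed = df.index.name is not None
        write_table(df, path, index=indexed)
        logger.info("wrote %s (%d rows)", path, len(df))
        paths.append(path)
    return paths
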