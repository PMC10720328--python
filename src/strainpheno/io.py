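"""Readers and writers for the package's plain-text interchange formats.

Trace dialect (one file per subject, tab-separated)::

    #frame_rate_hz	62.5
    #r_peak_s	0.0
    #p_peak_s	0.71
    #avc_s	0.33
    time_s	strain_pct
    0.0	0.0
    0.016	-0.95
    ...

Floats are written with ``repr`` so files round-trip bit-identically through
``read_trace``.  A two-column headerless export with landmarks in a sidecar
JSON (``{"frame_rate_hz": ..., "r_peak_s": ..., "avc_s": ..., "p_peak_s":
...}``) is also accepted, to accommodate clinical workstation exports.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .preprocess import CardiacLandmarks, StrainTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_trace_with_sidecar",
    "read_cohort_table",
    "write_cohort_table",
    "FEATURE_COLUMNS",
    "read_feature_matrix",
    "write_feature_matrix",
]

#: Column order of the feature-matrix CSV.
FEATURE_COLUMNS = [
    "slope_sys",
    "slope_ed",
    "slope_ld",
    "diastasis_dur",
    "diastasis_height",
    "peak_strain",
]


def write_trace(trace: StrainTrace, path: str | Path) -> Path:
    path = Path(path)
    lm = trace.landmarks
    lines = [f"#frame_rate_hz\t{float(trace.frame_rate)!r}"]
    if lm is not None:
        lines += [
            f"#r_peak_s\t{float(lm.r_peak)!r}",
            f"#p_peak_s\t{float(lm.p_peak)!r}",
            f"#avc_s\t{float(lm.avc)!r}",
        ]
    lines.append("time_s\tstrain_pct")
    for t, s in zip(trace.time, trace.strain):
        lines.append(f"{float(t)!r}\t{float(s)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path: str | Path, subject_id: str | None = None) -> StrainTrace:
    path = Path(path)
    meta: dict[str, float] = {}
    times: list[float] = []
    strains: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("\t")
            meta[key.strip()] = float(val)
        elif line.startswith("time_s"):
            continue
        else:
            t, _, s = line.partition("\t")
            times.append(float(t))
            strains.append(float(s))
    if "frame_rate_hz" not in meta:
        raise ValueError(f"{path}: missing #frame_rate_hz header")
    landmarks = None
    if {"r_peak_s", "avc_s", "p_peak_s"} <= meta.keys():
        landmarks = CardiacLandmarks(
            r_peak=meta["r_peak_s"], avc=meta["avc_s"], p_peak=meta["p_peak_s"]
        )
    return StrainTrace(
        subject_id=subject_id or path.stem,
        time=np.array(times),
        strain=np.array(strains),
        frame_rate=meta["frame_rate_hz"],
        landmarks=landmarks,
    )


def read_trace_with_sidecar(
    data_path: str | Path, sidecar_path: str | Path, subject_id: str | None = None
) -> StrainTrace:
    """Read a headerless two-column (time, strain) file plus a landmark JSON."""
    data_path = Path(data_path)
    arr = np.loadtxt(data_path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{data_path}: expected two columns (time_s, strain_pct)")
    meta = json.loads(Path(sidecar_path).read_text())
    landmarks = CardiacLandmarks(
        r_peak=float(meta["r_peak_s"]),
        avc=float(meta["avc_s"]),
        p_peak=float(meta["p_peak_s"]),
    )
    return StrainTrace(
        subject_id=subject_id or data_path.stem,
        time=arr[:, 0],
        strain=arr[:, 1],
        frame_rate=float(meta["frame_rate_hz"]),
        landmarks=landmarks,
    )


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> Path:
    """Write the subjects x 6 feature matrix CSV.

    Expects columns ``subject_id``, the six feature columns and
    ``degenerate_flag`` (diastasis not detected and imputed).
    """
    cols = ["subject_id", *FEATURE_COLUMNS, "degenerate_flag"]
    missing = set(cols) - set(features.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns: {sorted(missing)}")
    features[cols].to_csv(path, index=False)
    return Path(path)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(["subject_id", *FEATURE_COLUMNS]) - set(df.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns: {sorted(missing)}")
    return df
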