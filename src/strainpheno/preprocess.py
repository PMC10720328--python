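"""Quality control, landmark-based alignment and strain-rate derivation.

Left-ventricular longitudinal strain traces arrive with heterogeneous heart
rates and acquisition frame rates, so curves from different subjects are not
directly comparable sample-by-sample.  This module filters out unusable
recordings, splits each trace at the ECG landmarks (R-peak, aortic valve
closure, P-peak), resamples each inter-landmark segment onto a cohort-wide
common sample count, and derives strain-rate curves by finite differencing.

Strain is stored signed (physiologic longitudinal strain is negative);
downstream feature extraction and reporting use magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CardiacLandmarks",
    "StrainTrace",
    "AlignedCurve",
    "StrainRateCurve",
    "qc_filter",
    "align_and_resample",
    "strain_rate",
    "cluster_centroids",
    "MIN_SAMPLES",
]

#: Minimum number of samples for a trace to be considered analyzable.
MIN_SAMPLES = 20

#: Tolerated relative deviation of the median sampling interval from the
#: nominal 1/frame_rate.
_SAMPLING_TOL = 0.10


@dataclass(frozen=True)
class CardiacLandmarks:
    """ECG landmark times (seconds, same clock as the trace time axis).

    ``r_peak`` marks the start of the cycle, ``avc`` (aortic valve closure)
    end-systole, and ``p_peak`` atrial activation in late diastole.
    """

    r_peak: float
    avc: float
    p_peak: float

    def ordered(self, cycle_end: float) -> bool:
        return 0.0 <= self.r_peak < self.avc < self.p_peak < cycle_end


@dataclass
class StrainTrace:
    """One subject's LV longitudinal strain curve over a single cardiac cycle.

    ``strain`` is signed (negative during systole); ``time`` starts at 0 at
    the R-peak.  Invariant violations are not raised at construction time —
    they are reported by :func:`qc_filter` so that a cohort containing bad
    recordings can still be loaded and triaged.
    """

    subject_id: str
    time: np.ndarray
    strain: np.ndarray
    frame_rate: float
    landmarks: CardiacLandmarks | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.time.shape != self.strain.shape:
            raise ValueError("time and strain must have equal length")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def cycle_end(self) -> float:
        return float(self.time[-1])

    def qc_reasons(self, min_frame_rate: float = 45.0) -> list[str]:
        """Machine-readable reasons this trace should be excluded (empty if none)."""
        reasons: list[str] = []
        if self.frame_rate < min_frame_rate:
            reasons.append("frame_rate")
        if self.n_samples < MIN_SAMPLES:
            reasons.append("too_few_samples")
        if np.any(np.diff(self.time) <= 0):
            reasons.append("non_monotone_time")
        if self.landmarks is None:
            reasons.append("missing_landmarks")
        elif not self.landmarks.ordered(self.cycle_end):
            reasons.append("landmark_order")
        if not reasons:
            dt = float(np.median(np.diff(self.time)))
            if abs(dt - 1.0 / self.frame_rate) > _SAMPLING_TOL / self.frame_rate:
                reasons.append("sampling_interval")
        return reasons


@dataclass
class AlignedCurve:
    """A strain curve resampled onto the cohort-common index grid.

    All curves in an aligned cohort share the same length and the same
    landmark indices ``boundaries = (r_idx, avc_idx, p_idx)``; the ``time``
    axis remains subject-specific (each segment spans the subject's own
    inter-landmark duration) so that slopes in %/s and durations in seconds
    keep their physical meaning.
    """

    subject_id: str
    strain: np.ndarray
    time: np.ndarray
    boundaries: tuple[int, int, int]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.strain)

    @property
    def n_samples(self) -> int:
        return self.strain.size


@dataclass
class StrainRateCurve:
    """First-difference strain rate (%/s) on a trace's native grid."""

    subject_id: str
    values: np.ndarray
    time: np.ndarray  # midpoints of the differencing intervals


def qc_filter(
    traces: Iterable[StrainTrace], min_frame_rate: float = 45.0
) -> tuple[list[StrainTrace], list[tuple[StrainTrace, str]]]:
    """Partition traces into analyzable ones and excluded ones with reasons.

    Recordings below ``min_frame_rate`` Hz are excluded (default 45 Hz), as
    are traces with non-monotone time axes, missing or mis-ordered ECG
    landmarks, too few samples, or a sampling interval inconsistent with the
    declared frame rate.  The union of the two returned lists is the input.
    """
    kept: list[StrainTrace] = []
    excluded: list[tuple[StrainTrace, str]] = []
    for tr in traces:
        reasons = tr.qc_reasons(min_frame_rate=min_frame_rate)
        if reasons:
            excluded.append((tr, reasons[0]))
        else:
            kept.append(tr)
    return kept, excluded


def _segment_slices(trace: StrainTrace) -> list[tuple[float, float]]:
    lm = trace.landmarks
    assert lm is not None
    return [(lm.r_peak, lm.avc), (lm.avc, lm.p_peak), (lm.p_peak, trace.cycle_end)]


def _segment_counts(trace: StrainTrace) -> list[int]:
    counts = []
    for lo, hi in _segment_slices(trace):
        counts.append(int(np.sum((trace.time >= lo) & (trace.time <= hi))))
    return counts


def align_and_resample(
    traces: Sequence[StrainTrace],
    target_lengths: Sequence[int] | None = None,
) -> tuple[list[AlignedCurve], list[tuple[StrainTrace, str]]]:
    """Landmark-align a cohort onto a common per-segment sample grid.

    Each trace is split at (R, AVC, P) into systolic, early-diastolic +
    diastasis, and late-diastolic segments.  Each segment is linearly
    interpolated onto a fixed number of samples — the maximum native sample
    count of that segment over the cohort (i.e. the longest recorded
    sequence, segment-wise) — so that landmarks land on identical indices
    for every subject.  Samples preceding the R-peak are discarded.

    Returns ``(aligned, rejected)`` where rejected traces carry reason
    ``degenerate_segment`` (a segment with fewer than 2 native samples).

    Pass ``target_lengths`` (3 ints) to resample onto a pre-existing grid,
    e.g. when applying a frozen model to an external cohort.
    """
    usable: list[StrainTrace] = []
    rejected: list[tuple[StrainTrace, str]] = []
    for tr in traces:
        if tr.landmarks is None:
            rejected.append((tr, "missing_landmarks"))
            continue
        if min(_segment_counts(tr)) < 2:
            rejected.append((tr, "degenerate_segment"))
            continue
        usable.append(tr)

    if not usable:
        return [], rejected

    if target_lengths is None:
        counts = np.array([_segment_counts(tr) for tr in usable])
        target_lengths = counts.max(axis=0).tolist()
    if len(target_lengths) != 3 or any(n < 2 for n in target_lengths):
        raise ValueError("target_lengths must be three integers >= 2")

    aligned: list[AlignedCurve] = []
    n1, n2, n3 = (int(n) for n in target_lengths)
    avc_idx, p_idx = n1 - 1, n1 + n2 - 2
    for tr in usable:
        times: list[np.ndarray] = []
        for (lo, hi), n in zip(_segment_slices(tr), (n1, n2, n3)):
            seg_t = np.linspace(lo, hi, n)
            times.append(seg_t if not times else seg_t[1:])
        t = np.concatenate(times)
        y = np.interp(t, tr.time, tr.strain)
        aligned.append(
            AlignedCurve(
                subject_id=tr.subject_id,
                strain=y,
                time=t - t[0],
                boundaries=(0, avc_idx, p_idx),
            )
        )
    return aligned, rejected


def strain_rate(trace: StrainTrace) -> StrainRateCurve:
    """Strain rate (%/s) as consecutive-sample differences on the native grid."""
    if trace.n_samples < 2:
        raise ValueError("strain_rate requires at least 2 samples")
    dt = np.diff(trace.time)
    if np.any(dt == 0):
        raise ValueError(f"duplicate time stamps in trace {trace.subject_id!r}")
    values = np.diff(trace.strain) / dt
    return StrainRateCurve(
        subject_id=trace.subject_id,
        values=values,
        time=(trace.time[:-1] + trace.time[1:]) / 2.0,
    )


def _aligned_rate(curve: AlignedCurve) -> np.ndarray:
    return np.diff(curve.strain) / np.diff(curve.time)


@dataclass
class Centroid:
    """Per-cluster mean curves on the common aligned grid."""

    label: int
    n: int
    strain: np.ndarray
    strain_rate: np.ndarray
    time: np.ndarray  # mean subject time axis, for plotting


def cluster_centroids(
    aligned: Sequence[AlignedCurve], labels: Sequence[int]
) -> dict[int, Centroid]:
    """Pointwise mean strain and strain-rate curve per cluster label."""
    labels = np.asarray(labels)
    if len(aligned) != labels.size:
        raise ValueError("labels must align one-to-one with curves")
    if len(aligned) == 0:
        raise ValueError("empty cohort")
    out: dict[int, Centroid] = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"empty label group {lab}")
        strains = np.stack([aligned[i].strain for i in idx])
        rates = np.stack([_aligned_rate(aligned[i]) for i in idx])
        times = np.stack([aligned[i].time for i in idx])
        out[int(lab)] = Centroid(
            label=int(lab),
            n=idx.size,
            strain=strains.mean(axis=0),
            strain_rate=rates.mean(axis=0),
            time=times.mean(axis=0),
        )
    return out
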