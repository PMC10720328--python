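"""Cardiac-phase segmentation and the six temporal strain features.

Each aligned curve is approximated by a continuous piecewise-linear
interpolant through a small set of knots chosen among the sample positions
to minimize the residual sum of squares (exact dynamic programming).  The
fitted segments delimit the cardiac phases:

* systole — R-peak to the global peak of strain magnitude;
* early diastole — peak to the onset of the flattest fitted segment between
  the peak and the P-wave;
* diastasis — that flattest segment (merged with adjacent sub-threshold
  segments), capped at the P-wave landmark;
* late diastole — end of diastasis to the end of the cycle.

From these phases six features are extracted per subject: the least-squares
slopes of strain magnitude over systole, early and late diastole (%/s), the
duration (s) and mean height (% magnitude) of the diastasis, and the peak
strain magnitude (%).  Systolic slope is positive and diastolic slopes are
negative under the magnitude convention (systole builds strain magnitude,
diastole releases it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FEATURE_COLUMNS
from .preprocess import AlignedCurve

__all__ = [
    "PhaseSegmentation",
    "FeatureVector",
    "fit_piecewise_linear",
    "extract_features",
    "build_feature_matrix",
    "PLATEAU_THRESHOLD",
]

#: Default plateau threshold (%/s magnitude): a fitted segment flatter than
#: this can belong to the diastasis.
PLATEAU_THRESHOLD = 10.0

#: A plateau candidate must sit below this fraction of peak strain: the
#: diastasis lies in the lower part of the release (height/peak is ~0.25-0.65
#: physiologically), while noise shelves on the upper decline and smoothed
#: peak corners sit close to the peak.
_LEVEL_FRAC = 0.75


@dataclass
class PhaseSegmentation:
    """Index intervals (inclusive endpoints) of the cardiac phases on the
    aligned grid, plus the fitted piecewise-linear knots.

    ``diastasis_times`` are the continuous plateau onset/offset times from
    the chord-intersection refinement (sub-sample precision); the index
    interval ``diastasis`` is their rounding to the sample grid.
    """

    systole: tuple[int, int]
    early_diastole: tuple[int, int]
    diastasis: tuple[int, int]
    late_diastole: tuple[int, int]
    knot_indices: np.ndarray
    knot_times: np.ndarray
    diastasis_times: tuple[float, float] = (0.0, 0.0)
    degenerate_diastasis: bool = False

    @property
    def peak_index(self) -> int:
        return self.systole[1]


@dataclass
class FeatureVector:
    """The six temporal features of one strain curve."""

    subject_id: str
    slope_sys: float
    slope_ed: float
    slope_ld: float
    diastasis_dur: float
    diastasis_height: float
    peak_strain: float
    degenerate_flag: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.slope_sys, self.slope_ed, self.slope_ld,
             self.diastasis_dur, self.diastasis_height, self.peak_strain]
        )


def _interp_knot_fit(x: np.ndarray, y: np.ndarray, n_knots: int) -> np.ndarray:
    """Indices of the RSS-optimal interpolating piecewise-linear knots.

    The approximation passes through the data at the chosen knots, which
    decouples segment costs and makes the dynamic program exact.  Endpoints
    are always knots; ``n_knots`` interior knots are placed.  Ties resolve to
    the earliest predecessor, so the result is deterministic.
    """
    n = x.size
    if n_knots + 2 > n:
        raise ValueError(f"n_knots={n_knots} exceeds available samples ({n})")
    # prefix sums for O(1) segment cost of the chord through (x_i,y_i),(x_j,y_j)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])

    idx = np.arange(n)

    def seg_cost_row(i: int) -> np.ndarray:
        """cost[i, j] for all j > i (vectorized over j)."""
        j = idx[i + 1:]
        b = (y[j] - y[i]) / (x[j] - x[i])
        a = y[i] - b * x[i]
        cnt = j - i + 1
        sx = cx[j + 1] - cx[i]
        sxx = cxx[j + 1] - cxx[i]
        sy = cy[j + 1] - cy[i]
        syy = cyy[j + 1] - cyy[i]
        sxy = cxy[j + 1] - cxy[i]
        cost = (syy - 2 * a * sy - 2 * b * sxy + a * a * cnt
                + 2 * a * b * sx + b * b * sxx)
        return np.maximum(cost, 0.0)

    cost = np.full((n, n), np.inf)
    for i in range(n - 1):
        cost[i, i + 1:] = seg_cost_row(i)

    n_seg = n_knots + 1
    # dp[s, j]: min cost of covering [0, j] with s segments ending at knot j
    dp = np.full((n_seg + 1, n), np.inf)
    prev = np.zeros((n_seg + 1, n), dtype=int)
    dp[1] = cost[0]
    dp[1, 0] = np.inf
    for s in range(2, n_seg + 1):
        cand = dp[s - 1][:, None] + cost  # cand[i, j]
        best = np.argmin(cand, axis=0)
        dp[s] = cand[best, idx]
        prev[s] = best
    knots = [n - 1]
    s, j = n_seg, n - 1
    while s > 1:
        j = int(prev[s, j])
        knots.append(j)
        s -= 1
    knots.append(0)
    return np.array(knots[::-1])


def fit_piecewise_linear(
    curve: AlignedCurve,
    n_knots: int = 5,
    plateau_threshold: float = PLATEAU_THRESHOLD,
) -> PhaseSegmentation:
    """Fit the knot approximation and derive the cardiac-phase intervals.

    A fitted segment is a plateau candidate when it lies between the strain
    peak and the P-wave, its |slope| is below ``plateau_threshold`` (%/s),
    and its level sits clearly below the peak (a smoothed peak corner or a
    noise shelf on the upper decline can otherwise masquerade as a plateau).  The
    flattest candidate, merged with adjacent candidates, forms the
    diastasis; its onset/offset are refined to sub-sample precision by
    intersecting the plateau chord with the nearest steep-decline chords on
    either side, which undoes the bias that corner rounding puts on the
    knot positions.  With no candidate the diastasis is empty (zero width
    at the P-wave) and flagged degenerate.
    """
    y = curve.magnitude
    x = curve.time
    _, _, p_idx = curve.boundaries
    knots = _interp_knot_fit(x, y, n_knots)

    peak_idx = int(np.argmax(y))
    if peak_idx == 0 or peak_idx >= p_idx:
        # noise pathologies; fall back to the AVC landmark
        peak_idx = curve.boundaries[1]
    peak_val = y[peak_idx]

    # per-segment slope from the OLS line over the segment interior: far more
    # noise-robust than the two-point knot chord, especially for short plateaus
    segs = [
        (int(a), int(b), _region_line(x, y, int(a), int(b))[0])
        for a, b in zip(knots[:-1], knots[1:])
    ]

    def eligible(i: int) -> bool:
        a, b, slope = segs[i]
        in_window = min(b, p_idx) > max(a, peak_idx)
        level_ok = (y[a] + y[b]) / 2.0 < _LEVEL_FRAC * peak_val
        return in_window and abs(slope) <= plateau_threshold and level_ok

    n_last = curve.n_samples - 1
    candidates = [i for i in range(len(segs)) if eligible(i)]
    a = b = None
    if candidates:
        # the diastasis is the plateau immediately preceding atrial
        # activation, so take the eligible segment closest to the P-wave
        # (a flat noise shelf higher up the decline must not win) and merge
        # adjacent eligible segments into it
        core = max(candidates, key=lambda i: segs[i][1])
        lo_i = hi_i = core
        while lo_i > 0 and eligible(lo_i - 1):
            lo_i -= 1
        while hi_i < len(segs) - 1 and eligible(hi_i + 1):
            hi_i += 1
        a, b = segs[lo_i][0], segs[hi_i][1]
    else:
        # the DP may not spend a segment on a very short plateau; scan the
        # peak..P window directly for the flattest ~50 ms stretch
        a_b = _plateau_scan(x, y, peak_idx, p_idx, plateau_threshold, peak_val)
        if a_b is not None:
            a, b = a_b

    degenerate = a is None
    if degenerate:
        d_start = d_end = min(p_idx, n_last - 1)
        t_start = t_end = x[d_start]
    else:
        plateau = _region_line(x, y, a, b)
        # nearest-first scans of fitted segments on either side; a segment
        # may straddle the plateau edge (fallback windows are not DP-aligned)
        scan_early = [i for i in range(len(segs)) if segs[i][0] < a][::-1]
        scan_late = [i for i in range(len(segs)) if segs[i][1] > b]
        t_start = _corner_time(
            x, y, segs, scan_early, plateau, plateau_threshold, x[a]
        )
        t_end = _corner_time(
            x, y, segs, scan_late, plateau, plateau_threshold, x[b]
        )
        # late diastole begins no later than the P-wave landmark
        t_start = float(np.clip(t_start, x[min(peak_idx + 1, p_idx)], x[p_idx]))
        t_end = float(np.clip(t_end, t_start, x[p_idx]))
        d_start = int(np.clip(_nearest(x, t_start), peak_idx + 1, p_idx))
        d_end = int(np.clip(_nearest(x, t_end), d_start, min(p_idx, n_last - 1)))

    return PhaseSegmentation(
        systole=(0, peak_idx),
        early_diastole=(peak_idx, d_start),
        diastasis=(d_start, d_end),
        late_diastole=(d_end, n_last),
        knot_indices=knots,
        knot_times=x[knots],
        diastasis_times=(t_start, t_end),
        degenerate_diastasis=degenerate,
    )


def _plateau_scan(
    x: np.ndarray,
    y: np.ndarray,
    peak_idx: int,
    p_idx: int,
    plateau_threshold: float,
    peak_val: float,
    window_s: float = 0.05,
) -> tuple[int, int] | None:
    """Flattest sliding window between peak and P (fallback plateau search).

    Returns sample indices (start, end) of the flattest window whose OLS
    slope magnitude is below the plateau threshold and whose level sits
    clearly below the peak, or None when no such window exists.
    """
    lo, hi = peak_idx + 1, p_idx
    if hi - lo < 3:
        return None
    dt = float(np.median(np.diff(x[lo : hi + 1])))
    w = max(3, int(round(window_s / dt)))
    if hi - lo < w:
        w = hi - lo
    best: tuple[float, int] | None = None
    for i in range(lo, hi - w + 1):
        xs = x[i : i + w + 1]
        ys = y[i : i + w + 1]
        if ys.mean() >= _LEVEL_FRAC * peak_val:
            continue
        xm = xs - xs.mean()
        slope = abs(float(xm @ ys / (xm @ xm)))
        if slope <= plateau_threshold and (best is None or slope < best[0]):
            best = (slope, i)
    if best is None:
        return None
    return best[1], best[1] + w


def _nearest(x: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(x - t)))


def _region_line(x: np.ndarray, y: np.ndarray, a: int, b: int) -> tuple[float, float]:
    """(slope, intercept) of the OLS line over a fitted region's interior.

    The endpoints of a fitted region sit within one sample of a (possibly
    rounded) corner, so they are trimmed before the fit when enough samples
    remain; this keeps corner samples from tilting the line.
    """
    lo, hi = (a + 1, b - 1) if b - a >= 3 else (a, b)
    xs, ys = x[lo : hi + 1], y[lo : hi + 1]
    xm = xs - xs.mean()
    denom = xm @ xm
    if denom == 0:
        return 0.0, float(ys.mean())
    slope = float(xm @ ys / denom)
    return slope, float(ys.mean() - slope * xs.mean())


def _corner_time(
    x: np.ndarray,
    y: np.ndarray,
    segs: list[tuple[int, int, float]],
    scan: range,
    plateau: tuple[float, float],
    plateau_threshold: float,
    fallback: float,
) -> float:
    """Time where the plateau line meets the adjacent decline line.

    Scans outward from the plateau (nearest segment first) for a declining
    fitted segment (|slope| >= 2x the plateau threshold) that is long
    enough (>= 45 ms) to be a true phase rather than a rounded-corner or
    noise mini-segment; if only short steep segments exist the nearest one
    is used.  Falls back to the plateau knot when no steep decline exists.
    """
    sp, ip = plateau
    first_steep: tuple[int, int, float] | None = None
    best: tuple[int, int, float] | None = None
    for i in scan:
        a, b, slope = segs[i]
        if slope < 0 and abs(slope) >= 2.0 * plateau_threshold:
            if first_steep is None:
                first_steep = segs[i]
            if x[b] - x[a] >= 0.045:
                best = segs[i]
                break
    if best is None:
        best = first_steep
    if best is not None:
        ss, is_ = _region_line(x, y, best[0], best[1])
        if abs(ss - sp) > 1e-12:
            return (ip - is_) / (ss - sp)
    return fallback


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    return float(xm @ y / (xm @ xm))


def extract_features(curve: AlignedCurve, seg: PhaseSegmentation) -> FeatureVector:
    """Compute the six features of ``curve`` given its phase segmentation.

    Slopes are least-squares fits of strain magnitude vs time over each
    phase interval of the original (not the interpolated) curve.  A
    degenerate diastasis has duration 0 and height equal to the strain
    magnitude at the early/late-diastole junction.
    """
    y = curve.magnitude
    x = curve.time
    out: dict[str, float] = {}
    for name, (lo, hi) in (
        ("slope_sys", seg.systole),
        ("slope_ed", seg.early_diastole),
        ("slope_ld", seg.late_diastole),
    ):
        if hi - lo < 1:
            raise ValueError(
                f"{curve.subject_id}: phase {name} has fewer than 2 samples"
            )
        out[name] = _ols_slope(x[lo : hi + 1], y[lo : hi + 1])
    lo, hi = seg.diastasis
    if seg.degenerate_diastasis:
        out["diastasis_dur"] = 0.0
        out["diastasis_height"] = float(y[lo])
    else:
        t0, t1 = seg.diastasis_times
        out["diastasis_dur"] = float(t1 - t0)
        out["diastasis_height"] = float(y[lo : hi + 1].mean())
    out["peak_strain"] = float(y.max())
    return FeatureVector(
        subject_id=curve.subject_id,
        degenerate_flag=bool(seg.degenerate_diastasis),
        **out,
    )


def build_feature_matrix(
    curves: Sequence[AlignedCurve],
    n_knots: int = 5,
    plateau_threshold: float = PLATEAU_THRESHOLD,
) -> pd.DataFrame:
    """Featurize a cohort into a subjects x 6 DataFrame (input row order).

    Degenerate-diastasis subjects are imputed per the extract_features
    contract and flagged in ``degenerate_flag``; the matrix never contains
    missing values.
    """
    if not curves:
        raise ValueError("empty cohort")
    rows = []
    for c in curves:
        seg = fit_piecewise_linear(c, n_knots=n_knots, plateau_threshold=plateau_threshold)
        fv = extract_features(c, seg)
        rows.append(
            {
                "subject_id": fv.subject_id,
                **{k: getattr(fv, k) for k in FEATURE_COLUMNS},
                "degenerate_flag": fv.degenerate_flag,
            }
        )
    return pd.DataFrame(rows)
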