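"""Ratiometric (YFP/CFP) calcium-trace analysis.

A FRET calcium sensor emits more YFP and less CFP as intracellular calcium
rises, so the per-ROI YFP/CFP ratio ("Y/C ratio") tracks calcium while being
first-order insensitive to shared gain changes such as photobleaching or
focus drift.  This module implements the full trace-level analysis used for
a perfusion substance screen on brain slices:

* :func:`compute_yc_ratio` — element-wise Y/C ratio per ROI;
* :func:`correct_and_zscore` — baseline detrending and Z-scoring against the
  pre-application baseline ("Z_YC");
* :func:`mean_response` — mean Z over a post-onset response window (0–5 min
  for screening, 10–11 min for receptor-identification experiments);
* :func:`classify_substance` — the conservative quartile rule: a substance
  "increases" calcium when the third quartile of the per-ROI mean Z exceeds
  +2, "decreases" it when the first quartile is below −2, and is otherwise
  a non-responder;
* :func:`fwhm` — duration of a suppression transient as the full width at
  half of the smoothed minimum Z (Z_min120);
* :func:`peak_dr_over_r0` — peak ΔR/R₀ for stimulation experiments;
* :func:`screen_session` / :func:`screen_cohort` — session orchestration and
  cross-slice pooling.

Windows are half-open ``[start, end)`` in seconds; frame ``i`` maps to time
``i * frame_interval``.  Indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "Application",
    "RatiometricRecording",
    "ZScoreTrace",
    "FwhmResult",
    "SubstanceResult",
    "ResponseSummary",
    "SCREENING_WINDOW",
    "RECEPTOR_ID_WINDOW",
    "compute_yc_ratio",
    "correct_and_zscore",
    "mean_response",
    "classify_substance",
    "fwhm",
    "peak_dr_over_r0",
    "screen_session",
    "screen_cohort",
]

#: Post-onset response window (seconds) used in the substance screen.
SCREENING_WINDOW: tuple[float, float] = (0.0, 300.0)
#: Post-onset window used for receptor-identification comparisons.
RECEPTOR_ID_WINDOW: tuple[float, float] = (600.0, 660.0)

#: Quartile thresholds of the classification rule (Z units).
INCREASE_Q3_THRESHOLD = 2.0
DECREASE_Q1_THRESHOLD = -2.0


@dataclass(frozen=True)
class Application:
    """One substance application within a recording session."""

    substance: str
    onset: float  # seconds from recording start
    duration: float = 120.0  # standard 2-min perfusion

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class RatiometricRecording:
    """Per-ROI two-channel fluorescence time series with session layout.

    Parameters
    ----------
    yfp, cfp
        Arrays of shape ``(n_frames, n_rois)`` in arbitrary fluorescence
        units.  Must be strictly positive and of identical shape.
    frame_interval
        Acquisition frame interval in seconds.
    applications
        Substance applications in chronological order; their perfusion
        windows must not overlap.
    """

    yfp: np.ndarray
    cfp: np.ndarray
    frame_interval: float
    applications: list[Application] = field(default_factory=list)
    animal_id: str = ""
    slice_id: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.yfp = np.atleast_2d(np.asarray(self.yfp, dtype=float))
        self.cfp = np.atleast_2d(np.asarray(self.cfp, dtype=float))
        if self.yfp.shape != self.cfp.shape:
            raise ValueError(
                f"YFP shape {self.yfp.shape} != CFP shape {self.cfp.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        apps = sorted(self.applications, key=lambda a: a.onset)
        for prev, nxt in zip(apps, apps[1:]):
            if nxt.onset < prev.end:
                raise ValueError(
                    f"application windows overlap: {prev.substance!r} "
                    f"[{prev.onset}, {prev.end}) and {nxt.substance!r} "
                    f"[{nxt.onset}, {nxt.end})"
                )
        self.applications = apps

    @property
    def n_frames(self) -> int:
        return self.yfp.shape[0]

    @property
    def n_rois(self) -> int:
        return self.yfp.shape[1]

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ZScoreTrace:
    """Corrected, Z-scored Y/C ratio for one session segment.

    ``z`` has shape ``(n_frames,)`` or ``(n_frames, n_rois)``.  Over the
    baseline window the corrected trace has mean 0 and sample SD 1 by
    construction.  ``t_start`` is the absolute time of the segment's first
    frame so that windows given in recording time can be located.
    """

    z: np.ndarray
    baseline_window: tuple[float, float]
    ratio_raw: np.ndarray
    frame_interval: float
    t_start: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.z.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_frames) * self.frame_interval


@dataclass
class FwhmResult:
    """Full width at half-maximum of a suppression transient."""

    z_min120: float
    t_from: int  # frame index of first Z < 0.5 * z_min120
    t_to: int  # frame index of last Z < 0.5 * z_min120
    fwhm_frames: int
    fwhm_seconds: float
    excluded: bool
    censored: bool
    mean_z_5min: float
    ma_frames: int = 120
    ma_mode: str = "centered-truncated"


def _window_to_frames(
    start: float, end: float, frame_interval: float, n_frames: int, t0: float = 0.0
) -> tuple[int, int]:
    """Map a half-open time window [start, end) to frame indices [i0, i1)."""
    i0 = int(np.ceil((start - t0) / frame_interval - 1e-9))
    i1 = int(np.ceil((end - t0) / frame_interval - 1e-9))
    return max(i0, 0), min(i1, n_frames)


def compute_yc_ratio(rec: RatiometricRecording) -> np.ndarray:
    """Element-wise YFP/CFP ratio, shape ``(n_frames, n_rois)``.

    Raises
    ------
    ValueError
        If any CFP sample is non-positive (names the first offending ROI
        and frame).
    """
    bad = np.argwhere(rec.cfp <= 0)
    if bad.size:
        frame, roi = bad[0]
        raise ValueError(
            f"non-positive CFP value at ROI {roi}, frame {frame}: "
            f"{rec.cfp[frame, roi]!r}"
        )
    return rec.yfp / rec.cfp


def _fit_baseline_trend(
    t: np.ndarray, y: np.ndarray, method: str
) -> tuple[float, float]:
    """Fit slope/intercept of a line over the baseline samples."""
    if method == "theilsen":
        res = _stats.theilslopes(y, t)
        return float(res.slope), float(res.intercept)
    if method == "ols":
        slope, intercept = np.polyfit(t, y, 1)
        return float(slope), float(intercept)
    raise ValueError(f"unknown detrend method {method!r}")


def correct_and_zscore(
    ratio: np.ndarray,
    baseline_window: tuple[float, float],
    frame_interval: float,
    *,
    t_start: float = 0.0,
    detrend: str = "theilsen",
    min_baseline_samples: int = 30,
) -> ZScoreTrace:
    """Detrend against the pre-application baseline and Z-score.

    A line is fitted to the baseline samples (robust Theil–Sen by default,
    ``detrend="ols"`` for least squares, ``detrend="none"`` to skip) and
    subtracted from the whole segment; the result is standardised with the
    baseline mean and sample SD.  The correction is a strategy hook: the
    published trace-correction procedure is cited, not restated, in the
    source literature, so the detrend choice is deliberately swappable.

    Parameters
    ----------
    ratio
        Y/C ratio, shape ``(n_frames,)`` or ``(n_frames, n_rois)``.
    baseline_window
        Half-open ``[start, end)`` window in absolute seconds; must precede
        the application onset and contain at least ``min_baseline_samples``
        frames.
    """
    ratio = np.asarray(ratio, dtype=float)
    squeeze = ratio.ndim == 1
    r2 = ratio[:, None] if squeeze else ratio
    n = r2.shape[0]
    i0, i1 = _window_to_frames(*baseline_window, frame_interval, n, t_start)
    if i1 - i0 < min_baseline_samples:
        raise ValueError(
            f"baseline window [{baseline_window[0]}, {baseline_window[1]}) "
            f"contains {i1 - i0} samples; need >= {min_baseline_samples}"
        )
    t = t_start + np.arange(n) * frame_interval
    z = np.empty_like(r2)
    for j in range(r2.shape[1]):
        y = r2[:, j]
        if detrend == "none":
            corrected = y.copy()
        else:
            slope, intercept = _fit_baseline_trend(t[i0:i1], y[i0:i1], detrend)
            corrected = y - (slope * t + intercept)
        mu = corrected[i0:i1].mean()
        sd = corrected[i0:i1].std(ddof=1)
        # guard against float residue of an exactly (de)trended baseline
        if sd <= 1e-10 * max(np.abs(y[i0:i1]).max(), 1e-300):
            raise ValueError(
                f"baseline SD is zero for ROI {j}: degenerate constant trace"
            )
        z[:, j] = (corrected - mu) / sd
    return ZScoreTrace(
        z=z[:, 0] if squeeze else z,
        baseline_window=baseline_window,
        ratio_raw=ratio,
        frame_interval=frame_interval,
        t_start=t_start,
    )


def mean_response(
    zt: ZScoreTrace,
    onset: float,
    window: tuple[float, float] = SCREENING_WINDOW,
) -> np.ndarray | float:
    """Mean Z over the half-open window ``[onset + a, onset + b)``.

    ``window=(0, 300)`` gives the screening statistic (mean Z during the
    5 min after onset); ``window=(600, 660)`` the 10–11 min statistic used
    for receptor identification.
    """
    start, end = onset + window[0], onset + window[1]
    n = zt.n_frames
    end_time = zt.t_start + n * zt.frame_interval
    if end > end_time + 1e-9 or start < zt.t_start - 1e-9:
        raise ValueError(
            f"response window [{start}, {end}) extends outside the recording "
            f"[{zt.t_start}, {end_time})"
        )
    i0, i1 = _window_to_frames(start, end, zt.frame_interval, n, zt.t_start)
    if i1 <= i0:
        raise ValueError("empty response window")
    return zt.z[i0:i1].mean(axis=0)


def classify_substance(
    mean_z_values: np.ndarray,
    *,
    q3_threshold: float = INCREASE_Q3_THRESHOLD,
    q1_threshold: float = DECREASE_Q1_THRESHOLD,
) -> tuple[str, tuple[float, float, float]]:
    """Quartile rule over per-ROI mean-Z values pooled across slices.

    Returns ``(classification, (q1, median, q3))`` with classification one
    of ``"increase"`` (Q3 > 2), ``"decrease"`` (Q1 < −2) or ``"none"``.
    Quartiles use linear interpolation of order statistics at positions
    ``p * (n − 1)``.

    Raises
    ------
    ValueError
        On fewer than 4 values, or when both criteria fire at once (a
        bimodal cohort the rule cannot classify).
    """
    values = np.asarray(mean_z_values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 4:
        raise ValueError(f"need >= 4 mean-Z values, got {values.size}")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    inc = q3 > q3_threshold
    dec = q1 < q1_threshold
    if inc and dec:
        raise ValueError(
            f"bimodal response: Q3={q3:.3g} > {q3_threshold} and "
            f"Q1={q1:.3g} < {q1_threshold} simultaneously"
        )
    label = "increase" if inc else "decrease" if dec else "none"
    return label, (float(q1), float(med), float(q3))


def _moving_average_centered(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average truncated at the edges (window of available
    samples shrinks near the boundaries)."""
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def fwhm(
    zt: ZScoreTrace,
    onset: float,
    ma_frames: int = 120,
    *,
    exclusion_window: tuple[float, float] = SCREENING_WINDOW,
    exclusion_threshold: float = -2.0,
) -> FwhmResult:
    """Duration of a suppression transient (full width at half minimum).

    The minimum of the ``ma_frames``-frame moving average of Z_YC is taken
    as Z_min120; the transient spans the first through last frame at which
    the raw Z_YC is strictly below ``0.5 * Z_min120``, and the FWHM is their
    difference in frames (and seconds via the frame interval).

    ROIs whose mean Z during the 5 min after onset is not below −2 do not
    qualify as suppressed and are excluded (``excluded=True``; no width is
    computed).  ``censored=True`` flags a transient whose first or last
    crossing touches a recording edge, i.e. the true width may be longer.
    """
    z = np.asarray(zt.z, dtype=float)
    if z.ndim != 1:
        raise ValueError("fwhm operates on a single-ROI trace; got 2-D input")
    if z.shape[0] <= ma_frames:
        raise ValueError(
            f"recording has {z.shape[0]} frames; need more than ma_frames={ma_frames}"
        )
    m5 = float(mean_response(zt, onset, exclusion_window))
    if m5 >= exclusion_threshold:
        return FwhmResult(
            z_min120=float("nan"),
            t_from=-1,
            t_to=-1,
            fwhm_frames=0,
            fwhm_seconds=float("nan"),
            excluded=True,
            censored=False,
            mean_z_5min=m5,
            ma_frames=ma_frames,
        )
    ma = _moving_average_centered(z, ma_frames)
    z_min120 = float(ma.min())
    if z_min120 >= 0:
        raise RuntimeError(
            "smoothed minimum is non-negative for a non-excluded ROI; "
            "the suppression guard should have excluded it"
        )
    threshold = 0.5 * z_min120
    below = np.flatnonzero(z < threshold)
    t_from = int(below[0])
    t_to = int(below[-1])
    return FwhmResult(
        z_min120=z_min120,
        t_from=t_from,
        t_to=t_to,
        fwhm_frames=t_to - t_from,
        fwhm_seconds=(t_to - t_from) * zt.frame_interval,
        excluded=False,
        censored=(t_from == 0) or (t_to == z.shape[0] - 1),
        mean_z_5min=m5,
        ma_frames=ma_frames,
    )


def peak_dr_over_r0(
    ratio: np.ndarray,
    stim_window: tuple[float, float],
    frame_interval: float,
    *,
    baseline_duration: float = 30.0,
) -> float:
    """Peak ΔR/R₀ of the raw Y/C ratio around a stimulation.

    R₀ is the mean ratio over the ``baseline_duration`` seconds immediately
    before the stimulation window; ΔR is the peak ratio during stimulation
    minus R₀.  Invariant to uniform rescaling of the whole trace.
    """
    ratio = np.asarray(ratio, dtype=float)
    n = ratio.shape[0]
    t0, t1 = stim_window
    if t0 - baseline_duration < -1e-9:
        raise ValueError(
            f"need >= {baseline_duration} s of pre-stimulus data; "
            f"stimulation starts at {t0} s"
        )
    b0, b1 = _window_to_frames(t0 - baseline_duration, t0, frame_interval, n)
    s0, s1 = _window_to_frames(t0, t1, frame_interval, n)
    if s1 <= s0 or b1 <= b0:
        raise ValueError("empty stimulation or baseline window")
    r0 = ratio[b0:b1].mean()
    if r0 <= 0:
        raise ValueError(f"non-positive baseline ratio R0={r0!r}")
    return float((ratio[s0:s1].max() - r0) / r0)


@dataclass
class SubstanceResult:
    """Per-recording screening result for one application."""

    substance: str
    onset: float
    mean_z: np.ndarray  # per ROI; NaN when the session could not be scored
    flagged: bool = False
    flag_reason: str = ""
    zscore: ZScoreTrace | None = None


@dataclass
class ResponseSummary:
    """Pooled per-substance classification across recordings."""

    substance: str
    mean_z: np.ndarray  # pooled across recordings, one value per ROI
    classification: str
    quartiles: tuple[float, float, float]
    n_rois: int
    n_recordings: int


def screen_session(
    rec: RatiometricRecording,
    *,
    baseline_duration: float = 300.0,
    response_window: tuple[float, float] = SCREENING_WINDOW,
    detrend: str = "theilsen",
    min_baseline_samples: int = 30,
) -> list[SubstanceResult]:
    """Score every application of one recording (one slice).

    For each substance the baseline is the 5 min immediately before onset;
    the ratio segment from baseline start to the end of the response window
    is detrended and Z-scored, and the per-ROI mean Z over the response
    window is computed.  A session whose baseline is cut short by the
    previous application (or the recording start) is flagged rather than
    dropped; if fewer than ``min_baseline_samples`` baseline frames remain
    it is scored as NaN.
    """
    ratio = compute_yc_ratio(rec)
    results: list[SubstanceResult] = []
    for k, app in enumerate(rec.applications):
        b_start = app.onset - baseline_duration
        flagged = False
        reason = ""
        if k > 0 and b_start < rec.applications[k - 1].end - 1e-9:
            flagged = True
            b_start = rec.applications[k - 1].end
            reason = (
                f"baseline truncated by previous application "
                f"({rec.applications[k - 1].substance!r})"
            )
        if b_start < 0:
            flagged = True
            b_start = 0.0
            reason = reason or "baseline truncated by recording start"
        seg_end = app.onset + response_window[1]
        if seg_end > rec.duration + 1e-9:
            raise ValueError(
                f"response window for {app.substance!r} extends past the "
                f"recording end ({seg_end} > {rec.duration} s)"
            )
        i0, i1 = _window_to_frames(
            b_start, seg_end, rec.frame_interval, rec.n_frames
        )
        n_baseline = _window_to_frames(
            b_start, app.onset, rec.frame_interval, rec.n_frames
        )
        if n_baseline[1] - n_baseline[0] < min_baseline_samples:
            results.append(
                SubstanceResult(
                    substance=app.substance,
                    onset=app.onset,
                    mean_z=np.full(rec.n_rois, np.nan),
                    flagged=True,
                    flag_reason=reason or "baseline too short to score",
                )
            )
            continue
        zt = correct_and_zscore(
            ratio[i0:i1],
            baseline_window=(b_start, app.onset),
            frame_interval=rec.frame_interval,
            t_start=i0 * rec.frame_interval,
            detrend=detrend,
            min_baseline_samples=min_baseline_samples,
        )
        mz = np.asarray(mean_response(zt, app.onset, response_window))
        results.append(
            SubstanceResult(
                substance=app.substance,
                onset=app.onset,
                mean_z=mz,
                flagged=flagged,
                flag_reason=reason,
                zscore=zt,
            )
        )
    return results


def screen_cohort(
    recordings: list[RatiometricRecording], **kwargs
) -> dict[str, ResponseSummary]:
    """Screen several recordings and pool per-ROI mean-Z by substance.

    Classification applies the quartile rule to the pooled values, matching
    the combined-experiment quartiles of the screening design.  Flagged
    (NaN) sessions contribute nothing to the pool but are counted.
    """
    pooled: dict[str, list[np.ndarray]] = {}
    counts: dict[str, int] = {}
    for rec in recordings:
        for res in screen_session(rec, **kwargs):
            pooled.setdefault(res.substance, []).append(res.mean_z)
            counts[res.substance] = counts.get(res.substance, 0) + 1
    summaries: dict[str, ResponseSummary] = {}
    for substance, chunks in pooled.items():
        values = np.concatenate(chunks)
        values = values[~np.isnan(values)]
        label, quartiles = classify_substance(values)
        summaries[substance] = ResponseSummary(
            substance=substance,
            mean_z=values,
            classification=label,
            quartiles=quartiles,
            n_rois=values.size,
            n_recordings=counts[substance],
        )
    return summaries
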