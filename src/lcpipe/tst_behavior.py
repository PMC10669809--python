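"""Tail-suspension immobility scoring from a body-area time series.

A tail-suspended mouse swings passively like a pendulum (slow, narrowband)
and struggles actively (fast, broadband).  Both modulate the apparent body
area extracted from video.  The scorer separates the two with a continuous
wavelet transform: the struggle signal TS_WLT is the time-marginal of
wavelet coefficient magnitudes over struggle-band scales only, so the
pendulous component is subtracted out by construction.  Frames where TS_WLT
falls below half its session standard deviation (sigma_WLT / 2) are scored
immobile.  Consecutive mobile-immobile runs are paired into epochs for the
photometry stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "AreaSeries",
    "ImmobilityTrack",
    "PENDULUM_BAND",
    "STRUGGLE_BAND",
    "struggle_signal",
    "score_immobility",
    "cumulative_immobility",
    "score_tst",
]

#: Default pendulous-swing frequency band (Hz).
PENDULUM_BAND: tuple[float, float] = (0.2, 2.0)
#: Default struggling frequency band (Hz).
STRUGGLE_BAND: tuple[float, float] = (2.5, 10.0)


@dataclass
class AreaSeries:
    """Per-frame animal body area (pixels^2) from tail-suspension video."""

    area: np.ndarray
    frame_rate: float
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float).ravel()
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.area.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class ImmobilityTrack:
    """Struggle signal, threshold, immobility mask and derived epochs.

    ``epochs`` pairs each mobile run with the immobile run that follows it
    (half-open frame intervals); a leading immobile run or trailing mobile
    run has no partner and appears only in ``runs``.
    """

    ts_wlt: np.ndarray
    sigma_wlt: float
    immobile: np.ndarray  # boolean per frame
    frame_rate: float
    runs: list[tuple[str, int, int]] = field(default_factory=list)
    epochs: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )

    @property
    def threshold(self) -> float:
        return self.sigma_wlt / 2.0

    @property
    def total_immobility(self) -> float:
        """Total immobile time in seconds."""
        return float(self.immobile.sum()) / self.frame_rate


def _band_scales(
    wavelet: str, band: tuple[float, float], frame_rate: float, n_scales: int
) -> np.ndarray:
    """Wavelet scales whose center frequencies log-span the band."""
    freqs = np.geomspace(band[0], band[1], n_scales)
    return pywt.frequency2scale(wavelet, freqs / frame_rate)


def struggle_signal(
    a: AreaSeries,
    pendulum_band: tuple[float, float] = PENDULUM_BAND,
    struggle_band: tuple[float, float] = STRUGGLE_BAND,
    *,
    wavelet: str = "cmor1.5-1.0",
    n_scales: int = 24,
) -> np.ndarray:
    """Wavelet struggle signal TS_WLT of a body-area series.

    The mean-removed area series is transformed with an analytic Morlet
    wavelet at scales spanning ``struggle_band``; TS_WLT is the mean
    coefficient magnitude across those scales at each frame.  Scales inside
    ``pendulum_band`` are never included, so slow pendulous swinging
    contributes only through spectral leakage (small for disjoint bands).

    Raises
    ------
    ValueError
        If the bands overlap or ``struggle_band`` reaches the Nyquist
        frequency.
    """
    lo_p, hi_p = pendulum_band
    lo_s, hi_s = struggle_band
    if not (0 < lo_p < hi_p and 0 < lo_s < hi_s):
        raise ValueError("bands must be positive, increasing intervals")
    if max(lo_p, lo_s) < min(hi_p, hi_s):
        raise ValueError(
            f"pendulum band {pendulum_band} and struggle band "
            f"{struggle_band} overlap"
        )
    if hi_s >= a.frame_rate / 2:
        raise ValueError(
            f"struggle band upper edge {hi_s} Hz reaches Nyquist "
            f"({a.frame_rate / 2} Hz)"
        )
    x = a.area - a.area.mean()
    scales = _band_scales(wavelet, struggle_band, a.frame_rate, n_scales)
    coef, _ = pywt.cwt(x, scales, wavelet)
    return np.abs(coef).mean(axis=0)


def score_immobility(ts_wlt: np.ndarray, frame_rate: float) -> ImmobilityTrack:
    """Threshold TS_WLT at sigma_WLT / 2 into an immobility mask.

    sigma_WLT is the sample standard deviation of the whole series, so the
    mask is invariant to positive rescaling of TS_WLT.
    """
    ts_wlt = np.asarray(ts_wlt, dtype=float).ravel()
    if ts_wlt.size == 0:
        raise ValueError("empty struggle signal")
    sigma = float(ts_wlt.std())
    if sigma == 0:
        raise ValueError("sigma_WLT is zero: degenerate constant signal")
    immobile = ts_wlt < sigma / 2.0
    runs = _runs(immobile)
    epochs = _pair_epochs(runs)
    return ImmobilityTrack(
        ts_wlt=ts_wlt,
        sigma_wlt=sigma,
        immobile=immobile,
        frame_rate=frame_rate,
        runs=runs,
        epochs=epochs,
    )


def _runs(immobile: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encode the mask into alternating labelled intervals."""
    runs: list[tuple[str, int, int]] = []
    n = immobile.shape[0]
    start = 0
    for i in range(1, n + 1):
        if i == n or immobile[i] != immobile[start]:
            runs.append(("immobile" if immobile[start] else "mobile", start, i))
            start = i
    return runs


def _pair_epochs(
    runs: list[tuple[str, int, int]],
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    epochs = []
    for prev, nxt in zip(runs, runs[1:]):
        if prev[0] == "mobile" and nxt[0] == "immobile":
            epochs.append(((prev[1], prev[2]), (nxt[1], nxt[2])))
    return epochs


def cumulative_immobility(
    track: ImmobilityTrack, bin_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative immobility (seconds) at the end of each time bin.

    Returns ``(bin_ends, cumulative)``; the last bin is truncated when the
    session length is not a multiple of ``bin_seconds``.  The curve is
    non-decreasing and its final value equals ``track.total_immobility``.
    """
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be positive")
    n = track.immobile.shape[0]
    per_frame = track.immobile.astype(float) / track.frame_rate
    cum = np.cumsum(per_frame)
    frames_per_bin = bin_seconds * track.frame_rate
    edges = np.arange(frames_per_bin, n + frames_per_bin, frames_per_bin)
    idx = np.minimum(np.round(edges).astype(int), n) - 1
    bin_ends = np.minimum(edges / track.frame_rate, n / track.frame_rate)
    return bin_ends, cum[idx]


def score_tst(
    a: AreaSeries,
    pendulum_band: tuple[float, float] = PENDULUM_BAND,
    struggle_band: tuple[float, float] = STRUGGLE_BAND,
    **kwargs,
) -> ImmobilityTrack:
    """Convenience: struggle signal then immobility scoring."""
    ts = struggle_signal(a, pendulum_band, struggle_band, **kwargs)
    return score_immobility(ts, a.frame_rate)
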