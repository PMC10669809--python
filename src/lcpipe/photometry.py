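"""Fiber-photometry processing: raw interleaved PMT stream to onset statistic.

The acquisition alternates 470-nm (calcium-dependent) and 405-nm
(isosbestic, calcium-independent) LED excitation at 20 Hz: each 50-point
cycle of the 1 kHz PMT voltage stream holds a 25-point burst per channel.
Processing chain:

1. :func:`deinterleave` — one 20 Hz sample per burst as the mean of burst
   points 13-24 (1-based), skipping LED-settling samples;
2. :func:`isosbestic_correct` — F_GC = F470 − F405 · µ470 / µ405 with the
   channel means µ taken over the first third of the recording, removing
   motion and autofluorescence components shared by the two channels;
3. :func:`smooth_and_normalize` — 10-point moving average over the
   tail-suspension window (F_TS) and min-max rescaling to [0, 1] (F_TSre);
4. :func:`epoch_normalize` — per mobile→immobile epoch, rescale so the
   mobile-period maximum is 1 and the immobile-period minimum is 0
   (F_Enorm), and read off the value at the first immobile frame
   (F_Eonset).  The per-animal mean F_Eonset indexes how early calcium
   activity is suppressed relative to behavioral arrest.

PMT voltages are typically negative (operating point near −1 V and −0.5 V
for the 470- and 405-nm channels); every operation here is sign-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BurstLayout",
    "RawPmtStream",
    "PhotometrySession",
    "deinterleave",
    "isosbestic_correct",
    "smooth_and_normalize",
    "epochs_from_mask",
    "resample_mask",
    "epoch_normalize",
    "process_session",
]


@dataclass(frozen=True)
class BurstLayout:
    """Interleaving layout of the raw stream."""

    points_per_burst: int = 25
    cycle_points: int = 50
    first_channel: int = 470  # excitation wavelength of the first burst
    window: tuple[int, int] = (13, 24)  # 1-based inclusive averaging window

    def __post_init__(self) -> None:
        if self.cycle_points != 2 * self.points_per_burst:
            raise ValueError("cycle_points must be twice points_per_burst")
        if self.first_channel not in (470, 405):
            raise ValueError("first_channel must be 470 or 405")
        lo, hi = self.window
        if not 1 <= lo <= hi <= self.points_per_burst:
            raise ValueError(f"invalid averaging window {self.window}")


@dataclass
class RawPmtStream:
    """Raw 1 kHz PMT voltage stream (1 time point = 1 ms)."""

    voltage: np.ndarray
    layout: BurstLayout = field(default_factory=BurstLayout)
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float).ravel()


@dataclass
class Epoch:
    """One mobile→immobile pair as half-open 20 Hz index intervals."""

    mobile: tuple[int, int]
    immobile: tuple[int, int]


@dataclass
class PhotometrySession:
    """Processed session: de-interleaved, corrected, normalized series."""

    f470: np.ndarray
    f405: np.ndarray
    f_gc: np.ndarray
    f_ts: np.ndarray | None = None
    f_tsre: np.ndarray | None = None
    epoch_table: pd.DataFrame | None = None
    mean_f_eonset: float | None = None
    rate: float = 20.0


def deinterleave(raw: RawPmtStream) -> tuple[np.ndarray, np.ndarray]:
    """Collapse each 25-point burst to one 20 Hz sample per channel.

    The sample is the mean of burst points 13-24 (1-based, 12 samples);
    points 1-12 and 25 are discarded as LED-settling/transition samples.
    Returns ``(f470, f405)``.
    """
    lay = raw.layout
    n = raw.voltage.shape[0]
    if n % lay.cycle_points:
        raise ValueError(
            f"stream length {n} is not a multiple of cycle_points="
            f"{lay.cycle_points}"
        )
    cycles = raw.voltage.reshape(-1, lay.cycle_points)
    lo, hi = lay.window
    first = cycles[:, lo - 1 : hi].mean(axis=1)
    second = cycles[:, lay.points_per_burst + lo - 1 : lay.points_per_burst + hi].mean(
        axis=1
    )
    if lay.first_channel == 470:
        return first, second
    return second, first


def isosbestic_correct(
    f470: np.ndarray, f405: np.ndarray, *, first_fraction: float = 1 / 3
) -> np.ndarray:
    """F_GC = F470 − F405 · µ470 / µ405, µ's over the recording's first third.

    The µ ratio rescales the isosbestic channel onto the 470-nm channel's
    operating point so that components common to both channels (motion,
    fiber bending, autofluorescence) cancel.
    """
    f470 = np.asarray(f470, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f470.shape != f405.shape:
        raise ValueError("f470 and f405 must have equal length")
    n3 = int(f470.shape[0] * first_fraction)
    if n3 < 1:
        raise ValueError("first third of the series is empty")
    mu470 = f470[:n3].mean()
    mu405 = f405[:n3].mean()
    if mu405 == 0:
        raise ValueError("mean 405-nm signal over the first third is zero")
    return f470 - f405 * (mu470 / mu405)


def _trailing_mean(x: np.ndarray, n_points: int) -> np.ndarray:
    """Trailing moving average, truncated at the start."""
    c = np.cumsum(np.insert(x, 0, 0.0))
    out = np.empty_like(x)
    idx = np.arange(1, x.shape[0] + 1)
    lo = np.maximum(idx - n_points, 0)
    out[:] = (c[idx] - c[lo]) / (idx - lo)
    return out


def smooth_and_normalize(
    f_gc: np.ndarray,
    tst_window: tuple[int, int] | None = None,
    *,
    n_points: int = 10,
    mode: str = "trailing",
) -> tuple[np.ndarray, np.ndarray]:
    """Moving average (F_TS) and min-max normalization (F_TSre) over the TST.

    ``tst_window`` is a half-open 20 Hz index interval; ``None`` uses the
    whole series.  The moving average is trailing (causal) by default,
    truncated at the window start; ``mode="centered"`` switches to a
    centered window.  F_TSre = (F_TS − min) / (max − min) lies in [0, 1]
    and attains both bounds.
    """
    f_gc = np.asarray(f_gc, dtype=float)
    if tst_window is not None:
        f_gc = f_gc[tst_window[0] : tst_window[1]]
    if f_gc.shape[0] < n_points:
        raise ValueError(
            f"window has {f_gc.shape[0]} points; need >= {n_points}"
        )
    if mode == "trailing":
        f_ts = _trailing_mean(f_gc, n_points)
    elif mode == "centered":
        f_ts = (
            pd.Series(f_gc)
            .rolling(n_points, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    else:
        raise ValueError(f"unknown moving-average mode {mode!r}")
    lo, hi = f_ts.min(), f_ts.max()
    if hi == lo:
        raise ValueError("constant F_TS: min-max normalization undefined")
    return f_ts, (f_ts - lo) / (hi - lo)


def epochs_from_mask(immobile: np.ndarray) -> list[Epoch]:
    """Pair mobile runs with the immobile run that follows each of them.

    A leading immobile run and a trailing mobile run have no partner and
    are dropped.
    """
    immobile = np.asarray(immobile, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(immobile.astype(int))) + 1
    bounds = np.concatenate(([0], edges, [immobile.shape[0]]))
    epochs: list[Epoch] = []
    for s0, s1, s2 in zip(bounds, bounds[1:], bounds[2:]):
        if not immobile[s0] and immobile[s1]:
            epochs.append(Epoch(mobile=(int(s0), int(s1)), immobile=(int(s1), int(s2))))
    return epochs


def resample_mask(
    mask: np.ndarray, src_rate: float, dst_rate: float, n_out: int | None = None
) -> np.ndarray:
    """Resample a boolean per-frame mask to another rate by nearest sample."""
    mask = np.asarray(mask, dtype=bool).ravel()
    if n_out is None:
        n_out = int(round(mask.shape[0] * dst_rate / src_rate))
    t = np.arange(n_out) / dst_rate
    idx = np.minimum((t * src_rate).astype(int), mask.shape[0] - 1)
    return mask[idx]


def epoch_normalize(
    f_tsre: np.ndarray, epochs: list[Epoch]
) -> tuple[pd.DataFrame, float]:
    """Per-epoch normalization and the onset statistic F_Eonset.

    For each epoch, F_Emax is the maximum of the signal during the mobile
    period and F_Emin the minimum during the immobile period; the epoch's
    signal is rescaled as (F − F_Emin) / (F_Emax − F_Emin) and F_Eonset is
    its value at the first immobile frame.  Epochs with F_Emax ≤ F_Emin
    are flagged invalid and excluded from the per-animal mean.

    Returns ``(epoch_table, mean_f_eonset)`` where the table has one row per
    epoch with columns ``f_emax``, ``f_emin``, ``f_eonset``, ``valid`` and
    the epoch boundaries.
    """
    f = np.asarray(f_tsre, dtype=float)
    if not epochs:
        raise ValueError("no epochs supplied")
    rows = []
    for ep in epochs:
        m0, m1 = ep.mobile
        i0, i1 = ep.immobile
        if not (0 <= m0 < m1 <= i0 < i1 <= f.shape[0]):
            raise ValueError(f"epoch {ep} outside the signal or misordered")
        f_emax = float(f[m0:m1].max())
        f_emin = float(f[i0:i1].min())
        valid = f_emax > f_emin
        f_eonset = (
            (float(f[i0]) - f_emin) / (f_emax - f_emin) if valid else float("nan")
        )
        rows.append(
            {
                "mobile_start": m0,
                "mobile_end": m1,
                "immobile_start": i0,
                "immobile_end": i1,
                "f_emax": f_emax,
                "f_emin": f_emin,
                "f_eonset": f_eonset,
                "valid": valid,
            }
        )
    table = pd.DataFrame(rows)
    valid_onsets = table.loc[table["valid"], "f_eonset"]
    if valid_onsets.empty:
        raise ValueError("no valid epochs (every epoch has F_Emax <= F_Emin)")
    return table, float(valid_onsets.mean())


def process_session(
    raw: RawPmtStream,
    immobile_mask_20hz: np.ndarray | None = None,
    *,
    tst_window: tuple[int, int] | None = None,
    n_smooth: int = 10,
) -> PhotometrySession:
    """Full chain: de-interleave, correct, smooth/normalize, epoch stats."""
    f470, f405 = deinterleave(raw)
    f_gc = isosbestic_correct(f470, f405)
    session = PhotometrySession(f470=f470, f405=f405, f_gc=f_gc)
    f_ts, f_tsre = smooth_and_normalize(f_gc, tst_window, n_points=n_smooth)
    session.f_ts, session.f_tsre = f_ts, f_tsre
    if immobile_mask_20hz is not None:
        mask = np.asarray(immobile_mask_20hz, dtype=bool)
        if tst_window is not None:
            mask = mask[tst_window[0] : tst_window[1]]
        epochs = epochs_from_mask(mask)
        session.epoch_table, session.mean_f_eonset = epoch_normalize(
            f_tsre, epochs
        )
    return session
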