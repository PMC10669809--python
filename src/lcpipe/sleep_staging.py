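"""Rule-cascade vigilance staging of 4-s epochs from EEG/EMG/IR signals.

Each epoch is labelled wakefulness (W), non-REM sleep (NR) or REM sleep (R)
by a fixed first-match cascade of threshold rules:

1. high infrared activity  -> W
2. high EMG                -> W
3. high EEG delta (1.5-4 Hz) amplitude -> NR
4. high theta ratio (theta 5-8 Hz amplitude / delta amplitude) -> R
5. otherwise the epoch keeps the previous epoch's label.

"High" thresholds are resolved per recording from feature percentiles by
default (gain differences between animals make absolute thresholds
unreliable); the theta ratio uses a fixed dimensionless cut.  Band
"amplitude" is computed as the RMS of the band-passed signal per epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "EpochFeatures",
    "Hypnogram",
    "StagingThresholds",
    "DELTA_BAND",
    "THETA_BAND",
    "EMG_BAND",
    "STATES",
    "epoch_features",
    "stage_epochs",
    "state_durations",
]

DELTA_BAND: tuple[float, float] = (1.5, 4.0)
THETA_BAND: tuple[float, float] = (5.0, 8.0)
#: Acquisition EMG band; auto-clipped below Nyquist when left as default.
EMG_BAND: tuple[float, float] = (15.0, 300.0)
STATES = ("W", "NR", "R")

# Feature-table column names (one row per epoch).
FEATURE_COLUMNS = ("ir_activity", "emg_rms", "delta_amp", "theta_ratio")

#: Alias kept for documentation symmetry with the domain model; the feature
#: table itself is a pandas DataFrame with FEATURE_COLUMNS.
EpochFeatures = pd.DataFrame


@dataclass
class Hypnogram:
    """Vigilance-state label per epoch with provenance."""

    labels: np.ndarray  # array of "W" / "NR" / "R"
    epoch_length: float = 4.0
    provenance: np.ndarray | None = None  # "auto" or "manual" per epoch

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(STATES)
        if unknown:
            raise ValueError(f"unknown state labels: {sorted(unknown)}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.provenance is None:
            self.provenance = np.full(self.labels.shape, "auto", dtype=object)

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length


@dataclass
class StagingThresholds:
    """Threshold policy for the staging cascade.

    Percentiles are resolved against the recording's own feature
    distribution; set the corresponding ``*_abs`` field to override with an
    absolute value.
    """

    ir_percentile: float = 75.0
    emg_percentile: float = 75.0
    delta_percentile: float = 60.0
    theta_ratio_cut: float = 1.0
    ir_abs: float | None = None
    emg_abs: float | None = None
    delta_abs: float | None = None

    def resolve(self, features: pd.DataFrame) -> dict[str, float]:
        return {
            "ir": self.ir_abs
            if self.ir_abs is not None
            else float(np.percentile(features["ir_activity"], self.ir_percentile)),
            "emg": self.emg_abs
            if self.emg_abs is not None
            else float(np.percentile(features["emg_rms"], self.emg_percentile)),
            "delta": self.delta_abs
            if self.delta_abs is not None
            else float(
                np.percentile(features["delta_amp"], self.delta_percentile)
            ),
            "theta_ratio": self.theta_ratio_cut,
        }


def _bandpass(
    x: np.ndarray, band: tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi >= fs / 2:
        raise ValueError(
            f"band upper edge {hi} Hz reaches Nyquist ({fs / 2} Hz); "
            "sample rate too low for the requested band"
        )
    sos = _signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, x)


def _epoch_rms(x: np.ndarray, samples_per_epoch: int) -> np.ndarray:
    n_epochs = x.shape[0] // samples_per_epoch
    blocks = x[: n_epochs * samples_per_epoch].reshape(n_epochs, samples_per_epoch)
    return np.sqrt((blocks**2).mean(axis=1))


def epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    ir: np.ndarray,
    sample_rate: float,
    epoch_length: float = 4.0,
    *,
    delta_band: tuple[float, float] = DELTA_BAND,
    theta_band: tuple[float, float] = THETA_BAND,
    emg_band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-epoch staging features from raw EEG / EMG / IR-activity signals.

    Returns a DataFrame with one row per epoch and columns ``ir_activity``
    (summed counts), ``emg_rms``, ``delta_amp`` and ``theta_ratio``.  A
    trailing partial epoch is dropped with a warning.  ``emg_band=None``
    uses the acquisition band (15-300 Hz) clipped below Nyquist; an
    explicitly requested band that reaches Nyquist raises.
    """
    eeg = np.asarray(eeg, dtype=float).ravel()
    emg = np.asarray(emg, dtype=float).ravel()
    ir = np.asarray(ir, dtype=float).ravel()
    if not (eeg.shape == emg.shape == ir.shape):
        raise ValueError("eeg, emg and ir must have equal length")
    spe = int(round(epoch_length * sample_rate))
    if spe <= 0:
        raise ValueError("epoch shorter than one sample")
    n_epochs = eeg.shape[0] // spe
    if n_epochs == 0:
        raise ValueError("signals shorter than one epoch")
    if eeg.shape[0] % spe:
        warnings.warn(
            f"dropping trailing partial epoch ({eeg.shape[0] % spe} samples)",
            stacklevel=2,
        )
    if emg_band is None:
        emg_band = (EMG_BAND[0], min(EMG_BAND[1], 0.45 * sample_rate))
    delta = _epoch_rms(_bandpass(eeg, delta_band, sample_rate), spe)
    theta = _epoch_rms(_bandpass(eeg, theta_band, sample_rate), spe)
    emg_rms = _epoch_rms(_bandpass(emg, emg_band, sample_rate), spe)
    ir_counts = (
        ir[: n_epochs * spe].reshape(n_epochs, spe).sum(axis=1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_ratio = np.where(delta > 0, theta / delta, np.inf)
    return pd.DataFrame(
        {
            "ir_activity": ir_counts,
            "emg_rms": emg_rms,
            "delta_amp": delta,
            "theta_ratio": theta_ratio,
        }
    )


def stage_epochs(
    features: pd.DataFrame,
    thresholds: StagingThresholds | None = None,
    initial_state: str = "W",
    epoch_length: float = 4.0,
) -> Hypnogram:
    """Apply the staging rule cascade to a feature table.

    Rules fire in fixed order per epoch (IR -> W, EMG -> W, delta -> NR,
    theta ratio -> R); the first match wins and an epoch matching no rule
    copies the previous epoch's label (the first epoch falls back to
    ``initial_state``).
    """
    if len(features) == 0:
        raise ValueError("empty feature list")
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if initial_state not in STATES:
        raise ValueError(f"initial_state must be one of {STATES}")
    thr = (thresholds or StagingThresholds()).resolve(features)
    labels = np.empty(len(features), dtype=object)
    previous = initial_state
    for i, row in enumerate(features.itertuples(index=False)):
        if row.ir_activity > thr["ir"]:
            label = "W"
        elif row.emg_rms > thr["emg"]:
            label = "W"
        elif row.delta_amp > thr["delta"]:
            label = "NR"
        elif row.theta_ratio > thr["theta_ratio"]:
            label = "R"
        else:
            label = previous
        labels[i] = label
        previous = label
    return Hypnogram(labels=labels, epoch_length=epoch_length)


def state_durations(
    h: Hypnogram, schedule: list[tuple[str, float, float]]
) -> pd.DataFrame:
    """Total seconds per vigilance state per light/dark period.

    ``schedule`` is a list of ``(period_label, start_s, end_s)`` half-open
    intervals that must tile the recording without gaps and with boundaries
    aligned to epoch edges, so that per period the three state totals sum
    exactly to the period length.  Returns a DataFrame indexed by period
    occurrence with columns ``period``, ``start``, ``end``, ``W``, ``NR``,
    ``R``.
    """
    sched = sorted(schedule, key=lambda p: p[1])
    if not sched:
        raise ValueError("empty schedule")
    if abs(sched[0][1]) > 1e-9:
        raise ValueError("schedule must start at time 0")
    for (la, s0, e0), (lb, s1, e1) in zip(sched, sched[1:]):
        if abs(e0 - s1) > 1e-9:
            raise ValueError(f"schedule gap between {e0} and {s1} s")
    if sched[-1][2] < h.duration - 1e-9:
        raise ValueError(
            f"schedule ends at {sched[-1][2]} s but recording lasts "
            f"{h.duration} s"
        )
    L = h.epoch_length
    rows = []
    for label, start, end in sched:
        i0 = start / L
        i1 = min(end, h.duration) / L
        if abs(i0 - round(i0)) > 1e-9 or abs(i1 - round(i1)) > 1e-9:
            raise ValueError(
                f"period [{start}, {end}) is not aligned to {L}-s epochs"
            )
        chunk = h.labels[int(round(i0)) : int(round(i1))]
        row = {"period": label, "start": start, "end": end}
        for state in STATES:
            row[state] = float((chunk == state).sum()) * L
        rows.append(row)
    return pd.DataFrame(rows)
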