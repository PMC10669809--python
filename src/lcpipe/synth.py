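"""Synthetic-data generators with known ground truth for every stage.

Each generator emulates one acquisition modality of the pipeline and emits
a sidecar ground-truth object, so every downstream scorer can be validated
without any recorded data:

* :func:`generate_yc_recording` — two-channel (YFP/CFP) ratiometric traces
  with anti-correlated substance responses, shared exponential bleaching
  and additive channel noise;
* :func:`generate_tst_area_series` — tail-suspension body-area traces:
  baseline + always-on narrowband pendulum swing + broadband struggle
  bursts confined to specified bouts;
* :func:`generate_eeg_emg` — state-dependent EEG/EMG/IR signals for a given
  W/NR/R epoch sequence (delta-rich NR, theta-rich REM, high-EMG/IR wake);
* :func:`generate_photometry_raw` — a 1 kHz interleaved PMT stream encoding
  a 20 Hz latent calcium signal plus a motion artifact shared (scaled)
  between the 470- and 405-nm channels;
* :func:`generate_clustered_values` — one-way random-effects draws with a
  prescribed intraclass correlation.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .photometry import BurstLayout, RawPmtStream
from .ratio_imaging import Application, RatiometricRecording
from .sleep_staging import STATES, Hypnogram
from .tst_behavior import AreaSeries

__all__ = [
    "SubstanceEffectSpec",
    "YcGroundTruth",
    "TstGroundTruth",
    "EegGroundTruth",
    "PhotometryGroundTruth",
    "generate_yc_recording",
    "generate_tst_area_series",
    "generate_eeg_emg",
    "markov_state_sequence",
    "generate_photometry_raw",
    "generate_clustered_values",
]

_FWHM_TO_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: The response kernel peaks this fraction of its FWHM after
#: onset + onset_delay: late enough that the response is small (< 16% of
#: depth) at the application time, early enough that even slow responses
#: develop within the 5-min screening window.
_PEAK_OFFSET_FRACTION = 0.8


@dataclass(frozen=True)
class SubstanceEffectSpec:
    """Phenomenological response of one substance application.

    ``depth`` is the peak response in Z units of the downstream Z-scored
    ratio trace; ``duration_fwhm`` is the analytic full width at
    half-maximum of the response kernel in seconds; ``responder_fraction``
    is the fraction of ROIs that respond at all.
    """

    name: str
    direction: str = "none"  # increase | decrease | none
    depth: float = 0.0
    onset_delay: float = 10.0
    duration_fwhm: float = 240.0
    responder_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.duration_fwhm <= 0:
            raise ValueError("duration_fwhm must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")

    @property
    def sign(self) -> float:
        return {"increase": 1.0, "decrease": -1.0, "none": 0.0}[self.direction]


@dataclass
class YcGroundTruth:
    """Latent truth of a generated ratiometric recording.

    ``z_latent`` is the noiseless response in Z units (what the corrected,
    Z-scored trace would show with the noise averaged out); ``kernels``
    stores per-effect analytic parameters (Gaussian peak time and SD) so
    tests can evaluate the kernel independently.
    """

    responders: dict[str, np.ndarray]
    z_latent: np.ndarray  # (n_frames, n_rois)
    kernels: dict[str, dict] = field(default_factory=dict)
    onsets: dict[str, float] = field(default_factory=dict)

    def direction(self, substance: str) -> str:
        return self.kernels[substance]["direction"]


def _gaussian_kernel(t: np.ndarray, t_peak: float, fwhm: float) -> np.ndarray:
    sd = fwhm / _FWHM_TO_SD
    return np.exp(-0.5 * ((t - t_peak) / sd) ** 2)


def _response_kernel(
    t: np.ndarray, onset: float, onset_delay: float, fwhm: float
) -> np.ndarray:
    """Gated Gaussian response kernel with exact analytic FWHM.

    The Gaussian peaks at ``onset + onset_delay + 0.8 * fwhm``.  A
    smoothstep gate zeroes the kernel before the application onset and
    ramps to one by ``onset + onset_delay + 0.1 * fwhm``: the gate region
    lies strictly below the half-maximum (the Gaussian is < 0.26 there for
    every fwhm), so the half-width crossings — hence the FWHM — are those
    of the pure Gaussian, while nothing leaks into the pre-onset baseline.
    """
    t_peak = onset + onset_delay + _PEAK_OFFSET_FRACTION * fwhm
    kern = _gaussian_kernel(t, t_peak, fwhm)
    ramp_end = onset + onset_delay + 0.1 * fwhm
    x = np.clip((t - onset) / max(ramp_end - onset, 1e-9), 0.0, 1.0)
    gate = x * x * (3.0 - 2.0 * x)
    return kern * gate


def generate_yc_recording(
    effects: list[SubstanceEffectSpec],
    n_rois: int,
    frame_interval: float,
    session_layout: list[float] | None = None,
    seed: int = 0,
    *,
    application_duration: float = 120.0,
    baseline_duration: float = 300.0,
    noise_sd: float = 0.01,
    bleach_tau: float = 7200.0,
    yfp0: float = 1000.0,
    cfp0: float = 800.0,
    session_duration: float | None = None,
    animal_id: str = "sim",
    slice_id: str = "sim-slice",
    sex: str = "f",
) -> tuple[RatiometricRecording, YcGroundTruth]:
    """Simulate a perfusion screening session on one slice.

    Each effect is applied at its onset from ``session_layout`` (default:
    one application every ``baseline_duration + 600`` s, leaving a full
    5-min baseline and 5-min response window).  The response kernel is a
    Gaussian bump peaking ``onset_delay + 0.8 * duration_fwhm`` seconds
    after onset with analytic FWHM ``duration_fwhm``; YFP rises and CFP falls (or
    vice versa) so the Y/C ratio carries the response while single-channel
    bleaching cancels.  ``depth`` is calibrated in Z units against the
    analytic ratio noise at each application's baseline, so the downstream
    Z-scored trace reaches ``±depth`` at the kernel peak by construction.

    Channel model: ``chan(t) = chan0 · exp(−t/bleach_tau) · m(t) + ε`` with
    ``ε ~ N(0, (noise_sd · chan0)²)`` i.i.d. per frame and channel, and
    multiplicative response ``m(t) = sqrt(1 + r(t))`` for YFP and
    ``1/sqrt(1 + r(t))`` for CFP.

    Returns the recording and its ground truth.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if session_layout is None:
        spacing = baseline_duration + 600.0
        session_layout = [baseline_duration + k * spacing for k in range(len(effects))]
    if len(session_layout) != len(effects):
        raise ValueError("session_layout must give one onset per effect")
    order = np.argsort(session_layout)
    onsets = [float(session_layout[i]) for i in order]
    effects = [effects[i] for i in order]
    for o1, o2 in zip(onsets, onsets[1:]):
        if o2 < o1 + application_duration:
            raise ValueError(
                f"application windows overlap: onsets {o1} and {o2} with "
                f"duration {application_duration}"
            )
    if session_duration is None:
        session_duration = onsets[-1] + 700.0 if onsets else 600.0
    if onsets and onsets[-1] + application_duration > session_duration:
        raise ValueError("application extends past the session end")
    if onsets and onsets[0] < 0:
        raise ValueError("negative application onset")

    rng = np.random.default_rng(seed)
    n_frames = int(round(session_duration / frame_interval))
    t = np.arange(n_frames) * frame_interval

    # Analytic relative SD of the Y/C ratio at time tb (additive channel
    # noise, shared bleach): sqrt(2) * noise_sd * exp(tb / tau).
    def ratio_noise_rel(tb: float) -> float:
        return math.sqrt(2.0) * noise_sd * math.exp(tb / bleach_tau)

    z_latent = np.zeros((n_frames, n_rois))
    r_rel = np.zeros((n_frames, n_rois))  # relative ratio modulation
    responders: dict[str, np.ndarray] = {}
    kernels: dict[str, dict] = {}
    onset_map: dict[str, float] = {}
    for eff, onset in zip(effects, onsets):
        mask = rng.random(n_rois) < eff.responder_fraction
        responders[eff.name] = mask
        onset_map[eff.name] = onset
        t_peak = onset + eff.onset_delay + _PEAK_OFFSET_FRACTION * eff.duration_fwhm
        kernels[eff.name] = {
            "direction": eff.direction,
            "depth": eff.depth,
            "t_peak": t_peak,
            "sd": eff.duration_fwhm / _FWHM_TO_SD,
            "fwhm": eff.duration_fwhm,
            "onset": onset,
        }
        if eff.sign == 0.0 or eff.depth == 0.0:
            continue
        kern = _response_kernel(t, onset, eff.onset_delay, eff.duration_fwhm)
        z_eff = eff.sign * eff.depth * kern
        tb = max(onset - baseline_duration / 2.0, 0.0)
        amp = eff.depth * ratio_noise_rel(tb)
        r_eff = eff.sign * amp * kern
        z_latent[:, mask] += z_eff[:, None]
        r_rel[:, mask] += r_eff[:, None]

    if np.any(r_rel <= -1.0):
        raise ValueError("response modulation drives the ratio non-positive")
    bleach = np.exp(-t / bleach_tau)[:, None]
    mod = np.sqrt(1.0 + r_rel)
    yfp = yfp0 * bleach * mod + noise_sd * yfp0 * rng.standard_normal(
        (n_frames, n_rois)
    )
    cfp = cfp0 * bleach / mod + noise_sd * cfp0 * rng.standard_normal(
        (n_frames, n_rois)
    )
    np.clip(yfp, 1e-6, None, out=yfp)
    np.clip(cfp, 1e-6, None, out=cfp)
    rec = RatiometricRecording(
        yfp=yfp,
        cfp=cfp,
        frame_interval=frame_interval,
        applications=[
            Application(eff.name, onset, application_duration)
            for eff, onset in zip(effects, onsets)
        ],
        animal_id=animal_id,
        slice_id=slice_id,
        sex=sex,
    )
    truth = YcGroundTruth(
        responders=responders,
        z_latent=z_latent,
        kernels=kernels,
        onsets=onset_map,
    )
    return rec, truth


@dataclass
class TstGroundTruth:
    immobile: np.ndarray  # boolean per frame
    struggle_bouts: list[tuple[float, float]]

    @property
    def total_immobility_frames(self) -> int:
        return int(self.immobile.sum())


def generate_tst_area_series(
    duration: float = 360.0,
    frame_rate: float = 30.0,
    pendulum_freq: float = 0.7,
    struggle_bouts: list[tuple[float, float]] | None = None,
    seed: int = 0,
    *,
    base_area: float = 5000.0,
    pendulum_amp: float = 300.0,
    struggle_rms: float = 300.0,
    struggle_band: tuple[float, float] = (2.5, 10.0),
    noise_sd: float = 60.0,
) -> tuple[AreaSeries, TstGroundTruth]:
    """Simulate a tail-suspension body-area trace.

    The signal is ``base_area`` plus an always-on pendulum tone at
    ``pendulum_freq``, plus band-limited (``struggle_band``) broadband
    motion of RMS ``struggle_rms`` inside each struggle bout, plus white
    measurement noise.  Ground-truth immobility is the complement of the
    bouts.  The default amplitudes put the struggle-to-noise RMS ratio at 5.
    """
    if struggle_bouts is None:
        struggle_bouts = []
    if not 0 < pendulum_freq < frame_rate / 2:
        raise ValueError(
            f"pendulum_freq {pendulum_freq} Hz outside (0, Nyquist="
            f"{frame_rate / 2})"
        )
    for b0, b1 in struggle_bouts:
        if not 0 <= b0 < b1 <= duration:
            raise ValueError(f"struggle bout ({b0}, {b1}) outside the session")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    phase = rng.uniform(0, 2 * np.pi)
    area = base_area + pendulum_amp * np.sin(2 * np.pi * pendulum_freq * t + phase)

    sos = _signal.butter(4, struggle_band, btype="bandpass", fs=frame_rate, output="sos")
    broadband = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    broadband *= struggle_rms / max(broadband.std(), 1e-12)
    bout_mask = np.zeros(n, dtype=bool)
    for b0, b1 in struggle_bouts:
        bout_mask[int(round(b0 * frame_rate)) : int(round(b1 * frame_rate))] = True
    area += broadband * bout_mask
    area += noise_sd * rng.standard_normal(n)
    series = AreaSeries(area=area, frame_rate=frame_rate)
    return series, TstGroundTruth(
        immobile=~bout_mask, struggle_bouts=list(struggle_bouts)
    )


@dataclass
class EegGroundTruth:
    hypnogram: Hypnogram


#: Per-state signal levels (a.u.): tuned to the qualitative physiology —
#: NR is delta-dominated, REM theta-dominated with muscle atonia, wake has
#: high muscle tone and sensor-detected movement.
_STATE_LEVELS = {
    #        delta theta  emg   ir (expected counts / epoch)
    "W": dict(delta=7.0, theta=4.0, emg=40.0, ir=10.0),
    "NR": dict(delta=40.0, theta=5.0, emg=8.0, ir=0.3),
    "R": dict(delta=5.0, theta=28.0, emg=4.0, ir=0.3),
}


def generate_eeg_emg(
    state_sequence: list[str],
    epoch_length: float = 4.0,
    sample_rate: float = 250.0,
    seed: int = 0,
    *,
    eeg_base_rms: float = 10.0,
    level_jitter: float = 0.25,
    emg_floor: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, EegGroundTruth]:
    """Simulate EEG, EMG and IR-activity for a given W/NR/R epoch sequence.

    EEG = pink background + delta-band (1.5-4 Hz) and theta-band (5-8 Hz)
    narrowband noise with per-state, per-epoch log-normally jittered gains;
    EMG = band-limited noise (15 Hz to the acquisition band edge, clipped
    below Nyquist) with state-dependent RMS; IR activity = per-sample event
    counts with state-dependent epoch rates.

    Returns ``(eeg, emg, ir, ground_truth)``.
    """
    if sample_rate < 100:
        raise ValueError("sample_rate must be >= 100 Hz")
    unknown = set(state_sequence) - set(STATES)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_epochs = len(state_sequence)
    spe = int(round(epoch_length * sample_rate))
    n = n_epochs * spe

    def _band_noise(band: tuple[float, float]) -> np.ndarray:
        sos = _signal.butter(4, band, btype="bandpass", fs=sample_rate, output="sos")
        x = _signal.sosfiltfilt(sos, rng.standard_normal(n))
        return x / max(x.std(), 1e-12)

    # Pink (1/f) background keeps the wake theta/delta ratio below one.
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shaping = np.where(freqs > 0.5, 0.5 / np.maximum(freqs, 0.5), 1.0)
    pink = np.fft.irfft(spec * shaping, n)
    pink *= eeg_base_rms / max(pink.std(), 1e-12)

    delta_noise = _band_noise((1.5, 4.0))
    theta_noise = _band_noise((5.0, 8.0))
    emg_hi = min(300.0, 0.45 * sample_rate)
    emg_noise = _band_noise((15.0, emg_hi))

    def _gains(key: str) -> np.ndarray:
        base = np.array([_STATE_LEVELS[s][key] for s in state_sequence])
        jitter = np.exp(level_jitter * rng.standard_normal(n_epochs))
        return np.repeat(base * jitter, spe)

    eeg = pink + delta_noise * _gains("delta") + theta_noise * _gains("theta")
    emg = emg_noise * _gains("emg") + emg_floor * rng.standard_normal(n)
    ir_rate = np.repeat(
        np.array([_STATE_LEVELS[s]["ir"] for s in state_sequence]) / spe, spe
    )
    ir = rng.poisson(ir_rate).astype(float)
    truth = EegGroundTruth(
        hypnogram=Hypnogram(
            labels=np.asarray(state_sequence, dtype=object),
            epoch_length=epoch_length,
        )
    )
    return eeg, emg, ir, truth


def markov_state_sequence(
    n_epochs: int,
    seed: int = 0,
    *,
    persistence: float = 0.96,
    proportions: tuple[float, float, float] = (0.45, 0.45, 0.10),
    initial: str = "W",
) -> list[str]:
    """Persistent Markov W/NR/R sequence with target stationary proportions.

    A simple bout-structured chain: each epoch keeps the previous state with
    probability ``persistence``, otherwise jumps to a state drawn from
    ``proportions`` (W, NR, R).
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    seq = [initial]
    for _ in range(n_epochs - 1):
        if rng.random() < persistence:
            seq.append(seq[-1])
        else:
            seq.append(STATES[rng.choice(3, p=p)])
    return seq


@dataclass
class PhotometryGroundTruth:
    f470: np.ndarray  # noiseless steady 20 Hz burst values
    f405: np.ndarray
    f_gc: np.ndarray  # what isosbestic correction should recover
    latent: np.ndarray
    artifact: np.ndarray
    gain: float


def generate_photometry_raw(
    latent_calcium: np.ndarray,
    artifact: np.ndarray,
    burst_layout: BurstLayout | None = None,
    seed: int = 0,
    *,
    v470: float = -1.0,
    v405: float = -0.5,
    gain: float = 0.05,
    artifact_gain: float = 0.2,
    noise_sd: float = 0.0,
    settle: bool = True,
) -> tuple[RawPmtStream, PhotometryGroundTruth]:
    """Encode a 20 Hz latent calcium signal into a raw interleaved stream.

    Per 20 Hz sample ``i`` the steady burst values are::

        f470[i] = v470 * (1 + artifact_gain * artifact[i]) + gain * latent[i]
        f405[i] = v405 * (1 + artifact_gain * artifact[i])

    so the motion artifact scales both channels proportionally and the
    isosbestic correction removes it exactly; the corrected signal equals
    ``gain * latent`` exactly whenever the latent signal averages to zero
    over the first third of the recording.  Default operating points sit
    near −1 V (470 nm) and −0.5 V (405 nm).

    With ``settle=True`` the first 12 points of each burst ramp from the
    previous burst's level (LED settling) and the last point decays toward
    the next channel, which exercises the 13-24 averaging window; with
    ``settle=False`` bursts are constant and de-interleaving is exact.
    """
    layout = burst_layout or BurstLayout()
    latent = np.asarray(latent_calcium, dtype=float).ravel()
    art = np.asarray(artifact, dtype=float).ravel()
    if latent.shape != art.shape:
        raise ValueError("latent and artifact series must have equal length")
    n20 = latent.shape[0]
    rng = np.random.default_rng(seed)

    f470 = v470 * (1.0 + artifact_gain * art) + gain * latent
    f405 = v405 * (1.0 + artifact_gain * art)
    first, second = (f470, f405) if layout.first_channel == 470 else (f405, f470)

    ppb = layout.points_per_burst
    cycles = np.empty((n20, layout.cycle_points))
    cycles[:, :ppb] = first[:, None]
    cycles[:, ppb:] = second[:, None]
    if settle:
        ramp = np.linspace(0.8, 0.0, 12)
        prev_first = np.concatenate(([second[0]], second[:-1]))
        cycles[:, :12] = first[:, None] + (prev_first - first)[:, None] * ramp
        cycles[:, ppb - 1] = first + 0.3 * (second - first)
        cycles[:, ppb : ppb + 12] = (
            second[:, None] + (first - second)[:, None] * ramp
        )
        cycles[:, -1] = second + 0.3 * (first - second)
    stream = cycles.ravel()
    if noise_sd > 0:
        stream = stream + noise_sd * rng.standard_normal(stream.shape)
    raw = RawPmtStream(voltage=stream, layout=layout)
    truth = PhotometryGroundTruth(
        f470=f470,
        f405=f405,
        f_gc=gain * latent,
        latent=latent,
        artifact=art,
        gain=gain,
    )
    return raw, truth


def generate_clustered_values(
    k_clusters: int,
    m_per_cluster: int,
    icc_true: float,
    seed: int = 0,
    *,
    total_sd: float = 1.0,
    grand_mean: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-way random-effects draws with a prescribed intraclass correlation.

    ``value = grand_mean + b_cluster + e`` with ``Var(b) = icc_true``,
    ``Var(e) = 1 − icc_true`` (times ``total_sd²``).  Returns
    ``(values, cluster_labels)``.
    """
    if k_clusters < 2 or m_per_cluster < 2:
        raise ValueError("need k_clusters >= 2 and m_per_cluster >= 2")
    if not 0.0 <= icc_true <= 1.0:
        raise ValueError("icc_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sd_b = total_sd * math.sqrt(icc_true)
    sd_w = total_sd * math.sqrt(1.0 - icc_true)
    b = rng.normal(0.0, sd_b, size=k_clusters)
    e = rng.normal(0.0, sd_w, size=(k_clusters, m_per_cluster))
    values = (grand_mean + b[:, None] + e).ravel()
    labels = np.repeat(np.arange(k_clusters), m_per_cluster)
    return values, labels
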