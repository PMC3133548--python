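"""Forward model for block-design dual-wavelength fNIRS recordings.

Generates raw light-intensity recordings with known ground-truth hemodynamics
so that preprocessing, statistics and classification can be verified
end-to-end without any external data.  The protocol emulated is an
alternating rest/stimulation block design (default 20 s rest + 15 s
stimulation, 12 trials per condition, 100 Hz sampling, three channels at two
wavelengths).

Signal model
------------
Per channel the noiseless concentration series is::

    hemo(t) = sum_trials amp[cond, ch] * r(t - onset) + drift(t) + osc(t)

where ``r`` is a stimulation-length boxcar convolved with a unit-peak gamma
kernel and renormalised to unit peak, so the configured amplitude is the peak
of the isolated single-trial response.  ``forward_optics`` maps
concentrations to detector intensities through the Beer-Lambert relation
(adding ambient light and, optionally, noise); the inverse lives in
:mod:`nirstrial.preproc`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import optics

DEFAULT_CONDITIONS = ("MI-simple", "MI-complex")


@dataclass
class EventTable:
    """Stimulation events of one recording (rest phases are implicit gaps)."""

    onsets: np.ndarray          # seconds
    durations: np.ndarray       # seconds
    conditions: np.ndarray      # condition label per event
    total_duration: float       # seconds

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if not (len(self.onsets) == len(self.durations) == len(self.conditions)):
            raise ValueError("event columns must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onsets,
            "duration_s": self.durations,
            "condition": self.conditions,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, total_duration: float | None = None) -> "EventTable":
        if total_duration is None:
            total_duration = float(frame.onset_s.iloc[-1] + frame.duration_s.iloc[-1])
        return cls(frame.onset_s.to_numpy(), frame.duration_s.to_numpy(),
                   frame.condition.to_numpy(), total_duration)


@dataclass
class GeneratorConfig:
    """All knobs of the forward model.

    Amplitudes are peak amplitudes of the isolated single-trial response, in
    umol/l, one value per channel and condition (scalars broadcast).  Use
    :func:`nirstrial.pipeline.calibrate_amplitudes` to pick peaks that make
    the downstream stimulation-minus-rest means hit given targets.
    """

    n_trials_per_condition: int = 12
    stim_duration: float = 15.0
    rest_duration: float = 20.0
    sampling_rate: float = 100.0
    n_channels: int = 3
    wavelengths: tuple = optics.DEFAULT_WAVELENGTHS
    conditions: tuple = DEFAULT_CONDITIONS
    amp_o2hb: Mapping[str, Sequence[float] | float] = field(
        default_factory=lambda: {"MI-simple": (0.101, 0.054, 0.038),
                                 "MI-complex": (0.192, 0.095, 0.065)})
    amp_hhb: Mapping[str, Sequence[float] | float] = field(
        default_factory=lambda: {"MI-simple": (-0.017, -0.013, -0.011),
                                 "MI-complex": (-0.008, -0.010, -0.007)})
    hrf_peak: float = 6.0           # kernel peak latency, s
    hrf_dispersion: float = 0.75    # gamma scale, s; 0.75 gives FWHM ~ 5 s
    onset_delay: float = 0.0        # extra response latency after cue, s
    drift_slope: float = 0.02       # umol/l per minute, both chromophores
    osc_components: tuple = ((0.1, 0.05), (1.0, 0.02))  # (Hz, umol/l)
    white_noise_sd: float = 0.05    # umol/l, concentration-domain, per sample
    intensity_noise_sd: float = 0.0  # detector units, on intensities
    ambient_level: float = 50.0     # detector units
    baseline_intensity: float = 4000.0  # detector units
    extinction: np.ndarray | None = None   # None -> packaged table
    dpf: Mapping[float, float] = field(default_factory=lambda: dict(optics.DEFAULT_DPF))
    distance_mm: float = 12.5
    seed: int = 0
    allow_hrf_overlap: bool = False
    max_extinction_cond: float = 1e3

    # -- derived helpers ---------------------------------------------------
    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_condition

    @property
    def trial_duration(self) -> float:
        return self.rest_duration + self.stim_duration

    @property
    def total_duration(self) -> float:
        return self.n_trials * self.trial_duration

    def extinction_matrix(self) -> np.ndarray:
        if self.extinction is not None:
            return np.asarray(self.extinction, dtype=float)
        return optics.extinction_matrix(self.wavelengths)

    def amp_array(self, which: str = "o2hb") -> np.ndarray:
        """Amplitudes as a (n_conditions, n_channels) array."""
        mapping = self.amp_o2hb if which == "o2hb" else self.amp_hhb
        out = np.empty((len(self.conditions), self.n_channels))
        for i, cond in enumerate(self.conditions):
            val = np.asarray(mapping[cond], dtype=float)
            out[i] = np.broadcast_to(val, (self.n_channels,))
        return out

    def validate(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        for name in ("stim_duration", "rest_duration", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")
        if self.osc_components:
            fmax = max(f for f, _ in self.osc_components)
            if self.sampling_rate <= 2 * fmax:
                raise ValueError("sampling_rate must exceed twice the max oscillation frequency")
        for which in ("o2hb", "hhb"):
            self.amp_array(which)   # raises on shape mismatch
        optics.check_invertible(self.extinction_matrix(), self.max_extinction_cond)

    def rngs(self) -> tuple:
        """Deterministic per-stage random generators (events, hemo, optics)."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


@dataclass
class GroundTruth:
    """Noiseless concentration series plus the quantities used to build it."""

    sampling_rate: float
    time: np.ndarray                  # seconds, 1-D
    response_o2hb: np.ndarray         # (n_channels, n) evoked component only
    response_hhb: np.ndarray
    background_o2hb: np.ndarray       # drift + oscillations
    background_hhb: np.ndarray
    events: EventTable
    trial_amplitudes_o2hb: np.ndarray  # (n_trials, n_channels)
    trial_amplitudes_hhb: np.ndarray

    @property
    def o2hb(self) -> np.ndarray:
        return self.response_o2hb + self.background_o2hb

    @property
    def hhb(self) -> np.ndarray:
        return self.response_hhb + self.background_hhb

    @property
    def trial_labels(self) -> np.ndarray:
        return self.events.conditions


def build_event_table(config: GeneratorConfig) -> EventTable:
    """Seeded random interleaving of the two conditions on the block grid.

    Trial k occupies ``[k*T, (k+1)*T)`` with ``T = rest + stim``; the
    stimulation onset is ``k*T + rest``.  Exactly
    ``n_trials_per_condition`` trials of each condition appear.
    """
    config.validate()
    rng_events, _, _ = config.rngs()
    labels = np.repeat(np.asarray(config.conditions, dtype=object),
                       config.n_trials_per_condition)
    labels = labels[rng_events.permutation(len(labels))]
    k = np.arange(config.n_trials)
    onsets = k * config.trial_duration + config.rest_duration
    durations = np.full(config.n_trials, config.stim_duration)
    return EventTable(onsets, durations, labels, config.total_duration)


def hrf_kernel(config: GeneratorConfig, sampling_rate: float | None = None) -> np.ndarray:
    """Unit-peak gamma kernel h(t) = (t/p)^(p/d) * exp((p - t)/d).

    Truncated where the tail falls below 1e-6 of the peak.  Kernels whose
    support exceeds one trial length are rejected unless
    ``allow_hrf_overlap`` is set (they would alias across trials).
    """
    fs = sampling_rate if sampling_rate is not None else config.sampling_rate
    p, d = config.hrf_peak, config.hrf_dispersion
    if p <= 0 or d <= 0:
        raise ValueError("hrf_peak and hrf_dispersion must be > 0")
    # generous upper bound on support, then truncate
    t = np.arange(0.0, 20.0 * p + 1.0 / fs, 1.0 / fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0, np.exp((p / d) * np.log(t / p) + (p - t) / d), 0.0)
    peak_idx = int(np.argmax(h))
    tail = np.nonzero(h[peak_idx:] < 1e-6)[0]
    if tail.size:
        h = h[: peak_idx + tail[0]]
    support = len(h) / fs
    if support > config.trial_duration and not config.allow_hrf_overlap:
        raise ValueError(
            f"HRF kernel support {support:.1f} s exceeds one trial "
            f"({config.trial_duration:.1f} s); set allow_hrf_overlap to permit this")
    return h


def trial_response(config: GeneratorConfig, sampling_rate: float | None = None) -> np.ndarray:
    """Single-trial response: stimulation boxcar * gamma kernel, unit peak."""
    fs = sampling_rate if sampling_rate is not None else config.sampling_rate
    h = hrf_kernel(config, fs)
    boxcar = np.ones(int(round(config.stim_duration * fs)))
    r = np.convolve(boxcar, h)
    peak = r.max()
    if peak <= 0:
        raise ValueError("degenerate trial response")
    return r / peak


def simulate_hemodynamics(config: GeneratorConfig, events: EventTable) -> GroundTruth:
    """Noiseless per-channel concentration series for a given event table."""
    config.validate()
    fs = config.sampling_rate
    n = int(round(events.total_duration * fs))
    t = np.arange(n) / fs
    resp = trial_response(config)

    amp_o2 = config.amp_array("o2hb")
    amp_hh = config.amp_array("hhb")
    cond_index = {c: i for i, c in enumerate(config.conditions)}

    response_o2 = np.zeros((config.n_channels, n))
    response_hh = np.zeros((config.n_channels, n))
    trial_amp_o2 = np.empty((events.n_trials, config.n_channels))
    trial_amp_hh = np.empty((events.n_trials, config.n_channels))
    for k in range(events.n_trials):
        ci = cond_index[events.conditions[k]]
        start = int(round((events.onsets[k] + config.onset_delay) * fs))
        stop = min(start + len(resp), n)
        if start >= n:
            continue
        seg = resp[: stop - start]
        trial_amp_o2[k] = amp_o2[ci]
        trial_amp_hh[k] = amp_hh[ci]
        response_o2[:, start:stop] += amp_o2[ci][:, None] * seg[None, :]
        response_hh[:, start:stop] += amp_hh[ci][:, None] * seg[None, :]

    _, rng_hemo, _ = config.rngs()
    drift = (config.drift_slope / 60.0) * t
    background_o2 = np.tile(drift, (config.n_channels, 1))
    background_hh = np.tile(drift, (config.n_channels, 1))
    for ch in range(config.n_channels):
        for freq, amp in config.osc_components:
            phase_o2 = rng_hemo.uniform(0.0, 2.0 * np.pi)
            phase_hh = rng_hemo.uniform(0.0, 2.0 * np.pi)
            background_o2[ch] += amp * np.sin(2.0 * np.pi * freq * t + phase_o2)
            background_hh[ch] += 0.1 * amp * np.sin(2.0 * np.pi * freq * t + phase_hh)

    return GroundTruth(fs, t, response_o2, response_hh, background_o2,
                       background_hh, events, trial_amp_o2, trial_amp_hh)


def forward_optics(truth: GroundTruth, config: GeneratorConfig):
    """Map ground-truth concentrations to raw detector intensities.

    I(lambda, t) = baseline * 10^(-dA(lambda, t)) + ambient with
    dA = (eps_o2hb * dC_o2hb + eps_hhb * dC_hhb) * distance * DPF(lambda).
    Concentration-domain white noise (``white_noise_sd``) is added before the
    optical mapping; detector noise (``intensity_noise_sd``) afterwards.
    """
    from .preproc import RawRecording   # deferred to avoid a cycle

    config.validate()
    _, _, rng_opt = config.rngs()
    o2hb = truth.o2hb.copy()
    hhb = truth.hhb.copy()
    if config.white_noise_sd > 0:
        o2hb = o2hb + rng_opt.normal(0.0, config.white_noise_sd, o2hb.shape)
        hhb = hhb + rng_opt.normal(0.0, config.white_noise_sd, hhb.shape)

    coupling = optics.absorbance_system(config.extinction_matrix(),
                                        config.distance_mm, config.dpf,
                                        config.wavelengths)
    # dA: (n_channels, n_wavelengths, n)
    conc = np.stack([o2hb, hhb], axis=1)               # (ch, chrom, n)
    d_absorb = np.einsum("lc,kcn->kln", coupling, conc)
    intensity = config.baseline_intensity * 10.0 ** (-d_absorb) + config.ambient_level
    if config.intensity_noise_sd > 0:
        intensity = intensity + rng_opt.normal(0.0, config.intensity_noise_sd,
                                               intensity.shape)
    if np.any(intensity <= 0):
        raise ValueError("forward model produced non-positive intensities; "
                         "check baseline/noise configuration")
    ambient = np.full(intensity.shape[-1], float(config.ambient_level))
    return RawRecording(
        sampling_rate=config.sampling_rate,
        intensity=intensity,
        ambient=ambient,
        events=truth.events,
        wavelengths=tuple(config.wavelengths),
        distance_mm=config.distance_mm,
        log=[{"step": "simulate", "seed": config.seed}],
    )


def simulate(config: GeneratorConfig):
    """Convenience wrapper: event table + hemodynamics + optics.

    Returns ``(raw, truth)``; identical ``(config, seed)`` pairs yield
    bit-identical output.
    """
    events = build_event_table(config)
    truth = simulate_hemodynamics(config, events)
    raw = forward_optics(truth, config)
    return raw, truth


def sample_subject_configs(base: GeneratorConfig, n_subjects: int, seed: int,
                           amp_cv: float = 0.15,
                           latency_sd: float = 0.0) -> list:
    """Per-subject configs with amplitudes/latencies drawn around the base.

    Amplitudes are scaled by factors from a normal distribution (mean 1,
    SD ``amp_cv``) truncated at zero; response peak latency is jittered by a
    zero-truncated normal when ``latency_sd`` > 0.  Each subject also gets a
    distinct generator seed.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n_subjects):
        scale = 0.0
        while scale <= 0.0:
            scale = rng.normal(1.0, amp_cv) if amp_cv > 0 else 1.0
        peak = 0.0
        while peak <= 0.0:
            peak = rng.normal(base.hrf_peak, latency_sd) if latency_sd > 0 else base.hrf_peak
        amp_o2 = {c: tuple(scale * np.atleast_1d(np.asarray(v, float)))
                  for c, v in base.amp_o2hb.items()}
        amp_hh = {c: tuple(scale * np.atleast_1d(np.asarray(v, float)))
                  for c, v in base.amp_hhb.items()}
        configs.append(base.replace(amp_o2hb=amp_o2, amp_hhb=amp_hh,
                                    hrf_peak=peak,
                                    seed=int(rng.integers(0, 2**31 - 1))))
    return configs
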