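"""Seeded synthetic EEG recordings and behavioural tables.

Recordings compose 1/f background noise, narrowband oscillations whose
amplitude envelopes carry a controllable DFA exponent, condition-locked
ERP kernels at event onsets, and optional blink artifacts.  Behavioural
tables follow a mixed-effects logistic accuracy model plus per-condition
log-normal reaction times, so every downstream analysis stage has a
known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal
from scipy.special import expit

from .chord_stimuli import ChordCategory, Schedule
from .montage import MontageSpec

__all__ = [
    "Event",
    "RawRecording",
    "ERPComponent",
    "BandTruth",
    "BehaviourTruth",
    "GroundTruth",
    "condition_of",
    "gen_lrtc_series",
    "gen_pink_noise",
    "gen_band_oscillation",
    "gen_erp_template",
    "simulate_recording",
    "simulate_epochs",
    "simulate_behaviour",
    "simulate_trial_tables",
]

CONDITIONS = ("consonant", "dissonant", "neutral")
RESPONSES = ("pleasant", "unpleasant", "neutral")
#: a-priori correct response per stimulus type
CONGRUENT_RESPONSE = {
    "consonant": "pleasant",
    "dissonant": "unpleasant",
    "neutral": "neutral",
}


def condition_of(category: ChordCategory | str) -> str:
    category = ChordCategory(category)
    if category in (ChordCategory.consonant_root, ChordCategory.consonant_64):
        return "consonant"
    if category in (ChordCategory.dissonant_t1, ChordCategory.dissonant_t2):
        return "dissonant"
    return "neutral"


@dataclass(frozen=True)
class Event:
    sample: int
    stimulus_id: str
    condition: str


@dataclass
class RawRecording:
    """Multichannel EEG: (channels x samples) in microvolts."""

    data: np.ndarray
    sfreq: float
    channel_names: tuple[str, ...]
    events: tuple[Event, ...] = ()
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        samples = [e.sample for e in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("events must be strictly increasing in time")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ERPComponent:
    latency_ms: float
    width_ms: float          # Gaussian SD of the temporal bump
    amplitude_uv: float
    centre_channel: str
    spread_rad: float = 0.8  # SD of the Gaussian spatial falloff


@dataclass(frozen=True)
class BandTruth:
    name: str
    low_hz: float
    high_hz: float
    hurst: float
    mean_amplitude_uv: float

    def __post_init__(self) -> None:
        if not 0 < self.hurst < 1:
            raise ValueError("Hurst exponent must lie in (0, 1)")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("band edges must satisfy 0 < low < high")


@dataclass(frozen=True)
class BehaviourTruth:
    """Parameters of the accuracy / response / reaction-time generator."""

    # multinomial response probabilities per stimulus type
    response_probs: dict = field(
        default_factory=lambda: {
            "consonant": {"pleasant": 0.78, "neutral": 0.15, "unpleasant": 0.07},
            "dissonant": {"pleasant": 0.08, "neutral": 0.20, "unpleasant": 0.72},
            "neutral": {"pleasant": 0.10, "neutral": 0.75, "unpleasant": 0.15},
        }
    )
    # mean RT (ms) per (stimulus type, congruent flag); values from the
    # published group means
    rt_mean_ms: dict = field(
        default_factory=lambda: {
            ("consonant", True): 464.0,
            ("dissonant", True): 522.0,
            ("neutral", True): 747.0,
            ("consonant", False): 1158.0,
            ("dissonant", False): 1123.0,
            ("neutral", False): 688.0,
        }
    )
    rt_sigma: float = 0.25  # log-normal shape parameter
    # accuracy model: logit(P(correct)) with consonant as reference level
    intercept: float = 1.25
    beta_dissonant: float = -0.30
    beta_neutral: float = 0.40
    beta_predictor: float = -0.40
    beta_dissonant_x: float = -0.80
    beta_neutral_x: float = -0.50
    sd_subject_intercept: float = 0.5
    sd_subject_slope: float = 0.3
    sd_item_intercept: float = 0.2

    def __post_init__(self) -> None:
        for cond, probs in self.response_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"response probabilities for {cond} sum to {total}")
        if any(m <= 0 for m in self.rt_mean_ms.values()):
            raise ValueError("RT means must be positive")

    def fixed_effects(self) -> np.ndarray:
        return np.array(
            [
                self.intercept,
                self.beta_dissonant,
                self.beta_neutral,
                self.beta_predictor,
                self.beta_dissonant_x,
                self.beta_neutral_x,
            ]
        )

    def accuracy_logit(self, condition: str, x: float | np.ndarray) -> np.ndarray:
        d = 1.0 if condition == "dissonant" else 0.0
        n = 1.0 if condition == "neutral" else 0.0
        return (
            self.intercept
            + self.beta_dissonant * d
            + self.beta_neutral * n
            + (self.beta_predictor + self.beta_dissonant_x * d
               + self.beta_neutral_x * n) * np.asarray(x)
        )


def _default_components() -> dict:
    return {
        "consonant": (
            ERPComponent(100.0, 15.0, -3.2, "Cz"),
            ERPComponent(200.0, 20.0, 2.6, "Cz"),
            ERPComponent(300.0, 25.0, 2.4, "Pz"),
        ),
        "dissonant": (
            ERPComponent(100.0, 15.0, -3.6, "Cz"),
            ERPComponent(200.0, 20.0, 4.4, "Cz"),
            ERPComponent(300.0, 25.0, 5.2, "Pz"),
        ),
        "neutral": (
            ERPComponent(100.0, 15.0, -3.0, "Cz"),
            ERPComponent(200.0, 20.0, 2.4, "Cz"),
            ERPComponent(300.0, 25.0, 3.0, "Pz"),
        ),
    }


def _default_bands() -> tuple[BandTruth, ...]:
    return (
        BandTruth("alpha", 8.0, 12.0, 0.70, 4.0),
        BandTruth("beta", 20.0, 25.0, 0.65, 2.0),
        BandTruth("gamma", 35.0, 40.0, 0.60, 1.0),
    )


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of the synthetic EEG + behaviour generator."""

    components: dict = field(default_factory=_default_components)
    bands: tuple[BandTruth, ...] = field(default_factory=_default_bands)
    behaviour: BehaviourTruth = field(default_factory=BehaviourTruth)
    sample_rate: float = 500.0
    epoch_ms: tuple[float, float] = (-100.0, 800.0)
    background_rms_uv: float = 8.0
    background_exponent: float = 1.0
    envelope_sigma: float = 0.4  # log-amplitude SD of the LRTC envelopes
    blink_rate_hz: float = 0.0
    blink_amplitude_uv: float = 120.0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_ms
        for comps in self.components.values():
            for c in comps:
                if not lo <= c.latency_ms <= hi:
                    raise ValueError(
                        f"component latency {c.latency_ms} ms outside epoch {self.epoch_ms}"
                    )

    def scaled(self, erp_gain: float = 1.0, noise_gain: float = 1.0) -> "GroundTruth":
        comps = {
            cond: tuple(replace(c, amplitude_uv=c.amplitude_uv * erp_gain)
                        for c in cs)
            for cond, cs in self.components.items()
        }
        bands = tuple(
            replace(b, mean_amplitude_uv=b.mean_amplitude_uv * noise_gain)
            for b in self.bands
        )
        return replace(
            self,
            components=comps,
            bands=bands,
            background_rms_uv=self.background_rms_uv * noise_gain,
        )


# ---------------------------------------------------------------------------
# elementary generators


def _power_law_noise(
    n_samples: int, half_exponent: float, rng, size
) -> np.ndarray:
    """Randomly-phased spectrum with amplitude f**half_exponent, standardised.

    Synthesis runs at an FFT-friendly padded length and is truncated, so
    arbitrary ``n_samples`` stay fast.
    """
    nfft = sp_fft.next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(nfft)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** half_exponent
    shape = (nfft // 2 + 1,) if size is None else (size, nfft // 2 + 1)
    spec = amp * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    x = sp_fft.irfft(spec, n=nfft, axis=-1)[..., :n_samples]
    x -= x.mean(axis=-1, keepdims=True)
    x /= x.std(axis=-1, keepdims=True)
    return x


def gen_lrtc_series(n_samples: int, hurst: float, seed, size: int | None = None) -> np.ndarray:
    """Zero-mean, unit-variance series whose DFA exponent approximates H.

    Spectral synthesis of fractional Gaussian noise: Fourier amplitudes
    follow f**((1-2H)/2) with independent random phases.  With ``size``
    an independent batch of series is returned, shape (size, n_samples).
    """
    if not 0 < hurst < 1:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if n_samples < 2**12:
        raise ValueError("need at least 4096 samples for a stable spectrum")
    rng = np.random.default_rng(seed)
    return _power_law_noise(n_samples, (1.0 - 2.0 * hurst) / 2.0, rng, size)


def gen_pink_noise(
    n_samples: int, exponent: float, seed, size: int | None = None
) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent."""
    rng = np.random.default_rng(seed)
    return _power_law_noise(n_samples, -exponent / 2.0, rng, size)


def gen_band_oscillation(
    band: tuple[float, float],
    envelope: np.ndarray,
    sample_rate: float,
    seed,
) -> np.ndarray:
    """Narrowband carrier of unit variance multiplied by a given envelope."""
    low, high = band
    nyq = sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} invalid at sample rate {sample_rate}")
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(envelope.shape)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=sample_rate, output="sos")
    carrier = signal.sosfiltfilt(sos, white, axis=-1)
    sd = carrier.std(axis=-1, keepdims=True)
    carrier = np.divide(carrier, sd, out=carrier, where=sd > 0)
    return carrier * envelope


def lrtc_envelope(
    n_samples: int, hurst: float, mean_amplitude: float, sigma: float, seed,
    size: int | None = None,
    sample_rate: float | None = None,
    smooth_hz: float | None = None,
) -> np.ndarray:
    """Strictly positive envelope exp(sigma * fGn), rescaled to a target mean.

    The exponential keeps the envelope positive; for sigma <= 0.5 the
    monotone transform approximately preserves the DFA exponent.  With
    ``smooth_hz`` the fGn is low-passed first so the modulation stays
    within a narrow band's bandwidth (sub-Hz smoothing leaves the DFA
    scaling at multi-second windows untouched).
    """
    g = gen_lrtc_series(n_samples, hurst, seed, size=size)
    if smooth_hz is not None:
        if sample_rate is None:
            raise ValueError("smooth_hz requires sample_rate")
        # circular spectral low-pass (Butterworth-magnitude): the fGn is
        # spectrally synthesised, so this avoids filter edge transients
        freqs = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
        gain = 1.0 / np.sqrt(1.0 + (freqs / smooth_hz) ** 8)
        g = np.fft.irfft(np.fft.rfft(g, axis=-1) * gain, n=n_samples, axis=-1)
        g /= g.std(axis=-1, keepdims=True)
    env = np.exp(sigma * g)
    env *= mean_amplitude / env.mean(axis=-1, keepdims=True)
    return env


# ---------------------------------------------------------------------------
# ERP templates and recordings


def spatial_map(montage: MontageSpec, centre_channel: str, spread_rad: float) -> np.ndarray:
    """Smooth weight map: Gaussian falloff in great-circle distance."""
    centre = montage.positions[montage.index(centre_channel)]
    d = np.arccos(np.clip(montage.positions @ centre, -1.0, 1.0))
    return np.exp(-(d**2) / (2.0 * spread_rad**2))


def template_times_ms(truth: GroundTruth, sample_rate: float) -> np.ndarray:
    lo, hi = truth.epoch_ms
    n = round((hi - lo) / 1000.0 * sample_rate) + 1
    return lo + np.arange(n) * 1000.0 / sample_rate


def gen_erp_template(
    condition: str,
    montage: MontageSpec,
    truth: GroundTruth,
    sample_rate: float | None = None,
) -> np.ndarray:
    """Condition template (channels x time) over the epoch window."""
    if condition not in truth.components:
        raise ValueError(f"unknown condition {condition!r}")
    sr = sample_rate or truth.sample_rate
    t = template_times_ms(truth, sr)
    out = np.zeros((montage.n_channels, len(t)))
    for comp in truth.components[condition]:
        bump = comp.amplitude_uv * np.exp(
            -((t - comp.latency_ms) ** 2) / (2.0 * comp.width_ms**2)
        )
        out += np.outer(spatial_map(montage, comp.centre_channel, comp.spread_rad), bump)
    return out


def _blink_kernel(sample_rate: float) -> np.ndarray:
    """Biphasic ~300 ms blink deflection, unit peak."""
    t = np.arange(round(0.3 * sample_rate)) / sample_rate
    w = np.exp(-((t - 0.10) ** 2) / (2 * 0.035**2)) - 0.35 * np.exp(
        -((t - 0.20) ** 2) / (2 * 0.05**2)
    )
    return w / np.max(np.abs(w))


def simulate_recording(
    montage: MontageSpec,
    schedule: Schedule,
    truth: GroundTruth,
    seed,
    tail_s: float = 1.5,
) -> RawRecording:
    """Full synthetic session: noise + oscillations + event-locked ERPs."""
    if not schedule.trials:
        raise ValueError("schedule is empty")
    sr = truth.sample_rate
    last = schedule.trials[-1]
    n = int(np.ceil((last.onset_s + tail_s) * sr))
    rng = np.random.default_rng(seed)
    data = np.zeros((montage.n_channels, n))

    if truth.background_rms_uv > 0:
        data += truth.background_rms_uv * gen_pink_noise(
            n, truth.background_exponent, rng, size=montage.n_channels
        )

    for band in truth.bands:
        if band.mean_amplitude_uv <= 0:
            continue
        env = lrtc_envelope(
            n, band.hurst, band.mean_amplitude_uv, truth.envelope_sigma, rng,
            size=montage.n_channels, sample_rate=sr,
            smooth_hz=min(1.0, (band.high_hz - band.low_hz) / 4.0),
        )
        # carrier variance 1 -> RMS of the band signal ~ envelope; the
        # Hilbert envelope mean then sits near band.mean_amplitude_uv
        data += gen_band_oscillation((band.low_hz, band.high_hz), env, sr, rng)

    templates = {
        cond: gen_erp_template(cond, montage, truth, sr) for cond in truth.components
    }
    lo_ms, _ = truth.epoch_ms
    pre = round(-lo_ms / 1000.0 * sr)
    events = []
    for tr in schedule.trials:
        onset = int(round(tr.onset_s * sr))
        cond = condition_of(tr.category)
        kern = templates[cond][:, pre:]  # post-onset part only
        stop = min(n, onset + kern.shape[1])
        data[:, onset:stop] += kern[:, : stop - onset]
        events.append(Event(sample=onset, stimulus_id=tr.stimulus_id, condition=cond))

    blink_samples: list[int] = []
    if truth.blink_rate_hz > 0:
        kern = _blink_kernel(sr)
        bmap = spatial_map(montage, "Fp1", 0.45) + spatial_map(montage, "Fp2", 0.45)
        bmap /= bmap.max()
        t = 0.0
        while True:
            t += rng.exponential(1.0 / truth.blink_rate_hz)
            s = int(round(t * sr))
            if s + len(kern) >= n:
                break
            blink_samples.append(s)
            data[:, s : s + len(kern)] += truth.blink_amplitude_uv * np.outer(
                bmap, kern
            )

    return RawRecording(
        data=data,
        sfreq=sr,
        channel_names=montage.channel_names,
        events=tuple(events),
        annotations={"blink_samples": blink_samples},
    )


def simulate_epochs(
    montage: MontageSpec,
    truth: GroundTruth,
    n_trials_per_condition: int,
    seed,
    sample_rate: float = 250.0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fast path: epoch array (trials x channels x time) of template + 1/f noise.

    Bypasses continuous-recording synthesis for simulation studies that
    only need epoch-level data (cluster-test power/size experiments).
    """
    rng = np.random.default_rng(seed)
    times = template_times_ms(truth, sample_rate)
    n_t = len(times)
    n_ch = montage.n_channels
    epochs = []
    labels = []
    for cond in conditions:
        tmpl = gen_erp_template(cond, montage, truth, sample_rate)
        noise = gen_pink_noise(
            n_t, truth.background_exponent, rng,
            size=n_trials_per_condition * n_ch,
        ).reshape(n_trials_per_condition, n_ch, n_t)
        epochs.append(tmpl[None] + truth.background_rms_uv * noise)
        labels.extend([cond] * n_trials_per_condition)
    return np.concatenate(epochs), labels, times


# ---------------------------------------------------------------------------
# behaviour


def simulate_behaviour(
    schedule: Schedule,
    truth: GroundTruth,
    neural: float | np.ndarray,
    seed,
    subject: str = "S00",
    subject_effects: tuple[float, float, float] | None = None,
    item_effects: dict | None = None,
) -> pd.DataFrame:
    """One subject's trial table from the logistic accuracy model.

    ``neural`` is the standardised neural predictor (scalar per subject or
    one value per trial).  ``subject_effects`` are (intercept, dissonant
    slope, neutral slope) random deviations; drawn from the truth SDs when
    not supplied.  ``item_effects`` maps stimulus id -> random intercept.
    """
    beh = truth.behaviour
    rng = np.random.default_rng(seed)
    x = np.broadcast_to(np.asarray(neural, dtype=float), (len(schedule.trials),))
    if subject_effects is None:
        subject_effects = (
            rng.normal(0.0, beh.sd_subject_intercept),
            rng.normal(0.0, beh.sd_subject_slope),
            rng.normal(0.0, beh.sd_subject_slope),
        )
    if item_effects is None:
        ids = sorted({tr.stimulus_id for tr in schedule.trials})
        item_effects = {
            sid: rng.normal(0.0, beh.sd_item_intercept) for sid in ids
        }
    u0, u_d, u_n = subject_effects
    rows = []
    for tr, xi in zip(schedule.trials, x):
        cond = condition_of(tr.category)
        eta = beh.accuracy_logit(cond, xi)
        eta += u0 + (u_d if cond == "dissonant" else 0.0)
        eta += u_n if cond == "neutral" else 0.0
        eta += item_effects[tr.stimulus_id]
        accurate = bool(rng.random() < expit(eta))
        congruent_resp = CONGRUENT_RESPONSE[cond]
        if accurate:
            response = congruent_resp
        else:
            others = [r for r in RESPONSES if r != congruent_resp]
            w = np.array([beh.response_probs[cond][r] for r in others], dtype=float)
            if w.sum() <= 0:
                w = np.ones_like(w)
            response = others[rng.choice(len(others), p=w / w.sum())]
        congruent = response == congruent_resp
        mean_rt = beh.rt_mean_ms[(cond, congruent)]
        mu = np.log(mean_rt) - beh.rt_sigma**2 / 2.0
        rt = float(rng.lognormal(mu, beh.rt_sigma))
        rows.append(
            {
                "subject": subject,
                "item": tr.stimulus_id,
                "stimulus_type": cond,
                "response": response,
                "rt_ms": rt,
                "congruent": congruent,
                "accuracy": congruent,
                "neural": float(xi),
            }
        )
    return pd.DataFrame(rows)


def simulate_trial_tables(
    schedule: Schedule,
    truth: GroundTruth,
    subject_neural: np.ndarray,
    seed,
) -> pd.DataFrame:
    """Trial tables for many subjects; item effects shared across subjects."""
    rng = np.random.default_rng(seed)
    beh = truth.behaviour
    ids = sorted({tr.stimulus_id for tr in schedule.trials})
    item_effects = {sid: rng.normal(0.0, beh.sd_item_intercept) for sid in ids}
    frames = []
    for s, x in enumerate(np.asarray(subject_neural, dtype=float)):
        frames.append(
            simulate_behaviour(
                schedule,
                truth,
                x,
                rng,
                subject=f"S{s:02d}",
                item_effects=item_effects,
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
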