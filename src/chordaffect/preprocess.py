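"""EEG preprocessing chain: filters, resampling, CAR, bad channels,
FastICA ocular cleanup, epoching and baseline correction.

The canonical stage order (enforced by :func:`preprocess_pipeline`) is
downsample -> notch -> band-pass -> common average reference -> bad
channel exclusion -> ICA -> epoching.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .montage import channel_position
from .synth_eeg import RawRecording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "temporal_filter",
    "downsample",
    "rereference_car",
    "detect_bad_channels",
    "drop_channels",
    "fastica_remove_ocular",
    "epoch_and_baseline",
    "preprocess_pipeline",
    "PreprocessConfig",
]

log = logging.getLogger(__name__)

FRONTAL_CHANNELS = ("Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8")


@dataclass(frozen=True)
class FilterSpec:
    kind: str                     # "band_stop" | "band_pass"
    edges_hz: tuple[float, float]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.edges_hz
        if not 0 < lo < hi:
            raise ValueError(f"filter edges must satisfy 0 < low < high, got {self.edges_hz}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.kind not in ("band_stop", "band_pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")


#: defaults from the analysis protocol: 2nd-order 45-55 Hz notch,
#: then 1-45 Hz band-pass, both zero-phase Butterworth
NOTCH_45_55 = FilterSpec("band_stop", (45.0, 55.0), order=2)
BANDPASS_1_45 = FilterSpec("band_pass", (1.0, 45.0), order=4)


@dataclass
class EpochSet:
    """Trials x channels x time (microvolts), time in ms relative to onset."""

    data: np.ndarray
    times_ms: np.ndarray
    conditions: tuple[str, ...]
    channel_names: tuple[str, ...]
    sfreq: float
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    stimulus_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        nt, nc, ns = self.data.shape
        if nt != len(self.conditions) or nc != len(self.channel_names):
            raise ValueError("epoch array shape does not match labels")
        if ns != len(self.times_ms):
            raise ValueError("epoch array shape does not match time axis")
        b0, b1 = self.baseline_ms
        if b1 > 0:
            raise ValueError("baseline window must lie in the pre-stimulus interval")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def save(self, base_path: str | Path) -> None:
        base = Path(base_path)
        np.save(base.with_suffix(".npy"), self.data)
        sidecar = {
            "times_ms": self.times_ms.tolist(),
            "conditions": list(self.conditions),
            "channel_names": list(self.channel_names),
            "sfreq": self.sfreq,
            "baseline_ms": list(self.baseline_ms),
            "stimulus_ids": list(self.stimulus_ids),
            "units": "uV",
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, base_path: str | Path) -> "EpochSet":
        base = Path(base_path)
        meta = json.loads(base.with_suffix(".json").read_text())
        return cls(
            data=np.load(base.with_suffix(".npy")),
            times_ms=np.asarray(meta["times_ms"]),
            conditions=tuple(meta["conditions"]),
            channel_names=tuple(meta["channel_names"]),
            sfreq=meta["sfreq"],
            baseline_ms=tuple(meta["baseline_ms"]),
            stimulus_ids=tuple(meta.get("stimulus_ids", ())),
        )


def _sos(spec: FilterSpec, sfreq: float) -> np.ndarray:
    nyq = sfreq / 2.0
    if spec.edges_hz[1] >= nyq:
        raise ValueError(f"filter edge {spec.edges_hz[1]} Hz >= Nyquist {nyq} Hz")
    btype = "bandstop" if spec.kind == "band_stop" else "bandpass"
    return signal.butter(spec.order, spec.edges_hz, btype=btype, fs=sfreq, output="sos")


def temporal_filter(rec: RawRecording, spec: FilterSpec) -> RawRecording:
    """Apply a Butterworth filter; zero-phase (forward-backward) by default."""
    sos = _sos(spec, rec.sfreq)
    if spec.zero_phase:
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = signal.sosfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def downsample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Anti-aliased polyphase resampling with event index rescaling."""
    if target_rate >= rec.sfreq:
        raise ValueError("target rate must be below the source rate")
    frac = Fraction(target_rate / rec.sfreq).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = float(frac)
    # nearest sample, ties round down
    events = tuple(
        replace(e, sample=int(np.ceil(e.sample * ratio - 0.5))) for e in rec.events
    )
    return replace(rec, data=data, sfreq=rec.sfreq * ratio, events=events)


def rereference_car(rec: RawRecording) -> RawRecording:
    """Common average reference: subtract the per-sample channel mean."""
    if rec.n_channels < 2:
        raise ValueError("CAR needs at least two channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def detect_bad_channels(
    rec: RawRecording,
    threshold_uv: float = 100.0,
    bandpower_z: float | None = None,
) -> list[str]:
    """Channels with any sample exceeding ``threshold_uv`` in magnitude.

    Optionally also flags channels whose broadband power is a
    ``bandpower_z``-sigma outlier across channels (z-scored log power).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    bad = set(
        np.asarray(rec.channel_names)[
            np.max(np.abs(rec.data), axis=1) > threshold_uv
        ].tolist()
    )
    if bandpower_z is not None:
        power = np.log(np.mean(rec.data**2, axis=1) + 1e-30)
        z = (power - power.mean()) / (power.std() + 1e-30)
        bad |= set(np.asarray(rec.channel_names)[np.abs(z) > bandpower_z].tolist())
    return sorted(bad, key=rec.channel_names.index)


def drop_channels(rec: RawRecording, names: list[str]) -> RawRecording:
    keep = [i for i, c in enumerate(rec.channel_names) if c not in set(names)]
    return replace(
        rec,
        data=rec.data[keep],
        channel_names=tuple(rec.channel_names[i] for i in keep),
    )


def _frontal_template(channel_names: tuple[str, ...]) -> np.ndarray:
    """Blink spatial template on the recording's channels."""
    pos = np.stack([channel_position(c) for c in channel_names])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    tmpl = np.zeros(len(channel_names))
    for anchor in ("Fp1", "Fp2"):
        a = channel_position(anchor)
        a /= np.linalg.norm(a)
        d = np.arccos(np.clip(pos @ a, -1, 1))
        tmpl += np.exp(-(d**2) / (2 * 0.45**2))
    return tmpl / np.max(tmpl)


def fastica_remove_ocular(
    rec: RawRecording,
    n_components: int | None = None,
    seed: int = 0,
    spatial_threshold: float = 0.7,
    temporal_threshold: float = 0.5,
    max_iter: int = 500,
) -> tuple[RawRecording, dict]:
    """Remove blink components identified by topography and time course.

    Deflationary fixed-point FastICA with a tanh (log-cosh) contrast after
    whitening.  A component is zeroed when its mixing column correlates
    with a frontal blink template above ``spatial_threshold`` AND its
    source correlates with the low-passed frontal mean signal above
    ``temporal_threshold``.
    """
    if rec.n_samples < 30 * rec.sfreq:
        raise ValueError("need at least 30 s of data for a stable unmixing")
    if n_components is not None and n_components > rec.n_channels:
        raise ValueError("n_components cannot exceed channel count")

    ica = FastICA(
        n_components=n_components,
        algorithm="deflation",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(rec.data.T)
        except ConvergenceWarning:
            warnings.simplefilter("ignore", ConvergenceWarning)
            ica = FastICA(
                n_components=n_components,
                algorithm="deflation",
                fun="logcosh",
                whiten="unit-variance",
                max_iter=max_iter,
                random_state=np.random.default_rng(seed).integers(2**31 - 1),
            )
            sources = ica.fit_transform(rec.data.T)
            converged = False

    template = _frontal_template(rec.channel_names)
    frontal_idx = [
        i for i, c in enumerate(rec.channel_names) if c in FRONTAL_CHANNELS
    ]
    if not frontal_idx:
        frontal_idx = list(np.argsort(-template)[:4])
    lp = signal.butter(4, 8.0, btype="lowpass", fs=rec.sfreq, output="sos")
    blink_ref = signal.sosfiltfilt(lp, rec.data[frontal_idx].mean(axis=0))

    mixing = ica.mixing_  # (channels, components)
    removed = []
    report_rows = []
    for k in range(mixing.shape[1]):
        s_corr = abs(float(np.corrcoef(mixing[:, k], template)[0, 1]))
        t_corr = abs(float(np.corrcoef(sources[:, k], blink_ref)[0, 1]))
        hit = s_corr > spatial_threshold and t_corr > temporal_threshold
        report_rows.append(
            {"component": k, "spatial_corr": s_corr, "temporal_corr": t_corr,
             "removed": hit}
        )
        if hit:
            removed.append(k)

    cleaned_sources = sources.copy()
    cleaned_sources[:, removed] = 0.0
    cleaned = ica.inverse_transform(cleaned_sources).T
    report = {
        "removed_components": removed,
        "n_components": mixing.shape[1],
        "converged": converged,
        "components": report_rows,
        "mixing": mixing,
        "sources": sources,
    }
    if not converged:
        log.warning("FastICA did not converge within %d iterations", max_iter)
    return replace(rec, data=cleaned), report


def epoch_and_baseline(
    rec: RawRecording,
    window_ms: tuple[float, float] = (-100.0, 800.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked epochs and subtract the pre-stimulus mean."""
    lo, hi = window_ms
    if baseline_ms[0] < lo or baseline_ms[1] > 0:
        raise ValueError("baseline window must lie inside the pre-stimulus interval")
    start = round(lo / 1000.0 * rec.sfreq)
    stop = round(hi / 1000.0 * rec.sfreq)
    times = (np.arange(start, stop + 1) / rec.sfreq) * 1000.0
    epochs, conds, stim_ids = [], [], []
    dropped = 0
    for ev in rec.events:
        a, b = ev.sample + start, ev.sample + stop + 1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, a:b])
        conds.append(ev.condition)
        stim_ids.append(ev.stimulus_id)
    if dropped:
        log.info("dropped %d trials with incomplete epoch windows", dropped)
    if not epochs:
        raise ValueError("no complete epochs inside the recording")
    data = np.stack(epochs)
    bmask = (times >= baseline_ms[0]) & (times <= baseline_ms[1])
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        times_ms=times,
        conditions=tuple(conds),
        channel_names=rec.channel_names,
        sfreq=rec.sfreq,
        baseline_ms=baseline_ms,
        stimulus_ids=tuple(stim_ids),
    )


@dataclass(frozen=True)
class PreprocessConfig:
    downsample_to_hz: float = 250.0
    notch: FilterSpec = NOTCH_45_55
    bandpass: FilterSpec = BANDPASS_1_45
    bad_channel_threshold_uv: float = 100.0
    bad_channel_bandpower_z: float | None = None
    run_ica: bool = False
    ica_seed: int = 0
    window_ms: tuple[float, float] = (-100.0, 800.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)


def preprocess_pipeline(
    rec: RawRecording, config: PreprocessConfig | None = None
) -> tuple[EpochSet, dict]:
    """Run the full stage chain in the canonical order."""
    cfg = config or PreprocessConfig()
    info: dict = {}
    rec = downsample(rec, cfg.downsample_to_hz)
    rec = temporal_filter(rec, cfg.notch)
    rec = temporal_filter(rec, cfg.bandpass)
    rec = rereference_car(rec)
    bad = detect_bad_channels(
        rec, cfg.bad_channel_threshold_uv, cfg.bad_channel_bandpower_z
    )
    info["bad_channels"] = bad
    if bad:
        rec = drop_channels(rec, bad)
    if cfg.run_ica:
        rec, ica_report = fastica_remove_ocular(rec, seed=cfg.ica_seed)
        info["ica"] = ica_report
    info["continuous"] = rec
    epochs = epoch_and_baseline(rec, cfg.window_ms, cfg.baseline_ms)
    info["n_trials"] = epochs.n_trials
    return epochs, info
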