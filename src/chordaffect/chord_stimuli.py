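"""Equal-temperament chord stimulus construction, synthesis and scheduling.

Builds the full stimulus inventory (7 root-position major triads, 7
six-four inversions, 2 x 7 dissonant four-note structures, and neutral
click tones), renders RMS-normalised audio, and produces randomised
presentation schedules with jittered inter-stimulus intervals.
"""

from __future__ import annotations

import csv
import wave
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Pitch",
    "ChordCategory",
    "Chord",
    "TimbreParams",
    "StimulusSpec",
    "ScheduledTrial",
    "Schedule",
    "pitch_frequency",
    "build_chord",
    "build_stimulus_set",
    "synthesize_waveform",
    "make_schedule",
    "write_wav",
    "write_manifest",
    "write_schedule_tsv",
]

# MIDI semitone indices: C3 = 48 ... B4 = 71
PITCH_RANGE = (48, 71)

_PC_NAMES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]
_DIATONIC_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


class ChordCategory(str, Enum):
    consonant_root = "consonant_root"
    consonant_64 = "consonant_64"
    dissonant_t1 = "dissonant_t1"
    dissonant_t2 = "dissonant_t2"
    neutral_click = "neutral_click"


#: Semitone offsets applied to the (octave-adjusted) root per category.
CATEGORY_OFFSETS = {
    ChordCategory.consonant_root: (0, 4, 7, 12),
    ChordCategory.consonant_64: (-5, 0, 4, 7),
    ChordCategory.dissonant_t1: (0, 6, 11, 12),
    ChordCategory.dissonant_t2: (0, 1, 6, 12),
}


@dataclass(frozen=True, order=True)
class Pitch:
    """A single equal-temperament pitch, MIDI convention (C4 = 60)."""

    semitone_index: int

    @property
    def name(self) -> str:
        octave = self.semitone_index // 12 - 1
        return f"{_PC_NAMES[self.semitone_index % 12]}{octave}"

    @property
    def pitch_class(self) -> str:
        return _PC_NAMES[self.semitone_index % 12]

    @property
    def frequency(self) -> float:
        return pitch_frequency(self)


def pitch_frequency(p: Pitch | int) -> float:
    """Frequency in Hz of a pitch under 12-TET with A4 (index 69) = 440 Hz."""
    index = p.semitone_index if isinstance(p, Pitch) else int(p)
    return 440.0 * 2.0 ** ((index - 69) / 12.0)


@dataclass(frozen=True)
class Chord:
    root: Pitch
    category: ChordCategory
    pitches: tuple[Pitch, ...]
    label: str

    def __post_init__(self) -> None:
        idx = [p.semitone_index for p in self.pitches]
        if self.category is ChordCategory.neutral_click:
            if len(self.pitches) != 1:
                raise ValueError("neutral click must contain exactly one pitch")
        else:
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"chord pitches must be strictly ascending: {idx}")
        lo, hi = PITCH_RANGE
        if any(i < lo or i > hi for i in idx):
            raise ValueError(f"pitch indices {idx} outside allowed range {PITCH_RANGE}")


def _root_index(root_name: str, category: ChordCategory) -> int:
    """Semitone index of the chord root, registered so every note fits C3-B4."""
    pc = _DIATONIC_PC[root_name]
    offsets = CATEGORY_OFFSETS[category]
    lo, hi = PITCH_RANGE
    for octave_base in (60, 48) if category is ChordCategory.consonant_64 else (48, 60):
        root = octave_base + pc
        notes = [root + o for o in offsets]
        if min(notes) >= lo and max(notes) <= hi:
            return root
    raise ValueError(f"no register keeps {root_name}/{category.value} inside C3-B4")


def build_chord(root_name: str, category: ChordCategory | str) -> Chord:
    """Build a four-note chord from a diatonic root letter and a category.

    Roots live on the natural diatonic scale (C D E F G A B); the fixed
    semitone-offset pattern of the category is stacked on the root, with
    the register chosen so that every note lies in C3-B4.
    """
    category = ChordCategory(category)
    if category is ChordCategory.neutral_click:
        raise ValueError("build_chord does not produce neutral clicks; use a Pitch")
    if root_name not in _DIATONIC_PC:
        raise ValueError(f"unknown diatonic root {root_name!r}")
    root = _root_index(root_name, category)
    pitches = tuple(Pitch(root + o) for o in CATEGORY_OFFSETS[category])
    label = "–".join(p.pitch_class for p in pitches)
    return Chord(root=Pitch(root), category=category, pitches=pitches, label=label)


@dataclass(frozen=True)
class TimbreParams:
    """Additive damped-harmonic piano-like synthesiser settings."""

    n_harmonics: int = 8
    t60_s: float = 1.0              # time for the fundamental to decay 60 dB
    brightness: float = 1.2         # harmonic amplitude rolloff exponent
    harmonic_damping: float = 0.25  # extra decay rate per harmonic number
    attack_ms: float = 5.0


@dataclass(frozen=True)
class StimulusSpec:
    stimulus_id: str
    chord: Chord
    duration_ms: float = 800.0
    timbre: TimbreParams = field(default_factory=TimbreParams)
    rms_target: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


def build_stimulus_set(
    n_neutral: int = 14,
    click_duration_ms: float = 100.0,
    timbre: TimbreParams | None = None,
) -> list[StimulusSpec]:
    """The full inventory: 7+7 consonant, 7+7 dissonant chords, plus clicks.

    Neutral clicks default to the 14 diatonic tones of the C3-B4 double
    octave; for ``n_neutral < 14`` an evenly spaced subset is used.
    """
    if n_neutral < 1:
        raise ValueError("n_neutral must be >= 1")
    if n_neutral > 14:
        raise ValueError("at most 14 distinct diatonic click pitches are available")
    timbre = timbre or TimbreParams()
    specs: list[StimulusSpec] = []
    for cat in (
        ChordCategory.consonant_root,
        ChordCategory.consonant_64,
        ChordCategory.dissonant_t1,
        ChordCategory.dissonant_t2,
    ):
        for i, root in enumerate("CDEFGAB"):
            chord = build_chord(root, cat)
            specs.append(
                StimulusSpec(
                    stimulus_id=f"{cat.value}_{i:02d}_{root}",
                    chord=chord,
                    duration_ms=800.0,
                    timbre=timbre,
                )
            )
    diatonic = sorted(
        48 + 12 * octave + pc for octave in (0, 1) for pc in _DIATONIC_PC.values()
    )
    pick = np.linspace(0, len(diatonic) - 1, n_neutral).round().astype(int)
    for k, j in enumerate(pick):
        p = Pitch(diatonic[j])
        chord = Chord(
            root=p, category=ChordCategory.neutral_click, pitches=(p,),
            label=p.pitch_class,
        )
        specs.append(
            StimulusSpec(
                stimulus_id=f"neutral_click_{k:02d}_{p.name}",
                chord=chord,
                duration_ms=click_duration_ms,
                timbre=timbre,
            )
        )
    return specs


def synthesize_waveform(spec: StimulusSpec, sample_rate: float = 44100.0) -> np.ndarray:
    """Render a mono float waveform for one stimulus, RMS-normalised.

    Chords are additive damped-harmonic tones (one per pitch); clicks are
    a single short damped sinusoid at the click pitch.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    if not spec.chord.pitches:
        raise ValueError("cannot synthesise an empty chord")
    n = round(sample_rate * spec.duration_ms / 1000.0)
    t = np.arange(n) / sample_rate
    tp = spec.timbre
    out = np.zeros(n)
    is_click = spec.chord.category is ChordCategory.neutral_click
    base_decay = np.log(1000.0) / tp.t60_s
    for p in spec.chord.pitches:
        f0 = pitch_frequency(p)
        if is_click:
            # single partial, fast decay -> spectral peak exactly at f0
            out += np.sin(2 * np.pi * f0 * t) * np.exp(-t / 0.02)
            continue
        for h in range(1, tp.n_harmonics + 1):
            fh = h * f0
            if fh >= sample_rate / 2:
                break
            amp = h ** (-tp.brightness)
            decay = base_decay * (1.0 + tp.harmonic_damping * (h - 1))
            out += amp * np.sin(2 * np.pi * fh * t) * np.exp(-decay * t)
    attack = 1.0 - np.exp(-t / (tp.attack_ms / 1000.0))
    out *= attack
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= spec.rms_target / rms
    return out


@dataclass(frozen=True)
class ScheduledTrial:
    trial: int
    stimulus_id: str
    category: ChordCategory
    onset_s: float
    isi_ms: float


@dataclass(frozen=True)
class Schedule:
    trials: tuple[ScheduledTrial, ...]
    repetitions: int
    seed: int

    def __len__(self) -> int:
        return len(self.trials)


def make_schedule(
    stimuli: list[StimulusSpec],
    repetitions: int = 5,
    seed: int = 0,
    isi_range_ms: tuple[float, float] = (200.0, 300.0),
    lead_in_s: float = 1.0,
) -> Schedule:
    """Seeded random presentation order with uniform ISI jitter.

    Each stimulus appears exactly ``repetitions`` times; consecutive
    onsets are separated by the previous stimulus duration plus an ISI
    drawn uniformly from ``isi_range_ms``.
    """
    if not stimuli:
        raise ValueError("stimulus list is empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(len(stimuli)), repetitions))
    isis = rng.uniform(*isi_range_ms, size=len(order))
    trials = []
    onset = lead_in_s
    for k, (j, isi) in enumerate(zip(order, isis)):
        spec = stimuli[j]
        trials.append(
            ScheduledTrial(
                trial=k,
                stimulus_id=spec.stimulus_id,
                category=spec.chord.category,
                onset_s=onset,
                isi_ms=float(isi),
            )
        )
        onset += spec.duration_ms / 1000.0 + isi / 1000.0
    return Schedule(trials=tuple(trials), repetitions=repetitions, seed=seed)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: float) -> None:
    """Write mono float samples as 16-bit PCM WAV."""
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    scale = 0.99 / peak if peak > 1.0 else 1.0
    pcm = np.clip(samples * scale * 32767.0, -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(int(sample_rate))
        w.writeframes(pcm.tobytes())


def write_manifest(path: str | Path, stimuli: list[StimulusSpec]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["stimulus_id", "category", "label", "pitches", "duration_ms"])
        for s in stimuli:
            w.writerow(
                [
                    s.stimulus_id,
                    s.chord.category.value,
                    s.chord.label,
                    ",".join(str(p.semitone_index) for p in s.chord.pitches),
                    f"{s.duration_ms:g}",
                ]
            )


def write_schedule_tsv(path: str | Path, schedule: Schedule) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["trial", "stimulus_id", "category", "onset_s", "isi_ms"])
        for tr in schedule.trials:
            w.writerow(
                [tr.trial, tr.stimulus_id, tr.category.value,
                 f"{tr.onset_s:.6f}", f"{tr.isi_ms:.3f}"]
            )
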