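"""Synthetic annotated ECG records and beat datasets.

The generator emulates single-lead 360 Hz recordings in which each beat
belongs to one of the five AAMI classes (N, S, V, F, Q).  Beat morphology is
built from parameterized Gaussian deflections standing in for the P wave,
the QRS complex (a positive R deflection flanked by negative Q and S dips)
and the T wave:

* **N** — full P-QRS-T morphology with a narrow, tall R wave;
* **S** — supraventricular ectopy: the P wave is absent, the QRS stays
  narrow;
* **V** — ventricular ectopy: no P wave, a broad high-amplitude QRS and a
  discordant (inverted) T wave;
* **F** — fusion: intermediate QRS width and reduced amplitude with a
  small P wave;
* **Q** — unclassifiable/paced: a narrow pacing-stimulus spike riding on a
  broad, low-amplitude complex, with little discernible P or T activity
  (paced beats dominate this class in ambulatory databases).

Records are corrupted with additive white Gaussian noise and a sinusoidal
baseline wander, the two dominant artifact families in ambulatory ECG.  The
default class mixture reproduces the severe imbalance of the MIT-BIH
database (about two thirds normal beats).

Everything is driven by a single integer seed: identical specs produce
bit-identical datasets and records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .io import AAMI_CLASSES, BeatDataset, ECGRecord

FS = 360.0  # Hz, the MIT-BIH sampling rate

#: Default class mixture: MIT-BIH per-class beat totals (N, S, V, F, Q)
#: 27872 / 2441 / 6840 / 787 / 3856 out of 41796, as fractions.
DEFAULT_PROPORTIONS = (
    27872 / 41796, 2441 / 41796, 6840 / 41796, 787 / 41796, 3856 / 41796,
)

#: Default beat window: 280 samples with the R peak at index 99
#: (~0.275 s before, ~0.5 s after the R peak at 360 Hz).
DEFAULT_SEGMENT_LEN = 280
DEFAULT_R_OFFSET = 99


@dataclass(frozen=True)
class BeatTemplate:
    """Noise-free waveform archetype for one AAMI class.

    ``waveform`` holds amplitudes in mV over a fixed duration at 360 Hz;
    ``r_offset`` is the sample index of the R peak inside it.
    """

    class_label: str
    waveform: np.ndarray
    r_offset: int

    def __post_init__(self) -> None:
        if self.class_label not in AAMI_CLASSES:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        wf = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(wf)):
            raise ValidationError("template waveform must be finite")
        if not (0 <= self.r_offset < wf.size):
            raise ValidationError("r_offset must lie inside the waveform")
        object.__setattr__(self, "waveform", wf)


# Per-class morphology parameters.  Each deflection is (center offset
# relative to the R peak in seconds, width in seconds, amplitude in mV).
# QRS is modelled as Q/R/S sub-deflections scaled together.
_MORPHOLOGY = {
    # label: (p_amp, qrs_width_scale, qrs_amp, t_amp, t_center_s, extras)
    "N": dict(p_amp=0.15, qrs_w=1.0, r_amp=1.00, t_amp=0.30, t_c=0.28),
    "S": dict(p_amp=0.00, qrs_w=1.0, r_amp=0.90, t_amp=0.40, t_c=0.24),
    "V": dict(p_amp=0.00, qrs_w=3.0, r_amp=1.30, t_amp=-0.45, t_c=0.34),
    "F": dict(p_amp=0.08, qrs_w=2.0, r_amp=0.65, t_amp=0.18, t_c=0.30),
    "Q": dict(p_amp=0.00, qrs_w=4.0, r_amp=0.45, t_amp=0.05, t_c=0.32,
              spike_amp=0.70),
}


def _gauss(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def make_template(
    class_label: str,
    length: int = DEFAULT_SEGMENT_LEN,
    r_offset: int = DEFAULT_R_OFFSET,
    fs: float = FS,
) -> BeatTemplate:
    """Build the Gaussian-bump beat archetype for one AAMI class."""
    if class_label not in _MORPHOLOGY:
        raise ValidationError(f"unknown class label {class_label!r}")
    if not (0 <= r_offset < length):
        raise ValidationError("r_offset must lie inside the beat window")
    m = _MORPHOLOGY[class_label]
    t = (np.arange(length) - r_offset) / fs  # seconds relative to the R peak

    w = m["qrs_w"]
    wave = np.zeros(length)
    # QRS complex: R deflection with Q and S dips; widths scale together.
    wave += _gauss(t, 0.0, 0.012 * w, m["r_amp"])
    wave += _gauss(t, -0.022 * w, 0.008 * w, -0.12 * m["r_amp"])
    wave += _gauss(t, 0.024 * w, 0.009 * w, -0.18 * m["r_amp"])
    # Pacing-stimulus spike (paced morphologies only): very narrow, sharp.
    if m.get("spike_amp"):
        wave += _gauss(t, 0.0, 0.004, m["spike_amp"])
    # P wave (absent for ectopic/unclassifiable morphologies).
    wave += _gauss(t, -0.17, 0.022, m["p_amp"])
    # T wave.
    wave += _gauss(t, m["t_c"], 0.055, m["t_amp"])
    return BeatTemplate(class_label=class_label, waveform=wave, r_offset=r_offset)


def default_templates(
    length: int = DEFAULT_SEGMENT_LEN, r_offset: int = DEFAULT_R_OFFSET
) -> dict[str, BeatTemplate]:
    return {c: make_template(c, length, r_offset) for c in AAMI_CLASSES}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic generation run.

    ``class_proportions`` are the five class fractions (N, S, V, F, Q) and
    must sum to 1; ``noise_sd`` is the SD of additive white noise in mV;
    ``baseline_amp``/``baseline_freq`` parameterize a sinusoidal baseline
    wander (mV, Hz).
    """

    n_beats: int
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    noise_sd: float = 0.05
    baseline_amp: float = 0.05
    baseline_freq: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        props = tuple(float(p) for p in self.class_proportions)
        object.__setattr__(self, "class_proportions", props)
        if len(props) != 5:
            raise ValidationError(
                f"class_proportions needs 5 entries, got {len(props)}"
            )
        if any(p < 0 for p in props):
            raise ValidationError("class_proportions must be nonnegative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValidationError(
                f"class_proportions must sum to 1, got {sum(props)!r}"
            )
        if self.n_beats < 5:
            raise ValidationError(f"n_beats must be >= 5, got {self.n_beats}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.baseline_amp < 0:
            raise ValidationError("baseline_amp must be >= 0")


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """IID categorical labels; per-class counts are a multinomial draw."""
    return rng.choice(5, size=spec.n_beats, p=np.asarray(spec.class_proportions))


def generate_beat_dataset(
    spec: SyntheticSpec, segment_len: int = DEFAULT_SEGMENT_LEN
) -> BeatDataset:
    """Generate ``spec.n_beats`` labeled beat segments of ``segment_len`` samples.

    Each segment is its class template plus white noise of SD
    ``spec.noise_sd`` and a baseline-wander arc with a random phase.  The
    R peak sits at index ``min(DEFAULT_R_OFFSET, segment_len // 3)``.
    """
    if segment_len < 32:
        raise ValidationError(f"segment_len must be >= 32, got {segment_len}")
    rng = np.random.default_rng(spec.seed)
    r_offset = min(DEFAULT_R_OFFSET, segment_len // 3)
    templates = default_templates(segment_len, r_offset)
    labels = _draw_labels(spec, rng)

    t = np.arange(segment_len) / FS
    segments = np.empty((spec.n_beats, segment_len))
    for i, lab in enumerate(labels):
        seg = templates[AAMI_CLASSES[lab]].waveform.copy()
        if spec.baseline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            seg += spec.baseline_amp * np.sin(
                2 * np.pi * spec.baseline_freq * t + phase
            )
        if spec.noise_sd > 0:
            seg += rng.normal(0.0, spec.noise_sd, size=segment_len)
        segments[i] = seg
    return BeatDataset(segments, labels)


def generate_record(
    spec: SyntheticSpec, heart_rate_bpm: float = 72.0
) -> tuple[ECGRecord, ECGRecord]:
    """Generate a continuous annotated 360 Hz record of concatenated beats.

    Returns ``(record, clean)`` where ``clean`` is the same record without
    noise or baseline wander (identical annotations); the clean copy serves
    as ground truth for denoising and detection experiments.
    """
    if not (30.0 <= heart_rate_bpm <= 220.0):
        raise ValidationError(
            f"heart_rate_bpm must be in [30, 220], got {heart_rate_bpm}"
        )
    rng = np.random.default_rng(spec.seed)
    period = int(round(60.0 / heart_rate_bpm * FS))  # samples per beat
    r_offset = min(DEFAULT_R_OFFSET, period // 3)
    templates = default_templates(period, r_offset)
    labels = _draw_labels(spec, rng)

    clean = np.concatenate(
        [templates[AAMI_CLASSES[lab]].waveform for lab in labels]
    )
    annotations = [
        (i * period + r_offset, AAMI_CLASSES[lab]) for i, lab in enumerate(labels)
    ]

    signal = clean.copy()
    n = signal.size
    if spec.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + spec.baseline_amp * np.sin(
            2 * np.pi * spec.baseline_freq * np.arange(n) / FS + phase
        )
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n)

    return (
        ECGRecord(signal=signal, fs=FS, annotations=annotations),
        ECGRecord(signal=clean, fs=FS, annotations=list(annotations)),
    )
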