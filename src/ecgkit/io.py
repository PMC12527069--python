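"""Reading and writing annotated ECG records and beat datasets.

Containers
----------
:class:`ECGRecord`
    A continuous single-channel signal in millivolts at a known sampling
    rate, plus per-beat annotations ``(sample_index, symbol)``.
:class:`BeatDataset`
    A matrix of fixed-length heartbeat segments with integer labels for the
    five AAMI classes (0=N, 1=S, 2=V, 3=F, 4=Q).

File formats
------------
Records are stored in a WFDB-compatible layout: a plain-text ``.hea``
header, a format-16 (little-endian int16) ``.dat`` signal file, and a
``.atr`` annotation file using the MIT annotation word coding (including
SKIP escapes for inter-annotation gaps of 1024 samples or more).  The
reader/writer here cover exactly that subset of the WFDB specification.

Beat datasets travel either as delimited text (one row per beat, the last
column the integer label) or as a compressed NumPy ``.npz`` archive.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical AAMI class order; integer labels index into this tuple.
AAMI_CLASSES = ("N", "S", "V", "F", "Q")

#: Sentinel returned by :func:`map_to_aami` for non-beat annotations.
EXCLUDED = "excluded"

# Consolidation of MIT-BIH beat annotation symbols into the five AAMI
# classes.  Symbols absent from this table (rhythm changes '+', noise '~',
# artifacts '|', comments, episode markers, ...) are not beats and are
# excluded.
_AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

# Standard WFDB annotation type codes for the symbols this package emits.
_SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16,
    "+": 28, "e": 34, "f": 38,
}
_CODE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_CODE.items()}

_SKIP = 59          # annotation escape: 32-bit interval follows
_DEFAULT_GAIN = 200.0   # adu per mV, the MIT-BIH convention


def map_to_aami(symbol: str) -> str:
    """Consolidate a beat annotation symbol into its AAMI class.

    Returns one of ``"N" "S" "V" "F" "Q"`` for beat symbols and the
    sentinel :data:`EXCLUDED` for every non-beat annotation.  The mapping
    is total: unknown symbols are excluded with a log message rather than
    raising.
    """
    cls = _AAMI_MAP.get(symbol)
    if cls is None:
        logger.debug("annotation symbol %r is not a beat; excluded", symbol)
        return EXCLUDED
    return cls


def aami_label(symbol: str) -> int | None:
    """Integer label (0-4) for a beat symbol, or None if excluded."""
    cls = map_to_aami(symbol)
    return None if cls == EXCLUDED else AAMI_CLASSES.index(cls)


@dataclass
class ECGRecord:
    """A continuous annotated ECG signal.

    Parameters
    ----------
    signal : ndarray
        Amplitudes in millivolts.
    fs : float
        Sampling rate in Hz (MIT-BIH records use 360).
    annotations : list of (int, str)
        ``(sample_index, symbol)`` pairs at R-peak locations, strictly
        increasing in index.
    """

    signal: np.ndarray
    fs: float = 360.0
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        idx = np.array([i for i, _ in self.annotations], dtype=int)
        if idx.size:
            if np.any(np.diff(idx) <= 0):
                raise ValidationError("annotation indices must be strictly increasing")
            if idx[0] < 0 or idx[-1] >= self.signal.size:
                raise ValidationError("annotation index outside signal bounds")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs

    def annotation_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.annotations], dtype=int)


@dataclass
class BeatDataset:
    """Fixed-length labeled heartbeat segments.

    ``segments`` has one row per beat; ``labels`` holds the integer AAMI
    class of each row (0=N, 1=S, 2=V, 3=F, 4=Q).
    """

    segments: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.segments.shape[0] != self.labels.size:
            raise ValidationError(
                f"{self.segments.shape[0]} segments but {self.labels.size} labels"
            )
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 4):
            raise ValidationError("labels must lie in 0..4")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_beats(self) -> int:
        return self.labels.size

    @property
    def segment_len(self) -> int:
        return self.segments.shape[1]

    @property
    def class_counts(self) -> np.ndarray:
        """Per-class beat counts in AAMI order (length 5)."""
        return np.bincount(self.labels, minlength=5)[:5]

    def subset(self, idx) -> "BeatDataset":
        idx = np.asarray(idx)
        return BeatDataset(self.segments[idx], self.labels[idx])

    # ---- containers -----------------------------------------------------

    def to_csv(self, path) -> None:
        """Delimited text: one row per beat, last column the integer label."""
        mat = np.column_stack([self.segments, self.labels.astype(float)])
        np.savetxt(path, mat, delimiter=",", fmt="%.9g")

    @classmethod
    def from_csv(cls, path) -> "BeatDataset":
        try:
            mat = np.atleast_2d(np.loadtxt(path, delimiter=","))
        except OSError as exc:
            raise FormatError(f"cannot read beat dataset {path!s}: {exc}") from exc
        if mat.shape[1] < 2:
            raise FormatError(f"{path!s}: need at least one sample column plus a label")
        return cls(mat[:, :-1], np.rint(mat[:, -1]).astype(int))

    def to_npz(self, path) -> None:
        np.savez_compressed(path, segments=self.segments, labels=self.labels)

    @classmethod
    def from_npz(cls, path) -> "BeatDataset":
        with np.load(path) as z:
            return cls(z["segments"], z["labels"])

    @classmethod
    def load(cls, path) -> "BeatDataset":
        """Dispatch on extension: ``.npz`` binary, anything else delimited text."""
        path = Path(path)
        if path.suffix == ".npz":
            return cls.from_npz(path)
        return cls.from_csv(path)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".npz":
            self.to_npz(path)
        else:
            self.to_csv(path)


def concat_datasets(parts: list[BeatDataset]) -> BeatDataset:
    parts = [p for p in parts if len(p)]
    if not parts:
        raise ValidationError("no beats to concatenate")
    return BeatDataset(
        np.vstack([p.segments for p in parts]),
        np.concatenate([p.labels for p in parts]),
    )


# ---------------------------------------------------------------------------
# WFDB-subset record I/O
# ---------------------------------------------------------------------------

def write_record(rec: ECGRecord, path_prefix, gain: float = _DEFAULT_GAIN) -> None:
    """Write ``<prefix>.hea``, ``<prefix>.dat`` (format 16) and ``<prefix>.atr``.

    The signal is digitized as ``round(signal * gain)`` int16 with baseline
    0, the MIT-BIH amplitude convention at ``gain=200`` adu/mV.
    """
    prefix = Path(path_prefix)
    name = prefix.name
    digital = np.clip(np.rint(rec.signal * gain), -32768, 32767).astype("<i2")

    fs_txt = f"{rec.fs:g}"
    header = (
        f"{name} 1 {fs_txt} {digital.size}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 11 0 {int(digital[0]) if digital.size else 0} 0 0 ECG\n"
    )
    prefix.with_suffix(".hea").write_text(header)
    prefix.with_suffix(".dat").write_bytes(digital.tobytes())
    _write_annotations(rec.annotations, prefix.with_suffix(".atr"))


def _write_annotations(annotations, path: Path) -> None:
    out = bytearray()
    prev = 0
    for idx, symbol in annotations:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            logger.warning("symbol %r has no annotation code; written as Q", symbol)
            code = _SYMBOL_TO_CODE["Q"]
        dt = idx - prev
        if dt >= 1024 or dt < 0:
            # SKIP escape: interval 0 word, then the 32-bit interval,
            # most-significant 16-bit word first.
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (code << 10) | dt)
        prev = idx
    out += struct.pack("<H", 0)  # end of annotations
    path.write_bytes(bytes(out))


def _read_annotations(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    words = np.frombuffer(raw, dtype="<u2")
    ann: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending = 0
    while i < words.size:
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 2 >= words.size:
                raise FormatError(f"{path!s}: truncated SKIP escape")
            pending = (int(words[i + 1]) << 16) | int(words[i + 2])
            if pending & 0x80000000:
                pending -= 1 << 32
            i += 3
            continue
        if code in (60, 61, 62):   # NUM / SUB / CHN modifiers: ignored
            i += 1
            continue
        if code == 63:             # AUX: interval counts payload bytes
            i += 1 + (interval + 1) // 2
            continue
        t += interval + pending
        pending = 0
        ann.append((t, _CODE_TO_SYMBOL.get(code, "Q")))
        i += 1
    return ann


def read_record(path_prefix, channel: int = 0) -> ECGRecord:
    """Read a WFDB-subset record written by :func:`write_record`.

    Multi-channel format-16 files are supported (samples interleaved);
    ``channel`` selects the lead, defaulting to the first (MLII in most
    MIT-BIH records).
    """
    prefix = Path(path_prefix)
    hea = prefix.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea!s}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
        n_samp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{hea!s}: malformed record line {lines[0]!r}") from exc
    if not (0 <= channel < n_sig):
        raise ValidationError(f"channel {channel} out of range for {n_sig} signals")
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea!s}: header declares {n_sig} signals "
                          f"but lists {len(lines) - 1}")

    sig_line = lines[1 + channel].split()
    dat_name, fmt = sig_line[0], sig_line[1]
    if fmt.split("x")[0] != "16":
        raise FormatError(f"{hea!s}: unsupported signal format {fmt!r} (only 16)")
    gain, baseline = _DEFAULT_GAIN, 0.0
    if len(sig_line) > 2:
        gtok = sig_line[2].split("/")[0]
        if "(" in gtok:
            gtok, btok = gtok.split("(")
            baseline = float(btok.rstrip(")"))
        gain = float(gtok) or _DEFAULT_GAIN

    dat = prefix.parent / dat_name
    if not dat.exists():
        raise FormatError(f"missing signal file {dat!s}")
    digital = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if digital.size % n_sig:
        raise FormatError(f"{dat!s}: size not a multiple of {n_sig} channels")
    if n_samp and digital.size // n_sig != n_samp:
        raise FormatError(
            f"{dat!s}: header declares {n_samp} samples/channel, file holds "
            f"{digital.size // n_sig}"
        )
    signal = (digital.reshape(-1, n_sig)[:, channel].astype(float) - baseline) / gain

    atr = prefix.with_suffix(".atr")
    annotations = _read_annotations(atr) if atr.exists() else []
    return ECGRecord(signal=signal, fs=fs, annotations=annotations)


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def stratified_split(
    ds: BeatDataset, train_fraction: float, seed: int
) -> tuple[BeatDataset, BeatDataset]:
    """Partition a dataset into train/test with proportional class representation.

    Per class ``c`` with ``n_c`` members the training set receives
    ``floor(n_c * train_fraction)`` beats; remaining training slots (to
    reach ``round(N * train_fraction)`` in total) go to the classes with the
    largest fractional remainders, ties broken by lower class index.
    Membership within a class is a seeded uniform draw, so the same seed
    reproduces the same split and different seeds share per-class counts.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(ds) == 0:
        raise ValidationError("cannot split an empty dataset")

    counts = ds.class_counts
    total_train = int(np.floor(len(ds) * train_fraction + 0.5))
    base = np.floor(counts * train_fraction).astype(int)
    remainders = counts * train_fraction - base
    short = total_train - int(base.sum())
    # Largest fractional remainder first; ties by lower class index.
    order = sorted(range(5), key=lambda c: (-remainders[c], c))
    take = base.copy()
    for c in order:
        if short <= 0:
            break
        if take[c] < counts[c]:
            take[c] += 1
            short -= 1

    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in range(5):
        members = np.flatnonzero(ds.labels == c)
        perm = rng.permutation(members.size)
        train_idx.append(members[perm[: take[c]]])
        test_idx.append(members[perm[take[c]:]])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return ds.subset(tr), ds.subset(te)
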