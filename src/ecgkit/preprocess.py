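"""Beat-level preprocessing: R-peak detection, segmentation, normalization,
majority-class subsampling, non-finite cleanup, and wavelet denoising.

The canonical pipeline order is

    raw record -> R peaks -> segment -> z-score -> subsample N -> clean
    -> DWT denoise

and :func:`run_pipeline` composes it.  Denoising uses a multi-level
discrete wavelet transform (Symlet-5, three levels by default) with the
universal hard threshold of Donoho & Johnstone: the noise scale is
estimated from the finest detail band as sigma = median(|cd|)/0.6745 and
the threshold is lambda = sigma * sqrt(2 ln n) with n the segment length.
Detail coefficients with |c| <= lambda are zeroed at every level;
approximation coefficients pass through untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal as sps

from ._exceptions import ConfigurationError, ValidationError
from .io import BeatDataset, ECGRecord, aami_label

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationConfig:
    """Fixed beat window around each R peak.

    The segment is ``pre_samples`` before the peak, the peak itself, and
    ``post_samples`` after, so the segment length is
    ``pre_samples + post_samples + 1`` and the R peak lands at index
    ``pre_samples``.  Defaults give the package's standard 280-sample
    window with the peak at index 99.
    """

    pre_samples: int = 99
    post_samples: int = 180
    use_annotations: bool = True

    def __post_init__(self) -> None:
        if self.pre_samples < 1 or self.post_samples < 1:
            raise ValidationError("pre_samples and post_samples must be >= 1")

    @property
    def segment_len(self) -> int:
        return self.pre_samples + self.post_samples + 1


@dataclass(frozen=True)
class DenoiseParams:
    """Wavelet denoising parameters.

    ``sigma`` and ``lam`` may be pre-populated (e.g. by
    :func:`estimate_denoise_params`); when ``lam`` is None it is derived
    per segment from the finest detail band via the universal threshold.
    """

    wavelet_name: str = "sym5"
    levels: int = 3
    sigma: float | None = None
    lam: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValidationError(f"levels must be >= 1, got {self.levels}")
        if self.sigma is not None and self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.lam is not None and self.lam < 0:
            raise ValidationError("lam must be >= 0")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def _refine_to_local_max(x: np.ndarray, idx: int, radius: int) -> int:
    lo = max(0, idx - radius)
    hi = min(x.size, idx + radius + 1)
    return lo + int(np.argmax(x[lo:hi]))

def detect_r_peaks(
    rec: ECGRecord, use_annotations: bool = True, refine_s: float = 0.05
) -> np.ndarray:
    """Locate R peaks, returning strictly increasing sample indices.

    With ``use_annotations`` and annotations present, each annotated index
    is refined to the local signal maximum within ``+-refine_s`` seconds.
    Otherwise a Pan-Tompkins-style detector runs: band-pass 5-15 Hz ->
    derivative -> squaring -> moving-window integration -> adaptive
    threshold, with a 0.2 s refractory period between accepted peaks.
    """
    x = np.asarray(rec.signal, dtype=float)
    fs = rec.fs
    if x.size < 2 * fs:
        raise ValidationError(
            f"signal too short for peak detection ({x.size} samples < 2 s)"
        )
    radius = max(1, int(round(refine_s * fs)))

    if use_annotations and rec.annotations:
        peaks = [_refine_to_local_max(x, i, radius) for i in rec.annotation_indices()]
        out = []
        for p in peaks:            # enforce strict increase after refinement
            if not out or p > out[-1]:
                out.append(p)
        return np.array(out, dtype=int)

    # Pan-Tompkins-style pipeline on the raw lead.
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    deriv = np.gradient(filtered)
    squared = deriv ** 2
    win = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # Two-level adaptive thresholding with searchback: running signal and
    # noise peak levels set THR1; when the gap since the last accepted beat
    # exceeds 1.66x the running RR average, the interval is re-searched at
    # the lower THR2.
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.median(mwi))
    if spki <= npki:               # no beats in the lead-in (e.g. flat signal)
        spki = npki * 4.0 + 1e-12
    accepted: list[int] = []
    rr: list[int] = []
    rejected: list[int] = []

    def thr1() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        c = int(c)
        if mwi[c] > thr1():
            if accepted and rr:
                rr_avg = float(np.mean(rr[-8:]))
                if c - accepted[-1] > 1.66 * rr_avg and rejected:
                    # searchback: tallest rejected candidate above THR2
                    gap = [g for g in rejected if accepted[-1] < g < c]
                    gap = [g for g in gap if mwi[g] > 0.25 * thr1()]
                    if gap:
                        sb = max(gap, key=lambda g: mwi[g])
                        spki = 0.25 * float(mwi[sb]) + 0.75 * spki
                        rr.append(sb - accepted[-1])
                        accepted.append(sb)
            if accepted:
                rr.append(c - accepted[-1])
            accepted.append(c)
            spki = 0.125 * float(mwi[c]) + 0.875 * spki
        else:
            rejected.append(c)
            npki = 0.125 * float(mwi[c]) + 0.875 * npki

    peaks: list[int] = []
    for c in accepted:
        p = _refine_to_local_max(x, c, radius)
        if not peaks or p - peaks[-1] >= refractory:
            peaks.append(p)
        elif x[p] > x[peaks[-1]]:  # keep the taller of two conflicting peaks
            peaks[-1] = p
    return np.array(peaks, dtype=int)


# ---------------------------------------------------------------------------
# Segmentation and per-segment transforms
# ---------------------------------------------------------------------------

def segment_beats(
    rec: ECGRecord, peaks: np.ndarray, cfg: SegmentationConfig
) -> BeatDataset:
    """Cut one fixed-length window per peak; label from nearby annotations.

    Peaks whose window would overrun the signal are dropped (and counted in
    a log message).  A peak's label is taken from the closest annotation
    within half a window, mapped to its AAMI class; peaks without a beat
    annotation in range default to class N.
    """
    peaks = np.asarray(peaks, dtype=int)
    ann_idx = rec.annotation_indices()
    ann_lab = [aami_label(sym) for _, sym in rec.annotations]

    segs, labels, dropped = [], [], 0
    for p in peaks:
        lo, hi = p - cfg.pre_samples, p + cfg.post_samples + 1
        if lo < 0 or hi > rec.signal.size:
            dropped += 1
            continue
        lab = 0
        if ann_idx.size:
            j = int(np.argmin(np.abs(ann_idx - p)))
            if abs(int(ann_idx[j]) - int(p)) <= cfg.segment_len // 2:
                lab = ann_lab[j] if ann_lab[j] is not None else None
        if lab is None:            # closest annotation is a non-beat marker
            dropped += 1
            continue
        segs.append(rec.signal[lo:hi])
        labels.append(lab)
    if dropped:
        logger.info("segment_beats: dropped %d boundary/unlabeled peaks", dropped)
    if not segs:
        return BeatDataset(np.empty((0, cfg.segment_len)), np.empty(0, dtype=int))
    return BeatDataset(np.vstack(segs), np.array(labels))


def zscore(segment: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to population SD 1; constant input -> zeros."""
    seg = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(seg)):
        raise ValidationError("zscore requires a finite segment")
    sd = seg.std()
    if sd == 0.0:
        return np.zeros_like(seg)
    return (seg - seg.mean()) / sd


def zscore_dataset(ds: BeatDataset) -> BeatDataset:
    mu = ds.segments.mean(axis=1, keepdims=True)
    sd = ds.segments.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (ds.segments - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return BeatDataset(out, ds.labels)


def subsample_majority(
    ds: BeatDataset, keep_prob: float = 0.15, target_class: int = 0, seed: int = 0
) -> BeatDataset:
    """Thin the majority class by independent Bernoulli(keep_prob) draws.

    Every beat outside ``target_class`` is retained; each target-class beat
    survives with probability ``keep_prob``.  Survivor order is preserved.
    The default 0.15 retention for normal beats counteracts the roughly
    2:1-to-35:1 imbalance of the N class against the others.
    """
    if not (0.0 <= keep_prob <= 1.0):
        raise ValidationError(f"keep_prob must be in [0, 1], got {keep_prob}")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(ds))
    keep = (ds.labels != target_class) | (draws < keep_prob)
    removed = int(np.sum(~keep))
    if removed:
        logger.info("subsample_majority: removed %d class-%d beats", removed,
                    target_class)
    return ds.subset(np.flatnonzero(keep))


def clean_nonfinite(ds: BeatDataset) -> BeatDataset:
    """Drop segments containing NaN or infinite samples."""
    finite = np.all(np.isfinite(ds.segments), axis=1)
    removed = int(np.sum(~finite))
    if removed:
        logger.info("clean_nonfinite: removed %d non-finite segments", removed)
    return ds.subset(np.flatnonzero(finite))


# ---------------------------------------------------------------------------
# Wavelet denoising
# ---------------------------------------------------------------------------

def estimate_sigma(detail_coeffs: np.ndarray) -> float:
    """Donoho's noise-scale estimate: median(|cd|) / 0.6745."""
    cd = np.asarray(detail_coeffs, dtype=float)
    if cd.size == 0:
        raise ValidationError("estimate_sigma needs a nonempty coefficient vector")
    return float(np.median(np.abs(cd)) / 0.6745)


def universal_threshold(sigma: float, n: int) -> float:
    """Universal threshold lambda = sigma * sqrt(2 ln n)."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    return float(sigma * math.sqrt(2.0 * math.log(n)))


def hard_threshold(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Zero coefficients with |c| <= lam, leave the rest unchanged."""
    c = np.asarray(coeffs, dtype=float)
    return np.where(np.abs(c) <= lam, 0.0, c)


def estimate_denoise_params(
    segment: np.ndarray, params: DenoiseParams = DenoiseParams()
) -> DenoiseParams:
    """Populate sigma (finest detail band) and lambda for one segment."""
    seg = np.asarray(segment, dtype=float)
    coeffs = _wavedec(seg, params)
    sigma = estimate_sigma(coeffs[-1])
    lam = universal_threshold(sigma, seg.size)
    return replace(params, sigma=sigma, lam=lam, n=seg.size)


def _wavedec(seg: np.ndarray, params: DenoiseParams):
    try:
        wavelet = pywt.Wavelet(params.wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(
            f"unknown wavelet {params.wavelet_name!r}"
        ) from exc
    if seg.size < 2 ** params.levels:
        raise ValidationError(
            f"segment of {seg.size} samples too short for "
            f"{params.levels}-level decomposition"
        )
    return pywt.wavedec(seg, wavelet, level=params.levels, mode="symmetric")


def denoise_dwt(
    segment: np.ndarray, params: DenoiseParams = DenoiseParams()
) -> np.ndarray:
    """Multi-level DWT hard-threshold denoising of one segment.

    Decomposes with ``params.wavelet_name`` to ``params.levels`` levels,
    estimates sigma from the finest detail band (unless given), thresholds
    every detail level at lambda = sigma*sqrt(2 ln n) (n = segment length,
    unless ``params.lam`` is preset), keeps the approximation band, and
    reconstructs at the original length.
    """
    seg = np.asarray(segment, dtype=float)
    coeffs = _wavedec(seg, params)
    lam = params.lam
    if lam is None:
        sigma = params.sigma if params.sigma is not None else estimate_sigma(coeffs[-1])
        lam = universal_threshold(sigma, seg.size)
    out = [coeffs[0]] + [hard_threshold(c, lam) for c in coeffs[1:]]
    rec = pywt.waverec(out, pywt.Wavelet(params.wavelet_name), mode="symmetric")
    return rec[: seg.size]


def denoise_dataset(ds: BeatDataset, params: DenoiseParams = DenoiseParams()) -> BeatDataset:
    out = np.empty_like(ds.segments)
    for i in range(len(ds)):
        out[i] = denoise_dwt(ds.segments[i], params)
    return BeatDataset(out, ds.labels)


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

def run_pipeline(
    rec: ECGRecord,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    denoise: DenoiseParams = DenoiseParams(),
    keep_prob: float = 0.15,
    target_class: int = 0,
    seed: int = 0,
    apply_denoise: bool = True,
) -> BeatDataset:
    """Full record-to-dataset preprocessing in the canonical order."""
    peaks = detect_r_peaks(rec, use_annotations=seg_cfg.use_annotations)
    ds = segment_beats(rec, peaks, seg_cfg)
    ds = zscore_dataset(ds)
    ds = subsample_majority(ds, keep_prob, target_class, seed)
    ds = clean_nonfinite(ds)
    if apply_denoise:
        ds = denoise_dataset(ds, denoise)
    return ds
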