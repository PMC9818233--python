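"""Beat segmentation by the midpoint rule, labelling, and image rendering.

A beat is the half-open sample window between the midpoints of the two RR
intervals flanking its R peak: for interior peak R_k the window is
[floor((R_{k-1}+R_k)/2), floor((R_k+R_{k+1})/2)).  The first and last
peaks have no two-sided midpoint and are dropped, so consecutive windows
tile the covered span exactly.

Each beat is rendered deterministically as an RGB raster: the waveform as
a connected polyline on a plain background, min-max normalized per beat,
no axes or margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import AnnotatedRecord, BeatAnnotation, BeatLabel

logger = logging.getLogger(__name__)


@dataclass
class Beat:
    record_id: str
    subject_id: str
    r_index: int
    window: tuple[int, int]  # half-open [start, end)
    samples: np.ndarray
    label: BeatLabel | None = None

    def __post_init__(self) -> None:
        start, end = self.window
        if not (start <= self.r_index < end):
            raise ValueError(f"r_index {self.r_index} outside window {self.window}")
        if end - start < 2:
            raise ValueError(f"window {self.window} shorter than 2 samples")


def segment_beats(rec: AnnotatedRecord, r_peaks: list[int]) -> list[Beat]:
    """Segment by the midpoint rule; first and last peaks are dropped.

    Peaks must be strictly increasing with gaps of at least 2 samples
    (guaranteed upstream by the detector's refractory period), otherwise a
    midpoint window would not contain its own R peak.
    """
    peaks = list(r_peaks)
    if any(b - a < 2 for a, b in zip(peaks, peaks[1:])):
        raise ValueError("r_peaks must be strictly increasing with gaps >= 2 samples")
    if peaks and not (0 <= peaks[0] and peaks[-1] < rec.samples.size):
        raise ValueError("r_peaks outside the record")
    if len(peaks) < 3:
        logger.warning(
            "segment_beats: %d peak(s) in %s, need >= 3 for a two-sided midpoint",
            len(peaks), rec.record_id,
        )
        return []
    beats = []
    for k in range(1, len(peaks) - 1):
        start = (peaks[k - 1] + peaks[k]) // 2
        end = (peaks[k] + peaks[k + 1]) // 2
        beats.append(
            Beat(
                record_id=rec.record_id,
                subject_id=rec.subject_id,
                r_index=peaks[k],
                window=(start, end),
                samples=rec.samples[start:end].copy(),
            )
        )
    return beats


def label_beats(
    beats: list[Beat],
    annotations: list[BeatAnnotation],
    sampling_rate_hz: float,
    tolerance_s: float = 0.15,
) -> list[Beat]:
    """Attach to each beat the label of the nearest annotation within tolerance.

    Beats with no annotation inside the tolerance, or whose nearest match is
    an OTHER-class annotation, are discarded (counts logged).
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance_s must be > 0")
    tol = tolerance_s * sampling_rate_hz
    ann_idx = np.array([a.sample_index for a in annotations])
    kept: list[Beat] = []
    n_unmatched = n_other = 0
    for b in beats:
        if ann_idx.size == 0:
            n_unmatched += 1
            continue
        j = int(np.argmin(np.abs(ann_idx - b.r_index)))
        if abs(int(ann_idx[j]) - b.r_index) > tol:
            n_unmatched += 1
            continue
        label = annotations[j].label
        if label is BeatLabel.OTHER:
            n_other += 1
            continue
        b.label = label
        kept.append(b)
    if n_unmatched or n_other:
        logger.info(
            "label_beats: discarded %d unmatched and %d OTHER beat(s)",
            n_unmatched, n_other,
        )
    return kept


@dataclass(frozen=True)
class RenderConfig:
    """Deterministic rasterization style for beat images."""

    height: int = 224
    width: int = 224
    line_width: int = 2
    foreground: tuple[int, int, int] = (16, 16, 160)  # dark blue
    background: tuple[int, int, int] = (255, 255, 255)


@dataclass
class BeatImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    height: int
    width: int
    source: str  # "record_id:r_index"

    def to_chw_float(self) -> np.ndarray:
        """(3, H, W) float32 in [0, 1] — the classifier's input layout."""
        return np.transpose(self.pixels, (2, 0, 1)).astype(np.float32) / 255.0


def render_beat_image(beat: Beat, cfg: RenderConfig = RenderConfig()) -> BeatImage:
    """Render a beat as a polyline raster; a pure function of (samples, cfg)."""
    x = np.asarray(beat.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("beat has no samples")
    H, W = cfg.height, cfg.width
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        norm = np.full_like(x, 0.5)  # constant beat -> mid-height line
    else:
        norm = (x - lo) / (hi - lo)
    # pixel coordinates: columns span the window, row 0 at the top
    if x.size == 1:
        cols = np.array([W // 2])
    else:
        cols = np.round(np.arange(x.size) / (x.size - 1) * (W - 1)).astype(int)
    rows = np.round((1.0 - norm) * (H - 1)).astype(int)

    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = np.array(cfg.background, dtype=np.uint8)

    half = cfg.line_width // 2
    lo_off, hi_off = -half, cfg.line_width - half
    fg = np.array(cfg.foreground, dtype=np.uint8)

    def stamp(r: np.ndarray, c: np.ndarray) -> None:
        for dr in range(lo_off, hi_off):
            for dc in range(lo_off, hi_off):
                rr = np.clip(r + dr, 0, H - 1)
                cc = np.clip(c + dc, 0, W - 1)
                img[rr, cc] = fg

    for k in range(x.size - 1):
        r0, c0, r1, c1 = rows[k], cols[k], rows[k + 1], cols[k + 1]
        npts = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
        rr = np.round(np.linspace(r0, r1, npts)).astype(int)
        cc = np.round(np.linspace(c0, c1, npts)).astype(int)
        stamp(rr, cc)
    if x.size == 1:
        stamp(rows, cols)

    return BeatImage(
        pixels=img, height=H, width=W, source=f"{beat.record_id}:{beat.r_index}"
    )


def save_beat_image(image: BeatImage, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(image.pixels).save(str(path))
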