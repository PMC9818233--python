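"""Pan-Tompkins QRS detection at 200 Hz.

The classic real-time detector: cascaded integer-coefficient recursive
band-pass (~5-15 Hz), five-point derivative, squaring, and a 150 ms
moving-window integration, followed by adaptive dual-threshold peak
picking with a 200 ms refractory period, T-wave rejection by slope
comparison inside a 360 ms window, and search-back at the lower threshold
when no beat is found within 1.66 x the running RR average.

The original difference equations are specified for a 200 Hz input, so
records at other rates are resampled before detection and detections are
mapped back to native-rate indices by the exact rational index ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, lfilter

from .records import AnnotatedRecord, resample_record

FS = 200.0
REFRACTORY_S = 0.200
T_WAVE_WINDOW_S = 0.360
SEARCHBACK_FACTOR = 1.66

# Group delays (samples at 200 Hz) of the individual stages.
LP_DELAY = 5          # (1 - z^-6)^2 / (1 - z^-1)^2
HP_DELAY = 16         # z^-16 - (1/32)(1 - z^-32)/(1 - z^-1)
DERIV_DELAY = 2
MWI_WINDOW = 30       # 150 ms at 200 Hz
MWI_DELAY = MWI_WINDOW // 2


class InputTooShortError(ValueError):
    pass


@dataclass
class PTStages:
    """Aligned intermediate sequences plus per-stage group delays (samples)."""

    filtered: np.ndarray     # band-passed
    derivative: np.ndarray
    squared: np.ndarray
    integrated: np.ndarray
    delays: dict[str, float]


def bandpass(x: np.ndarray) -> np.ndarray:
    """Cascaded low-pass and high-pass recursive filters (5-15 Hz passband)."""
    # low-pass: y[n] = 2y[n-1] - y[n-2] + x[n] - 2x[n-6] + x[n-12], gain 36
    b_lp = np.zeros(13)
    b_lp[[0, 6, 12]] = 1.0, -2.0, 1.0
    lp = lfilter(b_lp / 36.0, [1.0, -2.0, 1.0], x)
    # high-pass: all-pass minus low-pass, unity passband gain, delay 16
    b_hp = np.zeros(33)
    b_hp[0] = -1.0 / 32.0
    b_hp[16] = 1.0
    b_hp[17] = -1.0
    b_hp[32] = 1.0 / 32.0
    return lfilter(b_hp, [1.0, -1.0], lp)


def derivative(x: np.ndarray) -> np.ndarray:
    """Five-point derivative: y[n] = (2x[n] + x[n-1] - x[n-3] - 2x[n-4]) / 8."""
    return lfilter(np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0, [1.0], x)


def moving_window_integrate(x: np.ndarray, window: int = MWI_WINDOW) -> np.ndarray:
    return lfilter(np.ones(window) / window, [1.0], x)


def preprocess(samples: np.ndarray, sampling_rate_hz: float = FS) -> PTStages:
    """Run the four fixed pre-processing stages on a 200 Hz voltage series."""
    if abs(sampling_rate_hz - FS) > 1e-6:
        raise ValueError(
            f"preprocess expects {FS:g} Hz input (got {sampling_rate_hz:g}); "
            "resample the record first"
        )
    x = np.asarray(samples, dtype=np.float64)
    if x.size < MWI_WINDOW:
        raise InputTooShortError(
            f"need at least {MWI_WINDOW} samples (one integration window), got {x.size}"
        )
    f = bandpass(x)
    d = derivative(f)
    s = d * d
    m = moving_window_integrate(s)
    return PTStages(
        filtered=f,
        derivative=d,
        squared=s,
        integrated=m,
        delays={
            "filtered": float(LP_DELAY + HP_DELAY),
            "derivative": float(LP_DELAY + HP_DELAY + DERIV_DELAY),
            "squared": float(LP_DELAY + HP_DELAY + DERIV_DELAY),
            "integrated": float(LP_DELAY + HP_DELAY + DERIV_DELAY + MWI_DELAY),
        },
    )


@dataclass
class DetectorState:
    """Running state of the adaptive dual-threshold peak picker."""

    signal_peak_level: float = 0.0
    noise_peak_level: float = 0.0
    rr_average_recent: float = 0.0
    rr_average_limited: float = 0.0
    refractory: float = REFRACTORY_S
    t_wave_window: float = T_WAVE_WINDOW_S

    @property
    def threshold_1(self) -> float:
        return self.noise_peak_level + 0.25 * (
            self.signal_peak_level - self.noise_peak_level
        )

    @property
    def threshold_2(self) -> float:
        return 0.5 * self.threshold_1


def _detect_200hz(x200: np.ndarray) -> list[int]:
    """Core detector; returns refined R indices on the 200 Hz timeline."""
    stages = preprocess(x200)
    mwi = stages.integrated
    bp = stages.filtered
    delay = int(round(stages.delays["integrated"]))
    bp_delay = int(round(stages.delays["filtered"]))
    refr = int(round(REFRACTORY_S * FS))

    # candidate fiducials: local maxima at refractory-scale separation, so
    # ripple on a single QRS's rising edge yields one candidate (its max)
    peaks, _ = find_peaks(mwi, distance=refr)
    if peaks.size == 0:
        return []

    # learning phase: signal level from the running maximum, noise level
    # from the mean, over the first two seconds
    learn = slice(0, min(int(2 * FS), mwi.size))
    state = DetectorState(
        signal_peak_level=float(np.max(mwi[learn])),
        noise_peak_level=float(np.mean(mwi[learn])),
    )

    def slope_at(i: int) -> float:
        lo, hi = max(0, i - 15), min(mwi.size, i + 1)
        return float(np.max(np.abs(stages.derivative[lo:hi]))) if hi > lo else 0.0

    detections: list[int] = []      # fiducial marks on the MWI timeline
    qrs_slopes: list[float] = []
    rr_recent: list[float] = []
    rr_limited: list[float] = []
    last_unchecked = 0              # index into peaks for search-back

    def accept(pk: int, searchback: bool) -> None:
        level = float(mwi[pk])
        if searchback:
            state.signal_peak_level = 0.25 * level + 0.75 * state.signal_peak_level
        else:
            state.signal_peak_level = 0.125 * level + 0.875 * state.signal_peak_level
        if detections:
            rr = (pk - detections[-1]) / FS
            rr_recent.append(rr)
            del rr_recent[:-8]
            state.rr_average_recent = float(np.mean(rr_recent))
            limit_ref = state.rr_average_limited or rr
            if 0.92 * limit_ref <= rr <= 1.16 * limit_ref:
                rr_limited.append(rr)
                del rr_limited[:-8]
            if rr_limited:
                state.rr_average_limited = float(np.mean(rr_limited))
        detections.append(pk)
        qrs_slopes.append(slope_at(pk))

    for pi, pk in enumerate(peaks):
        level = float(mwi[pk])
        if detections and pk - detections[-1] < refr:
            continue
        is_qrs = level > state.threshold_1
        if is_qrs and detections and (pk - detections[-1]) / FS < T_WAVE_WINDOW_S:
            # T-wave discrimination: an overshoot with less than half the
            # slope of the preceding QRS is a T wave, not a beat
            if slope_at(pk) < 0.5 * qrs_slopes[-1]:
                is_qrs = False
        if is_qrs:
            accept(pk, searchback=False)
            last_unchecked = pi + 1
        else:
            state.noise_peak_level = 0.125 * level + 0.875 * state.noise_peak_level

        # search-back: no beat within 1.66 x the limited RR average
        rr_ref = state.rr_average_limited or state.rr_average_recent
        if detections and rr_ref > 0:
            gap = (pk - detections[-1]) / FS
            if gap > SEARCHBACK_FACTOR * rr_ref:
                cands = [
                    q
                    for q in peaks[last_unchecked : pi + 1]
                    if q - detections[-1] >= refr
                    and pk - q >= 0
                    and mwi[q] > state.threshold_2
                    and q not in detections
                ]
                if cands:
                    best = int(max(cands, key=lambda q: mwi[q]))
                    accept(best, searchback=True)
                    detections.sort()
                    last_unchecked = pi + 1

    # refine each fiducial mark to the local extremum of the band-passed
    # signal within +/- 40 ms, compensating the group delays
    refine = int(round(0.040 * FS))
    refined = []
    for pk in detections:
        c = pk - delay + bp_delay  # position on the band-passed timeline
        lo, hi = max(0, c - refine), min(bp.size, c + refine + 1)
        if hi <= lo:
            continue
        r_bp = lo + int(np.argmax(np.abs(bp[lo:hi])))
        r = r_bp - bp_delay  # back to the signal-domain timeline
        refined.append(max(0, min(x200.size - 1, r)))
    refined = sorted(set(refined))
    return refined


def detect_r_peaks(rec: AnnotatedRecord) -> list[int]:
    """Detect R peaks; returns strictly increasing native-rate sample indices."""
    if abs(rec.sampling_rate_hz - FS) > 1e-6:
        rec200 = resample_record(rec, FS)
        x200 = rec200.samples
        ratio = rec.sampling_rate_hz / FS
    else:
        x200 = rec.samples
        ratio = 1.0
    idx200 = _detect_200hz(np.asarray(x200, dtype=np.float64))
    native = []
    for i in idx200:
        j = int(round(i * ratio))
        j = max(0, min(rec.samples.size - 1, j))
        if ratio != 1.0:
            # refine on the native-rate signal inside +/- 40 ms
            w = int(round(0.040 * rec.sampling_rate_hz))
            lo, hi = max(0, j - w), min(rec.samples.size, j + w + 1)
            j = lo + int(np.argmax(np.abs(rec.samples[lo:hi])))
        if not native or j > native[-1]:
            native.append(j)
    return native
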