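"""Annotated single-lead ECG records and record-level operations.

The in-memory container mirrors the PhysioNet convention: a voltage series
in millivolts at a fixed sampling rate, plus beat annotations given as
(sample index, symbol) pairs.  Annotation symbols follow the WFDB mnemonic
set ('N' normal, 'V' premature ventricular contraction, ...); they are
mapped onto the three-way label set {NORMAL, PVC, OTHER} used throughout
the pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from scipy.signal import resample_poly


class BeatLabel(enum.Enum):
    NORMAL = "NORMAL"
    PVC = "PVC"
    OTHER = "OTHER"


#: Default symbol -> label mapping.  'N' is the sinus beat, 'V' the PVC;
#: every other mnemonic (atrial premature 'A', paced '/', fusion 'F', ...)
#: falls into OTHER and is excluded downstream at labelling time.
DEFAULT_SYMBOL_MAP: Mapping[str, BeatLabel] = {
    "N": BeatLabel.NORMAL,
    "V": BeatLabel.PVC,
}


def map_annotation_symbol(
    symbol: str, symbol_map: Mapping[str, BeatLabel] | None = None
) -> BeatLabel:
    """Map a WFDB annotation mnemonic to a beat label (total mapping)."""
    table = DEFAULT_SYMBOL_MAP if symbol_map is None else symbol_map
    return table.get(symbol, BeatLabel.OTHER)


@dataclass(frozen=True)
class BeatAnnotation:
    sample_index: int
    symbol: str
    label: BeatLabel

    @classmethod
    def from_symbol(
        cls,
        sample_index: int,
        symbol: str,
        symbol_map: Mapping[str, BeatLabel] | None = None,
    ) -> "BeatAnnotation":
        return cls(int(sample_index), symbol, map_annotation_symbol(symbol, symbol_map))


@dataclass
class AnnotatedRecord:
    """A sampled single-lead ECG voltage series with beat annotations.

    samples are in mV; annotation indices refer to ``samples`` at
    ``sampling_rate_hz`` (0-based).
    """

    record_id: str
    subject_id: str
    lead_name: str
    sampling_rate_hz: float
    samples: np.ndarray
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        n = self.samples.size
        prev = -1
        for ann in self.annotations:
            if not 0 <= ann.sample_index < n:
                raise ValueError(
                    f"annotation index {ann.sample_index} outside record "
                    f"of length {n} ({self.record_id})"
                )
            if ann.sample_index <= prev:
                raise ValueError(
                    f"annotation indices not strictly increasing at "
                    f"{ann.sample_index} ({self.record_id})"
                )
            prev = ann.sample_index

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def n_beats(self, label: BeatLabel | None = None) -> int:
        if label is None:
            return len(self.annotations)
        return sum(1 for a in self.annotations if a.label is label)


def resample_record(rec: AnnotatedRecord, target_hz: float) -> AnnotatedRecord:
    """Resample a record to ``target_hz`` with polyphase (band-limited) filtering.

    Annotation indices are rescaled by ``target_hz / source_hz`` and rounded
    half-to-even; count and ordering are preserved.
    """
    if target_hz <= 0:
        raise ValueError(f"target_hz must be > 0, got {target_hz}")
    if target_hz == rec.sampling_rate_hz:
        return replace(rec, samples=rec.samples.copy(), annotations=list(rec.annotations))
    ratio = Fraction(target_hz).limit_denominator(10**6) / Fraction(
        rec.sampling_rate_hz
    ).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    out = resample_poly(rec.samples, up, down)
    scale = target_hz / rec.sampling_rate_hz
    anns = []
    prev = -1
    for a in rec.annotations:
        idx = int(np.round(a.sample_index * scale))  # round-half-to-even
        idx = min(max(idx, 0), out.size - 1)
        if idx <= prev:  # guard against collisions under extreme downsampling
            idx = prev + 1
        anns.append(replace(a, sample_index=idx))
        prev = idx
    return AnnotatedRecord(
        record_id=rec.record_id,
        subject_id=rec.subject_id,
        lead_name=rec.lead_name,
        sampling_rate_hz=float(target_hz),
        samples=out,
        annotations=anns,
    )


@dataclass(frozen=True)
class SelectionPolicy:
    """Record-selection rules: exclusion list, PVC-presence filter, truncation.

    ``max_records`` keeps the first k records in ascending record-id order
    (used for the 22-of-61 subset convention).
    """

    exclude_ids: frozenset[str] = frozenset()
    require_pvc: bool = False
    max_records: int | None = None


def select_records(
    records: Iterable[AnnotatedRecord], policy: SelectionPolicy
) -> list[AnnotatedRecord]:
    kept = [r for r in records if r.record_id not in policy.exclude_ids]
    if policy.require_pvc:
        kept = [r for r in kept if r.n_beats(BeatLabel.PVC) >= 1]
    kept.sort(key=lambda r: r.record_id)
    if policy.max_records is not None:
        kept = kept[: policy.max_records]
    return kept


#: MIT-BIH records excluded for paced beats / surgical dressings.
MITBIH_EXCLUDED_RECORDS = frozenset({"102", "104", "107", "217"})
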