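"""Minimal WFDB-convention record serialization.

Implements the subset of the PhysioNet waveform-database formats the
pipeline needs: text headers (``.hea``), interleaved 16-bit little-endian
signal files (format 16 ``.dat``), and the MIT annotation format
(``.atr``).  Amplitudes are stored as ADC units and converted to mV with
the per-signal gain at read time, so the whole package works in a single
unit convention.

Only a constrained subset of the header grammar is emitted (one segment,
format 16, explicit gain/baseline); the reader accepts that subset and
raises informative errors otherwise.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np

from .records import AnnotatedRecord, BeatAnnotation, map_annotation_symbol

# MIT annotation codes (ecgcodes): mnemonic <-> numeric annotation type.
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    30: "?", 34: "e", 35: "n", 38: "f", 31: "!",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

DEFAULT_GAIN = 200.0  # ADC units per mV
DEFAULT_ADC_RES = 11  # bits, as in the MIT-BIH digitizer


class WFDBFormatError(ValueError):
    pass


def _record_base(path: str | os.PathLike) -> Path:
    p = Path(path)
    if p.suffix in {".hea", ".dat", ".atr"}:
        p = p.with_suffix("")
    return p


def write_record(
    directory: str | os.PathLike,
    rec: AnnotatedRecord,
    extra_leads: dict[str, np.ndarray] | None = None,
    gain: float = DEFAULT_GAIN,
    comments: tuple[str, ...] = (),
) -> Path:
    """Write ``rec`` (plus optional extra leads) as a .hea/.dat/.atr triplet.

    Samples are quantized to ``round(mV * gain)`` ADC units (the stored
    precision); annotations are written with their WFDB mnemonics.
    Returns the record base path (without extension).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / rec.record_id
    leads: list[tuple[str, np.ndarray]] = [(rec.lead_name, rec.samples)]
    for name, sig in (extra_leads or {}).items():
        sig = np.asarray(sig, dtype=np.float64)
        if sig.shape != rec.samples.shape:
            raise WFDBFormatError(
                f"extra lead {name!r} length {sig.size} != {rec.samples.size}"
            )
        leads.append((name, sig))

    adc = np.stack(
        [np.clip(np.round(sig * gain), -32768, 32767) for _, sig in leads]
    ).astype(np.int16)

    # header
    n_sig, n_samp = adc.shape[0], adc.shape[1]
    fs = rec.sampling_rate_hz
    fs_str = f"{fs:g}"
    lines = [f"{rec.record_id} {n_sig} {fs_str} {n_samp}"]
    for k, (name, _) in enumerate(leads):
        checksum = int(np.int16(adc[k].astype(np.int64).sum() & 0xFFFF))
        lines.append(
            f"{rec.record_id}.dat 16 {gain:g}(0)/mV {DEFAULT_ADC_RES} 0 "
            f"{int(adc[k, 0])} {checksum} 0 {name}"
        )
    lines += [f"# {c}" for c in comments]
    lines += [f"# subject_id: {rec.subject_id}"]
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    # signal: frame-interleaved int16 little-endian
    base.with_suffix(".dat").write_bytes(
        adc.T.astype("<i2").tobytes(order="C")
    )

    _write_annotations(base.with_suffix(".atr"), rec.annotations)
    return base


def _write_annotations(path: Path, annotations: list[BeatAnnotation]) -> None:
    out = bytearray()
    prev = 0
    for ann in annotations:
        code = _SYMBOL_TO_CODE.get(ann.symbol, 13)  # unknown -> 'Q'
        dt = ann.sample_index - prev
        if dt > 1023 or dt < 0:
            out += struct.pack("<H", _SKIP << 10)
            # PDP-11 long: high 16 bits first, each word little-endian
            out += struct.pack("<H", (dt >> 16) & 0xFFFF)
            out += struct.pack("<H", dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (code << 10) | dt)
        prev = ann.sample_index
    out += struct.pack("<H", 0)  # end of file
    path.write_bytes(bytes(out))


def _read_annotations(path: Path) -> list[tuple[int, str]]:
    data = path.read_bytes()
    anns: list[tuple[int, str]] = []
    t = 0
    pos = 0
    pending_skip = 0
    while pos + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, pos)
        pos += 2
        code, dt = word >> 10, word & 0x3FF
        if code == 0 and dt == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", data, pos)
            pos += 4
            pending_skip = struct.unpack("<i", struct.pack("<HH", lo, hi))[0]
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            pos += dt + (dt & 1)
            continue
        t += dt + pending_skip
        pending_skip = 0
        anns.append((t, _CODE_TO_SYMBOL.get(code, "Q")))
    return anns


def read_record(path: str | os.PathLike, lead: str) -> AnnotatedRecord:
    """Read the selected lead of a WFDB record triplet into mV.

    ``path`` is the record base (with or without extension).  Raises a
    FileNotFoundError naming the missing file, or a WFDBFormatError listing
    the available leads when ``lead`` is absent.
    """
    base = _record_base(path)
    hea = base.with_suffix(".hea")
    dat = base.with_suffix(".dat")
    atr = base.with_suffix(".atr")
    for f in (hea, dat):
        if not f.exists():
            raise FileNotFoundError(f"WFDB file not found: {f}")

    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    header = [ln for ln in lines if not ln.startswith("#")]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    rec_fields = header[0].split()
    record_id, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    sig_lines = header[1 : 1 + n_sig]

    names, gains, baselines, fmts = [], [], [], []
    for ln in sig_lines:
        parts = ln.split()
        fmts.append(parts[1].split("x")[0].split(":")[0])
        gain_spec = parts[2]
        gain_part = gain_spec.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_part) if float(gain_part) != 0 else DEFAULT_GAIN)
            baselines.append(0)
        names.append(parts[8] if len(parts) > 8 else f"sig{len(names)}")
    if any(f != "16" for f in fmts):
        raise WFDBFormatError(f"unsupported signal format(s) {fmts}; only format 16 is supported")
    if lead not in names:
        raise WFDBFormatError(
            f"lead {lead!r} not present in {hea.name}; available leads: {names}"
        )
    k = names.index(lead)

    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size % n_sig:
        raise WFDBFormatError(f"{dat.name}: size not divisible by {n_sig} signals")
    adc = raw.reshape(-1, n_sig)[:, k].astype(np.float64)
    samples = (adc - baselines[k]) / gains[k]

    subject_id = record_id
    for c in comments:
        if c.startswith("subject_id:"):
            subject_id = c.split(":", 1)[1].strip()

    annotations = []
    if atr.exists():
        annotations = [
            BeatAnnotation.from_symbol(t, sym) for t, sym in _read_annotations(atr)
        ]
    return AnnotatedRecord(
        record_id=record_id,
        subject_id=subject_id,
        lead_name=lead,
        sampling_rate_hz=fs,
        samples=samples,
        annotations=annotations,
    )
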