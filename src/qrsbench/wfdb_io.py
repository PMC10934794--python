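"""Reading and writing WFDB-style ECG records and beat annotations.

Implements the subset of the PhysioNet WFDB file family this package needs:

* headers (``.hea``) — read and write;
* signal files (``.dat``) — read formats 212 (the MIT-BIH Arrhythmia
  Database dialect, 12-bit packed) and 16 (little-endian int16); write
  format 16;
* annotation files (``.atr``/``.ann``, MIT format) — read and write,
  keeping beat annotations only.

Amplitudes are converted to physical units with the per-signal gain and
baseline from the header: ``phys = (adc - baseline) / gain``.
Annotation positions are 0-based sample indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import AnnotationSet, DetectionResult, EcgRecord, MorphologyCode

__all__ = [
    "read_record",
    "write_record",
    "read_annotations",
    "read_annotation_symbols",
    "write_annotations",
    "count_database_beats",
    "write_detections_csv",
    "read_detections_csv",
    "BEAT_SYMBOLS",
]

# MIT annotation-code <-> symbol tables (WFDB ecgcodes numbering).
_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# Annotation codes that mark QRS complexes (beats).  Everything else
# (rhythm changes, signal-quality flags, waveform boundaries, notes) is
# discarded by `read_annotations`.
_BEAT_CODES = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 30, 34, 35, 38, 41}
)

#: WFDB symbols counted as beats, e.g. by :func:`count_database_beats`.
BEAT_SYMBOLS = frozenset(_CODE_TO_SYMBOL[c] for c in _BEAT_CODES)

_PSEUDO_SKIP = 59
_PSEUDO_NUM = 60
_PSEUDO_SUB = 61
_PSEUDO_CHN = 62
_PSEUDO_AUX = 63


@dataclass(frozen=True)
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str


@dataclass(frozen=True)
class _Header:
    record_name: str
    n_sig: int
    fs: float
    n_samp: int
    signals: tuple[_SignalSpec, ...]


def _parse_header(path: Path) -> _Header:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header: {path}")
    rec_tokens = lines[0].split()
    if len(rec_tokens) < 2:
        raise ValueError(f"malformed record line in {path}: {lines[0]!r}")
    record_name = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    if n_sig <= 0:
        raise ValueError(f"header {path} declares {n_sig} signals")
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    n_samp = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise ValueError(f"malformed signal line in {path}: {ln!r}")
        file_name = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        adc_zero = 0
        if len(tok) > 2:
            gspec = tok[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                baseline = int(bpart.rstrip(")"))
                gspec = gpart
            gain = float(gspec) if gspec else 200.0
            if gain == 0:
                gain = 200.0  # WFDB convention: 0 means "unspecified"
        if len(tok) > 4:
            adc_zero = int(tok[4])
        if baseline is None:
            baseline = adc_zero
        signals.append(_SignalSpec(file_name, fmt, gain, baseline, units))
    if len(signals) != n_sig:
        raise ValueError(f"header {path} declares {n_sig} signals, found {len(signals)}")
    return _Header(record_name, n_sig, fs, n_samp, tuple(signals))


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    usable = (len(b) // 3) * 3
    b = b[:usable].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    values = np.empty(2 * len(b), dtype=np.int32)
    values[0::2] = first
    values[1::2] = second
    values[values > 2047] -= 4096  # 12-bit two's complement
    if n_values > values.size:
        raise ValueError(
            f"signal file too short: need {n_values} samples, decoded {values.size}"
        )
    return values[:n_values]


def read_record(path: str | Path, channel: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record, converted to physical units.

    Parameters
    ----------
    path : str or Path
        Path to the header file, with or without the ``.hea`` extension.
    channel : int
        0-based channel index ("the first channel" is 0, the default).
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    header = _parse_header(hea_path)
    if not 0 <= channel < header.n_sig:
        raise ValueError(
            f"channel {channel} out of range for record with {header.n_sig} signals"
        )
    spec = header.signals[channel]
    dat_path = hea_path.parent / spec.file_name
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = dat_path.read_bytes()

    # All signals of the MIT-BIH dialect share one .dat; samples interleaved.
    same_file = [i for i, s in enumerate(header.signals) if s.file_name == spec.file_name]
    n_interleaved = len(same_file)
    col = same_file.index(channel)

    if spec.fmt == 212:
        n_samp = header.n_samp or (len(raw) * 2 // 3) // n_interleaved
        values = _decode_212(raw, n_samp * n_interleaved)
    elif spec.fmt == 16:
        values = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        n_samp = header.n_samp or values.size // n_interleaved
        if values.size < n_samp * n_interleaved:
            raise ValueError(
                f"signal file {dat_path} too short for {n_samp} samples"
            )
        values = values[: n_samp * n_interleaved]
    else:
        raise ValueError(f"unsupported WFDB signal format {spec.fmt} in {hea_path}")

    adc = values.reshape(-1, n_interleaved)[:, col]
    if header.n_samp and adc.size != header.n_samp:
        raise ValueError(
            f"decoded {adc.size} samples, header declares {header.n_samp}"
        )
    phys = (adc - spec.baseline) / spec.gain
    return EcgRecord(
        record_id=header.record_name, fs=header.fs, samples=phys, channel_index=channel
    )


def write_record(
    record: EcgRecord, path: str | Path, gain: float | None = None
) -> Path:
    """Write a record as a WFDB header + format-16 signal pair.

    The ADC gain defaults to using most of the int16 range for the
    record's amplitude span, so the quantization step is at most
    ``max|x| / 30000`` mV.  Returns the header path.
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    name = hea_path.stem
    x = record.samples
    if gain is None:
        peak = float(np.max(np.abs(x)))
        gain = 30000.0 / peak if peak > 0 else 200.0
    adc = np.clip(np.rint(x * gain), -32768, 32767).astype(np.int16)
    checksum = int(np.sum(adc.astype(np.int64)) & 0xFFFF)
    if checksum >= 0x8000:
        checksum -= 0x10000
    hea_path.parent.mkdir(parents=True, exist_ok=True)
    dat_name = f"{name}.dat"
    fs = record.fs
    fs_str = f"{fs:.6g}"
    header = (
        f"{name} 1 {fs_str} {len(record)}\n"
        f"{dat_name} 16 {gain:.8g}(0)/mV 16 0 {int(adc[0])} {checksum} 0 ECG\n"
    )
    hea_path.write_text(header)
    (hea_path.parent / dat_name).write_bytes(adc.astype("<i2").tobytes())
    return hea_path


# ---------------------------------------------------------------------------
# MIT-format annotations


def read_annotation_symbols(path: str | Path) -> list[tuple[int, str]]:
    """Read all annotations of an MIT-format file as (sample, symbol) pairs.

    Unknown annotation codes are kept with symbol ``"?"``; modifier
    pseudo-annotations (NUM/SUB/CHN/AUX/SKIP) are consumed but not emitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    pending = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = raw[i] | (raw[i + 1] << 8)
        code = word >> 10
        data = word & 0x3FF
        i += 2
        if word == 0:
            break
        if code == _PSEUDO_SKIP:
            if i + 3 >= n:
                raise ValueError(f"truncated SKIP annotation at byte {i - 2} in {path}")
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            dt = (high << 16) | low
            if dt >= 1 << 31:
                dt -= 1 << 32
            pending += dt
        elif code in (_PSEUDO_NUM, _PSEUDO_SUB, _PSEUDO_CHN):
            continue
        elif code == _PSEUDO_AUX:
            skip = data + (data & 1)
            if i + skip > n:
                raise ValueError(f"truncated AUX annotation at byte {i - 2} in {path}")
            i += skip
        else:
            time += pending + data
            pending = 0
            out.append((time, _CODE_TO_SYMBOL.get(code, "?")))
    return out


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read an MIT-format annotation file, keeping beat annotations only.

    Beat symbols are mapped to the six morphology classes (paced ``/``
    becomes ``P``); beat symbols outside the six classes map to ``OTHER``.
    """
    pairs = [
        (t, sym) for t, sym in read_annotation_symbols(path) if sym in BEAT_SYMBOLS
    ]
    pairs.sort(key=lambda p: p[0])
    # Duplicate positions cannot be two distinct beats; keep the first.
    dedup: list[tuple[int, str]] = []
    for t, sym in pairs:
        if dedup and dedup[-1][0] == t:
            continue
        dedup.append((t, sym))
    positions = np.array([t for t, _ in dedup], dtype=np.int64)
    labels = tuple(MorphologyCode.from_symbol(sym) for _, sym in dedup)
    return AnnotationSet(positions=positions, labels=labels)


def write_annotations(
    positions: Sequence[int], symbols: Sequence[str], path: str | Path
) -> Path:
    """Write (sample, symbol) annotations as an MIT-format file.

    Positions must be nondecreasing; long inter-annotation gaps are
    encoded with SKIP pseudo-annotations, so arbitrary spacings round-trip.
    """
    path = Path(path)
    if len(positions) != len(symbols):
        raise ValueError("positions and symbols must have equal length")
    buf = bytearray()
    prev = 0
    for pos, sym in zip(positions, symbols):
        pos = int(pos)
        if pos < prev:
            raise ValueError("annotation positions must be nondecreasing")
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"unknown annotation symbol {sym!r}")
        delta = pos - prev
        if delta > 0x3FF:
            buf += (_PSEUDO_SKIP << 10).to_bytes(2, "little")
            buf += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            buf += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        buf += ((code << 10) | delta).to_bytes(2, "little")
        prev = pos
    buf += b"\x00\x00"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(bytes(buf))
    return path


def count_database_beats(
    db_dir: str | Path, extension: str = ".atr"
) -> dict[str, dict[str, int]]:
    """Count beats per record and per morphology class over a database directory.

    Every annotation whose symbol is in :data:`BEAT_SYMBOLS` is counted
    (the full WFDB beat alphabet, not only the six classes); symbols
    outside the six classes contribute to ``OTHER`` and to ``TOTAL``.
    Returns ``{record_id: {class_name: count, ..., "TOTAL": n}}``.
    """
    db_dir = Path(db_dir)
    files = sorted(db_dir.glob(f"*{extension}"))
    if not files:
        raise FileNotFoundError(f"no {extension} annotation files in {db_dir}")
    out: dict[str, dict[str, int]] = {}
    for f in files:
        ann = read_annotations(f)
        counts = {code.value: 0 for code in MorphologyCode}
        for label in ann.labels:
            counts[label.value] += 1
        counts["TOTAL"] = len(ann)
        out[f.stem] = counts
    return out


# ---------------------------------------------------------------------------
# Detections CSV


def write_detections_csv(
    detections: Mapping[str, DetectionResult] | Iterable[tuple[str, Sequence[int]]],
    path: str | Path,
) -> Path:
    """Export detections as CSV with columns (record_id, sample_index)."""
    path = Path(path)
    if isinstance(detections, Mapping):
        items: Iterable[tuple[str, Sequence[int]]] = (
            (rid, det.positions) for rid, det in detections.items()
        )
    else:
        items = detections
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "sample_index"])
        for rid, positions in items:
            for pos in positions:
                writer.writerow([rid, int(pos)])
    return path


def read_detections_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a detections CSV back as {record_id: sorted position array}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"detections CSV not found: {path}")
    out: dict[str, list[int]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_index" not in reader.fieldnames:
            raise ValueError(f"{path} lacks a sample_index column")
        for row in reader:
            out.setdefault(row["record_id"], []).append(int(row["sample_index"]))
    return {rid: np.array(sorted(v), dtype=np.int64) for rid, v in out.items()}
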