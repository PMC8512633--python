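"""Reading and writing single-lead ECG records.

Two on-disk formats are supported:

* WFDB / PhysioNet records (``.hea`` header, ``.dat`` signal in format 212
  or 16, ``.atr`` MIT-format beat annotations) — the format of the MIT-BIH
  arrhythmia database.
* Plain CSV, one sample per row, with an optional ``fs=<Hz>`` header line.

Only beat annotations are kept on read; rhythm / signal-quality notes are
dropped so that every retained annotation marks one QRS complex.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "ECGInputError",
    "ECGFormatError",
    "BEAT_CODES",
    "read_wfdb",
    "write_wfdb",
    "read_csv",
    "write_csv",
]


class ECGInputError(Exception):
    """A required input file is missing or empty."""


class ECGFormatError(Exception):
    """A file exists but cannot be parsed."""


#: MIT annotation code -> mnemonic for the 18 beat annotation types.
#: Codes outside this table (rhythm changes, noise markers, comments …)
#: are non-beat annotations and are dropped on read.
BEAT_CODES: dict[int, str] = {
    1: "N",   # normal
    2: "L",   # left bundle branch block
    3: "R",   # right bundle branch block
    4: "a",   # aberrated atrial premature
    5: "V",   # premature ventricular contraction
    6: "F",   # fusion of ventricular and normal
    7: "J",   # nodal (junctional) premature
    8: "A",   # atrial premature
    9: "S",   # supraventricular premature
    10: "E",  # ventricular escape
    11: "j",  # nodal escape
    12: "/",  # paced
    13: "Q",  # unclassifiable
    25: "B",  # bundle branch block (unspecified)
    34: "e",  # atrial escape
    35: "n",  # supraventricular escape
    38: "f",  # fusion of paced and normal
    41: "r",  # R-on-T premature ventricular
}

_SYMBOL_TO_CODE = {v: k for k, v in BEAT_CODES.items()}

# MIT annotation pseudo-codes
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class ECGRecord:
    """A single-lead ECG: samples in mV, sampling rate, beat annotations.

    ``annotations`` is a list of ``(sample_index, beat_symbol)`` pairs with
    strictly increasing 0-based indices, each inside the record. Synthetic
    ground-truth R peaks use the sentinel symbol ``"N"``.
    """

    samples: np.ndarray
    fs: float
    name: str = "record"
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D series")
        prev = -1
        for idx, _sym in self.annotations:
            if not (0 <= idx < self.samples.size):
                raise ValueError(f"annotation index {idx} outside record")
            if idx <= prev:
                raise ValueError("annotation indices must be strictly increasing")
            prev = idx

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def annotation_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.annotations], dtype=int)


# ---------------------------------------------------------------------------
# WFDB
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ECGFormatError(f"empty header {hea_path}")
    head = lines[0].split()
    if len(head) < 3:
        raise ECGFormatError(f"malformed header line: {lines[0]!r}")
    name = head[0].split("/")[0]
    try:
        nsig = int(head[1])
        fs = float(head[2].split("/")[0])
        nsamp = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise ECGFormatError(f"malformed header line: {lines[0]!r}") from exc
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        if len(parts) < 2:
            raise ECGFormatError(f"malformed signal line: {ln!r}")
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part[:-1].split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_part
            baseline = None
        gain = float(gain_str) or 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        sigs.append(
            {
                "file": parts[0],
                "fmt": fmt,
                "gain": gain,
                "baseline": baseline if baseline is not None else adc_zero,
            }
        )
    return name, nsig, fs, nsamp, sigs


def _read_dat(dat_path: Path, fmt: int, nsig: int) -> np.ndarray:
    """Return the interleaved ADC matrix, shape (n_frames, nsig)."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = (data.size // nsig) * nsig
        return data[:n].reshape(-1, nsig)
    if fmt == 212:
        n_triplets = len(raw) // 3
        b = np.frombuffer(raw[: n_triplets * 3], dtype=np.uint8).reshape(-1, 3)
        s1 = ((b[:, 1].astype(np.int32) & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1].astype(np.int32) & 0xF0) << 4) | b[:, 2]
        out = np.empty(2 * n_triplets, dtype=np.int32)
        out[0::2], out[1::2] = s1, s2
        out[out > 2047] -= 4096  # 12-bit two's complement
        n = (out.size // nsig) * nsig
        return out[:n].reshape(-1, nsig)
    raise ECGFormatError(f"unsupported WFDB signal format {fmt}")


def _read_annotations(atr_path: Path) -> list[tuple[int, int]]:
    """Decode an MIT-format annotation file to (sample, code) pairs."""
    raw = atr_path.read_bytes()
    out: list[tuple[int, int]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:  # EOF
            break
        if code == _SKIP:
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            continue
        if code == _AUX:
            i += delta + (delta & 1)  # aux string, padded to even length
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += delta
        out.append((t, code))
    return out


def read_wfdb(path: str | Path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record, keeping beat annotations only.

    ``path`` is the record path without extension (``…/100`` reads
    ``100.hea``, ``100.dat`` and, when present, ``100.atr``). ADC values are
    converted to mV with the header gain and baseline.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise ECGInputError(f"header not found: {hea}")
    name, nsig, fs, nsamp, sigs = _parse_header(hea)
    if not 0 <= channel < nsig:
        raise ValueError(f"channel {channel} out of range for {nsig} signals")
    dat = base.parent / sigs[channel]["file"]
    if not dat.exists():
        raise ECGInputError(f"signal file not found: {dat}")
    adc = _read_dat(dat, sigs[channel]["fmt"], nsig)
    if nsamp:
        adc = adc[:nsamp]
    sig = sigs[channel]
    mv = (adc[:, channel].astype(float) - sig["baseline"]) / sig["gain"]

    annotations: list[tuple[int, str]] = []
    atr = base.with_suffix(".atr")
    if atr.exists():
        for sample, code in _read_annotations(atr):
            if code in BEAT_CODES and 0 <= sample < mv.size:
                annotations.append((sample, BEAT_CODES[code]))
    return ECGRecord(mv, fs=fs, name=name, annotations=annotations)


def write_wfdb(record: ECGRecord, path: str | Path, gain: float = 200.0) -> None:
    """Write a record as a format-16 WFDB file (plus ``.atr`` if annotated).

    Mainly used to build round-trip fixtures; quantisation to ADC units
    limits amplitude precision to 1/gain mV.
    """
    base = Path(path)
    adc = np.round(record.samples * gain).astype("<i2")
    base.with_suffix(".dat").write_bytes(adc.tobytes())
    base.with_suffix(".hea").write_text(
        f"{base.name} 1 {record.fs:g} {record.samples.size}\n"
        f"{base.name}.dat 16 {gain:g}(0)/mV 16 0 {adc[0]} 0 0 ECG\n"
    )
    if record.annotations:
        chunks = []
        t = 0
        for idx, sym in record.annotations:
            code = _SYMBOL_TO_CODE.get(sym, 1)
            delta = idx - t
            if delta > 1023:
                chunks.append(struct.pack("<H", (_SKIP << 10)))
                chunks.append(struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF))
                delta = 0
                t = idx
            chunks.append(struct.pack("<H", (code << 10) | delta))
            t = idx
        chunks.append(struct.pack("<H", 0))
        base.with_suffix(".atr").write_bytes(b"".join(chunks))


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, fs: float | None = None, name: str | None = None) -> ECGRecord:
    """Read a one-column CSV of samples; ``fs=<Hz>`` header overrides none given."""
    p = Path(path)
    if not p.exists():
        raise ECGInputError(f"file not found: {p}")
    lines = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
    header_fs = None
    if lines and lines[0].lower().startswith("fs="):
        header_fs = float(lines[0][3:])
        lines = lines[1:]
    if not lines:
        raise ECGInputError(f"no samples in {p}")
    vals = np.empty(len(lines))
    for i, ln in enumerate(lines):
        try:
            vals[i] = float(ln)
        except ValueError as exc:
            raise ECGFormatError(f"non-numeric sample at row {i + 1}: {ln!r}") from exc
    fs_eff = fs if fs is not None else header_fs
    if fs_eff is None:
        raise ValueError("sampling rate not given and no fs= header present")
    return ECGRecord(vals, fs=fs_eff, name=name or p.stem)


def write_csv(record: ECGRecord, path: str | Path, annotations_path: str | Path | None = None) -> None:
    """Write samples (with an ``fs=`` header) and, optionally, annotations."""
    p = Path(path)
    with p.open("w") as fh:
        fh.write(f"fs={record.fs:g}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    if annotations_path is not None:
        with Path(annotations_path).open("w") as fh:
            fh.write("sample,symbol\n")
            for idx, sym in record.annotations:
                fh.write(f"{idx},{sym}\n")


def read_annotation_csv(path: str | Path) -> list[tuple[int, str]]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].lower().startswith("sample"):
        lines = lines[1:]
    out = []
    for ln in lines:
        parts = ln.split(",")
        out.append((int(parts[0]), parts[1] if len(parts) > 1 else "N"))
    return out
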