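"""Reading, scaling and windowing of single-lead ECG sample sequences.

Supports the WFDB file family in its MIT-BIH dialect — a text header
(``.hea``), a packed binary data file (``.dat``, signal formats 212 and 16)
and an optional binary annotation file (``.atr``) — plus plain delimited
text with a JSON sidecar.  The WFDB reader/writer here covers exactly the
subset those records use; it is not a general WFDB implementation.

Raw ADC samples are converted to physical lead values by dividing by the
ADC gain, 200 adu/mV for MIT-BIH, which is why the conventional scaling
constant for these records is 200.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError, FormatError, ValidationError

__all__ = [
    "ECGRecord",
    "SequenceWindow",
    "DEFAULT_ADC_GAIN",
    "DEFAULT_WINDOW_LENGTH",
    "read_wfdb_record",
    "write_wfdb_record",
    "extract_lead",
    "segment_windows",
    "minmax_normalize",
    "read_sequence_text",
    "write_sequence_text",
]

#: MIT-BIH ADC gain in adu/mV; raw samples are divided by this.
DEFAULT_ADC_GAIN = 200.0

#: Training sequence length used throughout the package.
DEFAULT_WINDOW_LENGTH = 3120


@dataclass
class ECGRecord:
    """One subject's recording: per-lead integer sample arrays at a common
    sampling rate, with optional beat annotations."""

    record_id: str
    sampling_rate: float
    leads: List[np.ndarray]
    annotations: List[Tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )
        self.leads = [np.asarray(lead) for lead in self.leads]
        if not self.leads:
            raise ValidationError("record must have at least one lead")
        lengths = {len(lead) for lead in self.leads}
        if len(lengths) != 1:
            raise ValidationError(f"leads have unequal lengths: {sorted(lengths)}")

    @property
    def n_leads(self) -> int:
        return len(self.leads)

    @property
    def n_samples(self) -> int:
        return len(self.leads[0])


@dataclass
class SequenceWindow:
    """A fixed-length single-lead segment — the unit fed to the models.

    Windows are half-open sample ranges ``[start_index, start_index + L)``
    with 0-based indices.
    """

    values: np.ndarray
    source_record: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("window values must be one-dimensional")

    @property
    def length(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# WFDB (MIT-BIH dialect)
# ---------------------------------------------------------------------------

# MIT annotation mnemonics for the common beat/non-beat codes.
_ANN_CODES = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")",
}
_ANN_MNEMONICS = {v: k for k, v in _ANN_CODES.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _parse_int_prefix(token: str) -> int:
    digits = ""
    for ch in token:
        if ch.isdigit() or (ch == "-" and not digits):
            digits += ch
        else:
            break
    if not digits:
        raise FormatError(f"cannot parse integer from {token!r}")
    return int(digits)


def _parse_gain(token: str) -> float:
    # "200", "200(0)/mV", "200/mV" all mean gain 200.
    for sep in "(/":
        token = token.split(sep, 1)[0]
    try:
        gain = float(token)
    except ValueError as exc:
        raise FormatError(f"cannot parse ADC gain from {token!r}") from exc
    return gain if gain != 0 else DEFAULT_ADC_GAIN


def read_wfdb_record(header_path, verify_checksum: bool = True) -> ECGRecord:
    """Read a WFDB record given its ``.hea`` header path.

    Signal formats 212 (two 12-bit samples packed into 3 bytes) and 16
    (little-endian int16) are supported; all signals must live in a single
    data file.  A same-stem ``.atr`` annotation file is read if present.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header: {header_path}")
    rec_tokens = lines[0].split()
    if len(rec_tokens) < 2:
        raise FormatError(f"malformed record line in {header_path}: {lines[0]!r}")
    record_id = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    if len(lines) - 1 < n_sig:
        raise FormatError(
            f"header declares {n_sig} signals but has {len(lines) - 1} signal lines"
        )

    filenames, formats, gains, checksums = [], [], [], []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed signal line in {header_path}: {ln!r}")
        filenames.append(tok[0])
        formats.append(_parse_int_prefix(tok[1]))
        gains.append(_parse_gain(tok[2]) if len(tok) > 2 else DEFAULT_ADC_GAIN)
        checksums.append(int(tok[6]) if len(tok) > 6 else None)
    if len(set(filenames)) != 1:
        raise FormatError("records spanning multiple data files are not supported")
    if len(set(formats)) != 1:
        raise FormatError("mixed signal formats within one record are not supported")
    fmt = formats[0]

    dat_path = header_path.parent / filenames[0]
    if not dat_path.exists():
        raise FileNotFoundError(f"data file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype=np.uint8)

    if fmt == 212:
        samples = _unpack_212(raw)
        total = n_sig * n_samples if n_samples else (len(samples) // n_sig) * n_sig
        samples = samples[:total]
        leads = [samples[i::n_sig].astype(np.int32) for i in range(n_sig)]
    elif fmt == 16:
        samples = raw.view("<i2").astype(np.int32)
        total = n_sig * n_samples if n_samples else (len(samples) // n_sig) * n_sig
        samples = samples[:total]
        leads = [samples[i::n_sig] for i in range(n_sig)]
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt}")

    if n_samples and any(len(lead) != n_samples for lead in leads):
        raise FormatError(
            f"data file {dat_path} holds fewer samples than the header declares"
        )
    if verify_checksum:
        for i, (lead, want) in enumerate(zip(leads, checksums)):
            if want is None:
                continue
            got = _wfdb_checksum(lead)
            if got != want:
                raise FormatError(
                    f"checksum mismatch on signal {i} of {record_id}: "
                    f"header {want}, computed {got}"
                )

    atr_path = header_path.with_suffix(".atr")
    annotations = _read_annotations(atr_path) if atr_path.exists() else []
    return ECGRecord(
        record_id=record_id,
        sampling_rate=fs,
        leads=leads,
        annotations=annotations,
    )


def _unpack_212(raw: np.ndarray) -> np.ndarray:
    """Unpack format-212 byte triplets into interleaved 12-bit samples."""
    usable = (len(raw) // 3) * 3
    b = raw[:usable].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out >= 2048] -= 4096  # 12-bit two's complement
    return out


def _pack_212(samples: np.ndarray) -> np.ndarray:
    vals = np.asarray(samples, dtype=np.int64)
    if vals.min() < -2048 or vals.max() > 2047:
        raise ValidationError("format 212 samples must fit in 12 bits")
    if len(vals) % 2:
        vals = np.concatenate([vals, [0]])
    vals = np.where(vals < 0, vals + 4096, vals).astype(np.uint16)
    first, second = vals[0::2], vals[1::2]
    out = np.empty((len(first), 3), dtype=np.uint8)
    out[:, 0] = first & 0xFF
    out[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
    out[:, 2] = second & 0xFF
    return out.ravel()


def _wfdb_checksum(samples: np.ndarray) -> int:
    total = int(np.asarray(samples, dtype=np.int64).sum()) & 0xFFFF
    return total - 0x10000 if total >= 0x8000 else total


def _read_annotations(path: Path) -> List[Tuple[int, str]]:
    raw = np.fromfile(path, dtype=np.uint8)
    anns: List[Tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        word = int(raw[i]) | (int(raw[i + 1]) << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise FormatError(f"truncated SKIP annotation in {path}")
            pending_skip = (
                (int(raw[i]) << 16)
                | (int(raw[i + 1]) << 24)
                | int(raw[i + 2])
                | (int(raw[i + 3]) << 8)
            )
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
            i += 4
        elif code == _AUX:
            i += interval + (interval % 2)
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += interval + pending_skip
            pending_skip = 0
            anns.append((t, _ANN_CODES.get(code, str(code))))
    return anns


def _write_annotations(path: Path, annotations: Sequence[Tuple[int, str]]) -> None:
    words = bytearray()
    prev = 0
    for sample, label in annotations:
        code = _ANN_MNEMONICS.get(label)
        if code is None:
            try:
                code = int(label)
            except ValueError as exc:
                raise ValidationError(f"unknown annotation label {label!r}") from exc
        delta = sample - prev
        if delta < 0:
            raise ValidationError("annotation sample indices must be nondecreasing")
        if delta > 0x3FF:
            words += int(_SKIP << 10).to_bytes(2, "little")
            words += bytes(
                [(delta >> 16) & 0xFF, (delta >> 24) & 0xFF, delta & 0xFF, (delta >> 8) & 0xFF]
            )
            delta = 0
        words += int((code << 10) | delta).to_bytes(2, "little")
        prev = sample
    words += b"\x00\x00"
    path.write_bytes(bytes(words))


def write_wfdb_record(
    record: ECGRecord,
    directory,
    fmt: int = 212,
    lead_names: Optional[Sequence[str]] = None,
    adc_gain: float = DEFAULT_ADC_GAIN,
) -> Path:
    """Write `record` as a WFDB header/data(/annotation) triplet.

    Returns the header path.  Samples are stored as integers; callers are
    responsible for any physical-to-ADC quantization beforehand.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    if lead_names is None:
        lead_names = [f"lead{i}" for i in range(record.n_leads)]

    leads = [np.round(np.asarray(lead)).astype(np.int64) for lead in record.leads]
    interleaved = np.empty(record.n_leads * record.n_samples, dtype=np.int64)
    for i, lead in enumerate(leads):
        interleaved[i :: record.n_leads] = lead

    dat_path = directory / f"{name}.dat"
    if fmt == 212:
        adc_res = 12
        _pack_212(interleaved).tofile(dat_path)
    elif fmt == 16:
        adc_res = 16
        if interleaved.min() < -(1 << 15) or interleaved.max() >= 1 << 15:
            raise ValidationError("format 16 samples must fit in 16 bits")
        interleaved.astype("<i2").tofile(dat_path)
    else:
        raise ValidationError(f"unsupported WFDB signal format {fmt}")

    fs_txt = f"{record.sampling_rate:g}"
    lines = [f"{name} {record.n_leads} {fs_txt} {record.n_samples}"]
    for lead, lead_name in zip(leads, lead_names):
        init = int(lead[0]) if len(lead) else 0
        lines.append(
            f"{name}.dat {fmt} {adc_gain:g}(0)/mV {adc_res} 0 "
            f"{init} {_wfdb_checksum(lead)} 0 {lead_name}"
        )
    header_path = directory / f"{name}.hea"
    header_path.write_text("\n".join(lines) + "\n")

    if record.annotations:
        _write_annotations(directory / f"{name}.atr", record.annotations)
    return header_path


# ---------------------------------------------------------------------------
# Lead extraction, windowing, normalization
# ---------------------------------------------------------------------------


def extract_lead(
    record: ECGRecord, lead_index: int = 0, adc_gain: float = DEFAULT_ADC_GAIN
) -> np.ndarray:
    """Return one lead as physical values: ``raw / adc_gain``.

    Only a single lead is used for training; the default is the record's
    first signal (MLII in most MIT-BIH records).
    """
    if not 0 <= lead_index < record.n_leads:
        raise IndexError(
            f"lead_index {lead_index} out of range for {record.n_leads} leads"
        )
    return np.asarray(record.leads[lead_index], dtype=np.float64) / adc_gain


def segment_windows(
    sequence: np.ndarray,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    hop: Optional[int] = None,
    source_record: str = "",
) -> List[SequenceWindow]:
    """Cut `sequence` into fixed-length windows starting at 0, hop, 2*hop, ...

    Any trailing partial window is discarded; a sequence shorter than one
    window yields an empty list.  With ``hop == window_length`` (the
    default) the windows tile a prefix of the input without overlap.
    """
    if window_length < 1:
        raise ValidationError(f"window_length must be >= 1, got {window_length}")
    if hop is None:
        hop = window_length
    if hop < 1:
        raise ValidationError(f"hop must be >= 1, got {hop}")
    sequence = np.asarray(sequence, dtype=np.float64)
    windows = []
    for start in range(0, len(sequence) - window_length + 1, hop):
        windows.append(
            SequenceWindow(
                values=sequence[start : start + window_length].copy(),
                source_record=source_record,
                start_index=start,
            )
        )
    return windows


def minmax_normalize(sequence: np.ndarray, mode: str = "unit") -> np.ndarray:
    """Affine min-max rescaling of a sequence.

    mode="unit" (default) maps min -> 0 and max -> 1.  mode="as_printed"
    computes (x - x_max) / (x_max - x_min), mapping max -> 0 and min -> -1;
    it is kept for fidelity with the published formula, whose numerator is
    almost certainly a sign typo for standard [0, 1] scaling.
    """
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.size == 0:
        raise ValidationError("cannot normalize an empty sequence")
    lo, hi = sequence.min(), sequence.max()
    if hi == lo:
        raise DegenerateInputError(
            "cannot min-max normalize a constant sequence (max == min)"
        )
    if mode == "unit":
        return (sequence - lo) / (hi - lo)
    if mode == "as_printed":
        return (sequence - hi) / (hi - lo)
    raise ValidationError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Delimited text + JSON sidecar
# ---------------------------------------------------------------------------


def write_sequence_text(path, values: np.ndarray, metadata: Optional[dict] = None) -> Path:
    """Write one sample per line, plus a JSON sidecar with provenance."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float64)
    np.savetxt(path, values, fmt="%.10g")
    sidecar = dict(metadata or {})
    sidecar.setdefault("n_samples", int(values.size))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_sequence_text(path) -> Tuple[np.ndarray, dict]:
    """Read a one-sample-per-line (or single-column CSV) sequence file and
    its JSON sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sequence file not found: {path}")
    try:
        values = np.loadtxt(path, delimiter=None, ndmin=1)
    except ValueError:
        try:
            values = np.loadtxt(path, delimiter=",", ndmin=1)
        except ValueError as exc:
            raise FormatError(f"cannot parse numeric sequence from {path}") from exc
    if values.ndim > 1:
        values = values[:, 0]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return values.astype(np.float64), metadata
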