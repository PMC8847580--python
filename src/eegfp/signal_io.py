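"""Reading and writing EEG recordings and fingerprint stores.

Supports the European Data Format (EDF) for real recordings, an NPZ container
for synthetic recordings and fixtures, and a versioned JSON container for
enrollment (fingerprint) stores.  Channel labels are normalized to bare
10-10 montage names (``"Oz.."`` -> ``"Oz"``) so channel selections match
across datasets.

The EDF reader/writer here is intentionally minimal: continuous signals only,
one shared sampling rate, no EDF+ annotations or event channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ChannelLookupError,
    FormatError,
    ShapeError,
    UnsupportedInputError,
)

__all__ = [
    "EegRecording",
    "MontageMap",
    "MONTAGE_64",
    "COMMERCIAL_20",
    "normalize_label",
    "read_edf",
    "write_edf",
    "read_array",
    "write_array",
    "save_fingerprint_store",
    "load_fingerprint_store",
]

# 64-electrode international 10-10 layout as used by 64-channel research caps
# (labels listed frontal to occipital).
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "Af7", "Af3", "Afz", "Af4", "Af8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "Ft7", "Fc5", "Fc3", "Fc1", "Fcz", "Fc2", "Fc4", "Fc6", "Ft8",
    "T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10",
    "Tp7", "Cp5", "Cp3", "Cp1", "Cpz", "Cp2", "Cp4", "Cp6", "Tp8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po3", "Poz", "Po4", "Po8",
    "O1", "Oz", "O2",
    "Iz",
)

# 20-label subset reachable by common commercial headsets (consumer 14-channel
# layouts plus the standard midline/central positions).  Contains the
# occipital/temporal/central labels a rest-state channel search needs.
COMMERCIAL_20: tuple[str, ...] = (
    "Af3", "Af4", "F7", "F3", "Fz", "F4", "F8",
    "Fc5", "Fc6", "T7", "C3", "Cz", "C4", "T8",
    "P7", "Pz", "P8", "O1", "Oz", "O2",
)

_CANONICAL = {label.upper(): label for label in MONTAGE_64}

_REGIONS = {
    "FP": "prefrontal", "AF": "anterior-frontal", "F": "frontal",
    "FT": "fronto-temporal", "FC": "fronto-central", "T": "temporal",
    "C": "central", "TP": "temporo-parietal", "CP": "centro-parietal",
    "P": "parietal", "PO": "parieto-occipital", "O": "occipital",
    "I": "inion",
}


def normalize_label(label: str) -> str:
    """Normalize an EDF channel label to its bare 10-10 montage form.

    Strips whitespace and trailing periods (Physionet pads labels with dots,
    e.g. ``"Oz.."``) and canonicalizes case against the 64-electrode montage.
    Labels outside the montage are returned stripped but otherwise untouched.
    Idempotent.
    """
    cleaned = label.strip().strip(".").strip()
    return _CANONICAL.get(cleaned.upper(), cleaned)


def _position_of(label: str) -> str:
    """Scalp position identifier for a montage label, e.g. ``occipital/midline``."""
    head = "".join(ch for ch in label if ch.isalpha() and ch.lower() != "z")
    tail = label[len(head):]
    region = _REGIONS.get(head.upper(), "unknown")
    if label.lower().endswith("z") or not tail:
        side = "midline"
    else:
        side = "left" if int(tail) % 2 == 1 else "right"
    return f"{region}/{side}"


@dataclass(frozen=True)
class MontageMap:
    """Label -> scalp-position map for an electrode montage, with a
    designated commercial subset usable by consumer headsets."""

    positions: dict[str, str]
    commercial_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in self.commercial_subset if c not in self.positions]
        if missing:
            raise ChannelLookupError(
                f"commercial subset labels not in montage: {missing}"
            )

    @classmethod
    def standard_1010(cls) -> "MontageMap":
        return cls(
            positions={lb: _position_of(lb) for lb in MONTAGE_64},
            commercial_subset=COMMERCIAL_20,
        )

    def resolve(self, label: str) -> str:
        key = normalize_label(label)
        if key not in self.positions:
            raise ChannelLookupError(f"label {label!r} not in montage")
        return self.positions[key]

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self.positions


@dataclass
class EegRecording:
    """One subject's multi-channel EEG signal.

    ``data`` has shape ``(n_channels, n_samples)`` in recorded physical
    units, kept in double precision because downstream orthogonalization is
    numerically sensitive.  ``meta`` carries free-form provenance such as the
    session index of a synthetic cohort.
    """

    subject_id: str
    sample_rate_hz: float
    channel_names: list[str]
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError(f"data must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ShapeError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ShapeError("channel names must be unique")
        if self.data.shape[1] < 1:
            raise ShapeError("recording must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise ShapeError("sample_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Signal of one channel by (normalized) label."""
        key = normalize_label(label)
        try:
            idx = self.channel_names.index(key)
        except ValueError:
            raise ChannelLookupError(
                f"channel {label!r} not in recording "
                f"(has {self.channel_names})"
            ) from None
        return self.data[idx]

    def select(self, labels: list[str] | tuple[str, ...]) -> np.ndarray:
        """Sub-matrix of channels in the given order, shape (len(labels), n_samples)."""
        return np.stack([self.channel(lb) for lb in labels])

    def slice_samples(self, start: int, stop: int) -> "EegRecording":
        """Recording restricted to the half-open sample range [start, stop)."""
        return EegRecording(
            subject_id=self.subject_id,
            sample_rate_hz=self.sample_rate_hz,
            channel_names=list(self.channel_names),
            data=self.data[:, start:stop].copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# EDF (European Data Format)
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def write_edf(path, recording: EegRecording) -> None:
    """Write a recording as a minimal single-record EDF file.

    Signals are quantized to 16-bit integers against per-channel physical
    extrema, so round-tripping preserves data to EDF's format precision
    (~1/65535 of the channel range).
    """
    data = recording.data
    ns = recording.n_channels
    n_samples = recording.n_samples
    duration = n_samples / recording.sample_rate_hz

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max <= phys_min
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _ascii("0", 8),
        _ascii(recording.subject_id, 80),
        _ascii("eegfp", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(1, 8),
        _ascii(f"{duration:g}"[:8], 8),
        _ascii(ns, 4),
    ])

    def field_block(width: int, values) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    header += field_block(16, recording.channel_names)
    header += field_block(80, [""] * ns)
    header += field_block(8, ["uV"] * ns)
    header += field_block(8, [f"{v:.6g}"[:8] for v in phys_min])
    header += field_block(8, [f"{v:.6g}"[:8] for v in phys_max])
    header += field_block(8, [dig_min] * ns)
    header += field_block(8, [dig_max] * ns)
    header += field_block(80, [""] * ns)
    header += field_block(8, [n_samples] * ns)
    header += field_block(32, [""] * ns)

    # re-read the 8-char physical extrema exactly as a reader will parse them,
    # so quantization is consistent with the stored header
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # one record, signals sequential


def read_edf(path) -> EegRecording:
    """Read a continuous EDF file into an :class:`EegRecording`.

    All signals must share one sampling rate (equal samples-per-record);
    EDF+ annotations and event channels are not supported.  Channel labels
    are normalized to bare montage form.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")

    def text(offset: int, width: int) -> str:
        return raw[offset:offset + width].decode("ascii", "replace").strip()

    try:
        header_bytes = int(text(184, 8))
        n_records = int(text(236, 8))
        record_duration = float(text(244, 8))
        ns = int(text(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
    if ns < 1 or header_bytes != 256 * (ns + 1) or len(raw) < header_bytes:
        raise FormatError(f"{path}: inconsistent EDF header")

    def signal_fields(width: int, base: int):
        start = 256 + base
        return [text(start + i * width, width) for i in range(ns)]

    labels = signal_fields(16, 0)
    base = ns * 16 + ns * 80 + ns * 8
    try:
        phys_min = [float(v) for v in signal_fields(8, base)]
        phys_max = [float(v) for v in signal_fields(8, base + ns * 8)]
        dig_min = [int(v) for v in signal_fields(8, base + ns * 16)]
        dig_max = [int(v) for v in signal_fields(8, base + ns * 24)]
        spr = [int(v) for v in signal_fields(8, base + ns * 32 + ns * 80)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed signal header: {exc}") from exc

    if len(set(spr)) != 1:
        raise UnsupportedInputError(
            f"{path}: mixed per-channel sampling rates are not supported "
            f"(samples per record: {sorted(set(spr))})"
        )
    samples_per_record = spr[0]
    if record_duration <= 0:
        raise FormatError(f"{path}: non-positive record duration")
    sample_rate = samples_per_record / record_duration

    expected = header_bytes + n_records * ns * samples_per_record * 2
    if len(raw) < expected:
        raise FormatError(f"{path}: truncated EDF data section")

    records = np.frombuffer(
        raw, dtype="<i2", count=n_records * ns * samples_per_record,
        offset=header_bytes,
    ).reshape(n_records, ns, samples_per_record)
    digital = np.concatenate(records, axis=1).astype(np.float64)

    pmin = np.asarray(phys_min)
    pmax = np.asarray(phys_max)
    dmin = np.asarray(dig_min, dtype=np.float64)
    dmax = np.asarray(dig_max, dtype=np.float64)
    span = np.where(dmax > dmin, dmax - dmin, 1.0)
    data = (digital - dmin[:, None]) * ((pmax - pmin) / span)[:, None] + pmin[:, None]

    return EegRecording(
        subject_id=path.stem,
        sample_rate_hz=sample_rate,
        channel_names=[normalize_label(lb) for lb in labels],
        data=data,
    )


# ---------------------------------------------------------------------------
# NPZ array container (synthetic recordings, fixtures)
# ---------------------------------------------------------------------------

def write_array(path, recording: EegRecording) -> None:
    """Persist a recording in the package's NPZ container."""
    np.savez(
        path,
        data=recording.data,
        sample_rate_hz=np.float64(recording.sample_rate_hz),
        channel_names=np.array(recording.channel_names, dtype=object),
        subject_id=np.array(recording.subject_id, dtype=object),
        meta=np.array(json.dumps(recording.meta), dtype=object),
    )


def read_array(path, sample_rate_hz: float | None = None,
               channel_names: list[str] | None = None) -> EegRecording:
    """Load a recording from the NPZ container or a bare numeric matrix.

    For a bare ``.npy``/text matrix (rows = channels), ``sample_rate_hz`` and
    ``channel_names`` must be supplied.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=True) as npz:
            meta = json.loads(str(npz["meta"])) if "meta" in npz else {}
            return EegRecording(
                subject_id=str(npz["subject_id"]),
                sample_rate_hz=float(npz["sample_rate_hz"]),
                channel_names=[str(c) for c in npz["channel_names"]],
                data=npz["data"],
                meta=meta,
            )
    if sample_rate_hz is None or channel_names is None:
        raise FormatError(
            "bare matrices require explicit sample_rate_hz and channel_names"
        )
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        try:
            data = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if data.shape[0] != len(channel_names):
        raise ShapeError(
            f"matrix has {data.shape[0]} rows but {len(channel_names)} "
            "channel names were given"
        )
    return EegRecording(
        subject_id=path.stem,
        sample_rate_hz=sample_rate_hz,
        channel_names=[normalize_label(c) for c in channel_names],
        data=data,
    )


# ---------------------------------------------------------------------------
# Fingerprint store container (versioned JSON: identity -> vector + metadata)
# ---------------------------------------------------------------------------

STORE_FORMAT = "eegfp-store"
STORE_VERSION = 1


def save_fingerprint_store(path, model_version: str, entries: dict) -> None:
    """Serialize an identity -> fingerprint table.

    ``entries`` maps identity to a dict with keys ``fingerprint`` (list of
    floats), ``channels``, and ``params``.  Only fixed-length fingerprints are
    written — never raw signals or model inputs.
    """
    payload = {
        "format": STORE_FORMAT,
        "version": STORE_VERSION,
        "model_version": model_version,
        "entries": {
            identity: {
                "fingerprint": [float(v) for v in entry["fingerprint"]],
                "channels": list(entry["channels"]),
                "params": dict(entry["params"]),
            }
            for identity, entry in entries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_fingerprint_store(path) -> tuple[str, dict]:
    """Load a fingerprint store; returns ``(model_version, entries)``."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read store {path}: {exc}") from exc
    if payload.get("format") != STORE_FORMAT:
        raise FormatError(f"{path} is not an eegfp fingerprint store")
    if payload.get("version") != STORE_VERSION:
        raise FormatError(
            f"unsupported store version {payload.get('version')!r}"
        )
    return payload["model_version"], payload["entries"]
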