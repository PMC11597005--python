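"""Readers and writers for the formats the sleep-qEEG pipeline touches.

Recordings travel as EDF (European Data Format), hypnograms as plain-text
or CSV stage files, the montage as a small CSV, and all analysis outputs
as CSV/JSON tables.  Everything is coerced to microvolts at read time so
that downstream power thresholds (stated in μV²) apply directly.
"""

from __future__ import annotations

import datetime as _dt
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Hypnogram",
    "Montage",
    "FormatError",
    "MontageError",
    "HypnogramParseError",
    "STAGES",
    "read_recording",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_montage",
    "write_montage",
    "default_montage",
    "write_table",
    "read_table",
]

#: Canonical sleep-stage alphabet (wake + AASM sleep stages).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

#: Scored-epoch length in seconds.
SCORED_EPOCH_S: float = 30.0

#: Accepted spellings for each stage token, upper-cased before lookup.
STAGE_TOKEN_MAP: dict[str, str] = {
    "W": "W", "WK": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "SWS": "N3", "3": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
}

MODALITIES: tuple[str, ...] = ("TCRE", "EEG")


class FormatError(ValueError):
    """An input file violates its declared format."""


class MontageError(KeyError):
    """A channel label cannot be resolved through the montage."""


class HypnogramParseError(FormatError):
    """A stage file contains a token outside the 5-stage alphabet."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multi-channel scalp time series in μV.

    Parameters
    ----------
    channel_labels
        One label per row of ``data`` (10–20 site names, e.g. ``"Cz"`` for a
        focal channel or ``"Cz-M1"`` for a referenced EEG derivation).
    channel_modality
        Per channel, ``"TCRE"`` or ``"EEG"``.
    sample_rate
        Sampling frequency in Hz.
    data
        ``(n_channels, n_samples)`` array, microvolts.
    start_time
        Recording start timestamp.
    """

    channel_labels: list[str]
    channel_modality: list[str]
    sample_rate: float
    data: np.ndarray
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 22, 0, 0)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch:
            raise ValueError("one label per channel required")
        if len(self.channel_modality) != n_ch:
            raise ValueError("one modality tag per channel required")
        bad = set(self.channel_modality) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modality tags: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]


@dataclass
class Hypnogram:
    """Ordered 30-s sleep-stage labels aligned to the recording start."""

    stages: list[str]
    epoch_length: float = SCORED_EPOCH_S

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    def __getitem__(self, i: int) -> str:
        return self.stages[i]

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_length


@dataclass
class Montage:
    """Maps recorded channel labels to 10–20 sites and scalp coordinates.

    ``positions`` holds a unit-disc 2-D projection per site (x to the
    right, y toward the nasion).  ``channels`` maps each recordable channel
    label to its ``(site, modality)``, which pairs each focal channel with
    its conventional counterpart at the same site.
    """

    positions: dict[str, tuple[float, float]]
    channels: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for site, (x, y) in self.positions.items():
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"site {site} outside the unit disc")
        for label, (site, modality) in self.channels.items():
            if site not in self.positions:
                raise MontageError(f"channel {label}: unknown site {site}")
            if modality not in MODALITIES:
                raise ValueError(f"channel {label}: bad modality {modality}")

    @property
    def sites(self) -> list[str]:
        return list(self.positions)

    def site_of(self, label: str) -> str:
        try:
            return self.channels[label][0]
        except KeyError:
            raise MontageError(f"channel label {label!r} not in montage") from None

    def modality_of(self, label: str) -> str:
        try:
            return self.channels[label][1]
        except KeyError:
            raise MontageError(f"channel label {label!r} not in montage") from None

    def labels_for(self, modality: str) -> list[str]:
        return [c for c, (_, m) in self.channels.items() if m == modality]


# Approximate 2-D unit-disc projection of the 18 recorded 10–20 sites.
_SITE_XY: dict[str, tuple[float, float]] = {
    "Fpz": (0.00, 0.90), "Fp1": (-0.28, 0.86), "Fp2": (0.28, 0.86),
    "F7": (-0.73, 0.53), "F3": (-0.34, 0.46), "Fz": (0.00, 0.45),
    "F4": (0.34, 0.46), "F8": (0.73, 0.53),
    "T3": (-0.90, 0.00), "C3": (-0.45, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.45, 0.00), "T4": (0.90, 0.00),
    "P3": (-0.34, -0.46), "Pz": (0.00, -0.45), "P4": (0.34, -0.46),
    "O1": (-0.28, -0.86), "O2": (0.28, -0.86),
}

DEFAULT_SITES: tuple[str, ...] = tuple(_SITE_XY)


def default_montage(sites: Sequence[str] = DEFAULT_SITES,
                    eeg_reference: str = "M1") -> Montage:
    """Standard dual-modality montage over the given 10–20 sites.

    The focal channel at a site carries the bare site label; the paired
    conventional derivation is ``<site>-<eeg_reference>``.
    """
    positions = {}
    channels = {}
    for site in sites:
        if site not in _SITE_XY:
            raise MontageError(f"no default coordinate for site {site!r}")
        positions[site] = _SITE_XY[site]
        channels[site] = (site, "TCRE")
        channels[f"{site}-{eeg_reference}"] = (site, "EEG")
    return Montage(positions=positions, channels=channels)


def write_montage(montage: Montage, path: str | Path) -> Path:
    """Serialise a montage as CSV (channel, site, x, y, modality)."""
    rows = []
    for label, (site, modality) in montage.channels.items():
        x, y = montage.positions[site]
        rows.append({"channel": label, "site": site, "x": x, "y": y,
                     "modality": modality})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_montage(path: str | Path) -> Montage:
    df = pd.read_csv(path)
    required = {"channel", "site", "x", "y", "modality"}
    if not required.issubset(df.columns):
        raise FormatError(f"montage file must have columns {sorted(required)}")
    positions = {}
    channels = {}
    for row in df.itertuples(index=False):
        positions[row.site] = (float(row.x), float(row.y))
        channels[row.channel] = (row.site, row.modality)
    return Montage(positions=positions, channels=channels)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path,
              physical_unit: str = "uV") -> Path:
    """Write a Recording as plain EDF with 1-s data records.

    Signals are quantised to 16 bits over a symmetric physical range just
    covering the data; a trailing partial second is discarded (EDF records
    must be whole).  Requires an integer sample rate.
    """
    path = Path(path)
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    n_ch = recording.n_channels
    data = recording.data[:, : n_records * fs]
    scale = 1.0 / _UNIT_TO_UV[physical_unit]  # μV -> declared unit

    phys_max = np.maximum(np.abs(data).max(axis=1) * scale, 1e-4)
    # round the range up to 7 significant characters so the header is exact
    phys_max = np.array([float(f"{v:.6g}") * 1.0000001 for v in phys_max])
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    start = recording.start_time
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field(start.strftime("%d.%m.%y"), 8)
    header += _edf_field(start.strftime("%H.%M.%S"), 8)
    header += _edf_field(str(256 * (n_ch + 1)), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)
    header += _edf_field(str(n_ch), 4)

    def block(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += block(recording.channel_labels, 16)
    header += block([""] * n_ch, 80)                       # transducer
    header += block([physical_unit] * n_ch, 8)
    header += block([f"{v:.6g}"[:8] for v in phys_min], 8)
    header += block([f"{v:.6g}"[:8] for v in phys_max], 8)
    header += block([str(dig_min)] * n_ch, 8)
    header += block([str(dig_max)] * n_ch, 8)
    header += block([""] * n_ch, 80)                       # prefiltering
    header += block([str(fs)] * n_ch, 8)
    header += block([""] * n_ch, 32)

    # re-parse the headers we wrote so quantisation matches a reader exactly
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)
    offset = pmin - dig_min * gain

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            seg = data[:, rec * fs:(rec + 1) * fs] * scale
            dig = np.rint((seg - offset[:, None]) / gain[:, None])
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())
    return path


def _edf_samples_per_record(path: Path) -> tuple[list[str], list[int]]:
    """Channel labels and per-channel samples/record from the EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: bad channel count field") from exc
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise FormatError(f"{path}: truncated EDF signal headers")
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
              for i in range(n_ch)]
    off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = []
    for i in range(n_ch):
        fldo = off + 8 * i
        try:
            spr.append(int(sig[fldo:fldo + 8].decode("ascii").strip()))
        except ValueError as exc:
            raise FormatError(f"{path}: bad samples-per-record field") from exc
    return labels, spr


def read_recording(path: str | Path, montage: Montage) -> Recording:
    """Read an EDF file, tag channels by modality, convert to μV.

    All analysed channels (those resolvable through the montage) must share
    one sample rate; per-channel rates are checked against the EDF header
    before the data are loaded through MNE.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, spr = _edf_samples_per_record(path)
    for label in labels:
        if label not in montage.channels:
            raise MontageError(f"channel label {label!r} not in montage")
    analysed_spr = {s for lab, s in zip(labels, spr) if lab in montage.channels}
    if len(analysed_spr) > 1:
        raise FormatError(
            f"{path}: analysed channels have mixed sample rates {sorted(analysed_spr)}"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    data_uv = raw.get_data() * 1e6  # MNE returns SI volts
    meas = raw.info.get("meas_date")
    start = (meas.replace(tzinfo=None) if meas is not None
             else _dt.datetime(2000, 1, 1))
    ch_names = list(raw.ch_names)
    return Recording(
        channel_labels=ch_names,
        channel_modality=[montage.modality_of(c) for c in ch_names],
        sample_rate=float(raw.info["sfreq"]),
        data=data_uv,
        start_time=start,
    )


# ---------------------------------------------------------------------------
# Hypnogram files
# ---------------------------------------------------------------------------

def _normalise_token(token: str, lineno: int) -> str:
    stage = STAGE_TOKEN_MAP.get(token.strip().upper())
    if stage is None:
        raise HypnogramParseError(
            f"line {lineno}: unknown stage token {token.strip()!r}"
        )
    return stage


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Parse a stage file: one token per line, or CSV with a stage column.

    Tokens are normalised through a fixed map (``Wake``/``W``/``0`` → W,
    ``R``/``REM``/``5`` → REM, ...); anything else raises
    :class:`HypnogramParseError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty hypnogram file")
    lines = text.splitlines()
    stages: list[str] = []
    if "," in lines[0]:
        # CSV dialect: last column is the stage; a non-numeric first row
        # that fails token lookup on every column is treated as a header.
        start = 0
        first = [t.strip() for t in lines[0].split(",")]
        if all(t.upper() not in STAGE_TOKEN_MAP for t in first):
            start = 1
        if start == len(lines):
            raise FormatError(f"{path}: no stage rows")
        for i, line in enumerate(lines[start:], start=start + 1):
            token = line.split(",")[-1]
            stages.append(_normalise_token(token, i))
    else:
        for i, line in enumerate(lines, start=1):
            if line.strip():
                stages.append(_normalise_token(line, i))
    return Hypnogram(stages=stages)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(hypnogram.stages) + "\n")
    return path


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path,
                format: str | None = None) -> Path:
    """Write a table as CSV or JSON with lossless numeric round-trip.

    Floats are written with 17 significant digits; non-finite values
    serialise as ``inf``/``-inf``/``nan`` (CSV) or ``Infinity``/``NaN``
    (JSON) and are recovered by :func:`read_table`.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    format = format.lower()
    if len(records) == 0:
        raise ValueError("refusing to write an empty table")
    if format == "csv":
        records.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = records.to_dict(orient="list")
        clean = {
            k: [v.item() if isinstance(v, np.generic) else v for v in col]
            for k, col in payload.items()
        }
        with open(path, "w") as fh:
            json.dump(clean, fh, allow_nan=True, indent=1)
    else:
        raise ValueError(f"unknown table format {format!r}")
    return path


def read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format.lower() == "csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
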