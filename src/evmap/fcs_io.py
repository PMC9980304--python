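"""Reading and writing FCS event data, acquisition metadata, and QC.

Flow Cytometry Standard (FCS) files hold one row per detected event and one
column per optical channel.  For EV microflow cytometry the channels of
interest are a large-angle light scatter (LALS) channel and two fluorescence
marker channels.  This module reads FCS 3.0/3.1, writes FCS 3.1 (list mode,
single float32 data segment), attaches acquisition metadata from a sidecar
manifest, groups per-patient replicates, and applies the event-rate QC
window: replicates acquired outside 400–20 000 events·s⁻¹ are flagged and
excluded from all downstream stages.

Flow rate, acquisition duration and dilution are deliberately taken from the
manifest rather than from instrument-specific FCS keywords, which are not
reliable across vendors.  If a recognized keyword conflicts with the
manifest, the manifest wins and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default QC window on the event rate (events per second).
QC_RATE_LO = 400.0
QC_RATE_HI = 20_000.0

#: qc_status values for a replicate.
QC_PASS = "pass"
QC_TOO_SLOW = "too_slow"
QC_TOO_FAST = "too_fast"
QC_UNKNOWN = "unknown"


class FCSFormatError(ValueError):
    """Raised when a file cannot be parsed as FCS 3.0/3.1."""


class SchemaError(ValueError):
    """Raised when declared channels are absent or inconsistent."""


@dataclass(frozen=True)
class ChannelSchema:
    """Ordered channel labels plus a role map (scatter / marker1 / marker2).

    Parameters
    ----------
    names:
        Ordered channel labels, e.g. ``("LALS", "PSMA", "Ghrelin")``.
    roles:
        Map from semantic role to channel label.  The conventional roles are
        ``scatter``, ``marker1`` and ``marker2``.
    """

    names: tuple[str, ...]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate channel labels in {names}")
        for role, label in dict(self.roles).items():
            if label not in names:
                raise SchemaError(
                    f"role {role!r} maps to unknown channel {label!r}"
                )
        object.__setattr__(self, "roles", dict(self.roles))

    def __len__(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise SchemaError(f"channel {label!r} not in schema {self.names}")


def default_schema() -> ChannelSchema:
    """The three-channel EV schema used throughout: LALS + two markers."""
    return ChannelSchema(
        names=("LALS", "PSMA", "Ghrelin"),
        roles={"scatter": "LALS", "marker1": "PSMA", "marker2": "Ghrelin"},
    )


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings for one FCS file.

    ``flow_rate_ul_min`` is the sample flow rate in μL·min⁻¹ (3.01 on the
    instrument used to define the defaults), ``duration_s`` the acquisition
    time in seconds, and ``dilution_factor`` the fold-dilution of the
    original plasma (≥ 1).
    """

    flow_rate_ul_min: float = 3.01
    duration_s: float = 120.0
    dilution_factor: float = 100.0
    replicate_id: int = 0
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.flow_rate_ul_min > 0:
            raise ValueError("flow_rate_ul_min must be > 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not self.dilution_factor >= 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def analysed_volume_ml(self) -> float:
        """Volume of diluted sample analysed, in mL."""
        return self.flow_rate_ul_min * (self.duration_s / 60.0) * 1e-3


@dataclass
class EventTable:
    """Per-event channel intensities for one acquisition.

    ``intensities`` is an (events × channels) array of finite, non-negative
    reals in the order given by ``schema.names``.  Raw intensities live
    here; the log transform happens at binning time.
    """

    intensities: np.ndarray
    schema: ChannelSchema
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            arr = arr.reshape(-1, len(self.schema))
        if arr.shape[1] != len(self.schema):
            raise SchemaError(
                f"{arr.shape[1]} columns but schema has {len(self.schema)} channels"
            )
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("event intensities must be finite")
        self.intensities = arr

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    def channel(self, label: str) -> np.ndarray:
        return self.intensities[:, self.schema.index(label)]


def event_rate(table: EventTable) -> float:
    """Events per second: row count divided by acquisition duration."""
    return table.n_events / table.meta.duration_s


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 binary format
# ---------------------------------------------------------------------------

_HEADER_LEN = 58


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write an :class:`EventTable` as an FCS 3.1 file.

    List mode, one float32 little-endian data segment, channel names stored
    as ``$PnN``.  Readable by :func:`read_fcs` and by mainstream FCS
    parsers.
    """
    path = Path(path)
    data = np.ascontiguousarray(table.intensities, dtype="<f4")
    n_events, n_par = data.shape

    delim = "/"
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        # zero-padded placeholders keep the text length fixed while the
        # actual offsets are filled in below
        ("$BEGINDATA", "%012d"),
        ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
    ]
    for i, name in enumerate(table.schema.names, start=1):
        if delim in name:
            raise SchemaError(f"channel name {name!r} contains the delimiter")
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1.0, float(data[:, i - 1].max() if n_events else 1.0))) + 1)),
        ]

    def render(begin_data: int, end_data: int) -> bytes:
        parts = [delim]
        for key, val in keywords:
            if val == "%012d":
                val = "%012d" % (begin_data if key == "$BEGINDATA" else end_data)
            parts += [key, delim, val, delim]
        return "".join(parts).encode("ascii")

    text_start = _HEADER_LEN
    text_len = len(render(0, 0))
    text_end = text_start + text_len - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1 if data.nbytes else 0
    text = render(data_start, data_end)

    def hdr_field(value: int) -> bytes:
        s = str(value)
        if len(s) > 8:  # offset too wide for the header; 0 defers to TEXT
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1" + b" " * 4
    header += hdr_field(text_start) + hdr_field(text_end)
    if data.nbytes and data_end <= 99_999_999:
        header += hdr_field(data_start) + hdr_field(data_end)
    else:
        header += hdr_field(data_start if data.nbytes else 0) + hdr_field(0)
    header += hdr_field(0) + hdr_field(0)
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # Escaped (doubled) delimiters are not produced by this package and are
    # rare in the wild; they are not un-escaped here.
    parts = body.split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    kv: dict[str, str] = {}
    for i in range(0, len(parts) - 1, 2):
        kv[parts[i].strip().upper()] = parts[i + 1]
    return kv


def read_fcs(
    path: str | Path,
    meta: AcquisitionMeta | None = None,
    schema: ChannelSchema | None = None,
) -> EventTable:
    """Read an FCS 3.0 or 3.1 file into an :class:`EventTable`.

    Parameters
    ----------
    path:
        FCS file to read.
    meta:
        Acquisition metadata to attach (from the manifest).  Defaults to the
        standard settings if omitted.
    schema:
        Expected channels.  When given, the declared channels must all be
        present in the file; columns are returned in schema order.  When
        omitted, the file's own ``$PnN`` labels define the schema.

    Raises
    ------
    FCSFormatError
        If the file is not parseable FCS 3.0/3.1.
    SchemaError
        If a declared channel is missing (the error names the channel).
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FCSFormatError(f"{path}: file shorter than an FCS header")
    version = blob[0:6].decode("latin-1", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def hdr_int(lo: int, hi: int) -> int:
        s = blob[lo:hi].decode("latin-1").strip()
        return int(s) if s else 0

    text_start, text_end = hdr_int(10, 18), hdr_int(18, 26)
    data_start, data_end = hdr_int(26, 34), hdr_int(34, 42)
    if text_end <= text_start:
        raise FCSFormatError(f"{path}: invalid TEXT segment offsets")
    kv = _parse_text_segment(blob[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(kv.get("$BEGINDATA", "0"))
        data_end = int(kv.get("$ENDDATA", "0"))

    try:
        n_par = int(kv["$PAR"])
        n_tot = int(kv["$TOT"])
        datatype = kv["$DATATYPE"].strip().upper()
        mode = kv.get("$MODE", "L").strip().upper()
        byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from exc
    if mode != "L":
        raise FCSFormatError(f"{path}: only list mode ($MODE L) is supported")
    endian = "<" if byteord.startswith("1") else ">"

    file_names = []
    for i in range(1, n_par + 1):
        file_names.append(kv.get(f"$P{i}N", f"P{i}").strip())

    if n_tot == 0:
        data = np.zeros((0, n_par), dtype=np.float64)
    else:
        if datatype == "F":
            dtype = np.dtype(endian + "f4")
        elif datatype == "D":
            dtype = np.dtype(endian + "f8")
        elif datatype == "I":
            bits = {int(kv.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
            if len(bits) != 1 or bits.pop() not in (16, 32):
                raise FCSFormatError(
                    f"{path}: integer data requires uniform 16- or 32-bit $PnB"
                )
            nbits = int(kv["$P1B"])
            dtype = np.dtype(endian + ("u2" if nbits == 16 else "u4"))
        else:
            raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")
        nbytes = n_tot * n_par * dtype.itemsize
        raw = blob[data_start : data_start + nbytes]
        if len(raw) < nbytes:
            raise FCSFormatError(f"{path}: data segment truncated")
        data = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    if schema is None:
        schema = ChannelSchema(names=tuple(file_names))
    else:
        cols = []
        for name in schema.names:
            if name not in file_names:
                raise SchemaError(
                    f"{path}: declared channel {name!r} not in file channels {file_names}"
                )
            cols.append(file_names.index(name))
        data = data[:, cols]

    if meta is None:
        meta = AcquisitionMeta()
    return EventTable(intensities=data, schema=schema, meta=meta)


# ---------------------------------------------------------------------------
# Replicate grouping and QC
# ---------------------------------------------------------------------------


@dataclass
class Replicate:
    table: EventTable
    qc_status: str = QC_UNKNOWN

    @property
    def rate(self) -> float:
        return event_rate(self.table)


@dataclass
class SampleSet:
    """Per-patient replicate EventTables with QC status per replicate.

    ``replicates`` maps patient_id → list of :class:`Replicate`.  Patient
    order is the insertion order and is preserved by every operation.
    """

    replicates: dict[str, list[Replicate]] = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(self.replicates)

    def add(self, table: EventTable, qc_status: str = QC_UNKNOWN) -> None:
        pid = table.meta.patient_id
        reps = self.replicates.setdefault(pid, [])
        if reps and reps[0].table.schema.names != table.schema.names:
            raise SchemaError(
                f"patient {pid!r}: replicate schema {table.schema.names} differs "
                f"from {reps[0].table.schema.names}"
            )
        reps.append(Replicate(table=table, qc_status=qc_status))

    def pass_replicates(self, patient_id: str) -> list[EventTable]:
        return [
            r.table
            for r in self.replicates.get(patient_id, [])
            if r.qc_status == QC_PASS
        ]

    def patients_with_pass(self) -> list[str]:
        return [p for p in self.patients if self.pass_replicates(p)]

    def iter_pass_tables(self) -> Iterable[EventTable]:
        for pid in self.patients:
            yield from self.pass_replicates(pid)


def qc_filter(
    samples: SampleSet,
    lo: float = QC_RATE_LO,
    hi: float = QC_RATE_HI,
) -> SampleSet:
    """Flag replicates by event rate; nothing is removed, only marked.

    Replicates with rate below ``lo`` are marked ``too_slow``, above ``hi``
    ``too_fast``, otherwise ``pass``.  Downstream stages use only ``pass``
    replicates.  Counts of excluded replicates and of patients left with
    zero usable replicates are logged.
    """
    if not lo < hi:
        raise ValueError(f"QC bounds must satisfy lo < hi, got {lo} >= {hi}")
    out = SampleSet()
    n_slow = n_fast = 0
    zero_pass: list[str] = []
    for pid, reps in samples.replicates.items():
        new_reps = []
        for rep in reps:
            r = rep.rate
            if r < lo:
                status = QC_TOO_SLOW
                n_slow += 1
            elif r > hi:
                status = QC_TOO_FAST
                n_fast += 1
            else:
                status = QC_PASS
            new_reps.append(Replicate(table=rep.table, qc_status=status))
        out.replicates[pid] = new_reps
        if not any(r.qc_status == QC_PASS for r in new_reps):
            zero_pass.append(pid)
    logger.info(
        "QC [%g, %g] ev/s: %d too_slow, %d too_fast, %d patients with zero "
        "usable replicates%s",
        lo,
        hi,
        n_slow,
        n_fast,
        len(zero_pass),
        f" ({zero_pass})" if zero_pass else "",
    )
    return out


# ---------------------------------------------------------------------------
# Manifest: sidecar metadata mapping FCS files to patients/replicates
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "patient_id",
    "replicate_id",
    "path",
    "flow_rate_ul_min",
    "duration_s",
    "dilution",
)


def write_manifest(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    df = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def load_samples(
    manifest_path: str | Path,
    schema: ChannelSchema | None = None,
    base_dir: str | Path | None = None,
) -> SampleSet:
    """Read every FCS file listed in a manifest into a :class:`SampleSet`.

    Paths in the manifest are resolved relative to ``base_dir`` (default:
    the manifest's directory).  QC status is left ``unknown``; apply
    :func:`qc_filter` afterwards.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = read_manifest(manifest_path)
    samples = SampleSet()
    for row in df.itertuples(index=False):
        meta = AcquisitionMeta(
            flow_rate_ul_min=float(row.flow_rate_ul_min),
            duration_s=float(row.duration_s),
            dilution_factor=float(row.dilution),
            replicate_id=int(row.replicate_id),
            patient_id=str(row.patient_id),
        )
        fcs_path = Path(row.path)
        if not fcs_path.is_absolute():
            fcs_path = base / fcs_path
        samples.add(read_fcs(fcs_path, meta=meta, schema=schema))
    return samples
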