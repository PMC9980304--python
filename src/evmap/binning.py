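"""Log-binning of events into a fixed ROI grid and the feature matrix.

Every event's channel intensities are log10-transformed and assigned to a
B × B grid of regions of interest (ROIs) per channel pair (default B = 32,
i.e. 1024 ROIs per bivariate histogram, three pairs → 3072 features).  ROI
counts become particle concentrations per mL of original plasma via the
analysed volume and dilution factor, replicates are averaged, and the
flattened grids are concatenated into a patients × ROIs feature matrix.

Bin edges are equal-width in the log domain over the pooled cohort range
clipped at configurable quantiles, and are *frozen*: new data maps onto the
identical ROIs.  Events outside the edge range clamp into the edge bins, so
binning never drops an event — the QC filter is the only event-dropping
stage.  A fixed rectangular gate (the manual-gating baseline) shares the
same concentration arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from evmap.fcs_io import AcquisitionMeta, EventTable, SampleSet, SchemaError

DEFAULT_BINS = 32
DEFAULT_CLIP = (0.001, 0.999)

#: Default channel pairs by role: scatter–marker1, scatter–marker2,
#: marker1–marker2.
DEFAULT_ROLE_PAIRS = (
    ("scatter", "marker1"),
    ("scatter", "marker2"),
    ("marker1", "marker2"),
)


class DegenerateChannelError(ValueError):
    """All pooled values of a channel are identical; no edges can be fit."""


def log_transform(values: np.ndarray, log_floor: float) -> np.ndarray:
    """log10 with values ≤ 0 replaced by ``log_floor`` (> 0) first.

    The instrument's channels are non-negative; the floor (the smallest
    positive recorded value of the channel) keeps zeros at the bottom of
    the scale without breaking the ordering.
    """
    if not log_floor > 0:
        raise ValueError("log_floor must be positive")
    v = np.asarray(values, dtype=np.float64)
    return np.log10(np.where(v > 0, v, log_floor))


@dataclass(frozen=True)
class BinningSpec:
    """Frozen binning for one channel pair.

    ``edges`` holds, per channel label, B+1 strictly increasing log10-domain
    edge values; ``log_floor`` the per-channel positive substitute for
    non-positive intensities.
    """

    channel_pair: tuple[str, str]
    bins_per_channel: int
    edges: dict[str, np.ndarray]
    log_floor: dict[str, float]

    def __post_init__(self) -> None:
        if self.bins_per_channel < 2:
            raise ValueError("bins_per_channel must be >= 2")
        object.__setattr__(self, "channel_pair", tuple(self.channel_pair))
        edges = {}
        for ch in self.channel_pair:
            if ch not in self.edges:
                raise SchemaError(f"no edges for channel {ch!r}")
            e = np.asarray(self.edges[ch], dtype=np.float64)
            if e.shape != (self.bins_per_channel + 1,):
                raise ValueError(
                    f"channel {ch!r}: expected {self.bins_per_channel + 1} edges, "
                    f"got {e.shape}"
                )
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"channel {ch!r}: edges must strictly increase")
            edges[ch] = e
        object.__setattr__(self, "edges", edges)

    @property
    def n_rois(self) -> int:
        return self.bins_per_channel ** 2

    def to_dict(self) -> dict:
        return {
            "channel_pair": list(self.channel_pair),
            "bins_per_channel": self.bins_per_channel,
            "edges": {ch: e.tolist() for ch, e in self.edges.items()},
            "log_floor": dict(self.log_floor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningSpec":
        return cls(
            channel_pair=tuple(d["channel_pair"]),
            bins_per_channel=int(d["bins_per_channel"]),
            edges={ch: np.asarray(e) for ch, e in d["edges"].items()},
            log_floor={ch: float(v) for ch, v in d["log_floor"].items()},
        )


@dataclass
class ROIGrid:
    """B × B event counts for one replicate under one :class:`BinningSpec`."""

    spec: BinningSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        B = self.spec.bins_per_channel
        if c.shape != (B, B):
            raise ValueError(f"counts shape {c.shape} != ({B}, {B})")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RectGate:
    """Fixed rectangular gate in the log domain, half-open [low, high)."""

    channel_pair: tuple[str, str]
    low: tuple[float, float]
    high: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.low, self.high):
            if not lo < hi:
                raise ValueError(f"gate bounds must satisfy low < high ({lo} >= {hi})")


def _pool_channel(samples: SampleSet, channel: str) -> np.ndarray:
    chunks = [t.channel(channel) for t in samples.iter_pass_tables()]
    if not chunks:
        raise ValueError("no pass replicates in cohort; run qc_filter first")
    return np.concatenate(chunks)


def channel_log_floor(samples: SampleSet, channel: str) -> float:
    """Smallest positive recorded value of a channel over pass replicates."""
    pooled = _pool_channel(samples, channel)
    positive = pooled[pooled > 0]
    if positive.size == 0:
        raise DegenerateChannelError(
            f"channel {channel!r} has no positive values in the cohort"
        )
    return float(positive.min())


def fit_bin_edges(
    samples: SampleSet,
    channel: str,
    B: int = DEFAULT_BINS,
    quantile_clip: tuple[float, float] = DEFAULT_CLIP,
    log_floor: float | None = None,
) -> np.ndarray:
    """Fit B+1 equal-width log10-domain edges for one channel.

    The edge span is the pooled (over all pass replicates) log-intensity
    range clipped at the given quantile pair.  Raises
    :class:`DegenerateChannelError` when the clipped range is empty (all
    values identical).
    """
    if log_floor is None:
        log_floor = channel_log_floor(samples, channel)
    pooled = log_transform(_pool_channel(samples, channel), log_floor)
    lo_q, hi_q = quantile_clip
    lo, hi = np.quantile(pooled, [lo_q, hi_q])
    if not hi > lo:
        raise DegenerateChannelError(
            f"channel {channel!r}: degenerate log range [{lo}, {hi}]"
        )
    return np.linspace(lo, hi, B + 1)


def fit_binning_specs(
    samples: SampleSet,
    B: int = DEFAULT_BINS,
    quantile_clip: tuple[float, float] = DEFAULT_CLIP,
    role_pairs: Sequence[tuple[str, str]] = DEFAULT_ROLE_PAIRS,
) -> list[BinningSpec]:
    """Fit one :class:`BinningSpec` per channel pair on a cohort.

    Channel pairs are resolved from the schema's role map (default:
    scatter–marker1, scatter–marker2, marker1–marker2).  Edges and floors
    for a channel are fit once and shared across the pairs using it.
    """
    tables = list(samples.iter_pass_tables())
    if not tables:
        raise ValueError("no pass replicates in cohort")
    schema = tables[0].schema
    roles = dict(schema.roles)
    if not roles and len(schema.names) >= 3:
        # positional fallback: scatter, marker1, marker2 in channel order
        roles = {
            "scatter": schema.names[0],
            "marker1": schema.names[1],
            "marker2": schema.names[2],
        }
    pairs = [(roles[a], roles[b]) for a, b in role_pairs]
    channels = sorted({ch for pair in pairs for ch in pair})
    floors = {ch: channel_log_floor(samples, ch) for ch in channels}
    edges = {
        ch: fit_bin_edges(samples, ch, B=B, quantile_clip=quantile_clip,
                          log_floor=floors[ch])
        for ch in channels
    }
    return [
        BinningSpec(
            channel_pair=pair,
            bins_per_channel=B,
            edges={ch: edges[ch] for ch in pair},
            log_floor={ch: floors[ch] for ch in pair},
        )
        for pair in pairs
    ]


def _bin_indices(log_values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # interior edges define the bins; out-of-range values clamp to edge bins
    idx = np.searchsorted(edges[1:-1], log_values, side="right")
    return idx  # already in [0, B-1]


def assign_events(table: EventTable, spec: BinningSpec) -> ROIGrid:
    """Assign every event of a replicate to an ROI; no event is dropped."""
    B = spec.bins_per_channel
    ch_x, ch_y = spec.channel_pair
    ix = _bin_indices(
        log_transform(table.channel(ch_x), spec.log_floor[ch_x]), spec.edges[ch_x]
    )
    iy = _bin_indices(
        log_transform(table.channel(ch_y), spec.log_floor[ch_y]), spec.edges[ch_y]
    )
    flat = np.bincount(ix * B + iy, minlength=B * B)
    return ROIGrid(spec=spec, counts=flat.reshape(B, B))


def to_concentration(grid: ROIGrid | np.ndarray, meta: AcquisitionMeta) -> np.ndarray:
    """Convert ROI counts to particles·mL⁻¹ of original plasma.

    Each count is divided by the analysed volume (flow rate × duration) and
    multiplied by the dilution factor.  With the standard settings
    (3.01 μL·min⁻¹ × 120 s = 6.02 μL, 100×), 602 events → 1.0 × 10⁷ mL⁻¹.
    """
    volume_ml = meta.analysed_volume_ml
    if not volume_ml > 0:
        raise ValueError("analysed volume must be positive")
    counts = grid.counts if isinstance(grid, ROIGrid) else np.asarray(grid)
    return counts / volume_ml * meta.dilution_factor


def average_replicates(grids: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean over the pass replicates of a patient."""
    if len(grids) == 0:
        raise ValueError("no pass replicates to average; patient should have "
                         "been dropped upstream")
    stack = np.stack([np.asarray(g, dtype=np.float64) for g in grids])
    return stack.mean(axis=0)


@dataclass
class FeatureMatrix:
    """Patients × ROI-concentration feature matrix.

    ``columns`` carries one ``(channel_pair, row_bin, col_bin)`` triple per
    column; the mapping column-index ↔ triple is bijective.
    """

    patients: list[str]
    values: np.ndarray
    columns: list[tuple[tuple[str, str], int, int]]
    specs: list[BinningSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.patients), len(self.columns)):
            raise ValueError(
                f"values shape {v.shape} inconsistent with {len(self.patients)} "
                f"patients × {len(self.columns)} columns"
            )
        if v.size and v.min() < 0:
            raise ValueError("concentrations must be non-negative")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column metadata must be bijective with columns")
        self.values = v

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def column_index(self, pair: tuple[str, str], i: int, j: int) -> int:
        return self.columns.index((tuple(pair), i, j))

    def pair_block(self, pair: tuple[str, str]) -> np.ndarray:
        """Columns of one channel pair reshaped to (patients, B, B)."""
        pair = tuple(pair)
        idx = [k for k, (p, _, _) in enumerate(self.columns) if p == pair]
        if not idx:
            raise KeyError(f"channel pair {pair} not in feature matrix")
        B = int(round(len(idx) ** 0.5))
        return self.values[:, idx].reshape(len(self.patients), B, B)

    def subset_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            patients=list(self.patients),
            values=self.values[:, indices],
            columns=[self.columns[k] for k in indices],
            specs=self.specs,
        )

    def to_dataframe(self):
        import pandas as pd

        names = [f"{p[0]}-{p[1]}:{i}:{j}" for p, i, j in self.columns]
        return pd.DataFrame(self.values, index=self.patients, columns=names)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.csv`` (matrix) and ``<prefix>.spec.json`` (edges)."""
        prefix = Path(prefix)
        self.to_dataframe().to_csv(prefix.with_suffix(".csv"))
        sidecar = {"specs": [s.to_dict() for s in self.specs]}
        prefix.with_suffix(".spec.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        import pandas as pd

        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"), index_col=0)
        columns = []
        for name in df.columns:
            pair_s, i, j = name.rsplit(":", 2)
            a, b = pair_s.split("-", 1)
            columns.append(((a, b), int(i), int(j)))
        sidecar = json.loads(prefix.with_suffix(".spec.json").read_text())
        specs = [BinningSpec.from_dict(d) for d in sidecar["specs"]]
        return cls(
            patients=[str(p) for p in df.index],
            values=df.to_numpy(),
            columns=columns,
            specs=specs,
        )


def patient_concentration_grid(
    samples: SampleSet, patient_id: str, spec: BinningSpec
) -> np.ndarray:
    """Replicate-averaged concentration grid for one patient and pair."""
    tables = samples.pass_replicates(patient_id)
    grids = [to_concentration(assign_events(t, spec), t.meta) for t in tables]
    return average_replicates(grids)


def build_feature_matrix(
    samples: SampleSet, specs: Sequence[BinningSpec]
) -> FeatureMatrix:
    """Concatenate flattened replicate-averaged grids over all channel pairs.

    One row per patient with ≥ 1 pass replicate (patients with none are
    dropped upstream by the QC policy); columns ordered pair-major,
    then row bin, then column bin.
    """
    patients = samples.patients_with_pass()
    if not patients:
        raise ValueError("no patients with pass replicates")
    columns: list[tuple[tuple[str, str], int, int]] = []
    for spec in specs:
        B = spec.bins_per_channel
        columns += [
            (tuple(spec.channel_pair), i, j) for i in range(B) for j in range(B)
        ]
    rows = []
    for pid in patients:
        blocks = [
            patient_concentration_grid(samples, pid, spec).ravel() for spec in specs
        ]
        rows.append(np.concatenate(blocks))
    return FeatureMatrix(
        patients=patients,
        values=np.vstack(rows),
        columns=columns,
        specs=list(specs),
    )


def gate_count(
    table: EventTable, gate: RectGate, meta: AcquisitionMeta | None = None,
    log_floor: dict[str, float] | None = None,
) -> float:
    """Concentration of events inside a fixed rectangular log-domain gate.

    The manual-gating baseline: same volume/dilution arithmetic as
    :func:`to_concentration`.  ``log_floor`` defaults to the smallest
    positive value of each gated channel within the table itself.
    """
    if meta is None:
        meta = table.meta
    ch_x, ch_y = gate.channel_pair
    inside = np.ones(table.n_events, dtype=bool)
    for ch, lo, hi in zip(gate.channel_pair, gate.low, gate.high):
        raw = table.channel(ch)
        if log_floor and ch in log_floor:
            floor = log_floor[ch]
        else:
            pos = raw[raw > 0]
            floor = float(pos.min()) if pos.size else 1.0
        lv = log_transform(raw, floor)
        inside &= (lv >= lo) & (lv < hi)
    n = int(inside.sum())
    return float(to_concentration(np.asarray(n), meta))


def aggregate_grid(counts: np.ndarray, factor: int) -> np.ndarray:
    """Sum adjacent ``factor × factor`` blocks (e.g. 64×64 → 32×32).

    With nested edges this reproduces the coarser grid exactly.
    """
    B = counts.shape[0]
    if B % factor:
        raise ValueError(f"grid size {B} not divisible by {factor}")
    b = B // factor
    return counts.reshape(b, factor, b, factor).sum(axis=(1, 3))
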