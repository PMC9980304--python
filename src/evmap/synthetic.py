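"""Synthetic EV-cytometry cohorts: triplicate event files plus clinical data.

Each patient's events are drawn from a mixture of log-normal particle
populations (Gaussian in log10 intensity over scatter and two marker
channels), mimicking the decades-spanning, heterogeneous EV mixtures seen
in plasma.  Class structure is planted either as per-population count
multipliers (a population is more abundant in the positive class) or as
mean shifts in log intensity; with all multipliers at 1 and zero shifts the
cohort is an exact null.

Between-patient variability acts on population *composition* (log-normal
abundance factors per population, renormalized so the expected total at
the null composition equals the configured events per replicate).  Class
count-multipliers then scale the affected populations' expected counts
on top of that baseline, so a planted effect adds particles where it is
planted without distorting the rest of the mixture.  Pinning the baseline
total mirrors the laboratory practice of diluting every sample into the
instrument's acceptable event-rate window and keeps all default cohorts
inside the 400–20 000 events·s⁻¹ QC filter (the default 3× effect raises
class-1 totals to ≈ 1.4×, still comfortably in-window).  Replicate-to-
replicate variation within a patient is Poisson (counts) plus fresh
Gaussian draws (intensities).

Everything is deterministic given the cohort seed: patient p derives its
own generator from ``SeedSequence([seed, p])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from evmap.clinical import InstructionSheet, FeatureInstruction
from evmap.fcs_io import (
    AcquisitionMeta,
    ChannelSchema,
    EventTable,
    SampleSet,
    default_schema,
    write_fcs,
    write_manifest,
)
from evmap.binning import BinningSpec

REFERENCE_DATE = date(2015, 6, 1)

# grade group → (primary, secondary) Gleason patterns; 0 codes benign
_GG_TO_GLEASON = {0: (0, 0), 1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}


@dataclass(frozen=True)
class PopulationSpec:
    """One log-normal particle population.

    ``mean_log`` / ``cov_log`` parameterize the Gaussian of log10
    intensities over (scatter, marker1, marker2); ``weight`` is the
    population's share of the expected events per replicate.  Class-1
    effects: ``class_count_multiplier`` scales the population's abundance,
    ``class_mean_shift`` moves its log-mean.
    """

    name: str
    mean_log: tuple[float, float, float]
    cov_log: tuple[tuple[float, ...], ...]
    weight: float
    class_count_multiplier: float = 1.0
    class_mean_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov_log, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError(f"{self.name}: covariance must be symmetric 3×3")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(f"{self.name}: covariance must be positive definite")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be >= 0")


def _diag_cov(sd: Sequence[float]) -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(row) for row in np.diag(np.square(sd)))


def default_populations(
    planted_multiplier: float = 1.0,
) -> list[PopulationSpec]:
    """The standard four-population EV mixture.

    A dominant dim/negative population, small and large marker1-positive
    populations, and a marker2-positive population.  ``planted_multiplier``
    scales the class-1 abundance of the large-marker1 and marker2-positive
    populations (1.0 → exact null; 3.0 → the standard planted effect,
    echoing the higher abundance of large antigen-positive particles in
    high-grade disease).
    """
    return [
        PopulationSpec(
            name="dim_negative",
            mean_log=(1.8, 1.0, 1.0),
            cov_log=_diag_cov((0.35, 0.30, 0.30)),
            weight=0.60,
        ),
        PopulationSpec(
            name="small_marker1",
            mean_log=(2.0, 2.8, 1.3),
            cov_log=_diag_cov((0.25, 0.25, 0.25)),
            weight=0.18,
        ),
        PopulationSpec(
            name="large_marker1",
            mean_log=(3.2, 3.0, 1.5),
            cov_log=_diag_cov((0.25, 0.25, 0.25)),
            weight=0.10,
            class_count_multiplier=planted_multiplier,
        ),
        PopulationSpec(
            name="marker2_positive",
            mean_log=(2.4, 1.2, 2.9),
            cov_log=_diag_cov((0.25, 0.25, 0.25)),
            weight=0.12,
            class_count_multiplier=planted_multiplier,
        ),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort description.

    Defaults reflect the standard acquisition settings: triplicates,
    3.01 μL·min⁻¹ for 120 s at 100× dilution, 5 × 10⁴ expected events per
    replicate (417 events·s⁻¹, inside the QC window).
    """

    n_per_class: tuple[int, int] = (60, 60)
    populations: tuple[PopulationSpec, ...] = field(
        default_factory=lambda: tuple(default_populations())
    )
    replicates: int = 3
    events_per_replicate: float = 5e4
    flow_rate_ul_min: float = 3.01
    duration_s: float = 120.0
    dilution_factor: float = 100.0
    between_patient_sigma: float = 0.25
    soc_class_psa_multiplier: float = 1.5
    seed: int = 0
    event_count_overrides: tuple[tuple[str, int, int], ...] = ()
    # (patient_id, replicate_id, forced event count) triples

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise ValueError("need >= 1 patient per class")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")


def null_cohort_spec(n_per_class: int = 60, seed: int = 0, **kw) -> CohortSpec:
    """Cohort with no class effect anywhere in the μFCM channels."""
    return CohortSpec(
        n_per_class=(n_per_class, n_per_class),
        populations=tuple(default_populations(planted_multiplier=1.0)),
        soc_class_psa_multiplier=1.0,
        seed=seed,
        **kw,
    )


def planted_cohort_spec(
    n_per_class: int = 60, seed: int = 0, multiplier: float = 3.0, **kw
) -> CohortSpec:
    """Cohort with two populations 3× more abundant in the positive class."""
    return CohortSpec(
        n_per_class=(n_per_class, n_per_class),
        populations=tuple(default_populations(planted_multiplier=multiplier)),
        seed=seed,
        **kw,
    )


def _patient_rng(spec_seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, patient_index]))


def simulate_patient(
    spec: CohortSpec,
    class_label: int,
    patient_seed: int,
    patient_id: str = "",
    schema: ChannelSchema | None = None,
) -> tuple[list[EventTable], dict]:
    """Simulate one patient: replicate EventTables plus raw clinical fields.

    Population abundances get one log-normal factor per patient (the
    composition effect), normalized so the expected replicate total at the
    null composition is ``spec.events_per_replicate``; class count
    multipliers scale the planted populations on top.  Counts per
    population per replicate are Poisson, and intensities are fresh
    log-normal draws with the class mean-shift applied for label 1.
    """
    schema = schema or default_schema()
    rng = _patient_rng(spec.seed, patient_seed)
    pops = spec.populations

    factors = np.array([
        p.weight * rng.lognormal(0.0, spec.between_patient_sigma)
        for p in pops
    ])
    # patient variability is compositional: the expected total at the null
    # composition is pinned to the configured events per replicate, so
    # every default cohort sits inside the event-rate QC window
    base_expected = factors / factors.sum() * spec.events_per_replicate
    multipliers = np.array([
        p.class_count_multiplier if class_label == 1 else 1.0 for p in pops
    ])
    expected = base_expected * multipliers

    chol = [np.linalg.cholesky(np.asarray(p.cov_log)) for p in pops]
    tables = []
    for rep in range(spec.replicates):
        n_events = None
        for pid_ov, rep_ov, n_ov in spec.event_count_overrides:
            if pid_ov == patient_id and rep_ov == rep:
                n_events = n_ov
        counts = rng.poisson(expected)
        if n_events is not None:
            total = counts.sum()
            counts = (counts * (n_events / max(total, 1))).astype(int)
            counts[0] += n_events - counts.sum()
        chunks = []
        for p, L, c in zip(pops, chol, counts):
            if c == 0:
                continue
            mean = np.asarray(p.mean_log, dtype=float)
            if class_label == 1:
                mean = mean + np.asarray(p.class_mean_shift)
            draws = rng.standard_normal((c, 3)) @ L.T + mean
            chunks.append(np.power(10.0, draws))
        data = (np.vstack(chunks) if chunks else np.zeros((0, 3)))
        # interleave populations as an instrument would record them
        data = data.take(rng.permutation(data.shape[0]), axis=0)
        meta = AcquisitionMeta(
            flow_rate_ul_min=spec.flow_rate_ul_min,
            duration_s=spec.duration_s,
            dilution_factor=spec.dilution_factor,
            replicate_id=rep,
            patient_id=patient_id,
        )
        tables.append(EventTable(intensities=data, schema=schema, meta=meta))

    gg = _draw_grade_group(rng, class_label)
    primary, secondary = _GG_TO_GLEASON[gg]
    age = int(np.clip(round(rng.normal(64, 7)), 45, 85))
    dob = date(REFERENCE_DATE.year - age, REFERENCE_DATE.month, REFERENCE_DATE.day)
    psa = float(rng.lognormal(np.log(7.0), 0.5))
    if class_label == 1:
        psa *= spec.soc_class_psa_multiplier
    clinical = {
        "patient_id": patient_id,
        "gleason_primary": primary,
        "gleason_secondary": secondary,
        "psa": round(psa, 2),
        "dob": dob.isoformat(),
        "dre_abnormal": int(rng.random() < (0.40 if class_label else 0.25)),
        "family_history": int(rng.random() < 0.20),
        "prior_negative_biopsy": int(rng.random() < 0.20),
        "race_black": int(rng.random() < 0.05),
        "weight_kg": round(float(rng.normal(85, 12)), 1),
    }
    return tables, clinical


def _draw_grade_group(rng: np.random.Generator, class_label: int) -> int:
    if class_label == 1:
        return int(rng.choice([3, 4, 5], p=[0.5, 0.3, 0.2]))
    return int(rng.choice([0, 1, 2], p=[0.35, 0.35, 0.30]))


def simulate_samples(
    spec: CohortSpec, schema: ChannelSchema | None = None
) -> tuple[SampleSet, pd.DataFrame, np.ndarray]:
    """In-memory cohort: (SampleSet, raw clinical table, class labels).

    Patient order: all class-0 patients, then all class-1 patients.  QC
    status is left unset; apply :func:`evmap.fcs_io.qc_filter`.
    """
    schema = schema or default_schema()
    samples = SampleSet()
    clin_rows = []
    labels = []
    idx = 0
    for cls in (0, 1):
        for _ in range(spec.n_per_class[cls]):
            pid = f"P{idx:04d}"
            tables, clinical = simulate_patient(
                spec, cls, patient_seed=idx, patient_id=pid, schema=schema
            )
            for t in tables:
                samples.add(t)
            clin_rows.append(clinical)
            labels.append(cls)
            idx += 1
    clin = pd.DataFrame(clin_rows).set_index("patient_id")
    return samples, clin, np.asarray(labels)


def default_instruction_sheet() -> InstructionSheet:
    """Instruction sheet matching the synthetic clinical table's columns."""
    f = FeatureInstruction
    return InstructionSheet(features=[
        f("grade_group", "gleason_primary+gleason_secondary", "ordinal",
          missing_code="-1", transform="gleason_to_gg"),
        f("psa", "psa", "ordinal", missing_code="-1"),
        f("psa_elevated", "psa", "binary", missing_code="-1",
          transform="threshold(10,>=)"),
        f("age", "dob", "ordinal", missing_code="",
          transform=f"age_from_dob({REFERENCE_DATE.isoformat()})"),
        f("dre_abnormal", "dre_abnormal", "binary", missing_code="-1"),
        f("family_history", "family_history", "binary", missing_code="-1"),
        f("prior_negative_biopsy", "prior_negative_biopsy", "binary",
          missing_code="-1"),
        f("race_black", "race_black", "binary", missing_code="-1"),
        f("weight", "weight_kg", "ordinal", missing_code="-1"),
    ])


def simulate_cohort(
    spec: CohortSpec, outdir: str | Path, schema: ChannelSchema | None = None
) -> dict[str, Path]:
    """Write a complete runnable cohort fixture to disk.

    FCS files (one per patient-replicate), the acquisition manifest, the
    raw clinical table and the instruction sheet.  Deterministic given
    ``spec.seed``.  Returns the paths.
    """
    schema = schema or default_schema()
    outdir = Path(outdir)
    fcs_dir = outdir / "fcs"
    fcs_dir.mkdir(parents=True, exist_ok=True)
    samples, clin, labels = simulate_samples(spec, schema=schema)
    manifest_rows = []
    for pid, reps in samples.replicates.items():
        for rep in reps:
            t = rep.table
            fname = f"{pid}_r{t.meta.replicate_id}.fcs"
            write_fcs(t, fcs_dir / fname)
            manifest_rows.append({
                "patient_id": pid,
                "replicate_id": t.meta.replicate_id,
                "path": f"fcs/{fname}",
                "flow_rate_ul_min": t.meta.flow_rate_ul_min,
                "duration_s": t.meta.duration_s,
                "dilution": t.meta.dilution_factor,
            })
    paths = {
        "manifest": outdir / "manifest.tsv",
        "clinical": outdir / "clinical.tsv",
        "instructions": outdir / "instructions.csv",
        "fcs_dir": fcs_dir,
    }
    write_manifest(manifest_rows, paths["manifest"])
    clin.to_csv(paths["clinical"], sep="\t")
    default_instruction_sheet().to_csv(paths["instructions"])
    return paths


# ---------------------------------------------------------------------------
# Ground-truth helpers for planted effects
# ---------------------------------------------------------------------------


def expected_bin(
    population: PopulationSpec, spec: BinningSpec
) -> tuple[int, int]:
    """Grid cell containing the population's (unshifted) log-mean."""
    schema = default_schema()
    idx = {name: k for k, name in enumerate(schema.names)}
    cell = []
    for ch in spec.channel_pair:
        edges = spec.edges[ch]
        v = population.mean_log[idx[ch]]
        b = int(np.searchsorted(edges[1:-1], v, side="right"))
        cell.append(b)
    return cell[0], cell[1]


def _population_bin_range(
    population: PopulationSpec, spec: BinningSpec, channel_index: dict[str, int],
    n_sigma: float,
) -> list[tuple[int, int]]:
    """Inclusive bin-index range [lo, hi] of mean ± n_sigma per pair channel."""
    out = []
    cov = np.asarray(population.cov_log)
    for ch in spec.channel_pair:
        k = channel_index[ch]
        sd = float(np.sqrt(cov[k, k]))
        lo_v = population.mean_log[k] - n_sigma * sd
        hi_v = population.mean_log[k] + n_sigma * sd
        edges = spec.edges[ch]
        lo = int(np.searchsorted(edges[1:-1], lo_v, side="right"))
        hi = int(np.searchsorted(edges[1:-1], hi_v, side="right"))
        out.append((lo, hi))
    return out


def planted_neighbourhood_columns(
    columns: Sequence[tuple[tuple[str, str], int, int]],
    populations: Sequence[PopulationSpec],
    specs: Sequence[BinningSpec],
    n_sigma: float = 2.0,
) -> np.ndarray:
    """Feature-column indices inside a planted population's footprint.

    The footprint of a population on a channel pair is the box of bins
    covered by its log-mean ± ``n_sigma`` standard deviations per channel
    (≈ 95% of the population's events at the default 2σ).  Populations with
    a count multiplier ≠ 1 or a nonzero mean shift count as planted.
    """
    schema = default_schema()
    channel_index = {name: k for k, name in enumerate(schema.names)}
    planted = [
        p for p in populations
        if p.class_count_multiplier != 1.0 or any(p.class_mean_shift)
    ]
    boxes: dict[tuple[str, str], list[list[tuple[int, int]]]] = {}
    for s in specs:
        boxes[tuple(s.channel_pair)] = [
            _population_bin_range(p, s, channel_index, n_sigma) for p in planted
        ]
    keep = []
    for k, (pair, i, j) in enumerate(columns):
        for (ilo, ihi), (jlo, jhi) in boxes.get(tuple(pair), []):
            if ilo <= i <= ihi and jlo <= j <= jhi:
                keep.append(k)
                break
    return np.asarray(keep, dtype=int)
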