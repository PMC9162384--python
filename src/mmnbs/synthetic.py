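"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group cross-sectional MRI study of cerebellar-type
multiple system atrophy (MSA-c) versus healthy controls: 29 patients and 27
controls by default, five regional metrics (GMV, WMV, FA, MD, fiber-bundle
count) over a 116-region AAL-style parcellation, per-subject functional
connectivity derived from simulated BOLD-like time series, and a clinical table
(UMSARS-I/II/total, age, gender, MoCA, HAMA, HAMD).

Planted structure
-----------------
* regional effects: standardized mean shifts (Cohen's d) in designated regions,
  by default cerebellar decreases in GMV/WMV/FA/fiber counts and MD increases;
* connectivity effects: designated edges whose population correlation is
  shifted by ``delta_r`` in patients, forming connected components;
* clinical coupling: UMSARS-total built as a linear blend
  ``z_total = sum_k rho_k z(feature_k) + sqrt(1 - sum rho_k^2) * noise`` so each
  targeted feature carries the requested population correlation.

One master seed expands into independent per-stage child streams (regional
tables, FC, clinical, phantom) via ``numpy.random.SeedSequence.spawn``, so each
stage is individually reproducible and regeneration is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .parcellation import LabelVolume, ROITimeSeries, fc_matrix

__all__ = [
    "METRICS",
    "CEREBELLAR_REGIONS",
    "MetricSpec",
    "EffectSpec",
    "FCSpec",
    "ClinicalSpec",
    "CohortSpec",
    "SyntheticCohort",
    "CohortSpecError",
    "generate_cohort",
    "generate_regional_tables",
    "generate_fc_data",
    "generate_clinical",
    "generate_phantom",
    "write_cohort",
    "default_spec",
]

METRICS = ("GMV", "WMV", "FA", "MD", "FIBER_COUNT")

#: 0-based indices of the cerebellar + vermis block of an AAL-style
#: 116-region parcellation (atlas positions 91-116).
CEREBELLAR_REGIONS = tuple(range(90, 116))


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class MetricSpec:
    """Baseline mean and between-subject SD of one regional metric."""

    mean: float
    sd: float


# Baselines chosen to look like real regional summaries: tissue-probability
# means for the weighted volumes, typical FA, MD in mm^2/s, streamline counts.
DEFAULT_METRIC_SPECS: dict[str, MetricSpec] = {
    "GMV": MetricSpec(0.45, 0.05),
    "WMV": MetricSpec(0.35, 0.05),
    "FA": MetricSpec(0.45, 0.06),
    "MD": MetricSpec(8.0e-4, 8.0e-5),
    "FIBER_COUNT": MetricSpec(1200.0, 300.0),
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted standardized group difference (negative = lower in patients)."""

    metric: str
    regions: tuple[int, ...]
    effect_size: float


@dataclass(frozen=True)
class FCSpec:
    """Functional-connectivity generation parameters.

    ``planted_edges`` lists (i, j, delta_r): in patients the population
    correlation of edge (i, j) is ``base_correlation + delta_r``.
    """

    series_length: int = 170
    base_correlation: float = 0.1
    planted_edges: tuple[tuple[int, int, float], ...] = ()


@dataclass(frozen=True)
class ClinicalSpec:
    """Clinical-table parameters (Table-1-style marginals plus planted
    feature-score correlations)."""

    umsars1_mean: float = 17.34
    umsars1_sd: float = 5.65
    umsars2_mean: float = 17.07
    umsars2_sd: float = 5.66
    umsars_total_sd: float = 10.42
    target_correlations: tuple[tuple[str, int, float], ...] = ()
    age_mean_patients: float = 57.62
    age_sd_patients: float = 6.00
    age_mean_controls: float = 57.37
    age_sd_controls: float = 5.64
    male_fraction_patients: float = 18 / 29
    male_fraction_controls: float = 11 / 27
    duration_mean: float = 2.34
    duration_sd: float = 1.49
    moca_mean: float = 24.17
    moca_sd: float = 3.76
    hama_mean: float = 13.33
    hama_sd: float = 6.43
    hamd_mean: float = 13.94
    hamd_sd: float = 8.61


def _default_effects() -> tuple[EffectSpec, ...]:
    return (
        EffectSpec("GMV", CEREBELLAR_REGIONS, -2.0),
        EffectSpec("WMV", (94, 95, 114, 115), -1.5),
        EffectSpec("FA", (90, 91, 98, 99, 106, 107), -1.5),
        EffectSpec("MD", (36, 56, 90, 91, 98, 99), 1.5),
        EffectSpec("FIBER_COUNT", (94, 95, 106, 107), -1.5),
    )


def _default_fc() -> FCSpec:
    # two planted components: one mixed-sign component around left cerebellar
    # nodes, one increased-connectivity component around right cerebellar nodes
    return FCSpec(
        series_length=170,
        base_correlation=0.1,
        planted_edges=(
            (6, 104, -0.4),
            (6, 96, -0.4),
            (60, 110, -0.4),
            (78, 110, 0.4),
            (79, 110, 0.4),
            (78, 96, 0.4),
            (24, 101, 0.4),
            (24, 105, 0.4),
            (32, 101, 0.4),
        ),
    )


def _default_clinical() -> ClinicalSpec:
    # negative microstructure-severity coupling: FA at the bilateral planted
    # cerebellar pair and fiber count at one right cerebellar region
    return ClinicalSpec(
        target_correlations=(
            ("FA", 106, -0.5),
            ("FA", 107, -0.5),
            ("FIBER_COUNT", 95, -0.5),
        )
    )


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 29
    n_controls: int = 27
    n_regions: int = 116
    region_labels: tuple[str, ...] | None = None
    metric_specs: dict[str, MetricSpec] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_SPECS)
    )
    effects: tuple[EffectSpec, ...] = field(default_factory=_default_effects)
    fc: FCSpec = field(default_factory=_default_fc)
    clinical: ClinicalSpec = field(default_factory=_default_clinical)
    seed: int = 0

    def labels(self) -> tuple[str, ...]:
        if self.region_labels is not None:
            return tuple(self.region_labels)
        return tuple(f"R{i + 1:03d}" for i in range(self.n_regions))

    def validate(self) -> None:
        if self.n_patients < 2:
            raise CohortSpecError("n_patients must be >= 2")
        if self.n_controls < 2:
            raise CohortSpecError("n_controls must be >= 2")
        if self.n_regions < 2:
            raise CohortSpecError("n_regions must be >= 2")
        if self.region_labels is not None and len(self.region_labels) != self.n_regions:
            raise CohortSpecError("region_labels length must equal n_regions")
        for metric, ms in self.metric_specs.items():
            if metric not in METRICS:
                raise CohortSpecError(f"unknown metric {metric!r} in metric_specs")
            if not ms.sd > 0:
                raise CohortSpecError(f"metric_specs[{metric!r}].sd must be > 0")
        for eff in self.effects:
            if eff.metric not in METRICS:
                raise CohortSpecError(f"effects: unknown metric {eff.metric!r}")
            if not np.isfinite(eff.effect_size):
                raise CohortSpecError(f"effects[{eff.metric!r}].effect_size must be finite")
            for r in eff.regions:
                if not 0 <= r < self.n_regions:
                    raise CohortSpecError(
                        f"effects[{eff.metric!r}]: region index {r} out of range"
                    )
        if self.fc.series_length < 8:
            raise CohortSpecError("fc.series_length must be >= 8")
        if not -1 < self.fc.base_correlation < 1:
            raise CohortSpecError("fc.base_correlation must be in (-1, 1)")
        for i, j, delta in self.fc.planted_edges:
            if i == j or not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise CohortSpecError(f"fc.planted_edges: bad edge ({i}, {j})")
            if not abs(self.fc.base_correlation + delta) < 1:
                raise CohortSpecError(
                    f"fc.planted_edges ({i}, {j}): |base + delta_r| must be < 1"
                )
        cs = self.clinical
        for name in ("umsars1_sd", "umsars2_sd", "umsars_total_sd", "age_sd_patients",
                     "age_sd_controls"):
            if not getattr(cs, name) > 0:
                raise CohortSpecError(f"clinical.{name} must be > 0")
        rho_sq = 0.0
        for metric, region, rho in cs.target_correlations:
            if metric not in METRICS:
                raise CohortSpecError(
                    f"clinical.target_correlations: unknown metric {metric!r}"
                )
            if not -1 < rho < 1:
                raise CohortSpecError("clinical.target_correlations: |rho| must be < 1")
            if not 0 <= region < self.n_regions:
                raise CohortSpecError(
                    f"clinical.target_correlations: region {region} out of range"
                )
            rho_sq += rho * rho
        if rho_sq >= 1:
            raise CohortSpecError(
                "clinical.target_correlations: sum of rho^2 must be < 1"
            )


def default_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default study conditions with a given master seed."""
    return CohortSpec(seed=seed, **overrides)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subject_ids: list[str]
    groups: np.ndarray  # "patient" / "control", aligned with subject_ids
    tables: dict[str, pd.DataFrame]
    fc: np.ndarray  # n_subjects x R x R
    timeseries: list[ROITimeSeries]
    clinical: pd.DataFrame

    @property
    def y(self) -> np.ndarray:
        """Binary group labels, 1 = patient."""
        return (self.groups == "patient").astype(int)


def _stage_rngs(spec: CohortSpec) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(4)
    names = ("regional", "fc", "clinical", "phantom")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _subject_ids(spec: CohortSpec) -> tuple[list[str], np.ndarray]:
    ids = [f"P{i + 1:02d}" for i in range(spec.n_patients)] + [
        f"C{i + 1:02d}" for i in range(spec.n_controls)
    ]
    groups = np.array(["patient"] * spec.n_patients + ["control"] * spec.n_controls)
    return ids, groups


def generate_regional_tables(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """One subjects x regions table per metric, with planted group shifts.

    Patients' values in effect regions are shifted by ``effect_size * sd``.
    FA is clipped to [0, 1]; fiber counts are rounded to non-negative integers.
    """
    spec.validate()
    if rng is None:
        rng = _stage_rngs(spec)["regional"]
    ids, groups = _subject_ids(spec)
    n = len(ids)
    labels = spec.labels()
    is_patient = groups == "patient"
    tables: dict[str, pd.DataFrame] = {}
    for metric in METRICS:
        ms = spec.metric_specs.get(metric, DEFAULT_METRIC_SPECS[metric])
        values = rng.normal(ms.mean, ms.sd, size=(n, spec.n_regions))
        for eff in spec.effects:
            if eff.metric == metric:
                shift = eff.effect_size * ms.sd
                values[np.ix_(is_patient, list(eff.regions))] += shift
        if metric == "FA":
            values = np.clip(values, 0.0, 1.0)
        elif metric == "FIBER_COUNT":
            values = np.clip(np.rint(values), 0, None)
        table = pd.DataFrame(values, columns=list(labels))
        table.insert(0, "group", groups)
        table.insert(0, "subject_id", ids)
        tables[metric] = table
    return tables


def _group_covariance(spec: CohortSpec, patient: bool) -> np.ndarray:
    R = spec.n_regions
    cov = np.full((R, R), spec.fc.base_correlation)
    np.fill_diagonal(cov, 1.0)
    if patient:
        for i, j, delta in spec.fc.planted_edges:
            cov[i, j] = cov[j, i] = spec.fc.base_correlation + delta
    return cov


def generate_fc_data(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[ROITimeSeries]]:
    """Per-subject FC matrices computed from sampled multivariate time series.

    Each subject's T x R series is drawn from a zero-mean multivariate normal
    whose correlation structure carries the planted edges (patients only); the
    Pearson matrix is then computed with :func:`mmnbs.parcellation.fc_matrix`,
    i.e. through the same code path real ROI time series would take.
    """
    spec.validate()
    if rng is None:
        rng = _stage_rngs(spec)["fc"]
    ids, groups = _subject_ids(spec)
    labels = list(spec.labels())
    chols = {}
    for patient in (True, False):
        cov = _group_covariance(spec, patient)
        try:
            chols[patient] = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise CohortSpecError(
                "implied population covariance is not positive-definite; "
                "reduce |delta_r| or the planted-edge density"
            ) from None
    T = spec.fc.series_length
    matrices = np.empty((len(ids), spec.n_regions, spec.n_regions))
    series_list: list[ROITimeSeries] = []
    for s, (sid, grp) in enumerate(zip(ids, groups)):
        z = rng.standard_normal((T, spec.n_regions))
        data = z @ chols[grp == "patient"].T
        ts = ROITimeSeries(data, labels, subject_id=sid)
        series_list.append(ts)
        matrices[s] = fc_matrix(ts)
    return matrices, series_list


def generate_clinical(
    spec: CohortSpec,
    tables: dict[str, pd.DataFrame],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Clinical table with UMSARS scores coupled to realized feature values.

    UMSARS-total is a linear blend of the standardized target features plus
    independent noise, so each targeted feature carries the requested
    population correlation; UMSARS-I + UMSARS-II = UMSARS-total exactly.
    Controls carry no UMSARS/MoCA/HAMA/HAMD scores.
    """
    spec.validate()
    if rng is None:
        rng = _stage_rngs(spec)["clinical"]
    ids, groups = _subject_ids(spec)
    labels = spec.labels()
    is_patient = groups == "patient"
    n_pat = int(is_patient.sum())
    cs = spec.clinical

    z_parts = np.zeros(n_pat)
    rho_sq = 0.0
    for metric, region, rho in cs.target_correlations:
        if metric not in tables:
            raise CohortSpecError(f"target feature {metric!r} not present in tables")
        col = labels[region]
        if col not in tables[metric].columns:
            raise CohortSpecError(
                f"target feature {metric!r} region {region} not present in tables"
            )
        vals = tables[metric].loc[is_patient, col].to_numpy(float)
        sd = vals.std(ddof=1)
        if sd == 0:
            raise CohortSpecError(
                f"target feature {metric!r} region {region} has zero variance"
            )
        z_parts += rho * (vals - vals.mean()) / sd
        rho_sq += rho * rho
    z_total = z_parts + np.sqrt(max(1.0 - rho_sq, 0.0)) * rng.standard_normal(n_pat)

    total_mean = cs.umsars1_mean + cs.umsars2_mean
    total = total_mean + cs.umsars_total_sd * z_total
    w1 = cs.umsars1_mean / total_mean
    var_split = max(cs.umsars1_sd**2 - (w1 * cs.umsars_total_sd) ** 2, 0.25)
    delta = rng.normal(0.0, np.sqrt(var_split), size=n_pat)
    umsars1 = w1 * total + delta
    umsars2 = total - umsars1

    age = np.where(
        is_patient,
        rng.normal(cs.age_mean_patients, cs.age_sd_patients, len(ids)),
        rng.normal(cs.age_mean_controls, cs.age_sd_controls, len(ids)),
    )
    # gender drawn as exact per-group counts (Table-1-style margins)
    gender = np.empty(len(ids), dtype=object)
    for patient, frac, count in (
        (True, cs.male_fraction_patients, n_pat),
        (False, cs.male_fraction_controls, len(ids) - n_pat),
    ):
        n_male = int(round(frac * count))
        g = np.array(["M"] * n_male + ["F"] * (count - n_male))
        rng.shuffle(g)
        gender[is_patient == patient] = g

    clinical = pd.DataFrame({"subject_id": ids, "group": groups, "age": age,
                             "gender": gender})
    for name, values in (
        ("umsars_1", umsars1),
        ("umsars_2", umsars2),
        ("umsars_total", umsars1 + umsars2),
        ("disease_duration", rng.normal(cs.duration_mean, cs.duration_sd, n_pat)),
        ("moca", rng.normal(cs.moca_mean, cs.moca_sd, n_pat)),
        ("hama", rng.normal(cs.hama_mean, cs.hama_sd, n_pat)),
        ("hamd", rng.normal(cs.hamd_mean, cs.hamd_sd, n_pat)),
    ):
        col = np.full(len(ids), np.nan)
        col[is_patient] = values
        clinical[name] = col
    return clinical


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete cohort (tables, FC, clinical) from one master seed."""
    if spec is None:
        spec = default_spec()
    if seed is not None:
        spec = CohortSpec(**{**spec.__dict__, "seed": seed})
    spec.validate()
    rngs = _stage_rngs(spec)
    ids, groups = _subject_ids(spec)
    tables = generate_regional_tables(spec, rngs["regional"])
    fc, series = generate_fc_data(spec, rngs["fc"])
    clinical = generate_clinical(spec, tables, rngs["clinical"])
    return SyntheticCohort(spec, ids, groups, tables, fc, series, clinical)


# ---------------------------------------------------------------------------
# voxel-space phantom for exercising the parcellation module

@dataclass
class Phantom:
    atlas: LabelVolume
    metric_volumes: dict[str, np.ndarray]
    region_values: dict[str, np.ndarray]
    streamlines: list[np.ndarray]
    bold: np.ndarray
    region_series: np.ndarray  # T x R ground-truth series


def generate_phantom(
    atlas_shape: tuple[int, int, int] = (16, 16, 16),
    n_regions: int = 8,
    seed: int = 0,
    metrics: tuple[str, ...] = ("FA",),
    noise_sd: float = 0.0,
    n_streamlines: int = 20,
    series_length: int = 40,
) -> Phantom:
    """Brain-like label volume with piecewise-constant metric maps, random
    polyline streamlines, and region-wise BOLD-like series."""
    shape = tuple(int(s) for s in atlas_shape)
    if min(shape) < 8:
        raise ValueError("atlas_shape must be at least 8 x 8 x 8")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.asarray(shape) / 2.0 - 0.5
    mask = (((grid - center) / radii) ** 2).sum(axis=1) <= 1.0
    voxels = grid[mask].astype(int)
    if n_regions > len(voxels):
        raise ValueError("n_regions exceeds the number of voxels in the brain mask")
    # contiguous slab partition: lexicographic order chunked into n_regions blocks
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    labels = np.zeros(shape, dtype=int)
    chunks = np.array_split(order, n_regions)
    for rid, chunk in enumerate(chunks, start=1):
        v = voxels[chunk]
        labels[v[:, 0], v[:, 1], v[:, 2]] = rid
    atlas = LabelVolume(labels, (1.0, 1.0, 1.0),
                        {r: f"R{r:03d}" for r in range(1, n_regions + 1)})

    region_values: dict[str, np.ndarray] = {}
    metric_volumes: dict[str, np.ndarray] = {}
    for metric in metrics:
        vals = np.arange(1.0, n_regions + 1.0)
        vol = np.zeros(shape)
        for rid in range(1, n_regions + 1):
            vol[labels == rid] = vals[rid - 1]
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, size=shape)
        region_values[metric] = vals
        metric_volumes[metric] = vol

    streamlines: list[np.ndarray] = []
    in_mask = voxels + 0.5  # voxel centers
    for _ in range(n_streamlines):
        a, b = in_mask[rng.integers(len(in_mask))], in_mask[rng.integers(len(in_mask))]
        n_pts = max(int(np.ceil(np.linalg.norm(b - a) * 2)) + 1, 2)
        t = np.linspace(0.0, 1.0, n_pts)[:, None]
        streamlines.append(a + t * (b - a))

    region_series = rng.standard_normal((series_length, n_regions))
    bold = np.zeros(shape + (series_length,))
    for rid in range(1, n_regions + 1):
        bold[labels == rid] = region_series[:, rid - 1]
    if noise_sd > 0:
        bold = bold + rng.normal(0.0, noise_sd, size=bold.shape)
    return Phantom(atlas, metric_volumes, region_values, streamlines, bold,
                   region_series)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write the cohort as TSVs + per-subject matrix files + a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for metric, table in cohort.tables.items():
        path = outdir / f"{metric.lower()}.tsv"
        mio.write_regional_table(table, path)
        written[metric] = str(path)
    fc_dir = outdir / "fc"
    fc_dir.mkdir(exist_ok=True)
    for sid, matrix in zip(cohort.subject_ids, cohort.fc):
        mio.write_matrix(matrix, fc_dir / f"{sid}.txt")
    mio.write_clinical_table(cohort.clinical, outdir / "clinical.tsv")
    groups = pd.DataFrame({"subject_id": cohort.subject_ids, "group": cohort.groups})
    groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    spec = cohort.spec
    sidecar = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "n_controls": spec.n_controls,
        "n_regions": spec.n_regions,
        "series_length": spec.fc.series_length,
        "base_correlation": spec.fc.base_correlation,
        "planted_edges": [list(e) for e in spec.fc.planted_edges],
        "effects": [
            {"metric": e.metric, "regions": list(e.regions), "d": e.effect_size}
            for e in spec.effects
        ],
    }
    mio.write_json(sidecar, outdir / "cohort.json")
    return written
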