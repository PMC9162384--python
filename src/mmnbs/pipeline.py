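"""End-to-end orchestration: simulate/load -> stats -> NBS -> classify -> report.

A single :class:`PipelineConfig` drives the whole analysis with one master
seed.  Per-stage seeds derive deterministically from it, every numeric
threshold used by any stage is recorded in the run manifest together with
SHA-256 checksums of all written files, and rerunning with the same config and
seed reproduces byte-identical outputs (all outputs are plain text with fixed
float formatting).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .classify import assemble_features, nested_loocv_svm, rank_regions
from .group_stats import (clinical_correlation, demographic_tests,
                          qq_outlier_screen, two_sample_t)
from .nbs import threshold_sweep
from .svm import DEFAULT_C_GRID
from .synthetic import METRICS, SyntheticCohort, default_spec, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "subject_exclusion",
]

log = logging.getLogger("mmnbs")

STAGE_ORDER = ("simulate", "stats", "nbs", "classify", "report")
__version__ = "0.1.0"


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def _default_thresholds() -> tuple[float, ...]:
    return tuple(round(0.0001 * k, 4) for k in range(1, 11))


@dataclass
class PipelineConfig:
    outdir: str = "mmnbs_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    input_dir: str | None = None  # load an existing cohort instead of simulating
    # cohort (when simulating)
    n_patients: int = 29
    n_controls: int = 27
    n_regions: int = 116
    series_length: int = 170
    # statistics
    alpha_discovery: float = 0.001
    alpha_feature: float = 0.05
    corr_alpha: float = 0.001
    outlier_k: float = 3.5
    manual_exclusions: tuple[str, ...] = ()
    exclusions: tuple[str, ...] = ()
    # extended NBS
    thresholds: tuple[float, ...] = field(default_factory=_default_thresholds)
    n_perm: int = 5000
    nbs_alpha: float = 0.05
    plus_one: bool = False
    nbs_feature_threshold: float = 0.0010
    # classification
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    accuracy_cutoff: float = 0.90
    global_scaling: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for name in ("alpha_discovery", "alpha_feature", "corr_alpha", "nbs_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if any(not 0 < t < 1 for t in self.thresholds):
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        enabled = [s for s in STAGE_ORDER if s in self.stages]
        if "classify" in enabled and "stats" not in enabled:
            raise ConfigError("classify requires the stats stage; run stats first")
        if "classify" in enabled and "nbs" not in enabled:
            raise ConfigError("classify requires the nbs stage; run nbs first")
        if "simulate" not in enabled and self.input_dir is None and enabled:
            if enabled != ["report"]:
                raise ConfigError("no input_dir given and simulate stage disabled")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["c_grid"] = list(self.c_grid)
        d["stages"] = list(self.stages)
        d["manual_exclusions"] = list(self.manual_exclusions)
        d["exclusions"] = list(self.exclusions)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("stages", "thresholds", "c_grid", "manual_exclusions",
                    "exclusions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    version: str
    stages_run: list[str]
    parameters: dict
    checksums: dict[str, str]
    started: str
    finished: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGE_ORDER))
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(STAGE_ORDER, state)}


def _spec_for(config: PipelineConfig, seed: int):
    """Cohort spec for the configured sizes.

    When ``n_regions`` is below the default atlas size, planted effects, FC
    edges and clinical couplings that reference out-of-range regions are
    dropped (the remaining structure is unchanged), so shrunken runs stay
    valid without silently relocating effects.
    """
    import dataclasses as _dc

    spec = default_spec(
        seed=seed,
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        n_regions=config.n_regions,
    )
    R = config.n_regions
    if R < 116:
        effects = tuple(
            _dc.replace(e, regions=tuple(r for r in e.regions if r < R))
            for e in spec.effects
        )
        effects = tuple(e for e in effects if e.regions)
        fc = _dc.replace(
            spec.fc,
            planted_edges=tuple(
                (i, j, d) for i, j, d in spec.fc.planted_edges if i < R and j < R
            ),
        )
        clinical = _dc.replace(
            spec.clinical,
            target_correlations=tuple(
                (m, r, rho) for m, r, rho in spec.clinical.target_correlations
                if r < R
            ),
        )
        spec = _dc.replace(spec, effects=effects, fc=fc, clinical=clinical)
    return spec


def subject_exclusion(cohort: SyntheticCohort, exclusions) -> SyntheticCohort:
    """Remove subjects uniformly from tables, FC stack and clinical table."""
    exclusions = list(exclusions)
    if not exclusions:
        return cohort
    unknown = set(exclusions) - set(cohort.subject_ids)
    if unknown:
        raise ConfigError(f"unknown subject id(s) in exclusion list: {sorted(unknown)}")
    keep = np.array([sid not in exclusions for sid in cohort.subject_ids])
    groups = cohort.groups[keep]
    if len(np.unique(groups)) < 2:
        raise ConfigError("exclusion list would remove an entire group")
    tables = {
        m: t[keep].reset_index(drop=True) for m, t in cohort.tables.items()
    }
    clinical = cohort.clinical[keep].reset_index(drop=True)
    ids = [sid for sid, k in zip(cohort.subject_ids, keep) if k]
    ts = [s for s, k in zip(cohort.timeseries, keep) if k] if cohort.timeseries else []
    log.info("stage=exclude removed=%d remaining=%d", len(exclusions), len(ids))
    return SyntheticCohort(cohort.spec, ids, groups, tables, cohort.fc[keep],
                           ts, clinical)


def _load_cohort(input_dir: str | Path) -> SyntheticCohort:
    input_dir = Path(input_dir)
    tables = {}
    for metric in METRICS:
        path = input_dir / f"{metric.lower()}.tsv"
        if not path.exists():
            raise StageError(f"missing {path}; run the simulate stage first")
        tables[metric] = mio.read_regional_table(path)
    ref = tables[METRICS[0]]
    ids = list(ref["subject_id"])
    groups = ref["group"].to_numpy()
    fc_dir = input_dir / "fc"
    matrices = []
    for sid in ids:
        path = fc_dir / f"{sid}.txt"
        if not path.exists():
            raise StageError(f"missing {path}; run the simulate stage first")
        matrices.append(mio.read_matrix(path))
    clinical = mio.read_clinical_table(input_dir / "clinical.tsv")
    spec = default_spec()
    return SyntheticCohort(spec, ids, groups, tables, np.array(matrices), [],
                           clinical)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest."""
    config.validate()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    written: list[Path] = []

    cohort = None
    stat_results = None
    sweep_results = None
    reports = None

    def _run_stage(name, fn):
        log.info("stage=%s status=start", name)
        try:
            fn()
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {name} failed: {exc}") from exc
        log.info("stage=%s status=done", name)

    # --- simulate / load -------------------------------------------------
    def _simulate():
        nonlocal cohort
        if config.input_dir is not None:
            cohort = _load_cohort(config.input_dir)
        else:
            cohort = generate_cohort(_spec_for(config, seeds["simulate"]))
            cohort_dir = outdir / "cohort"
            from .synthetic import write_cohort

            write_cohort(cohort, cohort_dir)
            written.extend(sorted(cohort_dir.rglob("*")))
        cohort = subject_exclusion(cohort, config.exclusions)

    if "simulate" in enabled or config.input_dir is not None:
        _run_stage("simulate", _simulate)

    # --- statistics -------------------------------------------------------
    def _stats():
        nonlocal stat_results
        if cohort is None:
            raise StageError("no cohort available; run the simulate stage first")
        stat_results = {
            metric: two_sample_t(cohort.tables[metric], metric=metric)
            for metric in cohort.tables
        }
        tidy = pd.concat(
            [r.to_frame(config.alpha_discovery) for r in stat_results.values()],
            ignore_index=True,
        )
        stats_dir = outdir / "stats"
        stats_dir.mkdir(exist_ok=True)
        path = stats_dir / "region_stats.tsv"
        tidy.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

        demo = demographic_tests(cohort.clinical)
        mio.write_json(demo, stats_dir / "demographics.json")
        written.append(stats_dir / "demographics.json")

        # clinical correlation of discovery-significant features, with
        # robust-z outlier screening on the severity score
        sig_features = []
        for metric, res in stat_results.items():
            for label in (res.region_labels[i]
                          for i in res.significant(config.alpha_discovery)):
                sig_features.append((metric, label))
        patients = cohort.clinical[cohort.clinical["group"] == "patient"]
        excluded: tuple[str, ...] = tuple(config.manual_exclusions)
        if len(patients) >= 5:
            screen = qq_outlier_screen(
                patients.set_index("subject_id")["umsars_total"],
                k=config.outlier_k,
                manual_exclusions=config.manual_exclusions,
            )
            excluded = tuple(screen.flagged)
        if sig_features:
            corr = clinical_correlation(
                cohort.tables, cohort.clinical, sig_features,
                exclude=excluded, alpha=config.corr_alpha,
            )
        else:
            corr = pd.DataFrame(
                columns=["metric", "region", "r", "p", "n", "excluded", "selected"]
            )
        path = stats_dir / "clinical_correlation.tsv"
        corr.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    if "stats" in enabled:
        _run_stage("stats", _stats)

    # --- extended NBS ------------------------------------------------------
    def _nbs():
        nonlocal sweep_results
        if cohort is None:
            raise StageError("no cohort available; run the simulate stage first")
        thresholds = sorted(set(config.thresholds) | {config.nbs_feature_threshold})
        ref_table = cohort.tables[next(iter(cohort.tables))]
        labels = [c for c in ref_table.columns if c not in ("subject_id", "group")]
        sweep_results = threshold_sweep(
            cohort.fc, cohort.y, thresholds=thresholds, n_perm=config.n_perm,
            seed=seeds["nbs"], alpha=config.nbs_alpha, plus_one=config.plus_one,
            region_labels=labels[: cohort.fc.shape[1]],
        )
        nbs_dir = outdir / "nbs"
        nbs_dir.mkdir(exist_ok=True)
        edge_rows = []
        for res in sweep_results:
            path = nbs_dir / f"threshold_{res.threshold:.4f}.json"
            mio.write_json(res.to_dict(), path)
            written.append(path)
            for ci, comp in enumerate(res.components):
                for i, j, sign, t in comp.edges:
                    edge_rows.append(
                        {
                            "threshold": res.threshold,
                            "component": ci,
                            "i": res.region_labels[i],
                            "j": res.region_labels[j],
                            "sign": sign,
                            "t": t,
                            "empirical_p": float(res.component_pvalues[ci]),
                        }
                    )
        path = nbs_dir / "edges.tsv"
        pd.DataFrame(
            edge_rows,
            columns=["threshold", "component", "i", "j", "sign", "t", "empirical_p"],
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    if "nbs" in enabled:
        _run_stage("nbs", _nbs)

    # --- classification ----------------------------------------------------
    def _classify():
        nonlocal reports
        if stat_results is None:
            raise StageError("stats outputs missing; run the stats stage first")
        if sweep_results is None:
            raise StageError("nbs outputs missing; run the nbs stage first")
        feature_res = next(
            (r for r in sweep_results
             if np.isclose(r.threshold, config.nbs_feature_threshold)),
            None,
        )
        reports = []
        n_regions = cohort.fc.shape[1]
        skipped = 0
        for region in range(n_regions):
            fs = assemble_features(
                region, stat_results, cohort.tables, feature_res, cohort.fc,
                alpha=config.alpha_feature,
            )
            if fs.unclassifiable:
                skipped += 1
                continue
            reports.append(
                nested_loocv_svm(fs, c_grid=config.c_grid,
                                 global_scaling=config.global_scaling)
            )
        log.info("stage=classify regions=%d unclassifiable=%d",
                 n_regions, skipped)

    if "classify" in enabled:
        _run_stage("classify", _classify)

    # --- report ------------------------------------------------------------
    def _report():
        report_dir = outdir / "report"
        report_dir.mkdir(exist_ok=True)
        if reports:
            ranked, high = rank_regions(reports, cutoff=config.accuracy_cutoff)
            for name, frame in (("region_ranking.tsv", ranked),
                                ("high_accuracy_regions.tsv", high)):
                path = report_dir / name
                frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
                written.append(path)
            roc_rows = []
            for rep in reports:
                if rep.accuracy > config.accuracy_cutoff:
                    for x, yv in zip(rep.roc_fpr, rep.roc_tpr):
                        roc_rows.append({"region_label": rep.region_label,
                                         "fpr": x, "tpr": yv})
            path = report_dir / "roc_points.tsv"
            pd.DataFrame(roc_rows, columns=["region_label", "fpr", "tpr"]).to_csv(
                path, sep="\t", index=False, float_format="%.10g")
            written.append(path)

    if "report" in enabled:
        _run_stage("report", _report)

    checksums = {
        str(p.relative_to(outdir)): mio.sha256_file(p)
        for p in sorted(set(written))
        if p.is_file()
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seeds=seeds,
        version=__version__,
        stages_run=enabled,
        parameters=config.to_dict(),
        checksums=checksums,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    mio.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
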