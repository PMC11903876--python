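"""End-to-end orchestration: simulate -> ingest -> filter -> SNV -> screen
-> label -> model -> evaluate.

A run directory receives the exclusion log, SNV matrices, correlation
curves, candidate sets, per-marker model reports, CV fold tables, a
Table-style summary (one row per marker x model kind) and a structured
JSON log with seeds, versions and per-stage timing.  A single root seed
expands deterministically into independent per-stage seeds.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import cv_optimism
from .exceptions import ConfigurationError, DegenerateOutcomeError
from .io import (build_matrices, cohort_to_records, filter_saturated,
                 read_dataset, write_dataset)
from .labels import dichotomize, load_marker_definitions, split_ph
from .models import best_subset  # noqa: F401  (re-export for users)
from .screening import (CandidateSet, correlation_curve, encode_ordinal,
                        select_candidates)
from .simulate import (CohortConfig, WavelengthGrid, default_marker_profiles,
                       generate_cohort)


@dataclass
class PipelineConfig:
    """Validated, fully serializable configuration of one pipeline run."""

    out_dir: str = "run"
    spectra_path: str | None = None  # analyze an existing dataset ...
    lab_path: str | None = None
    simulate: bool = True            # ... or generate one
    n_patients: int = 168
    markers: list[str] | None = None
    seed: int = 0
    saturation_limit: float = 65000.0
    dataset_wide_filter: bool = False
    alpha: float = 0.05
    plateau_window: int = 15
    plateau_tol: float = 0.05
    max_candidates: int = 6
    priors: dict = field(default_factory=dict)  # marker -> [wavelengths]
    model_kinds: list[str] = field(default_factory=lambda: ["lr", "lrre"])
    n_quadrature: int = 15
    max_subset_size: int | None = None
    candidate_cap: int = 12
    k_folds: int = 5
    bac_threshold: float = 0.5
    grouped_folds: bool = False
    layout: str = "wide"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha: must be in (0,1)")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds: must be >= 2")
        for kind in self.model_kinds:
            if kind not in ("lr", "lrre"):
                raise ConfigurationError(f"model_kinds: unknown kind {kind!r}")
        if not self.simulate and (self.spectra_path is None or self.lab_path is None):
            raise ConfigurationError(
                "spectra_path/lab_path: required when simulate is false")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage_seeds(root: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root)
    names = ("simulate", "folds")
    states = [int(c.generate_state(1)[0] % (2 ** 31 - 1)) for c in ss.spawn(len(names))]
    return dict(zip(names, states))


def _design_from_candidates(matrices, cands: CandidateSet):
    """Complete-case design matrix at the candidate channels.

    Returns (X DataFrame, sample ids, patient ids); samples missing any
    involved setting are dropped.
    """
    settings = sorted({c.setting for c in cands.features})
    common = None
    for s in settings:
        ids = set(matrices[s].sample_ids)
        common = ids if common is None else common & ids
    common = sorted(common)
    cols = {}
    pid_of = {}
    for s in settings:
        mat = matrices[s]
        pos = {sid: i for i, sid in enumerate(mat.sample_ids)}
        rows = [pos[sid] for sid in common]
        for c in cands.features:
            if c.setting == s:
                cols[c.feature_name] = mat.values[rows, c.channel]
        for sid in common:
            pid_of[sid] = mat.patient_ids[pos[sid]]
    X = pd.DataFrame(cols, index=pd.RangeIndex(len(common)))
    patients = [pid_of[sid] for sid in common]
    return X, common, patients


def _marker_outcomes(records, definitions, wanted):
    """(name, labels-aligned-to-records, definition-or-None) per outcome."""
    lab_cols = set()
    for rec in records:
        lab_cols.update(rec.lab_values)
    out = []
    for name in wanted:
        if name not in lab_cols:
            continue
        values = [rec.lab_values[name] for rec in records]
        if name == "ph":
            acidic, basic = split_ph(values)
            out.append(("ph_acidic", acidic, definitions.get("ph")))
            out.append(("ph_basic", basic, definitions.get("ph")))
            continue
        defn = definitions.get(name)
        if defn is None:
            continue
        out.append((name, dichotomize(values, defn), defn))
    return out


def run_pipeline(config: PipelineConfig, markers_profiles=None,
                 grid: WavelengthGrid | None = None) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log = {"version": __version__, "seed": config.seed, "stage_seeds": seeds,
           "stages": {}}
    t_all = time.perf_counter()

    def tick(stage, t0):
        log["stages"][stage] = round(time.perf_counter() - t0, 4)

    config.to_yaml(out / "config.yaml")
    definitions = load_marker_definitions()

    # -- data ---------------------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate:
        profiles = markers_profiles or default_marker_profiles()
        cc = CohortConfig(n_patients=config.n_patients,
                          saturation_limit=config.saturation_limit,
                          seed=seeds["simulate"])
        cohort = generate_cohort(cc, profiles, grid=grid)
        write_dataset(cohort, out / "data", layout=config.layout)
        records = cohort_to_records(cohort)
    else:
        records = read_dataset(config.spectra_path, config.lab_path)
    tick("data", t0)
    n_input = len(records)

    # -- saturation filter + SNV -------------------------------------------
    t0 = time.perf_counter()
    records, exclusion_log = filter_saturated(
        records, limit=config.saturation_limit,
        dataset_wide=config.dataset_wide_filter)
    exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
    matrices = build_matrices(records, apply_snv=True)
    snv_dir = out / "snv"
    snv_dir.mkdir(exist_ok=True)
    for setting, mat in matrices.items():
        df = pd.DataFrame(mat.values,
                          columns=[f"wl_{w:.3f}" for w in mat.wavelengths])
        df.insert(0, "patient_id", mat.patient_ids)
        df.insert(0, "sample_id", mat.sample_ids)
        df.to_csv(snv_dir / f"snv_{mat.label}.csv", index=False)
    tick("normalize", t0)

    # -- screening + modeling per marker -------------------------------------
    wanted = config.markers or sorted(
        {k for rec in records for k in rec.lab_values})
    outcomes = _marker_outcomes(records, definitions, wanted)
    sample_pos = {rec.sample_id: i for i, rec in enumerate(records)}
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)

    summary_rows = []
    cand_rows = []
    for name, labels_full, defn in outcomes:
        t0 = time.perf_counter()
        base = name.rsplit("_", 1)[0] if name.startswith("ph_") else name
        scale = defn.scale if defn is not None else "quantitative"
        curves = []
        for setting, mat in matrices.items():
            rows = [sample_pos[sid] for sid in mat.sample_ids]
            if name.startswith("ph_"):
                lab_vec = np.asarray(labels_full)[rows].astype(float)
                sc = "quantitative"
            elif scale == "ordinal":
                vals = [records[i].lab_values[name] for i in rows]
                lab_vec = encode_ordinal(vals, defn.ordinal_levels)
                sc = "ordinal"
            else:
                lab_vec = np.asarray(
                    [float(records[i].lab_values[name]) for i in rows])
                sc = "quantitative"
            if np.unique(lab_vec).size < 2:
                continue
            curves.append(correlation_curve(mat, lab_vec, sc, marker=name))
        if curves:
            pd.concat([c.to_frame() for c in curves]).to_csv(
                curves_dir / f"curves_{name}.csv", index=False)
        cands = select_candidates(
            curves, alpha=config.alpha, max_per_marker=config.max_candidates,
            priors=config.priors.get(name) or config.priors.get(base),
            plateau_window=config.plateau_window,
            plateau_tol=config.plateau_tol)
        for c in cands.features:
            cand_rows.append({"marker": name, "feature": c.feature_name,
                              "coefficient": c.coefficient,
                              "p_value": c.p_value, "provenance": c.provenance})
        if cands.terminated:
            for kind in config.model_kinds:
                summary_rows.append({"marker": name, "model": kind.upper(),
                                     "status": "terminated at screening",
                                     "n_covariates": 0})
            tick(f"marker:{name}", t0)
            continue

        X, ids, patients = _design_from_candidates(matrices, cands)
        y = np.asarray(labels_full)[[sample_pos[s] for s in ids]]
        if np.unique(y).size < 2:
            for kind in config.model_kinds:
                summary_rows.append({"marker": name, "model": kind.upper(),
                                     "status": "single-class outcome",
                                     "n_covariates": 0})
            tick(f"marker:{name}", t0)
            continue
        X = X.iloc[:, :config.candidate_cap]
        for kind in config.model_kinds:
            report = cv_optimism(
                X, y, groups=patients, kind=kind, k=config.k_folds,
                seed=seeds["folds"], max_size=config.max_subset_size,
                threshold=config.bac_threshold,
                n_quadrature=config.n_quadrature,
                grouped_folds=config.grouped_folds, marker=name)
            summary_rows.append(report.summary_row())
            report.to_frame().to_csv(
                models_dir / f"cv_{name}_{kind}.csv", index=False)
            (models_dir / f"model_{name}_{kind}.txt").write_text(
                report.global_selection.best.summary() + "\n")
        tick(f"marker:{name}", t0)

    pd.DataFrame(cand_rows).to_csv(out / "candidates.csv", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)
    log["n_samples_input"] = n_input
    log["n_excluded_spectra"] = int(len(exclusion_log))
    log["elapsed"] = round(time.perf_counter() - t_all, 4)
    (out / "log.json").write_text(json.dumps(log, indent=2))
    return out
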