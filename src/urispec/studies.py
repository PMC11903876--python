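"""Seeded validation studies: parameter recovery, screening localization,
subset-selection behaviour and optimism correction on synthetic cohorts.

Each study regenerates its cohorts from a base seed, runs the relevant
pipeline stage end to end and returns raw per-seed outcomes, so the same
code backs both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import cv_optimism, roc_auc
from .io import build_matrices, cohort_to_records, filter_saturated, snv
from .models import RandomInterceptLogitModel, best_subset
from .screening import correlation_curve, select_candidates
from .simulate import (CohortConfig, MarkerProfile, Dist, generate_cohort,
                       single_band_marker)

_NULL_MARKER = MarkerProfile(
    name="flat", scale="quantitative", healthy_fraction=0.7,
    healthy_dist=Dist("gamma", (1.6, 0.3)),
    pathological_dist=Dist("gamma", (2.2, 1.1, 0.3)), cutoff=1.0)
_NULL_CHANNELS = (30, 70, 110, 150, 190, 230)


def sigma_recovery_study(n_seeds: int = 10, n_patients: int = 200,
                         samples_per_patient: int = 4, sigma_b: float = 1.0,
                         base_seed: int = 0) -> list[float]:
    """Refit sigma_b from cohorts generated with a known patient effect.

    The intercept-only random-intercept logit is exactly the generating
    model of the class labels; a balanced outcome maximises information
    about the variance component.
    """
    marker = single_band_marker(healthy_fraction=0.5)
    out = []
    for i in range(n_seeds):
        cohort = generate_cohort(
            CohortConfig(n_patients=n_patients,
                         samples_per_patient_dist=samples_per_patient,
                         patient_effect_sd=sigma_b, seed=base_seed + i),
            [marker])
        y = cohort.truth["single_band_class"].to_numpy()
        res = RandomInterceptLogitModel(
            y, np.empty((y.size, 0)), cohort.patient_ids).fit(
                compute_bse=False)
        out.append(float(res.sigma_b))
    return out


def localization_study(n_seeds: int = 20, n_patients: int = 130,
                       center_nm: float = 426.0,
                       base_seed: int = 0) -> list[float]:
    """Top screening candidate's wavelength for a one-band marker, per seed."""
    tops = []
    for i in range(n_seeds):
        marker = single_band_marker(center_nm=center_nm)
        cohort = generate_cohort(
            CohortConfig(n_patients=n_patients, seed=base_seed + i), [marker])
        records, _ = filter_saturated(cohort_to_records(cohort))
        mats = build_matrices(records)
        pos = {sid: k for k, sid in enumerate(cohort.sample_ids)}
        conc = cohort.truth["single_band_concentration"].to_numpy()
        curves = []
        for mat in mats.values():
            lab = conc[[pos[sid] for sid in mat.sample_ids]]
            curves.append(correlation_curve(mat, lab, "quantitative",
                                            marker="single_band"))
        cands = select_candidates(curves, max_per_marker=6)
        tops.append(float(cands.features[0].wavelength_nm)
                    if cands.features else np.nan)
    return tops


def selection_study(n_seeds: int = 20, n_patients: int = 250,
                    samples_per_patient: int = 4,
                    base_seed: int = 0) -> pd.DataFrame:
    """AIC best subset with 1 informative SNV channel + 3 pure-noise columns.

    Returns per-seed flags: informative feature retained / all noise
    features excluded (n ~ 1000 samples per seed).
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        marker = single_band_marker()
        cohort = generate_cohort(
            CohortConfig(n_patients=n_patients,
                         samples_per_patient_dist=samples_per_patient,
                         seed=seed), [marker])
        ch = cohort.grid.nearest_channel(426.0)
        rng = np.random.default_rng(10_000 + seed)
        X = pd.DataFrame({
            "band": snv(cohort.spectra[("DT", "low")])[:, ch],
            "noise1": rng.normal(size=cohort.n_samples),
            "noise2": rng.normal(size=cohort.n_samples),
            "noise3": rng.normal(size=cohort.n_samples)})
        y = cohort.truth["single_band_class"].to_numpy()
        feats = set(best_subset(X, y, kind="lr").selected_features)
        rows.append({"seed": seed, "informative": "band" in feats,
                     "noise_free": not feats & {"noise1", "noise2", "noise3"},
                     "n": cohort.n_samples})
    return pd.DataFrame(rows)


def null_optimism_study(n_seeds: int = 20, n_patients: int = 150,
                        base_seed: int = 0) -> pd.DataFrame:
    """Optimism correction with spectra carrying no marker signal.

    Six arbitrary SNV channels of an absorption-free marker's cohort act
    as candidates; subset selection is restricted to feature-bearing
    models so the inner performance exhibits overfitting.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cohort = generate_cohort(
            CohortConfig(n_patients=n_patients, samples_per_patient_dist=3,
                         seed=seed), [_NULL_MARKER])
        S = snv(cohort.spectra[("DT", "low")])
        X = pd.DataFrame({f"ch{k}": S[:, k] for k in _NULL_CHANNELS})
        y = cohort.truth["flat_class"].to_numpy()
        rep = cv_optimism(X, y, groups=cohort.patient_ids, kind="lr",
                          seed=seed, include_baseline=False, marker="flat")
        rows.append({"seed": seed, "inner_auc": rep.global_inner.auc,
                     "corrected_auc": rep.corrected_auc})
    return pd.DataFrame(rows)


def holdout_closeness_study(n_seeds: int = 20, n_patients: int = 100,
                            holdout_n: int = 10_000,
                            base_seed: int = 0) -> pd.DataFrame:
    """Corrected vs inner AUC against a large fresh holdout, per seed.

    Clustered cohorts with a random-intercept model: conditional (BLUP)
    inner predictions are strongly optimistic, which is exactly what the
    cross-validated correction is meant to remove.
    """
    marker = single_band_marker(healthy_fraction=0.7)
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cohort = generate_cohort(
            CohortConfig(n_patients=n_patients, samples_per_patient_dist=3,
                         patient_effect_sd=1.0, seed=seed), [marker])
        ch = cohort.grid.nearest_channel(426.0)
        S = snv(cohort.spectra[("DT", "low")])
        X = pd.DataFrame({"band": S[:, ch], "off": S[:, 230]})
        y = cohort.truth["single_band_class"].to_numpy()
        rep = cv_optimism(X, y, groups=cohort.patient_ids, kind="lrre",
                          seed=seed, marker="single_band")

        hold = generate_cohort(
            CohortConfig(n_patients=(holdout_n + 2) // 3,
                         samples_per_patient_dist=3, patient_effect_sd=1.0,
                         seed=900_000 + seed), [marker])
        Sh = snv(hold.spectra[("DT", "low")])
        Xh = pd.DataFrame({"band": Sh[:, ch],
                           "off": Sh[:, 230]}).iloc[:holdout_n]
        yh = hold.truth["single_band_class"].to_numpy()[:holdout_n]
        sel = rep.global_selection
        Xh_sel = Xh[list(sel.selected_features)] if sel.selected_features \
            else Xh[[]]
        scores = sel.best.predict(Xh_sel, groups=["unseen"] * len(Xh),
                                  mode="marginal")
        auc_h = roc_auc(scores, yh)
        rows.append({
            "seed": seed, "inner_auc": rep.global_inner.auc,
            "corrected_auc": rep.corrected_auc, "holdout_auc": auc_h,
            "corrected_closer": abs(rep.corrected_auc - auc_h)
                                < abs(rep.global_inner.auc - auc_h)})
    return pd.DataFrame(rows)
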