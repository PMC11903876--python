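"""Synthetic hyperspectral urine cohorts.

Emulates the measurement setup of a catheter-output mini-spectrometer:
each sample is read out along three light paths (direct transmission DT,
angular transmission AT, angular reflection AR) at two exposure times,
giving six spectra of 288 channels over 340-850 nm with a 65,000-count
detector ceiling.  Marker concentrations imprint Beer-Lambert absorption
bands on a smooth broadband baseline; per-spectrum multiplicative scatter
and additive offset artifacts reproduce the distortion family that SNV
normalization removes; repeated samples from one patient share a latent
patient effect so that mixed-model validation is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import ConfigurationError

LIGHT_PATHS = ("DT", "AT", "AR")
EXPOSURES = ("low", "high")
SETTINGS = tuple((p, e) for p in LIGHT_PATHS for e in EXPOSURES)


# ---------------------------------------------------------------------------
# wavelength grid

@dataclass(frozen=True)
class WavelengthGrid:
    """Channel-index -> wavelength calibration of the detector.

    The default is a linear map of 288 channels onto [340, 850] nm.  The
    true device calibration is instrument specific, so the grid is
    injectable everywhere it is consumed.
    """

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ConfigurationError("wavelengths: need a 1-D grid with >= 2 channels")
        if not np.all(np.diff(wl) > 0):
            raise ConfigurationError("wavelengths: grid must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    @classmethod
    def default(cls, n_channels: int = 288, low_nm: float = 340.0,
                high_nm: float = 850.0) -> "WavelengthGrid":
        return cls(np.linspace(low_nm, high_nm, n_channels))

    def nearest_channel(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


# ---------------------------------------------------------------------------
# marker profiles

@dataclass(frozen=True)
class Dist:
    """A small parametric-distribution spec for latent concentrations."""

    family: str  # lognormal | gamma | normal | uniform
    params: tuple

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f, p = self.family, self.params
        if f == "lognormal":
            return rng.lognormal(mean=p[0], sigma=p[1], size=size)
        if f == "gamma":
            loc = p[2] if len(p) > 2 else 0.0
            return loc + rng.gamma(shape=p[0], scale=p[1], size=size)
        if f == "normal":
            return rng.normal(loc=p[0], scale=p[1], size=size)
        if f == "uniform":
            return rng.uniform(low=p[0], high=p[1], size=size)
        raise ConfigurationError(f"dist family: unknown family {f!r}")


@dataclass(frozen=True)
class AbsorptionBand:
    """Gaussian extinction band: epsilon(lambda) per unit concentration."""

    center_nm: float
    width_nm: float
    extinction_scale: float

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ConfigurationError("absorption_bands: width_nm must be > 0")

    def extinction(self, wavelengths: np.ndarray) -> np.ndarray:
        d = (np.asarray(wavelengths) - self.center_nm) / self.width_nm
        return self.extinction_scale * np.exp(-0.5 * d * d)


@dataclass(frozen=True)
class MarkerProfile:
    """Generative definition of one urine marker.

    ``healthy_fraction`` is the marginal proportion of healthy samples;
    the per-patient random effect shifts the class log-odds, and the
    class-probability intercept is calibrated so the marginal fraction is
    exact under that effect.  ``ordinal_thresholds`` cut the latent
    concentration into the dipstick levels (first threshold = cutoff, so
    class and dipstick level agree).
    """

    name: str
    scale: str  # quantitative | ordinal
    healthy_fraction: float
    healthy_dist: Dist
    pathological_dist: Dist
    absorption_bands: tuple[AbsorptionBand, ...] = ()
    ordinal_levels: tuple[str, ...] = ()
    ordinal_thresholds: tuple[float, ...] = ()
    cutoff: float | None = None
    direction: str = "high_is_pathological"
    range_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if self.scale not in ("quantitative", "ordinal"):
            raise ConfigurationError(f"scale: {self.scale!r} for marker {self.name}")
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ConfigurationError(f"healthy_fraction: out of [0,1] for {self.name}")
        if self.scale == "ordinal":
            if len(self.ordinal_levels) < 2:
                raise ConfigurationError(f"ordinal_levels: need >= 2 for {self.name}")
            if len(self.ordinal_thresholds) != len(self.ordinal_levels) - 1:
                raise ConfigurationError(
                    f"ordinal_thresholds: need len(levels)-1 for {self.name}")
        if self.direction == "range":
            if self.range_bounds is None or not self.range_bounds[0] < self.range_bounds[1]:
                raise ConfigurationError(f"range_bounds: need low < high for {self.name}")

    def extinction(self, wavelengths: np.ndarray) -> np.ndarray:
        eps = np.zeros(np.asarray(wavelengths).shape, dtype=float)
        for band in self.absorption_bands:
            eps = eps + band.extinction(wavelengths)
        return eps

    def ordinal_level(self, concentration: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.ordinal_thresholds), concentration,
                              side="right")
        return np.asarray(self.ordinal_levels, dtype=object)[idx]


# ---------------------------------------------------------------------------
# cohort configuration

def _default_baseline(grid: WavelengthGrid, scale: float) -> np.ndarray:
    """Smooth broadband baseline: UV + full-spectrum + NIR emitter mix."""
    wl = grid.wavelengths
    def g(c, w):
        return np.exp(-0.5 * ((wl - c) / w) ** 2)
    shape = 0.55 * g(365.0, 22.0) + 1.0 * g(520.0, 150.0) + 0.5 * g(780.0, 60.0) + 0.05
    return scale * shape / shape.max()


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and instrument parameters of a synthetic cohort.

    Defaults emulate the pilot cohort this package targets: patients
    contribute 1-11 samples (truncated-geometric, mean ~3), the detector
    ceiling is 65,000 counts, and the high exposure saturates a minority
    of samples.
    """

    n_patients: int = 168
    samples_per_patient_dist: Mapping[int, float] | int | None = None
    patient_effect_sd: float = 1.0
    baseline_spectra: Mapping[str, np.ndarray] | None = None
    pathlength: Mapping[str, float] = field(
        default_factory=lambda: {"DT": 1.0, "AT": 0.6, "AR": 0.35})
    scatter_sd: float = 0.15
    offset_sd: float = 300.0
    noise_sd: float = 60.0
    exposure_gains: tuple[float, float] = (1.0, 4.5)
    saturation_limit: float = 65000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients: must be >= 1")
        for name in ("patient_effect_sd", "scatter_sd", "offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if not self.exposure_gains[0] < self.exposure_gains[1]:
            raise ConfigurationError("exposure_gains: must be strictly increasing")
        if self.saturation_limit <= 0:
            raise ConfigurationError("saturation_limit: must be > 0")

    def baselines(self, grid: WavelengthGrid) -> dict[str, np.ndarray]:
        if self.baseline_spectra is not None:
            out = {p: np.asarray(self.baseline_spectra[p], float) for p in LIGHT_PATHS}
        else:
            out = {"DT": _default_baseline(grid, 12000.0),
                   "AT": _default_baseline(grid, 8500.0),
                   "AR": _default_baseline(grid, 5500.0)}
        for p, i0 in out.items():
            if np.any(i0 < 0):
                raise ConfigurationError(f"baseline_spectra: negative intensity ({p})")
        return out

    def draw_samples_per_patient(self, rng: np.random.Generator, n: int) -> np.ndarray:
        dist = self.samples_per_patient_dist
        if dist is None:
            # truncated geometric on 1..11; p chosen for mean ~3 samples/patient
            counts = np.arange(1, 12)
            pmf = (1 - 0.31) ** (counts - 1) * 0.31
            pmf /= pmf.sum()
            return rng.choice(counts, size=n, p=pmf)
        if isinstance(dist, int):
            return np.full(n, dist, dtype=int)
        counts = np.array(sorted(dist), dtype=int)
        if counts.min() < 1 or counts.max() > 11:
            raise ConfigurationError("samples_per_patient_dist: support must be in 1..11")
        pmf = np.array([dist[int(c)] for c in counts], dtype=float)
        if not np.isclose(pmf.sum(), 1.0):
            raise ConfigurationError("samples_per_patient_dist: probabilities must sum to 1")
        return rng.choice(counts, size=n, p=pmf)


# ---------------------------------------------------------------------------
# physics

def synth_spectrum(i0: np.ndarray,
                   markers: Sequence[MarkerProfile],
                   concentrations: Mapping[str, float],
                   wavelengths: np.ndarray,
                   pathlength: float = 1.0,
                   exposure_gain: float = 1.0,
                   scatter: float = 1.0,
                   offset: float = 0.0,
                   noise: np.ndarray | float = 0.0,
                   limit: float = 65000.0) -> np.ndarray:
    """One detector read-out from a Beer-Lambert transmission model.

    I(lambda) = clip(scatter * gain * I0(lambda) * 10^(-L * sum_m eps_m(lambda) c_m)
                     + offset + noise, 0, limit)
    """
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 < 0):
        raise ConfigurationError("baseline intensity: must be non-negative")
    absorbance = np.zeros_like(i0)
    for m in markers:
        c = float(concentrations.get(m.name, 0.0))
        if c < 0:
            raise ValueError(f"negative concentration for marker {m.name!r}")
        if c and m.absorption_bands:
            absorbance += c * m.extinction(wavelengths)
    raw = scatter * exposure_gain * i0 * np.power(10.0, -pathlength * absorbance)
    return np.clip(raw + offset + noise, 0.0, limit)


def calibrate_class_intercept(p_pathological: float, sd: float,
                              n_nodes: int = 64) -> float:
    """Intercept a such that E_b[expit(a + b)] = p for b ~ N(0, sd^2).

    Gauss-Hermite integration of the logistic-normal mean plus 1-D root
    finding; exact marginal class balance under patient clustering.
    """
    if p_pathological <= 0.0:
        return -np.inf
    if p_pathological >= 1.0:
        return np.inf
    if sd == 0.0:
        return float(logit(p_pathological))
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    b = np.sqrt(2.0) * sd * x
    wn = w / np.sqrt(np.pi)

    def marginal(a):
        return float(wn @ expit(a + b)) - p_pathological

    lo = logit(p_pathological) - 6 * sd - 1.0
    hi = logit(p_pathological) + 6 * sd + 1.0
    return float(brentq(marginal, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# cohort container + generation

@dataclass
class Cohort:
    """In-memory synthetic dataset: six spectra matrices + lab + truth tables."""

    grid: WavelengthGrid
    sample_ids: list[str]
    patient_ids: list[str]
    spectra: dict[tuple[str, str], np.ndarray]  # (path, exposure) -> (n, channels)
    lab: pd.DataFrame
    truth: pd.DataFrame
    markers: tuple[MarkerProfile, ...]
    config: CohortConfig

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_spectra(self) -> int:
        return sum(v.shape[0] for v in self.spectra.values())


def generate_cohort(config: CohortConfig,
                    markers: Sequence[MarkerProfile],
                    grid: WavelengthGrid | None = None) -> Cohort:
    """Draw a complete cohort: patients, classes, concentrations, spectra.

    Returns a :class:`Cohort`; the ``truth`` table records latent patient
    effects, class labels and concentrations for recovery tests.  Fully
    reproducible from ``config.seed``.
    """
    names = [m.name for m in markers]
    if len(set(names)) != len(names):
        raise ConfigurationError("markers: names must be unique")
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(config.seed)

    per_patient = config.draw_samples_per_patient(rng, config.n_patients)
    n = int(per_patient.sum())
    patient_index = np.repeat(np.arange(config.n_patients), per_patient)
    patient_ids = [f"P{i + 1:04d}" for i in patient_index]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    lab = {"sample_id": sample_ids, "patient_id": patient_ids}
    truth = {"sample_id": sample_ids, "patient_id": patient_ids}
    conc = np.zeros((n, len(markers)))
    for j, m in enumerate(markers):
        # independent per-marker patient effect: markers are not confounded
        # through a common latent, so an absorption-free marker stays
        # uncorrelated with every spectral channel
        b = rng.normal(0.0, config.patient_effect_sd, size=config.n_patients)
        b_sample = b[patient_index]
        p_path = 1.0 - m.healthy_fraction
        alpha = calibrate_class_intercept(p_path, config.patient_effect_sd)
        prob = expit(alpha + b_sample) if np.isfinite(alpha) else np.full(n, p_path)
        cls = rng.random(n) < prob
        c = np.where(cls,
                     m.pathological_dist.sample(rng, n),
                     m.healthy_dist.sample(rng, n))
        c = np.maximum(c, 0.0)
        conc[:, j] = c
        truth[f"{m.name}_patient_effect"] = b_sample
        truth[f"{m.name}_class"] = cls.astype(int)
        truth[f"{m.name}_concentration"] = c
        lab[m.name] = m.ordinal_level(c) if m.scale == "ordinal" else c

    baselines = config.baselines(grid)
    eps = np.vstack([m.extinction(grid.wavelengths) for m in markers])  # (M, C)
    spectra: dict[tuple[str, str], np.ndarray] = {}
    gains = dict(zip(EXPOSURES, config.exposure_gains))
    for path in LIGHT_PATHS:
        absorb = config.pathlength[path] * (conc @ eps)  # (n, C)
        trans = baselines[path][None, :] * np.power(10.0, -absorb)
        for exposure in EXPOSURES:
            scatter = np.exp(rng.normal(0.0, config.scatter_sd, size=(n, 1)))
            offset = rng.normal(0.0, config.offset_sd, size=(n, 1))
            noise = rng.normal(0.0, config.noise_sd, size=trans.shape)
            raw = scatter * gains[exposure] * trans + offset + noise
            spectra[(path, exposure)] = np.clip(raw, 0.0, config.saturation_limit)

    return Cohort(grid=grid, sample_ids=sample_ids, patient_ids=patient_ids,
                  spectra=spectra, lab=pd.DataFrame(lab),
                  truth=pd.DataFrame(truth), markers=tuple(markers),
                  config=config)


# ---------------------------------------------------------------------------
# default marker battery

def default_marker_profiles() -> tuple[MarkerProfile, ...]:
    """A compact battery mirroring a catheter-urinalysis panel.

    Band centers follow literature absorption maxima (bilirubin ~426 nm,
    haemoglobin Soret band ~414 nm, urobilinogen ~490 nm); glucose carries
    no band in the visible range, so its spectra are uninformative and
    its classifier cross-validates to chance.
    """
    dip = ("neg", "1+", "2+", "3+")
    return (
        MarkerProfile(
            name="bilirubin", scale="ordinal", healthy_fraction=0.93,
            healthy_dist=Dist("gamma", (1.6, 0.3)),
            pathological_dist=Dist("gamma", (2.2, 1.1, 0.3)),
            absorption_bands=(AbsorptionBand(426.0, 12.0, 0.02),),
            ordinal_levels=dip, ordinal_thresholds=(1.0, 2.5, 5.0),
            cutoff=1.0),
        MarkerProfile(
            name="erythrocytes", scale="quantitative", healthy_fraction=0.70,
            healthy_dist=Dist("gamma", (1.5, 10.0)),
            pathological_dist=Dist("gamma", (2.0, 45.0, 15.0)),
            absorption_bands=(AbsorptionBand(414.0, 12.0, 0.0004),
                              AbsorptionBand(541.0, 15.0, 0.00012)),
            cutoff=25.0),
        MarkerProfile(
            name="urobilinogen", scale="ordinal", healthy_fraction=0.85,
            healthy_dist=Dist("gamma", (1.6, 0.35)),
            pathological_dist=Dist("gamma", (2.0, 1.4, 0.5)),
            absorption_bands=(AbsorptionBand(490.0, 12.0, 0.02),),
            ordinal_levels=dip, ordinal_thresholds=(1.0, 3.0, 6.0),
            cutoff=1.0),
        MarkerProfile(
            name="protein", scale="quantitative", healthy_fraction=0.55,
            healthy_dist=Dist("gamma", (1.8, 60.0)),
            pathological_dist=Dist("gamma", (2.2, 130.0, 60.0)),
            absorption_bands=(AbsorptionBand(352.0, 28.0, 0.0002),),
            cutoff=150.0),
        MarkerProfile(
            name="glucose", scale="quantitative", healthy_fraction=0.90,
            healthy_dist=Dist("gamma", (1.5, 5.0)),
            pathological_dist=Dist("gamma", (2.0, 30.0, 10.0)),
            absorption_bands=(),
            cutoff=15.0),
    )


def single_band_marker(center_nm: float = 426.0, width_nm: float = 10.0,
                       extinction_scale: float = 0.015,
                       healthy_fraction: float = 0.93) -> MarkerProfile:
    """Canonical one-band quantitative marker for localization studies.

    Typical pathological absorbances stay below ~0.1 (linear Beer-Lambert
    regime), so the correlation extremum coincides with the band center.
    """
    return MarkerProfile(
        name="single_band", scale="quantitative",
        healthy_fraction=healthy_fraction,
        healthy_dist=Dist("gamma", (1.6, 0.3)),
        pathological_dist=Dist("gamma", (2.2, 1.1, 0.3)),
        absorption_bands=(AbsorptionBand(center_nm, width_nm, extinction_scale),),
        cutoff=1.0)
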