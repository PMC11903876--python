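"""Per-wavelength correlation screening of spectra against lab values.

For each spectrometer setting the SNV-scaled intensities form an n x 288
matrix; each column is correlated with the laboratory vector — Pearson
for quantitative markers, Kendall tau-b (tie-corrected, normal-
approximation p-value) for ordinal dipstick read-outs.  The resulting
correlation curves are screened for significant local extrema of |r|
outside flat "plateau" stretches, which are nonspecific and excluded;
literature-prior wavelengths can be added when significant.  Markers
with no significant feature terminate screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateMarkerError
from .io import SpectraMatrix


@dataclass
class CorrelationCurve:
    marker: str
    setting: tuple[str, str]
    method: str  # pearson | kendall
    wavelengths: np.ndarray
    coefficients: np.ndarray
    p_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker,
            "setting": f"{self.setting[0]}_{self.setting[1]}",
            "wavelength_nm": self.wavelengths,
            "coefficient": self.coefficients,
            "p_value": self.p_values})


@dataclass(frozen=True)
class Candidate:
    setting: tuple[str, str]
    channel: int
    wavelength_nm: float
    coefficient: float
    p_value: float
    provenance: str  # curve_extremum | literature_prior

    @property
    def feature_name(self) -> str:
        return f"{self.setting[0]}_{self.setting[1]}_{self.wavelength_nm:.2f}"


@dataclass
class CandidateSet:
    marker: str
    features: list[Candidate]
    terminated: bool = False


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction; normal-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("kendall_tau_b: need equal-length vectors of size >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateMarkerError("kendall_tau_b: all-tied input vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _encode_lab(lab_values, scale: str) -> np.ndarray:
    vals = np.asarray(lab_values)
    if scale == "ordinal" and vals.dtype == object:
        levels = {v: i for i, v in enumerate(pd.unique(vals))}
        raise ValueError(
            "ordinal lab values must be numerically encoded before screening; "
            f"got labels {sorted(map(str, levels))}")
    return vals.astype(float)


def encode_ordinal(values, levels) -> np.ndarray:
    """Map ordinal dipstick labels to their rank in the declared level order."""
    lut = {str(level): i for i, level in enumerate(levels)}
    try:
        return np.array([lut[str(v)] for v in np.asarray(values, dtype=object)],
                        dtype=float)
    except KeyError as e:
        raise ValueError(f"unknown ordinal level {e.args[0]!r}") from None


def correlation_curve(S: SpectraMatrix, lab_values, scale: str,
                      marker: str = "") -> CorrelationCurve:
    """Coefficient and two-sided p-value of each wavelength vs the lab vector."""
    l = _encode_lab(lab_values, scale)
    if l.size != S.values.shape[0]:
        raise ValueError("lab vector length does not match the spectra matrix")
    if np.unique(l).size < 2:
        raise DegenerateMarkerError(f"marker {marker or '?'}: constant lab vector")
    n_ch = S.values.shape[1]
    coef = np.empty(n_ch)
    pval = np.empty(n_ch)
    if scale == "quantitative":
        method = "pearson"
        for i in range(n_ch):
            col = S.values[:, i]
            if np.std(col) == 0:
                coef[i], pval[i] = 0.0, 1.0
                continue
            r, p = stats.pearsonr(col, l)
            coef[i], pval[i] = r, p
    else:
        method = "kendall"
        for i in range(n_ch):
            col = S.values[:, i]
            if np.unique(col).size < 2:
                coef[i], pval[i] = 0.0, 1.0
                continue
            coef[i], pval[i] = kendall_tau_b(col, l)
    return CorrelationCurve(marker=marker, setting=S.setting, method=method,
                            wavelengths=np.asarray(S.wavelengths, float),
                            coefficients=coef, p_values=pval)


def detect_plateau(curve: CorrelationCurve | np.ndarray, window: int = 15,
                   flatness_tol: float = 0.05) -> np.ndarray:
    """Mask channels lying in flat stretches of the correlation curve.

    A channel is flagged when the rolling range (max - min) of the
    coefficients over a centred window stays below ``flatness_tol`` for a
    run of at least ``window`` channels.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    coef = curve.coefficients if isinstance(curve, CorrelationCurve) else np.asarray(curve)
    n = coef.size
    s = pd.Series(coef)
    rng = (s.rolling(window, center=True, min_periods=1).max()
           - s.rolling(window, center=True, min_periods=1).min()).to_numpy()
    flat = rng < flatness_tol
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if flat[i]:
            j = i
            while j < n and flat[j]:
                j += 1
            if j - i >= window:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def _local_extrema(abscoef: np.ndarray) -> np.ndarray:
    """Channels whose |r| >= both neighbours (ties -> lower wavelength)."""
    n = abscoef.size
    idx = []
    for i in range(n):
        left = abscoef[i - 1] if i > 0 else -np.inf
        right = abscoef[i + 1] if i < n - 1 else -np.inf
        if abscoef[i] >= left and abscoef[i] >= right:
            # tie run: keep only its first channel
            if i > 0 and abscoef[i] == abscoef[i - 1] and idx and idx[-1] == i - 1:
                continue
            idx.append(i)
    return np.array(idx, dtype=int)


def select_candidates(curves: list[CorrelationCurve], alpha: float = 0.05,
                      max_per_marker: int = 6,
                      priors: list[float] | None = None,
                      plateau_window: int = 15,
                      plateau_tol: float = 0.05) -> CandidateSet:
    """Significant local |r| extrema outside plateaus, plus significant priors.

    Candidates are ranked by |coefficient| and truncated to
    ``max_per_marker``; an empty result is flagged ``terminated`` (the
    marker leaves the analysis at screening).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if max_per_marker < 1:
        raise ValueError("max_per_marker must be >= 1")
    marker = curves[0].marker if curves else ""
    found: dict[tuple[tuple[str, str], int], Candidate] = {}
    for curve in curves:
        mask = detect_plateau(curve, window=plateau_window, flatness_tol=plateau_tol)
        abscoef = np.abs(curve.coefficients)
        for ch in _local_extrema(abscoef):
            if mask[ch] or not curve.p_values[ch] < alpha:
                continue
            key = (curve.setting, int(ch))
            found[key] = Candidate(curve.setting, int(ch),
                                   float(curve.wavelengths[ch]),
                                   float(curve.coefficients[ch]),
                                   float(curve.p_values[ch]), "curve_extremum")
    ranked = sorted(found.values(),
                    key=lambda c: (-abs(c.coefficient), c.wavelength_nm,
                                   c.setting))[:max_per_marker]
    keys = {(c.setting, c.channel) for c in ranked}
    if priors:
        for wl in priors:
            for curve in curves:
                ch = int(np.argmin(np.abs(curve.wavelengths - wl)))
                key = (curve.setting, ch)
                if key in keys or not curve.p_values[ch] < alpha:
                    continue
                ranked.append(Candidate(curve.setting, ch,
                                        float(curve.wavelengths[ch]),
                                        float(curve.coefficients[ch]),
                                        float(curve.p_values[ch]),
                                        "literature_prior"))
                keys.add(key)
    return CandidateSet(marker=marker, features=ranked, terminated=not ranked)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional multiplicity control; off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        adj[order[rank]] = running
    return adj
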