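"""Dataset I/O, saturation filtering and SNV normalization.

The on-disk dialect is plain CSV (UTF-8, "." decimal).  Two layouts are
supported: *wide* (one row per recorded spectrum, one column per channel,
columns named by wavelength) and *long* (one row per channel).  The lab
table carries one row per sample with sample_id, patient_id and one
column per marker.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (DegenerateSpectrumError, FormatError, JoinError)
from .simulate import Cohort

_WL_FMT = "wl_{:.3f}"


# ---------------------------------------------------------------------------
# containers

@dataclass
class Spectrum:
    """One light-path/exposure read-out of one sample."""

    sample_id: str
    patient_id: str
    light_path: str
    exposure: str
    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise FormatError(
                f"spectrum {self.sample_id}/{self.light_path}/{self.exposure}: "
                "wavelengths and intensities differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError(f"spectrum {self.sample_id}: wavelengths not increasing")

    @property
    def setting(self) -> tuple[str, str]:
        return (self.light_path, self.exposure)


@dataclass
class SampleRecord:
    """The (up to) six spectra of one sample joined to its lab values."""

    sample_id: str
    patient_id: str
    spectra: dict[tuple[str, str], Spectrum] = field(default_factory=dict)
    lab_values: dict[str, object] = field(default_factory=dict)


@dataclass
class SpectraMatrix:
    """n x channels matrix of one spectrometer setting, row-aligned to samples."""

    setting: tuple[str, str]
    sample_ids: list[str]
    patient_ids: list[str]
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.wavelengths)):
            raise FormatError("SpectraMatrix: shape does not match ids/grid")

    @property
    def label(self) -> str:
        return f"{self.setting[0]}_{self.setting[1]}"


# ---------------------------------------------------------------------------
# SNV

def snv(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard Normal Variate transform of a spectrum (or rows of a matrix).

    s~_i = (s_i - mean(s)) / sd(s); the output has zero mean and unit
    variance per spectrum.  The sample (n-1) standard deviation is used,
    the chemometrics convention.
    """
    x = np.asarray(values, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("constant spectrum: standard deviation is zero")
    return (x - mu) / sd


def snv_spectrum(spectrum: Spectrum, ddof: int = 1) -> Spectrum:
    """SNV-transform one :class:`Spectrum`, naming the sample on failure."""
    try:
        scaled = snv(spectrum.intensities, ddof=ddof)
    except DegenerateSpectrumError:
        raise DegenerateSpectrumError(
            f"constant spectrum for sample {spectrum.sample_id!r} "
            f"({spectrum.light_path}/{spectrum.exposure})") from None
    return Spectrum(spectrum.sample_id, spectrum.patient_id, spectrum.light_path,
                    spectrum.exposure, spectrum.wavelengths, scaled)


# ---------------------------------------------------------------------------
# saturation filter

def filter_saturated(records: Sequence[SampleRecord],
                     limit: float = 65000.0,
                     dataset_wide: bool = False
                     ) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Remove oversaturated high-exposure measurements.

    If any high-exposure spectrum of a sample contains a channel at or
    above ``limit`` (the ceiling value itself counts as clipped), the
    high-exposure spectra of all three light paths are removed for that
    sample; low-exposure spectra are always retained.  With
    ``dataset_wide=True`` a single saturated sample removes the high
    exposure for the whole dataset.

    Returns the filtered records and an exclusion log with one row per
    removed (sample, light_path) pair.
    """
    if limit <= 0:
        raise ValueError("limit must be > 0")
    triggers: dict[str, tuple[str, int, float]] = {}
    for rec in records:
        for (path, exposure), sp in rec.spectra.items():
            if exposure != "high":
                continue
            peak = int(np.argmax(sp.intensities))
            if sp.intensities[peak] >= limit:
                if rec.sample_id not in triggers:
                    triggers[rec.sample_id] = (path, peak, float(sp.intensities[peak]))

    drop_all = dataset_wide and bool(triggers)
    out: list[SampleRecord] = []
    log_rows = []
    for rec in records:
        hit = rec.sample_id in triggers or drop_all
        kept = {k: v for k, v in rec.spectra.items() if not (hit and k[1] == "high")}
        out.append(SampleRecord(rec.sample_id, rec.patient_id, kept,
                                dict(rec.lab_values)))
        if hit:
            tpath, tchan, tval = triggers.get(
                rec.sample_id, next(iter(triggers.values())))
            for (path, exposure) in rec.spectra:
                if exposure == "high":
                    log_rows.append({
                        "sample_id": rec.sample_id, "light_path": path,
                        "exposure": exposure, "trigger_path": tpath,
                        "trigger_channel": tchan, "trigger_intensity": tval,
                        "reason": "saturated" if rec.sample_id in triggers
                                  else "dataset_wide"})
    log = pd.DataFrame(log_rows, columns=["sample_id", "light_path", "exposure",
                                          "trigger_path", "trigger_channel",
                                          "trigger_intensity", "reason"])
    return out, log


# ---------------------------------------------------------------------------
# matrix assembly

def build_matrices(records: Sequence[SampleRecord],
                   settings: Iterable[tuple[str, str]] | None = None,
                   apply_snv: bool = True) -> dict[tuple[str, str], SpectraMatrix]:
    """Stack per-setting spectra into n x 288 matrices (complete-case).

    Samples lacking a setting (e.g. removed by the saturation filter) are
    dropped from that setting's matrix only.
    """
    if settings is None:
        settings = sorted({s for rec in records for s in rec.spectra})
    out = {}
    for setting in settings:
        ids, pids, rows, wl = [], [], [], None
        for rec in records:
            sp = rec.spectra.get(setting)
            if sp is None:
                continue
            ids.append(rec.sample_id)
            pids.append(rec.patient_id)
            rows.append(sp.intensities)
            wl = sp.wavelengths
        if not ids:
            continue
        values = np.vstack(rows)
        if apply_snv:
            values = snv(values)
        out[setting] = SpectraMatrix(setting, ids, pids, wl, values)
    return out


# ---------------------------------------------------------------------------
# writing

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def cohort_to_wide(cohort: Cohort) -> pd.DataFrame:
    cols = [_WL_FMT.format(w) for w in cohort.grid.wavelengths]
    frames = []
    for (path, exposure), mat in sorted(cohort.spectra.items()):
        df = pd.DataFrame(mat, columns=cols)
        df.insert(0, "exposure", exposure)
        df.insert(0, "light_path", path)
        df.insert(0, "patient_id", cohort.patient_ids)
        df.insert(0, "sample_id", cohort.sample_ids)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_to_long(cohort: Cohort) -> pd.DataFrame:
    wl = cohort.grid.wavelengths
    n_ch = wl.size
    frames = []
    for (path, exposure), mat in sorted(cohort.spectra.items()):
        n = mat.shape[0]
        frames.append(pd.DataFrame({
            "sample_id": np.repeat(cohort.sample_ids, n_ch),
            "patient_id": np.repeat(cohort.patient_ids, n_ch),
            "light_path": path, "exposure": exposure,
            "channel": np.tile(np.arange(1, n_ch + 1), n),
            "wavelength_nm": np.tile(wl, n),
            "intensity": mat.ravel()}))
    return pd.concat(frames, ignore_index=True)


def write_dataset(cohort: Cohort, out_dir: str | Path,
                  layout: str = "wide") -> pd.DataFrame:
    """Write spectra, lab and truth tables as CSV; return a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if layout == "wide":
        spectra_df = cohort_to_wide(cohort)
    elif layout == "long":
        spectra_df = cohort_to_long(cohort)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    files = {"spectra.csv": spectra_df, "lab.csv": cohort.lab,
             "truth.csv": cohort.truth}
    rows = []
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=False)
        rows.append({"file": name, "sha256": _sha256(path), "n_rows": len(df)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# reading

def _records_from_parts(parts, lab: pd.DataFrame) -> list[SampleRecord]:
    lab = lab.copy()
    if "sample_id" not in lab.columns:
        raise FormatError("lab table: missing sample_id column")
    lab_ids = set(lab["sample_id"].astype(str))
    seen = {sid for sid, *_ in parts}
    missing = sorted(seen - lab_ids)
    if missing:
        raise JoinError("spectra reference sample ids absent from the lab table: "
                        + ", ".join(missing))
    markers = [c for c in lab.columns if c not in ("sample_id", "patient_id")]
    by_id: dict[str, SampleRecord] = {}
    for _, row in lab.iterrows():
        sid = str(row["sample_id"])
        by_id[sid] = SampleRecord(sid, str(row.get("patient_id", "")),
                                  lab_values={m: row[m] for m in markers})
    for sid, pid, path, exposure, wl, inten in parts:
        rec = by_id[sid]
        rec.spectra[(path, exposure)] = Spectrum(sid, pid, path, exposure, wl, inten)
    return [by_id[sid] for sid in lab["sample_id"].astype(str)]


def read_dataset(spectra_path: str | Path, lab_path: str | Path,
                 n_channels: int = 288) -> list[SampleRecord]:
    """Read a spectra CSV (wide or long layout) joined to its lab table.

    Every spectrum's sample id must appear in the lab table; channel
    counts are validated against ``n_channels``.
    """
    spectra = pd.read_csv(spectra_path)
    lab = pd.read_csv(lab_path)
    parts = []
    if "intensity" in spectra.columns:  # long layout
        for (sid, pid, path, exposure), grp in spectra.groupby(
                ["sample_id", "patient_id", "light_path", "exposure"], sort=False):
            grp = grp.sort_values("channel")
            if len(grp) != n_channels:
                raise FormatError(
                    f"spectrum {sid}/{path}/{exposure}: {len(grp)} channels, "
                    f"expected {n_channels}")
            parts.append((str(sid), str(pid), path, exposure,
                          grp["wavelength_nm"].to_numpy(),
                          grp["intensity"].to_numpy()))
    else:  # wide layout
        wl_cols = [c for c in spectra.columns if c.startswith("wl_")]
        if len(wl_cols) != n_channels:
            raise FormatError(f"wide spectra table: {len(wl_cols)} channel columns, "
                              f"expected {n_channels}")
        wl = np.array([float(c[3:]) for c in wl_cols])
        values = spectra[wl_cols].to_numpy(dtype=float)
        for i, row in enumerate(spectra.itertuples(index=False)):
            parts.append((str(row.sample_id), str(row.patient_id), row.light_path,
                          row.exposure, wl, values[i]))
    return _records_from_parts(parts, lab)


def cohort_to_records(cohort: Cohort) -> list[SampleRecord]:
    """In-memory equivalent of write_dataset + read_dataset."""
    recs = {sid: SampleRecord(sid, pid, lab_values={})
            for sid, pid in zip(cohort.sample_ids, cohort.patient_ids)}
    markers = [c for c in cohort.lab.columns if c not in ("sample_id", "patient_id")]
    for _, row in cohort.lab.iterrows():
        recs[str(row["sample_id"])].lab_values = {m: row[m] for m in markers}
    for (path, exposure), mat in cohort.spectra.items():
        for i, sid in enumerate(cohort.sample_ids):
            recs[sid].spectra[(path, exposure)] = Spectrum(
                sid, cohort.patient_ids[i], path, exposure,
                cohort.grid.wavelengths, mat[i])
    return [recs[sid] for sid in cohort.sample_ids]
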