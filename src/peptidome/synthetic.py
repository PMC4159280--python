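"""Synthetic MALDI-TOF cohort generator with known ground truth.

Emulates linear-mode urinary peptidome profiles: ~200 common peptide peaks
on m/z 1,000-12,000, Gaussian peak shapes with instrument resolution
``FWHM = m/z / R``, an exponentially decaying chemical baseline, additive
detector noise, a per-spectrum multiplicative calibration error in ppm,
replicate spots per subject, and case/control cohorts with planted
fold-change differences and age/sex covariates.  Every downstream stage of
the pipeline therefore has a recoverable right answer.

The simulated cohort structure mirrors a renal-carcinoma case/control
study: patients (ccRCC plus optional non-ccRCC malignancies) versus
healthy controls plus optional benign renal masses, with group-specific
age distributions truncated to realistic clinical ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np
import pandas as pd

from .io import FeatureMatrix, Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "LM_REFERENCE_MZ",
    "simulate_spectrum",
    "simulate_cohort",
    "simulate_feature_matrix",
]

# Frequent common peaks used downstream as linear-mode realignment anchors.
LM_REFERENCE_MZ = (1162.0, 1511.0, 1681.0, 1895.0, 1912.0, 2236.0, 3373.0)

# Age models: controls/benign 24-79 y, patients 33-88 y; patient mean/sd
# from the clinical table, control sd chosen to cover the stated range.
_AGE_MODELS = {
    "control": (48.7, 12.0, 24.0, 79.0),
    "benign": (48.7, 12.0, 24.0, 79.0),
    "ccRCC": (64.53, 10.97, 33.0, 88.0),
    "non-ccRCC-malignant": (64.53, 10.97, 33.0, 88.0),
}
_MALE_FRACTION = 0.6


@dataclass
class SimulationConfig:
    """All knobs of the simulated study, with the study design as defaults."""

    n_cases: int = 118
    n_controls: int = 137
    n_benign: int = 0
    n_non_ccrcc: int = 0
    n_replicates_per_subject: int = 3
    mz_range: tuple[float, float] = (1000.0, 12000.0)
    grid_step: float = 0.5
    n_common_peaks: int = 200
    planted_discriminant_peaks: tuple = ()  # (center m/z, fold_change, "up"/"down")
    resolution: float = 800.0  # FWHM = m/z / resolution
    baseline_amplitude: float = 30.0
    baseline_tau: float = 2000.0
    noise_sd: float = 1.0
    calibration_error_ppm: float = 150.0  # sd of per-spectrum ppm distortion
    subject_cv: float = 0.4  # lognormal sigma of biological variation
    replicate_cv: float = 0.1  # lognormal sigma of technical variation
    age_linked_peaks: tuple = ()  # (m/z, spearman-strength rho)
    area_range: tuple[float, float] = (100.0, 2000.0)
    include_reference_peaks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must satisfy low < high")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (FWHM = m/z / resolution)")
        for center, fold, direction in self.planted_discriminant_peaks:
            if fold <= 0:
                raise ValueError(f"fold_change must be > 0 (peak {center})")
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be 'up'/'down' (peak {center})")
            if not lo <= center <= hi:
                raise ValueError(f"planted peak {center} outside mz_range")

    def grid(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("mz_range", "area_range"):
            d[k] = tuple(d[k])
        d["planted_discriminant_peaks"] = tuple(tuple(p) for p in d["planted_discriminant_peaks"])
        d["age_linked_peaks"] = tuple(tuple(p) for p in d["age_linked_peaks"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was actually planted, for oracle-style checks downstream."""

    group: dict  # subject_id -> group label
    peak_mz: np.ndarray  # common-peak centers
    true_mean_area: pd.DataFrame  # groups x peaks: noise-free mean areas
    discriminant_mz: list  # m/z planted with a case/control fold change
    age_linked_mz: list
    calibration_ppm: dict = field(default_factory=dict)  # (subject, replicate) -> ppm

    def to_tsv(self, path) -> None:
        df = self.true_mean_area.copy()
        df.index.name = "group"
        df.to_csv(path, sep="\t")


def _gaussian_profile(grid: np.ndarray, center: float, area: float, fwhm: float) -> np.ndarray:
    """Dense Gaussian with unit-consistent area, evaluated only within ±6σ."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    lo = np.searchsorted(grid, center - 6 * sigma)
    hi = np.searchsorted(grid, center + 6 * sigma)
    out = np.zeros_like(grid)
    if hi > lo:
        x = grid[lo:hi]
        out[lo:hi] = area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((x - center) / sigma) ** 2
        )
    return out


def simulate_spectrum(
    peaks,
    config: SimulationConfig,
    seed: int,
    *,
    calibration_ppm: float | None = None,
    subject_id: str = "",
    replicate_id: str = "",
) -> Spectrum:
    """Render one dense linear-mode spectrum from (m/z, area) pairs.

    The spectrum is the sum of Gaussian peaks (FWHM = m/z / resolution),
    an exponentially decaying baseline, additive Gaussian noise, with the
    whole m/z axis stretched by ``1 + calibration_ppm * 1e-6`` (drawn from
    the configured ppm distribution when not given explicitly).  Negative
    intensities are clipped to zero.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.mz_range
    for mz, _ in peaks:
        if not lo <= mz <= hi:
            raise ValueError(f"peak at m/z {mz} outside mz_range {config.mz_range}")
    grid = config.grid()
    y = np.zeros_like(grid)
    for mz, area in peaks:
        y += _gaussian_profile(grid, mz, area, mz / config.resolution)
    if config.baseline_amplitude:
        y += config.baseline_amplitude * np.exp(-(grid - lo) / config.baseline_tau)
    if calibration_ppm is None:
        calibration_ppm = float(rng.normal(0.0, config.calibration_error_ppm))
    if config.noise_sd:
        y += rng.normal(0.0, config.noise_sd, size=grid.size)
    mz_axis = grid * (1.0 + calibration_ppm * 1e-6)
    return Spectrum(
        mz_axis,
        np.clip(y, 0.0, None),
        mode="linear",
        subject_id=subject_id,
        replicate_id=replicate_id,
    )


def _draw_common_peaks(config: SimulationConfig, rng: np.random.Generator):
    """Peak centers and base areas shared by all subjects."""
    lo, hi = config.mz_range
    centers = list(config.include_reference_peaks and LM_REFERENCE_MZ or ())
    centers = [c for c in centers if lo <= c <= hi]
    for mz, _, _ in config.planted_discriminant_peaks:
        centers.append(mz)
    for mz, _ in config.age_linked_peaks:
        centers.append(mz)
    n_extra = max(0, config.n_common_peaks - len(centers))
    # log-uniform positions mimic the crowded low-mass region of peptide maps
    extra = np.exp(rng.uniform(np.log(lo * 1.01), np.log(hi * 0.99), size=n_extra))
    min_sep = 2.5 / config.resolution  # keep common peaks resolvable
    for c in np.sort(extra):
        if all(abs(c - o) > min_sep * max(c, o) for o in centers):
            centers.append(float(c))
    centers = np.sort(np.asarray(centers, dtype=float))
    a_lo, a_hi = config.area_range
    areas = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=centers.size))
    # anchors are "frequent common peaks": give them robust abundance
    for ref in LM_REFERENCE_MZ:
        idx = np.flatnonzero(np.isclose(centers, ref))
        if idx.size:
            areas[idx[0]] = max(areas[idx[0]], a_hi * 0.75)
    return centers, areas


def _true_mean_areas(centers, base_areas, config: SimulationConfig) -> pd.DataFrame:
    """Noise-free per-group mean areas; cases differ exactly by fold_change."""
    groups = ["control", "benign", "ccRCC", "non-ccRCC-malignant"]
    table = pd.DataFrame(
        np.tile(base_areas, (len(groups), 1)), index=groups,
        columns=[f"{c:.4f}" for c in centers],
    )
    for mz, fold, direction in config.planted_discriminant_peaks:
        j = int(np.argmin(np.abs(centers - mz)))
        factor = fold if direction == "up" else 1.0 / fold
        for g in ("ccRCC", "non-ccRCC-malignant"):
            table.iloc[table.index.get_loc(g), j] = base_areas[j] * factor
    return table


def _draw_ages(groups: list[str], rng: np.random.Generator) -> np.ndarray:
    ages = np.empty(len(groups))
    for i, g in enumerate(groups):
        mean, sd, lo, hi = _AGE_MODELS[g]
        a = rng.normal(mean, sd)
        while not lo <= a <= hi:  # truncation by redraw
            a = rng.normal(mean, sd)
        ages[i] = round(a, 1)
    return ages


def _subject_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n, prefix in (
        ("control", config.n_controls, "C"),
        ("benign", config.n_benign, "B"),
        ("ccRCC", config.n_cases, "P"),
        ("non-ccRCC-malignant", config.n_non_ccrcc, "M"),
    ):
        rows += [(f"{prefix}{i + 1:04d}", group) for i in range(n)]
    md = pd.DataFrame(rows, columns=["subject_id", "group"]).set_index("subject_id")
    md["age"] = _draw_ages(md["group"].tolist(), rng)
    md["sex"] = np.where(rng.random(len(md)) < _MALE_FRACTION, "M", "F")
    return md


def _subject_areas(
    centers, truth: pd.DataFrame, metadata: pd.DataFrame,
    config: SimulationConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-subject noise-free peak areas (before replicate/technical noise)."""
    n_sub, n_pk = len(metadata), centers.size
    z = rng.normal(size=(n_sub, n_pk))
    age = metadata["age"].to_numpy()
    z_age = (age - age.mean()) / (age.std() or 1.0)
    for mz, rho in config.age_linked_peaks:
        j = int(np.argmin(np.abs(centers - mz)))
        rho = float(np.clip(rho, -0.999, 0.999))
        z[:, j] = rho * z_age + math.sqrt(1 - rho * rho) * z[:, j]
    means = truth.loc[metadata["group"]].to_numpy()
    areas = means * np.exp(config.subject_cv * z)
    return pd.DataFrame(areas, index=metadata.index, columns=truth.columns)


def simulate_feature_matrix(config: SimulationConfig) -> tuple[FeatureMatrix, GroundTruth]:
    """Fast path: per-subject replicate-averaged peak areas, no dense spectra.

    Used for statistical calibration studies where rendering thousands of
    profiles would only add the spectral-processing layer being bypassed.
    """
    rng = np.random.default_rng(config.seed)
    centers, base_areas = _draw_common_peaks(config, rng)
    truth = _true_mean_areas(centers, base_areas, config)
    metadata = _subject_table(config, rng)
    areas = _subject_areas(centers, truth, metadata, config, rng)
    reps = [
        areas * np.exp(rng.normal(0, config.replicate_cv, size=areas.shape))
        for _ in range(config.n_replicates_per_subject)
    ]
    mean_areas = sum(reps) / len(reps)
    gt = GroundTruth(
        group=metadata["group"].to_dict(),
        peak_mz=centers,
        true_mean_area=truth,
        discriminant_mz=[mz for mz, _, _ in config.planted_discriminant_peaks],
        age_linked_mz=[mz for mz, _ in config.age_linked_peaks],
    )
    return FeatureMatrix(mean_areas, metadata), gt


def simulate_cohort(config: SimulationConfig):
    """Full cohort of dense replicate spectra.

    Returns ``(spectra, metadata, ground_truth)`` where ``spectra`` holds
    ``n_replicates_per_subject`` acquisitions per subject and ``metadata``
    one row per subject (id, group, age, sex).
    """
    rng = np.random.default_rng(config.seed)
    centers, base_areas = _draw_common_peaks(config, rng)
    truth = _true_mean_areas(centers, base_areas, config)
    metadata = _subject_table(config, rng)
    areas = _subject_areas(centers, truth, metadata, config, rng)

    spectra: list[Spectrum] = []
    calib: dict = {}
    for sid in metadata.index:
        subj_areas = areas.loc[sid].to_numpy()
        for r in range(config.n_replicates_per_subject):
            rep_areas = subj_areas * np.exp(
                rng.normal(0, config.replicate_cv, size=subj_areas.size)
            )
            ppm = float(rng.normal(0.0, config.calibration_error_ppm))
            rep_id = f"r{r + 1}"
            spectra.append(
                simulate_spectrum(
                    list(zip(centers, rep_areas)),
                    config,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    calibration_ppm=ppm,
                    subject_id=sid,
                    replicate_id=rep_id,
                )
            )
            calib[(sid, rep_id)] = ppm

    gt = GroundTruth(
        group=metadata["group"].to_dict(),
        peak_mz=centers,
        true_mean_area=truth,
        discriminant_mz=[mz for mz, _, _ in config.planted_discriminant_peaks],
        age_linked_mz=[mz for mz, _ in config.age_linked_peaks],
        calibration_ppm=calib,
    )
    return spectra, metadata, gt
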