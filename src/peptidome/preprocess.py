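"""Spectrum-level processing: baseline, normalization, recalibration, averaging.

The fixed pipeline order is baseline subtraction -> total-ion-current
normalization -> reference-peak recalibration -> replicate averaging;
spectra that carry no signal ("null") or that cannot be anchored to enough
reference peaks ("non-recalibratable") are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d

from .io import NullSpectrumError, Spectrum
from .peaks import refine_apex
from scipy import signal as _signal

__all__ = [
    "ReferencePeakSet",
    "RecalibrationResult",
    "PreprocessReport",
    "NonRecalibratableError",
    "LM_REFERENCES",
    "RM_REFERENCES",
    "convex_hull_baseline",
    "normalize_tic",
    "recalibrate",
    "average_replicates",
    "preprocess_cohort",
]

log = logging.getLogger(__name__)


class NonRecalibratableError(ValueError):
    """Too few reference peaks matched to anchor a calibration warp."""


@dataclass
class ReferencePeakSet:
    """Calibration anchors for one acquisition mode.

    Linear mode uses seven frequent common peaks with a 1000 ppm matching
    tolerance; reflector mode uses four internal calibrants at 100 ppm
    (200 ppm for the heaviest).
    """

    mode: str
    reference_mz: tuple
    tolerance_ppm: tuple

    def __post_init__(self) -> None:
        if not self.reference_mz:
            raise ValueError("reference peak list is empty")
        if len(self.tolerance_ppm) != len(self.reference_mz):
            raise ValueError("one tolerance per reference peak required")
        if any(t <= 0 for t in self.tolerance_ppm):
            raise ValueError("tolerances must be positive")


LM_REFERENCES = ReferencePeakSet(
    mode="linear",
    reference_mz=(1162.0, 1511.0, 1681.0, 1895.0, 1912.0, 2236.0, 3373.0),
    tolerance_ppm=(1000.0,) * 7,
)
RM_REFERENCES = ReferencePeakSet(
    mode="reflector",
    reference_mz=(1680.93, 1912.06, 2040.17, 2659.32),
    tolerance_ppm=(100.0, 100.0, 100.0, 200.0),
)

_DEFAULT_MIN_MATCHES = {"linear": 4, "reflector": 2}


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain lower hull of the polyline (x ascending)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on/above the j->i segment (non-convex turn)
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (x[i] - x[j]) * (y[k] - y[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def convex_hull_baseline(
    s: Spectrum, flatness: float = 0.8
) -> tuple[np.ndarray, Spectrum]:
    """Convex-hull baseline with a flatness relaxation.

    The baseline is the lower convex envelope of the (m/z, intensity)
    polyline, computed on a running-minimum copy whose window spans
    ``(1 - flatness)`` of the m/z range, so ``flatness = 1`` is the pure
    hull and smaller values let the baseline hug broader curvature.
    Returns ``(baseline, corrected)`` with the corrected intensity floored
    at zero; the corrected spectrum touches zero at every hull vertex.
    """
    if not 0.0 < flatness <= 1.0:
        raise ValueError("flatness must be in (0, 1]")
    if len(s) < 3:
        return np.zeros(len(s)), s.with_intensity(s.intensity.copy())
    span = s.mz[-1] - s.mz[0]
    step = float(np.median(np.diff(s.mz)))
    window_da = (1.0 - flatness) * span + 1e-12
    window_pts = max(1, int(round(window_da / step)))
    floor = minimum_filter1d(s.intensity, size=window_pts, mode="nearest")
    idx = _lower_hull_indices(s.mz, floor)
    baseline = np.interp(s.mz, s.mz[idx], floor[idx])
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return baseline, s.with_intensity(corrected)


def normalize_tic(s: Spectrum, target: float = 1.0) -> Spectrum:
    """Scale intensities so their sum equals ``target`` (TIC normalization)."""
    total = s.total_intensity()
    if total <= 0:
        raise NullSpectrumError(
            f"null spectrum (subject={s.subject_id!r}): zero total intensity"
        )
    return s.with_intensity(s.intensity * (target / total))


@dataclass
class RecalibrationResult:
    spectrum: Spectrum | None
    matched: int
    residual_ppm: float  # max |residual| at matched references after warp
    ok: bool
    matches: list = field(default_factory=list)  # (reference, observed apex)


def _apex_positions(s: Spectrum, min_rel_height: float = 0.01) -> np.ndarray:
    """Sub-grid apex m/z of prominent local maxima (for anchor matching)."""
    y = s.intensity
    if y.size < 3:
        return np.empty(0)
    idx, _ = _signal.find_peaks(y, height=min_rel_height * float(y.max() or 1.0))
    return np.asarray([refine_apex(s.mz, y, int(i))[0] for i in idx])


def recalibrate(
    s: Spectrum,
    refs: ReferencePeakSet,
    min_matches: int | None = None,
) -> RecalibrationResult:
    """Warp the m/z axis so detected apexes land on the reference peaks.

    Each reference is matched to the nearest detected apex within its ppm
    tolerance; the warp interpolates the matched ppm shifts piecewise
    linearly across m/z with constant extrapolation beyond the outermost
    anchor.  Fewer than ``min_matches`` anchors flags the spectrum as
    non-recalibratable.
    """
    if min_matches is None:
        min_matches = _DEFAULT_MIN_MATCHES.get(refs.mode, 2)
    apexes = _apex_positions(s)
    pairs = []
    for ref, tol in zip(refs.reference_mz, refs.tolerance_ppm):
        if apexes.size == 0:
            continue
        d = np.abs(apexes - ref)
        i = int(np.argmin(d))
        if d[i] / ref * 1e6 <= tol:
            pairs.append((float(apexes[i]), float(ref)))
    if len(pairs) < min_matches:
        return RecalibrationResult(None, len(pairs), np.inf, False)

    obs = np.asarray([p[0] for p in pairs])
    ref = np.asarray([p[1] for p in pairs])
    order = np.argsort(obs)
    obs, ref = obs[order], ref[order]
    shift_ppm = (ref - obs) / obs * 1e6
    warped_axis = s.mz * (1.0 + np.interp(s.mz, obs, shift_ppm) * 1e-6)
    # resample back onto the original grid so cohorts stay comparable
    intensity = np.interp(s.mz, warped_axis, s.intensity, left=0.0, right=0.0)
    out = s.with_intensity(intensity)

    new_apexes = _apex_positions(out)
    residuals = []
    for r, tol in zip(refs.reference_mz, refs.tolerance_ppm):
        if new_apexes.size == 0:
            continue
        d = np.abs(new_apexes - r)
        i = int(np.argmin(d))
        if d[i] / r * 1e6 <= tol:
            residuals.append((new_apexes[i] - r) / r * 1e6)
    resid = float(np.max(np.abs(residuals))) if residuals else np.inf
    return RecalibrationResult(out, len(pairs), resid, True, pairs)


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean spectrum of one subject's replicates."""
    if not spectra:
        raise ValueError("no replicate spectra")
    modes = {s.mode for s in spectra}
    if len(modes) > 1:
        raise ValueError(f"mixed acquisition modes {sorted(modes)}")
    subjects = {s.subject_id for s in spectra}
    if len(subjects) > 1:
        raise ValueError(f"replicates from different subjects {sorted(subjects)}")
    grid = spectra[0].mz
    acc = np.zeros_like(grid)
    for s in spectra:
        if s.mz.size == grid.size and np.array_equal(s.mz, grid):
            acc += s.intensity
        else:
            acc += np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)
    return Spectrum(grid, acc / len(spectra), mode=spectra[0].mode,
                    subject_id=spectra[0].subject_id, replicate_id="mean")


@dataclass
class PreprocessReport:
    spectra_in: int = 0
    excluded_null: int = 0
    excluded_nonrecalibratable: int = 0
    kept: int = 0
    per_spectrum: list = field(default_factory=list)  # dict records

    def __post_init__(self) -> None:
        assert self.spectra_in == self.kept + self.excluded_null + \
            self.excluded_nonrecalibratable or self.spectra_in == 0

    def to_dict(self) -> dict:
        return {
            "spectra_in": self.spectra_in,
            "excluded_null": self.excluded_null,
            "excluded_nonrecalibratable": self.excluded_nonrecalibratable,
            "kept": self.kept,
            "per_spectrum": self.per_spectrum,
        }


def preprocess_cohort(
    spectra: list[Spectrum],
    refs: ReferencePeakSet = LM_REFERENCES,
    flatness: float = 0.8,
    tic_target: float = 1.0,
    min_matches: int | None = None,
    recalibrate_spectra: bool = True,
) -> tuple[list[Spectrum], PreprocessReport]:
    """Full chain per spectrum, then replicate averaging per subject.

    Order is fixed: baseline -> normalize -> recalibrate -> average.
    Returns one mean spectrum per subject plus the exclusion bookkeeping.
    """
    report = PreprocessReport()
    by_subject: dict[str, list[Spectrum]] = {}
    for s in spectra:
        report.spectra_in += 1
        rec = {"subject_id": s.subject_id, "replicate_id": s.replicate_id}
        try:
            _, corrected = convex_hull_baseline(s, flatness)
            normalized = normalize_tic(corrected, tic_target)
        except NullSpectrumError:
            report.excluded_null += 1
            rec["excluded"] = "null"
            report.per_spectrum.append(rec)
            continue
        if recalibrate_spectra:
            result = recalibrate(normalized, refs, min_matches)
            if not result.ok:
                report.excluded_nonrecalibratable += 1
                rec.update(excluded="non-recalibratable", matched=result.matched)
                report.per_spectrum.append(rec)
                continue
            rec.update(matched=result.matched, residual_ppm=result.residual_ppm)
            normalized = result.spectrum
        report.kept += 1
        report.per_spectrum.append(rec)
        by_subject.setdefault(s.subject_id, []).append(normalized)

    means = [average_replicates(reps) for reps in by_subject.values()]
    log.info(
        "preprocess: %d in, %d kept, %d null, %d non-recalibratable, %d subjects",
        report.spectra_in, report.kept, report.excluded_null,
        report.excluded_nonrecalibratable, len(means),
    )
    return means, report
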