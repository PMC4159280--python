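"""Consensus peak detection and zero-level area integration.

Peaks are picked once on the total average spectrum (the pointwise mean of
all subject mean spectra) with an S/N threshold, then every subject's areas
are integrated between the consensus valley bounds from the zero line, so
each subject contributes a value for every consensus feature (0 when the
peak is absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import FeatureMatrix, Spectrum

__all__ = [
    "Peak",
    "total_average_spectrum",
    "detect_peaks",
    "integrate_areas",
    "build_feature_matrix",
    "refine_apex",
]

_MAD_TO_SD = 1.4826


@dataclass
class Peak:
    apex_mz: float
    left_bound: float
    right_bound: float
    snr: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.left_bound < self.apex_mz < self.right_bound:
            raise ValueError(
                f"peak bounds must bracket the apex: "
                f"{self.left_bound} < {self.apex_mz} < {self.right_bound}"
            )
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not self.label:
            self.label = str(int(round(self.apex_mz)))


def _resample(s: Spectrum, grid: np.ndarray) -> np.ndarray:
    if s.mz.size == grid.size and np.array_equal(s.mz, grid):
        return s.intensity
    return np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)


def total_average_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean across subject spectra (resampled to the first grid)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].mz
    acc = np.zeros_like(grid)
    for s in spectra:
        acc += _resample(s, grid)
    return Spectrum(grid, acc / len(spectra), mode=spectra[0].mode,
                    subject_id="__total__", replicate_id="mean")


def refine_apex(mz: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid apex position/height by parabolic interpolation.

    A parabola is least-squares fitted to the points above 35% of the
    apex height (noise averages out over the peak top; a symmetric
    window keeps the vertex unbiased); when fewer than three such points
    exist, the classic 3-point interpolation is used.
    """
    if i <= 0 or i >= y.size - 1:
        return float(mz[i]), float(y[i])
    half = 0.35 * y[i]
    li = i
    while li > 0 and y[li - 1] > half and i - li < 50:
        li -= 1
    ri = i
    while ri < y.size - 1 and y[ri + 1] > half and ri - i < 50:
        ri += 1
    if ri - li >= 2:
        x = mz[li:ri + 1] - mz[i]
        a, b, c = np.polyfit(x, y[li:ri + 1], 2)
        if a < 0:
            dx = -b / (2 * a)
            span = mz[ri] - mz[li]
            if abs(dx) <= span:
                return float(mz[i] + dx), float(c - b * b / (4 * a))
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep grid apex
        return float(mz[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = 0.5 * (mz[i + 1] - mz[i - 1])
    return float(mz[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def _local_background(y: np.ndarray, i: int, window: int) -> tuple[float, float]:
    """(median, MAD-based sd) of the intensity around point ``i``.

    The median absorbs any residual pedestal (e.g. the positive offset
    left by zero-clipped noise) so S/N measures height above the local
    background, and the MAD stays robust to neighbouring peaks.
    """
    lo = max(0, i - window // 2)
    hi = min(y.size, i + window // 2)
    seg = y[lo:hi]
    med = float(np.median(seg))
    mad = float(np.median(np.abs(seg - med)))
    return med, _MAD_TO_SD * mad


def _half_height_width(mz: np.ndarray, y: np.ndarray, i: int, floor: float) -> float:
    """Width of the bump around apex ``i`` at half its height above ``floor``."""
    half = floor + 0.5 * (y[i] - floor)
    li = i
    while li > 0 and y[li - 1] > half:
        li -= 1
    ri = i
    while ri < y.size - 1 and y[ri + 1] > half:
        ri += 1
    return float(mz[ri] - mz[li])


def detect_peaks(
    avg: Spectrum,
    snr_threshold: float = 3.0,
    resolution: float = 800.0,
    noise_window: int = 100,
    min_width_fraction: float = 0.4,
) -> list[Peak]:
    """Local maxima with S/N >= threshold, valley-bounded, resolution-merged.

    Noise is estimated as 1.4826 x the median absolute deviation of the
    intensity in a ``noise_window``-point window around each apex (robust to
    neighbouring peaks).  Candidates must also be at least
    ``min_width_fraction`` of the instrument peak width (FWHM =
    apex / resolution) at half height, which rejects single-point noise
    spikes that a resolution-800 profile cannot produce.  Apexes closer
    than ``apex_mz / resolution`` are merged into the taller one.
    """
    y = avg.intensity
    mz = avg.mz
    if y.size < 3 or np.all(y == y[0]):
        return []
    apex_idx, _ = signal.find_peaks(y)
    candidates = []
    for i in apex_idx:
        med, noise = _local_background(y, i, noise_window)
        height = y[i] - med
        snr = height / noise if noise > 0 else (np.inf if height > 0 else 0.0)
        if snr < snr_threshold:
            continue
        width = _half_height_width(mz, y, i, med)
        if width < min_width_fraction * mz[i] / resolution:
            continue
        candidates.append((i, snr))
    if not candidates:
        return []

    # merge apexes below the resolution limit, keeping the taller
    merged: list[tuple[int, float]] = []
    for i, snr in candidates:
        if merged:
            j, jsnr = merged[-1]
            if mz[i] - mz[j] < mz[i] / resolution:
                if y[i] > y[j]:
                    merged[-1] = (i, snr)
                continue
        merged.append((i, snr))

    # valley bounds: nearest local minimum (or spectrum edge) on each side
    minima = signal.argrelmin(y, order=1)[0]
    peaks = []
    for i, snr in merged:
        left_cands = minima[minima < i]
        right_cands = minima[minima > i]
        li = int(left_cands[-1]) if left_cands.size else 0
        ri = int(right_cands[0]) if right_cands.size else y.size - 1
        apex, _ = refine_apex(mz, y, i)
        if not mz[li] < apex < mz[ri]:
            continue  # degenerate flat shoulder
        peaks.append(Peak(apex, float(mz[li]), float(mz[ri]), float(min(snr, 1e12))))

    _assign_labels(peaks)
    return peaks


def _assign_labels(peaks: list[Peak]) -> None:
    """Nominal integer-Da labels; collisions keep the first decimal."""
    seen: dict[str, Peak] = {}
    for p in peaks:
        lab = str(int(round(p.apex_mz)))
        if lab in seen:
            other = seen.pop(lab)
            other.label = f"{other.apex_mz:.1f}"
            seen[other.label] = other
            lab = f"{p.apex_mz:.1f}"
        p.label = lab
        seen[lab] = p


def integrate_areas(subject_spectrum: Spectrum, consensus: list[Peak]) -> np.ndarray:
    """Zero-level trapezoidal area of each consensus peak window."""
    mz, y = subject_spectrum.mz, subject_spectrum.intensity
    out = np.zeros(len(consensus))
    for k, p in enumerate(consensus):
        if p.right_bound < mz[0] or p.left_bound > mz[-1]:
            warnings.warn(
                f"peak {p.label} bounds outside spectrum range; area set to 0",
                stacklevel=2,
            )
            continue
        lo = np.searchsorted(mz, p.left_bound, side="left")
        hi = np.searchsorted(mz, p.right_bound, side="right")
        if hi - lo >= 2:
            out[k] = max(0.0, float(np.trapezoid(y[lo:hi], mz[lo:hi])))
    return out


def build_feature_matrix(
    subject_spectra: list[Spectrum],
    consensus: list[Peak],
    metadata: pd.DataFrame,
) -> FeatureMatrix:
    """Assemble subjects x features areas in metadata row order."""
    by_subject = {s.subject_id: s for s in subject_spectra}
    unknown = sorted(set(by_subject) - set(metadata.index))
    if unknown:
        raise ValueError(f"spectra for subjects missing from metadata: {unknown}")
    ids = [sid for sid in metadata.index if sid in by_subject]
    rows = np.vstack([integrate_areas(by_subject[sid], consensus) for sid in ids])
    areas = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"),
                         columns=[p.label for p in consensus])
    return FeatureMatrix(areas, metadata.loc[ids])


def consensus_to_frame(consensus: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.label, p.apex_mz, p.left_bound, p.right_bound, p.snr) for p in consensus],
        columns=["label", "apex_mz", "left_bound", "right_bound", "snr"],
    )
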