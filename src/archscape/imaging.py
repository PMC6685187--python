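"""Image-based chromatin quantification.

Spatial autocorrelation of chromatin density in electron-microscopy ROIs
with a power-law shape fit (the D value), dispersion statistics of D across
nuclei, relative heterochromatin fraction (RHF) with chromocenter counting
in stained nuclei, and antibody/counterstain intensity ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

DEFAULT_PIXEL_NM = 2.0
DEFAULT_FIT_RANGE_NM = (20.0, 60.0)


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular region of interest, in pixels."""

    x: int
    y: int
    width: int
    height: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI must have positive area")

    def slice(self):
        return (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))


@dataclass
class AcfCurve:
    """Radially averaged, variance-normalized autocovariance of an image ROI."""

    radii_nm: np.ndarray
    values: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("ACF must equal 1 at radius 0 after normalization")


@dataclass
class AcfFit:
    """Power-law shape fit of an ACF curve over a length-scale window.

    ``d`` is defined operationally as ``3 + slope`` of the least-squares
    line on (log radius, log ACF); a steeper decay (more negative slope)
    means a lower D, i.e. chromatin density correlated over a narrower
    range of length scales.
    """

    d: float
    amplitude: float
    fit_range_nm: tuple[float, float]
    rms_residual: float
    n_points: int


def radial_acf(
    image: np.ndarray,
    roi: Optional[RoiSpec] = None,
    pixel_size_nm: float = DEFAULT_PIXEL_NM,
    max_radius_px: Optional[int] = None,
) -> AcfCurve:
    """Radial spatial autocorrelation function of an image ROI.

    The ROI is mean-subtracted and its non-periodic autocovariance computed
    by zero-padded FFT with bias correction by the lag overlap counts, then
    normalized by the variance and radially averaged on a 1-pixel-spaced
    grid of radii, converted to nm.
    """
    img = np.asarray(image, dtype=float)
    if roi is not None:
        img = img[roi.slice()]
    ny, nx = img.shape
    if min(ny, nx) < 64:
        raise ValueError("ROI must be at least 64x64 pixels")
    x = img - img.mean()
    if not np.any(x):
        raise ValueError("constant ROI: zero variance")

    pad = (2 * ny, 2 * nx)
    F = np.fft.rfft2(x, s=pad)
    corr = np.fft.irfft2(F * np.conj(F), s=pad)
    ones = np.fft.rfft2(np.ones_like(x), s=pad)
    counts = np.fft.irfft2(ones * np.conj(ones), s=pad)

    corr = np.fft.fftshift(corr)
    counts = np.fft.fftshift(counts)
    cy, cx = ny, nx
    var = corr[cy, cx] / counts[cy, cx]

    rmax = min(ny, nx) // 2 if max_radius_px is None else int(max_radius_px)
    yy, xx = np.ogrid[-cy : pad[0] - cy, -cx : pad[1] - cx]
    r = np.hypot(yy, xx)
    valid = (counts > 0.5) & (r <= rmax)
    rbin = np.rint(r[valid]).astype(np.int64)
    acf_vals = corr[valid] / counts[valid] / var
    sums = np.bincount(rbin, weights=acf_vals, minlength=rmax + 1)
    ns = np.bincount(rbin, minlength=rmax + 1)
    profile = sums / np.maximum(ns, 1)
    profile[0] = 1.0
    radii = np.arange(rmax + 1, dtype=float) * pixel_size_nm
    return AcfCurve(radii_nm=radii, values=profile, pixel_size_nm=pixel_size_nm)


def fit_acf(curve: AcfCurve,
            fit_range_nm: tuple[float, float] = DEFAULT_FIT_RANGE_NM) -> AcfFit:
    """Least-squares power-law fit of the ACF over a length-scale window.

    A line is fit on (log r, log ACF) for radii inside ``fit_range_nm``
    whose ACF value is positive (non-positive points are dropped); at least
    5 points must remain. ``D = 3 + slope``; the amplitude is the exponent
    of the intercept.
    """
    lo, hi = fit_range_nm
    r, v = curve.radii_nm, curve.values
    sel = (r >= lo) & (r <= hi) & (v > 0) & (r > 0)
    if sel.sum() < 5:
        raise ValueError(
            f"fewer than 5 positive ACF samples in fit range [{lo}, {hi}] nm"
        )
    logr, logv = np.log(r[sel]), np.log(v[sel])
    slope, intercept = np.polyfit(logr, logv, 1)
    resid = logv - (slope * logr + intercept)
    return AcfFit(
        d=float(3.0 + slope),
        amplitude=float(math.exp(intercept)),
        fit_range_nm=(float(lo), float(hi)),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=int(sel.sum()),
    )


def d_dispersion(groups: Mapping[str, Sequence[float]]) -> dict[str, dict[str, float]]:
    """Spread statistics of D estimates per group (median, IQR, range)."""
    out = {}
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            out[label] = {k: float("nan") for k in ("median", "iqr", "range", "n")}
            out[label]["n"] = float(v.size)
            continue
        q1, q3 = np.percentile(v, [25, 75])
        out[label] = {
            "median": float(np.median(v)),
            "iqr": float(q3 - q1),
            "range": float(v.max() - v.min()),
            "n": float(v.size),
        }
    return out


def dispersion_test(a: Sequence[float], b: Sequence[float]):
    """Two-sided rank-sum comparison of dispersion between two groups of D.

    Each value is replaced by its absolute deviation from its own group
    median; a Mann-Whitney test on these deviations asks whether one group's
    estimates scatter more widely. Returns ``(statistic, p)``, or NaNs if a
    group has fewer than 3 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        return float("nan"), float("nan")
    da = np.abs(a - np.median(a))
    db = np.abs(b - np.median(b))
    stat, p = stats.mannwhitneyu(da, db, alternative="two-sided")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Heterochromatin and immunosignal quantification


@dataclass
class RhfResult:
    """Relative heterochromatin fraction of one nucleus.

    ``rhf`` is the fraction of total nuclear stain intensity found inside
    chromocenter regions; ``cc_count`` the number of such regions.
    """

    rhf: float
    cc_count: int
    nucleus_area: float  # um^2 if a pixel size was given, else px

    def __post_init__(self) -> None:
        if not (0.0 <= self.rhf <= 1.0):
            raise ValueError("rhf must lie in [0, 1]")


def quantify_rhf(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cc_mask: Optional[np.ndarray] = None,
    k: float = 2.0,
    min_area_px: int = 12,
    pixel_size_um: Optional[float] = None,
) -> RhfResult:
    """Relative heterochromatin fraction and chromocenter count.

    With a supplied ``cc_mask`` (e.g. manually drawn ROIs) the ratio is
    computed directly. In auto mode chromocenters are detected as connected
    components of pixels brighter than ``mean + k*SD`` of the nuclear
    intensity distribution, discarding components below ``min_area_px``.
    The result is invariant to global intensity scaling.
    """
    from skimage import measure

    img = np.asarray(image, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    if cc_mask is None:
        vals = img[mask]
        thr = vals.mean() + k * vals.std()
        cand = (img > thr) & mask
        labels = measure.label(cand, connectivity=2)
        cc = np.zeros_like(mask)
        n_cc = 0
        for region in measure.regionprops(labels):
            if region.area >= min_area_px:
                cc[labels == region.label] = True
                n_cc += 1
    else:
        cc = np.asarray(cc_mask, dtype=bool) & mask
        n_cc = int(measure.label(cc, connectivity=2).max())
    total = float(img[mask].sum())
    if total <= 0:
        raise ValueError("nucleus has no positive total intensity")
    rhf = float(img[cc].sum()) / total
    area = float(mask.sum()) * (pixel_size_um**2 if pixel_size_um else 1.0)
    return RhfResult(rhf=max(0.0, min(1.0, rhf)), cc_count=n_cc, nucleus_area=area)


def immuno_ratio(
    ab_image: np.ndarray,
    counterstain_image: np.ndarray,
    nucleus_mask: np.ndarray,
    reference_ratios: Optional[Sequence[float]] = None,
):
    """Mean antibody signal over mean counterstain signal within a nucleus.

    When per-nucleus ratios of a reference group (e.g. wild type) are
    given, the ratio relative to the reference-group mean is also returned
    as ``(ratio, relative)``; otherwise ``relative`` is None.
    """
    ab = np.asarray(ab_image, dtype=float)
    cs = np.asarray(counterstain_image, dtype=float)
    if ab.shape != cs.shape:
        raise ValueError("images must have identical shapes")
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    cs_mean = cs[mask].mean()
    if cs_mean <= 0:
        raise ValueError("counterstain mean is zero inside the mask")
    ratio = float(ab[mask].mean() / cs_mean)
    relative = None
    if reference_ratios is not None:
        ref = float(np.mean(reference_ratios))
        if ref <= 0:
            raise ValueError("reference ratio mean must be positive")
        relative = ratio / ref
    return ratio, relative
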