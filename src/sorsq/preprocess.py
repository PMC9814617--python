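"""Scaled subtraction and spectral preprocessing.

Pipeline order (fixed): polynomial baseline -> scaled subtraction ->
Whittaker/AsLS baseline -> area normalization.  The scaled subtraction
``content = offset - s * traditional`` removes container (surface) features;
the scale factor s is estimated either from container-band windows (weighted
median of point-wise offset/traditional ratios, the exact minimiser of the
windowed L1 criterion) or, when no container bands are available, as the
largest s whose negative-lobe energy remains within the estimated noise floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.sparse.linalg import splu

from .simulate import ShiftModel
from .spectra import Spectrum, SpectrumPair


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the standard preprocessing chain.

    whittaker_lambda: smoothness penalty of the asymmetric-least-squares
        baseline (larger -> stiffer baseline); default 1e5 for ~1 cm^-1 grids.
    whittaker_p: asymmetry weight given to points above the baseline;
        0.01 treats peaks as outliers while tracking the broad background.
    poly_order: order of the pre-subtraction iterative polynomial baseline.
    """

    whittaker_lambda: float = 1e5
    whittaker_p: float = 0.01
    normalization: str = "area"  # area | none
    poly_order: int = 5
    whittaker_iterations: int = 10

    def __post_init__(self) -> None:
        if self.whittaker_lambda <= 0:
            raise ValueError("whittaker_lambda must be positive")
        if not (0.0 < self.whittaker_p < 1.0):
            raise ValueError("whittaker_p must lie in (0, 1)")
        if self.normalization not in ("area", "none"):
            raise ValueError("normalization must be 'area' or 'none'")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")


# ---------------------------------------------------------------------------
# baselines


def polynomial_baseline(s: Spectrum, order: int = 5, n_iter: int = 30) -> Spectrum:
    """Iterative (modified-polyfit) polynomial baseline removal.

    Repeatedly fits a polynomial and clips the working signal to its minimum
    with the fit, so peaks are progressively excluded and the polynomial
    settles onto the broad background.
    """
    nu = s.grid.values
    x = (nu - nu.mean()) / (np.ptp(nu) / 2.0)  # scaled for conditioning
    y = s.intensities.astype(float).copy()
    work = y.copy()
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coef = np.polynomial.polynomial.polyfit(x, work, order)
        fit = np.polynomial.polynomial.polyval(x, coef)
        new_work = np.minimum(work, fit)
        if np.max(np.abs(new_work - work)) < 1e-12 * max(1.0, np.max(np.abs(y))):
            work = new_work
            break
        work = new_work
    return s.with_intensities(y - fit)


def _asls_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    """Whittaker smoother with peak-adaptive asymmetric weights.

    Points above the baseline get weight p * exp(-r / k) where r is the
    positive residual and k a fraction of the signal span (psalsa-style
    weighting): strong peaks are excluded entirely, so the baseline does not
    creep up under bands on repeated application, while low-contrast broad
    humps are still followed and removed.
    """
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y
    k = 0.1 * max(float(np.ptp(y)), 1e-300)
    for _ in range(n_iter):
        wmat = sparse.diags(w, 0, format="csc")
        z = splu((wmat + penalty).tocsc()).solve(w * y)
        r = y - z
        w = np.where(r > 0, p * np.exp(-r / k), 1.0 - p)
    return z


def baseline_whittaker(s: Spectrum, cfg: Optional[PreprocessConfig] = None) -> Spectrum:
    """Asymmetric-least-squares (Whittaker smoother) baseline correction.

    Returns the spectrum minus the estimated baseline.  Peak positions of
    isolated bands are preserved to within one grid step.
    """
    cfg = cfg or PreprocessConfig()
    z = _asls_baseline(s.intensities.astype(float), cfg.whittaker_lambda,
                       cfg.whittaker_p, cfg.whittaker_iterations)
    return s.with_intensities(s.intensities - z)


def auto_whittaker_lambda(
    s: Spectrum,
    p: float = 0.01,
    grid_lambdas: Sequence[float] = (1e3, 1e4, 1e5, 1e6, 1e7),
) -> float:
    """Automatic smoothness selection: balance baseline fidelity below the
    signal against baseline roughness (product criterion on a log grid)."""
    y = s.intensities.astype(float)
    scale = max(np.ptp(y), 1e-12)
    best_lam, best_score = grid_lambdas[0], np.inf
    for lam in grid_lambdas:
        z = _asls_baseline(y, lam, p, 10)
        under = np.clip(y - z, None, 0.0)
        fidelity = float(np.sqrt(np.mean(under**2))) / scale
        roughness = float(np.sqrt(np.mean(np.diff(z, 2) ** 2))) / scale
        score = math.log10(fidelity + 1e-12) + math.log10(roughness + 1e-12)
        if score < best_score:
            best_lam, best_score = lam, score
    return float(best_lam)


# ---------------------------------------------------------------------------
# scaled subtraction


@dataclass
class ScaledSubtractionResult:
    content_spectrum: Spectrum
    scale_factor: float
    container_residual: float
    warning: Optional[str] = None


def _window_mask(nu: np.ndarray, centers: Iterable[float], half_width: float) -> np.ndarray:
    mask = np.zeros(nu.size, dtype=bool)
    for c in centers:
        mask |= np.abs(nu - c) <= half_width
    return mask


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise scale from second differences (MAD-based)."""
    d2 = np.diff(y, 2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return 1.4826 * mad / math.sqrt(6.0)


def _negative_energy(residual: np.ndarray) -> float:
    neg = np.clip(residual, None, 0.0)
    return float(np.sum(neg * neg))


def scaled_subtract(
    pair: SpectrumPair,
    container_bands: Optional[Sequence[float]] = None,
    window_half_width: float = 12.0,
    s_max: float = 10.0,
    clip_floor: Optional[float] = None,
) -> ScaledSubtractionResult:
    """Recover the content spectrum: ``content = offset - s * traditional``.

    With ``container_bands`` given, s minimises the L1 norm of the residual
    restricted to windows around those bands (computed exactly as the
    |traditional|-weighted median of point-wise ratios).  With
    ``container_bands=None`` (unknown container), s is the largest value in
    [0, s_max] whose negative-lobe energy stays within the noise floor — the
    point at which surface features start to over-subtract.  An explicitly
    empty band list (featureless container, e.g. glass: broad background
    only, removed later by the Whittaker baseline) skips subtraction with
    s = 0.  Negative excursions are kept unless ``clip_floor`` is set.
    """
    trad = pair.traditional.intensities.astype(float)
    off = pair.offset.intensities.astype(float)
    nu = pair.grid.values

    scale = float(np.max(np.abs(trad))) if trad.size else 0.0
    warning = None
    if scale <= 1e-12 * max(1.0, float(np.max(np.abs(off), initial=0.0))):
        s = 0.0
        warning = "all-zero traditional spectrum; returning offset unchanged"
        content = off.copy()
    elif container_bands is not None and len(container_bands) == 0:
        s = 0.0
        warning = "featureless container: no bands to cancel, subtraction skipped"
        content = off.copy()
    elif container_bands:
        # Per-window |traditional|-weighted median of point-wise ratios; the
        # window least contaminated by content signal gives the smallest
        # median (content enrichment in the offset can only bias ratios
        # upward, since v_c/v_s > w_c/w_s), so take the minimum over windows.
        medians = []
        for center in container_bands:
            m = (np.abs(nu - center) <= window_half_width) & (np.abs(trad) > 1e-9 * scale)
            if np.any(m):
                medians.append(_weighted_median(off[m] / trad[m], np.abs(trad[m])))
        if not medians:
            raise ValueError("no usable grid points inside the container-band windows")
        s = float(np.clip(min(medians), 0.0, s_max))
        content = off - s * trad
    else:
        sigma = _noise_sigma(off)
        tol = 2.0 * off.size * sigma**2 + 1e-10 * float(np.sum(off * off))
        if _negative_energy(off) > tol:
            s = 0.0
        else:
            lo, hi = 0.0, s_max
            if _negative_energy(off - s_max * trad) <= tol:
                lo = s_max
            else:
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if _negative_energy(off - mid * trad) <= tol:
                        lo = mid
                    else:
                        hi = mid
            s = lo
        content = off - s * trad

    if clip_floor is not None:
        content = np.clip(content, clip_floor, None)

    if container_bands:
        mask = _window_mask(nu, container_bands, window_half_width)
        denom = float(np.sum(np.abs(off[mask])))
        residual = float(np.sum(np.abs(content[mask])) / denom) if denom > 0 else 0.0
    else:
        residual = float("nan")

    spec = Spectrum(grid=pair.grid, intensities=content,
                    acquisition="scaled_subtracted", sample_id=pair.sample_id)
    return ScaledSubtractionResult(content_spectrum=spec, scale_factor=s,
                                   container_residual=residual, warning=warning)


# ---------------------------------------------------------------------------
# normalization and peak location


def spectrum_area(s: Spectrum, smooth_lambda: float = 1e4) -> float:
    """Noise-robust spectral area: trapezoidal integral of the absolute value
    of a Whittaker-smoothed copy.

    Smoothing preserves band integrals while suppressing the rectification
    bias that |noise| would otherwise add — without it, noisier acquisitions
    (opaque containers) would get systematically inflated areas and hence
    depressed normalized band amplitudes.
    """
    y = s.intensities.astype(float)
    if smooth_lambda > 0 and y.size > 4:
        n = y.size
        d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
        z = splu((sparse.identity(n, format="csc") + smooth_lambda * (d.T @ d)).tocsc()).solve(y)
    else:
        z = y
    return float(np.trapezoid(np.abs(z), s.grid.values))


def normalize_area(s: Spectrum) -> Spectrum:
    """Scale so the (noise-robust) spectral area over the grid is 1."""
    area = spectrum_area(s)
    if area <= 0.0:
        raise ValueError("cannot area-normalize a zero-area spectrum")
    return s.with_intensities(s.intensities / area)


def locate_peak(s: Spectrum, window: Tuple[float, float]) -> float:
    """Position of the maximum inside ``window``, refined to sub-grid
    resolution by 3-point parabolic interpolation."""
    lo, hi = window
    nu = s.grid.values
    if lo < nu[0] - 1e-9 or hi > nu[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"window {window} must lie inside the grid [{nu[0]}, {nu[-1]}]")
    mask = (nu >= lo) & (nu <= hi)
    idx = np.flatnonzero(mask)
    y = s.intensities[idx]
    if np.ptp(y) <= 0.0:
        raise ValueError("flat window: no peak to locate")
    k = idx[int(np.argmax(y))]
    if k == 0 or k == nu.size - 1:
        return float(nu[k])
    y0, y1, y2 = s.intensities[k - 1], s.intensities[k], s.intensities[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:  # not a local maximum of a concave triple
        return float(nu[k])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(nu[k] + delta * s.grid.spacing)


# ---------------------------------------------------------------------------
# shift-curve fitting


@dataclass
class ShiftFit:
    model: ShiftModel
    asymptote: float
    residual: float  # RMS of fit residuals, cm^-1


def fit_shift_curve(positions: Sequence[Tuple[float, float]]) -> ShiftFit:
    """Fit band position vs alcohol fraction with nu(x) = nu_inf + d*A*exp(-x/t).

    Returns the exponential-decay shift law (amplitude A, decay t, direction d)
    plus the fitted asymptote and RMS residual.  Requires >= 3 distinct
    concentrations and a non-constant trend.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("positions must be (concentration, wavenumber) tuples")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(y) < 1e-9:
        raise ValueError("positions are constant; no shift to fit")

    def model(x, nu_inf, amp, t):
        return nu_inf + amp * np.exp(-x / t)

    # initial guess: asymptote at the highest concentration, amplitude from span
    order = np.argsort(x)
    nu_inf0 = y[order[-1]]
    amp0 = y[order[0]] - nu_inf0
    t0 = max(np.ptp(x) / 2.0, 1.0)
    popt, _ = curve_fit(model, x, y, p0=(nu_inf0, amp0 if amp0 != 0 else 1.0, t0),
                        maxfev=20000)
    nu_inf, amp, t = popt
    if t <= 0:  # re-fit with positive-decay parametrisation
        popt, _ = curve_fit(lambda x, ni, a, lt: ni + a * np.exp(-x / np.exp(lt)),
                            x, y, p0=(nu_inf0, amp0 or 1.0, math.log(t0)), maxfev=20000)
        nu_inf, amp, t = popt[0], popt[1], math.exp(popt[2])
    resid = float(np.sqrt(np.mean((model(x, nu_inf, amp, t) - y) ** 2)))
    direction = 1 if amp >= 0 else -1
    return ShiftFit(
        model=ShiftModel(amplitude=abs(float(amp)), decay=float(t), direction=direction),
        asymptote=float(nu_inf),
        residual=resid,
    )


# ---------------------------------------------------------------------------
# full pipeline


def preprocess_pair(
    pair: SpectrumPair,
    cfg: Optional[PreprocessConfig] = None,
    container_bands: Optional[Sequence[float]] = None,
) -> Tuple[Spectrum, ScaledSubtractionResult]:
    """Standard chain: polynomial baseline on both acquisitions, scaled
    subtraction, Whittaker/AsLS baseline, area normalization."""
    cfg = cfg or PreprocessConfig()
    trad = polynomial_baseline(pair.traditional, cfg.poly_order)
    off = polynomial_baseline(pair.offset, cfg.poly_order)
    result = scaled_subtract(SpectrumPair(traditional=trad, offset=off), container_bands)
    content = baseline_whittaker(result.content_spectrum, cfg)
    if cfg.normalization == "area":
        content = normalize_area(content)
    return content, result


def preprocess_reference(s: Spectrum, cfg: Optional[PreprocessConfig] = None) -> Spectrum:
    """Apply the post-subtraction steps (Whittaker + normalization) to a clean
    reference spectrum so it is comparable with pipeline output."""
    cfg = cfg or PreprocessConfig()
    out = baseline_whittaker(
        Spectrum(grid=s.grid, intensities=s.intensities,
                 acquisition="scaled_subtracted", sample_id=s.sample_id),
        cfg,
    )
    if cfg.normalization == "area":
        out = normalize_area(out)
    return out
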