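"""Four-axis noise-fidelity protocol for generated-vs-real MR images.

Per slice and per image source the protocol measures, always on the shared
ground-truth mask:

1. **Spectral content** — radial power spectral density of the Gaussian
   high-pass residual inside the ROI, with mask-autocorrelation bias
   correction, summarised as the mean-squared log10-PSD distance to the
   median curve of the real set.
2. **Signal-dependent variance** — the first-order coefficient of a
   least-squares fit of windowed local noise std against windowed local mean
   intensity (local std taken on a detrended residual so in-window signal
   gradients do not inflate it).
3. **Short-range spatial correlation** — the trapezoidal integral of the
   normalised, mask-corrected radial autocorrelation of the high-pass
   residual over lags 0..10 px.
4. **Distributional shape** — excess kurtosis (and skewness) of the
   high-pass residual inside the ROI.

A wavelet-MAD noise-std estimate on an extra-myocardial tissue mask and the
mean ROI intensity complete the per-slice record. ``evaluate_sets`` runs the
whole protocol over paired (real, generated) cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats as sps

from .phantom import SlicePair

__all__ = [
    "SupportError",
    "RadialPSD",
    "NoiseFidelityRecord",
    "highpass_residual",
    "estimate_sigma_wavelet_mad",
    "radial_psd_masked",
    "median_psd",
    "log_psd_distance",
    "sigma_mu_slope",
    "short_range_correlation",
    "highpass_moments",
    "mean_roi_intensity",
    "extra_myocardial_tissue_mask",
    "evaluate_sets",
]

#: A lag cell / frequency bin needs at least this many contributing pixel
#: pairs before the mask-autocorrelation correction is trusted.
MIN_PAIRS = 32

#: Bins below this spatial frequency (cycles/px) carry the high-pass
#: pre-filter roll-off, not a discriminating noise feature, and are excluded
#: when comparing PSDs across sources.
LOW_FREQ_CUTOFF = 0.03


class SupportError(ValueError):
    """An ROI is too small (or too fragmented) to support a metric."""


@dataclass(frozen=True)
class RadialPSD:
    """Radially binned power spectral density in cycles/px."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be aligned")
        if (np.diff(self.freqs) <= 0).any():
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[-1] > 0.5 + 1e-12:
            raise ValueError("frequencies beyond Nyquist (0.5 cycles/px)")

    @property
    def n_bins(self) -> int:
        return self.freqs.size


@dataclass
class NoiseFidelityRecord:
    """Per-slice values of the four noise axes for one image source."""

    patient_id: str
    slice_index: int
    source: str
    psd_distance: float = np.nan
    sigma_mu_slope: float = np.nan
    short_range_corr: float = np.nan
    hp_kurtosis: float = np.nan
    hp_skewness: float = np.nan
    sigma_hat: float = np.nan
    mean_roi_intensity: float = np.nan
    slope_supported: bool = False
    corr_supported: bool = False
    shape_supported: bool = False


def highpass_residual(image: np.ndarray, sigma_hp: float = 6.0) -> np.ndarray:
    """Gaussian high-pass: image minus its sigma_hp-px blur (reflective edges)."""
    if sigma_hp <= 0:
        raise ValueError("sigma_hp must be positive")
    image = np.asarray(image, dtype=float)
    return image - ndimage.gaussian_filter(image, sigma_hp, mode="reflect")


def estimate_sigma_wavelet_mad(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    wavelet: str = "db2",
    min_px: int = 64,
) -> float:
    """Robust noise-std estimate from fine-scale wavelet detail coefficients.

    Single-level 2D decomposition; sigma-hat = median(|HH coefficients whose
    support lies in the mask|) / 0.6745. The mask is eroded by 2 px before
    mapping to coefficient resolution so edge-straddling coefficients are
    excluded.
    """
    image = np.asarray(image, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.sum() < min_px:
        raise SupportError(f"tissue mask has fewer than {min_px} pixels")
    _, (_, _, hh) = pywt.dwt2(image, wavelet)
    eroded = ndimage.binary_erosion(tissue_mask, iterations=2)
    # coefficient (i, j) sits over the 2x2 pixel block at (2i, 2j); boundary
    # coefficients beyond the image (from signal extension) are dropped
    h2 = min(hh.shape[0], eroded.shape[0] // 2)
    w2 = min(hh.shape[1], eroded.shape[1] // 2)
    blocks = eroded[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).all(axis=(1, 3))
    coeffs = hh[:h2, :w2][blocks]
    if coeffs.size < min_px // 4:
        raise SupportError("too few wavelet coefficients inside the tissue mask")
    return float(np.median(np.abs(coeffs)) / 0.6745)


def _masked_autocovariance(
    residual: np.ndarray, mask: np.ndarray, min_pairs: int = MIN_PAIRS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag unbiased second-moment estimate of a masked field.

    Zero-fills outside the mask, computes raw lag sums and pair counts by
    zero-padded FFT products, and divides sum by count where at least
    ``min_pairs`` pixel pairs contribute (elsewhere the estimate is zeroed
    and flagged invalid). No mean subtraction: the input is a high-pass
    residual whose DC is already removed, and keeping raw second moments
    lets a perfectly correlated (constant) field report correlation one.
    Returns (cov, valid) arrays on the doubled FFT grid.
    """
    residual = np.asarray(residual, dtype=float)
    m = np.asarray(mask, dtype=float)
    H, W = residual.shape
    shape = (2 * H, 2 * W)
    fr = np.fft.rfft2(residual * m, s=shape)
    fm = np.fft.rfft2(m, s=shape)
    lag_sum = np.fft.irfft2(fr * np.conj(fr), s=shape)
    n_pairs = np.rint(np.fft.irfft2(fm * np.conj(fm), s=shape))
    valid = n_pairs >= min_pairs
    cov = np.zeros(shape)
    cov[valid] = lag_sum[valid] / n_pairs[valid]
    return cov, valid


def _lag_radii(shape: tuple[int, int]) -> np.ndarray:
    """Radial lag distance (px) on the doubled FFT grid, fftfreq-ordered."""
    ly = np.fft.fftfreq(shape[0], d=1.0 / shape[0])[:, None]
    lx = np.fft.fftfreq(shape[1], d=1.0 / shape[1])[None, :]
    return np.hypot(ly, lx)


def radial_psd_masked(
    residual: np.ndarray,
    roi_mask: np.ndarray,
    min_pairs: int = MIN_PAIRS,
    min_bins: int = 8,
    lag_taper: float | None = None,
) -> RadialPSD:
    """Mask-corrected radial power spectral density of an ROI-restricted field.

    The mask-autocorrelation correction divides the raw lag sums by the
    number of contributing pixel pairs before transforming to the spectral
    domain, so the ROI's shape does not bias the spectrum; a radial Hann
    taper over lags (half-width ``lag_taper`` px, default min(H, W)/4)
    controls the variance of the long-lag estimates, Blackman-Tukey style.
    Radial bin width is 1/max(H, W) cycles/px up to Nyquist. Power can be
    slightly negative in individual bins from estimation noise; such bins
    are reported as-is and excluded from log-distance comparisons.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() < MIN_PAIRS:
        raise SupportError("ROI too small to support spectral binning")
    cov, _ = _masked_autocovariance(residual, roi_mask, min_pairs)
    shape = cov.shape
    if lag_taper is None:
        lag_taper = max(16.0, min(roi_mask.shape) / 4.0)
    lag_r = _lag_radii(shape)
    taper = np.where(
        lag_r < lag_taper, 0.5 * (1.0 + np.cos(np.pi * lag_r / lag_taper)), 0.0
    )
    psd = np.fft.fft2(cov * taper).real
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fy, fx)
    h, w = roi_mask.shape
    bin_width = 1.0 / max(h, w)
    idx = np.floor(rho / bin_width).astype(int)
    n_bins = int(np.floor(0.5 / bin_width))
    sel = idx < n_bins
    sums = np.bincount(idx[sel], weights=psd[sel], minlength=n_bins)
    counts = np.bincount(idx[sel], minlength=n_bins)
    good = counts > 0
    if good.sum() < min_bins:
        raise SupportError("too few populated frequency bins")
    freqs = (np.arange(n_bins) + 0.5) * bin_width
    return RadialPSD(freqs[good], sums[good] / counts[good])


def median_psd(psds: Sequence[RadialPSD]) -> RadialPSD:
    """Per-bin median reference curve over a set of PSDs on a shared grid."""
    if not psds:
        raise ValueError("need at least one PSD")
    f0 = psds[0].freqs
    for p in psds:
        if p.freqs.shape != f0.shape or not np.allclose(p.freqs, f0):
            raise ValueError("PSDs must share a frequency grid")
    return RadialPSD(f0.copy(), np.median(np.stack([p.power for p in psds]), axis=0))


def log_psd_distance(
    psd: RadialPSD, ref_psd: RadialPSD, min_freq: float = 0.0
) -> float:
    """Mean over supported bins of (log10 p - log10 p_ref)^2 (dimensionless).

    Bins with nonpositive power in either curve, or below ``min_freq``, are
    excluded from the mean.
    """
    if psd.freqs.shape != ref_psd.freqs.shape or not np.allclose(psd.freqs, ref_psd.freqs):
        raise ValueError("PSDs must share a frequency grid")
    ok = (psd.power > 0) & (ref_psd.power > 0) & (psd.freqs >= min_freq)
    if not ok.any():
        raise SupportError("no supported frequency bins for the log-PSD distance")
    d = np.log10(psd.power[ok]) - np.log10(ref_psd.power[ok])
    return float(np.mean(d**2))


def sigma_mu_slope(
    image: np.ndarray,
    roi_mask: np.ndarray,
    window: int = 7,
    sigma_detrend: float = 1.0,
    min_windows: int = 10,
    label_map: np.ndarray | None = None,
    label_margin: int = 2,
) -> tuple[float, int]:
    """Slope of local noise std against local mean intensity.

    The ROI is tiled with non-overlapping ``window`` x ``window`` patches
    fully inside the mask; when ``label_map`` is given a patch must also be
    label-pure with ``label_margin`` px to spare, so sharp inter-class edges
    (and the detrending blur's leakage across them) cannot masquerade as
    noise. Per patch the mean is taken from the raw image and the std
    (ddof=1) from the image minus a ``sigma_detrend``-px Gaussian blur; the
    returned slope is the first-order coefficient of an unweighted
    least-squares line sigma = a + b*mu. Returns (slope, n_windows).
    """
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    detrended = image - ndimage.gaussian_filter(image, sigma_detrend, mode="reflect")
    h, w = image.shape
    mus, sigmas = [], []
    for i0 in range(0, h - window + 1, window):
        for j0 in range(0, w - window + 1, window):
            sl = (slice(i0, i0 + window), slice(j0, j0 + window))
            if not roi_mask[sl].all():
                continue
            if label_map is not None:
                m = label_margin
                sl_wide = (
                    slice(max(i0 - m, 0), min(i0 + window + m, h)),
                    slice(max(j0 - m, 0), min(j0 + window + m, w)),
                )
                if np.unique(label_map[sl_wide]).size > 1:
                    continue
            mus.append(image[sl].mean())
            sigmas.append(detrended[sl].std(ddof=1))
    n = len(mus)
    if n < min_windows:
        raise SupportError(f"only {n} valid windows (< {min_windows})")
    b, _a = np.polyfit(np.asarray(mus), np.asarray(sigmas), 1)
    return float(b), n


def short_range_correlation(
    residual: np.ndarray,
    roi_mask: np.ndarray,
    max_lag: int = 10,
    min_pairs: int = MIN_PAIRS,
) -> float:
    """Integral of the normalised radial autocorrelation over lags 0..max_lag px.

    The autocorrelation is mask-corrected (per-lag pair-count normalisation),
    radially averaged into integer-lag bins (nearest-integer assignment) and
    normalised so rho(0) = 1; the return value is the trapezoidal integral,
    in px, between 0 and ``max_lag`` (max_lag for a perfectly correlated
    field, about 0.5 for white noise).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    cov, valid = _masked_autocovariance(residual, roi_mask, min_pairs)
    radii = _lag_radii(cov.shape)
    lag_bin = np.rint(radii).astype(int)
    rho = np.empty(max_lag + 1)
    for r in range(max_lag + 1):
        cells = (lag_bin == r) & valid & (radii <= max_lag + 0.5)
        if not cells.any():
            raise SupportError(f"no valid lag cells at lag {r} px")
        rho[r] = cov[cells].mean()
    if rho[0] <= 0:
        raise SupportError("nonpositive zero-lag power: degenerate residual")
    rho = rho / rho[0]
    return float(np.trapezoid(rho, dx=1.0))


def highpass_moments(residual: np.ndarray, roi_mask: np.ndarray, min_px: int = 100) -> tuple[float, float]:
    """(excess kurtosis, skewness) of the residual values inside the ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    vals = np.asarray(residual, dtype=float)[roi_mask]
    if vals.size < min_px:
        raise SupportError(f"ROI has fewer than {min_px} pixels")
    if vals.std() == 0:
        raise SupportError("zero-variance residual")
    return float(sps.kurtosis(vals, fisher=True, bias=False)), float(
        sps.skew(vals, bias=False)
    )


def mean_roi_intensity(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of [0, 1]-scale intensities inside the ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    return float(np.asarray(image, dtype=float)[roi_mask].mean())


def extra_myocardial_tissue_mask(mask: np.ndarray, margin_px: int = 4) -> np.ndarray:
    """Background region safely away from the myocardium, for sigma-hat.

    Dilates the myocardium (labels 1 and 2) by ``margin_px`` and returns the
    complement, so partial-volume pixels at the annulus boundary do not leak
    tissue structure into the noise estimate.
    """
    mask = np.asarray(mask)
    myo = mask > 0
    if margin_px > 0:
        myo = ndimage.binary_dilation(myo, iterations=margin_px)
    return ~myo


def _roi_from_mask(mask: np.ndarray, roi: str) -> np.ndarray:
    if roi == "myocardium":
        return mask > 0
    if roi == "scar":
        return mask == 2
    raise ValueError("roi must be 'myocardium' or 'scar'")


def edge_safe_roi(mask: np.ndarray, roi: str, margin_px: int) -> np.ndarray:
    """ROI with every pixel at least ``margin_px`` from any label transition.

    Erodes each constituent class region separately and takes the union, so
    the Gaussian high-pass pre-filter's blur of inter-class intensity edges
    cannot leak tissue structure into residual-based noise metrics.
    """
    mask = np.asarray(mask)
    classes = (1, 2) if roi == "myocardium" else (2,)
    if roi not in ("myocardium", "scar"):
        raise ValueError("roi must be 'myocardium' or 'scar'")
    out = np.zeros(mask.shape, dtype=bool)
    for c in classes:
        region = mask == c
        if margin_px > 0 and region.any():
            region = ndimage.binary_erosion(region, iterations=margin_px)
        out |= region
    return out


def evaluate_sets(
    real_slices: Sequence[SlicePair],
    gen_slices_by_source: Mapping[str, Sequence[SlicePair]],
    roi: str = "myocardium",
    min_scar_px: int = 100,
    sigma_hp: float = 6.0,
    max_lag: int = 10,
    min_freq: float = LOW_FREQ_CUTOFF,
    roi_margin_px: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the four-axis protocol over paired real and generated cohorts.

    Every generated slice must pair with a real slice by (patient_id,
    slice_index) and share its label mask bit-for-bit. The extra-myocardial
    tissue mask used for sigma-hat is derived once per slice from the shared
    mask and reused across sources; the PSD reference is the per-bin median
    curve of the real set. Scar-ROI analyses keep only slices whose scar
    covers at least ``min_scar_px`` pixels.

    Residual-based metrics (PSD, short-range correlation, high-pass moments)
    run on the edge-safe ROI (``roi_margin_px`` from any label transition)
    so the high-pass blur of sharp phantom edges cannot masquerade as noise;
    the sigma(mu) slope and mean intensity use the full ROI, the slope with
    label-pure windows.

    Returns a long-format DataFrame (one row per slice and source, real
    included under source "REAL") and a dict of exclusion counts.
    """
    real_by_key = {(s.patient_id, s.slice_index): s for s in real_slices}
    for name, slices in gen_slices_by_source.items():
        for s in slices:
            key = (s.patient_id, s.slice_index)
            if key not in real_by_key:
                raise ValueError(f"{name} slice {key} has no real counterpart")
            if not np.array_equal(s.mask, real_by_key[key].mask):
                raise ValueError(f"{name} slice {key} mask differs from the real mask")

    exclusions = {
        "scar_below_threshold": 0,
        "slope_unsupported": 0,
        "corr_unsupported": 0,
        "shape_unsupported": 0,
        "psd_unsupported": 0,
    }
    sources: dict[str, Mapping] = {"REAL": real_by_key}
    for name, slices in gen_slices_by_source.items():
        sources[name] = {(s.patient_id, s.slice_index): s for s in slices}

    records: list[NoiseFidelityRecord] = []
    psd_cache: dict[tuple, RadialPSD | None] = {}
    keys = sorted(real_by_key)
    for key in keys:
        mask = real_by_key[key].mask
        roi_mask = _roi_from_mask(mask, roi)
        if roi == "scar" and roi_mask.sum() < min_scar_px:
            exclusions["scar_below_threshold"] += 1
            continue
        if not roi_mask.any():
            exclusions["scar_below_threshold" if roi == "scar" else "psd_unsupported"] += 1
            continue
        safe_roi = edge_safe_roi(mask, roi, roi_margin_px)
        if not safe_roi.any():
            safe_roi = roi_mask
        tissue = extra_myocardial_tissue_mask(mask)
        for name, by_key in sources.items():
            sp = by_key.get(key)
            if sp is None:
                continue
            rec = NoiseFidelityRecord(sp.patient_id, sp.slice_index, name)
            residual = highpass_residual(sp.image, sigma_hp)
            try:
                psd_cache[(key, name)] = radial_psd_masked(residual, safe_roi)
            except SupportError:
                psd_cache[(key, name)] = None
                exclusions["psd_unsupported"] += 1
            try:
                rec.sigma_mu_slope, _ = sigma_mu_slope(sp.image, roi_mask, label_map=mask)
                rec.slope_supported = True
            except SupportError:
                exclusions["slope_unsupported"] += 1
            try:
                rec.short_range_corr = short_range_correlation(residual, safe_roi, max_lag)
                rec.corr_supported = True
            except SupportError:
                exclusions["corr_unsupported"] += 1
            try:
                rec.hp_kurtosis, rec.hp_skewness = highpass_moments(residual, safe_roi)
                rec.shape_supported = True
            except SupportError:
                exclusions["shape_unsupported"] += 1
            try:
                rec.sigma_hat = estimate_sigma_wavelet_mad(sp.image, tissue)
            except SupportError:
                rec.sigma_hat = np.nan
            rec.mean_roi_intensity = mean_roi_intensity(sp.image, roi_mask)
            records.append(rec)

    real_psds = [
        psd_cache[(key, "REAL")]
        for key in keys
        if psd_cache.get((key, "REAL")) is not None
    ]
    ref = median_psd(real_psds) if real_psds else None
    for rec in records:
        p = psd_cache.get(((rec.patient_id, rec.slice_index), rec.source))
        if p is not None and ref is not None:
            try:
                rec.psd_distance = log_psd_distance(p, ref, min_freq=min_freq)
            except SupportError:
                exclusions["psd_unsupported"] += 1

    df = pd.DataFrame([vars(r) for r in records])
    return df, exclusions
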