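"""Quantitative analysis of 1D carbon spectra.

Fits baseline-plus-peaks models (Gaussian, Lorentzian or pseudo-Voigt,
via lmfit) inside user-specified ppm windows to obtain peak centers, FWHM
linewidths and areas with 1-sigma uncertainties, and converts side-chain
reporter peak areas into the A:B composition ratio of a two-component
nanofiber.  The lysine C-gamma peak (~23 ppm, unique to the cationic
chain) and the glutamate C-delta peak (~181 ppm, unique to the anionic
chain) are the canonical reporters; each area is normalized by the number
of contributing carbons per chain before the ratio is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import models as lmfit_models
from scipy.signal import find_peaks

from .errors import ConfigurationError, InputError

__all__ = [
    "NMRSpectrum",
    "PeakFit",
    "WindowFit",
    "CompositionResult",
    "fit_peaks",
    "composition_from_areas",
    "synth_spectrum",
    "reporter_multiplicities",
]

K_CGAMMA_PPM = 23.0
E_CDELTA_PPM = 181.0

_SHAPES = {
    "gaussian": lmfit_models.GaussianModel,
    "lorentzian": lmfit_models.LorentzianModel,
    "pseudo_voigt": lmfit_models.PseudoVoigtModel,
}


@dataclass
class NMRSpectrum:
    """1D trace: strictly monotone ppm axis and matching intensities."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise InputError("ppm and intensity must be equal-length 1D arrays")
        diffs = np.diff(self.ppm)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InputError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise InputError("intensities must be finite")

    @classmethod
    def from_csv(cls, path) -> "NMRSpectrum":
        """Two-column CSV (ppm, intensity), optional header line."""
        df = pd.read_csv(path, comment="#")
        if df.shape[1] < 2:
            raise InputError(f"{path}: expected two columns (ppm, intensity)")
        first = df.columns[0]
        try:  # headerless file: the 'header' row is actually data
            float(first)
            df = pd.read_csv(path, comment="#", header=None)
        except ValueError:
            pass
        return cls(ppm=df.iloc[:, 0].to_numpy(float),
                   intensity=df.iloc[:, 1].to_numpy(float))

    def window(self, lo: float, hi: float) -> "NMRSpectrum":
        """Ascending-ppm slice of the trace between lo and hi."""
        lo, hi = sorted((lo, hi))
        mask = (self.ppm >= lo) & (self.ppm <= hi)
        if mask.sum() < 5:
            raise InputError(f"window [{lo}, {hi}] covers <5 samples")
        ppm = self.ppm[mask]
        inten = self.intensity[mask]
        if ppm[0] > ppm[-1]:
            ppm, inten = ppm[::-1], inten[::-1]
        return NMRSpectrum(ppm=ppm, intensity=inten)


@dataclass
class PeakFit:
    center: float                 # ppm
    fwhm: float                   # ppm
    area: float                   # intensity * ppm
    shape: str = "pseudo_voigt"
    mixing: float | None = None   # Lorentzian fraction for pseudo-Voigt
    stderr: dict = field(default_factory=dict)  # 1-sigma per parameter


@dataclass
class WindowFit:
    window: tuple
    success: bool
    peaks: list = field(default_factory=list)
    message: str = ""
    redchi: float = float("nan")


@dataclass
class CompositionResult:
    ratio_a_to_b: float
    area_k_cgamma: float
    area_e_cdelta: float
    n_k_per_a: int
    n_e_per_b: int
    stderr: float | None = None


def _initial_centers(spec: NMRSpectrum, n_peaks: int) -> list:
    """Peak-pick local maxima; shoulders that do not produce a separate
    maximum are seeded from intensity-weighted quantiles of the window."""
    inten = spec.intensity - np.median(spec.intensity)
    idx, props = find_peaks(inten, prominence=0.1 * max(inten.max(), 1e-30))
    order = np.argsort(props["prominences"])[::-1] if idx.size else []
    centers = [spec.ppm[idx[k]] for k in order[:n_peaks]]
    if len(centers) < n_peaks:
        mass = np.clip(inten, 0.0, None)
        total = mass.sum()
        if total <= 0:
            mass = np.ones_like(inten)
            total = mass.sum()
        cum = np.cumsum(mass) / total
        quantiles = [(k + 0.5) / n_peaks for k in range(n_peaks)]
        centers = [spec.ppm[np.searchsorted(cum, q)] for q in quantiles]
    return sorted(centers)


def fit_peaks(spectrum: NMRSpectrum, regions,
              baseline_order: int = 1,
              shape: str = "pseudo_voigt") -> list:
    """Least-squares peak deconvolution per window.

    ``regions`` is a list of ``((lo_ppm, hi_ppm), n_peaks)``.  Each window
    is fitted independently with a polynomial baseline plus ``n_peaks``
    analytic peaks; initial centers come from local maxima, so the fit is
    deterministic.  Windows that fail report ``success=False`` with a
    message and do not abort the remaining windows.
    """
    if shape not in _SHAPES:
        raise ConfigurationError(
            f"shape must be one of {sorted(_SHAPES)}, got {shape!r}")
    results = []
    for (lo, hi), n_peaks in regions:
        if n_peaks < 1:
            raise ConfigurationError("each window needs n_peaks >= 1")
        try:
            spec = spectrum.window(lo, hi)
            results.append(_fit_window(spec, (lo, hi), n_peaks,
                                       baseline_order, shape))
        except (InputError, ValueError) as exc:
            results.append(WindowFit(window=(lo, hi), success=False,
                                     message=str(exc)))
    return results


def _fit_window(spec: NMRSpectrum, window: tuple, n_peaks: int,
                baseline_order: int, shape: str) -> WindowFit:
    x, y = spec.ppm, spec.intensity
    span = x[-1] - x[0]
    if baseline_order == 0:
        model = lmfit_models.ConstantModel(prefix="bl_")
        params = model.make_params(c=float(np.median(y)))
    else:
        model = lmfit_models.PolynomialModel(degree=baseline_order, prefix="bl_")
        params = model.make_params(**{f"c{k}": 0.0
                                      for k in range(baseline_order + 1)})
        params["bl_c0"].set(value=float(np.median(y)))
    centers = _initial_centers(spec, n_peaks)
    base = np.median(y)
    for k, center in enumerate(centers):
        peak = _SHAPES[shape](prefix=f"p{k}_")
        height = max(float(np.interp(center, x, y) - base), 1e-12)
        sigma0 = max(span / (8.0 * n_peaks), 2.0 * abs(np.median(np.diff(x))))
        pp = peak.make_params()
        pp[f"p{k}_center"].set(value=center, min=x[0], max=x[-1])
        pp[f"p{k}_sigma"].set(value=sigma0, min=1e-6 * span)
        pp[f"p{k}_amplitude"].set(value=height * sigma0 * 3.0)
        if shape == "pseudo_voigt":
            pp[f"p{k}_fraction"].set(value=0.5, min=0.0, max=1.0)
        model = model + peak
        params.update(pp)
    try:
        out = model.fit(y, params, x=x)
    except Exception as exc:  # numerical failure stays local to the window
        return WindowFit(window=window, success=False, message=str(exc))
    peaks = []
    for k in range(n_peaks):
        pv = out.params
        stderr = {name: (pv[f"p{k}_{name}"].stderr
                         if pv[f"p{k}_{name}"].stderr is not None else float("nan"))
                  for name in ("center", "fwhm", "amplitude")
                  if f"p{k}_{name}" in pv}
        peaks.append(PeakFit(
            center=float(pv[f"p{k}_center"].value),
            fwhm=float(pv[f"p{k}_fwhm"].value),
            area=float(pv[f"p{k}_amplitude"].value),
            shape=shape,
            mixing=(float(pv[f"p{k}_fraction"].value)
                    if shape == "pseudo_voigt" else None),
            stderr=stderr,
        ))
    peaks.sort(key=lambda p: p.center)
    return WindowFit(window=window, success=bool(out.success), peaks=peaks,
                     message=out.message if hasattr(out, "message") else "",
                     redchi=float(out.redchi))


def reporter_multiplicities(seq_a: str, seq_b: str):
    """(n_K on chain A, n_E on chain B): carbons behind each reporter peak."""
    return seq_a.upper().count("K"), seq_b.upper().count("E")


def composition_from_areas(fit_k_cgamma: PeakFit, fit_e_cdelta: PeakFit,
                           n_k_per_a: int, n_e_per_b: int) -> CompositionResult:
    """A:B ratio from reporter peak areas, normalized per contributing carbon.

    ratio = (area_K / n_K_per_A) / (area_E / n_E_per_B); invariant under
    global intensity scaling.
    """
    if n_k_per_a < 1 or n_e_per_b < 1:
        raise ConfigurationError("reporter multiplicities must be >= 1")
    if fit_k_cgamma.area <= 0 or fit_e_cdelta.area <= 0:
        raise InputError("reporter peak areas must be positive")
    ratio = (fit_k_cgamma.area / n_k_per_a) / (fit_e_cdelta.area / n_e_per_b)
    stderr = None
    sk = fit_k_cgamma.stderr.get("amplitude")
    se = fit_e_cdelta.stderr.get("amplitude")
    if sk is not None and se is not None and np.isfinite([sk, se]).all():
        rel = np.sqrt((sk / fit_k_cgamma.area) ** 2
                      + (se / fit_e_cdelta.area) ** 2)
        stderr = float(ratio * rel)
    return CompositionResult(ratio_a_to_b=float(ratio),
                             area_k_cgamma=fit_k_cgamma.area,
                             area_e_cdelta=fit_e_cdelta.area,
                             n_k_per_a=n_k_per_a, n_e_per_b=n_e_per_b,
                             stderr=stderr)


def _shape_profile(x: np.ndarray, peak: PeakFit) -> np.ndarray:
    """Analytic line shapes matching the fitting models' conventions."""
    c, a = peak.center, peak.area
    if peak.shape == "gaussian":
        sigma = peak.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return a / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - c) / sigma) ** 2)
    if peak.shape == "lorentzian":
        gamma = peak.fwhm / 2.0
        return a / np.pi * gamma / ((x - c) ** 2 + gamma ** 2)
    if peak.shape == "pseudo_voigt":
        eta = 0.5 if peak.mixing is None else peak.mixing
        gauss = PeakFit(center=c, fwhm=peak.fwhm, area=a, shape="gaussian")
        lor = PeakFit(center=c, fwhm=peak.fwhm, area=a, shape="lorentzian")
        return ((1 - eta) * _shape_profile(x, gauss)
                + eta * _shape_profile(x, lor))
    raise ConfigurationError(f"unknown peak shape {peak.shape!r}")


def synth_spectrum(peaks, noise_sd: float, axis, rng_seed: int | None = None,
                   baseline: tuple = (0.0, 0.0)) -> NMRSpectrum:
    """Synthetic spectrum: analytic peaks + linear baseline + Gaussian noise.

    ``axis`` is either an explicit ppm array or ``(lo, hi, n_points)``;
    ``baseline`` is (slope, intercept).  Deterministic per seed.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    if isinstance(axis, tuple) and len(axis) == 3:
        x = np.linspace(axis[0], axis[1], int(axis[2]))
    else:
        x = np.asarray(axis, dtype=float)
    y = baseline[0] * x + baseline[1]
    for peak in peaks:
        y = y + _shape_profile(x, peak)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return NMRSpectrum(ppm=x, intensity=y)
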