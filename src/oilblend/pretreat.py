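"""Spectral pretreatments: SNV, MSC, Savitzky-Golay smoothing, wavelet
denoising, and raw passthrough.

Each pretreatment is a fit/apply pair so that anything learned from data
(only MSC learns anything: its reference spectrum) is learned from the
calibration partition alone and reused unchanged on prediction samples.

SNV and MSC both undo the per-sample affine scatter distortion
``x -> b*x + a`` that differences in particle size, density and packing
impose on diffuse-reflectance measurements: SNV by standardising each
spectrum to mean 0 / sd 1, MSC by regressing each spectrum on a
reference spectrum and inverting the fitted offset and gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy.signal import savgol_filter

from .exceptions import (
    CorrectionError,
    DegenerateSpectrumError,
    FitError,
    ParameterError,
)
from .spectra import SpectrumSet, validate

logger = logging.getLogger(__name__)

METHODS = ("raw", "snv", "msc", "sg", "wt")
WT_RULES = ("universal-soft", "universal-hard", "none")


@dataclass
class PretreatmentState:
    """A fitted (or stateless) pretreatment ready to apply to spectra."""

    method: str = "raw"
    msc_reference: np.ndarray | None = None
    sg_window: int = 11
    sg_polyorder: int = 2
    wt_family: str = "db4"
    wt_level: int = 4
    wt_threshold_rule: str = "universal-soft"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown pretreatment {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ParameterError(
                f"SG window must be odd and > polyorder "
                f"(window={self.sg_window}, polyorder={self.sg_polyorder})"
            )
        if self.wt_threshold_rule not in WT_RULES:
            raise ParameterError(
                f"unknown wavelet threshold rule {self.wt_threshold_rule!r}"
            )

    @property
    def fitted(self) -> bool:
        return self.method != "msc" or self.msc_reference is not None


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, sd with n-1.

    Output has mean 0 and sample sd 1; invariant under any affine
    distortion ``b*x + a`` with b > 0.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ParameterError("SNV needs a spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSpectrumError("constant spectrum has no SNV transform")
    return (x - x.mean()) / sd


def msc_fit(calibration: SpectrumSet) -> PretreatmentState:
    """Fit MSC: the reference is the pointwise mean calibration spectrum."""
    if calibration.n_samples < 2:
        raise FitError("MSC needs at least 2 calibration spectra")
    ref = calibration.reflectance.mean(axis=0)
    return PretreatmentState(method="msc", msc_reference=ref)


def msc_apply(state: PretreatmentState, spectrum: np.ndarray, *,
              sample_id: str = "?", b_tol: float = 1e-8) -> np.ndarray:
    """Apply MSC: least-squares fit ``x = a + b*ref``; return ``(x - a)/b``."""
    if state.method != "msc" or state.msc_reference is None:
        raise FitError("MSC state is not fitted")
    x = np.asarray(spectrum, dtype=float)
    ref = state.msc_reference
    if x.shape != ref.shape:
        raise ParameterError(
            f"spectrum length {x.size} != reference length {ref.size}"
        )
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise CorrectionError("MSC reference spectrum is constant")
    b = (ref_c @ (x - x.mean())) / denom
    a = x.mean() - b * ref.mean()
    if abs(b) < b_tol:
        raise CorrectionError(
            f"sample {sample_id!r} uncorrelated with MSC reference (b={b:g})"
        )
    return (x - a) / b


def sg_smooth(spectrum: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay moving-window polynomial smoothing.

    Edges use local polynomial interpolation so that any signal that is
    itself a polynomial of degree <= polyorder passes through unchanged.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError(
            f"window must be odd and > polyorder (window={window}, "
            f"polyorder={polyorder})"
        )
    if x.size < window:
        raise ParameterError(f"spectrum length {x.size} < window {window}")
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")


def wt_denoise(spectrum: np.ndarray, family: str = "db4", level: int = 4,
               rule: str = "universal-soft") -> np.ndarray:
    """Wavelet shrinkage: decompose, threshold detail coefficients, rebuild.

    The default rule is the universal threshold ``sigma * sqrt(2 ln n)``
    with ``sigma`` estimated per spectrum from the median absolute
    deviation of the finest detail level, applied as soft thresholding.
    ``rule="none"`` reconstructs without shrinkage (identity up to
    float error for orthogonal wavelets).
    """
    x = np.asarray(spectrum, dtype=float)
    if rule not in WT_RULES:
        raise ParameterError(f"unknown threshold rule {rule!r}")
    try:
        wavelet = pywt.Wavelet(family)
    except ValueError as exc:
        raise ParameterError(f"unknown wavelet family {family!r}") from exc
    max_level = pywt.dwt_max_level(x.size, wavelet.dec_len)
    if level < 1 or level > max_level:
        raise ParameterError(
            f"level {level} infeasible for length {x.size} "
            f"(max {max_level} for {family})"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    if rule != "none":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(x.size))
        if thr > 0:
            mode = "soft" if rule == "universal-soft" else "hard"
            coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode=mode)
                                    for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet, mode="symmetric")[: x.size]


def fit_pretreatment(method: str, calibration: SpectrumSet | None = None,
                     **params) -> PretreatmentState:
    """Build a ready-to-apply state for ``method``.

    Only MSC needs calibration data (its reference spectrum); the other
    methods are per-spectrum and stateless.
    """
    if method == "msc":
        if calibration is None:
            raise FitError("MSC requires a calibration SpectrumSet")
        state = msc_fit(calibration)
        return replace(state, **params) if params else state
    return PretreatmentState(method=method, **params)


def apply_pretreatment(state: PretreatmentState, data: SpectrumSet) -> SpectrumSet:
    """Apply a fitted pretreatment row-wise; metadata passes through untouched."""
    if not state.fitted:
        raise FitError(f"pretreatment {state.method!r} is not fitted")
    out = np.empty_like(data.reflectance, dtype=float)
    for i in range(data.n_samples):
        x = data.reflectance[i]
        sid = data.meta[i].sample_id if i < len(data.meta) else str(i)
        try:
            if state.method == "raw":
                out[i] = x
            elif state.method == "snv":
                out[i] = snv(x)
            elif state.method == "msc":
                out[i] = msc_apply(state, x, sample_id=sid)
            elif state.method == "sg":
                out[i] = sg_smooth(x, state.sg_window, state.sg_polyorder)
            else:  # wt
                out[i] = wt_denoise(x, state.wt_family, state.wt_level,
                                    state.wt_threshold_rule)
        except (DegenerateSpectrumError, CorrectionError, ParameterError) as exc:
            raise type(exc)(f"sample {sid!r}: {exc}") from exc
    logger.info("applied pretreatment %s to %d spectra", state.method,
                data.n_samples)
    result = data.with_reflectance(out)
    # pretreated values are no longer reflectance factors; sign is unconstrained
    return validate(result, allow_negative=True)
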