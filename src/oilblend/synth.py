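"""Synthetic Vis-NIR spectra of binary edible-oil blends.

The study design this generator emulates: two adulteration cases
(sesame oil and rapeseed oil, each cut with soybean oil), mixing ratios
0-100% of the genuine oil in 10% steps, five replicate groups — 110
spectra in total.  Each pure oil is a parametric *endmember* spectrum
(smooth baseline plus Gaussian absorption features); blends are linear
in the mixing ratio; measurement artefacts are an affine per-sample
scatter distortion (multiplicative gain and additive offset — exactly
what SNV/MSC are designed to remove) plus per-point white noise.

Qualitative structure built into the default endmembers:

* the visible band (400-700 nm) carries the largest between-oil
  separation, with soybean oil the brightest of the three;
* soybean oil has one broad visible absorption trough, rapeseed oil two
  narrow ones, sesame oil a slow featureless rise;
* in the NIR (720-1700 nm) soybean oil reflects more than either genuine
  oil, so blend reflectance rises with the soybean fraction;
* above ~1700 nm all three oils coincide (the flat band).

Randomness is a deterministic function of ``(seed, sample_index)``: each
sample's draws come from ``numpy.random.default_rng([seed, sample_index])``
(PCG64 seeded through SeedSequence), so a fixed seed reproduces a
bit-identical dataset regardless of generation order or platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import LabellingError, ParameterError, ValidationError
from .spectra import CASES, SampleMeta, SpectrumSet, WavelengthGrid, default_grid, validate

logger = logging.getLogger(__name__)

#: The seven class labels of the qualitative task (pure soybean is shared
#: between the two cases).
CLASS_LABELS = (
    "pure_sesame",
    "low_adulterated_sesame",
    "high_adulterated_sesame",
    "pure_soybean",
    "high_adulterated_rapeseed",
    "low_adulterated_rapeseed",
    "pure_rapeseed",
)

_FLAT_BAND = (1700.0, 2500.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class EndmemberModel:
    """Parametric pure-oil reflectance spectrum.

    ``baseline`` maps wavelength (nm) to reflectance; ``peaks`` are
    Gaussian features ``(center nm, width nm, signed amplitude)`` added
    on top (negative amplitude = absorption trough).  Within
    ``flat_band`` all endmembers of a set are expected to coincide.
    """

    oil: str
    baseline: Callable[[np.ndarray], np.ndarray]
    peaks: tuple[tuple[float, float, float], ...] = ()
    flat_band: tuple[float, float] = _FLAT_BAND

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.asarray(self.baseline(wl), dtype=float).copy()
        for center, width, amp in self.peaks:
            out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out


def _shared_baseline(wl: np.ndarray) -> np.ndarray:
    """Low visible reflectance rising to a bright, feature-poor NIR plateau."""
    base = 0.20 + 0.50 * _sigmoid((wl - 750.0) / 100.0)
    # shared NIR absorption troughs (overtone-like features), common to all oils
    for center, width, depth in ((930.0, 25.0, 0.03), (1210.0, 30.0, 0.05),
                                 (1450.0, 35.0, 0.08)):
        base -= depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return base


def _vis_window(wl: np.ndarray) -> np.ndarray:
    """Smooth indicator of the visible band, zero well before 1700 nm."""
    return _sigmoid((wl - 380.0) / 30.0) * _sigmoid((700.0 - wl) / 50.0)


def _nir_window(wl: np.ndarray) -> np.ndarray:
    """Smooth indicator of 720-1700 nm, decayed to ~1e-3 of scale by 1700 nm."""
    return _sigmoid((wl - 760.0) / 40.0) * _sigmoid((1620.0 - wl) / 20.0)


def default_endmembers() -> dict[str, EndmemberModel]:
    """The three default pure-oil endmembers on any grid.

    Offsets are windowed so the oils coincide above 1700 nm.  Visible
    offsets order the oils soybean > rapeseed > sesame (soybean looks
    brightest); NIR offsets order them soybean > rapeseed > sesame so
    reflectance increases with the soybean fraction in both blend cases.
    """

    def make(vis_offset: float, nir_offset: float, vis_slope: float):
        def baseline(wl: np.ndarray) -> np.ndarray:
            wlf = np.asarray(wl, dtype=float)
            vis = _vis_window(wlf)
            ramp = (wlf - 550.0) / 350.0  # gentle tilt across the visible band
            return (_shared_baseline(wlf)
                    + (vis_offset + vis_slope * ramp) * vis
                    + nir_offset * _nir_window(wlf))
        return baseline

    return {
        "soybean": EndmemberModel(
            oil="soybean",
            baseline=make(0.18, 0.06, 0.00),
            peaks=((480.0, 90.0, -0.12),),  # one broad visible trough
        ),
        "rapeseed": EndmemberModel(
            oil="rapeseed",
            baseline=make(0.06, 0.02, 0.00),
            peaks=((445.0, 12.0, -0.08), (475.0, 12.0, -0.08)),  # two narrow troughs
        ),
        "sesame": EndmemberModel(
            oil="sesame",
            baseline=make(0.02, 0.00, 0.04),  # slow rise, no visible troughs
            peaks=(),
        ),
    }


@dataclass(frozen=True)
class ScatterNoiseModel:
    """Per-sample affine scatter distortion plus per-point white noise.

    A distorted spectrum is ``b * x + a + e`` with gain
    ``b = exp(N(0, sigma_mult^2))``, offset ``a = N(0, sigma_add^2)``
    drawn once per sample, and ``e`` i.i.d. ``N(0, sigma_white^2)`` per
    wavelength.  All sigmas zero reproduces the clean mixture exactly.
    """

    sigma_mult: float = 0.05
    sigma_add: float = 0.01
    sigma_white: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_mult, self.sigma_add, self.sigma_white) < 0:
            raise ParameterError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class DesignSpec:
    """The blend design: which ratios, how many replicate groups, which cases."""

    ratios: tuple[float, ...] = tuple(np.round(np.arange(11) / 10, 1))
    n_groups: int = 5
    cases: tuple[str, ...] = CASES

    def __post_init__(self) -> None:
        if not self.ratios or self.n_groups < 1 or not self.cases:
            raise ParameterError("design must have >= 1 ratio, group and case")
        for r in self.ratios:
            if not (0.0 <= r <= 1.0):
                raise ParameterError(f"ratio {r} outside [0, 1]")
        for c in self.cases:
            if c not in CASES:
                raise ParameterError(f"unknown case {c!r}")


def mix_spectrum(genuine: EndmemberModel, adulterant: EndmemberModel,
                 ratio: float, grid: WavelengthGrid) -> np.ndarray:
    """Linear blend: ``ratio * genuine + (1 - ratio) * adulterant`` on the grid."""
    if not (0.0 <= ratio <= 1.0):
        raise ParameterError(f"mixing ratio must lie in [0, 1], got {ratio}")
    wl = grid.values
    return ratio * genuine(wl) + (1.0 - ratio) * adulterant(wl)


def apply_scatter_noise(spectrum: np.ndarray, model: ScatterNoiseModel,
                        sample_index: int) -> np.ndarray:
    """Distort one spectrum; deterministic in ``(model.seed, sample_index)``.

    Negative results are clipped at zero (reflectance factors cannot be
    negative); the clip count is logged.
    """
    x = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("spectrum contains non-finite values")
    rng = np.random.default_rng([model.seed, int(sample_index)])
    b = math.exp(model.sigma_mult * rng.standard_normal())
    a = model.sigma_add * rng.standard_normal()
    e = model.sigma_white * rng.standard_normal(x.size)
    out = b * x + a + e
    n_clip = int(np.count_nonzero(out < 0))
    if n_clip:
        logger.info("clipped %d negative reflectance points in sample %d",
                    n_clip, sample_index)
        out = np.clip(out, 0.0, None)
    return out


def _genuine_oil(case: str) -> str:
    return "sesame" if case == "sesame_soy" else "rapeseed"


def generate_dataset(design: DesignSpec = DesignSpec(),
                     endmembers: dict[str, EndmemberModel] | None = None,
                     noise: ScatterNoiseModel = ScatterNoiseModel(),
                     grid: WavelengthGrid | None = None) -> SpectrumSet:
    """Enumerate the blend design and emit a validated SpectrumSet.

    One spectrum per (group, case, ratio) in deterministic order: groups
    ascending, cases in declared order, ratios ascending.  Under the
    default design each group contributes 9 adulterated sesame blends,
    9 adulterated rapeseed blends and 4 pure oils (one sesame, one
    rapeseed, two soybean — one per case), 110 samples in all.
    Sample ids follow ``{case}_{ratio%}_{group}``.
    """
    if endmembers is None:
        endmembers = default_endmembers()
    if grid is None:
        grid = default_grid()
    rows: list[np.ndarray] = []
    meta: list[SampleMeta] = []
    sample_index = 0
    for group in range(1, design.n_groups + 1):
        for case in design.cases:
            genuine = endmembers[_genuine_oil(case)]
            soy = endmembers["soybean"]
            for ratio in sorted(design.ratios):
                clean = mix_spectrum(genuine, soy, ratio, grid)
                rows.append(apply_scatter_noise(clean, noise, sample_index))
                meta.append(SampleMeta(
                    sample_id=f"{case}_{int(round(ratio * 100))}_{group}",
                    case=case,
                    genuine_ratio=float(ratio),
                    group=group,
                ))
                sample_index += 1
    return validate(SpectrumSet(grid=grid, reflectance=np.array(rows), meta=meta))


def _label_for(case: str, ratio: float) -> str | None:
    """Seven-class rule; ``None`` for the excluded 50% blends."""
    oil = _genuine_oil(case)
    lattice = round(ratio * 10)
    if abs(ratio * 10 - lattice) > 1e-9:
        raise LabellingError(
            f"ratio {ratio} is not on the 10%-step design lattice"
        )
    tenth = int(lattice)
    if tenth == 10:
        return f"pure_{oil}"
    if tenth == 0:
        return "pure_soybean"
    if tenth == 5:
        return None
    if 6 <= tenth <= 9:
        return f"low_adulterated_{oil}"
    return f"high_adulterated_{oil}"  # 1..4


def assign_class_labels(data: SpectrumSet) -> SpectrumSet:
    """Attach the seven qualitative class labels; 50% blends stay unlabelled.

    Classes per case: pure genuine oil (ratio 1), low-adulterated
    (0.6-0.9 genuine), high-adulterated (0.1-0.4 genuine), plus the
    shared pure-soybean class (ratio 0).  Samples at ratio 0.5 are
    excluded from the qualitative task and get no label.
    """
    new_meta = []
    for m in data.meta:
        label = _label_for(m.case, m.genuine_ratio)
        new_meta.append(SampleMeta(sample_id=m.sample_id, case=m.case,
                                   genuine_ratio=m.genuine_ratio, group=m.group,
                                   class_label=label))
    return data.with_meta(new_meta)
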