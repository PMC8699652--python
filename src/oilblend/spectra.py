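"""Core data types and CSV I/O for Vis-NIR reflectance spectra.

A :class:`SpectrumSet` couples a reflectance matrix (samples x
wavelengths, unitless reflectance factor) with a shared
:class:`WavelengthGrid` and per-sample :class:`SampleMeta`.  All other
modules consume and produce this container, and every module boundary
runs the same :func:`validate` check.

The on-disk format is plain UTF-8 CSV: one row per sample, metadata
columns ``sample_id, case, genuine_ratio, group, class_label`` followed
by one column per wavelength named by its nm value.  The format is
deliberately diffable; no binary or vendor spectral formats are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, GridError, ValidationError

logger = logging.getLogger(__name__)

#: The two binary-blend adulteration cases: a genuine oil cut with soybean oil.
CASES = ("sesame_soy", "rapeseed_soy")

#: Pure-oil identities used by the endmember models.
OILS = ("sesame", "rapeseed", "soybean")

#: Metadata columns, in canonical on-disk order.
META_COLUMNS = ("sample_id", "case", "genuine_ratio", "group", "class_label")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm shared by a set of spectra."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise GridError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise GridError("wavelengths must be finite and > 0")
        if np.any(np.diff(vals) <= 0):
            raise GridError("wavelengths must be strictly increasing (no duplicates)")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def default_grid() -> WavelengthGrid:
    """The instrument grid: 350-2500 nm inclusive at 1 nm spacing (2151 points)."""
    return WavelengthGrid(np.arange(350.0, 2501.0, 1.0))


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    ``genuine_ratio`` is the fraction of the genuine oil (sesame or
    rapeseed) in the blend: 0 is pure soybean oil, 1 is pure genuine oil.
    ``class_label`` is empty until the seven-class labelling rule runs.
    """

    sample_id: str
    case: str
    genuine_ratio: float
    group: int
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValidationError(
                f"unknown case {self.case!r}; expected one of {CASES}"
            )
        if not (0.0 <= self.genuine_ratio <= 1.0):
            raise ValidationError(
                f"genuine_ratio must lie in [0, 1], got {self.genuine_ratio}"
            )
        if self.group < 1:
            raise ValidationError(f"group index must be >= 1, got {self.group}")


@dataclass
class SpectrumSet:
    """Reflectance matrix on a shared grid plus aligned sample metadata."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    meta: list[SampleMeta] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return int(self.reflectance.shape[0])

    @property
    def n_wavelengths(self) -> int:
        return int(self.reflectance.shape[1])

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame in canonical column order."""
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "case": [m.case for m in self.meta],
                "genuine_ratio": [m.genuine_ratio for m in self.meta],
                "group": [m.group for m in self.meta],
                "class_label": [m.class_label or "" for m in self.meta],
            }
        )

    def ratios(self) -> np.ndarray:
        return np.array([m.genuine_ratio for m in self.meta])

    def labels(self) -> list[str | None]:
        return [m.class_label for m in self.meta]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectrumSet":
        rows = np.asarray(rows, dtype=int)
        return SpectrumSet(
            grid=self.grid,
            reflectance=self.reflectance[rows].copy(),
            meta=[self.meta[i] for i in rows],
        )

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectrumSet":
        """Same grid and metadata with a replacement reflectance matrix."""
        return SpectrumSet(grid=self.grid, reflectance=np.asarray(reflectance, float),
                           meta=list(self.meta))

    def with_meta(self, meta: Iterable[SampleMeta]) -> "SpectrumSet":
        return SpectrumSet(grid=self.grid, reflectance=self.reflectance.copy(),
                           meta=list(meta))


def validate(data: SpectrumSet, *, allow_negative: bool = False) -> SpectrumSet:
    """Check the SpectrumSet invariants; return the set unchanged if valid.

    Raises :class:`ValidationError` on shape mismatch, non-finite or
    negative reflectance, or duplicate sample ids.  Reflectance factors
    above 1.2 are permitted (measured factors can exceed the white
    reference) but logged.  ``allow_negative`` relaxes the sign check for
    pretreated spectra, which are no longer reflectance factors.
    """
    refl = np.asarray(data.reflectance, dtype=float)
    if refl.ndim != 2:
        raise ValidationError(f"reflectance must be 2-D, got ndim={refl.ndim}")
    if refl.shape[0] != len(data.meta):
        raise ValidationError(
            f"row count {refl.shape[0]} != metadata count {len(data.meta)}"
        )
    if refl.shape[1] != len(data.grid):
        raise ValidationError(
            f"column count {refl.shape[1]} != grid length {len(data.grid)}"
        )
    if refl.size and not np.all(np.isfinite(refl)):
        raise ValidationError("reflectance contains missing or non-finite entries")
    if not allow_negative and refl.size and refl.min() < 0:
        i, j = np.unravel_index(int(np.argmin(refl)), refl.shape)
        raise ValidationError(
            f"negative reflectance {refl[i, j]:g} at sample row {i}, "
            f"wavelength {data.grid.values[j]:g} nm"
        )
    ids = [m.sample_id for m in data.meta]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise ValidationError(f"duplicate sample_id {dup!r}")
    if refl.size and refl.max() > 1.2:
        logger.info(
            "reflectance factor exceeds 1.2 (max %.4g); permitted but unusual",
            refl.max(),
        )
    data.reflectance = refl
    return data


def _parse_meta_row(row: pd.Series, index: int) -> SampleMeta:
    label = row["class_label"]
    if pd.isna(label) or str(label) == "":
        label = None
    try:
        ratio = float(row["genuine_ratio"])
        group = int(row["group"])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"unparsable metadata in row {index}: {exc}") from exc
    try:
        return SampleMeta(
            sample_id=str(row["sample_id"]),
            case=str(row["case"]),
            genuine_ratio=ratio,
            group=group,
            class_label=None if label is None else str(label),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {index}: {exc}") from exc


def read_spectra(path) -> SpectrumSet:
    """Read a spectral-table CSV into a validated :class:`SpectrumSet`.

    Wavelength columns are re-ordered ascending regardless of file order.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str, "case": str,
                                     "class_label": str},
                        float_precision="round_trip")
    for col in META_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"missing required metadata column {col!r}")
    wl_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if not wl_cols:
        raise FormatError("no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"wavelength column name not numeric: {exc}") from exc
    order = np.argsort(wavelengths, kind="stable")
    grid = WavelengthGrid(wavelengths[order])  # raises GridError on duplicates

    refl = np.empty((len(frame), len(wl_cols)), dtype=float)
    for k, col_idx in enumerate(order):
        col = wl_cols[col_idx]
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"non-numeric reflectance in row {row}, column {col!r}: "
                f"{frame[col].iloc[row]!r}"
            )
        if values.isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise ValidationError(f"missing reflectance in row {row}, column {col!r}")
        refl[:, k] = values.to_numpy(dtype=float)

    meta = [_parse_meta_row(frame.iloc[i], i) for i in range(len(frame))]
    return validate(SpectrumSet(grid=grid, reflectance=refl, meta=meta))


def write_spectra(data: SpectrumSet, path) -> str:
    """Write a :class:`SpectrumSet` as the canonical CSV; returns the path.

    Column order is deterministic (metadata, then wavelengths ascending)
    and numeric cells use shortest round-trip ``repr``, so two writes of
    the same set are byte-identical and ``read(write(S)) == S`` to float
    precision.
    """
    validate(data)
    frame = data.meta_frame()
    # repr of the float value gives lossless shortest round-trip text
    for j, wl in enumerate(data.grid.values):
        name = repr(float(wl)) if wl != int(wl) else str(int(wl))
        frame[name] = data.reflectance[:, j]
    frame.to_csv(path, index=False, lineterminator="\n")
    return str(path)
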