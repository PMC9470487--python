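"""Band-weighted optical properties of spectra.

A specimen's per-wavelength reflectance E(λ) or transmittance S(λ) (percent,
against a diffuse white / open-beam standard) is reduced to a scalar band
*reflectivity* R or *transmissivity* T by weighting with the light-source
irradiance I(λ) and the filter transmittance F(λ) of the illumination path:

    R = ∫ I(λ) F(λ) E(λ) dλ / ∫ I(λ) F(λ) dλ        (same form for T with S)

over a named wavelength band.  Absorptivity follows from energy bookkeeping,
A = 100 − (T + R).  Integrals are evaluated on a common 1-nm
linear-interpolation grid with per-cell Gauss–Legendre quadrature that is
exact for the products of the interpolants.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandDefinition",
    "OpticalSummary",
    "VIS",
    "NIR",
    "TOTAL",
    "DEFAULT_BANDS",
    "read_spectrum",
    "resample_spectrum",
    "band_weighted_fraction",
    "absorptivity_from_RT",
    "summarize_optics",
    "band_energy_fraction",
    "optics_to_frame",
]

#: Spectrum kinds: E reflectance, S sample transmittance, F filter
#: transmittance (all percent), I irradiance (W m^-2 nm^-1).
SPECTRUM_KINDS = ("E", "S", "F", "I")


@dataclass(frozen=True)
class Spectrum:
    """A sampled wavelength → value function.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm.
    values
        Same-length values: percent for kinds ``E``/``S``/``F``,
        W·m⁻²·nm⁻¹ for kind ``I``.
    kind
        One of ``E`` (reflectance), ``S`` (transmittance), ``F`` (filter),
        ``I`` (irradiance).
    label
        Free-text identifier (specimen id, file stem, ...).
    qc_flags
        Warnings accumulated while reading/processing (e.g. duplicate
        wavelengths collapsed, percent values outside [0, 100]).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "E"
    label: str = ""
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 1:
            raise ValueError("spectrum must contain at least one sample")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths must be finite")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing with no duplicates")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.kind == "I" and np.any(vals < 0):
            raise ValueError("irradiance values must be non-negative")
        # Percent spectra may legitimately stray outside [0, 100] in raw
        # instrument output; keep the data, flag it.
        if self.kind in ("E", "S", "F") and (np.any(vals < 0) or np.any(vals > 100)):
            if "values_outside_0_100" not in self.qc_flags:
                object.__setattr__(
                    self, "qc_flags", self.qc_flags + ("values_outside_0_100",)
                )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        lo, hi = self.support
        return lo <= lo_nm and hi >= hi_nm


@dataclass(frozen=True)
class BandDefinition:
    """A named wavelength interval [lo_nm, hi_nm]."""

    name: str
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(f"band {self.name}: lo_nm must be < hi_nm")


VIS = BandDefinition("VIS", 400.0, 700.0)
NIR = BandDefinition("NIR", 700.0, 1700.0)
TOTAL = BandDefinition("TOTAL", 400.0, 1700.0)
DEFAULT_BANDS: tuple[BandDefinition, ...] = (VIS, NIR, TOTAL)


@dataclass(frozen=True)
class OpticalSummary:
    """Scalar band optics for one specimen: the (R, T, A) triple in percent."""

    specimen_id: str
    band: str
    reflectivity_R: float
    transmissivity_T: float
    absorptivity_A: float
    qc_flags: tuple[str, ...] = ()


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


_NUMERIC_ROW = re.compile(r"^\s*[-+.\d]")


def read_spectrum(path: str | Path, kind: str = "E", label: str | None = None) -> Spectrum:
    """Read a two-column (wavelength_nm, value) delimited table.

    The delimiter (comma, tab, semicolon or whitespace) is auto-detected and a
    single header line is tolerated.  Rows are sorted by wavelength; duplicate
    wavelengths are collapsed to their mean with a QC flag.

    Raises
    ------
    SpectrumParseError
        For an empty file or a malformed row (the message names the line).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    rows: list[tuple[float, float]] = []
    flags: list[str] = []
    n_data_lines = 0
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        n_data_lines += 1
        if n_data_lines == 1 and not _NUMERIC_ROW.match(ln):
            continue  # header
        parts = re.split(r"[,\t;]+|\s+", ln.strip())
        parts = [p for p in parts if p]
        if len(parts) < 2:
            raise SpectrumParseError(f"{path}: line {lineno}: expected two columns, got {ln!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumParseError(f"{path}: line {lineno}: non-numeric row {ln!r}") from exc
    if not rows:
        raise SpectrumParseError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=["wl", "val"]).sort_values("wl", kind="stable")
    if df["wl"].duplicated().any():
        flags.append("duplicate_wavelengths_averaged")
        df = df.groupby("wl", as_index=False)["val"].mean()
    return Spectrum(
        wavelengths_nm=df["wl"].to_numpy(),
        values=df["val"].to_numpy(),
        kind=kind,
        label=label if label is not None else path.stem,
        qc_flags=tuple(flags),
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV with header."""
    value_col = "irradiance_W_m2_nm" if spectrum.kind == "I" else "value_percent"
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm, value_col: spectrum.values}
    ).to_csv(path, index=False)


def resample_spectrum(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    Grid points coinciding with original samples are returned unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.support
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside spectrum support [{lo}, {hi}]; "
            "extrapolation is not performed"
        )
    vals = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, vals, kind=s.kind, label=s.label, qc_flags=s.qc_flags)


def _band_grid(band: BandDefinition, step_nm: float) -> np.ndarray:
    n = int(round((band.hi_nm - band.lo_nm) / step_nm))
    return band.lo_nm + step_nm * np.arange(n + 1)


def band_weighted_fraction(
    I: Spectrum,
    F: Spectrum,
    X: Spectrum,
    band: BandDefinition,
    step_nm: float = 1.0,
) -> float:
    """Irradiance-and-filter-weighted mean of X over a band, in percent.

    Evaluates ∫ I F X dλ / ∫ I F dλ on a common linear-interpolation grid of
    spacing ``step_nm`` (default 1 nm).  Within each grid cell the three
    interpolants are linear, so their product is cubic; each cell is
    integrated with two-point Gauss–Legendre quadrature, which is exact for
    cubics — the result is the exact integral of the gridded interpolants.
    ``X`` is a reflectance (E) or transmittance (S) spectrum in percent.

    Raises
    ------
    ValueError
        If any spectrum does not cover the band, or the weight integral
        ∫ I F dλ is not positive ("no incident energy in band").
    """
    for s, name in ((I, "irradiance"), (F, "filter"), (X, "sample")):
        if not s.covers(band.lo_nm, band.hi_nm):
            raise ValueError(
                f"{name} spectrum support {s.support} does not cover band "
                f"{band.name} [{band.lo_nm}, {band.hi_nm}]"
            )
    grid = _band_grid(band, step_nm)
    iv = np.interp(grid, I.wavelengths_nm, I.values)
    fv = np.interp(grid, F.wavelengths_nm, F.values)
    xv = np.interp(grid, X.wavelengths_nm, X.values)

    # Gauss-Legendre nodes at fractional positions within each cell
    h = np.diff(grid)
    t_nodes = (0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0))

    def _cell_sum(*arrs: np.ndarray) -> float:
        total = np.zeros_like(h)
        for t in t_nodes:
            prod = np.ones_like(h)
            for a in arrs:
                prod = prod * (a[:-1] + t * (a[1:] - a[:-1]))
            total += 0.5 * prod
        return float(np.sum(total * h))

    denom = _cell_sum(iv, fv)
    if denom <= 0:
        raise ValueError(f"no incident energy in band {band.name}: ∫ I·F dλ = {denom}")
    return float(_cell_sum(iv, fv, xv) / denom)


def absorptivity_from_RT(R: float, T: float) -> tuple[float, tuple[str, ...]]:
    """Absorptivity A = 100 − (T + R), with a QC flag instead of clamping.

    Returns ``(A, qc_flags)``; ``qc_flags`` contains
    ``"out_of_physical_range"`` when A falls outside [0, 100] (instrument
    artifacts such as R + T > 100 are preserved, never silently clamped).
    """
    if not (np.isfinite(R) and np.isfinite(T)):
        raise ValueError("R and T must be finite")
    A = 100.0 - (T + R)
    flags: tuple[str, ...] = ()
    if A < 0.0 or A > 100.0:
        flags = ("out_of_physical_range",)
    return A, flags


def band_energy_fraction(
    I: Spectrum,
    band: BandDefinition,
    denominator: BandDefinition | tuple[float, float] | None = None,
    step_nm: float = 1.0,
) -> float:
    """Share of source energy falling in ``band``, in percent.

    ``denominator`` selects the reference range for the total: another band,
    an explicit (lo, hi) pair, or (default) the spectrum's full support.
    Exposed as a configuration choice because published "percent of solar
    energy" figures depend on both the reference spectrum and its range.
    """
    if denominator is None:
        lo, hi = I.support
    elif isinstance(denominator, BandDefinition):
        lo, hi = denominator.lo_nm, denominator.hi_nm
    else:
        lo, hi = denominator
    num_grid = _band_grid(band, step_nm)
    den_grid = _band_grid(BandDefinition("denom", lo, hi), step_nm)
    num = np.trapezoid(np.interp(num_grid, I.wavelengths_nm, I.values), num_grid)
    den = np.trapezoid(np.interp(den_grid, I.wavelengths_nm, I.values), den_grid)
    if den <= 0:
        raise ValueError("no source energy in denominator range")
    return float(100.0 * num / den)


def summarize_optics(
    specimens: Iterable[tuple[str, Spectrum, Spectrum]],
    I: Spectrum,
    F_by_band: Mapping[str, Spectrum],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    step_nm: float = 1.0,
) -> list[OpticalSummary]:
    """Per specimen × band (R, T, A) from the weighted-integral definitions.

    Parameters
    ----------
    specimens
        Iterable of ``(specimen_id, E_spectrum, S_spectrum)``.
    I
        Source irradiance spectrum.
    F_by_band
        Filter transmittance spectrum per band name (TOTAL is typically a
        flat 100% filter: the uncovered glass portal).
    """
    out: list[OpticalSummary] = []
    for specimen_id, E, S in specimens:
        if E.kind != "E" or S.kind != "S":
            raise ValueError(f"specimen {specimen_id}: expected (E, S) spectra, got kinds ({E.kind}, {S.kind})")
        for band in bands:
            try:
                F = F_by_band[band.name]
            except KeyError:
                raise KeyError(f"no filter spectrum supplied for band {band.name!r}") from None
            R = band_weighted_fraction(I, F, E, band, step_nm=step_nm)
            T = band_weighted_fraction(I, F, S, band, step_nm=step_nm)
            A, a_flags = absorptivity_from_RT(R, T)
            flags = tuple(dict.fromkeys(E.qc_flags + S.qc_flags + a_flags))
            out.append(OpticalSummary(specimen_id, band.name, R, T, A, flags))
    return out


def optics_to_frame(summaries: Sequence[OpticalSummary]) -> pd.DataFrame:
    """Tidy table: specimen_id, band, reflectivity_R, transmissivity_T, absorptivity_A, qc_flags."""
    return pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in summaries],
            "band": [s.band for s in summaries],
            "reflectivity_R": [s.reflectivity_R for s in summaries],
            "transmissivity_T": [s.transmissivity_T for s in summaries],
            "absorptivity_A": [s.absorptivity_A for s in summaries],
            "qc_flags": [";".join(s.qc_flags) for s in summaries],
        }
    )
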