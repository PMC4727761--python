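"""Reading, writing, validation and grid alignment of IR spectra.

A :class:`Spectrum` is one sample's absorbance trace on its own wavenumber
grid; a :class:`SpectraSet` stacks many spectra on a shared grid and is the
calibration matrix ``X`` consumed by the PLS machinery; a
:class:`ReferenceTable` carries the per-sample analyte concentrations
(``y``, mg per 500 µl aliquot) against which models are calibrated.

Wavenumbers are stored ascending internally (one canonical order avoids
sign errors in derivative spectra); descending files are reversed on read.
Supported on-disk formats are a two-column CSV and a minimal JCAMP-DX 4.24
subset (``##XYDATA=(X++(Y..Y))``, AFFN-encoded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoverageError, DataError, SpectrumParseError, UnitError

ANALYTES = ("daidzin", "genistin", "glycitin")
"""The three isoflavone glycosides quantified by the pipeline."""

ALL_PROPERTIES = ANALYTES + ("total",)

#: Default shared wavenumber grid for simulated spectra: 4000-650 cm-1 at
#: 2 cm-1 spacing (a typical FT-IR working resolution; configurable).
DEFAULT_GRID = np.arange(650.0, 4000.0 + 1e-9, 2.0)


def _validate_axis(wavenumbers: np.ndarray, absorbance: np.ndarray, sample_id: str):
    if wavenumbers.ndim != 1 or absorbance.ndim != 1:
        raise DataError(f"{sample_id}: wavenumbers and absorbance must be 1-D")
    if len(wavenumbers) != len(absorbance):
        raise DataError(
            f"{sample_id}: wavenumber/absorbance length mismatch "
            f"({len(wavenumbers)} vs {len(absorbance)})"
        )
    if len(wavenumbers) < 2:
        raise DataError(f"{sample_id}: a spectrum needs at least 2 points")
    if not (np.isfinite(wavenumbers).all() and np.isfinite(absorbance).all()):
        raise DataError(f"{sample_id}: non-finite values in spectrum")


@dataclass(frozen=True)
class Spectrum:
    """One sample's IR spectrum.

    Parameters
    ----------
    sample_id : str
        Unique sample label.
    wavenumbers : array-like
        Strictly monotone wavenumber axis in cm⁻¹.  A descending axis is
        canonicalized to ascending (both arrays reversed together).
    absorbance : array-like
        Absorbance values (dimensionless), same length as ``wavenumbers``.
    meta : dict, optional
        Free-form metadata (instrument, preparation notes...).
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        _validate_axis(wn, ab, self.sample_id)
        dw = np.diff(wn)
        if (dw < 0).all():  # descending input: reverse as a pair
            wn, ab = wn[::-1], ab[::-1]
            dw = np.diff(wn)
        if (dw <= 0).any():
            if (dw == 0).any():
                raise DataError(f"{self.sample_id}: duplicate wavenumbers")
            raise DataError(f"{self.sample_id}: wavenumbers not monotone")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass(frozen=True)
class SpectraSet:
    """Spectra aligned on a common ascending grid, row-indexed by sample id."""

    grid: np.ndarray
    matrix: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        ids = tuple(str(s) for s in self.sample_ids)
        if (np.diff(grid) <= 0).any():
            raise DataError("SpectraSet grid must be strictly ascending")
        if matrix.shape != (len(ids), len(grid)):
            raise DataError(
                f"SpectraSet matrix shape {matrix.shape} does not match "
                f"{len(ids)} samples x {len(grid)} grid points"
            )
        if len(set(ids)) != len(ids):
            raise DataError("SpectraSet sample ids must be unique")
        if not np.isfinite(matrix).all():
            raise DataError("SpectraSet matrix contains non-finite values")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def spectrum(self, sample_id: str) -> Spectrum:
        idx = self.sample_ids.index(sample_id)
        return Spectrum(sample_id, self.grid.copy(), self.matrix[idx].copy())


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sample analyte concentrations in mg per 500 µl aliquot.

    ``source`` records provenance: ``"HPLC"`` for measured reference values
    or ``"SIMULATED"`` for exact ground truth from the simulator.  For
    simulated tables the ``total`` column must equal the sum of the three
    analytes to 1e-9 (exact ground truth admits no bookkeeping slack).
    """

    data: pd.DataFrame
    source: str = "HPLC"

    def __post_init__(self):
        df = self.data.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise DataError("reference table needs a sample_id column")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids in reference table: {dups}")
        present = [a for a in ANALYTES if a in df.columns]
        if not present:
            raise DataError("reference table has no analyte columns")
        df[present] = df[present].astype(float)
        if (df[present].to_numpy() < 0).any():
            raise DataError("negative concentration in reference table")
        if "total" not in df.columns:
            if len(present) == len(ANALYTES):
                df["total"] = df[list(ANALYTES)].sum(axis=1)
        else:
            df["total"] = df["total"].astype(float)
            if (df["total"].to_numpy() < 0).any():
                raise DataError("negative total in reference table")
            if self.source == "SIMULATED" and len(present) == len(ANALYTES):
                gap = np.abs(
                    df["total"].to_numpy() - df[list(ANALYTES)].sum(axis=1).to_numpy()
                )
                if (gap > 1e-9).any():
                    bad = df.index[gap > 1e-9].tolist()
                    raise DataError(
                        "simulated reference table total does not equal the "
                        f"sum of analytes for samples {bad}"
                    )
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def concentrations(self, analyte: str) -> pd.Series:
        if analyte not in self.data.columns:
            raise DataError(f"analyte {analyte!r} not in reference table")
        return self.data[analyte]


# ---------------------------------------------------------------------------
# CSV I/O


def read_spectrum_csv(path, sample_id: str | None = None, delimiter: str = ",") -> Spectrum:
    """Read a two-column ``wavenumber,absorbance`` CSV into a Spectrum.

    An optional single header line is tolerated.  Non-numeric data rows
    raise :class:`SpectrumParseError` naming the offending line; duplicate
    wavenumbers raise :class:`DataError`.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 and not rows:  # header line
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(rows) < 2:
        raise DataError(f"{path}: a spectrum needs at least 2 points")
    arr = np.asarray(rows, dtype=float)
    return Spectrum(sample_id or path.stem, arr[:, 0], arr[:, 1])


def write_spectrum_csv(spectrum: Spectrum, path, descending: bool = True) -> None:
    """Write a Spectrum as CSV; descending wavenumber order by IR convention."""
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    if descending:
        wn, ab = wn[::-1], ab[::-1]
    df = pd.DataFrame({"wavenumber_cm1": wn, "absorbance": ab})
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# JCAMP-DX 4.24 subset


def read_jcamp(path) -> Spectrum:
    """Read a JCAMP-DX file (``##XYDATA=(X++(Y..Y))``, AFFN values only).

    ``##XUNITS`` must be ``1/CM``; anything else raises :class:`UnitError`.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                in_data = False
                if "=" not in line:
                    raise SpectrumParseError(f"{path}: malformed record {line!r}")
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                val = val.strip()
                labels[key] = val
                if key == "XYDATA":
                    if val.replace(" ", "") != "(X++(Y..Y))":
                        raise SpectrumParseError(
                            f"{path}: unsupported XYDATA form {val!r}"
                        )
                    in_data = True
            elif in_data:
                data_lines.append(line)
    if "XYDATA" not in labels:
        raise SpectrumParseError(f"{path}: no ##XYDATA record")
    xunits = labels.get("XUNITS", "").upper()
    if xunits != "1/CM":
        raise UnitError(f"{path}: XUNITS must be 1/CM, got {xunits or 'none'!r}")
    try:
        xfactor = float(labels.get("XFACTOR", "1"))
        yfactor = float(labels.get("YFACTOR", "1"))
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: non-numeric FACTOR record") from exc
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        toks = line.replace(",", " ").split()
        try:
            vals = [float(t) for t in toks]
        except ValueError:
            raise SpectrumParseError(f"{path}: non-AFFN data line {line!r}") from None
        if len(vals) < 2:
            raise SpectrumParseError(f"{path}: data line with no Y values {line!r}")
        xs.append(vals[0])
        ys.extend(vals[1:])
        # consecutive lines each restate X; reconstruct per-point X afterwards
    npoints = int(float(labels.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise SpectrumParseError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found"
        )
    firstx = float(labels.get("FIRSTX", xs[0] * xfactor))
    lastx = float(labels.get("LASTX", xs[-1] * xfactor))
    wn = np.linspace(firstx, lastx, npoints)
    ab = np.asarray(ys, dtype=float) * yfactor
    title = labels.get("TITLE", path.stem)
    meta = {"yunits": labels.get("YUNITS", "ABSORBANCE")}
    return Spectrum(title, wn, ab, meta)


def write_jcamp(spectrum: Spectrum, path, values_per_line: int = 6) -> None:
    """Write a Spectrum as a minimal JCAMP-DX 4.24 file (AFFN, factors 1)."""
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    # uniform grid is required for (X++(Y..Y)) with linspace reconstruction
    spacing = np.diff(wn)
    if not np.allclose(spacing, spacing[0], rtol=1e-9, atol=0):
        raise DataError(
            f"{spectrum.sample_id}: JCAMP (X++(Y..Y)) export needs a uniform grid"
        )
    buf = io.StringIO()
    buf.write(f"##TITLE={spectrum.sample_id}\n")
    buf.write("##JCAMP-DX=4.24\n")
    buf.write("##DATA TYPE=INFRARED SPECTRUM\n")
    buf.write("##XUNITS=1/CM\n")
    buf.write("##YUNITS=ABSORBANCE\n")
    buf.write("##XFACTOR=1\n")
    buf.write("##YFACTOR=1\n")
    buf.write(f"##FIRSTX={wn[0]:.8g}\n")
    buf.write(f"##LASTX={wn[-1]:.8g}\n")
    buf.write(f"##NPOINTS={len(wn)}\n")
    buf.write("##XYDATA=(X++(Y..Y))\n")
    for start in range(0, len(ab), values_per_line):
        chunk = ab[start : start + values_per_line]
        ys = " ".join(f"{y:.10g}" for y in chunk)
        buf.write(f"{wn[start]:.8g} {ys}\n")
    buf.write("##END=\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Alignment and reference tables


def align_to_grid(spectra: Sequence[Spectrum], target_grid=None) -> SpectraSet:
    """Linearly interpolate spectra onto a common grid (no extrapolation).

    Every spectrum's measured range must cover the target grid; a grid
    point outside a spectrum's support raises :class:`CoverageError`
    naming the sample.  When ``target_grid`` is None the first spectrum's
    grid is used.
    """
    spectra = list(spectra)
    if not spectra:
        raise DataError("align_to_grid needs at least one spectrum")
    grid = np.asarray(
        target_grid if target_grid is not None else spectra[0].wavenumbers,
        dtype=float,
    )
    rows = []
    for sp in spectra:
        if grid[0] < sp.wavenumbers[0] - 1e-9 or grid[-1] > sp.wavenumbers[-1] + 1e-9:
            raise CoverageError(
                f"sample {sp.sample_id!r} covers "
                f"[{sp.wavenumbers[0]:g}, {sp.wavenumbers[-1]:g}] cm-1 but the "
                f"target grid spans [{grid[0]:g}, {grid[-1]:g}] cm-1"
            )
        rows.append(np.interp(grid, sp.wavenumbers, sp.absorbance))
    return SpectraSet(grid, np.vstack(rows), tuple(sp.sample_id for sp in spectra))


def read_reference_table(path, source: str = "HPLC") -> ReferenceTable:
    """Read a ``sample_id,daidzin,genistin,glycitin[,total]`` CSV.

    ``total`` is computed as the sum of the three analytes when absent.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: reference CSV needs a sample_id column")
    return ReferenceTable(df, source=source)


def write_reference_table(table: ReferenceTable, path) -> None:
    table.data.to_csv(path, index=True, float_format="%.10g")


def find_orphans(spectra_set: SpectraSet, reference: ReferenceTable) -> dict:
    """Report sample ids present on one side of the spectra/reference join only."""
    s, r = set(spectra_set.sample_ids), set(reference.sample_ids)
    return {
        "spectra_without_reference": sorted(s - r),
        "reference_without_spectra": sorted(r - s),
    }
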