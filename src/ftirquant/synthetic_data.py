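"""Synthetic FT-IR calibration sets with exact ground truth.

No public spectra exist for the spiking-based soy-supplement calibration
this pipeline targets, so every stage is exercised against a simulator
built on the same physical assumption that justifies linear multivariate
calibration in the first place — Beer–Lambert additivity:

    x(ν) = g · [ Σ_k c_k · s_k(ν) + m(ν) + α + β·ν ] + ε(ν)

where s_k are invented pure-component band profiles (sums of Gaussian /
Lorentzian bands) for daidzin, genistin and glycitin plus a red-clover-like
interferent, m(ν) is an extract matrix background, α + β·ν is additive
baseline drift, g a multiplicative scatter factor near 1, and ε Gaussian
noise.  Concentrations are in mg per 500 µl aliquot; amplitudes are
absorbance per (mg per 500 µl).

The sampling plan emulates a standard-addition calibration: unspiked
extract aliquots, aliquots spiked with known volumes of a 0.244 mg mL⁻¹
single-standard stock, and "fractionated" aliquots from which one analyte
has been removed — replicated with fresh drift/scatter/noise draws.  The
default design produces exactly 335 samples.  Band positions, widths and
amplitudes are artifact defaults chosen to make the analytes genuinely
overlap in 1500–900 cm⁻¹ (overlap is the phenomenon PLS must resolve);
they are not measured values.

Reproducibility: one mandatory global seed; each sample draws from an RNG
stream derived deterministically from (seed, sample index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .spectra_io import (
    ANALYTES,
    DEFAULT_GRID,
    ReferenceTable,
    SpectraSet,
    Spectrum,
)

STOCK_MG_PER_ML = 0.244  # single-standard stock concentration, mg mL-1


# ---------------------------------------------------------------------------
# Band profiles


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center (cm⁻¹), FWHM (cm⁻¹), peak amplitude
    (absorbance per mg per 500 µl for analytes; absolute for backgrounds),
    and line shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ConfigError(f"band fwhm must be > 0, got {self.fwhm}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ConfigError(f"unknown band shape {self.shape!r}")


def component_spectrum(bands: Sequence[BandSpec], grid) -> np.ndarray:
    """Sum of band profiles on the grid.

    Gaussian: a·exp(−4 ln2 (ν−c)²/fwhm²); Lorentzian: a/(1+(2(ν−c)/fwhm)²).
    An empty band list yields the zero vector.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for b in bands:
        d = grid - b.center
        if b.shape == "gaussian":
            out += b.amplitude * np.exp(-4.0 * math.log(2.0) * d**2 / b.fwhm**2)
        else:
            out += b.amplitude / (1.0 + (2.0 * d / b.fwhm) ** 2)
    return out


def spike_mass(volume_ul: float, stock_mg_per_ml: float = STOCK_MG_PER_ML) -> float:
    """Analyte mass (mg) delivered by spiking ``volume_ul`` µl of stock."""
    if volume_ul < 0:
        raise ConfigError(f"spike volume must be >= 0, got {volume_ul}")
    return stock_mg_per_ml * volume_ul / 1000.0


# Default pure-component band sets: 5-6 overlapping bands per analyte in
# 1800-900 cm-1, distinct patterns but pairwise overlap inside 1500-900.
DEFAULT_ANALYTE_BANDS: dict[str, tuple[BandSpec, ...]] = {
    "daidzin": (
        BandSpec(1630.0, 30.0, 1.30),
        BandSpec(1512.0, 25.0, 1.05),
        BandSpec(1256.0, 35.0, 1.15),
        BandSpec(1195.0, 28.0, 0.90, "lorentzian"),
        BandSpec(1043.0, 40.0, 1.45),
        BandSpec(888.0, 22.0, 0.55),
    ),
    "genistin": (
        BandSpec(1652.0, 28.0, 1.35),
        BandSpec(1611.0, 24.0, 0.95),
        BandSpec(1515.0, 26.0, 0.85),
        BandSpec(1358.0, 34.0, 1.10, "lorentzian"),
        BandSpec(1178.0, 30.0, 1.15),
        BandSpec(1064.0, 42.0, 1.30),
    ),
    "glycitin": (
        BandSpec(1656.0, 32.0, 1.20),
        BandSpec(1520.0, 24.0, 1.00),
        BandSpec(1462.0, 30.0, 0.90),
        BandSpec(1288.0, 32.0, 1.05, "lorentzian"),
        BandSpec(1076.0, 38.0, 1.25),
        BandSpec(1024.0, 28.0, 0.95),
    ),
}

# Red-clover-like interferent: bands deliberately riding on the analyte
# windows so an uncorrelated concentration degrades calibration.
DEFAULT_INTERFERENT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1622.0, 34.0, 1.20),
    BandSpec(1504.0, 28.0, 1.05),
    BandSpec(1232.0, 36.0, 1.10, "lorentzian"),
    BandSpec(1152.0, 30.0, 0.95),
    BandSpec(1040.0, 44.0, 1.30),
)

# Extract matrix background: the dried-extract film is mostly sugars and
# protein, so the matrix dominates the absorbance (the analytes are minor
# constituents) with both broad and fingerprint-sharp features.  Absolute
# absorbance units, scaled per sample by matrix_strength_range.
DEFAULT_MATRIX_BANDS: tuple[BandSpec, ...] = (
    BandSpec(3380.0, 420.0, 0.80),
    BandSpec(2928.0, 120.0, 0.45),
    BandSpec(1742.0, 60.0, 0.50),
    BandSpec(1628.0, 90.0, 0.70),
    BandSpec(1460.0, 40.0, 0.50),
    BandSpec(1402.0, 110.0, 0.60, "lorentzian"),
    BandSpec(1240.0, 50.0, 0.45),
    BandSpec(1054.0, 140.0, 1.00),
    BandSpec(1030.0, 35.0, 0.60),
    BandSpec(920.0, 45.0, 0.30),
)


# ---------------------------------------------------------------------------
# Simulation design


@dataclass(frozen=True)
class SimDesign:
    """Everything needed to generate a reproducible calibration set.

    The sample count is ``n_replicates * (n_base + 3*len(spike_volumes)
    + 3)``: unspiked base aliquots, single-standard spikes of each analyte
    at each volume, and three two-analyte "fractionated" aliquots (one
    analyte removed), each preparation replicated with fresh noise, drift
    and scatter draws.
    """

    seed: int
    analyte_bands: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_BANDS)
    )
    interferent_bands: tuple = DEFAULT_INTERFERENT_BANDS
    matrix_bands: tuple = DEFAULT_MATRIX_BANDS
    #: unspiked-extract concentrations, mg per 500 µl aliquot
    base_levels: Mapping[str, float] = field(
        default_factory=lambda: {"daidzin": 0.022, "genistin": 0.038, "glycitin": 0.012}
    )
    #: ±relative jitter applied to base levels per preparation (different
    #: supplements carry different native isoflavone loads)
    base_variation: float = 0.35
    n_base: int = 4
    spike_volumes: tuple = tuple(float(v) for v in range(25, 501, 25))  # µl
    stock_concentration: float = STOCK_MG_PER_ML
    n_replicates: int = 5
    #: peak interferent level, mg-per-500µl-equivalent; 0 disables it
    interferent_level: float = 0.0
    baseline_intercept_range: tuple = (-0.01, 0.01)  # absorbance units
    baseline_slope_range: tuple = (-5e-6, 5e-6)  # absorbance per cm-1
    scatter_range: tuple = (0.97, 1.03)  # multiplicative factor
    matrix_strength_range: tuple = (0.95, 1.05)
    noise_sd: float = 0.0015  # absorbance units
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("SimDesign requires a seed")
        for name, rng in (
            ("baseline_intercept_range", self.baseline_intercept_range),
            ("baseline_slope_range", self.baseline_slope_range),
            ("scatter_range", self.scatter_range),
            ("matrix_strength_range", self.matrix_strength_range),
        ):
            if rng[0] > rng[1]:
                raise ConfigError(f"{name} is not well-ordered: {rng}")
        if self.noise_sd < 0 or self.interferent_level < 0:
            raise ConfigError("noise_sd and interferent_level must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_replicates * (self.n_base + 3 * len(self.spike_volumes) + 3)

    def replace(self, **kw) -> "SimDesign":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def default_paper_like_design(seed: int = 0) -> SimDesign:
    """The documented default design: 5 replicates of (4 base preparations
    + 3 analytes x 20 spike volumes + 3 fractionated aliquots) = 335
    samples.  Only the total count mirrors the emulated study; the
    composition and all band/noise parameters are artifact defaults."""
    d = SimDesign(seed=seed)
    assert d.n_samples == 335
    return d


# ---------------------------------------------------------------------------
# Sample synthesis


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_mixture(
    concentrations: Mapping[str, float],
    design: SimDesign,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> Spectrum:
    """One spectrum from concentrations (mg per 500 µl; key ``interferent``
    optional) under the design's noise model.

    Without an RNG the deterministic, noise-free, drift-free, unit-scatter
    spectrum is returned (pure Beer–Lambert signal + matrix background).
    """
    if any(v < 0 for v in concentrations.values()):
        raise DataError(f"{sample_id}: negative concentration")
    grid = np.asarray(design.grid, dtype=float)
    signal = np.zeros_like(grid)
    for analyte in ANALYTES:
        c = float(concentrations.get(analyte, 0.0))
        if c:
            signal += c * component_spectrum(design.analyte_bands[analyte], grid)
    c_int = float(concentrations.get("interferent", 0.0))
    if c_int:
        signal += c_int * component_spectrum(design.interferent_bands, grid)

    if rng is None:
        signal += component_spectrum(design.matrix_bands, grid)
        return Spectrum(sample_id, grid.copy(), signal)

    m = rng.uniform(*design.matrix_strength_range)
    alpha = rng.uniform(*design.baseline_intercept_range)
    beta = rng.uniform(*design.baseline_slope_range)
    g = rng.uniform(*design.scatter_range)
    noise = rng.normal(0.0, design.noise_sd, size=grid.shape)
    x = g * (signal + m * component_spectrum(design.matrix_bands, grid) + alpha + beta * grid) + noise
    return Spectrum(sample_id, grid.copy(), x)


def _preparations(design: SimDesign, rng: np.random.Generator):
    """The concentration plan: list of (label, {analyte: mg per 500 µl})."""
    preps: list[tuple[str, dict]] = []
    bases = []
    for j in range(design.n_base):
        jit = {
            a: design.base_levels[a] * rng.uniform(1 - design.base_variation, 1 + design.base_variation)
            for a in ANALYTES
        }
        bases.append(jit)
        preps.append((f"base{j}", dict(jit)))
    for a_i, analyte in enumerate(ANALYTES):
        for v_i, vol in enumerate(design.spike_volumes):
            base = bases[(a_i * len(design.spike_volumes) + v_i) % design.n_base]
            conc = dict(base)
            conc[analyte] = conc[analyte] + spike_mass(vol, design.stock_concentration)
            preps.append((f"spike_{analyte}_v{int(vol):03d}", conc))
    for a_i, analyte in enumerate(ANALYTES):  # HPLC-fractionated: analyte removed
        conc = dict(bases[a_i % design.n_base])
        conc[analyte] = 0.0
        preps.append((f"frac_no_{analyte}", conc))
    return preps


def generate_calibration_set(design: SimDesign) -> tuple[SpectraSet, ReferenceTable]:
    """Generate the full spiking-design calibration set.

    Emits unspiked bases, single-standard spikes and two-analyte
    fractionated aliquots, each with ``n_replicates`` independent
    measurement realizations; the reference table carries the exact
    ground-truth concentrations (and their total).  Deterministic in the
    design seed.
    """
    plan_rng = _sample_rng(design.seed, 0)
    preps = _preparations(design, plan_rng)
    rows, ids, recs = [], [], []
    index = 1
    for label, conc in preps:
        c_full = dict(conc)
        if design.interferent_level > 0:
            c_full["interferent"] = plan_rng.uniform(0.0, design.interferent_level)
        for r in range(design.n_replicates):
            sid = f"{label}_r{r}"
            sp = simulate_mixture(c_full, design, _sample_rng(design.seed, index), sid)
            rows.append(sp.absorbance)
            ids.append(sid)
            recs.append({"sample_id": sid, **{a: conc[a] for a in ANALYTES}})
            index += 1
    spectra = SpectraSet(design.grid, np.vstack(rows), tuple(ids))
    reference = ReferenceTable(pd.DataFrame(recs), source="SIMULATED")
    return spectra, reference


def generate_prediction_set(
    design: SimDesign, n_samples: int, seed_offset: int = 10_000
) -> tuple[SpectraSet, ReferenceTable]:
    """Held-out supplement-like samples for closed-loop recovery checks.

    Each sample is a freshly jittered base extract with one randomly
    chosen analyte spiked by a uniform volume up to the design's maximum,
    so every held-out concentration vector lies inside the calibrated
    domain (a calibration must never be asked to extrapolate).
    """
    rng = _sample_rng(design.seed, seed_offset)
    vmax = max(design.spike_volumes)
    rows, ids, recs = [], [], []
    for i in range(n_samples):
        conc = {
            a: design.base_levels[a]
            * rng.uniform(1 - design.base_variation, 1 + design.base_variation)
            for a in ANALYTES
        }
        spiked = ANALYTES[rng.integers(len(ANALYTES))]
        conc[spiked] += spike_mass(rng.uniform(0.0, vmax), design.stock_concentration)
        if design.interferent_level > 0:
            conc["interferent"] = rng.uniform(0.0, design.interferent_level)
        sid = f"test{i:03d}"
        sp = simulate_mixture(conc, design, _sample_rng(design.seed, seed_offset + 1 + i), sid)
        rows.append(sp.absorbance)
        ids.append(sid)
        recs.append({"sample_id": sid, **{a: conc[a] for a in ANALYTES}})
    spectra = SpectraSet(design.grid, np.vstack(rows), tuple(ids))
    return spectra, ReferenceTable(pd.DataFrame(recs), source="SIMULATED")


def interference_sweep(
    amplitudes: Sequence[float] = (0.0, 0.3, 0.6),
    n_seeds: int = 10,
    base_seed: int = 0,
    analyte: str = "total",
    max_lv: int = 8,
    recipe=None,
) -> "pd.DataFrame":
    """Mean cross-validated SEP% versus interferent level.

    For each interferent amplitude (peak mg-per-500µl-equivalent of the
    red-clover-like component, drawn uncorrelated with the analytes) a
    scaled-down calibration set is generated and calibrated per seed; the
    mean SEP% over seeds traces how an uncorrelated co-extracted species
    degrades quantification — the mechanism suspected when a supplement
    containing red clover deviates from its declaration.
    """
    from .calibration import calibrate_analyte
    from .preprocess import default_recipe as _default_recipe

    recipe = recipe or _default_recipe()
    rows = []
    for level in amplitudes:
        for s in range(n_seeds):
            design = SimDesign(
                seed=base_seed + 1000 * s + 17,
                n_replicates=1,
                spike_volumes=tuple(float(v) for v in range(50, 501, 50)),
                interferent_level=float(level),
            )
            spectra, reference = generate_calibration_set(design)
            _, report = calibrate_analyte(
                spectra, reference, analyte, recipe, max_lv=max_lv
            )
            rows.append(
                {"interferent_level": float(level), "seed": s, "sep_percent": report.sep_percent}
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby("interferent_level", as_index=False)["sep_percent"]
        .mean()
        .rename(columns={"sep_percent": "mean_sep_percent"})
    )


def noiseless_design(seed: int = 0, **kw) -> SimDesign:
    """A drift-free, scatter-free, noise-free variant for exact-rank and
    closed-loop identities."""
    base = SimDesign(
        seed=seed,
        baseline_intercept_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
        scatter_range=(1.0, 1.0),
        matrix_strength_range=(1.0, 1.0),
        noise_sd=0.0,
        n_replicates=1,
        spike_volumes=(100.0, 250.0, 400.0),
        n_base=3,
    )
    return base.replace(**kw) if kw else base
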