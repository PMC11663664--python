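"""Synthetic pea composition tables and NIR spectra.

The generator has two halves:

1. A correlated, range-truncated sampler for the composition/sensory table.
   Marginal means, standard deviations and observed ranges of the eleven
   variables (five chemical components, four size/weight measures, two
   ordinal scores) follow the descriptive statistics of the pea sample set,
   and the thirteen reported pairwise Pearson correlations are imposed on
   the latent Gaussian. Because range truncation and ordinal discretization
   attenuate both moments and correlations, the latent parameters are
   calibrated (univariate truncated-normal mean matching; iterative
   multiplicative inflation of the latent correlations against a pilot
   sample) so the *realized* statistics hit the targets.

2. A Beer-Lambert-style spectral renderer: each chemical component
   contributes a pure spectrum built from Gaussian absorption bands at its
   characteristic NIR wavelengths (O-H, C-H, N-H overtone/combination
   bands), mixed linearly by concentration, then corrupted by per-sample
   multiplicative scatter, a quadratic baseline and white noise - exactly
   the artifacts scatter correction and derivative preprocessing exist to
   remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    CHEMICAL_COMPONENTS,
    ORDINAL_VARIABLES,
    VARIABLES,
    SpectraSet,
    default_grid,
)

# --------------------------------------------------------------------------
# Composition specification
# --------------------------------------------------------------------------


@dataclass
class VariableSpec:
    """Marginal specification of one composition/sensory variable."""

    mean: float
    sd: float
    min: float
    max: float

    def validate(self, name: str = "") -> None:
        if not self.min < self.max:
            raise ValueError(f"{name}: min must be < max")
        if self.sd <= 0:
            raise ValueError(f"{name}: sd must be > 0")


# Descriptive statistics of the pea sample set: mean, sd, observed range.
# Units: g/100 g for starch/protein/fiber/fat, % for moisture, mm for
# length/width/height, g for 100-seed weight, ordinal 1-4 for shape/color.
_TABLE1 = {
    "starch": VariableSpec(51.41, 4.56, 43.05, 57.55),
    "crude_protein": VariableSpec(23.80, 2.10, 19.80, 28.45),
    "moisture": VariableSpec(11.94, 0.94, 10.14, 13.31),
    "crude_fiber": VariableSpec(6.55, 0.85, 5.40, 8.75),
    "crude_fat": VariableSpec(3.53, 0.32, 3.00, 4.25),
    "length": VariableSpec(7.78, 0.61, 6.83, 9.69),
    "width": VariableSpec(6.65, 0.44, 5.76, 7.56),
    "height": VariableSpec(5.96, 0.49, 5.10, 6.88),
    "hundred_seed_weight": VariableSpec(22.47, 3.59, 15.80, 30.53),
    "seed_shape": VariableSpec(1.97, 1.03, 1.00, 4.00),
    "color": VariableSpec(1.60, 0.81, 1.00, 4.00),
}

# The thirteen reported pairwise Pearson correlations.
CORRELATION_PAIRS = {
    ("length", "width"): 0.52,
    ("length", "hundred_seed_weight"): 0.59,
    ("width", "height"): 0.48,
    ("seed_shape", "height"): -0.46,
    ("height", "starch"): 0.47,
    ("height", "crude_fiber"): -0.51,
    ("seed_shape", "crude_fiber"): 0.39,
    ("starch", "moisture"): -0.53,
    ("starch", "crude_fiber"): -0.57,
    ("starch", "crude_protein"): -0.36,
    ("crude_protein", "crude_fiber"): 0.64,
    ("crude_protein", "crude_fat"): 0.66,
    ("crude_fiber", "crude_fat"): 0.60,
}


@dataclass
class CompositionSpec:
    """Marginals plus an 11x11 correlation matrix over :data:`VARIABLES`."""

    variables: dict[str, VariableSpec]
    correlation: np.ndarray

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in VARIABLES:
            if name not in self.variables:
                raise ValueError(f"missing variable spec: {name}")
            self.variables[name].validate(name)
        r = self.correlation
        d = len(VARIABLES)
        if r.shape != (d, d):
            raise ValueError(f"correlation must be {d}x{d}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlation entries must be in [-1, 1]")

    def index(self, name: str) -> int:
        return VARIABLES.index(name)

    def means(self) -> np.ndarray:
        return np.array([self.variables[v].mean for v in VARIABLES])

    def sds(self) -> np.ndarray:
        return np.array([self.variables[v].sd for v in VARIABLES])

    def mins(self) -> np.ndarray:
        return np.array([self.variables[v].min for v in VARIABLES])

    def maxs(self) -> np.ndarray:
        return np.array([self.variables[v].max for v in VARIABLES])


def build_default_spec() -> CompositionSpec:
    """Default :class:`CompositionSpec`: published marginals, reported
    correlations, unreported pairs zero-filled then PSD-repaired."""
    d = len(VARIABLES)
    r = np.eye(d)
    for (a, b), val in CORRELATION_PAIRS.items():
        i, j = VARIABLES.index(a), VARIABLES.index(b)
        r[i, j] = r[j, i] = val
    r = nearest_correlation(r)
    return CompositionSpec(variables=dict(_TABLE1), correlation=r)


def nearest_correlation(
    matrix: np.ndarray, eig_floor: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix.

    Repairs by eigenvalue clipping at ``eig_floor`` followed by diagonal
    renormalization, iterated until the result is PSD with unit diagonal.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-10):
        raise ValueError("input must have unit diagonal")
    out = a.copy()
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= 0:
            break
        vals = np.clip(vals, eig_floor, None)
        out = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2
        np.fill_diagonal(out, 1.0)
    return out


# --------------------------------------------------------------------------
# Truncated correlated sampling with latent calibration
# --------------------------------------------------------------------------


def _latent_means(spec: CompositionSpec) -> np.ndarray:
    """Latent-normal means such that each univariate truncated marginal has
    the spec's target mean (truncation-bias correction)."""
    out = np.empty(len(VARIABLES))
    for i, name in enumerate(VARIABLES):
        v = spec.variables[name]

        def gap(mu: float, v: VariableSpec = v) -> float:
            a, b = (v.min - mu) / v.sd, (v.max - mu) / v.sd
            return stats.truncnorm.mean(a, b, loc=mu, scale=v.sd) - v.mean

        lo, hi = v.min - 3 * v.sd, v.max + 3 * v.sd
        out[i] = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return out


def _draw_truncated(
    means: np.ndarray,
    sds: np.ndarray,
    mins: np.ndarray,
    maxs: np.ndarray,
    corr: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_reject: float = 0.99,
) -> np.ndarray:
    """Rejection sampling of a range-truncated correlated Gaussian."""
    d = len(means)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(d))
    rows: list[np.ndarray] = []
    accepted = drawn = 0
    while accepted < n:
        batch = max(2 * (n - accepted), 512)
        z = rng.standard_normal((batch, d)) @ chol.T
        x = means + sds * z
        ok = np.all((x >= mins) & (x <= maxs), axis=1)
        rows.append(x[ok])
        accepted += int(ok.sum())
        drawn += batch
        if drawn >= 100 * n + 10_000 and accepted / drawn < 1 - max_reject:
            raise RuntimeError(
                "rejection rate exceeds 99%: composition spec is infeasible"
            )
    return np.concatenate(rows, axis=0)[:n]


def _discretize_ordinals(x: np.ndarray) -> np.ndarray:
    """Round ordinal columns to the nearest level in {1, 2, 3, 4}."""
    x = x.copy()
    for name in ORDINAL_VARIABLES:
        j = VARIABLES.index(name)
        x[:, j] = np.clip(np.rint(x[:, j]), 1, 4)
    return x


def _calibrate_latent(
    spec: CompositionSpec,
    latent_means: np.ndarray,
    rng: np.random.Generator,
    n_pilot: int = 6000,
    n_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly calibrate latent means and correlations against pilot draws.

    Truncation, joint rejection and ordinal discretization all bias the
    realized statistics; each iteration draws a pilot sample, shifts the
    latent means by the observed mean error and inflates the latent
    correlations multiplicatively (damped, capped at PSD via repair) so the
    realized table matches the spec targets.
    """
    target = nearest_correlation(spec.correlation)
    latent = target.copy()
    means = latent_means.copy()
    sds, mins, maxs = spec.sds(), spec.mins(), spec.maxs()
    target_means = spec.means()
    nonzero = (np.abs(target) > 1e-12) & ~np.eye(len(VARIABLES), dtype=bool)
    for _ in range(n_iter):
        x = _draw_truncated(means, sds, mins, maxs, latent, n_pilot, rng)
        x = _discretize_ordinals(x)
        means = means + 0.8 * (target_means - x.mean(axis=0))
        realized = np.corrcoef(x, rowvar=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(
                np.abs(realized) > 0.05, target / realized, 1.25 * np.sign(target)
            )
        factor = np.clip(np.nan_to_num(factor, nan=1.0), 0.6, 1.67)
        step = np.clip(latent * factor, -0.97, 0.97)
        latent = np.where(nonzero, latent + 0.7 * (step - latent), latent)
        latent = (latent + latent.T) / 2
        np.fill_diagonal(latent, 1.0)
        latent = nearest_correlation(latent)
    return means, latent


def sample_composition(
    spec: CompositionSpec, n: int, seed: int, calibrate: bool = True
) -> pd.DataFrame:
    """Draw ``n`` composition/sensory rows honoring the spec.

    Values stay inside each variable's observed range (joint rejection
    sampling); ordinal scores are discretized to {1,...,4}; latent means and
    correlations are pre-calibrated so the realized statistics match the
    targets despite truncation. Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ss = np.random.SeedSequence(seed)
    rng_cal, rng_final = (np.random.default_rng(c) for c in ss.spawn(2))
    latent_means = _latent_means(spec)
    if calibrate:
        latent_means, latent_corr = _calibrate_latent(spec, latent_means, rng_cal)
    else:
        latent_corr = nearest_correlation(spec.correlation)
    x = _draw_truncated(
        latent_means, spec.sds(), spec.mins(), spec.maxs(), latent_corr, n, rng_final
    )
    x = _discretize_ordinals(x)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(x, index=pd.Index(ids, name="sample_id"), columns=list(VARIABLES))
    for name in ORDINAL_VARIABLES:
        df[name] = df[name].astype(int)
    return df


# --------------------------------------------------------------------------
# Spectral rendering
# --------------------------------------------------------------------------

#: Gaussian absorption bands per component: (center nm, FWHM nm, amplitude
#: in absorbance per unit concentration). Centers are the characteristic
#: overtone/combination bands: 927 (C-H 3rd overtone), 952/1280 (O-H
#: overtones), 1125/1181 (C-H 2nd overtones), 1212 (CH2), 1243 (C-H
#: combination), 1385 (CH3 combination), 1428 (N-H 1st overtone).
#: Amplitudes scale each component's total contribution to ~0.5 absorbance
#: at its mean concentration so every component spans a comparable dynamic
#: range.
BandTable = dict[str, list[tuple[float, float, float]]]

_BAND_CENTERS: dict[str, list[float]] = {
    "moisture": [952.0, 1280.0],
    "crude_fat": [927.0, 1181.0, 1212.0, 1243.0],
    "crude_protein": [1125.0, 1428.0],
    "starch": [952.0, 1125.0, 1385.0],
    "crude_fiber": [1280.0, 1385.0],
}

DEFAULT_FWHM = 60.0
_TOTAL_AMPLITUDE = 0.5


def default_band_table() -> BandTable:
    """Each component's first-listed (primary) band is strongest; secondary
    bands carry 60% of its amplitude. Total amplitude is normalized so a
    sample at mean concentration contributes ~0.5 absorbance per component."""
    table: BandTable = {}
    for comp, centers in _BAND_CENTERS.items():
        weights = np.array([1.0] + [0.6] * (len(centers) - 1))
        amps = _TOTAL_AMPLITUDE * weights / (weights.sum() * _TABLE1[comp].mean)
        table[comp] = [
            (c, DEFAULT_FWHM, float(a)) for c, a in zip(centers, amps)
        ]
    return table


def component_spectra(
    band_table: BandTable, grid: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Pure component spectra (one row per component) on ``grid``.

    Each band is a Gaussian ``amp * exp(-4 ln2 (lam - center)^2 / fwhm^2)``
    so that ``fwhm`` is the full width at half maximum.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    names = list(band_table)
    out = np.zeros((len(names), grid.size))
    for i, name in enumerate(names):
        for center, fwhm, amp in band_table[name]:
            if fwhm <= 0:
                raise ValueError(f"{name}: band FWHM must be > 0")
            if amp < 0:
                raise ValueError(f"{name}: band amplitude must be >= 0")
            if not grid[0] <= center <= grid[-1]:
                warnings.warn(
                    f"{name}: band center {center} nm outside grid span "
                    f"[{grid[0]}, {grid[-1]}] nm",
                    stacklevel=2,
                )
            out[i] += amp * np.exp(-4 * np.log(2) * (grid - center) ** 2 / fwhm**2)
    return names, out


@dataclass
class SpectraGenConfig:
    """Instrumental artifact magnitudes for spectral rendering.

    ``scatter_slope_sd``/``scatter_offset_sd`` control the per-sample
    multiplicative/additive scatter ``A' = (1+b) A + a``;
    ``baseline_poly_coeff_sds`` are sds of quadratic baseline coefficients
    (constant, linear, quadratic in a [-1, 1]-scaled wavelength);
    ``noise_sd`` is i.i.d. channel noise. All in absorbance units except the
    unitless slope.
    """

    scatter_slope_sd: float = 0.005
    scatter_offset_sd: float = 0.02
    baseline_poly_coeff_sds: tuple[float, float, float] = (0.005, 0.005, 0.005)
    noise_sd: float = 3e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.scatter_slope_sd,
            self.scatter_offset_sd,
            *self.baseline_poly_coeff_sds,
            self.noise_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all sds must be >= 0")


def generate_spectra(
    comp_table: pd.DataFrame,
    band_table: BandTable | None = None,
    config: SpectraGenConfig | None = None,
) -> SpectraSet:
    """Render absorbance spectra for a composition table.

    Noiseless spectrum = linear mixture of pure component spectra weighted
    by concentration (natural units), then multiplicative scatter, quadratic
    baseline and channel noise per :class:`SpectraGenConfig`. Deterministic
    under ``config.rng_seed``.
    """
    band_table = band_table if band_table is not None else default_band_table()
    config = config if config is not None else SpectraGenConfig()
    missing = [c for c in band_table if c not in comp_table.columns]
    if missing:
        raise KeyError(f"composition table lacks components: {missing}")
    conc = comp_table[list(band_table)].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative concentrations are not physical")
    grid = default_grid()
    _, pure = component_spectra(band_table, grid)
    clean = conc @ pure

    n = clean.shape[0]
    rng = np.random.default_rng(config.rng_seed)
    slope = rng.normal(0.0, config.scatter_slope_sd, size=n)
    offset = rng.normal(0.0, config.scatter_offset_sd, size=n)
    coeff_sds = np.asarray(config.baseline_poly_coeff_sds, dtype=float)
    coeffs = rng.normal(0.0, 1.0, size=(n, coeff_sds.size)) * coeff_sds
    noise = rng.normal(0.0, config.noise_sd, size=clean.shape)

    u = (grid - grid.mean()) / ((grid[-1] - grid[0]) / 2)  # [-1, 1]
    basis = np.vstack([u**k for k in range(coeff_sds.size)])
    a = (1 + slope)[:, None] * clean + offset[:, None] + coeffs @ basis + noise
    return SpectraSet(grid, a, list(comp_table.index.astype(str)))
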