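"""Spectral preprocessing: the seven single methods and composite chains.

Single methods: smoothing (Savitzky-Golay, deriv 0), unit-norm
normalization, row-minimum baseline offset, SNV, polynomial detrend, MSC,
and first/second Savitzky-Golay derivatives. Chains combine up to four
steps; MSC is stateful (its reference spectrum is fitted on calibration
data and reused on validation data). ``select_best_chain`` ranks candidate
chains by the cross-validated error of a PLS model built on the
preprocessed calibration spectra.

All numeric routines operate on ``(n_samples, n_wavelengths)`` arrays;
wavelengths enter where the physics does (detrend polynomial basis,
derivative scaling by the 6 nm channel spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

STEP_KINDS = (
    "smoothing",
    "normalization",
    "baseline",
    "snv",
    "detrend",
    "msc",
    "derivative1",
    "derivative2",
)

#: Savitzky-Golay defaults: 11-channel window, polyorder 2 (3 for the
#: second derivative) - the common chemometric choice for ~129-channel
#: spectra.
DEFAULT_WINDOW = 11
DEFAULT_POLYORDER = 2

MAX_CHAIN_LENGTH = 4


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("spectra contain NaN or Inf")
    return x


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: row-wise center and scale to unit sd
    (sample sd, n-1 denominator). Removes affine scatter per spectrum."""
    x = _as_matrix(spectra)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"constant spectrum (sd=0) at row index {bad[0]}")
    return (x - mean) / sd


def msc(
    spectra: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum is regressed on the reference (``x ~ a + b*ref``) and
    corrected to ``(x - a) / b``. The reference defaults to the column mean
    of the input (calibration) set and is returned for reuse on validation
    spectra.
    """
    x = _as_matrix(spectra)
    if reference is None:
        if x.shape[0] < 2:
            raise ValueError("need >= 2 spectra to fit an MSC reference")
        reference = x.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.size != x.shape[1]:
        raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * ref.mean()
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("degenerate MSC slope (|b| < 1e-12)")
    return (x - a[:, None]) / b[:, None], ref


def detrend(spectra: np.ndarray, wavelengths: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract each row's least-squares polynomial in wavelength."""
    if order < 0:
        raise ValueError("order must be >= 0")
    x = _as_matrix(spectra)
    lam = np.asarray(wavelengths, dtype=float)
    if lam.size <= order:
        raise ValueError("need more channels than the polynomial order")
    # scaled basis for conditioning; column space is what matters
    u = (lam - lam.mean()) / (np.ptp(lam) / 2 if np.ptp(lam) > 0 else 1.0)
    basis = np.vander(u, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
    return x - (basis @ coef).T


def savgol(
    spectra: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    deriv: int = 0,
    delta: float = 6.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative per spectrum.

    Derivatives are scaled by the physical channel spacing ``delta`` (nm) so
    magnitudes are grid-independent; edges are handled by the polynomial fit
    on the terminal window (no length shrinkage).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    x = _as_matrix(spectra)
    return savgol_filter(
        x, window, polyorder, deriv=deriv, delta=delta, axis=1, mode="interp"
    )


# --------------------------------------------------------------------------
# Chains
# --------------------------------------------------------------------------


@dataclass
class PreprocessStep:
    """One preprocessing step: a kind plus its parameters.

    MSC stores the fitted reference spectrum in ``params['msc_reference']``
    after :meth:`PreprocessChain.fit_transform`.
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise ValueError(f"unknown step kind: {self.kind!r}")

    def _savgol_args(self, deriv: int) -> tuple[int, int]:
        window = int(self.params.get("window", DEFAULT_WINDOW))
        default_order = 3 if deriv == 2 else DEFAULT_POLYORDER
        polyorder = int(self.params.get("polyorder", default_order))
        return window, polyorder

    def apply(
        self, x: np.ndarray, wavelengths: np.ndarray, fit: bool
    ) -> np.ndarray:
        if self.kind == "snv":
            return snv(x)
        if self.kind == "msc":
            ref = self.params.get("msc_reference")
            if ref is None and not fit:
                raise ValueError(
                    "MSC reference missing: fit the chain on calibration data first"
                )
            out, ref_used = msc(x, None if fit else np.asarray(ref))
            if fit:
                self.params["msc_reference"] = np.asarray(ref_used)
            return out
        if self.kind == "detrend":
            return detrend(x, wavelengths, int(self.params.get("order", 2)))
        if self.kind == "normalization":
            norms = np.linalg.norm(x, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("cannot normalize an all-zero spectrum")
            return x / norms
        if self.kind == "baseline":
            return x - x.min(axis=1, keepdims=True)
        if self.kind == "smoothing":
            w, p = self._savgol_args(0)
            return savgol(x, w, p, deriv=0)
        if self.kind == "derivative1":
            w, p = self._savgol_args(1)
            return savgol(x, w, p, deriv=1)
        if self.kind == "derivative2":
            w, p = self._savgol_args(2)
            return savgol(x, w, p, deriv=2)
        raise AssertionError(self.kind)

    def to_dict(self) -> dict[str, Any]:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return {"kind": self.kind, "params": params}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessStep":
        params = dict(d.get("params") or {})
        if "msc_reference" in params and params["msc_reference"] is not None:
            params["msc_reference"] = np.asarray(params["msc_reference"], dtype=float)
        return cls(kind=d["kind"], params=params)


@dataclass
class PreprocessChain:
    """An ordered chain of up to four preprocessing steps."""

    steps: list[PreprocessStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.steps) > MAX_CHAIN_LENGTH:
            raise ValueError(f"chains are limited to {MAX_CHAIN_LENGTH} steps")

    @classmethod
    def from_kinds(cls, kinds: list[str]) -> "PreprocessChain":
        return cls([PreprocessStep(k) for k in kinds])

    @property
    def kinds(self) -> list[str]:
        return [s.kind for s in self.steps]

    def name(self) -> str:
        return " + ".join(self.kinds) if self.steps else "raw"

    def copy(self) -> "PreprocessChain":
        return PreprocessChain(
            [PreprocessStep(s.kind, dict(s.params)) for s in self.steps]
        )

    def fit_transform(self, x: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        """Apply left to right, fitting stateful steps (MSC reference)."""
        return apply_chain(x, self, wavelengths, fit=True)

    def transform(self, x: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        """Apply with previously fitted state; never refits."""
        return apply_chain(x, self, wavelengths, fit=False)

    def to_yaml(self) -> str:
        return yaml.safe_dump([s.to_dict() for s in self.steps], sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessChain":
        raw = yaml.safe_load(text) or []
        return cls([PreprocessStep.from_dict(d) for d in raw])


def apply_chain(
    spectra: np.ndarray,
    chain: PreprocessChain,
    wavelengths: np.ndarray,
    fit: bool = True,
) -> np.ndarray:
    """Apply a chain's steps left to right; empty chain is the identity."""
    x = _as_matrix(spectra).copy()
    for step in chain.steps:
        x = step.apply(x, np.asarray(wavelengths, dtype=float), fit=fit)
    return x


# --------------------------------------------------------------------------
# Chain search
# --------------------------------------------------------------------------


def default_candidate_chains() -> list[PreprocessChain]:
    """Default search space: raw, all seven single methods, the known-good
    derivative composites, and all ordered 2-step combinations of the six
    workhorse methods."""
    kinds_sets: list[list[str]] = [[]]
    kinds_sets += [[k] for k in STEP_KINDS]
    kinds_sets += [
        ["derivative1", "derivative2"],
        ["derivative1", "derivative2", "detrend"],
    ]
    pool = ["snv", "msc", "detrend", "derivative1", "derivative2", "smoothing"]
    for a in pool:
        for b in pool:
            if a != b and [a, b] not in kinds_sets:
                kinds_sets.append([a, b])
    return [PreprocessChain.from_kinds(k) for k in kinds_sets]


def select_best_chain(
    spectra: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    candidate_chains: list[PreprocessChain] | None = None,
    n_latent_max: int = 15,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[PreprocessChain, pd.DataFrame]:
    """Rank candidate chains by PLS cross-validated error on calibration data.

    For each chain the calibration spectra are preprocessed (chain fitted
    here), the latent-variable count is chosen by k-fold cross-validation,
    and RMSECV / R2cv at that count are recorded. Returns the fitted winning
    chain (minimum RMSECV; ties broken by fewer steps then list order) and
    the full score table.
    """
    from .plsr import select_n_latent  # local import to avoid a cycle

    if candidate_chains is None:
        candidate_chains = default_candidate_chains()
    if not candidate_chains:
        raise ValueError("candidate chain list is empty")
    y = np.asarray(y, dtype=float).ravel()
    x = _as_matrix(spectra)
    if y.size != x.shape[0]:
        raise ValueError("y length does not match sample count")
    sst = np.sum((y - y.mean()) ** 2)

    rows = []
    fitted: list[PreprocessChain | None] = []
    for idx, cand in enumerate(candidate_chains):
        chain = cand.copy()
        try:
            xp = chain.fit_transform(x, wavelengths)
            n_latent, secv_curve, press_curve = select_n_latent(
                xp, y, max_latent=n_latent_max, cv_folds=cv_folds, seed=seed,
                return_press=True,
            )
            press = press_curve[n_latent - 1]
            rmsecv = float(np.sqrt(press / y.size))
            r2cv = float(1 - press / sst)
            rows.append(
                {
                    "chain": chain.name(),
                    "n_steps": len(chain.steps),
                    "order": idx,
                    "n_latent": n_latent,
                    "rmsecv": rmsecv,
                    "r2cv": r2cv,
                    "failed": False,
                }
            )
            fitted.append(chain)
        except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
            rows.append(
                {
                    "chain": chain.name(),
                    "n_steps": len(chain.steps),
                    "order": idx,
                    "n_latent": 0,
                    "rmsecv": np.inf,
                    "r2cv": -np.inf,
                    "failed": True,
                    "error": str(exc),
                }
            )
            fitted.append(None)

    table = pd.DataFrame(rows).sort_values(
        ["rmsecv", "n_steps", "order"], kind="stable"
    )
    best_order = int(table.iloc[0]["order"])
    best = fitted[best_order]
    if best is None:
        raise RuntimeError("every candidate chain failed")
    return best, table.reset_index(drop=True)
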