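"""Preprocessing tests: single methods, chains, and the chain search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peachem import (
    PreprocessChain,
    SpectraGenConfig,
    apply_chain,
    detrend,
    generate_spectra,
    msc,
    sample_composition,
    savgol,
    select_best_chain,
    snv,
)

GRID = 908.0 + 6.0 * np.arange(129)


# ----------------------------------------------------------------- snv


def test_snv_simple_row():
    assert np.allclose(snv(np.array([[1.0, 2.0, 3.0]])), [[-1.0, 0.0, 1.0]])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=5, max_size=30))
def test_snv_output_standardized(values):
    row = np.array(values)
    if np.std(row, ddof=1) < 1e-9:
        return
    z = snv(row[None, :])
    assert abs(z.mean()) < 1e-10
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_snv_affine_invariant(rng):
    x = rng.normal(size=(4, 50))
    assert np.allclose(snv(x), snv(3.0 * x + 7.0), atol=1e-10)


def test_snv_constant_row_names_sample():
    x = np.vstack([np.arange(10.0), np.full(10, 2.0)])
    with pytest.raises(ValueError, match="row index 1"):
        snv(x)


# ----------------------------------------------------------------- msc


def test_msc_reference_spectrum_unchanged(rng):
    ref = rng.normal(size=30)
    out, used = msc(ref[None, :], reference=ref)
    assert np.allclose(out[0], ref, atol=1e-10)
    assert np.allclose(used, ref)


def test_msc_inverts_affine_distortion(rng):
    ref = rng.normal(size=40)
    distorted = 2.0 * ref + 5.0
    out, _ = msc(distorted[None, :], reference=ref)
    assert np.allclose(out[0], ref, atol=1e-10)


def test_msc_corrected_set_refits_to_identity(rng):
    x = rng.normal(size=(5, 20)) + np.linspace(0, 1, 20)
    corrected, ref = msc(x)
    # regressing each corrected row on the reference gives a=0, b=1
    ref_c = ref - ref.mean()
    for row in corrected:
        b = (row - row.mean()) @ ref_c / (ref_c @ ref_c)
        a = row.mean() - b * ref.mean()
        assert b == pytest.approx(1.0, abs=1e-10)
        assert a == pytest.approx(0.0, abs=1e-10)


# ------------------------------------------------------------- detrend


def test_detrend_removes_exact_quadratic():
    lam = GRID
    x = (2.0 + 0.01 * lam + 1e-5 * lam**2)[None, :]
    assert np.abs(detrend(x, lam, order=2)).max() < 1e-10


def test_detrend_residual_orthogonal_to_basis(rng):
    lam = GRID
    x = rng.normal(size=(3, lam.size))
    res = detrend(x, lam, order=2)
    u = (lam - lam.mean()) / (np.ptp(lam) / 2)
    basis = np.vander(u, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, res.T, rcond=None)
    assert np.abs(coef).max() < 1e-10


def test_detrend_order_zero_is_mean_centering(rng):
    x = rng.normal(size=(2, 50))
    assert np.allclose(
        detrend(x, GRID[:50], order=0), x - x.mean(axis=1, keepdims=True), atol=1e-10
    )


def test_detrend_idempotent(rng):
    x = rng.normal(size=(3, 60))
    once = detrend(x, GRID[:60], order=2)
    twice = detrend(once, GRID[:60], order=2)
    assert np.allclose(once, twice, atol=1e-10)


def test_detrend_negative_order_rejected():
    with pytest.raises(ValueError):
        detrend(np.ones((1, 10)), GRID[:10], order=-1)


# -------------------------------------------------------------- savgol


def test_savgol_identity_on_low_order_polynomial():
    lam = GRID
    x = (1.0 + 0.5 * lam + 2e-4 * lam**2)[None, :]
    out = savgol(x, window=11, polyorder=2, deriv=0)
    assert np.abs(out - x).max() < 1e-8


def test_savgol_second_derivative_of_quadratic():
    lam = GRID
    x = (lam**2)[None, :]
    out = savgol(x, window=11, polyorder=2, deriv=2)
    assert np.abs(out[0, 5:-5] - 2.0).max() < 1e-8


def test_savgol_first_derivative_of_line():
    lam = GRID
    x = (3.0 * lam + 1.0)[None, :]
    out = savgol(x, window=11, polyorder=2, deriv=1)
    assert np.abs(out[0, 5:-5] - 3.0).max() < 1e-8


def test_savgol_is_linear(rng):
    x = rng.normal(size=(2, 129))
    y = rng.normal(size=(2, 129))
    lhs = savgol(2.0 * x + 3.0 * y, deriv=1)
    rhs = 2.0 * savgol(x, deriv=1) + 3.0 * savgol(y, deriv=1)
    assert np.abs(lhs - rhs).max() < 1e-10


@pytest.mark.parametrize(
    "kwargs",
    [
        {"window": 10},  # even window
        {"window": 11, "polyorder": 11},  # polyorder >= window
        {"window": 11, "polyorder": 2, "deriv": 3},  # deriv > polyorder
    ],
)
def test_savgol_precondition_errors(kwargs):
    with pytest.raises(ValueError):
        savgol(np.ones((1, 129)), **kwargs)


# -------------------------------------------------------------- chains


def test_empty_chain_is_identity(rng):
    x = rng.normal(size=(3, 129))
    out = apply_chain(x, PreprocessChain(), GRID)
    assert np.array_equal(out, x)


def test_single_step_chain_matches_function(rng):
    x = rng.normal(size=(3, 129))
    chain = PreprocessChain.from_kinds(["snv"])
    assert np.allclose(apply_chain(x, chain, GRID), snv(x))


def test_derivative_chain_gives_third_derivative():
    # d2(d1(lam^3)) = 6: the first-derivative step's polynomial-truncation
    # offset is a constant, which the second derivative annihilates
    lam = GRID
    x = (lam**3)[None, :]
    chain = PreprocessChain.from_kinds(["derivative1", "derivative2"])
    out = apply_chain(x, chain, lam)
    assert np.abs(out[0, 12:-12] - 6.0).max() < 1e-6


def test_chain_rejects_more_than_four_steps():
    with pytest.raises(ValueError):
        PreprocessChain.from_kinds(["snv", "detrend", "msc", "smoothing", "baseline"])


def test_msc_chain_requires_fitted_reference(rng):
    x = rng.normal(size=(4, 30))
    chain = PreprocessChain.from_kinds(["msc"])
    with pytest.raises(ValueError, match="reference"):
        chain.transform(x, GRID[:30])
    chain.fit_transform(x, GRID[:30])
    out = chain.transform(x[:2], GRID[:30])
    assert out.shape == (2, 30)


def test_msc_reference_independent_of_calibration_row_order(rng):
    cal = rng.normal(size=(10, 40))
    val = rng.normal(size=(3, 40))
    chain = PreprocessChain.from_kinds(["msc"])
    chain.fit_transform(cal, GRID[:40])
    out1 = chain.transform(val, GRID[:40])
    chain2 = PreprocessChain.from_kinds(["msc"])
    chain2.fit_transform(cal[::-1], GRID[:40])
    out2 = chain2.transform(val, GRID[:40])
    assert np.allclose(out1, out2, atol=1e-12)


def test_chain_yaml_roundtrip(rng):
    chain = PreprocessChain.from_kinds(["msc", "derivative2"])
    chain.fit_transform(rng.normal(size=(5, 129)), GRID)
    restored = PreprocessChain.from_yaml(chain.to_yaml())
    assert restored.kinds == chain.kinds
    assert np.allclose(
        restored.steps[0].params["msc_reference"],
        chain.steps[0].params["msc_reference"],
    )


# -------------------------------------------------------- chain search


@pytest.fixture(scope="module")
def scattered_dataset(default_spec):
    comp = sample_composition(default_spec, 60, seed=21)
    cfg = SpectraGenConfig(
        scatter_slope_sd=0.3,
        scatter_offset_sd=0.2,
        baseline_poly_coeff_sds=(0.0, 0.0, 0.0),
        noise_sd=1e-4,
        rng_seed=21,
    )
    spectra = generate_spectra(comp, config=cfg)
    return spectra, comp["starch"].to_numpy(dtype=float)


def test_select_best_chain_single_empty_candidate(scattered_dataset):
    spectra, y = scattered_dataset
    best, table = select_best_chain(
        spectra.absorbance, y, spectra.wavelengths,
        candidate_chains=[PreprocessChain()], seed=0,
    )
    assert best.kinds == []
    assert np.isfinite(table.iloc[0]["rmsecv"])


def test_scatter_correction_beats_raw(scattered_dataset):
    spectra, y = scattered_dataset
    cands = [
        PreprocessChain(),
        PreprocessChain.from_kinds(["snv"]),
        PreprocessChain.from_kinds(["msc"]),
    ]
    best, table = select_best_chain(
        spectra.absorbance, y, spectra.wavelengths, candidate_chains=cands, seed=0
    )
    assert best.kinds in (["snv"], ["msc"])
    raw_rank = table.index[table["chain"] == "raw"][0]
    assert raw_rank > 0  # raw never wins under strong scatter


def test_duplicate_candidates_tie_broken_by_order(scattered_dataset):
    spectra, y = scattered_dataset
    cands = [
        PreprocessChain.from_kinds(["snv"]),
        PreprocessChain.from_kinds(["snv"]),
    ]
    _, table = select_best_chain(
        spectra.absorbance, y, spectra.wavelengths, candidate_chains=cands, seed=0
    )
    assert table.iloc[0]["rmsecv"] == table.iloc[1]["rmsecv"]
    assert table.iloc[0]["order"] == 0
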