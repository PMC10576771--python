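"""ACE core: covariance algebra, FIML oracles, fitting, profile CIs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from twinace import (
    ComponentMatrices,
    ModelError,
    ModelSpec,
    OptimizerOptions,
    TraitSpec,
    TwinPairTable,
    expected_covariance,
    fiml_minus2ll,
    fit_model,
    profile_ci,
    simulate,
)
from twinace.ace import _ProfiledObjective, _profile_min
from twinace.simulate import default_wellbeing_params

from conftest import FAST


def _comp(A, C, E, means=None):
    A, C, E = (np.atleast_2d(np.asarray(m, float)) for m in (A, C, E))
    means = np.zeros(A.shape[0]) if means is None else means
    return ComponentMatrices(A, C, E, means)


def _table_from_rows(rows, traits, zyg, sexes=None):
    """rows: (n, 2p) array in twin1-block/twin2-block order."""
    rows = np.atleast_2d(np.asarray(rows, float))
    p = traits.p
    d = {"family_id": [f"f{i}" for i in range(len(rows))], "zygosity": zyg,
         "sex1": sexes or ["male"] * len(rows), "sex2": sexes or ["male"] * len(rows)}
    for j, t in enumerate(traits.names):
        d[f"{t}_1"] = rows[:, j]
        d[f"{t}_2"] = rows[:, p + j]
    return TwinPairTable(pd.DataFrame(d), traits)


# ---------------------------------------------------------------------------
# expected covariance
# ---------------------------------------------------------------------------

def test_pure_e_identity_covariance():
    comp = _comp(np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2))
    for z in ("MZ", "DZ"):
        np.testing.assert_allclose(expected_covariance(comp, z), np.eye(4))


def test_univariate_expected_covariance_values():
    comp = _comp([[0.34]], [[0.0]], [[0.66]])
    np.testing.assert_allclose(expected_covariance(comp, "MZ"), [[1, 0.34], [0.34, 1]])
    np.testing.assert_allclose(expected_covariance(comp, "DZ"), [[1, 0.17], [0.17, 1]])


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_cross_block_difference_is_half_A(seed):
    rng = np.random.default_rng(seed)
    p = rng.integers(1, 4)

    def psd():
        M = rng.standard_normal((p, p))
        return M @ M.T

    comp = ComponentMatrices(psd(), psd(), psd() + 0.1 * np.eye(p), np.zeros(p))
    diff = expected_covariance(comp, "MZ") - expected_covariance(comp, "DZ")
    np.testing.assert_allclose(diff[:p, p:], 0.5 * comp.A, atol=1e-10)
    np.testing.assert_allclose(diff[:p, :p], 0.0, atol=1e-10)


def test_bad_zygosity_rejected():
    comp = _comp([[0.0]], [[0.0]], [[1.0]])
    with pytest.raises(ModelError):
        expected_covariance(comp, "OS")


# ---------------------------------------------------------------------------
# FIML likelihood oracles
# ---------------------------------------------------------------------------

def test_single_standard_normal_pair_closed_form():
    t = _table_from_rows([[0.0, 0.0]], TraitSpec(["y"]), ["MZ"])
    comp = _comp([[0.0]], [[0.0]], [[1.0]])
    assert fiml_minus2ll(comp, t) == pytest.approx(2 * math.log(2 * math.pi), abs=1e-12)


def test_complete_data_fiml_equals_mvn_logpdf_sum():
    """On complete tables FIML must equal the two-group multivariate-normal
    -2LL computed independently by scipy.stats at the same parameters."""
    params = default_wellbeing_params(nMZ=40, nDZ=60, seed=8)
    table = simulate(params)
    comp = params.components()
    mu = np.tile(comp.means, 2)
    oracle = 0.0
    for z in ("MZ", "DZ"):
        Y = table.trait_matrix(z)
        oracle += -2.0 * multivariate_normal(mu, expected_covariance(comp, z)).logpdf(Y).sum()
    assert fiml_minus2ll(comp, table) == pytest.approx(oracle, abs=1e-8)


def test_masking_changes_fiml_by_marginal_likelihood():
    """Masking one value changes -2LL by exactly the difference between the
    pair's joint and marginalized densities (brute-force oracle, 3 pairs)."""
    traits = TraitSpec(["u", "v"])
    rows = np.array([
        [0.3, -0.2, 0.5, 0.1],
        [1.0, 0.4, -0.3, 0.2],
        [-0.5, 0.6, 0.2, -0.1],
    ])
    table = _table_from_rows(rows, traits, ["MZ", "DZ", "DZ"])
    comp = _comp(0.3 * np.eye(2), 0.1 * np.eye(2), np.array([[0.6, 0.1], [0.1, 0.6]]))
    full = fiml_minus2ll(comp, table)

    masked = table.copy()
    masked.data.loc[1, "v_1"] = np.nan  # column index 1 of the DZ pair's 4-vector
    got = fiml_minus2ll(comp, masked)

    Sigma = expected_covariance(comp, "DZ")
    y = rows[1]
    keep = [0, 2, 3]
    dens_full = -2.0 * multivariate_normal(np.zeros(4), Sigma).logpdf(y)
    dens_marg = -2.0 * multivariate_normal(np.zeros(3), Sigma[np.ix_(keep, keep)]).logpdf(y[keep])
    assert got - full == pytest.approx(dens_marg - dens_full, abs=1e-10)


def test_all_missing_row_contributes_nothing():
    traits = TraitSpec(["y"])
    t1 = _table_from_rows([[0.2, -0.1]], traits, ["MZ"])
    t2 = _table_from_rows([[0.2, -0.1], [np.nan, np.nan]], traits, ["MZ", "DZ"])
    comp = _comp([[0.2]], [[0.1]], [[0.7]])
    assert fiml_minus2ll(comp, t1) == pytest.approx(fiml_minus2ll(comp, t2), abs=1e-12)


def test_singular_sigma_gives_penalty_not_crash():
    t = _table_from_rows([[0.1, 0.2]], TraitSpec(["y"]), ["MZ"])
    comp = _comp([[1.0]], [[0.0]], [[0.0]])  # MZ covariance singular
    assert fiml_minus2ll(comp, t) == math.inf


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_null_heritability_recovered(univariate_params):
    t = simulate(univariate_params(a=0.0, c=0.0, nMZ=5000, nDZ=5000, seed=4))
    fit = fit_model(t, "AE", FAST)
    std_a = fit.estimates.A[0, 0] / fit.estimates.total[0, 0]
    assert abs(std_a) < 0.05


def test_likelihood_dominance_of_nested_models(wellbeing_table):
    fits = {m: fit_model(wellbeing_table, m, FAST) for m in ("ACE", "AE", "CE", "E")}
    tol = 1e-6
    assert fits["ACE"].minus2ll <= fits["AE"].minus2ll + tol
    assert fits["ACE"].minus2ll <= fits["CE"].minus2ll + tol
    assert fits["AE"].minus2ll <= fits["E"].minus2ll + tol
    assert fits["CE"].minus2ll <= fits["E"].minus2ll + tol


def test_minus2ll_invariant_to_row_order_and_twin_swap():
    params = default_wellbeing_params(nMZ=60, nDZ=90, seed=15, missing_rate=0.1)
    table = simulate(params)
    comp = params.components()
    base = fiml_minus2ll(comp, table)

    perm = np.random.default_rng(1).permutation(table.n_pairs)
    shuffled = TwinPairTable(table.data.iloc[perm].reset_index(drop=True), table.traits)
    assert fiml_minus2ll(comp, shuffled) == pytest.approx(base, abs=1e-8)

    swapped_df = table.data.copy()
    for t in table.traits.names:
        swapped_df[[f"{t}_1", f"{t}_2"]] = swapped_df[[f"{t}_2", f"{t}_1"]].to_numpy()
    swapped = TwinPairTable(swapped_df, table.traits)
    assert fiml_minus2ll(comp, swapped) == pytest.approx(base, abs=1e-8)


def test_df_accounting_hand_count():
    traits = TraitSpec(["u", "v"])
    rows = np.array([
        [0.1, 0.2, 0.3, 0.4],
        [0.5, np.nan, 0.7, 0.8],
        [0.9, 1.0, 1.1, np.nan],
        [0.2, 0.1, 0.0, -0.1],
    ])
    table = _table_from_rows(rows, traits, ["MZ", "MZ", "DZ", "DZ"])
    fit = fit_model(table, ModelSpec(("A", "E"), 2), OptimizerOptions(n_starts=1, polish=False))
    # 14 observed values; AE free params = 2 means + 2*3 symmetric entries = 8
    assert fit.n_observed_values == 14
    assert fit.n_free_params == 8
    assert fit.df == 6


def test_falconer_direction_sanity(univariate_params):
    t = simulate(univariate_params(a=0.5, c=0.0, nMZ=2000, nDZ=2000, seed=6))
    fit = fit_model(t, "AE", FAST)
    std_a = fit.estimates.A[0, 0] / fit.estimates.total[0, 0]
    df = t.data
    rmz = np.corrcoef(df[df.zygosity == "MZ"]["y_1"], df[df.zygosity == "MZ"]["y_2"])[0, 1]
    rdz = np.corrcoef(df[df.zygosity == "DZ"]["y_1"], df[df.zygosity == "DZ"]["y_2"])[0, 1]
    assert 0.0 < std_a < 2 * (rmz - rdz) + 0.1


def test_trivariate_parameter_recovery_single_replicate(wellbeing_params, wellbeing_table):
    """A single study-scale AE fit lands within ~3 empirical SE of truth."""
    fit = fit_model(wellbeing_table, "AE", FAST)
    assert fit.converged
    std_a = np.diag(fit.estimates.A) / np.diag(fit.estimates.total)
    np.testing.assert_allclose(std_a, wellbeing_params.a, atol=0.12)
    rA = fit.estimates.A[0, 2] / math.sqrt(fit.estimates.A[0, 0] * fit.estimates.A[2, 2])
    assert rA == pytest.approx(0.36, abs=0.2)


def test_empty_zygosity_group_refused():
    params = default_wellbeing_params(nMZ=50, nDZ=0, seed=1)
    table = simulate(params)
    with pytest.raises(ModelError, match="zygosity"):
        fit_model(table, "ACE", FAST)


# ---------------------------------------------------------------------------
# profile CIs
# ---------------------------------------------------------------------------

def test_profile_ci_brackets_estimate_and_matches_grid(univariate_params):
    t = simulate(univariate_params(a=0.4, c=0.0, nMZ=400, nDZ=400, seed=12))
    fit = fit_model(t, "AE", FAST)
    ci = profile_ci(fit, ("std", "A", 0))
    assert ci["lower"] < ci["estimate"] < ci["upper"]
    assert not ci["one_sided"]

    # independent dense-grid search of the profiled -2LL crossing
    pobj = _ProfiledObjective(fit, ("std", "A", 0))
    red = pobj.reduce(fit._theta)
    grid = np.linspace(ci["lower"] - 0.05, ci["upper"] + 0.05, 241)
    prof = np.array([_profile_min(pobj, red, t_)[0] for t_ in grid])
    thresh = fit.minus2ll + 3.8414588206941254
    below = grid[prof <= thresh]
    # crossing points from the grid bracket the reported bounds
    step = grid[1] - grid[0]
    assert abs(below.min() - ci["lower"]) <= step + 1e-3
    assert abs(below.max() - ci["upper"]) <= step + 1e-3


def test_profile_ci_entry_target_univariate(univariate_params):
    t = simulate(univariate_params(a=0.4, c=0.0, nMZ=500, nDZ=500, seed=14))
    fit = fit_model(t, "AE", FAST)
    ci = profile_ci(fit, ("entry", "A", 0, 0))
    assert ci["lower"] < fit.estimates.A[0, 0] < ci["upper"]
    width = ci["upper"] - ci["lower"]
    assert 0.05 < width < 1.0
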