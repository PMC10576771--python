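"""Constrained saturated twin model: the descriptive baseline fit.

Before any biometrical structure is imposed, twin data are summarized by a
per-zygosity 2p x 2p multivariate-normal model constrained only by the
exchangeability of co-twins: within each zygosity group the two twins share
means and variances per trait and the cross-twin block is symmetric; means
and variances are further equated across zygosity groups, so that one
phenotypic variance (and hence one phenotypic correlation per trait pair)
describes the sample. Within-twin covariances and cross-twin blocks stay
free per zygosity. This fit supplies the twin correlations (rMZ, rDZ), the
cross-twin cross-trait (CTCT) correlations, and the baseline -2LL against
which the ACE-family models are tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import LinAlgError, cho_factor
from scipy.stats import chi2

from .ace import (
    _PENALTY,
    ConvergenceError,
    ModelError,
    OptimizerOptions,
    _minimize,
    _nan_cov,
    minus2ll_from_stats,
    pattern_stats,
)
from .data import TwinPairTable, ZYGOSITIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaturatedSpec:
    """Marker spec; every ACE-family model is nested in this model."""

    p: int
    label: str = "saturated"


class _SatLayout:
    """Flat parameter vector for the constrained saturated model.

    Order: p means, p variances (shared across twins and zygosity), then per
    zygosity the p(p-1)/2 within-twin covariances and the p(p+1)/2 entries of
    the symmetric cross-twin block.
    """

    def __init__(self, p: int):
        self.p = p
        self.offd = [(i, j) for i in range(p) for j in range(i + 1, p)]
        self.vech = [(i, j) for i in range(p) for j in range(i, p)]
        self.n_offd, self.n_vech = len(self.offd), len(self.vech)
        self.off_mean = 0
        self.off_var = p
        self.off_w = {"MZ": 2 * p, "DZ": 2 * p + self.n_offd}
        base = 2 * p + 2 * self.n_offd
        self.off_x = {"MZ": base, "DZ": base + self.n_vech}
        self.n_params = base + 2 * self.n_vech

    def unpack(self, theta):
        p = self.p
        means = theta[:p]
        v = theta[p : 2 * p]
        W, X = {}, {}
        for z in ZYGOSITIES:
            Wz = np.diag(v.copy())
            for k, (i, j) in enumerate(self.offd):
                Wz[i, j] = Wz[j, i] = theta[self.off_w[z] + k]
            Xz = np.zeros((p, p))
            for k, (i, j) in enumerate(self.vech):
                Xz[i, j] = Xz[j, i] = theta[self.off_x[z] + k]
            W[z], X[z] = Wz, Xz
        return means, v, W, X

    def pack(self, means, v, W, X):
        theta = np.empty(self.n_params)
        theta[: self.p] = means
        theta[self.p : 2 * self.p] = v
        for z in ZYGOSITIES:
            for k, (i, j) in enumerate(self.offd):
                theta[self.off_w[z] + k] = W[z][i, j]
            for k, (i, j) in enumerate(self.vech):
                theta[self.off_x[z] + k] = X[z][i, j]
        return theta

    def sigma(self, Wz, Xz):
        return np.block([[Wz, Xz], [Xz, Wz]])


class _SatObjective:
    def __init__(self, layout: _SatLayout, stats: dict):
        self.layout = layout
        self.stats = stats

    def __call__(self, theta):
        means, v, W, X = self.layout.unpack(theta)
        mu = np.tile(means, 2)
        val = minus2ll_from_stats(
            {z: mu for z in ZYGOSITIES},
            {z: self.layout.sigma(W[z], X[z]) for z in ZYGOSITIES},
            self.stats,
        )
        return val if math.isfinite(val) else _PENALTY


@dataclass
class SaturatedFit:
    """Converged constrained saturated fit."""

    means: np.ndarray
    variances: np.ndarray
    within: dict  # zygosity -> p x p within-twin covariance (shared diagonal)
    cross: dict  # zygosity -> p x p symmetric cross-twin block
    minus2ll: float
    df: int
    n_free_params: int
    converged: bool
    optimizer_status: str
    spec: SaturatedSpec
    n_pairs: dict
    n_observed_values: int
    traits: tuple
    data_checksum: float = 0.0
    constraints: str = (
        "means and variances equated across twin order and zygosity; "
        "within-twin covariances and symmetric cross-twin blocks free per zygosity"
    )
    table: TwinPairTable | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    _layout: _SatLayout | None = field(default=None, repr=False)
    _stats: dict | None = field(default=None, repr=False)

    def sigma(self, zygosity: str) -> np.ndarray:
        return self._layout.sigma(self.within[zygosity], self.cross[zygosity])


def _moment_start(table: TwinPairTable):
    p = table.p
    Y = {z: table.trait_matrix(z) for z in ZYGOSITIES}
    stacked = np.vstack([np.vstack([Y[z][:, :p], Y[z][:, p:]]) for z in ZYGOSITIES if Y[z].size])
    means = np.nanmean(stacked, axis=0)
    v = np.nanvar(stacked, axis=0, ddof=1)
    v = np.where(np.isfinite(v) & (v > 0), v, 1.0)
    W, X = {}, {}
    for z in ZYGOSITIES:
        if Y[z].shape[0] >= 3:
            ind = np.vstack([Y[z][:, :p], Y[z][:, p:]])
            Wz = _nan_cov(ind, ind)
            np.fill_diagonal(Wz, v)
            Xz = _nan_cov(Y[z][:, :p], Y[z][:, p:])
            Xz = 0.5 * (Xz + Xz.T)
        else:
            Wz, Xz = np.diag(v), np.zeros((p, p))
        # shrink toward the diagonal until the block matrix is PD
        lay = _SatLayout(p)
        for shrink in (1.0, 0.9, 0.7, 0.5, 0.3, 0.1, 0.0):
            Wt = np.diag(v) + shrink * (Wz - np.diag(np.diag(Wz)))
            Xt = shrink * Xz
            try:
                cho_factor(lay.sigma(Wt, Xt))
                Wz, Xz = Wt, Xt
                break
            except LinAlgError:
                continue
        W[z], X[z] = Wz, Xz
    return means, v, W, X


def fit_constrained_saturated(
    table: TwinPairTable, options: OptimizerOptions | None = None
) -> SaturatedFit:
    """Maximize the FIML likelihood of the constrained saturated model."""
    options = options or OptimizerOptions()
    nz = table.n_by_zygosity()
    if min(nz.values()) < 2:
        raise ModelError(f"need at least 2 pairs per zygosity group, got {nz}")

    layout = _SatLayout(table.p)
    stats = pattern_stats(table)
    obj = _SatObjective(layout, stats)
    theta0 = layout.pack(*_moment_start(table))
    scale = np.maximum(np.abs(theta0), 0.1)

    rng = np.random.default_rng(options.seed)
    best, diagnostics = None, []
    for s in range(max(1, options.n_starts)):
        th = theta0 if s == 0 else theta0 + options.perturb_scale * scale * rng.standard_normal(len(theta0))
        res = _minimize(obj, th, options)
        diagnostics.append(f"start {s}: -2LL={res.fun:.6f} success={res.success}")
        if math.isfinite(res.fun) and res.fun < _PENALTY / 2 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError("saturated model: no start converged", diagnostics)

    means, v, W, X = layout.unpack(np.asarray(best.x, float))
    if np.any(v <= 0):
        raise ModelError(f"degenerate saturated fit: non-positive fitted variance {v}")
    n_obs = table.n_observed_values()
    checksum = float(np.nansum(table.trait_matrix())) + 1e-6 * table.n_pairs
    return SaturatedFit(
        means=means,
        variances=v,
        within=W,
        cross=X,
        minus2ll=float(best.fun),
        df=n_obs - layout.n_params,
        n_free_params=layout.n_params,
        converged=True,
        optimizer_status=diagnostics[-1],
        spec=SaturatedSpec(table.p),
        n_pairs=nz,
        n_observed_values=n_obs,
        traits=table.traits.names,
        data_checksum=checksum,
        table=table,
        _theta=np.asarray(best.x, float),
        _layout=layout,
        _stats=stats,
    )


# ---------------------------------------------------------------------------
# correlation report (phenotypic, twin, CTCT) with CIs
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Phenotypic, twin and cross-twin cross-trait correlations with 95% CIs."""

    traits: tuple
    rph: np.ndarray
    rMZ: np.ndarray
    rDZ: np.ndarray
    ctct_MZ: np.ndarray
    ctct_DZ: np.ndarray
    ci: dict = field(default_factory=dict)
    ci_method: str = "none"
    n_used: dict = field(default_factory=dict)
    constraints: str = ""

    def to_dict(self) -> dict:
        def conv(v):
            a = np.atleast_2d(np.asarray(v, dtype=float))
            return [[None if not np.isfinite(x) else float(x) for x in row] for row in a]

        out = {
            "traits": list(self.traits),
            "rph": conv(self.rph),
            "rMZ": conv(self.rMZ)[0],
            "rDZ": conv(self.rDZ)[0],
            "ctct_MZ": conv(self.ctct_MZ),
            "ctct_DZ": conv(self.ctct_DZ),
            "ci_method": self.ci_method,
            "n_used": self.n_used,
            "constraints": self.constraints,
        }
        out["ci"] = {k: [float(a), float(b)] for k, (a, b) in self.ci.items()}
        return out


def _report_quantities(fit: SaturatedFit) -> dict:
    """Named scalar correlations derived from a saturated parameter state."""
    p = fit.spec.p
    v = fit.variances
    sd = np.sqrt(v)
    n_ind = {z: 2 * fit.n_pairs[z] for z in ZYGOSITIES}
    wsum = sum(n_ind.values())
    W_pool = sum(n_ind[z] * fit.within[z] for z in ZYGOSITIES) / wsum
    out = {}
    for i in range(p):
        for j in range(i + 1, p):
            out[f"rph[{i},{j}]"] = W_pool[i, j] / (sd[i] * sd[j])
    for z in ZYGOSITIES:
        Xz = fit.cross[z]
        for i in range(p):
            out[f"r{z}[{i}]"] = Xz[i, i] / v[i]
            for j in range(i + 1, p):
                # symmetric under the twin-order constraint
                out[f"ctct_{z}[{i},{j}]"] = Xz[i, j] / (sd[i] * sd[j])
    return out


def _fit_from_theta(fit: SaturatedFit, theta: np.ndarray) -> SaturatedFit:
    means, v, W, X = fit._layout.unpack(theta)
    import copy

    clone = copy.copy(fit)
    clone.means, clone.variances, clone.within, clone.cross = means, v, W, X
    return clone


def _profile_scalar_ci(fit: SaturatedFit, key: str, level: float) -> tuple[float, float]:
    """Profile-likelihood CI for one named correlation via equality-constrained
    re-optimization (SLSQP) and stepwise bracketing."""
    layout, stats = fit._layout, fit._stats
    obj = _SatObjective(layout, stats)
    crit = chi2.ppf(level, df=1)
    threshold = fit.minus2ll + crit

    def gval(theta):
        return _report_quantities(_fit_from_theta(fit, theta))[key]

    t_hat = gval(fit._theta)

    def profiled(t, x0):
        res = optimize.minimize(
            obj,
            x0,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda th: gval(th) - t}],
            options={"maxiter": 300, "ftol": 1e-10},
        )
        return float(res.fun), np.asarray(res.x, float)

    def crossing(direction):
        t_in, x = t_hat, fit._theta.copy()
        step = 0.05
        for _ in range(30):
            t_out = np.clip(t_in + direction * step, -0.999, 0.999)
            f_out, x_out = profiled(t_out, x)
            if f_out >= threshold:
                a, b, xa = t_in, t_out, x
                for _ in range(40):
                    m = 0.5 * (a + b)
                    if abs(b - a) < 1e-4:
                        return m
                    fm, xm = profiled(m, xa)
                    if fm >= threshold:
                        b = m
                    else:
                        a, xa = m, xm
                return 0.5 * (a + b)
            if abs(t_out) >= 0.999:
                return direction * math.inf  # bound at the correlation boundary
            t_in, x = t_out, x_out
            step *= 1.6
        return direction * math.inf

    return crossing(-1), crossing(+1)


def _bootstrap_cis(fit: SaturatedFit, keys, level, n_boot, seed, options) -> dict:
    table = fit.table
    if table is None:
        raise ModelError("bootstrap CIs need the fitted table attached to the fit")
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in keys}
    df = table.data
    idx = {z: np.flatnonzero((df["zygosity"] == z).to_numpy()) for z in ZYGOSITIES}
    boot_opts = OptimizerOptions(n_starts=1, seed=seed, polish=False)
    for _ in range(n_boot):
        rows = np.concatenate([rng.choice(idx[z], size=len(idx[z]), replace=True) for z in ZYGOSITIES])
        bt = TwinPairTable(df.iloc[rows].reset_index(drop=True), table.traits)
        try:
            bfit = fit_constrained_saturated(bt, boot_opts)
        except (ModelError, ConvergenceError):
            continue
        q = _report_quantities(bfit)
        for k in keys:
            draws[k].append(q[k])
    alpha = 1.0 - level
    out = {}
    for k in keys:
        d = np.asarray(draws[k])
        if d.size < 10:
            raise ConvergenceError(f"bootstrap failed: only {d.size} successful refits for {k}")
        out[k] = (float(np.quantile(d, alpha / 2)), float(np.quantile(d, 1 - alpha / 2)))
    return out


def correlation_report(
    fit: SaturatedFit,
    ci_method: str = "profile",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    options: OptimizerOptions | None = None,
) -> CorrelationReport:
    """Convert a saturated fit into the correlation table twin reports print.

    The phenotypic correlation pools the per-zygosity within-twin covariances
    (weighted by individuals; variances are already equated), the cross-twin
    diagonal gives rMZ/rDZ, and the cross-twin off-diagonal the CTCT
    correlations. 95% CIs by profile likelihood (default), pair-resampling
    bootstrap, or none.
    """
    if np.any(fit.variances <= 0):
        raise ModelError("degenerate fit: non-positive fitted variance")
    p = fit.spec.p
    q = _report_quantities(fit)

    rph = np.eye(p)
    ctct = {z: np.zeros((p, p)) for z in ZYGOSITIES}
    rMZ = np.array([q[f"rMZ[{i}]"] for i in range(p)])
    rDZ = np.array([q[f"rDZ[{i}]"] for i in range(p)])
    for i in range(p):
        for z in ZYGOSITIES:
            ctct[z][i, i] = q[f"r{z}[{i}]"]
        for j in range(i + 1, p):
            rph[i, j] = rph[j, i] = q[f"rph[{i},{j}]"]
            for z in ZYGOSITIES:
                ctct[z][i, j] = ctct[z][j, i] = q[f"ctct_{z}[{i},{j}]"]

    ci = {}
    if ci_method == "profile":
        for k in q:
            lo, hi = _profile_scalar_ci(fit, k, level)
            ci[k] = (lo, hi)
    elif ci_method == "bootstrap":
        ci = _bootstrap_cis(fit, list(q), level, n_boot, seed, options)
    elif ci_method != "none":
        raise ModelError(f"unknown ci_method {ci_method!r}; use profile, bootstrap or none")

    n_used = {z: fit.n_pairs[z] for z in ZYGOSITIES}
    return CorrelationReport(
        traits=fit.traits,
        rph=rph,
        rMZ=rMZ,
        rDZ=rDZ,
        ctct_MZ=ctct["MZ"],
        ctct_DZ=ctct["DZ"],
        ci=ci,
        ci_method=ci_method,
        n_used=n_used,
        constraints=fit.constraints,
    )
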