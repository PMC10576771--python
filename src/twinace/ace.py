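"""Correlated-factors ACE model core.

The classical twin design decomposes phenotypic (co)variance into additive
genetic (A), shared environmental (C) and nonshared environmental (E)
components by contrasting monozygotic (MZ) pairs, who share all their
segregating genetic variants, with dizygotic (DZ) pairs, who share on
average half. For p traits each component is a p x p covariance matrix and
the expected covariance of the 2p-vector (twin 1 traits, twin 2 traits) is

    Sigma_z = [[A + C + E,  k_z A + C],
               [k_z A + C,  A + C + E]],   k_MZ = 1, k_DZ = 1/2.

Fitting is by full-information maximum likelihood (FIML): each pair
contributes a multivariate-normal density over its non-missing values only.
Components are parameterized directly by their free symmetric entries
("direct variance estimation"): diagonals are NOT squared or
Cholesky-constrained, so variance components may go (slightly) negative and
likelihood-ratio tests of them are unbiased. Only the total Sigma must be
positive definite at the solution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.stats import chi2

from .data import TwinPairTable, ZYGOSITIES

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)
#: -2LL rises by this much at the edge of a 95% profile interval
CHI2_95_1DF = chi2.ppf(0.95, df=1)

_PENALTY = 1e12  # finite stand-in for +inf inside optimizers


class ModelError(ValueError):
    """Invalid model specification or degenerate input."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# component matrices and expected covariance
# ---------------------------------------------------------------------------

def _as_sym(M, name, p):
    M = np.asarray(M, dtype=float)
    if M.shape != (p, p):
        raise ModelError(f"{name} must be {p}x{p}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ModelError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


@dataclass
class ComponentMatrices:
    """Phenotype-scale A, C, E covariance matrices plus per-trait means."""

    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    means: np.ndarray

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        p = self.means.shape[0]
        self.A = _as_sym(self.A, "A", p)
        self.C = _as_sym(self.C, "C", p)
        self.E = _as_sym(self.E, "E", p)

    @property
    def p(self) -> int:
        return self.means.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Phenotypic covariance Sigma = A + C + E."""
        return self.A + self.C + self.E

    def component(self, name: str) -> np.ndarray:
        return {"A": self.A, "C": self.C, "E": self.E}[name]


def expected_covariance(comp: ComponentMatrices, zygosity: str) -> np.ndarray:
    """Expected 2p x 2p covariance of (twin1, twin2) trait vectors.

    The cross-twin block is A + C for MZ pairs and 0.5*A + C for DZ pairs;
    the within-twin blocks are A + C + E for both.
    """
    if zygosity not in ZYGOSITIES:
        raise ModelError(f"zygosity must be one of {ZYGOSITIES}, got {zygosity!r}")
    k = 1.0 if zygosity == "MZ" else 0.5
    W = comp.total
    X = k * comp.A + comp.C
    return np.block([[W, X], [X, W]])


# ---------------------------------------------------------------------------
# FIML likelihood over missingness patterns
# ---------------------------------------------------------------------------

def pattern_stats(table: TwinPairTable) -> dict:
    """Group pairs by zygosity and missingness pattern; cache sufficient stats.

    For each pattern: the observed column indices, pair count n, the sum of
    observed subvectors and their raw scatter sum(y y^T). -2LL then needs
    only one Cholesky per pattern per evaluation, independent of n.
    """
    stats: dict[str, list] = {}
    for z in ZYGOSITIES:
        Y = table.trait_matrix(z)
        groups = []
        if Y.shape[0]:
            obs = np.isfinite(Y)
            keep = obs.any(axis=1)
            Y, obs = Y[keep], obs[keep]
            if Y.shape[0]:
                pats, inverse = np.unique(obs, axis=0, return_inverse=True)
                for g, pat in enumerate(pats):
                    idx = np.flatnonzero(pat)
                    Sub = Y[inverse == g][:, idx]
                    groups.append((idx, Sub.shape[0], Sub.sum(axis=0), Sub.T @ Sub))
        stats[z] = groups
    return stats


def _group_minus2ll(mu: np.ndarray, Sigma: np.ndarray, groups) -> float:
    total = 0.0
    for idx, n, sy, S0 in groups:
        mu_s = mu[idx]
        Sig = Sigma[np.ix_(idx, idx)]
        try:
            cf = cho_factor(Sig, lower=True, check_finite=False)
        except LinAlgError:
            return math.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        S = S0 - np.outer(sy, mu_s) - np.outer(mu_s, sy) + n * np.outer(mu_s, mu_s)
        quad = float(np.trace(cho_solve(cf, S, check_finite=False)))
        total += n * (len(idx) * LOG_2PI + logdet) + quad
    return total


def minus2ll_from_stats(mu_by_z: dict, Sigma_by_z: dict, stats: dict) -> float:
    """-2 log likelihood given per-zygosity 2p mean vectors and covariances."""
    total = 0.0
    for z in ZYGOSITIES:
        total += _group_minus2ll(mu_by_z[z], Sigma_by_z[z], stats[z])
        if not math.isfinite(total):
            return math.inf
    return total


def fiml_minus2ll(comp: ComponentMatrices, table: TwinPairTable, spec: "ModelSpec | None" = None) -> float:
    """FIML -2LL of a twin-pair table under the ACE expected structure.

    Pairs contribute a multivariate-normal term over their non-missing
    values; all-missing pairs contribute nothing. A singular observed
    submatrix makes the value +inf (a penalty, not an exception).
    """
    if spec is not None:
        comp = ComponentMatrices(
            comp.A if "A" in spec.components_free else np.zeros((comp.p, comp.p)),
            comp.C if "C" in spec.components_free else np.zeros((comp.p, comp.p)),
            comp.E,
            comp.means,
        )
    stats = pattern_stats(table)
    mu = np.tile(comp.means, 2)
    return minus2ll_from_stats(
        {z: mu for z in ZYGOSITIES},
        {z: expected_covariance(comp, z) for z in ZYGOSITIES},
        stats,
    )


# ---------------------------------------------------------------------------
# model specification and parameter layout
# ---------------------------------------------------------------------------

COMPONENT_ORDER = ("A", "C", "E")
MODEL_LABELS = {"ACE": ("A", "C", "E"), "AE": ("A", "E"), "CE": ("C", "E"), "E": ("E",)}


@dataclass(frozen=True)
class ModelSpec:
    """Which components are free. E is always free; omitted ones are zero."""

    components_free: tuple[str, ...]
    p: int
    equal_means_across_zygosity: bool = True

    def __post_init__(self):
        free = tuple(c for c in COMPONENT_ORDER if c in self.components_free)
        if "E" not in free:
            raise ModelError("E must always be free (it carries measurement error)")
        unknown = set(self.components_free) - set(COMPONENT_ORDER)
        if unknown:
            raise ModelError(f"unknown component(s): {sorted(unknown)}")
        object.__setattr__(self, "components_free", free)

    @classmethod
    def from_label(cls, label: str, p: int, **kw) -> "ModelSpec":
        if label not in MODEL_LABELS:
            raise ModelError(f"unknown model label {label!r}; expected one of {sorted(MODEL_LABELS)}")
        return cls(MODEL_LABELS[label], p, **kw)

    @property
    def label(self) -> str:
        return "".join(self.components_free)

    def is_nested_in(self, other) -> bool:
        if getattr(other, "label", None) == "saturated":
            # every ACE-family model is nested in the constrained saturated model
            return self.p == getattr(other, "p", self.p)
        return self.p == other.p and set(self.components_free) <= set(other.components_free)


def _vech_indices(p):
    return [(i, j) for i in range(p) for j in range(i, p)]


class _Layout:
    """Maps between the flat free-parameter vector and ComponentMatrices."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p = spec.p
        self.p = p
        self.vech = _vech_indices(p)
        self.n_mean_sets = 1 if spec.equal_means_across_zygosity else 2
        self.n_means = self.n_mean_sets * p
        self.n_vech = len(self.vech)
        self.names: list[str] = []
        for s in range(self.n_mean_sets):
            tag = "" if self.n_mean_sets == 1 else ("_MZ", "_DZ")[s]
            self.names += [f"mean{tag}[{j}]" for j in range(p)]
        self.offsets: dict[str, int] = {}
        off = self.n_means
        for c in spec.components_free:
            self.offsets[c] = off
            self.names += [f"{c}[{i},{j}]" for i, j in self.vech]
            off += self.n_vech
        self.n_params = off

    def index_of_entry(self, comp: str, i: int, j: int) -> int:
        if comp not in self.offsets:
            raise ModelError(f"component {comp} is not free in this model")
        i, j = min(i, j), max(i, j)
        return self.offsets[comp] + self.vech.index((i, j))

    def unpack(self, theta: np.ndarray):
        p = self.p
        means = theta[: self.n_means].reshape(self.n_mean_sets, p)
        mats = {}
        for c in COMPONENT_ORDER:
            M = np.zeros((p, p))
            if c in self.offsets:
                off = self.offsets[c]
                for k, (i, j) in enumerate(self.vech):
                    M[i, j] = M[j, i] = theta[off + k]
            mats[c] = M
        return means, mats

    def pack(self, comp: ComponentMatrices, means_dz: np.ndarray | None = None) -> np.ndarray:
        theta = np.empty(self.n_params)
        theta[: self.p] = comp.means
        if self.n_mean_sets == 2:
            theta[self.p : 2 * self.p] = comp.means if means_dz is None else means_dz
        for c, off in self.offsets.items():
            M = comp.component(c)
            for k, (i, j) in enumerate(self.vech):
                theta[off + k] = M[i, j]
        return theta

    def to_components(self, theta: np.ndarray) -> ComponentMatrices:
        means, mats = self.unpack(theta)
        return ComponentMatrices(mats["A"], mats["C"], mats["E"], means[0])


class _ACEObjective:
    """FIML -2LL as a function of the flat free-parameter vector."""

    def __init__(self, layout: _Layout, stats: dict):
        self.layout = layout
        self.stats = stats

    def __call__(self, theta: np.ndarray) -> float:
        means, mats = self.layout.unpack(theta)
        comp = object.__new__(ComponentMatrices)
        comp.A, comp.C, comp.E, comp.means = mats["A"], mats["C"], mats["E"], means[0]
        mu = {
            "MZ": np.tile(means[0], 2),
            "DZ": np.tile(means[-1], 2),
        }
        Sig = {z: expected_covariance(comp, z) for z in ZYGOSITIES}
        val = minus2ll_from_stats(mu, Sig, self.stats)
        return val if math.isfinite(val) else _PENALTY


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class OptimizerOptions:
    """Quasi-Newton multi-start settings; tolerance is on -2LL."""

    n_starts: int = 5
    seed: int = 0
    perturb_scale: float = 0.1
    tol: float = 1e-8
    maxiter: int = 5000
    polish: bool = True


@dataclass
class FitResult:
    """One fitted model: estimates, -2LL, df, convergence and optional CIs."""

    estimates: ComponentMatrices
    minus2ll: float
    df: int
    n_free_params: int
    converged: bool
    optimizer_status: str
    spec: ModelSpec
    n_pairs: dict
    n_observed_values: int
    ci: dict = field(default_factory=dict)
    data_checksum: float = 0.0
    # internal handles for profiling / refits
    _theta: np.ndarray | None = None
    _layout: _Layout | None = None
    _stats: dict | None = None

    @property
    def aic_standard(self) -> float:
        return self.minus2ll + 2 * self.n_free_params


def _nan_cov(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise-complete cross-covariance of column blocks X (n,p) and Y (n,q)."""
    p, q = X.shape[1], Y.shape[1]
    out = np.zeros((p, q))
    for i in range(p):
        for j in range(q):
            m = np.isfinite(X[:, i]) & np.isfinite(Y[:, j])
            if m.sum() >= 2:
                out[i, j] = np.cov(X[m, i], Y[m, j])[0, 1]
    return out


def _nearest_pd_floor(M: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Symmetrize and lift eigenvalues to at least `floor` times the mean diagonal."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    lo = floor * max(np.mean(np.diag(M)), 1e-8)
    return V @ np.diag(np.maximum(w, lo)) @ V.T


def moment_start(table: TwinPairTable, spec: ModelSpec) -> ComponentMatrices:
    """Moment-based initial values from within/cross-twin sample covariances.

    The MZ/DZ expectation equations are solved (least squares where
    over-determined) for the free components, then E is inflated just enough
    that both expected covariance matrices are positive definite.
    """
    p = spec.p
    Y = {z: table.trait_matrix(z) for z in ZYGOSITIES}
    stacked = np.vstack([np.vstack([Y[z][:, :p], Y[z][:, p:]]) for z in ZYGOSITIES if Y[z].size])
    means = np.nanmean(stacked, axis=0)
    W = _nan_cov(stacked, stacked)
    X = {}
    for z in ZYGOSITIES:
        if Y[z].shape[0] >= 3:
            Xz = _nan_cov(Y[z][:, :p], Y[z][:, p:])
            X[z] = 0.5 * (Xz + Xz.T)
        else:
            X[z] = np.zeros((p, p))

    free = set(spec.components_free)
    A = np.zeros((p, p))
    C = np.zeros((p, p))
    if free >= {"A", "C"}:
        A = 2.0 * (X["MZ"] - X["DZ"])
        C = 2.0 * X["DZ"] - X["MZ"]
    elif "A" in free:
        # E(X_MZ) = A, E(X_DZ) = A/2: least squares of (X_MZ, 2 X_DZ)
        A = 0.5 * (X["MZ"] + 2.0 * X["DZ"])
    elif "C" in free:
        C = 0.5 * (X["MZ"] + X["DZ"])
    E = W - A - C
    E = _nearest_pd_floor(E, 0.05)

    comp = ComponentMatrices(A, C, E, means)
    # inflate E until both expected covariances are PD
    for _ in range(60):
        try:
            for z in ZYGOSITIES:
                cho_factor(expected_covariance(comp, z))
            break
        except LinAlgError:
            comp = ComponentMatrices(comp.A, comp.C, comp.E + 0.1 * np.mean(np.diag(W)) * np.eye(p), means)
    return comp


def _minimize(obj, theta0, options: OptimizerOptions):
    res = optimize.minimize(
        obj,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": options.maxiter, "ftol": 1e-13, "gtol": 1e-7},
    )
    if options.polish:
        res2 = optimize.minimize(
            obj,
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 400 * len(theta0), "fatol": options.tol * 1e-2, "xatol": 1e-9},
        )
        if res2.fun < res.fun:
            res = res2
    return res


def fit_model(
    table: TwinPairTable,
    spec: ModelSpec | str,
    options: OptimizerOptions | None = None,
) -> FitResult:
    """Fit an ACE-family model by FIML with multi-start quasi-Newton search.

    Free components are parameterized directly by their p(p+1)/2 symmetric
    entries (no Cholesky), so component estimates may be negative; the total
    covariance must be positive definite at the solution or the fit is
    flagged invalid. Starts are moment-based, perturbed per start.
    """
    options = options or OptimizerOptions()
    if isinstance(spec, str):
        spec = ModelSpec.from_label(spec, table.p)
    if spec.p != table.p:
        raise ModelError(f"spec has p={spec.p} but table has p={table.p}")

    nz = table.n_by_zygosity()
    if {"A", "C"} <= set(spec.components_free) and min(nz.values()) == 0:
        raise ModelError(
            "A and C are identified only by the MZ/DZ contrast; both zygosity groups must be non-empty"
        )
    for z, n in nz.items():
        if 0 < n < spec.p + 1:
            logger.warning("only %d %s pairs for p=%d traits; fit may be unstable", n, z, spec.p)

    layout = _Layout(spec)
    stats = pattern_stats(table)
    obj = _ACEObjective(layout, stats)

    start = moment_start(table, spec)
    theta0 = layout.pack(start)
    scale = np.maximum(np.abs(theta0), 0.1 * np.sqrt(np.mean(np.diag(start.total))))

    rng = np.random.default_rng(options.seed)
    diagnostics, best = [], None
    for s in range(max(1, options.n_starts)):
        th = theta0 if s == 0 else theta0 + options.perturb_scale * scale * rng.standard_normal(len(theta0))
        try:
            res = _minimize(obj, th, options)
        except Exception as exc:  # pragma: no cover - optimizer internals
            diagnostics.append(f"start {s}: raised {exc!r}")
            continue
        diagnostics.append(f"start {s}: -2LL={res.fun:.6f} success={res.success} ({res.message})")
        if math.isfinite(res.fun) and res.fun < _PENALTY / 2 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError("no optimizer start converged", diagnostics)

    comp = layout.to_components(best.x)
    valid = True
    try:
        cho_factor(comp.total)
    except LinAlgError:
        valid = False
    n_obs = table.n_observed_values()
    Ycheck = table.trait_matrix()
    checksum = float(np.nansum(Ycheck)) + 1e-6 * table.n_pairs
    return FitResult(
        estimates=comp,
        minus2ll=float(best.fun),
        df=n_obs - layout.n_params,
        n_free_params=layout.n_params,
        converged=bool(valid),
        optimizer_status="; ".join(diagnostics[-1:]) + ("" if valid else " [total Sigma not PD]"),
        spec=spec,
        n_pairs=nz,
        n_observed_values=n_obs,
        data_checksum=checksum,
        _theta=np.asarray(best.x, dtype=float),
        _layout=layout,
        _stats=stats,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

class _ProfiledObjective:
    """Objective over the reduced vector with one target quantity pinned.

    Targets are pinned by exact reparameterization:

    - ``("entry", X, i, j)``: the raw entry X[i,j] is fixed.
    - ``("mean", j)``: the trait-j mean is fixed.
    - ``("std", X, j)``: the standardized share X[j,j]/Sigma[j,j]; the pair
      (X[j,j], E[j,j]) is re-expressed as (share, total variance V[j,j]) and
      the share fixed, V left free (remainder goes to E, or to the other
      free component when X is E).
    - ``("corr", X, i, j)``: the etiological correlation
      X[i,j]/sqrt(X[i,i] X[j,j]) is fixed; X[i,j] follows the free diagonals.
    """

    def __init__(self, fit: FitResult, target):
        self.layout = fit._layout
        self.base = _ACEObjective(self.layout, fit._stats)
        kind = target[0]
        self.kind = kind
        if kind == "mean":
            self.fixed_idx = [int(target[1])]
        elif kind == "entry":
            _, comp, i, j = target
            self.fixed_idx = [self.layout.index_of_entry(comp, i, j)]
        elif kind == "std":
            _, comp, j = target
            free = self.layout.spec.components_free
            remainder = "E" if comp != "E" else next(c for c in free if c != "E")
            self.comp_idx = self.layout.index_of_entry(comp, j, j)
            self.rem_idx = self.layout.index_of_entry(remainder, j, j)
            self.other_diag = [
                self.layout.index_of_entry(c, j, j)
                for c in free
                if c not in (comp, remainder)
            ]
            # reduced vector keeps rem_idx slot as "total variance V"
            self.fixed_idx = [self.comp_idx]
        elif kind == "corr":
            _, comp, i, j = target
            self.ij = self.layout.index_of_entry(comp, i, j)
            self.ii = self.layout.index_of_entry(comp, i, i)
            self.jj = self.layout.index_of_entry(comp, j, j)
            self.fixed_idx = [self.ij]
        else:
            raise ModelError(f"unknown profile target kind {kind!r}")
        self.free_idx = [k for k in range(self.layout.n_params) if k not in self.fixed_idx]
        self.value = None  # pinned target value, set per profile point

    def reduce(self, theta_full: np.ndarray) -> np.ndarray:
        th = np.asarray(theta_full, dtype=float)
        red = th[self.free_idx].copy()
        if self.kind == "std":
            # the remainder slot carries V = sum of free diagonals at (j, j)
            pos = self.free_idx.index(self.rem_idx)
            red[pos] = th[self.comp_idx] + th[self.rem_idx] + sum(th[k] for k in self.other_diag)
        return red

    def expand(self, reduced: np.ndarray) -> np.ndarray:
        th = np.empty(self.layout.n_params)
        th[self.free_idx] = reduced
        if self.kind in ("mean", "entry"):
            th[self.fixed_idx[0]] = self.value
        elif self.kind == "std":
            V = th[self.rem_idx]  # slot reused as total variance
            pinned = self.value * V
            th[self.comp_idx] = pinned
            th[self.rem_idx] = V - pinned - sum(th[k] for k in self.other_diag)
        elif self.kind == "corr":
            prod = th[self.ii] * th[self.jj]
            th[self.ij] = self.value * math.sqrt(prod) if prod > 0 else math.nan
        return th

    def __call__(self, reduced: np.ndarray) -> float:
        th = self.expand(reduced)
        if not np.all(np.isfinite(th)):
            return _PENALTY
        return self.base(th)


def _profile_min(pobj: _ProfiledObjective, red0: np.ndarray, value: float):
    """Re-optimize the nuisance parameters with the target pinned at `value`."""
    pobj.value = value
    res = optimize.minimize(
        pobj, red0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-7}
    )
    if not math.isfinite(res.fun) or res.fun >= _PENALTY / 2:
        res_nm = optimize.minimize(
            pobj, red0, method="Nelder-Mead",
            options={"maxiter": 200 * len(red0), "fatol": 1e-7, "xatol": 1e-7},
        )
        if res_nm.fun < res.fun:
            res = res_nm
    return float(res.fun), np.asarray(res.x, dtype=float)


def profile_ci(
    fit: FitResult,
    target,
    level: float = 0.95,
    options: OptimizerOptions | None = None,
    max_expand: int = 40,
):
    """Profile-likelihood confidence interval for a parameter or derived quantity.

    Walks the target away from its estimate, re-optimizing all other free
    parameters, until -2LL exceeds the minimum by the chi-square(1) quantile
    (3.841 at 95%), then solves for the crossing by bisection. A bound that
    cannot be bracketed is returned as -inf/+inf and flagged one-sided.
    """
    if fit._theta is None or fit._layout is None:
        raise ModelError("fit does not carry optimizer state; refit with fit_model")
    options = options or OptimizerOptions()
    crit = chi2.ppf(level, df=1)
    threshold = fit.minus2ll + crit

    pobj = _ProfiledObjective(fit, target)
    red_hat = pobj.reduce(fit._theta)
    t_hat = _target_value(fit, target)

    step0 = 0.1 * abs(t_hat) + 0.05

    def crossing(direction: int):
        t_in = t_hat
        red = red_hat.copy()
        step = step0
        for _ in range(max_expand):
            t_out = t_in + direction * step
            f_out, red_out = _profile_min(pobj, red, t_out)
            if f_out >= threshold:
                return _bisect(pobj, red, t_in, t_out, threshold)
            t_in, red = t_out, red_out
            step *= 1.7
        return direction * math.inf

    lo = crossing(-1)
    hi = crossing(+1)
    one_sided = not (math.isfinite(lo) and math.isfinite(hi))
    return {"lower": lo, "upper": hi, "level": level, "one_sided": one_sided, "estimate": t_hat}


def _bisect(pobj, red0, t_in, t_out, threshold, tol=1e-4, maxit=60):
    a, b = t_in, t_out
    red = red0.copy()
    for _ in range(maxit):
        m = 0.5 * (a + b)
        if abs(b - a) < tol:
            return m
        fm, red_m = _profile_min(pobj, red, m)
        if fm >= threshold:
            b = m
        else:
            a, red = m, red_m
    return 0.5 * (a + b)


def _target_value(fit: FitResult, target) -> float:
    comp = fit.estimates
    kind = target[0]
    if kind == "mean":
        return float(comp.means[target[1]])
    if kind == "entry":
        return float(comp.component(target[1])[target[2], target[3]])
    if kind == "std":
        _, c, j = target
        return float(comp.component(c)[j, j] / comp.total[j, j])
    if kind == "corr":
        _, c, i, j = target
        M = comp.component(c)
        return float(M[i, j] / math.sqrt(M[i, i] * M[j, j]))
    raise ModelError(f"unknown profile target kind {kind!r}")
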