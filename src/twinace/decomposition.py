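"""Standardize fitted ACE components and decompose phenotypic correlations.

From fitted component covariance matrices this module derives the quantities
behaviour-genetic reports tabulate: per-trait standardized variance shares
(a, c, e), etiological correlations (rA, rC, rE), the model-implied
phenotypic correlation

    rph_jk = rA_jk sqrt(a_j a_k) + rC_jk sqrt(c_j c_k) + rE_jk sqrt(e_j e_k),

and the proportion of each rph carried by each component,
share_X = rX sqrt(x_j x_k) / rph. Under direct variance estimation a
component share can be (slightly) negative; shares are reported signed and
flagged, never truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ace import ComponentMatrices, FitResult, ModelError

COMPONENTS = ("A", "C", "E")


@dataclass
class StandardizedSolution:
    """Per-trait standardized shares and etiological correlation matrices.

    ``std["A"][j]`` is A_jj / (A_jj + C_jj + E_jj); ``corr["A"]`` is A in
    correlation form (NaN off-diagonal where a diagonal entry is <= 0, with
    the offending traits listed in ``flags``).
    """

    traits: tuple
    std: dict
    corr: dict
    flags: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.traits)


def standardize(comp: ComponentMatrices, traits=None) -> StandardizedSolution:
    """Standardized variance shares and correlation forms of A, C, E."""
    p = comp.p
    total = np.diag(comp.total)
    if np.any(total <= 0):
        raise ModelError(f"non-positive total variance for trait index {np.flatnonzero(total <= 0)}")
    traits = tuple(traits) if traits is not None else tuple(f"trait{j + 1}" for j in range(p))

    std, corr, flags = {}, {}, []
    for name in COMPONENTS:
        M = comp.component(name)
        d = np.diag(M)
        std[name.lower()] = d / total
        R = np.full((p, p), np.nan)
        np.fill_diagonal(R, 1.0)
        for i in range(p):
            for j in range(i + 1, p):
                if d[i] > 0 and d[j] > 0:
                    R[i, j] = R[j, i] = M[i, j] / math.sqrt(d[i] * d[j])
        bad = np.flatnonzero(d <= 0)
        if bad.size and not np.allclose(M, 0):
            flags.append(f"r{name} undefined for trait(s) {[traits[b] for b in bad]}: non-positive {name} variance")
        corr[name] = R
    return StandardizedSolution(traits, std, corr, flags)


def _component_terms(std: StandardizedSolution) -> dict:
    """Per-component contribution rX_jk sqrt(x_j x_k) to the phenotypic correlation."""
    terms = {}
    for name in COMPONENTS:
        shares = std.std[name.lower()]
        s = np.sqrt(np.clip(shares, 0.0, None))
        T = np.nan_to_num(std.corr[name], nan=0.0) * np.outer(s, s)
        np.fill_diagonal(T, shares)  # diagonal carries the variance share itself
        terms[name] = T
    return terms


def implied_rph(std: StandardizedSolution) -> np.ndarray:
    """Model-implied phenotypic correlation matrix (unit diagonal)."""
    terms = _component_terms(std)
    R = terms["A"] + terms["C"] + terms["E"]
    np.fill_diagonal(R, 1.0)
    return R


def proportion_rph(std: StandardizedSolution, denominator: np.ndarray | None = None) -> dict:
    """Fraction of each phenotypic correlation attributable to A, C and E.

    The denominator is the model-implied rph by default, which makes the
    shares sum to one exactly; pass an observed correlation matrix to divide
    by that instead. Cells with |denominator| < 1e-6 are NaN and flagged.
    """
    terms = _component_terms(std)
    denom = implied_rph(std) if denominator is None else np.asarray(denominator, dtype=float)
    p = std.p
    shares = {name: np.full((p, p), np.nan) for name in COMPONENTS}
    flags = []
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if abs(denom[i, j]) < 1e-6:
                flags.append(f"share undefined for ({std.traits[i]}, {std.traits[j]}): rph ~ 0")
                continue
            for name in COMPONENTS:
                shares[name][i, j] = terms[name][i, j] / denom[i, j]
    negative = [
        (std.traits[i], std.traits[j], name)
        for name in COMPONENTS
        for i in range(p)
        for j in range(i + 1, p)
        if np.isfinite(shares[name][i, j]) and shares[name][i, j] < 0
    ]
    if negative:
        flags.append(f"negative component share(s) (kept signed): {negative}")
    return {"share_A": shares["A"], "share_C": shares["C"], "share_E": shares["E"], "flags": flags}


@dataclass
class DecompositionReport:
    """Table of standardized estimates, etiological correlations and rph shares."""

    traits: tuple
    std_a: np.ndarray
    std_c: np.ndarray
    std_e: np.ndarray
    rA: np.ndarray
    rC: np.ndarray
    rE: np.ndarray
    implied_rph: np.ndarray
    share_A: np.ndarray
    share_C: np.ndarray
    share_E: np.ndarray
    observed_rph: np.ndarray | None = None
    shares_observed_denom: dict | None = None
    flags: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return [[None if not np.isfinite(x) else float(x) for x in row] for row in np.atleast_2d(v)]
            return v

        out = {k: conv(getattr(self, k)) for k in (
            "traits", "std_a", "std_c", "std_e", "rA", "rC", "rE",
            "implied_rph", "share_A", "share_C", "share_E", "flags",
        )}
        out["traits"] = list(self.traits)
        for k in ("std_a", "std_c", "std_e"):
            out[k] = out[k][0]
        if self.observed_rph is not None:
            out["observed_rph"] = conv(self.observed_rph)
            out["shares_observed_denom"] = {
                k: conv(v) for k, v in self.shares_observed_denom.items() if k != "flags"
            }
        if self.ci:
            out["ci"] = self.ci
        return out


def decompose(fit_or_comp, traits=None, observed_rph: np.ndarray | None = None) -> DecompositionReport:
    """Full decomposition of a fitted model (or raw component matrices)."""
    if isinstance(fit_or_comp, FitResult):
        comp = fit_or_comp.estimates
    else:
        comp = fit_or_comp
    std = standardize(comp, traits)
    rph = implied_rph(std)
    shares = proportion_rph(std)
    report = DecompositionReport(
        traits=std.traits,
        std_a=std.std["a"], std_c=std.std["c"], std_e=std.std["e"],
        rA=std.corr["A"], rC=std.corr["C"], rE=std.corr["E"],
        implied_rph=rph,
        share_A=shares["share_A"], share_C=shares["share_C"], share_E=shares["share_E"],
        flags=list(std.flags) + list(shares["flags"]),
    )
    if observed_rph is not None:
        report.observed_rph = np.asarray(observed_rph, dtype=float)
        report.shares_observed_denom = proportion_rph(std, denominator=report.observed_rph)
    return report


def solution_from_tables(a, e, rA, rE, c=None, rC=None, traits=None) -> StandardizedSolution:
    """Build a standardized solution directly from published standardized
    estimates (shares and etiological correlations), e.g. to check a printed
    table's internal arithmetic. Shares need not sum exactly to one, since
    published values are rounded."""
    a = np.atleast_1d(np.asarray(a, float))
    e = np.atleast_1d(np.asarray(e, float))
    p = a.shape[0]
    c = np.zeros(p) if c is None else np.atleast_1d(np.asarray(c, float))
    traits = tuple(traits) if traits is not None else tuple(f"trait{j + 1}" for j in range(p))

    def corr(R):
        return np.eye(p) if R is None else np.asarray(R, dtype=float)

    return StandardizedSolution(
        traits,
        {"a": a, "c": c, "e": e},
        {"A": corr(rA), "C": corr(rC), "E": corr(rE)},
    )
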