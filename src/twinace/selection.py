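"""Nested model comparison: likelihood-ratio tests, information criteria and
the parsimony-based selection rule.

-2LL differences between nested FIML fits are chi-square distributed with
degrees of freedom equal to the difference in free parameters. AIC follows
the convention common in twin reports, AIC = -2LL - 2 df, where df is the
model's degrees of freedom (observed data values minus free parameters); the
textbook convention -2LL + 2k is emitted alongside as ``aic_standard``. Both
BIC conventions are emitted too, since "size-adjusted" BIC variants differ
across software.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .ace import FitResult

logger = logging.getLogger(__name__)

#: tie-break ordering: prefer later (more parsimonious) labels on exact ties
LABEL_ORDER = ("ACE", "AE", "CE", "E")


class ComparisonError(ValueError):
    """Non-nested specs or mismatched datasets."""


@dataclass
class ComparisonRow:
    """One line of a model-fit table: LRT vs a reference plus criteria."""

    label: str
    minus2ll: float
    df: int
    n_free_params: int
    chi2: float | None = None
    delta_df: int | None = None
    p_value: float | None = None
    aic: float = math.nan
    aic_standard: float = math.nan
    bic: float = math.nan
    bic_standard: float = math.nan
    reference: str | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "label", "minus2ll", "df", "n_free_params", "chi2", "delta_df",
            "p_value", "aic", "aic_standard", "bic", "bic_standard", "reference", "flags",
        )}


def lrt(reference: FitResult, nested: FitResult) -> ComparisonRow:
    """Likelihood-ratio test of a nested model against a reference fit.

    chi2 = -2LL(nested) - -2LL(reference); a slightly negative difference
    (optimizer noise) is clamped to zero for the p-value and flagged when it
    exceeds 1e-4 in magnitude.
    """
    if not nested.spec.is_nested_in(reference.spec):
        raise ComparisonError(
            f"{nested.spec.label} is not nested in {reference.spec.label}"
        )
    if nested.n_pairs != reference.n_pairs or not math.isclose(
        nested.data_checksum, reference.data_checksum, rel_tol=0, abs_tol=1e-6
    ):
        raise ComparisonError("fits come from different datasets")

    return lrt_from_stats(
        reference.minus2ll,
        reference.df,
        nested.minus2ll,
        nested.df,
        label=nested.spec.label,
        reference_label=reference.spec.label,
        n_free_params=nested.n_free_params,
        n_pairs=sum(nested.n_pairs.values()),
    )


def lrt_from_stats(
    minus2ll_ref: float,
    df_ref: int,
    minus2ll_nested: float,
    df_nested: int,
    label: str = "nested",
    reference_label: str = "reference",
    n_free_params: int = 0,
    n_pairs: int = 1,
) -> ComparisonRow:
    """Likelihood-ratio arithmetic from raw fit statistics (e.g. a published
    fit table): chi2 from the -2LL difference, delta-df from the df
    difference, the chi-square tail p, and both AIC/BIC conventions."""
    stat = minus2ll_nested - minus2ll_ref
    ddf = df_nested - df_ref
    flags = []
    if stat < -1e-4:
        flags.append(f"nested model fit better than reference by {-stat:.3g} (optimizer noise?)")
        logger.warning(flags[-1])
    p = 1.0 if stat <= 0 or ddf <= 0 else float(chi2.sf(stat, df=ddf))
    row = ComparisonRow(
        label=label,
        minus2ll=minus2ll_nested,
        df=df_nested,
        n_free_params=n_free_params,
        chi2=float(stat),
        delta_df=int(ddf),
        p_value=p,
        reference=reference_label,
        flags=flags,
    )
    _add_criteria(row, n_pairs=max(n_pairs, 1))
    return row


def information_criteria(fit: FitResult, n_pairs: int | None = None) -> tuple[float, float]:
    """(AIC, BIC) under the df-based twin-report convention.

    AIC = -2LL - 2 df and BIC = -2LL - df ln(n) with n the number of twin
    pairs. Use ``aic_standard``/``bic_standard`` on a ComparisonRow for the
    -2LL + 2k and -2LL + k ln(n) forms.
    """
    n = n_pairs if n_pairs is not None else sum(fit.n_pairs.values())
    aic = fit.minus2ll - 2.0 * fit.df
    bic = fit.minus2ll - fit.df * math.log(n)
    return aic, bic


def _add_criteria(row: ComparisonRow, n_pairs: int) -> None:
    row.aic = row.minus2ll - 2.0 * row.df
    row.bic = row.minus2ll - row.df * math.log(n_pairs)
    row.aic_standard = row.minus2ll + 2.0 * row.n_free_params
    row.bic_standard = row.minus2ll + row.n_free_params * math.log(n_pairs)


def comparison_table(reference: FitResult, nested_fits: list[FitResult]) -> list[ComparisonRow]:
    """LRT rows for each nested fit against the common reference, with the
    reference itself as the first row."""
    ref_row = ComparisonRow(
        label=reference.spec.label,
        minus2ll=reference.minus2ll,
        df=reference.df,
        n_free_params=reference.n_free_params,
    )
    _add_criteria(ref_row, n_pairs=sum(reference.n_pairs.values()))
    return [ref_row] + [lrt(reference, f) for f in nested_fits]


def select_model(rows: list[ComparisonRow], delta_aic: float = 10.0, alpha: float = 0.05) -> dict:
    """Choose the most parsimonious adequate model from a comparison table.

    A model is *admissible* if its LRT against the full (reference) model is
    nonsignificant at `alpha` (the reference is always admissible). Among
    admissible models whose AIC lies within `delta_aic` of the minimum AIC,
    the most parsimonious (fewest free parameters) wins; exact ties fall to
    the documented label ordering ACE < AE < CE < E and are flagged.
    Returns the chosen label and an ordered decision trace.
    """
    if not rows:
        raise ComparisonError("select_model needs at least one comparison row")
    trace = []
    min_aic = min(r.aic for r in rows)
    trace.append(f"minimum AIC = {min_aic:.2f}")

    def order_key(r):
        return LABEL_ORDER.index(r.label) if r.label in LABEL_ORDER else len(LABEL_ORDER)

    admissible = []
    for r in rows:
        ok_lrt = r.p_value is None or r.p_value >= alpha
        ok_aic = (r.aic - min_aic) < delta_aic
        trace.append(
            f"{r.label}: AIC={r.aic:.2f} (delta={r.aic - min_aic:.2f}, "
            f"{'within' if ok_aic else 'beyond'} {delta_aic}); "
            + ("no LRT (reference)" if r.p_value is None else f"LRT p={r.p_value:.3g} "
               f"({'nonsignificant' if ok_lrt else 'significant'} at {alpha})")
        )
        if ok_lrt and ok_aic:
            admissible.append(r)
    if not admissible:
        chosen = min(rows, key=lambda r: (r.aic, order_key(r)))
        trace.append(f"no model admissible under both rules; falling back to lowest AIC: {chosen.label}")
        return {"label": chosen.label, "trace": trace, "tie": False}

    min_k = min(r.n_free_params for r in admissible)
    finalists = sorted((r for r in admissible if r.n_free_params == min_k), key=order_key)
    tie = len(finalists) > 1
    chosen = finalists[0]
    if tie:
        trace.append(
            f"tie among {[r.label for r in finalists]} at {min_k} parameters; "
            f"label ordering {LABEL_ORDER} picks {chosen.label}"
        )
    trace.append(f"selected {chosen.label}: most parsimonious admissible model")
    return {"label": chosen.label, "trace": trace, "tie": tie}
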