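"""Twin-pair phenotype tables: the data model, CSV I/O, and covariate residualization.

A twin-pair table is wide: one row per pair, with a family identifier,
zygosity (MZ/DZ), the sex of each twin, and two columns per trait
(``<trait>_1`` for twin 1, ``<trait>_2`` for twin 2). Missing values are
allowed anywhere except zygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

ZYGOSITIES = ("MZ", "DZ")
SEX_LEVELS = ("male", "female")

#: tokens treated as missing on read, besides the empty cell
MISSING_TOKENS = ("", "NA")


class TwinDataError(ValueError):
    """Malformed twin-pair data (bad columns, degenerate designs...)."""


@dataclass(frozen=True)
class TraitSpec:
    """Ordered trait labels; the order fixes matrix row/column indices downstream."""

    names: tuple[str, ...]

    def __init__(self, names):
        names = tuple(str(n) for n in names)
        if len(names) == 0:
            raise TwinDataError("TraitSpec needs at least one trait name")
        if len(set(names)) != len(names):
            raise TwinDataError(f"trait names must be unique, got {names}")
        if any(n == "" for n in names):
            raise TwinDataError("trait names must be non-empty")
        object.__setattr__(self, "names", names)

    @property
    def p(self) -> int:
        return len(self.names)

    def columns(self) -> list[str]:
        """The 2p wide trait columns, twin-1 block interleaved as <t>_1, <t>_2."""
        return [f"{t}_{i}" for t in self.names for i in (1, 2)]


@dataclass
class TwinPairTable:
    """Wide per-pair phenotype table.

    ``data`` holds one row per twin pair with columns ``family_id``,
    ``zygosity`` ('MZ'/'DZ'), ``sex1``/``sex2`` ('male'/'female' or NaN) and
    ``<trait>_1`` / ``<trait>_2`` float columns for each trait in ``traits``.
    """

    data: pd.DataFrame
    traits: TraitSpec
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        required = ["family_id", "zygosity", "sex1", "sex2"] + self.traits.columns()
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise TwinDataError(f"missing required column(s): {missing}")
        bad = set(self.data["zygosity"].dropna().unique()) - set(ZYGOSITIES)
        if bad or self.data["zygosity"].isna().any():
            raise TwinDataError(f"zygosity must be one of {ZYGOSITIES}, got {sorted(map(str, bad))}")
        self.data = self.data.reset_index(drop=True)
        for c in self.traits.columns():
            self.data[c] = pd.to_numeric(self.data[c])

    @property
    def p(self) -> int:
        return self.traits.p

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def n_by_zygosity(self) -> dict[str, int]:
        return {z: int((self.data["zygosity"] == z).sum()) for z in ZYGOSITIES}

    def trait_matrix(self, zygosity: str | None = None) -> np.ndarray:
        """(n, 2p) float array ordered twin-1 traits then twin-2 traits.

        Column order is [t1_trait1..t1_traitp, t2_trait1..t2_traitp], the
        ordering every expected-covariance matrix in this package uses.
        """
        df = self.data if zygosity is None else self.data[self.data["zygosity"] == zygosity]
        cols = [f"{t}_1" for t in self.traits.names] + [f"{t}_2" for t in self.traits.names]
        return df[cols].to_numpy(dtype=float)

    def n_observed_values(self) -> int:
        """Count of non-missing trait values; the data side of df accounting."""
        return int(self.data[self.traits.columns()].notna().to_numpy().sum())

    def copy(self) -> "TwinPairTable":
        return TwinPairTable(self.data.copy(), self.traits, list(self.log))


def _drop_uninformative(df: pd.DataFrame, traits: TraitSpec, log: list[str]) -> pd.DataFrame:
    """Drop pairs with every trait value missing; they carry no likelihood."""
    all_missing = df[traits.columns()].isna().all(axis=1)
    if all_missing.any():
        n = int(all_missing.sum())
        msg = f"dropped {n} pair(s) with all trait values missing"
        log.append(msg)
        logger.warning(msg)
        df = df[~all_missing]
    return df


def read_twin_csv(path, traits: TraitSpec) -> TwinPairTable:
    """Read a wide twin-pair CSV.

    Empty cells and the token ``NA`` are missing. Rows whose zygosity does
    not parse to MZ/DZ are rejected (logged, with reason); rows with all
    trait values missing are dropped with a warning.
    """
    df = pd.read_csv(
        path,
        dtype={"family_id": str, "zygosity": str, "sex1": str, "sex2": str},
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        skip_blank_lines=True,
        float_precision="round_trip",
    )
    required = ["family_id", "zygosity", "sex1", "sex2"] + traits.columns()
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise TwinDataError(f"{path}: missing required column(s): {missing_cols}")

    log: list[str] = []
    zyg = df["zygosity"].str.strip().str.upper()
    bad = ~zyg.isin(ZYGOSITIES)
    if bad.any():
        for idx in df.index[bad]:
            msg = f"rejected row {idx} (family_id={df.at[idx, 'family_id']}): unparseable zygosity {df.at[idx, 'zygosity']!r}"
            log.append(msg)
            logger.warning(msg)
        df, zyg = df[~bad], zyg[~bad]
    df = df.assign(zygosity=zyg)

    for s in ("sex1", "sex2"):
        vals = df[s].str.strip().str.lower()
        vals = vals.where(vals.isin(SEX_LEVELS))
        df = df.assign(**{s: vals})
    for c in traits.columns():
        df[c] = pd.to_numeric(df[c], errors="raise")

    df = _drop_uninformative(df, traits, log)
    return TwinPairTable(df.reset_index(drop=True), traits, log)


def write_twin_csv(table: TwinPairTable, path) -> None:
    """Write the same wide dialect ``read_twin_csv`` accepts; missing = empty cell."""
    cols = ["family_id", "zygosity", "sex1", "sex2"] + table.traits.columns()
    out = table.data[cols].copy()
    for c in table.traits.columns():
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="")


def residualize(table: TwinPairTable, covariates=("sex",)) -> TwinPairTable:
    """Regress each trait on the covariate(s) and keep the residuals.

    All individuals (both twins, both zygosity groups) are pooled into one
    long sample per trait and the trait is replaced by the residual of a
    pooled OLS fit with intercept. Individuals whose covariate is missing
    have their trait values set missing (logged) rather than imputed.
    Residuals have zero sample correlation with the covariate.
    """
    covariates = tuple(covariates)
    unknown = set(covariates) - {"sex"}
    if unknown:
        raise TwinDataError(f"unsupported covariate(s): {sorted(unknown)} (only 'sex' is available)")

    out = table.copy()
    if not covariates:
        return out
    df = out.data

    sex_codes = {"male": 0.0, "female": 1.0}
    sex = {i: df[f"sex{i}"].map(sex_codes).to_numpy(dtype=float) for i in (1, 2)}

    sex_all = np.concatenate([sex[1], sex[2]])
    finite = sex_all[np.isfinite(sex_all)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise TwinDataError("covariate 'sex' is constant (or absent) across all individuals: degenerate design")

    for i in (1, 2):
        miss = ~np.isfinite(sex[i])
        if miss.any():
            affected = [f"{t}_{i}" for t in out.traits.names]
            n_set = int(df.loc[miss, affected].notna().to_numpy().sum())
            if n_set:
                msg = f"sex{i} missing for {int(miss.sum())} pair(s): set {n_set} trait value(s) missing"
                out.log.append(msg)
                logger.warning(msg)
            df.loc[miss, affected] = np.nan

    for t in out.traits.names:
        y = np.concatenate([df[f"{t}_1"].to_numpy(float), df[f"{t}_2"].to_numpy(float)])
        x = sm.add_constant(sex_all)
        fit = sm.OLS(y, x, missing="drop").fit()
        resid = y - fit.predict(x)  # NaN where y or x missing
        n = len(df)
        df[f"{t}_1"] = resid[:n]
        df[f"{t}_2"] = resid[n:]

    out.data = _drop_uninformative(df, out.traits, out.log)
    return out
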