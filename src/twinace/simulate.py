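"""Simulate twin-pair phenotype tables under a known correlated-factors ACE structure.

Phenotypes live on a standardized scale: for trait j the additive-genetic,
shared- and nonshared-environmental variance shares a_j + c_j + e_j = 1, and
cross-trait structure enters through the etiological correlation matrices
rA, rC, rE. The generative model mirrors the fitted one: latent additive
factors correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins,
shared-environment factors are common to a pair, nonshared factors are drawn
independently per twin.

`default_wellbeing_params` provides a study-like trivariate preset (presence
of mindful attention, happiness, life satisfaction at 429 MZ / 707 DZ pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ace import ComponentMatrices, ModelError, expected_covariance
from .data import TraitSpec, TwinPairTable


def _check_corr(R: np.ndarray, name: str, p: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (p, p):
        raise ModelError(f"{name} must be {p}x{p}, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ModelError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ModelError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ModelError(f"{name} is not positive semidefinite")
    return R


@dataclass
class GeneratingParams:
    """Ground-truth parameters for the twin-pair simulator.

    a, c, e are per-trait standardized variance shares (summing to one per
    trait, e > 0 since E absorbs measurement error); rA, rC, rE the latent
    correlation matrices; sex_effect an additive mean shift applied to
    females; missing_rate the per-value masking probability (MCAR).
    """

    traits: TraitSpec
    a: np.ndarray
    c: np.ndarray
    e: np.ndarray
    rA: np.ndarray | None = None
    rC: np.ndarray | None = None
    rE: np.ndarray | None = None
    means: np.ndarray | None = None
    sex_effect: np.ndarray | None = None
    missing_rate: float = 0.0
    nMZ: int = 429
    nDZ: int = 707
    seed: int = 0
    #: (MZ male, MZ female, DZ male, DZ female, DZ opposite-sex) mix weights
    sex_mix: tuple = (145, 284, 138, 227, 342)
    _allow_degenerate_e: bool = field(default=False, repr=False)

    def __post_init__(self):
        p = self.traits.p
        for name in ("a", "c", "e"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.shape != (p,):
                raise ModelError(f"{name} must have length p={p}")
            if np.any(v < 0) or np.any(v > 1):
                raise ModelError(f"{name} entries must lie in [0, 1]")
            setattr(self, name, v)
        if not np.allclose(self.a + self.c + self.e, 1.0, atol=1e-8):
            raise ModelError("a + c + e must equal 1 for every trait")
        if not self._allow_degenerate_e and np.any(self.e <= 0):
            raise ModelError("e must be > 0 for every trait (E carries measurement error)")
        for name in ("rA", "rC", "rE"):
            R = getattr(self, name)
            R = np.eye(p) if R is None else _check_corr(R, name, p)
            setattr(self, name, R)
        self.means = np.zeros(p) if self.means is None else np.atleast_1d(np.asarray(self.means, float))
        self.sex_effect = (
            np.zeros(p) if self.sex_effect is None else np.atleast_1d(np.asarray(self.sex_effect, float))
        )
        if self.means.shape != (p,) or self.sex_effect.shape != (p,):
            raise ModelError("means and sex_effect must have length p")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ModelError("missing_rate must be in [0, 1)")

    @property
    def p(self) -> int:
        return self.traits.p

    def components(self) -> ComponentMatrices:
        """The generating A, C, E covariance matrices (standardized scale)."""
        def cov(shares, R):
            s = np.sqrt(shares)
            return R * np.outer(s, s)

        return ComponentMatrices(cov(self.a, self.rA), cov(self.c, self.rC), cov(self.e, self.rE), self.means)


def default_wellbeing_params(**overrides) -> GeneratingParams:
    """Trivariate mindfulness/wellbeing-like preset at study scale.

    Traits presence, happiness, life satisfaction with heritabilities
    0.34/0.42/0.57, no shared environment, genetic correlations
    (0.22, 0.36, 0.80) and nonshared-environment correlations
    (0.15, 0.14, 0.47); 429 MZ and 707 DZ pairs with the observed
    same-/opposite-sex mix.
    """
    a = np.array([0.34, 0.42, 0.57])
    params = dict(
        traits=TraitSpec(("presence", "happiness", "lifesat")),
        a=a,
        c=np.zeros(3),
        e=1.0 - a,
        rA=np.array([[1.0, 0.22, 0.36], [0.22, 1.0, 0.80], [0.36, 0.80, 1.0]]),
        rE=np.array([[1.0, 0.15, 0.14], [0.15, 1.0, 0.47], [0.14, 0.47, 1.0]]),
        nMZ=429,
        nDZ=707,
    )
    params.update(overrides)
    return GeneratingParams(**params)


def _draw_sexes(rng, nMZ, nDZ, mix):
    """Assign pair sexes: MZ same-sex; DZ same- or opposite-sex per the mix."""
    mz_m, mz_f, dz_m, dz_f, dz_o = (np.asarray(mix, float) + 1e-12)
    mz = rng.choice(["mm", "ff"], size=nMZ, p=np.array([mz_m, mz_f]) / (mz_m + mz_f))
    dz = rng.choice(
        ["mm", "ff", "mf"], size=nDZ, p=np.array([dz_m, dz_f, dz_o]) / (dz_m + dz_f + dz_o)
    )
    code = {"mm": ("male", "male"), "ff": ("female", "female"), "mf": ("male", "female")}
    both = np.concatenate([mz, dz])
    return [code[x][0] for x in both], [code[x][1] for x in both]


def simulate(params: GeneratingParams) -> TwinPairTable:
    """Draw a twin-pair table from the generating ACE structure.

    The 2p phenotype vector of a pair is multivariate normal with the
    zygosity-appropriate expected covariance; the female mean shift is added
    per individual, then values are masked independently at missing_rate.
    Identical seeds give identical tables.
    """
    p = params.p
    rng = np.random.default_rng(params.seed)
    comp = params.components()

    blocks = []
    for z, n in (("MZ", params.nMZ), ("DZ", params.nDZ)):
        Sigma = expected_covariance(comp, z)
        # guard: the stacked latent construction requires PSD joint covariance
        if np.linalg.eigvalsh(Sigma).min() < -1e-8:
            raise ModelError(f"expected covariance for {z} is not PSD")
        Y = rng.multivariate_normal(np.tile(params.means, 2), Sigma, size=n, method="svd")
        blocks.append(Y)
    Y = np.vstack(blocks) if blocks else np.empty((0, 2 * p))

    n_total = params.nMZ + params.nDZ
    zyg = np.array(["MZ"] * params.nMZ + ["DZ"] * params.nDZ)
    sex1, sex2 = _draw_sexes(rng, params.nMZ, params.nDZ, params.sex_mix)
    for t, sexes in ((0, sex1), (1, sex2)):
        shift = (np.array(sexes) == "female").astype(float)[:, None] * params.sex_effect[None, :]
        Y[:, t * p : (t + 1) * p] += shift

    if params.missing_rate > 0:
        mask = rng.random((n_total, 2 * p)) < params.missing_rate
        Y = np.where(mask, np.nan, Y)

    cols = {"family_id": [f"fam{i:05d}" for i in range(n_total)], "zygosity": zyg, "sex1": sex1, "sex2": sex2}
    for j, t in enumerate(params.traits.names):
        cols[f"{t}_1"] = Y[:, j]
        cols[f"{t}_2"] = Y[:, p + j]
    df = pd.DataFrame(cols)
    # pairs masked on every trait carry no information; drop like the reader does
    keep = df[params.traits.columns()].notna().any(axis=1)
    return TwinPairTable(df[keep].reset_index(drop=True), params.traits)


def expected_correlations(params: GeneratingParams) -> dict:
    """Closed-form population correlations implied by the generating values.

    Returns per-trait twin correlations rMZ = a + c and rDZ = a/2 + c, the
    phenotypic correlation matrix
    rph_jk = rA_jk sqrt(a_j a_k) + rC_jk sqrt(c_j c_k) + rE_jk sqrt(e_j e_k),
    and the cross-twin cross-trait matrices (the rph formula without the E
    term, with the genetic term halved for DZ pairs).
    """
    a, c, e = params.a, params.c, params.e
    sa, sc, se = np.sqrt(a), np.sqrt(c), np.sqrt(e)
    gen = params.rA * np.outer(sa, sa)
    sha = params.rC * np.outer(sc, sc)
    non = params.rE * np.outer(se, se)
    rph = gen + sha + non
    return {
        "traits": params.traits.names,
        "rMZ": a + c,
        "rDZ": 0.5 * a + c,
        "rph": rph,
        "ctct_MZ": gen + sha,
        "ctct_DZ": 0.5 * gen + sha,
    }
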