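"""Isotemporal (ISM) and compositional isotemporal (CISM) substitution models.

Both approaches regress a standardised cardiometabolic outcome on the
daily behaviour profile plus covariates, then translate fitted
coefficients into the estimated effect of moving ``t`` minutes from one
behaviour to another while waking time stays fixed.

**ISM** enters waking wear hours, standing hours and stepping hours into
an ordinary least-squares model and omits sitting.  With total time held
constant, the standing (stepping) coefficient is the estimated effect of
replacing one hour of sitting with one hour of standing (stepping).
Estimates are therefore exactly linear in ``t`` and exactly antisymmetric
under reversing the direction of the swap.

**CISM** maps the (sit, stand, step) composition to two isometric
log-ratio (ILR) coordinates and regresses the outcome on those.  A
reallocation effect is the predicted outcome difference between a
perturbed composition and a base composition (typically the cohort mean),
so estimates are non-linear in ``t`` and asymmetric between directions —
the geometry of the simplex, not an artefact.  Predictions are invariant
to which orthonormal ILR basis is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .composition import (
    BehaviourComposition,
    ILRBasis,
    PARTS,
    default_basis,
    ilr_transform,
    reallocate,
)

#: Covariates adjusted for in every model, in design order.
DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "imd", "bp_med", "lipid_med")

#: Ethnicity categories; the first is the reference level.
ETHNICITY_LEVELS = ("white_european", "south_asian", "other")

Z_CRIT = 1.96  # normal 95% critical value


class DesignError(ValueError):
    """Model design matrix problem (rank deficiency, missing columns)."""


@dataclass
class ModelFit:
    """Fitted substitution regression: coefficients, covariance, metadata."""

    method: str  # "ISM" | "CISM"
    outcome: str
    params: pd.Series
    cov: pd.DataFrame
    n: int
    resid_df: int
    basis: ILRBasis | None = None  # CISM only
    behaviour_unit: str = "hour"

    @property
    def gamma(self) -> np.ndarray:
        """ILR coefficient vector (CISM fits only)."""
        if self.method != "CISM":
            raise AttributeError("gamma is defined for CISM fits only")
        names = [f"z{i + 1}" for i in range(self.basis.n_parts - 1)]
        return self.params[names].to_numpy()

    @property
    def gamma_cov(self) -> np.ndarray:
        if self.method != "CISM":
            raise AttributeError("gamma_cov is defined for CISM fits only")
        names = [f"z{i + 1}" for i in range(self.basis.n_parts - 1)]
        return self.cov.loc[names, names].to_numpy()


@dataclass
class ReallocationEstimate:
    """Estimated standardised-outcome difference for a t-minute reallocation."""

    method: str
    outcome: str
    from_part: str
    to_part: str
    minutes: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    delta_z: np.ndarray | None = None  # CISM only

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "outcome": self.outcome,
            "from": self.from_part,
            "to": self.to_part,
            "minutes": self.minutes,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
        }


def behaviours_to_hours(comp) -> np.ndarray:
    """Convert behaviour minutes to hours (elementwise / 60)."""
    if isinstance(comp, BehaviourComposition):
        return comp.as_array() / 60.0
    return np.asarray(comp, dtype=float) / 60.0


def build_covariate_design(df: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Expand covariates into numeric design columns.

    Ethnicity is reference-coded with White European as the reference;
    other covariates enter as supplied (IMD linearly, binaries as 0/1).
    """
    cols = {}
    for cov in covariates:
        if cov == "ethnicity":
            if "ethnicity" not in df.columns:
                raise DesignError("missing covariate column 'ethnicity'")
            eth = df["ethnicity"].astype(str)
            unknown = set(eth.unique()) - set(ETHNICITY_LEVELS)
            if unknown:
                raise DesignError(f"unknown ethnicity categories: {sorted(unknown)}")
            for level in ETHNICITY_LEVELS[1:]:
                cols[f"ethnicity_{level}"] = (eth == level).astype(float)
        else:
            if cov not in df.columns:
                raise DesignError(f"missing covariate column '{cov}'")
            cols[cov] = pd.to_numeric(df[cov], errors="raise").astype(float)
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offenders via pivoted QR: columns pivoted past the rank
        _, _, piv = scipy.linalg.qr(mat, mode="economic", pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ols(y: pd.Series, X: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame, int]:
    _check_rank(X)
    model = sm.OLS(np.asarray(y, dtype=float), X.to_numpy())
    res = model.fit()
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return params, cov, int(res.df_resid)


def fit_ism(
    cohort: pd.DataFrame, outcome: str, covariates=DEFAULT_COVARIATES
) -> ModelFit:
    """Fit the isotemporal substitution regression for one outcome.

    The design holds waking wear hours, standing hours and stepping hours
    simultaneously (sitting omitted), plus covariates and an intercept.
    ``outcome`` names a column of ``cohort`` that is already standardised.
    """
    for col in ("sit_min", "stand_min", "step_min", "wear_min", outcome):
        if col not in cohort.columns:
            raise DesignError(f"cohort table is missing column '{col}'")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "wear_h": cohort["wear_min"] / 60.0,
            "stand_h": cohort["stand_min"] / 60.0,
            "step_h": cohort["step_min"] / 60.0,
        },
        index=cohort.index,
    )
    X = pd.concat([X, build_covariate_design(cohort, covariates)], axis=1)
    params, cov, df_resid = _ols(cohort[outcome], X)
    return ModelFit(
        method="ISM", outcome=outcome, params=params, cov=cov, n=len(cohort), resid_df=df_resid
    )


def ism_reallocation(
    fit: ModelFit, to_part: str, minutes: float, from_part: str = "sit"
) -> ReallocationEstimate:
    """Reallocation estimate from an ISM fit.

    Sitting-to-X estimates scale the standing/stepping coefficient by
    ``minutes / 60``; X-to-sitting estimates are the exact negation (the
    model is linear in durations, so reversing the swap flips the sign).
    """
    if fit.method != "ISM":
        raise ValueError("ism_reallocation requires an ISM fit")
    if from_part == to_part or from_part not in PARTS or to_part not in PARTS:
        raise ValueError(f"parts must be distinct members of {PARTS}")
    if from_part == "sit":
        coef_part, sign = to_part, 1.0
    elif to_part == "sit":
        coef_part, sign = from_part, -1.0
    else:
        raise ValueError("ISM models substitution of sitting; one part must be 'sit'")
    name = f"{coef_part}_h"
    scale = sign * minutes / 60.0
    est = float(fit.params[name]) * scale
    se = float(np.sqrt(fit.cov.loc[name, name])) * abs(scale)
    coef_se = float(np.sqrt(fit.cov.loc[name, name]))
    p = _wald_p(fit.params[name], coef_se)
    return ReallocationEstimate(
        method="ISM",
        outcome=fit.outcome,
        from_part=from_part,
        to_part=to_part,
        minutes=minutes,
        estimate=est,
        se=se,
        ci_low=est - Z_CRIT * se,
        ci_high=est + Z_CRIT * se,
        p_value=p if minutes > 0 else 1.0,
        n=fit.n,
    )


def fit_cism(
    cohort: pd.DataFrame,
    outcome: str,
    basis: ILRBasis | None = None,
    covariates=DEFAULT_COVARIATES,
) -> ModelFit:
    """Fit the compositional substitution regression for one outcome.

    The (sit, stand, step) composition of each participant is mapped to
    ILR coordinates under ``basis`` (default pivot basis) and entered with
    covariates and an intercept.  All compositions must be strictly
    positive; apply a zero-replacement policy upstream if needed.
    """
    basis = basis or default_basis()
    for col in ("sit_min", "stand_min", "step_min", outcome):
        if col not in cohort.columns:
            raise DesignError(f"cohort table is missing column '{col}'")
    parts = cohort[["sit_min", "stand_min", "step_min"]].to_numpy(dtype=float)
    z = ilr_transform(parts, basis).z
    X = pd.DataFrame({"const": 1.0}, index=cohort.index)
    for i in range(z.shape[1]):
        X[f"z{i + 1}"] = z[:, i]
    X = pd.concat([X, build_covariate_design(cohort, covariates)], axis=1)
    params, cov, df_resid = _ols(cohort[outcome], X)
    return ModelFit(
        method="CISM",
        outcome=outcome,
        params=params,
        cov=cov,
        n=len(cohort),
        resid_df=df_resid,
        basis=basis,
    )


def delta_z_for_reallocation(
    base: BehaviourComposition,
    from_part: str,
    to_part: str,
    minutes: float,
    basis: ILRBasis | None = None,
) -> np.ndarray:
    """ILR coordinate shift induced by a t-minute reallocation of ``base``."""
    basis = basis or default_basis()
    if minutes == 0:
        return np.zeros(basis.n_parts - 1)
    perturbed = reallocate(base, from_part, to_part, minutes)
    return ilr_transform(perturbed, basis).z - ilr_transform(base, basis).z


def cism_reallocation(
    fit: ModelFit,
    base: BehaviourComposition,
    from_part: str,
    to_part: str,
    minutes: float,
) -> ReallocationEstimate:
    """Reallocation estimate from a CISM fit, evaluated at ``base``.

    The estimate is the inner product of the ILR coefficient vector with
    the coordinate shift of the perturbed composition; its standard error
    comes from the delta method (linear combination of coefficients), so
    the 95% CI is ``estimate +/- 1.96 * sqrt(dz' Sigma dz)``.  Both are
    invariant to the choice of orthonormal ILR basis.
    """
    if fit.method != "CISM":
        raise ValueError("cism_reallocation requires a CISM fit")
    dz = delta_z_for_reallocation(base, from_part, to_part, minutes, fit.basis)
    gamma = fit.gamma
    est = float(gamma @ dz)
    se = float(np.sqrt(dz @ fit.gamma_cov @ dz))
    return ReallocationEstimate(
        method="CISM",
        outcome=fit.outcome,
        from_part=from_part,
        to_part=to_part,
        minutes=minutes,
        estimate=est,
        se=se,
        ci_low=est - Z_CRIT * se,
        ci_high=est + Z_CRIT * se,
        p_value=_wald_p(est, se) if minutes > 0 else 1.0,
        n=fit.n,
        delta_z=dz,
    )


def cism_reallocation_bootstrap(
    cohort: pd.DataFrame,
    outcome: str,
    base: BehaviourComposition,
    from_part: str,
    to_part: str,
    minutes: float,
    basis: ILRBasis | None = None,
    covariates=DEFAULT_COVARIATES,
    n_boot: int = 500,
    seed: int = 0,
) -> ReallocationEstimate:
    """Nonparametric-bootstrap alternative to the delta-method CI.

    Resamples participants with replacement, refits CISM each time and
    takes percentile 2.5/97.5 bounds.  Slower than the delta method and
    available for sensitivity checks.
    """
    basis = basis or default_basis()
    point = cism_reallocation(
        fit_cism(cohort, outcome, basis, covariates), base, from_part, to_part, minutes
    )
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    idx = np.arange(len(cohort))
    for b in range(n_boot):
        sample = cohort.iloc[rng.choice(idx, size=len(idx), replace=True)]
        fit_b = fit_cism(sample.reset_index(drop=True), outcome, basis, covariates)
        stats[b] = cism_reallocation(fit_b, base, from_part, to_part, minutes).estimate
    lo, hi = np.percentile(stats, [2.5, 97.5])
    point.ci_low, point.ci_high = float(lo), float(hi)
    point.se = float(np.std(stats, ddof=1))
    return point


def solve_gamma_from_estimates(
    base: BehaviourComposition,
    reallocations: list[tuple[str, str, float]],
    estimates: np.ndarray,
    basis: ILRBasis | None = None,
) -> np.ndarray:
    """Recover the ILR coefficient vector implied by known reallocation effects.

    Given ``D - 1`` (or more) reallocation effects evaluated at ``base``,
    solve the linear system ``gamma . delta_z_k = estimate_k``.  Useful for
    reconstructing a model's coefficients from published effect estimates.
    """
    basis = basis or default_basis()
    A = np.array(
        [delta_z_for_reallocation(base, f, t, m, basis) for (f, t, m) in reallocations]
    )
    b = np.asarray(estimates, dtype=float)
    if A.shape[0] == A.shape[1]:
        return np.linalg.solve(A, b)
    gamma, *_ = np.linalg.lstsq(A, b, rcond=None)
    return gamma


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * scipy.stats.norm.sf(abs(est) / se))
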