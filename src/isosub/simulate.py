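"""Synthetic cohorts with the statistical structure the substitution models assume.

The generator emulates a pooled cross-sectional sample of adults at high
risk of type 2 diabetes wearing a thigh-mounted posture monitor: daily
sitting/standing/stepping minutes, demographic and medication covariates,
and cardiometabolic outcomes driven by a *known* compositional (or
isotemporal) linear model.  Because the truth is known, parameter-recovery
and coverage properties of the fitting code can be tested end to end.

Behaviour compositions are drawn logistic-normally: a bivariate normal on
isometric log-ratio (ILR) coordinates (guaranteeing strictly positive
parts) scaled by an independently drawn waking wear total.  The six free
parameters (ILR mean and spread, wear mean and spread) are moment-matched
numerically so that the minute-scale means and SDs of the three
behaviours hit their targets; closed-form minute-scale moments do not
exist for this family.

Outcomes are built as ``target_mean + target_sd * u`` where ``u`` is a
unit-variance linear predictor: the chosen truth (ILR-scale ``gamma`` or
per-hour ``beta``) applied to the centred behaviour signal, plus centred
covariate effects, plus Gaussian noise sized to bring the total variance
to one.  Regressing the standardised outcome on the behaviour terms
therefore recovers the configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.optimize

from .composition import default_basis, ilr_transform, inverse_ilr
from .qc import MIN_STEP_EVENTS, MIN_WEAR_MIN

_CAL_SEED = 987654321  # fixed draws for moment matching (common random numbers)
_CAL_N = 4096

OUTCOME_COLUMNS = (
    "bmi",
    "waist",
    "hba1c",
    "total_chol",
    "hdl",
    "ldl",
    "triglycerides",
    "sbp_mmhg",
    "dbp_mmhg",
)


@dataclass(frozen=True)
class OutcomeSpec:
    """Target marginal moments and behaviour-effect truth for one outcome.

    ``gamma`` is the true ILR coefficient pair (pivot basis, standardised
    outcome scale); ``beta`` is the true per-hour (standing, stepping)
    substitution effect.  Which one drives generation is chosen by
    ``GeneratorParams.truth_mode``.
    """

    mean: float
    sd: float
    gamma: tuple[float, float] = (0.0, 0.0)
    beta: tuple[float, float] = (0.0, 0.0)


def _default_outcomes() -> dict[str, OutcomeSpec]:
    # Behaviour-effect truths follow the qualitative pattern reported for
    # posture-based substitution studies: adiposity and lipids respond,
    # glycaemia and total/LDL cholesterol do not.  Marginal targets for
    # markers without a published pooled value are typical of UK adults at
    # high diabetes risk.
    return {
        "bmi": OutcomeSpec(30.3, 5.7, gamma=(1.2, -0.34), beta=(-0.10, -0.37)),
        "waist": OutcomeSpec(100.0, 14.0, gamma=(1.1, -0.31), beta=(-0.09, -0.33)),
        "hba1c": OutcomeSpec(5.8, 0.4, gamma=(0.0, 0.0), beta=(0.0, 0.0)),
        "total_chol": OutcomeSpec(5.2, 1.0, gamma=(0.0, 0.0), beta=(0.0, 0.0)),
        "hdl": OutcomeSpec(1.3, 0.35, gamma=(-0.5, 0.15), beta=(0.04, 0.18)),
        "ldl": OutcomeSpec(3.0, 0.9, gamma=(0.0, 0.0), beta=(0.0, 0.0)),
        "triglycerides": OutcomeSpec(1.7, 0.9, gamma=(0.6, -0.15), beta=(-0.05, -0.20)),
        "sbp_mmhg": OutcomeSpec(132.0, 16.0, gamma=(0.4, -0.10), beta=(-0.03, -0.12)),
        "dbp_mmhg": OutcomeSpec(80.0, 10.0, gamma=(0.3, -0.08), beta=(-0.02, -0.10)),
    }


def _default_covariate_effects() -> dict[str, float]:
    # Per-unit effects on the standardised outcome scale, shared across
    # outcomes; modest by design so behaviour effects dominate.
    return {
        "age": 0.008,
        "sex": -0.05,
        "ethnicity_south_asian": 0.05,
        "ethnicity_other": 0.0,
        "imd": 0.004,
        "bp_med": 0.10,
        "lipid_med": 0.08,
    }


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort generator (defaults: pooled-sample targets)."""

    n: int = 1524
    seed: int = 1
    behaviour_mean_min: tuple[float, float, float] = (548.0, 286.0, 107.0)
    behaviour_sd_min: tuple[float, float, float] = (112.0, 96.0, 40.0)
    #: correlation between the two ILR coordinates; None lets the moment
    #: matcher fit it (the minute-scale SD targets pin it down).
    ilr_correlation: float | None = None
    age_mean: float = 59.8
    age_sd: float = 11.9
    male_prop: float = 0.517
    ethnicity_props: tuple[tuple[str, float], ...] = (
        ("white_european", 0.729),
        ("south_asian", 0.200),
        ("other", 0.071),
    )
    imd_mean: float = 20.0
    imd_sd: float = 12.0
    bp_med_prop: float = 0.402
    lipid_med_prop: float = 0.279
    truth_mode: str = "gamma"  # "gamma" (CISM truth) or "beta" (ISM truth)
    outcomes: tuple[tuple[str, OutcomeSpec], ...] = tuple(_default_outcomes().items())
    covariate_effects: tuple[tuple[str, float], ...] = tuple(
        _default_covariate_effects().items()
    )
    confound_age_rho: float = 0.0  # correlation between age and the first ILR coordinate

    def outcome_dict(self) -> dict[str, OutcomeSpec]:
        return dict(self.outcomes)

    def effect_dict(self) -> dict[str, float]:
        return dict(self.covariate_effects)

    def with_truth(self, outcome: str, gamma=None, beta=None) -> "GeneratorParams":
        """Copy of the params with one outcome's truth replaced."""
        specs = self.outcome_dict()
        spec = specs[outcome]
        specs[outcome] = replace(
            spec,
            gamma=tuple(gamma) if gamma is not None else spec.gamma,
            beta=tuple(beta) if beta is not None else spec.beta,
        )
        return replace(self, outcomes=tuple(specs.items()))


def default_params(**overrides) -> GeneratorParams:
    """Generator parameters calibrated to the pooled-sample descriptives."""
    return replace(GeneratorParams(), **overrides) if overrides else GeneratorParams()


@dataclass(frozen=True)
class BehaviourDistribution:
    """Calibrated logistic-normal behaviour model (internal)."""

    mu_z: tuple[float, float]
    sd_z: tuple[float, float]
    corr_z: float
    wear_mu: float
    wear_sd: float
    hours_cov: tuple  # 3x3 covariance of (sit, stand, step) hours, from calibration draws
    hours_mean: tuple

    def cov_z(self) -> np.ndarray:
        s1, s2 = self.sd_z
        c = self.corr_z * s1 * s2
        return np.array([[s1**2, c], [c, s2**2]])


def _simulate_parts(theta, eps, corr_z):
    """Minutes of (sit, stand, step) for standard-normal draws ``eps`` (n x 3)."""
    mu1, mu2, ls1, ls2, wmu, lwsd = theta
    s1, s2 = np.exp(ls1), np.exp(ls2)
    e1 = eps[:, 0]
    e2 = corr_z * eps[:, 0] + np.sqrt(1.0 - corr_z**2) * eps[:, 1]
    z = np.column_stack([mu1 + s1 * e1, mu2 + s2 * e2])
    props = inverse_ilr(z, default_basis(), kappa=1.0)
    wear = np.maximum(wmu + np.exp(lwsd) * eps[:, 2], 300.0)
    return props * wear[:, None]


@lru_cache(maxsize=8)
def _calibrate(mean_min: tuple, sd_min: tuple, corr_z: float | None) -> BehaviourDistribution:
    """Moment-match the logistic-normal model to minute-scale means and SDs.

    Uses a fixed bank of standard-normal draws so the objective is smooth
    and deterministic, and solves the moment system by least squares.
    With ``corr_z=None`` the ILR correlation is a seventh free parameter
    (via tanh, keeping it in (-1, 1)); the six moment targets then pin it
    down and the system is solved essentially exactly.  A fixed
    correlation leaves 6 parameters for 6 moments, which some target sets
    cannot satisfy — a residual above 2% raises.
    """
    targets_mean = np.asarray(mean_min, dtype=float)
    targets_sd = np.asarray(sd_min, dtype=float)
    rng = np.random.default_rng(_CAL_SEED)
    eps = rng.standard_normal((_CAL_N, 3))

    z0 = ilr_transform(targets_mean / targets_mean.sum(), default_basis()).z
    fit_corr = corr_z is None

    def residuals(theta):
        corr = np.tanh(theta[6]) if fit_corr else corr_z
        with np.errstate(over="ignore"):  # explored extremes may overflow harmlessly
            parts = _simulate_parts(theta[:6], eps, corr)
            m = parts.mean(axis=0)
            s = parts.std(axis=0, ddof=1)
        res = np.concatenate([(m - targets_mean) / targets_mean, (s - targets_sd) / targets_sd])
        return np.clip(np.where(np.isfinite(res), res, 1e3), -1e3, 1e3)

    theta0 = np.array([z0[0], z0[1], np.log(0.3), np.log(0.3), targets_mean.sum(), np.log(60.0)])
    if fit_corr:
        theta0 = np.append(theta0, 0.0)
    sol = scipy.optimize.least_squares(residuals, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 0.02:
        raise RuntimeError(
            "behaviour moment matching failed: the requested means/SDs are "
            f"not attainable by the logistic-normal family (max rel err {np.max(np.abs(sol.fun)):.3f})"
        )
    corr_fitted = float(np.tanh(sol.x[6])) if fit_corr else float(corr_z)
    mu1, mu2, ls1, ls2, wmu, lwsd = sol.x[:6]
    parts = _simulate_parts(sol.x[:6], eps, corr_fitted)
    hours = parts / 60.0
    return BehaviourDistribution(
        mu_z=(float(mu1), float(mu2)),
        sd_z=(float(np.exp(ls1)), float(np.exp(ls2))),
        corr_z=corr_fitted,
        wear_mu=float(wmu),
        wear_sd=float(np.exp(lwsd)),
        hours_cov=tuple(map(tuple, np.cov(hours, rowvar=False))),
        hours_mean=tuple(hours.mean(axis=0)),
    )


def behaviour_distribution(params: GeneratorParams) -> BehaviourDistribution:
    corr = None if params.ilr_correlation is None else float(params.ilr_correlation)
    return _calibrate(tuple(params.behaviour_mean_min), tuple(params.behaviour_sd_min), corr)


def _covariate_signal_variance(params: GeneratorParams) -> float:
    """Population variance of the covariate part of the linear predictor."""
    eff = params.effect_dict()
    props = dict(params.ethnicity_props)
    var = (
        eff["age"] ** 2 * params.age_sd**2
        + eff["sex"] ** 2 * params.male_prop * (1 - params.male_prop)
        + eff["imd"] ** 2 * params.imd_sd**2
        + eff["bp_med"] ** 2 * params.bp_med_prop * (1 - params.bp_med_prop)
        + eff["lipid_med"] ** 2 * params.lipid_med_prop * (1 - params.lipid_med_prop)
    )
    # multinomial dummies: Var(d_i) = p_i (1 - p_i), Cov(d_i, d_j) = -p_i p_j
    p_sa, p_ot = props["south_asian"], props["other"]
    a, b = eff["ethnicity_south_asian"], eff["ethnicity_other"]
    var += a**2 * p_sa * (1 - p_sa) + b**2 * p_ot * (1 - p_ot) - 2 * a * b * p_sa * p_ot
    return var


def _behaviour_signal_variance(params: GeneratorParams, dist: BehaviourDistribution, spec) -> float:
    if params.truth_mode == "gamma":
        g = np.asarray(spec.gamma)
        return float(g @ dist.cov_z() @ g)
    b = np.asarray(spec.beta)
    cov = np.asarray(dist.hours_cov)[1:, 1:]  # (stand, step) hours
    return float(b @ cov @ b)


def generate_cohort(params: GeneratorParams | None = None) -> pd.DataFrame:
    """Draw a full participant table, reproducible from ``params.seed``.

    Columns: ``participant_id``, behaviour minutes (``sit_min``,
    ``stand_min``, ``step_min``, ``wear_min``), covariates (``age``,
    ``sex``, ``ethnicity``, ``imd``, ``bp_med``, ``lipid_med``) and the
    nine raw outcome columns.
    """
    params = params or default_params()
    if params.truth_mode not in ("gamma", "beta"):
        raise ValueError("truth_mode must be 'gamma' or 'beta'")
    n = params.n
    rng = np.random.default_rng(params.seed)
    dist = behaviour_distribution(params)

    eps = rng.standard_normal((n, 3))
    theta = np.array(
        [
            dist.mu_z[0],
            dist.mu_z[1],
            np.log(dist.sd_z[0]),
            np.log(dist.sd_z[1]),
            dist.wear_mu,
            np.log(dist.wear_sd),
        ]
    )
    parts = _simulate_parts(theta, eps, dist.corr_z)
    basis = default_basis()
    z = ilr_transform(parts, basis).z

    rho = params.confound_age_rho
    age_noise = rng.standard_normal(n)
    age_std = rho * eps[:, 0] + np.sqrt(1 - rho**2) * age_noise
    age = params.age_mean + params.age_sd * age_std
    sex = (rng.random(n) < params.male_prop).astype(int)
    eth_names = [name for name, _ in params.ethnicity_props]
    eth_p = np.array([p for _, p in params.ethnicity_props])
    ethnicity = rng.choice(eth_names, size=n, p=eth_p / eth_p.sum())
    imd = np.clip(params.imd_mean + params.imd_sd * rng.standard_normal(n), 0.0, None)
    bp_med = (rng.random(n) < params.bp_med_prop).astype(int)
    lipid_med = (rng.random(n) < params.lipid_med_prop).astype(int)

    eff = params.effect_dict()
    cov_signal = (
        eff["age"] * (age - params.age_mean)
        + eff["sex"] * (sex - params.male_prop)
        + eff["imd"] * (imd - params.imd_mean)
        + eff["bp_med"] * (bp_med - params.bp_med_prop)
        + eff["lipid_med"] * (lipid_med - params.lipid_med_prop)
        + eff["ethnicity_south_asian"]
        * ((ethnicity == "south_asian") - dict(params.ethnicity_props)["south_asian"])
        + eff["ethnicity_other"]
        * ((ethnicity == "other") - dict(params.ethnicity_props)["other"])
    )
    cov_var = _covariate_signal_variance(params)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:05d}" for i in range(n)],
            "sit_min": parts[:, 0],
            "stand_min": parts[:, 1],
            "step_min": parts[:, 2],
            "wear_min": parts.sum(axis=1),
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "imd": imd,
            "bp_med": bp_med,
            "lipid_med": lipid_med,
        }
    )

    mu_z = np.asarray(dist.mu_z)
    hours = parts / 60.0
    hours_mean = np.asarray(dist.hours_mean)
    for name, spec in params.outcomes:
        if params.truth_mode == "gamma":
            beh_signal = (z - mu_z) @ np.asarray(spec.gamma)
        else:
            beh_signal = (hours[:, 1:] - hours_mean[1:]) @ np.asarray(spec.beta)
        signal_var = _behaviour_signal_variance(params, dist, spec) + cov_var
        if signal_var >= 0.95:
            raise ValueError(
                f"outcome '{name}': configured effects explain {signal_var:.2f} of unit "
                "variance; reduce them so residual variance stays positive"
            )
        resid_sd = np.sqrt(1.0 - signal_var)
        u = beh_signal + cov_signal + resid_sd * rng.standard_normal(n)
        df[name] = spec.mean + spec.sd * u
    return df


_INVALID_KINDS = ("short_wear", "low_steps", "monobehaviour")


def generate_days(
    cohort: pd.DataFrame,
    days_per_participant: int = 7,
    invalid_day_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand a cohort into day-level monitor records with known validity labels.

    Valid days jitter each participant's composition multiplicatively and
    are repaired, if necessary, to satisfy every screening criterion.
    Invalid days are built from a valid day by breaking exactly one named
    criterion; the construction is recorded in ``truth_label`` so screening
    code can be audited against ground truth.
    """
    if not 0.0 <= invalid_day_rate <= 1.0:
        raise ValueError("invalid_day_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    dates = pd.date_range("2024-01-01", periods=days_per_participant, freq="D")
    for r in cohort.itertuples():
        base = np.array([r.sit_min, r.stand_min, r.step_min], dtype=float)
        for d in range(days_per_participant):
            parts = base * np.exp(rng.normal(0.0, 0.10, size=3))
            wear = parts.sum()
            # repair: guarantee a constructively valid day
            if wear < MIN_WEAR_MIN:
                parts *= 1.02 * MIN_WEAR_MIN / wear
                wear = parts.sum()
            frac = parts / wear
            if frac.max() > 0.94:
                k = int(frac.argmax())
                excess = parts[k] - 0.94 * wear
                parts[k] -= excess
                others = [i for i in range(3) if i != k]
                parts[others] += excess * parts[others] / parts[others].sum()
            events = max(
                MIN_STEP_EVENTS, int(round(parts[2] * 40 + rng.normal(0.0, 50.0)))
            )
            label = "valid"
            if rng.random() < invalid_day_rate:
                label = _INVALID_KINDS[rng.integers(0, len(_INVALID_KINDS))]
                if label == "short_wear":
                    parts *= rng.uniform(480.0, 590.0) / parts.sum()
                elif label == "low_steps":
                    events = int(rng.integers(0, MIN_STEP_EVENTS))
                else:  # monobehaviour: sitting dominates the day
                    wear = parts.sum()
                    sit = rng.uniform(0.96, 0.99) * wear
                    rest = wear - sit
                    parts = np.array([sit, 0.7 * rest, 0.3 * rest])
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "date": dates[d].date().isoformat(),
                    "wear_min": parts.sum(),
                    "sit_min": parts[0],
                    "stand_min": parts[1],
                    "step_min": parts[2],
                    "step_events": events,
                    "truth_label": label,
                }
            )
    return pd.DataFrame(rows)
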