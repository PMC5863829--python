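"""Causal mediation of a binary outcome through a continuous mediator.

Implements the full mediation chain for the placental pathway
(methylation → placental surface area → full-term low birth weight):

* the four stepwise mediation conditions — (a) exposure associated with the
  mediator, (b) exposure associated with the outcome without the mediator,
  (c) mediator associated with the outcome, (d) the exposure effect
  attenuates once the mediator enters the model;
* the Sobel z-test of the product of path coefficients;
* an imputation-based natural-effects estimator that decomposes the total
  odds ratio into a natural direct effect (NDE) and a natural indirect
  effect (NIE), with TE = NDE × NIE exactly on the OR scale;
* nonparametric subject-level bootstrap percentile intervals;
* the log-scale proportion mediated, 100 · ln(NIE) / ln(TE).

The natural-effects estimator expands each observation over a grid of
hypothetical direct-path exposure levels, imputes the expected outcome from
a working logistic model evaluated at the hypothetical exposure but the
*observed* mediator, and refits a logistic natural-effect model with
separate direct-path and indirect-path exposure columns.  The OR-scale
decomposition is interpretable under a rare outcome; estimates from
case-control samples carry the same caveat.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .association import (
    DegenerateInputError,
    ModelFitError,
    fit_linear,
    fit_logistic,
)

__all__ = [
    "PathEstimate",
    "MediationPathEstimates",
    "ConditionReport",
    "MediationResult",
    "UnstableEstimateError",
    "estimate_paths",
    "check_mediation_conditions",
    "sobel_test",
    "expand_counterfactual",
    "fit_natural_effects",
    "bootstrap_mediation",
    "proportion_mediated",
    "path_diagram",
    "NaturalEffectsMediator",
]


class UnstableEstimateError(RuntimeError):
    """Too many bootstrap replicates failed to produce estimates."""


@dataclasses.dataclass(frozen=True)
class PathEstimate:
    estimate: float
    se: float
    p_value: float


@dataclasses.dataclass(frozen=True)
class MediationPathEstimates:
    """The four path coefficients of the mediation diagram.

    theta1: exposure → outcome log-OR without the mediator in the model;
    theta1_prime: the same with the mediator added; theta2: mediator →
    outcome log-OR (adjusted); beta1: exposure → mediator linear coefficient
    (SD units when both are standardized).
    """

    theta1: PathEstimate
    theta1_prime: PathEstimate
    theta2: PathEstimate
    beta1: PathEstimate


def estimate_paths(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    covariates: Sequence[str] = (),
) -> MediationPathEstimates:
    """Fit the four adjusted path models on complete cases.

    theta1 and theta2 come from logistic models without/with only the other
    path variable; theta1_prime and theta2 share one model with both exposure
    and mediator; beta1 from the linear mediator model.
    """
    covs = list(covariates)
    cc = data.dropna(subset=[outcome, exposure, mediator] + covs)

    r1 = fit_logistic(cc[outcome], cc[[exposure] + covs])[exposure]
    both = fit_logistic(cc[outcome], cc[[exposure, mediator] + covs])
    r2 = fit_logistic(cc[outcome], cc[[mediator] + covs])[mediator]
    rb = fit_linear(cc[mediator], cc[[exposure] + covs])[exposure]

    def pe(r) -> PathEstimate:
        return PathEstimate(estimate=r.coefficient, se=r.se, p_value=r.p_value)

    return MediationPathEstimates(
        theta1=pe(r1),
        theta1_prime=pe(both[exposure]),
        theta2=pe(r2),
        beta1=pe(rb),
    )


@dataclasses.dataclass(frozen=True)
class ConditionReport:
    """Stepwise mediation conditions (a)–(d) with the verdict."""

    a_exposure_mediator: bool
    b_exposure_outcome: bool
    c_mediator_outcome: bool
    d_attenuation: bool
    attenuation_percent: float
    alpha: float
    paths: MediationPathEstimates

    @property
    def mediation_present(self) -> bool:
        return (
            self.a_exposure_mediator
            and self.b_exposure_outcome
            and self.c_mediator_outcome
            and self.d_attenuation
        )


def check_mediation_conditions(
    paths: MediationPathEstimates, alpha: float = 0.05
) -> ConditionReport:
    """Evaluate conditions (a)–(d): significance of beta1, theta1, theta2,
    and strict attenuation |theta1'| < |theta1| (significance loss alone does
    not satisfy (d))."""
    for name in ("theta1", "theta1_prime", "theta2", "beta1"):
        pe = getattr(paths, name)
        if pe is None or not math.isfinite(pe.estimate):
            raise ValueError(f"path estimate {name!r} missing or non-finite")
    t1 = abs(paths.theta1.estimate)
    t1p = abs(paths.theta1_prime.estimate)
    attenuation = 100.0 * (t1 - t1p) / t1 if t1 > 0 else 0.0
    return ConditionReport(
        a_exposure_mediator=paths.beta1.p_value < alpha,
        b_exposure_outcome=paths.theta1.p_value < alpha,
        c_mediator_outcome=paths.theta2.p_value < alpha,
        d_attenuation=t1p < t1,
        attenuation_percent=attenuation,
        alpha=alpha,
        paths=paths,
    )


def sobel_test(
    beta1: float, se_beta1: float, theta2: float, se_theta2: float
) -> tuple[float, float]:
    """Sobel z-test of the product of path coefficients.

    z = (beta1 * theta2) / sqrt(beta1^2 se_theta2^2 + theta2^2 se_beta1^2),
    two-sided p from the standard normal.  Symmetric in the two paths.
    """
    if se_beta1 <= 0 or se_theta2 <= 0:
        raise ValueError("standard errors must be positive")
    denom = math.sqrt(beta1**2 * se_theta2**2 + theta2**2 * se_beta1**2)
    if denom == 0.0:
        raise ValueError("both path coefficients are zero: Sobel z undefined")
    z = beta1 * theta2 / denom
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def expand_counterfactual(
    data: pd.DataFrame,
    exposure: str,
    grid_offsets: Sequence[float] = (0.0, -1.0),
) -> pd.DataFrame:
    """Replicate each row once per hypothetical exposure offset.

    The replica carries ``x_direct = exposure + offset`` (the hypothetical
    level steering the direct path) and ``x_indirect = exposure`` (the
    observed level whose mediator value it keeps); mediator and covariates
    are unchanged.  Bookkeeping columns ``_offset`` and ``_source_row`` link
    replicas to their source rows.
    """
    if len(grid_offsets) == 0:
        raise ValueError("grid_offsets is empty")
    frames = []
    for off in grid_offsets:
        rep = data.copy()
        rep["x_direct"] = rep[exposure] + off
        rep["x_indirect"] = rep[exposure]
        rep["_offset"] = off
        rep["_source_row"] = np.arange(len(data))
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


@dataclasses.dataclass
class MediationResult:
    """Natural-effects decomposition of the total effect on the OR scale."""

    nde_or: float
    nie_or: float
    te_or: float
    proportion_mediated: float  # percent, log-OR scale
    sobel_z: float
    sobel_p: float
    n: int
    stratum: str = "all"
    nde_ci: tuple[float, float] | None = None
    nie_ci: tuple[float, float] | None = None
    te_ci: tuple[float, float] | None = None
    proportion_ci: tuple[float, float] | None = None
    bootstrap_reps: int = 0
    bootstrap_failures: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["note"] = (
            "OR-scale NDE/NIE from case-control or non-rare-outcome data are "
            "interpretable only under the rare-outcome assumption"
        )
        return d


def _check_standardized(series: pd.Series, name: str) -> None:
    obs = series.dropna()
    mu, sd = float(obs.mean()), float(obs.std(ddof=1))
    if abs(mu) > 0.5 or not 0.5 < sd < 2.0:
        raise ValueError(
            f"{name} does not look standardized (mean {mu:.3f}, SD {sd:.3f}); "
            "z-score it before the natural-effects fit"
        )


def fit_natural_effects(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    covariates: Sequence[str] = (),
    grid_offsets: Sequence[float] = (0.0, -1.0),
    stratum: str = "all",
) -> MediationResult:
    """Imputation-based natural-effects point estimates.

    Algorithm: (1) fit the working logistic model
    outcome ~ exposure + mediator + covariates; (2) expand each row over the
    hypothetical-exposure grid; (3) impute each replica's expected outcome
    from the working model at (x_direct, observed mediator, covariates);
    (4) fit the natural-effect logistic model of the imputed outcomes on
    (x_direct, x_indirect, covariates), all replicas weighted equally;
    (5) NDE = exp(coef of x_direct), NIE = exp(coef of x_indirect),
    TE = NDE · NIE.  With the default grid the effects are per one SD of
    exposure.  The Sobel test is evaluated on the fitted mediator and
    working-model coefficients.
    """
    covs = list(covariates)
    cc = data.dropna(subset=[outcome, exposure, mediator] + covs).reset_index(
        drop=True
    )
    _check_standardized(cc[exposure], f"exposure {exposure!r}")
    _check_standardized(cc[mediator], f"mediator {mediator!r}")

    working = fit_logistic(
        cc[outcome], cc[[exposure, mediator] + covs], return_intercept=True
    )
    coefs = {t: r.coefficient for t, r in working.items()}
    intercept = coefs.pop("const")

    expanded = expand_counterfactual(cc, exposure, grid_offsets)
    eta = np.full(len(expanded), intercept)
    eta += coefs[exposure] * expanded["x_direct"].to_numpy(float)
    eta += coefs[mediator] * expanded[mediator].to_numpy(float)
    for c in covs:
        eta += coefs[c] * expanded[c].to_numpy(float)
    expanded["_imputed"] = 1.0 / (1.0 + np.exp(-eta))

    ne = fit_logistic(
        expanded["_imputed"], expanded[["x_direct", "x_indirect"] + covs]
    )
    log_nde = ne["x_direct"].coefficient
    log_nie = ne["x_indirect"].coefficient

    beta1 = fit_linear(cc[mediator], cc[[exposure] + covs])[exposure]
    theta2 = working[mediator]
    sobel_z, sobel_p = sobel_test(
        beta1.coefficient, beta1.se, theta2.coefficient, theta2.se
    )

    nde, nie = math.exp(log_nde), math.exp(log_nie)
    return MediationResult(
        nde_or=nde,
        nie_or=nie,
        te_or=nde * nie,
        proportion_mediated=proportion_mediated(nde, nie),
        sobel_z=sobel_z,
        sobel_p=sobel_p,
        n=len(cc),
        stratum=stratum,
    )


def bootstrap_mediation(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    covariates: Sequence[str] = (),
    grid_offsets: Sequence[float] = (0.0, -1.0),
    reps: int = 1000,
    seed: int = 0,
    stratum: str = "all",
    max_failure_fraction: float = 0.10,
) -> MediationResult:
    """Percentile bootstrap CIs for the natural-effects decomposition.

    Subjects (original rows, never expanded replicas) are resampled with
    replacement; each replicate refits the full estimator.  Replicates that
    fail (separation, degenerate resample) are counted; more than
    ``max_failure_fraction`` failures raises :class:`UnstableEstimateError`.
    Deterministic under a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    point = fit_natural_effects(
        data, outcome, exposure, mediator, covariates, grid_offsets, stratum
    )
    rng = np.random.default_rng(seed)
    cc = data.dropna(
        subset=[outcome, exposure, mediator] + list(covariates)
    ).reset_index(drop=True)
    n = len(cc)
    draws: list[tuple[float, float]] = []
    failures = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            r = fit_natural_effects(
                cc.iloc[idx], outcome, exposure, mediator, covariates,
                grid_offsets, stratum,
            )
            draws.append((r.nde_or, r.nie_or))
        except (ModelFitError, DegenerateInputError, ValueError):
            failures += 1
    if failures > max_failure_fraction * reps:
        raise UnstableEstimateError(
            f"{failures}/{reps} bootstrap replicates failed"
        )
    arr = np.array(draws)
    nde_d, nie_d = arr[:, 0], arr[:, 1]
    te_d = nde_d * nie_d
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = 100.0 * np.log(nie_d) / np.log(te_d)
    prop_d = prop_d[np.isfinite(prop_d)]

    def pct(x: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    point.nde_ci = pct(nde_d)
    point.nie_ci = pct(nie_d)
    point.te_ci = pct(te_d)
    point.proportion_ci = pct(prop_d) if len(prop_d) else None
    point.bootstrap_reps = reps
    point.bootstrap_failures = failures
    return point


def proportion_mediated(nde_or: float, nie_or: float) -> float:
    """Percent of the total effect mediated, on the log-OR scale:
    100 · ln(NIE) / (ln(NDE) + ln(NIE))."""
    if nde_or <= 0 or nie_or <= 0:
        raise ValueError("odds ratios must be positive")
    log_nie = math.log(nie_or)
    log_te = math.log(nde_or) + math.log(nie_or)
    if log_te == 0.0:
        if log_nie == 0.0:
            return 0.0
        raise ValueError("total effect is null: proportion mediated undefined")
    return 100.0 * log_nie / log_te


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def path_diagram(paths: MediationPathEstimates, stratum: str = "all") -> str:
    """Text summary of the mediation path diagram with significance stars
    (* p < 0.05, ** p < 0.01)."""
    lines = [
        f"Mediation paths ({stratum}):",
        f"  theta1  (exposure -> outcome, no mediator) = "
        f"{paths.theta1.estimate:+.4f} (SE {paths.theta1.se:.4f})"
        f"{_stars(paths.theta1.p_value)}",
        f"  theta1' (exposure -> outcome, with mediator) = "
        f"{paths.theta1_prime.estimate:+.4f} (SE {paths.theta1_prime.se:.4f})"
        f"{_stars(paths.theta1_prime.p_value)}",
        f"  theta2  (mediator -> outcome) = "
        f"{paths.theta2.estimate:+.4f} (SE {paths.theta2.se:.4f})"
        f"{_stars(paths.theta2.p_value)}",
        f"  beta1   (exposure -> mediator) = "
        f"{paths.beta1.estimate:+.4f} (SE {paths.beta1.se:.4f})"
        f"{_stars(paths.beta1.p_value)}",
        "  (* p < 0.05; ** p < 0.01)",
    ]
    return "\n".join(lines)


class NaturalEffectsMediator(BaseEstimator):
    """Scikit-learn style estimator for the natural-effects decomposition.

    Parameters name the exposure, mediator and covariate columns of the
    feature frame; ``fit(X, y)`` takes the standardized feature frame and
    the binary outcome and exposes the decomposition as fitted attributes
    (``nde_or_``, ``nie_or_``, ``te_or_``, ``proportion_mediated_``,
    ``sobel_z_``, ``sobel_p_``, ``conditions_``, ``result_``).  With
    ``bootstrap_reps > 0`` percentile CIs are attached.
    """

    def __init__(
        self,
        exposure: str = "z_meth",
        mediator: str = "z_area",
        covariates: Sequence[str] = (),
        grid_offsets: Sequence[float] = (0.0, -1.0),
        bootstrap_reps: int = 0,
        seed: int = 0,
        alpha: float = 0.05,
    ):
        self.exposure = exposure
        self.mediator = mediator
        self.covariates = covariates
        self.grid_offsets = grid_offsets
        self.bootstrap_reps = bootstrap_reps
        self.seed = seed
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "NaturalEffectsMediator":
        X = pd.DataFrame(X)
        data = X.copy()
        data["_outcome"] = np.asarray(y)
        if self.bootstrap_reps > 0:
            result = bootstrap_mediation(
                data, "_outcome", self.exposure, self.mediator,
                self.covariates, self.grid_offsets,
                reps=self.bootstrap_reps, seed=self.seed,
            )
        else:
            result = fit_natural_effects(
                data, "_outcome", self.exposure, self.mediator,
                self.covariates, self.grid_offsets,
            )
        paths = estimate_paths(
            data, "_outcome", self.exposure, self.mediator, self.covariates
        )
        self.result_ = result
        self.paths_ = paths
        self.conditions_ = check_mediation_conditions(paths, alpha=self.alpha)
        self.nde_or_ = result.nde_or
        self.nie_or_ = result.nie_or
        self.te_or_ = result.te_or
        self.proportion_mediated_ = result.proportion_mediated
        self.sobel_z_ = result.sobel_z
        self.sobel_p_ = result.sobel_p
        return self
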