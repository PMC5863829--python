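"""Association layer: standardization, descriptive comparison, adjusted
logistic/linear models and the correlation-block Bonferroni procedure.

Coefficients are made comparable across equations by fitting every model on
z-scores, ``z = (x - mu) / sigma``.  Logistic models report odds ratios per
SD increment with Wald confidence intervals; linear models report SD-unit
coefficients.  Multiple testing over correlated CpGs is handled by grouping
CpGs into correlation blocks (single linkage at |r| >= cutoff) and dividing
alpha by the number of blocks.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DEFAULT_COVARIATES",
    "DegenerateInputError",
    "ModelFitError",
    "StandardizedVariable",
    "RegressionResult",
    "BlockPartition",
    "Standardizer",
    "CorrelationBlockGrouper",
    "ellipse_area",
    "standardize",
    "compare_groups",
    "fit_logistic",
    "fit_linear",
    "association_scan",
    "correlation_blocks",
    "correlation_blocks_from_corr",
    "bonferroni_threshold",
]

#: confounders of the adjusted models: maternal age, education, family
#: income, ETS exposure during pregnancy, gestational age, newborn's sex
DEFAULT_COVARIATES = (
    "maternal_age",
    "education",
    "income_low",
    "ets_exposure",
    "gestational_age",
    "female",
)


class DegenerateInputError(ValueError):
    """Zero-variance or otherwise unusable model input."""


class ModelFitError(RuntimeError):
    """A regression failed to converge or the design is degenerate."""


def ellipse_area(major_axis: float, minor_axis: float) -> float:
    """Placental surface area from its axes: major * minor * pi / 4 (cm^2)."""
    major = np.asarray(major_axis, float)
    minor = np.asarray(minor_axis, float)
    if np.any(major <= 0) or np.any(minor <= 0):
        raise ValueError("ellipse axes must be positive")
    out = major * minor * math.pi / 4.0
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class StandardizedVariable:
    """z-scores with the mean/SD they were computed from."""

    values: pd.Series
    source_mean: float
    source_sd: float


def standardize(values: pd.Series | np.ndarray) -> StandardizedVariable:
    """z = (x - mean) / SD over non-missing entries (sample SD, ddof=1).

    Missing entries stay missing.  Raises :class:`DegenerateInputError` on
    fewer than two non-missing values or zero variance.
    """
    s = pd.Series(np.asarray(values, float)) if not isinstance(values, pd.Series) else values.astype(float)
    obs = s.dropna()
    if len(obs) < 2:
        raise DegenerateInputError("standardize needs >= 2 non-missing values")
    mu = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("cannot standardize a constant series")
    return StandardizedVariable(values=(s - mu) / sd, source_mean=mu, source_sd=sd)


class Standardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring transformer that preserves missing values.

    Unlike plain scalers it records per-column source means/SDs
    (``means_``, ``sds_``) with sample (ddof=1) SDs, errors on constant
    columns, and passes NaN through untouched — the conventions the
    association models rely on.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "Standardizer":
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.means_ = {}
        self.sds_ = {}
        for c in self.columns_:
            sv = standardize(X[c])
            self.means_[c] = sv.source_mean
            self.sds_[c] = sv.source_sd
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        out = X.copy()
        for c in self.columns_:
            out[c] = (X[c] - self.means_[c]) / self.sds_[c]
        return out


def compare_groups(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "case_status",
) -> pd.DataFrame:
    """Descriptive two-group comparison (cases vs controls).

    Continuous variables get group means (SD) and a pooled-variance two-sample
    t test; binary/categorical variables get counts (%) and a chi-squared test
    without continuity correction.  A variable with at most two distinct
    non-missing values is treated as categorical.
    """
    g1 = cohort[cohort[group_col] == 1]
    g0 = cohort[cohort[group_col] == 0]
    rows = []
    for var in variables:
        if var not in cohort.columns:
            raise KeyError(f"variable {var!r} not in cohort")
        x1 = g1[var].dropna()
        x0 = g0[var].dropna()
        categorical = cohort[var].dropna().nunique() <= 2
        if categorical:
            table = np.array(
                [[(x1 == 1).sum(), (x1 == 0).sum()], [(x0 == 1).sum(), (x0 == 0).sum()]],
                float,
            )
            if table.sum() == 0 or (table.sum(axis=0) == 0).any():
                stat, p = np.nan, np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                {
                    "variable": var,
                    "kind": "categorical",
                    "cases": f"{int((x1 == 1).sum())} ({100 * (x1 == 1).mean():.2f})",
                    "controls": f"{int((x0 == 1).sum())} ({100 * (x0 == 1).mean():.2f})",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
        else:
            stat, p = stats.ttest_ind(x1, x0, equal_var=True)
            rows.append(
                {
                    "variable": var,
                    "kind": "continuous",
                    "cases": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
                    "controls": f"{x0.mean():.2f} ({x0.std(ddof=1):.2f})",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RegressionResult:
    """One fitted model term."""

    term: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    family: str  # 'logistic' or 'linear'
    covariates: tuple[str, ...]

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise AttributeError("odds_ratio is defined for logistic fits only")
        return math.exp(self.coefficient)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _design(terms: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(terms).astype(float)
    for c in X.columns:
        if X[c].nunique(dropna=True) <= 1:
            raise DegenerateInputError(f"predictor {c!r} is constant")
    return sm.add_constant(X, has_constant="add")


def _results_from_fit(res, terms, n, family, covariates, alpha=0.05):
    z = stats.norm.ppf(1 - alpha / 2)
    out = {}
    for term in terms:
        coef = float(res.params[term])
        se = float(res.bse[term])
        out[term] = RegressionResult(
            term=term,
            coefficient=coef,
            se=se,
            ci_low=coef - z * se,
            ci_high=coef + z * se,
            p_value=float(res.pvalues[term]),
            n=n,
            family=family,
            covariates=tuple(covariates),
        )
    return out


def fit_logistic(
    outcome: pd.Series,
    terms: pd.DataFrame,
    alpha: float = 0.05,
    maxiter: int = 100,
    tol: float = 1e-8,
    return_intercept: bool = False,
) -> dict[str, RegressionResult]:
    """Adjusted logistic regression by IRLS (via a binomial GLM).

    Returns a per-term :class:`RegressionResult` with Wald CIs and p-values;
    ``odds_ratio`` is exp(coefficient).  Convergence: relative deviance
    change below ``tol`` within ``maxiter`` iterations.  The outcome may be
    fractional in [0, 1] (used by the natural-effects imputation fit).
    """
    y = np.asarray(outcome, float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values; restrict to complete cases")
    if y.min() < 0 or y.max() > 1:
        raise ValueError("logistic outcome must lie in [0, 1]")
    X = _design(terms)
    if len(y) < X.shape[1] + 1:
        raise DegenerateInputError("fewer complete-case rows than model terms + 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
    if not res.converged:
        raise ModelFitError(
            f"logistic fit did not converge in {maxiter} IRLS iterations "
            f"(terms: {list(terms.columns)})"
        )
    slopes = res.params.drop("const", errors="ignore")
    if len(slopes) and slopes.abs().max() > 15:
        raise ModelFitError(
            "logistic fit suggests complete separation (|coefficient| > 15 "
            f"for {slopes.abs().idxmax()!r})"
        )
    keys = list(terms.columns) + (["const"] if return_intercept else [])
    return _results_from_fit(res, keys, len(y), "logistic",
                             terms.columns, alpha)


def fit_linear(
    response: pd.Series, terms: pd.DataFrame, alpha: float = 0.05
) -> dict[str, RegressionResult]:
    """Ordinary least squares with Wald (normal) CIs per term."""
    y = np.asarray(response, float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values; restrict to complete cases")
    X = _design(terms)
    if len(y) <= X.shape[1]:
        raise DegenerateInputError("need more complete-case rows than terms")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ModelFitError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    return _results_from_fit(res, terms.columns, len(y), "linear",
                             terms.columns, alpha)


def _stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=df.index)
    if stratum == "girls":
        return df["female"] == 1
    if stratum == "boys":
        return df["female"] == 0
    raise ValueError(f"unknown stratum {stratum!r}")


def association_scan(
    beta_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    strata: Sequence[str] = ("all", "girls", "boys"),
    drop_ets: bool = False,
    exclude_alcohol: bool = False,
    standardize_scope: str = "qc_valid",
) -> pd.DataFrame:
    """Per-CpG adjusted association models, optionally stratified by sex.

    For every QC-retained CpG and stratum, fits the adjusted logistic model
    FT-LBW ~ z-methylation + covariates and the adjusted linear model
    z-area ~ z-methylation + covariates.  Within sex strata the sex covariate
    is dropped; sensitivity toggles drop the ETS covariate or exclude
    alcohol-exposed subjects.  Methylation and area are standardized over all
    QC-valid samples for that variable before the model-specific
    complete-case restriction (``standardize_scope='per_model'`` re-scales
    within each model sample instead).

    Returns a tidy frame with columns (cpg, stratum, model, n, coefficient,
    se, or, ci_low, ci_high, p, note); CIs are on the OR scale for logistic
    rows and on the coefficient scale for linear rows.
    """
    if standardize_scope not in {"qc_valid", "per_model"}:
        raise ValueError("standardize_scope must be 'qc_valid' or 'per_model'")
    df = cohort.set_index("subject_id", drop=False)
    df = df.join(beta_wide, how="left")
    if exclude_alcohol:
        df = df[df["alcohol_use"] == 0]

    rows = []
    for cpg in beta_wide.columns:
        for stratum in strata:
            covs = [c for c in covariates if not (drop_ets and c == "ets_exposure")]
            if stratum in ("girls", "boys"):
                covs = [c for c in covs if c != "female"]
            sub = df[_stratum_mask(df, stratum)]

            if standardize_scope == "qc_valid":
                try:
                    z_meth = standardize(sub[cpg]).values
                    z_area = standardize(sub["placental_area"]).values
                except DegenerateInputError as exc:
                    rows.append(_scan_failure(cpg, stratum, "both", str(exc)))
                    continue
            else:
                z_meth = sub[cpg]
                z_area = sub["placental_area"]

            work = sub[["case_status"] + covs].copy()
            work["z_meth"] = z_meth
            work["z_area"] = z_area

            # logistic: FT-LBW ~ z-methylation + covariates
            cc = work.dropna(subset=["case_status", "z_meth"] + covs)
            rows.append(
                _scan_fit(
                    cpg, stratum, "logistic", cc, covs, standardize_scope
                )
            )
            # linear: z-area ~ z-methylation + covariates
            cc = work.dropna(subset=["z_area", "z_meth"] + covs)
            rows.append(
                _scan_fit(cpg, stratum, "linear", cc, covs, standardize_scope)
            )
    return pd.DataFrame(rows)


def _scan_failure(cpg, stratum, model, note):
    return {
        "cpg": cpg, "stratum": stratum, "model": model, "n": 0,
        "coefficient": np.nan, "se": np.nan, "or": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "note": note,
    }


def _scan_fit(cpg, stratum, model, cc, covs, scope):
    try:
        terms = cc[["z_meth"] + covs]
        if scope == "per_model":
            cc = cc.copy()
            cc["z_meth"] = standardize(cc["z_meth"]).values
            if model == "linear":
                cc["z_area"] = standardize(cc["z_area"]).values
            terms = cc[["z_meth"] + covs]
        if model == "logistic":
            res = fit_logistic(cc["case_status"], terms)["z_meth"]
            or_, (lo, hi) = res.odds_ratio, res.or_ci
        else:
            res = fit_linear(cc["z_area"], terms)["z_meth"]
            or_, lo, hi = np.nan, res.ci_low, res.ci_high
        return {
            "cpg": cpg, "stratum": stratum, "model": model, "n": res.n,
            "coefficient": res.coefficient, "se": res.se, "or": or_,
            "ci_low": lo, "ci_high": hi, "p": res.p_value, "note": "",
        }
    except (DegenerateInputError, ModelFitError, ValueError) as exc:
        return _scan_failure(cpg, stratum, model, str(exc))


@dataclasses.dataclass
class BlockPartition:
    """Disjoint CpG blocks grouped by pairwise correlation."""

    blocks: list[list[str]]
    cutoff: float

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "blocks": self.blocks}


def correlation_blocks_from_corr(
    corr: pd.DataFrame, cutoff: float = 0.30
) -> BlockPartition:
    """Single-linkage grouping of variables with pairwise |r| >= cutoff."""
    names = list(corr.columns)
    r = corr.to_numpy(float).copy()
    np.fill_diagonal(r, 0.0)
    adjacency = csr_matrix((np.abs(np.nan_to_num(r)) >= cutoff).astype(int))
    n_comp, labels = connected_components(adjacency, directed=False)
    blocks = [sorted(np.array(names)[labels == k].tolist()) for k in range(n_comp)]
    blocks.sort(key=lambda b: names.index(b[0]) if b else 0)
    return BlockPartition(blocks=blocks, cutoff=cutoff)


def correlation_blocks(
    beta_matrix: pd.DataFrame, cutoff: float = 0.30
) -> BlockPartition:
    """Pairwise-complete Pearson correlations, then single-linkage blocks.

    CpGs with fewer than 3 pairwise-complete observations against every other
    CpG trigger an isolated-block warning and form singleton blocks.
    """
    if beta_matrix.shape[1] < 2:
        raise ValueError("need at least 2 CpGs to form correlation blocks")
    corr = beta_matrix.corr(method="pearson", min_periods=3)
    off_diag = corr.where(~np.eye(len(corr), dtype=bool))
    isolated = off_diag.columns[off_diag.isna().all(axis=0)]
    if len(isolated):
        warnings.warn(
            f"CpGs with <3 pairwise-complete observations form isolated "
            f"blocks: {list(isolated)}",
            UserWarning,
            stacklevel=2,
        )
    return correlation_blocks_from_corr(corr, cutoff)


class CorrelationBlockGrouper(BaseEstimator):
    """Clusterer-style wrapper around :func:`correlation_blocks`.

    ``fit(X)`` on a samples × CpGs β matrix exposes ``labels_`` (block index
    per column), ``blocks_`` and ``partition_``.
    """

    def __init__(self, cutoff: float = 0.30):
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationBlockGrouper":
        X = pd.DataFrame(X)
        self.partition_ = correlation_blocks(X, cutoff=self.cutoff)
        self.blocks_ = self.partition_.blocks
        block_of = {c: k for k, b in enumerate(self.blocks_) for c in b}
        self.labels_ = np.array([block_of[c] for c in X.columns])
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_


def bonferroni_threshold(
    partition: BlockPartition | int, alpha: float = 0.05
) -> float:
    """alpha divided by the number of independent correlation blocks."""
    n_blocks = partition if isinstance(partition, int) else partition.n_blocks
    if n_blocks < 1:
        raise ValueError("partition has no blocks")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_blocks
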