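"""Synthetic cohort and EpiTYPER-style plate generation.

The generator draws, in a fixed documented order, (1) maternal and fetal
covariates, (2) latent standardized CpG methylation with a block correlation
structure, (3) the standardized placental surface area as a linear structural
equation in methylation and covariates, (4) the binary full-term low birth
weight outcome from a logistic model, and (5) the geometric back-transform of
area into elliptical axes.  Because every structural coefficient is known,
downstream estimators can be checked against closed-form truths
(:func:`true_effects`).

Draw order (one ``numpy.random.default_rng(seed)`` stream):

1. covariates: maternal_age, education, income_low, ets_exposure,
   alcohol_use, parity, gestational_age, female (one vector each);
2. latent CpG z-scores (one multivariate normal draw);
3. mediator residual;
4. outcome uniforms;
5. placental aspect ratios;
6. placental weight noise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .params import AssayParams, GenerativeParams

__all__ = [
    "TrueEffects",
    "MethylationPlateSet",
    "generate_cohort",
    "subsample_case_control",
    "generate_epityper_plates",
    "true_effects",
    "COHORT_COLUMNS",
]

#: observable cohort columns (latent ``z_meth_*`` / ``beta_*`` columns follow)
COHORT_COLUMNS = [
    "subject_id",
    "case_status",
    "female",
    "maternal_age",
    "education",
    "income_low",
    "ets_exposure",
    "alcohol_use",
    "gestational_age",
    "parity",
    "placental_major_axis",
    "placental_minor_axis",
    "placental_area",
    "placental_weight",
]

# marginal covariate distributions (Table-1-like dichotomies and scales)
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 28.0, 5.0, 18.0, 45.0
_GA_MEAN, _GA_SD, _GA_LO, _GA_HI = 38.0, 0.97, 37.0, 42.0
_P_EDUCATION = 0.41
_P_INCOME_LOW = 0.55
_P_ETS = 0.30
_P_ALCOHOL = 0.04
_P_PARITY = 0.73


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _zscale(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (values - mean) / sd


def covariate_z_moments() -> dict[str, tuple[float, float]]:
    """Theoretical (mean, SD) used to standardize covariates inside the
    structural equations, so covariate coefficients are per-SD effects."""
    age = _truncnorm(_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI)
    ga = _truncnorm(_GA_MEAN, _GA_SD, _GA_LO, _GA_HI)

    def bern(p: float) -> tuple[float, float]:
        return p, math.sqrt(p * (1 - p))

    return {
        "maternal_age": (float(age.mean()), float(age.std())),
        "gestational_age": (float(ga.mean()), float(ga.std())),
        "education": bern(_P_EDUCATION),
        "income_low": bern(_P_INCOME_LOW),
        "ets_exposure": bern(_P_ETS),
        "female": (0.0, 1.0),  # resolved per-params from girl_fraction
    }


def generate_cohort(params: GenerativeParams) -> pd.DataFrame:
    """Generate a cohort of mother–baby records with known causal structure.

    Returns one row per subject with observable covariates, placental
    measures and the FT-LBW flag, plus latent columns ``z_meth_<cpg>``
    (standardized methylation), ``beta_<cpg>`` (true methylation fraction)
    and ``z_area_latent`` used by the assay simulator and by oracle tests.
    Identical params (including seed) give identical tables.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    cpgs = list(params.cpg_ids)

    if n == 0:
        cols = COHORT_COLUMNS + [f"z_meth_{c}" for c in cpgs] + [
            f"beta_{c}" for c in cpgs
        ] + ["z_area_latent"]
        return pd.DataFrame(columns=cols)

    # 1. covariates (fixed order)
    age_dist = _truncnorm(_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI)
    maternal_age = age_dist.ppf(rng.uniform(size=n))
    education = rng.uniform(size=n) < _P_EDUCATION
    income_low = rng.uniform(size=n) < _P_INCOME_LOW
    ets = rng.uniform(size=n) < _P_ETS
    alcohol = rng.uniform(size=n) < _P_ALCOHOL
    parity = rng.uniform(size=n) < _P_PARITY
    ga_dist = _truncnorm(_GA_MEAN, _GA_SD, _GA_LO, _GA_HI)
    gestational_age = ga_dist.ppf(rng.uniform(size=n))
    female = rng.uniform(size=n) < params.girl_fraction

    # 2. latent CpG z-scores with the block correlation structure
    corr = params.cpg_block_corr.matrix(cpgs)
    z_meth = rng.multivariate_normal(
        np.zeros(len(cpgs)), corr, size=n, method="cholesky"
    )

    # standardized covariates for the structural equations
    moments = covariate_z_moments()
    pg = params.girl_fraction
    sd_female = math.sqrt(pg * (1 - pg)) if 0 < pg < 1 else 1.0
    z_cov = {
        "maternal_age": _zscale(maternal_age, *moments["maternal_age"]),
        "education": _zscale(education.astype(float), _P_EDUCATION,
                             math.sqrt(_P_EDUCATION * (1 - _P_EDUCATION))),
        "income_low": _zscale(income_low.astype(float), _P_INCOME_LOW,
                              math.sqrt(_P_INCOME_LOW * (1 - _P_INCOME_LOW))),
        "ets_exposure": _zscale(ets.astype(float), _P_ETS,
                                math.sqrt(_P_ETS * (1 - _P_ETS))),
        "gestational_age": _zscale(gestational_age, *moments["gestational_age"]),
        "female": _zscale(female.astype(float), pg, sd_female),
    }

    # 3. mediator: standardized placental surface area
    z_causal = z_meth[:, cpgs.index(params.causal_cpg)]
    eta_m = params.beta1 * z_causal
    for name, eff in params.covariate_effects.items():
        if eff.on_mediator and name in z_cov:
            eta_m = eta_m + eff.on_mediator * z_cov[name]
    z_area = eta_m + rng.normal(0.0, params.resolved_mediator_residual_sd(), size=n)

    # 4. outcome
    eta_y = params.prevalence_intercept + params.theta1_prime * z_causal
    eta_y = eta_y + params.theta2 * z_area
    for name, eff in params.covariate_effects.items():
        if eff.on_outcome and name in z_cov:
            eta_y = eta_y + eff.on_outcome * z_cov[name]
    case = rng.uniform(size=n) < expit(eta_y)

    # 5. area in cm^2, decomposed into elliptical axes; the stored area is
    # recomputed from the rounded axes so the ellipse identity holds exactly
    area = np.maximum(params.area_mean + params.area_sd * z_area, 60.0)
    ratio_dist = _truncnorm(1.08, 0.04, 1.0, 1.30)
    ratio = ratio_dist.ppf(rng.uniform(size=n))
    major = np.round(np.sqrt(4.0 * area * ratio / math.pi), 2)
    minor = np.round(major / ratio, 2)
    area_stored = major * minor * math.pi / 4.0

    # 6. placental weight, correlated with area
    weight = np.round(0.6 * area + 320.0 + rng.normal(0.0, 45.0, size=n), 1)
    weight = np.maximum(weight, 200.0)

    out = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "case_status": case.astype(int),
            "female": female.astype(int),
            "maternal_age": np.round(maternal_age, 1),
            "education": education.astype(int),
            "income_low": income_low.astype(int),
            "ets_exposure": ets.astype(int),
            "alcohol_use": alcohol.astype(int),
            "gestational_age": np.round(gestational_age, 1),
            "parity": parity.astype(int),
            "placental_major_axis": major,
            "placental_minor_axis": minor,
            "placental_area": area_stored,
            "placental_weight": weight,
        }
    )
    # latent methylation fractions are kept Gaussian; values straying past
    # [0, 1] in the tails are clipped only at measurement time, where the
    # assay's detection limits (and QC censoring) apply
    for j, c in enumerate(cpgs):
        out[f"z_meth_{c}"] = z_meth[:, j]
        out[f"beta_{c}"] = params.cpg_means[c] + params.cpg_sds[c] * z_meth[:, j]
    out["z_area_latent"] = z_area
    return out


def subsample_case_control(
    cohort: pd.DataFrame, n_cases: int, n_controls: int, seed: int
) -> pd.DataFrame:
    """Draw a case-control sample (e.g. 86 cases vs 79 controls) from a
    generated cohort.  The returned frame records the sampling regime in
    ``attrs['sampling_regime']``."""
    rng = np.random.default_rng(seed)
    cases = cohort.index[cohort["case_status"] == 1].to_numpy()
    controls = cohort.index[cohort["case_status"] == 0].to_numpy()
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"cohort holds {len(cases)} cases / {len(controls)} controls; "
            f"requested {n_cases}/{n_controls}"
        )
    idx = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    out = cohort.loc[idx].reset_index(drop=True)
    out.attrs["sampling_regime"] = "case-control"
    return out


@dataclasses.dataclass
class MethylationPlateSet:
    """Batched EpiTYPER-style readouts in long format.

    ``entries`` columns: sample_id, cpg_id, batch_id, beta (NaN = poor
    readout), is_repeat, is_conversion_control.  ``case_status`` maps
    sample_id to the FT-LBW flag.  ``injections`` is the generator's ledger
    of deliberately corrupted entries (kind in {missing, censored_low,
    censored_high}) against which QC recovery is tested.
    """

    entries: pd.DataFrame
    case_status: pd.Series
    injections: pd.DataFrame

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def _measure(
    latent: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    if noise_sd == 0:
        return np.clip(latent, 0.0, 1.0)
    return np.clip(latent + rng.normal(0.0, noise_sd, size=latent.shape), 0.0, 1.0)


def generate_epityper_plates(
    cohort: pd.DataFrame,
    assay: AssayParams,
    cpg_ids: list[str],
    seed: int = 0,
    fragment_split: dict[str, tuple[str, str]] | None = None,
) -> MethylationPlateSet:
    """Simulate plate-batched methylation readouts for a cohort.

    Samples are interleaved case/control and chunked into plates of
    ``assay.batch_size`` (half cases, half controls whenever counts allow).
    Each plate re-measures ``repeat_per_batch`` random samples and carries
    one conversion-control entry.  ``fragment_split`` maps a composite CpG to
    the two CG-containing fragments it is measured as (each fragment gets
    independent noise); QC later averages them back.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if not cpg_ids:
        raise ValueError("cpg_ids is empty")
    missing_latent = [c for c in cpg_ids if f"beta_{c}" not in cohort.columns]
    if missing_latent:
        raise ValueError(f"cohort lacks latent beta columns for {missing_latent}")

    rng = np.random.default_rng(seed)

    # interleave cases and controls so plates are balanced
    cases = cohort.index[cohort["case_status"] == 1].tolist()
    controls = cohort.index[cohort["case_status"] == 0].tolist()
    order: list[int] = []
    i = j = 0
    while i < len(cases) or j < len(controls):
        if i < len(cases):
            order.append(cases[i])
            i += 1
        if j < len(controls):
            order.append(controls[j])
            j += 1

    # measured columns: composite CpGs optionally split into fragments
    fragment_split = fragment_split or {}
    measured: list[tuple[str, str]] = []  # (emitted cpg_id, latent source cpg)
    for c in cpg_ids:
        if c in fragment_split:
            fa, fb = fragment_split[c]
            measured.extend([(fa, c), (fb, c)])
        else:
            measured.append((c, c))

    n_batches = math.ceil(len(order) / assay.batch_size)
    rows: list[dict] = []
    injections: list[dict] = []
    noise = assay.measurement_noise_sd

    for b in range(n_batches):
        batch_id = f"plate{b + 1:03d}"
        members = order[b * assay.batch_size : (b + 1) * assay.batch_size]
        sample_ids = cohort.loc[members, "subject_id"].to_numpy()

        for emitted, source in measured:
            latent = cohort.loc[members, f"beta_{source}"].to_numpy(float)
            beta = _measure(latent, noise, rng)
            miss = rng.uniform(size=len(members)) < assay.missing_rate
            inject = rng.uniform(size=len(members)) < assay.censor_inject_rate
            low_tail = rng.uniform(size=len(members)) < 0.5
            for k, sid in enumerate(sample_ids):
                val: float = beta[k]
                if miss[k]:
                    val = np.nan
                    injections.append(
                        {"sample_id": sid, "cpg_id": emitted, "kind": "missing"}
                    )
                elif inject[k]:
                    if low_tail[k]:
                        val = float(rng.uniform(0.0, 0.0499))
                        kind = "censored_low"
                    else:
                        val = float(rng.uniform(0.9501, 1.0))
                        kind = "censored_high"
                    injections.append(
                        {"sample_id": sid, "cpg_id": emitted, "kind": kind}
                    )
                rows.append(
                    {
                        "sample_id": sid,
                        "cpg_id": emitted,
                        "batch_id": batch_id,
                        "beta": val,
                        "is_repeat": False,
                        "is_conversion_control": False,
                    }
                )

        # one (or more) random in-plate samples re-measured as repeats
        n_rep = min(assay.repeat_per_batch, len(members))
        if n_rep > 0:
            rep_members = rng.choice(members, size=n_rep, replace=False)
            for m in rep_members:
                sid = cohort.at[m, "subject_id"]
                for emitted, source in measured:
                    latent1 = np.array([cohort.at[m, f"beta_{source}"]], float)
                    rows.append(
                        {
                            "sample_id": sid,
                            "cpg_id": emitted,
                            "batch_id": batch_id,
                            "beta": float(_measure(latent1, noise, rng)[0]),
                            "is_repeat": True,
                            "is_conversion_control": False,
                        }
                    )

        lo, hi = assay.conversion_efficiency_range
        rows.append(
            {
                "sample_id": f"CTRL-{batch_id}",
                "cpg_id": "conversion_control",
                "batch_id": batch_id,
                "beta": float(rng.uniform(lo, hi)),
                "is_repeat": False,
                "is_conversion_control": True,
            }
        )

    entries = pd.DataFrame(rows)
    case_status = pd.Series(
        cohort["case_status"].to_numpy(), index=cohort["subject_id"].to_numpy()
    )
    return MethylationPlateSet(
        entries=entries,
        case_status=case_status,
        injections=pd.DataFrame(injections, columns=["sample_id", "cpg_id", "kind"]),
    )


@dataclasses.dataclass(frozen=True)
class TrueEffects:
    """Closed-form rare-outcome effects implied by the generative params."""

    nde_or: float
    nie_or: float
    te_or: float
    proportion_mediated: float  # percent


def true_effects(
    params: GenerativeParams, max_prevalence: float = 0.10
) -> TrueEffects:
    """Rare-outcome closed forms: NDE = exp(theta1'), NIE = exp(beta1*theta2),
    TE = NDE*NIE, proportion mediated = 100*ln(NIE)/ln(TE).

    Valid only when the outcome is rare; the baseline prevalence implied by
    the intercept must be below ``max_prevalence`` (default 10%).
    """
    base = float(expit(params.prevalence_intercept))
    if base >= max_prevalence:
        raise ValueError(
            f"baseline prevalence {base:.3f} exceeds the rare-outcome bound "
            f"{max_prevalence}; OR-scale closed forms are not valid"
        )
    nde = math.exp(params.theta1_prime)
    nie = math.exp(params.beta1 * params.theta2)
    te = nde * nie
    if math.isclose(te, 1.0, abs_tol=1e-12):
        if math.isclose(nie, 1.0, abs_tol=1e-12):
            prop = 0.0
        else:
            raise ValueError("total effect is null but NIE is not: proportion undefined")
    else:
        prop = 100.0 * math.log(nie) / math.log(te)
    return TrueEffects(nde_or=nde, nie_or=nie, te_or=te, proportion_mediated=prop)
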