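"""Parameter models for the synthetic cohort and assay simulators.

The generative model mirrors a case-control study of full-term low birth
weight (FT-LBW): placental CpG methylation (exposure) acts on the outcome
both directly and through placental surface area (mediator).  All structural
coefficients are expressed on standardized (z-score) scales:

* ``theta1_prime`` — direct-path log odds ratio per SD of methylation,
* ``theta2``       — log odds ratio per SD of placental surface area,
* ``beta1``        — SD change in area per SD of methylation.

Parameters are pydantic models so that JSON configs are schema-validated on
load (:func:`GenerativeParams.from_json` / :meth:`to_json`).
"""

from __future__ import annotations

import json
import math
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CPG_IDS",
    "CAUSAL_CPG",
    "BlockCorrelation",
    "CovariateEffect",
    "GenerativeParams",
    "AssayParams",
]

#: the five analysis units retained by the assay design ("CpG 3.4" is a
#: composite of two CG-containing fragments averaged at QC time)
CPG_IDS = ("CpG 2", "CpG 3.4", "CpG 5", "CpG 7", "CpG 11")

#: the CpG that carries the causal effect in the default generative model
CAUSAL_CPG = "CpG 11"


class BlockCorrelation(BaseModel):
    """Correlation structure of the latent CpG z-scores.

    CpGs are grouped into named blocks; every pair within a block shares the
    block's correlation, and every cross-block pair shares ``between``.
    """

    model_config = ConfigDict(frozen=True)

    blocks: Mapping[str, tuple[str, ...]] = Field(
        default={"A": ("CpG 2", "CpG 3.4"), "B": ("CpG 5", "CpG 7", "CpG 11")}
    )
    within: Mapping[str, float] = Field(default={"A": 0.66, "B": 0.45})
    between: float = 0.10

    @model_validator(mode="after")
    def _check(self) -> "BlockCorrelation":
        seen: set[str] = set()
        for name, members in self.blocks.items():
            if name not in self.within:
                raise ValueError(f"no within-block correlation for block {name!r}")
            if not -1.0 <= self.within[name] <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"CpGs assigned to two blocks: {sorted(overlap)}")
            seen.update(members)
        if not -1.0 <= self.between <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
        return self

    @property
    def cpg_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for members in self.blocks.values():
            out.extend(members)
        return tuple(out)

    def matrix(self, cpg_ids: Sequence[str]) -> np.ndarray:
        """Correlation matrix for ``cpg_ids``; raises if not positive
        semi-definite."""
        block_of = {c: name for name, members in self.blocks.items() for c in members}
        unknown = [c for c in cpg_ids if c not in block_of]
        if unknown:
            raise ValueError(f"CpGs without a block assignment: {unknown}")
        k = len(cpg_ids)
        corr = np.full((k, k), self.between)
        for i, ci in enumerate(cpg_ids):
            for j, cj in enumerate(cpg_ids):
                if i == j:
                    corr[i, j] = 1.0
                elif block_of[ci] == block_of[cj]:
                    corr[i, j] = self.within[block_of[ci]]
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"implied CpG correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )
        return corr


class CovariateEffect(BaseModel):
    """Structural coefficients of one covariate, on its standardized scale.

    ``on_mediator`` is the SD-area change per SD of the covariate;
    ``on_outcome`` is the log odds ratio per SD of the covariate.
    """

    model_config = ConfigDict(frozen=True)

    on_mediator: float = 0.0
    on_outcome: float = 0.0


def _default_covariate_effects() -> dict[str, CovariateEffect]:
    # Modest, epidemiologically plausible nuisance effects: social covariates
    # act on the outcome; gestational age and fetal sex act on placental size.
    return {
        "maternal_age": CovariateEffect(on_mediator=0.0, on_outcome=-0.05),
        "education": CovariateEffect(on_mediator=0.0, on_outcome=-0.25),
        "income_low": CovariateEffect(on_mediator=0.0, on_outcome=0.25),
        "ets_exposure": CovariateEffect(on_mediator=0.0, on_outcome=0.20),
        "gestational_age": CovariateEffect(on_mediator=0.15, on_outcome=0.0),
        "female": CovariateEffect(on_mediator=-0.05, on_outcome=0.05),
    }


class GenerativeParams(BaseModel):
    """True path coefficients and nuisance parameters of the synthetic cohort.

    Defaults reproduce the headline mediation structure: direct-path log-OR
    ``ln 1.41 = 0.3436``, area log-OR ``ln 0.43 = -0.8440`` and mediator path
    ``beta1 = -0.3816`` so that the indirect effect is
    ``exp(beta1 * theta2) = 1.38`` and the log-scale proportion mediated is
    48.4%.  The intercept gives a marginal outcome prevalence near 5%, the
    rare-outcome regime in which odds-ratio mediation formulas are valid.
    """

    model_config = ConfigDict(frozen=True)

    n_subjects: int = Field(default=165, ge=0)
    prevalence_intercept: float = -3.46  # marginal prevalence ~5% under defaults
    theta1_prime: float = 0.3436
    theta2: float = -0.8440
    beta1: float = -0.3816
    covariate_effects: Mapping[str, CovariateEffect] = Field(
        default_factory=_default_covariate_effects
    )
    cpg_means: Mapping[str, float] = Field(
        default={
            "CpG 2": 0.36,
            "CpG 3.4": 0.365,
            "CpG 5": 0.48,
            "CpG 7": 0.185,
            "CpG 11": 0.37,
        }
    )
    cpg_sds: Mapping[str, float] = Field(
        default={
            "CpG 2": 0.21,
            "CpG 3.4": 0.08,
            "CpG 5": 0.13,
            "CpG 7": 0.12,
            "CpG 11": 0.10,
        }
    )
    cpg_block_corr: BlockCorrelation = Field(default_factory=BlockCorrelation)
    #: residual SD of the standardized mediator; None completes the structural
    #: variance to exactly 1 so the generated z-area has unit marginal variance
    mediator_residual_sd: float | None = None
    girl_fraction: float = Field(default=0.588, ge=0.0, le=1.0)
    causal_cpg: str = CAUSAL_CPG
    #: cm^2 scale used to back-transform the standardized area
    area_mean: float = 274.8
    area_sd: float = 58.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GenerativeParams":
        for cpg, m in self.cpg_means.items():
            if not 0.0 < m < 1.0:
                raise ValueError(f"cpg_means[{cpg!r}]={m} must lie in (0, 1)")
        for cpg, s in self.cpg_sds.items():
            if s <= 0:
                raise ValueError(f"cpg_sds[{cpg!r}]={s} must be > 0")
        if set(self.cpg_means) != set(self.cpg_sds):
            raise ValueError("cpg_means and cpg_sds must cover the same CpGs")
        if self.causal_cpg not in self.cpg_means:
            raise ValueError(f"causal_cpg {self.causal_cpg!r} has no mean/SD")
        if self.mediator_residual_sd is not None and self.mediator_residual_sd <= 0:
            raise ValueError("mediator_residual_sd must be > 0")
        # fails fast on a non-PSD correlation structure
        self.cpg_block_corr.matrix(self.cpg_ids)
        if self.resolved_mediator_residual_sd() <= 0:
            raise ValueError(
                "structural coefficients leave no residual mediator variance; "
                "set mediator_residual_sd explicitly"
            )
        return self

    @property
    def cpg_ids(self) -> tuple[str, ...]:
        return tuple(self.cpg_means)

    def mediator_structural_variance(self) -> float:
        """Variance of the deterministic part of the standardized mediator."""
        var = self.beta1**2
        var += sum(e.on_mediator**2 for e in self.covariate_effects.values())
        return var

    def resolved_mediator_residual_sd(self) -> float:
        if self.mediator_residual_sd is not None:
            return self.mediator_residual_sd
        return math.sqrt(max(1.0 - self.mediator_structural_variance(), 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "GenerativeParams":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


class AssayParams(BaseModel):
    """Plate-level measurement model of an EpiTYPER-style assay.

    Each plate holds ``batch_size`` samples composed half of cases and half
    of controls, carries ``repeat_per_batch`` re-measured samples and one
    bisulfite conversion-control entry.  Readouts are the latent methylation
    fractions plus Gaussian noise clipped to [0, 1], with missingness at
    ``missing_rate`` and a small fraction of values pushed into the
    detection-limit tails (< 0.05 or > 0.95) so downstream censoring rules
    are exercised.
    """

    model_config = ConfigDict(frozen=True)

    batch_size: int = Field(default=24, ge=2)
    repeat_per_batch: int = Field(default=1, ge=0)
    conversion_efficiency_range: tuple[float, float] = (0.985, 0.999)
    missing_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    #: technical replicate SD consistent with repeat-pair concordance
    #: (|Δβ| < 0.05) holding across plates
    measurement_noise_sd: float = Field(default=0.01, ge=0.0)
    censor_inject_rate: float = Field(default=0.02, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "AssayParams":
        lo, hi = self.conversion_efficiency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("conversion_efficiency_range must be within [0, 1]")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "AssayParams":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))
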