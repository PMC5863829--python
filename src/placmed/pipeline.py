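"""End-to-end pipeline: simulate → QC → associate → mediate.

``run_pipeline`` executes the stages in order, persists every intermediate
artifact under the output directory, and triggers mediation only for
CpG × stratum combinations whose adjusted logistic scan p-value passes the
correlation-block-corrected threshold (discovery tier); within the mediation
stage the stepwise conditions are tested at their own alpha (default 0.05).
A fixed global seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .association import (
    DEFAULT_COVARIATES,
    association_scan,
    bonferroni_threshold,
    compare_groups,
    correlation_blocks,
    standardize,
)
from .mediation import (
    bootstrap_mediation,
    check_mediation_conditions,
    estimate_paths,
    fit_natural_effects,
    path_diagram,
)
from .params import AssayParams, GenerativeParams
from .qc import QCThresholds, run_qc
from .simulate import generate_cohort, generate_epityper_plates, subsample_case_control

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline"]

log = logging.getLogger("placmed")

#: composite CpG units measured as two CG-containing fragments
DEFAULT_FRAGMENT_MAP = {"CpG 3.4": ("CpG 3a", "CpG 3b")}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class PipelineConfig(BaseModel):
    """Schema-validated configuration of a full run."""

    model_config = ConfigDict(frozen=True)

    generator: GenerativeParams = Field(default_factory=GenerativeParams)
    assay: AssayParams = Field(default_factory=AssayParams)
    qc: QCThresholds = Field(default_factory=QCThresholds)
    cohort_path: str | None = None  # load instead of simulate when set
    plates_path: str | None = None
    case_control: tuple[int, int] | None = None  # (n_cases, n_controls)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    strata: tuple[str, ...] = ("all", "girls", "boys")
    drop_ets: bool = False
    exclude_alcohol: bool = False
    scan_alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    block_cutoff: float = 0.30
    mediation_alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    bootstrap_reps: int = Field(default=1000, ge=0)
    split_fragments: bool = True
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


@dataclasses.dataclass
class RunReport:
    """Artifacts and summaries of one pipeline run."""

    config_hash: str
    version: str
    qc: dict
    descriptives: pd.DataFrame
    scan: pd.DataFrame
    blocks: dict
    threshold: float
    triggered: list[dict]
    mediation: list[dict]
    outdir: str

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "qc": self.qc,
            "descriptives": self.descriptives.to_dict(orient="records"),
            "scan": self.scan.to_dict(orient="records"),
            "blocks": self.blocks,
            "significance_threshold": self.threshold,
            "mediation_triggered": self.triggered,
            "mediation": self.mediation,
            "outdir": self.outdir,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, outdir: Path):
    from .io import read_cohort, write_cohort

    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    else:
        params = config.generator.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(params)
        if config.case_control:
            n_cases, n_controls = config.case_control
            cohort = subsample_case_control(
                cohort, n_cases, n_controls, seed=config.seed + 1
            )
    write_cohort(cohort, outdir / "cohort.csv")
    return cohort


@_stage("plates")
def _plates(config: PipelineConfig, cohort, outdir: Path):
    from .io import read_beta_matrix, write_plates

    if config.plates_path:
        case = pd.Series(
            cohort["case_status"].to_numpy(), index=cohort["subject_id"].to_numpy()
        )
        return read_beta_matrix(config.plates_path, case_status=case)
    split = (
        {k: v for k, v in DEFAULT_FRAGMENT_MAP.items()}
        if config.split_fragments
        else None
    )
    plates = generate_epityper_plates(
        cohort,
        config.assay,
        cpg_ids=list(config.generator.cpg_ids),
        seed=config.seed + 2,
        fragment_split=split,
    )
    write_plates(plates, outdir / "plates.csv")
    return plates


@_stage("qc")
def _qc(config: PipelineConfig, plates, outdir: Path):
    fragment_map = DEFAULT_FRAGMENT_MAP if config.split_fragments else None
    wide, report = run_qc(
        plates.entries,
        thresholds=config.qc,
        fragment_map=fragment_map,
        case_status=plates.case_status,
    )
    report.to_json(outdir / "qc_report.json")
    wide.to_csv(outdir / "beta_wide.csv")
    return wide, report


@_stage("descriptives")
def _descriptives(cohort, outdir: Path):
    variables = [
        "maternal_age", "education", "income_low", "ets_exposure",
        "alcohol_use", "parity", "female", "gestational_age",
        "placental_weight", "placental_major_axis", "placental_minor_axis",
        "placental_area",
    ]
    table = compare_groups(cohort, variables)
    table.to_csv(outdir / "descriptives.csv", index=False)
    return table


@_stage("associate")
def _associate(config: PipelineConfig, wide, cohort, outdir: Path):
    scan = association_scan(
        wide,
        cohort,
        covariates=config.covariates,
        strata=config.strata,
        drop_ets=config.drop_ets,
        exclude_alcohol=config.exclude_alcohol,
    )
    scan.to_csv(outdir / "scan.tsv", sep="\t", index=False)
    partition = correlation_blocks(wide, cutoff=config.block_cutoff)
    threshold = bonferroni_threshold(partition, alpha=config.scan_alpha)
    with open(outdir / "blocks.json", "w") as fh:
        json.dump(
            {"partition": partition.to_dict(), "threshold": threshold}, fh, indent=2
        )
    return scan, partition, threshold


@_stage("mediate")
def _mediate(config: PipelineConfig, scan, threshold, wide, cohort, outdir: Path):
    hits = scan[
        (scan["model"] == "logistic") & (scan["p"] < threshold) & scan["p"].notna()
    ]
    triggered = [
        {"cpg": r["cpg"], "stratum": r["stratum"], "p": r["p"]}
        for _, r in hits.iterrows()
    ]
    results = []
    df = cohort.set_index("subject_id", drop=False).join(wide, how="left")
    for t in triggered:
        cpg, stratum = t["cpg"], t["stratum"]
        covs = [c for c in config.covariates
                if not (config.drop_ets and c == "ets_exposure")]
        if stratum in ("girls", "boys"):
            covs = [c for c in covs if c != "female"]
        sub = df if stratum == "all" else df[
            df["female"] == (1 if stratum == "girls" else 0)
        ]
        if config.exclude_alcohol:
            sub = sub[sub["alcohol_use"] == 0]
        work = sub[["case_status"] + covs].copy()
        work["z_meth"] = standardize(sub[cpg]).values
        work["z_area"] = standardize(sub["placental_area"]).values
        work = work.dropna()

        paths = estimate_paths(work, "case_status", "z_meth", "z_area", covs)
        conditions = check_mediation_conditions(paths, alpha=config.mediation_alpha)
        entry = {
            "cpg": cpg,
            "stratum": stratum,
            "n": len(work),
            "covariates": covs,
            "conditions": {
                "a": conditions.a_exposure_mediator,
                "b": conditions.b_exposure_outcome,
                "c": conditions.c_mediator_outcome,
                "d": conditions.d_attenuation,
                "attenuation_percent": conditions.attenuation_percent,
                "mediation_present": conditions.mediation_present,
            },
            "path_diagram": path_diagram(paths, stratum),
        }
        if conditions.mediation_present:
            if config.bootstrap_reps > 0:
                res = bootstrap_mediation(
                    work, "case_status", "z_meth", "z_area", covs,
                    reps=config.bootstrap_reps, seed=config.seed + 3,
                    stratum=stratum,
                )
            else:
                res = fit_natural_effects(
                    work, "case_status", "z_meth", "z_area", covs,
                    stratum=stratum,
                )
            entry["result"] = res.to_dict()
        results.append(entry)
    payload = {
        "triggered": triggered if triggered else "not triggered",
        "results": results,
    }
    with open(outdir / "mediation.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return triggered, results


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Run all stages; artifacts land under ``outdir``.

    A stage failure raises :class:`PipelineError` naming the stage; artifacts
    written by earlier stages persist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    config.to_json(outdir / "config.json")

    cohort = _simulate(config, outdir)
    if cohort.empty:
        raise PipelineError("stage 'simulate' produced an empty cohort")
    plates = _plates(config, cohort, outdir)
    wide, qc = _qc(config, plates, outdir)
    descriptives = _descriptives(cohort, outdir)
    scan, partition, threshold = _associate(config, wide, cohort, outdir)
    triggered, mediation = _mediate(
        config, scan, threshold, wide, cohort, outdir
    )

    report = RunReport(
        config_hash=config.config_hash(),
        version=__version__,
        qc=qc.to_dict(),
        descriptives=descriptives,
        scan=scan,
        blocks=partition.to_dict(),
        threshold=threshold,
        triggered=triggered,
        mediation=mediation,
        outdir=str(outdir),
    )
    report.to_json(outdir / "run_report.json")
    return report
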