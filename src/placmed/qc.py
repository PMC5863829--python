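"""Quality control for EpiTYPER-style β-value readouts.

The filters reproduce the standard plate-assay QC chain: fragment averaging
into composite CpG units, per-CpG removal of poor readouts (missing β) and of
values in the detection-limit tails (β < 0.05 or β > 0.95), exclusion of CpGs
with fewer than 75% valid samples, and plate-control checks (repeat-pair
concordance within 0.05 β units; bisulfite conversion efficiency above 98%).

All operations take/return the long-format entry table written by
:mod:`placmed.simulate` (columns sample_id, cpg_id, batch_id, beta,
is_repeat, is_conversion_control).  ``filter_sample_readouts`` adds a
``qc_status`` column partitioning every analysis entry into exactly one of
{valid, removed_missing, removed_censored}; control/repeat rows are labelled
``control`` and never enter the valid set.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "QCThresholds",
    "QCReport",
    "MissingControlError",
    "aggregate_fragments",
    "filter_sample_readouts",
    "filter_cpgs",
    "validate_plate_controls",
    "qc_report",
    "run_qc",
    "beta_wide_matrix",
]


class MissingControlError(ValueError):
    """A plate lacks its bisulfite conversion control entry."""


class QCThresholds(BaseModel):
    """Cutoffs of the QC chain.

    β values strictly below ``beta_lower`` or strictly above ``beta_upper``
    are censored (boundary values are retained); a CpG is kept when its valid
    fraction is at least ``min_valid_fraction``; a repeat pair fails at
    absolute difference ≥ ``repeat_max_diff``; conversion efficiency must be
    strictly greater than ``min_conversion``.
    """

    model_config = ConfigDict(frozen=True)

    beta_lower: float = 0.05
    beta_upper: float = 0.95
    min_valid_fraction: float = Field(default=0.75, gt=0.0, le=1.0)
    repeat_max_diff: float = Field(default=0.05, gt=0.0)
    min_conversion: float = Field(default=0.98, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "QCThresholds":
        if not 0.0 <= self.beta_lower < self.beta_upper <= 1.0:
            raise ValueError("need 0 <= beta_lower < beta_upper <= 1")
        return self


def _analysis_mask(entries: pd.DataFrame) -> pd.Series:
    return ~(entries["is_repeat"] | entries["is_conversion_control"])


def aggregate_fragments(
    entries: pd.DataFrame, fragment_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Average CG-containing fragments into composite CpG units.

    ``fragment_map`` maps a composite id (e.g. ``"CpG 3.4"``) to its member
    fragment ids.  For each (sample, batch, repeat-flag) group holding all
    members, the members are replaced by one composite row whose β is their
    unweighted mean; the composite is missing whenever any member is missing.
    Groups missing a member row are skipped for that sample.
    """
    entries = entries.copy()
    present = set(entries["cpg_id"].unique())
    for composite, members in fragment_map.items():
        unknown = [m for m in members if m not in present]
        if unknown:
            raise ValueError(
                f"fragment_map for {composite!r} references CpG ids not in the "
                f"entry table: {unknown}"
            )

    keep = entries
    out_frames = [
        keep[~keep["cpg_id"].isin({m for ms in fragment_map.values() for m in ms})]
    ]
    for composite, members in fragment_map.items():
        members = list(members)
        sub = entries[entries["cpg_id"].isin(members)]
        if sub.empty:
            continue
        grouped = sub.groupby(
            ["sample_id", "batch_id", "is_repeat", "is_conversion_control"],
            sort=False,
        )
        rows = []
        for key, grp in grouped:
            if set(grp["cpg_id"]) != set(members):
                continue  # incomplete fragment set for this sample
            beta = grp["beta"].to_numpy(float)
            val = np.nan if np.isnan(beta).any() else float(beta.mean())
            rows.append(
                {
                    "sample_id": key[0],
                    "cpg_id": composite,
                    "batch_id": key[1],
                    "beta": val,
                    "is_repeat": key[2],
                    "is_conversion_control": key[3],
                }
            )
        if rows:
            out_frames.append(pd.DataFrame(rows))
    return pd.concat(out_frames, ignore_index=True)


def filter_sample_readouts(
    entries: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Flag each analysis entry per CpG as valid / removed_missing /
    removed_censored.  Idempotent: re-applying does not change statuses."""
    thresholds = thresholds or QCThresholds()
    out = entries.copy()
    beta = out["beta"].to_numpy(float)
    status = np.full(len(out), "valid", dtype=object)
    status[np.isnan(beta)] = "removed_missing"
    with np.errstate(invalid="ignore"):
        censored = (beta < thresholds.beta_lower) | (beta > thresholds.beta_upper)
    status[censored & ~np.isnan(beta)] = "removed_censored"
    status[~_analysis_mask(out).to_numpy()] = "control"
    out["qc_status"] = status
    return out


def filter_cpgs(
    entries: pd.DataFrame, thresholds: QCThresholds | None = None
) -> list[str]:
    """CpGs retained by the valid-fraction rule.

    The fraction is valid analysis entries over all analysis entries assayed
    for that CpG; a CpG is retained when the fraction is at least
    ``min_valid_fraction`` (inclusive boundary).
    """
    thresholds = thresholds or QCThresholds()
    if "qc_status" not in entries.columns:
        entries = filter_sample_readouts(entries, thresholds)
    sub = entries[entries["qc_status"] != "control"]
    if sub.empty:
        return []
    counts = sub.groupby("cpg_id")["qc_status"].agg(
        assayed="size", valid=lambda s: int((s == "valid").sum())
    )
    frac = counts["valid"] / counts["assayed"]
    return sorted(frac.index[frac >= thresholds.min_valid_fraction].tolist())


def validate_plate_controls(
    entries: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Per-batch control checks.

    Returns one row per batch with ``repeat_ok``, ``conversion_ok`` and a
    combined ``status`` (PASS, FAIL-repeat, FAIL-conversion, or both joined
    by '+').  A repeat pair fails when |Δβ| ≥ ``repeat_max_diff`` for any CpG
    with both readouts present; conversion fails when any control efficiency
    is ≤ ``min_conversion``.  A batch with no conversion control raises
    :class:`MissingControlError`.
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    for batch_id, grp in entries.groupby("batch_id", sort=True):
        conv = grp.loc[grp["is_conversion_control"], "beta"]
        if conv.empty:
            raise MissingControlError(f"batch {batch_id!r} has no conversion control")
        conversion_ok = bool((conv > thresholds.min_conversion).all())

        repeat_ok = True
        max_diff = 0.0
        reps = grp[grp["is_repeat"]]
        mains = grp[~grp["is_repeat"] & ~grp["is_conversion_control"]]
        if not reps.empty:
            merged = reps.merge(
                mains[["sample_id", "cpg_id", "beta"]],
                on=["sample_id", "cpg_id"],
                suffixes=("_rep", "_main"),
            )
            diff = (merged["beta_rep"] - merged["beta_main"]).abs().dropna()
            if not diff.empty:
                max_diff = float(diff.max())
                repeat_ok = bool((diff < thresholds.repeat_max_diff).all())

        flags = []
        if not repeat_ok:
            flags.append("FAIL-repeat")
        if not conversion_ok:
            flags.append("FAIL-conversion")
        rows.append(
            {
                "batch_id": batch_id,
                "repeat_ok": repeat_ok,
                "conversion_ok": conversion_ok,
                "max_repeat_diff": max_diff,
                "status": "+".join(flags) if flags else "PASS",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["batch_id", "repeat_ok", "conversion_ok", "max_repeat_diff", "status"],
    )


@dataclasses.dataclass
class QCReport:
    """Outcome of the full QC chain.

    ``counts`` has one row per CpG with input / removed_missing /
    removed_censored / valid entry counts (the first equals the sum of the
    other three), plus valid counts split by case status when available.
    """

    counts: pd.DataFrame
    retained_cpgs: list[str]
    batch_controls: pd.DataFrame
    thresholds: QCThresholds

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.model_dump(),
            "retained_cpgs": self.retained_cpgs,
            "counts": self.counts.to_dict(orient="records"),
            "batch_controls": self.batch_controls.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def qc_report(
    entries: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    case_status: pd.Series | None = None,
) -> QCReport:
    """Run the sample/CpG filters and plate-control checks; tabulate counts."""
    thresholds = thresholds or QCThresholds()
    flagged = filter_sample_readouts(entries, thresholds)
    retained = filter_cpgs(flagged, thresholds)
    controls = validate_plate_controls(entries, thresholds)

    sub = flagged[flagged["qc_status"] != "control"]
    if sub.empty:
        counts = pd.DataFrame(
            columns=[
                "cpg_id", "input", "removed_missing", "removed_censored",
                "valid", "valid_cases", "valid_controls", "retained",
            ]
        )
        return QCReport(counts, retained, controls, thresholds)

    tab = (
        sub.groupby("cpg_id")["qc_status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["valid", "removed_missing", "removed_censored"], fill_value=0)
    )
    tab["input"] = tab.sum(axis=1)
    if case_status is not None:
        valid = sub[sub["qc_status"] == "valid"].copy()
        valid["case"] = valid["sample_id"].map(case_status)
        by_case = valid.groupby("cpg_id")["case"].agg(
            valid_cases=lambda s: int((s == 1).sum()),
            valid_controls=lambda s: int((s == 0).sum()),
        )
        tab = tab.join(by_case).fillna({"valid_cases": 0, "valid_controls": 0})
    else:
        tab["valid_cases"] = np.nan
        tab["valid_controls"] = np.nan
    tab = tab.reset_index()
    tab["retained"] = tab["cpg_id"].isin(retained)
    counts = tab[
        [
            "cpg_id", "input", "removed_missing", "removed_censored", "valid",
            "valid_cases", "valid_controls", "retained",
        ]
    ]
    return QCReport(counts, retained, controls, thresholds)


def beta_wide_matrix(flagged: pd.DataFrame, retained_cpgs: Sequence[str]) -> pd.DataFrame:
    """Valid β values as a samples × CpGs matrix (NaN where removed)."""
    valid = flagged[
        (flagged["qc_status"] == "valid") & flagged["cpg_id"].isin(retained_cpgs)
    ]
    if valid.empty:
        return pd.DataFrame(columns=list(retained_cpgs))
    wide = valid.pivot_table(
        index="sample_id", columns="cpg_id", values="beta", aggfunc="first"
    )
    return wide.reindex(columns=list(retained_cpgs))


def run_qc(
    entries: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    fragment_map: Mapping[str, Sequence[str]] | None = None,
    case_status: pd.Series | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, QCReport]:
    """Full chain: fragment aggregation → filters → report → wide matrix.

    With ``strict=True`` batches failing a control check are dropped before
    filtering (by default failures are only flagged in the report, since a
    well-run assay is expected to pass all controls).
    """
    thresholds = thresholds or QCThresholds()
    if fragment_map:
        entries = aggregate_fragments(entries, fragment_map)
    if strict:
        controls = validate_plate_controls(entries, thresholds)
        bad = set(controls.loc[controls["status"] != "PASS", "batch_id"])
        entries = entries[~entries["batch_id"].isin(bad)]
    report = qc_report(entries, thresholds, case_status=case_status)
    flagged = filter_sample_readouts(entries, thresholds)
    wide = beta_wide_matrix(flagged, report.retained_cpgs)
    return wide, report
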