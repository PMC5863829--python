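"""CSV readers/writers with validation for cohort and plate tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import COHORT_COLUMNS, MethylationPlateSet

__all__ = [
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "read_beta_matrix",
    "write_plates",
]


class ValidationError(ValueError):
    """An input table violates the documented column contract."""


_PLATE_COLUMNS = [
    "sample_id", "cpg_id", "batch_id", "beta", "is_repeat",
    "is_conversion_control",
]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (one row per mother–baby pair).

    Checks mandatory columns, positive placental axes, the elliptical-area
    identity within rounding, and the full-term gestational range 37–42
    weeks; errors name the offending row and column.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file lacks mandatory columns {missing}")
    for col in ("placental_major_axis", "placental_minor_axis"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive {col} at row {int(bad[0])}"
            )
    expected = df["placental_major_axis"] * df["placental_minor_axis"] * np.pi / 4
    off = (df["placental_area"] - expected).abs()
    bad = df.index[off > 0.5]  # rounding of axes to 2 decimals
    if len(bad):
        raise ValidationError(
            f"placental_area deviates from the ellipse formula at row "
            f"{int(bad[0])} (|delta| = {off[bad[0]]:.3f} cm^2)"
        )
    ga = df["gestational_age"]
    bad = df.index[(ga < 37) | (ga > 42)]
    if len(bad):
        raise ValidationError(
            f"gestational_age outside the full-term range [37, 42] at row "
            f"{int(bad[0])} (value {ga[bad[0]]})"
        )
    bad = df.index[~df["case_status"].isin([0, 1])]
    if len(bad):
        raise ValidationError(f"case_status not binary at row {int(bad[0])}")
    return df


def write_plates(plates: MethylationPlateSet, path) -> None:
    plates.entries.to_csv(path, index=False)


def read_beta_matrix(path, case_status: pd.Series | None = None) -> MethylationPlateSet:
    """Read a long-format plate CSV into a :class:`MethylationPlateSet`.

    β must be missing or within [0, 1]; violations name the row and column.
    ``case_status`` (sample_id → flag) may be supplied from the cohort.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate file lacks mandatory columns {missing}")
    beta = df["beta"]
    bad = df.index[((beta < 0) | (beta > 1)) & beta.notna()]
    if len(bad):
        raise ValidationError(
            f"beta out of [0, 1] at row {int(bad[0])}, column 'beta' "
            f"(value {beta[bad[0]]})"
        )
    df["is_repeat"] = df["is_repeat"].astype(bool)
    df["is_conversion_control"] = df["is_conversion_control"].astype(bool)
    if case_status is None:
        case_status = pd.Series(dtype=int)
    return MethylationPlateSet(
        entries=df,
        case_status=case_status,
        injections=pd.DataFrame(columns=["sample_id", "cpg_id", "kind"]),
    )
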