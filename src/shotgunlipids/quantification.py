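"""From raw counts to the two analysis currencies.

Semi-quantitative shotgun profiles are analysed on two scales: the
internal-standard-normalized ratio (species counts divided by the
counts of its class standard in the same injection, then averaged over
technical replicates) and, per class, the compositional mol% of each
species.  Effects are expressed as x-fold change in percent of the
solvent-control group mean, per cell line.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .lipid_model import LipidClass
from .synthetic_data import RAW_COLUMNS

logger = logging.getLogger(__name__)

KEY_COLS = ["cell_line", "treatment", "biological_replicate"]
TECH_KEY_COLS = KEY_COLS + ["technical_replicate"]


class NormalizationError(ValueError):
    """A species row without a usable class-standard row."""


class CompositionError(ValueError):
    """A class composition that cannot be formed (e.g. all-zero vector)."""


class DesignError(ValueError):
    """Fold-change request inconsistent with the study design."""


def normalize_to_class_standard(raw: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Normalize counts to the class internal standard, per injection,
    then average the ratio over technical replicates.

    Returns one row per (sample, species) with columns
    ``cell_line, treatment, biological_replicate, lipid_name,
    lipid_class, ratio``.
    """
    missing_cols = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise NormalizationError(f"raw table is missing columns: {missing_cols}")

    std_names = set(panel["internal_standard_name"])
    species = raw[raw["lipid_name"].isin(set(panel["name"]))].copy()
    if species.empty:
        raise NormalizationError("raw table contains no panel species rows")
    species = species.merge(
        panel[["name", "lipid_class", "internal_standard_name"]],
        left_on="lipid_name",
        right_on="name",
        how="left",
    ).drop(columns="name")

    standards = raw[raw["lipid_name"].isin(std_names)].rename(
        columns={"lipid_name": "internal_standard_name", "counts": "standard_counts"}
    )
    merged = species.merge(
        standards[TECH_KEY_COLS + ["internal_standard_name", "standard_counts"]],
        on=TECH_KEY_COLS + ["internal_standard_name"],
        how="left",
    )
    if merged["standard_counts"].isna().any():
        bad = merged[merged["standard_counts"].isna()].iloc[0]
        raise NormalizationError(
            "missing internal standard "
            f"{bad['internal_standard_name']!r} (class {bad['lipid_class']}) for sample "
            f"({bad['cell_line']}, {bad['treatment']}, replicate {bad['biological_replicate']}, "
            f"technical {bad['technical_replicate']})"
        )
    if (merged["standard_counts"] == 0).any():
        bad = merged[merged["standard_counts"] == 0].iloc[0]
        raise NormalizationError(
            f"zero standard counts for {bad['internal_standard_name']!r} in sample "
            f"({bad['cell_line']}, {bad['treatment']}, replicate {bad['biological_replicate']})"
        )

    merged["ratio"] = merged["counts"] / merged["standard_counts"]
    n_tech = merged.groupby(KEY_COLS + ["lipid_name"], sort=False)["ratio"].size()
    expected = raw["technical_replicate"].nunique()
    if (n_tech < expected).any():
        short = n_tech[n_tech < expected]
        logger.warning(
            "%d (sample, species) cells have fewer than %d technical replicates; "
            "averaging over the available ones", len(short), expected
        )
    out = (
        merged.groupby(KEY_COLS + ["lipid_name", "lipid_class"], sort=False, as_index=False)[
            "ratio"
        ].mean()
    )
    return out


def compute_mol_percent(
    normalized: pd.DataFrame, lipid_class: Optional[str] = None
) -> pd.DataFrame:
    """Per-sample, per-class compositional mol% (sums to 100 per class).

    Cholesterol (a single-species class) is excluded: a singleton
    composition is identically 100.  Restrict to one class by passing
    ``lipid_class``.
    """
    df = normalized
    if lipid_class is not None:
        df = df[df["lipid_class"] == lipid_class]
        if df.empty:
            raise CompositionError(f"no species of class {lipid_class!r} in profile")
    df = df[df["lipid_class"] != LipidClass.CHOL.value].copy()
    if df.empty:
        raise CompositionError("no multi-species classes in profile")
    totals = df.groupby(KEY_COLS + ["lipid_class"], sort=False)["ratio"].transform("sum")
    if (totals == 0).any():
        bad = df[totals == 0].iloc[0]
        raise CompositionError(
            f"all-zero class vector for {bad['lipid_class']} in sample "
            f"({bad['cell_line']}, {bad['treatment']}, replicate {bad['biological_replicate']})"
        )
    df["mol_pct"] = 100.0 * df["ratio"] / totals
    return df[KEY_COLS + ["lipid_name", "lipid_class", "mol_pct"]]


def fold_change_vs_control(
    values: pd.DataFrame,
    value_col: str = "value",
    parameter_col: str = "parameter",
    control_label: str = "control",
) -> pd.DataFrame:
    """Express per-sample parameter values in % of the control-group mean.

    The control mean is taken per (cell line, parameter); the control
    group's own mean fold change is therefore exactly 100 %.
    """
    if values.empty:
        raise DesignError("empty value table")
    out = values.copy()
    ctrl = out[out["treatment"] == control_label]
    if ctrl.empty:
        raise DesignError(f"no rows with control label {control_label!r}")
    ctrl_mean = (
        ctrl.groupby(["cell_line", parameter_col], sort=False)[value_col]
        .mean()
        .rename("control_mean")
    )
    out = out.merge(ctrl_mean, on=["cell_line", parameter_col], how="left")
    if out["control_mean"].isna().any():
        bad = out[out["control_mean"].isna()].iloc[0]
        raise DesignError(
            f"no control group for parameter {bad[parameter_col]!r} "
            f"in cell line {bad['cell_line']!r}"
        )
    if (out["control_mean"] == 0).any():
        bad = out[out["control_mean"] == 0].iloc[0]
        raise DesignError(
            f"zero control mean for parameter {bad[parameter_col]!r} "
            f"in cell line {bad['cell_line']!r}"
        )
    out["fc_pct"] = 100.0 * out[value_col] / out["control_mean"]
    return out
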