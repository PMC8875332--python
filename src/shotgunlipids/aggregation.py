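"""Structural aggregates over normalized profiles and mol% compositions.

Per sample the analysis reports, for every class: the total normalized
level, and mol% partitions by saturation (SFA/MUFA/PUFA), chain length
(short/medium/long), double-bond count (``X:n``), carbon number
(``Cn:X``) and — for ceramides — the sn1 sphingoid-base composition.
Each partition's bins sum to 100 mol% per sample and class by
construction.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .lipid_model import (
    GAP_CLOSED_SCHEME,
    CategoryScheme,
    LipidClass,
    MissingBaseError,
    carbon_bin,
    chain_length_category,
    double_bond_bin,
    parse_species_name,
    saturation_category,
)
from .quantification import KEY_COLS

PARTITIONS = ("saturation", "chain", "double_bond", "carbon", "sn1_base")


def aggregate_total(normalized: pd.DataFrame, lipid_class: Optional[str] = None) -> pd.DataFrame:
    """Per-sample class totals (sum of normalized ratios).

    Columns: sample key, ``lipid_class``, ``total``.
    """
    df = normalized
    if lipid_class is not None:
        df = df[df["lipid_class"] == lipid_class]
    out = (
        df.groupby(KEY_COLS + ["lipid_class"], sort=False, as_index=False)["ratio"]
        .sum()
        .rename(columns={"ratio": "total"})
    )
    return out


def _bin_label(name: str, partition: str, scheme: CategoryScheme) -> Optional[str]:
    sp = parse_species_name(name)
    if partition == "saturation":
        return saturation_category(sp)
    if partition == "chain":
        return chain_length_category(sp, scheme)
    if partition == "double_bond":
        return double_bond_bin(sp)
    if partition == "carbon":
        return carbon_bin(sp)
    if partition == "sn1_base":
        if sp.lipid_class is not LipidClass.CER:
            return None  # partition only defined for ceramides
        if sp.base is None:
            raise MissingBaseError(
                f"{name} lacks base/acyl detail needed for the sn1 partition"
            )
        return sp.base.label
    raise ValueError(f"unknown partition {partition!r}; choose from {PARTITIONS}")


def aggregate_partition(
    molp: pd.DataFrame,
    partition: str,
    scheme: CategoryScheme = GAP_CLOSED_SCHEME,
) -> pd.DataFrame:
    """Sum species mol% into partition bins, per sample and class.

    Columns: sample key, ``lipid_class``, ``partition``, ``bin``,
    ``value`` (mol%).  For ``sn1_base`` only ceramide rows contribute.
    """
    labels = {
        name: _bin_label(name, partition, scheme)
        for name in molp["lipid_name"].unique()
    }
    df = molp.copy()
    df["bin"] = df["lipid_name"].map(labels)
    df = df[df["bin"].notna()]
    out = (
        df.groupby(KEY_COLS + ["lipid_class", "bin"], sort=False, as_index=False)["mol_pct"]
        .sum()
        .rename(columns={"mol_pct": "value"})
    )
    out.insert(len(KEY_COLS) + 1, "partition", partition)
    return out


def aggregate_all_partitions(
    molp: pd.DataFrame, scheme: CategoryScheme = GAP_CLOSED_SCHEME
) -> pd.DataFrame:
    """All five partitions stacked into one tidy table."""
    frames = [aggregate_partition(molp, p, scheme) for p in PARTITIONS]
    return pd.concat(frames, ignore_index=True)
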