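"""Ratio indices between lipid-class totals.

Four per-sample indices summarise membrane remodelling:

* ``PCae_over_PCaa`` — plasmalogen over diacyl PC; plasmalogens carry
  an oxidation-prone enol-ether bond, so the ratio indexes oxidative
  stress.
* ``LysoPC_over_PCaa`` — lyso-PC is the PLA2 cleavage product of PC,
  so the ratio proxies phospholipase A2 activity.
* ``SM_over_PCaa`` — sphingomyelin synthesis consumes PC
  (phosphocholine transfer), so the ratio reflects SM anabolism.
* ``Cer_over_SM`` — sphingomyelinases hydrolyse SM to ceramide, so the
  ratio reflects SM catabolism.

Each index can be stratified by saturation (the numerator and the
denominator are restricted to the same SFA/MUFA/PUFA stratum).
Indices are computed per sample first and then related to the
control-group mean (in %), per cell line.
"""

from __future__ import annotations

import pandas as pd

from .lipid_model import LipidClass, parse_species_name, saturation_category
from .quantification import KEY_COLS, fold_change_vs_control

INDEX_CLASSES: dict[str, tuple[LipidClass, LipidClass]] = {
    "PCae_over_PCaa": (LipidClass.PC_AE, LipidClass.PC_AA),
    "LysoPC_over_PCaa": (LipidClass.LYSO_PC, LipidClass.PC_AA),
    "SM_over_PCaa": (LipidClass.SM, LipidClass.PC_AA),
    "Cer_over_SM": (LipidClass.CER, LipidClass.SM),
}

STRATA = ("total", "SFA", "MUFA", "PUFA")

_INTERPRETATION = {
    "PCae_over_PCaa": "oxidative stress indicator",
    "LysoPC_over_PCaa": "PLA2 activity proxy",
    "SM_over_PCaa": "SM anabolism",
    "Cer_over_SM": "SM catabolism",
}


class IndexError_(ValueError):
    """Ratio index cannot be computed (unknown name or zero denominator)."""


def interpret_index(name: str) -> str:
    """Biological reading of a ratio index."""
    try:
        return _INTERPRETATION[name]
    except KeyError:
        raise IndexError_(f"unknown index {name!r}; known: {sorted(INDEX_CLASSES)}") from None


def _stratum_total(normalized: pd.DataFrame, cls: LipidClass, stratum: str) -> pd.DataFrame:
    sub = normalized[normalized["lipid_class"] == cls.value]
    if stratum != "total":
        keep = [
            n for n in sub["lipid_name"].unique()
            if saturation_category(parse_species_name(n)) == stratum
        ]
        sub = sub[sub["lipid_name"].isin(keep)]
    if sub.empty:
        raise IndexError_(f"no {cls.value} species in stratum {stratum!r}")
    return sub.groupby(KEY_COLS, sort=False, as_index=False)["ratio"].sum()


def compute_ratio_index(
    normalized: pd.DataFrame,
    name: str,
    stratum: str = "total",
    control_label: str = "control",
) -> pd.DataFrame:
    """One ratio index per sample, absolute and in % of control.

    Columns: sample key, ``index``, ``stratum``, ``value``,
    ``relative_pct``.
    """
    if name not in INDEX_CLASSES:
        raise IndexError_(f"unknown index {name!r}; known: {sorted(INDEX_CLASSES)}")
    if stratum not in STRATA:
        raise IndexError_(f"unknown stratum {stratum!r}; known: {STRATA}")
    num_cls, den_cls = INDEX_CLASSES[name]
    num = _stratum_total(normalized, num_cls, stratum).rename(columns={"ratio": "num"})
    den = _stratum_total(normalized, den_cls, stratum).rename(columns={"ratio": "den"})
    df = num.merge(den, on=KEY_COLS, how="inner")
    if (df["den"] == 0).any():
        raise IndexError_(f"zero denominator ({den_cls.value}) for index {name!r}")
    df["value"] = df["num"] / df["den"]
    df["parameter"] = name
    fc = fold_change_vs_control(df, value_col="value", control_label=control_label)
    out = df[KEY_COLS].copy()
    out["index"] = name
    out["stratum"] = stratum
    out["value"] = df["value"].to_numpy()
    out["relative_pct"] = fc["fc_pct"].to_numpy()
    return out


def compute_all_indices(
    normalized: pd.DataFrame, control_label: str = "control"
) -> pd.DataFrame:
    """All four indices at every saturation stratum, stacked."""
    frames = [
        compute_ratio_index(normalized, name, stratum, control_label)
        for name in INDEX_CLASSES
        for stratum in STRATA
    ]
    return pd.concat(frames, ignore_index=True)
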