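"""Seedable synthetic shotgun-lipidomics raw intensity tables.

The generator emulates the study design the analysis assumes: two
neuroblastoma cell lines, five methylxanthine treatments plus a water
solvent control, >=5 biological replicates measured in technical
triplicate, a 188-species panel across seven lipid classes with one
internal standard per class, lognormal biological variation,
multiplicative Gaussian technical noise and a bounded per-injection
matrix effect (|effect| <= 1.12 %, mean magnitude 1.05 %).

Model for one species *s* in one biological sample:

    biological value  B = exp(mu_s) * m(treatment, s) * exp(sigma_b * Z)
    technical rep  cps  = B * (1 + cv_t * Z') * (1 + matrix effect)

with ``sigma_b = sqrt(ln(1 + cv_b^2))`` so ``cv_b`` is the biological
coefficient of variation, and ``m`` a treatment/selector multiplier
(1 for the control).  Internal standards carry technical noise only.
A fixed (seed, design, config) triple yields a bit-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .lipid_model import (
    GAP_CLOSED_SCHEME,
    LipidClass,
    carbon_bin,
    chain_length_category,
    double_bond_bin,
    parse_species_name,
    saturation_category,
)

RAW_COLUMNS = (
    "cell_line",
    "treatment",
    "biological_replicate",
    "technical_replicate",
    "lipid_name",
    "counts",
)

PANEL_COLUMNS = ("name", "lipid_class", "internal_standard_name")

#: One internal standard per class, modelled on the usual short-chain /
#: deuterated class standards spiked into each injection.
INTERNAL_STANDARDS: Mapping[LipidClass, str] = {
    LipidClass.PC_AA: "IS PC aa C6:0",
    LipidClass.PC_AE: "IS PC ae mix",
    LipidClass.LYSO_PC: "IS Lyso-PC C19:0",
    LipidClass.SM: "IS SM C6:0",
    LipidClass.CER: "IS Cer d18:1/6:0",
    LipidClass.TAG: "IS TAG mix",
    LipidClass.CHOL: "IS D7-cholesterol",
}


class GeneratorConfigError(ValueError):
    """Invalid generator configuration (bad multiplier or selector)."""


class SchemaError(ValueError):
    """A table file does not carry the required columns."""


# ---------------------------------------------------------------------------
# default species panel

# (carbons -> inclusive double-bond range) grids per class; sizes chosen
# once so the panel totals exactly 188 species over the seven classes.
_PC_GRID = {28: (0, 2), 30: (0, 3), 32: (0, 3), 34: (0, 4),
            36: (0, 5), 38: (0, 6), 40: (1, 6), 42: (2, 6)}          # 40 species
_LYSO_PC = [(6, 0), (14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2),
            (20, 3), (20, 4), (22, 4), (22, 5), (24, 0), (26, 0), (26, 1),
            (28, 0), (28, 1)]                                         # 16
_SM = [(30, 1), (32, 1), (32, 2), (34, 0), (34, 1), (34, 2), (36, 0),
       (36, 1), (36, 2), (38, 0), (38, 1), (38, 2), (40, 1), (40, 2),
       (42, 1), (42, 2), (44, 1), (44, 2)]                            # 18
_CER_ACYL = {  # sphingoid base label -> N-acyl (carbons, double bonds)
    "d18:1": [(2, 0), (6, 0), (14, 0), (16, 0), (18, 0), (18, 1), (20, 0),
              (20, 3), (22, 0), (22, 5), (24, 0), (24, 1), (24, 6),
              (26, 0), (26, 1)],                                      # 15
    "d18:2": [(14, 0), (16, 0), (18, 0), (18, 1), (20, 0), (22, 0),
              (24, 0), (24, 1), (26, 0)],                             # 9
}
_TAG_GRID = {c: (0, 6) for c in range(44, 57, 2)}                     # 49


def _grid_names(prefix: str, grid: Mapping[int, tuple[int, int]]) -> list[str]:
    return [f"{prefix} C{c}:{d}" for c in sorted(grid)
            for d in range(grid[c][0], grid[c][1] + 1)]


@lru_cache(maxsize=1)
def _default_panel() -> pd.DataFrame:
    rows: list[tuple[str, str]] = []
    for cls, names in (
        (LipidClass.PC_AA, _grid_names("PC aa", _PC_GRID)),
        (LipidClass.PC_AE, _grid_names("PC ae", _PC_GRID)),
        (LipidClass.LYSO_PC, [f"Lyso-PC C{c}:{d}" for c, d in _LYSO_PC]),
        (LipidClass.SM, [f"SM C{c}:{d}" for c, d in _SM]),
        (LipidClass.CER, [f"Cer {base}/{c}:{d}"
                          for base in ("d18:1", "d18:2")
                          for c, d in _CER_ACYL[base]]),
        (LipidClass.TAG, _grid_names("TAG", _TAG_GRID)),
        (LipidClass.CHOL, ["Cholesterol"]),
    ):
        rows.extend((n, cls.value) for n in names)
    df = pd.DataFrame(rows, columns=["name", "lipid_class"])
    df["internal_standard_name"] = [
        INTERNAL_STANDARDS[LipidClass(c)] for c in df["lipid_class"]
    ]
    for name in df["name"]:
        parse_species_name(name)  # every panel entry must be parseable
    return df


def default_species_panel() -> pd.DataFrame:
    """The built-in 188-species panel (name, lipid_class, internal_standard_name)."""
    return _default_panel().copy()


def read_species_panel(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel file {path} is missing columns: {missing}")
    return df[list(PANEL_COLUMNS)]


def write_species_panel(panel: pd.DataFrame, path: Union[str, Path]) -> None:
    panel[list(PANEL_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study design / generator configuration

@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the emulated experiment."""

    cell_lines: Sequence[str] = ("SH-SY5Y", "N2a")
    treatments: Sequence[str] = ("control", "C", "TP", "P", "TB", "PPF")
    n_biological: int = 5
    n_technical: int = 3
    control_label: str = "control"

    def __post_init__(self) -> None:
        if list(self.treatments).count(self.control_label) != 1:
            raise ValueError(
                f"design must contain the control label {self.control_label!r} exactly once"
            )
        if self.n_biological < 2:
            raise ValueError("n_biological must be >= 2 for inference")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        if not self.cell_lines:
            raise ValueError("at least one cell line required")

    @property
    def n_samples(self) -> int:
        return len(self.cell_lines) * len(self.treatments) * self.n_biological


@dataclass
class GeneratorConfig:
    """Noise levels, baselines and treatment effects for the generator.

    ``effect_multipliers`` maps treatment -> {selector -> multiplier}.
    A selector is either a canonical species name, or a filter
    expression of ``;``-separated ``key:value`` terms with keys
    ``class`` (required), ``sat``, ``chain``, ``db`` and ``carbon``,
    e.g. ``"class:PC_AA"`` or ``"class:PC_AE;sat:PUFA"``.
    """

    seed: int
    biological_cv: float = 0.20
    technical_cv: float = 0.04
    matrix_effect_max: float = 0.0112
    matrix_effect_mean: float = 0.0105
    effect_multipliers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    standard_intensity: Union[float, Mapping[str, float]] = 1.0e5
    baseline_log_mean: Optional[Mapping[str, float]] = None

    def standard_intensity_for(self, lipid_class: str) -> float:
        if isinstance(self.standard_intensity, Mapping):
            return float(self.standard_intensity[lipid_class])
        return float(self.standard_intensity)


#: Typical counts-per-second scale per class; the per-species baselines
#: fan out deterministically around these so class compositions are
#: uneven, as in real profiles.
_CLASS_BASE_CPS: Mapping[LipidClass, float] = {
    LipidClass.PC_AA: 2.0e5,
    LipidClass.PC_AE: 8.0e4,
    LipidClass.LYSO_PC: 2.0e4,
    LipidClass.SM: 1.2e5,
    LipidClass.CER: 3.0e4,
    LipidClass.TAG: 6.0e4,
    LipidClass.CHOL: 5.0e5,
}


def default_baseline_log_means(panel: pd.DataFrame) -> dict[str, float]:
    """Deterministic per-species log-mean baselines (counts-per-second)."""
    out: dict[str, float] = {}
    for cls_value, sub in panel.groupby("lipid_class", sort=False):
        base = math.log(_CLASS_BASE_CPS[LipidClass(cls_value)])
        m = len(sub)
        offsets = np.linspace(1.2, -1.8, m) if m > 1 else np.zeros(1)
        for name, off in zip(sub["name"], offsets):
            out[name] = base + float(off)
    return out


# ---------------------------------------------------------------------------
# selector resolution

def resolve_selector(selector: str, panel: pd.DataFrame) -> list[str]:
    """Expand a multiplier selector to the matching panel species names."""
    names = list(panel["name"])
    if selector in set(names):
        return [selector]
    terms: dict[str, str] = {}
    for part in selector.split(";"):
        if ":" not in part:
            raise GeneratorConfigError(
                f"selector {selector!r} is neither a panel species nor a key:value filter"
            )
        key, _, value = part.partition(":")
        terms[key.strip()] = value.strip()
    unknown = set(terms) - {"class", "sat", "chain", "db", "carbon"}
    if unknown:
        raise GeneratorConfigError(f"selector {selector!r} has unknown keys {sorted(unknown)}")
    if "class" not in terms:
        raise GeneratorConfigError(f"selector {selector!r} must name a class")
    try:
        cls = LipidClass(terms["class"])
    except ValueError:
        raise GeneratorConfigError(f"unknown lipid class {terms['class']!r}") from None

    matched = []
    for name in panel.loc[panel["lipid_class"] == cls.value, "name"]:
        sp = parse_species_name(name)
        if "sat" in terms and saturation_category(sp) != terms["sat"]:
            continue
        if "chain" in terms and chain_length_category(sp, GAP_CLOSED_SCHEME) != terms["chain"]:
            continue
        if "db" in terms and double_bond_bin(sp) != terms["db"]:
            continue
        if "carbon" in terms and carbon_bin(sp) != terms["carbon"]:
            continue
        matched.append(name)
    if not matched:
        raise GeneratorConfigError(f"selector {selector!r} matches no panel species")
    return matched


def _multiplier_matrix(
    design: StudyDesign, config: GeneratorConfig, panel: pd.DataFrame
) -> np.ndarray:
    """(n_treatments, n_species) treatment-effect multipliers."""
    names = list(panel["name"])
    index = {n: i for i, n in enumerate(names)}
    mult = np.ones((len(design.treatments), len(names)))
    for treatment, sel_map in config.effect_multipliers.items():
        if treatment not in design.treatments:
            raise GeneratorConfigError(f"multiplier for unknown treatment {treatment!r}")
        if treatment == design.control_label:
            raise GeneratorConfigError("the solvent control cannot carry an effect multiplier")
        t = list(design.treatments).index(treatment)
        for selector, m in sel_map.items():
            if not (m > 0):
                raise GeneratorConfigError(
                    f"multiplier for ({treatment!r}, {selector!r}) must be > 0, got {m}"
                )
            for name in resolve_selector(selector, panel):
                mult[t, index[name]] *= m
    return mult


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(
    design: StudyDesign,
    config: GeneratorConfig,
    panel: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Generate a long-format raw intensity table for the given design.

    One row per (cell line, treatment, biological replicate, technical
    replicate) and panel species, plus one row per class internal
    standard in each injection.  Identical inputs give an identical
    table.
    """
    if panel is None:
        panel = default_species_panel()
    if config.technical_cv < 0 or config.biological_cv < 0:
        raise GeneratorConfigError("coefficients of variation must be >= 0")
    lo = 2 * config.matrix_effect_mean - config.matrix_effect_max
    if not (0 <= lo <= config.matrix_effect_max):
        raise GeneratorConfigError(
            "matrix_effect_mean must lie between matrix_effect_max/2 and matrix_effect_max"
        )

    rng = np.random.default_rng(config.seed)
    names = list(panel["name"])
    classes = list(dict.fromkeys(panel["lipid_class"]))  # stable order
    std_names = [INTERNAL_STANDARDS[LipidClass(c)] for c in classes]
    n_spec, n_cls = len(names), len(classes)
    n_tech = design.n_technical

    baselines = dict(config.baseline_log_mean or default_baseline_log_means(panel))
    try:
        mu = np.array([baselines[n] for n in names])
    except KeyError as exc:
        raise GeneratorConfigError(f"no baseline log-mean for species {exc.args[0]!r}") from None
    mult = _multiplier_matrix(design, config, panel)
    sigma_b = math.sqrt(math.log1p(config.biological_cv**2))

    samples = [
        (cl, trt, b)
        for cl in design.cell_lines
        for trt in design.treatments
        for b in range(1, design.n_biological + 1)
    ]
    n_samp = len(samples)
    trt_idx = np.array([list(design.treatments).index(s[1]) for s in samples])

    bio = np.exp(mu[None, :] + sigma_b * rng.standard_normal((n_samp, n_spec)))
    bio *= mult[trt_idx, :]

    tech_noise = 1.0 + config.technical_cv * rng.standard_normal((n_samp, n_tech, n_spec))
    mag = rng.uniform(lo, config.matrix_effect_max, size=(n_samp, n_tech))
    sign = rng.integers(0, 2, size=(n_samp, n_tech)) * 2 - 1
    matrix = 1.0 + sign * mag
    counts = bio[:, None, :] * tech_noise * matrix[:, :, None]

    std_level = np.array([config.standard_intensity_for(c) for c in classes])
    std_counts = std_level[None, None, :] * (
        1.0 + config.technical_cv * rng.standard_normal((n_samp, n_tech, n_cls))
    )

    counts = np.maximum(counts, 1e-9)
    std_counts = np.maximum(std_counts, 1e-9)

    # assemble: per injection, species rows then standard rows
    per_inj = n_spec + n_cls
    values = np.concatenate([counts, std_counts], axis=2).reshape(-1)
    lipid_col = np.tile(np.array(names + std_names, dtype=object), n_samp * n_tech)
    cell = np.repeat(np.array([s[0] for s in samples], dtype=object), n_tech * per_inj)
    trt = np.repeat(np.array([s[1] for s in samples], dtype=object), n_tech * per_inj)
    bio_rep = np.repeat(np.array([s[2] for s in samples]), n_tech * per_inj)
    tech_rep = np.tile(np.repeat(np.arange(1, n_tech + 1), per_inj), n_samp)

    return pd.DataFrame(
        {
            "cell_line": cell,
            "treatment": trt,
            "biological_replicate": bio_rep,
            "technical_replicate": tech_rep,
            "lipid_name": lipid_col,
            "counts": values,
        }
    )


# ---------------------------------------------------------------------------
# table IO

def write_raw_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a raw intensity table as CSV (full float precision)."""
    missing = [c for c in RAW_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"raw table is missing columns: {missing}")
    table[list(RAW_COLUMNS)].to_csv(path, index=False)


def read_raw_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a raw intensity table, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"raw table {path} is missing columns: {missing}")
    return df[list(RAW_COLUMNS)]
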