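"""End-to-end pipeline: raw counts -> comparison tables.

``run_pipeline`` orchestrates generate/load -> validate -> normalize ->
mol% -> aggregates -> ratio indices -> Dunnett comparisons with volcano
categorisation, and writes a fixed set of tidy CSV outputs plus a run
manifest.  Identical configuration and seed give byte-identical CSVs.

Comparison families follow the reporting structure of the study
design: one family is (cell line x lipid class x parameter set); cell
lines are never pooled.  The default volcano SD threshold is the
standard deviation of all species-level effects (% of control) in the
family (cell line, treatment, class) — a data-driven magnitude scale —
and can be fixed to a percentage via ``sd_mode="fixed:<pct>"``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import aggregate_all_partitions, aggregate_total
from .indices import INDEX_CLASSES, compute_all_indices
from .lipid_model import category_scheme
from .quantification import (
    KEY_COLS,
    compute_mol_percent,
    fold_change_vs_control,
    normalize_to_class_standard,
)
from .stats import dunnett_test, significance_stars, volcano_categorize
from .synthetic_data import (
    GeneratorConfig,
    RAW_COLUMNS,
    StudyDesign,
    default_species_panel,
    generate_dataset,
    read_raw_table,
    read_species_panel,
)

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "normalized.csv",
    "molpercent.csv",
    "aggregates.csv",
    "indices.csv",
    "comparisons.csv",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ValidationFailure(PipelineError):
    """Input validation reported blocking findings."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: Union[str, Path] = "results"
    seed: Optional[int] = None
    raw_path: Optional[Union[str, Path]] = None
    panel_path: Optional[Union[str, Path]] = None
    design: StudyDesign = field(default_factory=StudyDesign)
    generator: Optional[GeneratorConfig] = None
    scheme: str = "gap-closed"
    sd_mode: str = "family-sd"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.raw_path is None and self.generator is None:
            raise ValueError("config needs either raw_path or a generator section")
        if self.sd_mode != "family-sd":
            self._fixed_sd()  # validates the fixed:<pct> form

    def _fixed_sd(self) -> float:
        if not self.sd_mode.startswith("fixed:"):
            raise ValueError(f"sd_mode must be 'family-sd' or 'fixed:<pct>', got {self.sd_mode!r}")
        value = float(self.sd_mode.split(":", 1)[1])
        if value <= 0:
            raise ValueError("fixed SD threshold must be > 0")
        return value


def config_from_yaml(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig (with design/generator sections) from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    design = StudyDesign(**doc.get("design", {}))
    gen = None
    if "generator" in doc:
        gen = GeneratorConfig(**doc["generator"])
    run = doc.get("run", {})
    return RunConfig(design=design, generator=gen, **run)


@dataclass
class ValidationReport:
    passed: bool
    items: list[str]


def validate_inputs(
    raw: pd.DataFrame, design: StudyDesign, panel: pd.DataFrame
) -> ValidationReport:
    """Check completeness of the raw table against design and panel."""
    items: list[str] = []
    missing_cols = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        return ValidationReport(False, [f"raw table missing columns: {missing_cols}"])

    if design.control_label not in set(raw["treatment"]):
        items.append(f"no control group: treatment {design.control_label!r} absent from raw table")
    if (raw["counts"] <= 0).any():
        n = int((raw["counts"] <= 0).sum())
        items.append(f"{n} rows with non-positive counts")

    injections = raw.groupby(
        ["cell_line", "treatment", "biological_replicate", "technical_replicate"], sort=False
    )["lipid_name"].agg(set)
    species = set(panel["name"])
    standards = set(panel["internal_standard_name"])
    for key, present in injections.items():
        for miss in sorted(species - present):
            items.append(f"sample {key}: missing species {miss!r}")
        for miss in sorted(standards - present):
            items.append(f"sample {key}: missing internal standard {miss!r}")

    group_sizes = (
        raw[raw["lipid_name"].isin(species)]
        .groupby(["cell_line", "treatment"], sort=False)["biological_replicate"]
        .nunique()
    )
    for key, n in group_sizes.items():
        if n < 2:
            items.append(f"group {key}: only {n} biological replicate(s); inference needs >= 2")

    return ValidationReport(passed=not items, items=items)


# ---------------------------------------------------------------------------
# comparisons

def _parameter_table(
    normalized: pd.DataFrame,
    molp: pd.DataFrame,
    totals: pd.DataFrame,
    aggregates: pd.DataFrame,
    indices: pd.DataFrame,
) -> pd.DataFrame:
    """Stack every tested parameter into sample-keyed (parameter, value) rows."""
    frames = []

    sp = normalized.rename(columns={"lipid_name": "parameter", "ratio": "value"}).copy()
    sp["parameter_type"] = "species"
    frames.append(sp[KEY_COLS + ["parameter", "parameter_type", "lipid_class", "value"]])

    tot = totals.rename(columns={"total": "value"}).copy()
    tot["parameter"] = tot["lipid_class"] + " total"
    tot["parameter_type"] = "total"
    frames.append(tot[KEY_COLS + ["parameter", "parameter_type", "lipid_class", "value"]])

    agg = aggregates.copy()
    agg["parameter"] = agg["lipid_class"] + " " + agg["partition"] + " " + agg["bin"]
    agg = agg.rename(columns={"partition": "parameter_type"})
    frames.append(agg[KEY_COLS + ["parameter", "parameter_type", "lipid_class", "value"]])

    idx = indices.copy()
    idx["parameter"] = idx["index"] + " " + idx["stratum"]
    idx["parameter_type"] = "index"
    # family of an index = its numerator class
    idx["lipid_class"] = idx["index"].map(lambda n: INDEX_CLASSES[n][0].value)
    frames.append(idx[KEY_COLS + ["parameter", "parameter_type", "lipid_class", "value"]])

    return pd.concat(frames, ignore_index=True)


def build_comparisons(
    normalized: pd.DataFrame,
    molp: pd.DataFrame,
    totals: pd.DataFrame,
    aggregates: pd.DataFrame,
    indices: pd.DataFrame,
    design: StudyDesign,
    sd_mode: str = "family-sd",
) -> pd.DataFrame:
    """Dunnett comparisons of every parameter vs the solvent control.

    One row per (cell line, parameter, treatment) with the effect in %
    of control, the Dunnett-adjusted two-sided p, significance stars
    and the volcano category.
    """
    params = _parameter_table(normalized, molp, totals, aggregates, indices)
    fc = fold_change_vs_control(params, control_label=design.control_label)
    ctrl = design.control_label
    treatments = [t for t in design.treatments if t != ctrl]

    records = []
    for (cell, parameter), sub in fc.groupby(["cell_line", "parameter"], sort=False):
        control_vals = sub.loc[sub["treatment"] == ctrl, "fc_pct"].to_numpy()
        groups = [sub.loc[sub["treatment"] == t, "fc_pct"].to_numpy() for t in treatments]
        try:
            res = dunnett_test(control_vals, groups)
        except ValueError as exc:
            raise PipelineError(
                f"stats stage failed for parameter {parameter!r} in {cell!r}: {exc}"
            ) from exc
        ptype = sub["parameter_type"].iloc[0]
        cls = sub["lipid_class"].iloc[0]
        ctrl_native = sub.loc[sub["treatment"] == ctrl, "value"].mean()
        for t, g, p in zip(treatments, groups, res.pvalue):
            records.append(
                {
                    "cell_line": cell,
                    "parameter": parameter,
                    "parameter_type": ptype,
                    "lipid_class": cls,
                    "treatment": t,
                    "effect_pct": float(np.mean(g)),
                    "control_mean": float(ctrl_native),
                    "treatment_mean": float(
                        sub.loc[sub["treatment"] == t, "value"].mean()
                    ),
                    "p_adjusted": float(p),
                }
            )
    comp = pd.DataFrame.from_records(records)

    if sd_mode == "family-sd":
        fam = (
            comp[comp["parameter_type"] == "species"]
            .groupby(["cell_line", "treatment", "lipid_class"], sort=False)["effect_pct"]
            .std(ddof=1)
            .rename("sd_threshold")
        )
        comp = comp.merge(fam, on=["cell_line", "treatment", "lipid_class"], how="left")
        # families without species-level spread (should not happen) fall back
        # to the global species SD
        fallback = comp.loc[comp["parameter_type"] == "species", "effect_pct"].std(ddof=1)
        comp["sd_threshold"] = comp["sd_threshold"].fillna(fallback)
    else:
        fixed = float(sd_mode.split(":", 1)[1])
        comp["sd_threshold"] = fixed

    comp["stars"] = comp["p_adjusted"].map(significance_stars)
    comp["volcano_category"] = [
        volcano_categorize(e, p, s)
        for e, p, s in zip(comp["effect_pct"], comp["p_adjusted"], comp["sd_threshold"])
    ]
    comp["neg_log10_p"] = -np.log10(np.maximum(comp["p_adjusted"], 1e-300))
    return comp


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the whole pipeline and write the output bundle to ``outdir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = category_scheme(config.scheme)

    panel = (
        read_species_panel(config.panel_path)
        if config.panel_path is not None
        else default_species_panel()
    )

    if config.raw_path is not None:
        raw = read_raw_table(config.raw_path)
        design = config.design
    else:
        gen = config.generator
        assert gen is not None
        if config.seed is not None and config.seed != gen.seed:
            gen = dataclasses.replace(gen, seed=config.seed)
        design = config.design
        raw = generate_dataset(design, gen, panel)

    report = validate_inputs(raw, design, panel)
    if not report.passed:
        raise ValidationFailure(
            "input validation failed:\n  " + "\n  ".join(report.items[:20])
        )

    try:
        normalized = normalize_to_class_standard(raw, panel)
        molp = compute_mol_percent(normalized)
        totals = aggregate_total(normalized)
        aggregates = aggregate_all_partitions(molp, scheme)
        indices = compute_all_indices(normalized, design.control_label)
        comparisons = build_comparisons(
            normalized, molp, totals, aggregates, indices, design, config.sd_mode
        )
    except PipelineError:
        raise
    except ValueError as exc:
        raise PipelineError(f"pipeline stage failed: {exc}") from exc

    outputs = {
        "normalized": normalized,
        "molpercent": molp,
        "aggregates": aggregates,
        "indices": indices,
        "comparisons": comparisons,
    }
    for stem, df in outputs.items():
        df.to_csv(outdir / f"{stem}.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed if config.seed is not None else getattr(config.generator, "seed", None),
        "scheme": config.scheme,
        "sd_mode": config.sd_mode,
        "design": dataclasses.asdict(config.design),
        "generator": dataclasses.asdict(config.generator) if config.generator else None,
        "raw_path": str(config.raw_path) if config.raw_path else None,
        "panel_path": str(config.panel_path) if config.panel_path else None,
        "outputs": [f"{stem}.csv" for stem in outputs],
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    logger.info("pipeline outputs written to %s", outdir)
    return outputs
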