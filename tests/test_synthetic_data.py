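"""Generator: panel, determinism, noise structure, IO, selectors."""

import numpy as np
import pandas as pd
import pytest

from shotgunlipids.aggregation import aggregate_total
from shotgunlipids.quantification import normalize_to_class_standard
from shotgunlipids.synthetic_data import (
    GeneratorConfig,
    GeneratorConfigError,
    SchemaError,
    StudyDesign,
    default_species_panel,
    generate_dataset,
    read_raw_table,
    read_species_panel,
    resolve_selector,
    write_raw_table,
    write_species_panel,
)


class TestPanel:
    def test_panel_size_and_classes(self, panel):
        assert len(panel) == 188
        assert set(panel["lipid_class"]) == {
            "PC_AA", "PC_AE", "LYSO_PC", "SM", "CER", "TAG", "CHOL"
        }
        assert panel["name"].is_unique

    def test_every_species_has_a_class_standard(self, panel):
        assert panel["internal_standard_name"].notna().all()
        # exactly one standard per class
        assert (panel.groupby("lipid_class")["internal_standard_name"].nunique() == 1).all()

    def test_panel_round_trips_through_csv(self, panel, tmp_path):
        p = tmp_path / "panel.csv"
        write_species_panel(panel, p)
        pd.testing.assert_frame_equal(read_species_panel(p), panel)


class TestDesignAndConfig:
    def test_control_must_be_present_once(self):
        with pytest.raises(ValueError, match="control"):
            StudyDesign(treatments=("C", "TP"))
        with pytest.raises(ValueError, match="control"):
            StudyDesign(treatments=("control", "control", "C"))

    def test_minimum_replication(self):
        with pytest.raises(ValueError):
            StudyDesign(n_biological=1)
        with pytest.raises(ValueError):
            StudyDesign(n_technical=0)

    def test_nonpositive_multiplier_rejected(self, small_panel, small_design):
        cfg = GeneratorConfig(seed=0, effect_multipliers={"PPF": {"class:PC_AA": 0.0}})
        with pytest.raises(GeneratorConfigError, match="> 0"):
            generate_dataset(small_design, cfg, small_panel)

    def test_unknown_selector_rejected(self, small_panel, small_design):
        cfg = GeneratorConfig(seed=0, effect_multipliers={"PPF": {"PC aa C99:0": 1.2}})
        with pytest.raises(GeneratorConfigError):
            generate_dataset(small_design, cfg, small_panel)

    def test_selector_resolution(self, panel):
        assert resolve_selector("PC aa C30:0", panel) == ["PC aa C30:0"]
        pufa_pcae = resolve_selector("class:PC_AE;sat:PUFA", panel)
        assert pufa_pcae and all(n.startswith("PC ae") for n in pufa_pcae)
        assert "PC ae C34:1" not in pufa_pcae  # MUFA excluded
        with pytest.raises(GeneratorConfigError):
            resolve_selector("class:NOPE", panel)


class TestGeneration:
    def test_same_seed_gives_identical_tables(self, small_design, small_panel):
        a = generate_dataset(small_design, GeneratorConfig(seed=7), small_panel)
        b = generate_dataset(small_design, GeneratorConfig(seed=7), small_panel)
        pd.testing.assert_frame_equal(a, b)
        c = generate_dataset(small_design, GeneratorConfig(seed=8), small_panel)
        assert not np.allclose(a["counts"], c["counts"])

    def test_row_count_matches_design(self, small_design, small_panel, small_raw):
        n_cls = small_panel["lipid_class"].nunique()
        expected = (
            small_design.n_samples
            * small_design.n_technical
            * (len(small_panel) + n_cls)
        )
        assert len(small_raw) == expected
        assert (small_raw["counts"] > 0).all()

    def test_null_fold_changes_near_100(self, small_panel):
        """With unit multipliers every class-total effect hovers at 100 %."""
        design = StudyDesign(cell_lines=("SH-SY5Y",))
        raw = generate_dataset(design, GeneratorConfig(seed=5), small_panel)
        totals = aggregate_total(normalize_to_class_standard(raw, small_panel))
        by = totals.groupby(["lipid_class", "treatment"])["total"].mean().unstack()
        effects = 100.0 * by.div(by["control"], axis=0).drop(columns="control")
        assert ((effects - 100).abs() < 15).all().all()
        assert abs(effects.to_numpy().mean() - 100) < 5

    def test_matrix_effect_bounds(self, small_design, small_panel):
        """With all other noise off, technical spread is exactly the matrix effect."""
        cfg = GeneratorConfig(seed=3, biological_cv=0.0, technical_cv=0.0)
        raw = generate_dataset(small_design, cfg, small_panel)
        species = raw[raw["lipid_name"] == small_panel["name"].iloc[0]]
        bio = species.groupby(
            ["cell_line", "treatment", "biological_replicate"]
        )["counts"]
        rel = species["counts"] / bio.transform("mean") - 1.0
        # per-injection multiplicative deviation honours the printed bounds
        dev = species.assign(rel=rel).groupby(
            ["cell_line", "treatment", "biological_replicate", "technical_replicate"]
        )["rel"].mean()
        assert (dev.abs() <= 2 * 0.0112).all()

    def test_multiplier_scales_target_class_only(self, small_panel, small_design):
        cfg = GeneratorConfig(seed=9, effect_multipliers={"PPF": {"class:SM": 0.5}})
        base = generate_dataset(small_design, GeneratorConfig(seed=9), small_panel)
        shifted = generate_dataset(small_design, cfg, small_panel)
        merged = base.merge(
            shifted,
            on=["cell_line", "treatment", "biological_replicate",
                "technical_replicate", "lipid_name"],
            suffixes=("_base", "_eff"),
        )
        sm = merged["lipid_name"].str.startswith("SM C")
        ppf = merged["treatment"] == "PPF"
        ratio = merged["counts_eff"] / merged["counts_base"]
        assert np.allclose(ratio[sm & ppf], 0.5)
        assert np.allclose(ratio[~(sm & ppf)], 1.0)


class TestTableIO:
    def test_round_trip_preserves_values(self, small_raw, tmp_path):
        p = tmp_path / "raw.csv"
        write_raw_table(small_raw, p)
        back = read_raw_table(p)
        pd.testing.assert_frame_equal(back, small_raw)

    def test_missing_column_raises_schema_error(self, small_raw, tmp_path):
        p = tmp_path / "bad.csv"
        small_raw.drop(columns="treatment").to_csv(p, index=False)
        with pytest.raises(SchemaError, match="treatment"):
            read_raw_table(p)
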