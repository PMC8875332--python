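"""Reusable validation experiments over the synthetic study.

These routines back the analysis drivers and the reproduction script:
null calibration of the familywise error rate, recovery of a known
class-total effect, agreement of the Dunnett integrator with its
Monte-Carlo oracle, and reconstruction of a partition bin from its
complements under the mol% closure invariant.

The calibration and recovery experiments run the real generator and
quantification code on a single-class sub-panel and one cell line:
lipid classes are generated independently, so the tested family (class
total versus the five treatments) has the same distribution as in the
full panel while keeping thousands of replicate simulations cheap.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregation import aggregate_partition, aggregate_total
from .lipid_model import GAP_CLOSED_SCHEME, CategoryScheme
from .quantification import normalize_to_class_standard
from .stats import dunnett_test, monte_carlo_max_abs_sf, prob_max_abs_le
from .synthetic_data import (
    GeneratorConfig,
    StudyDesign,
    default_species_panel,
    generate_dataset,
)


def _subpanel(lipid_class: str) -> pd.DataFrame:
    panel = default_species_panel()
    return panel[panel["lipid_class"] == lipid_class].reset_index(drop=True)


def _class_total_by_group(
    design: StudyDesign, config: GeneratorConfig, panel: pd.DataFrame
) -> pd.DataFrame:
    raw = generate_dataset(design, config, panel)
    normalized = normalize_to_class_standard(raw, panel)
    return aggregate_total(normalized)


def null_familywise_rate(
    n_sims: int = 2000,
    seed: int = 0,
    lipid_class: str = "LYSO_PC",
    alpha: float = 0.05,
    design: Optional[StudyDesign] = None,
) -> float:
    """Empirical familywise rejection rate under the global null.

    Each simulation generates a fresh dataset with unit multipliers,
    runs normalization and the class total through Dunnett against the
    control, and records whether any of the five treatments is called
    significant at *alpha*.  With exact error control the rate is
    *alpha*.
    """
    if design is None:
        design = StudyDesign(cell_lines=("SH-SY5Y",))
    panel = _subpanel(lipid_class)
    ctrl = design.control_label
    treatments = [t for t in design.treatments if t != ctrl]
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_sims)
    hits = 0
    for s in seeds:
        totals = _class_total_by_group(design, GeneratorConfig(seed=int(s)), panel)
        vals = {t: g["total"].to_numpy() for t, g in totals.groupby("treatment", sort=False)}
        res = dunnett_test(vals[ctrl], [vals[t] for t in treatments])
        if np.any(res.pvalue <= alpha):
            hits += 1
    return hits / n_sims


def recover_class_multiplier(
    multiplier: float = 0.721,
    treatment: str = "PPF",
    lipid_class: str = "PC_AA",
    n_biological: int = 5,
    n_seeds: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per-seed pipeline estimates (% of control) of a class-total effect.

    A multiplier *m* on every species of one class under one treatment
    should be recovered as a class-total fold change of 100*m %.
    Returns the ``n_seeds`` estimates; their mean is the headline
    recovery number.
    """
    design = StudyDesign(cell_lines=("SH-SY5Y",), n_biological=n_biological)
    panel = _subpanel(lipid_class)
    mult = {treatment: {f"class:{lipid_class}": multiplier}}
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)
    estimates = np.empty(n_seeds)
    for i, s in enumerate(seeds):
        cfg = GeneratorConfig(seed=int(s), effect_multipliers=mult)
        totals = _class_total_by_group(design, cfg, panel)
        by = totals.groupby("treatment", sort=False)["total"].mean()
        estimates[i] = 100.0 * by[treatment] / by[design.control_label]
    return estimates


def dunnett_oracle_agreement(
    ks: Sequence[int] = (1, 3, 5),
    ns: Sequence[int] = (3, 5),
    n_draws: int = 10**6,
    seed: int = 0,
) -> pd.DataFrame:
    """Integrator vs Monte-Carlo oracle on seeded balanced instances.

    For every (k treatments, n per group) the adjusted p of the first
    contrast from the deterministic integrator is compared with a
    direct Monte-Carlo evaluation of the same max-|t| exceedance
    probability, and (for k=1) with the classical two-sample pooled
    t-test.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        for n in ns:
            control = rng.normal(0.0, 1.0, n)
            groups = [rng.normal(0.4, 1.0, n) for _ in range(k)]
            res = dunnett_test(control, groups)
            t0 = abs(res.statistic[0])
            if k == 1:
                p_int = 1.0 - prob_max_abs_le(t0, tuple(res.b), res.df)
            else:
                p_int = float(res.pvalue[0])
            p_mc = monte_carlo_max_abs_sf(
                t0, [n] * k, n, n_draws=n_draws, seed=int(rng.integers(2**31 - 1))
            )
            row = {
                "k": k,
                "n": n,
                "p_integrator": p_int,
                "p_reported": float(res.pvalue[0]),
                "p_montecarlo": p_mc,
                "abs_diff": abs(p_int - p_mc),
            }
            if k == 1:
                p_t = float(sps.ttest_ind(groups[0], control, equal_var=True).pvalue)
                row["p_ttest"] = p_t
                row["ttest_abs_diff"] = abs(float(res.pvalue[0]) - p_t)
            rows.append(row)
    return pd.DataFrame(rows)


def bin_from_complements(
    lipid_class: str,
    partition: str,
    known_bins: dict[str, float],
    target_bin: str,
    scheme: CategoryScheme = GAP_CLOSED_SCHEME,
) -> float:
    """Recover a partition bin's mol% from its printed complements.

    Builds a single-sample species-level mol% composition of the given
    class whose bins reproduce ``known_bins`` (members share their
    bin's mass uniformly) with the remaining mass on the target bin's
    members, runs the real partition aggregation, and returns the
    target bin's value.  Under mol% closure this must equal
    ``100 - sum(known_bins.values())``.
    """
    from .aggregation import _bin_label  # same labelling path as production

    panel = _subpanel(lipid_class)
    labels = {name: _bin_label(name, partition, scheme) for name in panel["name"]}
    members: dict[str, list[str]] = {}
    for name, lab in labels.items():
        if lab is not None:
            members.setdefault(lab, []).append(name)
    for lab in list(known_bins) + [target_bin]:
        if lab not in members:
            raise ValueError(f"bin {lab!r} has no members in class {lipid_class}")
    extra = set(members) - set(known_bins) - {target_bin}
    if extra:
        raise ValueError(f"partition has unaccounted bins {sorted(extra)}")

    rows = []
    remainder = 100.0 - sum(known_bins.values())
    for lab, mass in {**known_bins, target_bin: remainder}.items():
        share = mass / len(members[lab])
        for name in members[lab]:
            rows.append(
                {
                    "cell_line": "SH-SY5Y",
                    "treatment": "control",
                    "biological_replicate": 1,
                    "lipid_name": name,
                    "lipid_class": lipid_class,
                    "mol_pct": share,
                }
            )
    molp = pd.DataFrame(rows)
    agg = aggregate_partition(molp, partition, scheme)
    total = agg["value"].sum()
    if abs(total - 100.0) > 1e-9:
        raise AssertionError(f"partition bins sum to {total}, not 100")
    return float(agg.loc[agg["bin"] == target_bin, "value"].iloc[0])
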