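"""Run the full differential-profile pipeline on the simulated study.

Reads results/study_config.yaml written by 01_simulate_study.py,
executes normalize -> mol% -> aggregates -> indices -> Dunnett, writes
the output bundle to results/pipeline/, and prints the headline
class-total findings (effect % of control, adjusted p, volcano cell).
"""

import argparse
from pathlib import Path

from shotgunlipids.pipeline import config_from_yaml, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=Path("results/study_config.yaml"))
    args = ap.parse_args()

    cfg = config_from_yaml(args.config)
    outputs = run_pipeline(cfg)
    comp = outputs["comparisons"]

    totals = comp[comp["parameter_type"] == "total"]
    print("class totals, % of solvent control (Dunnett-adjusted p):")
    for _, row in totals.sort_values(["cell_line", "parameter", "treatment"]).iterrows():
        if row["p_adjusted"] <= 0.05:
            print(
                f"  {row['cell_line']:8s} {row['parameter']:14s} {row['treatment']:4s} "
                f"{row['effect_pct']:6.1f} %  p={row['p_adjusted']:.3g} {row['stars']:3s} "
                f"[{row['volcano_category']}]"
            )
    n_sig = int((comp["p_adjusted"] <= 0.05).sum())
    print(f"\n{len(comp)} comparisons, {n_sig} significant at p<=0.05; outputs in {cfg.outdir}")


if __name__ == "__main__":
    main()
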