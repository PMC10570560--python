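"""Score every (variant, state): energies, reference RMSD, flexibility, monitors.

Runs the full descriptor stack over the smoke cohort and writes the two
central tables: results/score_table.csv (raw per-(variant, state) metrics)
and results/wt_standardized_scores.csv (per-variant scores in WT standard
deviations, the input to meta-classification).  Also reports which variants
are WT-like by the |SSR| < 0.5 Å² flexibility criterion.
"""

import sys
from pathlib import Path

from krasdyn import RunConfig
from krasdyn.pipeline import analyze_cohort, simulate_cohort, write_results

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    cfg = RunConfig(preset="smoke", seed=SEED, embedding_method="pca_fallback")
    result = analyze_cohort(simulate_cohort(cfg), cfg)
    write_results(result, OUT)

    scores = result.class_scores
    print(f"scored {len(result.score_table)} (variant, state) systems; "
          f"{result.score_table.shape[1]} metrics each")

    thr = cfg.classification.ssr_threshold
    for state in ("GDP", "GTP"):
        wt_like = scores[scores[f"ssr_{state}"].abs() < thr].index.tolist()
        print(f"\n{state}: {len(wt_like)}/{len(scores)} variants WT-like "
              f"(|SSR| < {thr} Å²): {', '.join(sorted(wt_like))}")

    print("\ninteraction-energy z (WT σ units):")
    print(scores[["eint_z_GDP", "eint_z_GTP"]].round(2).to_string())


if __name__ == "__main__":
    main()
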