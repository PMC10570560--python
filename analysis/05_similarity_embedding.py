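"""Cross-correlate all metrics and embed variant-states in two dimensions.

Reads results/score_table.csv from 03_variant_scores.py, computes the
Spearman cross-correlation matrix over all metrics, embeds the standardized
(variant, state) rows in 2-D, and checks that the two nucleotide states
separate in the embedding (the pipeline's analogue of GDP and GTP forming
distinct clusters).

Writes results/metric_correlations.csv and results/embedding.csv.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from krasdyn.embedding import embed_2d, metric_correlation_matrix

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "score_table.csv", index_col=["variant", "state"])
    corr = metric_correlation_matrix(table)
    corr.to_csv(OUT / "metric_correlations.csv")

    strongest = (
        corr.where(~(corr.abs() >= 1.0))
        .abs()
        .unstack()
        .dropna()
        .sort_values(ascending=False)
    )
    print("strongest inter-metric Spearman correlations:")
    seen = set()
    shown = 0
    for (a, b), v in strongest.items():
        if (b, a) in seen or shown >= 5:
            continue
        seen.add((a, b))
        print(f"  {a} ↔ {b}: ρ = {corr.loc[a, b]:+.2f}")
        shown += 1

    emb = embed_2d(table, method="pca_fallback", seed=SEED)
    emb.to_csv(OUT / "embedding.csv")
    states = [s for _, s in emb.index]
    sil = silhouette_score(emb.to_numpy(), states)
    print(f"\n2-D embedding of {len(emb)} variant-states written; "
          f"GDP/GTP silhouette = {sil:.2f} "
          f"({'states separate' if sil > 0 else 'states overlap'})")


if __name__ == "__main__":
    main()
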