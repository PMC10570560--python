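"""Meta-classify variants and cluster them into per-state signature groups.

Reads the WT-standardized scores from 03_variant_scores.py, discretizes each
score family at the 1σ threshold into its label vocabulary (9-cell energy
grid, reference-RMSD combinations, PC1 well fraction, monitor levels, SSR
classes), clusters the binary label matrix with k-means (k = 6 per state),
and prints each group's top defining features.

Writes results/metaclass_matrix.csv, results/groups_{state}.csv and
results/signatures.json (via the pipeline writer in 03) plus a readable
summary here.
"""

import sys
from pathlib import Path

import pandas as pd

from krasdyn.classify import (
    ClassificationConfig,
    build_metaclass_matrix,
    defining_features,
    kmeans_groups,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    scores = pd.read_csv(OUT / "wt_standardized_scores.csv", index_col="variant")
    cc = ClassificationConfig(seed=SEED)
    matrix = build_metaclass_matrix(scores, cc)
    print(f"label vocabulary: {matrix.shape[1]} meta-classifications "
          f"over {len(matrix)} variants")

    for state in ("GDP", "GTP"):
        assign = kmeans_groups(matrix, state, cc.k, cc.seed, cc.n_restarts)
        per_group, retained = defining_features(assign, matrix, cc.top_n)
        print(f"\n{state}: {assign.k} groups, {len(retained)} labels retained "
              f"after top-{cc.top_n} filtering")
        for g in sorted(per_group):
            members = ", ".join(assign.members(g))
            top = "; ".join(per_group[g][:5]) or "(none)"
            print(f"  group {g} ({len(assign.members(g))}): {members}")
            print(f"    top features: {top}")


if __name__ == "__main__":
    main()
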