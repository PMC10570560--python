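"""Score-matrix assembly, inter-metric correlations, and 2-D embeddings.

The full complement of per-(variant, state) scores — interaction energy,
RMSD to binding-competent references, flexibility summaries, PC standard
scores, Switch-1 well occupancy, and the monitor medians — is assembled into
one numeric table.  A Spearman cross-correlation matrix summarizes how the
metrics inter-relate, and a 2-D embedding of the standardized rows shows
which variant-states share dynamic profiles.  External melting-temperature
measurements can be overlaid as annotation without altering coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "assemble_score_matrix",
    "standardize_columns",
    "metric_correlation_matrix",
    "embed_2d",
    "overlay_measurements",
    "ddtm_star",
]


def assemble_score_matrix(
    metrics: Mapping[tuple[str, str], Mapping[str, float]],
    required: list[str] | None = None,
) -> pd.DataFrame:
    """Build the (variant, state)-indexed score table.

    ``metrics`` maps (variant, state) → {metric name → value}.  Metrics
    missing from any row raise with the full list of holes — absences must
    be explicit, never silent.  GDP-only metrics (well occupancy) are
    imputed as 0 for GTP rows alongside an indicator column.
    """
    if not metrics:
        raise ValueError("no metrics given")
    columns = required or sorted({m for row in metrics.values() for m in row})
    holes = [
        (variant, state, col)
        for (variant, state), row in metrics.items()
        for col in columns
        if col not in row and not _gdp_only(col)
    ]
    if holes:
        raise ValueError(f"missing metrics: {holes}")
    index = pd.MultiIndex.from_tuples(sorted(metrics), names=["variant", "state"])
    df = pd.DataFrame(index=index, columns=columns, dtype=float)
    for key, row in metrics.items():
        for col in columns:
            df.loc[key, col] = row.get(col, np.nan)
    for col in [c for c in columns if _gdp_only(c)]:
        indicator = f"{col}_measured"
        df[indicator] = (~df[col].isna()).astype(float)
        df[col] = df[col].fillna(0.0)
    return df


def _gdp_only(col: str) -> bool:
    return col == "well_occupancy_ratio"


def standardize_columns(table: pd.DataFrame) -> pd.DataFrame:
    """z-standardized copy; constant columns become 0."""
    out = table.copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        sd = np.nanstd(x)
        mean = np.nanmean(x)
        out[col] = (x - mean) / sd if sd > 0 else 0.0
    return out


def metric_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman matrix over metrics, pairwise-complete.

    Constant columns get NaN correlations (undefined, not zero); the
    diagonal is 1 for non-constant metrics.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 rows for correlations")
    corr = table.corr(method="spearman")
    for col in table.columns:
        if np.nanstd(table[col].to_numpy(dtype=float)) == 0:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
    return corr


def embed_2d(
    table: pd.DataFrame,
    method: str = "umap_default",
    seed: int = 0,
) -> pd.DataFrame:
    """2-D embedding of the standardized score rows.

    ``umap_default`` runs UMAP with library-default parameters (the
    user-facing view); ``pca_fallback`` is the deterministic alternative
    used wherever reproducibility matters more than manifold structure.
    """
    if len(table) < 4:
        raise ValueError("need >= 4 rows to embed")
    X = standardize_columns(table).to_numpy(dtype=float)
    X = np.nan_to_num(X)
    if method == "pca_fallback":
        Xc = X - X.mean(axis=0)
        # deterministic 2-component PCA with a fixed sign convention
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        comps = vt[:2]
        for j in range(2):
            lead = comps[j][np.argmax(np.abs(comps[j]))]
            if lead < 0:
                comps[j] = -comps[j]
        coords = Xc @ comps.T
    elif method == "umap_default":
        import umap

        coords = umap.UMAP(random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=table.index, columns=["x", "y"])


def ddtm_star(dtm_pnp: float, dtm_gdp: float) -> float:
    """Activation stability change: ΔΔT_m* = ΔT_m^PNP − ΔT_m^GDP (°C)."""
    return float(dtm_pnp - dtm_gdp)


def overlay_measurements(
    embedding: pd.DataFrame,
    measurements: pd.DataFrame,
) -> pd.DataFrame:
    """Join external melting-temperature data onto embedding rows.

    ``measurements`` needs a ``variant`` column (case-sensitive join) and any
    annotation columns (``tm``, ``ddtm_star`` ...).  Rows without a
    measurement are flagged ``measured=False`` (rendered grey downstream);
    coordinates are never altered.
    """
    if measurements["variant"].duplicated().any():
        dupes = measurements.loc[measurements["variant"].duplicated(), "variant"]
        raise ValueError(f"duplicate measurement keys: {sorted(set(dupes))}")
    out = embedding.reset_index()
    merged = out.merge(measurements, on="variant", how="left")
    value_cols = [c for c in measurements.columns if c != "variant"]
    merged["measured"] = ~merged[value_cols].isna().all(axis=1) if value_cols else False
    if len(merged) != len(embedding):
        raise AssertionError("join changed row count")
    return merged
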