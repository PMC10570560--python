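"""σ-based meta-classification of variants and k-means group signatures.

Every continuous score is first standardized against WT (a z in WT standard
deviations) and then discretized at a σ threshold, giving each variant one
label per *score family*:

* the 9-cell interaction-energy grid (Stable/Neutral/Unstable × GDP/GTP),
* the RMSD-to-reference grids (Closed/WT-like/Deviated per state, per
  reference conformation),
* the GDP-state Switch-1 well-occupancy fraction (minus/WT-like/plus SD),
* each distance monitor in each state (Below/WT-like/Above),
* the RMSF-profile SSR class per state (WT-like vs Deviated).

Stacking the one-hot labels over all families gives the binary meta-class
matrix.  k-means over each state's labels groups variants with shared
dynamic signatures; each group is then summarized by its most enriched
labels ("defining features").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationConfig",
    "GroupAssignment",
    "sigma_classify",
    "eint_grid_classify",
    "EINT_GRID_LABELS",
    "rmsd_reference_classify",
    "build_metaclass_matrix",
    "kmeans_groups",
    "defining_features",
    "group_difference_tests",
    "load_variant_catalogue",
]

STATES = ("GDP", "GTP")

#: The nine interaction-energy grid labels (GDP axis × GTP axis).
EINT_GRID_LABELS: tuple[str, ...] = tuple(
    f"Eint GDP {g} GTP {t}"
    for g, t in itertools.product(("Stable", "Neutral", "Unstable"), repeat=2)
)


@dataclass(frozen=True)
class ClassificationConfig:
    sigma: float = 1.0
    ssr_threshold: float = 0.5  # Å², |SSR| below this is WT-like
    k: int = 6
    top_n: int = 10
    seed: int = 0
    n_restarts: int = 25
    hotspots: tuple[int, ...] = (12, 13, 61)
    families: tuple[str, ...] = ("eint", "rmsd_refs", "pc1_fraction", "monitors", "ssr")

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k < 1 or self.top_n < 1:
            raise ValueError("k and top_n must be >= 1")


@dataclass(frozen=True)
class GroupAssignment:
    """Variant → group id (1..k) for one state, with ranked defining features."""

    state: str
    groups: Mapping[str, int]
    defining: Mapping[int, tuple[str, ...]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(set(self.groups.values()))

    def members(self, group: int) -> list[str]:
        return sorted(v for v, g in self.groups.items() if g == group)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for g in self.groups.values():
            out[g] = out.get(g, 0) + 1
        return out


def load_variant_catalogue() -> pd.DataFrame:
    """The packaged variant table: 86 mutations + WT, group ids, hotspot flag."""
    with resources.files("krasdyn.data").joinpath("variants.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# σ classifiers
# ---------------------------------------------------------------------------

def sigma_classify(z: float, sigma: float = 1.0) -> str:
    """Three-way split at ±σ; boundaries are inclusive (≥ +σ high, ≤ −σ low)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z >= sigma:
        return "high"
    if z <= -sigma:
        return "low"
    return "wt_like"


_EINT_AXIS = {"low": "Stable", "wt_like": "Neutral", "high": "Unstable"}


def eint_grid_classify(z_gdp: float, z_gtp: float, sigma: float = 1.0) -> str:
    """One of the nine interaction-energy grid labels.

    More negative (favorable) E_int than WT = Stable; within σ = Neutral;
    less favorable = Unstable, independently per nucleotide axis.
    """
    g = _EINT_AXIS[sigma_classify(z_gdp, sigma)]
    t = _EINT_AXIS[sigma_classify(z_gtp, sigma)]
    return f"Eint GDP {g} GTP {t}"


_RMSD_AXIS = {"low": "Closed", "wt_like": "WT-like", "high": "Deviated"}


def rmsd_reference_classify(
    z_gdp: float, z_gtp: float, sigma: float = 1.0, reference: str = "NF1"
) -> str:
    """Combined closed/WT-like/deviated label against a binding-competent pose.

    A variant below WT's RMSD distribution sits *closer* to the reference
    conformation than WT does (Closed); above it, further away (Deviated).
    """
    g = _RMSD_AXIS[sigma_classify(z_gtp, sigma)]
    d = _RMSD_AXIS[sigma_classify(z_gdp, sigma)]
    return f"RMSD {reference} GTP {g} GDP {d}"


def rmsd_reference_labels(reference: str) -> list[str]:
    return [
        f"RMSD {reference} GTP {g} GDP {d}"
        for g, d in itertools.product(("Closed", "WT-like", "Deviated"), repeat=2)
    ]


PC1_FRACTION_LABELS = (
    "PC1 Fraction Minus SD",
    "PC1 Fraction WT-like",
    "PC1 Fraction Plus SD",
)


# ---------------------------------------------------------------------------
# Meta-class matrix
# ---------------------------------------------------------------------------

def _monitor_label(name: str, level: str, state: str) -> str:
    word = {"low": "Below", "wt_like": "WTlike", "high": "Above"}[level]
    return f"{name} {word} {state}"


def label_vocabulary(
    config: ClassificationConfig, monitor_names: Sequence[str]
) -> dict[str, list[str]]:
    """Programmatically generated label vocabulary, keyed by family."""
    vocab: dict[str, list[str]] = {}
    if "eint" in config.families:
        vocab["eint"] = list(EINT_GRID_LABELS)
    if "rmsd_refs" in config.families:
        for ref in ("NF1", "SOS1"):
            vocab[f"rmsd_{ref.lower()}"] = rmsd_reference_labels(ref)
    if "pc1_fraction" in config.families:
        vocab["pc1_fraction"] = list(PC1_FRACTION_LABELS)
    if "monitors" in config.families:
        for name in monitor_names:
            for state in STATES:
                vocab[f"monitor:{name}:{state}"] = [
                    _monitor_label(name, lvl, state)
                    for lvl in ("low", "wt_like", "high")
                ]
    if "ssr" in config.families:
        for state in STATES:
            vocab[f"ssr:{state}"] = [f"SSR WT-like {state}", f"SSR Deviated {state}"]
    return vocab


def label_states(label: str) -> tuple[str, ...]:
    """Which nucleotide states a label speaks about (both for grid labels)."""
    has_gtp = "GTP" in label
    has_gdp = "GDP" in label
    if has_gdp and has_gtp:
        return STATES
    if has_gdp:
        return ("GDP",)
    if has_gtp:
        return ("GTP",)
    return STATES  # state-free scores (e.g. PC1 fraction) inform both


def build_metaclass_matrix(
    score_table: pd.DataFrame,
    config: ClassificationConfig | None = None,
    monitor_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary variant × label matrix, one-hot within each score family.

    ``score_table`` is indexed by variant with the per-family z/SSR columns:
    ``eint_z_{state}``, ``rmsd_{ref}_z_{state}``, ``pc1_fraction_z``,
    ``monitor_z:{name}:{state}``, ``ssr_{state}`` (lower-case state tags in
    column names are accepted as produced by the pipeline).
    """
    config = config or ClassificationConfig()
    if monitor_names is None:
        monitor_names = sorted(
            {c.split(":")[1] for c in score_table.columns if c.startswith("monitor_z:")}
        )
    vocab = label_vocabulary(config, monitor_names)
    all_labels = [lab for labs in vocab.values() for lab in labs]
    mat = pd.DataFrame(0, index=score_table.index, columns=all_labels, dtype=int)

    def need(variant, col):
        if col not in score_table.columns or pd.isna(score_table.loc[variant, col]):
            raise ValueError(f"missing score for ({variant!r}, {col!r})")
        return float(score_table.loc[variant, col])

    for variant in score_table.index:
        if "eint" in config.families:
            lab = eint_grid_classify(
                need(variant, "eint_z_GDP"), need(variant, "eint_z_GTP"), config.sigma
            )
            mat.loc[variant, lab] = 1
        if "rmsd_refs" in config.families:
            for ref in ("NF1", "SOS1"):
                lab = rmsd_reference_classify(
                    need(variant, f"rmsd_{ref.lower()}_z_GDP"),
                    need(variant, f"rmsd_{ref.lower()}_z_GTP"),
                    config.sigma,
                    ref,
                )
                mat.loc[variant, lab] = 1
        if "pc1_fraction" in config.families:
            lvl = sigma_classify(need(variant, "pc1_fraction_z"), config.sigma)
            lab = PC1_FRACTION_LABELS[("low", "wt_like", "high").index(lvl)]
            mat.loc[variant, lab] = 1
        if "monitors" in config.families:
            for name in monitor_names:
                for state in STATES:
                    z = need(variant, f"monitor_z:{name}:{state}")
                    lab = _monitor_label(name, sigma_classify(z, config.sigma), state)
                    mat.loc[variant, lab] = 1
        if "ssr" in config.families:
            for state in STATES:
                ssr = need(variant, f"ssr_{state}")
                wt_like = abs(ssr) < config.ssr_threshold
                lab = f"SSR {'WT-like' if wt_like else 'Deviated'} {state}"
                mat.loc[variant, lab] = 1
    return mat


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def _state_columns(matrix: pd.DataFrame, state: str) -> list[str]:
    return [c for c in matrix.columns if state in label_states(c)]

def kmeans_groups(
    matrix: pd.DataFrame,
    state: str,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 25,
) -> GroupAssignment:
    """k-means over a state's binary label columns.

    Best of ``n_restarts`` k-means++ runs by inertia; group ids are
    renumbered 1..k by descending size, ties broken by the lexicographically
    smallest member, so the numbering is deterministic.
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} rows")
    cols = _state_columns(matrix, state)
    X = matrix[cols].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    variants = list(matrix.index)
    by_raw: dict[int, list[str]] = {}
    for v, g in zip(variants, raw):
        by_raw.setdefault(int(g), []).append(v)
    ordered = sorted(
        by_raw.items(), key=lambda item: (-len(item[1]), sorted(item[1])[0])
    )
    relabel = {old: new + 1 for new, (old, _) in enumerate(ordered)}
    return GroupAssignment(
        state=state, groups={v: relabel[int(g)] for v, g in zip(variants, raw)}
    )


def defining_features(
    assignment: GroupAssignment,
    matrix: pd.DataFrame,
    top_n: int = 10,
) -> tuple[dict[int, tuple[str, ...]], list[str]]:
    """Rank each group's labels by enrichment; return the retained union.

    Enrichment of a label for a group = (in-group frequency) − (overall
    frequency); descending, ties alphabetical.  Labels with non-positive
    enrichment never define a group.  The retained set is the union of every
    group's top ``top_n``.
    """
    cols = _state_columns(matrix, assignment.state)
    overall = matrix[cols].mean(axis=0)
    per_group: dict[int, tuple[str, ...]] = {}
    retained: set[str] = set()
    for g in sorted(set(assignment.groups.values())):
        members = assignment.members(g)
        freq = matrix.loc[members, cols].mean(axis=0)
        enrich = (freq - overall).sort_index()
        ranked = enrich.sort_values(ascending=False, kind="stable")
        top = tuple(ranked.index[i] for i in range(min(top_n, len(ranked))) if ranked.iloc[i] > 0)
        per_group[g] = top
        retained.update(top)
    return per_group, sorted(retained)


def group_difference_tests(
    score_table: pd.DataFrame,
    assignment: GroupAssignment,
) -> pd.DataFrame:
    """Two-sided Welch t-tests of every score between every group pair."""
    rows = []
    groups = sorted(set(assignment.groups.values()))
    numeric = score_table.select_dtypes(include=[np.number]).columns
    for a, b in itertools.combinations(groups, 2):
        va = [v for v in assignment.members(a) if v in score_table.index]
        vb = [v for v in assignment.members(b) if v in score_table.index]
        if len(va) < 2 or len(vb) < 2:
            logger.warning("group pair (%d, %d) skipped: fewer than 2 members", a, b)
            continue
        for col in numeric:
            xa = score_table.loc[va, col].dropna().to_numpy()
            xb = score_table.loc[vb, col].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            if np.std(xa) == 0 and np.std(xb) == 0 and np.mean(xa) == np.mean(xb):
                t, p = 0.0, 1.0
            else:
                t, p = ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {"group_a": a, "group_b": b, "score": col, "t": float(t), "p": float(p)}
            )
    return pd.DataFrame(rows)
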