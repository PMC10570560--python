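"""Pooled PCA, free-energy landscapes, and Switch-1 well occupancy.

The PCA is fit once on the pooled, flattened Cα coordinates of *all*
superposed ensembles (both nucleotide states, every variant and replicate),
so that a single set of collective coordinates describes the whole cohort.
Frames are then projected per state to build state-specific landscapes.

A free-energy landscape is the Boltzmann inversion of the sampling density,
F = −kT·ln(ρ/ρ_max), so the most occupied bin sits at F = 0.  Along the
GDP-state PC1, the density is bimodal: well I (positive side, Switch 1
folded in, predominantly WT-occupied) and well II (negative side, Switch 1
extended).  A variant's well-II occupancy ratio — 0 if it never leaves
well I, 1 if it never visits it — is the headline Switch-1 score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .trajectory import TrajectoryEnsemble

__all__ = [
    "PCModel",
    "FreeEnergyLandscape",
    "WellPartition",
    "UnimodalLandscapeError",
    "fit_pca",
    "project",
    "compute_fel",
    "detect_wells",
    "well_occupancy_ratio",
    "pc_standard_score",
    "framewise_correlation",
]


class UnimodalLandscapeError(ValueError):
    """Raised when fewer than two free-energy minima are detected."""


@dataclass(frozen=True)
class PCModel:
    """Mean conformation plus orthonormal principal axes of Cα motion."""

    mean: np.ndarray  # (3n,)
    components: np.ndarray  # (k, 3n), orthonormal rows
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components must be orthonormal")
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be non-increasing and sum <= 1")

    @property
    def k(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class FreeEnergyLandscape:
    """2-D free energy (kT units) over a PC subspace."""

    free_energy: np.ndarray  # (n_bins, n_bins)
    x_edges: np.ndarray
    y_edges: np.ndarray
    kT: float

    def __post_init__(self) -> None:
        if not np.isclose(np.min(self.free_energy), 0.0):
            raise ValueError("minimum free energy must be 0")


@dataclass(frozen=True)
class WellPartition:
    """1-D two-well partition of the GDP-state PC1 axis.

    ``boundary`` is the free-energy barrier position; well I is the positive
    side, well II the negative side.
    """

    boundary: float
    well_i_center: float
    well_ii_center: float

    def __post_init__(self) -> None:
        lo, hi = sorted((self.well_i_center, self.well_ii_center))
        if not (lo <= self.boundary <= hi):
            raise ValueError("boundary must lie between the two well centers")
        if self.well_i_center < self.well_ii_center:
            raise ValueError("well I must sit on the positive PC1 side")


def _flatten(ensembles: Sequence[TrajectoryEnsemble]) -> np.ndarray:
    n_res = ensembles[0].n_residues
    for e in ensembles:
        if e.n_residues != n_res:
            raise ValueError("all ensembles must share a residue count")
    return np.concatenate([e.coords.reshape(e.n_frames, -1) for e in ensembles])


def fit_pca(
    ensembles: Sequence[TrajectoryEnsemble],
    k: int = 3,
    random_state: int = 0,
) -> tuple[PCModel, pd.DataFrame]:
    """Fit pooled Cartesian-coordinate PCA and project every frame.

    Returns the model and a tidy projection table with one row per frame
    (variant, state, replicate, frame, PC1..PCk).  PC signs are fixed so the
    WT mean PC1 projection is non-negative (WT occupies the positive-side
    well I); PCs with no WT preference fall back to making the
    largest-magnitude loading positive.
    """
    X = _flatten(ensembles)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds available rank")
    pca = PCA(n_components=k, random_state=random_state)
    scores = pca.fit_transform(X)

    model_components = pca.components_.copy()
    wt_rows = np.concatenate(
        [
            np.full(e.n_frames, e.variant == "WT")
            for e in ensembles
        ]
    )
    for j in range(k):
        wt_mean = scores[wt_rows, j].mean() if wt_rows.any() else 0.0
        if abs(wt_mean) > 1e-9:
            flip = wt_mean < 0
        else:
            lead = model_components[j][np.argmax(np.abs(model_components[j]))]
            flip = lead < 0
        if flip:
            model_components[j] *= -1
            scores[:, j] *= -1

    model = PCModel(
        mean=pca.mean_,
        components=model_components,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    rows = []
    offset = 0
    for e in ensembles:
        block = scores[offset : offset + e.n_frames]
        offset += e.n_frames
        df = pd.DataFrame(block, columns=[f"PC{j + 1}" for j in range(k)])
        df.insert(0, "frame", np.arange(e.n_frames))
        df.insert(0, "replicate", e.replicate)
        df.insert(0, "state", e.state)
        df.insert(0, "variant", e.variant)
        rows.append(df)
    return model, pd.concat(rows, ignore_index=True)


def project(model: PCModel, ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Project an ensemble's frames onto the model's components."""
    X = ensemble.coords.reshape(ensemble.n_frames, -1)
    return (X - model.mean) @ model.components.T


def compute_fel(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 50,
    kT: float = 1.0,
) -> FreeEnergyLandscape:
    """Boltzmann-invert a 2-D sampling histogram into a free-energy surface.

    Occupied bins get F = −kT·ln(ρ/ρ_max); empty bins are assigned the
    maximum occupied value so the surface stays finite.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    hist, xe, ye = np.histogram2d(np.asarray(x), np.asarray(y), bins=n_bins)
    occupied = hist > 0
    if not occupied.any():
        raise ValueError("no frames to bin")
    F = np.full_like(hist, np.nan)
    F[occupied] = -kT * np.log(hist[occupied] / hist.max())
    F[~occupied] = np.nanmax(F)
    return FreeEnergyLandscape(free_energy=F, x_edges=xe, y_edges=ye, kT=kT)


def detect_wells(
    pc1: np.ndarray,
    smoothing_bandwidth: float = 0.5,
    n_grid: int = 512,
    kT: float = 1.0,
) -> WellPartition:
    """Locate the two GDP-state PC1 free-energy wells and the barrier between.

    A histogram of the pooled projections is smoothed with a Gaussian kernel
    of ``smoothing_bandwidth`` (PC units); the two highest-density local
    maxima become the wells and the density minimum between them the
    boundary.  Well I is the positive-side well.
    """
    pc1 = np.asarray(pc1, dtype=float)
    if pc1.size < 200:
        raise ValueError("well detection needs >= 200 pooled frames")
    lo, hi = pc1.min(), pc1.max()
    pad = 3 * smoothing_bandwidth
    edges = np.linspace(lo - pad, hi + pad, n_grid + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(pc1, bins=edges)
    bin_width = edges[1] - edges[0]
    density = gaussian_filter1d(
        counts.astype(float), sigma=smoothing_bandwidth / bin_width, mode="constant"
    )
    peaks = argrelextrema(density, np.greater_equal, order=2)[0]
    # collapse plateaus and drop zero-density artifacts
    peaks = np.array([p for p in peaks if density[p] > 0])
    if len(peaks) > 1:
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] <= 2 and np.isclose(density[p], density[keep[-1]]):
                continue
            keep.append(p)
        peaks = np.array(keep)
    if len(peaks) < 2:
        raise UnimodalLandscapeError("fewer than two free-energy minima detected")
    top2 = peaks[np.argsort(density[peaks])[-2:]]
    left, right = np.sort(top2)
    between = slice(left, right + 1)
    boundary_idx = left + int(np.argmin(density[between]))
    return WellPartition(
        boundary=float(centers[boundary_idx]),
        well_i_center=float(centers[right]),
        well_ii_center=float(centers[left]),
    )


def well_occupancy_ratio(pc1: np.ndarray, partition: WellPartition) -> float:
    """Fraction of frames in well II (the negative, Switch-1-extended side)."""
    pc1 = np.asarray(pc1, dtype=float)
    if pc1.size == 0:
        raise ValueError("no frames given")
    return float(np.mean(pc1 < partition.boundary))


def pc_standard_score(
    variant_proj: np.ndarray, wt_proj: np.ndarray
) -> float:
    """Variant mean projection in WT standard deviations from the WT mean."""
    wt_proj = np.asarray(wt_proj, dtype=float)
    sd = float(np.std(wt_proj, ddof=0))
    if sd == 0:
        raise ValueError("degenerate WT spread on this PC")
    return float((np.mean(variant_proj) - np.mean(wt_proj)) / sd)


def framewise_correlation(
    projections: pd.DataFrame,
    monitors: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Spearman correlation of each PC with each monitor, pooled over frames.

    ``projections`` and ``monitors`` must be frame-aligned (same row order).
    Constant series yield an undefined correlation, reported as NaN rather
    than 0.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlations are supported")
    if len(projections) != len(monitors):
        raise ValueError("frame-aligned tables required")
    pc_cols = [c for c in projections.columns if c.startswith("PC")]
    out = pd.DataFrame(index=pc_cols, columns=monitors.columns, dtype=float)
    for pc in pc_cols:
        x = projections[pc].to_numpy()
        for mon in monitors.columns:
            y = monitors[mon].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                out.loc[pc, mon] = np.nan
                continue
            rho = spearmanr(x, y).statistic
            out.loc[pc, mon] = rho
    return out
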