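"""Per-variant scalar descriptors.

Three families of descriptors summarize each (variant, nucleotide state):

* **Distance monitors** — ten residue-pair distances that the RAS literature
  has characterized as markers of biophysical phenomena (Switch-2 loop-out,
  p-loop/Switch-2 coupling, Switch-1/Switch-2 coordination, Mg²⁺/T35
  coordination).  The packaged catalogue transcribes these pairs.
* **Ligand interaction energy** — per-frame nucleotide–protein interaction
  energy series (kcal/mol, negative = favorable), consumed as data and
  summarized in WT standard deviations.
* **RMSD to binding-competent references** — mean Cα RMSD of evenly selected
  frames against GAP-bound-like (NF1) and GEF-bound-like (SOS1) reference
  conformations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory import (
    ResidueRegionMap,
    StructureModel,
    TrajectoryEnsemble,
    kabsch_transform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Monitor",
    "MonitorCatalogue",
    "EnergySeries",
    "ReferenceSet",
    "FUNCTIONAL_ATOMS",
    "monitor_distances",
    "summarize_metric",
    "interaction_energy_summary",
    "select_frames",
    "rmsd_to_reference",
]

#: Fixed per-residue "functional atom" used when side-chain coordinates are
#: available; Cα–Cα is the default convention for Cα-only trajectories.
FUNCTIONAL_ATOMS: dict[str, str] = {
    "GLY": "CA",
    "TYR": "OH",
    "GLN": "NE2",
    "GLU": "CD",
    "ASP": "CG",
    "HIS": "NE2",
    "ALA": "CB",
    "SER": "OG",
    "THR": "OG1",
    "ILE": "CD1",
}

THEMES = (
    "switch2_helix3_loopout",
    "ploop_switch2_coupling",
    "switch1_switch2_coordination",
    "mg_t35_coordination",
)


@dataclass(frozen=True)
class Monitor:
    name: str
    res1: int
    aa1: str
    res2: int
    aa2: str
    theme: str
    description: str = ""
    mutation_studied: str = ""


@dataclass(frozen=True)
class MonitorCatalogue:
    """The residue-pair distance monitors and their biophysical themes."""

    monitors: tuple[Monitor, ...]

    def __post_init__(self) -> None:
        pairs = [(m.res1, m.res2) for m in self.monitors]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate monitor residue pairs")
        for m in self.monitors:
            if m.res1 < 1 or m.res2 < 1:
                raise ValueError(f"monitor {m.name}: invalid residue ids")
            if m.theme not in THEMES:
                raise ValueError(f"monitor {m.name}: unknown theme {m.theme!r}")

    def __len__(self) -> int:
        return len(self.monitors)

    @property
    def themes(self) -> set[str]:
        return {m.theme for m in self.monitors}

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.monitors]

    @classmethod
    def default(cls) -> "MonitorCatalogue":
        """Load the packaged catalogue of ten experimentally grounded pairs."""
        with resources.files("krasdyn.data").joinpath("monitors.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MonitorCatalogue":
        return cls(
            tuple(
                Monitor(
                    name=row["name"],
                    res1=int(row["res1"]),
                    aa1=row["aa1"],
                    res2=int(row["res2"]),
                    aa2=row["aa2"],
                    theme=row["theme"],
                    description=row.get("description", ""),
                    mutation_studied=row.get("mutation_studied", ""),
                )
                for _, row in df.iterrows()
            )
        )


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame ligand–protein interaction energy for one replicate."""

    variant: str
    state: str
    replicate: int
    energies: np.ndarray  # kcal/mol, negative = favorable

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or not np.all(np.isfinite(e)):
            raise ValueError("energies must be a finite 1-D series")

    @classmethod
    def read_csv(cls, path: str | Path, variant: str, state: str, replicate: int) -> "EnergySeries":
        df = pd.read_csv(path)
        return cls(variant, state, replicate, df["energy"].to_numpy(dtype=float))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frame": np.arange(len(self.energies)), "energy": self.energies}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ReferenceSet:
    """Named reference conformations (WT initial, NF1-bound-like, SOS1-bound-like)."""

    references: Mapping[str, StructureModel]

    def __post_init__(self) -> None:
        counts = {name: ref.n_residues for name, ref in self.references.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"reference residue counts differ: {counts}")

    def __getitem__(self, name: str) -> StructureModel:
        return self.references[name]

    def items(self):
        return self.references.items()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def monitor_distances(
    ensemble: TrajectoryEnsemble,
    catalogue: MonitorCatalogue | None = None,
    atom_convention: str = "ca",
    sidechain_frames: Sequence[Mapping[int, Mapping[str, np.ndarray]]] | None = None,
) -> pd.DataFrame:
    """Per-frame Euclidean distance (Å) for every monitor pair.

    ``atom_convention='ca'`` measures Cα–Cα.  ``'functional'`` uses the fixed
    per-residue functional atom where per-frame side-chain coordinates are
    supplied, falling back to Cα otherwise.
    """
    catalogue = catalogue or MonitorCatalogue.default()
    id_to_idx = {int(r): i for i, r in enumerate(ensemble.residue_ids)}
    cols = {}
    for mon in catalogue.monitors:
        for res in (mon.res1, mon.res2):
            if res not in id_to_idx:
                raise ValueError(
                    f"monitor {mon.name}: residue {res} missing from ensemble"
                )
        a = _monitor_coords(ensemble, mon.res1, mon.aa1, id_to_idx, atom_convention, sidechain_frames)
        b = _monitor_coords(ensemble, mon.res2, mon.aa2, id_to_idx, atom_convention, sidechain_frames)
        cols[mon.name] = np.linalg.norm(a - b, axis=1)
    return pd.DataFrame(cols)


def _monitor_coords(ensemble, res_id, aa, id_to_idx, convention, sidechain_frames):
    ca = ensemble.coords[:, id_to_idx[res_id], :]
    if convention == "ca":
        return ca
    if convention == "functional":
        atom = FUNCTIONAL_ATOMS.get(aa, "CA")
        if atom == "CA" or sidechain_frames is None:
            return ca
        out = np.array(
            [
                sidechain_frames[f].get(res_id, {}).get(atom, ca[f])
                for f in range(ensemble.n_frames)
            ]
        )
        return out
    raise ValueError(f"unknown atom convention {convention!r}")


def summarize_metric(series: np.ndarray, wt_series: np.ndarray) -> dict[str, float]:
    """Median/mean/sd summary plus the WT-standardized score.

    z = (median_mut − median_wt) / sd_wt: how many WT standard deviations a
    variant's typical value sits from the WT typical value.
    """
    series = np.asarray(series, dtype=float)
    wt_series = np.asarray(wt_series, dtype=float)
    if wt_series.size == 0:
        raise ValueError("WT series is empty")
    sd_wt = float(np.std(wt_series, ddof=0))
    if sd_wt == 0:
        raise ValueError("degenerate WT spread (sd = 0)")
    return {
        "median": float(np.median(series)),
        "mean": float(np.mean(series)),
        "sd": float(np.std(series, ddof=0)),
        "z": float((np.median(series) - np.median(wt_series)) / sd_wt),
    }


def interaction_energy_summary(
    series: Sequence[EnergySeries],
    wt: Sequence[EnergySeries],
) -> dict[str, float]:
    """Replicate-pooled mean E_int and its score in WT standard deviations.

    Positive z means a *less* favorable (destabilized) nucleotide interaction
    than WT.
    """
    if not series:
        raise ValueError("no replicate energy series given")
    if not wt:
        raise ValueError(f"missing WT energy series for state {series[0].state!r}")
    pooled = np.concatenate([s.energies for s in series])
    wt_pooled = np.concatenate([s.energies for s in wt])
    sd_wt = float(np.std(wt_pooled, ddof=0))
    if sd_wt == 0:
        raise ValueError("degenerate WT energy spread")
    mean = float(np.mean(pooled))
    return {
        "mean": mean,
        "sd": float(np.std(pooled, ddof=0)),
        "z": float((mean - np.mean(wt_pooled)) / sd_wt),
    }


def select_frames(n_frames: int, n_samples: int) -> np.ndarray:
    """Evenly strided frame indices, first frame always included.

    10 frames at n_samples=5 → {0, 2, 4, 6, 8}.  n_samples larger than the
    trajectory clamps to every frame (with a logged warning).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples > n_frames:
        logger.warning(
            "n_samples=%d exceeds n_frames=%d; clamping", n_samples, n_frames
        )
        n_samples = n_frames
    stride = max(1, n_frames // n_samples)
    return np.arange(0, n_frames, stride)[:n_samples]


def rmsd_to_reference(
    ensemble: TrajectoryEnsemble,
    refs: ReferenceSet,
    n_samples: int = 100,
    *,
    exclude_regions: Sequence[str] = ("switch1", "switch2"),
    region_map: ResidueRegionMap | None = None,
    per_frame: bool = False,
) -> dict[str, float] | dict[str, np.ndarray]:
    """Mean Cα RMSD (Å) of evenly selected frames against each reference.

    Each selected frame is independently superposed onto the reference on the
    non-Switch fit set; the RMSD is then taken over *all* residues, so it
    reports how far the Switch conformation sits from the binding-competent
    pose.  ``per_frame=True`` returns the full selected-frame series instead
    of the mean (used for WT-standardization).
    """
    region_map = region_map or ResidueRegionMap()
    idx = select_frames(ensemble.n_frames, n_samples)
    out: dict[str, object] = {}
    for name, ref in refs.items():
        if ref.n_residues != ensemble.n_residues:
            raise ValueError(f"reference {name!r} residue count mismatch")
        excl = region_map.mask(ensemble.residue_ids, exclude_regions)
        fit = ~excl
        ref_fit = ref.coords[fit]
        vals = np.empty(len(idx))
        for j, f in enumerate(idx):
            R, mc, tc = kabsch_transform(ensemble.coords[f][fit], ref_fit)
            aligned = (ensemble.coords[f] - mc) @ R.T + tc
            vals[j] = np.sqrt(np.mean(np.sum((aligned - ref.coords) ** 2, axis=1)))
        out[name] = vals if per_frame else float(np.mean(vals))
    return out  # type: ignore[return-value]
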