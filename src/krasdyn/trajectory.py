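"""Domain types and primitives for Cα trajectory ensembles.

The atom of all structural computation here is the :class:`TrajectoryEnsemble`:
the Cα coordinates of one (variant, nucleotide state, replicate) system over
time.  Everything downstream — superposition, RMSD/RMSF, PCA, distance
monitors — consumes these arrays.

Conventions
-----------
* Residue ids are 1-based and contiguous (KRAS G-domain numbering, UniProt
  P01116).
* Coordinates are in Å.  Frame indices are 0-based.
* Superposition is a rigid Kabsch fit on Cα atoms outside the two mobile
  Switch loops, mirroring how GTPase trajectories are conventionally aligned
  so that Switch motion is measured rather than fitted away.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "ResidueRegionMap",
    "StructureModel",
    "TrajectoryEnsemble",
    "FlexibilityProfile",
    "TrajectoryFormatError",
    "DegenerateFitError",
    "read_trajectory",
    "write_trajectory",
    "read_structure",
    "write_structure",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "ssr_from_profile",
]

#: Conventional KRAS region bounds (1-based, inclusive).  The p-loop wraps the
#: nucleotide phosphates; Switch 1/2 are the mobile effector-binding loops;
#: the allosteric lobe is the C-terminal half of the G-domain.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "p_loop": (10, 17),
    "switch1": (30, 38),
    "switch2": (59, 76),
    "allosteric_lobe": (87, 166),
}


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates the declared format."""


class DegenerateFitError(ValueError):
    """Raised when too few residues remain to define a rigid-body fit."""


@dataclass(frozen=True)
class ResidueRegionMap:
    """Named residue regions as inclusive 1-based intervals."""

    regions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"region {name!r} has invalid bounds ({lo}, {hi})")
        s1, s2 = self.regions.get("switch1"), self.regions.get("switch2")
        if s1 and s2 and not (s1[1] < s2[0] or s2[1] < s1[0]):
            raise ValueError("switch1 and switch2 intervals overlap")

    def mask(self, residue_ids: np.ndarray, names: Iterable[str]) -> np.ndarray:
        """Boolean mask over ``residue_ids`` covering the union of ``names``."""
        mask = np.zeros(len(residue_ids), dtype=bool)
        for name in names:
            try:
                lo, hi = self.regions[name]
            except KeyError:
                raise KeyError(f"unknown region {name!r}") from None
            mask |= (residue_ids >= lo) & (residue_ids <= hi)
        return mask

    def validate_against(self, n_residues: int) -> None:
        for name, (lo, hi) in self.regions.items():
            if hi > n_residues:
                raise ValueError(
                    f"region {name!r} upper bound {hi} exceeds chain length {n_residues}"
                )


@dataclass(frozen=True)
class StructureModel:
    """A single conformation: one Cα per residue, optional side-chain atoms.

    ``sidechain`` maps residue id → {atom name → xyz}, used only by the
    functional-atom monitor convention.
    """

    residue_ids: np.ndarray
    residue_names: tuple[str, ...]
    coords: np.ndarray
    sidechain: Mapping[int, Mapping[str, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.residue_ids, dtype=int)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_ids", ids)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(ids), 3):
            raise ValueError("coords must be (n_residues, 3)")
        if len(self.residue_names) != len(ids):
            raise ValueError("one residue name per residue required")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate residue ids (one Cα per residue)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Cα frames for one (variant, nucleotide state, replicate)."""

    variant: str
    state: str
    replicate: int
    coords: np.ndarray  # (n_frames, n_residues, 3), Å
    residue_ids: np.ndarray
    residue_names: tuple[str, ...] = ()
    frame_stride: float = 1.0  # metadata: analysis frames per stored frame

    def __post_init__(self) -> None:
        if self.state not in ("GDP", "GTP"):
            raise ValueError(f"nucleotide state must be GDP or GTP, got {self.state!r}")
        coords = np.asarray(self.coords, dtype=float)
        ids = np.asarray(self.residue_ids, dtype=int)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", ids)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_residues, 3)")
        if coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if coords.shape[1] != len(ids):
            raise ValueError("residue ids must match coordinate second axis")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "TrajectoryEnsemble":
        return replace(self, coords=coords)


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-residue RMSF (Å), optionally averaged over replicates."""

    residue_ids: np.ndarray
    rmsf: np.ndarray
    replicate_averaged: bool = False

    def __post_init__(self) -> None:
        rmsf = np.asarray(self.rmsf, dtype=float)
        object.__setattr__(self, "rmsf", rmsf)
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, dtype=int))
        if rmsf.ndim != 1 or len(rmsf) != len(self.residue_ids):
            raise ValueError("one RMSF value per residue required")
        if np.any(rmsf < 0):
            raise ValueError("RMSF must be non-negative")


# ---------------------------------------------------------------------------
# I/O: multi-model PDB and the frames_table CSV dialect
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, res_name: str, res_id: int, xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:>5d}  CA  {res_name:<3s} A{res_id:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single-model Cα PDB."""
    lines = [
        _pdb_atom_line(i + 1, model.residue_names[i], int(model.residue_ids[i]), model.coords[i])
        for i in range(model.n_residues)
    ]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path) -> StructureModel:
    """Read a single-model PDB, keeping Cα atoms and side-chain heavy atoms."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise TrajectoryFormatError(f"no Cα atoms in {path}")
    order = np.argsort(ca.res_id, kind="stable")
    sidechain: dict[int, dict[str, np.ndarray]] = {}
    heavy = atoms[(atoms.atom_name != "CA") & (atoms.element != "H")]
    for i in range(heavy.array_length()):
        rid = int(heavy.res_id[i])
        sidechain.setdefault(rid, {})[str(heavy.atom_name[i])] = heavy.coord[i].astype(float)
    return StructureModel(
        residue_ids=ca.res_id[order],
        residue_names=tuple(str(n) for n in ca.res_name[order]),
        coords=ca.coord[order].astype(float),
        sidechain=sidechain or None,
    )


def _read_pdb_multimodel(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise TrajectoryFormatError(f"empty PDB file: {path}")
    frames = []
    ref_ids: np.ndarray | None = None
    names: tuple[str, ...] = ()
    for m in range(1, n_models + 1):
        atoms = pdb_file.get_structure(model=m)
        ca = atoms[atoms.atom_name == "CA"]
        order = np.argsort(ca.res_id, kind="stable")
        ids = ca.res_id[order]
        if ref_ids is None:
            ref_ids = ids
            names = tuple(str(n) for n in ca.res_name[order])
        elif len(ids) != len(ref_ids) or not np.array_equal(ids, ref_ids):
            raise TrajectoryFormatError(
                f"model {m} has inconsistent residues "
                f"({len(ids)} Cα vs {len(ref_ids)} in model 1)"
            )
        frames.append(ca.coord[order].astype(float))
    return np.stack(frames), ref_ids, names


def read_trajectory(
    path: str | Path,
    format: str = "pdb_multimodel",
    *,
    variant: str = "unknown",
    state: str = "GDP",
    replicate: int = 1,
) -> TrajectoryEnsemble:
    """Read an ensemble from a multi-model PDB or a frames_table CSV.

    The frames_table dialect is a headered CSV with columns
    ``frame,residue,x,y,z`` (frame 0-based, residue 1-based, Å).
    """
    path = Path(path)
    if format == "pdb_multimodel":
        coords, ids, names = _read_pdb_multimodel(path)
        return TrajectoryEnsemble(variant, state, replicate, coords, ids, names)
    if format == "frames_table":
        if path.stat().st_size == 0:
            raise TrajectoryFormatError(f"empty file: {path}")
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"frame", "residue", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise TrajectoryFormatError(
                f"frames_table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        frames = sorted(df["frame"].unique())
        ids = np.sort(df.loc[df["frame"] == frames[0], "residue"].unique())
        coords = np.empty((len(frames), len(ids), 3))
        for fi, f in enumerate(frames):
            sub = df[df["frame"] == f].sort_values("residue")
            if len(sub) != len(ids) or not np.array_equal(sub["residue"].to_numpy(), ids):
                raise TrajectoryFormatError(f"frame {f} has inconsistent residues")
            coords[fi] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        return TrajectoryEnsemble(variant, state, replicate, coords, ids)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(ensemble: TrajectoryEnsemble, path: str | Path, format: str = "pdb_multimodel") -> None:
    """Write an ensemble; frames_table round-trips coordinates bit-identically."""
    path = Path(path)
    if format == "pdb_multimodel":
        names = ensemble.residue_names or tuple("ALA" for _ in ensemble.residue_ids)
        with open(path, "w") as fh:
            for f in range(ensemble.n_frames):
                fh.write(f"MODEL     {f + 1:>4d}\n")
                for i, rid in enumerate(ensemble.residue_ids):
                    fh.write(_pdb_atom_line(i + 1, names[i], int(rid), ensemble.coords[f, i]) + "\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    if format == "frames_table":
        n_f, n_r = ensemble.n_frames, ensemble.n_residues
        buf = io.StringIO()
        buf.write("frame,residue,x,y,z\n")
        for f in range(n_f):
            for i, rid in enumerate(ensemble.residue_ids):
                x, y, z = (float(v) for v in ensemble.coords[f, i])
                # repr-level precision so read→write→read is bit-identical
                buf.write(f"{f},{int(rid)},{x!r},{y!r},{z!r}\n")
        Path(path).write_text(buf.getvalue())
        return
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Superposition and deviation primitives
# ---------------------------------------------------------------------------

def kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping ``mobile`` onto ``target``.

    Returns ``(R, mobile_centroid, target_centroid)`` such that
    ``(x - mobile_centroid) @ R.T + target_centroid`` minimizes the RMSD.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.as_matrix(), mc, tc


def superpose(
    ensemble: TrajectoryEnsemble,
    reference: StructureModel,
    exclude_regions: Sequence[str] = ("switch1", "switch2"),
    region_map: ResidueRegionMap | None = None,
) -> TrajectoryEnsemble:
    """Rigidly fit every frame onto ``reference``, ignoring the Switch loops.

    The rotation/translation is computed on Cα atoms *outside*
    ``exclude_regions`` and applied to all atoms, so Switch motion is
    preserved in the aligned frame.  Returns a new ensemble.
    """
    if ensemble.n_residues != reference.n_residues:
        raise ValueError("ensemble and reference residue counts differ")
    region_map = region_map or ResidueRegionMap()
    excl = region_map.mask(ensemble.residue_ids, exclude_regions) if exclude_regions else \
        np.zeros(ensemble.n_residues, dtype=bool)
    fit = ~excl
    if fit.sum() < 3:
        raise DegenerateFitError(
            f"only {int(fit.sum())} residues left for fitting; need >= 3"
        )
    ref_fit = reference.coords[fit]
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        R, mc, tc = kabsch_transform(ensemble.coords[f][fit], ref_fit)
        out[f] = (ensemble.coords[f] - mc) @ R.T + tc
    return ensemble.with_coords(out)


def rmsd_series(
    ensemble: TrajectoryEnsemble,
    reference: StructureModel,
    selection: np.ndarray | None = None,
    *,
    superpose_first: bool = False,
    exclude_regions: Sequence[str] = ("switch1", "switch2"),
    region_map: ResidueRegionMap | None = None,
) -> np.ndarray:
    """Per-frame Cα RMSD (Å) to ``reference`` over ``selection`` (bool mask)."""
    if superpose_first:
        ensemble = superpose(ensemble, reference, exclude_regions, region_map)
    if selection is None:
        selection = np.ones(ensemble.n_residues, dtype=bool)
    selection = np.asarray(selection, dtype=bool)
    if selection.sum() == 0:
        raise ValueError("empty residue selection")
    diff = ensemble.coords[:, selection, :] - reference.coords[selection]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def rmsf_profile(ensembles: Sequence[TrajectoryEnsemble]) -> FlexibilityProfile:
    """Replicate-averaged per-residue RMSF.

    Each replicate's RMSF_i is the root time-mean squared deviation of residue
    i from its own time-mean position; the profile is the arithmetic mean over
    replicates.  Replicates must already be superposed to a common reference.
    """
    if not ensembles:
        raise ValueError("no replicates given")
    profiles = []
    ids = ensembles[0].residue_ids
    for ens in ensembles:
        if ens.n_frames < 2:
            raise ValueError("RMSF needs at least 2 frames per replicate")
        if not np.array_equal(ens.residue_ids, ids):
            raise ValueError("replicates must share residue ids")
        mean_pos = ens.coords.mean(axis=0)
        dev = ens.coords - mean_pos
        profiles.append(np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0)))
    return FlexibilityProfile(
        residue_ids=ids,
        rmsf=np.mean(profiles, axis=0),
        replicate_averaged=len(ensembles) > 1,
    )


def ssr_from_profile(mut: FlexibilityProfile, wt: FlexibilityProfile) -> float:
    """Sum of squared residuals (Å²) between two RMSF profiles."""
    if len(mut.rmsf) != len(wt.rmsf):
        raise ValueError(
            f"profile lengths differ ({len(mut.rmsf)} vs {len(wt.rmsf)})"
        )
    return float(np.sum((mut.rmsf - wt.rmsf) ** 2))
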