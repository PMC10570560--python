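"""End-to-end orchestration: cohort → scores → classes → groups → embedding.

``simulate_cohort`` materializes a synthetic cohort; ``analyze_cohort`` runs
the whole scoring and meta-classification stack over any set of superposable
ensembles and energy series; ``write_results`` serializes every artifact as
CSV/JSON.  All steps are deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    STATES,
    ClassificationConfig,
    GroupAssignment,
    build_metaclass_matrix,
    defining_features,
    group_difference_tests,
    kmeans_groups,
    label_vocabulary,
)
from .config import RunConfig
from .descriptors import (
    EnergySeries,
    MonitorCatalogue,
    ReferenceSet,
    interaction_energy_summary,
    monitor_distances,
    rmsd_to_reference,
    summarize_metric,
)
from .embedding import assemble_score_matrix, embed_2d, metric_correlation_matrix
from .landscape import (
    FreeEnergyLandscape,
    PCModel,
    UnimodalLandscapeError,
    WellPartition,
    compute_fel,
    detect_wells,
    framewise_correlation,
    fit_pca,
    pc_standard_score,
    well_occupancy_ratio,
)
from .synthetic import (
    GroundTruth,
    SyntheticSpec,
    build_template,
    make_reference_set,
    preset_cohort,
    simulate_system,
)
from .trajectory import (
    ResidueRegionMap,
    TrajectoryEnsemble,
    rmsf_profile,
    ssr_from_profile,
    superpose,
    write_trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortData",
    "AnalysisResult",
    "simulate_cohort",
    "analyze_cohort",
    "write_results",
    "cmd_simulate",
    "cmd_analyze",
    "render_fel",
]

#: WT per-replicate occupancy spread floor for the PC1-fraction score family
#: (WT rarely samples well II, so the raw 3-replicate sd can degenerate).
_OCCUPANCY_SD_FLOOR = 0.01


@dataclass
class CohortData:
    ensembles: list[TrajectoryEnsemble]
    energies: list[EnergySeries]
    truths: dict[tuple[str, str], GroundTruth] = field(default_factory=dict)


@dataclass
class AnalysisResult:
    pc_model: PCModel
    projections: pd.DataFrame
    landscapes: dict[str, FreeEnergyLandscape]
    partition: WellPartition | None
    score_table: pd.DataFrame  # (variant, state) × metric
    class_scores: pd.DataFrame  # variant × WT-standardized score columns
    metaclass_matrix: pd.DataFrame
    assignments: dict[str, GroupAssignment]
    signatures: dict[str, dict[int, tuple[str, ...]]]
    retained_labels: dict[str, list[str]]
    ttests: dict[str, pd.DataFrame]
    metric_correlations: pd.DataFrame
    pc_monitor_correlations: dict[str, pd.DataFrame]
    embedding: pd.DataFrame
    run_log: dict


def simulate_cohort(config: RunConfig) -> CohortData:
    """Generate the configured synthetic preset, superposition-ready."""
    specs = preset_cohort(config.preset, config.seed)
    if config.n_frames_override:
        specs = [replace(s, n_frames=config.n_frames_override) for s in specs]
    if config.n_residues_override:
        specs = [replace(s, n_residues=config.n_residues_override) for s in specs]
    template, modes = build_template(specs[0].n_residues)
    data = CohortData([], [], {})
    for spec in specs:
        ens, en, truth = simulate_system(spec, template, modes)
        data.ensembles.extend(ens)
        data.energies.extend(en)
        data.truths[(spec.variant, spec.state)] = truth
    # E_int z ground truth relative to WT
    for state in STATES:
        wt = data.truths.get(("WT", state))
        if wt is None:
            continue
        for key, truth in data.truths.items():
            if key[1] == state:
                data.truths[key] = replace(
                    truth, eint_z_star=(truth.eint_mean - wt.eint_mean) / wt.eint_sd
                )
    return data


def _group_systems(
    ensembles: Sequence[TrajectoryEnsemble],
) -> dict[tuple[str, str], list[TrajectoryEnsemble]]:
    out: dict[tuple[str, str], list[TrajectoryEnsemble]] = {}
    for e in ensembles:
        out.setdefault((e.variant, e.state), []).append(e)
    return out


def analyze_cohort(
    cohort: CohortData,
    config: RunConfig,
    references: ReferenceSet | None = None,
    catalogue: MonitorCatalogue | None = None,
) -> AnalysisResult:
    """Run the full scoring and meta-classification stack over a cohort."""
    cc = config.classification
    catalogue = catalogue or MonitorCatalogue.default()
    region_map = ResidueRegionMap(
        {k: tuple(v) for k, v in config.regions.items()}
    )
    n_res = cohort.ensembles[0].n_residues
    if references is None:
        template, modes = build_template(n_res)
        references = make_reference_set(template, modes)
    wt_ref = references["wt_initial"]

    logger.info("superposing %d ensembles", len(cohort.ensembles))
    aligned = [
        superpose(e, wt_ref, ("switch1", "switch2"), region_map)
        for e in cohort.ensembles
    ]
    systems = _group_systems(aligned)
    variants = sorted({v for v, _ in systems}, key=lambda v: (v != "WT", v))

    logger.info("fitting pooled PCA (k=%d)", config.n_pcs)
    pc_model, projections = fit_pca(aligned, k=config.n_pcs, random_state=config.seed)

    landscapes = {}
    for state in STATES:
        sub = projections[projections["state"] == state]
        if len(sub) and config.n_pcs >= 2:
            landscapes[state] = compute_fel(
                sub["PC1"], sub["PC2"], n_bins=config.fel_bins, kT=config.kT
            )

    gdp_pc1 = projections.loc[projections["state"] == "GDP", "PC1"].to_numpy()
    try:
        partition = detect_wells(gdp_pc1, config.well_bandwidth, kT=config.kT)
    except (UnimodalLandscapeError, ValueError) as exc:
        logger.warning("well detection fell back to configured boundary: %s", exc)
        partition = WellPartition(
            boundary=config.fallback_boundary,
            well_i_center=config.fallback_boundary + 1.0,
            well_ii_center=config.fallback_boundary - 1.0,
        )

    # ---- per-(variant, state) metric computation -------------------------
    energies_by_system: dict[tuple[str, str], list[EnergySeries]] = {}
    for s in cohort.energies:
        energies_by_system.setdefault((s.variant, s.state), []).append(s)

    # monitor tables built in ensemble order so rows stay frame-aligned with
    # the projection table
    mon_frames = [monitor_distances(e, catalogue) for e in aligned]
    mon_all = pd.concat(mon_frames, ignore_index=True)
    monitor_cache: dict[tuple[str, str], pd.DataFrame] = {}
    for e, df in zip(aligned, mon_frames):
        key = (e.variant, e.state)
        monitor_cache[key] = (
            pd.concat([monitor_cache[key], df], ignore_index=True)
            if key in monitor_cache
            else df
        )

    # per-frame RMSD to every reference, pooled over replicates, per system
    ref_series_by_system: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for key, reps in systems.items():
        per_rep = [
            rmsd_to_reference(
                e, references, config.n_ref_samples,
                region_map=region_map, per_frame=True,
            )
            for e in reps
        ]
        ref_series_by_system[key] = {
            name: np.concatenate([d[name] for d in per_rep])
            for name, _ in references.items()
        }

    proj_by_system = {
        key: projections[
            (projections["variant"] == key[0]) & (projections["state"] == key[1])
        ]
        for key in systems
    }
    rmsf_by_system = {key: rmsf_profile(reps) for key, reps in systems.items()}
    wt_occ_reps: dict[str, list[float]] = {}
    for state in STATES:
        key = ("WT", state)
        if key in systems:
            wt_occ_reps[state] = [
                well_occupancy_ratio(
                    proj_by_system[key].loc[
                        proj_by_system[key]["replicate"] == r, "PC1"
                    ].to_numpy(),
                    partition,
                )
                for r in sorted(proj_by_system[key]["replicate"].unique())
            ]

    metrics: dict[tuple[str, str], dict[str, float]] = {}
    class_rows: dict[str, dict[str, float]] = {v: {} for v in variants}
    for (variant, state), reps in systems.items():
        key = (variant, state)
        wt_key = ("WT", state)
        if wt_key not in systems:
            raise ValueError(f"cohort lacks a WT system for state {state}")
        row: dict[str, float] = {}

        e_summary = interaction_energy_summary(
            energies_by_system[key], energies_by_system[wt_key]
        )
        row["eint_mean"] = e_summary["mean"]
        row["eint_z"] = e_summary["z"]
        class_rows[variant][f"eint_z_{state}"] = e_summary["z"]

        ref_series = ref_series_by_system[key]
        wt_ref_series = ref_series_by_system[wt_key]
        for name, short in (("nf1_bound", "nf1"), ("sos1_bound", "sos1"), ("wt_initial", "wt_initial")):
            vals = ref_series[name]
            row[f"rmsd_{short}"] = float(np.mean(vals))
            sd = float(np.std(wt_ref_series[name]))
            z = float((np.mean(vals) - np.mean(wt_ref_series[name])) / sd) if sd > 0 else 0.0
            if short in ("nf1", "sos1"):
                class_rows[variant][f"rmsd_{short}_z_{state}"] = z

        prof = rmsf_by_system[key]
        wt_prof = rmsf_by_system[wt_key]
        row["rmsf_global"] = float(np.mean(prof.rmsf))
        for region in ("switch1", "switch2", "allosteric_lobe"):
            mask = region_map.mask(prof.residue_ids, [region])
            row[f"rmsf_{region}"] = float(np.mean(prof.rmsf[mask]))
        ssr = ssr_from_profile(prof, wt_prof)
        row["ssr"] = ssr
        class_rows[variant][f"ssr_{state}"] = ssr

        proj = proj_by_system[key]
        wt_proj = proj_by_system[wt_key]
        for j in range(1, config.n_pcs + 1):
            z = pc_standard_score(
                proj[f"PC{j}"].to_numpy(), wt_proj[f"PC{j}"].to_numpy()
            )
            row[f"pc{j}_z"] = z
        if state == "GDP":
            ratio = well_occupancy_ratio(proj["PC1"].to_numpy(), partition)
            row["well_occupancy_ratio"] = ratio
            occ = wt_occ_reps["GDP"]
            sd = max(float(np.std(occ)), _OCCUPANCY_SD_FLOOR)
            class_rows[variant]["pc1_fraction_z"] = float(
                (ratio - np.mean(occ)) / sd
            )

        mons = monitor_cache[key]
        wt_mons = monitor_cache[wt_key]
        for name in catalogue.names:
            summ = summarize_metric(mons[name].to_numpy(), wt_mons[name].to_numpy())
            row[f"monitor_med:{name}"] = summ["median"]
            class_rows[variant][f"monitor_z:{name}:{state}"] = summ["z"]
        metrics[key] = row

    score_table = assemble_score_matrix(metrics)
    class_scores = pd.DataFrame.from_dict(class_rows, orient="index").sort_index()
    class_scores.index.name = "variant"

    metaclass = build_metaclass_matrix(class_scores, cc, catalogue.names)
    assignments, signatures, retained, ttests = {}, {}, {}, {}
    for state in STATES:
        assign = kmeans_groups(metaclass, state, cc.k, cc.seed, cc.n_restarts)
        per_group, kept = defining_features(assign, metaclass, cc.top_n)
        assignments[state] = GroupAssignment(state, assign.groups, per_group)
        signatures[state] = per_group
        retained[state] = kept
        ttests[state] = group_difference_tests(class_scores, assign)

    corr = metric_correlation_matrix(score_table)
    pc_mon = {}
    state_mask = projections["state"].to_numpy()
    for state in STATES:
        rows = state_mask == state
        pc_mon[state] = framewise_correlation(
            projections.loc[rows].reset_index(drop=True),
            mon_all.loc[rows].reset_index(drop=True),
        )

    emb = embed_2d(score_table, config.embedding_method, config.seed)

    total_groups = sum(a.k for a in assignments.values())
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "n_variants": len(variants),
        "n_systems": len(systems),
        "n_frames_total": int(sum(e.n_frames for e in aligned)),
        "label_vocabulary_size": int(metaclass.shape[1]),
        "retained_label_count": {s: len(retained[s]) for s in STATES},
        "group_sizes": {s: assignments[s].sizes() for s in STATES},
        "total_groups": total_groups,
        "pc_variance_pct": [
            float(100 * f) for f in pc_model.explained_variance_ratio
        ],
        "well_boundary": partition.boundary if partition else None,
    }
    logger.info(
        "label vocabulary: %d columns; %d total groups",
        metaclass.shape[1],
        total_groups,
    )
    return AnalysisResult(
        pc_model=pc_model,
        projections=projections,
        landscapes=landscapes,
        partition=partition,
        score_table=score_table,
        class_scores=class_scores,
        metaclass_matrix=metaclass,
        assignments=assignments,
        signatures=signatures,
        retained_labels=retained,
        ttests=ttests,
        metric_correlations=corr,
        pc_monitor_correlations=pc_mon,
        embedding=emb,
        run_log=run_log,
    )


# ---------------------------------------------------------------------------
# Serialization and CLI-facing commands
# ---------------------------------------------------------------------------

def write_results(result: AnalysisResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.score_table.to_csv(out / "score_table.csv")
    result.class_scores.to_csv(out / "wt_standardized_scores.csv")
    result.metaclass_matrix.to_csv(out / "metaclass_matrix.csv")
    result.metric_correlations.to_csv(out / "metric_correlations.csv")
    result.embedding.to_csv(out / "embedding.csv")
    for state, assign in result.assignments.items():
        pd.DataFrame(
            {"variant": list(assign.groups), "group": list(assign.groups.values())}
        ).to_csv(out / f"groups_{state}.csv", index=False)
        result.ttests[state].to_csv(out / f"ttests_{state}.csv", index=False)
        result.pc_monitor_correlations[state].to_csv(
            out / f"pc_monitor_correlations_{state}.csv"
        )
    sig = {
        state: {str(g): list(feats) for g, feats in per_group.items()}
        for state, per_group in result.signatures.items()
    }
    (out / "signatures.json").write_text(json.dumps(sig, indent=2))
    if result.partition is not None:
        (out / "wells.json").write_text(
            json.dumps(
                {
                    "boundary": result.partition.boundary,
                    "well_i_center": result.partition.well_i_center,
                    "well_ii_center": result.partition.well_ii_center,
                },
                indent=2,
            )
        )
    (out / "run_log.json").write_text(json.dumps(result.run_log, indent=2))


def render_fel(fel: FreeEnergyLandscape, path: str | Path, title: str = "") -> None:
    """Optional PNG rendering of a free-energy landscape."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    m = ax.pcolormesh(
        fel.x_edges, fel.y_edges, fel.free_energy.T, cmap="RdYlBu_r", shading="auto"
    )
    fig.colorbar(m, ax=ax, label="F (kT)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cmd_simulate(config: RunConfig) -> dict:
    """Write a synthetic cohort (trajectories + energies) and its manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    entries = []
    for ens in cohort.ensembles:
        stem = f"{ens.variant}_{ens.state}_r{ens.replicate}"
        suffix = "csv" if config.trajectory_format == "frames_table" else "pdb"
        traj_path = out / f"{stem}.{suffix}"
        write_trajectory(ens, traj_path, config.trajectory_format)
        entries.append(
            {
                "variant": ens.variant,
                "state": ens.state,
                "replicate": ens.replicate,
                "trajectory": traj_path.name,
                "n_frames": ens.n_frames,
                "sha256": hashlib.sha256(traj_path.read_bytes()).hexdigest(),
            }
        )
    for series in cohort.energies:
        path = out / f"{series.variant}_{series.state}_r{series.replicate}_energy.csv"
        series.write_csv(path)
    manifest = {
        "version": __version__,
        "preset": config.preset,
        "seed": config.seed,
        "format": config.trajectory_format,
        "systems": entries,
        "ground_truth": {
            f"{v}|{s}": {
                "p_star": t.p_star,
                "pc1_mean_shift": t.pc1_mean_shift,
                "eint_mean": t.eint_mean,
                "eint_sd": t.eint_sd,
                "eint_z_star": t.eint_z_star,
                "switch2_amp": t.switch2_amp,
            }
            for (v, s), t in cohort.truths.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_cohort(input_dir: str | Path) -> CohortData:
    """Read a simulated cohort back from a manifest directory."""
    from .trajectory import read_trajectory

    input_dir = Path(input_dir)
    manifest = json.loads((input_dir / "manifest.json").read_text())
    cohort = CohortData([], [], {})
    for entry in manifest["systems"]:
        cohort.ensembles.append(
            read_trajectory(
                input_dir / entry["trajectory"],
                manifest["format"],
                variant=entry["variant"],
                state=entry["state"],
                replicate=entry["replicate"],
            )
        )
        energy_path = (
            input_dir
            / f"{entry['variant']}_{entry['state']}_r{entry['replicate']}_energy.csv"
        )
        cohort.energies.append(
            EnergySeries.read_csv(
                energy_path, entry["variant"], entry["state"], entry["replicate"]
            )
        )
    return cohort


def cmd_analyze(config: RunConfig) -> AnalysisResult:
    """Orchestrate the full analysis and write all artifacts."""
    if config.preset:
        cohort = simulate_cohort(config)
    else:
        cohort = load_cohort(config.input_dir)
    result = analyze_cohort(cohort, config)
    write_results(result, config.out_dir)
    return result
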