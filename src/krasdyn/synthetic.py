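"""Synthetic Cα trajectory generator with known ground truth.

Real GTPase trajectory ensembles are expensive; this generator emulates the
*statistical* structure the analysis pipeline assumes, at desk scale, with
every generative parameter known:

* a bistable Switch-1 collective coordinate x(t) evolving by overdamped
  Euler–Maruyama Langevin dynamics on a tilted double well
  ``U(x) = h((x/w)² − 1)² − b·x`` (kT = 1), so the well-II occupancy has a
  closed Boltzmann ground truth;
* two orthogonal Switch-2 displacement modes driven by Ornstein–Uhlenbeck
  processes with tunable stationary amplitude (Switch-2 flexibility);
* static residue displacements that shift specific monitor distances;
* iid Gaussian per-frame ligand interaction-energy series per state.

Positive well bias ``b`` favors well I (positive x, Switch 1 folded in, the
WT-like preset); negative bias favors the extended-Switch-1 well II.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .descriptors import EnergySeries, ReferenceSet
from .trajectory import ResidueRegionMap, StructureModel, TrajectoryEnsemble

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "build_template",
    "simulate_system",
    "preset_cohort",
    "occupancy_from_bias",
    "bias_for_occupancy",
    "make_reference_set",
    "KRAS_SEQUENCE",
]

#: Human KRAS G-domain sequence, residues 1-169 (UniProt P01116 numbering),
#: used only to give the synthetic template realistic residue names.
KRAS_SEQUENCE = (
    "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAG"
    "QEEYSAMRDQYMRTGEGFLCVFAINNTKSFEDIHHYREQIKRVKDSEDVPMVLVGNKCDL"
    "PSRTVDTKQAQDLARSYGIPFIETSAKTRQGVDDAFYTLVREIRQYRLK"
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one (variant, state) system."""

    variant: str
    state: str
    well_bias: float = 3.0  # b; positive favors well I (WT-like)
    switch2_amp: float = 1.0  # a2, stationary OU sd (Å) on each Switch-2 mode
    sigma_res: float = 0.35  # baseline iid coordinate noise sd (Å)
    monitor_offsets: Mapping[int, tuple[float, float, float]] = field(default_factory=dict)
    mu_E: float = -100.0  # kcal/mol
    sd_E: float = 5.0
    n_frames: int = 500
    n_replicates: int = 3
    seed: int = 0
    # Langevin parameters for the Switch-1 well coordinate
    barrier_height: float = 3.0  # h, kT
    well_half_width: float = 1.0  # w
    dt: float = 0.01
    thinning: int = 10
    mobility: float = 4.0  # diffusion coefficient; sets the hopping rate
    well_scale: float = 6.0  # s, maps x to Å of Switch-1 displacement
    switch2_tau: float = 1.0  # OU correlation time (simulation time units)
    n_residues: int = 169

    def __post_init__(self) -> None:
        if self.sigma_res <= 0:
            raise ValueError("sigma_res must be positive")
        if self.n_frames < 100:
            raise ValueError("n_frames must be >= 100")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for p in (self.barrier_height, self.well_half_width, self.well_bias):
            if not np.isfinite(p):
                raise ValueError("well potential parameters must be finite")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    variant: str
    state: str
    p_star: float  # Boltzmann well-II occupancy
    pc1_mean_shift: float  # well_scale · E[x], Å along mode 1
    eint_mean: float
    eint_sd: float
    eint_z_star: float | None = None  # vs WT, set by cohort builders
    switch2_amp: float = 1.0
    latent_x: tuple[np.ndarray, ...] = ()  # per-replicate well coordinate


# ---------------------------------------------------------------------------
# Template and displacement modes
# ---------------------------------------------------------------------------

def build_template(n_residues: int = 169) -> tuple[StructureModel, np.ndarray]:
    """Deterministic idealized Cα trace plus three displacement modes.

    The trace is a regular helix (3.83 Å consecutive Cα spacing).  Mode 1 is
    a unit-norm "Switch-1 opening" field supported on switch1; modes 2-3 are
    mutually orthogonal Switch-2 fields (axial and radial), all zero
    elsewhere.  Returns ``(template, modes)`` with ``modes`` of shape
    ``(3, n_residues, 3)``.
    """
    if n_residues < 60:
        raise ValueError("template needs >= 60 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    radius, rise = 2.3, 1.5
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i]
    )
    ids = i + 1
    names = tuple(
        _ONE_TO_THREE[KRAS_SEQUENCE[j]] if j < len(KRAS_SEQUENCE) else "ALA"
        for j in i
    )
    template = StructureModel(residue_ids=ids, residue_names=names, coords=coords)

    regions = ResidueRegionMap()
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n_residues)])
    axial = np.tile([0.0, 0.0, 1.0], (n_residues, 1))

    def _mode(region: str, direction: np.ndarray) -> np.ndarray:
        mask = regions.mask(ids, [region])
        w = np.zeros(n_residues)
        span = np.where(mask)[0]
        w[span] = np.hanning(len(span) + 2)[1:-1]
        field_ = w[:, None] * direction
        return field_ / np.linalg.norm(field_)

    mode1 = _mode("switch1", radial)  # Switch-1 opening
    mode2 = _mode("switch2", axial)  # Switch-2 axial swing
    mode3 = _mode("switch2", radial)  # Switch-2 radial breathing
    return template, np.stack([mode1, mode2, mode3])


def make_reference_set(
    template: StructureModel | None = None,
    modes: np.ndarray | None = None,
    well_scale: float = 6.0,
) -> ReferenceSet:
    """Synthetic reference conformations on the template's displacement modes.

    These are constructed archetypes, not experimental structures: the WT
    initial pose sits in well I; the GAP-bound-like (NF1) and GEF-bound-like
    (SOS1) poses both have Switch 1 extended (well II side) but opposite
    Switch-2 displacements, so variants can favor one over the other.
    """
    if template is None or modes is None:
        template, modes = build_template()

    def shifted(x1: float, x2: float, x3: float) -> StructureModel:
        coords = (
            template.coords
            + x1 * well_scale * modes[0]
            + x2 * modes[1]
            + x3 * modes[2]
        )
        return StructureModel(template.residue_ids, template.residue_names, coords)

    return ReferenceSet(
        {
            "wt_initial": shifted(1.0, 0.0, 0.0),
            "nf1_bound": shifted(-1.0, 2.0, 0.0),
            "sos1_bound": shifted(-1.0, -2.0, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# Well potential ground truth
# ---------------------------------------------------------------------------

def _potential(x: np.ndarray, h: float, w: float, b: float) -> np.ndarray:
    return h * ((x / w) ** 2 - 1) ** 2 - b * x


def _force(x: float, h: float, w: float, b: float) -> float:
    return -(4 * h * x * ((x / w) ** 2 - 1) / w**2 - b)


def _barrier_position(h: float, w: float, b: float) -> float:
    xs = np.linspace(-w, w, 4001)
    U = _potential(xs, h, w, b)
    return float(xs[np.argmax(U)])


def occupancy_from_bias(
    bias: float, barrier_height: float = 3.0, well_half_width: float = 1.0
) -> float:
    """Boltzmann well-II occupancy p* by numerical quadrature (kT = 1).

    Well II is the negative-x side of the barrier top.
    """
    h, w, b = barrier_height, well_half_width, bias
    xs = np.linspace(-4 * w, 4 * w, 20001)
    rho = np.exp(-(_potential(xs, h, w, b) - _potential(xs, h, w, b).min()))
    xb = _barrier_position(h, w, b)
    total = np.trapezoid(rho, xs)
    below = np.trapezoid(np.where(xs < xb, rho, 0.0), xs)
    return float(below / total)


def bias_for_occupancy(
    p_target: float, barrier_height: float = 3.0, well_half_width: float = 1.0
) -> float:
    """Invert the occupancy ↦ bias relation (monotone decreasing in b)."""
    if not 0 < p_target < 1:
        raise ValueError("target occupancy must be in (0, 1)")
    return float(
        brentq(
            lambda b: occupancy_from_bias(b, barrier_height, well_half_width) - p_target,
            -14.0,
            14.0,
            xtol=1e-10,
        )
    )


def _equilibrium_mean_x(h: float, w: float, b: float) -> float:
    xs = np.linspace(-4 * w, 4 * w, 20001)
    rho = np.exp(-(_potential(xs, h, w, b) - _potential(xs, h, w, b).min()))
    return float(np.trapezoid(xs * rho, xs) / np.trapezoid(rho, xs))


def _sample_equilibrium(rng: np.random.Generator, h: float, w: float, b: float) -> float:
    xs = np.linspace(-4 * w, 4 * w, 20001)
    rho = np.exp(-(_potential(xs, h, w, b) - _potential(xs, h, w, b).min()))
    cdf = np.cumsum(rho)
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, xs))


def _simulate_well_coordinate(
    spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Metropolis-adjusted overdamped Langevin sampling of the well coordinate.

    Euler–Maruyama proposals (x → x + D·F(x)·dt + √(2Ddt)·η) are filtered
    through a Metropolis acceptance step so the chain's stationary law is
    exactly the Boltzmann density of U, making the quadrature ground truth
    p* the true sampled occupancy at any step size.  Frames are recorded
    every ``thinning`` steps; the start point is drawn from equilibrium.
    """
    h, w, b = spec.barrier_height, spec.well_half_width, spec.well_bias
    D, dt = spec.mobility, spec.dt
    noise_scale = np.sqrt(2 * D * dt)
    x = _sample_equilibrium(rng, h, w, b)
    out = np.empty(spec.n_frames)
    n_steps = spec.n_frames * spec.thinning
    eta = rng.standard_normal(n_steps)
    log_u = np.log(rng.random(n_steps))
    k = 0
    u_x = float(_potential(np.asarray(x), h, w, b))
    for f in range(spec.n_frames):
        for _ in range(spec.thinning):
            drift = D * _force(x, h, w, b) * dt
            y = x + drift + noise_scale * eta[k]
            u_y = float(_potential(np.asarray(y), h, w, b))
            drift_y = D * _force(y, h, w, b) * dt
            log_q_fwd = -((y - x - drift) ** 2) / (4 * D * dt)
            log_q_rev = -((x - y - drift_y) ** 2) / (4 * D * dt)
            if log_u[k] < (u_x - u_y) + (log_q_rev - log_q_fwd):
                x, u_x = y, u_y
            k += 1
        out[f] = x
    return out


def _simulate_ou(
    n_frames: int, amp: float, tau: float, dt_frame: float, rng: np.random.Generator
) -> np.ndarray:
    decay = np.exp(-dt_frame / tau)
    kick = amp * np.sqrt(1 - decay**2)
    y = np.empty(n_frames)
    y[0] = amp * rng.standard_normal()
    eta = rng.standard_normal(n_frames - 1)
    for f in range(1, n_frames):
        y[f] = y[f - 1] * decay + kick * eta[f - 1]
    return y


# ---------------------------------------------------------------------------
# System simulation
# ---------------------------------------------------------------------------

def simulate_system(
    spec: SyntheticSpec,
    template: StructureModel | None = None,
    modes: np.ndarray | None = None,
) -> tuple[list[TrajectoryEnsemble], list[EnergySeries], GroundTruth]:
    """Generate the replicate ensembles, energy series, and ground truth.

    Each frame is ``template + x(t)·s·mode1 + OU₂(t)·mode2 + OU₃(t)·mode3 +
    iid noise + static monitor offsets``; the same seed always yields
    bit-identical output.
    """
    if template is None or modes is None:
        template, modes = build_template(spec.n_residues)
    offsets = np.zeros_like(template.coords)
    id_to_idx = {int(r): i for i, r in enumerate(template.residue_ids)}
    for rid, vec in spec.monitor_offsets.items():
        offsets[id_to_idx[int(rid)]] = np.asarray(vec, dtype=float)
    base = template.coords + offsets

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    ensembles, energies, latents = [], [], []
    dt_frame = spec.dt * spec.thinning
    for rep, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        x = _simulate_well_coordinate(spec, rng)
        y2 = _simulate_ou(spec.n_frames, spec.switch2_amp, spec.switch2_tau, dt_frame, rng)
        y3 = _simulate_ou(spec.n_frames, spec.switch2_amp, spec.switch2_tau, dt_frame, rng)
        noise = spec.sigma_res * rng.standard_normal((spec.n_frames, spec.n_residues, 3))
        coords = (
            base[None, :, :]
            + (spec.well_scale * x)[:, None, None] * modes[0][None]
            + y2[:, None, None] * modes[1][None]
            + y3[:, None, None] * modes[2][None]
            + noise
        )
        ensembles.append(
            TrajectoryEnsemble(
                variant=spec.variant,
                state=spec.state,
                replicate=rep,
                coords=coords,
                residue_ids=template.residue_ids,
                residue_names=template.residue_names,
            )
        )
        energies.append(
            EnergySeries(
                spec.variant,
                spec.state,
                rep,
                spec.mu_E + spec.sd_E * rng.standard_normal(spec.n_frames),
            )
        )
        latents.append(x)

    truth = GroundTruth(
        variant=spec.variant,
        state=spec.state,
        p_star=occupancy_from_bias(spec.well_bias, spec.barrier_height, spec.well_half_width),
        pc1_mean_shift=spec.well_scale
        * _equilibrium_mean_x(spec.barrier_height, spec.well_half_width, spec.well_bias),
        eint_mean=spec.mu_E,
        eint_sd=spec.sd_E,
        switch2_amp=spec.switch2_amp,
        latent_x=tuple(latents),
    )
    return ensembles, energies, truth


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

#: Archetype parameters: target well-II occupancy per state, Switch-2
#: amplitude, E_int shifts from WT (kcal/mol) per state, and static residue
#: displacements (Å) that move specific monitors.
_ARCHETYPES: dict[str, dict] = {
    "wt_like": {
        "p": {"GDP": 0.03, "GTP": 0.01},
        "a2": 1.0,
        "eint_shift": {"GDP": 0.0, "GTP": 0.0},
        "offsets": {},
    },
    "g12d_like": {  # well-II favoring, Switch-2 loop-out, GTP-destabilized
        "p": {"GDP": 0.90, "GTP": 0.06},
        "a2": 1.3,
        "eint_shift": {"GDP": 4.0, "GTP": 12.0},
        "offsets": {61: (1.8, 0.0, 0.6), 62: (1.5, 0.0, 0.0)},
    },
    "g12r_like": {  # balanced two-well sampling, nucleotide-stabilized
        "p": {"GDP": 0.50, "GTP": 0.03},
        "a2": 1.2,
        "eint_shift": {"GDP": -8.0, "GTP": -9.0},
        "offsets": {35: (-1.0, 0.5, 0.0), 12: (0.6, 0.0, 0.0)},
    },
    "switch2_flexible": {  # high Switch-2 amplitude, GDP-destabilized
        "p": {"GDP": 0.05, "GTP": 0.02},
        "a2": 2.5,
        "eint_shift": {"GDP": 8.0, "GTP": 1.0},
        "offsets": {68: (0.0, -1.2, 0.8)},
    },
}

#: WT interaction-energy baselines per nucleotide state (kcal/mol).  GTP
#: binds more favorably through its gamma-phosphate contacts.
_WT_EINT = {"GDP": (-100.0, 5.0), "GTP": (-120.0, 5.0)}

_SMOKE_VARIANTS: dict[str, str] = {
    "K5N": "wt_like", "G12V": "wt_like", "D30E": "wt_like",
    "G12D": "g12d_like", "H27Y": "g12d_like", "Y71D": "g12d_like",
    "G12R": "g12r_like", "Q22R": "g12r_like", "F28L": "g12r_like",
    "Q61H": "switch2_flexible", "E62G": "switch2_flexible", "M72I": "switch2_flexible",
}


def _spec_for(
    variant: str,
    state: str,
    archetype: str,
    seed: int,
    n_frames: int,
    rng: np.random.Generator,
) -> SyntheticSpec:
    arch = _ARCHETYPES[archetype]
    mu_wt, sd_wt = _WT_EINT[state]
    jitter = 0.0 if variant == "WT" else float(rng.normal(0.0, 2.0))
    scale = 1.0 if variant == "WT" else float(rng.uniform(0.85, 1.15))
    p = min(max(arch["p"][state] * scale, 1e-4), 0.97)
    offsets = {
        rid: tuple(scale * np.asarray(vec)) for rid, vec in arch["offsets"].items()
    }
    return SyntheticSpec(
        variant=variant,
        state=state,
        well_bias=bias_for_occupancy(p),
        switch2_amp=arch["a2"] * (1.0 if variant == "WT" else float(rng.uniform(0.9, 1.1))),
        monitor_offsets=offsets,
        mu_E=mu_wt + arch["eint_shift"][state] + jitter,
        sd_E=sd_wt,
        n_frames=n_frames,
        seed=seed,
    )


def preset_cohort(name: str, seed: int = 0) -> list[SyntheticSpec]:
    """Ready-made cohorts of (variant, state) specs.

    ``smoke``: WT + 12 variants (three per archetype), 500 frames — runs the
    full pipeline end to end in seconds.  ``paper_scale``: WT + the 86
    catalogued mutations, 2000 frames, archetypes assigned deterministically
    from the seed.  Every spec carries 3 replicates.
    """
    rng = np.random.default_rng(seed)
    if name == "smoke":
        assignment = {"WT": "wt_like", **_SMOKE_VARIANTS}
        n_frames = 500
    elif name == "paper_scale":
        from .classify import load_variant_catalogue

        variants = [v for v in load_variant_catalogue()["variant"] if v != "WT"]
        arch_names = sorted(_ARCHETYPES)
        assignment = {"WT": "wt_like"}
        for v in variants:
            assignment[v] = arch_names[int(rng.integers(len(arch_names)))]
        n_frames = 2000
    else:
        raise ValueError(f"unknown preset {name!r}")

    specs = []
    for i, (variant, archetype) in enumerate(assignment.items()):
        var_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, i))
        )
        for j, state in enumerate(("GDP", "GTP")):
            specs.append(
                _spec_for(
                    variant,
                    state,
                    archetype,
                    seed=int((seed * 1_000_003 + i * 17 + j) % (2**31 - 1)),
                    n_frames=n_frames,
                    rng=var_rng,
                )
            )
    return specs
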