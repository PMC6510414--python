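"""Synthetic conformer ensembles with planted ground truth.

The generator emulates the statistical structure of a two-state β-barrel
ensemble study at desk scale: an idealized backbone topology (antiparallel
hairpin plus one α-helix), conformers displaced along two orthogonal smooth
collective modes plus isotropic per-atom noise, observables (S², NOE-style
restraints, chemical shifts) derived from the ensemble itself, hydrogen
bonds that switch between ligation states, and one "hidden" conformer
displaced along a reserved third mode whose |Δω|-style shift-difference
profile is planted into the experimental table.

Everything is deterministic under a fixed seed: each public operation
creates one ``numpy`` Generator from a documented offset of ``spec.seed``
and consumes it in a fixed order, so adding an observable never perturbs
earlier draws.

What this generator does *not* emulate: force-field energetics, side-chain
rotamers (backbone atoms only), realistic shift physics (the surrogate
predictor is a frozen deterministic map), or temperature dependence beyond
independent noise per temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._geom import place_atom
from .ensemble_io import AtomKey, Conformer, ConformerEnsemble, DeltaOmegaSet, \
    OrderParameterSet, ShiftTable
from .noe_restraints import AtomGroup, DistanceRestraint, bin_upper_bound
from .order_params import backcalc_s2
from .shift_eval import surrogate_predictor

__all__ = ["GeneratorSpec", "make_topology", "generate_ensemble",
           "synth_observables", "plant_hidden_state", "reporter_pair"]

# ---------------------------------------------------------------------------
# Ideal backbone geometry (Å / degrees)
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# dihedral recipes per secondary-structure element; the hairpin turn is a
# type-II' two-residue turn, which lets the ideal antiparallel ladder close
_HELIX = (-57.0, -47.0)
_STRAND = (-135.0, 135.0)
_TURN = ((60.0, -120.0), (-80.0, 0.0))
_COIL = (-70.0, 150.0)


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic study, with planted ground truth.

    ``mode_sds`` are the standard deviations (Å, in projection units) of
    the collective-mode amplitudes; the third mode is reserved for the
    hidden state and is not sampled by default (sd 0).
    """

    n_residues: int = 32
    n_members: int = 100
    mode_sds: tuple[float, ...] = (2.0, 1.0, 0.0)
    noise_sd: float = 0.1
    seed: int = 0
    state: str = "apo"
    planted_hbond_switches: list[tuple[int, int, str]] = field(default_factory=list)
    hidden_displacement: float = 8.0
    hidden_mode_index: int = 2
    state_displacement: float = 12.0  # holo mean offset along mode 1, Å
    n_decoys: int = 200
    temperatures: tuple[float, ...] = (283.0, 287.0, 291.0)
    s2_obs_noise: float = 0.02
    turn_mobility: float = 1.0  # optional noise-sd multiplier in turns/termini
    delta_omega_noise: float = 0.10
    delta_omega_coverage: float = 0.8
    restraint_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if any(sd < 0 for sd in self.mode_sds) or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


def _dihedral_plan(n_residues: int) -> list[tuple[float, float]]:
    """Per-residue (φ, ψ) laying out hairpin + linker + helix."""
    helix_len = max(6, n_residues // 3)
    rest = n_residues - helix_len - 2  # 2-residue linker
    if rest < 6:  # too small for a hairpin: all helix
        return [_HELIX] * n_residues
    strand_len = (rest - 2) // 2
    plan: list[tuple[float, float]] = []
    plan += [_STRAND] * strand_len
    plan += list(_TURN)
    plan += [_STRAND] * (rest - 2 - strand_len)
    plan += [_COIL] * 2
    plan += [_HELIX] * (n_residues - len(plan))
    return plan


def default_switches(n_residues: int) -> list[tuple[int, int, str]]:
    """A sensible pair of planted state-dependent H-bond switches: one bond
    characteristic of each state, between residues that exist at this size."""
    return [
        (max(2, n_residues // 6), n_residues // 2, "apo"),
        (n_residues - max(4, n_residues // 5), max(3, n_residues // 3), "holo"),
    ]


def make_topology(n_residues: int) -> Conformer:
    """Idealized backbone (N, H, CA, C, O per residue), hairpin + helix.

    All bond lengths and angles take canonical values; the conformation is
    set purely by the per-residue (φ, ψ) plan.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    return build_backbone(_dihedral_plan(n_residues))


def build_backbone(plan: Sequence[tuple[float, float]]) -> Conformer:
    """Backbone chain from an explicit per-residue (φ, ψ) list in degrees."""
    n_residues = len(plan)
    rad = math.radians
    n_pos: list[np.ndarray] = []
    ca_pos: list[np.ndarray] = []
    c_pos: list[np.ndarray] = []
    # residue 1 seeded explicitly in the xy-plane
    n_pos.append(np.zeros(3))
    ca_pos.append(np.array([_B_N_CA, 0.0, 0.0]))
    ang = rad(_A_N_CA_C)
    c_pos.append(ca_pos[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0]))
    for i in range(1, n_residues):
        phi, _ = plan[i]
        _, psi_prev = plan[i - 1]
        n_i = place_atom(n_pos[-1], ca_pos[-1], c_pos[-1],
                         _B_C_N, rad(_A_CA_C_N), rad(psi_prev))
        ca_i = place_atom(ca_pos[-1], c_pos[-1], n_i,
                          _B_N_CA, rad(_A_C_N_CA), rad(180.0))
        c_i = place_atom(c_pos[-1], n_i, ca_i,
                         _B_CA_C, rad(_A_N_CA_C), rad(phi))
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)

    atoms: list[AtomKey] = []
    coords: list[np.ndarray] = []
    for i in range(n_residues):
        res = i + 1
        _, psi = plan[i]
        o_i = place_atom(n_pos[i], ca_pos[i], c_pos[i],
                         _B_C_O, rad(_A_CA_C_O), rad(psi + 180.0))
        if i == 0:
            u = n_pos[i] - ca_pos[i]
            v = n_pos[i] - c_pos[i]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        else:
            u = n_pos[i] - c_pos[i - 1]
            v = n_pos[i] - ca_pos[i]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        h_i = n_pos[i] + _B_N_H * h_dir / np.linalg.norm(h_dir)
        for name, pos in (("N", n_pos[i]), ("H", h_i), ("CA", ca_pos[i]),
                          ("C", c_pos[i]), ("O", o_i)):
            atoms.append(AtomKey(res, "ALA", name))
            coords.append(pos)
    return Conformer(atoms, np.array(coords), model_id=1)


# ---------------------------------------------------------------------------
# Collective mode fields
# ---------------------------------------------------------------------------


def mode_fields(topology: Conformer, n_modes: int = 3) -> np.ndarray:
    """Orthonormal smooth displacement fields, shape (n_modes, n_atoms, 3).

    Mode k displaces atoms along a fixed direction with a sinusoidal
    profile over the chain, so that residue pairs at opposite phases act as
    localized distance reporters of that mode.
    """
    residues = np.array([a.residue_number for a in topology.atoms], float)
    t = (residues - residues.min()) / max(1.0, residues.max() - residues.min())
    directions = np.eye(3)[[1, 2, 0]]  # y, z, x
    profiles = [
        np.sin(2 * np.pi * t),
        np.cos(np.pi * t),
        np.sin(3 * np.pi * t),
    ]
    n_atoms = len(topology.atoms)
    fields = np.zeros((n_modes, n_atoms, 3))
    for k in range(n_modes):
        fields[k] = np.outer(profiles[k % len(profiles)], directions[k % 3])
    flat = fields.reshape(n_modes, -1)
    # remove the rigid-body subspace so superposition preserves the modes:
    # 3 translations and 3 infinitesimal rotations about the centroid
    centered = topology.coords - topology.coords.mean(axis=0)
    rigid = np.zeros((6, n_atoms, 3))
    for d in range(3):
        rigid[d, :, d] = 1.0
        axis = np.zeros(3)
        axis[d] = 1.0
        rigid[3 + d] = np.cross(axis, centered)
    rigid_flat = rigid.reshape(6, -1)
    for k in range(6):  # orthonormalize the rigid basis
        for j in range(k):
            rigid_flat[k] -= (rigid_flat[k] @ rigid_flat[j]) * rigid_flat[j]
        rigid_flat[k] /= np.linalg.norm(rigid_flat[k])
    # Gram-Schmidt the modes against the rigid basis and each other
    for k in range(n_modes):
        for rb in rigid_flat:
            flat[k] -= (flat[k] @ rb) * rb
        for j in range(k):
            flat[k] -= (flat[k] @ flat[j]) * flat[j]
        flat[k] /= np.linalg.norm(flat[k])
    return flat.reshape(n_modes, n_atoms, 3)


def reporter_pair(
    topology: Conformer, fields: np.ndarray, mode_index: int, min_separation: int = 3
) -> tuple[int, int]:
    """Residue pair whose Cα–Cα distance is the cleanest reporter of a mode.

    Chosen by the analytic sensitivity |(u_a − u_b) · r̂_ab| of the distance
    to the mode amplitude, penalizing sensitivity to the other modes.
    """
    ca = [(a.residue_number, topology.index_of(a))
          for a in topology.atoms if a.atom_name == "CA"]
    best, best_score = None, -np.inf
    for ia in range(len(ca)):
        for ib in range(ia + 1, len(ca)):
            ra, i = ca[ia]
            rb, j = ca[ib]
            if abs(ra - rb) < min_separation:
                continue
            r = topology.coords[i] - topology.coords[j]
            r_hat = r / np.linalg.norm(r)
            sens = [abs((fields[k, i] - fields[k, j]) @ r_hat)
                    for k in range(fields.shape[0])]
            others = max(s for k, s in enumerate(sens) if k != mode_index) \
                if fields.shape[0] > 1 else 0.0
            score = sens[mode_index] - 2.0 * others
            if score > best_score:
                best_score, best = score, (ra, rb)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------


def _mobility_profile(spec: GeneratorSpec, topology: Conformer) -> np.ndarray:
    """Per-atom noise-scale factors: turns, linkers and chain ends are more
    mobile than regular secondary structure, mimicking the low S² of turn
    regions in real relaxation data."""
    plan = _dihedral_plan(spec.n_residues)
    factor_by_res: dict[int, float] = {}
    for i, (phi, psi) in enumerate(plan):
        mobile = (phi, psi) not in (_HELIX, _STRAND) or i < 2 or i >= spec.n_residues - 2
        factor_by_res[i + 1] = spec.turn_mobility if mobile else 1.0
    return np.array([factor_by_res[a.residue_number] for a in topology.atoms])


def _apply_switches(topology: Conformer, spec: GeneratorSpec) -> Conformer:
    """Reposition acceptor carbonyl O next to the donor amide H for every
    planted switch active in this spec's state."""
    coords = topology.coords.copy()
    for donor_res, acceptor_res, state in spec.planted_hbond_switches:
        if state != spec.state:
            continue
        n = topology[AtomKey(donor_res, "ALA", "N")]
        h = topology[AtomKey(donor_res, "ALA", "H")]
        o_key = AtomKey(acceptor_res, "ALA", "O")
        direction = (h - n) / np.linalg.norm(h - n)
        coords[topology.index_of(o_key)] = h + 1.95 * direction
    return Conformer(topology.atoms, coords, topology.model_id)


def generate_ensemble(spec: GeneratorSpec) -> ConformerEnsemble:
    """Members = topology + Σ_k a_k·mode_k + isotropic noise.

    Amplitudes a_k ~ N(0, mode_sd_k²); per-coordinate noise ~ N(0, noise_sd²).
    Random stream: ``default_rng(seed)``, consuming amplitudes first, then
    noise, in one block each.
    """
    topo = make_topology(spec.n_residues)
    fields = mode_fields(topo, len(spec.mode_sds))
    if spec.state == "holo":  # the apo→holo transition is a mode-1 offset
        topo = Conformer(topo.atoms,
                         topo.coords + spec.state_displacement * fields[0],
                         topo.model_id)
    topo = _apply_switches(topo, spec)  # switches hold in the state's mean
    rng = np.random.default_rng(spec.seed)
    amps = rng.normal(0.0, 1.0, size=(spec.n_members, len(spec.mode_sds)))
    amps *= np.asarray(spec.mode_sds)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_members,) + topo.coords.shape)
    noise *= _mobility_profile(spec, topo)[None, :, None]
    members = []
    for m in range(spec.n_members):
        disp = np.tensordot(amps[m], fields, axes=(0, 0))
        members.append(Conformer(topo.atoms, topo.coords + disp + noise[m], m + 1))
    return ConformerEnsemble(members, label=f"synthetic-{spec.state}",
                             temperature=spec.temperatures[0])


def synth_observables(
    ensemble: ConformerEnsemble, spec: GeneratorSpec
) -> tuple[OrderParameterSet, list[DistanceRestraint], ShiftTable]:
    """Observables derived from the ensemble itself.

    S² = back-calculated values plus truncated Gaussian observation noise;
    restraints = every inter-residue amide H–H pair whose ensemble-mean
    distance is under ``restraint_cutoff`` Å, upper bound = that mean
    distance, binned; shifts = the surrogate predictor on the mean
    structure.  Random stream: ``default_rng(seed + 1)``, S² noise only.
    """
    rng = np.random.default_rng(spec.seed + 1)
    s2_true = backcalc_s2(ensemble)
    s2_noisy = {
        r: float(np.clip(v + rng.normal(0.0, spec.s2_obs_noise), 0.0, 1.0))
        if spec.s2_obs_noise > 0 else v
        for r, v in s2_true.items()
    }
    s2 = OrderParameterSet(s2_noisy, temperature=ensemble.temperature or 298.0)

    ref = ensemble.members[0]
    amide_h = [a for a in ensemble.atoms if a.atom_name == "H"]
    idx = [ref.index_of(a) for a in amide_h]
    coords = ensemble.coord_array()[:, idx, :]
    restraints: list[DistanceRestraint] = []
    for i in range(len(amide_h)):
        for j in range(i + 1, len(amide_h)):
            if amide_h[i].residue_number == amide_h[j].residue_number:
                continue
            mean_d = float(np.mean(np.linalg.norm(coords[:, i] - coords[:, j], axis=1)))
            if mean_d < spec.restraint_cutoff:
                restraints.append(
                    DistanceRestraint(
                        AtomGroup(frozenset({amide_h[i]})),
                        AtomGroup(frozenset({amide_h[j]})),
                        upper_bound=mean_d,
                        bin=bin_upper_bound(mean_d),
                    )
                )
    mean_structure = Conformer(ensemble.atoms, ensemble.coord_array().mean(axis=0), 1)
    shifts = surrogate_predictor(mean_structure)
    return s2, restraints, shifts


def plant_hidden_state(
    apo_ensemble: ConformerEnsemble, spec: GeneratorSpec
) -> tuple[ConformerEnsemble, DeltaOmegaSet, int]:
    """Decoy pool plus one planted excited-state conformer and its |Δω| table.

    The planted conformer is the topology displaced by
    ``hidden_displacement`` along the reserved hidden mode.  Its per-residue
    |Δδ(¹⁵N)| profile against the apo ensemble (mean over apo members of the
    absolute surrogate-shift difference — the same aggregation the scoring
    uses) is multiplied by independent ``(1 + delta_omega_noise·z)`` factors
    per temperature and planted as the experimental table, on a random
    ~``delta_omega_coverage`` subset of residues per temperature.  Random
    stream: ``default_rng(seed + 2)``: decoy amplitudes, decoy noise,
    coverage masks, then |Δω| noise.
    """
    if spec.hidden_displacement < 0:
        raise ValueError("hidden_displacement must be non-negative")
    topo = make_topology(spec.n_residues)
    fields = mode_fields(topo, max(len(spec.mode_sds), spec.hidden_mode_index + 1))
    rng = np.random.default_rng(spec.seed + 2)
    amps = rng.normal(0.0, 1.0, size=(spec.n_decoys, len(spec.mode_sds)))
    amps *= np.asarray(spec.mode_sds)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_decoys,) + topo.coords.shape)
    noise *= _mobility_profile(spec, topo)[None, :, None]
    members = []
    for m in range(spec.n_decoys):
        disp = np.tensordot(amps[m], fields[: len(spec.mode_sds)], axes=(0, 0))
        members.append(Conformer(topo.atoms, topo.coords + disp + noise[m], m + 1))
    planted = Conformer(
        topo.atoms,
        topo.coords + spec.hidden_displacement * fields[spec.hidden_mode_index],
        spec.n_decoys + 1,
    )
    members.append(planted)
    pool = ConformerEnsemble(members, label="pool")

    planted_table = surrogate_predictor(planted)
    apo_tables = [surrogate_predictor(m) for m in apo_ensemble.members]
    residues = sorted(
        set(planted_table.residues("N"))
        & set.intersection(*[set(t.residues("N")) for t in apo_tables])
    )
    profile = {
        r: float(np.mean([abs(planted_table.entries[(r, "N")] - t.entries[(r, "N")])
                          for t in apo_tables]))
        for r in residues
    }

    values: dict[tuple[int, float], float] = {}
    n_keep = max(3, int(round(spec.delta_omega_coverage * len(residues))))
    for temp in spec.temperatures:
        keep = sorted(rng.choice(residues, size=n_keep, replace=False))
        for r in keep:
            factor = 1.0 + spec.delta_omega_noise * rng.normal() \
                if spec.delta_omega_noise > 0 else 1.0
            values[(int(r), float(temp))] = max(0.0, profile[r] * factor)
    return pool, DeltaOmegaSet(values), planted.model_id
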