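"""Collective-motion analysis of pooled conformer ensembles.

The two dominant barrel-opening motions of lipid-binding β-barrels are
identified by principal component analysis of the pooled, superposed Cα
coordinates: conformers from all states (apo, holo, exploratory pools) are
superposed onto an iteratively refined mean structure, the 3n×3n coordinate
covariance is eigendecomposed, and every conformer is projected onto the
orthonormal modes.  Distances between Cα pairs are then correlated with the
per-conformer mode projections to locate the residue pairs that report on
each opening mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._geom import kabsch, apply_fit, pairwise_rmsd
from .ensemble_io import AtomKey, Conformer, ConformerEnsemble, write_pdb_ensemble

__all__ = [
    "superpose",
    "ensemble_rmsd",
    "pca",
    "square_fluctuations",
    "distance_mode_correlation",
    "top_correlated_pairs",
    "ModeDecomposition",
    "DistanceModeCorrelation",
]

BACKBONE_SELECTION = ("N", "CA", "C")


def superpose(
    ensemble: ConformerEnsemble,
    selection: Sequence[str] = ("CA",),
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> ConformerEnsemble:
    """Least-squares superpose all members onto the iteratively refined mean.

    Each member is rigid-body fitted (proper rotation + translation, never a
    reflection) on the selected atoms; the mean structure is recomputed and
    the fit repeated until the mean moves by less than ``tol`` Å.
    """
    sel_atoms = ensemble.select(selection)
    if len(sel_atoms) < 3:
        raise ValueError(f"need >= 3 selection atoms, got {len(sel_atoms)}")
    idx = [ensemble.members[0].index_of(a) for a in sel_atoms]
    full = ensemble.coord_array().copy()  # (M, N, 3)
    mean = full[0, idx, :].copy()
    for _ in range(max_rounds):
        for m in range(full.shape[0]):
            R, t, _ = kabsch(full[m, idx, :], mean)
            full[m] = apply_fit(full[m], R, t)
        new_mean = full[:, idx, :].mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    members = [
        Conformer(ensemble.atoms, full[m], ensemble.members[m].model_id)
        for m in range(full.shape[0])
    ]
    return ensemble.with_members(members)


def ensemble_rmsd(
    ensemble: ConformerEnsemble,
    selection: Sequence[str] = BACKBONE_SELECTION,
) -> tuple[float, float]:
    """Mean ± sd of pairwise best-fit RMSDs, by sub-ensemble.

    All pairwise RMSDs (each pair individually superposed) are averaged
    within each sub-ensemble; the mean and standard deviation across the
    per-sub-ensemble means are reported.  A deposited PDB ensemble forms a
    single sub-ensemble and therefore yields sd = 0.
    """
    if len(ensemble) < 2:
        raise ValueError("pairwise RMSD needs at least two members")
    sel_atoms = ensemble.select(selection)
    if not sel_atoms:
        raise ValueError("empty atom selection")
    coords = ensemble.coord_array(sel_atoms)
    groups = ensemble.sub_ensemble_ids or [0] * len(ensemble)
    per_sub: dict[int, list[float]] = {}
    for i in range(len(ensemble)):
        for j in range(i + 1, len(ensemble)):
            if groups[i] != groups[j]:
                continue
            per_sub.setdefault(groups[i], []).append(pairwise_rmsd(coords[i], coords[j]))
    sub_means = np.array([np.mean(v) for v in per_sub.values() if v])
    if sub_means.size == 0:
        raise ValueError("no intra-sub-ensemble pair available")
    return float(sub_means.mean()), float(sub_means.std(ddof=0) if sub_means.size > 1 else 0.0)


@dataclass
class ModeDecomposition:
    """Mean structure, orthonormal collective modes and projections."""

    atoms: list[AtomKey]
    mean_coordinates: np.ndarray          # (n_atoms, 3)
    modes: np.ndarray                     # (n_modes, 3*n_atoms), orthonormal rows
    eigenvalues: np.ndarray               # (n_modes,), Å², non-increasing
    projections: np.ndarray               # (n_members_total, n_modes), Å
    member_labels: list[str]              # originating ensemble label per row

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def reconstruct(self, member: int) -> np.ndarray:
        """Coordinates rebuilt from the mean plus all mode contributions."""
        flat = self.projections[member] @ self.modes
        return self.mean_coordinates + flat.reshape(-1, 3)

    def write(self, directory: str | Path, prefix: str = "modes") -> None:
        """Persist mean (PDB), modes (NMD) and projections (CSV)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mean_member = Conformer(self.atoms, self.mean_coordinates, 1)
        write_pdb_ensemble(
            ConformerEnsemble([mean_member], label="mean"), directory / f"{prefix}_mean.pdb"
        )
        self.write_nmd(directory / f"{prefix}.nmd")
        df = pd.DataFrame(
            self.projections, columns=[f"PC{i + 1}" for i in range(self.modes.shape[0])]
        )
        df.insert(0, "ensemble", self.member_labels)
        df.to_csv(directory / f"{prefix}_projections.csv", index=False)

    def write_nmd(self, path: str | Path) -> None:
        """NMD mode file readable by common normal-mode viewers."""
        lines = ["nmwiz_load " + Path(path).name, "name collective_modes"]
        lines.append("resids " + " ".join(str(a.residue_number) for a in self.atoms))
        lines.append("atomnames " + " ".join(a.atom_name for a in self.atoms))
        lines.append(
            "coordinates " + " ".join(f"{x:.3f}" for x in self.mean_coordinates.ravel())
        )
        for i, (vec, ev) in enumerate(zip(self.modes, self.eigenvalues), start=1):
            lines.append(
                f"mode {i} {ev:.6f} " + " ".join(f"{x:.6f}" for x in vec)
            )
        Path(path).write_text("\n".join(lines) + "\n")


def pca(
    ensembles: Sequence[ConformerEnsemble] | ConformerEnsemble,
    selection: Sequence[str] = ("CA",),
    n_modes: int | None = None,
) -> ModeDecomposition:
    """Principal component analysis of the pooled, superposed selection.

    Conformers of all input ensembles are pooled into one set (the modes
    live in a single shared PC plane), superposed on the selection, and the
    covariance of the flattened coordinates about the pooled mean is
    eigendecomposed.  Projections are the centered coordinates dotted with
    the modes.  Each mode's sign is fixed so its largest-magnitude component
    is positive.
    """
    if isinstance(ensembles, ConformerEnsemble):
        ensembles = [ensembles]
    pooled_members = [m for e in ensembles for m in e.members]
    labels = [e.label for e in ensembles for _ in e.members]
    if len(pooled_members) < 3:
        raise ValueError("pooled PCA needs at least 3 conformers")
    pool = ConformerEnsemble(pooled_members, label="pool")
    pool = superpose(pool, selection)
    sel_atoms = pool.select(selection)
    coords = pool.coord_array(sel_atoms)          # (M, n, 3)
    flat = coords.reshape(coords.shape[0], -1)    # (M, 3n)
    mean = flat.mean(axis=0)
    centered = flat - mean
    total_var = float(np.sum(centered ** 2) / (len(pooled_members) - 1))
    if total_var < 1e-12:
        raise ValueError("degenerate pool: zero coordinate variance")
    cov = centered.T @ centered / (len(pooled_members) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if n_modes is not None:
        evals = evals[:n_modes]
        evecs = evecs[:, :n_modes]
    modes = evecs.T.copy()
    for i in range(modes.shape[0]):  # reproducible sign convention
        j = int(np.argmax(np.abs(modes[i])))
        if modes[i, j] < 0:
            modes[i] = -modes[i]
    projections = centered @ modes.T
    return ModeDecomposition(
        atoms=sel_atoms,
        mean_coordinates=mean.reshape(-1, 3),
        modes=modes,
        eigenvalues=evals,
        projections=projections,
        member_labels=labels,
    )


def square_fluctuations(decomposition: ModeDecomposition, mode_index: int) -> dict[int, float]:
    """Per-residue square fluctuation (Å²) carried by one mode.

    For a unit-norm mode the values sum to the mode's eigenvalue.
    """
    mode = decomposition.modes[mode_index].reshape(-1, 3)
    ev = float(decomposition.eigenvalues[mode_index])
    out: dict[int, float] = {}
    for atom, comp in zip(decomposition.atoms, mode):
        out[atom.residue_number] = out.get(atom.residue_number, 0.0) + ev * float(comp @ comp)
    return out


@dataclass
class DistanceModeCorrelation:
    """Residue-pair → Pearson correlation of Cα distance with a mode projection."""

    residues: list[int]
    matrix: np.ndarray            # (n_res, n_res), NaN on diagonal/undefined
    mode_index: int

    def value(self, res_a: int, res_b: int) -> float:
        i, j = self.residues.index(res_a), self.residues.index(res_b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residues, columns=self.residues)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def distance_mode_correlation(
    ensembles: Sequence[ConformerEnsemble] | ConformerEnsemble,
    decomposition: ModeDecomposition,
    mode_index: int,
    selection: Sequence[str] = ("CA",),
) -> DistanceModeCorrelation:
    """Correlate every Cα–Cα distance with a mode's per-member projection.

    Distances are computed per pooled member (rigid-motion invariant) and
    correlated with that member's projection on ``mode_index``.  Pairs with
    zero distance variance are undefined and set to NaN, never to 0.
    """
    if isinstance(ensembles, ConformerEnsemble):
        ensembles = [ensembles]
    pooled = [m for e in ensembles for m in e.members]
    proj = decomposition.projections[:, mode_index]
    if len(pooled) != len(proj):
        raise ValueError("projections do not match pooled member count")
    pool = ConformerEnsemble(pooled, label="pool")
    sel_atoms = pool.select(selection)
    residues = [a.residue_number for a in sel_atoms]
    coords = pool.coord_array(sel_atoms)  # (M, n, 3)
    n = len(sel_atoms)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=-1))  # (M, n, n)
    dist_c = dist - dist.mean(axis=0)
    proj_c = proj - proj.mean()
    denom_d = np.sqrt(np.sum(dist_c ** 2, axis=0))
    denom_p = math.sqrt(float(np.sum(proj_c ** 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.einsum("m,mij->ij", proj_c, dist_c) / (denom_d * denom_p)
    corr[denom_d < 1e-12] = np.nan
    np.fill_diagonal(corr, np.nan)
    return DistanceModeCorrelation(residues, corr, mode_index)


def top_correlated_pairs(
    correlation: DistanceModeCorrelation,
    k: int,
    sign: int | None = None,
) -> list[tuple[int, int, float]]:
    """The k residue pairs of largest |correlation| with the requested sign.

    ``sign`` of +1/−1 restricts to positively/negatively correlated pairs;
    ties break deterministically by (lower residue index, second index).
    """
    import warnings

    res = correlation.residues
    entries: list[tuple[int, int, float]] = []
    n = len(res)
    for i in range(n):
        for j in range(i + 1, n):
            c = correlation.matrix[i, j]
            if np.isnan(c):
                continue
            if sign is not None and np.sign(c) != np.sign(sign):
                continue
            entries.append((res[i], res[j], float(c)))
    entries.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    if k > len(entries):
        warnings.warn(f"only {len(entries)} pairs available, requested {k}", stacklevel=2)
    return entries[:k]
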