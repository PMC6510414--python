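"""Hydrogen-bond detection, per-ensemble occupancy and apo/holo differencing.

Hydrogen bonds are identified with geometric distance–angle criteria on
N/O donors and acceptors: H···A ≤ 2.5 Å, D···A ≤ 3.5 Å and a D–H···A angle
of at least 120° (all three thresholds configurable).  Occupancy is the
fraction of ensemble members in which a donor-heavy-atom/acceptor pair is
bonded through any of the donor's hydrogens; differencing two occupancy
tables yields the bonds that change most between ligation states.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble_io import AtomKey, Conformer, ConformerEnsemble, EnsembleIOError

__all__ = [
    "HBondCriteria",
    "HBondKey",
    "OccupancyTable",
    "detect_hbonds",
    "occupancy",
    "state_difference",
]

_COVALENT_DH = 1.2  # Å, hydrogen counted as bound to its donor heavy atom


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric thresholds for donor–H···acceptor identification."""

    max_ha: float = 2.5       # H···A, Å
    min_angle: float = 120.0  # D–H···A, degrees
    max_da: float = 3.5       # D···A, Å


@dataclass(frozen=True, order=True)
class HBondKey:
    donor: AtomKey
    hydrogen: AtomKey
    acceptor: AtomKey

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")

    def heavy_pair(self) -> tuple[AtomKey, AtomKey]:
        return (self.donor, self.acceptor)

    def __str__(self) -> str:
        return (
            f"{self.donor.residue_number} {self.donor.atom_name}-"
            f"{self.acceptor.residue_number} {self.acceptor.atom_name}"
        )


def _element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[0] if stripped else "X"


def detect_hbonds(
    conformer: Conformer, criteria: HBondCriteria = HBondCriteria()
) -> set[HBondKey]:
    """All donor–H–acceptor triples meeting every criterion (N/O atoms only)."""
    atoms = conformer.atoms
    coords = conformer.coords
    heavy_no = [i for i, a in enumerate(atoms) if _element(a.atom_name) in ("N", "O")]
    hydrogens = [i for i, a in enumerate(atoms) if _element(a.atom_name) == "H"]
    if not hydrogens:
        raise EnsembleIOError(
            "hydrogen bond detection requires hydrogen atoms, none present"
        )
    heavy_coords = coords[heavy_no]
    out: set[HBondKey] = set()
    for ih in hydrogens:
        h = coords[ih]
        d_dh = np.linalg.norm(heavy_coords - h, axis=1)
        donor_candidates = [
            (heavy_no[k], d_dh[k]) for k in np.flatnonzero(d_dh <= _COVALENT_DH)
        ]
        if not donor_candidates:
            continue
        idon = min(donor_candidates, key=lambda t: t[1])[0]  # closest heavy atom
        d = coords[idon]
        for k, iacc in enumerate(heavy_no):
            if iacc == idon:
                continue
            ha = d_dh[k]
            if ha > criteria.max_ha:
                continue
            da = np.linalg.norm(coords[iacc] - d)
            if da > criteria.max_da:
                continue
            v1 = d - h
            v2 = coords[iacc] - h
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle < criteria.min_angle:
                continue
            out.add(HBondKey(atoms[idon], atoms[ih], atoms[iacc]))
    return out


@dataclass
class OccupancyTable:
    """Fraction of members in which each donor/acceptor heavy-atom pair bonds."""

    occupancy: dict[tuple[AtomKey, AtomKey], float]
    n_members: int

    def __post_init__(self) -> None:
        for pair, f in self.occupancy.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"occupancy outside [0,1] for {pair}: {f}")

    def get(self, donor: AtomKey, acceptor: AtomKey) -> float:
        return self.occupancy.get((donor, acceptor), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                # S1-Table-style key: a_<donorRes>_<donorAtom>_a_<accRes>_<accAtom>
                "bond": f"a_{d.residue_number}_{d.atom_name}_a_{a.residue_number}_{a.atom_name}",
                "donor_residue": d.residue_number,
                "donor_atom": d.atom_name,
                "acceptor_residue": a.residue_number,
                "acceptor_atom": a.atom_name,
                "occupancy": f,
            }
            for (d, a), f in sorted(self.occupancy.items())
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def occupancy(
    ensemble: ConformerEnsemble, criteria: HBondCriteria = HBondCriteria()
) -> OccupancyTable:
    """Per donor/acceptor pair, the fraction of members where any hydrogen
    of that donor satisfies the criteria.  Pairs never observed are simply
    absent (the table is sparse)."""
    counts: dict[tuple[AtomKey, AtomKey], int] = {}
    for member in ensemble.members:
        pairs = {hb.heavy_pair() for hb in detect_hbonds(member, criteria)}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
    n = len(ensemble)
    return OccupancyTable({p: c / n for p, c in counts.items()}, n)


def state_difference(
    occ_apo: OccupancyTable,
    occ_holo: OccupancyTable,
    min_delta: float = 0.5,
    mostly_cutoff: float = 0.75,
) -> list[tuple[tuple[AtomKey, AtomKey], float, str]]:
    """Bonds whose occupancy changes by at least ``min_delta`` between states.

    Returns (heavy-atom pair, occ_holo − occ_apo, state label) sorted by
    donor residue number.  Labels follow the prevailing state, with a
    "mostly" qualifier for margins below ``mostly_cutoff``.
    """
    keys = set(occ_apo.occupancy) | set(occ_holo.occupancy)
    out = []
    for key in keys:
        a = occ_apo.occupancy.get(key, 0.0)
        h = occ_holo.occupancy.get(key, 0.0)
        delta = h - a
        if abs(delta) < min_delta:
            continue
        state = "holo" if delta > 0 else "apo"
        label = state if abs(delta) >= mostly_cutoff else f"mostly {state}"
        out.append((key, delta, label))
    out.sort(key=lambda t: (t[0][0].residue_number, t[0][0].atom_name,
                            t[0][1].residue_number, t[0][1].atom_name))
    return out


def difference_frame(
    diff: Sequence[tuple[tuple[AtomKey, AtomKey], float, str]],
    regions: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Tabulate a state difference list; optional per-residue region labels."""
    regions = regions or {}
    rows = [
        {
            "bond": f"{d.residue_number} {d.atom_name}- {a.residue_number} {a.atom_name}",
            "state": label,
            "delta_occupancy": delta,
            "donor_region": regions.get(d.residue_number, ""),
            "acceptor_region": regions.get(a.residue_number, ""),
        }
        for (d, a), delta, label in diff
    ]
    return pd.DataFrame(rows)
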