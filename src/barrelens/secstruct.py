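"""Three-state secondary-structure assignment from backbone hydrogen bonds.

Backbone H-bonds are scored with the classic electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol]

(distances in Å between the donor N/H and acceptor C′/O), a bond existing
when E < −0.5 kcal/mol.  Helices (H) are residues inside repeating i→i+4
turn patterns; strands (E) are residues inside parallel or antiparallel
H-bond ladders of at least two consecutive bridges; everything else is
coil (C).  3₁₀/π helices fold into H and isolated bridges into C — the map
is a deliberate 3-state simplification of finer continuous assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .ensemble_io import Conformer, ConformerEnsemble

__all__ = [
    "backbone_hbond_energy",
    "assign_ss",
    "ensemble_ss_map",
    "SSMap",
]

_KS_FACTOR = 0.084 * 332.0  # kcal·Å/mol
_KS_CUTOFF = -0.5           # kcal/mol
_CHAIN_BREAK = 4.5          # Å between consecutive Cα atoms


def backbone_hbond_energy(
    n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray
) -> float:
    """Electrostatic backbone H-bond energy in kcal/mol.

    ``n``/``h`` are the donor amide positions, ``c``/``o`` the acceptor
    carbonyl positions.
    """
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        raise ValueError("coincident atoms in H-bond energy")
    return float(_KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _backbone_table(conformer: Conformer) -> tuple[list[int], dict[int, dict[str, np.ndarray]]]:
    residues = sorted(conformer.residue_numbers())
    table: dict[int, dict[str, np.ndarray]] = {r: {} for r in residues}
    for a in conformer.atoms:
        if a.atom_name in ("N", "H", "CA", "C", "O"):
            table[a.residue_number][a.atom_name] = conformer[a]
    return residues, table


def _hbond_matrix(residues: list[int], table: dict) -> set[tuple[int, int]]:
    """(donor_residue, acceptor_residue) pairs bonded by the energy criterion."""
    bonds: set[tuple[int, int]] = set()
    for d in residues:
        don = table[d]
        if "N" not in don or "H" not in don:
            continue
        for a in residues:
            if a == d or abs(a - d) < 2:
                continue
            acc = table[a]
            if "C" not in acc or "O" not in acc:
                continue
            if np.linalg.norm(don["N"] - acc["O"]) > 5.2:  # cheap distance gate
                continue
            e = backbone_hbond_energy(don["N"], don["H"], acc["C"], acc["O"])
            if e < _KS_CUTOFF:
                bonds.add((d, a))
    return bonds


def _segments(residues: list[int], table: dict) -> dict[int, int]:
    """Chain segment id per residue; breaks where Cα_i–Cα_{i+1} > 4.5 Å."""
    seg: dict[int, int] = {}
    current = 0
    for k, r in enumerate(residues):
        if k > 0:
            prev = residues[k - 1]
            ca_prev = table[prev].get("CA")
            ca = table[r].get("CA")
            if (
                r != prev + 1
                or ca_prev is None
                or ca is None
                or np.linalg.norm(ca - ca_prev) > _CHAIN_BREAK
            ):
                current += 1
        seg[r] = current
    return seg


def assign_ss(conformer: Conformer) -> dict[int, str]:
    """Assign H/E/C to every residue of one conformer."""
    residues, table = _backbone_table(conformer)
    if not residues:
        raise ValueError("empty conformer")
    seg = _segments(residues, table)
    hb = _hbond_matrix(residues, table)

    def bonded(d: int, a: int) -> bool:
        return (d, a) in hb

    ss = {r: "C" for r in residues}

    # helix: two consecutive i→i+4 turns mark a run; turns must not span breaks
    turn4 = {i for i in residues if bonded(i + 4, i) and seg.get(i) == seg.get(i + 4)}
    for i in residues:
        if i in turn4 and (i + 1) in turn4:
            for j in range(i + 1, i + 5):
                if j in ss:
                    ss[j] = "H"

    # strands: parallel / antiparallel bridges, ladders of length >= 2
    bridges: set[tuple[int, int]] = set()
    for i in residues:
        for j in residues:
            if seg[i] == seg[j] and abs(i - j) < 3:
                continue
            if i == j:
                continue
            anti = (bonded(i, j) and bonded(j, i)) or (
                bonded(i - 1, j + 1) and bonded(j - 1, i + 1)
            )
            para = (bonded(i, j - 1) and bonded(j + 1, i)) or (
                bonded(j, i - 1) and bonded(i + 1, j)
            )
            if anti or para:
                bridges.add((i, j))
    strand: set[int] = set()
    for i, j in bridges:
        # ladder: a neighbouring bridge continues the sheet in either direction
        if ((i + 1, j - 1) in bridges or (i + 1, j + 1) in bridges
                or (i - 1, j + 1) in bridges or (i - 1, j - 1) in bridges):
            strand.add(i)
            strand.add(j)
    for r in strand:
        if ss[r] != "H":
            ss[r] = "E"
    return ss


@dataclass
class SSMap:
    """Per-member, per-residue 3-state secondary structure matrix."""

    residues: list[int]
    rows: list[str]        # one string per member, one symbol per residue
    member_ids: list[int]

    @property
    def assignment(self) -> dict[tuple[int, int], str]:
        return {
            (mid, res): row[i]
            for mid, row in zip(self.member_ids, self.rows)
            for i, res in enumerate(self.residues)
        }

    def fractions(self, member: int) -> dict[str, float]:
        row = self.rows[member]
        n = len(row)
        return {s: row.count(s) / n for s in "HEC"}

    def to_text(self) -> str:
        return "\n".join(self.rows) + "\n"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(r) for r in self.rows], index=self.member_ids, columns=self.residues
        )

    def write(self, path: str | Path, csv_path: str | Path | None = None) -> None:
        Path(path).write_text(self.to_text())
        if csv_path is not None:
            self.to_frame().to_csv(csv_path)


def ensemble_ss_map(ensemble: ConformerEnsemble) -> SSMap:
    """Fig-4-style map: members as rows (ensemble order), residues as columns."""
    residues = sorted(ensemble.members[0].residue_numbers())
    rows = []
    for m in ensemble.members:
        ss = assign_ss(m)
        rows.append("".join(ss[r] for r in residues))
    return SSMap(residues, rows, [m.model_id for m in ensemble.members])
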