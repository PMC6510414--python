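"""Ensemble-averaged chemical-shift evaluation with a pluggable predictor.

A predictor is any deterministic callable ``Conformer -> ShiftTable`` that
covers at least the amide N and H nuclei.  Production use plugs in the
output files of an external empirical predictor (read through
:func:`read_predictor_output`); the package ships a deterministic
*surrogate* predictor — a fixed smooth map from local backbone geometry
(φ/ψ dihedrals and Cα-neighbour distances) to shifts with frozen
coefficients — so that every downstream stage is testable without any
external binary.  The surrogate is a synthetic stand-in: its absolute
values are not physically meaningful, only its deterministic sensitivity
to conformation is.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._geom import dihedral
from .ensemble_io import Conformer, ConformerEnsemble, ShiftTable

__all__ = [
    "surrogate_predictor",
    "ensemble_average_shifts",
    "shift_correlation",
    "read_predictor_output",
]

Predictor = Callable[[Conformer], ShiftTable]

# Frozen surrogate coefficients (random-phase sinusoids; chosen once, never
# tuned).  delta = base + a*cos(phi + p1) + b*sin(psi + p2) + c*(d_prev - 3.8)
# + e*(d_next - 3.8), with distances to the neighbouring CA atoms in Å.
_SURROGATE = {
    "N": dict(base=118.0, a=4.7, p1=0.61, b=3.9, p2=-1.13, c=2.3, e=-1.7),
    "H": dict(base=8.25, a=0.55, p1=-0.27, b=0.48, p2=0.94, c=0.21, e=0.17),
}


def surrogate_predictor(conformer: Conformer, nuclei: Sequence[str] = ("N", "H")) -> ShiftTable:
    """Deterministic structure → shift map used as the test-time predictor.

    Shifts are produced for interior residues only (those with both φ and ψ
    defined and both Cα neighbours present).
    """
    index: dict[tuple[int, str], np.ndarray] = {}
    for i, a in enumerate(conformer.atoms):
        if a.atom_name in ("N", "CA", "C"):
            index[(a.residue_number, a.atom_name)] = conformer.coords[i]
    residues = conformer.residue_numbers()
    entries: dict[tuple[int, str], float] = {}
    for res in residues:
        prev_c = index.get((res - 1, "C"))
        prev_ca = index.get((res - 1, "CA"))
        next_n = index.get((res + 1, "N"))
        next_ca = index.get((res + 1, "CA"))
        n = index.get((res, "N"))
        ca = index.get((res, "CA"))
        c = index.get((res, "C"))
        if any(x is None for x in (prev_c, prev_ca, next_n, next_ca, n, ca, c)):
            continue
        phi = dihedral(prev_c, n, ca, c)
        psi = dihedral(n, ca, c, next_n)
        d_prev = float(np.linalg.norm(ca - prev_ca))
        d_next = float(np.linalg.norm(ca - next_ca))
        for nuc in nuclei:
            k = _SURROGATE[nuc]
            entries[(res, nuc)] = (
                k["base"]
                + k["a"] * np.cos(phi + k["p1"])
                + k["b"] * np.sin(psi + k["p2"])
                + k["c"] * (d_prev - 3.8)
                + k["e"] * (d_next - 3.8)
            )
    return ShiftTable(entries)


def ensemble_average_shifts(ensemble: ConformerEnsemble, predictor: Predictor) -> ShiftTable:
    """Arithmetic mean of predicted shifts over members, per (residue, nucleus).

    Keys absent from some members are averaged over the members that carry
    them; a predictor failure propagates with the member id attached.
    """
    sums: dict[tuple[int, str], float] = {}
    counts: dict[tuple[int, str], int] = {}
    for m in ensemble.members:
        try:
            table = predictor(m)
        except Exception as exc:
            raise RuntimeError(f"predictor failed on member {m.model_id}: {exc}") from exc
        for key, val in table.entries.items():
            sums[key] = sums.get(key, 0.0) + val
            counts[key] = counts.get(key, 0) + 1
    return ShiftTable({k: sums[k] / counts[k] for k in sums})


def per_member_mean_correlation(
    ensemble: ConformerEnsemble, predictor: Predictor,
    experimental: ShiftTable, nucleus: str,
) -> float:
    """Alternative convention: mean over members of per-member correlations."""
    vals = [shift_correlation(experimental, predictor(m), nucleus) for m in ensemble.members]
    return float(np.mean(vals))


def shift_correlation(experimental: ShiftTable, calculated: ShiftTable, nucleus: str) -> float:
    """Pearson correlation over the shared (residue, nucleus) entries.

    Residues missing from either table are dropped pairwise, never imputed.
    """
    shared = sorted(
        set(experimental.residues(nucleus)) & set(calculated.residues(nucleus))
    )
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared {nucleus} shifts, got {len(shared)}")
    a = experimental.vector(nucleus, shared)
    b = calculated.vector(nucleus, shared)
    return float(stats.pearsonr(a, b)[0])


def read_predictor_output(path: str | Path) -> ShiftTable:
    """Adapter for the CSV output of external empirical shift predictors.

    Expects columns NUM, RES, ATOMNAME, SHIFT (case-insensitive), the
    common tabular format written by structure-based shift programs.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().upper() for c in df.columns]
    required = {"NUM", "ATOMNAME", "SHIFT"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    entries: dict[tuple[int, str], float] = {}
    for _, row in df.iterrows():
        nuc = str(row["ATOMNAME"]).strip().upper()
        if nuc in {"N", "H", "HN", "CA", "CB", "C", "HA"}:
            entries[(int(row["NUM"]), "H" if nuc == "HN" else nuc)] = float(row["SHIFT"])
    return ShiftTable(entries)
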