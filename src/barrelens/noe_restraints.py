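"""NOE distance-restraint preprocessing and r^-6 ensemble evaluation.

The preprocessing pipeline mirrors standard ensemble-validation practice for
proton–proton NOE upper bounds:

1. *removal of stereospecificity* — every stereospecific proton name is
   replaced by the full group of its stereo-equivalent partners (HB2/HB3
   become {HB2, HB3}; a Leu HD11 becomes all six HD protons), and ``#``
   pseudo-atom wildcards are expanded against the topology;
2. *binning* — each upper bound is rounded up to the next integer Ångström,
   yielding 1 Å wide bins on the 4–10 Å range (sub-4 Å bounds clamp up to
   the 4 Å bin; bounds above 10 Å are rejected);
3. *evaluation* — the effective distance of a restraint against an ensemble
   is the r^-6 average, summed over all cross pairs of the two (possibly
   ambiguous) groups within each member and averaged uniformly over members:

   ``d_eff = ( mean_m  sum_{a,b} r_ab^-6 )^(-1/6)``

A restraint is violated when ``d_eff > bin + tolerance`` (strict), with a
default tolerance of 0.5 Å.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ensemble_io import AtomKey, Conformer, ConformerEnsemble

__all__ = [
    "AtomGroup",
    "DistanceRestraint",
    "ViolationReport",
    "destereo",
    "bin_upper_bound",
    "effective_distance",
    "violation_report",
    "filter_unviolated",
]


@dataclass(frozen=True)
class AtomGroup:
    """Non-empty set of (possibly wildcarded) atom identities."""

    atoms: frozenset[AtomKey]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("AtomGroup must be non-empty")

    def __iter__(self):
        return iter(sorted(self.atoms))

    def __len__(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return "/".join(str(a) for a in self)


@dataclass(frozen=True)
class DistanceRestraint:
    """Ambiguous atom-group pair with an upper bound (and optionally a bin)."""

    group_a: AtomGroup
    group_b: AtomGroup
    upper_bound: float
    bin: int | None = None

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError(f"upper bound must be positive, got {self.upper_bound}")
        if self.bin is not None:
            if not (4 <= self.bin <= 10):
                raise ValueError(f"bin {self.bin} outside [4, 10]")
            if self.bin < self.upper_bound - 1e-9:
                raise ValueError(f"bin {self.bin} below upper bound {self.upper_bound}")

    @property
    def effective_bound(self) -> float:
        return float(self.bin) if self.bin is not None else self.upper_bound


# ---------------------------------------------------------------------------
# Stereo-equivalence
# ---------------------------------------------------------------------------

# Stereo-equivalent proton sets per residue type.  Methylene pairs, the two
# methyls of Leu/Val isopropyl groups, rotationally equivalent methyl and
# amino protons, and symmetric aromatic ring positions.  The generic
# methylene rule covers the standard HB2/HB3-style pairs for all residues.
_METHYLENE_STEMS = ("HA", "HB", "HG", "HG1", "HD", "HE", "HZ")

_SPECIAL_SETS: dict[str, list[set[str]]] = {
    "LEU": [{"HD11", "HD12", "HD13", "HD21", "HD22", "HD23"}],
    "VAL": [{"HG11", "HG12", "HG13", "HG21", "HG22", "HG23"}],
    "ILE": [{"HG21", "HG22", "HG23"}, {"HD11", "HD12", "HD13"}, {"HG12", "HG13"}],
    "ALA": [{"HB1", "HB2", "HB3"}],
    "THR": [{"HG21", "HG22", "HG23"}],
    "MET": [{"HE1", "HE2", "HE3"}],
    "LYS": [{"HZ1", "HZ2", "HZ3"}],
    "ASN": [{"HD21", "HD22"}],
    "GLN": [{"HE21", "HE22"}],
    "ARG": [{"HH11", "HH12", "HH21", "HH22"}],
    "PHE": [{"HD1", "HD2"}, {"HE1", "HE2"}],
    "TYR": [{"HD1", "HD2"}, {"HE1", "HE2"}],
}


def _stereo_set(residue_name: str, atom_name: str, present: set[str]) -> set[str]:
    """Names stereo-equivalent to ``atom_name`` among atoms ``present``."""
    for special in _SPECIAL_SETS.get(residue_name, ()):  # explicit table first
        if atom_name in special:
            hit = special & present
            if hit:
                return hit
    # generic methylene rule: H<pos>2 / H<pos>3 pairs
    for stem in _METHYLENE_STEMS:
        if atom_name in {stem + "2", stem + "3"}:
            pair = {stem + "2", stem + "3"} & present
            if len(pair) == 2:
                return pair
    return {atom_name}


def _expand_wildcard(key: AtomKey, topology: Conformer) -> set[AtomKey]:
    """Expand a ``#`` wildcard name against the topology (prefix match)."""
    if "#" not in key.atom_name and "*" not in key.atom_name:
        if key not in topology:
            raise KeyError(f"atom {key} not found in topology")
        return {key}
    prefix = key.atom_name.rstrip("#*")
    hits = {
        a
        for a in topology.atoms_of_residue(key.residue_number)
        if a.atom_name.startswith(prefix) and a.atom_name != prefix
        and a.atom_name[len(prefix):].isdigit()
    }
    # "HB#" should also match a lone "HB" if numbered variants are absent
    if not hits:
        hits = {
            a for a in topology.atoms_of_residue(key.residue_number)
            if a.atom_name == prefix
        }
    if not hits:
        raise KeyError(f"wildcard {key} matches no atom in topology")
    return hits


def _destereo_group(group: AtomGroup, topology: Conformer) -> AtomGroup:
    out: set[AtomKey] = set()
    for key in group.atoms:
        for concrete in _expand_wildcard(key, topology):
            present = {a.atom_name for a in topology.atoms_of_residue(concrete.residue_number)}
            names = _stereo_set(concrete.residue_name, concrete.atom_name, present)
            out.update(
                AtomKey(concrete.residue_number, concrete.residue_name, n) for n in names
            )
    return AtomGroup(frozenset(out))


def destereo(restraint: DistanceRestraint, topology: Conformer) -> DistanceRestraint:
    """Remove stereospecificity: widen each group to its stereo-equivalent set."""
    return replace(
        restraint,
        group_a=_destereo_group(restraint.group_a, topology),
        group_b=_destereo_group(restraint.group_b, topology),
    )


def bin_upper_bound(d: float) -> int:
    """Round an upper bound up to the next integer Å bin on the 4–10 Å range."""
    if d <= 0:
        raise ValueError(f"upper bound must be positive, got {d}")
    if d > 10:
        raise ValueError(f"upper bound {d} Å above the 10 Å bin range")
    return max(4, math.ceil(d))


def preprocess(
    restraints: Sequence[DistanceRestraint], topology: Conformer
) -> list[DistanceRestraint]:
    """Full preprocessing: destereo, then bin every upper bound."""
    out = []
    for r in restraints:
        r = destereo(r, topology)
        out.append(replace(r, bin=bin_upper_bound(r.upper_bound)))
    return out


# ---------------------------------------------------------------------------
# r^-6 evaluation
# ---------------------------------------------------------------------------


def effective_distance(
    ensemble: ConformerEnsemble,
    restraint: DistanceRestraint,
    ambiguity: Literal["sum", "mean"] = "sum",
) -> float:
    """r^-6 ensemble- and ambiguity-averaged effective distance in Å.

    Per member, ``s_m = sum over cross pairs of r^-6`` (the standard
    pseudo-atom sum convention; ``ambiguity='mean'`` divides by the pair
    count instead), then ``d_eff = (mean_m s_m)^(-1/6)``.
    """
    ref = ensemble.members[0]
    try:
        ia = [ref.index_of(a) for a in restraint.group_a]
        ib = [ref.index_of(b) for b in restraint.group_b]
    except KeyError as exc:
        raise KeyError(f"restraint atom missing from ensemble: {exc}") from exc
    coords = ensemble.coord_array()  # (M, N, 3)
    pa = coords[:, ia, None, :]  # (M, |A|, 1, 3)
    pb = coords[:, None, ib, :]  # (M, 1, |B|, 3)
    d2 = np.sum((pa - pb) ** 2, axis=-1)  # (M, |A|, |B|)
    if np.any(d2 < 1e-12):
        raise ValueError(f"zero distance pair in restraint {restraint.group_a}–{restraint.group_b}")
    s = np.sum(d2 ** -3, axis=(1, 2))  # (M,)
    if ambiguity == "mean":
        s = s / (len(ia) * len(ib))
    elif ambiguity != "sum":
        raise ValueError(f"unknown ambiguity mode {ambiguity!r}")
    return float(np.mean(s) ** (-1.0 / 6.0))


@dataclass
class ViolationReport:
    """Per-restraint effective distances and the summary violation fraction."""

    per_restraint: list[tuple[DistanceRestraint, float, bool]]
    tolerance: float

    @property
    def n(self) -> int:
        return len(self.per_restraint)

    @property
    def n_violated(self) -> int:
        return sum(1 for _, _, v in self.per_restraint if v)

    @property
    def percent_violated(self) -> float:
        return 100.0 * self.n_violated / self.n

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "restraint": i,
                "group_a": str(r.group_a),
                "group_b": str(r.group_b),
                "bin": r.bin,
                "effective_distance": d,
                "violated": v,
            }
            for i, (r, d, v) in enumerate(self.per_restraint)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n": self.n,
            "n_violated": self.n_violated,
            "percent": self.percent_violated,
            "tolerance": self.tolerance,
        }

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def violation_report(
    ensemble: ConformerEnsemble,
    restraints: Sequence[DistanceRestraint],
    tolerance: float = 0.5,
    ambiguity: Literal["sum", "mean"] = "sum",
) -> ViolationReport:
    """Evaluate binned restraints against the ensemble with r^-6 averaging."""
    if not restraints:
        raise ValueError("empty restraint list")
    per = []
    for r in restraints:
        if r.bin is None:
            raise ValueError("restraints must be binned before evaluation")
        d = effective_distance(ensemble, r, ambiguity)
        per.append((r, d, d > r.bin + tolerance))
    return ViolationReport(per, tolerance)


def filter_unviolated(
    restraints: Sequence[DistanceRestraint],
    reference_ensemble: ConformerEnsemble,
    tolerance: float = 0.5,
    ambiguity: Literal["sum", "mean"] = "sum",
) -> list[DistanceRestraint]:
    """Order-preserving subset of restraints unviolated in the reference."""
    kept = []
    for r in restraints:
        if r.bin is None:
            raise ValueError("restraints must be binned before filtering")
        if effective_distance(reference_ensemble, r, ambiguity) <= r.bin + tolerance:
            kept.append(r)
    return kept
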