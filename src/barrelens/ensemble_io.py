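"""Reading and writing of the data the pipeline consumes.

Multi-model structures are handled through biotite; restraint lists and
per-residue tables (chemical shifts, S² order parameters, |Δω| magnitudes)
use small documented text dialects so that every input is inspectable and
diffable.  Residue numbering always follows the author numbering of the
input file verbatim; no renumbering is ever performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomKey",
    "Conformer",
    "ConformerEnsemble",
    "ShiftTable",
    "OrderParameterSet",
    "DeltaOmegaSet",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_restraints",
    "read_table",
    "EnsembleIOError",
]

#: nuclei accepted in shift tables
NUCLEI = frozenset({"N", "H", "CA", "CB", "C", "HA"})


class EnsembleIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True, order=True)
class AtomKey:
    """Identity of one atom: author residue number, residue type, atom name."""

    residue_number: int
    residue_name: str
    atom_name: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    def __str__(self) -> str:  # e.g. "73 THR OG1"
        return f"{self.residue_number} {self.residue_name} {self.atom_name}"


class Conformer:
    """One member of a multi-model ensemble.

    Coordinates are stored as an (n_atoms, 3) array in Ångström, indexed by
    a shared tuple of :class:`AtomKey`.
    """

    def __init__(self, atoms: Sequence[AtomKey], coords: np.ndarray, model_id: int = 1):
        atoms = tuple(atoms)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(f"coords shape {coords.shape} does not match {len(atoms)} atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if len(set(atoms)) != len(atoms):
            raise ValueError("duplicate AtomKey in conformer")
        self.atoms = atoms
        self.coords = coords
        self.model_id = int(model_id)
        self._index = {a: i for i, a in enumerate(atoms)}

    def __contains__(self, key: AtomKey) -> bool:
        return key in self._index

    def __getitem__(self, key: AtomKey) -> np.ndarray:
        return self.coords[self._index[key]]

    def index_of(self, key: AtomKey) -> int:
        return self._index[key]

    @property
    def coordinates(self) -> Mapping[AtomKey, np.ndarray]:
        return {a: self.coords[i] for i, a in enumerate(self.atoms)}

    def residue_numbers(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_number, None)
        return list(seen)

    def residue_name(self, residue_number: int) -> str:
        for a in self.atoms:
            if a.residue_number == residue_number:
                return a.residue_name
        raise KeyError(residue_number)

    def atoms_of_residue(self, residue_number: int) -> list[AtomKey]:
        return [a for a in self.atoms if a.residue_number == residue_number]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Return a rigid-body transformed copy (x -> x @ R.T + t)."""
        return Conformer(self.atoms, self.coords @ np.asarray(rotation).T + translation,
                         self.model_id)


class ConformerEnsemble:
    """Ordered collection of conformers sharing one topology (AtomKey set)."""

    def __init__(
        self,
        members: Sequence[Conformer],
        label: str = "",
        temperature: float | None = None,
        sub_ensemble_ids: Sequence[int] | None = None,
    ):
        members = list(members)
        if not members:
            raise ValueError("ensemble needs at least one member")
        ref = members[0].atoms
        for m in members[1:]:
            if m.atoms != ref:
                raise ValueError("all members must share an identical AtomKey set")
        if sub_ensemble_ids is not None and len(sub_ensemble_ids) != len(members):
            raise ValueError("sub_ensemble_ids length mismatch")
        self.members = members
        self.label = label
        self.temperature = temperature
        self.sub_ensemble_ids = list(sub_ensemble_ids) if sub_ensemble_ids is not None else None

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def atoms(self) -> tuple[AtomKey, ...]:
        return self.members[0].atoms

    def coord_array(self, selection: Sequence[AtomKey] | None = None) -> np.ndarray:
        """Stacked coordinates, shape (n_members, n_selected, 3)."""
        if selection is None:
            return np.stack([m.coords for m in self.members])
        idx = [self.members[0].index_of(a) for a in selection]
        return np.stack([m.coords[idx] for m in self.members])

    def select(self, atom_names: Iterable[str]) -> list[AtomKey]:
        names = set(atom_names)
        return [a for a in self.atoms if a.atom_name in names]

    def with_members(self, members: Sequence[Conformer]) -> "ConformerEnsemble":
        return ConformerEnsemble(members, self.label, self.temperature, self.sub_ensemble_ids)


@dataclass
class ShiftTable:
    """Chemical shifts in ppm keyed by (residue_number, nucleus)."""

    entries: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (res, nuc), val in self.entries.items():
            if nuc not in NUCLEI:
                raise ValueError(f"unknown nucleus {nuc!r} for residue {res}")
            if not np.isfinite(val):
                raise ValueError(f"non-finite shift for residue {res} {nuc}")

    def residues(self, nucleus: str) -> list[int]:
        return sorted(res for (res, nuc) in self.entries if nuc == nucleus)

    def vector(self, nucleus: str, residues: Sequence[int]) -> np.ndarray:
        return np.array([self.entries[(r, nucleus)] for r in residues])


@dataclass
class OrderParameterSet:
    """Per-residue backbone S² values at one temperature."""

    values: dict[int, float]
    temperature: float

    def __post_init__(self) -> None:
        for res, s2 in self.values.items():
            if not 0.0 <= s2 <= 1.0:
                raise ValueError(f"S2 for residue {res} outside [0, 1]: {s2}")


@dataclass
class DeltaOmegaSet:
    """|Δω|(15N) magnitudes in ppm keyed by (residue_number, temperature)."""

    values: dict[tuple[int, float], float]

    def __post_init__(self) -> None:
        for (res, temp), v in self.values.items():
            if v < 0:
                raise ValueError(f"negative |d-omega| for residue {res} at {temp} K")

    @property
    def temperatures(self) -> list[float]:
        return sorted({t for (_, t) in self.values})

    def residues(self, temperature: float) -> list[int]:
        return sorted(r for (r, t) in self.values if t == temperature)

    def vector(self, temperature: float, residues: Sequence[int]) -> np.ndarray:
        return np.array([self.values[(r, temperature)] for r in residues])

    def without_temperature(self, temperature: float) -> "DeltaOmegaSet":
        return DeltaOmegaSet({k: v for k, v in self.values.items() if k[1] != temperature})


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O", "H")


def _atom_array_to_conformer(array: struc.AtomArray, model_id: int) -> Conformer:
    keep = (array.altloc_id == "A") | (array.altloc_id == "") | (array.altloc_id == ".") \
        if "altloc_id" in array.get_annotation_categories() else np.ones(array.array_length(), bool)
    array = array[keep]
    atoms = [
        AtomKey(int(array.res_id[i]), str(array.res_name[i]), str(array.atom_name[i]))
        for i in range(array.array_length())
    ]
    return Conformer(atoms, array.coord, model_id)


def read_pdb_ensemble(
    path: str | Path,
    selection: Iterable[str] | None = None,
    label: str | None = None,
) -> ConformerEnsemble:
    """Read a (multi-)model PDB file into a :class:`ConformerEnsemble`.

    One conformer is created per MODEL record, in file order; a file without
    MODEL records yields a single member.  When members disagree on their
    atom content, the AtomKey sets are equalized by intersection and a
    warning is emitted.  ``selection`` optionally restricts atoms by name
    (e.g. ``("N", "CA", "C")``).
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - passthrough of parser detail
        raise EnsembleIOError(f"cannot read PDB file {path}: {exc}") from exc
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise EnsembleIOError(f"{path}: no models found")

    raw: list[Conformer] = []
    for i in range(1, n_models + 1):
        arr = pdb.get_structure(model=i, altloc="first")
        raw.append(_atom_array_to_conformer(arr, i))

    key_sets = [set(c.atoms) for c in raw]
    common = set.intersection(*key_sets)
    if selection is not None:
        names = set(selection)
        common = {a for a in common if a.atom_name in names}
    if not common:
        raise EnsembleIOError(f"{path}: empty atom intersection across models")
    if selection is None and any(ks != key_sets[0] for ks in key_sets):
        warnings.warn(
            f"{path}: models differ in atom content; "
            f"intersected to {len(common)} shared atoms",
            stacklevel=2,
        )
    order = sorted(common, key=lambda a: (raw[0].index_of(a)))
    members = [
        Conformer(order, np.array([c[a] for a in order]), c.model_id) for c in raw
    ]
    return ConformerEnsemble(members, label=label or path.stem)


_ELEMENT_2 = {"FE", "ZN", "MG", "MN", "NA", "CL", "CA"}


def _element_of(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[0] if stripped else "X"


def write_pdb_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (MODEL/ENDMDL)."""
    atoms = ensemble.atoms
    n = len(atoms)
    template = struc.AtomArray(n)
    template.res_id = np.array([a.residue_number for a in atoms])
    template.res_name = np.array([a.residue_name for a in atoms])
    template.atom_name = np.array([a.atom_name for a in atoms])
    template.chain_id = np.full(n, "A")
    template.element = np.array([_element_of(a.atom_name) for a in atoms])
    template.hetero = np.zeros(n, bool)
    stack = struc.stack([template] * len(ensemble))
    stack.coord = ensemble.coord_array()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Restraint lists
# ---------------------------------------------------------------------------


def _parse_group(text: str, path: Path, lineno: int):
    parts = text.split()
    if len(parts) != 3:
        raise EnsembleIOError(f"{path}:{lineno}: malformed atom group {text!r}")
    try:
        resnum = int(parts[0])
    except ValueError as exc:
        raise EnsembleIOError(f"{path}:{lineno}: bad residue number {parts[0]!r}") from exc
    return AtomKey(resnum, parts[1].upper(), parts[2].upper())


def read_restraints(path: str | Path, dialect: str = "tsv"):
    """Read an NOE distance-restraint list.

    Two dialects are supported and must yield identical restraints on
    equivalent content:

    * ``tsv`` — three pipe-separated columns:
      ``23 LEU HD# | 77 ALA HB# | 5.0``
    * ``upl`` — CYANA-style whitespace columns:
      ``23 LEU HD#  77 ALA HB#  5.00``

    ``#`` is the pseudo-atom wildcard, expanded later against a topology.
    Groups are preserved verbatim; no preprocessing happens here.
    """
    from .noe_restraints import AtomGroup, DistanceRestraint  # local import: avoid cycle

    path = Path(path)
    dialect = dialect.lower()
    if dialect not in {"tsv", "upl"}:
        raise ValueError(f"unknown restraint dialect {dialect!r}")
    restraints = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        # records always start with a residue number, so '#' safely marks comments
        if not line or line.startswith("#"):
            continue
        if dialect == "tsv":
            fields = [f.strip() for f in line.split("|")]
            if len(fields) != 3:
                raise EnsembleIOError(f"{path}:{lineno}: expected 3 pipe-separated fields")
            ga_text, gb_text, bound_text = fields
        else:
            parts = line.split()
            if len(parts) < 7:
                raise EnsembleIOError(f"{path}:{lineno}: expected 7 whitespace columns")
            ga_text = " ".join(parts[0:3])
            gb_text = " ".join(parts[3:6])
            bound_text = parts[6]
        try:
            bound = float(bound_text)
        except ValueError as exc:
            raise EnsembleIOError(f"{path}:{lineno}: bad upper bound {bound_text!r}") from exc
        if bound <= 0:
            raise EnsembleIOError(f"{path}:{lineno}: non-positive upper bound {bound}")
        group_a = AtomGroup(frozenset({_parse_group(ga_text, path, lineno)}))
        group_b = AtomGroup(frozenset({_parse_group(gb_text, path, lineno)}))
        restraints.append(DistanceRestraint(group_a, group_b, bound))
    return restraints


# ---------------------------------------------------------------------------
# Per-residue tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path, kind: str, temperature: float | None = None):
    """Read a tab-separated per-residue table.

    ``kind='shifts'``      columns: residue, nucleus, shift
    ``kind='s2'``          columns: residue, s2 [, temperature]
    ``kind='delta_omega'`` columns: residue, temperature, delta_omega
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if kind == "shifts":
        _require(df, ("residue", "nucleus", "shift"), path)
        entries: dict[tuple[int, str], float] = {}
        for i, row in df.iterrows():
            key = (int(row["residue"]), str(row["nucleus"]).strip().upper())
            if key in entries:
                raise EnsembleIOError(f"{path}: duplicate entry {key} at row {i + 2}")
            entries[key] = float(row["shift"])
        return ShiftTable(entries)
    if kind == "s2":
        _require(df, ("residue", "s2"), path)
        if temperature is None:
            if "temperature" not in df.columns:
                raise EnsembleIOError(f"{path}: temperature column or argument required")
            temps = set(df["temperature"].astype(float))
            if len(temps) != 1:
                raise EnsembleIOError(f"{path}: mixed temperatures {sorted(temps)}")
            temperature = temps.pop()
        values: dict[int, float] = {}
        for i, row in df.iterrows():
            res = int(row["residue"])
            if res in values:
                raise EnsembleIOError(f"{path}: duplicate residue {res} at row {i + 2}")
            s2 = float(row["s2"])
            if not 0.0 <= s2 <= 1.0:
                raise EnsembleIOError(f"{path}: S2 outside [0,1] at row {i + 2}: {s2}")
            values[res] = s2
        return OrderParameterSet(values, float(temperature))
    if kind == "delta_omega":
        _require(df, ("residue", "temperature", "delta_omega"), path)
        dvalues: dict[tuple[int, float], float] = {}
        for i, row in df.iterrows():
            key = (int(row["residue"]), float(row["temperature"]))
            if key in dvalues:
                raise EnsembleIOError(f"{path}: duplicate entry {key} at row {i + 2}")
            v = float(row["delta_omega"])
            if v < 0:
                raise EnsembleIOError(f"{path}: negative |d-omega| at row {i + 2}")
            dvalues[key] = v
        return DeltaOmegaSet(dvalues)
    raise ValueError(f"unknown table kind {kind!r}")


def _require(df: pd.DataFrame, columns: tuple[str, ...], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise EnsembleIOError(f"{path}: missing columns {missing}")


def require_hydrogens(ensemble: ConformerEnsemble, operation: str) -> None:
    """Fail with a clear message when a stage needs hydrogens that are absent."""
    if not any(_element_of(a.atom_name) == "H" for a in ensemble.atoms):
        raise EnsembleIOError(
            f"{operation} requires hydrogen atoms, but the ensemble "
            f"{ensemble.label!r} contains none; no hydrogen building is performed"
        )
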