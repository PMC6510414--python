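"""Backbone S² order parameters from conformer ensembles.

S² is the generalized order parameter of the amide N–H bond vector: 1 for a
bond that points the same way in every member, 0 for an isotropically
disordered bond.  For unit bond vectors μ = (x, y, z) averaged uniformly
over the members of an unordered conformer set, the symmetric second-moment
form is used:

    S² = (3 (⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1) / 2

Prolines and residues with missing amide protons are skipped, matching NMR
observability.  No vibrational correction is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_io import AtomKey, ConformerEnsemble, OrderParameterSet

__all__ = ["backcalc_s2", "s2_compare", "S2Comparison"]



def backcalc_s2(
    ensemble: ConformerEnsemble,
    donor_atom: str = "N",
    hydrogen_atom: str = "H",
) -> dict[int, float]:
    """Back-calculate per-residue S² of the backbone N–H bond vector.

    Returns a map residue_number → S² for every residue that carries both
    amide atoms in the shared topology.  Members are weighted uniformly.
    """
    atoms = ensemble.atoms
    by_residue: dict[int, dict[str, AtomKey]] = {}
    for a in atoms:
        if a.atom_name in (donor_atom, hydrogen_atom):
            by_residue.setdefault(a.residue_number, {})[a.atom_name] = a

    coords = ensemble.coord_array()
    ref = ensemble.members[0]
    out: dict[int, float] = {}
    for res in sorted(by_residue):
        pair = by_residue[res]
        if ref.residue_name(res) == "PRO":
            continue
        if donor_atom not in pair or hydrogen_atom not in pair:
            warnings.warn(f"residue {res}: missing amide atom, skipped", stacklevel=2)
            continue
        i_n = ref.index_of(pair[donor_atom])
        i_h = ref.index_of(pair[hydrogen_atom])
        vec = coords[:, i_h, :] - coords[:, i_n, :]
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm < 1e-8):
            raise ValueError(f"residue {res}: zero-length N-H bond vector")
        mu = vec / norm[:, None]
        out[res] = _s2_from_unit_vectors(mu)
    return out


def _s2_from_unit_vectors(mu: np.ndarray) -> float:
    """Second-moment S² of unit vectors, clipped to [0, 1]."""
    x, y, z = mu[:, 0], mu[:, 1], mu[:, 2]
    s2 = 0.5 * (
        3.0
        * (
            np.mean(x * x) ** 2
            + np.mean(y * y) ** 2
            + np.mean(z * z) ** 2
            + 2 * np.mean(x * y) ** 2
            + 2 * np.mean(x * z) ** 2
            + 2 * np.mean(y * z) ** 2
        )
        - 1.0
    )
    return float(np.clip(s2, 0.0, 1.0))


@dataclass
class S2Comparison:
    """Experimental-vs-calculated S² with plain and corrected correlations.

    ``corrected_correlation`` is the Pearson correlation recomputed after
    excluding residues whose |experimental − calculated| exceeds ``cutoff``
    (0.2 by default).  With fewer than 3 surviving points the corrected
    value is undefined (NaN) and flagged.
    """

    per_residue: dict[int, tuple[float, float, float]]
    correlation: float
    corrected_correlation: float
    excluded: list[int]
    cutoff: float
    corrected_defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": r,
                "experimental": e,
                "calculated": c,
                "abs_difference": d,
                "excluded": r in set(self.excluded),
            }
            for r, (e, c, d) in sorted(self.per_residue.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n": len(self.per_residue),
            "correlation": self.correlation,
            "corrected_correlation": self.corrected_correlation,
            "corrected_defined": self.corrected_defined,
            "n_excluded": len(self.excluded),
            "cutoff": self.cutoff,
        }

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    def plot(self, ax=None):
        """Per-residue experimental vs calculated S² profile."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = sorted(self.per_residue)
        ax.plot(res, [self.per_residue[r][0] for r in res], "o-", label="experimental")
        ax.plot(res, [self.per_residue[r][1] for r in res], "s--", label="calculated")
        ax.set_xlabel("residue")
        ax.set_ylabel(r"S$^2$")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


def s2_compare(
    experimental: OrderParameterSet,
    calculated: dict[int, float],
    cutoff: float = 0.2,
) -> S2Comparison:
    """Compare experimental and back-calculated S² over shared residues."""
    shared = sorted(set(experimental.values) & set(calculated))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared residues, got {len(shared)}")
    per = {
        r: (experimental.values[r], calculated[r], abs(experimental.values[r] - calculated[r]))
        for r in shared
    }
    exp = np.array([per[r][0] for r in shared])
    calc = np.array([per[r][1] for r in shared])
    correlation = _pearson(exp, calc)
    excluded = [r for r in shared if per[r][2] > cutoff]
    kept = [r for r in shared if per[r][2] <= cutoff]
    if len(kept) >= 3:
        corrected = _pearson(
            np.array([per[r][0] for r in kept]), np.array([per[r][1] for r in kept])
        )
        defined = True
    else:
        corrected, defined = float("nan"), False
    return S2Comparison(per, correlation, corrected, excluded, cutoff, defined)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        # perfectly equal constant profiles correlate trivially
        return 1.0 if np.allclose(a, b) else float("nan")
    return float(stats.pearsonr(a, b)[0])
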