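"""Selection of "invisible state" candidates from |Δω|(¹⁵N) profiles.

CPMG relaxation dispersion yields, for residues in μs–ms exchange, the
magnitude |Δω| of the ¹⁵N chemical-shift difference between the observable
ground state and a sparsely populated excited state.  A pool conformer is a
candidate for that excited state when its predicted per-residue ¹⁵N shift
difference relative to the ground-state (apo) ensemble resembles the
experimental |Δω| profile.

For each pool conformer the |Δδ(¹⁵N)| profile is computed against every apo
reference conformer and aggregated (mean by default); per temperature, both
the profile and the |Δω| vector are min–max normalized over the residues
measured at that temperature, then compared by Pearson correlation and by
the root-mean-square difference of the normalized vectors.  Scores are
averaged over the available temperatures, and candidates are selected by
mean correlation above 0.35 or normalized RMSD below 0.00603 (both
selections reported independently).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_io import Conformer, ConformerEnsemble, DeltaOmegaSet, ShiftTable

__all__ = [
    "predicted_delta",
    "minmax_normalize",
    "score_candidate",
    "select_candidates",
    "CandidateScore",
    "SelectionResult",
    "CORRELATION_THRESHOLD",
    "RMSD_THRESHOLD",
]

#: default selection thresholds (mean correlation; RMSD on the 0–1
#: min–max-normalized scale — meaningless on raw ppm values)
CORRELATION_THRESHOLD = 0.35
RMSD_THRESHOLD = 0.00603

Predictor = Callable[[Conformer], ShiftTable]


def predicted_delta(
    pool_conformer: Conformer,
    apo_reference: ConformerEnsemble,
    predictor: Predictor,
    aggregate: Literal["mean", "median", "best"] = "mean",
    reference_tables: Sequence[ShiftTable] | None = None,
) -> dict[int, float]:
    """Per-residue |Δδ(¹⁵N)| of a pool conformer against the apo ensemble.

    The absolute ¹⁵N shift difference is computed against *each* apo
    reference conformer and aggregated over references ("mean" by default;
    "median", or "best" = per-residue minimum, are available).
    ``reference_tables`` optionally supplies the already-predicted shift
    tables of the references (they are recomputed otherwise).
    """
    pool_table = predictor(pool_conformer)
    pool_res = set(pool_table.residues("N"))
    per_ref: list[dict[int, float]] = []
    if len(apo_reference) == 0:
        raise ValueError("empty reference ensemble")
    if reference_tables is None:
        reference_tables = [predictor(ref) for ref in apo_reference.members]
    elif len(reference_tables) != len(apo_reference):
        raise ValueError("reference_tables length mismatch")
    shared: set[int] | None = None
    for table in reference_tables:
        res = pool_res & set(table.residues("N"))
        shared = res if shared is None else shared & res
        per_ref.append(
            {r: abs(pool_table.entries[(r, "N")] - table.entries[(r, "N")]) for r in res}
        )
    if shared is None or not shared:
        raise ValueError("no shared residues between pool conformer and references")
    if shared != pool_res:
        warnings.warn(
            f"{len(pool_res - shared)} residues dropped for incomplete coverage",
            stacklevel=2,
        )
    agg = {
        "mean": np.mean,
        "median": np.median,
        "best": np.min,
    }[aggregate]
    return {r: float(agg([d[r] for d in per_ref])) for r in sorted(shared)}


def minmax_normalize(vector: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rescale to the 0–1 range; returns (normalized, degenerate_flag).

    A constant vector cannot be rescaled: it maps to all zeros and is
    flagged degenerate.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.size < 2:
        raise ValueError("min-max normalization needs at least 2 entries")
    lo, hi = float(vector.min()), float(vector.max())
    if hi - lo < 1e-300:
        return np.zeros_like(vector), True
    return (vector - lo) / (hi - lo), False


@dataclass
class CandidateScore:
    """Per-conformer correspondence to the |Δω| profiles."""

    conformer_id: int
    per_temperature: dict[float, tuple[float, float]]  # temp -> (corr, rmsd)
    skipped_temperatures: list[float] = field(default_factory=list)

    @property
    def mean_correlation(self) -> float:
        return float(np.mean([c for c, _ in self.per_temperature.values()]))

    @property
    def mean_rmsd(self) -> float:
        return float(np.mean([r for _, r in self.per_temperature.values()]))


def score_candidate(
    delta_profile: dict[int, float],
    delta_omega: DeltaOmegaSet,
    conformer_id: int = 0,
) -> CandidateScore:
    """Score one |Δδ| profile against |Δω| at every available temperature.

    Per temperature, both vectors are restricted to the residues measured
    at that temperature (never unioned or imputed), min–max normalized,
    and compared by Pearson correlation and normalized-vector RMSD.
    """
    per_temp: dict[float, tuple[float, float]] = {}
    skipped: list[float] = []
    for temp in delta_omega.temperatures:
        residues = [r for r in delta_omega.residues(temp) if r in delta_profile]
        if len(residues) < 3:
            raise ValueError(
                f"fewer than 3 residues shared with |d-omega| data at {temp} K"
            )
        pred = np.array([delta_profile[r] for r in residues])
        expe = delta_omega.vector(temp, residues)
        pred_n, deg_p = minmax_normalize(pred)
        expe_n, deg_e = minmax_normalize(expe)
        if deg_p or deg_e:
            skipped.append(temp)
            continue
        corr = float(stats.pearsonr(pred_n, expe_n)[0])
        rmsd = float(np.sqrt(np.mean((pred_n - expe_n) ** 2)))
        per_temp[temp] = (corr, rmsd)
    if not per_temp:
        raise ValueError("all temperatures degenerate; candidate unscorable")
    return CandidateScore(conformer_id, per_temp, skipped)


def score_pool(
    pool: ConformerEnsemble,
    apo_reference: ConformerEnsemble,
    predictor: Predictor,
    delta_omega: DeltaOmegaSet,
    aggregate: Literal["mean", "median", "best"] = "mean",
) -> list[CandidateScore]:
    """Score every pool conformer (convenience wrapper over the primitives)."""
    reference_tables = [predictor(ref) for ref in apo_reference.members]
    scores = []
    for member in pool.members:
        profile = predicted_delta(member, apo_reference, predictor, aggregate,
                                  reference_tables=reference_tables)
        scores.append(score_candidate(profile, delta_omega, member.model_id))
    return scores


@dataclass
class SelectionResult:
    """Candidates passing each criterion, reported independently."""

    selected_by_correlation: list[int]
    selected_by_rmsd: list[int]
    corr_threshold: float
    rmsd_threshold: float
    normalization: str = "minmax-0-1-per-temperature"

    def summary(self) -> dict:
        return {
            "selected_by_correlation": self.selected_by_correlation,
            "selected_by_rmsd": self.selected_by_rmsd,
            "corr_threshold": self.corr_threshold,
            "rmsd_threshold": self.rmsd_threshold,
            "normalization": self.normalization,
        }


def select_candidates(
    scores: Sequence[CandidateScore],
    corr_threshold: float = CORRELATION_THRESHOLD,
    rmsd_threshold: float = RMSD_THRESHOLD,
) -> SelectionResult:
    """Threshold the mean scores; the two selections are independent lists."""
    if not scores:
        raise ValueError("no scores to select from")
    by_corr = [s.conformer_id for s in scores if s.mean_correlation > corr_threshold]
    by_rmsd = [s.conformer_id for s in scores if s.mean_rmsd < rmsd_threshold]
    return SelectionResult(by_corr, by_rmsd, corr_threshold, rmsd_threshold)


def scores_frame(scores: Sequence[CandidateScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {
            "conformer_id": s.conformer_id,
            "mean_correlation": s.mean_correlation,
            "mean_rmsd": s.mean_rmsd,
        }
        for t, (c, r) in sorted(s.per_temperature.items()):
            row[f"corr_{t:g}K"] = c
            row[f"rmsd_{t:g}K"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores(
    scores: Sequence[CandidateScore],
    selection: SelectionResult,
    csv_path: str | Path,
    json_path: str | Path,
) -> None:
    scores_frame(scores).to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(selection.summary(), indent=2) + "\n")


def plot_selection(scores, selection, projections, member_offset=0, ax=None):
    """Scatter candidate scores over a PCA plane (modes 1–2).

    ``projections`` are the pooled-mode projections aligned with the scored
    conformers starting at ``member_offset``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ids = {s.conformer_id for s in scores}
    sel = set(selection.selected_by_correlation) | set(selection.selected_by_rmsd)
    xy = projections[member_offset : member_offset + len(scores), :2]
    chosen = np.array([s.conformer_id in sel for s in scores])
    ax.scatter(xy[~chosen, 0], xy[~chosen, 1], marker="s", facecolors="none",
               edgecolors="purple", label="pool")
    if chosen.any():
        ax.scatter(xy[chosen, 0], xy[chosen, 1], c="black", label="selected")
    ax.set_xlabel("PC1 (Å)")
    ax.set_ylabel("PC2 (Å)")
    ax.legend()
    return ax
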