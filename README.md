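# barrelens

Validation and collective-motion analysis of NMR conformational ensembles of
β-barrel lipid-binding proteins.

Intracellular lipid-binding proteins (iLBPs) such as human gastrotropin
(I-BABP/FABP6) bind their ligands inside a ten-stranded antiparallel β-barrel,
so ligand entry requires transient barrel opening. Ensemble-restrained MD and
NMR relaxation experiments probe this: multi-model conformer ensembles must be
validated against NOE distance restraints, backbone S² order parameters and
chemical shifts; their collective motions are summarized by principal
component analysis; and sparsely populated "invisible" states detected by CPMG
relaxation dispersion can be matched to pool conformers through predicted
¹⁵N chemical-shift differences. `barrelens` implements this analysis chain as
a tested, reusable library with a CLI, exercisable end-to-end on synthetic
conformer ensembles with planted ground truth.

## What it computes

* **NOE restraint evaluation** — restraint preprocessing (removal of
  stereospecificity; rounding upper bounds up to 1 Å bins on 4–10 Å) and
  per-ensemble violation statistics with r⁻⁶ averaging over both
  intramolecular ambiguity and ensemble members:
  `d_eff = (⟨Σ_pairs r⁻⁶⟩_members)^(-1/6)`, violated iff
  `d_eff > bin + 0.5 Å`.
* **S² order parameters** — back-calculation from the amide N–H bond vectors,
  `S² = (3(⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1)/2`,
  with plain and *corrected* Pearson correlations against experiment (the
  corrected value excludes residues with |ΔS²| > 0.2).
* **Chemical-shift correspondence** — ensemble-averaged predicted shifts
  (pluggable predictor; a deterministic surrogate ships for testing) against
  experimental tables, Pearson per nucleus.
* **Collective modes** — iterative-mean superposition, pairwise backbone RMSD
  statistics, pooled Cα PCA (modes, eigenvalues, projections, per-residue
  square fluctuations, NMD export) and the Cα–Cα distance vs. mode-projection
  correlation matrix that localizes each barrel-opening mode.
* **Hydrogen-bond networks** — distance–angle detection
  (H···A ≤ 2.5 Å, D–H···A ≥ 120°, D···A ≤ 3.5 Å), per-ensemble occupancies,
  and apo/holo differencing of the most significantly changing bonds.
* **Secondary structure** — 3-state (H/E/C) per-conformer assignment from
  backbone H-bond patterns scored with the classic electrostatic energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol.
* **Invisible-state candidates** — per-conformer |Δδ(¹⁵N)| profiles against a
  reference ensemble, min–max-normalized comparison with experimental
  |Δω|(¹⁵N) from CPMG dispersion at three temperatures (Pearson correlation
  and normalized RMSD, averaged over temperatures), and threshold selection
  (correlation > 0.35, normalized RMSD < 0.00603).
* **Synthetic data** — an idealized hairpin+helix backbone, conformers
  displaced along orthogonal smooth collective modes plus noise, observables
  derived from the ensemble, planted state-dependent H-bonds and a planted
  hidden-state conformer — everything deterministic under a seed.

## Worked example

```bash
barrelens all --outdir demo --seed 3
```

generates a synthetic apo/holo study (100 members each, 32 residues) and runs
every stage. The log reports, per stage:

```
[noe-eval] 68 restraints, 0.00% violated
[s2] correlation 0.996, corrected 0.996
[shifts] correlations {'N': 0.9920, 'H': 0.9982}
[pca] eigenvalues [8.3222, 0.2963, 0.1457]
[distcorr] top pair (7, 24, -0.9949)
[hbonds] 4 bonds change by >= 0.5
[secstruct] 100 members x 32 residues
[hidden-state] 201 by correlation, 0 by RMSD
```

Reading the numbers: the ensemble satisfies all of its own NOE-style
restraints (0.00 % violated at the 0.5 Å tolerance); back-calculated S²
correlates at 0.996 with the planted experimental values; the pooled PCA
first eigenvalue (8.32 Å², dominated by the planted apo→holo opening offset)
dwarfs the second mode; the Cα pair 7–24 is the strongest distance reporter
of mode 1 (r = −0.995); four hydrogen bonds switch occupancy between the
states (including the two planted switches); and the hidden-state scoring
ranks the planted excited-state conformer (id 201) first with mean
correlation 0.993 (see `demo/hidden_state_scores.csv`). All artifacts
(CSV/JSON/PDB/NMD plus a run manifest) land in `demo/`.

The same stages run on real data: point `noe-eval`, `s2`, `pca`, `hbonds`,
`secstruct` or `hidden-state` at multi-model PDB files, restraint lists
(pipe-separated or CYANA `.upl`) and tab-separated shift/S²/|Δω| tables.

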