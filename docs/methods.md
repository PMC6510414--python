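# Methods

This note documents the models, conventions and numerical choices behind
`barrelens`, and what the synthetic benchmark does and does not demonstrate.

## Ensembles and coordinates

A conformer ensemble is an *unordered* set of structures sharing one
topology (identical atom identities, author residue numbering preserved
verbatim). No time ordering is assumed anywhere: S² uses the symmetric
second-moment estimator, PCA treats members as i.i.d. samples, and no
time-correlation quantities are computed. Multi-model PDB files are read
model-by-model; when models disagree on atom content the atom sets are
equalized by intersection (with a warning), and alternate locations other
than 'A'/blank are discarded. Hydrogens are never built: stages that need
them (NOE evaluation, H-bond detection) fail with a message naming the
requirement.

## NOE restraints

Preprocessing follows ensemble-validation practice for proton–proton upper
bounds. *Destereo*: each stereospecific proton is widened to its full
stereo-equivalent set, driven by an explicit per-residue table (isopropyl
methyls of Leu/Val widen to all six protons; methylene 2/3 pairs; aromatic
ring pairs; rotationally equivalent methyl/amino protons) plus a generic
H\<pos\>2/H\<pos\>3 methylene rule; `#`/`*` wildcards expand against the
topology. *Binning*: upper bounds are rounded up to the next integer Å
("next integer" read as ceiling, so integers are fixed points), clamped to
the declared 4–10 Å bin range from below; bounds above 10 Å are rejected.

Ambiguity within a restraint is combined by **summing** r⁻⁶ over all cross
pairs (the standard pseudo-atom convention); a mean-combination variant is
available behind the `ambiguity="mean"` flag. Members are weighted
uniformly. Violation is strict: `d_eff > bin + tolerance`, tolerance 0.5 Å
by default. Lower bounds are not modeled.

## S² order parameters

The generalized order parameter of each amide N–H unit vector is computed
with the symmetric second-moment form (see README). The raw estimator can
exceed [0, 1] by rounding error only; values are clipped to [0, 1].
Prolines and residues lacking amide protons are skipped, matching NMR
observability. No vibrational/zero-point scaling is applied. The
comparison statistic is the Pearson correlation on raw values; the
"corrected" variant excludes residues with |experimental − calculated| >
0.2 (cutoff configurable; with cutoff = ∞ it equals the plain
correlation by construction). Fewer than three surviving points flag the
corrected value as undefined (NaN) rather than inventing a number.

## Chemical shifts

Shift evaluation is predictor-agnostic: any deterministic map
Conformer → ShiftTable satisfies the contract, and output files of
external empirical predictors are read through an adapter rather than by
invoking binaries inside the library. Ensemble correspondence uses the
mean predicted shift per (residue, nucleus) over members (the
per-member-correlation convention is available as a function). The shipped
**surrogate predictor** is a frozen smooth map from local backbone geometry
(φ, ψ, Cα-neighbour distances) to N/H shifts. It is synthetic: its
coefficients were fixed once, it has no physical accuracy, and its only
guaranteed properties are determinism and smooth sensitivity to
conformation — exactly what the pipeline's statistics need for testing.

## Collective modes

Superposition fits each member to an iteratively refined mean (proper
rotations only; convergence when the mean moves < 1e-6 Å, max 50 rounds).
PCA pools all input ensembles into one decomposition — the apo/holo/pool
sets live in a single PC plane — and eigendecomposes the 3n×3n covariance
of the superposed Cα coordinates about the pooled mean (ddof = 1
throughout, so projection variances equal eigenvalues). Mode signs are
fixed by making each mode's largest-magnitude component positive.
Square fluctuations are eigenvalue × per-residue squared mode components,
summing to the eigenvalue per mode.

The ensemble RMSD statistic is the mean of pairwise best-fit RMSDs over
backbone N/Cα/C′ atoms within each sub-ensemble (replica), reported as
mean ± sd across sub-ensembles; a deposited single ensemble therefore has
sd = 0. The exact backbone atom set behind published RMSD values of this
kind is often unstated; N/Cα/C′ is this package's convention and the
deposited-data acceptance check exists precisely to falsify it if wrong.

Distance–mode correlation is the Pearson correlation, over pooled members,
of each Cα–Cα distance with the member's projection on a chosen mode.
Zero-variance distances yield NaN (flagged, never 0). Pooling apo and holo
members is the default, with per-ensemble analysis available by passing a
single ensemble.

## Hydrogen bonds

Detection is geometric, on N/O donors and acceptors: a hydrogen belongs to
the nearest heavy atom within 1.2 Å; a bond requires H···A ≤ 2.5 Å,
D···A ≤ 3.5 Å and D–H···A ≥ 120°. The literature thresholds behind
distance–angle H-bond detection vary; these defaults are deliberate,
config-exposed choices pinned by tests. Occupancy aggregates over the
donor heavy atom (any hydrogen may carry the bond) and is sparse: pairs
never observed are absent. State differencing lists bonds whose occupancy
changes by ≥ 0.5, labelled by the prevailing state with a "mostly"
qualifier below a 0.75 margin (the qualifier boundary is a package choice).

## Secondary structure

A deliberate 3-state simplification of continuous assignment schemes:
backbone H-bonds scored with the classic electrostatic energy (bonded
below −0.5 kcal/mol), helix from pairs of consecutive i→i+4 turns, strand
from parallel/antiparallel bridge ladders at least two bridges long;
isolated bridges and 3₁₀/π-like patterns fold into C and H respectively.
Chain breaks (numbering gaps or Cα–Cα > 4.5 Å) split assignment segments;
helix patterns never propagate across a break. Agreement with external
continuous-assignment programs at element boundaries is not expected to be
exact.

## Invisible-state matching

For each pool conformer the per-residue |Δδ(¹⁵N)| is computed against
*every* reference (apo) conformer and aggregated by the arithmetic mean
(median and per-residue minimum are exposed as options; the mean is the
default because one score per pool structure is required and the mean is
the only aggregation that commutes with the planted-profile construction
below). Per temperature, both the profile and the experimental |Δω| vector
are restricted to the residues measured at that temperature — typically a
30–40 residue subset, never unioned or imputed — then min–max normalized
to [0, 1]; the per-temperature Pearson correlation and RMSD of the
normalized vectors are averaged over the three temperatures (283, 287,
291 K). Normalization scope is per temperature over the shared residue
set. The selection thresholds (correlation > 0.35, normalized RMSD <
0.00603) are strict inequalities; the RMSD threshold is meaningful *only*
on the normalized scale and is stored with that convention. The two
selections are reported independently, never merged into one ranking.

## Synthetic data generator

The generator emulates the statistical structure of a two-state barrel
study at desk scale:

* **Topology** — an idealized backbone (N, H, Cα, C′, O per residue;
  canonical bond lengths/angles) laid out as an antiparallel β-hairpin
  (type-II′ turn, strand φ/ψ = −135°/135°, chosen so the ideal ladder of
  cross-strand H-bonds closes) plus a two-residue linker and one α-helix.
  Defaults: 32 residues, 100 members.
* **Modes** — smooth sinusoidal displacement fields along fixed directions,
  orthogonalized against the six rigid-body motions (so superposition
  preserves them) and against each other. Mode amplitudes are Gaussian
  with sd 2 Å and 1 Å (a 4:1 variance ratio); a third field is reserved,
  unsampled, for the hidden state. Isotropic per-atom noise has sd 0.1 Å;
  an optional `turn_mobility` factor (default 1, set to 3 in the S²
  demonstration conditions) raises the noise in turns/linkers/termini so
  the S² profile has realistic dynamic range.
* **States** — the apo→holo transition is a constant 12 Å offset along
  mode 1 applied to the holo base structure; planted H-bond switches then
  reposition the acceptor carbonyl O next to the donor amide H in the
  designated state, so each switch holds in that state's mean structure.
* **Observables** — S² = back-calculated values + truncated Gaussian noise
  (sd 0.02); restraints = all inter-residue amide-H pairs with ensemble
  mean distance < 5 Å, bound = that mean, binned; shifts = surrogate
  prediction on the mean structure.
* **Hidden state** — 200 decoys drawn from the apo distribution plus one
  conformer displaced 8 Å along the reserved mode. Its planted |Δω|
  profile is the mean over apo references of |δ(planted) − δ(ref)| — the
  same aggregation the scoring applies — times independent
  (1 + 0.10·z) factors per temperature, on a random 80 % residue subset
  per temperature. With zero noise the planted conformer therefore scores
  correlation = 1 and normalized RMSD = 0 exactly, a designed sanity
  anchor.
* **Determinism** — each public operation draws from one
  `numpy.random.default_rng` stream at a documented offset of the spec
  seed (+0 generation, +1 observables, +2 hidden state), consuming draws
  in a fixed order, so outputs are bit-stable under a seed and adding an
  observable never perturbs earlier draws.

**What passing the synthetic benchmark shows** — that the implementations
are internally consistent (oracle equivalence), recover planted ground
truth (mode variances, reporter pairs, H-bond switches, the hidden
conformer) and honor the documented invariances. **What it does not
show** — anything about force-field quality, predictor accuracy on real
proteins, or the physical realism of barrel opening: the generator has no
energetics, no side chains, and a toy shift map. Conclusions about real
ensembles additionally require the deposited-data checks (see below) and
real experimental tables.

## Problem sizes and benchmark conditions

Chosen once as the package's standard demonstration conditions: 32-residue
topology; 100-member state ensembles; 500 members for eigenvalue-ratio
recovery (ratio tolerance ±10 %, reflecting sampling error of a variance
ratio at n = 500); the hidden-state benchmark uses 100 repetitions of
200 decoys + 1 planted conformer scored against a 20-member reference
ensemble with 10 % profile noise, requiring the planted conformer to rank
first by mean correlation in ≥ 95 repetitions.

## Deposited-data checks

Two acceptance tests run the pipeline against deposited multi-model NMR
ensembles of human gastrotropin (the apo and holo entries) — NOE
self-consistency of the holo ensemble against its own preprocessed
restraint list (expected 0.00 % violations) and the 0.66 Å mean pairwise
backbone RMSD of the 10-model apo ensemble (which pins the RMSD atom-set
convention). The coordinate and restraint files are not redistributable in
this repository; the tests look for them under `data/deposited/` and fail
with an explanatory message when absent.

## Known limitations

* No mmCIF or trajectory input; no chemical-shift referencing corrections.
* No NMR-STAR parsing: shift/S²/|Δω| tables use the documented delimited
  dialect, conversion left to the user.
* No restraint weighting, intensity back-calculation or spin diffusion.
* H-bond detection has no energetic scoring and no water bridges; ligand
  atoms participate only as generic N/O donors/acceptors.
* The per-ensemble NOE evaluation assumes uniform member weights; replica
  weighting schemes are not modeled.
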