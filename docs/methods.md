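# Methods

This note records the models, defaults and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Structure container and numbering

Structures are single protein chains held in a biotite `AtomArray` with
author residue numbers preserved verbatim. Because biotite stores
coordinates in single precision, each `Structure` carries a float64
shadow of the coordinates that all geometry (patch definition,
superposition, RMSD) reads from; the `AtomArray` is used for file I/O and
surface sampling, where 10⁻⁷ Å is irrelevant. Insertion codes are not
supported: a residue index mapping to two residue types, or to two Cα
atoms, is rejected at parse time.

Two numbering conventions are interconverted by a fixed offset of 24, the
length of the AAT signal peptide: mature ("conventional AAT") numbering
counts the secreted chain, precursor (HGVS p.) numbering includes the
signal peptide, so mature 75 ≡ precursor 99 and mature 342 (the Z site)
≡ precursor 366. All analyses operate in mature numbering.

## Solvent accessibility

Relative side-chain accessibility uses Shrake–Rupley point sampling
(default probe 1.4 Å, 960 points per atom, Bondi van der Waals radii,
hydrogens excluded from both surface and occlusion; missing element
fields are inferred from the atom-name prefix with a warning). Side-chain
atoms are all heavy atoms outside {N, CA, C, O, OXT}; for glycine — and
for backbone-only synthetic models — the Cα stands in.

The reference ("maximal") exposure of a residue is computed by
re-evaluating the same side-chain SASA on that residue extracted in
isolation, rather than taken from a fixed literature table. This makes
the relative value exactly 1 for an isolated residue by construction,
and it remains meaningful for non-standard or backbone-only residues
that a tabulated maximum would not cover. Ratios are clipped to [0, 1].

A residue is called surface-accessible at relative accessibility ≥ 0.10.
No experimental criterion fixes this number; 10% is a conventional
exposure cutoff and both the threshold and probe settings are arguments
everywhere they are used.

## Kabsch superposition

Closed-form least-squares rigid superposition via SVD of the
cross-covariance matrix. Reflections are excluded by forcing the
determinant of the rotation to +1, so a mirror-image coordinate set is
*not* matched exactly — the physically correct behaviour for chiral
molecules. Degenerate inputs (fewer than 3 pairs) are rejected. The
implementation is checked against a Monte-Carlo oracle: over random
coordinate pairs, the closed form is never beaten by any of 10,000
random rotations after centroid alignment.

## Surface-patch divergence map

For each surface-accessible residue of the reference conformer, the
patch is all residues whose Cα lies within the patch radius (default
8 Å — roughly the footprint of an antibody epitope) of the central Cα.
The patch is paired against the alternate conformer on *identical
residues*: same author index and same residue type; mismatched types are
dropped from the pairing rather than substituted. Superposition and RMSD
both use Cα atoms only (a full-backbone N/CA/C/O option exists but is
off by default, since the divergence signal of interest is at the
residue level). Patches with fewer than three pairable residues are
flagged `unalignable`.

Patches containing any glycan attachment site are flagged
`glycan_masked`: an antibody raised against glycosylated material cannot
have its epitope there. The packaged default site list for AAT is
{46, 83, 247} in mature numbering (the three N-linked sequons) — a
curated default, configurable and clearly separated from the algorithm.

The map reports every reference residue exactly once with one of four
mutually exclusive flags (`scored`, `not_surface`, `glycan_masked`,
`unalignable`); output is ordered by residue index and unsmoothed.
Scored values are invariant under global rigid transforms of either
structure and identically zero for a self-comparison.

## Trajectory analysis

Ensembles are lists of replicate coordinate arrays over one topology
(with hydrogens). Multi-model PDB is read natively; XTC/DCD go through
mdtraj when available. Replicate boundaries are preserved because all
aggregation is *mean of replicate means*: replicates are independent
simulations, so pooling frames would understate between-replicate
variance and the SEM across replicates is the honest error bar.

**RMSF.** Within each replicate, every frame is least-squares superposed
onto the replicate mean structure using backbone heavy atoms, with two
refinement iterations (fit to running mean, recompute mean, refit); the
choice of two iterations is a numerical default — the mean is stable
after the second pass for the ensembles considered. The RMSF of an atom
is the root-mean-square deviation from its time-average position;
residues average over their selected atoms; the profile is the mean over
replicates. For isotropic per-coordinate Gaussian jitter of standard
deviation σ the expected RMSF is σ√3, which the implementation recovers
within 5% at 5,000 frames.

**Hydrogen bonds.** Donors are N/O heavy atoms with at least one
covalently attached hydrogen (attachment inferred from the topology
geometry at ≤ 1.25 Å); acceptors are all N/O atoms. A donor/acceptor
atom combination counts one bond in a frame when the heavy-atom distance
is ≤ 3.5 Å *and* any hydrogen on the donor makes an H–D–A angle ≤ 30°;
counts are summed over atom combinations of the residue pair, so a pair
can exceed 1 per frame (bidentate contacts). Both limits are
configurable; tightening either is provably count-monotone. Side-chain
and backbone polar atoms are both included by default because published
per-residue ledgers do not enumerate atoms; per-pair filtering is
possible by restricting the topology. Counts are sampled every 2 ps
(stride must be a multiple of the frame interval). The difference ledger
between two variants joins on the pair set and orders by descending
difference.

## Protection-assay fitting

Curves are baselined by subtracting the t = 0 intensity (the instrument
offset carries no kinetic information; configurable off). The fit
minimises Σ[I₊(t) − a·I₋(b·t)]² with linear interpolation of I₋ and no
extrapolation: only points whose scaled time falls inside the −antibody
support are used. Because a enters linearly, it is profiled out in
closed form for each candidate b; b is scanned over a deterministic
201-point log-spaced grid in [0.1, 10] and refined by bounded scalar
minimisation. Candidate time scales are compared by *mean* squared
residual over the overlap — raw SSR would favour large b, which shrinks
the overlap to a handful of points. The fit is deterministic; no random
starts.

The fractional intensity is defined as the fitted intensity scale a
(not a plateau ratio): it is the factor by which the +antibody curve is
dimmer after the time axis has absorbed any kinetic slowing. A position
is flagged protected when its replicate mean is ≤ 0.8 — an advisory
cutoff reported alongside the SEM (sample SD/√n; 0 by convention for
n = 1), not a hypothesis test.

## Conservation profiling

Alignments (Stockholm or aligned FASTA) are mapped to structure
positions through an ungapped reference row: the i-th non-gap reference
column corresponds to mature residue i + offset. This replaces manual,
secondary-structure-aware indel curation; for columns inside indel
regions of distant homologs the direct mapping can disagree with a
hand-curated one, which is the main caveat when comparing against
published logos. Column frequencies are exact rationals on counts
(columns sum to 1 exactly); counting is case-insensitive, `.` and `-`
are gaps, other non-standard letters count as gap-equivalent and are
tallied separately. Columns with > 50% gaps are flagged low-coverage.
No sequence weighting is applied by default, appropriate for seed
alignments that are already non-redundant.

## Synthetic data

Every generator is a pure function of its arguments including the seed.
What they emulate, and what they do not:

- **Structures**: ideal α-helices (1.5 Å rise, 100° twist, 2.3 Å radius;
  consecutive Cα ≈ 3.8 Å) and extended chains with full backbone N/CA/C/O
  placed at idealised covalent geometry, glycine residue names, no side
  chains. Two-helix bundles give a buried and an exposed face. Localised
  conformational change is emulated by Gaussian displacement of a residue
  window. Not emulated: real side-chain packing, secondary-structure
  hydrogen-bond networks, crystallographic disorder.
- **Trajectories**: frames are the base structure plus independent
  isotropic Gaussian jitter scaled per residue. This reproduces the RMSF
  observable exactly but has no kinetics or correlation structure — it
  validates estimator arithmetic, not force-field realism. Hydrogen-bond
  occupancy is prescribed by explicit geometry toggling between a
  satisfying (3.2 Å, 0°) and a violating (4.5 Å) arrangement, so the
  target occupancy is exact in expectation.
- **Kinetics**: I₋(t) = baseline + A(1 − e^(−kt)) + noise on a 0–30 min
  grid of 61 points (A = 1000 a.u., k = 0.15 min⁻¹, so the curve is ≈ 99%
  saturated at 30 min; 2% noise default), and I₊ with configured true
  (a\*, b\*). The 11-position survey panel shields positions 139 and 155
  (true a\* 0.60 and 0.55) with four replicates per position. Not
  emulated: photobleaching, pipetting offsets, drift.
- **Alignments**: rows drawn per column from prescribed compositions,
  with a gapless reference row carrying each column's most probable
  non-gap state. Phylogenetic correlation between rows is not emulated.

Passing tests on these inputs therefore demonstrate correctness of the
estimators and transforms, not fidelity of any molecular-dynamics force
field or instrument model.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
make sampling error negligible relative to the stated tolerances:
200 coordinate sets × 10,000 rotations for the superposition oracle,
60-residue bundles for divergence maps, 2 replicates × 4,000 frames for
occupancy recovery, 5,000 frames for the RMSF closed form, 100 curve
pairs for fit recovery, and 1,000 random triads for hydrogen-bond
monotonicity. Regenerating a cluster-scale per-variant hydrogen-bond
ledger (ten 10-ns solvated all-atom simulations per variant) is out of
scope; the ledger arithmetic and aggregation are validated on the
synthetic ensembles instead.

## Known limitations

- Insertion codes and multi-chain analyses are unsupported.
- The isolated-residue SASA reference differs numerically from published
  Gly-X-Gly tripeptide maxima (it slightly exceeds them since no
  neighbouring backbone occludes); thresholds calibrated against
  tripeptide scales should be re-checked.
- Hydrogen attachment is inferred from geometry, so topologies with
  non-covalent H placements would mis-assign donors.
- The protection fit assumes the two curves differ only by the two
  scales; strong baseline drift violates this and shows up as residual,
  not as a corrected estimate.
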