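# Methods

`posepop` packages the three analyses used to characterize fragment ligands
of the YTHDF2 m6A-reader pocket: binding-pose inference from MD
trajectories, post-docking hit triage, and competition-assay affinity
calculus. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Pose inference from trajectories

### Model

A thiourea-ring scaffold bound in the m6A pocket can adopt two orientations,
pose A and pose B, related by a 180° rotation about the exocyclic S=C double
bond. The flip preserves the number of polar contacts but swaps partners:
in pose A the scaffold's carbonyl oxygen hydrogen-bonds the Y418 backbone
NH; in pose B it reaches the conserved structural water instead. The
analysis treats each trajectory frame as a draw from a two-component
mixture over a 10-dimensional feature space of protein–ligand distances and
estimates the mixture weights — the pose populations — by Gaussian-mixture
clustering in a 2-D principal-component projection.

### Pipeline and parameters

1. **Subsampling.** Frames are kept at a fixed interval (default 1 ns)
   inside an analysis window that defaults to the second half of each run
   (ligand-relaxation burn-in discarded). Both window ends are inclusive:
   200 frames at 1 ns with the [100, 200] ns window keep 101 frames per
   replicate.
2. **Bound-frame selection.** A frame is bound iff the distance from the
   ligand's exocyclic sulfur to the C433 backbone nitrogen is strictly
   below 5 Å. The filter runs after subsampling.
3. **Featurization.** Ten distances per bound frame, fixed column order:
   four anchoring the scaffold to C433 (S→backbone N, carbonyl O→backbone
   O, the two ring N–H's→backbone N/O), the two ring N–H's to the D422
   carboxylate oxygens, and the exocyclic S to the Y418 backbone N and the
   three tryptophan-cage ring centroids (W432, W486, W491). The exact
   atom-to-atom pairs are configuration data
   (`posepop.topology.FEATURE_PAIRS`); the default pairs follow the
   hydrogen-bond partners of the two poses.
4. **Projection.** PCA on centered, *unscaled* distances (all columns share
   Å; standardizing would re-weight the anchors). Sign convention: the
   largest-magnitude loading of each component is positive. All-identical
   input is an error; rank-1 input (e.g. two noise-free templates) is
   valid and yields a degenerate second component with ≈0 explained
   variance.
5. **Mixture fit.** Full-covariance Gaussian mixture, k = 2 by default (the
   two-pose hypothesis), EM with k-means++ seeding, 10 restarts, tolerance
   1e-6, ≤500 iterations, fixed seed. Non-convergence is flagged on the
   result, never silent. Populations are hard-assignment fractions and sum
   to 1.
6. **Canonical naming.** Clusters are not identified by fit order: the
   cluster whose centroid frame puts the carbonyl O closer to Y418 N than
   to the water O is pose A (ties toward A). Centroid = assigned frame
   nearest the cluster mean in PC space, ties broken toward the earliest
   (replicate, frame).
7. **Stability.** Ligand heavy-atom RMSD after rigid superposition of each
   snapshot on the protein anchor atoms (the stand-in for Cα fitting on
   the synthetic pseudo-pocket), no re-fitting on the ligand; summarized
   across replicates by the median and one median absolute deviation per
   time point. Pose comparison reports time-averaged median RMSD and
   declares the lower one more stable, with no significance claim.

Replicate runs of both starting poses are pooled into one clustering by
default; per-pose clustering is available by passing the runs separately.

## Synthetic-data generator

The generator emulates the *statistical* structure the pipeline assumes,
not molecular physics. A pseudo-pocket places one labelled anchor atom per
recognition residue (Y418 backbone N/H, D422 OD1/OD2, W432/W486/W491 ring
centroids, C433 backbone N/O, D528, one water O) at fixed idealized
coordinates, chosen so that pose A puts the carbonyl O 2.6 Å from Y418 N
and pose B puts it 2.6 Å from the water — the hydrogen-bond swap the
clustering must resolve. The two templates are exact 180° rotations about
the S=C axis; their separation in the 10-distance feature space is ≈3.1 Å.

Frame generation: per replicate, the number of pose-A frames is the
stratified count `round(weight × n_frames)` (randomized rounding, shuffled
positions) — a standard variance-reduction design that keeps the realized
mixture proportion within a fraction of a percentage point of the nominal
weight at ensemble sizes of a few hundred frames, which is what makes
±3-percentage-point population-recovery checks meaningful at n ≈ 800.
Isotropic Gaussian noise (default 0.3 Å per atom coordinate, ≈0.4 Å per
distance — well below the 3.1 Å template separation) is added to every
atom; an optional AR(1) term can correlate noise along a replicate (off by
default — the 1 ns subsampling interval exists precisely to decorrelate
frames). Unbound excursions are i.i.d. with the stated probability and are
modelled as rigid translations placing the sulfur at 5 Å + offset (default
3 Å) from C433 N — enough to exercise the bound filter, with no pretense of
unbinding pathways.

What the generator does *not* emulate: anisotropic and correlated atomic
fluctuations, partial or intermediate poses, protein conformational
change, water dynamics, force-field energetics. Passing recovery tests
therefore show that the pipeline correctly infers mixture structure of the
kind assumed; they do not validate the 5 Å criterion or the distance set
against real MD data.

Dose–response panels follow a decreasing four-parameter logistic
`bottom + (top−bottom)/(1+(c/IC50)^h)` with multiplicative Gaussian noise
on the window term (default CV 2%, 4 replicates, 10 half-log dilutions).
Docking-pose sets plant a chosen number of pharmacophore-satisfying poses
(donor N–H at 2.9 Å, near-linear, to the C433 carbonyl; acceptor on the
Y418 NH axis) among decoys whose donor sits 6.5 Å out; planted poses also
draw more favorable energy terms.

## Docking triage

Poses are ranked twice — by total binding energy and by the
electrostatic-minus-desolvation term, both ascending — and the shortlist is
the **union** of the two top-n lists (the selection procedure inspects both
rankings; no composite score is formed). Ties break by pose id. The
pharmacophore filter then requires the mandatory hydrogen bond from a
ligand donor to the C433 backbone carbonyl plus at least one of: Y418
backbone NH → ligand acceptor, ligand donor → D422 carboxylate, or a polar
contact with the structural water (heavy-atom criterion, since water
hydrogens are unresolved). Hydrogen-bond geometry defaults: donor–acceptor
≤ 3.5 Å with donor–H–acceptor angle ≥ 120°, heavy-atom fallback ≤ 3.5 Å
when no hydrogen is present — standard structural-biology cutoffs,
configurable. Aromatic stacking is not part of the filter (the selection
rule names only polar contacts). Every pose appears in the output table
with both ranks, verdict, and interaction fingerprint.

## Affinity calculus

* **Triage:** percent residual signal at 1 mM vs the DMSO control
  (replicates averaged); compounds advance iff residual < 60% (strict).
* **IC50:** joint least-squares 4PL fit over replicates, IC50 parametrized
  as log10 for conditioning, Hill slope free by default (fixable at 1).
  Fits with IC50 outside the tested range, a window within 3 residual SDs
  of flat, or failed convergence are returned flagged ("IC50 could not be
  determined") — flagged compounds stay in every output with a status.
* **Cheng–Prusoff:** K_d = IC50 / (1 + [L]/K_d^probe), probe defaults 3 nM
  with K_d 5 nM (DF2), 7 nM (DC2), 5 nM (DC1); the DF2 divisor is exactly
  1.6.
* **Ligand efficiency:** LE = −RT·ln(IC50)/HAC, R = 1.987×10⁻³
  kcal/(mol·K), default T = 300 K (the assay temperature is near-ambient
  and LE is conventionally quoted at ~300 K; a tabulated LE can differ from
  the formula by ~0.01 through rounding of IC50 and temperature choice —
  e.g. IC50 18 μM with 11 heavy atoms gives 0.59 here vs a rounded 0.60).
* **Selectivity:** fold-ratios K_d[p]/K_d[DF2]; a censored K_d (">400 μM")
  propagates as a censored ratio (">308"), never as a number.
* **Hit rate:** 100 × actives/tested, rounded half-up to integer percent,
  with optional per-campaign breakdown.

## Numerical and I/O choices

* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); pipeline runs are bit-reproducible.
* Trajectories and docking poses serialize as multi-model PDB (text) with a
  small JSON sidecar for what PDB cannot carry: frame times, replicate
  ids, generator ground truth, donor/acceptor flags. Without a sidecar a
  trajectory reads as one replicate on a uniform user-supplied time grid.
  Binary trajectory formats are deliberately out of scope.
* Time-grid comparisons use an absolute tolerance of 1e-6 ns; subsampling
  keeps frames whose phase is on-grid within that tolerance.
* RMSD superposition uses the Kabsch solution
  (`scipy.spatial.transform.Rotation.align_vectors`) on the protein
  anchors.

## Problem sizes

Default study conditions — and the sizes exercised by the test suite and
the acceptance script — are 8 replicates × 200 frames (≈800 analysis
frames after subsampling, ≈730 bound), mixture weights in the 0.5–0.75
range, and assay panels of 10 half-log dilutions × 4 replicates at 2% CV.
A full pipeline run at these sizes takes well under a second.

## Known limitations

* The synthetic ligand is exactly symmetric about the flip axis, so
  S-anchored features (Y418, tryptophan-cage columns) carry no pose
  information; real scaffolds are only approximately symmetric.
* Populations come from hard assignments; near-overlapping clusters would
  call for responsibility-weighted populations and an
  information-criterion scan over k (provided but off by default).
* The RMSD reference is a single frame; the distinction between "first
  frame" and "equilibrated starting structure" collapses for synthetic
  data and is left to the caller for real trajectories.
* Censored fits are bounds, not likelihood-based censored regression.
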