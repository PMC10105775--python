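# Methods

This note documents the models implemented in `xlvalidate`, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions.

## Cross-link distance restraints

A DSSO-class cross-link between two lysines bounds their Cα–Cα
Euclidean distance by roughly the linker span plus two extended side
chains, conventionally **30 Å**.  A link is *satisfied* when the
measured distance is **≤ threshold (inclusive)**: common usage mixes
"within 30 Å" and "less than 30 Å", and the inclusive convention is
adopted so that a link at exactly the threshold counts as compatible.
Thresholds of 35 and 40 Å are supported for sensitivity analyses;
agreement is monotone non-decreasing in the threshold by construction.

Links touching residues without a Cα record in the model (disordered or
unmodelled regions) are *unmapped*: they appear in reports but never in
agreement denominators, since a missing coordinate is not evidence for
or against the model.

Residue numbering is the author numbering of the structure file and is
assumed to coincide with UniProt/PAE numbering for AF2 models (which
number 1..n contiguously).  A `residue_offset` is available for
structures on a shifted numbering.  Duplicate pairs in cross-link
tables, including the same pair in swapped order, collapse to one
canonical link; when the same pair is seen in several datasets the
maximum identification score is kept and source tags accumulate.
Scores are descriptive only — FDR control is assumed to have happened
in the upstream search.

## Assembly rescue

In a homo-oligomer, a link identified as intramolecular (same
accession) may physically connect two *copies* of the protein.  For an
assembly containing several chains of the accession, the package
computes the minimum Cα–Cα distance over **all ordered chain pairings**
of the two residues — both cross-copy orientations and the intra-copy
pairing — which is by construction ≤ the monomer distance.  A monomer
violation whose assembly minimum falls within the threshold is flagged
*rescued*; its monomer status is retained so reports can show both
numbers.

## PAE segmentation into rigid regions

The predicted aligned error PAE(x, y) — the expected positional error
of residue x when the prediction is aligned on residue y, in Å — is
asymmetric; since cross-links are unordered the matrix is first
averaged with its transpose.  Rigid, well-predicted regions appear as
low blocks on the diagonal.  The segmentation pipeline:

1. median filter (`median_window` = 5), applied `median_repeats` = 3
   times, to suppress speckle while preserving block edges;
2. topography = morphological gradient (local max − min over a
   `gradient_window` = 3 square);
3. markers: pixels with gradient ≤ the `marker_percentile` = 55th
   percentile, closed with a radius-2 disk, minus any pixel whose
   gradient exceeds `ridge_factor` = 3 × the marker threshold, then
   connected components of area ≥ `min_segment_width`² (= 100);
4. marker-controlled watershed of the topography (scikit-image);
5. labels read along the diagonal; runs shorter than
   `min_segment_width` = 10 residues (typically the thin
   self-similarity band hugging the diagonal) are erased and filled
   with the label of the adjoining longer run, preceding run preferred
   on ties;
6. surviving runs whose internal mean PAE exceeds the best run's by
   more than `background_contrast` = 7.5 Å are demoted to background
   (label 0): a rigid region must have mutually *low* error, and a
   disordered linker wide enough to survive step 5 otherwise masquerades
   as a body;
7. the remaining runs are renumbered 1..K in sequence order.

Because every decision is made on gradients or on *differences* of
means, adding a constant to the whole matrix changes nothing.

Parameter rationale.  The percentile marker rule transfers across
proteins without retuning an absolute Å threshold.  The defaults were
fixed by a robustness experiment on block-diagonal synthetic matrices
(K = 1..5 blocks, widths 30–120 residues, within-block noise sd 1 Å,
between–within contrast 10–17 Å): a *low* percentile fragments the
marker mask of a one-domain (flat) matrix into scattered seeds and
oversegments it, while a closing radius able to bridge the thin
high-gradient band between adjacent blocks merges them.  The chosen
combination — a generous percentile (55), a light closing, and the
ridge cut that re-opens any bridge across a genuine boundary — recovered
the correct block count with ≥ 95% residue co-assignment and ≤ 3
residues of boundary error in all trials of that experiment.  Real PAE
matrices are smoother than this noise model, but individual proteins may
still need per-protein adjustment; all knobs are exposed.

Boundary accuracy caveat: a flexible linker narrower than
`min_segment_width` cannot stand alone and is absorbed into an adjacent
domain, so recovered domain edges can be off by up to one short-linker
width when domains are padded by linkers.

A cross-link is *within* a rigid region if both residues carry the same
nonzero label, *between* if both are labelled but differently, and
*outside* if either residue is background.  The headline statistic
reported for a protein set is the fraction of violations classed
between-or-outside.

## Calibration curve

All mapped cross-links are ranked by their symmetrized PAE value and
cut into consecutive bins of 25 (the final partial bin is kept and
flagged).  Ties in PAE are broken by link identity so the binning is
deterministic; the per-bin spread is the population standard deviation
(a descriptive error bar; at n = 25 the sample/population distinction
is immaterial, but one convention must be fixed for reproducibility).
A separate check counts violations among links with PAE ≤ 3.5 Å, the
regime where a well-calibrated predictor should be violation-free.

## Rigid-body re-modeling

Rigid bodies (residue ranges, typically from the PAE segmentation) keep
their internal Cα geometry frozen; only their placements move.  The
restraint energy is a sum of three flat-bottom/soft terms, all zero in
an acceptable arrangement:

* cross-link: Σ k_xl · max(0, d − 30 Å)² over restrained pairs;
* connectivity: for consecutive bodies, Σ k_conn · max(0, gap −
  3.8 Å · (n_linker + 1))², where 3.8 Å is the Cα virtual bond length —
  linker residues are not modelled as beads, they only contribute
  slack (the alternative, explicit flexible beads, would add n_linker
  degrees of freedom without changing which arrangements are feasible);
* excluded volume: Σ k_ev · max(0, 3.5 Å − d)² over inter-body Cα
  pairs (single-bead-per-residue packing).

Defaults k_xl = k_conn = 1, k_ev = 0.1.  These functional forms are the
simplest that encode "distance restraint", "chain connectivity" and
"packing"; they are package choices, exposed in `SamplerConfig`.

Sampling is Metropolis Monte Carlo: per frame one body is chosen
uniformly and proposed a rotation about its centroid (axis uniform on
the sphere, angle uniform in [0, 0.2 rad]) plus a translation uniform
in a 2 Å ball; acceptance is min(1, exp(−ΔE/T)) with geometric cooling
from T = 5 to T = 0.1 over the run.  Energies are maintained
incrementally per interaction group and must agree with a full
rescoring (unit-tested to 1e-6).  An ensemble runs 10 independent
annealings of 20,000 frames; run k is seeded base_seed + k and the
initial condition applies the proposal distribution scaled ×10, so
every result is bit-reproducible from the base seed.  The reported
model is the minimum-energy state seen; an ensemble precision proxy
(mean pairwise all-Cα RMSD after superposition on the largest body of
the best run) indicates how consistently the runs agree.  On the
synthetic three-body benchmark the restraints constrain the
arrangement only to within tens of Å (25 links cannot pin three bodies
uniquely), so a large proxy value with all restraints satisfied is the
expected outcome, not a sampling failure.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed).

* **Structures**: Cα traces with exact 3.8 Å consecutive spacing; each
  domain grows as a self-avoiding walk (pairwise ≥ 3.5 Å) confined to a
  ball of radius 3·m^(1/3) Å, matching globular packing density;
  linkers are extended walks.  Domain residues get synthetic pLDDT
  ≈ 90, linkers ≈ 55.  "Lysines" are a pseudo-random subset of
  positions (default 7% of residues; scenario generators raise this to
  have workable pair pools); there is no sequence model, no real
  lysine chemistry, no missed cross-linking efficiency.
* **PAE matrices**: |N(3, 1)| Å within domains, |N(20, 3)| Å elsewhere,
  independent per direction (asymmetric, like raw AF2 output), diagonal
  0.2 Å, clipped to [0, 31.75] Å.  Real PAE is spatially smooth and its
  between-domain error grows with sequence separation; the iid noise
  here is *harder* for the segmentation than real data in that respect,
  but it lacks real features such as intra-domain substructure.
* **Cross-links**: satisfied links are drawn from lysine pairs ≤ 28 Å,
  violated links from pairs > 32 Å.  The 28–32 Å guard band keeps the
  ground truth deterministic at the 30 Å threshold, which is what makes
  exact-count bookkeeping tests possible; real data have no such band,
  so boundary-distance links in real analyses are sensitive to the
  threshold convention in a way these tests do not probe.
* **Assemblies and rescue**: a two-domain monomer with the second
  domain displaced 300 Å, dimerised with copy B translated so B's
  second domain overlays A's first-domain neighbourhood — inter-domain
  links then violate intra-copy but find a cross-copy pairing ≤ 28 Å.
* **Calibration assessments**: PAE uniform on [0.5, 30] Å with
  violation probability rising linearly from 0 at 3.5 Å to 0.6 at
  30 Å — a monotone miscalibration-free world; passing the trend test
  shows the binning recovers a monotone relationship, not that any real
  predictor is calibrated.

Passing the suite therefore demonstrates the *bookkeeping and
algorithms* are correct under controlled conditions; it does not by
itself certify accuracy on experimental structures, where numbering
mismatches, missing density, and boundary-distance links dominate the
error budget.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale problems chosen
to exercise every code path: ~10 proteins × 30 links for the violation
analysis, 1,225 links for the calibration binning, 100 segmentations
(K = 1..5 × 20 seeds, widths 50–120), and one 475-residue three-body
scramble for the default 10 × 20,000-frame ensemble.  All randomness
flows from explicit seeds; repeated runs with the same seed are
byte-identical, including CLI outputs (manifests contain no
timestamps).

## Known limitations

* Distances are Euclidean Cα–Cα; solvent-accessible surface distances,
  which are stricter in practice, are out of scope.
* Only Cα atoms are modelled anywhere; no side chains, no full-atom
  clash model.
* The segmentation reads labels from the diagonal only; discontinuous
  domains (a chain re-entering a spatial domain after an excursion)
  are reported as separate segments.
* The rigid-body sampler is single-temperature-schedule Monte Carlo,
  not replica exchange; it is meant for few-body problems at desk
  scale, and its cluster-precision proxy is a rough analogue of, not a
  substitute for, ensemble clustering analyses.
* Hetero-intermolecular cross-links are carried through parsing but the
  analysis unit is intramolecular links (including their homo-oligomer
  rescue).
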