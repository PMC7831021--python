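# Methods

This note records the models implemented in `pepevolve`, the parameter
choices that matter, the numerical conventions, and what the synthetic data
generators do and do not emulate.

## Geometry

Coordinates are angstrom everywhere inside the package; nanometres appear
only at boundaries where they are the field's convention (the clustering
cutoff, AFM heights) and are converted on input. Residue identity is
`(chain, residue number, insertion code)` with 1-based PDB numbering.

**PDB I/O.** A fixed-column parser (MODEL/ENDMDL for multi-model files)
that reports malformed coordinate records with their line number, skips
HETATM unless asked, drops alternate locations other than blank/A, and
preserves insertion codes. The element is taken from columns 77–78 and
inferred from the atom name when blank. The test suite cross-checks atom and
residue counts and coordinates against Bio.PDB on the same file.

**Superposition and RMSD.** Kabsch via SVD with the standard determinant
sign fix, so the returned rotation is always proper. Degenerate (collinear)
point sets are rejected rather than silently fit. RMSD optionally superposes
first (`fit=True`, the default for clustering and the backbone descriptor).

**Center of mass.** Mass-weighted by standard atomic masses, with a
geometric-centroid flag. The distinction is irrelevant at the precision of
any quantity derived from it here, so the conventional mass-weighted form is
the default.

**SASA.** Shrake–Rupley with a deterministic golden-spiral lattice
(default 960 points, probe 1.4 Å) over Bondi-type van der Waals radii
shipped in `geometry.VDW_RADII`. The fixed lattice makes values reproducible
bit-for-bit at fixed point count, at a cost: rotating a molecule
re-discretizes occlusion, so rotation invariance holds only to the lattice
error (≈1% at 960 points; translation invariance is exact). All atoms of a
structure act as occluders for a selection, so a site's SASA is its area in
the context of the whole protein. The probe radius and algorithm behind
literature site-area figures are typically unstated; agreement with such
figures is treated as approximate (±15%).

## Consensus site ranking

Per-pose site predictions are assigned to named surface regions by maximal
residue overlap (ties to the smaller, more specific region, then
lexicographic; zero overlap gives the sentinel `unassigned`). The consensus
score is the mean over poses of the region's best within-pose rank. Two
conventions were genuinely open:

- *Functional form.* Mean best rank (lower = better) is the default; a
  reciprocal variant `N / Σ r_Z(i)` (higher = better) is available behind a
  flag. The two produce identical orderings, which is the only testable
  output since reference region scores are published as a bar chart, not
  numbers.
- *Absence penalty.* A pose in which a region never appears contributes
  rank `(sites in that pose) + 1`, making absence strictly worse than any
  observed rank without dominating the mean.

## Sequence evolution

The evolving object is a cyclic peptide with terminal cysteines pinned
(default length 12, anchors at positions 1 and 12). Cys is excluded from the
mutable alphabet so the single disulfide bridge stays unique — consistent
with designed binders of this family, which carry no internal Cys. A move
mutates one uniformly chosen mutable position to a uniformly chosen
different residue; the proposal is symmetric, so Metropolis acceptance at
temperature `T_MC` gives a chain whose stationary distribution is Boltzmann
(verified in the tests by total-variation distance on an enumerable
16-sequence space).

Replicas at `T_MC = 0.3, 0.6, 0.9` a.u. run in lockstep; every
`exchange_interval` steps adjacent-temperature pairs attempt a sequence swap
with the standard parallel-tempering probability, alternating even/odd
pairings. Each replica draws from its own child stream of the master seed,
and exchanges from a dedicated stream, so runs are bit-reproducible and one
uniform variate is consumed per acceptance decision regardless of outcome.
Step counts and exchange frequency have no canonical values and are plain
config parameters.

The physical stages of a full design protocol — mutation minimization, REMD
conformational sampling, docking-score evaluation — are intentionally behind
the scorer interface: any callable mapping a sequence (or a frame) to a
finite score in arbitrary units, lower = better. This keeps the sampler
testable and lets real docking results enter as data
(`external_stub_scorer`).

## Surrogate scorers

`make_landscape` builds per-position random energies (i.i.d. normal, scale
1.0 a.u.) with optional sparse pair couplings (`ruggedness` sets their
density); with couplings present the stored optimum is verified by
exhaustive enumeration, so the searchable space must stay below 10⁶.

For optimizer-recovery checks the landscape supports a *planted* optimum
(`planted_gap`): one residue per mutable position is lowered to the position
minimum minus the gap. The reason is identifiability, not difficulty: with
i.i.d. weights the best/second-best gap at a position is an order statistic
frequently comparable to the lowest acceptance temperature, so no sampler
can reliably resolve the exact global optimum in a short run — a
non-discriminating oracle. A gap of 2.0 a.u. puts the per-position Boltzmann
occupancy of the planted residue at `1/(1 + 17·e^(−2.0/0.3)) ≈ 0.98` at
`T_MC = 0.3`, making recovery near-certain for a correct sampler while an
acceptance-rule bug still fails the check. The recovery acceptance test runs
20 seeded 5000-step replica-exchange runs and requires the `T_MC = 0.3`
replica to find the planted optimum in at least 19.

The structural surrogate is a symmetric residue-pair contact potential
summed over interface residue pairs with any heavy-atom distance within a
cutoff (default 4.5 Å), checked against a brute-force double loop.

## Ensemble clustering

Greedy RMSD-neighborhood clustering: compute the pairwise RMSD matrix
(least-squares fit first by default; matrix in nm), then repeatedly extract
the unassigned frame with the most unassigned neighbours within the cutoff
(default 0.105 nm) together with those neighbours. Ties in neighbour count
go to the lowest frame index, making output deterministic and matching the
common MD-package convention. Removal is immediate, so a frame within the
cutoff of two future centers joins the earlier-extracted cluster. The
population filter reads "more than 10 structures" strictly:
`min_cluster_size = 11`. The atom subset for clustering is configurable
(default: heavy atoms of the supplied selection), since published workflows
rarely state it. Representative selection scores only surviving clusters'
centers and returns the minimum, or nothing when no cluster survives — a
meaningful outcome, not an error.

## Screening

Three per-frame descriptors over a complex trajectory: binding score,
site–peptide COM distance (nm), and backbone RMSD of site + peptide against
frame 0 (nm). Rejection rules and their defaults:

- *weak_binding*: mean score above −10 a.u. The mean is used because the
  reference practice judges the plotted series qualitatively; sustained-
  excursion variants can be built from the series directly.
- *region_drift*: COM distance above 1.0 nm in more than 50% of frames.
  "Significantly shifted" has no published quantification; both knobs are
  explicit config values reported in the verdict.
- *anchor_contact*: an anchor Cys appears in any interface contact in more
  than the same persistence fraction of frames (the termini must stay free
  for DNA conjugation).
- *insoluble*: the solubility heuristic below.

Contacts are purely geometric, replacing interactive contact-diagram tools:
an h-bond when N/O of one side is within 3.5 Å of N/O of the other (hydrogen
positions are not required), a hydrophobic contact when two carbons are
within 4.0 Å. This over-counts h-bonds slightly (no angle term) but is
deterministic and adequate for identifying interacting residues.

Solubility is a documented local stand-in for proprietary web calculators:
`good` iff the charged fraction (D, E, K, R, H) is ≥ 0.20 and the
hydrophobic fraction (A, V, L, I, M, F, W, Y, C) is ≤ 0.60. Both reference
designed sequences (CRRYSHQHYRHC: charged 6/12, hydrophobic 4/12;
CFETAWRQNEWC: charged 3/12, hydrophobic 6/12) classify as `good`; an
all-alanine peptide does not.

## Nanopatch analysis

`S/A = R·N/W` with tip radius and patch width in µm, so the quantity is
dimensionless and the standard geometry (R = 0.01 µm, W = 1 µm) maps the
instrument stroke range N ∈ [96, 1536] onto S/A ∈ [0.96, 15.36]; N = 1024
gives 10.24, the saturated regime.

Relative height is `mean(patch) − mean(reference)` with the standard error
of a difference of means; roughness is the RMS of mean-removed patch pixels.
Both a whole-patch mean (default, robust when aggregates make the patch
non-homogeneous) and a line-profile method (central rows only, mimicking a
section tool) are implemented. Differential height subtracts two images'
relative heights and combines their errors in quadrature; identical images
give exactly zero.

The hybridization-response model is an explicit empirical stand-in (no
functional form is published): `δH = δH_max · c/(c + K_c) · g(S/A)` with a
Langmuir-type concentration factor and a piecewise-linear density factor
that rises to 1 at S/A = 2.5, holds to 6, and falls to 0 at 10 — chosen only
to preserve the observed qualitative facts (growth at low density, no height
change at saturated density). Defaults: δH_max = 2.2 nm, K_c = 250 (in the
concentration's units, conventionally nM).

The synthetic topography generator plants a centred square step of known
height plus i.i.d. Gaussian pixel noise and optional Gaussian aggregate
bumps, with a two-pixel guard ring between patch and reference masks. It
does **not** model scan-line artefacts, background tilt/bow, or tip
convolution at patch edges, so passing recovery tests demonstrate the
estimator's statistical correctness, not robustness to instrument
systematics; real images should be flattened upstream.

## Problem sizes in the shipped checks

The statistical acceptance checks use sizes chosen to make their tolerances
meaningful on a laptop: 10⁵ draws for the acceptance-frequency check
(3σ binomial), 10⁶ steps for Boltzmann stationarity (TV ≤ 0.02 on 16
states), 4×10⁴ steps for the two-replica occupancy check (batch-means
standard errors), 1000 random ≤8-frame ensembles against the brute-force
clustering reference, 20×5000-step recovery runs, and 200 seeded 96×96
images for planted-height recovery (3σ coverage ≥ 99%).

## Known limitations

- No force fields, docking functions, or MD: physical realism enters only
  through user-supplied scorers or precomputed score files.
- The SASA lattice trades exact rotation invariance for bit-reproducibility.
- The solubility rule and hybridization-response curve are documented
  heuristics; they preserve reference classifications and qualitative
  shapes, not measured values.
- Contact detection has no angular terms and no explicit hydrogens.
- The 1LDS-dependent site-area check requires the user to supply the PDB
  file; the package ships no third-party structure data.
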