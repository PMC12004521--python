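# Methods

This note documents the models and estimators implemented in `haplodyn`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical conventions adopted where the
design was genuinely open.

## Haplotype enumeration and translation

A haplotype is an ordered allele vector over a transcript's missense
variant sites, one per chromosome copy. Enumeration is pure counting: the
global frequency of a pattern is its count divided by the total number of
chromosomes (never an average of per-population frequencies), and
per-population frequencies are computed within each population's
chromosomes. The common-haplotype filter keeps patterns with frequency
strictly greater than the threshold (default 0.01); a pattern at exactly
the threshold is dropped.

Phasing is consumed, never inferred: VCF records with `/`-separated
genotypes raise an error. Multi-allelic sites are decomposed into
biallelic records on load, one per ALT allele. Translation applies
substitution alleles to the coding sequence (1-based, inclusive
coordinates) and translates with the standard codon table, stopping at the
first stop codon. Insertions and deletions are rejected explicitly:
a frameshifting or codon-deleting allele cannot be represented as a
same-length protein comparison, and the PLLR below is only defined for
substitution haplotypes.

## PLLR scoring

A position scorer maps a protein sequence to one log-probability per
position — that of the residue actually present. The pseudo-log-likelihood
of a sequence is the sum of these; the PLLR of a variant is the difference
of pseudo-log-likelihoods against the wild type, averaged over the
ensemble members. The sign convention is fixed: positive = more plausible
or less disruptive, negative = potentially harmful.

Scoring uses one unmasked forward pass per sequence by default (summing
the log-probabilities the model assigns to the residues present); a
masked-marginal mode is available behind a flag for scorers that support
it. For a positionwise (context-free) scorer the two modes coincide, and
the PLLR of a multi-substitution haplotype decomposes exactly into the sum
of its single-substitution PLLRs; neither property is assumed for
contextual models.

The wild type scores 0 by construction and is included in the
per-transcript *score variability* (max − min of the PLLR values). With
the published EXO5 ensemble scores {0, +5.05, +4.51, −2.74} this gives
7.79 ≈ 7.8. Cohort summaries report the share of haplotypes with
|PLLR| > 1 both with and without the wild-type rows, because including a
structurally-zero row dilutes the statistic and the preferable convention
is a judgement call. PLLR is not normalised by sequence length; length
normalisation would change cross-gene comparisons and is left to the
caller.

## Trajectory metrics

**Superposition and RMSD/RMSF.** Rigid-body fits are least-squares
(Kabsch, via quaternion alignment); the fit selection ("core", excluding
the mobile region) and the report selection are independent. RMSD is
measured against a fixed reference frame; RMSF is measured about the
trajectory-average structure after core alignment, per replica, and
replicas are combined as mean ± between-replica SEM. The default sampling
stride for both is 200 ps.

**Secondary structure.** Assignment uses the simplified PyDSSP scheme as
implemented in MDAnalysis: hydrogen bonds by the DSSP electrostatic
criterion (E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) kcal/mol,
bond iff E < −0.5), helix from consecutive (i, i+4) bonds, strand from
ladder patterns with β-bulges demoted to loop, everything else loop.
Hydrogen positions are taken from the topology, never guessed; proline
and chain-terminal residues without an amide hydrogen are never donors.
The assignment is cross-checked in the test suite against an independent
DSSP implementation (mdtraj) on ideal helix and hairpin constructs.

**Ordered fraction** of a region is the mean over frames of the share of
region residues labeled helix or strand. **Kink angles** are measured at
the α-carbon of the middle residue of a named triple — the atom is
configurable because only the residues, not the atoms, are canonical.
**Displacement maps** report the mean change of residue-pair distance
relative to a reference frame; positive entries mean the pair moved apart.

**Uncertainty.** The autocorrelation time τ of a series is the smallest
lag at which the biased (1/n) normalised ACF reaches e⁻¹; τ is reported in
frames of the strided series. The moving block bootstrap resamples
⌈n/l⌉ overlapping blocks of length l (default l = ⌈τ⌉) with replacement
and takes the standard deviation of the resampled means as the SEM.
A caveat the tests encode explicitly: for strongly correlated series the
block-l bootstrap converges to the *block-level* variance
σ²_l = 1 + (2/l)·Σ_{k<l}(l−k)ρᵏ rather than the long-run variance
(1+ρ)/(1−ρ); at ρ = 0.9 and l = τ = 10 this undercovers by ≈ 38%, and
recovering the long-run value within 25% requires blocks of a few τ
(the suite demonstrates both facts against closed-form expectations).
Reported uncertainties on trajectory averages are between-replica SEMs;
the within-replica bootstrap quantifies each replica's own noise.

Equilibration is handled by one knob: an initial time span (960 ns in the
full-scale configuration) discarded from the first replica before any
"equilibrated" statistic.

## Interaction networks

Edges are detected per frame with geometric criteria, all exposed through
`ContactParams`:

- salt bridge: any pair of oppositely charged side-chain group atoms
  (Arg NH1/NH2/NE/CZ, Lys NZ, His ring N; Asp OD1/OD2/CG, Glu OE1/OE2/CD)
  within 4.5 Å;
- hydrogen bond: donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 120°,
  donors identified as N/O atoms with a covalent hydrogen (≤ 1.2 Å);
- hydrophobic: side-chain centres of mass of apolar residues
  (Ala, Val, Leu, Ile, Phe, Met, Pro, Trp) within 5 Å.

Sequence-adjacent pairs are never edges. Per-type occurrence networks
(fraction of sampled frames with the edge present; 100 ps stride) are
combined by taking the per-edge maximum across types, then binarised at an
occurrence cutoff of 20% — strictly greater-than, since behaviour at
equality is a convention. Jaccard similarity between unweighted networks
is |E₁∩E₂|/|E₁∪E₂|, with the degenerate empty–empty case defined as 1.

Protein–DNA interfaces are residue × nucleotide integer maps: atom-pair
weights are 1 below 4 Å, 0 beyond 5 Å, and follow a smooth switch in
between — a cosine ramp by default, pluggable because any monotone smooth
switch with those endpoints leaves the integer-rounded maps essentially
unchanged. Weights are summed per residue–nucleotide pair and rounded to
the nearest integer. When maps are compared across variants, mutated
residues can be restricted to the atoms common to all systems.

## Essential dynamics and clustering

PCA runs on α-carbon coordinates after aligning every sampled frame
(0.5 ns stride at full scale) to a configured reference frame on the
α-carbons *excluding* the mobile region, so the mobile region cannot
dominate the rigid-body removal. Subspaces of the first D = 30 components
(scaled to D = 10 for the small synthetic systems in `analysis/`) are
compared with the RMSIP; the suite pins the analytic cases 1, 0 and
√(15/30) and checks invariance under re-basis within either span.

Density-peaks clustering is implemented in-package:

1. intrinsic dimension by the two-nearest-neighbour MLE,
   d = n / Σ ln(r₂/r₁);
2. adaptive k-NN log-density per point, F = ln k − d·ln r_k, growing k
   from 4 while the likelihood-ratio statistic (F_i − F_j)²·k/2 against
   the k-th neighbour stays below 23.928, capped at k_max = 100; the
   log-density error is 1/√k;
3. provisional peaks are points denser than everything in their adaptive
   neighbourhood; other points inherit the label of their nearest denser
   point in decreasing-density order (ties broken by lowest index, making
   the procedure deterministic);
4. clusters merge when the lower peak stands less than Z propagated
   errors above their connecting saddle (the highest min-density
   cross-cluster neighbour pair; peak and saddle errors summed in
   quadrature). Pairs of clusters with disjoint neighbourhoods take the
   closest cross-cluster pair as a fallback saddle, so a sufficiently
   large Z always merges everything and the cluster count is
   non-increasing in Z.

This is a self-contained simplification of the adaptive density-peaks
family, validated against ground truth (Gaussian mixtures with ≥ 99%
membership recovery) and against a brute-force kernel-density oracle on
small instances, rather than claimed identical to any reference
implementation. Dihedral features use raw angles in degrees with a
periodic per-coordinate metric (minimal angular difference, Euclidean
combination) — a sin/cos embedding would distort the Manhattan/Euclidean
semantics of angular differences. Interface-map features use the Manhattan
distance on the flattened integer maps. Z defaults follow the study
convention: 5 for the mobile-region dihedral set, 3 otherwise.

## Synthetic data: what it emulates, and what it does not

The generator produces *statistical stand-ins*, not physics:

- **Phased panels** sample chromosomes i.i.d. from a prescribed haplotype
  distribution and store the generating haplotype of each chromosome, so
  enumeration can be checked exactly (counting, not estimation). Real
  panels have linkage structure and population-specific frequencies; the
  fixture has neither unless planted.
- **Helix/coil trajectories** draw each frame either as an ideal α-helix
  (φ = −57°, ψ = −47°) with probability p or as a coil with dihedrals from
  the β/PPII basin (φ ∈ [−180°, −60°], ψ ∈ [60°, 180°]), rebuild Cartesian
  coordinates by sequential internal-coordinate construction (Engh–Huber
  geometry, trans ω), place amide hydrogens analytically on the external
  N–H bisector (the assigner reads hydrogens, never guesses them), and add
  isotropic Gaussian noise (default σ = 0.05 Å). Coil frames cannot form
  helical hydrogen bonds, so p is the exact expected ordered fraction of
  interior residues — the whole-chain draw is what makes the ground truth
  exact. Optional idealised β-carbons give each residue a side-chain
  proxy for hydrophobic-contact analyses. Planted contacts displace only
  the second atom of a pair onto the contact/open distance per frame,
  deliberately decoupling contact statistics from the dihedral draw (and
  knowingly breaking that atom's covalent geometry).
- **AR(1) series** are stationary with unit marginal variance; their
  autocorrelation time has the closed form −1/ln ρ.

Consequently, passing tests demonstrate estimator correctness — recovery
of planted frequencies, fractions, occurrences and correlation times —
not fidelity to real molecular dynamics: there is no force field, no
thermodynamic consistency, no coupling between secondary structure and
contacts, and frame-to-frame dynamics are i.i.d. rather than diffusive
(except the AR(1) fixtures used for the time-series estimators).

## Problem sizes and determinism

The synthetic study in `analysis/` uses three variants × three replicas ×
600 frames of a 16-residue chain, 1000 diploid individuals, and
1000-point clustering instances; the test suite uses 10⁴–10⁵-point series
for time-series statistics and 500-point Gaussian clouds for clustering —
sizes chosen so a full run of tests plus analysis completes interactively
on one CPU while keeping sampling errors well below the tested
tolerances. Every stochastic component takes an explicit seed
(NumPy `default_rng`); identical spec + seed reproduces outputs
bit for bit, and the pipeline manifest records seeds and parameter hashes
for every stage.

## Known limitations

- Only substitution haplotypes are scored; indel haplotypes are rejected
  at translation (upstream of scope).
- The network hydrogen-bond donor table is element-based (N/O with a
  covalent H); exotic donors/acceptors and water-mediated interactions
  are not modelled.
- The clustering engine materialises the full pairwise distance matrix;
  it is intended for up to ~10⁴ observations, not raw production
  trajectories (subsample first).
- Full 8-class DSSP, PSN centrality analytics, free-energy surfaces and
  kinetic embeddings are deliberately out of scope.
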