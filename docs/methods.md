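# Methods

This note records the models, parameter choices, and numerical conventions
behind `coapep`, and what the synthetic test surface does and does not
establish about real data.

## Design problem and sequence space

The design target is a pair of 11-residue peptides, A cationic and B
anionic, intended to coassemble into a two-layer β-sheet fibril when mixed
while neither chain self-assembles alone. The sequence space is constrained
to the hydrophobic/polar pattern `PPPHPHPHPPP` (H at 1-based positions 4,
6, 8), with each chain carrying exactly 3 hydrophobic, 3 uncharged-polar
and 5 charged residues, net side-chain charge +5 on A and −5 on B, and no
cysteine, proline or glycine. Charged residues are legal only on P sites; H
sites accept only hydrophobic residues. Termini are modeled as capped
(acetyl/amide), so net charge counts side chains only. Positions are
1-based in every report.

Default residue classes: hydrophobic {A, V, L, I, M, F, W, Y}, polar
{S, T, N, Q}, positive {K, R}, negative {D, E}, excluded {C, P, G, H}.
Histidine is excluded by default because its charge class is ambiguous at
neutral pH. All sets are configuration-overridable. With these defaults the
admissible space per chain is C(8,5)·2⁵·4³·8³ ≈ 5.9 × 10⁷ sequences
(`enumerate_space_size` reports the exact closed-form count, cross-checked
against brute-force enumeration on toy alphabets); the toolkit makes no
claim that this equals any externally quoted pool size, which depends on
the alphabet chosen for the count.

## Fibril scaffold

Scoring uses a fixed idealized backbone: 2 sheets × 6 straight strands of
11 Cα atoms, strand axis spacing 3.5 Å, in-sheet strand spacing 4.8 Å,
sheet separation 10.0 Å — canonical β-sheet dimensions. Adjacent in-sheet
strands are antiparallel; cross-sheet in-register strands are parallel;
species alternate A,B,A,B,… identically in each sheet, so the lattice
realizes the target architecture (alternating antiparallel sheets stacked
face-to-face) exactly. Twist and pleat curvature are omitted: the backbone
is fixed during design and only relative distances enter the score.
Side-chain centroids are placed along the sheet normal with alternating
pleat parity at per-residue canonical Cα→centroid distances (configurable
table); the two sheets' inward parities face each other, forming the
dry steric-zipper core. The inter-sheet registry is in-register
face-to-face by default. 12 peptides suffice for a per-peptide energy; the
scaffold size is configurable.

## Score function

The design objective is Γ = ΔG_binding + λ·P_agg, minimized by the Monte
Carlo engine. λ is dimensionless (3.0 and 4.0 are the values of practical
interest); Γ and ΔG are reported in kcal/mol.

**ΔG_binding** is the total inter-chain interaction energy of the threaded
pair divided by the number of peptides:

* backbone hydrogen bonds: `hbond_energy` (default −1.5 kcal/mol) ×
  `hbonds_per_neighbor_pair` (default 10, i.e. one per residue pair minus
  one) per registered in-sheet strand pair;
* side-chain contacts: a symmetric 20×20 table evaluated for centroid
  pairs within 6.5 Å. The default table attracts hydrophobic pairs in
  proportion to the product of min-max-normalized Kyte–Doolittle
  hydropathies (prefactor −0.8 kcal/mol) plus a −0.25 kcal/mol bonus for
  uncharged-polar pairs (the N⋯T carboxamide/hydroxyl motif). Any table can
  be loaded from CSV;
* electrostatics: Coulomb terms q·q·332.06/(ε·r) over all inter-chain
  charged pairs with a variable internal dielectric, ε_ij =
  max(ε_class(i), ε_class(j)) with class values nonpolar 1, polar 2,
  charged 4. Taking the more polarizable environment of the two partners
  damps charge–charge interactions relative to charge–nonpolar ones and
  avoids overestimating electrostatics in a +5/−5 interface;
* desolvation: +2.0 kcal/mol per charged residue whose centroid lies
  strictly inside the slab between the mean Cα planes of the two outermost
  sheets (a purely geometric burial rule, hence invariant under rigid
  motion).

The energy is computed vectorized over the full distance matrix; the test
suite checks it against an independent all-pairs double-loop oracle to
1 × 10⁻⁹ relative, plus invariance under slot re-enumeration and rigid
motion. Absolute magnitudes (≈ −120 kcal/mol per peptide with the default
constants) are on the scale of this reference model, not of atomistic
MM/GBSA; only orderings and the combination arithmetic are meaningful, and
tests assert exactly those (e.g. a charge-complementary pair always scores
below a like-charged one).

**P_agg** is a per-chain profile score: z_i = w_h·hydropathy(i) +
w_b·β-propensity(i) − w_c·|q_i| with Kyte–Doolittle hydropathy and
Chou–Fasman β-sheet propensity, defaults w_h = 0.05, w_b = 0.5, w_c = 0.4;
the profile is averaged over a centered window (default 5, truncated at the
termini), averaged over positions, and affinely normalized (gain 1.0,
offset −0.5). The defaults place charge-rich 11-mers of this family in the
range (−0.4, 0), dimensionless and of order 0.1 so that λ of a few units
meaningfully trades self-aggregation against binding. The pair-level P_agg
is the **mean** of the two chains (one value "per peptide"); the
functional form is monotone in hydropathy and symmetric under sequence
reversal, and both properties are tested.

## Monte Carlo engine

One trial move per step, chosen among intrachain mutation, intrachain
exchange and interchain exchange with probabilities (0.5, 0.25, 0.25).
Moves are constructed to be closed under every constraint: mutations stay
within the site's residue class (charged sites keep their sign), intrachain
exchanges swap two P-site or two H-site residues of one chain, interchain
exchanges swap residues that are hydrophobic on both sides or
uncharged-polar on both sides (charged residues never cross chains). A
degenerate alphabet triggers bounded retries, then an error.

Acceptance follows the Metropolis criterion on ΔΓ at an effective
temperature of 1.0 kcal/mol (constant by default; a linear annealing
schedule is available). The acceptance scale is a free parameter of the
method; 1.0 kcal/mol makes a typical single-residue perturbation (a few
kcal/mol under the default energy model) rejectable but not frozen.
Rejected trials leave the state unchanged and are counted. The engine
records the score trace at a configurable stride, the running best, and
the k lowest-scoring **distinct** pairs (default k = 6). Runs are
bit-reproducible from the seed.

Default run length is 2000 steps; tests use 100–600 steps, which is enough
to exhibit the qualitative trace shape (sharp early drop from a random
start, then a fluctuating plateau) that is asserted as a property, not as
values.

## Amyloidogenicity screen

Single chains are screened with a contact-scale rule: per-residue
expected-contacts values, averaged over a centered window (default 5,
truncated at the termini — not padded), classify a peptide amyloidogenic
iff ≥ `min_run` (default 7) consecutive window-averaged values exceed the
threshold (default 21.4, strict inequality). The packaged default scale is
a documented reconstruction of the expected-number-of-contacts-within-8 Å
packing-density scale used by contact-based amyloidogenicity predictors:
hydrophobic residues (V, I, L, M, F, W, Y, C) above the 21.4 threshold,
polar and charged residues below it. Classifier-logic tests use synthetic
scales, so correctness of the rule does not hinge on the packaged digits;
with the packaged scale all 12 benchmark design chains classify
nonamyloidogenic, as expected for sequences whose hydrophobic residues are
isolated at pattern positions 4/6/8.

## Assembly analysis

All statistics work on Cα coordinates only. Strand direction is the
principal axis of the Cα set signed N→C; pairs are parallel/antiparallel
when the dot product is ≥ +0.5 / ≤ −0.5, else unclassified. Two chains are
in-sheet neighbors when their mean in-register Cα distance (best of direct
and reversed index pairing) is < 5.5 Å; connected components of that
relation are sheets. Neighbor ranks group distances within a 1.5 Å tie
tolerance so that the two adjacent strands of an interior lattice position
share the "nearest" rank even under coordinate noise; the second tier is
"next-nearest". Unordered pairs are counted once, and a pair seen as
nearest by either member is not double-counted as next-nearest. β-sheet
content counts a chain as in-sheet when some partner has ≥ 4 aligned Cα
pairs within 6.0 Å; the A:B composition ratio counts chains in sheets of
size ≥ 2 (ratio undefined, reported as `None`, when no aggregated B chains
exist). All cutoffs live in `AnalysisParams`.

These criteria reproduce the built scaffold exactly (2 sheets of 6, 100%
A–B antiparallel nearest neighbors, 100% same-species parallel
next-nearest and cross-sheet neighbors, β-content 1.0, ratio 1.0) and are
robust to σ = 0.3 Å Gaussian coordinate noise. They are contact/registry
definitions chosen for Cα-only coarse input; they are not DSSP and have
not been calibrated against atomistic trajectories.

## NMR quantification

Spectra are two-column (ppm, intensity) traces with a strictly monotone
axis. Each fitting window gets an independent nonlinear least-squares model
(lmfit): a polynomial baseline (default linear) plus n analytic peaks —
Gaussian, Lorentzian, or pseudo-Voigt with fitted mixing (the default
shape). Initial centers come from prominence-filtered local maxima;
shoulders that produce no separate maximum are seeded from
intensity-weighted quantiles of the window, making the fit deterministic.
Failures are reported per window without aborting others. Parameter
uncertainties are the 1σ estimates from the fit covariance; on synthetic
single peaks their 68% nominal coverage is verified over 200 seeds.

The A:B ratio divides each reporter area by the number of contributing
carbons per chain — K Cγ is one carbon per lysine on chain A, E Cδ one per
glutamate on chain B, with multiplicities computed from the actual
sequences (5 and 4 for the benchmark design-4 pair) — then takes the
quotient. This per-carbon normalization is this package's documented
convention. The synthetic-recovery harness (SNR 50, Lorentzian reporters
at 23 and 181 ppm) recovers ratios and FWHM linewidths within 5% across
seeds; published experimental ratios/linewidths derive from unreleased
spectra and are not reproduction targets.

## Synthetic data and its limits

All fixtures are generated programmatically: ideal/noisy/half-dispersed
fibril frames from the scaffold builder, synthetic spectra from analytic
line shapes, and the benchmark sequence table. They establish internal
correctness — exact round-trips, oracle equivalence, closure, recovery at
stated noise levels — not external validity: real trajectory frames have
twist, partial order and registry defects the ideal lattice lacks, and real
spectra have baseline drift and shape deviations beyond the linear +
pseudo-Voigt model. Conclusions about real systems require the
corresponding real inputs.

## Known limitations

* The energy model is a reference architecture with configurable constants,
  not a fitted force field; absolute ΔG values are not transferable.
* Backbone is rigid during design; no side-chain rotamers (single-centroid
  placement), no explicit solvent.
* The amyloid screen's packaged scale is a reconstruction (ordering and
  threshold behavior correct; individual digits approximate).
* Sheet partitioning assumes equal-length chains and in-register or
  reversed pairing; large registry shifts are not searched.
* The MC engine does one trial per step with a constant (or linearly
  annealed) temperature; no replica exchange.
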