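# Methods

`rnapcollide` quantifies the structural and biochemical signatures of
transcriptional collisions in bacteria: an elongating RNA polymerase
(RNAP) that runs into a DNA-bound obstacle — a tightly bound protein
roadblock or a second, convergently transcribing RNAP — backtracks and
rotates its swivel module into a paused, catalytically inactive state.
This note documents the models and numerical procedures behind each
analysis stage, the choices made where the design was genuinely open, and
what the synthetic data generators do and do not emulate.

## Rigid-body geometry

Superposition uses the least-squares (Kabsch) solution: both point sets
are centered, the SVD of the cross-covariance is taken, and the smallest
singular direction is sign-corrected so the result is always a proper
rotation (no reflections). Collinear or under-determined inputs (fewer
than 3 points, or a second singular value at machine zero) raise a
degenerate-geometry error rather than returning an ill-conditioned fit.

Rotations are reported as axis + angle with the angle in degrees in
[0°, 180°] (the convention of the field's viewers): the angle from the
trace, the axis from the antisymmetric part, switching to the symmetric
eigenvector route within numerical reach of 180°. The screw anchor is the
least-squares solution of (I − R)p = t⊥, projected so it is the axis
point closest to the origin. The identity rotation reports axis (0, 0, 1)
by convention.

## Swivel angle

The swivel module comprises β residues 1241–1341 and β′ residues 1–342,
369–420, 787–930 and 1135–1375; the structural core is both α subunits
and ω in full plus rigid β segments (3–27, 142–152, 445–455, 520–713,
786–828) and β′ segments (343–368, 421–524, 530–552, 569–701, 720–786).
The published core/swivel residue lists overlap on β′ 412–420; because
the two modules must partition the molecule for the two-stage
superposition to be meaningful, those nine residues are assigned to the
swivel module and the core segment starts at 421. The effect on the
measured angle is negligible (9 of ~1100 core Cα pairs).

The measurement is: (1) pair core Cα atoms between query and reference by
identical (subunit, residue number) after chain mapping, dropping
unpaired residues symmetrically; (2) superpose the query core onto the
reference core and move the whole query; (3) superpose the reference
swivel Cα set onto the core-aligned query swivel set; (4) the swivel
angle is the rotation angle of that second transform (its translation is
reported but unused). Step 2 makes the result invariant to any prior
global motion of the query, which is verified by property test.

Coverage below 50% of the shared core or swivel residues is an error;
coverage between 50% and 80% warns. Deposited entries label RNAP chains
inconsistently, so the mapping from actual chain ids to subunits is
configurable, with `infer_rnap_chain_map` guessing it from chain sizes
(β′ reaches residue ~1375, β ~1342, α spans ~330, ω ~90).

## Downstream-DNA deformation

The reference frame is the PCA of the centers of mass of twelve
downstream nucleotides of the reference elongation complex: eigenvectors
of the 3×3 population (1/N) covariance of the twelve COMs, eigenvalues
descending. COMs are mass-weighted over heavy atoms by default
(molecular viewers' default); unweighted and hydrogen-including variants
are flags. Which twelve nucleotides to use is user configuration — the
natural choice is the six downstream base pairs, i.e. twelve nucleotides
across both strands.

Sign conventions (the frame would otherwise be defined only up to axis
flips): PC1 is oriented downstream, positive along the vector from the
lowest-numbered to the highest-numbered nucleotide COM (sorted by
residue key, so the frame is invariant to selection order); PC3 points
from the DNA centroid toward the centroid of the rest of the model (the
protein); for DNA-only models the largest-magnitude component of PC3 is
made positive instead; PC2 completes the right-handed frame. A query is
core-aligned to the reference, each nucleotide's COM displacement is
projected onto PC1/PC2, and the means over the twelve nucleotides are
reported. "Displacement along PC2" is therefore a signed, reproducible
quantity. Swivel–displacement coupling is summarised by ordinary least
squares plus Pearson r (`coupling_fit`).

## Steric scanning by SES overlap

Steric conflict between a walking RNAP and a fixed obstacle is scored by
the overlap of their solvent-excluded surfaces, `V(A) + V(B) − V(A∪B)`,
with all three volumes evaluated on one voxel lattice. The SES is the
morphological closing of the van der Waals body with a probe sphere
(default 1.4 Å, Bondi radii, hydrogens excluded). The grid algorithm:

1. Paint the signed distance `f` to the probe-inflated surface (min over
   atoms of `|x − c| − (r + probe)`), exact out to the carve shell.
2. Every voxel z with `f(z) > 0` is an accessible probe center; since f
   is 1-Lipschitz and exact outside the inflated body, the ball
   B(z, f(z) + probe) lies inside the probe-swept region. Tangent probes
   are added at lattice-edge crossings of the `f = 0` surface (linear
   interpolation along axis and face-diagonal edges, positions quantized
   to 1/16 of an edge with half the quantization error taken out of the
   radius) so thin accessible slivers still carve.
3. The swept region is removed; the signed field `s = max(f, −g)` (g =
   distance to the nearest carve ball) is negative exactly on the SES
   region, and the volume is the antialiased sum of per-voxel coverage
   weights `clip(0.5 − s/h, 0, 1) · h³`.

The antialiased, sub-voxel construction converges quadratically on
smooth bodies: at 0.3 Å spacing a single carbon sphere is within 0.8% of
the closed form and a two-sphere union within 1.2% of the analytic lens
value; halving the spacing from 0.6 Å changes a 50-atom tube's volume by
~1%. Grids are snapped to a global lattice (origin at integer multiples
of the spacing) so A, B and A∪B are commensurate and the overlap of
disjoint bodies is exactly zero. Probe-swept bridging means the overlap
becomes positive when two surfaces approach within two probe diameters —
the same behavior as viewer-computed SES volumes of a combined model.
Interior cavities large enough to hold a probe are treated as accessible
(they do not count toward the SES volume); probe-inaccessible crevices
are filled, as the closing definition requires.

The walk along DNA is the screw transform superposing the backbone atoms
(P, O5′, C5′, C4′, C3′, O3′ — present in every standard nucleotide) of a
window of residues onto the window shifted by n residues — a homopolymer
assumption, matching how collision trajectories are modeled. On ideal
B-DNA this recovers 3.4 Å rise and 34.2857° twist to machine precision.
`scan_collision` advances the mobile body by the cumulative single-step
transform, records the overlap at each template position, and rescales
so a chosen reference position (default 39 nt, default scan 20–44 nt)
reads zero.

## Roadblock efficiency and complex stability

Roadblock efficiency E_RB is (roadblock − background)/(scaffold −
background), floored at zero, then anchored so the 50 mM salt lane of
each titration equals 1 (background maps to 0 by construction). For
cross-condition comparison at the readout salt (default 300 mM),
replicates are rescaled so the reference condition's mean is exactly 1;
means ± SD (sample SD, ddof = 1) are reported. Both normalisations are
scale-invariant by construction and verified as such on random tables.

Stability time courses are normalised between a −NTP control (fully
intact) and a proteinase K control (background); values outside [0, 1]
are clipped and logged, never silently. The decay model is
a₁e^(−k₁t) + a₂e^(−k₂t) with a₁, a₂ ≥ 0 and k₁ ≥ k₂ ≥ 0, enforced by the
parametrisation (k₁ = k₂ + δ, all parameters bounded below by zero) in a
trust-region least-squares fit with four deterministic starts plus
seeded random restarts. When the two fitted rates coincide the
components are merged (a₂ = 0): equal rates are a single exponential in
disguise and the split of amplitude between them is not identifiable.
The half-life is the time at which the fitted curve reaches half its
fitted t = 0 value, found by bracketed root-finding (Brent). The 95% CI
is a parametric bootstrap: Gaussian noise is added to the fitted curve
and the fit repeated (1000 draws by default; the coverage studies use
200 draws per simulation, which changes percentile estimates by far less
than the interval width). Because the residual SD is itself estimated
from few degrees of freedom (n − 4), each bootstrap replicate draws its
noise scale from the scaled inverse-χ² sampling distribution of the
residual SD rather than treating it as known — with it the true-value
coverage of the 95% interval, measured over hundreds of seeded noisy
simulations (σ = 0.03, 12 timepoints), is ~92%; without it the interval
undercovers at ~86%.

Condition comparisons use the two-tailed unpaired Welch t-test
(Satterthwaite degrees of freedom) with Benjamini–Hochberg adjustment
across the requested pairs. Groups of two identical values produce an
infinite t rather than an error, per the formulas.

## SEnd-seq read classification

Each RNA molecule yields a 5′-end read and a 3′-end read. Both are
locally aligned (Smith–Waterman, affine gaps: match +2, mismatch −1,
gap open −5, gap extend −0.5; U ≡ T) against the forward and the reverse
candidate RNA; an orientation's score is the sum of its two best
single-read scores, and the higher total wins. An exact inter-orientation
tie is reported as unmapped/ambiguous, never assigned arbitrarily. Among
co-optimal alignments of one read the smallest reference start, then the
shortest span, is taken. The mapped 5′ end is the alignment start of the
5′ read; the 3′ end is the alignment end of the 3′ read; coordinates are
1-based and closed.

Filters, applied after orientation assignment: the ends must be more
than 15 nt apart (strict inequality), and the 5′ end must fall within
the start-site window, interpreted as |5′ − TSS| ≤ window/2 with a 10 nt
default window. A read failing any filter is reported as unmapped with
the reasons in `filters_failed`; its best-orientation coordinates and
both orientation scores are retained in the record. Transcript length is
3′ − 5′ + 1. The hairpin drop statistic divides the mean 3′-end-survival
coverage over the five nucleotides upstream of the hairpin boundary by
the mean over the five downstream — near 1 for uniform 3′ ends, large
when transcripts pile up at the boundary.

An alternative reading of the score-summation rule — the top two
positions of a single read's alignment — is noted but not used; the
two-read sum is the only interpretation consistent with having paired
5′/3′ reads per molecule.

## Synthetic data

Every generator is a pure function of its seed and parameters
(bit-reproducible) and carries its own ground truth.

- **Mock polymerases** place one Cα pseudo-atom per residue on smooth
  per-chain space curves covering the full default subunit ranges (two α
  1–329, β 1–1342, β′ 1–1375, ω 1–91), then rotate the swivel-selection
  residues by a known angle about a known axis, optionally adding
  Gaussian coordinate noise to the query. Cα-only suffices because the
  swivel measurement touches only Cα positions. What they do not
  emulate: real side chains, missing density, conformational coupling
  between modules, or correlated (non-isotropic) coordinate error.
- **Ideal B-DNA** is backbone-only (the six standard backbone atoms at
  idealized offsets), two antiparallel strands related by the dyad, with
  3.4 Å rise and 360/10.5° twist per base pair and residues numbered by
  base-pair level on both strands, so a +1 shift in residue number is
  exactly the helical screw step. It has no bases and no sequence, hence
  no groove chemistry — sufficient for stepping and steric anchoring,
  not for base-level contacts. Nucleotide-COM fixtures for the PCA frame
  place one pseudo-atom per nucleotide on a 2 Å-radius helix, emulating
  how real nucleotide COMs (bases stacked near the axis) sit close to
  the helix axis.
- **Collision scenes** anchor two pseudo-atom blobs (shells of carbon
  pseudo-atoms approximating spheres of requested radius) on the helix
  axis at given base-pair positions, so first contact is predictable
  from the rise.
- **Reads** are sampled from the forward/reverse RNA with 5′ ends
  jittered near the start site and 3′ ends from a uniform or
  hairpin-pileup end model, with independent per-base substitution
  errors. No indels, adapters, barcodes, or quality profiles.
- **Decay curves and titrations** map known bi-exponential fractions or
  known per-salt E_RB values through the control/anchor conventions,
  plus seeded Gaussian noise, and recover exactly at zero noise.

Because the generators build in the truth the pipeline is asked to
recover, green tests demonstrate correctness of the computations, not
robustness to real-data pathologies (radiation damage, partial
occupancy, RNA degradation, gel smile).

## Problem sizes and runtime choices

The default verification runs use 200 mock polymerases for swivel
recovery, 100 random fixtures for the displacement oracle, 100–200
simulations × 200 bootstrap draws for CI coverage, 200 synthetic read
pairs for classification accuracy, and 0.3 Å grids for the closed-form
volume checks (0.6 Å for scans). These sizes give sampling errors well
below the tolerances they are checked against while completing in
minutes on one CPU.

## Known limitations

- The swivel measurement assumes author residue numbering is shared
  between query and reference (true for E. coli RNAP entries); no
  sequence alignment fallback is provided.
- The SES overlap treats both bodies as rigid; DNA does not flex during
  the walk.
- The voxel SES converges quadratically on smooth surfaces but a
  pathological surface with probe-scale pocket topology can shift by a
  few percent between coarse lattices.
- The bi-exponential CI is a parametric bootstrap under Gaussian
  residuals; heteroscedastic gel noise would need a different resampling
  scheme.
- The classifier is template-level (two candidate RNAs), as the assay
  design dictates; it is not a genome aligner.
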