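# Methods

`zippersim` is a desk-scale model system for the early assembly of
cross-β hexapeptide aggregates (ILQINS and its mutants IFQINS, TFQINS).  It
builds idealized steric-zipper nanocrystals in all eight symmetry classes,
predicts their orientationally averaged solution X-ray scattering, tracks
parallel (P) versus antiparallel (AP) backbone hydrogen bonding, runs a
Hamiltonian replica-exchange (HREMD) aggregation engine over a coarse-grained
energy model, and decomposes interface free energies by block cutting.  All
lengths are Å, energies kcal/mol, temperatures K.

## Strand and lattice construction

Strands are built by backbone forward kinematics from ideal bond geometry at
a uniform (φ, ψ) = (−110°, 105°) pleated-β conformation.  Atoms per residue:
N, amide H, CA, C, O, CB, plus a single side-chain bead SC placed along the
CA→CB direction at a residue-specific centroid distance (1.5–4.1 Å); the
C-terminus carries OXT.  Termini are charged (NH₃⁺/COO⁻), as expected for
unbuffered assembly near neutral pH.  The dihedral pair was chosen inside the
β basin such that the end-to-end extent of a hexapeptide leaves a clash-free
(≥ 1.8 Å) terminus–terminus contact at the a = 20.6 Å lattice repeat.
Strands are canonically oriented: N→C along +x (a axis), carbonyl
alternation along z (c, hydrogen bonding), side chains along ±y (b, zipper);
the pleat is flipped, if necessary, so the face with the higher mean side-chain
hydrophobicity points +y, toward the mating sheet — steric zippers bury
their best face.

The eight symmetry classes are encoded as the three binary choices (strand
sense, sheet face packing, sheet orientation); the within-group ordering is a
documented lookup table (see `zippersim.lattice`).  AP sheets alternate
reversed strands along c; the reversal is a 180° rotation about c (classes
5–6, face-swapping) or about b (classes 7–8, face-preserving), plus a small
registry shift along the strand axis found by a deterministic scan that
maximizes ideal backbone hydrogen bonding to the unreversed neighbour.  The
mating sheet sits at b/2 with an a/2 stagger (falling back deterministically
to smaller or c-shifted staggers for classes whose geometry would clash), so
side chains interdigitate and charged termini are not juxtaposed across the
dry interface.  Default geometry: a = 20.6, b = 19.1, γ = 82°; c-rise 4.8 (P)
and 4.85 (AP), so the translated-equivalent repeat of an AP stack is 9.7.
Blocks are validated for peptide count, AP sense alternation, and a hard
1.8 Å minimum inter-peptide heavy-atom contact.

## Scattering

Intensities come from the Debye equation (exact orientational average over
pair distances) with 4-Gaussian Cromer–Mann form factors (H, C, N, O, S) and
dummy-atom solvent contrast `f'(q) = f(q) − ρ_s V exp(−q² V^{2/3}/4π)` with
Fraser–MacRae–Suzuki displaced volumes and ρ_s = 0.334 e/Å for water.
Systems above 3000 atoms automatically use a pair-distance-histogram path
(0.01 Å bins, evaluated at per-bin mean distances) that matches the exact
double sum to well under 0.5%.  Guinier radii are fitted iteratively on the
window q·Rg ≤ 1.3 (the bound is an argument; analytic-sphere validation uses
0.8, where the approximation is accurate to < 1%).  Peaks are local maxima
above a relative prominence threshold (default 1% of the windowed intensity
span), annotated with d = 2π/q; ties break toward lower q.

A finite-size caveat: the AP lattice's strand-spacing line (d = 4.85) lies
only 1% in q away from the P signature at d = 4.8.  Peak *positions*
discriminate the classes robustly at desk scale, but the *intensity* at
exactly q = 2π/4.8 in an AP block is suppressed only in proportion to the
c-axis coherence length (≈ 2–3× for blocks up to 2×2×192); a clean absence
of the 4.8 Å line requires fibril-like coherence lengths (≳ 10³ Å) that are
deliberately outside this package's scale.

## Hydrogen-bond topology

A backbone hydrogen bond is donor N–H to acceptor carbonyl O (or OXT) with
H···O < 2.5 Å and N–H···O angle > 135°; both cutoffs are exposed because the
criterion behind any published absolute count is conventional.  Strand
directions are signed principal axes of the CA trace; a strand pair is P when
the direction dot product ≥ +0.5, AP when ≤ −0.5, else unclassified, and
bonds inherit their strands' pairing.  Time series of (N_P, N_AP) support a
centered boxcar moving average with truncated edge windows.

## Coarse-grained energy model

Pairwise terms between peptides: Debye-screened Coulomb between terminal
charge sites (±1 on the N-terminal N and C-terminal C; ε_r = 15 as
appropriate inside a small oligomer, screening length 7 Å, the Bjerrum length
of water at 300 K); a 10–12 well on inter-peptide H···O pairs (depth 4.5
kcal/mol at 1.8 Å — set so sheets assemble at 300 K on the overdamped-Langevin
timescales used here); a 12–6 LJ between SC beads (σ 3.4–5.0 Å by residue,
depth 0.6·√(ε_i ε_j) kcal/mol); and a hydrophobic-burial Gaussian contact
(range 5 Å, scale 0.5 kcal/mol) standing in for a solvent-accessible-area
term.  An intra-peptide elastic network (all atom pairs < 5 Å, k = 10
kcal/mol/Å²) supplies bonded stiffness when peptides are flexible; it is
constant under rigid-body moves and is skipped there.  Every term is a pair
sum, so energies are extensive and vanish for separated neutral fragments.
The Bjerrum utility `e²/(4πε₀ ε_r k_B T)` gives 6.96 Å for water (ε_r = 80,
300 K) and 37.1 Å for ε_r = 15.

The minimizer is adaptive-step steepest descent, either on rigid-body
translations/rotations per peptide (torques about centroids; used for cut
blocks, matching the picture of pre-formed strands relaxing their packing in
a continuum solvent) or on all atoms; accepted steps never increase the
energy, and convergence is an RMS-gradient threshold.

## Replica exchange

The restraint Hamiltonian is U(x, λ) = ½λ|x − x_ref|², with the rigid
extended reference superimposed (proper-rotation Kabsch fit) on each peptide
at every evaluation, so only internal conformation is biased.  The ladder is
λ_i = λ_max (i/(M−1))² with M = 64 and λ_max = 0.032 by default; exchanges
between adjacent replicas alternate even/odd pairs every 5 ps with the
Metropolis rule on ΔU_ij = [U(λ_i,x_j)+U(λ_j,x_i)] − [U(λ_j,x_j)+U(λ_i,x_i)].
Dynamics is overdamped Langevin (dt = 0.01 ps, friction 0.5, deterministic
displacements capped at 0.25 Å per step so steep repulsive walls cannot
destabilize the integrator), vectorized across replicas; identical seeds give
bit-identical trajectories and exchange logs.  Peptide centroids are confined
by a half-harmonic wall (default radius 50 Å; 64 peptides there correspond to
0.2 M).  An optional harmonic on each strand's CA z-spread flattens strands
into the xy plane (off by default; production-style aggregation runs here use
0.3 kcal/mol/Å²).  Mixing diagnostics report per-pair acceptance rates and
configuration round trips replayed from the log.

Because the toy peptides are already near-extended, the λ ladder mainly
regularizes conformation; aggregation itself is driven by the nonbonded
terms, with antiparallel approach favoured by the terminus electrostatics.

## Interface thermodynamics

`dG_c` halves a 1×1×14 single sheet along c (interface cross-section: 1
peptide); `dG_zip` splits a 1×2×14 two-sheet block into its sheets (14
buried peptides).  Each cut block is relaxed by rigid-per-peptide
minimization (default tolerance 1e-2, 40 iterations) and estimates average at
least 50 blocks drawn without replacement from distinct post-burn-in frames
(frozen, zero-noise trajectories repeat one snapshot, giving the
deterministic variant with zero standard error).  ΔΔG(1−5) rows are exact
class-1-minus-class-5 differences.  On the default model the deterministic
fixtures give ΔΔG_c > 0 (AP sheet elongation stronger, driven by the
alternating terminal charges along c) and ΔΔG_zip < 0 (P zipper stronger,
driven by burial of the uniformly hydrophobic face), with the zipper
preference strengthening along ILQINS → IFQINS → TFQINS.  Absolute magnitudes
are far smaller than atomistic values and are not comparable; only signs and
orderings are meaningful.  The linearity assumption behind per-buried-peptide
normalization holds to ~2% (class 1, 8- vs 12-strand sheets) once the
relaxation is converged tightly; with loosely converged minimization,
size-dependent edge relaxation can masquerade as nonlinearity.

## Synthetic fixtures

Trajectory fixtures are seeded Gaussian jitter (per-atom σ, optional
random-walk drift) around ideal assemblies, with a labelled burn-in segment
and an optional progressive unraveling schedule (randomly re-oriented,
displaced peptides) for hydrogen-bond-decay studies.  They emulate the
statistical structure of converged molecular-dynamics snapshots, not real
force-field fluctuation spectra or explicit hydration; tests passing on them
validate the pipeline's bookkeeping and the toy model's signs, not atomistic
accuracy.  The demo pipeline (`zippersim demo`) chains the whole system at
small sizes (4×4×16 scattering blocks, 6-peptide/4-replica aggregation,
frozen 14-strand thermodynamics) in about two minutes on one CPU.

## Known limitations

- Absolute interface energies, absolute hydrogen-bond counts and absolute
  scattering envelopes are outside the model's reach; signs, peak positions
  and trends are the supported outputs.
- The AP 4.8 Å-line suppression is coherence-length-limited (see above).
- Side chains are single beads: no rotamers, no side-chain hydrogen bonds,
  sub-residue shape complementarity only via bead distance and σ.
- The aggregation engine's endpoint states are arrested, not equilibrated;
  different seeds can leave different small aggregates.
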