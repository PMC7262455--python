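# Methods

This note records the models, numerical choices and limitations behind
flexscatter, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
what passing the test suite does and does not demonstrate.

## Guinier analysis

The Guinier approximation ln I(q) = ln I(0) − q²Rg²/3 is fitted by
weighted linear least squares of ln I against q², with weights
1/σ_lnI², σ_lnI = σ/I (first-order propagation); unweighted when no
uncertainties are present.  Rg = √(−3m) holds exactly by construction,
and the reported Rg uncertainty is the SEM of the slope propagated
through that identity (Rg_err = 3·SE_m / 2Rg).

Because the window is expressed in qRg, point selection depends on the
fitted Rg; the fit is iterated to self-consistency (≤ 20 rounds).  The
default upper limit is qRg = 1.3, appropriate for partially compact
particles.  The automatic window search scans starting points from the
lowest q upward and accepts the widest window with R² ≥ 0.95, negative
slope, and an Rg stable to < 5% under removal of either endpoint —
which is what removes low-q aggregation upturns.  Ties prefer more
points, then lower starting q.

Systematics worth knowing: for a homogeneous sphere the Guinier fit
carries a positive window-truncation bias (≈ +0.26% at qRg ≤ 0.5,
+1.1% at qRg ≤ 1.0, +1.8% at qRg ≤ 1.3, computed from the closed-form
curve).  Tests that assert sub-0.5% recovery therefore use short
windows; results quoted at the default window inherit the ~1–2%
systematic, which is inherent to the method, not to this
implementation.

## Dimensionless Kratky transform

x = qRg, y = x²·I(q)/I(0) with Rg and I(0) taken from the Guinier fit.
For an ideal Guinier (globular) scatterer the peak is exactly at
(√3, 3/e ≈ 1.104); flexible chains plateau or rise instead.  The
transform is invariant under intensity rescaling.  Note that a hard
sphere peaks slightly *below* the Guinier-model reference — numeric
maximization of the closed form puts it at (1.612, 1.027) — so the
reference point is a model landmark, not a universal compact-particle
locus.

## Indirect Fourier transform

P(r) is represented by its values on a uniform grid of n = 101 points
over [0, Dmax] with both endpoints pinned to zero.  The forward map is
the trapezoid-discretized Fourier–Bessel kernel
A_ij = 4π Δr sin(q_i r_j)/(q_i r_j), and the solution minimizes
‖W(Ap − I)‖² + α‖D₂p‖² with W = diag(1/σ) and D₂ the second-difference
operator — a linear least-squares problem.  Non-negativity is not
imposed by default (flexible systems can be handled with a strictly
linear solver; a flag switches to NNLS).

α is chosen on a log grid (10⁻⁶…10³, 4 points per decade) as the
largest value whose data-space reduced χ² stays within 10% of the
grid minimum: the smoothest P(r) that does not degrade the fit.  The
data-space reduced χ² divides by the number of q points.

Diagnostics for Dmax scans follow common practice for flexible
proteins: percent deviation of the real-space Rg and I(0)
(Rg² = ∫r²P dr / 2∫P dr, I(0) = 4π∫P dr, trapezoidal quadrature) from
the Guinier values, and a tail-smoothness metric |dP/dr| at Dmax
relative to the peak of P.  An underestimated Dmax raises χ² sharply;
an overestimated one yields a smooth, uninformative tail — the scan
reports both signals and leaves the judgement explicit.

## Debye profiles and χ² fitting

Models are coarse-grained to one bead per residue at the Cα position
with a q-independent per-residue electron count (sums of atomic numbers
of the residue formulas; 30 for Gly … 98 for Trp).  The Debye double
sum is evaluated exactly over all pairs (blocked so the work buffer
stays in cache; ~1 s for 2000 beads × 200 q points).  Hydration-shell
and excluded-volume corrections are deliberately omitted: absolute
intensities are arbitrary and every comparison to data goes through a
fitted scale factor.  Consequently, geometry-driven statements (Rg,
Dmax, relative χ² ranking, compact-vs-extended discrimination) are
meaningful, while absolute χ² values against real detector data would
additionally reflect the missing solvent terms.

χ² fitting minimizes Σ((c·I_m + b − I_d)/σ)² in closed form over the
scale c (and optionally a flat background b) and reports the reduced
χ² divided by n − p.  Model curves are cubic-spline interpolated onto
the data grid when grids differ.

## Chain models and conformer pools

A chain layout tiles the sequence with rigid domains and disordered
linkers.  The default 414-residue layout places the NTD at 1–80, RRM1
at 106–176, RRM2 at 191–258, a rigid helical segment at 320–334, and
linkers at 81–105, 177–190, 259–319 and 335–414; boundaries are round
numbers for the canonical domain architecture and are fully
configurable.  When no source structure is supplied, domains are
synthetic compact Cα globules: sphere-clipped cubic lattices at 5.07 Å
spacing, reproducing the ~130 Å³ mean residue volume of folded
proteins and hence realistic domain Rg.  They are stand-ins labelled
synthetic; real coordinates can be read from PDB/mmCIF files.

Linkers are self-avoiding random walks: successive virtual Cα–Cα bonds
of 3.8 Å, pseudo-bond angles uniform in (75°, 150°), and a 3.0 Å clash
radius against all non-bonded beads including previously placed
domains.  Sampling is pure rejection — any clash discards the whole
walk — so the accepted ensemble is the bounded-angle distribution
conditioned on self-avoidance, with no growth-order (Rosenbluth) bias;
this is what makes the distribution provably identical to a
brute-force oracle sampler, which the test suite verifies by a
two-sample KS test on 10⁴ end-to-end distances.

Domains after the first are attached with a uniform random SO(3)
orientation (quaternion sampling) at a 3.8 Å bond, accepted only if
clash-free.  Pools draw per-conformer integer seeds from a
SeedSequence, making (n, seed) → pool bitwise reproducible.  Pool
generation is Monte-Carlo geometric sampling, NOT molecular dynamics:
the intent is to span compact-to-extended arrangements (Rg coefficient
of variation ≈ 19% under the defaults) so that the ranking and
compact-vs-extended analyses — which are the point of the module — can
be exercised; the pool is not a thermodynamic ensemble.

Ranking scores every conformer by its Debye profile fitted to the data
and reports whole-chain Rg, structured-region Rg (residues 1–258) and
per-linker end-to-end distances for the best and worst k.  Dimers are
built by duplicating a chain under an NTD head-to-tail transform; the
default transform is one step of the crystal filament helix (36°
rotation, 3.62 Å rise, 46 Å axis offset).

## Synthetic data

Noise is Gaussian with σ(q) = a·I(q) + floor; the defaults a = 1% and
floor = 10⁻⁶·max(I) produce Guinier Rg SEMs of a few tenths of an
Ångström on an Rg ≈ 41 Å particle, matching the order of uncertainty
typical of good synchrotron SEC-SAXS averages.  The default q grid is
500 log-spaced points over 0.0084–0.35 Å⁻¹.  The SEC-series generator
imposes an Rg drift by linearly interpolating a per-frame target Rg
(in Å) and selecting, from a small batch of freshly assembled
conformers, the one closest to the target (tolerance 1.5 Å); the
frame-to-frame conformational spread is therefore narrower than in a
real elution, which only strengthens, not weakens, the drift-detection
test's realism as a lower bound on noise.

These generators emulate counting noise, the experimental q range, and
conformational heterogeneity.  They do not emulate buffer-subtraction
residuals, inter-particle structure factors, radiation damage, or the
hydration shell — so passing tests demonstrates correctness of the
analysis chain, not instrument-level realism.

## Crystal filament geometry

Symmetry expansion applies all space-group operators (gemmi's tables)
combined with lattice translations in a ±3 cell neighbourhood and
keeps, iteratively, every copy with an atom within the contact radius
of the growing set — so helical filaments extend across two or more
turns instead of stopping at the first shell.  Every copy records its
generating operator and shift, and superposes exactly on its source
chain when the operator is inverted.

Filament tracing requires the molecule contact graph to be a simple
path (all degrees ≤ 2); branch points raise an explicit ambiguity
error with the degree distribution rather than guessing an order.  The
helix fit initializes the axis from the mean cross-product of
consecutive centre-of-mass chords (robust even for short arcs, where a
principal-component axis fails), centres it by an algebraic circle
fit, refines by minimizing the variance of radial distances, and then
reads rise and azimuthal step per molecule in cylindrical coordinates.
Pitch = rise × molecules-per-turn by construction.  COM radius and
atomic inner/outer radii are reported separately, since the three
answer different questions about a spiral's size.

Because no deposited filament coordinates ship with the package, the
test fixture is a synthetic crystal: five arc-shaped molecules in a
P2₁2₁2₁ cell whose c-axis 2₁ screw continues the helix, built to the
published NTD-spiral geometry (10 molecules per turn from two
asymmetric units, COM radius 46 Å, pitch 36.2 Å, outer atomic radius
92 Å).  Recovery of those numbers from the 5-molecule asymmetric unit
plus symmetry is a genuine end-to-end test of the expansion, tracing
and fitting machinery, but it is not a check against experimental
coordinates.  The synthetic lattice also keeps neighbouring spirals
out of contact; in a real crystal, spiral-spiral packing contacts
would make the raw contact graph branched, and a designated-interface
cutoff or distance filter must be chosen before tracing.

## SASA

Shrake–Rupley with deterministic golden-spiral sampling (default 960
points per atom, probe 1.4 Å; van der Waals radii C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80 Å, extensible per call).  Side-chain
SASA sums all non-hydrogen atoms beyond and including Cβ (backbone =
N, CA, C, O, OXT).  Quadrature convergence is sub-0.2% of the full
sphere area for typical atoms on doubling the point count; the worst
partially-buried atoms can move by up to ~1%, which bounds the
meaningful precision of single-atom values.  Percentile placement on a
reference distribution uses the midpoint convention
100·(#below + ½·#equal)/n; published tryptophan-exposure percentiles
depend on the specific reference database used, which is consumed as a
file and not reconstructed here.

## Problem sizes used in tests

The test suite and acceptance checks run at desk scale by choice: pools
of 30–200 conformers (the ranking analyses are size-agnostic; the
study-scale default of 7,000 is supported by the same code path),
q grids of 120–500 points, 30-frame SEC series, and 10⁴-sample linker
statistics.  All stochastic steps are seeded and reproducible.

## Known limitations

- Constant per-residue form factors: no q-dependence, no hydration
  shell, no excluded-volume term — absolute χ² against real data is
  out of reach by design.
- The conformer pool is a geometric ensemble, not Boltzmann-weighted.
- The IFT regularization is a curvature penalty with a discrepancy
  α-rule; perceptual GNOM-style criteria are not implemented.
- Filament tracing handles linear filaments only; branched crystal
  contact graphs are reported, not resolved.
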