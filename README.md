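# flexscatter

Solution small-angle X-ray scattering (SAXS) analysis and rigid-domain /
flexible-linker ensemble modelling for multidomain proteins — the kind of
system exemplified by full-length TDP-43: a few folded domains (NTD, two
RRMs, a short C-terminal helix) strung on long intrinsically disordered
linkers, studied by SEC-SAXS in solution and by crystallography of its
oligomerization domain.

## What it does

**Curve analysis.** `.dat` I/O and SEC-SAXS frame averaging; Guinier
analysis (ln I = ln I(0) − q²Rg²/3, with Rg = √(−3m) from the fitted
gradient m, automatic window search with qRg ≤ 1.3); Guinier-based
dimensionless Kratky plots ((qRg)²·I/I(0) vs qRg, with the globular
reference point (√3, 3/e ≈ 1.10)); per-frame Rg evolution across an
elution with group summaries (e.g. first vs last third).

**Real space.** Regularized indirect Fourier transform from I(q) to the
pair-distance distribution P(r) on a fixed support [0, Dmax]
(second-difference Tikhonov penalty, pinned endpoints, discrepancy-style
automatic α); Dmax scans scored by consistency of the real-space Rg and
I(0) with the Guinier values and by tail smoothness; P(r) directly from
coordinate models.

**Models.** Exact Debye-formula scattering profiles from Cα bead models
(I(q) = ΣᵢΣⱼ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ)); closed-form sphere and
Gaussian-chain oracles; closed-form χ² fitting of model curves to data;
full-chain conformer assembly from rigid domains plus self-avoiding
linker walks (3.8 Å virtual Cα bonds, bounded pseudo-angles); seeded
Monte-Carlo conformer pools, χ² ranking, and compact-vs-extended
analyses of the structured region (residues 1–258 by default).

**Crystal side.** Space-group symmetry expansion to the contacting
environment of an asymmetric unit; tracing of head-to-tail filaments
along the contact graph; helix fitting of the filament (radius, rise,
molecules per turn, pitch, atomic inner/outer radii); interface polar
contacts; Shrake–Rupley solvent accessible surface area with empirical
percentile placement against a reference distribution.

**Synthetic data.** Every generator (sphere, flexible chain, drifting
SEC series, filament crystal) returns ground truth, so each stage of the
pipeline is testable end to end without access to unpublished
experimental data.

## Worked example

```python
import flexscatter as fs

# synthetic sphere dataset: R = 53.05 A, so Rg = sqrt(3/5)*R = 41.1 A,
# 1% Gaussian noise on the experimental q range 0.0084-0.35 1/A
curve, truth = fs.make_sphere_dataset(53.05, noise=fs.NoiseModel(a=0.01, seed=3))

fit = fs.auto_guinier(curve)
kratky = fs.dimensionless_kratky(curve, fit)
scan = fs.dmax_scan(curve, [80, 90, 100, 110, 120], fit)
```

prints (via the obvious format calls):

```
Guinier: Rg = 41.8 +/- 0.1 A  (truth 41.1 A), I(0) = 1.002, window 0.35 < qRg < 1.30, R^2 = 0.995
Kratky peak: (1.56, 1.07); globular reference (1.732, 1.104)
 Dmax  delta_rg_pct  delta_i0_pct  tail_smoothness
   80         -1.73         -0.42             0.37
   90         -1.71         -0.41             0.58
  100         -1.61         -0.21             0.22
  110         -1.62         -0.22             0.00
  120         -1.62         -0.21             0.13
most Guinier-consistent Dmax: 100 A  (truth 106 A)
```

The Guinier Rg lands ~1.7% above √(3/5)·R — the well-known window
truncation systematic for a compact particle fitted out to qRg = 1.3 —
and the Dmax scan's Guinier-consistency criterion brackets the true
maximum dimension (2R = 106 Å) to within one scan step.  A sphere's
Kratky peak sits slightly below the Guinier-model reference point; a
flexible chain would instead plateau at large qRg.

The same analyses are available from the shell:

```
flexscatter simulate sphere --radius 53.05 --seed 3 -o sphere.dat
flexscatter guinier sphere.dat
flexscatter kratky sphere.dat
flexscatter pr sphere.dat --scan 80:120:10
flexscatter build -n 100 --seed 1 -o pool/
flexscatter rank pool/ sphere.dat -k 10
flexscatter helix crystal.pdb --cutoff 4.0
flexscatter sasa model.pdb --residues TRP --ref trp_ref.txt
```

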