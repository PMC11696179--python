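# Methods

`cophase` implements the quantitative machinery used to show that the
assembly state and material properties of CONSTANS (CO) / NF-Y condensates
gate *FT* promoter activation: image statistics that classify nuclear CO
assemblies, FRAP recovery kinetics that separate fluid from slow-diffusive
condensates, bivalent-analyte SPR kinetics for the pairwise protein
interactions, and a reduced coarse-grained simulation of oligomeric CO-NF-Y
complexes binding the multi-motif *FT* promoter fragment.  A synthetic-data
module generates every input with known ground truth, so each estimator is
validated by round trip.

## Condensate image statistics

**Spatial clustering index (SCI).**  For a wide line profile through a
nucleus (3 µm width by default, averaged perpendicular to the line, bilinear
sampling at pixel pitch), SCI is the mean of the top 5% of intensities
divided by the mean of the bottom 5%.  Tails contain `max(1, floor(0.05 n))`
values after a stable sort.  SCI is 1 for uniform signal, grows with
clustering, is invariant to intensity rescaling, and moves monotonically
toward 1 under additive offsets.  A zero bottom-tail mean (background-free
synthetic data) is rejected as degenerate rather than returned as infinity.

**Signal variance and three-state classification.**  The per-nucleus scalar
is `(SD/mean)^2` over the nuclear signal foreground, with the *population*
SD (`ddof=0`): the statistic describes the pixel population of one nucleus,
not a sample estimate.  The foreground is recovered by Otsu thresholding on
log-transformed intensities; connected components smaller than 4 px are
dropped.  The log transform matters: a plain Otsu threshold on a
high-contrast aggregate nucleus latches onto the bright blobs and discards
the nucleoplasm, inverting the statistic, whereas in log space the dominant
background/signal split is recovered for all three morphologies.  Whole-mask
variance (no thresholding) is available as `mode="whole"` because the
original protocol is ambiguous about whether thresholding preceded the
variance.  Classification uses fixed cutoffs: diffuse below 0.21, spherical
condensate in the closed interval [0.21, 0.45], irreversible aggregate
above 0.45.  Values exactly at a cutoff belong to the middle bin, matching
the closed printed range of the middle class.

**Variance mixture fitting.**  The multipeak fit over a population of
variances is a 1-D maximum-likelihood Gaussian mixture, fitted by EM with
seeded multi-start (10 restarts by default, alternating broad and tight
initial component widths; tight starts are needed to resolve the very
narrow diffuse-class mode next to the broad aggregate mode).  Component SDs
are floored at 1% of the data SD to exclude the singular one-point
solution.  Convergence requires a relative log-likelihood change below
1e-8; the per-iteration log-likelihood trace is exposed and is
non-decreasing (a property test).  Fits with overlapping components or a
component supported by fewer than 5 points are flagged `degenerate`
(weights non-identifiable).  Whether the original analysis used true
mixture ML or histogram peak fitting is unknown; EM mixture was chosen, and
the fitted crossing points between adjacent weighted densities are reported
so they can be compared with the fixed 0.21/0.45 cutoffs.

## FRAP

Normalization divides the bleach-ROI series by the reference-ROI series
(removing acquisition photobleaching, which the generator applies to both
ROIs), then rescales to full scale: prebleach mean 1, first post-bleach
frame 0.  The recovered fraction is therefore directly the fitted plateau.
A trace whose bleach depth is zero raises "no bleach event detected".

Recovery is fitted with the one-phase decay model
`F(t') = plateau * (1 - exp(-rate * t'))` on post-bleach frames (at least
8), by bounded least squares (plateau in [0, 1.5], rate in (0, 10] /s) with
two starts: a heuristic (last-quartile plateau, half-rise rate) and a
fast-rate start.  The second start guards against a boundary minimum in
which a slowly recovering trace is fitted as a huge plateau times a
vanishing rate; the lower-cost solution wins.  The baseline offset is fixed
at zero (full-scale normalization pins it); fits that are flat or pinned at
a rate bound are flagged invalid (rate unidentifiable) but still report the
plateau.  Mobility classification: liquid if plateau >= 0.4, else
slow-diffusive.  The cutoff is a package choice (the source gives only
qualitative classes) and is a config parameter; the two synthetic classes
(plateau 0.12 vs 0.85) sit far from it on either side.

Synthetic mixtures draw per-trace classes multinomially, jitter plateau
(Gaussian, SD 0.04) and rate (lognormal, 20%), and use a 120-s, 1-s-interval
grid: more than three recovery time constants of the slow class
(rate 0.03 /s), mirroring acquisition "until the emission reaches a
plateau".  In vivo (1 s interval) and in vitro (30 s interval, 10 min)
protocol presets are provided; the fitter is grid-agnostic.

## Bivalent SPR kinetics

The bivalent analyte model (singly bound AB, doubly bound AB2, free sites
`Rmax - AB - w*AB2`, response `AB + w*AB2`, w = 1 by default) is integrated
with LSODA for the 60 s association / 300 s dissociation protocol, all
concentrations of a dilution series in one vectorized solve.  ka2 is in
RU-based surface-site units, the conventional formulation; bulk shift and
drift are omitted (double-referenced data assumed).  The response can never
exceed Rmax and the noiseless dissociation phase is monotone non-increasing
(tested invariants).

Global fitting minimizes the stacked residuals of all curves over
log10-parameters (positivity by construction) with `scipy.optimize.
least_squares`, starting from a heuristic (Langmuir read of the
end-of-association responses for Kd and Rmax) plus seeded log-uniform
perturbations of it (8 starts, +/-2 decades).  Diagnostics report the
first-order Kd = kd1/ka1, per-curve residuals, and the Jacobian condition
number; a single-concentration input or a near-singular Jacobian raises an
ill-conditioning warning.  Noiseless round trips recover all five
parameters to better than 0.1%; at 1% multiplicative noise the first-order
Kd is recovered to a few percent.

The two homotypic kinetic presets (CO on CO: Kd 50 nM with slow
dissociation; NF-YB2 on NF-YB2: Kd 20 nM with faster dissociation) carry
rate constants read off the corresponding sensorgram panels; only the
first-order Kd values are printed in text, and only those are treated as
reference numbers.

## Single-particle analysis

Detection is single-scale Laplacian-of-Gaussian: local maxima of the
scale-normalized -LoG response above a quality threshold (default: 5x the
MAD-estimated response noise, floored at 5% of the peak response),
non-maximum suppression within 2 sigma, quadratic sub-pixel refinement.
Total intensity is the pixel sum over a disk of 3 sigma minus the annulus
(3-5 sigma) median times the disk area; spots whose annulus clips the image
border are flagged and excluded from statistics.  Colocalization is
mutual-nearest-neighbour matching within a radius, reported as the matched
fraction of the first channel.

## Reduced promoter-binding simulation

The simulator keeps the composition and counting conventions of the
residue-resolution study system — 15 DNA fragments carrying four CO
response elements each, 60 CO-NF-Y binding units, a 120-nm periodic cube, a
1.2-nm contact cutoff, the first half of each trajectory discarded — at
drastically reduced resolution: one bead per CO-NF-Y unit, one DNA bead per
~10 bp (the packaged 169-nt CORE fragment maps to 17 beads at full scale).
Reduced units: lengths in nm, energies in kT, unit mobility 1; the original
force-field settings (10 fs timestep, 0.01 ps^-1 friction, 300 K) are
provenance, not literally integrated.

Energetics: harmonic bonds (k = 100 kT/nm^2) along DNA and within
complexes, both with rest length 3.4 nm (the DNA bead pitch, so an s-mer
can engage s consecutive ~10-bp segments); worm-like-chain bending
stiffness on DNA (15 kT per angle — the ~170-bp fragment is much shorter
than the ~50-nm persistence length of dsDNA, so fragments behave as
near-straight rods) and angular stiffness 10 kT along oligomers (structured
assemblies held by native contacts, not floppy polymers); soft harmonic
repulsion between units (sigma 2.4 nm) and between DNA beads (sigma
2.0 nm); and a short-range attractive well between units and DNA beads,
`U(r) = -eps (1-(r/rw)^2)^2` for r < rw = 2.4 nm, with eps = 5 kT at motif
beads and 1.2 kT elsewhere (generic electrostatic protein-DNA attraction
that lets complexes slide along a fragment).  The unit-unit repulsion
radius exceeds the well range, so at most one unit occupies a motif's
attractive minimum (one CCT-NF-Y footprint per CORE).  Units have no
excluded volume against DNA; in the zero-affinity limit they are an ideal
gas and the random-contact expectation is exact, which the null-control
test uses.

Dynamics are overdamped Langevin (default dt 0.004, friction 1) with
periodic wrapping, run through a numba-compiled kernel; a pure-numpy force
routine is the reference implementation and the two are asserted equal in
tests.  A Metropolis Monte-Carlo mode over unit positions provides the
equilibrium cross-check (one unit/one site occupancy against direct
quadrature of the Boltzmann ratio).

**Contact statistic.**  A unit is bound to a chain when its minimum-image
distance to any bead of that chain is <= 1.2 nm (closed boundary).  The
source protocol counts complexes "contacting the DNA/COREs", i.e. contact
with the fragment, not only with motif beads; whole-chain counting is
therefore the default and motif-only counting is an option
(`mode="motif"`).  Counts are collected per chain per frame over the second
half of the trajectory.

**Desk scale.**  The default configuration scales geometry as well as
counts — 16 units, 4 chains of 9 beads, 36-nm box — preserving the 4:1
unit:chain ratio and the 4 motifs per chain while letting diffusive site
finding equilibrate within ~10 s of wall time per run; `full_scale()`
builds the 60/15/120 composition.  The oligomer-state scan (states 1-5,
three seeds each, 400k steps) yields mean bound units per chain strictly
increasing with oligomeric state (Spearman rho = 1): at fixed per-unit
affinity, larger complexes bind the multi-motif fragment more, which is the
avidity signature.  Units not divisible by the state enter as monomers and
are recorded.

## Synthetic data: what it emulates and what it does not

Nucleus images are a jittered ellipse footprint on a dim camera background:
constant nucleoplasm (diffuse), 2-8 Gaussian foci of fixed peak amplitude
3.9x the nucleoplasm (spherical — a fixed per-focus amplitude keeps the
variance statistic in the middle bin across focus counts, because the
larger numerator of many foci is offset by the brighter whole-nucleus
mean), or 1-3 irregular blobs built from overlapping discs at 2.8x on a
dimmer nucleoplasm (aggregate).  Noise is additive Gaussian read noise;
intensity units are arbitrary (no camera gain is reported for the original
data).  The three contrast constants were calibrated once against the
classifier so that each class lands in its variance bin for >= 95% of seeds
(measured: 100% over 300 seeds per class), as the generator contract
requires.  Not emulated: optical PSF blur and deconvolution, z-stack
photophysics, Poisson shot noise, tissue segmentation — so passing tests
demonstrate correctness of the statistics and classifier logic, not
robustness to real microscope artefacts.

FRAP traces are exact one-phase recoveries times an acquisition-bleach
exponential in both ROIs plus additive noise; there is no reaction-diffusion
structure or bleach-spot geometry.  Sensorgrams are exact bivalent-model
solutions with multiplicative (and optionally additive) noise; mass
transport is absent.  Particle fields are ideal Gaussian spots on a flat
background with a crowding flag when neighbours fall within 4 sigma.

Every generator is a pure function of its spec including the seed
(bit-identical outputs); population generators draw labels multinomially
and hand each item an independent child seed.

## Numerical choices and degenerate inputs

- Population SD everywhere a per-population statistic is meant (signal
  variance, summary curves); sample SD is never silently substituted.
- SCI tail size `max(1, floor(f*n))`; profiles shorter than `ceil(1/f)` are
  rejected.
- EM: restarts draw initial means from the data; convergence at relative
  log-likelihood change < 1e-8; singular solutions excluded by the SD
  floor; `k=1` is closed form.
- One-phase decay and bivalent fits are bounded least squares;
  log-parameterization keeps rates positive; boundary-pinned fits are
  flagged rather than hidden.
- Simulator timestep guard: `dt * k_bond / friction < 1.9` (overdamped
  Euler stability); non-finite coordinates abort with the step index.
  Contact decisions at exactly the cutoff are bound (closed boundary).
- Degenerate experiment inputs (single FRAP trace, single SPR
  concentration, single simulation seed) are processed but flagged, never
  silently averaged.

## Problem sizes used by tests and the acceptance script

Populations of 75 nuclei and 50 FRAP traces per replicate (the study's
sample sizes), 20 replicates in the acceptance script so the reported
percentages estimate the mixture expectation rather than one multinomial
draw; 6-point two-fold dilution series for SPR; desk-scale simulator runs
of 400k steps (about 8 s each).  These sizes keep the full suite and the
acceptance script in the minutes range on one CPU while leaving every
statistical tolerance intact.

## Known limitations

- The variance classifier assumes per-nucleus crops with visible camera
  background; a field of view containing several nuclei must be cropped or
  masked first (nucleus detection is out of scope).
- The reduced simulator reproduces the direction of the avidity effect,
  not the absolute bound-count histograms of the residue-resolution model;
  its energy scales are reduced-model parameters, not measured affinities.
- The bivalent fit assumes double-referenced, transport-free data; its ka2
  and kd2 are conditionally identifiable and should be read with the
  reported condition number.
- The FRAP model is a single exponential; subdiffusive or two-component
  recoveries will bias the plateau.
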