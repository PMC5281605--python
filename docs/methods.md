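# Methods

## Scope and model

`fiberpack` simulates the cross-section of a coherently oriented white-matter
tract as a two-dimensional packing of hard, circular, incompressible disks.
Each fiber consists of an inner (bare axon) circle of diameter *d* and a
concentric outer circle of diameter *d*/g(*d*) representing the myelin
periphery. The assumptions inherited from this reduction: fibers are
parallel (valid in spinal cord and similar tracts, not in fanning or
crossing regions), perfectly circular and non-deformable, all myelinated,
and separated by a *constant* gap Δ standing in for extracellular matrix and
glia. None of these hold exactly in tissue; they define a controlled
substrate for studying how FVF, MVF, AVF and fr co-vary, not a replica of
any particular sample.

## Diameter statistics

Inner diameters follow a Gamma law parameterized by mean μ (μm) and variance
σ² (μm²), with shape a = (μ/σ)² and scale b = σ²/μ, truncated to
[d_min, d_max] = [0.2, 10] μm to exclude non-physiological calibers.
Sampling uses a Metropolis–Hastings random walk: chain started at μ,
Gaussian proposals with standard deviation max(σ, 0.25 μm), acceptance
probability forced to zero outside the truncation window. The chain is
burned in for 1000 steps and thinned by 5; with these settings the sample
passes a two-sample KS test (α = 0.01, n = 10⁴) against direct inverse-CDF
sampling of the truncated law, which the test suite runs routinely. σ² = 0
is treated as the degenerate monodisperse case and bypasses the chain.
The 0.25 μm proposal floor keeps the walk mobile when σ is tiny relative to
the support.

## Myelin model

g(d) = slope·log(d) + intercept with defaults 0.220 and 0.508. The
logarithm base is base 10 by default: with the natural log the relation
crosses g = 1 near d ≈ 9.4 μm, inside the admissible diameter range, which
is unphysical (myelin of negative thickness); base e remains selectable for
comparison with implementations that used it. g is clamped to [0.10, 0.99]
(configurable) so extreme diameters cannot produce g ≤ 0 or g ≥ 1. At
d = 1 μm the relation equals its intercept in any base, a convenient exact
anchor used in the tests.

By default the packing operates on the *outer* circles — fibers touch at
their myelin peripheries — with the gap applied there (effective packed
diameter d′ = d_outer + Δ). Packing the inner circles instead is available
(`pack_on="inner"`), but with Δ smaller than the myelin thickness it lets
myelin annuli interpenetrate and is mainly useful for bare-disk experiments.

## Packing algorithm

Initialization: the square domain has area N·(2·max Rₖ + Δ)² (Rₖ the packed
radii). Disks are assigned without replacement to random cells of a
⌈√N⌉×⌈√N⌉ lattice centred at the origin and placed at cell centres. The
lattice pitch is max(side/⌈√N⌉, max effective diameter): the second term
guarantees every cell is at least as wide as the largest effective diameter,
so the initial configuration never contains an overlapping pair (for
monodisperse inputs the lattice is then exactly at contact). The recorded
domain side keeps the printed area formula.

Migration: at every iteration, synchronously for all disks,

* a disk with no overlapping neighbour (centre distance < sum of effective
  radii) moves toward the domain centre with fixed speed v_att = 0.01
  μm/iteration;
* a disk with overlapping neighbours moves along the normalized sum of unit
  vectors pointing away from each overlapper, with fixed speed v_rep = 0.1
  μm/iteration; its attraction is suppressed.

v_rep > v_att is required so overlaps are resolved faster than they are
created; both speeds are far below the minimum diameter (0.2 μm) to limit
bouncing. Degenerate directions (a disk exactly at the centre; repulsion
vectors cancelling exactly) produce zero displacement — no random jitter, so
a run is a pure function of the seed. A 10⁻¹² norm floor guards the unit
normalizations. Synchronous updating was chosen over per-disk sequential
updates after measuring both: sequential updates make the converged density
trace visibly noisier (trailing-window variation roughly doubles) and
introduce index-order dependence.

There is no stopping criterion by default; the iteration budget is fixed and
the FVF trace (sampled every `trace_every` iterations, default 250, on the
auto-selected analysis mask at 0.1 μm/px) is the convergence diagnostic.
`convergence_variation` reports max−min of the trace over an iteration
window.

Performance: the production loop is a numba kernel with a uniform cell list
(cell size = max effective diameter, rebuilt per iteration); overlapping
neighbours are accumulated in ascending index order, which makes the kernel
bit-for-bit identical to the O(N²) numpy reference path — an equality the
test suite asserts, so the acceleration can never silently change results.
N = 1000 × 35000 iterations runs in ~10 s on one CPU.

## Analysis mask and metrics

The analysis mask is a square centred at the centroid of disk centres with
half-side (R_cloud − m·max d_outer)/√2, where R_cloud is the maximum centre
distance from the centroid and m (margin_factor, default 2) keeps the mask
clear of the ragged cloud periphery; it errors out when the cloud is too
small to contain an interior mask. The substrate is rasterized at 0.05 μm/px
(≤ ¼ of the minimum diameter; configurable) by a pixel-centre-in-circle
test: inside any inner circle → intra-axonal, else inside any outer circle →
myelin (union semantics for the rare annulus collisions), else
extra-axonal. The three labels partition the mask exactly, so
AVF + MVF = FVF and fr = AVF/(1−MVF) hold to machine precision on every
computed instance. Rasterized single-fiber areas match the analytic circle
and annulus areas within 2% at the default resolution, and FVF converges to
the analytic disk-area fraction as the pixel size shrinks.

Residual disk overlap is quantified analytically, not from pixels: R_overlap
= Σ pairwise circle–circle lens areas / Σ disk areas, over the disks
intersecting the mask, so sub-pixel overlaps are not missed. With Δ = 0 the
converged packings keep R_overlap below 0.1%; a gap of 0.1 μm brings it
below 0.005% and Δ ≥ 0.3 μm removes overlap entirely, because a pair only
counts as overlapping in the *metric* sense when its effective-diameter
violation exceeds Δ.

## Validation experiments and problem sizes

* **Hexagonal close packing** — 250 identical 4 μm axons (σ² = 0), Δ = 0,
  7000 iterations. The jammed mask density lands near the hexagonal optimum
  π/√12 ≈ 0.9069 (measured ≈ 0.88–0.89, i.e. ~2% below theory) and interior
  disks average ≈ 6 contacts.
* **Stability** — N = 1000, μ = 3 μm, σ² = 1 μm², Δ = 0, 35000 iterations,
  FVF traced every 250. The trace plateaus near 0.84; the max−min variation
  over iterations 26000–35000 is of order 10⁻³. Two contributions keep it
  at that scale: disks rattle around the jammed state with amplitude set by
  v_rep, and the outer-circle packing (mean packed diameter ≈ 5.4 μm) makes
  the initial cloud large enough that slow compaction can extend into the
  window.
* **Reproducibility** — 10 independently seeded runs per diameter law
  (μ = 3; σ² ∈ {0.5, 1.5, 2.5}; N = 1000; 30000 iterations; Δ = 0). The
  replicate count trades the precision of the std estimate (relative error
  ≈ 24% at n = 10) against runtime; the measured std of the final FVF is
  ~2–3×10⁻³ per law, below the separation between the laws' means (the
  densest law is the most polydisperse one).
* **Mask-size stability** — nested centred masks on the σ² = 2.5 run; over
  masks holding > 200 disks the spread of FVF and fr is a few 10⁻³,
  combining finite-count scatter with the radial density gradient noted
  under limitations, and varies noticeably with the seed.
* **Gap sweep** — for fixed diameter laws, FVF and fr decrease strictly with
  Δ, fr faster than MVF; Δ = 0 maximizes all three fractions. Default sweep
  distributions span μ ∈ [2.5, 3.5] μm and σ ∈ [0.5, 2] μm, representative
  of spinal-cord histology ranges; exact per-tract fits are user input.

The unit suite uses scaled-down substrates (N = 40–250, ≤ 5000 iterations);
the experiments above run at the protocol sizes listed.

## Known limitations

The jammed density of a dynamics-based packer is algorithm-dependent
(maximally-random-jammed, not optimal), so absolute FVF values carry a
method signature of order 10⁻². Because the "container" is the attraction
field rather than hard walls, the equilibrium packing carries a mild radial
density gradient (the centre is slightly denser); the mask-size sweep sees
this as a monotone trend of FVF and fr across nested masks of order a few
10⁻³, on top of finite-count scatter. The constant-gap and circular-fiber
assumptions bias MVF/fr relative to tissue with deformed axons or variable
spacing. The density trace is a noisy order statistic over ~37 samples; its
max−min window variation fluctuates by tens of percent across seeds. The
generator produces substrates, not signals: no diffusion or relaxometry
simulation is included.
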