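# Methods

## The model

`segclock` simulates sequential segment formation in a one-dimensional tissue
of cellular phase oscillators. The tissue occupies `[0, L(t)]` with the
anterior end pinned at `x = 0` and grows linearly, `L(t) = t + L0`, under a
spatially *uniform* relative proliferation rate `r(t) = L'(t)/L(t) = 1/(t+L0)`.
Uniform growth makes the relative coordinate `ρ = x/L(t)` a conserved
Lagrangian label, so cell kinematics are exact: `x(t) = ρ·L(t)`.

Each cell carries a phase `φ` with observable state `z = z_max·cos(φ)`. The
phase advances as `dφ/dt = 2π/T`, where the period `T` depends on the variant:

* **distributed_distance** — `T(d) = T0·(1 + A·d)` with `d = L(t) − x` the
  distance from the posterior end. The posterior oscillates at the base period
  `T0`; oscillations slow toward the anterior. Proliferation is everywhere
  (the conserved-ρ advection above). This is the package's primary model: it
  shows that sequential, anterior-to-posterior segmentation does not require a
  localized posterior proliferation zone — only a posterior-anchored gradient
  of oscillation period, as could be supplied by a signalling gradient.
* **localized_age** — the classic progress-zone comparison variant. A
  posterior zone of width `pz_width` oscillates in phase at `T0`; growth adds
  new in-phase material at the posterior only, and a cell's period grows with
  its age `a` since leaving the zone, `T(a) = T0·(1 + A·a)`.

A cell **freezes** — its state stops oscillating and holds the value at the
freezing instant — when its period reaches the critical period `B`. That
happens at the critical distance `d* = (B − T0)/(A·T0)` (resp. critical age
`a* = d*`). The frozen region is always an anterior prefix; its
alternating-sign state profile is read as a sequence of segments.

The parameterisation `T = T0(1 + A·d)` with `B` as an arrest period is this
package's concrete reconstruction of the distance-slowed oscillator family:
with the default constants it yields faster posterior oscillations, an
anterior-to-posterior freezing wave, a first complete segment shortly before
`t = 10`, posteriorly shrinking new segments, and growth of established
segments — the full qualitative signature the model is meant to exhibit.

## Closed-form oracles (distributed variant, linear growth)

Along a material trajectory `d(t) = u·(t + L0)` with conserved
`u = 1 − ρ ∈ (0, 1]`:

* freeze time: `t_f(u) = d*/u − L0` (the posterior end, `u → 0`, never
  freezes);
* cycles accumulated at freezing:
  `N(u) = ln[(B/T0)/(1 + A·L0·u)] / (T0·A·u)`,
  strictly decreasing in `u`. With the default constants
  `N(u) = (2/u)·ln(5/(1+u))`, e.g. `N(1) = 2·ln 2.5 ≈ 1.833`.

The simulator never uses these; the test suite checks it against them (and
checks `N(u)` itself against independent numerical quadrature). In the age
variant every cell accumulates the same `N* = ln(1 + A·a*)/(T0·A) = 2·ln 5`
cycles between zone exit and arrest, which is why that variant produces
equal-width bands (width `T0/2` in lab units) — the contrast the two-variant
comparison is built around.

## Numerics

* **Integration.** The trajectory is exact, so only the phase quadrature needs
  a scheme: Simpson's rule per step on the known rate `2π/T(t)` (equivalent to
  RK4 for a phase-independent rate; 4th order). Default `dt = 0.01`, with a
  validity guard `dt ≤ T0/20`.
* **Freezing instant.** The threshold condition is linear in time in both
  variants, so the in-step crossing time is solved exactly and the phase is
  corrected back to it by Simpson quadrature over the overshoot. Freeze times
  and phases therefore agree with the closed forms to ~1e-5 at the default
  step, well inside the 1e-3 test tolerance; frozen values are immutable
  afterwards.
* **Initial condition.** All cells share `φ0 = 0` (the progress-zone picture
  is an in-phase pool; no other choice is distinguished). `φ0` is a parameter.
* **Resolution.** 4000 material cells by default (distributed variant). The
  posterior-most established bands are ~0.2 lab units wide at `t = 50`, ~15
  cells — enough for the strict width-monotonicity checks. The age variant is
  typically run at 400 initial cells; it appends cells posteriorly so spacing
  never exceeds the initial spacing and ends near 10⁴ cells.
* **Kymograph.** Cell state is sampled every `sample_dt = 0.1` onto a fixed
  grid of 520 half-open lab-coordinate bins spanning `[0, L(t_end)]` by linear
  interpolation between cells; bins outside the tissue carry a NaN sentinel
  (`NA` in the TSV export, gray level 0 in the ASCII-PGM export). Band
  *analysis* uses the cell-level freeze record carried alongside the grid,
  because bin-level quantization (0.1 length units) is comparable to the width
  differences between neighbouring posterior bands.

## Segment calls

Bands are maximal constant-sign runs of frozen `z`; boundaries are zero
crossings located by linear interpolation between adjacent cells. The
anterior-most run abuts the tissue edge rather than a crossing and spans less
than half an oscillation cycle (for `φ0 = 0`), and the posterior-most run is
still being traversed by the front — both are reported but flagged incomplete
and excluded from establishment statistics; with the edge run included, the
"widths strictly decrease" property would fail for an artefactual reason
(its truncated width, 1.19, is below the first complete band's 1.22 at the
default constants). A band is *established* when the front passes its
posterior boundary; the establishment time is interpolated from per-cell
freeze times. Widths are continuum lab lengths, not cell counts. The *first
segment time* is the moment the frozen-phase span reaches one full cycle
(2π); at the default constants this is ≈ 8.76, consistent with "just before
t = 10".

## Synthetic embryo patterns and the zone test

The generator emulates mitosis-marker labelled nuclei fields as a uniform
point pattern on the unit rectangle (AP axis × lateral axis) with Bernoulli
mitotic labels: constant probability `p0` (uniform regime), `p0·E` over the
posterior fraction `f` of the AP axis (posterior-zone regime), or `p0·E`
inside an annulus (ring regime). Defaults `n = 2000` nuclei and `p0 = 0.05`
are conventions chosen to resemble the sparsity of mitosis labelling in whole
embryos — real preparations report no coordinate data, so magnitudes are
generator conventions, not measured values. The flat 2D geometry deliberately
ignores embryo curvature; the zone test consumes only the AP coordinate, so
passing tests speak to the statistic's calibration and power under these
regimes, not to segmentation of real micrographs, their nuclei-density
gradients, or spatial autocorrelation of labelling.

The posterior-zone test bins nuclei into `K = 5` equal AP bins (half-open,
last bin closed) and tests one-sidedly whether the posterior-most bin holds
more mitoses than its nuclei share predicts, conditioning on the total mitosis
count `M`: an exact `Binomial(M, n_K/n)` tail (conservative — the conditional
null is hypergeometric, which is tighter) and a label-shuffling permutation
p-value with the add-one estimator `(1 + #{≥ obs})/(1 + n_perm)` (exact in
level). Rejection uses the smaller of the two; both `K` and the interrogated
bin are exposed. Calibration is verified by simulation in the test suite:
type-I error at `α = 0.05` over 500 uniform patterns, power > 0.9 against a
10-fold posterior hotspot over 200 patterns (200 permutations per test there;
10 000 is the CLI default for single analyses).

## Known limitations

* One spatial dimension, no cell–cell phase coupling, no oscillator noise, no
  gene-regulatory implementation, and no fitting of `A`, `B`, `T0` to images.
* The linear growth law is built in; `domain_length` is the single point of
  change for other laws, but the closed-form oracles assume linearity.
* The age-variant progress zone is a sharp boundary; cells present before
  `t = 0` outside the zone are assigned age 0 at `t = 0`.
* The zone test treats nuclei as exchangeable under the null; clustered
  labelling would require a spatial-dependence-aware null.
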