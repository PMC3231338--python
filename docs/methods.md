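# Methods

## The oscillator

Each image pixel is represented by a two-variable relaxation oscillator
built from saturating (tanh) transconductances:

    C1 dV1/dt = I_A tanh(a V1) - I_B tanh(b V1) - I_C tanh(c V2) + I_T
    C2 dV2/dt = I_D tanh(d V1) - I_C tanh(c V2)

V1 is the fast excitatory variable, V2 the slow inhibitory one.  With
I_A < I_B and a > b the fast-branch current I_A tanh(aV1) - I_B tanh(bV1)
is N-shaped; with C2/C1 >> 1 the system is fast-slow and, at suitable total
excitation I_T, orbits a relaxation limit cycle: V1 jumps abruptly between a
silent (V1 < 0) and an active (V1 > 0) branch while V2 drifts slowly.  The
binarized output V3 = [V1 > 0] is the cell's digital activity.

Defaults (the 0.35 um design point): I_A = 1.2, I_B = 2, I_C = 2, I_D = 2 uA;
a = 10, b = 2.44, c = 2.44, d = 500 V^-1; C1 = 0.05 pF, C2 = 1.1 pF.  All
computation uses the V / uA / pF / us unit system, in which uA/pF = V/us, so
the printed constants are used verbatim.  At the isolated-object-pixel
operating point I_T = -1.5 uA the model oscillates with settled amplitude
max|V1| ~= 0.52 V (design value 0.5 V) and period ~= 4.2 us, with an active
fraction of ~6%.

The oscillation amplitude is defined *operationally*: long integration,
discard the first half, take max|V1| (`amplitude_oracle`).  A closed-form
amplitude expression exists for this oscillator family, but the candidate
algebraic readings we tried disagree with the simulated amplitude by more
than 5%, so no closed form is exposed; the oracle is the definition.

### Supply-rail clamp

The oscillator equations alone are unbounded for strongly negative drive:
for
I_T < -(I_B - I_A) - I_C = -2.8 uA (every background pixel, at -3.5 or
-3.72 uA) the fast equation has no fixed point and V1 would ramp to
-infinity at ~14 V/us.  Physical node voltages cannot leave the supply
rails, so the integrator clamps both state variables to +/-1.5 V (3 V
supply, mid-rail reference).  The clamp never engages during normal
oscillation (|V1| < 0.55 V, |V2| < 0.9 V on the limit cycle); it only pins
hyperpolarized background cells.

### OTA transfer

The voltage-to-current blocks are operational transconductance amplifiers.
The exact transfer inverts the alpha-power differential-pair relation

    V_r(I_o) = ((I_sat + I_o) L_EFF / (2 W B))^(1/n)
             - ((I_sat - I_o) L_EFF / (2 W B))^(1/n)

numerically (bisection; the relation is monotone) on (-sigma, sigma) and
clamps to +/-I_sat outside, where sigma is the saturation voltage implied
by the pair parameters at I_o = +/-I_sat.  A single-tanh approximation is
provided whose slope at the origin is matched to the exact curve
(gain-matched); its worst deviation over the linear range is ~17% of I_sat,
near saturation.  No specific device geometry is normative for the
behavioral model; the defaults (n = 1.5, I_sat = 1 uA, sigma ~= 0.3 V)
describe a representative 0.35 um pair.

## The network

`build_network` assembles an HxW grid (one cell per pixel) plus one
auxiliary oscillator Os.  Per-cell total excitation follows

    I_T = I_out + I_F [any 4-neighbor active] - I_GI [GI active] - I_E

with I_out = +I_G for object pixels, -I_G for background, and defaults
I_G = 1, I_F = 0.8, I_GI = 0.22, I_E = 2.5 uA.  Consequences of the
operating points, all verifiable from the numbers above:

* isolated excited cell: -1.5 uA -> oscillates freely;
* excited cell under global inhibition: -1.72 uA -> parks at a stable
  silent-branch point (this is what holds other groups back);
* excited cell with an active neighbor: -0.92 uA even under inhibition ->
  no silent fixed point, the cell is forced to jump (recruitment beats
  inhibition, which is what synchronizes an object);
* background: -3.5/-3.72 uA -> pinned at the rail, never active.

The synapse is OR-gated (a single switched current source per cell): one
I_F regardless of how many neighbors are active.  The global inhibitor is
binary: active exactly when at least one grid cell has V1 > 0, with
Hev(0) = 0.  Os is excited, has no neighbors, is inhibited by GI but does
not drive it; its free cycles mark complete segmentation rounds and are
used as the readout clock and for object counting.

### Integration

Explicit fixed-step RK4 at dt = 2e-4 us (the stiffest linearized rate is
I_D d / C2 ~= 909 /us, so the stability bound is ~3e-3 us; the default is
~15x below it).  Coupling terms (neighbor V3, GI) are evaluated from the
previous accepted step and held through the four stages - a one-dt latency
that mimics physical gate delay and breaks the algebraic loop between
cells.  Halving dt changes amplitude and period by well under 0.1%.
Free-frequency measurements in the tuning loop use dt = 5e-4 us: still ~6x
below the stability bound, and only frequency *consistency* across cells
(all measured at the same dt) matters there.

Initial conditions: every cell starts at V1 = -0.5 V (silent branch) with
V2 = -0.55 V plus seeded uniform jitter of +/-10% of the settled V2 swing
(0.72 V).  The chip's power-up phases are uncontrolled; the seed makes runs
reproducible.

### Residual dispersion (why the default network is not mathematically ideal)

A grid of *exactly* identical oscillators has a degenerate symmetry: two
object groups whose lead cells pass the jump-up knee within the short
escape window of the global inhibitor fire together, and since their
subsequent dynamics are identical they remain phase-locked forever -
merged labels that no amount of settling repairs.  We observed exactly
this on crowded synthetic images.  Real hardware is never ideal: after the
tuning procedure the chip retains a residual free-frequency spread up to
the tuning tolerance (0.5%).  `simulate()` therefore applies a seeded
multiplicative dispersion (relative SD `residual_sigma`, default 0.005) to
the five bias currents of every grid cell (Os stays nominal as the
reference).  That small diversity lets coincidentally merged groups drift
apart within a few cycles while leaving every per-cell operating point
unchanged to first order.  `residual_sigma=0` recovers the strict
idealization for study.

### Stop rule and settling

By default a run ends when Os completes 3 active phases (or at
t_max = 50 us).  Three phases suffice for a single object; when several
groups start near-coincidentally the time-multiplexed order can need a few
more global-inhibitor cycles to shake out, so segmentation-quality runs
(the tiled pipeline and the test suite) use 6-9 Os phases.  This is a
settling-time choice, not a different model.

## Synchrony readout

Within the last complete Os cycle (onset to onset), cells with any
activity are clustered: two cells are linked when the Jaccard overlap of
their active windows is >= 0.5, and labels are connected components of
that graph, numbered by first activation (ties broken by raster order of
the group's top-left member).  Because the global inhibitor keeps distinct
groups nearly disjoint in time, any threshold well inside (0.1, 0.9)
yields the same partition; 0.5 is the documented default.  A label must
name a 4-connected set of cells - an image object cannot be spatially
split - so a synchrony group that spans several disjoint pixel regions
(two objects caught firing coincidentally in the readout cycle) is divided
along spatial 4-connectivity before numbering.  Within an
object, activation spreads as a recruitment wave (~0.02 us per cell
layer), so distant members of a large object can overlap weakly while
every adjacent pair overlaps strongly - the connected-component closure is
what makes the readout robust for elongated objects.

Counting via Os: activation episodes (maximal intervals with any grid
activity) that start strictly inside the last complete gap between two Os
active phases are deduplicated by member-set overlap (Jaccard >= 0.5) and
the number of distinct groups is reported.  The deduplication guards
against a group firing twice when the Os gap slightly exceeds the group
cycle.

The independent ground truth for all of this is classic 4-connected
component labeling (`flood_fill_oracle`, scipy-based, relabeled in raster
order), which involves no dynamics at all.

## Mismatch and tuning

Fabrication mismatch is modeled as independent multiplicative Gaussian
perturbations (relative SD sigma_m, seeded) of the five bias currents of
each grid cell - current mirrors dominate mismatch in this circuit, so the
gains a..d and capacitances stay nominal.  At sigma_m = 5% the
free-frequency spread is several percent, which is enough to fragment a
20-pixel chain object: a fast cell fires out of phase with the recruitment
wave and the chain splits into multiple labels.

The tuning procedure measures free frequencies with synapses and global
inhibition off (I_F = I_GI = 0; the printed procedure's "I_H" is read as
I_GI, the only inhibitor weight defined), finds the slowest cell f_s at
k = 1, and bisects each cell's coefficient k in [0, 1] - frequency is
monotone in the input current, hence in k - until all free frequencies lie
within tol (default 0.5%) of f_s.  The input transfer is

    I_out = I_G tanh(g (3 V * k - 1.5 V)),   background fixed at -I_G.

The gain g is not printed; the default g = 5 V^-1 maps k in {0, 1} to
within 0.1% of -/+I_G.  If some cell is silent at k = 1, I_E is reduced in
2% steps (at most 10) first; the reduction also continues until the
slowest cell's frequency is at least a quarter of the median, because
tuning can only slow cells down and a near-stalled reference would drag
the whole network into a glacial regime.  Cells still silent at k = 1
after the cap cannot be tuned (k only attenuates) and are reported
unconverged with their residuals.  The auxiliary Os cell is retimed to the
same target f_s by a single-cell bisection (it has nominal parameters):
tuning slows the grid, and an untuned Os clock would tick several times
per group cycle, leaving readout windows with no group activation.

Tuning only ever lowers a cell's frequency toward f_s (k attenuates the
drive).  Under the bias-current mismatch model, chain fragmentation at
sigma_m = 5% is draw-dependent - synapse recruitment rescues most draws,
and roughly one seeded draw in five fragments - so the recovery check runs
a small seed ensemble, finds a fragmenting draw, and shows that tuning it
to 0.5% spread restores a single label.

## Tiled pipeline

Large images are processed as non-overlapping 32x32 tiles (ceil division;
remainder tiles zero-padded, padding marked background).  Grayscale input
is first smoothed with a Gaussian (sigma = 1 px by default) - pixel noise
shrinks by ~3.5x while spots of the radii of interest are preserved - and
then thresholded per tile with Otsu's method under dark-object polarity
(objects of interest are dark spots on a brighter field).  A tile is
declared unimodal (all background) when the Otsu split separates its class
means by less than 20 intensity units: raw between-class variance cannot
make this call because it scales with class balance, so a tiny genuine
spot scores no higher than broad noise or smooth texture, whereas the
class-mean separation cleanly ranks spot tiles (~30 units after smoothing)
above texture (~12) and noise (~5).  Each tile runs its own network (all-background tiles are
resolved without integration - background cells provably never activate).
Labels of fragments split across tile borders are merged by union-find
over 4-adjacent foreground pixels (4-connectivity matches the synapse
topology), and global labels are renumbered in raster order.  The report
carries per-tile counts and the simulated per-tile segmentation time (one
active-oscillator period, ~1-4 us); hardware image-load time is out of
scope.  Internally all coordinates are 0-based row-major; user-facing
reports are 1-based to match the chip's row/column convention.

## Synthetic fixtures

`synth` generates, deterministically under a seed: separated rectangles
and ellipses with constructive ground truth; a width-1 serpentine chain (a
simple path, diameter = length - 1); the documented three-object 32x32 row
pattern (foreground runs at 1-based columns 3-7, 11-17, 21-28 on rows
13-15 - only the row-run structure of the source image is reconstructible,
so only it is encoded); and a grayscale islet phantom (dark disks of
contrast 3x the pixel-noise SD on a bright field with smooth seeded
texture, default canvas 224x160).  Every generator's ground truth equals
4-connected flood fill of its own image by construction.

What the phantoms do *not* emulate: MR physics, partial-volume effects,
anatomy, intensity inhomogeneity beyond smooth texture.  Passing tests
show the pipeline recovers objects whose contrast and separation match the
fixture assumptions; they do not certify performance on clinical data.

## Problem sizes used in the checks

Single-oscillator quantities use 20 us runs (1e5 RK4 steps).  The worked
three-object example and the four-quadrant image run the full 32x32 grid;
oracle-equivalence sweeps use 20 seeded 16x16 images and the chain studies
a 20-pixel chain on a 16x16 grid, all at the default dt with 6-9 Os settle
phases.  These sizes exercise every mechanism (recruitment, inhibition,
readout, tuning) at full dynamical fidelity; only the grid area is smaller
than the chip's.

## Known limitations

* The simulator is behavioral: no transistor-level effects (charge
  leakage, supply droop, parasitic coupling) beyond the rail clamp and the
  residual dispersion.
* Counting via Os assumes the Os gap covers one full segmentation round;
  for object counts approaching the duty-cycle capacity the gap can clip a
  group, which the episode deduplication only partly compensates.
* Labels are defined by temporal synchrony alone; two objects that
  genuinely fire together (above capacity, or in the ideal zero-dispersion
  network) are reported as one.
* The Otsu floor is a heuristic; extremely low-contrast objects (below
  ~1.5x noise SD) fall below it and are reported as background.
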