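# Methods

This note documents the models, conventions and numerical choices behind
`beadqc`, the assumptions baked into its synthetic-data generator, and what
the passing test suite does and does not establish about real scanner data.

## Geometry and coordinate conventions

A section is modelled as independent hexagonal-lattice segments. Grid
position (row *r*, column *c*) has nominal centre

    x = origin_x + c * pitch + (r mod 2) * pitch / 2
    y = origin_y + r * pitch * sqrt(3) / 2

with pitch 6 px and bead radius 2.5 px by default (odd rows offset by half a
pitch; the true parity convention of vendor chips is unknown, so this is a
fixed choice, unverified against vendor files). All nearest-neighbour
distances equal the pitch, and the neighbour graph connects exactly the ≤6
lattice points at pitch distance: interior beads have degree 6, edges 2–5.

Continuous coordinates place **pixel centres at integer positions**: pixel
`(ix, iy)` of `image[iy, ix]` covers `[ix-0.5, ix+0.5) × [iy-0.5, iy+0.5)`.
The anchor pixel of a bead centre is `(floor(x), floor(y))`. This convention
was chosen because the fractional foreground weight law (below) then has its
weighted-window centroid *exactly* at the bead centre, and because it is the
convention under which a digitized bead measures brightest at fractional
offset zero — the behaviour expected of the real pipeline. Under the
alternative corner convention everything shifts by a constant half pixel;
no other result changes.

Two built-in layouts are provided: a 6-sample × 2-section expression chip
with 9 segments of 326 × 397 = 129,422 beads, and a 2-sample × 12-section
genotyping/copy-number chip with 4 segments of 333 × 443 = 147,519 beads.
Custom layouts are plain JSON.

## Intensity extraction

Extraction is a documented *dialect* of the vendor pipeline: the published
constraints are honoured but the exact vendor coefficients are not public.

* **Sharpening** — convolution with the unit-sum kernel `centre 5, −1 at the
  four edge neighbours, 0 at corners`, borders edge-replicated, output
  clipped at 0. Uniform images are fixed points. The kernel is exposed so an
  alternative dialect can be swapped in.
* **Foreground** — weighted average of the sharpened 4×4 window at columns
  `anchor−1..anchor+2` (same for rows). Column weights are `(1−f, 1, 1, f)`
  for fractional part *f* of x (rows analogously with *g*); the table is
  their outer product, normalised to sum 1. The centre 2×2 always carries
  the maximal unnormalised weight; at zero fraction the law degrades to a
  3×3 mean. A uniform 16-pixel mode provides the location-independent
  variant used to study the location/intensity feedback.
* **Background** — summary of the five lowest pixels of the *raw* image in
  the 17×17 window about the anchor pixel (the fractional part of the centre
  is deliberately ignored here). Rules: `mean5` (default), `median5` (3rd
  order statistic), `rank_k`, and a trimmed mean. `median5` and the rank
  rules are robust to the isolated abnormally-low pixels that scanners
  produce near saturated beads.
* **Intensity** = foreground − background; negative values are preserved and
  only masked later in log-domain summaries (reason `nonpositive`).

Beads whose 4×4 or 17×17 windows would leave the image are flagged
`out_of_image` and given NaN, never silently dropped.

A brute-force translation scan shows a pitch-6 lattice can place at most 12
centres inside a 17×17 px window, so background pixels are shared; masking
every bead's 4×4 foreground square out of the 289 candidates leaves
141–153 "true background" pixels for an interior bead on the nominal
lattice (fewer than the isolated-bead value of 273).

## Departure from the grid and remapping

Per segment, `P_x` and `P_y` are fit by least squares on the regressors
`(1, G_col, G_row, G_row mod 2)`; the parity regressor absorbs the
hexagonal half-pitch offset so that a perfect lattice — and anything affine
in the grid indices — fits exactly. The departure statistic is the Euclidean
residual norm `d = sqrt(r_x² + r_y²)`. The default flag threshold is 1 px
(configurable); beads with `d` of several pixels are being read at the wrong
feature, given 2–3 px bead radii and 6 px spacing.

Whole-segment mis-registration randomises the annotation, so the segment's
within-bead-type variance of log2 intensity is near its maximum; being one
row or column off is as bad as being ten off. The remapper exhaustively
scores every integer shift in ±`max_shift` (default 10), pairing the id
recorded at node `(r+Δrow, c+Δcol)` with the intensity observed at `(r, c)`,
using types with ≥2 replicates; the correct shift appears as a unique sharp
minimum. Correlation of type medians against a reference segment is
reported as confirmation, not used as the objective (the variance criterion
alone recovered 25/25 random shifts in ±8 in the acceptance suite).

Between-channel diagnostics compute per-bead red−green coordinate shifts, a
local median field (11×11 grid-coordinate window; robust to the sparse
wrongly-mapped beads it is meant to expose), a linear trend of shift versus
grid position whose slope is the signature of channels imaged at different
effective pixel sizes, and flags for beads whose shift deviates from the
local median by more than 2 px or whose red coordinates collide.

The simplified registration (`register_grid`) detects bright local maxima,
refines them to intensity-weighted centroids, and fits origin and pitch to
the hex model in two assignment/fit passes. It recovers origins to ~0.03 px
on clean synthetic images; it is not a reimplementation of the full vendor
registration and assumes the dimmest lattice rows are still detectable.

## Spatial phenomena

* **Non-decoded clusters** — seeds are non-decoded beads whose six
  neighbours are all non-decoded; flood fill from seeds over non-decoded
  beads yields maximal networks, kept at ≥50 members (the invasion process).
  Scattered decode failures have no seed and are ignored by construction.
  The halo is the decoded beads within `rings` graph hops (default 2; the
  real spatial extent of halos is unknown, so this is a parameter, not a
  claim).
* **Bright features** — threshold (default mean + 5 sd), connected
  components, keep mass ≥ 40 px and circularity `4πA/P² ≥ 0.8`, map the
  centroid to the nearest bead; the bead is flagged `bright_bead` and its
  lattice neighbours `bright_neighbour`. In rendered tests most neighbours
  of a saturated bead read ≥1 log2 above their type median; a minority can
  instead be *suppressed* by the clipped negative ring the sharpening kernel
  creates around a very bright spot — both directions corrupt the bead.
* **Low pixels** — pixels below 0.5 × the modal background (mode of the
  lower half of the intensity distribution). A bead is flagged only if the
  pixel falls in its 17×17 window *and* ranks among that window's five
  smallest, i.e. only when it actually enters the background estimate.
* **Twins** — under i.i.d. uniform assembly of N beads from T types with
  mean degree k the expected neighbouring same-type pair count is
  `N·k/2/T`; the permutation null shuffles decoded identities over decoded
  positions (non-decoded fixed), preserving the type multiset and the
  neighbour structure, with `p = (1 + #{null ≥ obs}) / (n_perm + 1)`. The
  twin flag is informational and excluded from the default summarization
  mask. The package measures twin excess; it does not model its cause.
* **Fractional-coordinate map** — mean (residual) log2 intensity over a
  theoretical pixel broken into bins×bins sub-bins of the fractional centre
  coordinates, for visualising the location/intensity association.

## Bead digitization study

An idealized bead is a sphere evenly covered in probes: under orthographic
imaging its flux density at in-plane distance d is `density·sqrt(r²−d²)`
(total flux `2/3·π·density·r³`; a Gaussian profile is offered as an
alternative). Digitization integrates this over each pixel by midpoint
quadrature on a ≥32× sub-grid and rounds to integers; the offset profile
digitizes the bead at each fractional offset of an n×n grid, sharpens,
computes the fractional-weighted foreground at the known centre, and
reports log2 values (log base 2 throughout; configurable).

For a radius-3 px bead at peak pixel ≈ 60,000 the log2 range across offsets
is ≈ 0.031 — comfortably inside the ≈0.2 bound expected for large bright
beads — and the range grows as the bead shrinks relative to the pixels
(0.104 at r = 2.5, 0.353 at r = 2.0 with 20×20 offsets). The growth is not
strictly monotone in radius: there are resonance dips where the bead
diameter matches the effective foreground window (the measured range at
r = 1.5 is 0.189, below the r = 2.0 peak), which is why the property test
asserts monotonicity over r ∈ {2.0, 2.25, 2.5, 3.0} plus the endpoint
comparison range(1.5) > range(3.0) rather than a strict chain through 1.5.
The argmax of the profile sits at fractional offset (0,0) throughout the
2–2.5 px regime typical of real beads; at r = 3 the whole profile varies by
only ~0.03 and the argmax location is not meaningful.

## Summarization and detection

Two-pass summarization first drops beads flagged by the diagnostics (plus
non-positive intensities), then applies a generic outlier rule within each
type — default `|v − median| > 3 × 1.4826 × MAD` on log2, with the
convention that a zero MAD flags any value unequal to the median; a mean ±
3 sd rule is available. Survivors' mean/median/sd are reported with full
bookkeeping (`n_used = n_total − n_masked − n_outliers`); a fully masked
type is reported missing, never zero. Removing a known-bad bead can tighten
the MAD bounds and expose further outliers — the mechanism by which the
two-pass analysis outperforms generic outlier removal alone. Detection
calls score each type by the empirical fraction of negative-control log2
values exceeding its summarized mean ("expressed" below α = 0.05,
configurable); the exact vendor outlier bounds and detection rule are not
public, so both are documented stand-ins.

The two-pass advantage is regime-dependent: with many replicates per type a
robust outlier rule already removes a small number of inflated beads, and
masking adds little. The advantage is decisive at per-segment replicate
counts (~3 beads/type), where a cluster halo can cover a majority of a
type's replicates and drag the median itself — then only masking recovers
the truth. The acceptance experiment uses that regime.

## Synthetic data: what it emulates, what it does not

The generator emulates: per-type log2 intensity levels (normal, mean 10,
between-type sd 1.5) with replicate noise (sd 0.2); a 2% decode-failure
rate, with non-decoded beads fluorescing at a low level (log2 ≈ 7)
independent of any type, since decoding failure says nothing about
hybridization; a Gaussian background floor (level 500, sd 10, clipped at 0
— real backgrounds have low variability); projected-sphere spots whose peak
flux density equals the bead intensity, integrated per pixel and added
linearly; and 16-bit rounding/clipping. Default segments are 60×60 beads
(~20 replicates/type); tests use 20×20–50×50 for speed, stated per test.

Injectable artefacts, each recording exact truth: non-decoded discs grown by
breadth-first search (halo beads within 2 rings brightened ×4 — the paper
reports the phenomenon, not a magnitude, so the factor is a config
parameter); near-saturation beads with enlarged spots; abnormally low
pixels; whole-segment grid shifts expressed either as displaced recorded
centres (`segment_shift`) or directly on the annotation (`id_scramble`);
per-bead centre jitter; and linear between-channel shift gradients.

Not emulated: scanner optics beyond the radial spot profile (no PSF,
depth-of-field or scan-direction effects), chip-to-chip batch effects,
spatially structured background, non-independent bead assembly (the twin
excess real arrays show), and the inter-segment physical gaps of a whole
chip (segments are independent images). Passing tests therefore establish
that the algorithms recover *known* ground truth under this model — they
bound algorithmic error, not the full messiness of real scans, and
real-data artefact magnitudes (e.g. the published per-section affected-bead
counts) are not reproducible without the original raw arrays.

## Numerical choices and degenerate inputs

Least-squares fits use `numpy.linalg.lstsq` (minimum-norm under rank
deficiency; collinear grid designs are rejected explicitly). The remap
variance uses the unbiased per-type estimator over types with ≥2 positive
replicates. Background order statistics use partial sorts. Digitization
quadrature error at 32× sub-sampling keeps total flux within 1% of the
closed form; rendered-image quadrature uses 8× (flux error ≪1%, dominated
by 16-bit rounding). Determinism: every stochastic component draws from a
`numpy` Generator seeded from the configuration or an explicit argument;
dataset writes are byte-identical for a fixed config. Ties: the remap
argmin takes the first minimum in scan order (observed profiles have a
unique minimum); `flag_outliers` on a single value returns no outliers;
empty bins/types propagate NaN rather than zero.

## Known limitations

* All dialect choices above (kernel, weight law, outlier bounds, detection
  rule, locs layout) are documented reconstructions, not vendor-verified;
  real vendor binaries (.sdf/.idat/.locs) are not parsed.
* `register_grid` reports the origin modulo the lattice if entire border
  rows fall below the detection threshold.
* The channel-shift local median uses a Python-level sliding filter;
  adequate to ~100×100-bead grids, slow beyond.
* Hex orientation/parity of real chips is unverified; segment gaps and
  whole-chip mosaics are out of scope.
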