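# Methods

This note documents the models, numerical choices and open design decisions
behind `fusvasc`, and what the synthetic phantoms do and do not show about
real microscopy data.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)`; the voxel at index `i` has its physical
centre at `i * spacing_um[axis]`. All physical quantities are micrometres;
pressures are kPa. Anisotropic spacing is assumed throughout (light-sheet
stacks at 0.97 × 0.97 × 5 µm, confocal at 0.27 × 0.27 × 3.43 µm are the
motivating geometries); every distance transform receives the per-axis
spacing. Connectivity is 26-neighbourhood in 3D and 8 in 2D. Every stage is
a pure function of its inputs and a seed.

## Synthetic phantoms (`synthgen`)

The phantoms trade anatomical realism for summary-statistic fidelity: the
contract is that the shipped tissue presets, pushed through the *measurement*
pipeline, recover the statistics they encode. The vasculature is a jittered
square grid of gently curved, near-parallel tubes (10 % positional jitter,
±3 % tilt, small sinusoidal bow); vessel diameters are lognormal, matching
the right-skewed diameter histograms of real brain tissue.

**Preset construction.** Per tissue the preset fixes the mean inter-vessel
(surface-to-surface) distance — GM 34.8 µm, WM 62.5 µm, tumor 43.5 µm — and a
lognormal diameter law (GM 5.2 ± 1.4, WM 4.9 ± 1.3, tumor 7.4 ± 2.3 µm, all
inside the reported per-tissue ranges). For a square grid of tubes with
spacing `c` and mean radius `r`, the mean of the vessel-distance field over
the inter-vessel midlines is `0.5739·c − r` (an exact line integral over the
Voronoi cell edge), so the grid spacing that realizes a target IVD is
`c = (IVD/2 + r)/0.5739`. The intravascular volume fraction then follows
geometrically as `π·E[r²]/c²`; `density_target` defaults to this value, and
with the diameters above the GM:WM density ratio comes out at the reported
3.2-fold. The GM:tumor density ratio is *not* a target: no parallel-tube
arrangement can simultaneously honour the tumor's printed spacing, its large
diameters, and a 3.1-fold GM:tumor density ratio, so the tumor preset keeps
spacing/diameter fidelity and lets density follow geometry. A calibration
loop (up to two audit passes rasterizing the candidate network and measuring
the IVD with the same ridge estimator used downstream) closes any residual
gap between the analytic spacing and the realized statistic.

**Channel rendering.** The vascular channel is background autofluorescence
(level 100, arbitrary units) with a 10× plateau inside lumina, blurred by an
isotropic Gaussian PSF (σ = 0.5 µm default) with additive Gaussian noise
(σ = 3, i.e. 3 % of background) clipped at zero. Photon statistics,
clearing artifacts, photobleaching and stitching are out of scope. The drug
channel outside the lumen is `bg · (1 + (E − 1) · g(d))` where `E` is the
condition-specific enhancement factor, `d` the distance to the nearest lumen
surface and `g` a monotone decay profile; inside the lumen the intensity is
`1.5 · E · bg`, reflecting the reported intravascular brightening
(endothelial binding plus partial-volume effects). The plateau factor 1.5 is
a free default — the source data report no numeric intravascular:extravascular
ratio.

**Decay profile.** The default `g` holds its plateau and falls smoothly
(cubic smoothstep) through a transition band *centred* on the extravasation
extent, with full width 25 % of the extent. The centring is deliberate: the
measured quantity downstream is the supra-threshold signal front, and the
crossing point of any moderate data-driven threshold lies inside the
transition band, so the measured front tracks the extent parameter to within
±12.5 % regardless of where the threshold lands. A linear ramp (available as
`profile="linear"`) makes the front position threshold-dependent
(`front = L·(1 − (T−1)/(E−1))`) and provably cannot recover the encoded
extents together with the fold changes; it is retained, with an exponential
option, for sensitivity studies.

**Emission traces.** Baseline recordings are Gaussian around a nominal
amplitude; treatment-pulse noise is clipped at ±5 baseline SD, safely below
the 10-SD detection threshold, so "none" traces never trigger. Event models:
a single spike at a fixed pulse, or a spike whenever the commanded pressure
reaches a set point (evaluated by the controller at run time, closing the
feedback loop).

## Vascular morphometry (`vesselmap`)

**Preprocessing.** Slice-wise rolling-ball background subtraction (default
radius 25 in-plane voxels; the radius is not specified by the protocol),
percentile contrast anchoring at (0.35, 99.65) applied as an affine map with
only a lower clip — saturating the top of the histogram would move the Otsu
split, defeating the rescale's purpose — and in-plane Gaussian smoothing.
The quoted "radius 2 voxels" of the smoothing filter is read as 2σ, i.e.
σ = 1 voxel. For radii above 16 the rolling ball is computed as a separable
flat-window grey opening of the ball's diameter: it is exact for flat
backgrounds, never exceeds the image (a shrink-and-resample rolling ball
overshoots at vessel edges and poisons the residual), and is O(1) per pixel.

**Segmentation.** Global Otsu followed by removal of 26-connected components
below 27 voxels. A constant image raises a degenerate-threshold error.

**Diameters.** Per-voxel diameter = `2·EDT − 0.5·(in-plane voxel)` evaluated
on the 3D skeleton, where the EDT is the anisotropy-aware Euclidean distance
to background: the exact transform where the classical chamfer weights are
an approximation, and the half-voxel term corrects the voxel-centre bias of
the discrete transform (the nearest background centre lies up to half a
voxel beyond the true surface). Each lumen voxel inherits the diameter of
its nearest skeleton voxel; a *segment* is a skeleton branch between branch
points, and its representative diameter is the median over member voxels.
On digital cylinders of 3–16 µm at 1 µm voxels the estimate is within one
voxel of truth; on tilted tubes at anisotropic spacing the skeleton's
zigzag biases estimates low by up to ~15 %, a known limitation that does not
affect the class boundaries on the scales tested. Whether the original
protocol estimated diameters in 3D or slice-wise is unstated; this
implementation is 3D.

**Classification.** Capillary d < 5 µm, microvessel 5 ≤ d ≤ 10 µm (the
quoted "5–10 µm" read as closed at both ends), major d > 10 µm.

**Inter-vessel distance.** The tissue IVD is twice the mean of the vessel
distance field over its ridge. The ridge is detected as the Voronoi
boundary between influence zones of distinct lumen components — the
topographic crest of the field, robust against the spurious small local
maxima created by the discrete transform's staircase surface — with strict
axis-wise maxima as a fallback when the lumen is a single connected
component. Ridge voxels closer to the volume border than to their nearest
vessel are excluded (their true nearest vessel may lie outside the field of
view); if that guard empties the ridge the unguarded set is used as a
border-limited lower bound.

**Compartments.** Per voxel, with `D` the diameter of the nearest segment
and `IVD` the tissue inter-vessel distance: intravascular; PV
(0 < d ≤ 0.5·D); IVD25 (… ≤ 0.25·IVD); IVD50 (… ≤ 0.5·IVD); outside.
Boundaries are taken in ascending order, so bands may be empty for large
vessels; the five labels partition the tissue mask exactly, and no IVD50
voxel lies beyond half the inter-vessel spacing — the geometric ceiling on
measurable extravasation.

## Drug quantification (`drugmap`)

**Normalization.** Each slice's histogram is matched to the first slice
(countering depth fades; the reference is configurable), followed by a
gain-only contrast rescale — an offset-shifting stretch would distort the
background-relative fold changes — and σ = 1 in-plane smoothing.

**Thresholding.** Within each tissue mask the slice-wise rolling-ball
background is removed (default radius 50 in-plane voxels, large relative to
inter-vessel structures so broad extravasation plateaus are not absorbed
into the background), then an Otsu threshold is iteratively refined by
re-applying Otsu to the band between the background and signal class means
until it moves less than 0.5 intensity units (20-iteration cap, flagged if
reached). A single Otsu pass on a dominant-background histogram lands high;
the refinement converges downward to the background/signal boundary,
capturing faint extravasation. When the final threshold sits within 2
background SD of the background mean there is no separable signal peak: the
threshold is raised to mean + 3 SD of the whole tissue and flagged, so
background-only tissue reports < 2 % supra-threshold voxels instead of an
Otsu artifact. The background mean used to normalize fold changes is the
mean *input-scale* intensity of sub-threshold tissue voxels.

**Fold change.** Mean supra-threshold intensity divided by the background
mean, per (compartment × vessel class) stratum and in aggregate; empty
strata report fold change 1 with zero voxels. Sub-threshold extravascular
drug is absorbed into the background by construction.

**Extravasation distance.** Geodesic distance from the lumen through the
extravascular tissue (propagation cannot cross non-tissue voxels), computed
per slice by default — matching serialized-2D colocalization of anisotropic
stacks — with a 3D mode for isotropic phantoms. The reported mean is over
the *front* of the supra-threshold signal (supra-threshold extravascular
voxels bordering sub-threshold tissue), i.e. the extents of the extravasated
signal; a mean over all supra-threshold voxels is available
(`measure="all"`) but is a volume-weighted quantity roughly 0.6× the front
distance. Distances are capped at IVD50. On obstacle-free convex tissue the
geodesic front mean agrees with the Euclidean distance transform within one
in-plane voxel. Voxels within one z-spacing of the lumen may be
misattributed intravascular by slice thickness; no correction is applied.

**Per-class attribution.** Each measured signal voxel is attributed to its
nearest lumen segment (KD-tree over lumen voxels in physical coordinates);
exact ties resolve to the lower segment id. Attribution by nearest segment
rather than per-class mask dilation is a choice the protocol leaves open.

## Controller simulator (`fuscontrol`)

Defaults: 28 kPa baseline for 10 s, threshold = 10× the SD of the
mean-subtracted baseline amplitude, +8 kPa per event-free pulse at 1 Hz,
10 ms bursts, 120 s treatment, ×0.5 on the pulse after an emission reaches
the threshold, then hold — a literal reading of "reduced … and maintained";
a resume-ramp variant is available. Every consecutive pressure pair is
exactly one of {+8 kPa, ×0.5, hold}. No pressure ceiling is imposed by
default (none is stated); a configurable ceiling and a reporting-only skull
transmission derating (e.g. 73 %) exist. Grids above 9 targets are split
over two treatments with 300 s between sonication starts; targets are
interleaved within each repetition period, offset by one burst length. The
in-vivo steady-state pressure (~158 kPa) depends on real emission data and
is out of scope; the simulator's steady-state summary is the mean commanded
pressure after the first event, falling back (flagged) to the trailing half
of an event-free ramp.

## Statistics (`statkit`)

BH step-up and percent signal change are implemented from definition; the
data-driven significance threshold (the largest p declared significant) is
always an output of the procedure on the supplied p-values, never a stored
constant. Paired t, one-way ANOVA, Mann–Whitney U, Kolmogorov–Smirnov and
Pearson correlation delegate to scipy; the factorial GLM is OLS with
treatment-coded factors, all interactions, and Type II sums of squares
(I/II/III coincide on balanced designs; II is robust to mild imbalance —
the encoding used originally is unstated). Rank-deficient designs raise an
error naming the aliased terms.

## Problem sizes and what passing shows

Recovery tests run three seeded replicates per tissue at 64 × 176 × 176
voxels with (2, 1, 1) µm spacing — a volume holding ~25 GM or ~9 WM vessels,
chosen so a full cohort analysis stays interactive on a single core while
every vessel radius spans ≥ 2 in-plane voxels (the regime where rasterized
densities are faithful). At this scale the pipeline recovers GM IVD within
~4 %, the GM:WM density ratio within ~7 %, the GM fold change within ~7 %
and the WM extravasation distance within ~1 % of the preset targets.
Passing these tests shows the measurement chain is unbiased on data whose
generative process matches its assumptions (near-parallel tubes, flat
background, Gaussian noise); it does not certify performance on real
cleared-tissue stacks with stitching seams, depth-dependent scattering, or
connected vascular trees, where the single-component ridge fallback and the
rolling-ball radius become the sensitive choices.
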