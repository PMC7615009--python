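# Methods

This note documents the models and algorithmic choices behind `sparkline`:
what each pipeline stage assumes, which parameters matter and why their
defaults are what they are, what the synthetic generator does and does not
emulate, and the package's known limitations.

Conventions. Everywhere: axis 0 = time (scan lines), axis 1 = space; times
in ms from recording start, positions in µm from scan start; intervals
half-open `[start, end)`. Line scans are time-dominant (thousands of lines,
~hundreds–1024 spatial pixels), so the reader's "auto" orientation takes
the longer file axis as time, with an explicit override for unusual
geometries.

## 1. Baseline, normalisation, noise scale

The resting fluorescence F₀ varies along the scanned line (dye loading,
cell edges, optics) and slowly in time (bleaching, drift). The model is
multiplicative and separable: `F0(t, x) ≈ d(t)·c(x)` with `d` slowly
varying and mean 1.

Per spatial pixel, the temporal mean and SD are computed, lines brighter
than `mean + baseline_exclusion_z·SD` (default z = 2) are excluded, and the
statistics are recomputed — two passes, so release events do not inflate
F₀. The per-column baseline `c(x)` is smoothed along space with a 0.3 µm
Gaussian. A heavier smooth (≈1 µm) was tried first and rejected: sharp
background bands are then misfit at their edges, leaving standing F/F₀
ridges that downstream detection happily reports as events all along the
recording. With thousands of lines per column the column estimate is
already low-noise, so only light smoothing is justified. The drift `d(t)`
is the 500 ms-Gaussian-smoothed trace of per-line medians over included
pixels, normalised to mean 1.

The noise scale σ (in F/F₀ units) is `1.4826 × MAD` of `F/F0 − 1` over
included (event-free) pixels — robust to residual events. Baseline
estimation is exactly idempotent on separable fixed points of the smoother
(e.g. constant images); on curved profiles a second pass attenuates the
profile further by the smoother's transfer function, which at the 0.3 µm
scale is a sub-percent effect.

Denoising is Gaussian with physically specified widths, default 0.2 µm ×
4 ms — below the scale of the smallest plausible spark (FWHM ≳ 1 µm,
FDHM ≳ 15 ms), so even dim sparks gain contrast rather than washing out.
σ is rescaled by the discrete kernel's white-noise factor `√Σk²` so the
z-image `(F/F0 − 1)/σ` keeps its calibration after smoothing.

## 2. Detection and scoring

Candidates are connected components (8-connectivity by default; sparks are
compact blobs and diagonal adjacency avoids fragmenting dim ones) of
`z > candidate_z` with `candidate_z = 2` — deliberately permissive, since
the score does the real rejection. Components below `min_event_area`
(1 µm·ms, ≈5 pixels at the default calibration) are dropped outright.

The score combines brightness and size:

    s = sqrt(s_b · s_a),   s_b = z̄/(z̄ + z½),   s_a = A/(A + A½)

with `z̄` the mean z over the object's brightest quartile of pixels
(robust to the thresholded tail) and `A` its area in µm·ms. Both terms are
monotone and saturate at 1, so the score lives on a stable [0, 1] scale on
which thresholds are transferable across recordings: 0.45 (sensitive,
default) and 0.6 (less sensitive). Defaults `z½ = 8`, `A½ = 30 µm·ms` were
set from the separation the denoised z-image actually offers: correlated
noise blobs reach brightest-quartile z̄ ≈ 2.5–3.5, while even near-invisible
sparks (ΔF/F₀ ≈ 0.1 against σ ≈ 0.05 raw noise) reach z̄ ≈ 10 after
denoising. A half-saturation constant of 3 would put all objects on the
flat part of `s_b` and let noise blobs pass on size alone; `z½ = 8` keeps
the brightness term discriminative exactly in that regime.

Classification uses the contiguous half-maximum extent of the object's
max-projection profiles around their peaks: width ≥ 25 µm → wave; width in
[8, 25) µm → miniwave; narrow but half-max duration ≥ 150 ms → long spark;
else spark. Contiguity is essential: a cluster of separate sparks dips
below half max between peaks, so its measured width stays spark-scale and
it remains eligible for splitting, while genuine propagating release is
contiguous and measures wide. Classification precedes splitting, and wave-
and miniwave-class objects are never split — large events must not be
fragmented into pseudo-sparks.

## 3. Cluster splitting

Within each spark-scale component, markers are the h-maxima of the
(denoised) ΔF/F₀ image with prominence

    h = min(split_min_prominence, max(0.10 · peak ΔF/F0, 2.5 σ))

i.e. a relative criterion — bright spark pairs separate on a ~10% dip —
floored at 2.5× the denoised noise SD so noise cannot seed markers, and
capped by the configured absolute prominence (0.3 ΔF/F₀). Markers closer
than the anisotropic ellipse `(Δx/1.2 µm)² + (Δt/12 ms)² < 1` are
suppressed brighter-first; the survivors seed a watershed on −ΔF/F₀
restricted to the component. Children partition the parent exactly (pixel
conservation), are re-scored and re-classified, and sub-threshold children
are dropped. Separation defaults of 2 µm / 20 ms were tried first and
rejected: adjacent release sites sit 1–2 µm apart, and couplets at those
distances — which the generator produces on purpose — were systematically
left merged; 1.2 µm / 12 ms resolves them while h-maxima still prevent
double markers on a single smooth spark.

## 4. Event measurement

The event trace averages F/F₀ over the event's spatial window for each
line of its (20 ms-padded) time window, excluding pixels labelled as other
events; lines with no admissible pixel are undefined. Amplitude is the
trace peak minus 1 — note this is a *spatially averaged* amplitude,
systematically below the centre-pixel ΔF/F₀ (a Gaussian profile averaged
over its support retains ~40% of its peak). FDHM is the contiguous region
around the peak above `1 + amplitude/2`, with linear interpolation of the
two boundary crossings; FWHM analogously on the spatial profile through
the peak line. Full duration and width are the segmented object's
bounding-box extents — the object boundary already sits at the detection
threshold, so "full" means "to the detected edge", not to an extrapolated
zero. Single-pixel events are flagged degenerate.

The decay constant comes from least squares on `A·exp(−t/τ) + C` over the
post-peak trace up to the event end plus 20 ms, initialised at
`A = y₀ − y_end`, `C = y_end`, `τ = window/3`, retried with τ multipliers
{1, 0.3, 3, 0.1, 10}; fewer than 4 samples, a non-decaying trace, a
non-positive fitted A, non-convergence, or τ outside `(0, 10 × window]`
all yield "undefined" rather than a number. Downstream analyses that pool
τ conventionally exclude values above 120 ms as likely mis-segmentations
or fit failures.

Summaries report per-class counts, `spark frequency =
100 · n_sparks / (scan length µm · duration s)` (spark class only by
default; a flag merges long sparks in), and median + IQR per feature with
linear quartile interpolation, ignoring undefined values.

The latency map assigns each pixel the time since the end of the latest
event pixel within a spatial radius (1 µm default) at earlier times,
clamped at 0 inside events; pixels with no preceding event carry their own
time coordinate and are flagged invalid.

## 5. Refractoriness test

For each wave/miniwave, a box spans the event's spatial extent and the
150 ms after its end; sparks whose peak falls inside are counted and
converted to a frequency. Matched controls are same-size boxes placed
uniformly at random (5 per wave, averaged), rejected if they intersect any
wave or its follow-up window. The per-wave (post, control) pairs enter a
paired t test computed in closed form, two-sided p from the t
distribution. The control sampler draws from an RNG stream keyed as
`(seed, constant)` — distinct by construction from any generator stream
seeded with the same integer, since a replayed placement sequence would
put control boxes exactly on generated events. With ~1 expected spark per
box the counts are Poisson-skewed and the t test runs slightly
anticonservative (null rejection ≈ 5–10% at n = 20 waves); the suppressed
alternative separates by many orders of magnitude in p.

## 6. Synthetic generator

One image is built as: uniform background level (300–800 counts) → 2–6
dark/bright spatial bands (Gaussian cross-profiles, ±80 counts) →
per-column gain jitter (±3%) → 0–2 repetitive spark bands (one column
position, a rescaled reference spark repeated aperiodically with ±30%
intensity variation) → 2–6 couplets (second member at a random angle and a
tight 1.5–3 µm distance, temporal component scaled at 10 ms/µm) → 30–100
isolated sparks with an elliptical minimum separation (2 µm, 40 ms) →
multiplicative combination `background · (1 + Σ ΔF/F0)` → Gaussian noise
(SD 15–40 counts) → 12-bit clipping (clipped fraction logged). Placement
failures raise; counts are never silently reduced.

Spark shapes are parametric — spatial Gaussian (σ 0.5–1.1 µm) times
`(1 − e^{−t/τ_rise})·e^{−t/τ_decay}` (rise 2–6 ms, decay 15–40 ms),
truncated at 1% of peak — rather than a library of recorded shapes; the
template interface accepts a user-supplied stack so empirical shapes can
be dropped in. Amplitudes span 0.1–1.0 ΔF/F₀ against a raw noise floor of
σ ≈ 0.03–0.08 F/F₀, so the dimmest sparks are genuinely at or below
visibility — a detector comparison on these images measures false-negative
behaviour, not just the easy bright events. The ground-truth mask holds
one label per placed spark (couplet members and band repeats individually);
where supports overlap, a pixel belongs to the spark contributing the
larger template value. Canvas defaults mirror common mouse ventricular
imaging: 2604 lines × 1024 px, 1.92 ms/line, 0.1 µm/px, 12-bit.

What the generator does *not* emulate: waves and long sparks (spark-only
by design, so spark-detection benchmarks stay interpretable), detector
shot noise statistics (noise is additive Gaussian, not Poisson),
photobleaching drift, cell boundaries and off-cell regions, and motion.
Passing closed-loop benchmarks therefore demonstrates correct machinery
and sensible sensitivity on plausible data — not performance bounds on any
particular microscope's output.

A second, pixel-free generator produces event *layouts* (waves plus a
homogeneous Poisson spark field, optionally suppressed for 150 ms after
each wave within its spatial extent) for exercising recording-level
statistics at scale without rendering images.

## 7. Evaluation

Dice is computed on pixel sets; edges at Dice ≥ 0.15 enter a bipartite
graph and a maximum-cardinality matching (Hopcroft–Karp via networkx)
yields TP (matched), FN (unmatched ground truth), FP (unmatched
predictions). The counts are invariant to which maximum matching is chosen;
pair lists are reported in label order for determinism. This charges over-
and under-segmentation correctly: two true sparks covered by one predicted
blob cost exactly one false negative. The matcher is verified against an
exhaustive-search oracle on hundreds of random small instances. Agreement
is `TP/(TP+FP+FN)`, symmetric under swapping roles. For detectors that
emit only bounding boxes, the inscribed ellipse (pixel-centre test)
produces comparable pixel sets.

Autofit maximises mean agreement across image/reference pairs: the initial
parameters are always evaluated first (so a reference generated by the
detector itself is reproduced exactly with any budget ≥ 1), then a seeded
random search over the supplied bounds, then coordinate refinement with a
shrinking step. Deterministic given seed and budget.

## 8. Pseudo-line scans

Frames are Gaussian-blurred (σ = 1 px), 3×3 mean-smoothed, and
background-subtracted with a 25 px rolling ball; the stack is then sampled
along the user polyline at unit spacing (bilinear interpolation, thickness
1), frame index becoming time. Sample points include the first vertex and
every spacing step up to and including the final vertex's arc length. A
warning (not an error) fires when consecutive segments double back within
5 px, which would sample a single event twice. Reslicing is linear in the
stack, so intensity calibration survives.

## 9. Benchmark problem sizes

The packaged benchmarks run the full-frame geometry scaled to a 1024 × 512
canvas (≈2 s × 51 µm) with 20–40 sparks per image — density preserved —
with 10 images for the high-amplitude (ΔF/F₀ ≥ 0.8) recall/precision
check, 30 images for the sensitive/less-sensitive threshold comparison,
and 100 event-layout runs for the null calibration of the refractoriness
test; per-image seeds derive from one master seed via `SeedSequence`.

## 10. Known limitations

* Amplitude is trace-based (spatially averaged); centre-pixel ΔF/F₀ is
  systematically higher. Users comparing against centre-pixel conventions
  should rescale or extract profiles directly.
* The spark frequency denominator is the full scanned length; restricting
  to the cell's extent is the user's responsibility (crop first).
* Couplets closer than the marker-suppression ellipse (1.2 µm / 12 ms) are
  not split; at those distances the events overlap so heavily that even
  the ground-truth masks share pixels.
* The wave/miniwave width thresholds (25 / 8 µm) are field conventions,
  not fitted quantities; recordings from cells of very different size may
  need different values.
* The paired refractoriness test is mildly anticonservative at low spark
  counts per box; with few waves or very low spark rates its p-values
  should be read qualitatively.
* TIFF calibration metadata is read only from this package's own JSON page
  description; for foreign files, calibration must be given explicitly.
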