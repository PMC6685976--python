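# Methods

This note records the models, parameter choices and numerical
conventions behind flickermap, and what the synthetic benchmarks do and
do not establish about real data.

## Conventions

Pixel indices are 0-based with x = column, y = row; a subpixel
localization (x, y) lives on the pixel-center continuum (pixel (i, j)'s
center is (x=j, y=i)), and physical coordinates are pixel coordinates ×
`pixel_size` (µm). Frame k spans [k·Δt, (k+1)·Δt); event times are
reported both as frame indices and seconds. TIFF metadata is never
trusted: frame interval, pixel size and camera black level always come
from explicit arguments or the run configuration, because acquisition
software tags are unreliable in practice. All stochastic operations take
an explicit seed (default 0).

## Flicker detection

**Preprocessing.** The ratio movie is (F − black)/F₀ with F₀ the
per-pixel mean of (F − black) over the first `baseline_frames` frames
(default 100; typical practice uses the first ~50–100 frames of a
recording made before stimulation). Pixels with F₀ ≤ ε are flagged
invalid once and excluded from every downstream statistic. Drift and
photobleaching are removed with a high-pass Butterworth filter along
time — default order 2, cutoff 0.1 Hz at the ~9.5 frames/s acquisition
rate, which removes minute-scale trends while passing events lasting up
to a few seconds. The filter is applied forward–backward (zero phase) so
event onsets are not shifted; this costs nothing at desk scale and
avoids a frame-rate-dependent group delay. Each pixel trace is then
divided by its own baseline standard deviation (sample std, ddof = 1),
after which pure noise is N(0, 1) per pixel by construction — the
property the acceptance script verifies.

**Thresholding.** Each normalized frame is smoothed with a Gaussian
(σ = 1 px default; the spatial scale of a flicker is set by indicator
diffusion and optical blur, a couple of pixels) and thresholded at
z = 3. Smoothing leaves genuine events (which are spatially extended)
well above threshold while suppressing single-pixel noise excursions,
so the false-positive rate at these defaults is far below one event per
10⁶ voxels.

**Density-peak clustering.** For every supra-threshold voxel, ρ counts
supra-threshold voxels inside an ellipsoid of radii (r_t, r_y, r_x) =
(3 frames, 2 px, 2 px) around it (self included; boundary membership is
closed with a 1e−9 tolerance so integer offsets landing exactly on the
surface count). δ is the distance to the nearest *denser* voxel in the
ellipsoid-normalized metric d = √((Δt/r_t)² + (Δy/r_y)² + (Δx/r_x)²).
"Denser" is defined through the deterministic total order
(ρ desc, t, y, x): with integer densities, exact ρ ties at a blob's
peak are common, and defining δ against strictly-greater ρ only lets
*both* tied voxels inherit a large δ from some distant event — a single
blob then spawns duplicate cluster centers (we measured detection
precision dropping to ~0.67 from this alone). Ranking tied voxels is
the classic ordering convention for density-peak clustering and keeps
exactly one peak per blob. The unique first voxel in the order gets
δ = max pairwise distance; a singleton volume gets δ = 1 (one ellipsoid
radius), which can never seed a center at default thresholds. Distances
are compared after the square root, where summation-order differences
of d² in the last ulp collapse, making tie-breaks reproducible across
evaluation orders.

Centers are voxels with ρ > 8 and δ > 2 (defaults chosen on the
synthetic suite; the ρ–δ table is exported so thresholds can instead be
picked by eye from a decision plot, which is how the analysis is done
interactively). Every other voxel recursively joins the cluster of its
nearest denser voxel; chains that terminate at a non-center peak remain
unclustered; clusters below `min_cluster_size` (default 4) voxels are
discarded. The implementation computes ρ with a KD-tree and δ with a
chunked exact O(n²) pass; the test suite checks both against an
independent plain-loop enumeration on random volumes.

**Localization and amplitude.** The normalized movie is averaged over
the cluster's [t_start, t_end] and a symmetric 2D Gaussian
A·exp(−((x−x₀)² + (y−y₀)²)/2σ²) + B is least-squares-fitted in a window
of half-width 5 px around the cluster footprint's center of mass
(initialized there, with A = max − median, B = median, σ = 1.5 px).
If the optimizer fails or the center leaves the window, the centroid
falls back to the center of mass and the event is flagged. A symmetric
Gaussian is the default because flicker sources are point-like at this
resolution; an elliptical model adds parameters without improving
centroid accuracy at realistic SNR. Amplitudes are read off the *ratio*
movie (max ΔF/F₀ − 1 of the 3×3 ROI trace at the centroid during the
event), not the filtered movie, so they are comparable across
recordings and to raw-trace ΔF/F₀ values; the filtered movie's values
are in noise-σ units and depend on the filter settings.

Detection is invariant under multiplication of the raw movie by any
positive gain, because F/F₀ and the variance normalization both cancel
it; the suite tests this exactly.

## Puncta tracking

The DoG band-pass uses σ_small = 1 px and σ_large = 3 px, bracketing a
~1.3 px PSF. The default threshold is 5× the robust noise scale
(1.4826 × median absolute deviation) of the DoG image, replacing the
interactive threshold a user would set by eye. Particles are 8-connected
components with ≥ 3 pixels; each is refined with a symmetric Gaussian
fit *on the DoG image* (background is already removed there, so the
offset only absorbs residuals) in a 9×9 window, initialized at the
binary center of mass.

Linking uses the 3-px consecutive-frame rule with greedy
ascending-distance matching and deterministic tie-breaks; there is no
gap closing and no motion model, so a missed detection splits a track
rather than bridging it — conservative for diffusion estimation. The
ensemble MSD uses overlapping start times (all displacement pairs) by
default, which maximizes statistics at the cost of correlated pairs; a
non-overlapping mode (`overlapping=False`, lag-k pairs spaced k frames
apart) gives independent displacements and honest per-lag SEMs at the
cost of fewer pairs. Both give the same expected MSD.
D = slope/4 from an OLS line with intercept through the first 10 lags;
the intercept absorbs the static localization-error offset
(4σ_loc²), which otherwise biases D when forced through the origin.

The synthetic benchmark simulates Brownian motion at D = 0.067 µm²/s —
a typical membrane-protein mobility — at the tracking rig's acquisition
constants (0.1 s/frame, 0.16 µm/px), rendered as Gaussian PSFs
(σ = 1.3 px) at SNR 10 with Gaussian noise. The acceptance check pools
60 movies of 88 particles × 16 frames (≥ 5000 tracks, ~100k
localizations) and requires D recovered within 10%; this problem size
keeps the check under two minutes while leaving the statistical error
well below the tolerance. Motion blur within an exposure is not
simulated (positions are rendered at frame instants), so the benchmark
does not probe blur-induced MSD bias; on real data the intercept also
absorbs part of that term.

## Force maps

Backgrounds are subtracted per channel with negatives clamped to zero;
pixels with A + D below `intensity_floor` are invalid (default floor:
5× the background noise estimate when available, otherwise 0 — dim
pixels produce index estimates dominated by noise). The efficiency
equation's denominator α(γ − FRETᵢγ + FRETᵢ) is validated pixelwise;
α = γ = 1 defaults are uncalibrated placeholders and a warning is
logged whenever they are used, since both are experimentally determined
per sensor batch. The calibration table must be strictly monotone with
force decreasing in efficiency (stretching the sensor lowers FRET);
out-of-range efficiencies are clamped to the end knots with a logged
count rather than extrapolated, because the calibration's tails are not
constrained by the table. A *synthetic*, non-physical linear table
(`synthetic_force_curve`) is shipped for testing only.

Force regions are segmented on the blurred (σ = 2 px) FRET-*index* map:
pixels below 75% of the maximum blurred intensity within the
valid∩cell support are force generating. Thresholding "below 75% of
max" is only coherent on a scale where low intensity means high force,
i.e. the index/efficiency scale; an option to threshold the blurred
computed-force map *above* a fraction of its max is provided
(`source='force'`) for sensitivity analysis. The blur is a normalized
(masked) convolution so invalid pixels do not bleed into the support.
The reference maximum is taken within the cell mask when one is given,
else over the whole valid image. Only a translational registration
offset (bilinear) between channels is supported.

## Spatial statistics

Distances use the Euclidean distance transform of the region-mask
complement, sampled at centroids by bilinear interpolation; membership
is pixelwise, so any point whose containing pixel is in the mask is at
distance 0. Against a brute-force minimum over mask-pixel centers this
agrees within half a pixel (the transform's discretization). The null
draws points uniformly over cell-mask pixels with continuous jitter
inside the chosen pixel — uniform over the cell area — and is
reproducible given the seed. The experimental-vs-null comparison uses
the two-sample Kolmogorov–Smirnov test (asymptotic p), appropriate for
these skewed distance distributions; means per cell are reported
alongside, since pooled-KS and per-cell-mean views answer slightly
different questions and both are standard.

Square-geometry classification uses a border of width
w = `corner_fraction` × side (default 0.25, configurable — the region
partition is conventionally drawn rather than derived, so the fraction
is a free parameter recorded in every output): the four w×w vertex
squares are corners, the rest of the border strip is edge, the interior
is middle; with w = 0.25·side the area fractions are ¼, ½, ¼. The χ²
test (df = 2) uses area-proportional expected counts by default; an
equal-thirds expectation is available for sensitivity checks. Flicker
frequency is events/(cell area in µm² × duration in s), robust to cells
touching in the field of view.

## Synthetic data: what it does and does not emulate

The flicker generator builds black + F₀·drift·(1 + Σ events) + noise:
events are separable spatial Gaussians (σ = 1.5 px) × temporal kernels
with instant rise and exponential decay (τ = 0.3 s — fast-rise transient
kinetics typical of near-membrane Ca²⁺ events; the kernel is
pluggable), with additive Gaussian noise by default (matching the
detection chain's unit-variance noise assumption) and optional Poisson
shot noise and linear/exponential drift to exercise the high-pass
stage. Default scale: 200 frames of 128×128 px at 9.54 frames/s,
baseline 500 counts over a 100-count black level, noise σ = 20 counts —
so an event of peak ΔF/F₀ = a has peak z ≈ a·500/20 after
normalization, and the implanted-z ladder {3, 5, 8, 15} spans
sub-threshold to obvious. Ca²⁺-imaging pixel size defaults to 0.1 µm/px
(a realistic high-NA TIRF scale; the acquisition pixel size of that rig
is not otherwise pinned down).

What passing these benchmarks shows: the chain's arithmetic, the
clustering's segregation behavior, localization accuracy versus SNR,
linking and MSD estimation, the FRET equation round trip, and the
spatial statistics are all correct under the stated noise model. What
it does not show: robustness to structured baselines (organelles,
uneven illumination beyond smooth F₀ maps), correlated camera noise,
overlapping-event kinetics beyond the tested 12-px separation, sensor
photobleaching during FRET acquisition, or anomalous (non-Brownian)
channel motion — real-data analyses should treat those as open
validation questions.

## Degenerate inputs and numerical edges

All-invalid ratio movies, empty cell masks, empty force-region masks
and track sets with no length-≥2 track raise a dedicated
degenerate-input error; an *empty detection result* is success, not an
error. Binary volumes with no supra-threshold voxel yield empty
statistics ("no events"). Fit windows clipped at image borders shrink
with a logged warning. Config files reject unknown keys loudly, listing
the offending key, so typos cannot silently run defaults.
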