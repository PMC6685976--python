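# flickermap

Tools for localizing cell-generated mechanotransduction events in TIRF
microscopy: automated super-resolution detection of Ca²⁺ flickers,
single-particle tracking of channel puncta with diffusion estimation,
FRET tension-sensor force maps, and spatial statistics relating flicker
locations to force-generating regions. A seeded synthetic-data module
generates movies and image pairs with ground-truth manifests, so every
pipeline is testable end to end without any experimental data.

## The problem

Mechanically activated ion channels such as Piezo1 open in response to
membrane tension, producing brief, spatially restricted Ca²⁺ influx
events ("flickers") visible near the coverslip in TIRF recordings of a
Ca²⁺ indicator. Relating these events to the traction forces the cell
itself generates requires four computational pieces, which this package
provides:

1. **Flicker detection** (`flickermap.detect`, `flickermap.cluster`).
   The raw movie F is converted to a ratio movie F/F₀ (camera black
   level subtracted; F₀ = per-pixel mean over the first ~100 baseline
   frames), high-pass filtered in time with a zero-phase Butterworth
   filter to remove drift and bleaching, and divided by each pixel's
   baseline standard deviation. Noise in this *normalized* movie is
   N(0, 1) by construction, so a global z-threshold on a spatially
   smoothed copy marks candidate voxels. Supra-threshold voxels are
   grouped by **density-peak clustering**: each voxel's density ρ counts
   neighbours inside a user-defined (t, y, x) ellipsoid, δ is the
   distance to the nearest denser voxel in the ellipsoid-normalized
   metric, cluster centers combine high ρ with high δ, and every other
   voxel joins its nearest denser voxel's cluster recursively. This
   segregates events that overlap in time or space, which plain
   connected components would merge. Each event's subpixel centroid
   comes from a symmetric 2D Gaussian fit to the mean normalized image
   over the event's duration; amplitudes are reported as ΔF/F₀ from the
   ratio movie at a 3×3 ROI around the centroid.

2. **Puncta tracking** (`flickermap.tracking`). Frames are band-pass
   filtered with a difference of Gaussians, contiguous supra-threshold
   pixels become particles, and a 2D Gaussian fit initialized at each
   blob's center of mass gives subpixel localizations. Localizations in
   consecutive frames within 3 px are linked greedily (no gap closing).
   The ensemble mean-squared displacement over all tracks and start
   times follows MSD(τ) = 4Dτ for 2D Brownian motion; an ordinary
   least-squares line through the first 10 lags yields the apparent
   diffusion coefficient D = slope/4, with the intercept absorbing
   static localization error.

3. **Force maps** (`flickermap.fret`). From registered donor (D) and
   acceptor (A) images of a molecular tension sensor, the FRET index is
   FRETᵢ = A/(A+D) (backgrounds subtracted), converted to FRET
   efficiency E = FRETᵢ / (α·(γ − FRETᵢ·γ + FRETᵢ)) where α is the
   fraction of donor-labeled sensors carrying an acceptor and γ the
   quantum-yield correction, then to force (pN per sensor) through a
   monotone-decreasing calibration table. Force-generating regions are
   segmented by blurring the index map and keeping pixels below 75% of
   the maximum blurred intensity (low FRET = high force).

4. **Spatial statistics** (`flickermap.spatial`). Distances from flicker
   centroids to the nearest force-generating region (via the Euclidean
   distance transform) are compared with a null of 1000 points uniform
   inside the cell outline, using a two-sample Kolmogorov–Smirnov test.
   For square micropatterned cells, flickers are classified into
   corner/edge/middle regions and tested against the area-proportional
   expectation with a χ² test (df = 2). Flicker frequency is reported
   per µm² of cell-covered area per second.

## Worked example

Generate a synthetic flicker movie with 12 implanted events, detect
them, then simulate and track Brownian puncta:

```sh
$ flickermap simulate flickers --seed 7 --n-events 12 --out-prefix fx/
12 event(s) -> fx/movie.tif
$ flickermap --quiet detect fx/movie.tif --black-level 100 \
    --frame-interval 0.1048 --out events.csv --decision-plot rho_delta.csv
12 event(s) -> events.csv
$ flickermap simulate puncta --seed 7 --out-prefix fx/p_
40 particle(s) -> fx/p_movie.tif
$ flickermap --quiet track fx/p_movie.tif --tracks-out tracks.csv --msd-out msd.csv
41 track(s), D = 0.06995 um^2/s (R^2 = 1.000)
```

All 12 implanted flickers are recovered; `events.csv` holds one row per
event with frame interval, subpixel centroid in px and µm, ΔF/F₀ peak
amplitude, cluster size and Gaussian-fit width:

```
id,t_start,t_end,duration_s,x_px,y_px,x_um,y_um,peak_amplitude,n_voxels,fit_sigma,fit_ok
0,177,179,0.3144,64.0156,69.1867,6.4016,6.9187,0.4634,47,1.5083,True
1,179,181,0.3144,76.8043,106.0074,7.6804,10.6007,0.4037,41,1.5194,True
...
```

`rho_delta.csv` is the ρ–δ decision table, so cluster-center thresholds
can also be chosen by eye from a decision plot. The tracking run links
40 simulated particles into 41 tracks (one broke at a missed detection)
and recovers D = 0.070 µm²/s against a ground truth of 0.067 µm²/s —
within the sampling error of a single small movie. The `forcemap`,
`spatial` and `squares` subcommands complete the chain from donor/
acceptor images to force-region masks and distance/χ² statistics; see
`flickermap --help`.

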