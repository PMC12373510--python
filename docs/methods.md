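# Methods

## Scope and measurement model

`elsquant` quantifies ectopic lymphoid structures (ELS) on calibrated
multi-channel immunofluorescence fields (DAPI plus a T-cell and a B-cell
marker).  The measurement chain is:

1. **Pixel classification** — one global intensity threshold per channel
   (inclusive `>=` by default, configurable), optionally derived by Otsu's
   method when no operator-assigned value exists.
2. **Geometry** — positive areas are pixel counts × pixel area; the T/B
   intersection is the logical AND (or, equivalently, the intersection of the
   polygonized regions — polygonization traces pixel boundaries, so the two
   routes agree exactly).
3. **Aggregates** — 8-connected components of the T OR B positive mask,
   filtered by a minimum area (default 500 µm², i.e. a few cells).
   8-connectivity is used so diagonal cell contacts do not split an
   infiltrate.
4. **Foci and scores** — an aggregate is an inflammatory focus when its
   lymphocyte count is *strictly greater than* 50;
   `focus_score = (n_foci / gland_area_mm2) × 4`;
   `aggregate_area_fraction_pct = 100 × aggregate_area / gland_area`.
5. **Segregation** — `index = 1 − intersection / min(T, B)` per aggregate;
   `index ≥ 0.5` (default) is called segregated.  The index is 1 when only
   one marker is present and undefined (excluded from prevalence) when both
   areas are zero.  The index, the threshold and all per-aggregate values
   are reported so alternative rules can be audited.
6. **Statistics** — two-sided Mann–Whitney U and Wilcoxon signed-rank tests,
   Spearman matrices with Benjamini–Hochberg adjustment, Grubbs outlier
   exclusion, ΔΔCt fold changes.

Two normalization regimes coexist, as in field-based practice: with no gland
annotation the evaluated area is the fixed field (1,229,054.6934 µm²) and
results are raw per-field areas/counts; with a gland polygon (GeoJSON, the
semi-manual perimeter path) scores are normalized to the measured gland
area.

"Peri-ductal" context is **not** checked: no duct channel exists in the
data model, so the focus rule is operationalized purely by lymphocyte
count.  This is a documented limitation, not a configuration option.

Focus scores in clinical practice are counted on H&E sections while areas
come from immunofluorescence; this package computes both from the
fluorescence channels.  The per-aggregate nucleus counts that drive the
focus rule are therefore approximations of a manual H&E count (see below).

## Coordinates and I/O

Pixel coordinates are 0-based, origin top-left, y-down.  Polygon vertices
lie on pixel corners, so mask→polygon→mask roundtrips are exact and polygon
area equals pixel count × pixel area.  Images travel as multi-channel TIFF
with channel names and pixel calibration in the image description
(tifffile "shaped" metadata); regions as GeoJSON FeatureCollections with a
`label` property (QuPath-export-style; the ImageJ binary `.roi` format is
not implemented).  Reading an uncalibrated TIFF requires an explicit
`pixel_size_um` override rather than guessing.

## Nucleus counting

Two estimators of the lymphocyte count inside an aggregate footprint:

- `peaks` (default): local maxima of the Gaussian-smoothed DAPI channel
  (σ = 0.5 × nucleus radius), restricted to the footprint, above half the
  local maximum intensity, then greedily suppressed to a minimum Euclidean
  separation of two nucleus radii.  Exact for well-separated nuclei
  (spacing ≥ 3 radii); undercounts densely packed infiltrates by a few
  percent as neighbouring peaks merge.
- `area_ratio`: DAPI-positive area inside the footprint divided by the
  nominal nucleus area (π r²), rounded.  Insensitive to packing but
  inherits raster discretization (a few percent).

Both are approximations; the focus rule is robust to them as long as
planted/real counts are not concentrated at the 50-cell boundary.

## The synthetic sialadenitis generator

`synthgland` emulates the imaging substrate, not the optics: no PSF, no
texture, no H&E appearance.  Defaults define the simulated study
conditions:

- **Field**: 1392 × 1040 px.  The pixel pitch (≈0.9214 µm/px) is derived
  from the fixed evaluated area of 1,229,054.6934 µm², which is the only
  calibrated quantity the protocol fixes; the grid itself is a free choice.
- **Aggregates**: 4 per field, 60–120 nuclei each (uniform), placed by
  bounded rejection sampling so aggregates never overlap each other or
  leave the gland; failure after 1000 retries raises an error naming the
  aggregate.  Nuclei are placed by dart throwing with a minimum spacing of
  2.2 nucleus radii (no overlapping nuclei) at a packing fraction of 0.35,
  well below random-sequential-adsorption saturation; a crowded cluster
  disc may grow by up to 1.5 spacings, and aggregate envelopes reserve that
  slack.
- **Nuclei and cells**: nucleus radius 3 µm (lymphocyte scale), stamped as
  filled discs into DAPI.  Marker signal is stamped over a *cell* footprint
  of 3 × the nucleus radius: membrane/cytoplasmic stains plus acquisition
  blur make the stained footprint substantially wider than the nucleus, and
  this is what produces realistic marker overlap between interdigitated T
  and B cells in non-segregated aggregates.  With a narrower footprint the
  T/B intersection of a mixed aggregate would be near zero and segregation
  scoring would be vacuous.
- **Identity and zonation**: each nucleus is T with probability
  `t_fraction` (default 0.6, a T-dominant infiltrate).  In `segregated`
  mode the T and B populations occupy two sub-discs whose centres are
  `separation_factor` × aggregate radius apart (default 1.2, which makes
  the zones abut — as T and B zones do in organized ELS — while remaining
  one connected infiltrate); `separation_factor = 2` produces fully
  disjoint zones, and `mixed` mode interleaves both identities in one disc.
- **Signal**: background 20, marker intensity 200 (arbitrary units),
  additive Gaussian noise clipped at zero (default off; 10% of the marker
  intensity in the noisy test conditions).

Ground truth (per-aggregate T/B/intersection/union areas, nucleus counts
and positions, segregation labels, focus count and score, gland area) is
measured from the noise-free label rasters themselves, never approximated
analytically, so truth and measurement share the same discretization.
Cohorts derive one sub-seed per (seed, group name, field index) via
`SeedSequence`, making every field reproducible independently.

What passing tests on this generator shows: the measurement chain recovers
planted areas, counts and labels under intensity-separable signal and
additive noise.  What it does not show: robustness to uneven illumination,
autofluorescence, staining artefacts, out-of-focus light, or touching
aggregates — real-data properties the generator deliberately omits.

## Statistics

Implemented from first principles with midranks for ties and two-sided
defaults throughout:

- **Mann–Whitney U**: exact permutation p by enumerating all
  C(n₁+n₂, n₁) labelings of the pooled midranks when n₁+n₂ ≤ 12 (valid
  with ties); otherwise tie-corrected normal approximation with continuity
  correction.  Two-sided exact p is the permutation probability of a U at
  least as far from n₁n₂/2 as observed.
- **Wilcoxon signed-rank**: zero differences dropped (Wilcoxon's original
  convention — the choice matters and is exposed); exact enumeration of 2ⁿ
  sign patterns when effective n ≤ 15, else tie-corrected normal
  approximation.  All-zero differences are degenerate: p = 1 with a
  warning.
- **Spearman matrix**: pairwise-complete midranked Pearson r; p from the
  t approximation (|r| = 1 → p = 0); Benjamini–Hochberg step-up applied
  over the strict upper triangle only (each pair tested once); undefined
  pairs (constant variable, n < 3) are NaN and excluded from the family.
- **Grubbs**: G = max|xᵢ − x̄|/s with the n−1 standard deviation;
  two-sided critical value ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n)
  Student-t quantile with n−2 d.f.  Single-pass by default; an iterative
  mode repeats on the reduced sample (both provided because protocols
  rarely state which was used).
- **ΔΔCt**: replicate wells averaged on the Ct scale first, then
  `2^−[(Ct_target−Ct_ref)_sample − (Ct_target−Ct_ref)_calibrator]`.
- Significance stars at 0.05/0.01/0.001/0.0001, as in figure legends.

scipy supplies only the t/normal distribution functions and `rankdata`;
the tests cross-check every exact path against independent brute-force
enumeration oracles and against scipy/statsmodels.

## Numerical and design choices

- Threshold boundary semantics are inclusive (`>=`) by default and
  configurable; mask clean-up (minimum object area, hole filling) defaults
  to off because the reference protocol reports none.
- Otsu is the unattended stand-in for an operator-assigned threshold, but
  it requires a signal class: on a marker-free noisy field it would
  threshold noise.  The pipeline therefore defaults to the staining
  midpoint (background + intensity/2) when it drives the simulator, and to
  Otsu for externally supplied images.
- The aggregate area fraction guards against aggregate > gland area
  (inconsistent segmentation) with a 1e−9 relative tolerance; exact-test
  tie comparisons use a 1e−9 absolute guard on midrank arithmetic.
- Problem sizes in the test suite: 20 glands per noise condition for
  end-to-end recovery, 26 fields (≈150 aggregates) for segregation
  accuracy, 2,000 null pairs at n = 10/group for the type-I check, 100
  random masks for polygonization — sizes at which every check is stable
  across seeds while the suite stays interactive.

## Known limitations

- No duct modelling: the "peri-ductal" qualifier of the focus definition is
  not verifiable from the data model.
- Nucleus counts are estimator-based; counts near the 50-cell focus
  boundary can flip focus calls.
- The simulator plants non-overlapping aggregates; merging/touching
  infiltrates (common in severe disease) are not generated, so aggregate
  splitting/merging behaviour is untested against truth.
- Whole-slide pyramidal formats and OME-XML are out of scope; fields are
  single-resolution TIFFs.
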