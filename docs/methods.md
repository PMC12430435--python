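# Methods

## Overview

`betelmap` maps an evergreen palm crop in two stages: a knowledge-based
forest mask from dual-pol SAR signatures plus a GNDVI refinement, then a
random-forest betel/non-betel classification inside the mask using
logistic-regression-ranked features. This note records the models, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical conventions.

## Preprocessing

**Cloud masking.** Optical dates carry a QA bitmask; bits 10 (opaque
cloud) and 11 (cirrus) follow the common L2A convention and are
configurable. A set bit voids all ten bands at that pixel. Masking never
revives a nodata pixel.

**Median composite.** Per pixel and band, the median over valid
observations across dates; an even count takes the mean of the two central
order statistics; zero valid observations yield nodata. The composite is
permutation-invariant in date order and the identity for a single date.
No gap-filling is attempted: the intended use is a time series already
screened to low scene cloudiness, so most pixels retain several valid
observations.

**Speckle filtering.** The classical edge-adaptive (refined) Lee filter,
default 7×7 window: the dominant gradient direction is found from the 3×3
grid of sub-window means, statistics are restricted to the edge-aligned
directional half-window, and the MMSE weight
`b = max(0, var − σ_v²·mean²)/var` blends the local mean with the center
pixel, `out = mean + b·(x − mean)`. The multiplicative-noise coefficient
of variation σ_v is estimated as the median local CV over the image —
robust because homogeneous regions dominate the median — and can be given
explicitly. Filtering operates on dB-scaled backscatter; the σ_v·mean term
makes the noise floor scale with the local dB level, which is
self-consistent with how the local CV is measured. Constant regions pass
through unchanged; variance on homogeneous speckle fields decreases
monotonically with window size.

## The 58-feature bank

24 SAR features: VV, VH (dB), the six dual-pol indices AVE, DIF, RAT1,
RAT2, NDI, NL, and eight GLCM texture statistics per polarization
(homogeneity, contrast, correlation, mean, variance, dissimilarity,
entropy, angular second moment). 34 optical features: the ten
surface-reflectance bands B2–B12 and 24 spectral indices computed on
reflectance scaled to [0, 1] (inputs divided by 10,000). NDMI and NDNS1
share a formula; both names are emitted so the registry holds exactly 58
entries. 20 m bands are resampled to the 10 m grid by nearest neighbour.

Numerical conventions:

- All ratio denominators are guarded: |denominator| < 1e−12 yields nodata.
- SAR indices are computed in the dB domain (the domain the class
  signatures are analysed in). Note that ratio/normalized-difference
  indices of dB values change sign conventions relative to linear power;
  the signature analysis is self-consistent because rules are derived and
  applied in the same domain.
- SATVI, MCARI and TCARI are implemented exactly as tabulated here
  (SATVI = (B11−B4)/(B12+B4+0.1)·1.1 − B12/2), which differs from some
  literature variants; this keeps one authoritative formula per name.

**GLCM.** Windows default to 5×5 (moving window), 32 gray levels
quantized over the robust 2–98 percentile range of the band (outlier
resistant; range can be fixed explicitly, which makes the statistics
invariant under constant shifts). Co-occurrence is symmetric at offset
distance 1 and the four standard orientations, each orientation's matrix
normalized to sum 1, and the eight statistics averaged over orientations.
Border pixels use edge replication. Zero-variance windows define
correlation as 0 (the formula is 0/0). The windowed engine is a numba
kernel that computes moment statistics from the symmetric pair list and
entropy/ASM by pair-equality counting; it is verified against a
brute-force pair-enumeration oracle and against `skimage`'s single-window
co-occurrence on random images.

## Knowledge-based forest mask

Signatures (histograms and p1–p99 percentile tables, linear interpolation
between order statistics) are computed per super-class — tree cover
(betel + natural forest + rubber), cropland, built-up, water — over the
eight dual-pol features, from training pixels only.

Rules: the tree-cover [p5, p95] envelope on {VV, VH, AVE, NL, NDI, RAT1}
forms six include intervals; water is excluded below the midpoint between
its p95 and the forest p5 on AVE and NL; built-up falls outside the
envelope caps (its backscatter exceeds forest p95 on AVE/NL). A pixel is
forest when at least `m` include intervals contain it and no exclusion
fires.

**Vote threshold default m = 2 of 6.** The include envelopes carry the
stage's sensitivity, not its specificity: each [p5, p95] interval removes
10% of the forest population by construction, and the six features are
strongly correlated (all are functions of VV and VH), so demanding many
simultaneous votes compounds those tail cuts into a double-digit recall
loss that spatial cleaning cannot recover (the speckle filter correlates
residuals over the filter window, so vote failures arrive in blobs, not
salt-and-pepper). Specificity is carried by the exclusion bounds (water)
and the GNDVI refinement (cropland, built-up). `m` is configurable and
mask area is monotone non-increasing in it.

The GNDVI refinement threshold is the 5th percentile of GNDVI over forest
training pixels (≥ 20 required); mask pixels below it become non-forest.
Refinement never adds forest and is monotone in the threshold. A 5×5 modal
filter (ties keep the center label; nodata ignored — the modal label
equals the median for binary maps) removes salt-and-pepper noise, and
8-connected components under 0.5 ha (50 pixels at 10 m) are dropped as the
minimum mapping unit. Canopy-cover and tree-height criteria of the FAO
forest definition are not observable from these inputs and are not
enforced.

## Feature ranking and selection

A binomial logistic model is fit by Newton/IRLS on z-standardized features
with an L2 ridge of 1e−4 (intercept unpenalized), convergence tolerance
1e−8 on the step norm; the ridge keeps coefficients finite under complete
separation or duplicated columns, with a convergence flag exposed.
Standard errors come from the inverse penalized Fisher information; the
unpenalized fit matches `statsmodels` Logit to high precision.

Importance is the absolute Wald statistic |β̂/SE| on the standardized
scale — scale-free, so the ranking is invariant under affine rescaling of
any input — with |β̂| available as an alternative. Top-k selection takes
the first k names, ties broken by registry order. `accuracy_vs_k` reports
a cross-validated accuracy curve over k and the plateau point (smallest k
within 0.5 percentage points of the curve maximum). A published 20-name
preset (`paper_top20`) ships for use on real data; its optical/SAR
composition is 12/8.

## Classifier

100 bagged decision trees, √p random candidate features per split, each
tree grown on a 50% row subsample drawn *without* replacement (the
bag-fraction semantics of the cloud-platform implementation this mirrors;
with-replacement is a config switch), minimum leaf size 1, unbounded
depth, seeded. Out-of-bag accuracy is computed from the stored per-tree
sample indices and agrees with held-out accuracy within a few percentage
points on synthetic data. Predictions are restricted to the forest mask:
non-forest pixels get the non-betel code and nodata propagates.

## Assessment

Confusion matrices are oriented rows = mapped, columns = reference; UA is
the row-diagonal share (1 − commission), PA the column share
(1 − omission), OA the trace share, and
kappa = (p_o − p_e)/(1 − p_e) with p_e from the margin products. The
implementation is verified against exact rational arithmetic on all small
2×2 matrices. Accuracy is always measured on the pre-post-filter map; the
5×5 modal post-filter only serves cartographic quality. Areas are pixel
counts × 0.01 ha (10 m pixels); regional aggregation assigns pixels to the
polygon containing their center; regional consistency is summarized by OLS
of mapped on reference areas (R², slope) and the relative difference
100·(mapped − reference)/reference.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes, at
the package's benchmark size of 256×256 pixels (10 m grid) with six
optical dates:

- **Geometry.** Poisson-scattered seeds grow into irregular connected
  patches (~220 px mean) mimicking smallholder fragmentation; class
  proportions are matched within ±5 points at benchmark size. Betel seeds
  prefer low ground on a smoothed random-relief DEM (0–250 m).
- **Optical.** Per-date, per-pixel Gaussian draws from class-conditional
  10-band means (7% CV, diagonal covariance) with 3% date-level
  multiplicative drift; clouds are spatially coherent blobs covering the
  configured fraction (default 10%) and flagged in the QA bits.
- **SAR.** L-look Gamma multiplicative speckle on class mean power,
  delivered in dB; L = 4 by default (GRD-like). A per-class effective-looks
  multiplier models canopy smoothness; betel gets 2×, rubber 1.3×, giving
  palms the higher GLCM homogeneity that helps separate them from natural
  forest.
- **Radiometry.** Class means encode the qualitative orderings the method
  exploits: backscatter water (−22/−28 dB VV/VH) ≪ cropland (−14/−20) <
  tree cover (−8.5 to −9 / −13.4 to −14) < built-up (−4/−9); tree-tier
  GNDVI ~0.73–0.75 well above cropland ~0.47; betel differs from other
  tree cover mainly in the green/SWIR balance (GCVI, STI, CIG) and SAR
  texture. Within-tier SAR contrasts are kept sub-dB, as typical of C-band
  over closed tropical canopies.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: mixed pixels and boundary gradients, young or
intercropped palms, coconut palms (the main real-world confuser),
topographic radiometric distortion, seasonal phenology, spatially
correlated reflectance noise, and geolocation error. The near-perfect
benchmark accuracies characterize the pipeline's correctness on its own
assumptions, not expected field performance.

## Data formats

Rasters travel as TIFF with the affine transform, CRS id and nodata
sentinel embedded as JSON in the ImageDescription tag; round-trips are
bit-exact. ROIs are GeoJSON feature collections with `class_code` /
`class_name` properties, rasterized by pixel-center containment
(deterministic; overlapping polygons of different classes are an error).
Sample tables and reports are CSV/JSON.

## Known limitations

- The interval-rule stage assumes the training super-classes span the
  scene's radiometric variability; rules derived from one region or date
  may not transfer.
- The GNDVI refinement presumes dense evergreen canopy; deciduous or
  stressed forest below the threshold is removed.
- The logistic ranking is marginal per-feature (given the others, under a
  linear log-odds model); strongly collinear feature pairs share their
  Wald evidence, which the ridge stabilizes but does not resolve.
- The mask's recall is bounded by the percentile-envelope construction
  (each include interval discards population tails); the vote threshold
  trades this against specificity.
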