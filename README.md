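# betelmap

Mapping evergreen palm plantations — specifically betel palm (*Areca
catechu* L.) — from dual-polarization C-band SAR (Sentinel-1-like VV/VH
backscatter) and 10-band multispectral surface reflectance
(Sentinel-2-like), for remote-sensing scientists working on smallholder
crop mapping in cloud-prone tropical landscapes.

Betel palm is a perennial evergreen without a distinct phenological signal,
grown in fragmented smallholder fields among natural forest, rubber and
coconut. The package implements a two-stage strategy:

1. **Knowledge-based forest delineation.** Backscatter signatures of four
   land-cover super-classes (tree cover, cropland, built-up, water) are
   analysed over training regions for VV, VH and six dual-pol indices
   (AVE = (VV+VH)/2, DIF = VV−VH, RAT1 = VV/VH, RAT2 = VH/VV,
   NDI = (VV−VH)/(VV+VH), NL = VV·VH/(VV+VH)). Interval rules derived from
   the percentile envelopes vote each pixel in or out of a preliminary
   forest mask; water is excluded by low-backscatter bounds; remaining
   cropland is removed with a GNDVI threshold set at the 5th percentile of
   the forest training distribution, GNDVI = (NIR−Green)/(NIR+Green). A 5×5
   modal filter and a 0.5 ha minimum mapping unit clean the mask.
2. **Machine-learning betel extraction within the mask.** A 58-feature
   stack (24 SAR features including 8 windowed GLCM textures per
   polarization, averaged over the 0°/45°/90°/135° orientations; 10 optical
   bands; 24 vegetation indices) is ranked by the absolute Wald statistic
   |β̂/SE| of a ridge-stabilized binomial logistic regression
   P(y=1|x) = 1/(1+exp(−(β₀+βᵀx))) on z-standardized features. The top-20
   features feed a 100-tree random forest (√p candidate features per split,
   50% bagging without replacement) that labels betel vs non-betel inside
   the forest mask.

Accuracy is reported as overall accuracy, the kappa coefficient, and
per-class user's/producer's accuracy from a mapped-vs-reference confusion
matrix; area accounting uses 0.01 ha per 10 m pixel.

Because reproducing an island-scale map needs the original satellite
archive, the package ships a first-class synthetic-scene generator
(`betelmap.synthetic_scene`) that renders labeled six-class landscapes with
class-conditional reflectance, Gamma multiplicative speckle, cloud gaps and
smallholder patch geometry, so every stage is testable end to end.

## Worked example

```python
from betelmap.pipeline import run_pipeline

res = run_pipeline(seed=1)   # default 256x256 synthetic benchmark scene
print(f"forest mask precision: {res.forest_precision:.3f}")
print(f"forest mask recall:    {res.forest_recall:.3f}")
print(f"GNDVI forest cut:      {res.forest.gndvi_cut:.3f}")
print(f"top 5 features:        {', '.join(res.ranking.names[:5])}")
print(f"betel OA:              {res.report.oa:.4f}")
print(f"betel kappa:           {res.report.kappa:.4f}")
```

prints

```
forest mask precision: 0.998
forest mask recall:    0.951
GNDVI forest cut:      0.716
top 5 features:        CIG, B11, B12, B7, SATVI
betel OA:              0.9996
betel kappa:           0.9987
```

The forest mask recovers the tree-covered classes at ~99.8% precision and
~95% recall; the data-driven GNDVI cut lands near 0.72, the 5th percentile
of the dense-canopy GNDVI distribution the generator encodes; the ranking
surfaces chlorophyll (CIG) and SWIR (B11/B12, SATVI) contrasts, the axes on
which the synthetic betel class differs from other tree cover; and the
within-mask random forest separates betel almost perfectly on this
well-separated benchmark.

The same chain is available stage by stage from a shell:

```bash
betelmap simulate --seed 1 --shape 128 --out-dir scene/
betelmap preprocess --in-dir scene/ --out-dir pre/
betelmap features --in-dir pre/ --out-dir feat/
betelmap mask-forest --features-dir feat/ --labels scene/labels.tif --out-dir mask/
betelmap rank-features --features-dir feat/ --labels scene/labels.tif --out ranking.csv
betelmap train --features-dir feat/ --labels scene/labels.tif --ranking ranking.csv --model-out rf.joblib
betelmap predict --features-dir feat/ --model rf.joblib --forest-mask mask/forest_mask.tif --out betel.tif
betelmap assess --pred betel.tif --labels scene/labels.tif --out-dir report/
```

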