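# octarep

Repeatability and discrimination analysis of macular OCTA vessel-density
quantification under manual and automated image binarization.

## The problem

Optical coherence tomography angiography (OCTA) produces en-face images of
retinal blood flow. To quantify perfusion, an 8-bit greyscale angiogram is
binarized — vessel (white) vs background (black) — and two summary metrics
are computed:

- **Vessel density**: VD = n(white pixels)² / n(all pixels)² — the squared
  white-pixel fraction (the plain fraction is available as a convention
  switch and is stamped into every output row);
- **Vessel skeleton density**: VSD = n(white skeleton pixels) / n(all
  pixels)², where the skeleton is the 1-pixel-wide Zhang–Suen thinning of
  the binarized map (length-like, calibre-insensitive; ~10⁻⁸–10⁻⁷ for
  megapixel scans).

Everything downstream hinges on the binarization threshold. The common
choices are a *manual* procedure — delineate the foveal avascular zone
(FAZ), a capillary-free background reference, and take the maximum grey
value inside it (with a repeat-measurement protocol: two delineations, a
third if they differ by ≥ 5 grey levels, median of three) — or *automated*
global histogram algorithms: **Huang** (minimum fuzziness), **Li** (minimum
cross entropy), **Otsu** (between-class variance), **Moments**
(moment-preserving), **Mean** (grey mean), **Percentile** (median grey).
These disagree with each other, and the clinically relevant questions are:
which approach gives reproducible test–retest values on two consecutive
scans of the same eye, and which best separates healthy from impaired
maculae?

`octarep` implements the full comparison pipeline on synthetic cohorts with
known ground truth:

- a **simulator** of paired test–retest 3×3 mm angiograms: a branching
  vessel tree grown from the FAZ rim, multiplicative speckle (independent
  between the two acquisitions of a pair), a lower-signal deep-layer
  variant, pathology as terminal-capillary dropout, and an emulated manual
  rater with Gaussian vertex jitter;
- the seven **binarization** approaches above, plus VD/VSD measurement;
- **repeatability statistics**: relative test–retest differences,
  ICC(A,1) with F-based 95% CI, the repeatability coefficient
  RC = 1.96 · √(Σ(m₂−m₁)²/n), Friedman + Wilcoxon post-hocs with
  Holm–Bonferroni correction, Mann–Whitney-U / Kruskal–Wallis, and an
  age-adjusted regression of relative differences on age + seven algorithm
  indicators;
- **discrimination**: per algorithm/layer/metric an age-adjusted logistic
  model, ROC/AUC with Hanley–McNeil 95% CI, and paired DeLong AUC
  comparisons;
- a Monte-Carlo **power** routine for the Friedman test.

## Worked example

```python
import pandas as pd
from octarep import SimulationConfig, generate_cohort, measure_cohort, eye_metadata
from octarep.pipeline import analyze_measurements

config = SimulationConfig(image_size_px=256, n_healthy=4, n_pathology=4, seed=5)
cohort = generate_cohort(config)          # 8 eyes x 2 layers x 2 acquisitions
table = measure_cohort(cohort)            # 8 x 28 = 224 measurement rows
report = analyze_measurements(table, eye_metadata(cohort))

rep = pd.DataFrame(report["repeatability"])
print(rep[(rep.metric == "vd") & (rep.layer == "superficial")]
      [["algorithm", "icc", "rc"]].round(4).to_string(index=False))
```

prints

```
 algorithm    icc     rc
    Manual 0.9800 0.0041
     Huang 0.9886 0.0029
        Li 0.9985 0.0010
      Otsu 0.9974 0.0011
   Moments 0.9916 0.0012
      Mean 0.9878 0.0020
Percentile 0.9728 0.0034
```

RC is the width of the expected test–retest disagreement band (same units
as VD); ICC is the fraction of variance attributable to real between-eye
differences rather than measurement noise. The manual approach has the
largest RC: its threshold rides on a noisy maximum statistic and the
rater's hand, so repeated measurements scatter more than any automated
algorithm — the effect the full-size pipeline quantifies.

The `examples/` directory has one short script per capability (simulation,
thresholding, vessel metrics, repeatability, discrimination); each prints
the numbers it computes with a note on what they mean. A thin CLI wraps the
pipeline for on-disk cohorts:

```bash
octarep simulate --out cohort/ --seed 1
octarep measure  --input cohort/ --out measurements.csv
octarep compare  --measurements measurements.csv \
                 --manifest cohort/manifest.csv --out report/
```

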