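# echorestore

Restoration tools for echocardiographic (cardiac ultrasound) images,
plus the cohort statistics used to evaluate serum NT-proBNP as an early
predictor of symptomatic patent ductus arteriosus (PDA) in preterm
infants.

Echo images carry multiplicative speckle that defeats naive smoothing:
a filter strong enough to flatten the speckle also erodes the chamber
walls that clinicians measure. This package implements a sample-block
workflow built from three pieces:

1. **Multi-scale edge-preserving filter.** A Laplacian-pyramid filter
   whose output coefficient at level *l*, position *(x, y)* is taken
   from the pyramid of a point-wise remapped copy of the input, with
   the remapping

   *r(i) = i − m_f (i − g) exp(−(i − g)² / 2σ_r²)*

   anchored at that coefficient's own Gaussian reference
   *g = G_l[x, y]*. Intensity excursions below the contour threshold
   σ_r are attenuated (amplitude m_f), excursions above pass through —
   speckle is smoothed, edges are not. Optionally σ_r and m_f become
   per-pixel matrices inversely tied to the local intensity variance.
   The filtered image *S* and its residual *T = I − S* form an exact
   structure/texture decomposition.

2. **Structure-guided exemplar inpainting.** Dropout or shadowed
   regions are repaired Criminisi-style: fill-front pixels are ranked
   by confidence × data term, where the isophote data term is computed
   on the *structure* component so the fill follows chamber boundaries
   instead of speckle; the best source block is the fully-known patch
   minimising the masked sum of squared differences.

3. **Biomarker statistics.** Wilcoxon rank-sum (tie-corrected Z, exact
   enumeration at small n), Fisher / chi-square 2×2 tests, Pearson
   correlation, and empirical ROC analysis with the Youden-index best
   cut-off — the toolbox for asking whether day-3/day-5 serum NT-proBNP
   (pg/mL) separates PDA from asymptomatic (aPDA) infants. A synthetic
   cohort generator (lognormal margins moment-matched to published
   group summaries, Gaussian copula with target rank correlations to
   the echo indices) makes the whole pipeline testable without patient
   data.

## Worked example

```python
import numpy as np
from echorestore import (FilterConfig, HoleSpec, PhantomSpec,
                         inpaint_image, make_phantom, multiscale_filter)

spec = PhantomSpec(size=(64, 64), scene="step", tones=(0.25, 0.75),
                   noise_sd=0.05, hole=HoleSpec("rect", (32, 32), (10, 10)), seed=1)
img, truth, mask = make_phantom(spec)

out = multiscale_filter(img, FilterConfig(n_levels=3, base_sigma=0.15, base_mf=1.0))
left, right = np.s_[:, :28], np.s_[:, 36:]
print("flat variance", img[left].var(), "->", out[left].var())
print("edge contrast", img[right].mean() - img[left].mean(),
      "->", out[right].mean() - out[left].mean())

repaired = inpaint_image(img, mask, k=3, cfg=FilterConfig(n_levels=3))
wrong = ((repaired[mask] > 0.5) != (truth[mask] > 0.5)).mean()
print("mis-toned hole pixels:", wrong)
```

prints

```
flat variance 0.0024680523127042 -> 0.0002048507015708021
edge contrast 0.5021319531225753 -> 0.5020415191408889
mis-toned hole pixels: 0.0
```

— the flat-region variance drops ~12×, the cross-edge contrast moves by
less than 0.02 %, and every pixel of the repaired hole lands on the
correct side of the two-tone boundary.

The same operations are available from the shell:

```sh
echorestore phantom --out noisy.png --size 128 128 --noise-sd 0.05
echorestore filter --image noisy.png --out smooth.png --sigma0 0.15
echorestore inpaint --image img.png --mask mask.png --out repaired.png --patch-k 4
echorestore stats generate --preset table2 --seed 1 --out cohort.csv
echorestore stats roc --cohort cohort.csv --day 3
```

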