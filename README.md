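# celiascan

Capsule-endoscopy frame analysis for celiac-disease screening without deep
learning: bespoke preprocessing, a small filter bank, ten per-frame
descriptors summarized per video, and three lightweight classifiers.
A seeded synthetic frame generator makes the whole pipeline testable
without patient data.

## Pipeline

1. **preprocess** — overlay-text removal (bright regions with centroids in
   the outer 20 % border band are zeroed) and black-border cropping to the
   tight bounding box of non-zero pixels.
2. **filters** — true 2-D convolution with reflected edges, Sobel gradient
   magnitude, a narrow contrast window (`mean ± 0.2·std` rescaled to
   [0, 1]), the contrast-windowed Sobel edge mask, and a 3×3 crack kernel
   (coefficients A…I, center 7.8, coefficient sum 0.1) thresholded at 5 on
   the 8-bit gray scale — mask value 1 is tissue, 0 is crack.
3. **features** — per frame: intensity mean/std, R/G/B channel means, edge
   mask pixel sum, crack (tissue) mask pixel sum, 256-bin histogram entropy,
   and counts of large (area ≥ 1000) and small (10 ≤ area < 1000) filled
   edge regions.  Per video: mean, population standard deviation and
   variation (= variance) of each descriptor, giving a 30-column feature
   vector.
4. **classify** — fine KNN (k = 3), distance-weighted KNN (inverse-distance
   vote), and a linear hinge-loss SVM with balanced class weights; stratified
   50/50 split, z-scoring fitted on the training half; confusion counts,
   accuracy (percent), precision, sensibility and F1
   (`tp / (tp + (fp + fn)/2)`).
5. **synthetic** — seeded generator of labeled frames: circular mucosa field
   on black, class-conditioned base color (healthy redder than celiac),
   smooth texture noise, fold ridge/groove curves, Poisson-count dark crack
   polylines, and a bitmap timestamp overlay.

## CLI

```sh
# write a synthetic dataset of PNG frame directories + labels.csv
celiascan simulate --out data/ --n-healthy 10 --n-celiac 10 --n-frames 20 --seed 1

# extract the per-video feature table (CSV, 32 columns)
celiascan extract --frames data/ --out features.csv

# train and evaluate one classifier; writes a JSON report
celiascan train-eval --table features.csv --out report.json --classifier linear_svm --seed 1
```

Flags mirror the run configuration (border fraction, kernel threshold,
region area thresholds, classifier kind/k/C, train fraction, seed); a
`--config config.json` file overrides individual flags.

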