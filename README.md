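# pearspec

Toolkit for Vis/NIR spectrum-to-image encoding and fruit internal-defect
grading, exercisable entirely on synthetic data. It implements:

- **Synthetic data** (`pearspec.synthetic`): three-class spectra (1044
  wavelengths over 350–1150 nm) whose 600–900 nm amplitudes decrease strictly
  with mold severity, plus cross-section images carrying a dark mold blob of
  pixel-exact known area fraction.
- **Spectra prep** (`pearspec.prep`): CSV table I/O, replicate averaging,
  z-score outlier flagging, min-max normalization into [-1, 1] or [0, 1].
- **Gramian angular fields** (`pearspec.gaf`): GASF `cos(φi+φj)`, GADF
  `sin(φi−φj)`, and the fused IGAF (difference field on the upper triangle
  including the diagonal, summation field below), with bilinear resizing and
  PNG/float-matrix export.
- **LPMTF** (`pearspec.lpmtf`): piecewise aggregate approximation →
  equal-frequency quantile discretization → Markov transition matrix → field
  expansion → 3-level Laplacian pyramid → weighted fusion → [0, 1] image.
  A length-1044 series with window 5 yields a 208×208 image.
- **Mold quantification** (`pearspec.moldquant`): Canny contour → filled
  cross-section mask → Ridler–Calvard iterative threshold of the blue channel
  → 8-connectivity labeling → area percentage S and the three-level grade
  (S ≈ 0 healthy, 0 < S ≤ 10 slight, S > 10 severe).
- **Selection + SVM** (`pearspec.selection`): univariate F-statistic and
  random-forest importance wavelength selectors; one-vs-one RBF-SVM with an
  in-package majority vote and variance-scaled bandwidth heuristic.
- **Evaluation** (`pearspec.evaluation`): stratified train/val/test splits,
  confusion matrices, macro precision/recall/F1, McNemar's paired test.
- **Vision primitives** (`pearspec.vision`): 16×16 patch-token arithmetic
  (208 → 169 tokens, 224 → 196), scaled dot-product and multi-head attention,
  the depthwise-separable convolution cost ratio `1/N + 1/D_K²`, and a tiny
  trainable patch-attention classifier with a `--no-attention` ablation.

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds one test per acceptance criterion (token
arithmetic, external-validation arithmetic, oracle equivalences, structural
invariants, parameter recovery, ablation direction).

## CLI

All stages hang off a single entry point (see `pearspec --help`):

```bash
pearspec simulate --n-per-class 20 20 20 --seed 1 out/sim
pearspec encode-lpmtf --q 12 --window 5 out/sim/spectra.csv out/enc
pearspec encode-gaf --variant igaf --side 224 out/sim/spectra.csv out/gaf
pearspec quantify slice.png --json result.json
pearspec select --method us -k 100 out/sim/spectra.csv
pearspec classify --train train.csv --test test.csv --method rf
pearspec train-toy --encoder lpmtf --seed 0 --out out/toy   # add --no-attention to ablate
pearspec evaluate --truth t.csv --pred p.csv --compare p2.csv
```

A YAML config can supply defaults (`pearspec --config run.yaml ...`); flags
override file values. Each run writes a `provenance.json` with config, seeds
and package version.

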