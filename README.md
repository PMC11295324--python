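# qdl

A similarity-mapped medical image store toolkit:

- **synthetic fixtures** — seeded phantom images (blob "lesions" on noisy
  backgrounds), clustered feature matrices, 12-field metadata records and
  payload strings, so every stage is testable offline;
- **image prep** — z-score normalization, denoising/contrast adjustment,
  Otsu / fixed-threshold / region-growing segmentation, and intensity +
  shape + texture feature extraction with projection onto the probability
  simplex;
- **Bhattacharyya t-SNE** — a t-SNE engine whose input metric can be the
  Bhattacharyya distance between feature distributions and whose objective
  is a Bregman divergence (generalized KL or squared Euclidean), alongside
  the classic Euclidean / Student-t / KL baseline mode;
- **QR codec** — a from-scratch QR symbol encoder and decoder (numeric /
  alphanumeric / byte modes, versions 1–40, Reed–Solomon error correction
  over GF(256), standard mask penalty selection, BCH-protected format and
  version information, 1:1:3:1:1 finder-pattern detection);
- **SVD store** — truncated-SVD image compression (Eckart–Young-exact) and
  a file-backed deduplicating index: ingesting an image more than 70 %
  similar to an existing entry stores a *tag* to it instead of generating a
  new symbol;
- **evaluation** — confusion-matrix metrics, rank-statistic ROC AUC, and an
  end-to-end pipeline driver with a deterministic machine-readable report.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (one test per
criterion). The third-party interoperability test requires an independent
QR decoder (e.g. `pyzbar`); without one installed it fails with an
explanatory message rather than skipping.

## CLI

```sh
qdl synth images  --seed 1 --out scratch/imgs --count 8
qdl synth records --seed 1 --out scratch --images scratch/imgs
qdl synth features --seed 1 --out scratch
qdl synth payloads --seed 1 --out scratch/payloads --length 300

qdl embed --in scratch/features.csv --out scratch/emb.csv \
    --metric bhattacharyya --divergence generalized_kl --perplexity 30 --seed 1

qdl encode-qr --in payload.txt --ec M --out qr.png
qdl decode-qr qr.png

qdl ingest --store scratch/store --seed 1 scratch/imgs/img_*.png
qdl retrieve --store scratch/store --key R00000000
qdl retrieve --store scratch/store --qr scratch/store/qr/R00000000.png

qdl run --config run.toml --out scratch/run
```

`run.toml` is a flat key = value TOML file; every key has a default
(see `qdl.pipeline.DEFAULT_CONFIG`), so `seed = 1` alone is a valid config.

## Store layout

```
store/
  index.json          # records, payloads, tag references, feature index
  factors/<key>.bin   # "QDLF" magic, uint32 rank/rows/cols, float64 U, s, Vt
  qr/<key>.png        # rendered symbol for the entry payload
```
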