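# musemargin

Quantitative analysis of deep-UV surface-excitation fluorescence (MUSE)
mosaics of fresh breast surgical specimens, for tumor margin assessment:
given a stitched image of an excised surface stained with propidium iodide
(nuclei, yellow-red emission) and eosin Y (cytoplasm/stroma, green-yellow),
decide per 2×2 mm patch whether it looks like invasive carcinoma or normal
tissue.

The package covers the full chain:

1. **preprocess** — retrospective shading correction of the saturation and
   value channels in HSV space (per-pixel median across tiles + Gaussian
   smoothing, mean-1 multiplicative gain), and R/G histogram equalization
   of the stitched mosaic for visual review;
2. **stitch** — translation-only registration of overlapping stage tiles
   (normalized cross-correlation around the nominal offsets), global
   weighted least-squares placement, linear feather blending;
3. **ncquant** — nuclei segmentation on the red channel by hybrid edge +
   intensity thresholding,
   `mask = fill(close(|Sobel| > k·RMS)) ∧ (I ≥ 0.7·mean(top 1% of I))`,
   then two-level N/C scoring: small patches of 198×198 px (250×250 µm)
   with N/C = white/total pixels, merged 8×8 into 2×2 mm large patches,
   excluding blocks in which more than 32 of the 64 small patches contain
   no cells;
4. **classify** — ROC over the rule "invasive iff N/C ≥ t", AUC, Youden
   index J = max(sens + spec − 1) operating point, confusion-matrix reader
   statistics, and sample-level cluster-bootstrap group comparisons;
5. **phantom** — a synthetic MUSE-like scene generator with exact per-pixel
   nuclear masks and tissue labels (hard-core nucleus placement, adipocyte
   vacuoles, vignetting, sensor noise) so the whole analysis can be run and
   validated without the original specimens.

See `docs/methods.md` for the model details and the choices behind them.

## Worked example

Run the full pipeline on a three-class phantom (invasive ductal carcinoma |
fibrous stroma | adipose strips), at desk scale (64-px small patches merged
4×4):

```python
import tempfile
from musemargin import PipelineConfig, pipeline

cfg = PipelineConfig(seed=7, patch_px=64, large_block=4, zero_limit=8)
with tempfile.TemporaryDirectory() as d:
    summary = pipeline.run_all(cfg, d)
print(summary)
```

which logs each stage and prints (seed 7):

```
{'n_patches': 20, 'n_invasive': 8, 'n_normal': 12,
 'auc': 1.0, 'youden_threshold': 0.138, 'j': 1.0,
 'sensitivity_at_cutoff': 1.0, 'specificity_at_cutoff': 1.0,
 'mean_nc_by_class': {'IDC': 0.176, 'adipose': 0.037, 'stroma': 0.062}}
```

Reading: of the 20 large patches, the IDC strip scores a mean
nuclear-to-cytoplasm ratio of 0.176 against 0.062 for fibrous stroma and
0.037 for adipose tissue — the tumor/normal contrast the margin test relies
on — and thresholding N/C at 0.138 separates invasive from normal patches
perfectly on this clean phantom (AUC 1.0, J 1.0).  On real tissue the
classes overlap far more; the phantom demonstrates the machinery, not
clinical performance.

The same stages are available from a shell:

```sh
musemargin all --workdir out --seed 7
musemargin simulate --workdir out --config my_config.yaml   # stage by stage
```

Every stage writes its outputs (TIFF/PNG images, CSV tables) plus a JSON
provenance block with the full configuration, seed and input hashes.

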