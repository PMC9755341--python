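# hmquant

Quantification of heart-to-mediastinum (H/M) ratios on anterior-view planar
scintigraphy, with a synthetic-phantom simulator, two ROI-placement methods
(manual drawing vs. semi-automatic fixed-size ROIs anchored to an anatomical
landmark square), pathological classification against the published
cut-offs (early < 1.9, late < 1.7), and a complete inter-/intra-rater
agreement panel (ICC, Fleiss kappa, pairwise Cohen kappa, Spearman,
chi-square) with interpretive band labels.

## Modules

| Module | What it does |
| --- | --- |
| `hmquant.phantom` | Synthetic thoracic phantoms (256×256 by default): lungs, mediastinal band, liver, myocardial annulus + LV cavity; Poisson counts; early/late pairs via per-organ washout; cohorts with prescribed true H/M ratios; simulated raters with experience-dependent placement jitter and systematic manual-drawing bias. |
| `hmquant.io` | Planar images as tab-delimited text or single-frame DICOM (Explicit VR Little Endian, 16-bit); ROI sets as tagged JSON. |
| `hmquant.roi` | Rectangle/oval/polygon rasterization (pixel-center inclusion), landmark-square detection, and the fixed-size ROI placement rule (13×20 mediastinal rectangle in the upper half of the square, 60×70 cardiac oval at the lower-right quadrant centroid). |
| `hmquant.hm` | H/M ratio (mean counts/pixel) and strict cut-off classification. |
| `hmquant.agreement` | ICC (one-way / two-way absolute / consistency, F-based CIs), Fleiss kappa with a seeded bootstrap CI, Cohen kappa, Spearman rho, Pearson chi-square (plus McNemar), and interpretive bands. |
| `hmquant.pipeline` | End-to-end study runs behind `StudyConfig`, report serialization (JSON + text table), and analysis of external image/ROI directories. |

## CLI

```bash
hmquant run --seed 1 --outdir out            # full simulated study
hmquant simulate --outdir out                # cohort images + truth sidecars
hmquant rate --outdir out                    # simulated rater ROI files
hmquant quantify --outdir out                # per-subject H/M CSV
hmquant agree --outdir out                   # agreement panel from the CSV
hmquant analyze --images dir1 --rois dir2 --outdir out   # external data
```

All commands accept `--config cfg.yaml` (phantom parameters, rater
profiles, cut-offs, seeds), `--seed`, `--method {manual,semiautomatic,both}`
and `--format {dicom,text}`. Runs are deterministic in the master seed.

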