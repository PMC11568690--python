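# duospot

Dual-color combinatorial in situ signal decoding for multichannel
fluorescence microscopy, with cell segmentation, random-forest cell
classification, and spatial region clustering.

Each marker in the panel is encoded by an unordered pair of signal channels
("color code"): six channels yield 15 possible codes, and reserving the
bleed-through-prone TexasRed channel for a single pairing with Cy3 leaves an
11-marker panel. A decoded signal is a pair of spots colocalized in exactly
the two channels of one code. The pipeline:

1. **ROI detection** on the 8×8-binned nuclear (DAPI) image.
2. **Rigid registration** of the post-strip background scan (binned
   pre-alignment, ×8 translation upscaling, per-ROI refinement) and
   **background subtraction** for all signal channels.
3. **Nucleus segmentation** in two intensity passes (bright, then dim nuclei)
   and **cell expansion** by 12 px or 32 px depending on nucleus area
   (cutoff 2800 px²).
4. **Spot detection** per channel via adaptive minimum cross-entropy (Li)
   thresholding, with reduction of each component to its local-maximum pixel.
5. **Decoding**: per-code one-to-one colocalization, rejection of
   single-channel and off-code candidates, unspecific calls for groups
   spanning >4 channels, a two-level masking hierarchy (VIM/KRT mask AR-FL;
   VIM/KRT/AR-FL/PSA mask the low-expression markers), autofluorescence and
   registration-border masking, and assignment of accepted signals to cells.
6. **Classification** of per-cell count profiles into five classes
   (CTC / PBMC / artefact / false-positive / negative) with a random forest,
   plus evaluation (confusion matrix, precision/recall/F1/specificity,
   multiclass MCC) and cohort summaries (positivity, median, IQR).
7. **Spatial analyses** (tissue mode): grid-binned k-means region clustering
   of decoded signals and hierarchical clustering of per-cell profiles.

A synthetic-data module (`duospot.simgen`) renders matched original and
background scans with full ground truth — nuclei in two DAPI intensity
tiers, dual-color coding spots, autofluorescent multi-channel objects,
Cy5→TexasRed bleed-through, and a rigid misalignment between the scans — so
the whole pipeline is testable without real data.

## CLI

```bash
# generate a synthetic sample with ground truth
duospot simulate --out sample/ --seed 1

# run the full decoding pipeline
duospot decode --input sample/ --out results/

# train / apply / evaluate the cell classifier
duospot classify-train --counts annotated.csv --out model.pkl
duospot classify-apply --counts results/cell_counts.csv --model model.pkl --out predicted.csv
duospot evaluate --predicted predicted.csv --out report.json

# cohort summary and tissue-mode region clustering
duospot report --counts annotated.csv --out summary.csv
duospot spatial --signals results/decoded_signals.csv --k 4 --out regions
```

Input layout expected by `decode`: one TIFF per channel per scan under
`<dir>/original/<channel>.tif` and `<dir>/background/<channel>.tif`
(channels: DAPI, Atto425, Atto488, Cy3, TexasRed, Cy5, AF750).
Coordinates are 0-based, (row, col) = (y, x), with half-open bounding boxes.

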