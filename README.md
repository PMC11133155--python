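# icgfa

Patient-calibrated quantitative indocyanine-green fluorescence angiography
(ICGFA) for bowel transection support.

A patient's own baseline ("reference") perfusion curve, recorded early in
the operation, is adapted to each late-operation ("determinative") curve by
scaling and shifting along the time axis only. Agreement between the fitted
reference and the determinative curve is scored as one minus the relative
L1 area disagreement; fits with agreement below 85% are rejected. Among
accepted fits, perfusion sufficiency goes to the briskest curves (or those
at least 95% as fast as the briskest, on briskness = 1/scale), and the
transection recommendation is the most distal sufficient ROI. The same fit
can be run per pixel block over an annotated region and rendered as a
green / orange / red recommendation overlay on the white-light frame.

Because no clinical recordings ship with this package, a synthetic
bowel-perfusion phantom (gamma-variate inflow, exponential washout, a
proximal-to-distal ischemic gradient with known ground truth) generates all
test and demonstration data.

## Layout

| module | role |
| --- | --- |
| `icgfa.signal_io` | TIFF video stacks, stabilization, ROI/pixel curve extraction, curve CSV |
| `icgfa.preprocess` | background subtraction, resampling, Savitzky-Golay smoothing, normalization |
| `icgfa.curve_match` | scale-and-shift reference fitting, agreement scoring, acceptance |
| `icgfa.roi_recommender` | sufficiency classification, transection recommendation, Jaccard scoring |
| `icgfa.qicgfa_metrics` | conventional descriptors (latency, Fmax, Tmax, T1/2, slopes, TR, centre of mass) |
| `icgfa.pixel_recommender` | per-block fitting, histogram classification, heatmap overlays |
| `icgfa.phantom` | synthetic curves, phantom videos, simulated lactate, ground truth |
| `icgfa.stats_validation` | Spearman correlation matrices with interpretation bands |

## CLI

```sh
# synthetic phantom: curves CSV, ground truth, optional TIFF video + mask
icgfa simulate --seed 3 --out-dir phantom_out --video

# ROI-level recommendation from a curve CSV (reference + determinative rows)
icgfa recommend --curves phantom_out/curves.csv --out recommendation.json

# conventional descriptor table
icgfa metrics --curves phantom_out/curves.csv --out metrics.csv

# per-pixel overlay rendered on the white-light frame
icgfa heatmap --video phantom_out/video.tif --mask phantom_out/mask.png \
    --ref-curves phantom_out/curves.csv --metric recommendation --out overlay.png

# Spearman matrix with significance stars
icgfa correlate --table metrics.csv --out rho.csv
```

All knobs (phantom kinetics, preprocessing, match grids, classification
rules) live in a YAML config passed via `--config`; see
`tests/test_cli.py` for a worked example.

`recommend` exits 0 even when the result is `no_recommendation` — that is
a valid clinical outcome carried in the payload, not a failure.

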