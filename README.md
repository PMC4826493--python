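# mitospot

Fully automated quantification of tumor-cell proliferation in PHH3/MART1
dual-stained slide images, plus the method-agreement statistics used to
compare it against manual counting.

The pipeline:

1. **stains** — color deconvolution into hematoxylin / DAB / AP-red optical
   densities, a local standard-deviation filter, HSI intensity, and a
   threshold cascade classifying every pixel as background, PHH3 (brown),
   MART1 (red) or hematoxylin (blue).
2. **detect** — PHH3 dilation fuses split anaphase/telophase chromatin into
   single objects; each object is measured on its original pixels (area,
   mean brown OD, 1 − solidity, MART1-surround fraction) and gated into
   positive/negative; PHH3-negative blue tumor nuclei are reclassified into
   the MART1-verified tumor area used as the reference space.
3. **hotspot** — an object heat map (circles of radius 200 μm centred on
   every positive cell) selects the hottest position, encompassed by a
   1-mm² square; overlap between two hot spots is categorized as
   perfect / mayor / minor / none from |Δx| and |Δy| of the square centres.
4. **quantify** — global and hot-spot counts and MART1-adjusted indices
   (cells/mm²), with named dichotomization presets.
5. **evaluate** — Bland–Altman limits of agreement, the 2×2 detection
   contingency table, overlap-category tallies, and diagnostic performance
   (sensitivity/specificity/PPV/NPV with exact binomial CIs, rank-based ROC
   area).
6. **phantom** — calibrated synthetic dual-stain slides with exhaustive
   ground truth (split chromatin figures, PHH3⁺ lymphocytes without MART1,
   pigment granules, pale and over-dark MART1 artifacts, a planted spatial
   cluster), rendered through the same Beer–Lambert forward model that the
   deconvolution inverts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
of the hot-spot selector, planted-cluster recovery, detector fidelity on
phantoms, overlap-band exactness, contingency arithmetic, agreement
statistics).

## CLI

```bash
# render a synthetic slide + ground truth
mitospot simulate --spec spec.yaml --seed 7 --out sim/

# end-to-end: detect -> hotspot -> quantify (exit 0; 10 = no tumor area,
# 11 = no hot spot)
mitospot run --image sim/phantom.tif --outline sim/lesion.geojson --out run/

# individual stages
mitospot detect  --image slide.tif --outline roi.geojson --config cfg.yaml --out out/
mitospot hotspot --cells out/cells.csv --domain roi.geojson --radius-um 200 --out out/
mitospot quantify --cells out/cells.csv --tumor-mask out/tumor_mask.png \
    --um-per-px 0.46 --hotspot out/hotspot.json --out out/

# method comparison from a per-case CSV
mitospot evaluate --pairs pairs.csv --mode agreement --out eval/
```

All thresholds and radii live in a YAML config (`mitospot.config.RunConfig`;
an empty file means defaults). Every artifact embeds the SHA-256 hash of the
config that produced it. Calibration precedence: explicit `--um-per-px` >
image sidecar JSON > error.

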