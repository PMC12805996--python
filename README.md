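# ramanqa

Single-cell Raman flow cytometry (RFC) analytics for probiotic product
quality assessment.

Modern probiotic QA needs four numbers per strain, fast and culture-free:
who is in the product (strain identity), how many cells per gram (total
count), how many of them are alive (viability), and how active the live
ones are (vitality).  RFC acquires a spontaneous Raman spectrum from each
cell in flow (~1 cell/s); `ramanqa` turns those single-cell Raman spectra
(SCRS) into exactly those numbers:

* **Preprocessing** — asymmetrically reweighted penalized least squares
  (arPLS) baseline correction (smoothness λ = 10⁶, sensitivity 0.05),
  SNR/outlier quality control, band selection, per-cell max-min
  normalization to [0, 1].
* **Identification** — per-cell classification against a reference ramanome
  database built from pure cultures, using fingerprint-region (500–1800
  cm⁻¹) features.  Six classifier families (LDA via PCA retaining 99%
  variance, RF, SVM, NBC, KNN, DT), with 70/30×5 split evaluation,
  leave-batch-out cross-validation and sampling-depth curves.
* **Absolute counting** — a spike-in reference strain of known
  concentration `n_ref` converts classifier proportions into counts:
  `c_test = n_ref · (p_test/p_ref) · (v_ref/v_test)`, then CFU/g through the
  dilution chain.
* **Viability & vitality** — cells metabolizing in heavy water move C–H band
  intensity (2800–3100 cm⁻¹) into a C–D band (2040–2300 cm⁻¹).  Per cell,
  `CDR = CD/(CD+CH)`; `MAL = CDR − mean CDR(0 h control)`; `MAL > 0` marks a
  live cell; group vitality is the mean MAL and its cell-to-cell
  heterogeneity is `MAL-HI = var(MAL)`.
* **Simulator** — a seeded generator of species fingerprints, baseline
  drift, noise, batch effects and D₂O label transfer, providing exact
  ground truth for every stage.

Everything composes scikit-learn style: preprocessing steps are
transformers, the classifier is an estimator with `fit`/`predict`, and the
module-level functions are thin wrappers.

## Worked example

A complete strain-resolved QA of a synthetic three-strain product with a
spiked-in reference strain:

```python
from ramanqa import (
    SpikeInDesign, VitalitySpec, make_species_cohort, simulate_cells,
    simulate_mixture, simulate_spikein, train_classifier, run_qa,
)
from ramanqa.preprocess import preprocess_pipeline
from ramanqa.spectra import Ramanome

cohort = make_species_cohort(4, seed=60)       # 3 product strains + reference
strains, ref = cohort[:3], cohort[3]
vitality = {s.name: VitalitySpec(live_fraction=f)
            for s, f in zip(strains, (0.6, 0.9, 0.4))}
vitality["species4"] = VitalitySpec(live_fraction=0.0)

# reference database from pure cultures
rams = [simulate_cells(s, 150, seed=80 + i, d2o_hours=3.0, vitality=vitality[s.name])
        for i, s in enumerate(strains)]
rams += [simulate_cells(ref, 150, seed=90)]
train = Ramanome(rams[0].axis, tuple(c for r in rams for c in r.cells))
model = train_classifier(preprocess_pipeline(train, normalize=False)[0], "LDA")

# product acquisition with the reference spiked in at known dose
design = SpikeInDesign(n_ref=5e8)
product = simulate_spikein(strains, [0.5, 0.3, 0.2], ref, design,
                           true_cfu_per_g=5e9, n_total=800, seed=61,
                           vitality=vitality, d2o_hours=3.0)
control = simulate_mixture(strains, [0.5, 0.3, 0.2], 300, seed=62)  # 0 h

report = run_qa(product, model, design=design, control0h=control,
                ref_label="species4")
print(report.to_table())
```

Output:

```
strain	proportion_pct	total_cfu_per_g	viability_rate_pct	live_cfu_per_g	mean_mal	mal_hi
species1	49.2	2.49e+09	76.3	1.9e+09	0.0275	0.000711
species2	29.4	1.49e+09	95.3	1.42e+09	0.0456	0.000495
species3	21.4	1.08e+09	69.2	7.5e+08	0.0207	0.000692
# warning: below recommended sampling depth (1500): 800 spectra passed QC
```

Reading it: the classifier recovered the 50/30/20 strain composition within
sampling error; the spike-in arithmetic turned those proportions into
per-gram totals (summing to ≈5×10⁹ CFU/g, the simulated truth); the D₂O
metrics ranked the strains' viability in the simulated order (90% > 60% >
40%, each estimate sitting above its truth because noise scatters
boundary-dead cells upward — see `docs/methods.md`); and the report warns
that 800 spectra is below the recommended 1500-spectrum sampling depth.

The same workflow is available from the shell:

```bash
ramanqa simulate --species 2 --cells 200 --out sim.csv
ramanqa train --spectra sim.csv --model-out model/
ramanqa predict --spectra sim.csv --model model/ --out preds.csv
ramanqa run --spectra product.csv --model model/ --design design.yaml \
            --control control.csv --ref-label species4 --out report.json
```

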