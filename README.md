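# hypoxikit

Analysis toolkit for hypoxia biomarkers in preclinical xenograft tumour
models (patient-derived and cell line-derived xenografts, PDX/CDX), built
around three quantitative readouts:

1. **Hypoxia gene-signature scoring** of bulk RNA-seq count matrices.
   Counts are low-count filtered (≥ 10 in at least one sample and ≥ 15
   total per gene) and RLE/median-of-ratios normalised; per-gene z-scores
   against a xenograft reference population are clamped to [−3, 3] and
   summed into a signature score, and a **Hypoxia Score** in [0, 1] is the
   fraction of signature genes above the reference median — comparable
   across signatures of different sizes.
2. **Tumour growth-rate estimation** for drug-efficacy readout. Calliper
   volumes (V = π/6·w·l²) are smoothed per animal with a Gompertz curve in
   the W0-form, W(t) = A·exp(ln(W0/A)·exp(−(e·Ku/A)·t)), with W0 fixed from
   a linear regression over days −7..+5; the mean daily growth rate is the
   mean finite-difference slope of the fitted curve at days 1..21 (days
   with fitted volume < 10 mm³ excluded for shrinking tumours). Treated
   and control arms are compared per model by unpaired t-test with
   Holm-Sidak adjustment (significance at adjusted p < 0.005).
3. **Viral (HPV) RNA detection** from read alignments to viral genomes:
   a genome is called positive when ≥ 400 reads map to it and the pileup
   holds a contiguous run of ≥ 200 bp at depth ≥ 5.

Coefficient-of-variation and Pearson-correlation summaries relate the
biomarkers (signature scores, stained hypoxic fraction, proliferation
counts, growth rates) at the model level, and a seeded synthetic-data
module generates every input format with known ground truth, so the whole
pipeline is testable end to end without animal or sequencing data.

See `docs/methods.md` for the full model descriptions, parameter defaults
and design choices.

## Worked example

Generate a synthetic study and run every stage through the CLI:

```bash
hypoxikit --out-dir demo --seed 7 simulate
hypoxikit --out-dir demo score demo/counts.tsv demo/annotations.tsv demo/signatures.toml
hypoxikit --out-dir demo growth demo/measurements.tsv
hypoxikit --out-dir demo hpv demo/viral_alignments.tsv --genome-lengths HPV16=7904
```

`signature_scores.tsv` holds one row per sample × signature. The model at
planted hypoxia level h = 0 scores low on the planted 15-gene signature:

```
sample_id  model_id  signature        zsum_score  simple_score  hypoxia_score  n_genes_used
M00_r1     M00       planted_hypoxia  -10.4221    -9            0.2            15
M00_r2     M00       planted_hypoxia  -9.72877    -11           0.133333       15
```

(Hypoxia Score 0.2 = 3 of 15 signature genes above the xenograft reference
median; the z-sum around −10 means those genes sit roughly 0.7 sd below the
reference mean on average.)

`group_comparison.tsv` reports the treated-vs-control test per model; with
the generator's true 60% growth-rate reduction the effect is detected:

```
model_id  n_control  n_treated  mean_control  mean_treated  t_statistic  p_value     p_adjusted  significant
M00       8          8          36.5374       13.9595       -22.9177     1.6852e-12  1.6852e-12  True
```

(mean daily rates in mm³·day⁻¹; the treated mean is ≈ 0.38× the control
mean, matching the planted 0.4 multiplier on Ku.)

`hpv_calls.tsv` shows the dual-threshold call on 400 simulated reads piled
on a 250 bp region of an HPV16-length genome:

```
virus_id  positive  mapped_reads  longest_run_at_min_depth  region_start_1based  region_end_1based
HPV16     True      400           248                       1002                 1249
```

The same operations are importable as a library (`hypoxikit.rle_normalize`,
`hypoxikit.hypoxia_score`, `hypoxikit.fit_gompertz`,
`hypoxikit.call_hpv_status`, …).

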