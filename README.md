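# silamq

Protein-turnover quantification for ¹⁵N pulse-labeling (SILAM) proteomics.

When an animal is switched to a ¹⁵N-enriched diet, proteins synthesized
after the switch carry heavy nitrogen while pre-existing proteins stay
¹⁴N. In an MS1 survey scan the two isotopic forms of a peptide co-elute
as a light/heavy envelope pair, and the intensity ratio between the
channels — the **¹⁴N/¹⁵N ratio** — measures how much of a protein is
"old" versus "new": high ratios mark long-lived proteins, low ratios mark
rapidly renewed ones. This is the standard readout for tissues with
extreme protein longevity such as the crystalline lens, where many
proteins in the organelle-free nuclear core are never replaced at all and
show up only in their ¹⁴N form.

`silamq` implements the complete analysis from centroided MS1 spectra
(mzML) plus a peptide identification table to per-protein turnover
records, for researchers running or re-analyzing metabolic-labeling
experiments:

* theoretical isotope envelopes for the natural-abundance (light) and
  ¹⁵N-enriched (heavy) channels, from peptide elemental composition;
* per-peptide extracted ion chromatograms over both channels (10 ppm
  tolerance by default) and the ratio estimate
  `r̂ = Σ L_i H_i / Σ H_i²` (zero-intercept least squares of light on
  heavy), quality-scored by the Pearson correlation of the paired
  profiles (records pass only when r > 0.5);
* target-decoy FDR control and DTASelect-style identification filters
  (≥ 6 residues, ≥ 1 tryptic end, 10 ppm precursor window, 1% FDR);
* peptide-to-protein rollup: iterative Grubbs outlier removal on
  log-ratios (p < 0.01), intensity-weighted geometric-mean composite,
  ratio caps at [0.05, 20] (ceiling 100 in cortex/nucleus mode);
* three-way classification (¹⁴N-only / ¹⁵N-only / quantified),
  spectral-count abundance summaries and paired cortex-vs-nucleus
  comparisons;
* a synthetic labeled-run generator that produces mzML + PSM + FASTA
  bundles with exact ground truth, so the whole pipeline is testable
  without instrument data.

## Worked example

Simulate a small labeled run (12 proteins, a quarter of them never
labeled, 5% multiplicative noise) and quantify it:

```bash
$ cat sim.yaml
seed: 42
n_proteins: 12
fraction_unlabeled: 0.25
noise_cv: 0.05
output_dir: bundle

$ silamq simulate --config sim.yaml
bundle written to bundle: 12 proteins, 76 peptides, 1501 MS1 scans, 147 PSMs

$ cat quant.yaml
mode: lens
output_dir: out
runs:
  - {tissue: lens, mzml: bundle/run.mzML, psms: bundle/run_psms.tsv}

$ silamq quantify --config quant.yaml
INFO silamq: lens: 147/147 PSMs accepted
results written to out
```

`out/lens_proteins.tsv` holds one row per protein. Comparing with the
planted truth:

```
accession  state      true_ratio  turnover_class  ratio_14N_15N
SYNP0000   RATIO      0.0650      QUANTIFIED      0.0646
SYNP0001   RATIO      0.1065      QUANTIFIED      0.1057
SYNP0002   RATIO      6.0824      QUANTIFIED      6.0732
SYNP0003   UNLABELED              LIGHT_ONLY
SYNP0004   RATIO      0.9051      QUANTIFIED      0.8999
```

Quantified ratios land within about 1% of the planted values at this
noise level, and the never-labeled protein is classified ¹⁴N-only
(LIGHT_ONLY) rather than given a meaningless ratio.
`out/classification_summary.tsv` reports the per-tissue class counts and
fractions; in cortex/nucleus mode the pipeline additionally writes the
paired protein join and light/heavy spectral-count tables.

All of this is available as a library too — see `silamq.cli.quantify_run`
for the orchestration entry point and the individual modules
(`isotopes`, `spectra_io`, `xic_ratio`, `protein_rollup`, `fdr_filter`,
`tissue_compare`, `synthetic_data`) for each stage.

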