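# fractiomics

Post-whole-genome-duplication (WGD) fractionation analysis for mesopolyploid
plant genomes.

After a WGD, a genome carries two copies of every gene. Over millions of
years most duplicated loci return to single copy ("fractionation"), usually
unevenly: a least-fractionated (LF) subgenome keeps more genes than the
most-fractionated (MF) one. `fractiomics` implements the analysis chain used
to dissect this process in a mesopolyploid crucifer against a diploid
reference (e.g. *Arabidopsis thaliana*):

- **WGD dating** — fit a Gaussian mixture to the distribution of synonymous
  substitution rates (Ks) among paralog pairs by expectation–maximisation;
  each WGD leaves a peak. A peak at Ks = μ is dated linearly against a
  calibrated older event: `T = μ · T_calib / Ks_calib` (default anchor: the
  Brassicaceae α-WGD, Ks 0.96 = 32.42 Ma).
- **TE dating** — transposable-element copies are dated from their divergence
  *d* to the family consensus under a substitution clock, `T = d/r` (or
  `d/2r`), default `r = 8.22 × 10⁻⁹` substitutions/site/year; amplification
  bursts appear as peaks in the divergence histogram.
- **Syntenic windows** — collinearity anchors to the reference gene order are
  scanned into nonoverlapping windows (seeded by 10 consecutive anchors with
  both copies, spanning 100 reference genes, tolerating up to 20 consecutive
  nonsyntenic genes per copy track).
- **Subgenome assignment & bias** — gene trees place each copy as sister to a
  progenitor-side taxon; windows are 2-coloured accordingly and the side with
  more retained genes genome-wide is labelled LF. A per-window χ² test on
  retained/lost × LF/MF splits windows into low-bias and high-bias
  fractionation classes.
- **Selection & expression** — genes are classed purifying / neutral /
  positive from Ka/Ks with bands at 1 ± SD (0.787, 1.213); genes are
  "expressed" at TPM > 1; differential expression per treatment (cold, heat,
  drought, herbivory vs control) requires |log₂FC| > 1 and a BH-adjusted
  Welch test on log₂(TPM+1) replicates. TE-proximity effects are quantified
  by minimum gene–TE distance bins (0, 1–200, 201–2000, >2000 bp).
- **Duplicate fates** — every expressed duplicate pair is classified against
  its "progenitor singleton" ortholog by a deterministic cascade: neutral
  divergence, neofunctionalization candidate, dosage-balance conservation
  (with or without a shared environmental trigger), trigger loss, single-copy
  trigger conservation with the other copy constitutive, trigger gain, or
  other change.
- **Enrichment statistics** — Fisher's exact test, upper-tail hypergeometric
  gene-set enrichment with Benjamini–Hochberg q-values, rank tests.

Because the full analysis needs a genome that cannot ship with a package,
`fractiomics` includes a **synthetic mesopolyploid generator**
(`fractiomics.simulate`) that emits a fully labelled dataset — gene and TE
GFF3, anchor/Ka-Ks/TPM/orthogroup/progenitor-flag TSVs, one gene tree per
pair — with planted subgenome retention bias, TE density contrast, bimodal
paralog Ks, TE-proximity expression suppression and per-treatment trigger
evolution, so every stage is testable against ground truth.

## Worked example

```python
from fractiomics import SimulationConfig, simulate_dataset, analyze_bundle
from fractiomics.dating import date_by_calibration

bundle, truth = simulate_dataset(SimulationConfig(seed=1))
result = analyze_bundle(bundle, seed=1)
s = result.summary
print(f"windows detected:      {s['n_windows_detected']}")
print(f"Ks peaks:              {s['ks_peak_young']:.3f} / {s['ks_peak_old']:.3f}")
print(f"younger WGD age:       {s['wgd_age_ma']:.2f} Ma")
print(f"LF retention share:    {s['lf_retention_share_pct']:.1f} %")
print(f"TE mid-bin suppression:{s['te_mid_bin_log2_reduction']:.2f} log2")
print(f"dosage-balance share:  {s['dosage_balance_share_pct']:.1f} %")
```

prints (seed 1):

```
windows detected:      122
Ks peaks:              0.340 / 0.986
younger WGD age:       11.48 Ma
LF retention share:    55.1 %
TE mid-bin suppression:1.74 log2
dosage-balance share:  66.8 %
```

All 122 planted windows are recovered; the fitted Ks peaks sit on the planted
mixture modes (0.34, 0.96), so the calibrated age of the younger WGD lands at
~11.5 Ma; the LF subgenome retains more genes than the MF; the planted
1.83-log₂ TE suppression is estimated at 1.74; and about two-thirds of
expressed duplicate pairs are retained under dosage-balance constraints.

The same pipeline is scriptable from the shell:

```bash
fractiomics simulate --outdir bundle --seed 1
fractiomics windows bundle/anchors.tsv --out windows.tsv
fractiomics bias bundle/anchors.tsv bundle/gene_trees.tsv bundle/pairs.tsv --out bias.tsv
fractiomics de bundle/tpm.tsv --treatment cold --out de_cold.tsv
fractiomics fisher --a 57 --b 43 --c 32 --d 68
```

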