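# dubscreen

Identify substrates of deubiquitinating enzymes (DUBs) from label-free
quantitative proteomics of biotin-pulldown (bioUb) experiments.

Silencing a DUB lets ubiquitin accumulate on its substrates; pulling down the
ubiquitinated fraction with avidin and comparing label-free quantification
(LFQ) intensities between control and DUB-silenced samples reveals which
proteins became more ubiquitinated. `dubscreen` implements the complete
downstream analysis for this screen design, for proteomics groups who have a
MaxQuant `proteinGroups`-style table (and optionally a GlyGly/diGly site
table) and want a reproducible, scriptable alternative to a point-and-click
workflow:

1. **Filtering** — remove reverse (decoy) hits, contaminants, proteins only
   identified by site, and proteins with no unique peptides or no intensity.
2. **Imputation** — log2-transform LFQ intensities and replace missing
   values (LFQ = 0) with draws from a downshifted normal distribution,
   `N(m − 1.8·s, (0.3·s)²)` per sample column, where `m` and `s` are the
   observed column mean and standard deviation — a model for intensities
   below the detection limit. An imputation mask is kept throughout.
3. **Differential testing** — per protein, log2 fold change
   `FC = mean(silenced) − mean(control)` and a two-tailed pooled-variance
   Student's *t*-test on the imputed matrix.
4. **Substrate calling** — a protein is a *putative substrate* when it
   (i) shows `FC ≥ 1` (≥ 2-fold LFQ increase) with `p < 0.05`,
   (ii) has ≥ 2 unique peptides, and (iii) has no imputed value in at least
   one condition, or at most one imputed value in each. Proteins passing
   (i) alone form the *initial selection*.
5. **QC and reproducibility** — endogenously biotinylated carboxylases
   (ACACA, HLCS, MCCC1, PC, PCCA), ubiquitin and avidin must not shift
   between arms; replicate agreement via pairwise Pearson correlation of
   observed (non-imputed) intensities and Venn overlap counts.
6. **GlyGly sites** — diGly-remnant site tables are filtered on flags,
   intensity and localization probability (keep ≥ 0.75) and summarised per
   protein as annotation.
7. **Substrate store** — all differential results are ingested *unfiltered*
   into a queryable SQLite store; fold-change/p-value/peptide thresholds are
   applied at query time, in both directions (DUB → substrates,
   substrate → DUBs), with CSV export and volcano datasets. A curated
   example dataset ships with the package: the published putative substrates
   of a five-DUB silencing screen (USP1, USP7, USP9X, USP11, USP42).
8. **Synthetic data** — a generator emulating the screen (log-normal
   abundances, abundance-dependent dropout, spiked substrates, QC panel,
   decoys/contaminants) with ground truth, so the whole pipeline is testable
   without raw MS data.

## Worked example

Simulate a triplicate USP9X screen, run the pipeline, and query the store:

```bash
dubscreen simulate --seed 1 --out sim
# wrote sim/proteinGroups.tsv, sim/glygly.tsv and truth.csv (2042 rows)

dubscreen run --config config.yaml
# 1985 proteins tested; 30 initial selection; 28 putative substrates; QC pass; artifacts in results
```

`config.yaml` names the input files, the silenced DUB, the sample → condition
mapping and the seed (see `dubscreen run --help`). The results directory
contains the filtered table, the imputed matrix and its mask, the
differential and volcano CSVs, both substrate lists, the QC report and a
query-ready SQLite store. The first lines of `putative_substrates.csv`:

```
row_key,gene_name,...,log2_fc,p_value,...,n_imputed_control,n_imputed_silenced,unique_peptides,category
SYN00417,GENE0417,...,3.683,0.00468,...,2,0,7,up
SYN00021,GENE0021,...,2.987,0.00509,...,2,0,8,up
```

Each row is a protein whose ubiquitination rose ≥ 2-fold upon silencing
(log2 FC ≥ 1) at *p* < 0.05 with enough unique peptides and acceptably few
imputed values — e.g. GENE0417 is 2^3.68 ≈ 13-fold enriched, with its two
imputed control replicates excused because the silenced arm is fully
observed.

Query the bundled published screen:

```bash
dubscreen dubase ingest --db store.sqlite --published
# ingested 56 records (56 total)

dubscreen dubase query --db store.sqlite --dub USP7
# USP7  TTK     2.33  Dual specificity protein kinase TTK
# USP7  GABPA   1.66  GA-binding protein alpha chain
# USP7  RPL29   1.61  60S ribosomal protein L29
# USP7  RNF2    1.54  E3 ubiquitin-protein ligase RING2
# USP7  CREB1   1.44  Cyclic AMP-responsive element-binding protein 1
# USP7  MARCKS  1.21  Myristoylated alanine-rich C-kinase substrate
# 6 records

dubscreen dubase query --db store.sqlite --substrate RNF2
# USP7   RNF2  1.54  E3 ubiquitin-protein ligase RING2
# USP42  RNF2  1.11  E3 ubiquitin-protein ligase RING2
# 2 records
```

With default thresholds USP7 has 6 substrate records, and RNF2 — the one
protein targeted by two DUBs in that screen — is returned for both USP7 and
USP42. Thresholds persist per store
(`dubscreen dubase thresholds --fc 2 ...`), and tightening them only shrinks
the result lists.

The same functionality is available as a library
(`dubscreen.run_pipeline`, `DownshiftedNormalImputer`,
`DifferentialAnalyzer`, `SubstrateStore`, ...); the imputer and analyzer
follow scikit-learn estimator conventions (`fit`/`transform`,
`get_params`, fitted attributes ending in `_`).

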