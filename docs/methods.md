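# Methods

## Screen design and data model

The analysis compares biotin-pulldown LFQ intensities between a control-siRNA
arm and a DUB-silenced arm, by default three biological replicates each.
Input is a MaxQuant-dialect `proteinGroups` table: one row per protein group
with `LFQ intensity <label>` columns per sample, a unique-peptide count, and
`+`-encoded `Reverse`, `Potential contaminant` and `Only identified by site`
flags. An LFQ value of 0 encodes "not quantified" (missing), the MaxLFQ
convention. Column names are configurable through a column-mapping section of
the run config for other dialects. Gene names take the first symbol of a
semicolon-separated list, since the store keys records by a single symbol.

Row filtering removes, in this precedence order: reverse (decoy) hits,
contaminants, only-identified-by-site rows, rows with zero unique peptides,
and rows with no intensity in any sample. Each removed row is logged once
under the first matching reason; the filter is idempotent.

## Imputation

Missingness in LFQ data is missing-not-at-random: values drop out below the
detection limit. Missing cells are therefore imputed from a *downshifted
normal*: for sample column *j* with observed mean *m_j* and standard
deviation *s_j* (ddof = 1), each missing cell receives an independent draw
from

    N(m_j − downshift · s_j, (width · s_j)²),  defaults downshift = 1.8, width = 0.3.

Both parameters are expressed in units of the observed standard deviation —
the bare numbers 0.3/1.8 only make sense as multiples of *s*. Statistics are
per column by default (both conditions pooled within a column, as each column
is one sample); a whole-matrix mode is available as config. A column with
fewer than two observed values falls back to whole-matrix statistics with a
warning; a matrix with fewer than two observed values is an error. Draws
come from a single seeded `numpy.random.Generator` consumed in row-major
cell order, so results are bit-reproducible across platforms. The boolean
imputation mask marks exactly the filled cells and travels with the matrix;
observed cells are never modified.

## Differential testing and substrate calling

Per protein, on the imputed log2 matrix:

* `log2 FC = mean(silenced) − mean(control)`;
* equal-variance (pooled) two-sample Student's *t* with
  `df = n₁ + n₂ − 2`, two-tailed *p* (scipy's `ttest_ind`); *t* is positive
  when the silenced mean is higher. Degenerate rows with zero pooled
  variance yield `(t = 0, p = 1)` for equal means, and `(±∞, smallest
  positive float)` with a warning otherwise. Fold change and test use the
  same post-imputation matrix, so they never disagree about the data.

Volcano categories use the fixed screen boundaries (|log2 FC| ≥ 1,
p < 0.05) with precedence `qc_protein` > `silenced_dub` > up/down/
not_significant: QC-panel genes and the silenced DUB itself are labelled for
plotting and are never callable as substrates (the DUB's own drop in the
pulldown reflects its siRNA depletion, not deubiquitination).

A protein enters the **initial selection** when it passes the fold-change
and p-value thresholds (direction-aware), and is a **putative substrate**
when it additionally has at least `min_unique_peptides` unique peptides and
an acceptable imputation level: no imputed value in at least one condition,
or at most one imputed value in each condition. Over all
`(n_imputed_control, n_imputed_silenced)` pairs in `{0..3}²` exactly 8
patterns pass: `(0,·)` (4), `(·,0)` (3 more) and `(1,1)`.

Threshold boundary behaviour: the fold-change comparison is **inclusive**
(≥ 1 in log2, i.e. ≥ 2-fold) while the p-value comparison is strict
(< 0.05). The inclusive fold-change boundary is deliberate: published
substrate tables print rounded fold changes, and a record displayed at
log2 FC 1.00 is intended to pass a "2-fold" criterion. The unique-peptide
minimum is inclusive (≥ 2). Output lists sort by descending |log2 FC|, then
ascending p, then gene name, for deterministic ordering.

Defaults are `min_abs_log2_fc = 1`, `max_p = 0.05`,
`min_unique_peptides = 2`, `direction = "up"`. No multiple-testing
correction is applied by default, matching the screen's use of raw t-test
p-values; Benjamini–Hochberg is available as an opt-in (`correction.method:
bh`) and is clearly a deviation from the reference procedure.

## QC and reproducibility diagnostics

The QC panel defaults to the endogenously biotinylated carboxylases ACACA,
HLCS, MCCC1, PC and PCCA (biological-material control), the ubiquitin gene
products UBB, UBC, UBA52 and RPS27A (total ubiquitinated material), and
avidin (AVD, the bait). All identifier sets are configurable, because
ectopic ubiquitin constructs need not match a database entry. The QC report
fails when any detected panel member shifts at the calling thresholds;
members absent from the data are reported as not detected, never as
failures. Replicate agreement uses Pearson correlation over
pairwise-complete *observed* values only — imputed draws would leak the
imputation model into a data-quality metric — and pairs with fewer than 3
common observations are undefined (NaN). Identification overlap is reported
as exclusive Venn-region counts for 2–5 named sets (labels join member
names with `&`; counts sum to the union size) and as the containment
fraction `|A∩B| / min(|A|,|B|)`.

## GlyGly (diGly) sites

Site tables are filtered on reverse/contaminant flags, on having any
positive intensity, and on localization probability: sites **below** the
cut-off (default 0.75) are removed, so a site at exactly 0.75 is kept.
Positions are 1-based residue indices of the modified lysine. Kept sites are
summarised as unique ascending positions per protein and attached to store
records as annotation; they play no role in substrate calling. Because
published site totals do not state whether they are pre- or post-filter,
the summary reports both counts.

## Substrate store

A single SQLite file holds two logical tables, `experiment` and `evidence`.
Ingest stores *all* differential results unfiltered; thresholds act only at
query time, so users can re-screen the same evidence under their own
criteria. Queries run by DUB or by substrate gene (case-insensitive exact
match), return records sorted by descending log2 FC, and shrink
monotonically as thresholds tighten; the two query directions are mutually
consistent. Session thresholds persist in the store file until changed or
reset. Volcano datasets include every ingested record with a
passes-thresholds flag, so sub-threshold identifications remain visible.
Records ingested from the bundled published summary table carry
`provenance="published_table"` and have no p-values or peptide counts; they
pass those filters vacuously and each query emits a notice saying so. CSV
export is RFC-4180 with full float precision and round-trips losslessly.

## Synthetic data generator

The generator emulates the screen the pipeline assumes, at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 2000 | quantified protein groups (mid-depth instrument) |
| `n_substrates` / `n_down` | 40 / 10 | spiked rows with +/− effect in the silenced arm |
| `effect_log2` | 2.0 | spike size, log2 (4-fold LFQ) |
| `base_mean` / `base_sd` | 26 / 2.5 | log2 abundance distribution across proteins |
| `replicate_sd` | 0.3 | per-replicate technical noise, log2 |
| `n_reps` | 3 | replicates per arm |
| `dropout_midpoint` / `dropout_slope` | 22.5 / 1.5 | logistic detection curve, log2 units |
| `n_decoys` / `n_contaminants` | 20 / 15 | flagged rows exercising the filters |
| `unique_peptide_lambda` | 6 | unique peptides ~ 1 + Poisson(λ) |

Per protein, true abundance `a ~ N(base_mean, base_sd²)`; each sample value
is `a + effect·[silenced] + ε`, `ε ~ N(0, replicate_sd²)`; a value is
observed with probability `sigmoid((value − midpoint)/slope)` — the logistic
left-censoring that the downshifted-normal imputation is meant to model.
QC-panel genes are generated at `base_mean + 3` with zero effect and are
never missing. GlyGly files carry 1–3 sites per spiked substrate with
localization probabilities ~ U(0.5, 1). Everything derives from one seed;
identical configs produce byte-identical files.

What the generator does *not* emulate: peptide-to-protein rollup,
correlated (batch) noise, intensity-dependent variance, shared peptides
between groups, or instrument-specific depth. Passing recovery tests on
synthetic screens therefore demonstrates the pipeline's statistical logic
under the stated model, not performance on any particular instrument.

`score_recovery` evaluates a call list against the truth:
sensitivity = |called ∩ spiked-up| / n_substrates (undetected spikes count
against sensitivity) and FDP = |called \ spiked-up| / max(1, |called|).

## Measured operating point and known limitations

Under the default generator settings the full pipeline, averaged over 20
seeds, reaches sensitivity ≈ 0.76–0.80 with FDP ≈ 0.10–0.12 on the spiked
substrates, and calls ≈ 0.2% of proteins on null screens (no spiked
effects). Two intrinsic mechanisms bound this operating point, and both are
properties of the downshifted-normal workflow itself rather than of this
implementation:

* a substrate with even one imputed replicate receives a draw centred
  ~`1.8·s_col` (≈ 4 log2 units) below the column bulk, inflating its
  within-group variance; with 3 + 3 replicates (df = 4) the pooled *t* then
  often misses `p < 0.05` even at large fold changes. This is the very
  distortion the imputation-count rule polices, at the cost of sensitivity
  for low-abundance substrates.
* a null protein near the detection limit that happens to drop out of all
  control replicates but none of the silenced ones passes the rule through
  its "fully observed condition" clause and inherits a positive fold change
  from the downshifted control mean — the dominant source of false
  discoveries. The same pattern is, for true substrates, the expected
  signature of strong enrichment, so the rule cannot exclude it without
  losing exactly those calls.

Other numerical choices: zero-variance t-tests degrade gracefully (see
above); `p = 0` is replaced by the smallest positive float before −log10;
fold changes at the threshold boundary are included (see threshold
semantics); all file parsers are locale-independent (decimal point only).
Store queries on records lacking a filtered field pass vacuously with a
notice rather than silently excluding published evidence.
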