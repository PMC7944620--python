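# triadtrack

Homoeolog histone-modification and expression bias analysis for
polyploid wheat triads.

Allopolyploid bread wheat carries three homoeologous subgenomes (A, B,
D); 17,753 syntenic gene *triads* have a 1:1:1 A:B:D correspondence.
`triadtrack` implements, as a tested and reusable pipeline, the
gene-level analysis of whether the A and B homoeologs of each triad are
symmetrically marked by a histone modification (H3K4me3, H3K27me3) or
expressed (RNA), and how those per-triad states move across genotypes
during domestication (wild tetraploid WTW → domesticated tetraploid
DTW → extracted tetraploid ETW) and ploidy transition (hexaploid donor
TAA10 → ETW → resynthesised hexaploid XX329).

## The method

For each triad, genotype and assay, gene-level counts are converted to
TPM (per-sample columns sum to 10⁶) and the A/B pair is normalised
within the triad:

    rel_A = TPM_A / (TPM_A + TPM_B),   rel_B = 1 − rel_A

A triad is **modified** when TPM_A > 0.5 or TPM_B > 0.5 (strict).
Modified triads are assigned the category of the nearest Euclidean
anchor in the (rel_A, rel_B) plane:

    A = B → (0.5, 0.5)     A > B → (1, 0)     A < B → (0, 1)

so the balanced/biased boundary sits exactly at rel_A = 0.25 and 0.75.
Categories are tracked across a three-genotype series and collapsed to
four transition classes (Group I–IV for domestication, Pattern I–IV for
ploidy transition; see `triadtrack.tracking` for the exact rules).
Supporting statistics: exact binomial test for A-vs-B subgenome
asymmetry, Yates-corrected two-proportion tests, Wilcoxon rank-sum for
modification levels, hypergeometric GO enrichment with Benjamini–
Hochberg FDR, Pearson replicate QC, chromosomal-zone (R1/R2a/C/R2b/R3)
distributions, and modification–expression concordance tables.

The package ships a first-class synthetic-data generator
(`triadtrack.simulate`) that emits the exact input file contracts with
planted categories, planted transition labels, and negative-binomial
count noise, so every stage of the pipeline can be validated against a
recoverable ground truth.

## Worked example

```python
import triadtrack as tt

cfg = tt.domestication_config(n_triads=2000, seed=1)
ds = tt.simulate_series(cfg)
tpm = tt.tpm_matrix(ds.counts, ds.triads.gene_lengths())
calls = tt.classify_dataset(tt.aggregate_replicates(tpm), ds.triads)

wtw = calls.query("genotype == 'WTW' and assay == 'H3K4me3'")
mod = wtw[wtw.category != "unmodified"]
n_gt = (mod.category == "A_gt_B").sum()
n_lt = (mod.category == "A_lt_B").sum()
res = tt.binom_asymmetry(n_gt, n_lt)
print(f"WTW H3K4me3: {len(mod)} modified triads, "
      f"A>B {n_gt} vs A<B {n_lt}, binomial p = {res.p_value:.3g}")

tracks = tt.track_series(calls, ["WTW", "DTW", "ETW"], "domestication")
tab = tt.tabulate_tracks(tracks)
for _, row in tab.query("assay == 'H3K4me3'").iterrows():
    print(f"Group {row.label}: {row['count']:4d} triads "
          f"({100 * row.proportion:.1f}%)")
```

prints

```
WTW H3K4me3: 1658 modified triads, A>B 123 vs A<B 73, binomial p = 0.000436
Group I: 1437 triads (88.2%)
Group II:   78 triads (4.8%)
Group III:   54 triads (3.3%)
Group IV:   60 triads (3.7%)
```

Of 2,000 simulated triads, 1,658 carry H3K4me3 above threshold in the
wild tetraploid; the A subgenome is significantly more often the
dominant homoeolog (123 vs 73, exact binomial p ≈ 4×10⁻⁴); and 88.2% of
tracked triads keep the same A/B category through the whole
WTW → DTW → ETW series (Group I).

The same analysis is available from the shell:

```sh
triadtrack simulate --out-dir sim --seed 1 --series domestication
triadtrack classify --config sim/config.yaml --out-dir results
triadtrack track --config sim/config.yaml --series domestication --out-dir results
```

Core steps are also exposed as sklearn-style estimators
(`TriadBiasClassifier`, `SeriesTracker`) that compose with sklearn
pipelines and `clone`/`get_params`.

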