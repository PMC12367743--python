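# ifnsig

Desk-scale toolkit for paired pre/post peripheral-blood transcriptome
analysis: per-patient log2 fold changes and threshold DEG calling,
hierarchical clustering of fold-change profiles against outcome labels,
hypergeometric overrepresentation analysis, a single-sample rank
random-walk gene-set score, a signed z-score interferon signature score
(batch mean-centering → genewise z-scores → ±1 coefficients → signed sum),
and exact two-group clinical statistics (Fisher, chi-square,
Mann–Whitney, Welch, log-rank). A synthetic cohort generator plants
outcome-linked expression modules (type I/II/III interferon, B-cell,
coagulation), batch offsets and Gaussian log-scale noise so every stage
is testable without external data.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria: reference
Fisher's exact values, exhaustive-enumeration oracle equivalences,
planted-structure recovery over 20 seeds, null calibration, and the
analytic invariants.

## CLI

All tabular formats are plain TSV (UTF-8, tab-separated, `.` decimal);
gene sets are GMT with an optional two-column `gene<TAB>±1` sign sidecar.

```sh
# simulate the default 6-patient cohort (3 BRT survivors; 3 TC, 2 deceased)
ifnsig simulate --seed 1 --outdir sim/

# stage-wise
ifnsig deg --expr sim/expression.tsv --meta sim/metadata.tsv \
           --group outcome=survivor --fc 1 --p 0.05 --out degs.tsv
ifnsig enrich --degs degs.tsv --gmt sim/gene_sets.gmt --direction down --out ora.tsv
ifnsig ifnscore --expr sim/expression.tsv --meta sim/metadata.tsv \
                --gmt sim/gene_sets.gmt --out ifn
ifnsig clinstats --clinical sim/clinical.tsv --survival sim/survival.tsv --out table.tsv

# everything at once (TSV bundle + manifest.json; byte-deterministic per seed)
ifnsig run-all --seed 1 --outdir results/
```

`run-all` accepts `--config config.yaml` overriding the defaults shown by
`ifnsig.pipeline.default_config()` (DEG thresholds, clustering distance/
linkage/k, enrichment direction and τ, signature sets, z-score options).

## Notes on conventions

- Expression is log2-scale throughout; fold change is `post − pre`.
- DEG filter: `|mean log2FC| ≥ 1` and raw `p < 0.05` (one-sample t on
  per-patient paired differences); BH q-values are reported but unused.
- Clustering default: 1 − Pearson correlation, average linkage.
- The set-variation score is an ssGSEA-style integral walk statistic
  (weight `|z|^τ`, τ = 0.25 default), a documented stand-in for
  kernel-based GSVA.
- Fisher's exact test uses the two-sided point-probability rule computed
  in exact integer arithmetic.
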