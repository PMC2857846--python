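# File formats

All files are plain text (TSV or CSV with header rows).  Every writer/reader
pair round-trips exactly; readers validate and report the offending
row/column on error.

## Genotypes — `genotypes.tsv` (TSV)

| column | type | meaning |
|---|---|---|
| `individual_id` | string, unique | individual identifier |
| one column per SNP (header = snp id) | integer ∈ {1, 2, 3} | genotype code: 1 = 00, 2 = 01 or 10, 3 = 11 |

## Phenotypes — `phenotypes.csv` (CSV, long format)

| column | type | meaning |
|---|---|---|
| `individual_id` | string | phenotyped individual |
| `time` | numeric | observation time |
| `yield` | numeric | trait record |

One row per record; the pair (`individual_id`, `time`) must be unique.
Reading sorts by individual then time.

## Pedigree — `pedigree.csv` (CSV)

| column | type | meaning |
|---|---|---|
| `individual_id` | string | offspring id |
| `sire`, `dam` | string | parent ids |
| `family` | integer | full-sib family index |
| `set` | `training` or `candidate` | phenotyped vs genotype-only |

## SNP map — `snp_map.tsv` (TSV)

| column | type | meaning |
|---|---|---|
| `snp_id` | string | marker id (matches genotype columns) |
| `chrom` | integer | chromosome (1-based) |
| `pos_morgan` | float | map position within chromosome, Morgans |

## Truth tables (simulated data only)

`truth_qtl.csv`: `param` (`asym`/`xmid`/`scal`), `chrom`, `pos_morgan`,
`snp_id` (or `hidden` for QTL placed between markers), `effect` (allele
substitution effect on that growth parameter).

`truth_tbv.csv`: `individual_id` plus per-parameter true breeding values
`asym`, `xmid`, `scal` (each column mean-zero over all offspring).

## Pipeline outputs

* `fits.csv`: `individual_id`, `A`, `B`, `C`, `residual_ss`, `r_squared`,
  `converged` — one row per successfully fitted training individual.
* `posterior_<analysis>.tsv` (analysis ∈ A, B, C, t600): `snp_id`, `chrom`,
  `pos_morgan`, `incl_prob`, `alpha_mean`, `alpha_rescaled` (effects divided
  by the largest absolute effect of that analysis).
* `gebv.csv`: `individual_id`, `set`, `gebv_A`, `gebv_B`, `gebv_C`,
  `gebv_t600_I`, `gebv_t600_II` — centered GEBVs for every genotyped
  individual.
* `correlations.tsv`: square table over the GEBV vectors, Pearson below the
  diagonal, Spearman above.
* `snp_report.tsv`: per-SNP rescaled effects and inclusion probabilities for
  all four analyses side by side.
* `summary.txt`: π and variance posterior means per analysis, fit-failure and
  domain-clip counts, any recorded analysis failures.
* `manifest.yaml`: stage, seed, full configuration, config hash and library
  versions — sufficient to reproduce the run bit-identically.

## Configuration file (YAML)

```yaml
sim:            # any SimConfig field, e.g.
  n_families: 100
  n_snp: 453
mcmc:           # chain schedule overrides
  burn_in: 2000
  n_samples: 600
  thin: 5
```

Command-line flags (`--seed`, `--profile`, `--t-target`) override file
values.  Profiles: `desk-scale` (2000/600/5) and `full-scale`
(10000/10000/50).
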