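# polyrate

Analyses of subgenome evolution in allopolyploid genomes, exercisable
end-to-end on synthetic data with planted ground truth:

- **synthetic_data** — simulators for every input the pipeline consumes:
  codon alignments evolved on a dated amphidiploid species tree (two diploid
  progenitor proxies, five polyploids with A/D subgenome tips, an outgroup),
  gene presence/absence with planted gain/loss events, LTR element pairs
  diverging since a drawn insertion age, and phased SNP panels with planted
  low-recombination blocks plus matching methylation/contact tracks and
  genetic-map points.
- **divergence** — gap-aware p-distance, Jukes–Cantor correction,
  set-wide substitution totals, and NG86 Ka/Ks with shortest-pathway
  averaging.
- **rate_inference** — relative-rate testing via one-tailed Wilcoxon
  signed-rank on per-gene distance differences (exact null for small n,
  Bonferroni over test families), per-gene rate-shift classification, and
  chi-square tests on substitution totals.
- **dating** — molecular-clock conversion `T = Ks / (2 r)` with
  `r = 3.48e-9` substitutions/site/year by default, for species pairs and
  LTR insertion ages.
- **genome_composition** — k-mer frequency spectra with cumulative curves,
  and greedy >90%-identity TE clustering with shared/specific
  classification.
- **gene_flux** — diploid-anchored presence/absence filtering and
  per-branch gain/loss inference by loss-favoring Sankoff parsimony.
- **recomb_epigenome** — MAF/missingness panel filtering, D' with bootstrap
  confidence bounds, Gabriel-style haplotype-block (cold-spot) calling,
  Marey-map recombination rates by local linear regression, and
  cold-vs-hot correlation of methylation and chromatin-contact summaries.
- **cli** — a `polyrate` command orchestrating all stages with YAML config
  and a JSON run report.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes independent oracles (exhaustive NG86 pathway
enumeration, Wilcoxon sign-assignment enumeration, brute-force Sankoff
labelings, direct D' formula, naive column scans), statistical calibration
checks (type-I rate, power monotonicity, direction correctness) and
planted-structure recovery tests. `tests/test_acceptance.py` holds the
acceptance criteria, one test per criterion.

## CLI

```bash
# simulate fixtures and run every stage into out/
polyrate all --outdir out --seed 1

# individual stages (simulate first, or point --outdir at existing fixtures)
polyrate simulate --outdir out --seed 1
polyrate divergence --outdir out
polyrate rates --outdir out
polyrate date --outdir out
polyrate recomb --outdir out

# input validation with line-level diagnostics
polyrate validate --vcf out/panel.vcf --track out/meth_CG.tsv
```

Stage parameters (clock rate, D' thresholds, LOESS span, window sizes,
MAF/missingness filters, contact-intensity threshold, ...) are exposed via
a YAML config passed with `--config`; the resolved configuration and
per-stage record counts are echoed into `out/report.json`.

## File formats

Per-gene FASTA alignments (`taxon|subgenome|gene` record ids), Newick with
branch lengths in years (clock rate in a leading comment), VCF v4.2 with
phased GT, bedGraph-dialect TSV tracks (0-based half-open), TSV tables,
JSON truth manifest. All genomic intervals are 0-based half-open
internally; VCF positions are 1-based.
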