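# ribopause

Analysis toolkit for inhibitor time-course transcriptomics, driven end to end
by a built-in synthetic-data generator so every stage runs and is validated
without external downloads. Stages:

- **annotation** — parse GTF/GFF3 + genome FASTA into filtered, frame-validated
  gene models (one concatenated CDS per gene, codon index with
  segment-boundary flags).
- **synthetic** — deterministic fixture generator: transcriptomes with planted
  codon-bias genes, inhibitor time-course count matrices under exponential
  decay, paired ribo/RNA per-nucleotide coverage with planted pause sites, and
  nucleotide pileups with planted transcriptional errors and genomic variants.
  Every planted label is emitted in a truth table.
- **tdd** — translation-dependent decay indexing: CPM, stable-gene detection,
  stable-gene median-of-ratios size factors, per-mRNA TDD index
  `(R_TciTli - R_Tci) / R0`, per-gene linear model with a t-test on the
  condition effect, increased/decreased/unchanged classification.
- **peaks** — differential ribosome-density peak calling on RNA-normalized
  Ribo-seq coverage (cNorm → cDiff → cMean → threshold mean + 3 SD → runs →
  scores → filters), run in both directions (TC and CC).
- **composition** — codon/amino-acid statistics: matched-control randomization
  tests on peaks (10 000 control sets, empirical p with a 1/10 000 floor, BH),
  zero-inflated beta regression contrasts between gene sets, relative
  frequencies, codon window profiles around peaks, Kyte–Doolittle hydropathy.
- **enrichment** — amino-acid enrichment of labeled protein lists against
  proteome-sampled controls (`p_emp = (min(k,l)+1)/(n+1)`), GO/GAF list
  assembly, and the signed heatmap transform `1 - p_adj * s`.
- **mutations** — transcriptional-mutation tallies from pileups: depth
  subsampling, QUAL/depth/allele-fraction filters, per `REF>ALT` SNP-site
  proportions, logistic-regression comparison between conditions with relative
  frequencies.

## CLI

```sh
ribopause init-config config.yaml   # write the default YAML config
ribopause all --config config.yaml  # simulate -> ... -> report
ribopause simulate --config config.yaml   # or any single stage:
# simulate | annotate | tdd | peaks | composition | enrich | mutations | report
```

Outputs land under `outdir` from the config (default `ribopause_out/`), one
sub-directory per stage, plus a JSON manifest per stage (parameters, seeds,
input/output SHA-256) under `manifests/` and a markdown summary under
`report/` that includes truth-table recovery metrics. Runs are fully
deterministic for a fixed `seed`; per-stage sub-seeds are derived from it.

## Library use

```python
from ribopause.synthetic import SimConfig, simulate_transcriptome
from ribopause.peaks import bidirectional_call
from ribopause.composition import peak_randomization_test
from ribopause import tdd

cfg = SimConfig(n_genes=50, seed=1)
tx = simulate_transcriptome(cfg)
```

See module docstrings for the full API.
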