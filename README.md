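# sumovar

Lysine sumoylation site prediction and classification of amino-acid variants
by their effect on sumoylation.

The package implements a complete, testable pipeline:

- **`sumovar.seqio`** — FASTA/TSV I/O, substitution-token parsing
  (`Lys386Asn`, mixed `Lys477T`), lysine-centered 21-mer fragment extraction
  with `X` padding, labeled dataset construction (positives at annotated
  sites, negatives at every other lysine of the same proteins), and a greedy
  fragment-identity redundancy filter.
- **`sumovar.features`** — five encoder families (physicochemical
  properties, CKSAAP k-spaced pair composition, secondary structure,
  accessible surface area, PSSM profiles), F-score feature ranking and
  forward best-first wrapper selection with repeated cross-validation.
- **`sumovar.model`** — a balanced-negative ensemble of RBF-kernel SVMs
  (defaults C=8, γ=0.001953, 10 negative sets), probability output as the
  unweighted member mean, repeated stratified 10-fold cross-validation, and
  probability cutoffs calibrated to 70/80/90/95% specificity from held-out
  negative scores. Models persist as a JSON manifest plus per-member array
  blobs — no pickles.
- **`sumovar.metrics`** — Ac/Sn/Sp/MCC from confusion counts and ROC/AUC
  (trapezoid rule, tie-grouped cutoffs).
- **`sumovar.amvr`** — variant typing: I(−) removes a sumoylated lysine,
  I(+) creates one, II(±) flips a neighboring site within ±10 residues, III
  changes the recognition context of a site that stays modified. Works
  annotation-driven (before/after site sets) or model-driven (thresholded
  ensemble probabilities), plus sweep reports across specificity levels and
  per-class summaries with enrichment tests. The curated worked-example
  tables ship as package data.
- **`sumovar.stats`** — Pearson chi-square and Fisher exact contingency
  tests, two-sample-logo per-position residue enrichment, and motif-x-style
  iterative motif extraction with exact binomial p-values.
- **`sumovar.synthetic`** — synthetic proteomes with planted ΨKxE-context
  sites at configurable fidelity, fabricated PSSM/structure files, and
  variant sets whose ground-truth types are guaranteed by construction.

## CLI

```sh
sumovar simulate --out data --seed 7 --n-proteins 50 --n-sites 120
sumovar train --fasta data/proteome.fasta --sites data/sites.tsv \
              --out model --seed 7
sumovar evaluate --fasta data/proteome.fasta --sites data/sites.tsv \
                 --out eval --seed 7
sumovar predict --model model --fasta data/proteome.fasta --out pred.tsv
sumovar classify-variants --model model --fasta data/proteome.fasta \
                          --variants data/variants.tsv \
                          --levels default,0.90 --out calls
sumovar sweep --model model --fasta data/proteome.fasta \
              --variants data/variants.tsv --out sweep
sumovar stats --fasta data/proteome.fasta --sites data/sites.tsv --out stats
```

A YAML file passed as `sumovar --config conf.yaml <command>` pre-populates
options (one section per subcommand); explicit flags win. Every command
writes a `run.json` manifest with seed, config hash and versions; rerunning
with the same seed reproduces the outputs byte for byte.

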