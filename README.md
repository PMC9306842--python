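# gmycsampler

Taxon-resampling sensitivity analysis for single-locus species
delimitation with the single-threshold GMYC (Generalized Mixed Yule
Coalescent) model, plus concordance metrics that score molecular
delimitations against user-predefined groups (morphospecies, ecotypes).

The package provides five building blocks:

- **`gmycsampler.data_io`** — FASTA alignments, ultrametric trees
  (newick/NEXUS, translate tables honored), CSV group tables
  (`sample_name,group`), and the branching-event schedule (ordered
  waiting times with per-interval lineage bookkeeping) consumed by the
  GMYC likelihood.
- **`gmycsampler.resampler`** — random subsampling of alignments without
  replacement at chosen fractions and replicate counts, optionally
  guaranteeing one representative per predefined group; deterministic
  per seed.
- **`gmycsampler.gmyc_model`** — the single-threshold GMYC fit: a
  diversification rate class above a time threshold and a within-species
  coalescent class below it, analytic rate profiling, a threshold scan
  over inter-node midpoints, a likelihood-ratio test against a
  single-class null, species partitions, entity/cluster/singleton
  counts, and Akaike-weight node support.
- **`gmycsampler.concordance`** — per-species classification (merge type
  I/II, split, exact, singleton), the y/n match table, percentage
  matches with/without singletons, splitting ratios, singleton
  percentage, per-group split factors, exact match scores and incidence.
- **`gmycsampler.ensemble`** — means, sample SDs and t-based 95%
  confidence intervals per subset fraction, and accumulation-curve
  tables.
- **`gmycsampler.synthesizer`** — ground-truth simulation: Yule species
  trees, coalescent-within-species gene trees (via msprime), JC69
  sequences, and a byte-stable 16-tip/8-group worked-example fixture.

## CLI

```sh
# simulate a truth set (tree.nwk, groups.csv, optional seqs.fasta)
gmycsampler simulate --species 10 --samples 5 --coal-scale 0.02 --seed 1 \
    --sequence-length 400 --out sim/

# subsample the alignment, keeping every group represented
gmycsampler resample --alignment sim/seqs.fasta --fraction 0.5 \
    --replicates 10 --seed 7 --groups sim/groups.csv \
    --ensure-representation --out subsets/

# fit the single-threshold GMYC model to one or more ultrametric trees
gmycsampler delimit --trees sim/tree.nwk --format newick --df 3 \
    --out gmyc/gmyc_results.csv

# score GMYC partitions against the predefined groups
gmycsampler score --partitions gmyc/ --groups sim/groups.csv \
    --out metrics.csv

# aggregate replicate metrics across subset fractions
gmycsampler summarize --metrics replicates.csv --out summary.csv \
    --curves curves.csv --total-records 500
```

## Notes

- Node heights are measured from the tips (tips at 0); thresholds live on
  that scale.
- Trees must be rooted, binary and ultrametric within a relative
  tolerance (default `1e-6` of depth); tied node heights are jittered
  deterministically.
- Sequence names are matched to tree tips on the first
  whitespace-delimited token of the FASTA description line.
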