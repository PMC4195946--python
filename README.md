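# herv-nahr

Genome-wide prediction of human endogenous retrovirus (HERV) pairs capable
of mediating non-allelic homologous recombination (NAHR), with the
downstream analyses needed to study the CNVs they produce:

* **annotation_io** — readers/writers for UCSC-style RepeatMasker tables
  (rmsk TSV and `.out` dialects), FASTA, BED, genomicSuperDups segdup
  tables; joins RepeatMasker fragments sharing an ID into candidate
  elements.
* **pair_finder** — the pair screen: elements ≥ 4 kb, same chromosome and
  orientation, 10 kb–10 Mb apart, locally aligned (affine-gap
  Smith–Waterman, gap extension −25) with identity ≥ 94% over ≥ 2 kb, and
  exclusion of pairs overlapping directly oriented high-identity segmental
  duplications.
* **susceptibility_map** — merges pair spans into susceptibility regions
  and computes per-chromosome / genome coverage.
* **cnv_crossref** — probe-bounded breakpoint-uncertainty intervals,
  CNV-to-pair matching, and flanking-probe placement for a targeted array.
* **breakpoint_mapper** — catalogues cis-morphisms (paralogous sequence
  variants) between the two elements of a pair, localizes a junction
  sequence's crossover between informative cis-morphisms, and computes
  uncertainty widths / CNV sizes; windowed identity profiles.
* **clustering_test** — Monte-Carlo test for breakpoint clustering inside
  an aligned pair (median all-pairs distance statistic, identity-eligible
  null positions mapped to the nearest upstream cis-morphism, lower-tail
  empirical p with add-one correction).
* **hotspot_analysis** — PWM scan for the degenerate 13-mer recombination
  hotspot consensus (`CCNCCNTNNCCNC`), genome-background sampling, exact
  Poisson cluster-enrichment test and rank-based density comparisons.
* **synthetic_data** — seeded simulator for all of the above: planted
  element pairs at controlled divergence, fragmented annotations,
  recombinant junctions, probe grids and planted motifs, with recorded
  ground truth.

## CLI

```sh
herv-nahr simulate --config sim.yaml -o simdir/          # synthetic dataset
herv-nahr pairs --rmsk rmsk.tsv --genome genome.fa -o pairs.tsv
herv-nahr regions --pairs pairs.tsv --chrom-sizes chrom.sizes -o regions.bed --stats stats.tsv
herv-nahr crossref --cnvs cnvs.tsv --pairs pairs.tsv --rmsk rmsk.tsv --genome genome.fa -o flagged.tsv
herv-nahr breakpoints --junctions junctions.fa --pairs pairs.tsv --rmsk rmsk.tsv --genome genome.fa -o bp.tsv
herv-nahr cluster --alignment aln.fa --breakpoints bp.txt --n-sets 10000 --seed 17 -o cluster.json
herv-nahr hotspots --elements elems.fa --genome genome.fa --seed 17 -o hotspots.json
herv-nahr design --pairs pairs.tsv --rmsk rmsk.tsv --genome genome.fa -o probes.bed
herv-nahr run --config pipeline.yaml -o outdir/          # pairs -> regions -> crossref
```

Every output table begins with `#` provenance lines (tool version,
parameters, input checksums, RNG seed).

## Conventions

Coordinates are 0-based half-open internally; printed reports are 1-based
inclusive. Alignment identity counts identical columns over all alignment
columns (gap columns included; a gap-excluded mode is available). Element
separation is measured between inner edges. The aligner's deterministic
tie-break conventions are documented in `herv_nahr/_sw.py`.
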