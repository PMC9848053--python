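# hicscaf

Chromosome-scale scaffolding of genome assemblies from Hi-C read pairs.

Given assembly contigs (FASTA) and Hi-C read-pair alignments (pairs TSV,
BED-style interval pairs, or SAM/BAM), hicscaf:

1. optionally **breaks contigs** at Hi-C spanning-coverage valleys
   (candidate misassemblies);
2. builds a **chunked contact matrix** per resolution, with cells inside a
   contig (*intra*) and between contigs (*inter*);
3. estimates an **expected-contact profile** E(d) — the median intra-cell
   count at each chunk separation d, zeros included, forced
   non-increasing — and scores every candidate contig join in all four
   orientations as `sum(obs) / sum(E)` over the near-diagonal band, so a
   true neighbour scores ≈ 1;
4. builds a **scaffolding graph** over contig ends and simplifies it
   (low-score filtering, tip trimming, blunt-end trimming, repeat solving,
   transitive-edge removal, bubble popping, orientation resolution,
   weak-edge trimming, ambiguous-edge removal), then traverses paths;
5. repeats over a **ladder of increasing chunk sizes**, feeding each
   round's scaffolds into the next;
6. optionally **re-checks joins** after scaffolding and dissolves those
   without bridging coverage;
7. writes **AGP v2.1 + scaffold FASTA** plus a breaks report.

A truth-tracking simulator (`hicscaf.synthetic_data`) and a
provenance-based evaluator (`hicscaf.evaluation`) make the whole pipeline
testable offline: random multi-chromosome genomes, uniform fragmentation
into contigs, injected intra-/inter-chromosomal and double misjoins, and
Hi-C pairs with power-law distance decay plus uniform trans noise.

## CLI

```sh
# scaffold an assembly
hicscaf scaffold -a contigs.fa -p pairs.tsv \
    [-e GATC,GANTC] [-r 10000,20000,50000,...] [-q 10] \
    [--no-break] [--no-post-check] [-o prefix] [--seed N] [--config cfg.txt]

# generate a synthetic benchmark with known truth
hicscaf simulate --n-chromosomes 20 --chrom-length 1000000 \
    --misjoins 10,10,5 --seed 1 -o sim
```

`scaffold` writes `<prefix>_scaffolds_final.agp`,
`<prefix>_scaffolds_final.fa`, `<prefix>_breaks.tsv` and `<prefix>.log`.
The canonical pairs dialect is a 6-column TSV
`contig1 pos1 contig2 pos2 mapq1 mapq2` with 0-based positions; name-grouped
SAM/BAM from a standard Hi-C mapping pipeline works directly. All
thresholds can also be given as a `key=value` config file.

## Library layout

| module | role |
| --- | --- |
| `hicscaf.formats_io` | FASTA / pairs / AGP / scaffold-FASTA readers and writers |
| `hicscaf.contact_matrix` | chunk index, sparse contact matrix, expected profile, cut-site normalization |
| `hicscaf.join_scoring` | four-orientation join scores, candidate enumeration |
| `hicscaf.scaffold_graph` | graph build, simplification cascade, traversal |
| `hicscaf.error_correction` | spanning coverage, breakpoint detection, contig breaking, post-scaffold join check |
| `hicscaf.pipeline` | multi-round orchestration, coordinate lifting, CLI config |
| `hicscaf.synthetic_data` | genome/fragmentation/misjoin/Hi-C simulators with truth maps |
| `hicscaf.evaluation` | N50/L50-style stats, misassembly classification, correction scoring |
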