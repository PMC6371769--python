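# File formats

All tabular formats are tab-delimited text with a fixed header line; lines
starting with `#` are comments. All coordinates are 0-based, half-open
`[start, end)` except AGP output (1-based, inclusive, per AGP v2.1).
Readers reject missing columns and invalid intervals with the offending
line number; all writers round-trip through their readers.

## blocks (`ref_blocks.tsv`, `outgroup_blocks.tsv`)

Pairwise alignment blocks (the tabular product of an external aligner's
chain/net stage).

```
query_id  query_start  query_end  subject_id  subject_start  subject_end  strand  identity
```

`strand` is `+`/`-` (query relative to subject); `identity` in [0, 1].
For the scaffold-vs-reference table the query is a scaffold; for the
reference-vs-outgroup table the query is a reference chromosome.

## pairs (`pairs.tsv` or SAM)

One row per mapped proper read pair; the interval is the *insert* (outer
span of the pair) on the scaffold.

```
pair_id  scaffold_id  left_start  right_end  proper
```

`proper` is `0`/`1`. A text SAM file may be supplied instead; mapped
proper pairs are normalised to the same table using the leftmost mate's
position and template length.

## gene_map (`gene_map.tsv`)

Gene-to-scaffold alignment fragments (used to infer reliable adjacencies).

```
gene_id  scaffold_id  start  end
```

## marker_map (`marker_map.tsv`)

The ordered gene-marker map: one row per marker, `map_order` increasing
along each chromosome.

```
marker_id  chromosome_id  map_order
```

## marker alignments (`markers.tsv`)

Best-hit alignments of marker CDSs to scaffolds; `span_fraction` is the
fraction of the CDS covered by the alignment.

```
marker_id  scaffold_id  start  end  span_fraction  identity
```

## chrom_map (`chrom_map.tsv`)

Chromosome-to-outgroup homology pairings (FISH-style map); each
(chromosome, outgroup_chrom) pair appears once, `segment_index` numbering
the homology segments along the chromosome.

```
chromosome_id  outgroup_chrom  segment_index
```

## pcr_results (`pcr_results.tsv`)

Two-round junction verification verdicts. Outcomes are `amplified`,
`none`, `unexpected_size` (round 1 only) or `untested`.

```
junction_id  round1  round2_a  round2_b
```

`junction_id` is `<left_sf>|<right_sf>` as emitted in the candidate table.

## truth (`truth.tsv`, simulator output)

Per-scaffold provenance on the true genome; one row per scaffold part.

```
scaffold_id  part_index  true_chrom  true_start  true_end  orientation  is_chimera
```

## SFs (`sfs.tsv`) and PCFs (`pcfs_run*.tsv`)

Stage outputs; `.` denotes an absent optional value.

```
sf_id  scaffold_id  scaffold_start  scaffold_end  ref_chrom  ref_start  ref_end  orientation  outgroup_chrom  outgroup_start  outgroup_end  outgroup_strand
pcf_id  sf_index  sf_id  orientation  next_source  next_support  next_spanning  next_score
```

## AGP (`chromosomes.agp`)

Standard AGP v2.1: `W` rows place PCF components (1-based component
coordinates, orientation `+`/`-`/`?`), `N` rows are fixed-length scaffold
gaps (`scaffold`/`yes`/`align_genus`).
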