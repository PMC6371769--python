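# Methods

This note records the model behind `refchrom`, the conventions chosen where
the procedure admitted more than one reading, and what the synthetic-data
generator does and does not emulate.

## Model and assumptions

The reconstruction treats a scaffold assembly as a bag of intervals to be
ordered along a related reference genome, with three assumptions:

* **Colinearity above a resolution.** Homology segments of at least 150 kb
  (`resolution`) between a scaffold and the reference are trustworthy units
  (syntenic fragments, SFs); shorter blocks are noise-prone and dropped.
  Scaffolds of 10 kb or less are excluded outright (`min_scaffold_length`,
  strict inequality) to avoid spurious alignments.
* **Two independent witnesses for a target-specific arrangement.** A
  junction inside a scaffold that contradicts the reference may be a real
  lineage-specific rearrangement or a mis-join. The outgroup breaks the
  tie: if the outgroup shows the same arrangement as the scaffold, the
  junction stands; if both comparative channels are discordant, the
  junction is putatively chimeric and the read pairs decide.
* **Physical coverage separates real joins from chimeras.** The number of
  inserts whose outer span strictly contains a position ("physical"
  coverage, as opposed to read coverage) is approximately the genome-wide
  rate at any real junction and zero at a chimeric join, because no true
  fragment spans two distant loci.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `resolution` | 150 000 | bp | minimum target-side SF span |
| `min_scaffold_length` | 10 000 | bp | scaffolds kept iff strictly longer |
| `merge_max_gap` | 10 000 | bp | max query/subject gap when chaining colinear blocks; chosen small relative to `resolution` |
| `min_intracov_run1` | 5 | % of median physical coverage | run-I split threshold |
| run-II threshold | calibrated | % | derived from verification, never user-set (unless overridden) |
| `max_test_interval` | 6 000 | bp | junctions testable iff break interval strictly smaller |
| `adjacency_tolerance` | 100 000 | bp | max reference-coordinate gap for "adjacent"; below SF resolution |
| `marker_span_min` | 0.8 | fraction | marker hits kept iff CDS span strictly greater |
| `map_resolution` | 3 000 000 | bp | homology runs below this cannot falsify a PCF |
| `gap_length` | 100 | bp | N gap between SFs / PCFs in sequence output |

## Conventions chosen where the procedure was open

* **Junction window.** The window-size parameter of the coverage stage is
  interpreted as: junction coverage is the **minimum** spanning count over
  10 positions evenly spaced across a 1 kb window centred on the junction
  (widened to cover the whole break interval in the pipeline). The minimum
  makes the statistic sensitive to any uncovered gap inside the window.
* **Coverage percentage base.** `coverage_pct` is the spanning count as a
  percentage of the genome-wide **median** physical coverage, sampled every
  `coverage_sample_step` (1 kb) at interior positions. A median-relative
  definition is reproducible on any instance without external calibration
  data.
* **Adjacency score.** The probabilistic adjacency model of the original
  reference-assisted assembler is not reproduced; the score is the
  documented deterministic combination `1` for reliable junctions, else
  `0.5·comparative_support + 0.5·min(1, coverage_pct/100)`, where
  comparative support is the mean of the available channel indicators
  (reference colinear? outgroup colinear?). Junctions without read-pair
  evidence (joins between different scaffolds) take coverage 0 in the
  formula, capping their score at 0.5 — they are genuinely less supported.
  The decision-relevant boundary (comparative conflict × coverage
  threshold) is preserved.
* **Chaining priority.** When two join rules address the same SF end,
  reliable adjacencies outrank intact intra-scaffold junctions, which
  outrank reference-order adjacency; a reliable adjacency that contradicts
  an intact intra-scaffold junction is an error (inconsistent prior
  knowledge). Cycles — possible only through pathological edge sets — are
  broken at their lowest-scoring edge and logged.
* **Threshold calibration.** The calibrated threshold is the minimal
  *observed* coverage among confirmed junctions such that every classified
  junction at or above it is confirmed (exhaustive-search equivalent,
  property-tested). Whether a published threshold of this kind is an
  observed value or a midpoint between two observations is ambiguous; the
  observed-value convention is used here. Verification is applied to all
  comparative-conflict candidates (not only those run I happened to break),
  which guarantees the calibration sees both classes whenever they exist.
  When a run has no confirmed or no non-confirmed tests the calibration is
  undefined and run II reuses the run-I threshold.
* **Round-1 products of unexpected size** count as round-1 failures
  eligible for round 2 (conservative: the original arrangement is not
  positively confirmed).
* **Marker order rule.** "At least two markers in the same order" is
  implemented as strict monotonicity of PCF position versus map order over
  all retained hits; a single discordant marker among three or more routes
  the PCF to breaking. Markers from two different chromosomes on one PCF do
  the same. After one break-and-replace round, still-disagreeing PCFs stay
  in the assembly as unplaced (the inseparable-fragment case).
* **Naming.** SFs are lettered `a, b, c, …` per scaffold in coordinate
  order (spreadsheet-style beyond `z`); PCFs are numbered `PCF_1, PCF_2, …`
  by descending length; children of a broken PCF get `a`/`b` suffixes.
* **Degenerate inputs.** Single-SF PCFs take their SF's orientation and are
  flagged low-confidence. Ties in reference start order break on scaffold
  id; marker best-hit ties break on span, identity, then PCF id (logged).

## The synthetic-data generator

`synthetic_data.simulate` produces instances in which every downstream
decision has a known right answer:

* chromosomes are i.i.d. uniform A/C/G/T (no repeat model — repeats matter
  to the externalised aligner, not to the coordinate-driven logic tested
  here);
* the reference differs from the target by sampled inversions, reciprocal
  translocations, fissions and fusions (≥150 kb events); the outgroup is
  derived from the reference by an independent sample, which reproduces the
  real ambiguity that reference-lineage changes are visible in both
  comparative channels;
* scaffolds partition the genome minus fixed 1 kb inter-scaffold gaps;
  every segment is at least `min_segment_length` (200 kb) so that each
  survives the SF resolution filter; chimeric scaffolds concatenate two
  segments from different chromosomes or ≥1 Mb apart, so truth labels are
  unambiguous; each part is reverse-complemented with probability 0.5;
* read pairs (inserts uniform in [250, 750] bp) are drawn from the *true*
  genome and kept only if the whole insert lies inside one scaffold part —
  exactly what a proper-pair mapper would report — so chimeric joins
  receive zero spanning pairs and real junctions sit near the expected
  physical coverage (`pair_coverage`, default 20×);
* genes (2–30 kb) occasionally straddle inter-scaffold gaps, producing
  gene-span reliable adjacencies; markers are 3 kb CDSs at known ordered
  positions; the homology map lists (chromosome, outgroup chromosome)
  pairings of runs ≥ `map_resolution`, hiding shorter segments as a
  FISH-style map would.

Everything is deterministic given the config seed (stage-specific seed
sequences), and the writer emits byte-identical files across runs.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: alignment error and repeat-induced spurious
blocks, mapping artefacts and duplicate reads, insert-size dispersion
beyond the uniform model, assembly base errors, and wet-lab PCR failure
modes (primer dropout, unexpected products arise only if injected through
the verdict table).

## Problem sizes used by the test suite

The suite runs on five-chromosome, 2 Mb-per-chromosome genomes fragmented
into 40 scaffolds (≈400 k read pairs at 20×), with a 400 kb map resolution
standing in for the FISH scale at 2 Mb chromosome size; the oracle
equivalence checks use 100 instances of 2 × 1 Mb chromosomes and 8
scaffolds with up to 3 rearrangements, 1 000 random length lists for the
N50 definition, and 100 random verdict tables for the calibration search.
These sizes were chosen so each property is exercised by dozens of
junctions per instance while the whole suite stays interactive.

## Known limitations

* One reference plus one outgroup; no multi-reference reconciliation or
  ancestral-karyotype inference.
* Map-based breaking performs a single repair round; a PCF whose markers
  still disagree afterwards is left unplaced rather than iteratively
  dissected.
* PCFs lacking both markers and unambiguous homology-map support remain
  unplaced; nothing in the inputs can anchor them.
* The AGP writer emits fixed-length `N` gaps (100 bp default); real
  inter-fragment gap sizes are unknown to the method.
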