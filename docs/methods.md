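# Methods

## Problem and model

`aliensnp` discovers SNP markers that separate an alien (wild-relative)
chromosome arm from *all* homoeologous copies of a polyploid crop, and then
uses those markers to detect and delineate alien introgression segments in
derived breeding lines. The motivating setting is hexaploid wheat
(AABBDD): a wild-relative arm introduced by wide hybridisation is invisible
to ordinary SNP panels because any assay site usually differs between the
A, B and D homoeologues themselves. A marker is diagnostic only when the
three homoeologues share one identical allele and the alien arm carries
another; in any plant that combines wheat chromosomes with alien chromatin
such a marker reads *heterozygous*, which is exactly the signature the
introgression caller exploits.

The discovery pipeline mirrors the chromosome-genomics workflow it
implements: single-end short reads from a purified alien chromosome arm are
quality-trimmed, mapped independently against each homoeologous assembly
under a strict mismatch budget, piled up and called per reference, and the
three filtered call sets are intersected under a flank-identity constraint.

## Pipeline stages and their parameters

**Read QC** (`reads`). Terminal bases with phred ≤ 15 are trimmed from both
ends inward (interior bases are never altered); a trimmed read is kept iff
it is strictly longer than 30 bp and ≥ 80% of its bases have phred ≥ 15.
`N` calls count against the 80% rule whatever their score (conservative
choice; the rule is about trustable bases, and an `N` is not one). Length
is checked before the bulk-quality rule; the two checks are independent, so
the order cannot change the kept set. Defaults: `qual_floor=15`,
`min_len=30` (strict), `min_frac=0.8`, phred+33 encoding.

**Mapping** (`align`). Ungapped end-to-end placement on both strands, one
reference at a time, reporting the unique placement with the fewest
mismatches when that minimum is ≤ `max_mismatch` (default 3). Reads whose
best score is tied across two or more placements are deliberately left
unmapped (`ambiguous`): a tie usually means paralogous or repeat placement,
and a variant supported by arbitrarily assigned reads is exactly the kind
of false signal the trio intersection cannot repair. A `--random-best`
mode (seeded) reproduces report-one-of-the-ties behaviour for comparison.
Completeness is structural, not heuristic: the read is split into
`max_mismatch + 1` disjoint chunks, so any qualifying placement matches at
least one chunk exactly (pigeonhole); the index is queried with a 16-bp
prefix of each chunk and every candidate is verified by full comparison.
Reads shorter than `(max_mismatch + 1) × 16` bp fall back to exhaustive
scanning, so agreement with a brute-force all-offsets oracle is exact by
construction, which the test suite verifies on thousands of random reads
including planted ties and 4-mismatch decoys. `N` in read or reference
always counts as a mismatch (an `N` match carries no evidence). All
contigs of one reference FASTA form a single search space; uniqueness is
judged across contigs and strands together. External aligners can replace
this stage entirely via SAM import (NM tag used when present, mismatches
recomputed otherwise; unmapped/secondary/supplementary records skipped;
records above the mismatch budget dropped and counted).

**Calling** (`variants`). The sample is a single chromosome arm, so the
model is haploid: one alt allele per site. Because the original workflow's
"SNP quality" is the opaque score of an external caller, this package
defines quality explicitly as the phred-scaled binomial tail

    quality = −10·log10 P(X ≥ alt_count),  X ~ Binomial(depth, ε),

with ε implied by the mean phred of the alt-supporting bases, capped at
1000 to avoid log-of-underflow. This makes the conventional cut-offs —
depth ≥ 4 and quality ≥ 50, both inclusive — meaningful and testable: the
suite checks emitted qualities against direct `math.comb` tail summation to
1e-6 phred. Alt ties break by higher quality sum, then lexicographically
(flagged `ambiguous_alt`); sites whose second allele exceeds 20% of depth
are flagged `het_flag` (possible contamination or collapsed paralogy) but
still called. SNP density is reported as filtered SNPs per kb of *covered*
reference sequence — the closest well-defined quantity to "analysed bases";
reference length can be substituted via the coverage summary if preferred.

**Trio intersection** (`specific`). For each filtered call on the anchor
homoeologue (A by convention), the `(2·flank + 1)`-base window centred on
the SNP is searched for in the B and D references, both strands, requiring
the two 100-bp flanks to match exactly (the centre base is excluded from
the identity requirement) and requiring exactly one hit per reference.
Exact full-length search is used instead of a seeded local aligner
because the method demands 100% flank similarity anyway — wherever a
seeded aligner would matter, the site is rejected regardless — and exact
search is fully deterministic. A site is alien-specific iff the three
wheat alleles agree, the alien alt differs, *and* concordant filtered calls
exist at the B and D hit positions. Requiring both reference-base
agreement and concordant calls is the strictest reading of
"same alleles on all homoeologues"; `require_calls_on_all=False` relaxes to
reference bases only. Reverse-strand hits are compared on the reverse
complement and reported on the anchor's forward strand.

**Marker candidates.** A specific site is promoted to assay candidate iff
no other filtered anchor call lies within 100 bp (a variant under a primer
footprint destroys allele-specific PCR) and, when a de-novo alien assembly
is supplied, the anchor window with the alien allele substituted at centre
has a unique exact full-length match in the contigs — the guarantee that
primers designed on the wheat flank amplify the alien template too.
Without contigs that check is recorded `untested` rather than silently
passed. Candidates get serial ids `gsnp_<arm><n>` in anchor-coordinate
order; every rejected site is written with a reason code
(`flank_mismatch`, `trio_discordant`, `nearby_variant`, `no_contig_hit`,
…) so the two flank filters remain separable in the output.

**Introgression mapping** (`introgression`). Genotypes per (line, marker)
are `WHEAT_HOM / HET / ALIEN_HOM / MISSING`; counts can be converted with
`genotype_from_counts` (MISSING below depth 4; homozygous outside the
0.2–0.8 alien-fraction band). HET and ALIEN_HOM both count alien-positive,
because dosage depends on how many wheat homoeologues remain (a
substitution line lacks one). Lines classify `NO_ALIEN` at alien fraction
0, `WHOLE_ARM` at ≥ 0.9, else `PARTIAL`; `UNCALLED` when everything is
missing. The 0.9 default places a 97%-heterozygous whole-arm carrier on
one side and 25%/8% translocations on the other, and deliberately
tolerates sub-threshold assay noise instead of demanding 100%. Segments
are maximal runs of alien-positive calls in marker order; `noise_tolerance`
interior wheat calls may be absorbed per run (default 0), and MISSING
neither supports nor interrupts a run. Breakpoints between markers are
unobservable, so segment bounds are reported as marker indices and as
half-open coordinate intervals extending to the next marker.

## The simulator: what it emulates, and what it does not

`simulate` generates the full data geometry from a random ancestor:
three homoeologues at `trio_divergence` substitutions/site per branch
(default 0.01) and an alien arm at `alien_divergence` (default 0.02) —
divergence ratios chosen so that the alien-vs-anchor distance (~3%) makes a
substantial fraction of 100-bp reads exceed the 3-mismatch budget, as in
the real setting where only 23–30% of alien reads mapped. Planted truth
sites come in three classes: clean alien-specific sites (the marker ideal;
their ±100-bp windows are kept substitution-free), homoeologue-discordant
sites (B carries a third allele; must be rejected), and flank-contaminated
sites (a second alien variant within 100 bp; called specific but never
promoted — both members of the pair are recorded as contaminated since a
per-site scan cannot tell them apart). Every remaining alien-vs-anchor
difference is recorded as `background`. Planted sites keep > 200 bp
pairwise spacing and 100 bp from sequence ends; an explicit sizing error is
raised when the requested counts cannot fit.

Reads are single-end, default 100 bp at 30× with per-base error 1e-3; the
total count is fixed at `round(coverage·L/read_length)` and distributed
over 1-kb windows by a multinomial whose weights carry a lognormal
multiplier (`coverage_bias_sd`, default 0.3) emulating amplification bias
of whole-genome-amplified sorted chromosomes. Strands are assigned by
balanced quota, then shuffled. Body quality declares the simulated error
rate (phred 30 at 1e-3; 40 in the error-free limit); 10% of reads are
emitted entirely at phred 2 (QC must discard them) and 30% carry a short
appended phred-2 junk tail (QC must trim it). The synthetic "de-novo
assembly" is the alien arm sliced into 20-kb contigs: since evolution is
substitution-only, fragmentation is the only assembly artefact modelled,
and 20 kb keeps the unavoidable flank-spans-boundary loss near 1% of
candidate sites.

Deliberately *not* modelled: indels (coordinates stay shared across the
four sequences, which makes truth bookkeeping and test oracles exact — no
detection step assumes it), structural variation, paralogy and repeat
families, chromosome-sorting contamination by wheat fragments
(~7% in the real sorted fraction), and within-accession heterozygosity of
the alien donor. Passing tests therefore demonstrate the *logic* of the
method — intersection, flank filters, funnel, segment calling — under
realistic divergence, coverage bias and error, but say nothing about
repeat-rich genomes or assembly error, where the ambiguity-dropping mapper
and the unique-flank-hit requirements are the intended first line of
defence.

The genotype-panel generator emits clean calls for whole-arm carriers,
terminal translocations and null lines; translocation breakpoints always
retain a wheat stub of more than 10% of markers, because a "translocation"
whose alien fraction reaches the whole-arm band is, at marker resolution,
definitionally a whole-arm carrier (the real lines span 5–75% of the arm).

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open; 1-based conversion
  happens only at VCF and marker-sheet boundaries; BED stays 0-based.
* Quality cap 1000; binomial tails below ~1e-320 saturate to the cap.
* Thresholds are inclusive throughout (`depth ≥ 4`, `quality ≥ 50`,
  trim `≤ 15`, bulk quality `≥ 15`); read length after trimming is strictly
  `> 30`.
* Flank windows truncated by a contig end reject the site (`edge`) rather
  than shrinking the window — a shorter flank would weaken the uniqueness
  guarantee silently.
* Zero covered bases makes SNP density undefined (`None`), not 0.
* Rerunning any stage with identical inputs, config and seed is
  byte-identical; the run manifest stores content hashes and no
  timestamps.

## Problem sizes used by the test suite and acceptance script

The simulated study runs on a 200-kb trio with 150/50/30 planted sites at
30× coverage (~60,000 reads), three times (noisy, noisy-rerun for
determinism, error-free limit); the mapper oracle comparison uses 20
references ≤ 5 kb × 1,000 reads; the QC oracle 10,000 random quality
strings; the call-quality oracle 100 random columns; the panel 12 lines ×
40 markers. These sizes keep every distributional check (recall ≥ 95%,
zero leakage of discordant/contaminated sites, 3-σ count checks) well
clear of small-sample noise while the whole suite stays in the
single-digit-minute range.

## Known limitations

* The mapper is ungapped by design; indel-tolerant mapping must come
  through SAM import, and alien-vs-wheat indels would surface as mapping
  dropouts, not calls.
* The binomial quality model ignores correlated errors and mapping error;
  its absolute scale is honest but not calibrated to any external caller's
  score.
* Flank uniqueness is judged per reference file; a multi-arm or
  whole-genome reference would make the uniqueness requirement stricter
  than intended.
* The introgression caller assumes markers ordered on one anchor arm and
  at most moderate missingness; it reports marker-interval resolution and
  will not invent sub-interval breakpoints.
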