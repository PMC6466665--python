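# Methods

## The completeness model

Completeness is estimated as the fraction of a curated marker set that can
be recovered from the input sequence. The underlying assumption is that
the markers are (nearly) universally present in the clade of interest, so
an assembly that fails to yield them most likely failed to capture the
corresponding genomic regions. Three marker classes are used:

- **Protein families**: orthologous groups from reference species,
  including deliberately *multi-copy* families — unlike single-copy-only
  marker sets, these additionally let the tool detect collapsed repeats.
- **Highly conserved DNA elements (HDEs)**: non-coding segments ≥ 200 bp
  whose members share ≥ 70% identity, searched at the nucleotide level.
- **Copy-number expectations**: for each multi-copy family, the minimum
  copy count observed across a survey of reference genomes.

## Profiles and thresholds

Each family alignment becomes a position-specific scoring matrix. Columns
with ≥ 50% gaps are dropped; a retained column scores residue *a* as

    s(a) = log2( (c(a) + w·b(a)) / (n + w) / b(a) )

with observed count `c(a)`, column occupancy `n`, pseudocount weight
`w = 1`, and background `b` (uniform by default). Scores are in bits. `X`
(and `N` for nucleotide profiles) scores 0 everywhere; a stop codon (`*`)
scores −8 bits, so translated junk terminates extensions quickly.

`score_sequence` computes the best local alignment of a sequence against a
profile by dynamic programming with a flat 2-bit penalty per skipped
column or skipped residue; the empty alignment scores 0. Flat penalties
keep the scoring exactly reproducible by a brute-force oracle, which the
test suite exploits.

The family detection threshold is **80% of the lowest member self-score**,
so every member of the family passes its own family's threshold by
construction while unrelated sequences fall far short. HDE elements reuse
the same rule; the element counts as detected when its best genomic hit
reaches the threshold.

Candidate families are retained only if (i) they span at least
`ceil(0.99 × n_species)` reference species and (ii) they are unambiguous:
every member's self-score must exceed its score against every other
candidate family's profile by more than `paralog_margin` (default 0 bits,
i.e. self must strictly win). The margin rule replaces an E-value cutoff:
uncalibrated PSSM scores have no meaningful E-value, but the intent —
membership must be decidable from the alignment score alone — is the same,
and two near-identical (paralogous) candidate families eliminate each
other symmetrically.

## Homology search

The search is a native seed–extend–chain pipeline rather than a wrapper
around external aligners and gene predictors; the chained alignment *is*
the gene model.

1. **Translation.** Every contig is conceptually translated in six frames
   (standard code, `*` kept, N-containing codons → `X`). Coordinates are
   0-based half-open and always reported on the forward strand.
2. **Seeding.** Exact 4-mer matches between family member peptides and a
   frame peptide start extensions. Seeding on the members (not the profile
   consensus) guarantees recall on sequences resembling any member. A
   member k-mer is only usable when its residues occupy consecutive
   profile columns, so the extension diagonal is well defined.
3. **Extension.** Ungapped extension in both directions against the PSSM,
   terminated when the running score falls 20 bits (X-drop) below its
   running maximum. Same-diagonal overlapping hits keep the best score;
   hits under 15 bits are discarded. Extensions are batched in numpy with
   a 64-step window, re-extending the rare unterminated hits, so
   genome-scale scans stay fast in pure Python.
4. **Chaining.** Per family/contig/strand, HSPs are chained by DP:
   successors advance strictly in gene-oriented genome coordinates and in
   profile coordinates, genome gaps (introns) are capped at 10 kb, profile
   overlaps at 10 columns, with overlapped columns charged at the
   lower-scoring HSP's per-column rate so no score is double-counted. For
   more than 24 HSPs the DP confines predecessor checks to the intron
   window (the result is the same optimum; ties then resolve to the first
   candidate in canonical coordinate order instead of the full
   lexicographic exon-fingerprint rule used at small n — at realistic
   float scores exact ties essentially never occur).
5. **Classification.** A model is **aberrant** if its peptide is at least
   2.0× the family mean length; else **complete** if it reaches the family
   threshold with coverage ≥ 0.70 of profile columns; else **partial** if
   it reaches 30% of the threshold; otherwise it is discarded. Boundaries
   are inclusive. Completeness is always defined by "complete" only;
   complete-or-partial is reported alongside so users fragmented at the
   contig scale can see both.
6. **Copy counting.** After extracting the best chain, its HSPs are
   removed and chaining repeats, so multiple gene copies on one
   contig/strand are all reported. Peeling stops after the first chain
   below the family threshold: weaker chains cannot change the family
   status or the copy count. Copies are counted at distinct loci (< 50%
   reciprocal overlap); a multi-copy family with fewer threshold-passing
   distinct loci than expected is flagged as potentially collapsed.

### Noise floor

With 4-mer seeds and a 15-bit HSP floor, a large random genome produces
low-scoring spurious HSPs, and the chain DP can string some of them into
chains that clear the 30% partial floor (observed ≈ 60% of a typical
threshold at 2 Mb scale, well short of "complete"). Consequence: on very
incomplete assemblies some truly missing families may be reported
*partial* rather than *missing*. The complete percentage — the headline
number — is unaffected; the tests assert zero complete models on random
sequence. Score calibration (E-values) is deliberately out of scope.

## Read mode

Reads are grouped into blocks of `block_size` (default 10⁴) sequences;
`n_blocks` (default 1000) blocks are drawn by single-pass reservoir
sampling (Algorithm R) so the read file is streamed once and never held in
memory. Blocks are scanned one at a time against the not-yet-detected
families; a family counts as detected when any read yields an HSP at
≥ 30% of its threshold (reads cover gene fragments, so the partial floor
is the coherent choice). Scanning stops after `stop_patience` (default 20)
consecutive blocks with no new family, or when blocks run out. An
"unsuccessful attempt" is one scanned block with zero gain, and the
counter resets on any gain — so gains in blocks 1 and 15 delay the
earliest possible stop to iteration 35.

## Synthetic data: what it emulates and what it does not

The generator produces the ground truth the test suite measures against:

- **Families**: a random ancestor peptide (~200 residues by default) with
  members carrying independent substitutions at a 0.1/site divergence —
  matching the regime where every member still clears the 80% threshold.
  No indels, so the trivial ungapped alignment is exact.
- **Genomes**: i.i.d. background nucleotides at a target GC with each
  family's first member reverse-translated (uniform codon usage) and
  inserted at recorded, non-overlapping loci on random strands; multi-copy
  families are inserted `expected_min_copies` times; HDE members are
  inserted verbatim. Optional introns (≤ 2 per gene, 50–500 bp) exercise
  the chaining path.
- **Truncation**: non-overlapping windows (default 5 kb — the scale of a
  lost assembly segment) are deleted uniformly (length-weighted across
  contigs) until the removed total first crosses the target fraction;
  each deletion splits its contig, as a real assembly gap would.
- **Reads**: uniform positions and strands, normal-truncated lengths
  (default 8 kb ± 1 kb, floor 500 bp), substitution errors only. Indel
  errors are deliberately excluded: the homology engine is not
  frameshift-tolerant (a stated non-goal), so indels would test an
  undefined behavior rather than the sampling and detection logic.

Passing tests on this material demonstrates the bookkeeping, scoring,
chaining, sampling and stopping logic under known truth. It does **not**
demonstrate sensitivity on real fungal genomes — real markers diverge
non-uniformly, real genomes have repeats, codon bias and soft-masked
regions, and real long reads have indels. All generators are
bit-reproducible given (parameters, seed).

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `seed_k` | 4 residues | exact-match seed length (protein) |
| `hde_seed_k` | 12 bases | seed length for nucleotide elements |
| `xdrop` | 20 bits | extension termination drop |
| `min_hsp_score` | 15 bits | HSP reporting floor |
| `max_intron` | 10 kb | genome gap cap inside a chain |
| `max_profile_overlap` | 10 columns | profile overlap cap inside a chain |
| `coverage_complete` | 0.70 | profile coverage needed for "complete" |
| `partial_floor` | 0.30 | fraction of threshold for "partial"/read detection |
| `aberrant_factor` | 2.0 | length multiple defining "aberrant" |
| `presence_fraction` | 0.99 | species-presence filter (ceil applied) |
| `paralog_margin` | 0 bits | required self-vs-cross score margin |
| `block_size` | 10,000 reads | read-block size |
| `n_blocks` | 1000 | blocks reservoir-sampled |
| `stop_patience` | 20 | zero-gain blocks before stopping |
| `pseudocount_weight` | 1.0 | PSSM pseudocount mass |

## Numerical and design choices

- N50 is a length and L50 a count (the modern convention; some older texts
  swap the names). "First reaches half" is inclusive: a cumulative sum
  landing exactly on half the assembly counts, so `[5,5,5,5]` gives
  N50 = 5, L50 = 2.
- Headers are truncated at the first whitespace and duplicate ids are an
  error — ids key every downstream map. Lowercase (soft-masked) bases are
  uppercased, not treated as masked; `U`→`T`; ambiguity codes other than
  `N` map to `N` with a warning.
- Each FASTA record is one contig; N runs are not treated as scaffold
  breaks.
- Test and acceptance problem sizes (2 Mb genomes, 20–40 families, 5
  truncation replicates, 20× read coverage with 100-read blocks) were
  chosen as the smallest scales at which the statistical assertions have
  power; the statistical tolerances are 99% binomial intervals and a
  χ² test at α = 0.01 for reservoir uniformity.
- The report schema (TSV for humans, JSON that round-trips losslessly) is
  this package's own; marker sets are tar archives of plain FASTA
  alignments plus a JSON manifest carrying params, thresholds and copy
  expectations, so a bundle is inspectable with standard tools.

## Known limitations

- No splice-site model: introns are handled purely as chain gaps, so exact
  exon boundaries are approximate within a few residues.
- No frameshift tolerance; indel-rich sequence degrades detection.
- Score thresholds are uncalibrated (no E-values); the noise floor grows
  with genome size, affecting the partial/missing boundary (see above).
- The collapse audit cannot distinguish a collapsed repeat from a genome
  that truly lost a copy, nor from unassembled duplicated data.
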