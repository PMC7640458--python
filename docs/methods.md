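# Methods

## The quantification model

A gene's transcript set defines, for each transcript, an ordered list of
splice junctions: one per adjacent genomic exon pair, identified by the
1-based inclusive coordinates of the last base of the upstream exon
(`donor_end`) and the first base of the downstream exon
(`acceptor_start`).  A junction present in exactly one transcript of the
supplied set is *discriminating*: any read whose spliced alignment skips
precisely that interval is evidence for that variant and no other.
Uniqueness is judged within the supplied transcript set only — if the user
passes only protein-coding isoforms, a junction shared with an unlisted
retained-intron transcript would still be called discriminating.  Variants
all of whose junctions are shared are reported as unquantifiable rather
than dropped: they are invisible to junction-based counting and the user
must know.

Junction identity is strand-agnostic and counting operates in genomic
space; transcript orientation matters only for exon ranks and spliced
sequences (for a minus-strand gene, rank 1 is the genomically rightmost
exon and the mRNA sequence is the reverse complement of the concatenated
exons).

## Counting and filters

Spliced reads are recognized by skipped-region (`N`) CIGAR operations.
For each skip, the donor is the last reference base consumed before it and
the acceptor the first after; coordinates must match a catalogue junction
exactly, with no tolerance.  A read supports a junction only if it
contributes at least `min_anchor` aligned reference bases on both sides
(default 8 nt, "at least" inclusive — the same floor as the 8-base
junction-overlap rule used for junction-spanning qPCR primers; soft clips
never count, insertions consume no reference, deletions do).  Record-level
filters: mapped, primary, non-duplicate, non-supplementary records with
mapping quality ≥ `min_mapq` (default 0).  Paired-end mates count as
independent records.

Denominators are collected in the same pass: `total_reads` is every record
passing the record-level filters regardless of splicing (robust to
secondary-alignment inflation; a raw record count is available by relaxing
the flags), and `gene_reads` the subset overlapping the gene's genomic
span.  Both SAM and BAM are read by streaming the full file, so the
denominator never depends on index statistics and text and binary inputs
agree exactly.

Per variant,

- SJ TPM = junction reads / `total_reads` × 10⁶ (a zero-read library is an
  error, never a silent 0/0);
- gene-relative fraction = junction reads / `gene_reads`, reported as
  proportion and percent.

A variant with several discriminating junctions is quantified by summing
its junction counts before normalizing; the per-junction breakdown stays
in the counts table.  Fractions of different variants are not forced to
sum to 1 — discriminating-junction counts are not a partition of gene
reads — and the report header says so.

Aggregation: replicate averaging takes the arithmetic mean of SJ TPM and
fractions per donor (counts and denominators are summed so collapsed rows
remain valid count tables); group summaries report mean and sample SD
(ddof = 1, 0 for singletons); presence is the number of samples with raw
junction count ≥ a detection threshold (default 1 filtered read).  The
share-of-total-isoform-signal summary is provided in two flavors — pooled
(sum SJ TPM over samples, then normalize) and per-sample-then-averaged —
because the two weight deep samples differently and neither is canonical.

## The simulator

`synthetic_data` generates a toy gene (canonical transcript of `n_exons`
exons plus exon-skipping variants, the topology that creates
discriminating junctions) on a random contig, then emits already-aligned
SAM records: each read independently spans variant junction *j* with
probability `p_j`, is an unspliced read inside the gene span with
probability `gene_unspliced_fraction`, or is unspliced background
elsewhere on the contig.  Spliced reads get CIGARs `aM nN bM` with the
left anchor drawn uniformly over the feasible range (bounded by the
flanking exon lengths and the optional `anchor_min`/`anchor_max`), correct
POS, reference-matching SEQ, 50/50 forward/reverse FLAGs, and fixed base
qualities; MAPQ is configurable (default 60) to exercise the mapping-quality
filter.  A `TruthSet` records every assignment, so realized counts are known
exactly, and all randomness flows from a single integer seed
(identical configurations are byte-identical on disk).

Default regime and what it emulates: single-end 100 nt reads (the deeply
sequenced production libraries this mirrors are 100 bp single-end at
~2×10⁸ reads; ENCODE-style sets span ~75–200 bp), 10⁵ reads per library —
depth is emulated in ratio, not volume — per-junction probabilities down
to 10⁻³ (the ~0.7%-of-gene scale reported for lowly expressed variants),
a minus-strand gene by default (as *P4HB* is), exons of 120–300 nt and
introns of 200–1500 nt, and 2% of reads as unspliced gene reads.  Not
emulated: sequencing errors and mismatch profiles, fragment-length
correlation between mates, soft clipping, multi-mapping, expression-level
full-transcript coverage structure, and any aligner idiosyncrasies.
Passing tests therefore demonstrate the correctness of the counting and
normalization arithmetic under ideal alignments, not robustness to
alignment artifacts in real data.

One consequence worth knowing: with anchors uniform over [1, L−1], the
default 8-nt anchor filter removes roughly 2·7/(L−1) ≈ 14% of true
junction reads at L = 100, so SJ TPM under stringent filters
underestimates p·10⁶ by that factor.  Parameter-recovery experiments
therefore count at `min_anchor` 1, where the estimate is unbiased and
binomial; the anchor filter is exercised separately (boundary and
monotonicity checks, and an all-short-anchor regime that must drive
filtered counts to zero).

## Protein-level projection

Splice variants share exact exonic blocks with the canonical protein, so
variant products are aligned to the canonical by longest-matching-block
decomposition (ties resolved leftmost) rather than scored pairwise
alignment; sequences sharing no block of ≥ 5 aa are rejected as unrelated.
Domain coordinates are user-supplied input (TSV of name, start_aa,
end_aa) — the package never invents them.  Each domain is classified
intact / truncated / absent from the retained canonical positions; a CGHC
motif counts as surviving only when all four of its positions are
retained; KDEL must be the exact C-terminal tetrapeptide; start/stop-codon
flags are computed from the annotated CDS when given and reported unknown
otherwise (several real variants lack a classical start or stop, so
absence of annotation is information, not an error).

## Primer checking

A variant-specific qPCR primer must overlap the discriminating junction by
at least 8 bases on both the 5′ and 3′ sides (inclusive).  In-silico PCR
is exact-match and case-insensitive over A/C/G/T (ambiguity codes are
rejected), requires a unique site per primer, and reports the inclusive
amplicon from the forward-site start to the reverse-site end.  No melting
temperature, mismatch tolerance, or thermodynamics: a single mismatch
aborts amplification, which is the conservative contract for validating
published primer sequences.  `PrimerPair` enforces assay-realistic primer
lengths (≥ 15 nt); `in_silico_pcr` also accepts a bare `(fwd, rvs)` tuple
for shorter oligos.

The packaged `data/p4hb_primers.tsv` carries the published P4HB
junction-primer pairs with the assay's reported product sizes (89, 148 and
211 bp).  Predicting those sizes from sequence requires the corresponding
variant transcript sequences, which must be fetched online;
`synthetic_pcr_template` builds random templates with the primer sites
spaced to a given product size as a labelled-synthetic stand-in, which
verifies the matching and coordinate arithmetic but is not an independent
derivation of the published sizes.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere a user sees them; pysam's
  0-based half-open values are converted at the boundary.
- The counting filters default to: exact coordinate match, `min_anchor` 8,
  primary non-duplicate records, `min_mapq` 0.  "Stringent" is a policy
  knob; every report embeds the `FilterConfig` used.
- Problem sizes in the test and acceptance experiments: 10⁵-read
  libraries, 20 libraries for the recount-agreement check, 100 replicates
  × 4 junction probabilities (10⁻³–10⁻²) for recovery — sizes chosen so
  the binomial bounds are meaningful while a full run stays in the
  minutes range on one CPU.
- Determinism: simulation seeds feed `numpy.random.SeedSequence` with a
  stream index, so gene construction and read generation are independent
  and reproducible; pipeline reruns on identical inputs produce identical
  tables (the stamped header comment differs only if the config differs).
- Degenerate inputs fail loudly: empty libraries, zero gene reads,
  unreadable alignments, out-of-bounds exons or records, junctions with
  intron length < 1, overlapping exons, domains beyond the canonical
  length.

## Known limitations

- Discriminating means unique within the supplied transcript set; no
  genome-wide uniqueness check is attempted.
- No junction discovery: reads with unannotated junctions still count for
  any catalogue junction they span, but novel junctions are not reported.
- The simulator's idealized alignments mean filter behavior on noisy real
  BAMs (clipping, mismatches near junctions, duplicate structure) is not
  validated here.
- Fraction-of-gene normalization depends on the gene-span overlap
  definition (any overlap of a filtered record with the span), which
  includes intronic and antisense reads in the denominator.
- Protein projection assumes variants are exact block subsets of the
  canonical; frame-shifted tails that diverge in sequence simply appear
  as unmatched residues.
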