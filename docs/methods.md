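# Methods

## Problem and model

An RNA–DNA difference at a genomic site is evidence of RNA editing only
after three alternative explanations are excluded: sequencing error,
mapping artifact, and genomic variation.  `utcedit` operationalises this
as a pileup-based caller followed by two DNA filters and an orthogonal
chromatogram assay.  Coordinates are 1-based inclusive in every table and
file format; intervals are converted to half-open form only inside the
annotation routines.

**Conversion types.**  The 12 ordered substitution classes are expressed
on the transcript strand in the RNA alphabet.  For a genomic (ref, alt)
pair on a "+"-strand gene, both bases are transliterated T→U; on a
"−"-strand gene both bases are complemented first.  This map is a
bijection per strand, and the minus-strand classification equals the
plus-strand classification of the complemented pair — both properties are
checked exhaustively over all 24 (pair, strand) cases in the tests.
Legacy DNA spellings ("A-to-T", "G-to-T") are accepted by the parser and
normalised to A-to-U / G-to-U.  Intergenic sites are reported on the "+"
strand with gene id `NA`.

**Read QC.**  A read is discarded when (in this order) it is empty, it
contains the configured adapter as an exact substring, its `N` fraction
exceeds 10%, or more than 50% of its bases fall below Q20.  Both fraction
thresholds are strict: a 100-base read with exactly 10 Ns or exactly 50
sub-Q20 bases is kept.  Poly-N contamination is covered by the N-fraction
rule; no separate homopolymer scan is performed.  Adapter detection is
exact-substring only — fuzzy matching is out of scope, and whole reads are
discarded rather than trimmed.  In paired mode a failing mate discards
its partner.

**Placement.**  Clean reads are placed ungapped at their unique
minimum-mismatch position, with at most 2 mismatches tolerated; ties and
over-budget reads are left unplaced rather than guessed.  The search is
seed-and-verify: a read split into `max_mismatches + 1` chunks must, by
pigeonhole, have at least one chunk matching exactly at any admissible
placement, so the exact k-mer index yields a complete candidate set.  A
randomized brute-force oracle in the tests cross-checks placements,
including tie handling.

**Calling and filtering.**  Site depth is the A+C+G+T count (Ns are
tallied but excluded from depth).  An event requires, in at least one
sample, alt support ≥ 2 reads *and* alt fraction ≥ 0.05 (both
CLI-exposed).  The support floor of 2 keeps single stray reads —
overwhelmingly errors — out of the candidate list while still admitting
the low-coverage sites such surveys deliberately retain for follow-up.
The polymorphism rule removes events whose alt frequency is ≥ 0.999 in
every sample with nonzero depth: at high depth a single opposing error
read should not rescue a homozygous variant, and zero-depth samples carry
no information so they are ignored.  The blacklist rule removes events at
positions in a supplied known-variant table.  Spectrum percentages are
reported at integer precision (`round(100·n_type/n_total)`), the
convention for such summaries.

**Chromatogram model and efficiency.**  A trace is four non-negative
intensity series on a shared scan axis plus a base-call track.  The
synthetic generator places one Gaussian peak per called base (σ = 1.8
scan units on a 10-scan-per-base grid, amplitude 1000), hard-truncated to
the base's own scan window.  The truncation is deliberate: neighbouring
peaks then contribute exactly zero area to an adjacent call's window, so
the noiseless efficiency round-trip is exact to floating-point precision
rather than merely approximate; the price is a ~2.6% clip of each peak's
analytic mass (erf(4/(1.8·√2)) of it is retained), which cancels in all
area *ratios* because both site channels share the same shape.  Peak area
is the trapezoidal integral over the window bounded by midpoints to the
neighbouring calls (clipped at trace edges).  Editing efficiency uses
only the edited and unedited channels — neighbouring-peak signal on the
other two channels is irrelevant by construction of the ratio — and a
site with zero area in both relevant channels raises a no-signal error
rather than returning 0.  A *dual peak* requires the second-largest
channel area to reach 10% of the largest; the cutoff is the conventional
chromatogram heterozygosity threshold (the assay itself prescribes none)
and is CLI-exposed.  Confirmation demands a dual peak with nonzero edited
signal in ≥ 1 cDNA sample *and* a single-peak gDNA; a gDNA dual peak
flags genomic heterozygosity and vetoes the site outright.  Trace noise
is additive Gaussian per scan (σ expressed as a fraction of the peak
amplitude, intensities clipped at 0); at σ = 2% the mean absolute
efficiency-recovery error over 100 seeds stays below one percentage
point, which the test suite measures directly.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the discrimination
logic relies on: two samples; single-exon genes with contiguous
5′UTR/CDS/3′UTR blocks on either strand; planted editing sites whose
alt-read support is Binomial(coverage, efficiency) per sample, with
efficiencies defaulting to the 20–80% band observed for validated sites;
SNPs carried by 100% of reads in both samples; an i.i.d. per-base
substitution error channel (0.1% default, in the typical Illumina range);
and configurable fractions of adapter-tagged and poly-N reads to exercise
QC.  Per-site depth is Poisson in the direct pileup generator and emerges
from uniform read starts in the read generator — the sequencing-depth
distribution is this package's choice, as editing surveys do not pin one
down.  Everything is a pure function of the config (seed included), and
every planted feature is written to a truth table.

Not emulated — and therefore not demonstrated by passing tests: splicing
and indels (all simulated differences are substitutions and genes are
single-exon, so the ungapped placer suffices where real data needs a
splice-aware aligner), realistic quality-score profiles (qualities are
constant Q40; the low-quality QC rule is exercised with constructed
reads), strand-specific library artifacts, PCR duplicates, and
chromatogram pathologies such as baseline drift, dye blobs, or mobility
shifts.  Results on real traces depend on upstream base calling, which is
out of scope; the columnar trace TSV is the interchange format and its
schema is documented so converters from vendor formats can be written
externally.

## Packaged ledgers

`utcedit/data/candidate_sites.tsv` (56 rows: position, per-sample read
support, gene, description) and `utcedit/data/validated_sites.tsv`
(7 rows: position, edited-site feature, gene, per-sample peak-area
efficiency in percent) are verbatim transcriptions.  They contain
internal inconsistencies — a position↔gene pairing swapped between the
two tables, one efficiency quoted two ways, and three mutually
incompatible U-to-C gene counts — catalogued in `utcedit/data/errata.md`.
The parsers validate strictly (line-numbered errors) but keep the
efficiency columns verbatim so both ledgers round-trip byte-for-byte;
nothing in the code "fixes" a fixture.

## Numerical and design choices

- Frequencies at zero depth are NaN and excluded from every rule.
- Overlapping gene models are resolved first-by-start, ties by gene id;
  the generator never produces overlaps, so this is a tie-break contract,
  not a recommendation.
- The dual-peak boundary is inclusive (a secondary at exactly 10%
  counts), matching the strictness conventions stated for each QC rule.
- `n_genes = 0` is valid and yields an intergenic-only contig; an empty
  pileup yields an empty event stream; an empty candidate set reports
  UTR fraction `NA` rather than 0.
- Problem sizes in the shipped tests and acceptance script — e.g. 200
  planted sites at 1000-fold simulated coverage for the
  frequency-recovery check, ~9.8 kb genomes for end-to-end runs — were
  chosen as the smallest scales at which the binomial error bounds under
  test are meaningfully tight.

## Known limitations

The placer is exact but quadratic in repeat-dense references and intended
for the synthetic scale, not plant-genome scale; real surveys should feed
externally aligned pileups in through the pileup TSV instead.  The
polymorphism rule cannot distinguish a fixed editing site (100% edited in
every sample) from a homozygous SNP — a limitation inherited from the
design it implements, resolved only by the gDNA chromatogram assay.
Validation inside `run_pipeline` synthesizes traces from the planted
truth; it demonstrates the confirmation logic, not wet-lab concordance.
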