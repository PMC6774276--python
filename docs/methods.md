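# Methods

This note documents the models, conventions and numerical choices behind
`exoeval`, in the order data flows through the package.

## Coordinates and interval arithmetic

BED semantics throughout: 0-based, half-open `[start, end)`. A `RegionSet`
is canonical — per chromosome sorted, non-overlapping, with *adjacent*
intervals merged — so base-set identities (`|A∩B| + |A−B| = |A|`) hold
exactly and set equality is structural equality. VCF positions are 1-based;
the two conventions meet only in the membership test
`start < pos ≤ end`. Region restriction of a variant uses a point test on
its position, not its allele span; the exonic stratum in comparisons uses
the same convention. Chromosome names are compared by exact string
equality; no `chr`-prefix harmonization is attempted, on the grounds that
silent renaming hides input mismatches.

## Variant regularization

Regularization is the composition *split → decompose → left-align →
sort → deduplicate*:

- **Splitting** rewrites a k-allelic record into k biallelic records; the
  genotype is projected per alternate (indices of other alternates map to
  reference) with the original genotype retained as metadata.
- **Decomposition** turns an MNV into one SNV per mismatching position and
  splits complex alleles by a global Needleman–Wunsch alignment of REF vs
  ALT (match +1, mismatch −1, gap −2, deterministic leftmost-gap
  traceback). Gap runs become VCF-style indels anchored on the preceding
  reference base (right-anchored only at position 1). Primitives from one
  source record share a phase-set tag; since downstream matching is
  allele-level, phase affects reporting only. The contract is haplotype
  equivalence: substituting the primitives into the reference reproduces
  exactly the string the input allele produces (verified in tests, with
  indel-before-SNV application order at a shared anchor).
- **Left alignment** iteratively truncates equal trailing bases (extending
  left with the preceding reference base when an allele would empty) and
  trims equal leading bases while both alleles are length ≥ 2. The result
  is the unique minimal, leftmost representation; at the contig start the
  left extension is impossible and equal trailing bases are tolerated
  there. The normalizer is cross-checked against an exhaustive
  minimal-representation search and against `bcftools norm`.
- **Deduplication** collapses exact (chrom, pos, ref, alt) duplicates,
  keeping the highest quality, so equivalent representations cannot be
  double-counted as TPs.

N-containing alleles pass through normalization but never match any truth
allele. Symbolic alleles (`<DEL>`, breakends) are not representable and are
skipped with a warning count.

## Truth comparison

Matching is one-to-one on the normalized key; a genotype-aware mode
(unordered genotype must also agree) is available behind a flag, off by
default. Comparison refuses non-parsimonious input unless explicitly told
the input is raw (the pipeline's VCF1 stage). Percentages are rendered with
half-up rounding — two decimals for sensitivity/PPV, one for FP
reductions — matching how such tables are conventionally printed.
Undefined ratios (zero denominators) are `None`, deliberately distinct
from 0. Microarray concordance compares unordered diploid allele pairs on
shared sites, disregarding sites where both calls are homozygous
reference. The allele-fraction refilter keeps records with AF ≥ threshold
(boundary inclusive); records lacking AF are kept and counted in a warning.

## Error classification

`PileupEvidence` is a per-site summary (per-allele per-strand counts,
distances from the variant to the nearer read end with 1 = terminal base,
mean supporting base quality, call quality, homopolymer context, distinct
alternate count) standing in for a manual browser inspection. FP rules are
evaluated in a fixed, configurable precedence — strand bias, read end, low
quality, homopolymer, mixed allele, unknown — because several rules can
fire at once and a deterministic order is the least surprising resolution.
Boundary conventions: strand bias fires at exactly 2% minority-strand
fraction; read end requires *all* supporting reads within 5 bases (a
fraction threshold is available); quality exactly 20 does not fire;
homopolymer fires at run length exactly 4, where "at or next to" means the
run intersects the allele span padded by one base. FN causes are
flag-based: coverage below the 5X callable floor, alternate fraction in
(0, 0.2) (mirroring the caller's minimum-allele-frequency parameter),
mean base quality below 20, homopolymer context, and a signal-shift
marker. "Signal shift" has no sequence-level definition, so the classifier
only ever reads it as an externally supplied label (ground truth in the
simulator) and never infers it. Any library flag plus any sequencer flag
yields the top level "both"; no flags yields "unknown".

## Coverage statistics

Depth is binned into 45 fixed categories: `[0,5) [5,10)`, then 10X steps
to 400X, then `[400,600) [600,800) [800,1000) [1000,∞)` — the >400X tail
needs exactly four bins for the stated increments to reach 45, which is
asserted. Bin bounds are lower-inclusive/upper-exclusive, while the
callable interval [5X, 400X] is endpoint-inclusive; the two conventions
are deliberate and tested separately. The between-library Z-score
standardizes the per-bin coverage difference with the sample (n−1) SD —
material with only 45 bins — and is defined as all-zero when the SD is 0.
Differencing on raw base counts is the default; a normalized mode
(per-bin fractions) is provided for tracks over different region sizes.
Evenness is per-base depth divided by the track mean, with the
fraction-above-average using strict inequality.

## Read utilities

Downsampling is a Bernoulli keep per read with probability equal to the
requested fraction, driven by a hash of (seed, read id) rather than a
stream RNG, so results are order-independent and reproducible. Duplicate
marking groups reads by (chrom, start, end, strand) or by (chrom, strand,
5' position); within a group the read with the highest mean base quality
(ties: lexicographically smallest id) survives. Because start+end groups
refine 5'-only groups, the start+end flagged set is provably a subset of
the 5'-only flagged set on any input.

## The synthetic-data generator

The generator emulates two exome enrichment chemistries on a toy
single-chromosome reference (default 100 kb, uniform base composition)
with planted homopolymer runs (length 5–9, flanked by differing bases so
the recorded run length is exact) and tandem repeats. Two target designs
cover `[0, 0.85L)` and `[0.15L, L)`; their intersection is the overlap
region where truth variants are placed. The high-confidence region is the
chromosome minus "difficult" regions — the planted tandem repeats plus
dedicated exclusion windows — and a configurable fraction of truth
(default 95%) lies inside it. Truth variants (default 400 SNVs, 100
indels, 65% heterozygous) avoid colliding spans and homopolymer contexts
except where a homopolymer context is the point (hp-related FN sites, and
homopolymer-category FP injections).

Library profiles:

- **amplicon** — fixed 280 bp amplicons tiled every 190 bp; per-amplicon
  read counts are lognormal with σ = 1.0 (high dispersion, reproducing the
  heavy >400X tail and the excess of <10X bases seen in PCR enrichment at
  matched mean depth); reads start at the amplicon primer positions and
  are 3'-quality-trimmed to 40–280 bp. Default mean depth 270X, duplicate
  rate 0.13; injected FPs are biased toward strand bias.
- **capture** — fragments with uniformly jittered endpoints (120–240 bp)
  at gamma-overdispersed per-kilobase rates (dispersion 0.1, i.e. nearly
  Poisson depth). Default mean depth 115X, duplicate rate 0.001; injected
  FPs are biased toward homopolymer artifacts.

Reads carry a variable trimmed length rather than one fixed length: with
fixed-length reads every read of an amplicon/strand would share both
coordinates and coordinate-keyed duplicate marking would be meaningless.
Unique molecules draw distinct trims without replacement, so
coordinate-identical reads are, by construction, the injected PCR
duplicates — plus a small saturation excess when an amplicon's read count
exceeds the 241-wide trim space. That excess is analytically below ~5
percentage points at 60X mean depth, which is why dedup- and
coverage-oriented simulations in the tests and the acceptance script run
at 60X rather than the 270X/115X call-set defaults; at 270X with σ = 1 the
trim space saturates and accidental coordinate collisions would swamp the
configured rate. Depth tracks are computed from the simulated reads.

The query call set is constructed *from the truth* (not from the reads):
truth in the library's target, minus per-cause FN dropouts, plus
per-category FP injections, each with evidence built to fire exactly its
intended rule and no higher-precedence rule. TP allele fractions are
jittered around 0.5/1.0 (never below 0.45) while FP fractions lie in
[0.05, 0.40], so the 0.2 allele-fraction refilter can only remove FPs.
All draws descend from a single config seed; identical configs give
byte-identical FASTA/BED/VCF/SAM/TSV outputs.

What passing tests on this generator do *not* show about real data: there
is no flow-space or signal-level error model (the sequencer's homopolymer
length miscalls are represented only by context labels), no GC bias, no
paired ends, no mapping ambiguity, and call evidence is synthesized
per-site rather than derived from the simulated reads — so recovery rates
here measure the classifier's rule logic, not its robustness to pileup
noise.

## Pipeline

Stages: VCF1 (raw query vs raw truth in the target), VCF2 (both sets
regularized — the truth set is regularized with the same routine as the
query, which is idempotent on already-normal truth and safer than trusting
the input), VCF3 (target ∩ HCR), and optionally an allele-fraction
refilter stage. The report prints the truth-set size both before and after
truth-side normalization, and FP reductions against both the VCF1 and VCF2
baselines, since either can be the relevant reference point. Reports are
deterministic (no timestamps); provenance captures inputs, the verbatim
config and its SHA-256 hash.

## Problem sizes

Unit tests run on 200–1,000 bp references with exhaustive oracles; the
simulation-backed tests use a 100 kb reference, 500 truth variants and
60X depth; pipeline parameter recovery uses a 400 kb reference with 2,000
truth variants (call sets only, no reads). The acceptance script uses the
same sizes and completes in seconds.

## Known limitations

- Matching is exact-key after normalization; cluster-equivalent indel
  representations that normalization cannot reconcile (vcfeval-style
  haplotype grouping across multiple records) are out of scope.
- The effective-target-region concept is treated as an opaque input BED;
  no liftover between assemblies is provided.
- Single-end reads only; no optical-duplicate distance logic or mate-aware
  pair keying.
- The FN cause taxonomy reports flag combinations; it cannot distinguish
  correlated causes from coincidental ones at a site.
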