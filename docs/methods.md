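# Methods

## Run detection model

A run of homozygosity (ROH) is modelled as a maximal marker interval, per
individual and chromosome, satisfying:

* **gap rule** — every distance between consecutive panel markers inside the
  interval is at most `max_gap_bp` (default 1,000,000 bp). The rule applies
  to the assayed marker grid, including the flanks of missing-call markers;
  it prevents a run from spanning regions the array does not interrogate.
* **composition rules** — at most `max_het` heterozygous and `max_missing`
  missing calls, both class-specific (below).
* **support rule** — at least `min_snps` (default 30) *homozygous* calls.
  Tolerated heterozygous/missing markers sit inside the run but do not count
  toward the 30.
* **endpoint rule** — the interval is trimmed so its first and last marker
  are homozygous calls; allowances are interior-only. This is the standard
  behaviour of consecutive-SNP ROH callers.

Maximality means no single-marker extension keeps the gap and composition
rules true. The implementation finds, for every left endpoint, the largest
admissible right endpoint by bisection on prefix counts; a window is maximal
iff its right endpoint strictly exceeds that of the window starting one
marker earlier. An exhaustive all-windows enumeration (implemented with
independent matrix arithmetic) is kept in the test suite as an oracle and
the two are required to agree on hundreds of randomized panels.

### Length classes and error allowances

Runs are classified into 1–2, 2–4, 4–8, 8–16 and >16 Mb. Defaults:
heterozygote allowances (0, 0, 0, 0, 1) and missing-call allowances
(0, 0, 1, 2, 4). The heterozygote pattern is reproducible from first
principles: a zero-allowance pilot scan yields the mean SNP count per class,
and the allowance is the expected number of genotyping errors in a run of
that size at the array error rate (0.2%), rounded half-up
(`allowed_errors`). At ~55 kb spacing only the >16 Mb class (several hundred
SNPs per run) reaches an expectation of >= 0.5 errors. Classes are
configurable but must tile [1 Mb, infinity) without overlap.

### Cross-class deduplication

Each class is scanned independently because its allowances differ; the same
tract can therefore surface in several scans (e.g. a 5 Mb tract with one
missing call appears whole in the 4–8 class and as two fragments in the
zero-missing classes). Per individual and chromosome the union is
deduplicated greedily: longest segment first (ties: most homozygous SNPs,
then leftmost), discarding anything that overlaps a kept segment. The
resulting segment set is pairwise disjoint, so downstream F_ROH never counts
a base pair twice. One consequence worth knowing: the textbook monotonicity
"relaxing allowances never shrinks total detected length" holds for the
open-ended class but not for bounded classes, where a relaxed allowance can
merge two in-class runs into one run that exceeds the class ceiling; the
property test therefore targets the open-ended class.

## Quality control

Filters mirror standard array QC, applied samples-first (call rate on the
full pre-filter panel, the genotyping-lab convention), then markers:

* samples kept only with call rate strictly above 0.95;
* markers kept only with GenCall strictly above 0.7 and GenTrain strictly
  above 0.4 (when a quality table is supplied), and only on autosomes 1–29
  (sex chromosomes and contig-mapped markers dropped).

All three thresholds are strict by design. Genotype polarity (which
homozygote is "reference") follows first-seen allele order in the PED file;
ROH logic only distinguishes homozygous/heterozygous/missing, so polarity is
irrelevant and round-trips losslessly.

## F_ROH

F_ROH(i, L) = (summed length of individual i's deduplicated segments with
length >= L Mb) / (SNP-covered autosomal length). Thresholds are inclusive
(a segment of exactly 2 Mb counts toward F_ROH(>=2 Mb)) so the class floors
and the cumulative categories agree. The default denominator is 2510.6 Mb —
the covered autosomal length of a filtered bovine 54K panel; passing
`genome_length_mb=None` to `RohAnalysis` recomputes it from the map as the
sum over chromosomes of (last − first marker position), and the choice is
logged. Segment length is `end_bp − start_bp` (not +1), matching the
published region arithmetic the tests pin down. Population summaries report
mean/SD/min/max over animals with the n−1 SD denominator; animals with zero
ROH contribute zeros.

## Islands

The incidence track counts, per marker, the individuals whose segments cover
it (at most once per individual — guaranteed by deduplication). The top-1%
threshold is the nearest-rank order statistic: the count at rank
ceil(0.01 × n_markers) of the descending-sorted counts, with all ties at the
threshold included. Thresholding is applied to raw counts rather than
frequencies (equivalent within one population; counts avoid float ties).
Islands are maximal runs of consecutive flagged markers on one chromosome
with at least 3 members (the smallest region in the bundled catalogue has 3
SNPs); region length is reported in kb by truncation, which reproduces the
catalogue's printed lengths. Islands are per-population; cross-population
comparison happens at the gene level (`shared_genes`), not by interval
merging.

## Annotation overlap

Gene intervals come from BED (0-based half-open, converted on load) or GFF3
(`type == "gene"`, ID/Name attribute). Overlap is any-overlap (>= 1 bp) on
1-based inclusive coordinates, so a gene abutting an island by a single base
counts — stated explicitly because the BED conversion makes this subtle.
Lookup uses an interval tree; a brute-force pairwise oracle checks it in the
tests.

## Synthetic panels

The simulator emulates the study conditions of a filtered bovine 54K panel:

* **map** — 29 autosomes with approximate assembly-scale spans (~2.5 Gb
  total); spacings drawn i.i.d. from N(55.4 kb, 44.4 kb) truncated at 1 bp.
  Truncation lifts the realized mean ~4% above 55.4 kb; the map-spacing test
  budgets for this.
* **background genotypes** — per-marker alternate-allele frequencies uniform
  on [0.05, 0.95]; genotypes Binomial(2, q) under Hardy–Weinberg,
  independent across markers (no linkage disequilibrium).
* **autozygosity** — forced homozygosity, not coalescent IBD: tracts are
  marker-aligned runs where each genotype is homozygous with the allele
  drawn by its frequency. Tracts are specified by population frequency,
  length distribution and placement (shared fixed block or random per
  carrier), or via `target_autozygosity`, which plants non-overlapping
  random tracts (lengths uniform on 2–8 Mb by default) per individual until
  the target genome fraction is reached. Random placement keeps a 2-marker
  buffer between tracts, and by default the single marker flanking each
  tract on either side is forced heterozygous, so true boundaries are
  identifiable — without this, chance runs of homozygous background markers
  (P(hom) ≈ 0.53 per marker) would extend detected runs a marker or two past
  the truth and make exact-boundary recovery untestable.
* **corruption** — genotyping errors flip homozygous calls to heterozygous
  at rate 0.2% by default (the error class that breaks runs); het-to-hom
  errors are off by default but switchable. Missingness (default 0.5%,
  typical of a post-QC panel) is applied last. Truth (tract coordinates,
  per-individual autozygous fraction, corrupted-call coordinates) is
  recorded before corruption.

All randomness flows from the single mandatory seed through named child
generators; identical seeds give byte-identical PED/MAP/truth files.

What passing tests on these panels show — and do not show. They verify the
detector's window logic, allowance accounting, deduplication, incidence
thresholding and F_ROH arithmetic exactly, under controlled error and
missingness. They do not exercise linkage disequilibrium, realistic
allele-frequency spectra, population structure, or autozygosity arising from
a genealogical process, so sensitivity/precision figures from simulations
should not be read as field performance on real arrays.

## Problem sizes and numerical choices

The validation suite uses a noiseless 29-chromosome, ~43K-marker,
100-individual panel with 10% planted autozygosity for parameter recovery
(mean F_ROH within 0.01 of the target; every planted tract with >= 30 SNPs
and >= 1 Mb recovered with exact boundaries), a 5-chromosome 100-individual
panel for island recovery (a block shared by 80% of individuals merges into
one island), and 200 randomized panels of up to 200 markers × 10 samples for
oracle equivalence. Rounding: `allowed_errors` rounds half-up (the published
allowances are integers); island lengths truncate to kb; nearest-rank
percentiles never interpolate. Degenerate inputs are defined rather than
accidental: a chromosome with one marker contributes 0 Mb of coverage
(logged), an empty segment list yields F_ROH 0, an all-tied incidence track
flags every marker, and empty post-filter panels are hard errors.

## Known limitations

* Sliding-window (PLINK `--homozyg`-style) semantics are intentionally out
  of scope, as are genetic-map (cM) distances, binary PLINK/VCF ingestion
  and sex chromosomes.
* The per-class scan plus longest-wins deduplication is one defensible
  reconciliation of class-specific allowances; callers that cap
  heterozygotes per window rather than per run can classify borderline
  tracts differently.
* F_ROH accuracy is bounded by array density: tracts below ~30 markers
  (≈1.7 Mb at 55 kb spacing) are invisible by design, so ancient, short
  autozygosity is systematically undercounted on medium-density panels.
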