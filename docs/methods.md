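# Methods

## Study design being modelled

The pipeline targets F2 families segregating for parental haplotypes —
by default 12 diploid plants per family, named `S01`–`S12`. Because an F2
plant is homozygous for one parental allele at roughly a quarter of loci,
stretches of the genome exist where three or more plants are fixed for
the alternate allele while three or more are fixed for the reference.
Those stretches simultaneously fix any transposon insertion segregating
on the same haplotype, so comparing expression between the two fixed
trios isolates the insertion's association with transcription without a
designed cross for each locus.

## Homozygosity bins

A SNP record *qualifies* when ≥ `min_per_class` (default 3) samples are
`1/1` **and** ≥ `min_per_class` are `0/0`; heterozygous (`0/1`) and
missing (`./.`) calls count toward neither class, mirroring upstream
missingness filtering. A bin is a maximal run of qualifying records that
share a consistent trio assignment, where consistency is tracked as the
running intersections of the hom-alt and hom-ref sample sets: a record
extends the run only if both intersections stay ≥ `min_per_class`. Any
other record — non-qualifying or set-breaking — consumes one mismatch
credit from a per-bin budget of `max_mismatch` (default 2, chosen to
bridge isolated genotyping errors without chaining unrelated runs).
Design choices where the procedure was genuinely open:

- mismatch credits are counted **per bin**, not per gap;
- bin boundaries are the first/last *consistent qualifying* record;
  trailing skipped records are never included, and after a bin closes the
  skipped records are replayed so a new run can start among them;
- when more than three samples stay consistent, the emitted trio is the
  lexicographically smallest 3-subset (pure determinism);
- gene–bin intersection uses the gene *body* (the GFF gene span); the
  ± 2 kb window belongs to MITE–gene association only.

The streaming implementation is checked against an exhaustive oracle that
enumerates every candidate record interval, evaluates validity from
scratch and keeps greedy leftmost-maximal non-overlapping intervals; both
must agree exactly on random streams.

Bins with ≥ `min_genes` (default 20) genes yield the 3 + 3 contrast sets
used for differential expression. Single-record bins occur by chance in
background regions; the gene threshold removes them from all downstream
analysis, so they are reported but harmless.

## Insertion frequencies and zygosity

Signature rows follow the PopoolationTE2 output layout. For
reference-mode insertions the forward and reverse signatures are paired
by (sample, chromosome, position, family) and their frequencies averaged;
an unpaired F or R row is used as-is with a warning (the layout does not
guarantee pairing at low coverage). Non-reference insertions carry a
single FR row. A sample with no row at a site has frequency 0. Reference
and non-reference records at coincident positions remain distinct sites;
they are combined in one matrix but never deduplicated.

Zygosity thresholds: *f* > 0.7 homozygous occupied, *f* < 0.3 homozygous
empty, and the **closed** band [0.3, 0.7] heterozygous — the boundary
values themselves are heterozygous, the literal reading of "higher than
0.7 / below 0.3". Concordance with external verification (e.g. PCR) is
summarised as a confusion table whose percentages are rounded half-up to
two decimals; "no amplification" results count toward neither correct nor
incorrect calls.

## Genic context and enrichment

Gene models come from GFF3 via `gffutils`: sub-features are unions over
transcripts, introns are the mRNA span minus the exon union, and UTRs are
taken from explicit features or derived as exon-minus-CDS split at the
CDS. Flanks are strand-aware 2,000 bp windows clipped at chromosome ends
and *not* clipped against neighbouring genes. An insertion is a single
point; when it falls into several categories the precedence
**cds > utr5 > utr3 > intron > upstream2kb > downstream2kb** decides
(gene-body evidence outranks flank proximity). A point may associate with
several genes (body or flank) while contributing once to the global
context table.

Enrichment is Pearson's χ² on the superfamily × context count matrix
(`scipy.stats.chi2_contingency`, no continuity correction), with
per-cell residuals (obs − exp)/√exp and contributions residual², which
sum to the statistic (asserted to 1e-9 relative). The pipeline drops
all-zero rows/columns before testing, since sparse miniature tables
legitimately leave categories empty. Densities divide counts by the
cumulative genomic length of each category (overlaps merged within a
category, never across categories; default unit 100 kb).

## DEG calling and association

Each DE table supplies `gene_id`, `log2fc`, `padj` per algorithm. The
default combination rule is **intersection** (padj < 0.05 in every
table — conservative; `union` and `single` are available); direction is
the sign of the mean log2fc over calling algorithms, and genes whose
algorithms disagree in sign are excluded with a log message. Genes in
multiple bins count once in global fractions. An association record is a
(DEG, insertion) pair where the insertion point lies in the gene body or
± 2 kb (boundary inclusive). Its occupied/empty trios reuse the host
bin's trios when their zygosity at the site matches, otherwise any 3 + 3
split of matching homozygous samples (bin-trio members preferred,
lexicographic); pairs without a valid contrast are kept but flagged. The
expression report z-scores each record's six contrast samples with the
population standard deviation ((x − mean)/sd, ddof = 0, the usual
heatmap row z-score); zero-spread rows get z = 0 and a flag.

## Permutation test

P_obs counts DEGs with ≥ 1 insertion within the body or ± 2 kb. Each of
N (default 1000) iterations redraws the DEG label set uniformly without
replacement over the gene universe — implemented as independent row
permutations of the fixed MITE flag vector — preserving the DEG count.
The default p-value is the add-one-smoothed estimator
p = (1 + Σ 1(Pᵢ ≥ P_obs))/(N + 1), bounded in [1/(N+1), 1]; a literal
variant with the indicator 1(Pᵢ ≥ P_obs + 1) exists behind
`literal_indicator=True` for comparison, but the smoothed form is the
established valid estimator and the default. The universe used by the
pipeline is the set of genes inside the selected (≥ `min_genes`) bins,
i.e. the genes the DE contrast actually tested. Correctness is checked
three ways: exact enumeration of all label placements on small universes,
a Kolmogorov–Smirnov uniformity check of p under a true null, and
determinism under a fixed seed.

## Synthetic data generator

The generator emulates the five study inputs plus an expression matrix,
all as pure functions of a `SimulationConfig` (every stage derives its
RNG from the config seed plus a fixed stream tag, so outputs are
byte-identical across runs and independent across stages).

Default miniature scale — 2 chromosomes × 1 Mb, 60 genes, 12 samples, 20
MITE families over the five superfamilies (hAT, Mutator, Stowaway,
Tourist, uc), 1 SNP/kb, 40 insertions, 5 planted tracts: two spanning 22
genes each (above the 20-gene selection threshold) and three spanning 3
genes (below it), nine insertions segregating with their host tract's
trios and driving planted log2 fold-changes of ± 2, plus one planted DEG
with no insertion. This is small enough for exhaustive oracles yet large
enough for non-degenerate contingency tables and a clearly separated
permutation null.

Inside a planted tract every emitted SNP carries the tract's trio
pattern; outside, sites are forced with probability 0.95 to violate the
two-homozygote-classes rule (the remaining 5 % are fully random, so rare
chance-qualifying singleton records occur, as in real data). Up to *k*
discordant sites per tract can be injected (optionally consecutive) to
exercise the mismatch budget. Signature frequencies are the zygosity
target (1.0 / 0.5 / 0.0) plus truncated Gaussian noise (`noise_sd`,
default 0 — the paired F and R rows receive independent noise); the
truncated-Gaussian error model is the simplest one that exercises the
0.3/0.7 thresholds. DE tables are simulated directly (planted effects get
padj < 0.05 with the planted sign in every table; nulls draw padj from
(0.05, 1]) because DE-testing internals are out of scope — the pipeline's
contract is on DE result tables. Expression values scale a lognormal
baseline by 2^(log2fc × dosage) with dosage 1 / 0.5 / 0 for
occupied / het / empty at the linked site.

What the generator does **not** emulate: linkage disequilibrium decay and
recombination-based tract boundaries, read-level noise and mapping
artefacts, frequency biases of PopoolationTE2 at low coverage, correlated
errors between DE algorithms, multi-transcript genes, nested or
overlapping genes. Passing tests therefore demonstrate the correctness of
the downstream logic under the declared error model, not the robustness
of upstream variant or insertion calling on real sequencing data.

## Numerical and formatting choices

- Intervals are 1-based inclusive in memory (GFF convention) and
  converted to 0-based half-open at BED-style boundaries and in the
  interval-tree index.
- Percentages in concordance tables round half-up via `decimal` to match
  printed-table conventions (192/264 → 72.73).
- TSV floats use `%.10g`; reruns are byte-identical. The run manifest
  records a wall-clock timestamp (provenance), so determinism is asserted
  over the stage outputs, not the manifest file itself.
- Problem sizes in tests and the acceptance script (2,000-record genotype
  streams, 10,000 oracle points, 500 × 200 null-calibration replicates,
  20-seed planted-effect sweeps) were chosen as the smallest scales at
  which the statistical assertions have comfortable margins.

## Known limitations

- Trio consistency across a bin is one defensible reading of fixed
  per-bin trios; re-evaluating trios per record would admit longer bins
  with floating membership and is intentionally not offered.
- The copy-number totals count reference and non-reference sites at the
  same locus separately.
- The permutation null ignores gene length and insertion clustering; a
  covariate-matched null is out of scope.
- One bundle models one family; a two-family study is two bundles with
  different seeds/population labels.
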