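# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the design decisions taken where more than one reasonable
convention existed.

## Crossing-scheme model

Only the diploid A (sub)genome is modelled. The donor is a diploid AA
species and the recipient an allotetraploid whose A subgenome carries the
marker loci; its B subgenome is irrelevant to A-genome segregation and is
not simulated (B-genome presence is an assay question handled by the
B-detection marker filter, not a transmission question — aneuploid
B-chromosome inheritance would require a model the data do not constrain).

Founders are fully homozygous inbred lines: two identical haplotypes per
chromosome, with distinct allele codes between donor and recipient at every
polymorphic locus, so founder origin of every simulated allele is always
recoverable.

**Meiosis.** No crossover interference (Haldane model). Per chromosome the
number of crossovers is Poisson with mean equal to the terminal mapped cM
position divided by 100 (map length in Morgans); crossover positions are
uniform on the cM axis; the starting chromatid is fair and flips at each
crossover (parity rule). Between two loci *d* cM apart the recombination
fraction is therefore (1 − e^(−2d/100))/2, which is how cM on a linkage map
are usually meant. Loci mapped to the same cM position never recombine; to
support this, the map container requires non-decreasing (not strictly
increasing) cM within a chromosome, while bp positions stay strictly
increasing.

**Schemes.** A cross specification is an ordered list of steps from
{make_f1, backcross_to_recipient, self}, starting with make_f1. For the
standard BC1S1 scheme the exact single-locus genotype distribution,
propagated as rationals through (F1: pure H; backcross: A,H,B → gametes
against a recipient gamete; self: Mendelian transition A→A,
H→¼A+½H+¼B, B→B), is A:B:H = 1/8 : 5/8 : 2/8 with donor-genotype
frequency f\* = p_A + p_H/2 = 1/4. The enumeration (`expected_segregation`)
and the simulator (`run_cross`) are independent routes to the same numbers;
tests hold them to 3-σ Monte-Carlo agreement.

**Selection.** Distorting loci (e.g. self-incompatibility regions dragging
a population toward the recipient genotype) are modelled as *zygotic*
fitness reweighting: each offspring is accepted with probability
proportional to the fitness weight of its genotype at each selected locus
(rejection sampling, applied at every post-F1 generation). This is the
simplest mechanism that reproduces strong marker-specific skews; gametic
selection would be indistinguishable at the single-locus genotype level for
the schemes considered. The neutral `expected_segregation` deliberately
rejects specs with selection entries — it is the baseline that observed
data are tested against.

**Assay emulation.** `genotype_population` converts true genotypes to
A/B/H calls, each independently replaced by a uniformly random wrong code
with probability `error_rate` and by the missing code D with probability
`missing_rate` (missing wins when both fire). The default missing rate used
by the pipeline demo, 0.0228, is an empirical call-failure rate typical of
competitive allele-specific PCR panels (322 missing in 14 124 calls);
errors default to 0 because such assays, once validated, miscall rarely.

## What the generator does not emulate

Synthetic populations have exact map positions, no genotyping batch
effects, no segregation of structural variants, and founders that are
perfectly inbred and perfectly distinct at every marker. Passing tests
demonstrate the *pipeline's* correctness under the stated genetic model,
not robustness to misspecified maps, residual parental heterozygosity or
assay artefacts in real data.

## Marker design

Candidate diagnostic loci must satisfy six predicates evaluated as a
conjunction (hence order-independent and idempotent): all parents
homozygous; donor identical to the donor-side reference; donor and
recipients fixed-different; recipients mutually uniform; no variation
within the 100-bp flanking region; no homologous region in the
B-progenitor genome. Flanking variation and B-progenitor homology arrive
as precomputed annotations (they derive from read alignments outside this
package's scope). B-genome *detection* markers invert the polymorphism
requirement: uniform between donor and recipient A subgenomes, polymorphic
against the B-subgenome homoeolog, recipients uniform in both.

**Even spacing** is a greedy maximin: seed each chromosome with the two
candidates closest to its ends, then repeatedly add the candidate whose
minimum bp distance to the chosen set is largest, ties to the smaller bp —
deterministic, and within a few percent of the optimal minimum gap in
practice (tests verify it beats 1 000 random subsets). How a published
panel was thinned is rarely documented; greedy maximin is this package's
choice.

**Distribution statistics.** Published per-chromosome "average density"
columns are often not reproducible as chromosome-length/count, so two
density variants are computed and labelled: length-based (length / count)
and span-based (marker bp span / (count − 1)); the genetic interval is cM
span / (count − 1). Genome-wide summaries are arithmetic means of
per-chromosome values (chromosomes with one marker contribute no span-based
values and are skipped in those means). When per-chromosome values are
supplied externally, `genome_wide_means` just averages the columns. Gap
scans include the leading (0 cM → first marker) and trailing (last marker →
terminal mapped cM) intervals.

## Genotype matrix conventions

Calls are A (A^r A^r), B (A^j A^j), H (A^r A^j), D (missing). Markers are
ordered by chromosome then bp; matrices arriving unsorted are auto-sorted
with a logged warning. Missing fill replaces each D with the nearest
non-missing call in bp on the same chromosome, ties to the left (smaller
bp); a line's fully missing chromosome stays missing. "Nearest, left on
tie" was chosen as the minimal deterministic reading of adjacent-locus
filling, and the same rule is reused for dense-panel projection so one
spatial convention governs the pipeline. Per-line genotype proportions use
non-missing denominators (the convention that reproduces printed
proportions from published count tables); summaries are computed on the
unfilled matrix, filling happens only before projection.

## Segregation analytics

- Donor-genotype frequency: f = (2 n_A + n_H) / (2 (n_A + n_B + n_H)) —
  the donor allele frequency over non-missing calls; equals p̂_A + p̂_H/2.
- Goodness of fit: Pearson chi-square over {A, B, H} with df = 2; expected
  class counts below 5 produce a warning, below 1 a rejection. The test is
  meaningful per locus or for genuinely independent draws; whole-matrix
  counts pooled over linked markers are overdispersed and the package
  leaves that interpretation to the caller.
- Distortion flagging: per marker, a two-sided exact binomial test of the
  2N donor-allele draws against f\*, Bonferroni-corrected across markers
  (no distribution-free alternative is needed at these scales). Direction
  (above/below f\*) is reported separately from significance; the summary
  counts "positively selected" markers (f > f\*) and significantly
  recipient-skewed ones. Treating the 2N alleles of N individuals as
  independent draws is exact under the neutral scheme at a single locus.

## Projection and diversity

The dense panel partitions the summed genome length into `n_regions`
equal-width windows laid chromosome by chromosome (2 000 regions over a
~300 Mb genome ≈ 150 kb windows); within a window the variant homozygous
in *every* parent and accession that lies nearest the window midpoint is
kept (tie → smaller bp), so the panel has at most one SNP per region and
windows without eligible variants contribute nothing.

Projection assigns every (line, panel SNP) cell the genotype class of the
line's nearest diagnostic marker in bp (tie → left) and instantiates
alleles: A → donor homozygote, B → recipient-parent homozygote, H →
donor/recipient heterozygote; if donor and recipient share the allele the
cell is that homozygote regardless of class. Heterozygous cells are
legitimate even though panel SNPs are homozygous in all *parents* —
heterozygosity arises in hybrids. Chromosomes without markers leave their
panel SNPs missing for lines. Resolution is bounded by marker spacing:
donor dosage over the panel tracks marker-level donor frequency only to
within roughly one marker interval of mass, and recombination breakpoints
inside marker intervals are invisible.

Distances are 1 − IBS: the complement of mean allele sharing (identical
homozygotes share 2 of 2, het vs either homozygote 1, opposite homozygotes
0) over pairwise-complete loci; bounded in [0, 1], symmetric, zero on
identical genotypes (a semimetric; the triangle inequality is not
guaranteed and not needed). Pairs with no complete loci get NaN and are
rejected by tree building rather than silently zeroed.

Trees use classical neighbor-joining: Q(i,j) = (m−2)d(i,j) − r_i − r_j,
standard branch-length and distance-update formulas, closed-form three-
point resolution of the final triple. Ties in Q go to the lexicographically
smallest id pair; negative branch lengths are clamped to 0 with the total
deficit recorded on the tree object. On additive matrices the algorithm is
exact (property-tested to 1e-9 against random tree metrics, and
cross-checked topologically against an independent implementation).

## Pipeline

The CLI executes simulate → design → genotypes → stats → project →
diversity. All randomness flows from one config seed through named
substreams (SHA-derived spawn keys per stage), so stages are individually
reproducible and reruns are byte-identical; every tabular output carries a
comment header with a hash of the scientific parameters (the output
directory is excluded from the hash). Pre-flight validation names the first
missing inter-stage artifact before anything runs. The demo configuration
simulates 107 lines from six recipient parents (14/20/44/3/17/9 — a
realistic spread of family sizes for a BC1S1 programme), 10 chromosomes of
30 Mb / 90 cM with 13 markers each, no selection, 2.28% missing calls, a
2 000-region dense panel and 12 reference accessions.

## Problem sizes and numerical choices

Exact expectations use `fractions.Fraction` end to end. Monte-Carlo checks
use 40 000–100 000 individuals for distributional agreement (3-σ bands) and
500-line populations for distortion-power checks (20 replicates; near-zero
donor fitness at the selected locus gives essentially complete power, and
Bonferroni keeps familywise false positives at the nominal 5%). Brute-force
oracles (nearest-neighbour fill, nearest-marker projection, window-midpoint
panel choice, gap scans) run on instances of up to ~10 markers × ~12 SNPs
where exhaustive scanning is trivially correct. Tree recovery is tested on
random additive matrices with up to 8 leaves.

## Known limitations

- No crossover interference; organisms with strong interference will show
  less double-crossover noise than simulated.
- Selection is zygotic and locus-wise multiplicative; epistatic or gametic
  mechanisms are not distinguishable in this framework.
- Missing-fill and projection are nearest-neighbour rules, not HMM
  smoothing; they cannot recover breakpoints between markers.
- The IBS distance ignores allele frequencies (no similarity weighting),
  matching its use as a bounded descriptive distance rather than an
  evolutionary model.
- Published per-chromosome density columns whose provenance is unknown can
  only be averaged, not re-derived; both density definitions are reported
  to make the ambiguity explicit.
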