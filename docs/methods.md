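# Methods

## Strand collapse and context extraction

A somatic SNV at a cytosine can be reported on either strand (as `C>X` or, at
the paired guanine, as `G>Y`). Because a deaminase acts on the cytosine, the
two are the same event; all context analysis therefore re-expresses each C/G
mutation on the strand where the mutated base is a C. A `C>X` record keeps its
genomic window; a `G>Y` record takes the reverse complement of the window and
the complement of its alternate base. Position 0 is the mutated base, negative
positions 5′ on the oriented strand. Mutations at A/T reference bases are
excluded from context analysis (they carry no cytosine-deamination
information) but remain in the substitution spectra.

Windows that run off the sequence end or contain N are skipped with a logged
count rather than padded: a padded base would dilute the position composition.

Duplicate handling follows the rule that the same (sample, position, ref, alt)
is one event while identical mutations in different tumours are independent
events; `dedupe_mutations` enforces exactly that and is idempotent.

## Background (expected) context distribution

The null model for the flanking composition is the frequency of each cytosine
context in the reference: every C on the plus strand contributes its window,
every G contributes the reverse-complemented window (a C on the minus strand).
When exon intervals are supplied, a site contributes if its *centre* cytosine
lies inside a merged interval; flanks may extend past the interval edge. The
alternative (requiring the whole window inside) discards edge cytosines whose
context is perfectly well defined in the genome; overlapping exon annotations
are merged so no site is weighted twice.

## CpG stratification and the per-position chi-square

CpG-site mutations (oriented +1 base = G) are dominated by
methylcytosine-deamination transitions, a mutational process unrelated to
enzymatic deaminases, so the signature test is run per stratum. Within a
stratum the background k-mer distribution is renormalised over that stratum's
k-mers. This matters: the observed non-CpG mutations have, by construction, no
G at +1, and comparing them against an all-C background would report a
spurious "+1 depletion" that is pure conditioning, not biology.

The per-position test is a goodness-of-fit chi-square of the observed base
counts at one flanking position against the background marginal at that
position, with dof = (bases with nonzero expected frequency) − 1. A base
observed where the background gives zero frequency is an error naming the
base, not a silent infinity. No multiple-testing correction is applied across
positions by default — the analysis reports a single pre-specified position
(−1) as its headline test; a Bonferroni correction over the 2·flank flanking
positions can be applied by the caller (the CLI reports every position's raw
p, leaving correction explicit).

Ts/Tv site classes (CpG/CpH) are likewise evaluated on the cytosine-oriented
strand; contexts containing N are excluded from site-class filters, since the
stratum of an N-containing context is unknowable.

## Spectrum comparison

Two-group comparison defaults to a 2×2 Fisher exact test of [mutations at C/G
vs at A/T] × [group]: with the small counts typical of clone-sequencing
experiments the 6-class table is too sparse for a chi-square. The two-sided p
follows the conventional "sum of small p" rule (all tables with the observed
margins whose hypergeometric probability does not exceed the observed
table's). The exact contingency layout behind published figure-level p-values
is rarely stated, so the output labels this layout explicitly. A `full` mode
runs the 2×6 chi-square and logs a warning when any expected cell is < 5.

## Clone calling and the non-clonal filter

Clone sequences are compared base-by-base against the reference region
(alignment happens upstream; length mismatch is an error, and clones of
deviating length — indel carriers — are excluded with a logged count when
loading FASTA). N positions are subtracted from the surveyed-base
denominator. The non-clonal filter keeps one copy of each distinct (pos, ref,
alt) per population: clones sharing a mutation are treated as one clonal
expansion. Co-occurring *distinct* mutations in one clone are all kept. The
reported frequency is non-clonal mutations / surveyed bases; this
underestimates activity at genuine hotspots, which is the accepted trade-off
of the filter. Every observed mismatch is called — no quality model is
applied, since chromatogram-level evidence is outside this package's inputs.

## Fluctuation assays and expression

Fluctuation assays are summarised as per-culture frequency (resistant/plated)
and the per-construct median (midpoint convention for even n). No
Luria–Delbrück rate estimator is applied: the quantity reported is a
frequency, and converting to a rate requires assumptions (post-plating growth,
phenotypic lag) the inputs do not carry.

Group comparison uses a two-sided Mann–Whitney rank-sum test — chosen as the
conservative default for small, non-normal frequency samples; the choice is
recorded in the output metadata. For combined n ≤ 20 the p-value is computed
by exhaustive enumeration of all C(n, n_a) labelings using midranks, which is
exact in the presence of ties; larger samples use the tie-corrected normal
approximation.

Expression values are normalised per sample to a housekeeping reference gene
(TBP by default): v_i = log2(x_i / ref_i), then centred on the median across
samples, making the output invariant to any per-sample rescaling. Nonpositive
gene intensities raise by default; an explicit pseudocount is the opt-in
alternative, because silently flooring microarray intensities changes the
answer. Group differences use one-way ANOVA with Tukey HSD (scipy
implementations); for two groups F equals the squared pooled t statistic,
which the tests verify numerically.

## Synthetic data: what it emulates, what it does not

The generator suite emulates the *shape* of each input, with defaults chosen
as the study conditions the pipeline is designed to detect:

- **Reference**: i.i.d. bases (default uniform, 1 × 100 kb). Real exomes have
  GC structure, codon bias and depleted CpGs; none of that is modelled.
- **SNVs with a planted signature**: cytosine sites are drawn with probability
  proportional to a product of per-position base weights over the oriented
  context (the signature factorises across positions; CpG coupling is a
  separate multiplier ≥ 1, default 2, standing in for the methylation-driven
  CpG transition excess). The default −1 weights (T 0.6, C 0.25, G 0.1,
  A 0.05) encode the APOBEC1-style preference for 5′ T and avoidance of A;
  changes are drawn as C>T 0.7 / C>G 0.2 / C>A 0.1, transition-heavy as
  deamination products are; 10% of mutations are uniform A/T background
  noise. With uniform weights and multiplier 1 the generator samples sites
  exactly in proportion to their abundance, i.e. from the background context
  distribution — this makes the null calibration of the chi-square an honest
  test, not a tautology.
- **Clone sets**: independent per-base substitutions at a given rate
  (default 10⁻³/base, 20 clones) plus optional mutations planted in every
  clone to model a clonal expansion. No sequencing-error model.
- **Fluctuation counts**: resistant ~ Binomial(plated, f) per culture —
  appropriate for frequencies read directly from plating, deliberately not a
  Luria–Delbrück jackpot distribution (see above).
- **Expression**: log-normal background intensities, a flat low-noise
  reference gene, and per-group log2 shifts planted in one target gene
  (default design: three groups of 15 — healthy tissue, metaplastic
  precursor, tumour — with +3 log2 in the latter two).

Each generator draws from its own substream (seed mixed with a CRC32 of the
generator name), so outputs are reproducible per generator and adding a new
generator does not shift existing ones.

Passing tests on these inputs demonstrates that the statistics are implemented
correctly and calibrated under their own assumptions; it does not demonstrate
robustness to the failure modes of real data (alignment artefacts, sequencing
error, germline contamination, copy-number structure).

## Numerical and design choices

- Internal coordinates are 0-based half-open; mutation tables are read and
  written 1-based. The conversion lives in exactly one place
  (`MutationRecord.pos0`).
- Unknown IUPAC letters in FASTA become N with a warning (public references
  contain them); N sites are excluded downstream rather than guessed.
- Flank defaults to 1 (trinucleotide logos); Py/Pu at −2 needs flank ≥ 2.
- Ratios (Ts/Tv, Py/Pu) return +inf when the denominator class is empty but
  the numerator is not, and raise when both are empty — an empty input is a
  caller bug, not a number.
- Fisher, chi-square, Mann–Whitney (large-sample), ANOVA and Tukey HSD are
  scipy.stats; the exact small-sample rank-sum enumeration is implemented
  here because scipy's exact method does not admit ties.
- Problem sizes in tests and the acceptance script (100 kb reference, 1 000
  signature mutations, 50 000 null SNVs, 100 calibration replicates at
  n = 5 000, 50 clones × 1 kb) are chosen so every statistical check has
  comfortable power while the whole suite runs in seconds.

## Known limitations

- No mutational-signature deconvolution (NMF over the 96-context matrix) and
  no kataegis/cluster detection.
- No VCF input and no compressed/indexed genome access; inputs are plain
  FASTA/BED/TSV.
- The Fisher 2×2 layout for spectrum comparison is a reconstruction when the
  upstream contingency layout is unstated.
- Clone calling assumes pre-aligned, equal-length sequences and calls every
  mismatch; sequencing errors are not modelled.
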