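# Methods

This note documents the models and procedures implemented in `comphom`,
the tunable parameters and their defaults, the design decisions taken
where more than one reasonable construction exists, and what the
synthetic-data generators do and do not emulate.

## Chi-score: normalized compositional dissimilarity

Two sequences are compared through the chi-square test of homogeneity on
their amino-acid counts. The 2×K contingency table has one row per
sequence and one column per amino acid present in at least one of them;
amino acids absent from both rows are dropped (their cells contribute
0/0). Expected counts come from the row/column margins and the raw
statistic is the classical `chi2 = sum (O-E)^2 / E`.

**Normalization.** The score is `sqrt(chi2 / N)` with `N` the combined
residue count — Cramér's V for a two-row table. It is 0 exactly when the
two fraction vectors coincide and 1 exactly when the alphabets are
disjoint (this endpoint is returned as exactly 1.0: in real arithmetic
`chi2 = N` there, and the square root is short-circuited to avoid
returning 0.99999999999999989). The alternative normalization `chi2/N`
(phi-square) satisfies the same endpoints; V was chosen as the standard
[0,1] association measure for this table shape, and the raw `chi2` and
`N` ride along on every result so phi-square is recoverable. Output
metadata records the choice (`normalization = cramers_v`).

**Counts versus fractions.** Counts enter the table, so a longer
sequence carries more weight exactly as in the classical test. The
`equal_weight=True` option rescales both rows to a common total first;
it is not the default.

**Standardized reference.** `score_vs_uniform` scores a sequence
against a pseudo-row with the same total and 5% of each amino acid
(fractional expected counts are permitted); it depends only on the
query's fractions.

No p-values are emitted anywhere in this module: the statistic serves as
a dissimilarity, not a hypothesis test.

## Modularity segmentation

A sequence is segmented into modules of distinct compositional bias in
four stages.

1. **Boundary profile.** For every cut `i` in `[w, L-w]`, the chi-score
   between the `w`-residue flanks `(i-w+1..i)` and `(i+1..i+w)`.
   Default flank width `w = 30` residues: wide enough that the 20-column
   table is not hopelessly sparse, narrow enough to localize junctions.
2. **Candidate detection.** Local maxima of the profile (plateaus count
   once, at their left edge; an all-flat profile yields none), accepted
   greedily in decreasing score order subject to a minimum spacing of
   `min_module` (default 30) residues, ties toward the smaller position.
3. **Refinement.** A candidate is moved within `±⌊w/2⌋` (clamped so
   every module keeps `min_module` residues) to the position maximizing
   the chi-score between its two full flanking segments.
4. **Permutation validation, hierarchical.** Within a span (initially
   the whole sequence) the strongest candidate's segment-vs-segment
   chi-score is compared against a shuffle null: the span's residues are
   pooled and permuted `n_perm` times (default 1000) and *each shuffle
   is scored at its best admissible cut of the span*. The observed score
   is converted to a z-score against the null moments; if it clears the
   one-sided threshold (default `z = 1.645`, 95% confidence; the
   empirical null percentile is reported alongside for diagnostics), the
   boundary is accepted and the two child spans are searched recursively
   with the significance level split between them (Bonferroni). A
   degenerate null (zero variance, e.g. a homopolymer span) rejects the
   candidate. Candidates never confirmed are removed.

Two design points deserve emphasis, both adopted after measuring the
calibration of simpler constructions on structureless i.i.d. sequences:

- **The null must replicate the selection.** A null that re-splits each
  shuffle at the single observed cut is stochastically smaller than an
  observation that was *chosen* as a profile peak and then optimized;
  with that null the majority of structureless 400-mers yield a
  spuriously "validated" boundary. Scoring each shuffle at its best cut
  of the span makes observation and null maxima over comparable search
  spaces and restores the nominal error rate.
- **Test against wide spans, not between-candidate gaps.** Testing each
  candidate of a dense set only against the narrow span to its
  neighboring candidates leaves the null blind to the breadth of the
  scan that produced the candidates; global-scan extremes then survive
  far above the nominal rate. The hierarchical (top-down) order means
  every test is performed in the widest span consistent with the
  boundaries already accepted.

The null shuffles condition on the pooled composition of the span, so
the test asks precisely "are these two spans compositionally
different?", not "is the sequence non-random?". Whole-sequence shuffling
is available via `null_scheme="sequence"`. Null randomness derives from
`(seed, span)`, making a span's null independent of exploration order;
a consequence is that raising the z threshold always yields a nested,
never larger, boundary set. Measured on the synthetic study conditions
(50 seeded runs each): 1/50 structureless 400-mers report any boundary;
47/50 strong two-module sequences (80%-biased segments, 200+200) report
exactly one boundary within ±10 of the true junction.

## Alignment similarity and the scrambled-self baseline

Global Needleman–Wunsch alignment with affine gaps; defaults BLOSUM62,
gap open 10, gap extend 0.5 (EMBOSS-needle-style), recorded in output
metadata. Percent identity counts alignment columns with equal residues;
percent similarity additionally counts columns whose residue pair has a
positive substitution score. Gap columns score 0 and count in the
denominator (an alternative denominator — the shorter sequence's length
— is available). Published ortholog-panel similarity ranges were
produced with a commercial aligner whose parameters are not public, so
exact percentages are not reproduction targets; the package's claims are
structural (symmetry, bounds, and the relation of pairwise similarity to
the scrambled-self baseline).

The scrambled-self baseline aligns a sequence against `n` seeded
Fisher–Yates permutations of itself: the similarity expected from
composition alone. For a homopolymer the scramble is the identity and
the baseline is 100 by construction.

## Feature profiling

- **NCPR**: centered sliding mean of per-residue charge, K/R = +1,
  D/E = −1, histidine 0 (pH 7.4 convention). Window default 25, odd,
  truncated at the edges.
- **FCR**: (K+R+D+E)/L.
- **Isoelectric point**: bisection on pH ∈ [0,14] to 1e-3 of the
  Henderson–Hasselbalch net charge, titrating D, E, C, Y, H, K, R and
  (by default) the termini. pKa tables: `bjellqvist` (ExPASy values,
  default) and `emboss`. Net charge is strictly decreasing in pH so the
  root is unique; different published pKa sets move the pI of a basic
  IDR by up to ~0.3 units, which is the tolerance used wherever a pI is
  asserted.
- **CDK sites**: overlapping scan; minimal = S/T immediately followed
  by P; optimal = minimal with K/R three positions downstream. The
  phospho-dead transform replaces the acceptor S/T of every minimal
  site with alanine; it preserves length, leaves no minimal site, and is
  idempotent.
- **AT-hooks**: every non-overlapping occurrence of the `GRP` core
  (configurable regex) accepted when ≥ 2 K/R residues lie within 3
  positions of the core on the two sides combined. This matches the
  canonical AT-hook consensus and the motifs quoted for sponge and
  echinoderm Orc1 (`RKRGRPRKEE`, `KQGRPKK`); because the literature has
  no single fixed rule, motif *counts* in any particular protein are
  definition-dependent and are not asserted as exact values.
- **Site window matrix**: positional frequency matrix over ±4 residues
  around each phospho-acceptor (9 columns, site centered — "the eight
  residues immediately surrounding" the site; a variant without the
  center column is available). Sites near sequence ends contribute
  gap-padded windows; gaps are excluded from the per-column
  normalization. Each site counts once (no spectral-count weighting).
- **Sites-versus-length fit**: ordinary least squares of minimal-site
  count on sequence length with Pearson r, via `scipy.stats.linregress`.

## Partitioning quantitation

Inputs are per-timepoint ROI statistics (mean background-subtracted
intensity and area for the chromosome and cytosol compartments of one
cell); image segmentation is upstream and out of scope. Negative
intensities (over-subtraction) clamp to 0 with a warning.

- partition coefficient = `I_chr·A_chr / (I_chr·A_chr + I_cyt·A_cyt)`
  ∈ [0,1]; undefined (error) when both integrated signals are 0. It is
  invariant under common intensity rescaling, increasing in `I_chr`,
  decreasing in `I_cyt`.
- enrichment ratio = `I_chr / I_cyt`.
- fold change = a cell's metric divided by that cell's *mean* over all
  reference-stage rows (reference default metaphase); reference rows
  average to 1. The mean (rather than a single frame) is used because a
  single-frame reference is noisier and no convention is established.
- stage summary: per-cell stage means, then cross-cell mean ± sd and a
  two-tailed pooled-variance two-sample t-test between the two stages
  (Welch would differ only with strongly unequal variances; the pooled
  form matches the textbook statistic the tests verify against).

## Synthetic data

The generators produce data with the statistical structure the analyses
assume, at the scales used throughout the tests and analysis drivers:

- **Families**: i.i.d. draws from a shared composition. The default
  preset is enriched in S/T/P/K/R and depleted in W/C/F — a basic,
  phospho-site-rich, disorder-promoting composition typical of the IDRs
  this package targets; the preset values are repository constants, not
  measurements. Family members are compositionally homologous in
  expectation (the chi-score between two members decays as
  `~sqrt(19/N)` with combined length N, e.g. ≈ 0.03 at 2×10⁴) with
  unrelated residue order.
- **Modular sequences**: concatenated i.i.d. segments of distinct
  composition; the cumulative junctions are returned as ground truth.
  The recovery conditions use 80%-biased segments of 200 residues each.
- **ROI series**: intensities scaled so the noise-free partition equals
  the programmed per-stage target exactly (default study condition:
  metaphase 0.24, telophase 0.56, 20 cells), then multiplied by
  unit-mean lognormal noise (default CV 0.1; intensities are positive,
  so multiplicative noise is the natural model). Areas are mildly
  jittered but stage-independent.

What the generators deliberately do not emulate: indels and
substitution-matrix evolution along a phylogeny (family members are
exchangeable, real orthologs are not), position-dependent composition
within a module, correlated noise or bleaching trends in imaging series.
Passing the recovery tests therefore demonstrates correctness of the
statistics under their own assumptions, not robustness to every
violation real data can exhibit.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed and is reproducible
bit-for-bit for a fixed library release. The statistical suites use 50
seeded runs per condition for segmentation (400-residue sequences,
1000 permutations per test), 20 cells for partition recovery, and a
4-member family of 8000-residue sequences for the
composition/alignment decoupling check — sizes at which the asymptotic
claims are comfortably resolved while the whole suite runs in about a
minute on one CPU.

## Known limitations

- The ortholog panel analyzed in the motivating study is not deposited
  with accessions, so its printed similarity/dissimilarity ranges and
  per-protein values (pI, site counts) cannot be recomputed here without
  the user supplying the sequences; checks that need the fly Orc1
  sequence look for `tests/data/dmorc1.fasta` and state what is missing.
- Multiple sequence alignment is out of scope; cross-family conservation
  is summarized by pairwise global alignment only.
- The chi-score weights residues individually; no grouping into
  physicochemical classes and no k-mer composition.
- Boundary detection assumes modules at least `min_module` residues
  long and cannot place boundaries within `window` residues of the
  sequence ends.
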