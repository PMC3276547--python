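# Methods

## The problem

In a pedigreed population, a pair of alleles at two unlinked loci that is
deleterious in combination (a Dobzhansky–Müller incompatibility) leaves a
footprint in genotype data alone: the combination is under-represented among
surviving offspring relative to what independent Mendelian transmission
predicts, even though each allele looks unremarkable on its own. `imap`
screens parent–child trio genotypes for such imbalanced allele pairs without
any phenotype, using only a genotype matrix, a pedigree, and a marker map.

## The test statistic

For each trio *t* and marker *m*, the child's expected genotype distribution
is the Mendelian transmission probability given the two parental genotypes
(the six-row table of offspring probabilities for all parental combinations;
genotypes are coded as minor-allele dosage 0/1/2). Only trios with all three
members called — and a Mendelian-consistent child — contribute at a marker.

Single-locus transmission distortion (segregation distortion, one-locus
viability selection, meiotic drive) must not masquerade as interaction. Each
expected 3-vector is therefore multiplied by per-marker, per-genotype
correction factors — the ratio of the sample-wide observed to expected
genotype count — and renormalized to a probability vector. One
multiply-and-renormalize sweep moves the sample-wide expected counts toward
the observed ones but does not land on them, because the per-individual
renormalization redistributes mass. The sweep is therefore iterated per
marker (a biproportional / iterative-proportional-fitting scheme with unit
row sums and the observed genotype counts as column targets) until the
expected counts match the observed counts to within `CORRECTION_TOL = 1e-9`,
with a budget of `CORRECTION_MAX_SWEEPS = 500` sweeps. The stopping rule is
declared as part of the algorithm so that an independent reimplementation
stops at the same iterate.

*Degenerate markers.* When the observed marginal lies on the boundary of the
set attainable by factor scaling (extreme distortion — typically a genotype
class observed almost never while several trios are pinned to it), the
iteration converges only like 1/K and the budget leaves a residual of order
1e-2 counts. In the default simulated datasets this affects zero or one of
200 markers; all others match below 1e-9. The acceptance script reports the
realized worst residual (`marginal_matching_max_abs_dev`).

For a marker pair (a, b), observed 3×3 joint genotype counts O are compared
with expected counts E built per trio as the outer product of the two
corrected marginals — the independence (no-epistasis) null — summed over the
trios usable at both markers:

    S = Σ_{j,k : E_jk > 0} (O_jk − E_jk)² / E_jk

Cells with E_jk = 0 force O_jk = 0 (the correction zeroes a class only when
it is never observed) and contribute 0. Both tables sum to the number of
jointly usable trios; S is invariant under swapping the pair.

## Permutation p-values from pseudo-controls

The null distribution of S is marker-pair specific (it depends on allele
frequencies and the informativeness of the parents), so significance is
assessed by pseudo-controls: for each trio the four genotypes the child
could have inherited (one transmitted allele per parent, duplicates kept)
are enumerated, and a pseudo-offspring cohort is assembled by drawing one of
the four uniformly, independently per trio and marker. Each of B pseudo
cohorts is pushed through the identical pipeline — correction factors
recomputed from the pseudo data, renormalization, joint table, S — giving an
empirical null; the p-value is the fraction of null statistics at or above
the observed one, with add-one smoothing (1+k)/(1+B) so p > 0 (the raw
fraction is available via `smoothed=False`). Ties count against the observed
score. One RNG stream per marker pair is derived from (seed, a, b), so
results are independent of evaluation order. BH step-up q-values control the
FDR across screened pairs.

Implementation note: within a marker, one correction sweep maps each trio
vector v to (v∘f)/Σ(v∘f), so the state after any number of sweeps is
v∘F/Σ(v∘F) for a cumulative factor F. The permutation engine iterates F on
the ≤ 9 distinct parental Mendelian vectors instead of on all trios, which
makes B = 1000 permutations of a 500-trio pair a few milliseconds.

*Calibration.* For trios that share no individuals (a single genotyped
generation), observed and pseudo cohorts are exchangeable by construction
and the type-I error is exact (measured 27–28 rejections per 600 pairs at
nominal 5%). In a multi-generation pedigree an individual can be the child
of one trio and a parent of another; the pseudo-controls resample the first
role but condition on the second, and erroneous parent genotypes (the error
overlay) distort the conditional model slightly. Both effects make the test
mildly anti-conservative on the default three-generation fixture (measured
0.055–0.073 at nominal 0.05). The KS test against uniformity is insensitive
to this at the simulated scale.

## Two-step genome scan

Testing all marker pairs is wasteful when neighbouring markers are in strong
LD. Markers are first partitioned into blocks by greedy left-to-right
chaining: extend the current block while the dosage r² of adjacent markers
(computed on the trio parents only, since children duplicate parental
alleles) is at least `r2_threshold` (default 0.8). One representative per
block is drawn uniformly among the markers with the block-minimum number of
missing calls. Representatives are tested for all pairs on *different*
chromosomes — within-chromosome pairs are excluded because local LD, not
epistasis, dominates them — and block pairs with BH q ≤ `fdr_cutoff`
(default 0.25, deliberately permissive for a screen) are fine-mapped: every
cross-block marker pair is retested and the minimum-p pair (ties broken by
larger S) reported as the interacting pair. Fine-map p-values rank markers
inside regions already selected by the screen and carry no multiplicity
correction; they are labelled as ranking scores, not genome-wide p-values.

## Congruence of interaction profiles

Loci in the same pathway should share interaction partners. For two loci the
congruence score is −log10 of the hypergeometric upper-tail probability of
sharing at least the observed number of partners, given each locus's partner
count and the universe of loci tested. The two focal loci — and any direct
edge between them — are removed from the universe and from both partner sets
first, so one shared direct interaction cannot inflate the score. The score
is symmetric and nondecreasing in the overlap at fixed partner-set sizes.

## The pedigree simulator

The simulator is the null-calibration engine and the planted-truth factory.
It emulates a heterogeneous stock (HS): `n_lines = 8` fully inbred founder
lines (one haplotype per line, alleles i.i.d. Bernoulli(0.5) per marker),
`n_founders = 40` founders homozygous for one line's haplotypes assigned
round-robin with sexes alternating within line, then random mating. Gametes
follow a first-order Markov walk: a fair coin chooses the starting
haplotype per chromosome, and each adjacent-marker interval switches source
with its crossover probability (default 0.05 per interval, 5 chromosomes ×
40 markers). Genotyping errors (default 1%) replace a call with a different
genotype drawn uniformly among those consistent with every trio the
individual belongs to, so no Mendelian conflicts are created; missingness
(default 5%) is i.i.d. or copied from a mask. The default genotyped pedigree
is 3 generations × 170 children ≈ 510 trios.

A planted incompatibility is a single lethal genotype combination (j\*, k\*)
at two unlinked loci with selection coefficient s: a conceptus carrying it
is rejected and regenerated with probability s (capped at 10,000 attempts).
The default combination is the doubly-heterozygous state (Aa, Aa) — the
genotype in which dominant-acting incompatibilities classically manifest
(it is the F1-hybrid configuration, and inbred founders can never carry
it); a recessive incompatibility (aa, aa) is available via
`IncompatibilitySpec`. Under s = 1 a mating that can only produce the
lethal combination (e.g. AA × aa parents at both loci) is redrawn — such a
pair has no surviving offspring. With s = 0 the output is stream-identical
to a run without the incompatibility.

*Power fixture.* `planted_fixture_config()` inserts eight ungenotyped
random-mating generations ("premix", population 80) between the founding
cross and the genotyped pedigree, as in a real HS that is genotyped many
generations after founding. This matters: founder-parent trios are
genotypically deterministic (homozygous parents make the child's genotype
certain), so with genotyping started at the cross one third of trios carry
no information and s = 1 selection erodes the planted minor alleles,
occasionally to extinction. With premixing, trio parents are outbred and the
planted pair scores S ≈ 50–80 against a 16,000-pair null maximum of ≈ 30 —
top-ranked in 20/20 replicates. The incompatibility is planted after the
neutral premix at loci whose mixed-stock MAF is nearest 0.3 (so "MAF ≈ 0.3"
refers to the population actually genotyped), and this fixture carries no
error/missingness overlay: it is a positive control whose defining truth is
a structurally zero cell, which a 1% error overlay would corrupt with ~1–2
spurious carriers per replicate. The null-calibration fixture keeps the
default conditions (no premix, overlays on).

### What the simulator does not model

Coalescent founder history (line haplotypes are i.i.d. across markers, so
founder LD between markers is limited to the 8-haplotype constraint),
crossover interference, sex-specific recombination maps (the interface
accepts per-interval rates but the default is uniform), X-chromosome
inheritance, and genotyping error that correlates across markers or
individuals. Passing null calibration here shows the permutation machinery
is self-consistent under Mendelian transmission with realistic missingness
and error — not that every real-data artefact (batch effects, reference
bias, segmental duplications) is handled.

## Numerical and design choices

- Genotypes are stored as minor-allele dosage with MISSING = −1; the minor
  allele is the rarer allele among non-missing calls, ties broken toward
  the lexicographically later base.
- MAF is computed over non-missing calls and folded; QC defaults are 10%
  maximum missingness per individual and per marker and MAF ≥ 0.05, all
  configurable. No Hardy–Weinberg filter is applied: trio expectations
  condition on parents, and distortion is corrected, not filtered.
- Mendelian-inconsistent (trio, marker) calls are masked as missing for
  that trio (and logged) rather than erroring: a single bad call must not
  force a zero expectation onto an observed genotype.
- Pairs with fewer than `min_pair_trios = 20` jointly usable trios are
  skipped (logged) — 3×3 tables below that are too unstable to interpret.
- A 0/0 observed/expected ratio is defined as 1 (no information, and it
  multiplies a zero).
- The add-one smoothed p-value is the default; with B = 1 it takes values
  in {0.5, 1}, and the smallest attainable p is 1/(B+1) — choose B with the
  BH cutoff in mind (to clear q ≤ f over P pairs, B ≳ P/f − 1 is needed).
- `screen_block_pairs(max_pairs=...)` subsamples the representative pairs
  (seeded) for calibration studies; production screens test all pairs.
- Problem sizes in the test suite and acceptance script (600 screened pairs
  at B = 200 for calibration; 20 planted replicates ranked by S over all
  ~16,000 inter-chromosomal pairs) were chosen so the full validation runs
  in a few minutes on one CPU while keeping the binomial/KS checks
  well-powered.

## Known limitations

- Ranking planted pairs uses S, not p: permutation p-values saturate at
  1/(B+1) and cannot totally order the strongest pairs.
- The boundary-case correction residual (above) is reported, not hidden; a
  marker that needs an exactly-zero expected class with a nonzero pinned
  contribution cannot be matched by any finite factor.
- Multi-generation pedigrees make the test mildly anti-conservative at
  nominal 5% (see Calibration); interpret borderline screen hits
  accordingly — the screen's permissive FDR cutoff plus fine mapping is the
  intended workflow, not single-pair hypothesis tests.
- The congruence test treats partner sets as fixed-size random draws; it
  ignores the dependence structure among interaction calls that share a
  locus.
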