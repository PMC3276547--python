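# imap — imbalanced allele pairs in trio genotype data

`imap` detects epistatic interactions between pairs of loci from genotypes
alone. In a pedigreed population, a Dobzhansky–Müller-type incompatibility —
two alleles at unlinked loci that are harmless alone but deleterious
together — leaves a footprint in the offspring: the incompatible genotype
combination is under-represented relative to independent Mendelian
transmission, with no phenotype needed to see it. `imap` is built for
datasets like an outbred heterogeneous stock with a recorded pedigree, and
for anyone who wants a sequence-only screen for viability/fertility
epistasis: quantitative geneticists, mouse-resource analysts, and people
validating interaction methods on simulated pedigrees.

## The method

For each genotyped parent–child trio and marker, the child's expected
genotype distribution is the Mendelian transmission probability given the
parents, *P*(G_child | G_father, G_mother), with genotypes coded as
minor-allele dosage 0/1/2. Single-locus transmission distortion is removed
by multiplying each expected 3-vector with per-marker, per-genotype factors
(observed / expected sample-wide genotype count) and renormalizing,
iterated until the sample-wide expected counts equal the observed ones. For
a marker pair (a, b) on different chromosomes, observed 3×3 joint genotype
counts O_jk are compared with expected counts E_jk = Σ_t P_t(a = j)·P_t(b = k)
— the independence null — through the χ²-like score

    S = Σ_{j,k : E_jk > 0} (O_jk − E_jk)² / E_jk .

Significance comes from trio pseudo-controls: the four genotypes each child
could have inherited per marker are recombined at random into pseudo-offspring
cohorts, the full statistic pipeline is recomputed on each, and the p-value
is the (add-one smoothed) fraction of pseudo-control scores reaching the
observed S. BH q-values control the FDR across the screen. To keep the
number of tests manageable, markers are grouped into LD blocks (adjacent-r²
chaining), block representatives are screened across chromosomes, and
significant block pairs are fine-mapped at marker resolution. A
hypergeometric congruence score compares the interaction-partner profiles
of loci. A gene-dropping pedigree simulator (inbred founder lines, random
mating with recombination, Mendelian-consistent genotyping errors,
missingness, optional planted lethal incompatibilities) provides null
calibration and planted-truth validation.

## Worked example

Simulate a small heterogeneous stock (3 chromosomes × 8 markers, 510 trios)
with a lethal doubly-heterozygous incompatibility planted at two unlinked
loci, then run the full screen:

```bash
imap simulate --out-dir sim --seed 42 --planted --trios 170 \
              --chromosomes 3 --markers-per-chromosome 8
# wrote 590 individuals x 24 markers to sim
# truth.json records: {"marker_a": "c1m007", "marker_b": "c2m001",
#                      "lethal": [1, 1], "s": 1.0}

imap full --genotypes sim/sim --pedigree sim/sim.fam --out-dir out --seed 7 -B 999
# screen: 192 pairs; finemap: 2; congruence: 276
```

The three strongest rows of `out/screen.tsv`:

```
level  block_a  block_b  chrom_a marker_a  chrom_b marker_b  n_pair          S     p     q  significant
block        6        8        1   c1m007        2   c2m001     510 103.216163 0.001 0.096         True
block        5        8        1   c1m006        2   c2m001     510  16.169723 0.001 0.096         True
block        6       20        1   c1m007        3   c3m005     510  11.850880 0.006 0.384        False
```

The planted pair (c1m007, c2m001) is the top hit: its score S ≈ 103 says the
observed joint genotype counts sit far from the independence expectation —
driven by the double-heterozygote cell, which contains zero children although
47.5 were expected — and p = 0.001 is the smallest value B = 999 permutations
can resolve. The neighbouring marker c1m006 echoes the signal through local
LD with c1m007, which is exactly why the screen works on block
representatives and same-chromosome pairs are never tested. In
`out/finemap.tsv` the pair is flagged `top_pair` within its significant
block pair; fine-map p-values rank markers inside already-selected regions
and are not multiplicity-corrected. `out/manifest.json` records the seed,
configuration, and the individual/marker/trio counts at every filter stage;
re-running with the same inputs reproduces every table byte for byte.

The same workflow runs on real data: PLINK text PED/MAP (or a dosage TSV), a
FAM-like pedigree file, and the same `qc → blocks → screen → finemap →
congruence` subcommands (see `imap --help`).

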