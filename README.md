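# denovotrio

Bayesian de novo mutation (DNM) calling and transmission phasing in
parent–offspring trios, from a multi-sample VCF with per-genotype
phred-scaled likelihoods (PL) and a PED pedigree.

Germline de novo point mutations are rare (~1e-8 per site per
generation), so naïve Mendelian-violation screens drown true events in
genotyping error, especially at low coverage and on the X chromosome.
`denovotrio` addresses this for researchers running trio or cohort
sequencing studies: it scores every trio at every biallelic site under
an explicit model of trio genotype combinations, phases the inherited
variants as a by-product, and ships a truth-known simulator plus an
evaluation harness so its operating characteristics can be measured
end to end.

## Model

At a biallelic site, enumerate every (G_M, G_F, G_C) genotype
combination for the trio — 27 autosomal, 18 on X with a female
offspring (hemizygous father), 6 on X with a male offspring (haploid
child, maternal inheritance only) — and classify each by the minimum
number of child alleles not explainable by transmission: Mendelian,
single-DNM, or double-DNM. With mutation-rate prior μ, n single-DNM and
m double-DNM combinations, the combination prior is

    P_C = μ            (single DNM)
    P_C = μ²           (double DNM)
    P_C = (1 − nμ − mμ²) / k   (each of the k Mendelian combinations)

and the posterior of each combination given the observed read data D is

    P(G_M, G_F, G_C | D) ∝ L(D_M|G_M) · L(D_F|G_F) · L(D_C|G_C) · P_C

optionally multiplied by Hardy–Weinberg allele-frequency priors
AF(G_M)·AF(G_F) on the parents (from cohort founders or an external
sites VCF), with L = 10^(−PL/10), evaluated in log space. The trio is
assigned the maximum-posterior combination; a Mendelian-violating best
combination is reported as a putative DNM with confidence
Q = −10·log10(1 − posterior). For Mendelian combinations, allele
segregation determines phase deterministically — child written
maternal|paternal — except for the triple heterozygote and DNM calls,
which remain unphased.

## Worked example

Simulate four 30x autosomal trios with known truth, call with a
permissive mutation prior and founder allele-frequency priors, and
score against the truth table:

```sh
denovotrio simulate --out-dir demo/sim --n-trios 4 --n-sites 500 \
    --dnm-rate 0.01 --depth 30 --seed 7
denovotrio call --vcf demo/sim/trios.vcf --ped demo/sim/trios.ped \
    --out-dir demo/calls --mu 1e-5 --min-q 5
denovotrio evaluate --calls demo/calls/calls.tsv \
    --truth demo/sim/truth.tsv --ped demo/sim/trios.ped \
    --out-dir demo/eval --thresholds 0,5,20
```

prints

```
simulated 500 sites x 4 trios (18 de novo events) -> demo/sim
called 2000 trio-sites, 9 de novo candidates at Q>=5.0 -> demo/calls
sensitivity=0.5000 specificity=1.0000 (Q>=0.0) -> demo/eval
```

The ranked candidate table (`demo/calls/dnm_table.tsv`) starts

```
contig  pos  ref  alt  family  combination         posterior  q_score  filters
1       207  A    C    F0003   M=0/0,F=0/0,C=0/1   0.999997   54.75    PASS
1       471  A    C    F0001   M=0/0,F=0/0,C=0/1   0.999982   47.46    parent_alt_reads
```

Each row is one trio's best combination at a Mendelian-violating site:
a confident 0/0 × 0/0 → 0/1 de novo heterozygote, with the
`parent_alt_reads` filter marking candidates where a parent shows any
ALT-supporting read. The headline sensitivity of 0.50 is exactly the
genotype-visible fraction: at segregating sites a simulated mutation
can flip a child allele into a configuration still consistent with
inheritance (here 9 of 18 events), and the caller recovers all 9
visible events with no false positives. `demo/calls/calls.vcf` carries
the phased genotypes (e.g. child `1|0`, ALT maternal) and per-trio
phred-scaled combination posteriors in the `TP` FORMAT field.

X-chromosome cohorts work the same way with `--chromosome X`; child sex
from the PED file selects the female (diploid) or male (haploid,
father-free) X model per trio.

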