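# Methods

## Trio genotype-combination model

A biallelic site in a mother–father–child trio is modelled over every
joint genotype assignment compatible with the inheritance mode:

| mode               | mother  | father        | child   | total | Mendelian | 1 DNM | 2 DNM |
|--------------------|---------|---------------|---------|-------|-----------|-------|-------|
| autosomal          | diploid | diploid       | diploid | 27    | 15        | 10    | 2     |
| X, female offspring| diploid | haploid       | diploid | 18    | 8         | 8     | 2     |
| X, male offspring  | diploid | not modelled  | haploid | 6     | 4         | 2     | 0     |

A combination's de novo class is the minimum number of child alleles
that cannot be produced by transmitting one allele from each parent
(father contributes nothing to a male offspring's X); it is computed by
exhaustive assignment of the child's alleles to parental gametes and
cross-checked in the tests against an independent gamete-enumeration
oracle. Pseudo-autosomal regions should be excluded via the BED
mechanism when calling X; contigs named `X`/`chrX` select the X models,
all others are treated as autosomal.

### Priors

Given per-gamete mutation probability μ (default 1.5e-8, the canonical
human per-site per-generation rate), each single-DNM combination has
prior μ, each double-DNM combination μ², and the remaining mass
1 − nμ − mμ² is divided equally among the Mendelian combinations.
Mendelian combinations are deliberately weighted uniformly rather than
by gamete-transmission probabilities (1/4–1/2–1/4): the posterior is a
model over *which configuration explains the data*, and uniform
weighting avoids penalising heterozygous-parent configurations at
sites ascertained as variant. μ is validated so the mutant mass stays
below 1 in every mode.

### Posterior and calling

PL values are de-phredded (L = 10^(−PL/10)) and the combination
posterior is accumulated in natural-log space with log-sum-exp
normalisation, so arbitrarily large PLs cannot underflow. Allele
frequency priors, when enabled, multiply HWE genotype priors onto the
*parents only* — (p², 2pq, q²) diploid, (p, q) haploid; the child is
already constrained through the combination. The best combination is
the posterior argmax; exact ties break toward fewer de novo alleles,
then toward canonical enumeration order (conservative with flat or
symmetric likelihoods). Call confidence is Q = −10·log10(1 −
posterior), capped at 99 (configurable) to avoid infinities when the
posterior rounds to 1. Trios missing a PL for any modelled member are
skipped at that site and tallied; no imputation. Hemizygous samples
encoded diploid in the VCF (PL length 3) are reduced by dropping the
heterozygous entry (flag-controlled, on by default). Multi-allelic
records are skipped and counted.

### Allele-frequency priors

Founder mode counts ALT dosage over the hard genotypes of the cohort's
parents at each site (two chromosomes per diploid founder, one per
hemizygous X founder; diploid-het-encoded hemizygotes are treated as
missing). The estimate is clamped to [1/(2N+2), 1 − 1/(2N+2)], N the
number of called founders, so no genotype ever receives prior exactly
zero — a zero prior would veto a genotype regardless of likelihood.
External mode reads a sites-only VCF's `AF` INFO field, keyed exactly
on (contig, pos, ref, alt); absent sites get no AF prior. External
resources carry no sample size, so they clamp with a configurable
effective N (default 500). With no called founder at a site the
estimator falls back to q = 0.5 and logs a warning.

### Transmission phasing

For the assigned combination, all (maternal, paternal) gamete pairs
consistent with the three genotypes are enumerated. A unique pair
resolves phase: child written maternal|paternal, each parent
transmitted-first. Exactly one Mendelian configuration per diploid mode
is ambiguous — all three members heterozygous — and every DNM
combination is left unphased (the mutant allele has no transmitted
origin at genotype level). The phasing confidence is the combination's
joint posterior, carried on the call.

## Simulator

The generator reproduces the statistical structure the caller consumes
while staying desk-scale: per site an ALT frequency is drawn
(Uniform(0.05, 0.5) by default; a configurable fraction of sites is
monomorphic, emulating de novo injection at random genome positions),
parental haplotypes are Bernoulli(q), each child inherits one random
allele per transmitting parent, and a DNM flips one inherited child
allele with per-site probability `dnm_rate`, paternal with probability
0.70 (maternal forced on the male X). Read evidence is depth ~
Poisson(mean), ALT count ~ Binomial(depth, d/ploidy·(1−e) +
(1−d/ploidy)·e) with per-read error e, and PLs are the phred-scaled
binomial likelihoods, min-normalised and rounded to integers as a VCF
stores them. Defaults: 10 trios at a 0.5 male fraction, 30x mean depth
(the middle of the 60/30/15 grid the evaluation targets), e = 0.01,
dnm_rate = 1e-3. One seeded generator drives every draw, so a fixed
seed gives byte-identical VCF/PED/truth outputs.

What it does **not** emulate: read-level artifacts (mapping error,
indel realignment, strand bias), base-quality variation between reads,
linkage between nearby sites, or a genome-wide mutation-rate map
(per-site DNM probability is uniform). Passing tests therefore
demonstrate correctness of the probabilistic machinery and realistic
depth/error-driven operating characteristics, not robustness to
alignment pathology on real data. Note that at segregating sites a
simulated flip can land on a genotype configuration still consistent
with inheritance; such events are intrinsically invisible to any
genotype-level caller and are counted as false negatives by the
evaluator, which is why autosomal sensitivity on polymorphic
backgrounds sits near the genotype-visible fraction.

## Evaluation

A DNM call is `is_denovo` with Q at or above the chosen threshold.
Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), NaN on empty
denominators. Truth rows with no corresponding call count as false
negatives when they are de novo (configurable), mirroring pipelines
where an upstream genotyper never emits some true sites; inherited
rows with no call stay out of the denominator. ROC sweeps vary the Q
threshold on fixed calls; prior sweeps re-call the same likelihoods
across a μ grid (1.5e-8 … 1e-4). Both monotonicity properties asserted
in the tests — DNM posterior mass non-decreasing in μ, specificity
non-decreasing in threshold — follow directly from the prior form and
the call definition.

## Benchmark scenarios

`denovotrio.benchmarks` pins the reference scenarios: (a) paternal
bias — 20 autosomal trios × 2,650 sites at dnm_rate 0.2 (≥10,000
injected events) checking the realised 70/30 split; (b) X sensitivity
at 15x — 250 trios per offspring sex × 100 monomorphic-background
sites at dnm_rate 0.1 (≥2,000 true DNM trio-sites), e = 0.01, founder
AF priors, μ = 1e-5, threshold Q ≥ 0. The 500-parent founder panel is
cohort-scale and sets the AF clamp floor at ~1e-3.

Under these conditions measured sensitivity is ≈ 90% (female
offspring) and ≈ 96% (male offspring). This is an intrinsic ceiling of
the flat per-read error model, not a calling defect: with e = 0.01
each ALT read carries only 10·log10(0.5/0.01) ≈ 17 phred of
het-vs-hom-ref evidence, so a heterozygous child at 15x fails to clear
the ≈ 10·log10(P_mend/μ) ≈ 41-phred prior barrier whenever it draws
≤ 4 ALT reads (probability ≈ 6% at depth 15, more at lower draws), and
a mother drawing ≥ 2 error reads (probability ≈ 1%) is better
explained as a heterozygous carrier. Quality-aware read-level
pipelines assign ~1e-3 error to most bases (≈ 27–34 phred per ALT
read), under which the same barriers almost never bind and reported
sensitivities reach 98–99%; the male model is read-efficient
(hemizygous child, ≈ 20 phred per read) and so lands closer to its
reference than the female model.

## Known limitations

Biallelic SNVs/short indels only; trios only (no multi-generation
pedigrees, no read-backed parental-origin assignment of DNMs);
genotype-level input (no BAM/CRAM access); uniform per-site mutation
prior with no sequence-context or regional rate map; external AF
matching is exact on (contig, pos, ref, alt) with no allele
normalisation.
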