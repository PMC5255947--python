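"""Synthetic trio data with known truth.

The generator emulates the statistical structure the caller consumes,
without simulating reads or alignment.  Per site, an ALT allele
frequency is drawn (or the site is left monomorphic), parental
haplotypes are sampled from that frequency under Hardy-Weinberg
equilibrium, and each child inherits one allele per transmitting
parent.  De novo mutations flip one inherited child allele at a
configurable per-site rate, assigned to the paternal haplotype with
probability ``paternal_fraction`` (forced maternal for the haploid X of
a male offspring, which carries no paternal allele).

Sequencing evidence is summarised at the genotype-likelihood level:
per-sample depth is Poisson at the configured mean, the ALT read count
is binomial with a per-read error rate, and PL vectors are the
phred-scaled binomial likelihoods of the read counts under each
candidate genotype, min-normalised and rounded to integers as a VCF
would store them.

Everything is driven by one seeded generator, so a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genotypes import Sex, format_genotype
from .vcf_io import SiteRecord, Trio, X_CONTIGS

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_trios",
    "pl_from_counts",
    "simulate_sample_reads",
    "write_dataset",
]

PATERNAL = "paternal"
MATERNAL = "maternal"
NA = "na"

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``chromosome`` selects the inheritance model: "X"/"chrX" makes
    fathers hemizygous and male children haploid; anything else is
    autosomal.  ``male_fraction`` fixes the child sex mix (the first
    ``round(n_trios * male_fraction)`` children are male).  Inherited
    sites draw their ALT frequency uniformly from ``af_range``, except
    a ``monomorphic_fraction`` of sites that start with no ALT allele
    in the population and only become variant through a de novo event.
    """

    n_trios: int = 10
    n_sites: int = 1000
    chromosome: str = "1"
    male_fraction: float = 0.5
    af_range: tuple[float, float] = (0.05, 0.5)
    monomorphic_fraction: float = 0.0
    dnm_rate: float = 0.001
    paternal_fraction: float = 0.70
    mean_depth: float = 30.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1 or self.n_sites < 1:
            raise ValueError("n_trios and n_sites must be positive")
        for name in ("male_fraction", "monomorphic_fraction", "dnm_rate",
                     "paternal_fraction", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.af_range[0] <= self.af_range[1] <= 1.0):
            raise ValueError(f"invalid af_range {self.af_range}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def is_x(self) -> bool:
        return self.chromosome in X_CONTIGS


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    trios: list[Trio]
    sites: list[SiteRecord]
    truth: pd.DataFrame = field(repr=False)


def pl_from_counts(
    n_ref: int, n_alt: int, error_rate: float, ploidy: int = 2
) -> tuple[int, ...]:
    """Phred-scaled binomial likelihoods of (ref, alt) read counts.

    Under candidate genotype with ALT dosage d (out of ``ploidy``), a
    read supports ALT with probability ``(d/ploidy)*(1-e) +
    (1-d/ploidy)*e``.  The binomial coefficient is constant across
    genotypes and dropped.  Zero depth gives a flat PL vector.
    """
    n_genotypes = ploidy + 1
    depth = n_ref + n_alt
    if depth == 0:
        return (0,) * n_genotypes
    e = error_rate
    pls = []
    for dosage in range(n_genotypes):
        frac = dosage / ploidy
        p_alt = frac * (1.0 - e) + (1.0 - frac) * e
        ll = n_alt * math.log(p_alt) + n_ref * math.log(1.0 - p_alt)
        pls.append(-10.0 * ll / _LN10)
    lo = min(pls)
    return tuple(int(round(v - lo)) for v in pls)


def simulate_sample_reads(
    true_genotype: tuple[int, ...],
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], tuple[int, int]]:
    """Draw one sample's read counts and return (PL, AD)."""
    ploidy = len(true_genotype)
    depth = int(rng.poisson(mean_depth))
    frac = sum(true_genotype) / ploidy
    p_alt = frac * (1.0 - error_rate) + (1.0 - frac) * error_rate
    n_alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
    n_ref = depth - n_alt
    return pl_from_counts(n_ref, n_alt, error_rate, ploidy), (n_ref, n_alt)


def _make_trios(cfg: SimulationConfig) -> list[Trio]:
    n_male = round(cfg.n_trios * cfg.male_fraction)
    trios = []
    for i in range(cfg.n_trios):
        fam = f"F{i + 1:04d}"
        trios.append(
            Trio(
                family=fam,
                mother=f"{fam}-M",
                father=f"{fam}-F",
                child=f"{fam}-C",
                child_sex=Sex.MALE if i < n_male else Sex.FEMALE,
            )
        )
    return trios


def simulate_trios(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate sites, trios and the ground-truth table for one run."""
    rng = np.random.default_rng(cfg.seed)
    trios = _make_trios(cfg)
    is_x = cfg.is_x
    sites: list[SiteRecord] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_sites):
        pos = i + 1
        if rng.random() < cfg.monomorphic_fraction:
            q = 0.0
        else:
            q = float(rng.uniform(*cfg.af_range))
        site = SiteRecord(contig=cfg.chromosome, pos=pos, ref="A", alt="C")
        for trio in trios:
            male_child = trio.child_sex is Sex.MALE
            mother_h = tuple(int(rng.random() < q) for _ in range(2))
            father_ploidy = 1 if is_x else 2
            father_h = tuple(int(rng.random() < q) for _ in range(father_ploidy))

            maternal = mother_h[int(rng.integers(2))]
            if is_x and male_child:
                paternal = None
            elif is_x:
                paternal = father_h[0]
            else:
                paternal = father_h[int(rng.integers(2))]

            is_dnm = rng.random() < cfg.dnm_rate
            origin = NA
            if is_dnm:
                if paternal is None:
                    origin = MATERNAL
                else:
                    origin = (
                        PATERNAL
                        if rng.random() < cfg.paternal_fraction
                        else MATERNAL
                    )
                if origin == PATERNAL:
                    paternal = 1 - paternal
                else:
                    maternal = 1 - maternal

            gt_mother = tuple(sorted(mother_h))
            gt_father = tuple(sorted(father_h))
            gt_child = (
                (maternal,)
                if paternal is None
                else tuple(sorted((maternal, paternal)))
            )

            for sample, gt in (
                (trio.mother, gt_mother),
                (trio.father, gt_father),
                (trio.child, gt_child),
            ):
                pl, ad = simulate_sample_reads(
                    gt, cfg.mean_depth, cfg.error_rate, rng
                )
                site.gts[sample] = gt
                site.pls[sample] = pl
                site.ads[sample] = ad

            truth_rows.append(
                {
                    "contig": cfg.chromosome,
                    "pos": pos,
                    "family": trio.family,
                    "child_sex": trio.child_sex.value,
                    "gt_mother": format_genotype(gt_mother),
                    "gt_father": format_genotype(gt_father),
                    "gt_child": format_genotype(gt_child),
                    "is_dnm": is_dnm,
                    "origin": origin,
                }
            )
        sites.append(site)

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(config=cfg, trios=trios, sites=sites, truth=truth)


def _sim_header(cfg: SimulationConfig, trios: list[Trio]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(cfg.chromosome)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for t in trios:
        for s in t.samples:
            header.add_sample(s)
    return header


def write_dataset(
    ds: SimulatedDataset,
    vcf_path: str | Path,
    ped_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Write the dataset as a multi-sample VCF, a PED file and a truth TSV."""
    header = _sim_header(ds.config, ds.trios)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for site in ds.sites:
            rec = out.new_record(
                contig=site.contig, start=site.pos - 1, alleles=(site.ref, site.alt)
            )
            for t in ds.trios:
                for s in t.samples:
                    rec.samples[s]["GT"] = site.gts[s]
                    rec.samples[s]["PL"] = site.pls[s]
                    rec.samples[s]["AD"] = site.ads[s]
            out.write(rec)

    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    with open(ped_path, "w") as fh:
        for t in ds.trios:
            fh.write(f"{t.family} {t.father} 0 0 1 -9\n")
            fh.write(f"{t.family} {t.mother} 0 0 2 -9\n")
            fh.write(
                f"{t.family} {t.child} {t.father} {t.mother} "
                f"{sex_code[t.child_sex]} -9\n"
            )

    ds.truth.to_csv(truth_path, sep="\t", index=False)
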