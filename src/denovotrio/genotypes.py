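"""Core genotype representations for biallelic sites.

A genotype is a tuple of allele indices (0 = REF, 1 = ALT): diploid
genotypes are sorted length-2 tuples, haploid genotypes length-1 tuples.
Phase is never carried on the genotype itself; resolved phase is stored
separately as ordered allele tuples (see :mod:`denovotrio.phasing`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "DIPLOID_GENOTYPES",
    "HAPLOID_GENOTYPES",
    "Sex",
    "InheritanceMode",
    "GenotypeLikelihoods",
    "genotypes_for_ploidy",
    "genotype_index",
    "format_genotype",
]

#: Diploid genotypes in PL order (ALT dosage 0, 1, 2).
DIPLOID_GENOTYPES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 1))
#: Haploid genotypes in PL order (ALT dosage 0, 1).
HAPLOID_GENOTYPES: tuple[tuple[int], ...] = ((0,), (1,))

_LN10 = float(np.log(10.0))


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class InheritanceMode(enum.Enum):
    """Trio inheritance mode at a site.

    ``AUTOSOMAL`` has all members diploid.  On the X chromosome the father
    is hemizygous (haploid); a female offspring is diploid while a male
    offspring is haploid and inherits his X exclusively from his mother,
    so the father drops out of the male-offspring model entirely.
    """

    AUTOSOMAL = "autosomal"
    X_FEMALE_OFFSPRING = "x_female_offspring"
    X_MALE_OFFSPRING = "x_male_offspring"

    @property
    def mother_ploidy(self) -> int:
        return 2

    @property
    def father_ploidy(self) -> int | None:
        """Father's ploidy, or ``None`` when he does not enter the model."""
        if self is InheritanceMode.AUTOSOMAL:
            return 2
        if self is InheritanceMode.X_FEMALE_OFFSPRING:
            return 1
        return None

    @property
    def child_ploidy(self) -> int:
        return 1 if self is InheritanceMode.X_MALE_OFFSPRING else 2

    @property
    def models_father(self) -> bool:
        return self is not InheritanceMode.X_MALE_OFFSPRING


def genotypes_for_ploidy(ploidy: int) -> tuple[tuple[int, ...], ...]:
    if ploidy == 2:
        return DIPLOID_GENOTYPES
    if ploidy == 1:
        return HAPLOID_GENOTYPES
    raise ValueError(f"unsupported ploidy: {ploidy}")


def genotype_index(genotype: tuple[int, ...]) -> int:
    """PL-vector index of a biallelic genotype (equal to its ALT dosage)."""
    return sum(genotype)


def format_genotype(genotype: tuple[int, ...], phased: bool = False) -> str:
    sep = "|" if phased else "/"
    return sep.join(str(a) for a in genotype)


@dataclass(frozen=True, eq=False)
class GenotypeLikelihoods:
    """Phred-scaled genotype likelihoods for one sample at one site.

    One entry per candidate genotype, ordered by ALT dosage: (0/0, 0/1,
    1/1) for a diploid sample, (0, 1) for a haploid one.  Values are
    non-negative and finite; by VCF convention the best genotype has
    PL 0, but only non-negativity is required here because posteriors
    are normalised downstream.
    """

    pl: np.ndarray = field(repr=True)

    def __post_init__(self) -> None:
        pl = np.asarray(self.pl, dtype=float)
        if pl.ndim != 1 or len(pl) not in (2, 3):
            raise ValueError(f"PL vector must have length 2 or 3, got shape {pl.shape}")
        if not np.all(np.isfinite(pl)) or np.any(pl < 0):
            raise ValueError(f"PL values must be finite and >= 0, got {pl}")
        object.__setattr__(self, "pl", pl)

    @classmethod
    def from_phred(
        cls, values, *, haploid_from_diploid: bool = False
    ) -> "GenotypeLikelihoods":
        """Build from a raw PL vector.

        With ``haploid_from_diploid`` a length-3 diploid-encoded vector
        (as VCFs often store hemizygous males) is reduced to a haploid
        one: the heterozygous entry is dropped and the homozygous
        entries map to haploid REF/ALT.
        """
        values = np.asarray(values, dtype=float)
        if haploid_from_diploid and len(values) == 3:
            values = values[[0, 2]]
        values = values - values.min()
        return cls(values)

    @property
    def ploidy(self) -> int:
        return len(self.pl) - 1

    @cached_property
    def log_likelihoods(self) -> np.ndarray:
        """Natural-log likelihoods, de-phred via L = 10^(-PL/10)."""
        return -self.pl / 10.0 * _LN10
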