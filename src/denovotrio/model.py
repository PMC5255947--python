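"""Bayesian trio genotype-combination model.

At a biallelic site every (mother, father, child) genotype combination
compatible with the inheritance mode is enumerated and classified by the
minimum number of child alleles that cannot be explained by Mendelian
transmission (0, 1 or 2 de novo alleles).  Each combination receives a
prior driven by a per-site mutation rate ``mu``: a single-mutation
combination has prior ``mu``, a double-mutation combination ``mu**2``,
and the remaining probability mass is shared uniformly by the
Mendelian-consistent combinations.  The posterior of each combination is
the product of the three members' genotype likelihoods, the combination
prior and (optionally) Hardy-Weinberg allele-frequency priors on the
parental genotypes, normalised over all combinations in log space.

The trio is assigned the maximum-posterior combination; when that
combination requires at least one de novo allele the site is reported as
a putative de novo mutation with a phred-scaled quality derived from the
normalised posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .allele_freq import AlleleFrequencyPrior
from .genotypes import (
    GenotypeLikelihoods,
    InheritanceMode,
    genotype_index,
    genotypes_for_ploidy,
)

__all__ = [
    "TrioCombination",
    "MutationPriorConfig",
    "TrioCall",
    "UncallableSiteError",
    "classify_denovo",
    "enumerate_combinations",
    "combination_counts",
    "combination_priors",
    "combo_table",
    "trio_posterior",
    "call_trio",
]

DEFAULT_MU = 1.5e-8  # per-site, per-generation human point mutation rate


class UncallableSiteError(ValueError):
    """All genotype combinations have zero likelihood; the site cannot be called."""


@dataclass(frozen=True)
class TrioCombination:
    """One (mother, father, child) genotype assignment at a biallelic site.

    ``father`` is ``None`` in the X male-offspring mode, where the father
    contributes no allele and drops out of the model.
    """

    mother: tuple[int, ...]
    father: tuple[int, ...] | None
    child: tuple[int, ...]
    n_denovo_alleles: int
    prior: float | None = None
    index: int = -1

    @property
    def is_mendelian(self) -> bool:
        return self.n_denovo_alleles == 0

    def label(self) -> str:
        from .genotypes import format_genotype

        f = "." if self.father is None else format_genotype(self.father)
        return (
            f"M={format_genotype(self.mother)},F={f},"
            f"C={format_genotype(self.child)}"
        )


@dataclass(frozen=True)
class MutationPriorConfig:
    """Mutation-rate prior for the genotype-combination prior.

    ``mu`` is the per-site probability of a de novo mutation in one
    parental gamete.  It must be small enough that the total mass
    assigned to mutation-bearing combinations stays below 1 in every
    inheritance mode.
    """

    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")


def classify_denovo(
    mother: tuple[int, ...],
    father: tuple[int, ...] | None,
    child: tuple[int, ...],
    mode: InheritanceMode,
) -> int:
    """Minimum number of child alleles requiring a de novo event.

    The child's alleles are assigned to a (maternal, paternal) gamete
    pair in every possible order; each assignment costs one mutation per
    allele absent from the corresponding parent.  The minimum cost over
    assignments is returned.  In the X male-offspring mode the child is
    haploid and only the mother transmits.
    """
    if len(mother) != 2:
        raise ValueError(f"mother must be diploid, got {mother}")
    if mode is InheritanceMode.X_MALE_OFFSPRING:
        if len(child) != 1:
            raise ValueError(f"male X child must be haploid, got {child}")
        return 0 if child[0] in mother else 1
    if len(child) != 2:
        raise ValueError(f"child must be diploid in mode {mode}, got {child}")
    if father is None or len(father) != (mode.father_ploidy or 0):
        raise ValueError(f"father genotype {father} inconsistent with mode {mode}")
    m_alleles = set(mother)
    f_alleles = set(father)
    a, b = child
    return min(
        (a not in m_alleles) + (b not in f_alleles),
        (b not in m_alleles) + (a not in f_alleles),
    )


def enumerate_combinations(mode: InheritanceMode) -> list[TrioCombination]:
    """All trio genotype combinations for a mode, without priors.

    Autosomal: 3 x 3 x 3 = 27 combinations.  X with a female offspring:
    3 x 2 x 3 = 18 (haploid father).  X with a male offspring: 3 x 2 = 6
    mother-child combinations (the father transmits nothing).
    """
    mothers = genotypes_for_ploidy(mode.mother_ploidy)
    fathers: tuple = (
        (None,)
        if not mode.models_father
        else genotypes_for_ploidy(mode.father_ploidy)
    )
    children = genotypes_for_ploidy(mode.child_ploidy)
    combos: list[TrioCombination] = []
    for mother in mothers:
        for father in fathers:
            for child in children:
                nd = classify_denovo(mother, father, child, mode)
                combos.append(
                    TrioCombination(
                        mother=mother,
                        father=father,
                        child=child,
                        n_denovo_alleles=nd,
                        index=len(combos),
                    )
                )
    return combos


def combination_counts(mode: InheritanceMode) -> tuple[int, int, int, int]:
    """(total, mendelian, single de novo, double de novo) combination counts."""
    combos = enumerate_combinations(mode)
    nd = [c.n_denovo_alleles for c in combos]
    return (len(combos), nd.count(0), nd.count(1), nd.count(2))


def combination_priors(
    mode: InheritanceMode, cfg: MutationPriorConfig | None = None
) -> list[TrioCombination]:
    """Enumerated combinations with their mutation-rate-driven priors.

    With ``n`` single-mutation and ``m`` double-mutation combinations,
    each single gets prior ``mu``, each double ``mu**2``, and the
    Mendelian combinations share ``1 - n*mu - m*mu**2`` uniformly.
    """
    cfg = cfg or MutationPriorConfig()
    combos = enumerate_combinations(mode)
    _, k_mend, n_single, m_double = combination_counts(mode)
    mutant_mass = n_single * cfg.mu + m_double * cfg.mu**2
    if mutant_mass >= 1.0:
        raise ValueError(
            f"mu={cfg.mu} leaves no prior mass for Mendelian combinations in {mode}"
        )
    mendelian_prior = (1.0 - mutant_mass) / k_mend
    prior_by_class = {0: mendelian_prior, 1: cfg.mu, 2: cfg.mu**2}
    return [replace(c, prior=prior_by_class[c.n_denovo_alleles]) for c in combos]


class ComboTable:
    """Vectorised view of a mode's combinations for fast posterior evaluation."""

    def __init__(self, mode: InheritanceMode, combos: list[TrioCombination]):
        self.mode = mode
        self.combos = tuple(combos)
        self.mother_idx = np.array([genotype_index(c.mother) for c in combos])
        self.child_idx = np.array([genotype_index(c.child) for c in combos])
        if mode.models_father:
            self.father_idx = np.array([genotype_index(c.father) for c in combos])
        else:
            self.father_idx = None
        self.log_prior = np.log([c.prior for c in combos])
        self.n_denovo = np.array([c.n_denovo_alleles for c in combos])

    def __len__(self) -> int:
        return len(self.combos)


@lru_cache(maxsize=64)
def combo_table(mode: InheritanceMode, mu: float = DEFAULT_MU) -> ComboTable:
    return ComboTable(mode, combination_priors(mode, MutationPriorConfig(mu=mu)))


def _check_pl(pl: GenotypeLikelihoods, ploidy: int, who: str) -> None:
    if pl.ploidy != ploidy:
        raise ValueError(
            f"{who} PL vector implies ploidy {pl.ploidy}, mode expects {ploidy}"
        )


def trio_posterior(
    pl_mother: GenotypeLikelihoods,
    pl_father: GenotypeLikelihoods | None,
    pl_child: GenotypeLikelihoods,
    table: ComboTable,
    af_prior: AlleleFrequencyPrior | None = None,
) -> np.ndarray:
    """Normalised posterior over a mode's genotype combinations.

    posterior(c) is proportional to
    ``L(D_M|G_M) * L(D_F|G_F) * L(D_C|G_C) * P_C(c)``, with HWE
    genotype priors ``AF(G_M) * AF(G_F)`` multiplied in when an
    allele-frequency prior is supplied (parents only; the child's
    genotype is constrained through the combination itself).  Everything
    is accumulated in natural-log space and normalised with log-sum-exp.
    """
    mode = table.mode
    _check_pl(pl_mother, mode.mother_ploidy, "mother")
    _check_pl(pl_child, mode.child_ploidy, "child")
    logw = (
        pl_mother.log_likelihoods[table.mother_idx]
        + pl_child.log_likelihoods[table.child_idx]
        + table.log_prior
    )
    if mode.models_father:
        if pl_father is None:
            raise ValueError(f"mode {mode} requires father likelihoods")
        _check_pl(pl_father, mode.father_ploidy, "father")
        logw = logw + pl_father.log_likelihoods[table.father_idx]
    if af_prior is not None:
        logw = logw + af_prior.log_genotype_priors(2)[table.mother_idx]
        if mode.models_father:
            logw = logw + af_prior.log_genotype_priors(mode.father_ploidy)[
                table.father_idx
            ]
    peak = logw.max()
    if not np.isfinite(peak):
        raise UncallableSiteError("all genotype combinations have zero posterior mass")
    post = np.exp(logw - peak)
    return post / post.sum()


@dataclass(frozen=True)
class TrioCall:
    """Best genotype combination assigned to one trio at one site."""

    best_combination: TrioCombination
    posterior: float
    q_score: float
    is_denovo: bool
    mode: InheritanceMode
    contig: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    family: str | None = None
    phased_mother: tuple[int, ...] | None = None
    phased_father: tuple[int, ...] | None = None
    phased_child: tuple[int, ...] | None = None
    phase_ambiguous: bool | None = None
    filters: tuple[str, ...] = field(default=())

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.family)


def q_from_posterior(posterior: float, max_q: float = 99.0) -> float:
    """Phred-scaled call confidence, -10*log10(1 - posterior), capped."""
    err = 1.0 - posterior
    if err <= 0.0:
        return max_q
    return min(max_q, -10.0 * math.log10(err))


def call_trio(
    pl_mother: GenotypeLikelihoods,
    pl_father: GenotypeLikelihoods | None,
    pl_child: GenotypeLikelihoods,
    table: ComboTable,
    af_prior: AlleleFrequencyPrior | None = None,
    max_q: float = 99.0,
    **site_info,
) -> TrioCall:
    """Assign the maximum-posterior combination to a trio at one site.

    Ties are broken conservatively: first toward fewer de novo alleles,
    then toward the earlier combination in canonical enumeration order.
    """
    post = trio_posterior(pl_mother, pl_father, pl_child, table, af_prior)
    best = min(
        range(len(table)),
        key=lambda i: (-post[i], table.n_denovo[i], i),
    )
    combo = table.combos[best]
    p = float(post[best])
    return TrioCall(
        best_combination=combo,
        posterior=p,
        q_score=q_from_posterior(p, max_q=max_q),
        is_denovo=combo.n_denovo_alleles >= 1,
        mode=table.mode,
        **site_info,
    )
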