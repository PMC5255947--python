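"""Transmission phasing of trio genotypes.

Allele segregation in a trio determines phase deterministically for
almost all Mendelian-consistent genotype combinations: the child's
alleles are ordered (maternal | paternal) and each parent's alleles
(transmitted | untransmitted).  Two situations stay ambiguous — when
all three members are heterozygous for the same two alleles, and when
the best combination involves a de novo mutation (the mutant allele has
no transmitted parental origin at the genotype level).  The phasing
confidence is the joint posterior of the assigned combination, already
carried on the call.
"""

from __future__ import annotations

from dataclasses import replace

from .genotypes import InheritanceMode
from .model import TrioCall, TrioCombination

__all__ = ["consistent_transmissions", "phase_by_transmission"]


def consistent_transmissions(
    combo: TrioCombination, mode: InheritanceMode
) -> list[tuple[int, ...]]:
    """All (maternal, paternal) gamete assignments consistent with the combo.

    For the X male-offspring mode the child is haploid and only maternal
    transmissions are returned (length-1 tuples).
    """
    if mode is InheritanceMode.X_MALE_OFFSPRING:
        c = combo.child[0]
        return [(c,)] if c in combo.mother else []
    pairs = set()
    for m in set(combo.mother):
        for p in set(combo.father):
            if tuple(sorted((m, p))) == combo.child:
                pairs.add((m, p))
    return sorted(pairs)


def _split_transmitted(
    genotype: tuple[int, ...], transmitted: int
) -> tuple[int, ...]:
    """Order a parent's alleles as (transmitted, untransmitted)."""
    rest = list(genotype)
    rest.remove(transmitted)
    return (transmitted, *rest)


def phase_by_transmission(call: TrioCall) -> TrioCall:
    """Attach phased genotypes to a call when transmission is unambiguous.

    De novo combinations and the triple-heterozygote configuration are
    flagged ``phase_ambiguous`` and left unphased.
    """
    combo = call.best_combination
    if combo.n_denovo_alleles > 0:
        return replace(call, phase_ambiguous=True)
    transmissions = consistent_transmissions(combo, call.mode)
    if len(transmissions) != 1:
        return replace(call, phase_ambiguous=True)
    tx = transmissions[0]
    maternal = tx[0]
    phased_mother = _split_transmitted(combo.mother, maternal)
    if call.mode is InheritanceMode.X_MALE_OFFSPRING:
        return replace(
            call,
            phased_mother=phased_mother,
            phased_father=None,
            phased_child=(maternal,),
            phase_ambiguous=False,
        )
    paternal = tx[1]
    return replace(
        call,
        phased_mother=phased_mother,
        phased_father=_split_transmitted(combo.father, paternal),
        phased_child=(maternal, paternal),
        phase_ambiguous=False,
    )
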