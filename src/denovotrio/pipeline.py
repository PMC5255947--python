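"""Orchestration: run the trio caller over a stream of sites.

Ties together inheritance-mode selection (autosomal vs X, by contig
name and child sex), allele-frequency priors (none, cohort founders, or
an external sites VCF), the combination posterior, transmission phasing
and the parental ALT-read filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable

from .allele_freq import (
    AlleleFrequencyPrior,
    ExternalFrequencySource,
    estimate_founder_frequencies,
)
from .genotypes import GenotypeLikelihoods, InheritanceMode, Sex
from .model import DEFAULT_MU, TrioCall, UncallableSiteError, call_trio, combo_table
from .phasing import phase_by_transmission
from .vcf_io import FAIL, NOT_EVALUATED, SiteRecord, Trio, parent_alt_read_filter

__all__ = ["CallerConfig", "CallResult", "call_sites", "site_mode"]

logger = logging.getLogger(__name__)

AF_NONE = "none"
AF_FOUNDERS = "founders"
AF_EXTERNAL = "external"


@dataclass(frozen=True)
class CallerConfig:
    """Caller settings.

    ``af_source`` selects the allele-frequency prior: ``"none"``,
    ``"founders"`` (Hardy-Weinberg priors from the hard genotypes of the
    cohort's parents at each site) or ``"external"`` (a sites VCF with
    an AF INFO field, passed separately).  ``haploid_as_diploid``
    accepts diploid-encoded PL vectors for hemizygous samples, dropping
    the heterozygous entry.
    """

    mu: float = DEFAULT_MU
    af_source: str = AF_FOUNDERS
    max_q: float = 99.0
    haploid_as_diploid: bool = True
    founder_fallback_q: float = 0.5

    def __post_init__(self) -> None:
        if self.af_source not in (AF_NONE, AF_FOUNDERS, AF_EXTERNAL):
            raise ValueError(f"unknown af_source: {self.af_source!r}")
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")


@dataclass
class CallResult:
    calls: list[TrioCall]
    skipped: Counter = field(default_factory=Counter)


def site_mode(site: SiteRecord, trio: Trio) -> InheritanceMode | None:
    """Inheritance mode for one trio at one site; None if sex is needed but unknown."""
    if not site.is_x:
        return InheritanceMode.AUTOSOMAL
    if trio.child_sex is Sex.MALE:
        return InheritanceMode.X_MALE_OFFSPRING
    if trio.child_sex is Sex.FEMALE:
        return InheritanceMode.X_FEMALE_OFFSPRING
    return None


def _founder_genotype(
    gt: tuple[int, ...] | None, haploid: bool
) -> tuple[int, ...] | None:
    """Normalise a founder genotype, reducing diploid-encoded hemizygotes.

    A heterozygous diploid encoding of a haploid founder is treated as
    missing (it cannot be a real hemizygous genotype).
    """
    if gt is None or any(a is None for a in gt):
        return None
    if haploid and len(gt) == 2:
        return (gt[0],) if gt[0] == gt[1] else None
    return gt


def _founder_prior(
    site: SiteRecord, trios: list[Trio], fallback_q: float
) -> AlleleFrequencyPrior:
    gts = []
    seen: set[str] = set()
    for t in trios:
        for sample, male in ((t.mother, False), (t.father, True)):
            if sample in seen:
                continue
            seen.add(sample)
            gts.append(
                _founder_genotype(site.gts.get(sample), haploid=site.is_x and male)
            )
    return estimate_founder_frequencies(gts, fallback_q=fallback_q)


def _sample_pl(
    site: SiteRecord,
    sample: str,
    ploidy: int,
    haploid_as_diploid: bool,
) -> GenotypeLikelihoods | None:
    raw = site.pls.get(sample)
    if raw is None:
        return None
    gl = GenotypeLikelihoods.from_phred(
        raw, haploid_from_diploid=(ploidy == 1 and haploid_as_diploid)
    )
    if gl.ploidy != ploidy:
        return None
    return gl


def call_sites(
    sites: Iterable[SiteRecord],
    trios: list[Trio],
    config: CallerConfig | None = None,
    external_af: ExternalFrequencySource | None = None,
) -> CallResult:
    """Call, phase and filter every trio at every site.

    Trios lacking a PL vector for any modelled member at a site are
    skipped there (no imputation); reasons are tallied in
    ``result.skipped``.
    """
    cfg = config or CallerConfig()
    if cfg.af_source == AF_EXTERNAL and external_af is None:
        raise ValueError("af_source='external' requires an ExternalFrequencySource")
    result = CallResult(calls=[])
    for site in sites:
        af_prior: AlleleFrequencyPrior | None = None
        if cfg.af_source == AF_FOUNDERS:
            af_prior = _founder_prior(site, trios, cfg.founder_fallback_q)
        elif cfg.af_source == AF_EXTERNAL:
            af_prior = external_af.get(site.contig, site.pos, site.ref, site.alt)
        for trio in trios:
            mode = site_mode(site, trio)
            if mode is None:
                result.skipped["unknown_sex_on_x"] += 1
                continue
            pl_mother = _sample_pl(
                site, trio.mother, mode.mother_ploidy, cfg.haploid_as_diploid
            )
            pl_child = _sample_pl(
                site, trio.child, mode.child_ploidy, cfg.haploid_as_diploid
            )
            pl_father = None
            if mode.models_father:
                pl_father = _sample_pl(
                    site, trio.father, mode.father_ploidy, cfg.haploid_as_diploid
                )
            needed = [pl_mother, pl_child] + (
                [pl_father] if mode.models_father else []
            )
            if any(pl is None for pl in needed):
                result.skipped["missing_pl"] += 1
                continue
            try:
                call = call_trio(
                    pl_mother,
                    pl_father,
                    pl_child,
                    combo_table(mode, cfg.mu),
                    af_prior=af_prior,
                    max_q=cfg.max_q,
                    contig=site.contig,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    family=trio.family,
                )
            except UncallableSiteError:
                result.skipped["uncallable"] += 1
                continue
            call = phase_by_transmission(call)
            if call.is_denovo:
                status = parent_alt_read_filter(call, site, trio)
                if status == FAIL:
                    call = replace(call, filters=("parent_alt_reads",))
                elif status == NOT_EVALUATED:
                    call = replace(call, filters=("parent_ad_not_evaluated",))
            result.calls.append(call)
    return result
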