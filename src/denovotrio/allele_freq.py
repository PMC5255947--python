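"""Hardy-Weinberg allele-frequency priors for parental genotypes.

Population allele frequencies sharpen de novo calling at low coverage:
a variant common in the population is plausibly inherited from a poorly
covered parent, while a variant absent from the population is more
credibly de novo.  Frequencies come either from the founders (parents)
of the input cohort, counted from their hard genotypes, or from an
external sites-only VCF carrying an ``AF`` INFO field.  Genotype priors
follow Hardy-Weinberg expectation: (p^2, 2pq, q^2) for diploid samples
and (p, q) for hemizygous ones.

Frequencies are clamped away from 0 and 1 so that no genotype receives
a prior of exactly zero, which would veto it regardless of likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np

__all__ = [
    "AlleleFrequencyPrior",
    "clamp_frequency",
    "estimate_founder_frequencies",
    "ExternalFrequencySource",
]

logger = logging.getLogger(__name__)

#: Effective founder count used to clamp frequencies from external
#: resources, which do not report their sample size.
DEFAULT_EXTERNAL_N = 500


def clamp_frequency(q: float, n_founders: int) -> float:
    """Clamp an ALT frequency to [1/(2N+2), 1 - 1/(2N+2)], N = founder count."""
    if n_founders < 1:
        raise ValueError("clamping requires at least one founder")
    lo = 1.0 / (2 * n_founders + 2)
    return min(max(q, lo), 1.0 - lo)


@dataclass(frozen=True)
class AlleleFrequencyPrior:
    """REF/ALT dosage frequencies and the HWE genotype priors they imply."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q must lie strictly in (0, 1), got {self.q}")
        if abs(self.p + self.q - 1.0) > 1e-9:
            raise ValueError(f"p + q must equal 1, got {self.p + self.q}")

    @classmethod
    def from_alt_frequency(
        cls, q: float, n_founders: int | None = None
    ) -> "AlleleFrequencyPrior":
        if n_founders is not None:
            q = clamp_frequency(q, n_founders)
        return cls(p=1.0 - q, q=q)

    def genotype_priors(self, ploidy: int) -> np.ndarray:
        if ploidy == 2:
            return np.array([self.p**2, 2 * self.p * self.q, self.q**2])
        if ploidy == 1:
            return np.array([self.p, self.q])
        raise ValueError(f"unsupported ploidy: {ploidy}")

    @cached_property
    def _log_diploid(self) -> np.ndarray:
        return np.log(self.genotype_priors(2))

    @cached_property
    def _log_haploid(self) -> np.ndarray:
        return np.log(self.genotype_priors(1))

    def log_genotype_priors(self, ploidy: int) -> np.ndarray:
        return self._log_diploid if ploidy == 2 else self._log_haploid


def estimate_founder_frequencies(
    genotypes: Iterable[tuple[int, ...] | None],
    fallback_q: float = 0.5,
) -> AlleleFrequencyPrior:
    """Estimate p and q from founder hard genotypes at one site.

    Each called founder contributes its allele dosage: two chromosomes
    for a diploid genotype, one for a hemizygous genotype (X founder
    males).  Missing genotypes (``None`` or containing ``None``) are
    skipped.  With no called founder at all, a flat prior at
    ``fallback_q`` is returned and a warning logged.
    """
    alt = 0
    chroms = 0
    n_called = 0
    for gt in genotypes:
        if gt is None or any(a is None for a in gt):
            continue
        alt += sum(gt)
        chroms += len(gt)
        n_called += 1
    if n_called == 0:
        logger.warning(
            "no called founder genotypes at site; falling back to q=%s", fallback_q
        )
        return AlleleFrequencyPrior.from_alt_frequency(fallback_q)
    return AlleleFrequencyPrior.from_alt_frequency(
        alt / chroms, n_founders=n_called
    )


class ExternalFrequencySource:
    """Per-site ALT-frequency lookup backed by a sites-only VCF.

    Sites are keyed by (contig, position, ref, alt) with exact matching;
    a site absent from the resource yields ``None``, meaning no
    allele-frequency prior is applied there.
    """

    def __init__(self, frequencies: dict, effective_n: int = DEFAULT_EXTERNAL_N):
        self._freqs = dict(frequencies)
        self.effective_n = effective_n

    @classmethod
    def from_vcf(
        cls, path: str, effective_n: int = DEFAULT_EXTERNAL_N
    ) -> "ExternalFrequencySource":
        import pysam

        freqs: dict = {}
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                af = rec.info.get("AF")
                if af is None:
                    continue
                if isinstance(af, (tuple, list)):
                    af = af[0]
                freqs[(rec.contig, rec.pos, rec.ref, rec.alts[0])] = float(af)
        return cls(freqs, effective_n=effective_n)

    def __len__(self) -> int:
        return len(self._freqs)

    def get(
        self, contig: str, pos: int, ref: str, alt: str
    ) -> AlleleFrequencyPrior | None:
        q = self._freqs.get((contig, pos, ref, alt))
        if q is None:
            return None
        return AlleleFrequencyPrior.from_alt_frequency(
            q, n_founders=self.effective_n
        )
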