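"""Pedigree and VCF input/output.

Reads 6-column PED pedigrees into trios, streams multi-sample VCF
records into :class:`SiteRecord` objects (biallelic sites only, with
optional BED region exclusions), applies the parental ALT-read filter,
and writes the annotated/phased VCF plus the ranked de novo table.

Coordinates follow VCF convention (1-based positions); BED exclusion
intervals are 0-based half-open and converted internally.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from intervaltree import IntervalTree

from .genotypes import Sex
from .model import TrioCall

__all__ = [
    "Trio",
    "SiteRecord",
    "read_pedigree",
    "read_region_exclusions",
    "read_sites",
    "parent_alt_read_filter",
    "write_calls_vcf",
    "write_dnm_table",
]

logger = logging.getLogger(__name__)

X_CONTIGS = {"X", "chrX"}

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


@dataclass(frozen=True)
class Trio:
    family: str
    mother: str
    father: str
    child: str
    child_sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        if len({self.mother, self.father, self.child}) != 3:
            raise ValueError(
                f"trio {self.family}: mother/father/child ids must be distinct"
            )

    @property
    def samples(self) -> tuple[str, str, str]:
        return (self.mother, self.father, self.child)


def read_pedigree(path: str | Path) -> list[Trio]:
    """Parse a 6-column PED file into trios.

    One trio is emitted per child whose father and mother both appear as
    individuals in the file; children with a missing parent ("0") or a
    parent absent from the file are skipped with a warning.  Multiple
    children of the same parents (for example dizygotic twins) yield one
    trio each.
    """
    individuals: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}"
                )
            fam, iid, father, mother, sex = fields[:5]
            if iid in individuals:
                raise ValueError(f"{path}:{lineno}: duplicate individual id {iid!r}")
            individuals[iid] = (fam, father, mother, sex)
            order.append(iid)
    trios: list[Trio] = []
    for iid in order:
        fam, father, mother, sex = individuals[iid]
        if father == "0" or mother == "0":
            continue
        if father not in individuals or mother not in individuals:
            logger.warning(
                "child %s: parent(s) not present in pedigree, skipping", iid
            )
            continue
        trios.append(
            Trio(
                family=fam,
                mother=mother,
                father=father,
                child=iid,
                child_sex=_PED_SEX.get(sex, Sex.UNKNOWN),
            )
        )
    return trios


@dataclass
class SiteRecord:
    """One biallelic VCF site with the per-sample data the caller needs."""

    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    pls: dict[str, tuple[int, ...]] = field(default_factory=dict)
    ads: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    gts: dict[str, tuple[int, ...] | None] = field(default_factory=dict)
    af: float | None = None

    @property
    def is_x(self) -> bool:
        return self.contig in X_CONTIGS

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


def read_region_exclusions(bed_path: str | Path) -> dict[str, IntervalTree]:
    """Load BED intervals (0-based half-open) to exclude, per contig."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >=3 BED columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


def _is_excluded(
    exclusions: dict[str, IntervalTree] | None, contig: str, pos: int
) -> bool:
    if not exclusions:
        return False
    tree = exclusions.get(contig)
    # VCF pos is 1-based; BED trees are 0-based half-open
    return bool(tree is not None and tree.overlaps(pos - 1))


def read_sites(
    vcf_path: str | Path,
    samples: Iterable[str],
    exclusions: dict[str, IntervalTree] | None = None,
    skip_counter: Counter | None = None,
) -> Iterator[SiteRecord]:
    """Stream biallelic sites from a multi-sample VCF.

    Multi-allelic records and records inside excluded regions are
    skipped and counted in ``skip_counter`` (keys ``multiallelic`` and
    ``excluded_region``).  Samples named in ``samples`` must be present
    in the header; their GT, PL and AD fields are extracted when
    available.
    """
    samples = list(samples)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_samples = set(vcf.header.samples)
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise ValueError(
                f"samples absent from VCF header: {', '.join(sorted(missing))}"
            )
        has_af = "AF" in vcf.header.info
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or rec.alts[0] is None:
                if skip_counter is not None:
                    skip_counter["multiallelic"] += 1
                continue
            if _is_excluded(exclusions, rec.contig, rec.pos):
                if skip_counter is not None:
                    skip_counter["excluded_region"] += 1
                continue
            site = SiteRecord(
                contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0]
            )
            af = rec.info.get("AF") if has_af else None
            if af is not None:
                site.af = float(af[0] if isinstance(af, (tuple, list)) else af)
            for s in samples:
                data = rec.samples[s]
                gt = data.get("GT")
                if gt is not None and all(a is not None for a in gt):
                    site.gts[s] = tuple(gt)
                else:
                    site.gts[s] = None
                pl = data.get("PL")
                if pl is not None and all(v is not None for v in pl):
                    site.pls[s] = tuple(int(v) for v in pl)
                ad = data.get("AD")
                if ad is not None and all(v is not None for v in ad):
                    site.ads[s] = (int(ad[0]), int(ad[1]))
                else:
                    site.ads[s] = None
            yield site


PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not_evaluated"


def parent_alt_read_filter(call: TrioCall, site: SiteRecord, trio: Trio) -> str:
    """Fail a de novo candidate with any parental ALT read evidence.

    Returns ``"fail"`` when either parent shows one or more ALT-
    supporting reads in its AD field, ``"not_evaluated"`` when AD is
    missing for either parent, and ``"pass"`` otherwise.
    """
    ads = [site.ads.get(trio.mother), site.ads.get(trio.father)]
    if any(ad is None for ad in ads):
        return NOT_EVALUATED
    if any(ad[1] >= 1 for ad in ads):
        return FAIL
    return PASS


def _phred_int(posterior: float, cap: int = 99) -> int:
    from .model import q_from_posterior

    return int(round(q_from_posterior(posterior, max_q=cap)))


def _build_header(sites: list[SiteRecord], all_samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in dict.fromkeys(s.contig for s in sites):
        header.contigs.add(contig)
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.info.add("DNM", 0, "Flag", "At least one trio carries a de novo call here")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add(
        "TP", 1, "Integer", "Phred-scaled posterior of the assigned trio combination"
    )
    for s in all_samples:
        header.add_sample(s)
    return header


def write_calls_vcf(
    sites: list[SiteRecord],
    calls: list[TrioCall],
    trios: list[Trio],
    path: str | Path,
) -> None:
    """Write an annotated VCF with phased genotypes and trio posteriors.

    Child genotypes resolved by transmission are written phased with the
    maternal allele first (``maternal|paternal``); parents phased
    transmitted-first.  Each trio member carries the phred-scaled
    posterior of the trio's assigned combination in the ``TP`` FORMAT
    field, and sites with at least one de novo call get a ``DNM`` flag.
    """
    all_samples = list(dict.fromkeys(s for t in trios for s in t.samples))
    trio_by_family = {t.family: t for t in trios}
    calls_by_site: dict[tuple, list[TrioCall]] = {}
    for c in calls:
        calls_by_site.setdefault((c.contig, c.pos), []).append(c)

    header = _build_header(sites, all_samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
            )
            if site.af is not None:
                rec.info["AF"] = (site.af,)
            site_calls = calls_by_site.get(site.key, [])
            if any(c.is_denovo for c in site_calls):
                rec.info["DNM"] = True
            phased: dict[str, tuple[int, ...]] = {}
            tp: dict[str, int] = {}
            for c in site_calls:
                trio = trio_by_family[c.family]
                q = _phred_int(c.posterior)
                for s in trio.samples:
                    tp[s] = q
                if c.phase_ambiguous is False:
                    if c.phased_child is not None:
                        phased[trio.child] = c.phased_child
                    if c.phased_mother is not None:
                        phased[trio.mother] = c.phased_mother
                    if c.phased_father is not None:
                        phased[trio.father] = c.phased_father
            for s in all_samples:
                data = rec.samples[s]
                if s in phased:
                    data["GT"] = phased[s]
                    data.phased = True
                else:
                    gt = site.gts.get(s)
                    data["GT"] = gt if gt is not None else (None,)
                if s in site.pls:
                    data["PL"] = site.pls[s]
                ad = site.ads.get(s)
                if ad is not None:
                    data["AD"] = ad
                if s in tp:
                    data["TP"] = tp[s]
            out.write(rec)


def write_dnm_table(
    calls: list[TrioCall], path: str | Path, min_q: float = 0.0
) -> int:
    """Write the ranked de novo candidate table (TSV).

    Rows are de novo calls with ``q_score >= min_q``, sorted by
    descending q-score (stable on ties).  Returns the number of rows.
    """
    rows = [c for c in calls if c.is_denovo and c.q_score >= min_q]
    rows.sort(key=lambda c: -c.q_score)
    with open(path, "w") as fh:
        fh.write(
            "contig\tpos\tref\talt\tfamily\tcombination\tposterior\tq_score\tfilters\n"
        )
        for c in rows:
            filters = ";".join(c.filters) if c.filters else "PASS"
            fh.write(
                f"{c.contig}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.family}\t"
                f"{c.best_combination.label()}\t{c.posterior:.6g}\t"
                f"{c.q_score:.2f}\t{filters}\n"
            )
    return len(rows)
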