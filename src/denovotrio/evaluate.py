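"""Scoring calls against simulated truth.

A de novo *call* is a trio-site assignment whose best combination
violates Mendelian transmission and whose phred-scaled confidence
clears a threshold.  Scored against the truth table:

- true positive:  simulated de novo reported as de novo
- false negative: simulated de novo not reported (or not called at all,
  when missing trio-sites count as misses — the default)
- false positive: inherited trio-site reported as de novo
- true negative:  inherited trio-site not reported

Sensitivity is tp/(tp+fn) and specificity tn/(tn+fp); both are NaN when
their denominator is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genotypes import Sex
from .model import TrioCall
from .vcf_io import Trio, X_CONTIGS

__all__ = [
    "ConfusionCounts",
    "ScoreResult",
    "calls_to_frame",
    "score_calls",
    "roc_sweep",
    "prior_sweep",
    "per_offspring_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScoreResult:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float


def calls_to_frame(calls: Iterable[TrioCall]) -> pd.DataFrame:
    """Flatten calls into a table (one row per trio-site assignment)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "contig": c.contig,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "family": c.family,
                "combination": c.best_combination.label(),
                "n_denovo": c.best_combination.n_denovo_alleles,
                "posterior": c.posterior,
                "q_score": c.q_score,
                "is_denovo": c.is_denovo,
                "phase_ambiguous": c.phase_ambiguous,
                "filters": ";".join(c.filters) if c.filters else "PASS",
            }
        )
    columns = [
        "contig", "pos", "ref", "alt", "family", "combination", "n_denovo",
        "posterior", "q_score", "is_denovo", "phase_ambiguous", "filters",
    ]
    return pd.DataFrame(rows, columns=columns)


def _call_map(calls) -> dict[tuple, tuple[bool, float]]:
    if isinstance(calls, pd.DataFrame):
        return {
            (r.contig, int(r.pos), r.family): (bool(r.is_denovo), float(r.q_score))
            for r in calls.itertuples()
        }
    return {
        (c.contig, c.pos, c.family): (c.is_denovo, c.q_score) for c in calls
    }


def score_calls(
    calls,
    truth: pd.DataFrame,
    threshold: float = 0.0,
    count_missing_as_fn: bool = True,
) -> ScoreResult:
    """Confusion counts plus sensitivity/specificity at one q threshold.

    ``calls`` may be a list of :class:`TrioCall` or a frame from
    :func:`calls_to_frame`; ``truth`` needs columns contig, pos, family
    and is_dnm.  Truth rows with no corresponding call are counted as
    false negatives when they are de novo and ``count_missing_as_fn``
    is set (inherited rows with no call never enter the denominator).
    """
    call_map = _call_map(calls)
    tp = fp = tn = fn = 0
    for row in truth.itertuples():
        key = (row.contig, int(row.pos), row.family)
        entry = call_map.get(key)
        if entry is None:
            if row.is_dnm and count_missing_as_fn:
                fn += 1
            continue
        is_denovo, q = entry
        called = is_denovo and q >= threshold
        if row.is_dnm:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return ScoreResult(counts=counts, sensitivity=sens, specificity=spec)


def roc_sweep(
    calls,
    truth: pd.DataFrame,
    thresholds: Sequence[float],
    count_missing_as_fn: bool = True,
) -> pd.DataFrame:
    """One (threshold, counts, sensitivity, specificity) row per threshold."""
    if len(thresholds) == 0:
        raise ValueError("at least one threshold is required")
    rows = []
    for thr in thresholds:
        res = score_calls(
            calls, truth, threshold=thr, count_missing_as_fn=count_missing_as_fn
        )
        rows.append(
            {
                "threshold": thr,
                "tp": res.counts.tp,
                "fp": res.counts.fp,
                "tn": res.counts.tn,
                "fn": res.counts.fn,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
        )
    return pd.DataFrame(rows)


def prior_sweep(
    sites,
    trios,
    truth: pd.DataFrame,
    mus: Sequence[float],
    base_config=None,
    external_af=None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Re-call the dataset at each mutation prior and score each call set."""
    from dataclasses import replace as dc_replace

    from .pipeline import CallerConfig, call_sites

    base = base_config or CallerConfig()
    rows = []
    for mu in mus:
        result = call_sites(
            sites, trios, config=dc_replace(base, mu=mu), external_af=external_af
        )
        res = score_calls(result.calls, truth, threshold=threshold)
        rows.append(
            {
                "mu": mu,
                "tp": res.counts.tp,
                "fp": res.counts.fp,
                "tn": res.counts.tn,
                "fn": res.counts.fn,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
        )
    return pd.DataFrame(rows)


def per_offspring_summary(
    calls, trios: list[Trio], threshold: float = 0.0
) -> pd.DataFrame:
    """De novo call counts per child, split by autosomal vs X sites."""
    by_family = {t.family: t for t in trios}
    counts: dict[tuple[str, str], int] = {}
    for t in trios:
        counts[(t.family, "autosomal")] = 0
        counts[(t.family, "X")] = 0
    frame = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    for r in frame.itertuples():
        if not (r.is_denovo and r.q_score >= threshold):
            continue
        chrom_class = "X" if r.contig in X_CONTIGS else "autosomal"
        counts[(r.family, chrom_class)] = counts.get((r.family, chrom_class), 0) + 1
    sex_str = {Sex.MALE: "male", Sex.FEMALE: "female", Sex.UNKNOWN: "unknown"}
    rows = [
        {
            "family": fam,
            "child": by_family[fam].child if fam in by_family else fam,
            "child_sex": sex_str[by_family[fam].child_sex]
            if fam in by_family
            else "unknown",
            "chrom_class": chrom_class,
            "n_dnm": n,
        }
        for (fam, chrom_class), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
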