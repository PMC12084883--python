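"""Descriptive and inferential statistics of isomiR classes and NT tails.

Summaries are read-weighted by default: a retained isomiR contributes its
read count, not a single vote, because class percentages describe read
populations.  An isomiR-weighted variant is available behind a flag.
Internally uridine is carried as ``T``; outputs can relabel to RNA space.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .isomir import ISO_CLASSES, NT_TAIL, SampleProfile

__all__ = [
    "ClassFractionSummary",
    "TailCompositionTable",
    "GroupComparison",
    "EmptyProfileError",
    "NoNTTailsError",
    "class_fractions",
    "nt_nucleotide_freq",
    "tail_length_composition",
    "compare_groups",
]

_BASES = "ACGT"


class EmptyProfileError(ValueError):
    """The sample profile holds no records."""


class NoNTTailsError(ValueError):
    """The profile holds records but none with an NT tail."""


@dataclass(frozen=True)
class ClassFractionSummary:
    sample_id: str
    fractions: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, name=self.sample_id)


@dataclass
class TailCompositionTable:
    """Tail length x composition breakdown of a sample's NT tails.

    ``kmer_counts[L]`` counts each distinct tail sequence of length bin L
    (lengths above ``max_len`` pool into the last bin, keyed ``max_len``).
    ``position_freq`` is the read-weighted pooled per-position nucleotide
    frequency over all NT tails.
    """

    sample_id: str
    max_len: int
    kmer_counts: dict[int, Counter] = field(default_factory=dict)
    position_freq: dict[str, float] = field(default_factory=dict)

    def length_total(self, L: int) -> int:
        return sum(self.kmer_counts.get(L, Counter()).values())

    def mono_counts(self) -> dict[str, int]:
        """Length-1 categories mono(A)/mono(C)/mono(G)/mono(U)."""
        c1 = self.kmer_counts.get(1, Counter())
        return {b: c1.get(b, 0) for b in _BASES}

    def contains_a_counts(self, L: int) -> tuple[int, int]:
        """(contains-A, A-free) read counts for tails of length bin L >= 2."""
        cl = self.kmer_counts.get(L, Counter())
        with_a = sum(c for kmer, c in cl.items() if "A" in kmer)
        return with_a, sum(cl.values()) - with_a

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        rows = []
        for L in sorted(self.kmer_counts):
            for kmer, c in sorted(self.kmer_counts[L].items()):
                label = kmer.replace("T", "U") if rna else kmer
                rows.append(
                    {
                        "sample_id": self.sample_id,
                        "length_bin": L,
                        "tail": label,
                        "count": c,
                        "contains_a": "A" in kmer,
                    }
                )
        return pd.DataFrame(
            rows, columns=["sample_id", "length_bin", "tail", "count", "contains_a"]
        )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group rank-sum comparison of per-sample statistic values."""

    statistic_name: str
    group_values: tuple[tuple[float, ...], tuple[float, ...]]
    u_statistic: float
    p: float
    method: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def class_fractions(
    profile: SampleProfile, weighting: str = "reads"
) -> ClassFractionSummary:
    """Read-weighted (default) or isomiR-weighted class proportions."""
    if not profile.records:
        raise EmptyProfileError(f"profile {profile.sample_id!r} has no records")
    if weighting not in ("reads", "isomirs"):
        raise ValueError("weighting must be 'reads' or 'isomirs'")
    totals = {c: 0 for c in ISO_CLASSES}
    for rec in profile.records:
        totals[rec.iso_class] += rec.count if weighting == "reads" else 1
    denom = sum(totals.values())
    return ClassFractionSummary(
        profile.sample_id, {c: totals[c] / denom for c in ISO_CLASSES}
    )


def nt_nucleotide_freq(profile: SampleProfile, rna: bool = False) -> dict[str, float]:
    """Pooled per-position nucleotide frequency over all NT tails, read-weighted."""
    if not profile.records:
        raise EmptyProfileError(f"profile {profile.sample_id!r} has no records")
    counts = {b: 0 for b in _BASES}
    for rec in profile.records:
        if rec.iso_class == NT_TAIL:
            for b in rec.ext_seq:
                counts[b] += rec.count
    total = sum(counts.values())
    if total == 0:
        raise NoNTTailsError(f"profile {profile.sample_id!r} has no NT-tailed reads")
    freq = {b: counts[b] / total for b in _BASES}
    if rna:
        freq = {("U" if b == "T" else b): v for b, v in freq.items()}
    return freq


def tail_length_composition(
    profile: SampleProfile, max_len: int = 3
) -> TailCompositionTable:
    """Tabulate NT tails by length bin and sequence; lengths > max_len pool."""
    if not profile.records:
        raise EmptyProfileError(f"profile {profile.sample_id!r} has no records")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    table = TailCompositionTable(profile.sample_id, max_len)
    base_counts = {b: 0 for b in _BASES}
    for rec in profile.records:
        if rec.iso_class != NT_TAIL:
            continue
        L = min(len(rec.ext_seq), max_len)
        table.kmer_counts.setdefault(L, Counter())[rec.ext_seq] += rec.count
        for b in rec.ext_seq:
            base_counts[b] += rec.count
    total = sum(base_counts.values())
    table.position_freq = (
        {b: base_counts[b] / total for b in _BASES} if total else {b: 0.0 for b in _BASES}
    )
    return table


def compare_groups(
    group_a: list[float],
    group_b: list[float],
    method: str = "auto",
    statistic_name: str = "statistic",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of two sample groups.

    ``method='auto'`` uses exact enumeration when the pooled size is <= 12
    and there are no ties, and the tie-corrected normal approximation
    otherwise; ``'exact'``/``'normal'`` force the choice.
    """
    a = [float(v) for v in group_a]
    b = [float(v) for v in group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if method == "auto":
        has_ties = len(set(a + b)) < len(a) + len(b)
        chosen = "exact" if (len(a) + len(b) <= 12 and not has_ties) else "normal"
    elif method in ("exact", "normal"):
        chosen = method
    else:
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if chosen == "exact" else "asymptotic",
    )
    return GroupComparison(
        statistic_name=statistic_name,
        group_values=(tuple(a), tuple(b)),
        u_statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method=chosen,
        alpha=alpha,
    )
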