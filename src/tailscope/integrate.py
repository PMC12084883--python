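"""miRNA:target expression integration.

Starting from a predicted miRNA→target-gene pair table, pairs are filtered
to miRNAs carrying a mono(A)-tailed isomiR and to differentially accumulated
target genes, then each surviving interaction is scored by the Pearson
correlation of miRNA and gene expression over matched samples and by the
sign concordance of the two fold changes.

Two correlation modes reflect that miRNA and mRNA cohorts are often not
sample-matched: with matched sample ids the correlation runs across samples;
otherwise the classification falls back to the KO-vs-WT log2 fold-change
signs (an interaction is "negative" when the fold changes point in opposite
directions), and the record carries no r value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionRecord",
    "load_pairs",
    "filter_to_monoA_and_de",
    "correlate",
    "interaction_summary",
]

NEGATIVE = "negative"
POSITIVE = "positive"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class InteractionRecord:
    mirna: str
    gene: str
    pearson_r: float  # NaN when undefined
    r_p: float
    lfc_mirna: float
    lfc_gene: float
    sign_class: str  # negative | positive | undefined


def load_pairs(pairs_tsv: str | Path) -> list[tuple[str, str]]:
    """Load and deduplicate a miRNA→gene pair table (columns mirna, gene)."""
    df = pd.read_csv(pairs_tsv, sep="\t", dtype=str)
    for col in ("mirna", "gene"):
        if col not in df.columns:
            raise ValueError(f"{pairs_tsv}: missing column {col!r}")
    bad = df.index[df["mirna"].isna() | df["gene"].isna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based rows
        raise ValueError(f"{pairs_tsv}: malformed row at line {int(bad[0]) + 2}")
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for mirna, gene in zip(df["mirna"], df["gene"]):
        key = (mirna, gene)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


def filter_to_monoA_and_de(
    pairs: Iterable[tuple[str, str]],
    monoA_isomirs: set[str],
    de_genes: set[str],
) -> list[tuple[str, str]]:
    """Keep pairs whose miRNA has a mono(A) isomiR and whose gene is DE."""
    if not monoA_isomirs or not de_genes:
        raise ValueError("monoA_isomirs and de_genes must be nonempty sets")
    kept = [
        (m, g) for m, g in pairs if m in monoA_isomirs and g in de_genes
    ]
    if not kept:
        warnings.warn("no pair survives the mono(A)/DE filter")
    return kept


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate(
    pairs: Sequence[tuple[str, str]],
    mirna_norm_counts: pd.DataFrame,
    gene_norm_counts: pd.DataFrame,
    matched_samples: Sequence[str] | None = None,
    mirna_lfc: Mapping[str, float] | None = None,
    gene_lfc: Mapping[str, float] | None = None,
) -> list[InteractionRecord]:
    """Score each miRNA:gene pair by expression correlation and fold changes.

    With ``matched_samples`` (≥3 sample ids present in both matrices) the
    Pearson correlation runs across those samples and the sign class follows
    the sign of r.  Without matching, fold-change sign concordance classifies
    the interaction and r is NaN.  Fold changes default to 0 for ids missing
    from the provided maps.
    """
    mirna_lfc = mirna_lfc or {}
    gene_lfc = gene_lfc or {}
    if matched_samples is not None:
        matched = [
            s for s in matched_samples
            if s in mirna_norm_counts.columns and s in gene_norm_counts.columns
        ]
        if len(matched) < 3:
            raise ValueError("need at least 3 matched samples for correlation")
    records: list[InteractionRecord] = []
    for mirna, gene in pairs:
        if mirna not in mirna_norm_counts.index or gene not in gene_norm_counts.index:
            continue
        lm = float(mirna_lfc.get(mirna, 0.0))
        lg = float(gene_lfc.get(gene, 0.0))
        if matched_samples is not None:
            x = mirna_norm_counts.loc[mirna, matched].to_numpy(dtype=float)
            y = gene_norm_counts.loc[gene, matched].to_numpy(dtype=float)
            r, p = _pearson(x, y)
            if np.isnan(r):
                sign = UNDEFINED
            else:
                sign = NEGATIVE if r < 0 else POSITIVE
        else:
            r, p = float("nan"), float("nan")
            prod = lm * lg
            if prod == 0:
                sign = UNDEFINED
            else:
                sign = NEGATIVE if prod < 0 else POSITIVE
        records.append(InteractionRecord(mirna, gene, r, p, lm, lg, sign))
    return records


def interaction_summary(records: Sequence[InteractionRecord]) -> dict[str, float]:
    """Fractions of negative / positive / undefined interactions (sum to 1)."""
    n = len(records)
    if n == 0:
        return {NEGATIVE: 0.0, POSITIVE: 0.0, UNDEFINED: 0.0, "n": 0}
    out = {
        NEGATIVE: sum(r.sign_class == NEGATIVE for r in records) / n,
        POSITIVE: sum(r.sign_class == POSITIVE for r in records) / n,
        UNDEFINED: sum(r.sign_class == UNDEFINED for r in records) / n,
    }
    out["n"] = n
    return out
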