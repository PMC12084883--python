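"""Per-transcript and global poly(A) tail-length analysis.

Consumes per-read tail-length estimates in the nanopolish-polya TSV dialect
(tab-separated with a header; required columns ``readname``, ``contig``,
``position``, ``polya_length``, ``qc_tag``; extra columns tolerated).  Only
reads whose QC tag is in the accepted set (default PASS and SUFFCLIP) enter
the analysis.

Per-transcript comparisons pool reads across replicate animals within a
condition, require at least ``min_reads`` supporting reads in BOTH
conditions, test with the two-sided Mann-Whitney rank-sum, adjust with
Benjamini-Hochberg, and call a significant tail-length change when the
median difference is at least ``delta_min`` nt and the adjusted p-value is
below 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg

__all__ = [
    "PolyAReadRecord",
    "PolyASchemaError",
    "DEFAULT_PASS_TAGS",
    "read_polya_table",
    "write_polya_table",
    "per_transcript_test",
    "global_distribution",
]

logger = logging.getLogger(__name__)

DEFAULT_PASS_TAGS = frozenset({"PASS", "SUFFCLIP"})
_REQUIRED_COLUMNS = ("readname", "contig", "position", "polya_length", "qc_tag")


class PolyASchemaError(ValueError):
    pass


@dataclass(frozen=True)
class PolyAReadRecord:
    readname: str
    contig: str
    polya_length: float
    qc_tag: str


def read_polya_table(
    tsv: str | Path,
    pass_tags: Iterable[str] = DEFAULT_PASS_TAGS,
    exclude_contig_prefixes: tuple[str, ...] = (),
) -> list[PolyAReadRecord]:
    """Load a nanopolish-polya-dialect TSV, keeping QC-accepted rows only.

    ``exclude_contig_prefixes`` drops spike-in / carrier contigs (e.g.
    poly(A) standards or yeast carrier RNA) by contig-name prefix.
    """
    pass_tags = frozenset(pass_tags)
    df = pd.read_csv(tsv, sep="\t", dtype={"contig": str, "readname": str, "qc_tag": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PolyASchemaError(f"{tsv}: missing required column(s) {missing}")
    neg = df.index[pd.to_numeric(df["polya_length"], errors="coerce") < 0]
    if len(neg):
        raise ValueError(
            f"{tsv}: negative polya_length at data row {int(neg[0]) + 1}"
        )
    n_total = len(df)
    keep = df["qc_tag"].isin(pass_tags)
    if exclude_contig_prefixes:
        spike = df["contig"].str.startswith(tuple(exclude_contig_prefixes))
        keep &= ~spike
    df = df[keep]
    logger.info(
        "%s: kept %d/%d reads after QC-tag filtering", tsv, len(df), n_total
    )
    return [
        PolyAReadRecord(r.readname, r.contig, float(r.polya_length), r.qc_tag)
        for r in df.itertuples(index=False)
    ]


def write_polya_table(records: Sequence[PolyAReadRecord], path: str | Path) -> None:
    """Write records back in the dialect's required columns (round-trips)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REQUIRED_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.readname}\t{r.contig}\t0\t{r.polya_length}\t{r.qc_tag}\n")


def _by_contig(records: Iterable[PolyAReadRecord]) -> dict[str, np.ndarray]:
    acc: dict[str, list[float]] = {}
    for r in records:
        acc.setdefault(r.contig, []).append(r.polya_length)
    return {c: np.asarray(v, dtype=float) for c, v in acc.items()}


def per_transcript_test(
    wt: Sequence[PolyAReadRecord],
    ko: Sequence[PolyAReadRecord],
    min_reads: int = 10,
    delta_min: float = 5.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Two-group tail-length comparison per transcript.

    Transcripts with fewer than ``min_reads`` reads in either condition are
    excluded before testing.  Returns a DataFrame with columns ``n_wt``,
    ``n_ko``, ``median_wt``, ``median_ko``, ``delta`` (KO - WT), ``p``,
    ``padj`` and ``significant``, indexed by transcript and sorted by index.
    """
    wt_by = _by_contig(wt)
    ko_by = _by_contig(ko)
    rows = []
    for tid in sorted(set(wt_by) | set(ko_by)):
        a = wt_by.get(tid, np.empty(0))
        b = ko_by.get(tid, np.empty(0))
        if len(a) < min_reads or len(b) < min_reads:
            continue
        res = stats.mannwhitneyu(b, a, alternative="two-sided")
        rows.append(
            {
                "transcript": tid,
                "n_wt": len(a),
                "n_ko": len(b),
                "median_wt": float(np.median(a)),
                "median_ko": float(np.median(b)),
                "delta": float(np.median(b) - np.median(a)),
                "p": float(res.pvalue),
            }
        )
    if not rows:
        warnings.warn("no transcript passes the read-support filter")
        return pd.DataFrame(
            columns=[
                "n_wt", "n_ko", "median_wt", "median_ko", "delta", "p", "padj",
                "significant",
            ]
        )
    out = pd.DataFrame(rows).set_index("transcript")
    out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = (out["delta"].abs() >= delta_min) & (out["padj"] < padj_max)
    return out


def global_distribution(
    records: Sequence[PolyAReadRecord],
    subset: Iterable[str] | None = None,
) -> dict[str, float]:
    """Read-level tail-length summary (median, quartiles, n) of a stratum.

    ``subset`` restricts records to the given transcripts (e.g. DE up/down
    gene sets); subset names absent from the data are warned about and
    skipped.  Raises on an empty stratum.
    """
    if subset is not None:
        wanted = set(subset)
        present = {r.contig for r in records}
        unknown = wanted - present
        if unknown:
            warnings.warn(
                f"{len(unknown)} subset transcript(s) absent from data, skipped"
            )
        records = [r for r in records if r.contig in wanted]
    if not records:
        raise ValueError("empty stratum: no reads after subsetting")
    lengths = np.asarray([r.polya_length for r in records], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(len(lengths))}
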