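"""isomiR engine: read collapsing, miRNA assignment, 3'-end classification.

The pipeline entry point is :func:`profile_sample`, which turns an
adapter-trimmed small-RNA FASTQ into a :class:`SampleProfile`:

1. collapse identical reads and count them;
2. assign each distinct sequence to a miRNA by an exact internal motif match
   (the 13-mer at mature positions [2, 15) by default) plus a bounded
   Levenshtein distance between the read and mature 3' suffixes;
3. classify the 3' end of each assigned sequence against the mature sequence
   and its genomic (pri-miRNA) downstream context as canonical, trimmed,
   non-templated (NT) tail, or ambiguous;
4. retain an isomiR when its read count passes an absolute (``min_read``) or
   relative (``min_ratio`` of the miRNA's reads) threshold.

Classification follows a whole-extension rule: a 3' extension counts as
templated only when it matches the genomic downstream bases in full; a
mismatch at any position makes the whole extension non-templated.  A read that
is both shortened and extended never resolves to a clean class and is called
ambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import edlib
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import MiRNAReference

__all__ = [
    "CANONICAL",
    "TRIMMED",
    "NT_TAIL",
    "AMBIGUOUS",
    "ISO_CLASSES",
    "UNASSIGNED",
    "CollapsedRead",
    "IsomiRRecord",
    "AssignParams",
    "SampleProfile",
    "FastqParseError",
    "collapse_reads",
    "assign_read",
    "classify_isomir",
    "profile_sample",
    "write_profile",
    "read_profile",
]

logger = logging.getLogger(__name__)

CANONICAL = "canonical"
TRIMMED = "trimmed"
NT_TAIL = "nt_tail"
AMBIGUOUS = "ambiguous"
ISO_CLASSES = (CANONICAL, TRIMMED, NT_TAIL, AMBIGUOUS)

#: Sentinel returned by :func:`assign_read` for reads matching no miRNA.
UNASSIGNED = None


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class CollapsedRead:
    seq: str
    count: int


@dataclass(frozen=True)
class IsomiRRecord:
    """One collapsed read assigned to a miRNA, with its 3'-end call."""

    mirna: str
    seq: str
    count: int
    iso_class: str
    trim_len: int
    ext_seq: str
    ext_is_genomic: bool


@dataclass(frozen=True)
class AssignParams:
    """Assignment and retention thresholds.

    ``min_ratio``/``min_read`` follow the retention semantics of motif-based
    isomiR profilers: an isomiR is kept when its count reaches ``min_read``
    OR its within-miRNA frequency reaches ``min_ratio`` (``retain_rule='and'``
    switches to requiring both).  ``five_prime_tolerance`` of 0 demands that
    reads share the mature 5' end exactly; 1 tolerates a single-base 5' offset.
    """

    min_ratio: float = 0.1
    min_read: int = 9
    edit_distance_3p: int = 3
    motif_span: tuple[int, int] = (2, 15)
    five_prime_tolerance: int = 0
    retain_rule: str = "or"  # 'or' | 'and'

    def __post_init__(self) -> None:
        if self.min_ratio < 0 or self.min_read < 0 or self.edit_distance_3p < 0:
            raise ValueError("thresholds must be >= 0")
        if self.retain_rule not in ("or", "and"):
            raise ValueError("retain_rule must be 'or' or 'and'")
        if self.five_prime_tolerance not in (0, 1):
            raise ValueError("five_prime_tolerance must be 0 or 1")


@dataclass
class SampleProfile:
    """Per-sample isomiR table with assignment bookkeeping.

    ``n_assigned`` counts reads carried by retained records; reads assigned
    but dropped by the min_read/min_ratio rule are in ``n_filtered``.
    """

    sample_id: str
    genotype: str
    records: list[IsomiRRecord] = field(default_factory=list)
    n_unassigned: int = 0
    n_filtered: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(r.count for r in self.records)

    def by_class(self) -> dict[str, int]:
        counts = {c: 0 for c in ISO_CLASSES}
        for rec in self.records:
            counts[rec.iso_class] += rec.count
        return counts


# ---------------------------------------------------------------------------
# collapsing


def collapse_reads(fastq: str | Path) -> list[CollapsedRead]:
    """Collapse a 4-line FASTQ into distinct sequences with summed counts.

    Output is ordered by descending count, ties broken lexicographically by
    sequence.  Qualities are ignored (reads are expected adapter-trimmed).
    """
    counts: dict[str, int] = {}
    n = 0
    try:
        with open(fastq) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                seq = seq.upper().replace("U", "T")
                counts[seq] = counts.get(seq, 0) + 1
                n += 1
    except ValueError as exc:
        raise FastqParseError(
            f"{fastq}: malformed FASTQ near line {4 * n + 1}: {exc}"
        ) from exc
    return [
        CollapsedRead(seq, c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# assignment


def _levenshtein(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def assign_read(
    ref: MiRNAReference, seq: str, params: AssignParams = AssignParams()
) -> Optional[str]:
    """Assign a read sequence to a miRNA, or return ``UNASSIGNED`` (None).

    Candidates are miRNAs whose assignment motif occurs in the read at the
    same 5'-anchored position (within ``five_prime_tolerance`` bases) with the
    5' prefix matching.  Among candidates, the Levenshtein distance between
    the read suffix and the mature suffix downstream of the motif must not
    exceed ``edit_distance_3p``; ties are broken by smaller distance, then
    lexicographically smaller miRNA name.
    """
    if not seq:
        raise ValueError("empty read sequence")
    start, end = params.motif_span
    tol = params.five_prime_tolerance
    best: tuple[int, str] | None = None
    for off in range(-tol, tol + 1):
        s, e = start + off, end + off
        if s < 0 or len(seq) < e:
            continue
        for name in ref.motif_index.get(seq[s:e], ()):
            mature = ref.matures[name].seq
            # 5' anchor: the bases before the motif must match the mature 5' end
            if seq[max(s - start, 0) : s] != mature[max(start - s, 0) : start]:
                continue
            dist = _levenshtein(seq[e:], mature[end:])
            if dist > params.edit_distance_3p:
                continue
            key = (dist, name)
            if best is None or key < best:
                best = key
    return best[1] if best is not None else UNASSIGNED


# ---------------------------------------------------------------------------
# classification


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def classify_isomir(
    ref: MiRNAReference, mirna: str, seq: str
) -> tuple[str, int, str, bool]:
    """Classify the 3' end of ``seq`` against miRNA ``mirna``.

    Returns ``(iso_class, trim_len, ext_seq, ext_is_genomic)``:

    - equal to the mature → ``canonical``;
    - a proper 5'-anchored prefix of the mature → ``trimmed``;
    - mature plus an extension: extension identical to the genomic downstream
      bases in full → ``ambiguous`` (templated); any mismatch → ``nt_tail``
      with the whole extension reported as non-templated;
    - shortened mature plus an extension → ``ambiguous`` (whole-extension
      rule; ``ext_is_genomic`` reflects whether the extension matches the
      genomic bases following the breakpoint).

    Raises ``ValueError`` when ``seq`` does not share the mature 5' end.
    """
    m = ref.matures[mirna].seq
    if seq == m:
        return CANONICAL, 0, "", False
    if len(seq) < len(m) and m.startswith(seq):
        return TRIMMED, len(m) - len(seq), "", False
    if seq.startswith(m):
        ext = seq[len(m) :]
        flank = ref.genomic_extension(mirna, len(ext))
        if ext == flank:  # a short flank can never match in full
            return AMBIGUOUS, 0, ext, True
        return NT_TAIL, 0, ext, False
    k = _common_prefix_len(seq, m)
    if k == 0:
        raise ValueError(
            f"read does not share the 5' end of {mirna} (contract violation)"
        )
    # shortened with a 3' extension; k is maximal so ext[0] != m[k]
    ext = seq[k:]
    genomic = ref.downstream_of(mirna, k, len(ext)) == ext
    return AMBIGUOUS, len(m) - k, ext, genomic


# ---------------------------------------------------------------------------
# per-sample profiling


def profile_sample(
    ref: MiRNAReference,
    fastq: str | Path,
    params: AssignParams = AssignParams(),
    sample_id: str = "sample",
    genotype: str = "NA",
) -> SampleProfile:
    """Collapse, assign, classify and filter one FASTQ into a SampleProfile."""
    collapsed = collapse_reads(fastq)
    if not collapsed:
        warnings.warn(f"{fastq}: empty FASTQ, returning empty profile")
        return SampleProfile(sample_id, genotype)

    by_mirna: dict[str, list[tuple[str, int]]] = {}
    n_unassigned = 0
    for rec in collapsed:
        mirna = assign_read(ref, rec.seq, params)
        if mirna is UNASSIGNED:
            n_unassigned += rec.count
        else:
            by_mirna.setdefault(mirna, []).append((rec.seq, rec.count))

    records: list[IsomiRRecord] = []
    n_filtered = 0
    for mirna in sorted(by_mirna):
        seqs = by_mirna[mirna]
        total = sum(c for _, c in seqs)
        for seq, count in seqs:
            keep_abs = count >= params.min_read
            keep_rel = count / total >= params.min_ratio
            keep = (keep_abs or keep_rel) if params.retain_rule == "or" else (
                keep_abs and keep_rel
            )
            if not keep:
                n_filtered += count
                logger.debug(
                    "dropped isomiR %s/%s: count=%d ratio=%.4f",
                    mirna, seq, count, count / total,
                )
                continue
            iso_class, trim_len, ext_seq, ext_gen = classify_isomir(ref, mirna, seq)
            records.append(
                IsomiRRecord(mirna, seq, count, iso_class, trim_len, ext_seq, ext_gen)
            )
    records.sort(key=lambda r: (r.mirna, -r.count, r.seq))
    return SampleProfile(sample_id, genotype, records, n_unassigned, n_filtered)


# ---------------------------------------------------------------------------
# profile I/O

_PROFILE_COLUMNS = (
    "mirna", "seq", "count", "iso_class", "trim_len", "ext_seq", "ext_is_genomic"
)


def write_profile(profile: SampleProfile, path: str | Path, *, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# sample_id={profile.sample_id}\n")
        fh.write(f"# genotype={profile.genotype}\n")
        fh.write(f"# n_unassigned={profile.n_unassigned}\n")
        fh.write(f"# n_filtered={profile.n_filtered}\n")
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        for r in profile.records:
            fh.write(
                f"{r.mirna}\t{r.seq}\t{r.count}\t{r.iso_class}\t{r.trim_len}\t"
                f"{r.ext_seq}\t{int(r.ext_is_genomic)}\n"
            )


def read_profile(path: str | Path) -> SampleProfile:
    meta: dict[str, str] = {}
    records: list[IsomiRRecord] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if tuple(line.split("\t")) != _PROFILE_COLUMNS:
                    raise ValueError(f"{path}: unexpected profile header {line!r}")
                header_seen = True
                continue
            if not line:
                continue
            f = line.split("\t")
            records.append(
                IsomiRRecord(f[0], f[1], int(f[2]), f[3], int(f[4]), f[5], bool(int(f[6])))
            )
    return SampleProfile(
        sample_id=meta.get("sample_id", "sample"),
        genotype=meta.get("genotype", "NA"),
        records=records,
        n_unassigned=int(meta.get("n_unassigned", 0)),
        n_filtered=int(meta.get("n_filtered", 0)),
    )
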