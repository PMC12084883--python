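"""miRNA reference handling: mature sequences anchored in pri-miRNA context.

A mature miRNA is stored together with the primary transcript (pri-miRNA) it
derives from and its 0-based offset inside that transcript.  The pri-miRNA
sequence downstream of the mature 3' end serves as the genomic context against
which 3' extensions are judged templated or non-templated.

All sequences are stored in DNA space: ``U`` is converted to ``T`` on ingest,
because sequencing reads arrive as DNA.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "MatureMiRNA",
    "PriMiRNA",
    "MiRNAReference",
    "ReferenceConsistencyError",
    "load_reference",
    "write_reference",
    "genomic_extension",
    "DEFAULT_MOTIF_SPAN",
    "DEFAULT_FLANK_MIN",
]

DNA_ALPHABET = frozenset("ACGT")

#: Motif used for read assignment: the 13-mer at mature positions [2, 15).
DEFAULT_MOTIF_SPAN = (2, 15)

#: Minimum number of pri-miRNA bases required downstream of each mature 3' end
#: (tails are analyzed up to this length).
DEFAULT_FLANK_MIN = 8

MIN_MATURE_LEN = 16


class ReferenceConsistencyError(ValueError):
    """The mature/pri/mapping inputs contradict each other."""


def _normalize_seq(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA anchored inside its primary transcript."""

    name: str
    seq: str
    pri_name: str
    offset: int  # 0-based start of the mature inside the pri sequence

    @property
    def end(self) -> int:
        """0-based, exclusive end of the mature inside the pri sequence."""
        return self.offset + len(self.seq)


@dataclass(frozen=True)
class PriMiRNA:
    name: str
    seq: str


@dataclass
class MiRNAReference:
    """Validated collection of mature miRNAs with pri-miRNA context.

    ``motif_index`` maps the assignment motif (``seq[motif_span[0]:motif_span[1]]``
    of each mature) to the sorted list of mature names carrying it; every mature
    appears under exactly one motif.
    """

    matures: dict[str, MatureMiRNA]
    pris: dict[str, PriMiRNA]
    motif_span: tuple[int, int] = DEFAULT_MOTIF_SPAN
    flank_min: int = DEFAULT_FLANK_MIN
    min_mature_len: int = MIN_MATURE_LEN
    motif_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        if not self.motif_index:
            self.motif_index = self._build_motif_index()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for mat in self.matures.values():
            if not mat.seq:
                raise ReferenceConsistencyError(f"{mat.name}: empty mature sequence")
            if len(mat.seq) < self.min_mature_len:
                raise ReferenceConsistencyError(
                    f"{mat.name}: mature length {len(mat.seq)} < {self.min_mature_len}"
                )
            bad = set(mat.seq) - DNA_ALPHABET
            if bad:
                raise ReferenceConsistencyError(
                    f"{mat.name}: non-ACGT characters {sorted(bad)}"
                )
            if mat.pri_name not in self.pris:
                raise ReferenceConsistencyError(
                    f"{mat.name}: pri-miRNA {mat.pri_name!r} not found"
                )
            pri = self.pris[mat.pri_name]
            if pri.seq[mat.offset : mat.end] != mat.seq:
                raise ReferenceConsistencyError(
                    f"{mat.name}: mature sequence does not match {mat.pri_name} "
                    f"at offset {mat.offset}"
                )
            if len(pri.seq) - mat.end < self.flank_min:
                raise ReferenceConsistencyError(
                    f"{mat.name}: only {len(pri.seq) - mat.end} downstream bases in "
                    f"{mat.pri_name}, need >= {self.flank_min}"
                )
        for pri in self.pris.values():
            bad = set(pri.seq) - DNA_ALPHABET
            if bad:
                raise ReferenceConsistencyError(
                    f"{pri.name}: non-ACGT characters {sorted(bad)}"
                )

    def _build_motif_index(self) -> dict[str, list[str]]:
        start, end = self.motif_span
        index: dict[str, list[str]] = {}
        for name in sorted(self.matures):
            motif = self.matures[name].seq[start:end]
            if len(motif) != end - start:
                raise ReferenceConsistencyError(
                    f"{name}: mature too short for motif span {self.motif_span}"
                )
            index.setdefault(motif, []).append(name)
        return index

    # -- queries ------------------------------------------------------------

    def motif_of(self, mirna: str) -> str:
        start, end = self.motif_span
        return self.matures[mirna].seq[start:end]

    def genomic_extension(self, mirna: str, k: int) -> str:
        """The ≤k pri-miRNA bases immediately 3' of the mature end.

        Returns fewer than ``k`` bases when the pri transcript ends first;
        callers detect a short flank by ``len(result) < k``.
        """
        if mirna not in self.matures:
            raise KeyError(f"unknown miRNA {mirna!r}")
        if k < 1:
            raise ValueError("k must be >= 1")
        mat = self.matures[mirna]
        pri = self.pris[mat.pri_name]
        return pri.seq[mat.end : mat.end + k]

    def downstream_of(self, mirna: str, pos: int, k: int) -> str:
        """Pri-miRNA bases following mature position ``pos`` (templated path)."""
        mat = self.matures[mirna]
        pri = self.pris[mat.pri_name]
        start = mat.offset + pos
        return pri.seq[start : start + k]


def load_reference(
    mature_fasta: str | Path,
    pri_fasta: str | Path,
    mapping_tsv: str | Path,
    *,
    motif_span: tuple[int, int] = DEFAULT_MOTIF_SPAN,
    flank_min: int = DEFAULT_FLANK_MIN,
    min_mature_len: int = MIN_MATURE_LEN,
) -> MiRNAReference:
    """Load mature + pri FASTA files and the mature→pri anchoring table.

    The mapping TSV must have a header line with columns
    ``mature_name``, ``pri_name`` and ``offset`` (0-based start of the mature
    inside its pri sequence).  RNA-alphabet sequences (``U``) are converted to
    DNA on ingest.
    """
    mature_seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        if rec.id in mature_seqs:
            raise ReferenceConsistencyError(f"duplicate mature name {rec.id!r}")
        mature_seqs[rec.id] = _normalize_seq(rec.seq)
    pris: dict[str, PriMiRNA] = {}
    for rec in SeqIO.parse(str(pri_fasta), "fasta"):
        if rec.id in pris:
            raise ReferenceConsistencyError(f"duplicate pri name {rec.id!r}")
        pris[rec.id] = PriMiRNA(rec.id, _normalize_seq(rec.seq))

    matures: dict[str, MatureMiRNA] = {}
    with open(mapping_tsv, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"mature_name", "pri_name", "offset"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ReferenceConsistencyError(
                f"mapping table missing column(s): {sorted(missing)}"
            )
        for row in reader:
            name = row["mature_name"]
            if name in matures:
                raise ReferenceConsistencyError(f"duplicate mapping for {name!r}")
            if name not in mature_seqs:
                raise ReferenceConsistencyError(
                    f"mapping names mature {name!r} absent from mature FASTA"
                )
            if row["pri_name"] not in pris:
                raise ReferenceConsistencyError(
                    f"{name}: pri-miRNA {row['pri_name']!r} absent from pri FASTA"
                )
            matures[name] = MatureMiRNA(
                name=name,
                seq=mature_seqs[name],
                pri_name=row["pri_name"],
                offset=int(row["offset"]),
            )
    unmapped = set(mature_seqs) - set(matures)
    if unmapped:
        raise ReferenceConsistencyError(
            f"mature sequence(s) without mapping row: {sorted(unmapped)}"
        )
    return MiRNAReference(
        matures, pris, motif_span=motif_span, flank_min=flank_min,
        min_mature_len=min_mature_len,
    )


def write_reference(
    ref: MiRNAReference,
    mature_fasta: str | Path,
    pri_fasta: str | Path,
    mapping_tsv: str | Path,
) -> None:
    """Write a reference back to FASTA + mapping TSV (round-trips with load)."""
    with open(mature_fasta, "w") as fh:
        for name in sorted(ref.matures):
            fh.write(f">{name}\n{ref.matures[name].seq}\n")
    with open(pri_fasta, "w") as fh:
        for name in sorted(ref.pris):
            fh.write(f">{name}\n{ref.pris[name].seq}\n")
    with open(mapping_tsv, "w") as fh:
        fh.write("mature_name\tpri_name\toffset\n")
        for name in sorted(ref.matures):
            mat = ref.matures[name]
            fh.write(f"{name}\t{mat.pri_name}\t{mat.offset}\n")


def genomic_extension(ref: MiRNAReference, mirna: str, k: int) -> str:
    """Functional alias for :meth:`MiRNAReference.genomic_extension`."""
    return ref.genomic_extension(mirna, k)
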