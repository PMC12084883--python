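"""Read collapsing, motif assignment and 3'-end classification."""

import itertools
import random

import pytest

from tailscope.isomir import (
    AMBIGUOUS,
    CANONICAL,
    NT_TAIL,
    TRIMMED,
    UNASSIGNED,
    AssignParams,
    FastqParseError,
    assign_read,
    classify_isomir,
    collapse_reads,
    profile_sample,
    read_profile,
    write_profile,
)
from tailscope.reference import MatureMiRNA, MiRNAReference, PriMiRNA

from conftest import FLANK1, MATURE1

PERMISSIVE = AssignParams(min_read=1, min_ratio=0.0)


# -- collapsing --------------------------------------------------------------


def test_collapse_counts_distinct_sequences(write_fastq):
    path = write_fastq(["ACGT", "ACGT", "ACGT"])
    assert [(r.seq, r.count) for r in collapse_reads(path)] == [("ACGT", 3)]


def test_collapse_empty_file(write_fastq):
    assert collapse_reads(write_fastq([])) == []


def test_collapse_tie_broken_lexicographically(write_fastq):
    path = write_fastq(["ACGT", "ACGA", "ACGT", "ACGA"])
    assert [r.seq for r in collapse_reads(path)] == ["ACGA", "ACGT"]


def test_collapse_malformed_fastq_reports_position(tmp_path):
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r0\nACGT\n+\nIIII\nACGT\n+\nIIII\n")
    with pytest.raises(FastqParseError, match="line"):
        collapse_reads(bad)


# -- assignment --------------------------------------------------------------


def test_exact_mature_assigned(toy_ref):
    assert assign_read(toy_ref, MATURE1) == "m1"


def test_three_nt_extension_within_edit_gate(toy_ref):
    assert assign_read(toy_ref, MATURE1 + "AAA") == "m1"


def test_four_nt_extension_unassigned(toy_ref):
    assert assign_read(toy_ref, MATURE1 + "AAAA") is UNASSIGNED


def test_unrelated_sequence_unassigned(toy_ref):
    assert assign_read(toy_ref, "ACGT" * 6) is UNASSIGNED


def test_shared_motif_tie_goes_to_lexicographically_smaller_name():
    # two matures identical through the motif, equidistant 3' suffixes
    core = MATURE1[:15]
    seq_a, seq_b = core + "AAAAA", core + "TTTTT"
    pris = {
        "pa": PriMiRNA("pa", seq_a + "G" * 8),
        "pb": PriMiRNA("pb", seq_b + "G" * 8),
    }
    matures = {
        "mirB": MatureMiRNA("mirB", seq_b, "pb", 0),
        "mirA": MatureMiRNA("mirA", seq_a, "pa", 0),
    }
    ref = MiRNAReference(matures, pris)
    read = core + "GGGGG"  # distance 5 > 3 from both: unassigned
    assert assign_read(ref, read) is UNASSIGNED
    read = core + "AATTC"  # distance 3 from both suffixes
    assert assign_read(ref, read) == "mirA"


def test_five_prime_shifted_read_unassigned_by_default(toy_ref):
    shifted = MATURE1[1:]  # lost one 5' base
    assert assign_read(toy_ref, shifted) is UNASSIGNED
    tol = AssignParams(five_prime_tolerance=1)
    assert assign_read(toy_ref, shifted, tol) == "m1"


# -- classification ----------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [
        (MATURE1, (CANONICAL, 0, "", False)),
        (MATURE1[:-2], (TRIMMED, 2, "", False)),
        (MATURE1 + "AA", (NT_TAIL, 0, "AA", False)),  # flank starts GT
        (MATURE1 + FLANK1[0], (AMBIGUOUS, 0, "G", True)),  # templated
        (MATURE1 + FLANK1[:3], (AMBIGUOUS, 0, FLANK1[:3], True)),
        (MATURE1[:-1] + "A", (AMBIGUOUS, 1, "A", False)),  # trimmed + NT tail
        (MATURE1 + "GA", (NT_TAIL, 0, "GA", False)),  # whole-extension rule
    ],
)
def test_classify_three_prime_variants(toy_ref, seq, expected):
    assert classify_isomir(toy_ref, "m1", seq) == expected


def test_classify_requires_shared_five_prime_end(toy_ref):
    with pytest.raises(ValueError, match="5'"):
        classify_isomir(toy_ref, "m1", "C" + MATURE1[1:])


def test_mature_is_always_canonical(toy_ref):
    for name, mat in toy_ref.matures.items():
        assert classify_isomir(toy_ref, name, mat.seq)[0] == CANONICAL


def test_genomic_matching_extension_never_nt(toy_ref):
    for k in range(1, len(FLANK1) + 1):
        iso_class, _, _, genomic = classify_isomir(toy_ref, "m1", MATURE1 + FLANK1[:k])
        assert iso_class != NT_TAIL and genomic


def _oracle(seq: str, mature: str, pri: str, offset: int) -> str:
    """Brute-force classifier straight from the four class definitions."""
    if seq == mature:
        return CANONICAL
    if len(seq) < len(mature) and mature.startswith(seq):
        return TRIMMED
    if len(seq) > len(mature) and seq.startswith(mature):
        tail = seq[len(mature):]
        end = offset + len(mature)
        return AMBIGUOUS if pri[end : end + len(tail)] == tail else NT_TAIL
    return AMBIGUOUS  # shortened (or substituted) with a non-matching tail


def all_three_prime_variants(mature: str, max_edit: int):
    """Every sequence reachable by trimming <=max_edit bases and/or appending
    <=max_edit bases at the 3' end."""
    for trim in range(max_edit + 1):
        stem = mature[: len(mature) - trim]
        for ext_len in range(max_edit + 1):
            for ext in itertools.product("ACGT", repeat=ext_len):
                yield stem + "".join(ext)


def test_partition_and_oracle_agreement_on_all_variants(toy_ref):
    pri = toy_ref.pris["pri-m1"].seq
    offset = toy_ref.matures["m1"].offset
    seen = set()
    for seq in all_three_prime_variants(MATURE1, 4):
        if seq in seen:
            continue
        seen.add(seq)
        iso_class, trim_len, ext_seq, ext_gen = classify_isomir(toy_ref, "m1", seq)
        assert iso_class == _oracle(seq, MATURE1, pri, offset), seq
        # IsomiRRecord invariants
        if iso_class == CANONICAL:
            assert seq == MATURE1
        if trim_len > 0:
            assert iso_class in (TRIMMED, AMBIGUOUS)
        if iso_class == NT_TAIL:
            assert ext_seq and not ext_gen and trim_len == 0


# -- profiling ---------------------------------------------------------------


def test_retention_or_rule(toy_ref, write_fastq):
    # 8 canonical-variant reads at ratio 0.05 (dropped), the rest canonical
    tail_seqs = [MATURE1 + "AA"] * 8
    path = write_fastq([MATURE1] * 152 + tail_seqs)
    prof = profile_sample(toy_ref, path, AssignParams())
    assert [r.seq for r in prof.records] == [MATURE1]
    assert prof.n_filtered == 8

    # same count, ratio 0.12: retained under the OR rule
    path = write_fastq([MATURE1] * 58 + tail_seqs, name="b.fastq")
    prof = profile_sample(toy_ref, path, AssignParams())
    assert {r.seq for r in prof.records} == {MATURE1, MATURE1 + "AA"}
    assert prof.n_filtered == 0


def test_retention_and_rule_requires_both(toy_ref, write_fastq):
    path = write_fastq([MATURE1] * 58 + [MATURE1 + "AA"] * 8)
    prof = profile_sample(toy_ref, path, AssignParams(retain_rule="and"))
    assert [r.seq for r in prof.records] == [MATURE1]


def test_canonical_only_input(toy_ref, write_fastq):
    prof = profile_sample(toy_ref, write_fastq([MATURE1] * 20), PERMISSIVE)
    assert prof.by_class() == {CANONICAL: 20, TRIMMED: 0, NT_TAIL: 0, AMBIGUOUS: 0}
    assert prof.n_assigned == 20


def test_profile_invariant_to_read_order(toy_ref, write_fastq):
    seqs = [MATURE1] * 30 + [MATURE1[:-1]] * 20 + [MATURE1 + "AA"] * 10
    shuffled = seqs[:]
    random.Random(7).shuffle(shuffled)
    p1 = profile_sample(toy_ref, write_fastq(seqs, "a.fastq"), PERMISSIVE)
    p2 = profile_sample(toy_ref, write_fastq(shuffled, "b.fastq"), PERMISSIVE)
    assert p1.records == p2.records


def test_empty_fastq_warns_and_returns_empty_profile(toy_ref, write_fastq):
    with pytest.warns(UserWarning, match="empty"):
        prof = profile_sample(toy_ref, write_fastq([]))
    assert prof.records == [] and prof.n_assigned == 0


def test_profile_round_trips_through_tsv(toy_ref, write_fastq, tmp_path):
    seqs = [MATURE1] * 30 + [MATURE1 + "AA"] * 10 + [MATURE1[:-2]] * 5
    prof = profile_sample(
        toy_ref, write_fastq(seqs), PERMISSIVE, sample_id="s1", genotype="WT"
    )
    out = tmp_path / "profile.tsv"
    write_profile(prof, out)
    again = read_profile(out)
    assert again == prof
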