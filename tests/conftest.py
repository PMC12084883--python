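from pathlib import Path

import pytest

from tailscope.reference import MatureMiRNA, MiRNAReference, PriMiRNA

# 20-nt mature anchored in a pri transcript with an 8-nt downstream flank.
MATURE1 = "TGAGGTAGTAGGTTGTATAG"
FLANK1 = "GTCAACCT"
MATURE2 = "CCTTGGAGTAAAGTAGCAGC"
FLANK2 = "ATGGCTAA"


@pytest.fixture(scope="session")
def toy_ref() -> MiRNAReference:
    """Two-miRNA reference with known flanks for classifier tests."""
    pris = {
        "pri-m1": PriMiRNA("pri-m1", "AAA" + MATURE1 + FLANK1),
        "pri-m2": PriMiRNA("pri-m2", "CGCGC" + MATURE2 + FLANK2),
    }
    matures = {
        "m1": MatureMiRNA("m1", MATURE1, "pri-m1", 3),
        "m2": MatureMiRNA("m2", MATURE2, "pri-m2", 5),
    }
    return MiRNAReference(matures, pris)


@pytest.fixture
def write_fastq(tmp_path: Path):
    """Write the given sequences as a 4-line-record FASTQ, return the path."""

    def _write(seqs, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, seq in enumerate(seqs):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    return _write
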