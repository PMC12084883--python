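"""Ground-truthed synthetic inputs for every pipeline stage.

Generators
----------
- :func:`simulate_reference` — a random but internally consistent miRNA
  reference (matures anchored in pri transcripts with downstream flank).
- :func:`simulate_smallrna_sample` / :func:`simulate_smallrna_cohort` —
  small-RNA FASTQ files with controlled isomiR structure.  Each read is the
  mature sequence, a 3'-trimmed mature, the mature plus a templated extension
  copied from the pri-miRNA downstream flank, the mature plus a non-templated
  (NT) tail drawn i.i.d. per position from a genotype-specific nucleotide
  emission, or (rarely) a mixed extension with a one-base genomic prefix and
  an NT suffix, which exercises the classifier's whole-extension rule.
- :func:`simulate_polya_tables` — per-read poly(A) tail-length tables in the
  nanopolish-polya TSV dialect, with log-normal tail lengths, per-transcript
  median shifts planted in the KO condition, and a configurable fraction of
  QC-failed rows.
- :func:`simulate_count_matrix` — negative-binomial gene counts with planted
  differentially expressed genes and recorded library-size factors.
- :func:`simulate_repressive_pairs` — miRNA/target expression profiles with a
  planted inverse (repressive) relationship.

Every generator is a pure function of its parameters and seed: identical
inputs yield byte-identical outputs.  Alongside each output a
:class:`TruthManifest` fragment records the parameters and realized draws
needed to compute every expected downstream summary analytically or by
Monte Carlo, without re-reading the generated files.

Default parameter values emulate the structure of a mammalian hippocampus
small-RNA cohort: roughly 55% canonical reads, ~26% trimmed isoforms and
~10% NT-tailed reads, with an adenosine-rich NT-tail emission in the
wild type (A = 0.65) that drops in the knockout (A = 0.45) in favour of
uridine and cytidine.  Trim and tail lengths are bounded at 3 nt so that
every generated read clears the default 3'-edit-distance assignment gate;
this keeps the manifest's expected class fractions exactly analytic.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import MiRNAReference, MatureMiRNA, PriMiRNA

__all__ = [
    "GENOTYPES",
    "SmallRNASimParams",
    "PolyASimParams",
    "TruthManifest",
    "simulate_reference",
    "simulate_smallrna_sample",
    "simulate_smallrna_cohort",
    "simulate_polya_tables",
    "simulate_count_matrix",
    "simulate_repressive_pairs",
]

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
_BASES = "ACGT"

DEFAULT_NT_EMISSION = {
    # probabilities over (A, C, G, T); T is uridine in RNA space
    "WT": (0.65, 0.06, 0.04, 0.25),
    "KO": (0.45, 0.10, 0.05, 0.40),
}
DEFAULT_TAIL_LEN_DIST = {1: 0.6, 2: 0.3, 3: 0.1}


def _check_probs(vec, label: str) -> None:
    arr = np.asarray(vec, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{label}: probabilities must lie in [0, 1]")
    if not np.isclose(arr.sum(), 1.0, atol=1e-9):
        raise ValueError(f"{label}: probabilities must sum to 1 (got {arr.sum()})")


@dataclass
class SmallRNASimParams:
    """Mixture parameters of the small-RNA read generator.

    ``p_canonical`` is the probability a read is exactly the mature sequence.
    Conditional on not canonical, a read is 3'-extended with probability
    ``p_tail`` and trimmed otherwise.  Conditional on extension, the tail is
    fully templated with probability ``p_templated``, mixed
    (one genomic base + NT suffix) with probability ``p_mixed`` and pure NT
    otherwise.  NT tail bases are i.i.d. draws from ``nt_emission`` of the
    sample's genotype, ordered (A, C, G, T).
    """

    n_mirnas: int = 50
    depth: int = 100_000
    abundance_dispersion: float = 1.0  # log-normal sigma of per-miRNA expression
    p_canonical: float = 0.55
    trim_geom_p: float = 0.35
    max_trim: int = 3
    p_tail: float = 0.41
    p_templated: float = 0.43
    p_mixed: float = 0.02
    tail_len_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TAIL_LEN_DIST)
    )
    nt_emission: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NT_EMISSION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.n_mirnas <= 0:
            raise ValueError("depth and n_mirnas must be positive")
        for p, name in [
            (self.p_canonical, "p_canonical"),
            (self.trim_geom_p, "trim_geom_p"),
            (self.p_tail, "p_tail"),
            (self.p_templated, "p_templated"),
            (self.p_mixed, "p_mixed"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_templated + self.p_mixed > 1:
            raise ValueError("p_templated + p_mixed must not exceed 1")
        _check_probs(list(self.tail_len_dist.values()), "tail_len_dist")
        if any(L < 1 for L in self.tail_len_dist):
            raise ValueError("tail lengths must be >= 1")
        for g, row in self.nt_emission.items():
            _check_probs(row, f"nt_emission[{g}]")

    # branch probabilities over generation categories ----------------------

    def branch_probs(self) -> dict[str, float]:
        """Unconditional probabilities of the five generation categories."""
        q = 1.0 - self.p_canonical
        ext = q * self.p_tail
        return {
            "canonical": self.p_canonical,
            "trimmed": q * (1.0 - self.p_tail),
            "templated": ext * self.p_templated,
            "mixed": ext * self.p_mixed,
            "nt": ext * (1.0 - self.p_templated - self.p_mixed),
        }

    def trim_len_probs(self) -> dict[int, float]:
        """Truncated geometric distribution of trim lengths 1..max_trim."""
        g = self.trim_geom_p
        raw = {t: (1 - g) ** (t - 1) * g for t in range(1, self.max_trim + 1)}
        z = sum(raw.values())
        return {t: p / z for t, p in raw.items()}


@dataclass
class PolyASimParams:
    """Parameters of the per-read poly(A) tail-length table generator.

    Tail lengths are log-normal; ``shifted_set`` maps transcript names to the
    median shift (nt, KO minus WT) planted in the knockout condition.  A
    fraction ``qc_fail_rate`` of rows carries a non-PASS QC tag.
    """

    n_transcripts: int = 60
    reads_per_transcript: tuple[float, float] = (200.0, 0.1)  # (mean, NB dispersion)
    baseline_logmean: float = 4.6  # median exp(4.6) ~ 100 nt
    baseline_logsd: float = 0.18
    shifted_set: dict[str, float] = field(default_factory=dict)
    qc_fail_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if not 0 <= self.qc_fail_rate <= 1:
            raise ValueError("qc_fail_rate must lie in [0, 1]")
        if self.reads_per_transcript[0] <= 0 or self.reads_per_transcript[1] < 0:
            raise ValueError("reads_per_transcript mean must be > 0, dispersion >= 0")
        universe = set(self.transcript_names())
        unknown = set(self.shifted_set) - universe
        if unknown:
            raise ValueError(f"shifted_set names unknown transcripts: {sorted(unknown)}")

    def transcript_names(self) -> list[str]:
        return [f"T{i:04d}" for i in range(1, self.n_transcripts + 1)]


# ---------------------------------------------------------------------------
# truth manifest


@dataclass
class TruthManifest:
    """Serializable record of everything the generators drew.

    Fragments are keyed per generator; the manifest is sufficient to compute
    every expected downstream summary (class fractions, NT-base frequencies,
    planted shifts and fold changes) without re-reading the generated files.
    """

    schema_version: int = 1
    smallrna: dict = field(default_factory=dict)  # sample_id -> fragment
    polya: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)

    def merge(self, other: "TruthManifest") -> "TruthManifest":
        self.smallrna.update(other.smallrna)
        self.polya.update(other.polya)
        self.counts.update(other.counts)
        self.interactions.update(other.interactions)
        return self

    def to_json(self, path: str | Path) -> None:
        def _plain(o):
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=_plain)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    # -- analytic expectations for small-RNA fragments ----------------------

    def expected_class_fractions(self, sample_id: str) -> dict[str, float]:
        """Generation-category mixture weights for one sample."""
        frag = self.smallrna[sample_id]
        return dict(frag["branch_probs"])

    def expected_observed_class_fractions(self, sample_id: str) -> dict[str, float]:
        """Expected classifier output fractions (canonical/trimmed/nt/ambiguous).

        Accounts for NT and mixed tails that coincide with the genomic flank
        by chance and are therefore classified as templated (ambiguous).
        """
        frag = self.smallrna[sample_id]
        bp = frag["branch_probs"]
        em = {b: p for b, p in zip(_BASES, frag["nt_emission"])}
        tail_dist = {int(k): v for k, v in frag["tail_len_dist"].items()}
        abundance = frag["abundance"]
        flanks = frag["flanks"]

        p_match_nt = 0.0   # pure NT tail equals flank prefix in full
        p_match_mix = 0.0  # mixed tail's NT suffix equals flank continuation
        z_ge2 = sum(p for L, p in tail_dist.items() if L >= 2)
        for name, w in abundance.items():
            flank = flanks[name]
            for L, pL in tail_dist.items():
                prod = 1.0
                for i in range(L):
                    prod *= em[flank[i]]
                p_match_nt += w * pL * prod
                if L >= 2 and z_ge2 > 0:
                    prod_suffix = 1.0
                    for i in range(1, L):
                        prod_suffix *= em[flank[i]]
                    p_match_mix += w * (pL / z_ge2) * prod_suffix
        return {
            "canonical": bp["canonical"],
            "trimmed": bp["trimmed"],
            "nt_tail": bp["nt"] * (1 - p_match_nt) + bp["mixed"] * (1 - p_match_mix),
            "ambiguous": bp["templated"]
            + bp["nt"] * p_match_nt
            + bp["mixed"] * p_match_mix,
        }


# ---------------------------------------------------------------------------
# reference generator


def simulate_reference(
    n_mirnas: int = 50,
    mature_len: int = 22,
    flank_len: int = 12,
    upstream_len: int = 10,
    seed: int = 0,
    motif_span: tuple[int, int] = (2, 15),
) -> MiRNAReference:
    """Random miRNA reference with matures anchored in synthetic pri context.

    Assignment motifs are guaranteed unique across miRNAs so that motif-based
    read assignment is unambiguous by construction.
    """
    rng = np.random.default_rng(seed)
    matures: dict[str, MatureMiRNA] = {}
    pris: dict[str, PriMiRNA] = {}
    motifs: set[str] = set()
    s, e = motif_span
    i = 0
    while len(matures) < n_mirnas:
        i += 1
        seq = "".join(rng.choice(list(_BASES), size=mature_len))
        if seq[s:e] in motifs:
            continue  # redraw on motif collision
        motifs.add(seq[s:e])
        name = f"mir-{len(matures) + 1:03d}"
        pri_name = f"pri-{name}"
        upstream = "".join(rng.choice(list(_BASES), size=upstream_len))
        flank = "".join(rng.choice(list(_BASES), size=flank_len))
        matures[name] = MatureMiRNA(name, seq, pri_name, upstream_len)
        pris[pri_name] = PriMiRNA(pri_name, upstream + seq + flank)
    return MiRNAReference(matures, pris, motif_span=motif_span, flank_min=min(8, flank_len))


# ---------------------------------------------------------------------------
# small-RNA read generator


def _tail_enumeration(L: int, emission: Sequence[float]) -> tuple[list[str], np.ndarray]:
    tails = ["".join(t) for t in itertools.product(_BASES, repeat=L)]
    probs = np.array(
        [np.prod([emission[_BASES.index(b)] for b in t]) for t in tails]
    )
    return tails, probs


def simulate_smallrna_sample(
    ref: MiRNAReference,
    params: SmallRNASimParams,
    genotype: str,
    out_fastq: str | Path,
    sample_id: str | None = None,
    sample_index: int = 0,
) -> tuple[Path, TruthManifest]:
    """Write one synthetic small-RNA FASTQ and return its truth fragment.

    The RNG stream is seeded as ``params.seed + sample_index`` so cohorts get
    one independent stream per sample while remaining pure functions of the
    base seed.
    """
    if genotype not in params.nt_emission:
        raise ValueError(f"no NT emission defined for genotype {genotype!r}")
    rng = np.random.default_rng(params.seed + sample_index)
    sample_id = sample_id or f"{genotype}_{sample_index}"
    names = sorted(ref.matures)
    weights = rng.lognormal(0.0, params.abundance_dispersion, size=len(names))
    weights /= weights.sum()
    reads_per_mirna = rng.multinomial(params.depth, weights)

    bp = params.branch_probs()
    branch_names = ("canonical", "trimmed", "templated", "mixed", "nt")
    branch_p = np.array([bp[b] for b in branch_names])
    trim_probs = params.trim_len_probs()
    trim_lens = sorted(trim_probs)
    trim_p = np.array([trim_probs[t] for t in trim_lens])
    tail_lens = sorted(params.tail_len_dist)
    tail_p = np.array([params.tail_len_dist[L] for L in tail_lens])
    emission = params.nt_emission[genotype]
    tail_enum = {L: _tail_enumeration(L, emission) for L in tail_lens}
    mixed_lens = [L for L in tail_lens if L >= 2]
    mixed_p = None
    if mixed_lens:
        mixed_p = np.array([params.tail_len_dist[L] for L in mixed_lens])
        mixed_p = mixed_p / mixed_p.sum()

    seq_counts: list[tuple[str, int]] = []
    realized = {b: 0 for b in branch_names}
    nt_base_counts = {b: 0 for b in _BASES}
    n_templated_resampled = 0

    for name, n_reads in zip(names, reads_per_mirna):
        if n_reads == 0:
            continue
        m = ref.matures[name].seq
        flank = ref.genomic_extension(name, max(tail_lens))
        cls_counts = rng.multinomial(n_reads, branch_p)
        per_class = dict(zip(branch_names, cls_counts))

        if per_class["canonical"]:
            seq_counts.append((m, per_class["canonical"]))
        if per_class["trimmed"]:
            for t, c in zip(trim_lens, rng.multinomial(per_class["trimmed"], trim_p)):
                if c:
                    seq_counts.append((m[:-t], c))
        n_templated = per_class["templated"]
        n_nt = per_class["nt"]
        if n_templated:
            for L, c in zip(tail_lens, rng.multinomial(n_templated, tail_p)):
                if not c:
                    continue
                if len(flank) < L:
                    # flank too short to copy: fall back to an NT draw
                    n_nt += c
                    per_class["templated"] -= c
                    per_class["nt"] += c
                    n_templated_resampled += c
                    logger.debug("%s: %d templated tails resampled as NT", name, c)
                    continue
                seq_counts.append((m + flank[:L], c))
        if n_nt:
            for L, c in zip(tail_lens, rng.multinomial(n_nt, tail_p)):
                if not c:
                    continue
                tails, probs = tail_enum[L]
                for tail, ct in zip(tails, rng.multinomial(c, probs)):
                    if ct:
                        seq_counts.append((m + tail, ct))
                        for b in tail:
                            nt_base_counts[b] += ct
        if per_class["mixed"] and mixed_lens:
            for L, c in zip(mixed_lens, rng.multinomial(per_class["mixed"], mixed_p)):
                if not c:
                    continue
                tails, probs = tail_enum[L - 1] if L - 1 in tail_enum else _tail_enumeration(L - 1, emission)
                for tail, ct in zip(tails, rng.multinomial(c, probs)):
                    if ct:
                        seq_counts.append((m + flank[0] + tail, ct))
                        for b in tail:
                            nt_base_counts[b] += ct
        for b in branch_names:
            realized[b] += per_class[b]

    out_fastq = Path(out_fastq)
    rid = 0
    lines: list[str] = []
    for seq, count in seq_counts:
        qual = "I" * len(seq)
        for _ in range(count):
            rid += 1
            lines.append(f"@{sample_id}_r{rid:07d}\n{seq}\n+\n{qual}")
    out_fastq.write_text("\n".join(lines) + ("\n" if lines else ""))

    fragment = TruthManifest()
    fragment.smallrna[sample_id] = {
        "genotype": genotype,
        "seed": params.seed,
        "sample_index": sample_index,
        "depth": int(params.depth),
        "abundance": {n: float(w) for n, w in zip(names, weights)},
        "flanks": {n: ref.genomic_extension(n, max(tail_lens)) for n in names},
        "branch_probs": bp,
        "tail_len_dist": {str(k): v for k, v in params.tail_len_dist.items()},
        "nt_emission": list(emission),
        "realized_class_counts": realized,
        "realized_nt_base_counts": nt_base_counts,
        "n_templated_resampled_as_nt": n_templated_resampled,
    }
    return out_fastq, fragment


def simulate_smallrna_cohort(
    ref: MiRNAReference,
    params: SmallRNASimParams,
    outdir: str | Path,
    n_wt: int = 3,
    n_ko: int = 5,
) -> tuple[dict[str, Path], TruthManifest]:
    """Simulate a WT/KO cohort; returns {sample_id: fastq path} and the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = TruthManifest()
    paths: dict[str, Path] = {}
    layout = [("WT", i) for i in range(1, n_wt + 1)] + [
        ("KO", i) for i in range(1, n_ko + 1)
    ]
    for idx, (genotype, rep) in enumerate(layout):
        sample_id = f"{genotype}_{rep}"
        path, frag = simulate_smallrna_sample(
            ref, params, genotype, outdir / f"{sample_id}.fastq",
            sample_id=sample_id, sample_index=idx,
        )
        manifest.merge(frag)
        paths[sample_id] = path
    return paths, manifest


# ---------------------------------------------------------------------------
# poly(A) per-read tables

_POLYA_FAIL_TAGS = ("ADAPTER", "NOREGION", "READ_FAILED_LOAD")


def simulate_polya_tables(
    params: PolyASimParams,
    out_wt: str | Path,
    out_ko: str | Path,
) -> tuple[Path, Path, TruthManifest]:
    """Write WT and KO nanopolish-polya-dialect TSVs plus the truth fragment."""
    rng = np.random.default_rng(params.seed)
    mean, disp = params.reads_per_transcript
    names = params.transcript_names()
    truth_rows: dict[str, dict] = {}

    def _n_reads() -> int:
        if disp == 0:
            return int(rng.poisson(mean))
        r = 1.0 / disp
        return int(rng.negative_binomial(r, r / (r + mean)))

    def _write(path: str | Path, condition: str) -> Path:
        path = Path(path)
        lines = ["readname\tcontig\tposition\tpolya_length\tqc_tag"]
        for tid in names:
            shift = params.shifted_set.get(tid, 0.0) if condition == "KO" else 0.0
            mu = np.log(max(np.exp(params.baseline_logmean) + shift, 1.0))
            n = _n_reads()
            lengths = rng.lognormal(mu, params.baseline_logsd, size=n)
            fail = rng.random(n) < params.qc_fail_rate
            tag_choice = rng.random(n)
            fail_tag = rng.integers(0, len(_POLYA_FAIL_TAGS), size=n)
            for i in range(n):
                if fail[i]:
                    tag = _POLYA_FAIL_TAGS[fail_tag[i]]
                elif tag_choice[i] < 0.85:
                    tag = "PASS"
                else:
                    tag = "SUFFCLIP"
                lines.append(
                    f"{condition}_{tid}_r{i + 1:05d}\t{tid}\t0\t{lengths[i]:.2f}\t{tag}"
                )
            row = truth_rows.setdefault(
                tid, {"shift": params.shifted_set.get(tid, 0.0)}
            )
            row[f"n_{condition.lower()}"] = int(n)
            row[f"median_expected_{condition.lower()}"] = float(np.exp(mu))
        path.write_text("\n".join(lines) + "\n")
        return path

    wt_path = _write(out_wt, "WT")
    ko_path = _write(out_ko, "KO")
    fragment = TruthManifest()
    fragment.polya = {
        "seed": params.seed,
        "qc_fail_rate": params.qc_fail_rate,
        "baseline_median": float(np.exp(params.baseline_logmean)),
        "transcripts": truth_rows,
    }
    return wt_path, ko_path, fragment


# ---------------------------------------------------------------------------
# NB count matrices


def simulate_count_matrix(
    n_genes: int,
    n_per_group: int,
    planted: Sequence[tuple[str, float]],
    nb_dispersion: float,
    seed: int,
    *,
    base_mean_log2: float = 7.0,
    base_mean_log2_sd: float = 1.5,
    libsize_logsd: float = 0.15,
    planted_base_mean: float | None = None,
    out_tsv: str | Path | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """NB-distributed gene counts with planted log2 fold changes (KO vs WT).

    ``planted`` lists ``(gene_name, log2FC)``; planted genes must belong to
    the ``G0001..`` gene universe.  Library-size factors are drawn log-normal
    and recorded in the truth fragment.  When ``planted_base_mean`` is given,
    planted genes get exactly that WT base mean instead of a drawn one.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    universe = set(genes)
    for g, _ in planted:
        if g not in universe:
            raise ValueError(f"planted gene {g!r} outside universe of {n_genes} genes")
    rng = np.random.default_rng(seed)
    samples = [f"WT_{i}" for i in range(1, n_per_group + 1)] + [
        f"KO_{i}" for i in range(1, n_per_group + 1)
    ]
    groups = np.array(["WT"] * n_per_group + ["KO"] * n_per_group)
    base = 2.0 ** rng.normal(base_mean_log2, base_mean_log2_sd, size=n_genes)
    lfc = np.zeros(n_genes)
    planted_map = dict(planted)
    for i, g in enumerate(genes):
        if g in planted_map:
            lfc[i] = planted_map[g]
            if planted_base_mean is not None:
                base[i] = planted_base_mean
    sf = np.exp(rng.normal(0.0, libsize_logsd, size=len(samples)))
    mu = base[:, None] * (2.0 ** (lfc[:, None] * (groups == "KO")[None, :])) * sf[None, :]
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t")
    fragment = TruthManifest()
    fragment.counts = {
        "seed": seed,
        "nb_dispersion": nb_dispersion,
        "groups": {s: g for s, g in zip(samples, groups)},
        "size_factors": {s: float(v) for s, v in zip(samples, sf)},
        "planted": {g: float(v) for g, v in planted_map.items()},
        "base_means": {g: float(b) for g, b in zip(genes, base)},
    }
    return df, fragment


# ---------------------------------------------------------------------------
# repressive miRNA:target profiles


def simulate_repressive_pairs(
    n_pairs: int,
    n_samples: int = 6,
    noise_sd_frac: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]], TruthManifest]:
    """Matched miRNA/gene expression with a planted inverse relationship.

    Each pair follows ``gene = c - a * mirna + noise`` with ``a > 0`` and
    noise SD equal to ``noise_sd_frac`` of the signal SD, so the expected
    Pearson correlation is strongly negative.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(1, n_samples + 1)]
    mirna_rows, gene_rows, pairs = {}, {}, []
    slopes = {}
    for i in range(1, n_pairs + 1):
        mir, gene = f"mir-{i:03d}", f"G{i:04d}"
        base = rng.uniform(50, 500)
        x = base * np.exp(rng.normal(0.0, 0.4, size=n_samples))
        a = rng.uniform(0.5, 2.0)
        signal = a * x
        c = signal.max() * 1.5
        y = c - signal + rng.normal(0.0, noise_sd_frac * signal.std(), size=n_samples)
        mirna_rows[mir] = x
        gene_rows[gene] = np.maximum(y, 0.0)
        pairs.append((mir, gene))
        slopes[mir] = float(a)
    mirna_df = pd.DataFrame(mirna_rows, index=samples).T
    gene_df = pd.DataFrame(gene_rows, index=samples).T
    fragment = TruthManifest()
    fragment.interactions = {
        "seed": seed,
        "noise_sd_frac": noise_sd_frac,
        "slopes": slopes,
        "n_pairs": n_pairs,
    }
    return mirna_df, gene_df, pairs, fragment
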