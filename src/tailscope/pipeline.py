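"""Config-driven orchestration of the full synthetic-cohort pipeline.

``run_pipeline`` executes simulate → profile → summarize → test → integrate
on a single validated configuration and writes TSV outputs plus a
machine-readable manifest.  Every output carries a provenance header (tool
version, config hash, seed) and the whole run is a pure function of the
configuration: rerunning with an identical config reproduces identical
bytes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    call_differential,
    isomir_count_matrix,
    monoA_canonical_correlation,
    nb_wald_test,
    size_factors,
)
from .integrate import correlate, filter_to_monoA_and_de, interaction_summary, load_pairs
from .isomir import NT_TAIL, AssignParams, profile_sample, write_profile
from .polya import global_distribution, per_transcript_test, read_polya_table
from .simulate import (
    PolyASimParams,
    SmallRNASimParams,
    simulate_count_matrix,
    simulate_polya_tables,
    simulate_reference,
    simulate_smallrna_cohort,
)
from .tailstats import class_fractions, compare_groups, nt_nucleotide_freq, tail_length_composition

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "outdir": "tailscope_out",
    "reference": {"n_mirnas": 30, "mature_len": 22, "flank_len": 12},
    "smallrna": {
        "n_wt": 3,
        "n_ko": 5,
        "depth": 20000,
        "p_canonical": 0.55,
        "p_tail": 0.41,
        "p_templated": 0.43,
        "p_mixed": 0.02,
        "trim_geom_p": 0.35,
        "abundance_dispersion": 1.0,
    },
    "assign": {
        "min_ratio": 0.1,
        "min_read": 9,
        "edit_distance_3p": 3,
        "five_prime_tolerance": 0,
        "retain_rule": "or",
    },
    "thresholds": {
        "padj": 0.05,
        "lfc": 1.0,
        "delta_min": 5.0,
        "min_reads": 10,
    },
    "polya": {
        "n_transcripts": 40,
        "n_shifted": 5,
        "shift": -10.0,
        "reads_mean": 200.0,
        "reads_dispersion": 0.1,
        "qc_fail_rate": 0.1,
    },
    "counts": {
        "n_genes": 500,
        "n_per_group": 3,
        "n_planted": 20,
        "planted_lfc": 2.0,
        "nb_dispersion": 0.05,
    },
    "integration": {"pairs_per_gene": 1},
}


def _merge_validate(defaults: Mapping[str, Any], user: Mapping[str, Any], path: str = "") -> dict:
    merged = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config section {path + key!r} must be a mapping")
            merged[key] = _merge_validate(defaults[key], value, path=f"{path}{key}.")
        else:
            merged[key] = value
    return merged


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    data: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, user: Mapping[str, Any] | None = None) -> "PipelineConfig":
        cfg = cls(_merge_validate(_DEFAULTS, user or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(user)

    def validate(self) -> None:
        th = self.data["thresholds"]
        if th["min_reads"] < 0:
            raise ConfigError("thresholds.min_reads must be >= 0")
        if not 0 < th["padj"] <= 1:
            raise ConfigError("thresholds.padj must lie in (0, 1]")
        if th["delta_min"] < 0:
            raise ConfigError("thresholds.delta_min must be >= 0")
        if self.data["smallrna"]["n_wt"] < 2 or self.data["smallrna"]["n_ko"] < 2:
            raise ConfigError("smallrna cohorts need >= 2 samples per genotype")
        # constructing AssignParams validates the assignment block
        self.assign_params()

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def assign_params(self) -> AssignParams:
        a = self.data["assign"]
        return AssignParams(
            min_ratio=a["min_ratio"],
            min_read=a["min_read"],
            edit_distance_3p=a["edit_distance_3p"],
            five_prime_tolerance=a["five_prime_tolerance"],
            retain_rule=a["retain_rule"],
        )

    def sha256(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig) -> list[str]:
    return [
        f"tailscope {__version__}",
        f"config_sha256={cfg.sha256()}",
        f"seed={cfg['seed']}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig | Mapping[str, Any]) -> dict[str, Any]:
    """Run every stage on synthetic inputs; returns the manifest dict.

    The manifest lists produced files and headline numbers and is also
    written to ``<outdir>/manifest.json``.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    cfg = config
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, str] = {}
    summary: dict[str, Any] = {}
    t0 = time.time()

    def _stage(name: str):
        logger.info("[%s] %.1fs elapsed", name, time.time() - t0)

    # -- reference ----------------------------------------------------------
    _stage("reference")
    rcfg = cfg["reference"]
    ref = simulate_reference(
        n_mirnas=rcfg["n_mirnas"], mature_len=rcfg["mature_len"],
        flank_len=rcfg["flank_len"], seed=seed,
    )

    # -- small-RNA simulation and profiling ---------------------------------
    _stage("smallrna")
    scfg = cfg["smallrna"]
    sim_params = SmallRNASimParams(
        n_mirnas=rcfg["n_mirnas"],
        depth=scfg["depth"],
        abundance_dispersion=scfg["abundance_dispersion"],
        p_canonical=scfg["p_canonical"],
        p_tail=scfg["p_tail"],
        p_templated=scfg["p_templated"],
        p_mixed=scfg["p_mixed"],
        trim_geom_p=scfg["trim_geom_p"],
        seed=seed,
    )
    fastqs, truth = simulate_smallrna_cohort(
        ref, sim_params, outdir / "fastq", n_wt=scfg["n_wt"], n_ko=scfg["n_ko"]
    )
    truth_path = outdir / "truth_manifest.json"
    truth.to_json(truth_path)
    produced["truth_manifest"] = str(truth_path)

    assign = cfg.assign_params()
    profiles = {}
    for sid, fq in fastqs.items():
        genotype = sid.split("_")[0]
        prof = profile_sample(ref, fq, assign, sample_id=sid, genotype=genotype)
        profiles[sid] = prof
        ppath = outdir / f"profile_{sid}.tsv"
        write_profile(prof, ppath, header_lines=_provenance(cfg))
        produced[f"profile_{sid}"] = str(ppath)

    # -- tail summaries and group tests -------------------------------------
    _stage("tails")
    frac_rows, freq_rows, comp_frames = [], [], []
    for sid, prof in profiles.items():
        cf = class_fractions(prof)
        frac_rows.append({"sample_id": sid, "genotype": prof.genotype, **cf.fractions})
        freq = nt_nucleotide_freq(prof, rna=True)
        freq_rows.append({"sample_id": sid, "genotype": prof.genotype, **freq})
        comp_frames.append(tail_length_composition(prof).to_frame())
    frac_df = pd.DataFrame(frac_rows).set_index("sample_id")
    freq_df = pd.DataFrame(freq_rows).set_index("sample_id")
    comp_df = pd.concat(comp_frames, ignore_index=True)
    _write_tsv(frac_df, outdir / "class_fractions.tsv", cfg)
    _write_tsv(freq_df, outdir / "nt_freq.tsv", cfg)
    _write_tsv(comp_df, outdir / "tail_composition.tsv", cfg, index=False)
    produced.update(
        class_fractions=str(outdir / "class_fractions.tsv"),
        nt_freq=str(outdir / "nt_freq.tsv"),
        tail_composition=str(outdir / "tail_composition.tsv"),
    )

    wt_ids = [s for s in profiles if profiles[s].genotype == "WT"]
    ko_ids = [s for s in profiles if profiles[s].genotype == "KO"]
    tests = []
    for stat, getter in [
        ("nt_tail_fraction", lambda s: frac_df.loc[s, "nt_tail"]),
        ("nt_A_frequency", lambda s: freq_df.loc[s, "A"]),
        ("nt_U_frequency", lambda s: freq_df.loc[s, "U"]),
    ]:
        gc = compare_groups(
            [getter(s) for s in wt_ids], [getter(s) for s in ko_ids],
            statistic_name=stat,
        )
        tests.append(
            {
                "statistic": stat,
                "wt_mean": float(np.mean(gc.group_values[0])),
                "ko_mean": float(np.mean(gc.group_values[1])),
                "p": gc.p,
                "method": gc.method,
                "significant": gc.significant,
            }
        )
    tests_df = pd.DataFrame(tests).set_index("statistic")
    _write_tsv(tests_df, outdir / "group_tests.tsv", cfg)
    produced["group_tests"] = str(outdir / "group_tests.tsv")
    summary["group_tests"] = {
        r: {"p": float(tests_df.loc[r, "p"])} for r in tests_df.index
    }

    # -- isomiR differential accumulation ------------------------------------
    _stage("isomir_de")
    iso_counts, iso_meta = isomir_count_matrix(profiles)
    iso_groups = {s: profiles[s].genotype for s in iso_counts.columns}
    iso_res = nb_wald_test(iso_counts, iso_groups, reference="WT", pseudo_reference_sf=True)
    iso_res = call_differential(
        iso_res, padj_max=cfg["thresholds"]["padj"], lfc_min=cfg["thresholds"]["lfc"]
    )
    iso_out = iso_meta.join(iso_res)
    _write_tsv(iso_out, outdir / "isomir_de.tsv", cfg)
    produced["isomir_de"] = str(outdir / "isomir_de.tsv")
    summary["isomir_de_called"] = int(iso_res["called"].sum())

    corr_table, monoA_r, monoA_p = monoA_canonical_correlation(profiles)
    _write_tsv(corr_table, outdir / "monoA_canonical_corr.tsv", cfg, index=False)
    produced["monoA_canonical_corr"] = str(outdir / "monoA_canonical_corr.tsv")
    summary["monoA_canonical_r"] = None if np.isnan(monoA_r) else float(monoA_r)

    # -- gene-level differential expression ----------------------------------
    _stage("gene_de")
    ccfg = cfg["counts"]
    planted = [
        (f"G{i:04d}", ccfg["planted_lfc"] * (1 if i % 2 else -1))
        for i in range(1, ccfg["n_planted"] + 1)
    ]
    gene_counts, gene_truth = simulate_count_matrix(
        ccfg["n_genes"], ccfg["n_per_group"], planted, ccfg["nb_dispersion"],
        seed + 1000,
    )
    truth.merge(gene_truth)
    truth.to_json(truth_path)
    gene_groups = {c: c.split("_")[0] for c in gene_counts.columns}
    gene_res = nb_wald_test(gene_counts, gene_groups, reference="WT")
    gene_res = call_differential(gene_res, padj_max=cfg["thresholds"]["padj"], lfc_min=0.0)
    _write_tsv(gene_res, outdir / "gene_de.tsv", cfg)
    produced["gene_de"] = str(outdir / "gene_de.tsv")
    de_genes = set(gene_res.index[gene_res["called"]])
    summary["gene_de_called"] = len(de_genes)
    summary["gene_de_up"] = int((gene_res["called"] & (gene_res["log2fc"] > 0)).sum())
    summary["gene_de_down"] = int((gene_res["called"] & (gene_res["log2fc"] < 0)).sum())

    # -- poly(A) tail lengths -------------------------------------------------
    _stage("polya")
    pcfg = cfg["polya"]
    tnames = [f"T{i:04d}" for i in range(1, pcfg["n_transcripts"] + 1)]
    shifted = {t: pcfg["shift"] for t in tnames[: pcfg["n_shifted"]]}
    polya_params = PolyASimParams(
        n_transcripts=pcfg["n_transcripts"],
        reads_per_transcript=(pcfg["reads_mean"], pcfg["reads_dispersion"]),
        shifted_set=shifted,
        qc_fail_rate=pcfg["qc_fail_rate"],
        seed=seed + 2000,
    )
    wt_tsv, ko_tsv, polya_truth = simulate_polya_tables(
        polya_params, outdir / "polya_wt.tsv", outdir / "polya_ko.tsv"
    )
    truth.merge(polya_truth)
    truth.to_json(truth_path)
    wt_reads = read_polya_table(wt_tsv)
    ko_reads = read_polya_table(ko_tsv)
    polya_res = per_transcript_test(
        wt_reads, ko_reads,
        min_reads=cfg["thresholds"]["min_reads"],
        delta_min=cfg["thresholds"]["delta_min"],
        padj_max=cfg["thresholds"]["padj"],
    )
    _write_tsv(polya_res, outdir / "polya_per_transcript.tsv", cfg)
    produced["polya_per_transcript"] = str(outdir / "polya_per_transcript.tsv")
    glob_rows = []
    for name, reads, subset in [
        ("WT_all", wt_reads, None),
        ("KO_all", ko_reads, None),
        ("WT_shifted_set", wt_reads, sorted(shifted)),
        ("KO_shifted_set", ko_reads, sorted(shifted)),
    ]:
        glob_rows.append({"stratum": name, **global_distribution(reads, subset)})
    glob_df = pd.DataFrame(glob_rows).set_index("stratum")
    _write_tsv(glob_df, outdir / "polya_global.tsv", cfg)
    produced["polya_global"] = str(outdir / "polya_global.tsv")
    summary["polya_significant"] = int(polya_res["significant"].sum())
    summary["polya_global_median_wt"] = float(glob_df.loc["WT_all", "median"])
    summary["polya_global_median_ko"] = float(glob_df.loc["KO_all", "median"])

    # -- miRNA:target integration ---------------------------------------------
    _stage("integration")
    monoA_mirnas = sorted(
        iso_meta[(iso_meta["iso_class"] == NT_TAIL) & (iso_meta["ext_seq"] == "A")][
            "mirna"
        ].unique()
    )
    pairs_path = outdir / "pairs.tsv"
    with open(pairs_path, "w") as fh:
        fh.write("mirna\tgene\n")
        de_sorted = sorted(de_genes)
        if de_sorted and monoA_mirnas:
            for i, gene in enumerate(de_sorted):
                for k in range(cfg["integration"]["pairs_per_gene"]):
                    mir = monoA_mirnas[(i + k) % len(monoA_mirnas)]
                    fh.write(f"{mir}\t{gene}\n")
    produced["pairs"] = str(pairs_path)

    pairs = load_pairs(pairs_path)
    records = []
    if pairs:
        pairs = filter_to_monoA_and_de(pairs, set(monoA_mirnas), de_genes)
        gene_sf = size_factors(gene_counts, pseudo_reference=True)
        gene_norm = gene_counts.div(gene_sf, axis=1)
        iso_sf = size_factors(iso_counts, pseudo_reference=True)
        iso_norm = iso_counts.div(iso_sf, axis=1)
        monoA_feature = {
            m: fid
            for fid, row in iso_meta.iterrows()
            if row["iso_class"] == NT_TAIL and row["ext_seq"] == "A"
            for m in [row["mirna"]]
        }
        mirna_norm = iso_norm.loc[[monoA_feature[m] for m in monoA_mirnas]]
        mirna_norm.index = monoA_mirnas
        matched = sorted(set(mirna_norm.columns) & set(gene_norm.columns))
        records = correlate(
            pairs, mirna_norm, gene_norm,
            matched_samples=matched if len(matched) >= 3 else None,
            mirna_lfc={
                m: float(iso_res.loc[monoA_feature[m], "log2fc"]) for m in monoA_mirnas
            },
            gene_lfc=gene_res["log2fc"].to_dict(),
        )
    rec_df = pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["mirna", "gene", "pearson_r", "r_p", "lfc_mirna", "lfc_gene", "sign_class"],
    )
    _write_tsv(rec_df, outdir / "interactions.tsv", cfg, index=False)
    produced["interactions"] = str(outdir / "interactions.tsv")
    summary["interaction_fractions"] = interaction_summary(records)

    # -- manifest -------------------------------------------------------------
    manifest = {
        "tool": "tailscope",
        "version": __version__,
        "config_sha256": cfg.sha256(),
        "seed": seed,
        "config": cfg.data,
        "files": produced,
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return manifest
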