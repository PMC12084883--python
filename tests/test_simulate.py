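"""Determinism and parameter fidelity of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from tailscope.isomir import AssignParams, profile_sample
from tailscope.polya import read_polya_table
from tailscope.simulate import (
    PolyASimParams,
    SmallRNASimParams,
    TruthManifest,
    simulate_count_matrix,
    simulate_polya_tables,
    simulate_reference,
    simulate_repressive_pairs,
    simulate_smallrna_sample,
)


@pytest.fixture(scope="module")
def sim_ref():
    return simulate_reference(n_mirnas=10, seed=42)


def test_simulated_reference_is_valid_and_deterministic(sim_ref):
    again = simulate_reference(n_mirnas=10, seed=42)
    assert again.matures == sim_ref.matures
    assert len(sim_ref.matures) == 10
    # unique motifs by construction
    assert all(len(v) == 1 for v in sim_ref.motif_index.values())


def test_degenerate_all_canonical(sim_ref, tmp_path):
    params = SmallRNASimParams(n_mirnas=10, depth=500, p_canonical=1.0, seed=1)
    fq, _ = simulate_smallrna_sample(sim_ref, params, "WT", tmp_path / "c.fastq")
    matures = {m.seq for m in sim_ref.matures.values()}
    seqs = fq.read_text().splitlines()[1::4]
    assert set(seqs) <= matures


def test_same_seed_byte_identical_fastq(sim_ref, tmp_path):
    params = SmallRNASimParams(n_mirnas=10, depth=2000, seed=5)
    fq1, _ = simulate_smallrna_sample(sim_ref, params, "KO", tmp_path / "a.fastq")
    fq2, _ = simulate_smallrna_sample(sim_ref, params, "KO", tmp_path / "b.fastq")
    assert fq1.read_bytes() == fq2.read_bytes()


def test_nt_emission_recovered_at_depth(sim_ref, tmp_path):
    emission = {"WT": (0.7, 0.05, 0.05, 0.2), "KO": (0.45, 0.1, 0.05, 0.4)}
    params = SmallRNASimParams(
        n_mirnas=10, depth=100_000, nt_emission=emission, seed=9
    )
    _, truth = simulate_smallrna_sample(sim_ref, params, "WT", tmp_path / "w.fastq")
    frag = truth.smallrna["WT_0"]
    counts = frag["realized_nt_base_counts"]
    total = sum(counts.values())
    assert counts["A"] / total == pytest.approx(0.7, abs=0.02)


def test_truth_manifest_round_trips(sim_ref, tmp_path):
    params = SmallRNASimParams(n_mirnas=10, depth=1000, seed=2)
    _, truth = simulate_smallrna_sample(sim_ref, params, "WT", tmp_path / "t.fastq")
    path = tmp_path / "truth.json"
    truth.to_json(path)
    again = TruthManifest.from_json(path)
    assert again.smallrna == truth.smallrna


def test_expected_observed_fractions_match_classifier(sim_ref, tmp_path):
    """The manifest's analytic class fractions match what the pipeline sees."""
    params = SmallRNASimParams(n_mirnas=10, depth=50_000, seed=3)
    fq, truth = simulate_smallrna_sample(sim_ref, params, "WT", tmp_path / "e.fastq")
    prof = profile_sample(
        sim_ref, fq, AssignParams(min_read=1, min_ratio=0.0), "WT_0", "WT"
    )
    assert prof.n_unassigned == 0  # bounded trims/tails always pass the gate
    expected = truth.expected_observed_class_fractions("WT_0")
    observed = {k: v / prof.n_assigned for k, v in prof.by_class().items()}
    for cls in expected:
        assert observed[cls] == pytest.approx(expected[cls], abs=0.01), cls


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SmallRNASimParams(p_canonical=1.5)
    with pytest.raises(ValueError):
        SmallRNASimParams(nt_emission={"WT": (0.5, 0.5, 0.5, 0.5)})
    with pytest.raises(ValueError):
        PolyASimParams(qc_fail_rate=-0.1)
    with pytest.raises(ValueError):
        PolyASimParams(n_transcripts=5, shifted_set={"T9999": -10})


def test_polya_tables_deterministic_and_tagged(tmp_path):
    params = PolyASimParams(n_transcripts=10, qc_fail_rate=0.3, seed=11)
    wt1, ko1, _ = simulate_polya_tables(params, tmp_path / "w1.tsv", tmp_path / "k1.tsv")
    wt2, _, _ = simulate_polya_tables(params, tmp_path / "w2.tsv", tmp_path / "k2.tsv")
    assert wt1.read_bytes() == wt2.read_bytes()
    df = pd.read_csv(wt1, sep="\t")
    frac_fail = 1 - df["qc_tag"].isin(["PASS", "SUFFCLIP"]).mean()
    assert frac_fail == pytest.approx(0.3, abs=0.03)


def test_polya_null_medians_close(tmp_path):
    params = PolyASimParams(n_transcripts=8, shifted_set={}, seed=4)
    wt, ko, _ = simulate_polya_tables(params, tmp_path / "w.tsv", tmp_path / "k.tsv")
    med_wt = np.median([r.polya_length for r in read_polya_table(wt)])
    med_ko = np.median([r.polya_length for r in read_polya_table(ko)])
    assert abs(med_wt - med_ko) < 3  # stochastic only


def test_polya_planted_shift_moves_median(tmp_path):
    params = PolyASimParams(
        n_transcripts=4, shifted_set={"T0001": -10.0}, qc_fail_rate=0.0, seed=8
    )
    _, ko, truth = simulate_polya_tables(params, tmp_path / "w.tsv", tmp_path / "k.tsv")
    reads = [r for r in read_polya_table(ko) if r.contig == "T0001"]
    expected = truth.polya["transcripts"]["T0001"]["median_expected_ko"]
    assert expected == pytest.approx(params.baseline_logmean and np.exp(4.6) - 10)
    assert np.median([r.polya_length for r in reads]) == pytest.approx(expected, rel=0.05)


def test_count_matrix_null_groups_balanced():
    df, truth = simulate_count_matrix(300, 4, [], 0.05, seed=1)
    sf = pd.Series(truth.counts["size_factors"])
    norm = df / sf[df.columns]
    ratio = np.log2((norm.filter(like="KO").sum().sum() + 1) /
                    (norm.filter(like="WT").sum().sum() + 1))
    assert abs(ratio) < 0.1
    assert set(truth.counts["planted"]) == set()


def test_count_matrix_planted_ratio_and_determinism():
    planted = [("G0001", 3.0)]
    df1, truth = simulate_count_matrix(
        200, 50, planted, 0.05, seed=7, planted_base_mean=100.0
    )
    df2, _ = simulate_count_matrix(
        200, 50, planted, 0.05, seed=7, planted_base_mean=100.0
    )
    pd.testing.assert_frame_equal(df1, df2)
    sf = pd.Series(truth.counts["size_factors"])
    norm = df1.loc["G0001"] / sf[df1.columns]
    ratio = np.log2(norm.filter(like="KO").mean() / norm.filter(like="WT").mean())
    assert ratio == pytest.approx(3.0, abs=0.3)


def test_planted_gene_outside_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        simulate_count_matrix(10, 3, [("G9999", 2.0)], 0.05, seed=0)


def test_repressive_pairs_anticorrelated():
    mdf, gdf, pairs, _ = simulate_repressive_pairs(10, n_samples=8, seed=3)
    for mir, gene in pairs:
        r = np.corrcoef(mdf.loc[mir], gdf.loc[gene])[0, 1]
        assert r < 0
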