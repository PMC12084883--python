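"""Size factors, NB Wald testing, BH adjustment and threshold calls."""

import numpy as np
import pandas as pd
import pytest

from tailscope.differential import (
    benjamini_hochberg,
    call_differential,
    isomir_count_matrix,
    monoA_canonical_correlation,
    nb_wald_test,
    size_factors,
)
from tailscope.isomir import CANONICAL, NT_TAIL, IsomiRRecord, SampleProfile
from tailscope.simulate import simulate_count_matrix


def _df(rows, columns=None):
    return pd.DataFrame(rows, columns=columns or [f"s{i}" for i in range(len(rows[0]))])


# -- size factors ------------------------------------------------------------


def test_identical_columns_unit_factors():
    sf = size_factors(_df([[10, 10], [5, 5], [7, 7]]))
    assert np.allclose(sf, 1.0)


def test_worked_median_of_ratios_example():
    sf = size_factors(_df([[10, 20], [20, 40], [30, 60]]))
    assert sf.round(4).tolist() == [0.7071, 1.4142]


def test_scale_equivariance_of_factor_ratios():
    # factors are defined up to the geometric-mean reference, so scaling one
    # column by c multiplies its factor relative to any other column by c
    base = _df([[10, 20], [20, 40], [30, 60]])
    scaled = base.copy()
    scaled["s1"] = scaled["s1"] * 3
    sf0, sf1 = size_factors(base), size_factors(scaled)
    assert sf1["s1"] / sf1["s0"] == pytest.approx(3 * sf0["s1"] / sf0["s0"])


def test_order_invariance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.poisson(50, size=(40, 4)), columns=list("abcd"))
    sf = size_factors(df)
    perm = df.sample(frac=1, random_state=1)[list("dcab")]
    sf_perm = size_factors(perm)
    for c in "abcd":
        assert sf_perm[c] == pytest.approx(sf[c])


def test_no_common_positive_feature_suggests_fallback():
    df = _df([[5, 0], [0, 5]])
    with pytest.raises(ValueError, match="pseudo_reference"):
        size_factors(df)
    sf = size_factors(df, pseudo_reference=True)
    assert (sf > 0).all()


# -- BH ----------------------------------------------------------------------


def _bh_bruteforce(p):
    """Direct step-up definition: padj_i = min over j>=rank_i of p_(j)*n/j."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


@pytest.mark.parametrize("seed", range(5))
def test_bh_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(1, 20))
    assert np.allclose(benjamini_hochberg(p), _bh_bruteforce(p))


def test_bh_monotone_in_p_rank():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=15)
    adj = benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


# -- NB Wald -----------------------------------------------------------------


def test_flat_feature_not_significant():
    df = pd.DataFrame(
        {f"WT_{i}": [100, 50] for i in range(1, 4)}
        | {f"KO_{i}": [100, 50] for i in range(1, 4)}
    )
    groups = {c: c.split("_")[0] for c in df.columns}
    res = nb_wald_test(df, groups, reference="WT")
    assert abs(res["log2fc"]).max() < 1e-6
    assert (res["p"] > 0.5).all()


def test_log2fc_sign_matches_normalized_mean_difference():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        rng.poisson(40, size=(30, 8)),
        columns=[f"WT_{i}" for i in range(4)] + [f"KO_{i}" for i in range(4)],
    )
    groups = {c: c.split("_")[0] for c in df.columns}
    sf = size_factors(df)
    res = nb_wald_test(df, groups, reference="WT", sf=sf)
    norm = df / sf
    diff = norm.filter(like="KO").mean(axis=1) - norm.filter(like="WT").mean(axis=1)
    nz = df.sum(axis=1) > 0
    assert (np.sign(res.loc[nz, "log2fc"]) == np.sign(diff[nz])).all()


def test_all_zero_features_excluded_from_bh():
    df = pd.DataFrame(
        {
            "WT_1": [0, 10], "WT_2": [0, 12],
            "KO_1": [0, 11], "KO_2": [0, 9],
        }
    )
    res = nb_wald_test(df, {c: c.split("_")[0] for c in df.columns})
    assert np.isnan(res.iloc[0]["p"]) and np.isnan(res.iloc[0]["padj"])
    assert np.isfinite(res.iloc[1]["p"])


def test_planted_large_effect_called():
    planted = [("G0001", 3.0)]
    df, _ = simulate_count_matrix(500, 5, planted, 0.05, seed=2, planted_base_mean=100.0)
    res = nb_wald_test(df, {c: c.split("_")[0] for c in df.columns}, reference="WT")
    res = call_differential(res, padj_max=0.05, lfc_min=1.0)
    assert bool(res.loc["G0001", "called"])
    assert res.loc["G0001", "log2fc"] == pytest.approx(3.0, abs=0.7)


@pytest.mark.parametrize(
    "padj,lfc,called", [(0.049, 1.01, True), (0.049, 0.99, False), (0.051, 2.0, False)]
)
def test_call_thresholds_are_strict(padj, lfc, called):
    res = pd.DataFrame(
        {"base_mean": [10.0], "log2fc": [lfc], "p": [padj / 2], "padj": [padj]},
        index=["f"],
    )
    out = call_differential(res, padj_max=0.05, lfc_min=1.0)
    assert bool(out["called"].iloc[0]) is called


def test_call_on_empty_results():
    res = pd.DataFrame(columns=["base_mean", "log2fc", "p", "padj"])
    out = call_differential(res)
    assert out.empty


# -- isomiR matrices and mono(A) correlation ---------------------------------


def _mk_profile(sample_id, genotype, mono_count, canon_count):
    mat = "A" * 20
    recs = [
        IsomiRRecord("m1", mat, canon_count, CANONICAL, 0, "", False),
        IsomiRRecord("m1", mat + "A", mono_count, NT_TAIL, 0, "A", False),
    ]
    return SampleProfile(sample_id, genotype, recs)


def test_isomir_count_matrix_layout():
    profiles = {
        "WT_1": _mk_profile("WT_1", "WT", 5, 50),
        "KO_1": _mk_profile("KO_1", "KO", 2, 60),
    }
    counts, meta = isomir_count_matrix(profiles)
    assert counts.shape == (2, 2)
    assert set(meta["iso_class"]) == {CANONICAL, NT_TAIL}
    assert counts.loc["m1|" + "A" * 20, "KO_1"] == 60


def test_monoA_correlation_too_few_mirnas_is_nan():
    profiles = {
        "WT_1": _mk_profile("WT_1", "WT", 5, 50),
        "WT_2": _mk_profile("WT_2", "WT", 6, 52),
        "KO_1": _mk_profile("KO_1", "KO", 2, 60),
        "KO_2": _mk_profile("KO_2", "KO", 3, 55),
    }
    with pytest.warns(UserWarning, match="correlation undefined"):
        table, r, p = monoA_canonical_correlation(profiles)
    assert len(table) == 1 and np.isnan(r)


def test_monoA_correlation_perfect_anticorrelation():
    mat = {f"m{i}": ("ACGT" * 5)[:20] for i in range(6)}
    # construct per-miRNA mono(A) changes exactly opposite to canonical changes
    def prof(sid, genotype, factor):
        recs = []
        for i in range(6):
            m = f"m{i}"
            seq = mat[m][:-1] + "ACGTAC"[i]  # distinct seqs per miRNA
            canon = int(100 * (2 ** (i * 0.2 if genotype == "KO" else 0)) * factor)
            mono = int(100 * (2 ** (-i * 0.2 if genotype == "KO" else 0)) * factor)
            recs.append(IsomiRRecord(m, seq, canon, CANONICAL, 0, "", False))
            recs.append(IsomiRRecord(m, seq + "A", mono, NT_TAIL, 0, "A", False))
        return SampleProfile(sid, genotype, recs)

    profiles = {
        "WT_1": prof("WT_1", "WT", 1.0),
        "WT_2": prof("WT_2", "WT", 1.0),
        "KO_1": prof("KO_1", "KO", 1.0),
        "KO_2": prof("KO_2", "KO", 1.0),
    }
    table, r, p = monoA_canonical_correlation(profiles)
    assert len(table) == 6
    assert r < -0.9
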