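"""Row-wise differential tests, the substrate filter, and set overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cmaflux import QuantMatrix, call_substrates, overlap, rowwise_test
from cmaflux.simulate import NLConfig, make_nl_experiment


def test_welch_rowwise_matches_scipy_scalar_oracle(small_quant):
    """Vectorized Welch t per protein agrees with scipy's scalar test to 12
    significant digits on complete data."""
    res = rowwise_test(small_quant, design="unpaired")
    x = small_quant.intensities
    for pid in ["P1", "P3"]:
        nl = x.loc[pid, ["n1", "n2", "n3"]]
        ct = x.loc[pid, ["c1", "c2", "c3"]]
        t_ref, p_ref = sps.ttest_ind(nl, ct, equal_var=False)
        assert res.loc[pid, "t"] == pytest.approx(t_ref, rel=1e-12)
        assert res.loc[pid, "p_value"] == pytest.approx(p_ref, rel=1e-12)
        assert res.loc[pid, "log2_fc"] == pytest.approx(nl.mean() - ct.mean(), rel=1e-12)
    assert res.loc["P1", "log2_fc"] == pytest.approx(1.0, abs=1e-12)


def test_paired_rowwise_matches_scipy_scalar_oracle():
    rng = np.random.default_rng(5)
    donors = [f"D{i}" for i in range(1, 6)]
    cols, rows = [], {}
    intens = pd.DataFrame(
        rng.normal(20, 1, size=(20, 10)),
        index=[f"P{i}" for i in range(20)],
        columns=[f"{d}_{c}" for d in donors for c in ("control", "NL")],
    )
    design = pd.DataFrame(
        [
            {"sample": f"{d}_{c}", "condition": c, "donor": d}
            for d in donors
            for c in ("control", "NL")
        ]
    ).set_index("sample")
    quant = QuantMatrix(intensities=intens, design=design, scale="log2")
    res = rowwise_test(quant)  # donors present -> paired by default
    for pid in intens.index:
        nl = intens.loc[pid, [f"{d}_NL" for d in donors]].to_numpy()
        ct = intens.loc[pid, [f"{d}_control" for d in donors]].to_numpy()
        t_ref, p_ref = sps.ttest_rel(nl, ct)
        assert res.loc[pid, "t"] == pytest.approx(t_ref, rel=1e-12)
        assert res.loc[pid, "p_value"] == pytest.approx(p_ref, rel=1e-12)


def test_identical_groups_and_degenerate_variance(small_quant):
    res = rowwise_test(small_quant, design="unpaired")
    # P2 is constant everywhere: log2FC 0, t 0, p 1, flagged
    assert res.loc["P2", "log2_fc"] == 0.0
    assert res.loc["P2", "t"] == 0.0
    assert res.loc["P2", "p_value"] == 1.0
    assert res.loc["P2", "flag"] == "degenerate_variance"


def test_zero_variance_with_shift_reports_limiting_p():
    intens = pd.DataFrame(
        {"c1": [10.0], "c2": [10.0], "n1": [11.0], "n2": [11.0]}, index=["P1"]
    )
    design = pd.DataFrame(
        {"condition": ["control", "control", "NL", "NL"]},
        index=["c1", "c2", "n1", "n2"],
    ).rename_axis("sample")
    res = rowwise_test(QuantMatrix(intens, design, scale="log2"), design="unpaired")
    assert res.loc["P1", "p_value"] == 0.0
    assert res.loc["P1", "flag"] == "degenerate_variance"
    assert np.isposinf(res.loc["P1", "t"])


def test_one_condition_only_and_insufficient_n_flags():
    intens = pd.DataFrame(
        {
            "c1": [10.0, np.nan, 10.0],
            "c2": [10.2, np.nan, np.nan],
            "n1": [11.0, 12.0, 11.0],
            "n2": [11.2, 12.1, 11.1],
        },
        index=["ok", "nl_only", "too_few"],
    )
    design = pd.DataFrame(
        {"condition": ["control", "control", "NL", "NL"]},
        index=["c1", "c2", "n1", "n2"],
    ).rename_axis("sample")
    res = rowwise_test(QuantMatrix(intens, design, scale="log2"), design="unpaired")
    assert res.loc["ok", "flag"] == ""
    assert res.loc["nl_only", "flag"] == "one_condition_only"
    assert np.isnan(res.loc["nl_only", "p_value"])
    assert res.loc["too_few", "flag"] == "insufficient_n"


def test_raw_scale_median_centering_removes_sample_offsets():
    rng = np.random.default_rng(9)
    base = rng.uniform(10, 20, size=50)
    cols = {}
    design_rows = []
    for i, cond in enumerate(["control"] * 3 + ["NL"] * 3):
        # multiplicative (raw-scale) per-sample factor: removed by centering
        cols[f"s{i}"] = 2.0 ** (base + rng.normal(0, 0.05, 50) + (1.5 if i == 3 else 0.0))
        design_rows.append({"sample": f"s{i}", "condition": cond})
    quant = QuantMatrix(
        pd.DataFrame(cols, index=[f"P{i}" for i in range(50)]),
        pd.DataFrame(design_rows).set_index("sample"),
        scale="raw",
    )
    res = rowwise_test(quant, design="unpaired", normalize=True)
    assert res["log2_fc"].abs().median() < 0.1
    res_raw = rowwise_test(quant, design="unpaired", normalize=False)
    assert res_raw["log2_fc"].median() > 0.3  # offset leaks through without centering


def _diff_frame(rows):
    return pd.DataFrame(rows).set_index("protein")


def test_call_substrates_toy_filter():
    """FC > 1.25, p < 0.01, motif+ — each condition rejects exactly one protein."""
    diff = _diff_frame(
        [
            {"protein": "P1", "log2_fc": np.log2(1.5), "p_value": 0.001},
            {"protein": "P2", "log2_fc": np.log2(1.5), "p_value": 0.02},
            {"protein": "P3", "log2_fc": np.log2(1.2), "p_value": 0.001},
            {"protein": "P4", "log2_fc": np.log2(1.5), "p_value": 0.001},
        ]
    )
    motifs = {"P1": True, "P2": True, "P3": True, "P4": False}
    call = call_substrates(diff, motifs)
    assert call.proteins == frozenset({"P1"})

    # filter identity: trivial thresholds call every enriched motif+ protein
    all_motif = dict.fromkeys(motifs, True)
    call_all = call_substrates(diff, all_motif, fc_min=1.0, p_max=1.0)
    assert call_all.proteins == frozenset({"P1", "P2", "P3", "P4"})


def test_call_substrates_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    diff = _diff_frame(
        [
            {"protein": f"P{i}", "log2_fc": rng.normal(0, 1), "p_value": rng.random()}
            for i in range(200)
        ]
    )
    motifs = {f"P{i}": bool(rng.random() < 0.5) for i in range(200)}
    tight = call_substrates(diff, motifs, fc_min=1.5, p_max=0.01)
    loose = call_substrates(diff, motifs, fc_min=1.1, p_max=0.1)
    assert tight.proteins <= loose.proteins


def test_call_substrates_threshold_bounds():
    diff = _diff_frame([{"protein": "P1", "log2_fc": 1.0, "p_value": 0.001}])
    with pytest.raises(ValueError):
        call_substrates(diff, {"P1": True}, fc_min=0.0)
    with pytest.raises(ValueError):
        call_substrates(diff, {"P1": True}, p_max=1.5)


def test_overlap_identities():
    a, b = {"x", "y", "z"}, {"x", "y", "z"}
    assert overlap(a, b).jaccard == 1.0
    assert overlap({"a"}, {"b"}).jaccard == 0.0
    assert overlap(set(), set()).jaccard == 0.0

    rng = np.random.default_rng(0)
    a = {f"p{i}" for i in rng.integers(0, 100, 40)}
    b = {f"p{i}" for i in rng.integers(0, 100, 40)}
    res = overlap(a, b)
    assert res.union == res.size_a + res.size_b - res.intersection
    assert res.jaccard == overlap(b, a).jaccard


def test_substrate_set_overlap_printed_sizes():
    """Sets of 171 and 328 proteins sharing 118 members give Jaccard 0.3097."""
    shared = {f"S{i}" for i in range(118)}
    healthy = shared | {f"H{i}" for i in range(171 - 118)}
    amd = shared | {f"A{i}" for i in range(328 - 118)}
    res = overlap(healthy, amd)
    assert (res.size_a, res.size_b, res.intersection) == (171, 328, 118)
    assert round(res.jaccard, 4) == 0.3097
    # 118 is the unique integer intersection consistent with the printed index
    consistent = [
        k for k in range(0, 172) if round(k / (171 + 328 - k), 4) == 0.3097
    ]
    assert consistent == [118]


def test_null_experiments_call_rate_within_nominal_filter():
    """200 simulated null N/L experiments: the fraction of tested motif+
    proteins called at p < 0.01 stays within the nominal type-I budget (the
    joint filter also requires FC > 1.25, so the rate can only be lower)."""
    cfg = NLConfig(n_proteins=200, frac_substrates=0.0, accumulation_fc=1.0,
                   noise_sd=0.1, n_donors=5)
    rates = []
    for seed in range(200):
        quant, truth, motifs = make_nl_experiment(cfg, seed=seed)
        diff = rowwise_test(quant)
        call = call_substrates(diff, motifs)
        n_motif_tested = sum(
            motifs[p] for p in diff.index[diff["p_value"].notna()]
        )
        rates.append(len(call.proteins) / max(n_motif_tested, 1))
    # three Monte-Carlo standard errors above the nominal 1% ceiling
    mc_se = np.std(rates) / np.sqrt(len(rates))
    assert np.mean(rates) <= 0.01 + 3 * mc_se


def test_planted_substrate_recovery_single_experiment():
    """High signal-to-noise N/L design: the caller recovers planted truth."""
    cfg = NLConfig(n_proteins=500, frac_substrates=0.1, accumulation_fc=2.0,
                   noise_sd=0.1, n_donors=5)
    quant, truth, motifs = make_nl_experiment(cfg, seed=11)
    diff = rowwise_test(quant)
    call = call_substrates(diff, motifs)
    truth_ids = set(truth.loc[truth["is_substrate"], "protein_id"])
    tp = len(call.proteins & truth_ids)
    sens = tp / len(truth_ids)
    fdr = (call.n - tp) / max(call.n, 1)
    assert sens >= 0.9
    assert fdr <= 0.1
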