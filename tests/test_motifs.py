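"""Motif scanner: rule examples, oracle equivalence, and abundance summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cmaflux import (
    DEFAULT_RULES,
    MotifRuleSet,
    ProteinRecord,
    classify_window,
    compare_to_reference,
    read_fasta,
    scan_collection,
    scan_protein,
    summarize_collection,
    write_fasta,
)
from cmaflux.motifs import ACETYL, CANONICAL, PHOSPHO

from oracles import (
    brute_force_classify,
    brute_force_scan,
    exhaustive_canonical_count,
    fisher_two_sided,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def calls_as_tuples(calls):
    return {(c.motif_class, c.anchor_terminus, c.ptm_position) for c in calls}


@pytest.mark.parametrize(
    "window,expected",
    [
        # the eponymous motif: K,R positive x2, F hydrophobic, E negative, right Q
        ("KFERQ", {(CANONICAL, "right", None)}),
        ("AAAAA", set()),  # no anchor, no classed residues
        # S recounted as the acidic residue completes the composition
        ("QKILS", {(PHOSPHO, "left", 4)}),
        # terminal K as acetyl-Q mimic; both termini qualify by composition
        ("KFERK", {(ACETYL, "left", 0), (ACETYL, "right", 4)}),
        # right-anchor K does not fire: the remaining Q is an unclassed residue
        ("QFERK", {(CANONICAL, "left", None)}),
        ("QQQQQ", set()),  # second Q is an unclassed residue
    ],
)
def test_classify_window_examples(window, expected):
    assert calls_as_tuples(classify_window(window)) == expected
    assert brute_force_classify(window) == expected


def test_classify_window_rejects_wrong_length_and_voids_ambiguity():
    with pytest.raises(ValueError):
        classify_window("KFER")
    assert classify_window("KFXRQ") == set()
    assert classify_window("KFERQ".lower().upper()) != set()


def test_canonical_never_doubles_as_phospho_at_same_anchor():
    # KFSRQ: S recounted as acidic completes the composition
    assert calls_as_tuples(classify_window("KFSRQ")) == {(PHOSPHO, "right", 2)}
    # KFESQ: substitution would yield two acidic residues, so no motif
    assert classify_window("KFESQ") == set()
    # a canonical window reports canonical only at that anchor
    assert calls_as_tuples(classify_window("KFERQ")) == {(CANONICAL, "right", None)}


def test_scan_protein_examples():
    assert len(scan_protein(ProteinRecord("p", "KFERQ"))) == 1
    assert scan_protein(ProteinRecord("p", "KFE")) == []
    hits = scan_protein(ProteinRecord("p", "KFERQKFERQ"))
    starts = {(h.start, h.motif_class) for h in hits}
    # hand enumeration of all six windows via the oracle
    expected = {(s, c) for s, c, _t, _p in brute_force_scan("KFERQKFERQ")}
    assert starts == expected
    assert (0, CANONICAL) in starts and (5, CANONICAL) in starts
    assert [h.start for h in hits] == sorted(h.start for h in hits)


def test_scan_collection_rejects_duplicate_ids():
    recs = [ProteinRecord("a", "KFERQ"), ProteinRecord("a", "AAAAA")]
    with pytest.raises(ValueError, match="duplicate"):
        scan_collection(recs)


def test_oracle_equivalence_on_random_sequences():
    """Scanner output equals the exhaustive window/composition oracle on
    1000 random sequences."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        length = int(rng.integers(0, 61))
        seq = "".join(rng.choice(list(AA), size=length))
        got = [
            (h.start, h.motif_class, h.anchor_terminus, h.ptm_position)
            for h in scan_protein(ProteinRecord("r", seq))
        ]
        assert sorted(got) == sorted(brute_force_scan(seq)), seq


def test_concatenation_only_creates_junction_hits():
    rng = np.random.default_rng(7)
    for _ in range(50):
        a = "".join(rng.choice(list(AA), size=int(rng.integers(5, 30))))
        b = "".join(rng.choice(list(AA), size=int(rng.integers(5, 30))))
        hits_a = {(h.start, h.motif_class, h.anchor_terminus) for h in scan_protein(ProteinRecord("a", a))}
        hits_b = {
            (h.start + len(a), h.motif_class, h.anchor_terminus)
            for h in scan_protein(ProteinRecord("b", b))
        }
        hits_ab = {(h.start, h.motif_class, h.anchor_terminus) for h in scan_protein(ProteinRecord("ab", a + b))}
        assert hits_a | hits_b <= hits_ab
        for start, _cls, _t in hits_ab - (hits_a | hits_b):
            assert len(a) - 4 <= start < len(a)  # within 4 residues of the junction


def test_class_logic_invariants():
    rng = np.random.default_rng(11)
    for _ in range(2000):
        w = "".join(rng.choice(list(AA), size=5))
        calls = calls_as_tuples(classify_window(w))
        for cls, term, _p in calls:
            if cls == PHOSPHO:
                assert (CANONICAL, term, None) not in calls
            if cls == ACETYL:
                idx = 0 if term == "left" else 4
                assert w[idx] != "Q"


def test_exact_canonical_window_frequency():
    """Fraction of canonical 5-mers over all 20^5 windows: vectorized full
    enumeration equals the combinatorial closed form, and sampled estimates
    converge within binomial error."""
    letters = np.frombuffer(AA.encode(), dtype=np.uint8)
    # class codes: 1 hydrophobic, 2 positive, 3 negative, 4 anchor Q, 0 other
    code = np.zeros(256, dtype=np.int8)
    for c in "FILV":
        code[ord(c)] = 1
    for c in "KR":
        code[ord(c)] = 2
    for c in "ED":
        code[ord(c)] = 3
    code[ord("Q")] = 4

    grids = np.meshgrid(*([code[letters]] * 5), indexing="ij")
    stack = np.stack([g.ravel() for g in grids], axis=1)  # 3.2M x 5 class codes

    def canonical_at(anchor_col):
        rest = np.delete(stack, anchor_col, axis=1)
        h = (rest == 1).sum(1)
        p = (rest == 2).sum(1)
        n = (rest == 3).sum(1)
        return (
            (stack[:, anchor_col] == 4)
            & (h + p + n == 4)
            & (h >= 1) & (h <= 2)
            & (p >= 1) & (p <= 2)
            & (n == 1)
        )

    canon = canonical_at(0) | canonical_at(4)
    n_canon = int(canon.sum())
    assert n_canon == exhaustive_canonical_count() == 2304
    exact = n_canon / 20**5

    # spot-check enumeration against the per-window classifier on a sample
    rng = np.random.default_rng(3)
    idx = rng.integers(0, 20**5, size=300)
    for i in idx:
        digits = np.unravel_index(i, (20,) * 5)
        w = "".join(AA[d] for d in digits)
        has_canon = any(c.motif_class == CANONICAL for c in classify_window(w))
        assert has_canon == bool(canon[i])

    n_draw = 200_000
    draws = rng.integers(0, 20**5, size=n_draw)
    est = canon[draws].mean()
    se = np.sqrt(exact * (1 - exact) / n_draw)
    assert abs(est - exact) < 5 * se


def test_summarize_collection_modes():
    recs = [ProteinRecord("a", "KFERQ"), ProteinRecord("b", "AAAAA")]
    s = summarize_collection(recs)
    assert s.fractions[CANONICAL] == 0.5
    assert s.fractions[PHOSPHO] == 0.0 and s.fractions[ACETYL] == 0.0

    recs = [ProteinRecord("a", "KFERQ"), ProteinRecord("b", "QKILS")]
    s = summarize_collection(recs, mode="inclusive")
    assert s.fractions[CANONICAL] == 0.5 and s.fractions[PHOSPHO] == 0.5

    # priority: a protein with both canonical and phospho counts canonical only
    rec = ProteinRecord("a", "KFERQAAQKILS")
    s_ex = summarize_collection([rec], mode="exclusive")
    assert s_ex.counts == {CANONICAL: 1, PHOSPHO: 0, ACETYL: 0}
    s_in = summarize_collection([rec], mode="inclusive")
    assert s_in.counts[CANONICAL] == 1 and s_in.counts[PHOSPHO] == 1
    # inclusive count per class >= exclusive count
    for cls in s_ex.counts:
        assert s_in.counts[cls] >= s_ex.counts[cls]


def test_summarize_empty_collection_errors():
    with pytest.raises(ValueError):
        summarize_collection([])


def _summary(counts, total, mode="inclusive"):
    from cmaflux import MotifSummary

    return MotifSummary(
        counts=counts, fractions={k: v / total for k, v in counts.items()}, total=total, mode=mode
    )


def test_compare_to_reference_identical_and_enriched():
    classes = {CANONICAL: 50, PHOSPHO: 10, ACETYL: 5}
    q = _summary(classes, 100)
    r = _summary(classes, 100)
    res = compare_to_reference(q, r)
    assert np.allclose(res["odds_ratio"], 1.0)
    assert np.allclose(res["p_value"], 1.0)

    q = _summary({CANONICAL: 9, PHOSPHO: 0, ACETYL: 0}, 10)
    r = _summary({CANONICAL: 1, PHOSPHO: 0, ACETYL: 0}, 10)
    res = compare_to_reference(q, r)
    # exact two-sided p from full enumeration of the hypergeometric table set
    assert res.loc[CANONICAL, "p_value"] == pytest.approx(fisher_two_sided(9, 1, 1, 9), rel=1e-9)
    assert res.loc[CANONICAL, "odds_ratio"] > 1


def test_compare_to_reference_monotone_odds():
    q = _summary({CANONICAL: 60, PHOSPHO: 3, ACETYL: 3}, 100)
    r = _summary({CANONICAL: 40, PHOSPHO: 3, ACETYL: 3}, 100)
    res = compare_to_reference(q, r)
    assert res.loc[CANONICAL, "odds_ratio"] > 1


def test_fasta_roundtrip(tmp_path):
    recs = [ProteinRecord("sp|P1|X", "KFERQAAAA"), ProteinRecord("P2", "MLLT")]
    path = tmp_path / "x.fasta"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert [r.sequence for r in back] == [r.sequence for r in recs]


def test_configurable_rules_dialect(tmp_path):
    rules_yaml = tmp_path / "rules.yaml"
    rules_yaml.write_text("hydrophobic: [F, I, L, V, W]\n")
    rules = MotifRuleSet.from_yaml(rules_yaml)
    # W now counts as hydrophobic: KWERQ becomes canonical under this dialect
    assert any(c.motif_class == CANONICAL for c in classify_window("KWERQ", rules))
    assert classify_window("KWERQ", DEFAULT_RULES) == set()
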