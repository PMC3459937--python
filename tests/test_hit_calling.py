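"""Cut-off calling, histogram binning, calibration, and gene-level
concordance (checked against brute-force enumeration)."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import iresscreen as ir
from iresscreen.errors import CalibrationError, ParameterError
from iresscreen.hits import DOWN, NONE, UP, CutoffPair


def test_frequency_distribution_counts():
    edges, counts = ir.frequency_distribution([50, 150, 150, 350], bin_width=100)
    np.testing.assert_allclose(edges, [0, 100, 200, 300, 400])
    assert counts.tolist() == [1, 2, 0, 1]


def test_frequency_distribution_single_value_and_conservation():
    edges, counts = ir.frequency_distribution([42.0], bin_width=10)
    assert counts.sum() == 1
    scores = [50, 150, 150, 350, 99.9, 100.0]
    _, c1 = ir.frequency_distribution(scores, 100)
    _, c2 = ir.frequency_distribution(scores[::-1], 100)
    assert c1.tolist() == c2.tolist()
    assert c1.sum() == len(scores)
    with pytest.raises(ParameterError):
        ir.frequency_distribution([], 100)


def test_calibrate_cutoffs_uniform_rank_oracle():
    """On scores 1..1000 with target 10% and grid 1, the down cut-off stays at
    or below the 50th value, the up cut-off at or above the 951st, and the
    inclusive beyond-fraction never exceeds the target (sorting oracle)."""
    scores = np.arange(1, 1001, dtype=float)
    cuts = ir.calibrate_cutoffs(scores, target_hit_rate=0.10, grid=1.0)
    s = np.sort(scores)
    assert cuts.down_cutoff <= s[49]
    assert cuts.up_cutoff >= s[950]
    beyond = np.mean((scores <= cuts.down_cutoff) | (scores >= cuts.up_cutoff))
    assert beyond <= 0.10
    assert cuts.derivation == "calibrated"


def test_calibrate_respects_target_on_random_score_sets(rng):
    """Direct-counting oracle over 100 random score sets."""
    for _ in range(100):
        scores = 100 * rng.lognormal(0, 0.4, size=rng.integers(20, 400))
        target = float(rng.uniform(0.02, 0.3))
        cuts = ir.calibrate_cutoffs(scores, target_hit_rate=target, grid=1.0)
        beyond = np.mean((scores <= cuts.down_cutoff) | (scores >= cuts.up_cutoff))
        assert beyond <= target + 1e-12


def test_calibrate_near_total_target_stays_inside_data_range(rng):
    scores = 100 * rng.lognormal(0, 0.3, 500)
    cuts = ir.calibrate_cutoffs(scores, target_hit_rate=0.999, grid=1.0)
    assert cuts.down_cutoff >= scores.min() - 1.0
    assert cuts.up_cutoff <= scores.max() + 1.0


def test_calibrate_degenerate_scores_error():
    with pytest.raises(CalibrationError):
        ir.calibrate_cutoffs([100.0] * 50)


def test_cutoff_pair_must_bracket_control_level():
    with pytest.raises(ParameterError):
        CutoffPair(up_cutoff=90, down_cutoff=80)
    with pytest.raises(ParameterError):
        CutoffPair(up_cutoff=250, down_cutoff=120)


@pytest.mark.parametrize("score,expected", [
    (260, UP),
    (100, NONE),
    (250, UP),     # boundary values are calls (inclusive convention)
    (80, DOWN),
    (80.1, NONE),
    (249.9, NONE),
    (0, DOWN),
])
def test_call_direction_thresholds(score, expected):
    assert ir.call_direction(score, CutoffPair()) == expected


@given(st.floats(0, 1000), st.floats(0, 1000))
def test_call_direction_monotone(a, b):
    """Raising a score never removes an up call and never creates a down
    call."""
    lo, hi = min(a, b), max(a, b)
    cuts = CutoffPair()
    if ir.call_direction(lo, cuts) == UP:
        assert ir.call_direction(hi, cuts) == UP
    if ir.call_direction(lo, cuts) != DOWN:
        assert ir.call_direction(hi, cuts) != DOWN


def _oracle_gene_call(dirs):
    """Brute-force concordance rule: >= 2 identical non-none directions."""
    for d in (UP, DOWN):
        if sum(x == d for x in dirs) >= 2:
            return True, d
    return False, None


def test_call_gene_matches_enumeration_oracle():
    """Exhaustive agreement over all 3^3 direction vectors."""
    for dirs in itertools.product([UP, DOWN, NONE], repeat=3):
        got = ir.call_gene(list(dirs), "G", "kinase")
        want_hit, want_dir = _oracle_gene_call(dirs)
        assert got.hit == want_hit, dirs
        assert got.direction == want_dir, dirs
        if got.hit:
            assert got.n_supporting_sirnas == sum(d == want_dir for d in dirs)
            assert got.regulator_sign == ("negative" if want_dir == UP else "positive")


def test_call_gene_two_usable_reactions_can_hit():
    assert ir.call_gene([UP, UP]).hit
    assert not ir.call_gene([UP]).hit
    assert not ir.call_gene([UP, DOWN]).hit


def test_call_genes_table_agrees_with_scalar_calls(rng):
    import pandas as pd

    rows = []
    for g in range(50):
        for s in (1, 2, 3):
            rows.append((f"G{g}", s, float(rng.choice([50, 100, 300]))))
    calls = pd.DataFrame(rows, columns=["gene_symbol", "sirna_index", "score"])
    cuts = CutoffPair()
    calls["direction"] = [ir.call_direction(v, cuts) for v in calls["score"]]
    table = ir.call_genes(calls).set_index("gene_symbol")
    for g, group in calls.groupby("gene_symbol"):
        scalar = ir.call_gene(group["direction"].tolist(), g)
        assert table.loc[g, "hit"] == scalar.hit
        assert (table.loc[g, "direction"] or None) == scalar.direction


def test_summarize_screen_counts_planted_kinase_hits(rng):
    import pandas as pd

    genes = [f"G{i}" for i in range(10)]
    rows = []
    for g in genes:
        for s in (1, 2, 3):
            score = 300.0 if g in ("G0", "G1") else 100.0
            rows.append((g, s, score))
    calls = pd.DataFrame(rows, columns=["gene_symbol", "sirna_index", "score"])
    cuts = CutoffPair()
    calls["direction"] = [ir.call_direction(v, cuts) for v in calls["score"]]
    classes = pd.Series("kinase", index=genes)
    hits = ir.call_genes(calls, classes)
    summary = ir.summarize_screen(calls, hits, classes)
    assert summary["hits_by_class"] == {"kinase": 2}
    assert summary["n_genes_affected"] == 2
    assert sum(summary["hits_by_sign"].values()) == summary["n_hits"] == 2
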