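"""Micro-homology statistics, shuffled null, and insertion-origin mapping."""

import numpy as np
import pytest

from tmejsig.junction_signatures import (
    InsertionCategory,
    classify_insertion,
    compare_cell,
    junction_summary,
    mh_heatmap,
    mh_length,
    shuffled_null,
)
from tmejsig.seq_utils import RefGenome, revcomp
from tmejsig.variant_io import (
    DeletionEvent,
    JunctionContext,
    build_junction_context,
    normalize_deletion,
)


def _ctx_from(seq, start, end, w):
    ev = DeletionEvent("c", start, end, ref_allele=seq[start - 1 : end])
    return build_junction_context({"c": seq}, ev, w)


# ---------------------------------------------------------------------------
# mh_length
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,start,end,expected",
    [
        ("AATGCTGCAA", 6, 8, 3),  # retained ...TGC matches lost ...TGC, depth 4 differs
        ("AATACGCTAA", 5, 7, 0),  # junction bases differ immediately
        ("AGGGGT", 4, 5, 2),      # suffix homology through the G run
    ],
)
def test_mh_length_examples(seq, start, end, expected):
    assert mh_length(_ctx_from(seq, start, end, 5)) == expected


def _mh_oracle(seq, start, end, w):
    """Longest-common-suffix brute force straight off the reference string."""
    retained5 = seq[: start - 1]
    lost3 = seq[: end]
    size = end - start + 1
    k = 0
    while (
        k < min(w, size, len(retained5))
        and retained5[-(k + 1)] == lost3[-(k + 1)]
    ):
        k += 1
    return k


def test_mh_length_matches_brute_force_oracle(rng):
    w = 8
    for _ in range(2000):
        n = int(rng.integers(20, 60))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        start = int(rng.integers(2, n - 3))
        end = int(rng.integers(start, min(start + 15, n - 1)))
        ctx = _ctx_from(seq, start, end, w)
        assert mh_length(ctx) == _mh_oracle(seq, start, end, w)


# ---------------------------------------------------------------------------
# Heatmap
# ---------------------------------------------------------------------------

def test_single_event_heatmap_is_indicator_matrix():
    # AATGCTGCAA, deletion 6-8, mh 3
    ctx = _ctx_from("AATGCTGCAA", 6, 8, 3)
    hm = mh_heatmap([ctx])
    assert hm.cell(1, -1) == 1.0
    assert hm.cell(2, -2) == 1.0
    assert hm.cell(-1, 1) == 0.0
    assert hm.n_events == 1


def test_heatmap_invariant_under_event_duplication(fixture_ref, fixture_deletions):
    ctxs = [build_junction_context(fixture_ref, e, 6) for e in fixture_deletions[:10]]
    a = mh_heatmap(ctxs)
    b = mh_heatmap(ctxs * 2)
    np.testing.assert_allclose(a.fractions, b.fractions)
    assert b.n_events == 2 * a.n_events


def test_heatmap_uniform_flanks_monte_carlo(rng):
    """Cells over independent uniform flanks sit at 0.25 within 3 binomial SE."""
    w, n = 4, 10_000
    bases = np.array(list("ACGT"))
    ctxs = []
    for _ in range(n):
        s = "".join(rng.choice(bases, size=4 * w + 2 * w))
        # independent windows, deletion much longer than w so lost windows disjoint
        ctxs.append(
            JunctionContext(
                window=w,
                up_retained=s[:w],
                up_lost=s[w : 2 * w],
                down_lost=s[2 * w : 3 * w],
                down_retained=s[3 * w : 4 * w],
                deletion_size=100,
            )
        )
    hm = mh_heatmap(ctxs)
    bound = 3 * np.sqrt(0.25 * 0.75 / n)
    assert np.all(np.abs(hm.fractions - 0.25) < bound)


def test_heatmap_requires_events():
    with pytest.raises(ValueError):
        mh_heatmap([])


def test_heatmap_diagonal_bounds_mh_fraction(fixture_ref, fixture_deletions):
    """Cell (+k,-k) is at least the fraction of events with mh_length >= k."""
    w = 6
    ctxs = [build_junction_context(fixture_ref, e, w) for e in fixture_deletions]
    mhs = np.array([mh_length(c) for c in ctxs])
    hm = mh_heatmap(ctxs)
    for k in range(1, w + 1):
        assert hm.cell(k, -k) >= (mhs >= k).mean() - 1e-12


# ---------------------------------------------------------------------------
# Shuffled null
# ---------------------------------------------------------------------------

def test_null_monobase_windows_are_fixed_points():
    # each window mono-base: shuffling is the identity, so null == observed
    ctx = JunctionContext(6, "A" * 6, "C" * 6, "G" * 6, "T" * 6, 60)
    obs = mh_heatmap([ctx] * 5)
    null = shuffled_null([ctx] * 5, n_replicates=4, seed=0)
    np.testing.assert_allclose(obs.fractions, null.fractions)


def test_null_deterministic_and_skewed(rng):
    """Uniform-composition events: null cells ~0.25 but the (+1,-1) cell is
    elevated by re-annotation under maximal 5' conservation, and (-1,+1) is 0."""
    w, n = 5, 600
    bases = np.array(list("ACGT"))
    ctxs = []
    for _ in range(n):
        s = "".join(rng.choice(bases, size=4 * w))
        ctxs.append(JunctionContext(w, s[:w], s[w : 2 * w], s[2 * w : 3 * w], s[3 * w :], 80))
    null = shuffled_null(ctxs, n_replicates=8, seed=11)
    again = shuffled_null(ctxs, n_replicates=8, seed=11)
    np.testing.assert_allclose(null.fractions, again.fractions)
    assert null.cell(-1, 1) == 0.0
    bound = 3 * np.sqrt(0.25 * 0.75 / n)
    assert null.cell(1, -1) > 0.25 + bound          # methodological skew
    for i, j in [(3, 3), (-2, -3), (4, -4), (-5, 2)]:
        assert abs(null.cell(i, j) - 0.25) < bound  # unconstrained cells


def test_double_shuffle_statistically_matches_single_shuffle(rng):
    w, n = 5, 400
    bases = np.array(list("ACGT"))
    ctxs = []
    for _ in range(n):
        s = "".join(rng.choice(bases, size=4 * w))
        ctxs.append(JunctionContext(w, s[:w], s[w : 2 * w], s[2 * w : 3 * w], s[3 * w :], 80))
    one = shuffled_null(ctxs, n_replicates=6, seed=1)
    # shuffle of the shuffled set: rebuild contexts from a single-replicate null
    from tmejsig.junction_signatures import _reannotate

    g = np.random.default_rng(2)
    reshuffled = [_reannotate(c, g) for c in ctxs]
    two = shuffled_null(reshuffled, n_replicates=6, seed=3)
    mask = np.ones_like(one.fractions, dtype=bool)
    assert np.abs(one.fractions[mask] - two.fractions[mask]).mean() < 0.03


# ---------------------------------------------------------------------------
# Cell comparison
# ---------------------------------------------------------------------------

def _hm_with_cell(frac, n, w=2, cell=(1, -1)):
    hm = mh_heatmap(
        [JunctionContext(w, "A" * w, "C" * w, "G" * w, "T" * w, 50)] * n
    )
    i, j = hm._row_index(cell[0]), hm._col_index(cell[1])
    hm.identity[i, j] = frac * n
    hm.coverage[i, j] = n
    return hm


def test_compare_cell_strong_enrichment_is_significant():
    res = compare_cell(_hm_with_cell(0.8, 50), _hm_with_cell(0.25, 500), (1, -1))
    assert res["p"] < 0.001 and res["stars"] == "***"


def test_compare_cell_equal_fractions_not_significant():
    res = compare_cell(_hm_with_cell(0.4, 100), _hm_with_cell(0.4, 100), (1, -1))
    assert res["statistic"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0) and res["stars"] == "NS"


def test_compare_cell_statistic_scales_with_counts():
    a = compare_cell(_hm_with_cell(0.6, 50), _hm_with_cell(0.3, 200), (1, -1))
    b = compare_cell(_hm_with_cell(0.6, 100), _hm_with_cell(0.3, 400), (1, -1))
    assert b["statistic"] == pytest.approx(2 * a["statistic"])


def test_compare_cell_zero_margin_inapplicable():
    res = compare_cell(_hm_with_cell(0.0, 50), _hm_with_cell(0.0, 50), (1, -1))
    assert res["applicable"] is False and res["stars"] == "inapplicable"


# ---------------------------------------------------------------------------
# Insertion classification
# ---------------------------------------------------------------------------

def test_classify_insertion_examples(rng):
    seq = "".join(rng.choice(list("ACGT"), size=400))
    start, end = 150, 260
    ref = {"c": seq}
    simple = DeletionEvent("c", start, end, ref_allele=seq[start - 1 : end])
    assert classify_insertion(simple, ref) is InsertionCategory.SIMPLE

    # 5 bp insert copied from 12 bp upstream of the 5' breakpoint
    origin = seq[start - 13 : start - 8]
    templ = DeletionEvent("c", start, end, seq[start - 1 : end], origin)
    assert classify_insertion(templ, ref) is InsertionCategory.TEMPLATED
    # reverse-complement origins count as templated too
    templ_rc = DeletionEvent("c", start, end, seq[start - 1 : end], revcomp(origin))
    assert classify_insertion(templ_rc, ref) is InsertionCategory.TEMPLATED

    # a perfect 3 bp flank match stays misc: below the size threshold
    short = DeletionEvent("c", start, end, seq[start - 1 : end], seq[start - 4 : start - 1])
    assert classify_insertion(short, ref) is InsertionCategory.MISC

    # a 6 bp insert absent from both +/-40 bp windows is misc
    win5 = seq[start - 41 : start + 39]
    win3 = seq[end - 40 : end + 40]
    for _ in range(100):
        ins = "".join(rng.choice(list("ACGT"), size=6))
        if all(x not in w for x in (ins, revcomp(ins)) for w in (win5, win3)):
            break
    else:
        pytest.fail("could not construct an absent insert")
    misc = DeletionEvent("c", start, end, seq[start - 1 : end], ins)
    assert classify_insertion(misc, ref) is InsertionCategory.MISC


def _insertion_oracle(seq, start, end, ins, min_len=5, sw=40):
    """Exhaustive two-strand substring search over the literal windows."""
    if not ins:
        return "simple"
    if len(ins) < min_len:
        return "misc"
    windows = [
        seq[max(0, start - 1 - sw) : start - 1 + sw],
        seq[max(0, end - sw) : end + sw],
    ]
    for w in windows:
        for i in range(len(w) - len(ins) + 1):
            sub = w[i : i + len(ins)]
            if sub == ins or sub == revcomp(ins):
                return "templated"
    return "misc"


def test_classify_insertion_matches_exhaustive_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(150, 300))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        start = int(rng.integers(60, n - 70))
        end = int(rng.integers(start + 1, min(start + 30, n - 50)))
        ilen = int(rng.integers(0, 9))
        if ilen and rng.random() < 0.5:
            # half the time plant the insert near a breakpoint
            o = int(rng.integers(max(0, start - 30), start))
            ins = seq[o : o + ilen]
        else:
            ins = "".join(rng.choice(list("ACGT"), size=ilen))
        ev = DeletionEvent("c", start, end, seq[start - 1 : end], ins)
        got = classify_insertion(ev, {"c": seq}).label
        assert got == _insertion_oracle(seq, start, end, ins)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def test_junction_summary_all_simple(fixture_ref, fixture_deletions):
    pure = [e for e in fixture_deletions if e.insert_size == 0]
    out = junction_summary(pure, fixture_ref)
    assert out["fractions"] == {"simple": 1.0, "templated": 0.0, "misc": 0.0}
    assert sum(out["mh_histogram"].values()) == len(pure)


def test_junction_summary_fractions_sum_and_order_invariance(fixture_ref, fixture_deletions):
    out = junction_summary(fixture_deletions, fixture_ref)
    assert sum(out["fractions"].values()) == pytest.approx(1.0)
    rev = junction_summary(fixture_deletions[::-1], fixture_ref)
    assert out["fractions"] == rev["fractions"]
    assert out["mh_histogram"] == rev["mh_histogram"]


def test_junction_summary_recovers_planted_templated_fraction(fixture_sim, fixture_ref, fixture_deletions):
    big = [e for e in fixture_deletions if e.deletion_size >= 50]
    out = junction_summary(big, fixture_ref)
    truth = fixture_sim.truth
    planted = truth[truth.true_class == "deletion_50_500"].templated.mean()
    n = len(big)
    se = np.sqrt(max(planted * (1 - planted), 0.25 / n) / n)
    assert abs(out["fractions"]["templated"] - planted) <= 3 * se + 1e-12
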