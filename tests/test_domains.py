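from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppinet.domains import (
    DcPairScoreTable,
    DomainArchitecture,
    build_score_table,
    enumerate_dc_pairs,
    filter_domain_hits,
    predict_domain_interactions,
    score_dc_pair,
    score_domain_pair,
)
from ppinet.errors import ValidationError
from ppinet.io_formats import DomainHit, EdgeList


def arch(pid, *domains):
    return DomainArchitecture(pid, frozenset(domains))


# ---------------------------------------------------------------------------
# independent oracle: explicit subset enumeration
# ---------------------------------------------------------------------------


def brute_force_dc_pairs(domains_a, domains_b):
    """All unordered (subset, subset) pairs, enumerated explicitly."""
    def subsets(ds):
        ds = sorted(ds)
        return [
            tuple(c) for r in range(1, len(ds) + 1)
            for c in combinations(ds, r)
        ]
    pairs = set()
    for left in subsets(domains_a):
        for right in subsets(domains_b):
            pairs.add((left, right) if left <= right else (right, left))
    return pairs


def brute_force_domain_score(domains_a, domains_b, table):
    all_pairs = brute_force_dc_pairs(domains_a, domains_b)
    rated = {p: table.scores[p] for p in all_pairs if p in table.scores}
    if not rated:
        return 0.0
    return sum(rated.values()) * len(rated) / len(all_pairs)


# ---------------------------------------------------------------------------
# filter_domain_hits
# ---------------------------------------------------------------------------


def test_filter_evalue():
    hits = [DomainHit("P1", "D1", 1e-2, 1, 95, 100)]
    assert filter_domain_hits(hits) == {}


def test_filter_single_domain_coverage():
    hits = [DomainHit("P1", "D1", 1e-5, 1, 85, 100)]  # coverage 0.85 <= 0.9
    assert filter_domain_hits(hits) == {}
    hits = [DomainHit("P1", "D1", 1e-5, 1, 91, 100)]  # 0.91 > 0.9
    assert filter_domain_hits(hits)["P1"].domains == frozenset({"D1"})


def test_filter_multi_domain_coverage():
    hits = [
        DomainHit("P1", "D1", 1e-5, 1, 65, 100),  # 0.65 > 0.6 -> kept
        DomainHit("P1", "D2", 1e-5, 1, 95, 100),
    ]
    assert filter_domain_hits(hits)["P1"].domains == frozenset({"D1", "D2"})


def test_filter_classification_before_coverage():
    # second domain passes the e-value filter, making P1 multi-domain,
    # even though its own coverage then removes it
    hits = [
        DomainHit("P1", "D1", 1e-5, 1, 70, 100),   # passes 0.6, fails 0.9
        DomainHit("P1", "D2", 1e-5, 1, 30, 100),   # low coverage decoy
    ]
    assert filter_domain_hits(hits)["P1"].domains == frozenset({"D1"})


def test_filter_duplicate_hits_collapse():
    hits = [
        DomainHit("P1", "D1", 1e-5, 1, 95, 100),
        DomainHit("P1", "D1", 1e-6, 1, 92, 100),
    ]
    assert filter_domain_hits(hits)["P1"].domains == frozenset({"D1"})


# ---------------------------------------------------------------------------
# dc-pair enumeration and scoring
# ---------------------------------------------------------------------------


def test_enumerate_singletons():
    assert enumerate_dc_pairs(arch("a", "X"), arch("b", "Y")) == [(("X",), ("Y",))]


@pytest.mark.parametrize("m,n", [(1, 1), (1, 2), (2, 2), (3, 2), (3, 3),
                                 (4, 3), (4, 4), (5, 4), (5, 5)])
def test_enumerate_matches_brute_force(m, n):
    da = {f"A{i}" for i in range(m)}
    db = {f"B{i}" for i in range(n)}
    got = enumerate_dc_pairs(arch("a", *da), arch("b", *db))
    expected = brute_force_dc_pairs(da, db)
    assert len(got) == len(set(got)) == (2**m - 1) * (2**n - 1)
    assert set(got) == expected


def test_score_dc_pair_values():
    assert score_dc_pair(1, 1) == 1.0
    assert score_dc_pair(2, 2) == pytest.approx(1 / 9)
    assert score_dc_pair(3, 3) == pytest.approx(1 / 49)
    assert score_dc_pair(3, 2) == pytest.approx(1 / 21)


def test_score_dc_pair_invalid():
    with pytest.raises(ValidationError):
        score_dc_pair(0, 1)


@pytest.mark.parametrize("m,n", [(m, n) for m in range(1, 6)
                                 for n in range(1, 6)])
def test_score_dc_pair_is_reciprocal_of_count(m, n):
    da = {f"A{i}" for i in range(m)}
    db = {f"B{i}" for i in range(n)}
    assert score_dc_pair(m, n) == pytest.approx(
        1 / len(brute_force_dc_pairs(da, db))
    )


def test_empty_architecture_rejected():
    with pytest.raises(ValidationError):
        DomainArchitecture("p", frozenset())


# ---------------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------------


def test_build_score_table_max_rule():
    # edge1: single-single (score 1.0); edge2: 2x2 domains (score 1/9);
    # the shared dc-pair keeps the max
    archs = {
        "a": arch("a", "X"), "b": arch("b", "Y"),
        "c": arch("c", "X", "W"), "d": arch("d", "Y", "Z"),
    }
    ppis = {"org": EdgeList.from_pairs([("a", "b"), ("c", "d")])}
    table = build_score_table(ppis, archs)
    assert table.scores[(("X",), ("Y",))] == 1.0
    assert table.scores[(("W",), ("Z",))] == pytest.approx(1 / 9)


def test_build_score_table_single_observation():
    archs = {"a": arch("a", "X"), "b": arch("b", "Y", "Z")}
    ppis = {"org": EdgeList.from_pairs([("a", "b")])}
    table = build_score_table(ppis, archs)
    assert table.scores[(("X",), ("Y",))] == pytest.approx(1 / 3)
    assert len(table) == 3


def test_build_score_table_empty(caplog):
    with caplog.at_level("WARNING"):
        table = build_score_table({"org": EdgeList()}, {})
    assert len(table) == 0


def test_score_domain_pair_hand_examples():
    table = DcPairScoreTable()
    table.record((("X",), ("Y",)), 0.5)
    assert score_domain_pair(arch("a", "X"), arch("b", "Y"), table) == 0.5

    table2 = DcPairScoreTable()
    table2.record((("X",), ("Y",)), 1.0)
    # m=1, n=2 -> 3 dc-pairs, 1 rated at 1.0 -> 1.0 * 1/3
    assert score_domain_pair(
        arch("a", "X"), arch("b", "Y", "Z"), table2
    ) == pytest.approx(1 / 3)


def test_score_domain_pair_unrated_is_zero():
    assert score_domain_pair(arch("a", "X"), arch("b", "Y"),
                             DcPairScoreTable()) == 0.0


def test_score_domain_pair_symmetry(dc_table, architectures):
    names = sorted(architectures)[:10]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert score_domain_pair(architectures[a], architectures[b],
                                     dc_table) == pytest.approx(
                score_domain_pair(architectures[b], architectures[a], dc_table)
            )


def test_score_domain_pair_brute_force_agreement():
    """100 random architecture pairs against the subset-enumeration oracle."""
    rng = np.random.default_rng(1234)
    alphabet = [f"D{i}" for i in range(10)]
    table = DcPairScoreTable()
    # random rated dc-pairs over the same alphabet
    for _ in range(200):
        left = tuple(sorted(rng.choice(alphabet, size=rng.integers(1, 3),
                                       replace=False)))
        right = tuple(sorted(rng.choice(alphabet, size=rng.integers(1, 3),
                                        replace=False)))
        key = (left, right) if left <= right else (right, left)
        table.record(key, float(rng.uniform(0.01, 1.0)))
    for _ in range(100):
        da = set(rng.choice(alphabet, size=rng.integers(1, 5), replace=False))
        db = set(rng.choice(alphabet, size=rng.integers(1, 5), replace=False))
        fast = score_domain_pair(arch("a", *da), arch("b", *db), table)
        slow = brute_force_domain_score(da, db, table)
        assert abs(fast - slow) < 1e-12


@settings(max_examples=50, deadline=None)
@given(
    st.sets(st.sampled_from("ABCDE"), min_size=1, max_size=4),
    st.sets(st.sampled_from("FGHIJ"), min_size=1, max_size=4),
)
def test_score_domain_pair_bounds(da, db):
    table = DcPairScoreTable()
    for pair in brute_force_dc_pairs(da, db):
        table.record(pair, 1.0)
    score = score_domain_pair(arch("a", *da), arch("b", *db), table)
    assert 0 <= score <= len(table)


def test_table_round_trip(tmp_path, dc_table):
    path = tmp_path / "table.tsv"
    dc_table.to_tsv(path)
    loaded = DcPairScoreTable.from_tsv(path)
    assert loaded.scores.keys() == dc_table.scores.keys()
    for key, score in dc_table.scores.items():
        assert loaded.scores[key] == pytest.approx(score)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def test_predict_zero_scores_never_emitted():
    archs = {"a": arch("a", "X"), "b": arch("b", "Y")}
    assert predict_domain_interactions(archs, DcPairScoreTable(), 0.0) == []


def test_predict_threshold_zero_emits_all_rated():
    table = DcPairScoreTable()
    table.record((("X",), ("Y",)), 0.4)
    archs = {"a": arch("a", "X"), "b": arch("b", "Y"), "c": arch("c", "Z")}
    out = predict_domain_interactions(archs, table, 0.0)
    assert [c.pair for c in out] == [("a", "b")]
    assert out[0].provenance == frozenset({"domain"})


def test_predict_recovers_planted_pairs(universe, architectures,
                                        ref_architectures):
    """All rule-driven true pairs score > 0 on the noise-free table."""
    from ppinet.domains import build_score_table

    table = build_score_table(universe.ref_ppis, ref_architectures)
    out = predict_domain_interactions(architectures, table, 0.0)
    predicted = {c.pair for c in out}
    missing = [e for e in universe.true_edges.edges if e not in predicted]
    assert not missing
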