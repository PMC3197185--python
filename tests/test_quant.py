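"""NSAF computation, fold changes, ANOVA, and the differential table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixquant.ident_filter import ProteinIdentification
from sixquant.quant import (
    LOG_EPSILON,
    QuantRecord,
    anova_oneway,
    differential_table,
    fold_change,
    normalize_counts,
    nsaf,
    protein_length,
    quantify,
)
from sixquant.search_db import ProteinEntry


def brute_force_anova(groups):
    """Independent oracle: textbook one-way F from sums of squares."""
    k = len(groups)
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    return msb / msw


def _entry(eid, length):
    return ProteinEntry(eid, eid, "A" * length, "target", "t", 1)


def _group(gid, entries):
    return ProteinIdentification(gid, frozenset(entries), frozenset({"AAK", "GGR"}),
                                 5, 0.99, "target", "s1", "replete", 1)


class TestProteinLength:
    def test_longest_member(self):
        db = {"E1": _entry("E1", 120), "E2": _entry("E2", 98)}
        assert protein_length(_group("g", ["E1", "E2"]), db) == 120

    def test_singleton(self):
        db = {"E1": _entry("E1", 77)}
        assert protein_length(_group("g", ["E1"]), db) == 77

    def test_missing_member_rejected(self):
        with pytest.raises(KeyError):
            protein_length(_group("g", ["E9"]), {})


class TestNormalizeCounts:
    def test_scale_factors(self):
        factors = normalize_counts({"a": 1000, "b": 2000},
                                   {"a": "replete", "b": "deplete"}, "deplete")
        assert factors == {"a": 2.0, "b": 1.0}

    def test_identity_when_equal(self):
        factors = normalize_counts({"a": 500, "b": 500},
                                   {"a": "replete", "b": "deplete"}, "deplete")
        assert factors == {"a": 1.0, "b": 1.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts({"a": 0, "b": 10},
                             {"a": "replete", "b": "deplete"}, "deplete")


class TestNsaf:
    def test_hand_arithmetic(self):
        vals = nsaf([4, 6], [100, 300])
        assert vals == pytest.approx([2 / 3, 1 / 3])

    def test_single_protein(self):
        assert nsaf([7], [50]) == pytest.approx([1.0])

    def test_zero_count_protein(self):
        assert nsaf([5, 0], [10, 10]) == pytest.approx([1.0, 0.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nsaf([0, 0], [10, 10])

    @given(st.lists(st.integers(0, 500), min_size=2, max_size=40).filter(
        lambda c: sum(c) > 0))
    @settings(derandomize=True)
    def test_sums_to_one(self, counts):
        lengths = [(i % 7 + 1) * 50 for i in range(len(counts))]
        assert abs(nsaf(counts, lengths).sum() - 1.0) < 1e-9

    @given(st.lists(st.integers(1, 500), min_size=2, max_size=40),
           st.integers(2, 100))
    @settings(derandomize=True)
    def test_scale_invariance(self, counts, c):
        lengths = [(i % 5 + 1) * 30 for i in range(len(counts))]
        a = nsaf(counts, lengths)
        b = nsaf([c * x for x in counts], lengths)
        assert np.allclose(a, b, atol=1e-12)


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change(0.4, 0.2).value == pytest.approx(2.0)

    def test_identity(self):
        assert fold_change(0.3, 0.3).value == pytest.approx(1.0)

    def test_deplete_only_sentinel_with_bound(self):
        fc = fold_change(0.02, 0.0, pseudo_nsaf_replete=1e-4)
        assert fc.sentinel == "deplete_only"
        assert fc.value == pytest.approx(200.0)
        assert fc.render().startswith(">")

    def test_replete_only_sentinel(self):
        fc = fold_change(0.0, 0.02, pseudo_nsaf_deplete=1e-4)
        assert fc.sentinel == "replete_only"

    def test_absent(self):
        assert fold_change(0.0, 0.0).sentinel == "absent"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-0.1, 0.2)


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([[1, 1, 1], [1, 1, 1]], log_transform=False)
        assert f == 0.0 and p == 1.0

    def test_perfect_separation(self):
        f, p = anova_oneway([[1, 1, 1], [2, 2, 2]], log_transform=False)
        assert p == 0.0

    def test_hand_computed_f(self):
        f, p = anova_oneway([[1, 2, 3], [2, 3, 4]], log_transform=False)
        assert f == pytest.approx(1.5)
        assert f == pytest.approx(brute_force_anova([[1, 2, 3], [2, 3, 4]]))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1], [2, 3]])
        with pytest.raises(ValueError):
            anova_oneway([[1, 2]])

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = [list(rng.normal(size=int(rng.integers(2, 8)))) for _ in range(k)]
        f, _ = anova_oneway(groups, log_transform=False)
        expected = brute_force_anova(groups)
        assert abs(f - expected) < 1e-10


def _records(spc_by_sample, length=100):
    """Build QuantRecords for one protein roster from per-sample counts."""
    out = []
    for (cond, rep), counts in spc_by_sample.items():
        lens = [length] * len(counts)
        vals = nsaf(counts, lens)
        safs = [c / length for c in counts]
        for i, (c, v, s) in enumerate(zip(counts, vals, safs)):
            out.append(QuantRecord(f"g{i}", f"{cond}_{rep}", cond, rep,
                                   c, length, s, float(v)))
    return out


class TestDifferentialTable:
    def _table(self, dep_counts, rep_counts, **kw):
        spc = {}
        for r, counts in enumerate(dep_counts, 1):
            spc[("deplete", r)] = counts
        for r, counts in enumerate(rep_counts, 1):
            spc[("replete", r)] = counts
        return differential_table(_records(spc), **kw)

    def test_boundary_p_values_inclusive(self):
        # alpha semantics: p == alpha is significant
        rows = self._table([[10, 5], [11, 5], [10, 6]], [[5, 10], [5, 11], [6, 10]])
        for r in rows:
            assert r.significant == (r.p_value <= 0.05)

    def test_sentinels_sorted_first(self):
        rows = self._table([[10, 5, 8], [11, 5, 9], [10, 6, 7]],
                           [[5, 10, 0], [5, 11, 0], [6, 10, 0]])
        assert rows[0].fold_change.sentinel == "deplete_only"

    def test_deplete_only_bound_uses_pseudo_count(self):
        rows = self._table([[10, 5, 8], [11, 5, 9], [10, 6, 7]],
                           [[5, 10, 0], [5, 11, 0], [6, 10, 0]])
        sentinel = rows[0]
        assert sentinel.fold_change.value is not None
        assert sentinel.fold_change.value > 1

    def test_bh_adjustment_never_adds_significance(self):
        dep = [[10, 5, 8, 2], [11, 5, 9, 2], [10, 6, 7, 3]]
        rep = [[5, 10, 7, 2], [5, 11, 8, 2], [6, 10, 9, 3]]
        raw = self._table(dep, rep)
        adj = self._table(dep, rep, p_adjust="bh")
        raw_sig = {r.group_id for r in raw if r.significant}
        adj_sig = {r.group_id for r in adj if r.significant}
        assert adj_sig <= raw_sig

    def test_abundant_flag(self):
        rows = self._table([[10, 1], [11, 1], [10, 1]], [[5, 1], [5, 1], [6, 1]])
        flags = {r.group_id: r.abundant for r in rows}
        assert flags["g0"] is True and flags["g1"] is False


def test_quantify_builds_consistent_roster():
    db = {"E1": _entry("E1", 100), "E2": _entry("E2", 200)}
    groups = []
    for cond, rep in [("replete", 1), ("replete", 2), ("deplete", 1), ("deplete", 2)]:
        sample = f"{cond}_{rep}"
        groups.append(ProteinIdentification(
            "E1", frozenset({"E1"}), frozenset({"AAK", "GGR"}), 10, 0.99,
            "target", sample, cond, rep))
        if cond == "deplete":
            groups.append(ProteinIdentification(
                "E2", frozenset({"E2"}), frozenset({"CCK", "DDK"}), 4, 0.99,
                "target", sample, cond, rep))
    records = quantify(groups, db)
    by_sample = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r.nsaf)
    for vals in by_sample.values():
        assert abs(sum(vals) - 1.0) < 1e-9
    # E2 absent from replete samples gets SpC 0 there
    assert any(r.group_id == "E2" and r.condition == "replete" and r.spc == 0
               for r in records)
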