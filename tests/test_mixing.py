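"""Mixing matrices: counting convention, axes, normalization, abx policies."""

from __future__ import annotations

import numpy as np
import pytest

from tests.conftest import d, mk_adm, mk_exp, mk_stay
from wardmix.contact_network import ContactEvent
from wardmix.encounter_model import ABX_RANKS, EncounterBundle
from wardmix.mixing import (
    AGE_LABELS,
    Scope,
    UnclassifiableEventError,
    abx_mixing,
    abx_none_ratio,
    age_mixing,
    elixhauser_mixing,
    mixing_matrix,
    normalize,
    pattern_contingency,
)

SCOPE = Scope(hospital_id="H1", window=(d(1), d(31)))


def _shared_unit_bundle(specs, days=1, exposures=()):
    """All admissions share one unit for *days* days; specs = (id, age, elix)."""
    return EncounterBundle(
        admissions=[mk_adm(a, age=age, elix=el) for a, age, el in specs],
        stays=[mk_stay(a, unit="U", entry=d(1), exit=d(days)) for a, _, _ in specs],
        exposures=list(exposures),
    )


class TestMixingMatrixConvention:
    def test_single_cross_class_event(self):
        events = [ContactEvent("A", "B", "U", d(1))]
        classes = {"A": 30, "B": 40}
        m = mixing_matrix(events, lambda a, _: classes[a], AGE_LABELS, axis="age")
        assert m.cell(30, 40) == 1
        assert m.cell(40, 30) == 1
        assert m.counts.sum() == 2

    def test_three_same_age_patients_one_unit_day(self):
        """3 patients aged 50 -> 3 unordered pairs -> diagonal cell 6."""
        bundle = _shared_unit_bundle([("A", 50, 0), ("B", 50, 0), ("C", 50, 0)])
        m = age_mixing(bundle, SCOPE)
        assert m.cell(50, 50) == 6
        assert m.counts.sum() == 6

    def test_repeated_contact_days_mirror_edge_weight(self):
        bundle = _shared_unit_bundle([("A", 30, 0), ("B", 40, 0)], days=3)
        m = age_mixing(bundle, SCOPE)
        assert m.cell(30, 40) == 3 and m.cell(40, 30) == 3

    def test_strict_policy_raises_on_unclassifiable(self):
        events = [ContactEvent("A", "B", "U", d(1))]
        with pytest.raises(UnclassifiableEventError, match="B"):
            mixing_matrix(events, lambda a, _: 30 if a == "A" else None, AGE_LABELS)

    def test_lenient_policy_excludes_and_tallies(self):
        events = [ContactEvent("A", "B", "U", d(1))]
        m = mixing_matrix(events, lambda a, _: 30 if a == "A" else None,
                          AGE_LABELS, strict=False)
        assert m.counts.sum() == 0
        assert m.n_excluded == 1


class TestAgeAndElixhauserAxes:
    def test_all_one_age_concentrates_on_diagonal(self):
        bundle = _shared_unit_bundle([("A", 65, 0), ("B", 65, 0)])
        m = age_mixing(bundle, SCOPE)
        assert m.counts.sum() == m.cell(65, 65) == 2

    def test_elixhauser_pair_scores_4_and_4(self):
        bundle = _shared_unit_bundle([("A", 50, 4), ("B", 50, 4)])
        m = elixhauser_mixing(bundle, SCOPE)
        assert m.cell(4, 4) == 2

    def test_conservation_and_symmetry_on_generated_bundle(self):
        from wardmix.mixing import scope_events
        from wardmix.synthetic_data import archetype_config, generate_bundle

        cfg = archetype_config("uniform_adult", 80, 21)
        bundle = generate_bundle(cfg)
        scope = Scope(hospital_id=cfg.hospital_id, window=(d(1), d(31)))
        events = scope_events(bundle, scope)
        for m in (age_mixing(bundle, scope), elixhauser_mixing(bundle, scope)):
            assert m.counts.sum() == 2 * len(events)
            assert (m.counts == m.counts.T).all()

    def test_age_marginal_equals_weighted_degree_exposure(self):
        """Row sums collapsed over partner age = per-age total contact
        exposure, computed independently from the network's weighted degrees."""
        from wardmix.contact_network import build_network
        from wardmix.synthetic_data import archetype_config, generate_bundle

        cfg = archetype_config("elderly_small", 60, 17)
        bundle = generate_bundle(cfg)
        scope = Scope(hospital_id=cfg.hospital_id, window=(d(1), d(31)))
        m = age_mixing(bundle, scope)
        marginal = m.counts.sum(axis=1)

        net = build_network(bundle, cfg.hospital_id, scope.window)
        ages = {a.admission_id: a.age for a in bundle.admissions}
        exposure = np.zeros(91, dtype=np.int64)
        for node in net.graph.nodes:
            wdeg = sum(dd["weight"] for _, _, dd in net.graph.edges(node, data=True))
            exposure[ages[node]] += wdeg
        assert (marginal == exposure).all()

    def test_unit_type_scope_restricts_events(self):
        bundle = EncounterBundle(
            admissions=[mk_adm("A", age=30), mk_adm("B", age=30),
                        mk_adm("C", age=70), mk_adm("D", age=70)],
            stays=[
                mk_stay("A", unit="LD", unit_type="labor and delivery ward"),
                mk_stay("B", unit="LD", unit_type="labor and delivery ward"),
                mk_stay("C", unit="MED", unit_type="adult medical ward"),
                mk_stay("D", unit="MED", unit_type="adult medical ward"),
            ],
        )
        scope = Scope(hospital_id="H1", window=(d(1), d(31)),
                      unit_types=frozenset({"labor and delivery ward"}))
        m = age_mixing(bundle, scope)
        assert m.counts.sum() == m.cell(30, 30)


class TestAbxMixing:
    def test_both_on_narrow_only(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0)],
            exposures=[mk_exp("A", d(1), "narrow"), mk_exp("B", d(1), "narrow")],
        )
        m = abx_mixing(bundle, SCOPE)
        assert m.cell("narrow", "narrow") == 2
        assert m.counts.sum() == 2

    def test_multi_rank_day_contributes_cross_product(self):
        """a on {narrow, extended}, b on {narrow}: (n,n)+2, (e,n)+1, (n,e)+1."""
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0)],
            exposures=[
                mk_exp("A", d(1), "narrow"), mk_exp("A", d(1), "extended"),
                mk_exp("B", d(1), "narrow"),
            ],
        )
        m = abx_mixing(bundle, SCOPE)
        assert m.cell("narrow", "narrow") == 2
        assert m.cell("extended", "narrow") == 1
        assert m.cell("narrow", "extended") == 1
        assert m.counts.sum() == 4

    def test_collapse_highest_reduces_to_broadest_rank(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0)],
            exposures=[
                mk_exp("A", d(1), "narrow"), mk_exp("A", d(1), "extended"),
                mk_exp("B", d(1), "narrow"),
            ],
        )
        m = abx_mixing(bundle, SCOPE, collapse_highest=True)
        assert m.cell("extended", "narrow") == 1
        assert m.cell("narrow", "extended") == 1
        assert m.counts.sum() == 2

    def test_unexposed_events_excluded_and_tallied(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0), ("C", 50, 0)],
            exposures=[mk_exp("A", d(1), "broad"), mk_exp("B", d(1), "broad")],
        )
        m = abx_mixing(bundle, SCOPE)
        assert m.cell("broad", "broad") == 2
        assert m.n_excluded == 2  # A-C and B-C

    def test_whole_stay_policy_spreads_ranks_over_all_days(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0)], days=2,
            exposures=[mk_exp("A", d(1), "narrow"), mk_exp("B", d(2), "broad")],
        )
        per_day = abx_mixing(bundle, SCOPE, timing_policy="per_day")
        assert per_day.counts.sum() == 0 and per_day.n_excluded == 2
        whole = abx_mixing(bundle, SCOPE, timing_policy="whole_stay")
        assert whole.cell("narrow", "broad") == 2
        assert whole.counts.sum() == 4

    def test_unknown_policy_enumerates_options(self):
        bundle = _shared_unit_bundle([("A", 50, 0), ("B", 50, 0)])
        with pytest.raises(ValueError, match="per_day.*whole_stay"):
            abx_mixing(bundle, SCOPE, timing_policy="per_stay")


class TestAbxNoneRatio:
    def test_no_exposures_flags_missing_ratio(self):
        bundle = _shared_unit_bundle([("A", 50, 0), ("B", 50, 0)])
        r = abx_none_ratio(bundle, SCOPE)
        assert r["events_any"] == 0 and r["ratio_missing"] and r["ratio"] is None

    def test_everyone_exposed_gives_ratio_zero(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0)],
            exposures=[mk_exp("A", d(1)), mk_exp("B", d(1))],
        )
        r = abx_none_ratio(bundle, SCOPE)
        assert r["events_neither"] == 0 and r["ratio"] == 0.0

    def test_four_patients_two_exposed_hand_enumeration(self):
        """6 pairs; only the unexposed-unexposed pair counts as 'neither'."""
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0), ("C", 50, 0), ("D", 50, 0)],
            exposures=[mk_exp("A", d(1)), mk_exp("B", d(1))],
        )
        r = abx_none_ratio(bundle, SCOPE)
        assert r["events_neither"] == 1
        assert r["events_any"] == 5
        assert r["ratio"] == pytest.approx(0.2)

    def test_partition_conserves_total_events(self):
        from wardmix.mixing import scope_events
        from wardmix.synthetic_data import archetype_config, generate_bundle

        cfg = archetype_config("academic_pediatric", 100, 5)
        bundle = generate_bundle(cfg)
        scope = Scope(hospital_id=cfg.hospital_id, window=(d(1), d(31)))
        r = abx_none_ratio(bundle, scope)
        assert r["events_neither"] + r["events_any"] == len(scope_events(bundle, scope))


class TestNormalize:
    def test_printed_formula_on_2x2(self):
        m = mixing_matrix(
            [ContactEvent("A", "B", "U", d(1))],
            lambda a, _: "x" if a == "A" else "y",
            ["x", "y"],
        )
        m.counts = np.array([[1, 3], [3, 5]], dtype=np.int64)
        n = normalize(m)
        assert np.allclose(n.normalized, [[0.0, 0.5], [0.5, 1.0]])

    def test_constant_matrix_flagged_all_zeros(self):
        m = mixing_matrix([], lambda a, _: "x", ["x", "y"])
        n = normalize(m)
        assert n.degenerate_norm
        assert (n.normalized == 0).all()

    def test_min_zero_max_one_when_not_constant(self):
        from wardmix.synthetic_data import archetype_config, generate_bundle

        cfg = archetype_config("young_skew", 60, 8)
        bundle = generate_bundle(cfg)
        scope = Scope(hospital_id=cfg.hospital_id, window=(d(1), d(31)))
        n = normalize(age_mixing(bundle, scope))
        assert n.normalized.min() == 0.0 and n.normalized.max() == 1.0

    def test_idempotent_on_already_scaled_matrix(self):
        m = mixing_matrix([], lambda a, _: "x", ["x", "y"])
        m.counts = np.array([[0, 1], [1, 1]], dtype=np.int64)
        once = normalize(m)
        twice = normalize(once)
        assert np.array_equal(once.normalized, twice.normalized)


class TestPatternContingency:
    def test_all_narrow_single_category(self):
        bundle = _shared_unit_bundle(
            [(f"A{i}", 50, 0) for i in range(10)],
            exposures=[mk_exp(f"A{i}", d(1), "narrow") for i in range(10)],
        )
        t = pattern_contingency(bundle, SCOPE)
        assert list(t["category"]) == ["narrow"]
        assert t.loc[0, "pct"] == 100.0

    def test_four_distinct_combinations(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0), ("C", 50, 0), ("D", 50, 0)],
            exposures=[
                mk_exp("A", d(1), "narrow"),
                mk_exp("B", d(1), "extended"),
                mk_exp("C", d(1), "narrow"), mk_exp("C", d(1), "extended"),
            ],
        )
        t = pattern_contingency(bundle, SCOPE, grouping="by_rank_combination")
        assert set(t["category"]) == {"narrow", "extended", "narrow+extended", "none"}
        assert (t["pct"] == 25.0).all()

    def test_by_highest_rank_collapses(self):
        bundle = _shared_unit_bundle(
            [("A", 50, 0), ("B", 50, 0)],
            exposures=[mk_exp("A", d(1), "narrow"), mk_exp("A", d(1), "extended"),
                       mk_exp("B", d(1), "narrow")],
        )
        t = pattern_contingency(bundle, SCOPE, grouping="by_highest_rank")
        assert set(t["category"]) == {"extended", "narrow"}

    def test_percentages_sum_to_100(self):
        from wardmix.synthetic_data import archetype_config, generate_bundle

        cfg = archetype_config("academic_pediatric", 80, 31)
        bundle = generate_bundle(cfg)
        scope = Scope(hospital_id=cfg.hospital_id, window=(d(1), d(31)))
        t = pattern_contingency(bundle, scope)
        assert t["pct"].sum() == pytest.approx(100.0)

    def test_empty_scope_gives_empty_table(self):
        bundle = _shared_unit_bundle([("A", 50, 0)])
        scope = Scope(hospital_id="H1", window=(d(1), d(31)),
                      unit_ids=frozenset({"NOPE"}))
        assert pattern_contingency(bundle, scope).empty
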