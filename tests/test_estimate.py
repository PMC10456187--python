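"""Two-stage mental-representation estimator and its diagnostics."""

import warnings

import numpy as np
import pytest

from aurevcorr import (
    MentalPrototype,
    ResponseSet,
    StimulusCatalog,
    StimulusVector,
    TrialPair,
    build_prototype,
    complementary_proportions,
    complementary_set,
    convergence_curve,
    dominant_au,
    estimate_prototype,
    partition_by_au,
    selection_proportions,
)
from aurevcorr.estimate import ProportionTable, SelectionTally

from conftest import make_random_responses


def responses_from(catalog, rows):
    """rows: list of (left_active_ids, right_active_ids, choice)."""
    trials = [
        (
            TrialPair(
                t,
                StimulusVector.from_active_ids(catalog, l),
                StimulusVector.from_active_ids(catalog, r),
            ),
            c,
        )
        for t, (l, r, c) in enumerate(rows)
    ]
    return ResponseSet(trials, catalog=catalog)


def brute_force_proportion(responses, au_id, within_dominant=None):
    """Independent trial-by-trial recount of P(i|Ω_{i*}) (optionally inside
    Ω_d), kept deliberately naive."""
    num = den = 0
    for pair, choice in responses.trials:
        if within_dominant is not None and not (
            pair.left.has(within_dominant) and pair.right.has(within_dominant)
        ):
            continue
        l, r = pair.left.has(au_id), pair.right.has(au_id)
        if l == r:
            continue
        den += 1
        chosen = pair.left if choice == "left" else pair.right
        if chosen.has(au_id):
            num += 1
    return None if den == 0 else num / den


CAT5 = StimulusCatalog((1, 2, 3, 4, 5), k_active=2)


class TestPartition:
    def test_hand_checked_three_trial_example(self):
        resp = responses_from(
            CAT5,
            [({1, 2}, {1, 3}, "left"), ({2, 3}, {4, 5}, "left"), ({1, 4}, {2, 3}, "left")],
        )
        part = partition_by_au(resp, 1)
        assert part.exactly_one == (2,)
        assert part.both == (0,)
        assert part.neither == (1,)

    def test_absent_au_lands_every_trial_in_neither(self):
        resp = responses_from(CAT5, [({1, 2}, {1, 3}, "left"), ({2, 3}, {1, 5}, "right")])
        part = partition_by_au(resp, 4)
        assert part.neither == (0, 1) and part.exactly_one == () and part.both == ()

    def test_empty_response_set_gives_three_empty_subsets(self):
        resp = ResponseSet([], catalog=CAT5)
        part = partition_by_au(resp, 3)
        assert part.exactly_one == part.both == part.neither == ()

    def test_unknown_au_rejected(self):
        resp = responses_from(CAT5, [({1, 2}, {1, 3}, "left")])
        with pytest.raises(KeyError):
            partition_by_au(resp, 99)

    def test_conservation_on_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            resp = make_random_responses(rng)
            for au in resp.catalog.au_ids:
                p = partition_by_au(resp, au)
                assert len(p.exactly_one) + len(p.both) + len(p.neither) == resp.m


class TestSelectionProportions:
    def test_always_picking_the_bearer_gives_one(self, catalog16):
        rows = [({12, 1, 2}, {4, 5, 9}, "left"), ({4, 5, 9}, {12, 6, 7}, "right")]
        table = selection_proportions(responses_from(catalog16, rows))
        assert table.proportion(12) == 1.0

    def test_never_picking_the_bearer_gives_zero(self, catalog16):
        rows = [({12, 1, 2}, {4, 5, 9}, "right"), ({4, 5, 9}, {12, 6, 7}, "left")]
        table = selection_proportions(responses_from(catalog16, rows))
        assert table.proportion(12) == 0.0

    def test_seven_of_ten_gives_point_seven(self, catalog16):
        # ten trials where exactly one stimulus bears AU7; bearer chosen 7 times
        rows = [
            ({7, 1, 2}, {4, 5, 9}, "left" if t < 7 else "right") for t in range(10)
        ]
        # vary the non-bearing side so unordered pairs stay unique
        others = [(4, 5, 9), (4, 5, 10), (4, 5, 12), (4, 5, 14), (4, 5, 15),
                  (4, 5, 17), (4, 5, 20), (4, 5, 23), (4, 5, 25), (4, 5, 26)]
        rows = [({7, 1, 2}, set(o), c) for ((_, __, c), o) in zip(rows, others)]
        table = selection_proportions(responses_from(catalog16, rows))
        tally = table.tallies[7]
        assert (tally.selected_with_au, tally.denominator) == (7, 10)
        assert table.proportion(7) == pytest.approx(0.7)

    def test_undefined_entry_flagged_not_zero(self, catalog16):
        rows = [({12, 1, 2}, {12, 1, 4}, "left")]  # AU12 never differs
        table = selection_proportions(responses_from(catalog16, rows))
        assert table.proportion(12) is None
        assert 12 not in table.defined()

    def test_empty_set_rejected(self, catalog16):
        with pytest.raises(ValueError):
            selection_proportions(ResponseSet([], catalog=catalog16))

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            resp = make_random_responses(rng)
            table = selection_proportions(resp)
            for au in resp.catalog.au_ids:
                assert table.proportion(au) == brute_force_proportion(resp, au)

    def test_invariant_to_presentation_side_flips(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            resp = make_random_responses(rng)
            flipped = ResponseSet(
                [
                    (
                        TrialPair(p.trial_id, p.right, p.left),
                        "right" if c == "left" else "left",
                    )
                    for p, c in resp.trials
                ],
                catalog=resp.catalog,
            )
            t1, t2 = selection_proportions(resp), selection_proportions(flipped)
            for au in resp.catalog.au_ids:
                assert t1.proportion(au) == t2.proportion(au)


def table_from(proportions, context="dominant_stage", den=20, conditioned_on=None):
    tallies = {
        au: SelectionTally(au, round(p * den), den) for au, p in proportions.items()
    }
    return ProportionTable(context=context, tallies=tallies, conditioned_on=conditioned_on)


class TestDominantAU:
    def test_strict_maximum(self):
        assert dominant_au(table_from({12: 0.95, 6: 0.52, 4: 0.41})) == 12

    def test_tie_returns_smallest_id_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            assert dominant_au(table_from({4: 0.9, 9: 0.9})) == 4

    def test_all_undefined_rejected(self):
        table = ProportionTable(
            context="dominant_stage", tallies={1: SelectionTally(1, 0, 0)}
        )
        with pytest.raises(ValueError):
            dominant_au(table)


class TestComplementary:
    def test_forced_pick_within_dominant_subset_gives_one(self, catalog16):
        # both stimuli bear AU12; the AU6 bearer is always chosen
        rows = [
            ({12, 6, 1}, {12, 4, 5}, "left"),
            ({12, 9, 17}, {12, 6, 2}, "right"),
        ]
        table = complementary_proportions(responses_from(catalog16, rows), d=12)
        assert table.proportion(6) == 1.0
        assert 12 not in table.tallies  # the dominant AU is excluded

    def test_never_differing_au_is_undefined(self, catalog16):
        rows = [({12, 6, 1}, {12, 4, 5}, "left")]
        table = complementary_proportions(responses_from(catalog16, rows), d=12)
        assert table.proportion(20) is None

    def test_four_of_five_gives_point_eight(self, catalog16):
        partners = [(1, 2), (1, 4), (2, 5), (4, 5), (5, 9)]
        rows = [
            ({12, 20, 6}, {12, *o}, "left" if t < 4 else "right")
            for t, o in enumerate(partners)
        ]
        table = complementary_proportions(responses_from(catalog16, rows), d=12)
        tally = table.tallies[20]
        assert (tally.selected_with_au, tally.denominator) == (4, 5)
        assert table.proportion(20) == pytest.approx(0.8)

    def test_empty_dominant_subset_warns_all_undefined(self, catalog16):
        rows = [({6, 1, 2}, {4, 5, 9}, "left")]
        with pytest.warns(UserWarning, match="empty"):
            table = complementary_proportions(responses_from(catalog16, rows), d=12)
        assert table.defined() == {}

    def test_matches_brute_force_recount_within_dominant_subset(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            resp = make_random_responses(rng)
            d = resp.catalog.au_ids[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = complementary_proportions(resp, d)
            for au in resp.catalog.au_ids:
                if au == d:
                    continue
                assert table.proportion(au) == brute_force_proportion(
                    resp, au, within_dominant=d
                )


class TestComplementarySet:
    def test_threshold_selects_and_is_inclusive(self):
        table = table_from({6: 1.0, 20: 0.85, 5: 0.60}, context="complementary_stage")
        assert complementary_set(table, 0.8) == {6, 20}
        assert 20 in complementary_set(table, 0.85)  # boundary uses ≥

    def test_zero_threshold_takes_every_defined_entry(self):
        table = table_from({6: 1.0, 20: 0.85, 5: 0.60}, context="complementary_stage")
        assert complementary_set(table, 0.0) == {5, 6, 20}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        table = table_from(
            {au: float(rng.integers(0, 21)) / 20 for au in range(1, 11)},
            context="complementary_stage",
        )
        thresholds = [0.0, 0.2, 0.5, 0.8, 0.85, 1.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sets = [complementary_set(table, t) for t in thresholds]
        for lo, hi in zip(sets, sets[1:]):
            assert lo >= hi


class TestBuildPrototype:
    def test_assembles_dominant_plus_complementary(self, catalog16):
        proto = build_prototype(12, {6, 20}, catalog16, 0.8)
        assert proto.active_ids == {6, 12, 20}
        assert proto.vector.active_ids == {6, 12, 20}

    def test_single_au_prototype_warns(self, catalog16):
        with pytest.warns(UserWarning, match="1 AUs"):
            build_prototype(12, set(), catalog16, 0.8)

    def test_dominant_in_complementary_rejected(self, catalog16):
        with pytest.raises(ValueError):
            build_prototype(12, {12}, catalog16, 0.8)

    def test_out_of_catalog_au_rejected(self, catalog16):
        with pytest.raises(KeyError):
            build_prototype(12, {99}, catalog16, 0.8)

    def test_json_round_trip(self, tmp_path, catalog16):
        proto = build_prototype(12, {6, 20}, catalog16, 0.8, provenance={"m": 840})
        path = tmp_path / "proto.json"
        proto.to_json(path)
        back = MentalPrototype.from_json(path)
        assert back.dominant == 12
        assert back.complementary == {6, 20}
        assert back.threshold == 0.8
        assert back.active_ids == proto.active_ids


class TestConvergence:
    def test_final_point_is_self_correlation_one(self):
        rng = np.random.default_rng(5)
        resp = make_random_responses(rng, n_aus=8, max_trials=20)
        curve = convergence_curve(resp, "dominant", step=5)
        assert curve.points[-1][0] == resp.m
        assert curve.final_r == pytest.approx(1.0)

    def test_degenerate_partial_histograms_flagged_undefined(self, catalog16):
        rows = [
            ({1, 2, 4}, {1, 2}, "left"),   # only AU4 differs → a single defined bin
            ({1, 2, 5}, {1, 2}, "left"),   # now bins {4, 5}, both exactly 1.0
            ({9, 10, 25}, {12, 14, 26}, "right"),
        ]
        resp = responses_from(catalog16, rows)
        curve = convergence_curve(resp, "dominant", step=1)
        assert curve.points[0][1] is None  # fewer than two commonly defined bins
        assert curve.points[1][1] is None  # constant partial histogram, zero variance
        assert curve.final_r == pytest.approx(1.0)

    def test_step_must_be_positive(self, catalog16):
        rows = [({1, 2, 4}, {5, 6, 7}, "left")]
        with pytest.raises(ValueError):
            convergence_curve(responses_from(catalog16, rows), step=0)


class TestPipeline:
    def test_estimate_prototype_recovers_forced_structure(self, catalog16):
        # AU12 is the only AU always borne by the chosen stimulus when it
        # differs; within the AU12-both trials the AU6 bearer is always chosen
        rows = [
            ({12, 1, 2}, {4, 5, 9}, "left"),
            ({4, 5, 9}, {12, 6, 7}, "right"),
            ({1, 2, 7}, {4, 5, 6}, "right"),
            ({6, 1, 4}, {5, 9, 2}, "right"),
            ({12, 6, 1}, {12, 4, 5}, "left"),
            ({12, 9, 17}, {12, 6, 2}, "right"),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            proto, dom, comp = estimate_prototype(
                responses_from(catalog16, rows), threshold=0.8
            )
        assert proto.dominant == 12
        assert 6 in proto.complementary
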