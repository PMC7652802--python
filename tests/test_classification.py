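"""Cut-point learning, classification and confusion summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdzpopkit as mk
from mdzpopkit.classification import ORDERED_LABELS


def brute_force_cutpoints(values, labels):
    """Independent exhaustive reference: try every midpoint pair with
    pure-Python loops and the same smallest-thresholds tie-break."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(set(lab), key=lambda c: np.median(v[lab == c]))
    uniq = sorted(set(v))
    cands = [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    best = None
    for t_low, t_high in itertools.combinations(cands, 2):
        correct = 0
        for x, l in zip(v, lab):
            if x < t_low:
                pred = classes[0]
            elif x < t_high:
                pred = classes[1]
            else:
                pred = classes[2]
            correct += pred == l
        key = (-correct / len(v), t_low, t_high)
        if best is None or key < best:
            best = key
    return -best[0], best[1], best[2]


def _make_labels(rng, v):
    thirds = np.sort(v)
    lo, hi = thirds[len(v) // 3], thirds[2 * len(v) // 3]
    return np.where(v < lo, "inhibition",
                    np.where(v < hi, "no_modulation", "induction"))


class TestLearnCutpoints:
    def test_perfectly_separated_clusters(self):
        v = [5, 6, 7, 20, 22, 25, 60, 65, 70]
        lab = ["inhibition"] * 3 + ["no_modulation"] * 3 + ["induction"] * 3
        model = mk.learn_cutpoints(v, lab)
        assert model.training_accuracy == 1.0
        assert 7 < model.t_low < 20
        assert 25 < model.t_high < 60
        assert model.labels == ORDERED_LABELS

    def test_six_point_overlap_matches_brute_force(self):
        # one inhibition value sits inside the no-modulation cluster
        v = [5.0, 21.0, 18.0, 22.0, 55.0, 70.0]
        lab = ["inhibition", "inhibition", "no_modulation", "no_modulation",
               "induction", "induction"]
        model = mk.learn_cutpoints(v, lab)
        acc, t_low, t_high = brute_force_cutpoints(v, lab)
        assert model.training_accuracy == pytest.approx(acc)
        assert (model.t_low, model.t_high) == pytest.approx((t_low, t_high))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(9, 200))
    def test_equals_brute_force_on_random_instances(self, seed, n):
        rng = np.random.default_rng(seed)
        v = np.round(rng.lognormal(3.0, 0.8, n), 2)
        lab = _make_labels(rng, v)
        if len(set(lab)) < 3 or len(set(v)) < 3:
            return
        model = mk.learn_cutpoints(v, lab)
        acc, t_low, t_high = brute_force_cutpoints(v, lab)
        assert model.training_accuracy == pytest.approx(acc)
        assert (model.t_low, model.t_high) == pytest.approx((t_low, t_high))

    def test_lognormal_clusters_around_typical_clearances(self, rng):
        # three modulation states centered at the typical Q_met values
        centers = {"inhibition": 7.8, "no_modulation": 24.1, "induction": 62.1}
        v, lab = [], []
        for c, mu in centers.items():
            v.extend(np.exp(np.log(mu) + rng.normal(0, 0.2, 40)))
            lab.extend([c] * 40)
        model = mk.learn_cutpoints(v, lab)
        assert 7.8 < model.t_low < 24.1
        assert 24.1 < model.t_high < 62.1

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            mk.learn_cutpoints([1, 2, 3], ["inhibition", "inhibition", "induction"])


class TestClassify:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (7.8, "inhibition"),  # typical reversible-inhibition clearance
            (11.4, "inhibition"),  # typical irreversible-inhibition clearance
            (24.1, "no_modulation"),  # constitutive typical value
            (62.1, "induction"),  # typical induced clearance
            (3.0, "inhibition"),  # below the published range: still low
            (120.0, "induction"),
        ],
    )
    def test_published_cutpoints_on_typical_values(self, value, expected):
        model = mk.paper_cutpoints()
        assert mk.classify([value], model)[0] == expected

    def test_boundary_values_belong_to_the_upper_interval(self):
        model = mk.paper_cutpoints()
        assert mk.classify([16.4], model)[0] == "no_modulation"
        assert mk.classify([41.8], model)[0] == "induction"
        assert mk.classify([16.4 - 1e-9], model)[0] == "inhibition"

    def test_monotone_in_the_parameter(self, rng):
        model = mk.paper_cutpoints()
        order = {lab: i for i, lab in enumerate(ORDERED_LABELS)}
        v = np.sort(rng.uniform(1, 100, 200))
        ranks = [order[c] for c in mk.classify(v, model)]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_json_roundtrip(self, tmp_path):
        model = mk.learn_cutpoints([1, 2, 10, 11, 30, 31],
                                   ["inhibition", "inhibition", "no_modulation",
                                    "no_modulation", "induction", "induction"])
        path = tmp_path / "model.json"
        model.to_json(path)
        assert mk.CutPointModel.from_json(path) == model


class TestEvaluateClassification:
    def test_perfect_prediction_gives_identity_matrix(self):
        actual = ["inhibition"] * 3 + ["no_modulation"] * 4 + ["induction"] * 2
        summ = mk.evaluate_classification(actual, actual)
        assert summ.accuracy == 1.0
        m = summ.counts.to_numpy()
        assert np.trace(m) == 9 and m.sum() == 9

    def test_development_set_accuracy(self):
        # confusion counts of the development dataset: rows inhibition /
        # no-modulation / induction, same column order
        counts = [(59, 4, 0), ("inhibition",),
                  (2, 146, 0), ("no_modulation",),
                  (0, 0, 12), ("induction",)]
        actual, predicted = [], []
        for row, (cls,) in zip(counts[::2], counts[1::2]):
            for n, pred_cls in zip(row, ORDERED_LABELS):
                actual.extend([cls] * n)
                predicted.extend([pred_cls] * n)
        summ = mk.evaluate_classification(predicted, actual)
        assert 100 * summ.accuracy == pytest.approx(97.3, abs=0.05)

    def test_combined_set_sensitivity_and_specificity(self):
        counts = {"inhibition": (131, 18, 0),
                  "no_modulation": (3, 165, 0),
                  "induction": (0, 15, 21)}
        actual, predicted = [], []
        for cls, row in counts.items():
            for n, pred_cls in zip(row, ORDERED_LABELS):
                actual.extend([cls] * n)
                predicted.extend([pred_cls] * n)
        summ = mk.evaluate_classification(predicted, actual)
        assert 100 * summ.sensitivity["inhibition"] == pytest.approx(87.9, abs=0.05)
        assert 100 * summ.specificity_no_modulation == pytest.approx(98.2, abs=0.05)
        assert 100 * summ.sensitivity["induction"] == pytest.approx(58.3, abs=0.05)

    def test_row_sums_equal_actual_counts(self, rng):
        actual = rng.choice(ORDERED_LABELS, 60)
        predicted = rng.choice(ORDERED_LABELS, 60)
        summ = mk.evaluate_classification(predicted, actual)
        for cls in ORDERED_LABELS:
            assert summ.counts.loc[cls].sum() == (actual == cls).sum()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mk.evaluate_classification(["induction"], ["induction", "induction"])


class TestCollapseInhibition:
    def test_arm_categories_map_to_classifier_labels(self):
        out = mk.collapse_inhibition(
            ["constitutive", "reversible_inhibition", "irreversible_inhibition",
             "induction"]
        )
        assert list(out) == ["no_modulation", "inhibition", "inhibition", "induction"]


class TestEndToEndPilot:
    """Simulate all four CYP3A conditions, estimate per-profile Q_met,
    classify with the published cut-points."""

    def test_potent_arms_classified_correctly(self, model):
        pop, re, effects = model
        from mdzpopkit.config import design_preset

        design = design_preset("pilot_four_arm")
        table = mk.simulate_dataset(design, pop, re, effects, rng_seed=11)
        ebes = mk.compute_ebes(table, pop, re, effects)
        qmet = ebes[ebes["parameter"] == "Qmet"]
        actual = mk.collapse_inhibition(qmet["TRT"].tolist())
        predicted = mk.classify(qmet["value"].to_numpy(), mk.paper_cutpoints())
        potent = actual != "no_modulation"
        assert np.mean(predicted[potent] == actual[potent]) >= 0.85

    def test_typical_value_profiles_classified_perfectly(self, model):
        # zero variability and negligible residual error: every profile's
        # EBE collapses onto the arm-typical clearance
        import dataclasses

        pop, re, effects = model
        from mdzpopkit.config import design_preset

        quiet = dataclasses.replace(pop, err_early_mdz=1e-3, err_late_mdz=1e-3,
                                    err_early_ohmdz=1e-3, err_late_ohmdz=1e-3)
        design = design_preset("pilot_four_arm")
        table = mk.simulate_dataset(design, quiet, re.zero(), effects, rng_seed=1)
        ebes = mk.compute_ebes(table, quiet, re.zero(), effects)
        qmet = ebes[ebes["parameter"] == "Qmet"]
        actual = mk.collapse_inhibition(qmet["TRT"].tolist())
        predicted = mk.classify(qmet["value"].to_numpy(), mk.paper_cutpoints())
        assert (predicted == actual).all()
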