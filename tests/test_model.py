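"""Unit and property tests of the generative foraging model core."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from forage.descriptives import run_stats
from forage.model import (
    Item,
    ModelParams,
    SelectionSequence,
    SelectionState,
    TrialDisplay,
    enumerate_trial_probs,
    inv_logit,
    logit,
    selection_weights,
    simulate_trial,
    trial_loglik,
)


def make_display(target_specs, distractor_specs=(), width=1000.0, height=1000.0):
    """Display from (x, y, class) specs; ids follow list order."""
    items = [
        Item(item_id=i, x=x, y=y, item_class=c, is_target=True)
        for i, (x, y, c) in enumerate(target_specs)
    ]
    items += [
        Item(item_id=len(target_specs) + i, x=x, y=y, item_class=c, is_target=False)
        for i, (x, y, c) in enumerate(distractor_specs)
    ]
    return TrialDisplay(items=tuple(items), width=width, height=height)


def random_small_display(rng, n_targets=4):
    classes = rng.choice(["A", "B"], size=n_targets)
    xy = rng.uniform(50, 950, size=(n_targets, 2))
    return make_display([(x, y, c) for (x, y), c in zip(xy, classes)])


def random_params(rng):
    return ModelParams(
        b_A=float(rng.normal(0, 1)),
        b_S=float(rng.normal(0, 1)),
        sigma_rho=float(rng.normal(8, 4)),
        sigma_d=float(rng.normal(0, 1)),
    )


class TestLogit:
    @pytest.mark.parametrize(
        "p, expected, places",
        [(0.6, 0.405, 3), (0.5, 0.0, 12)],
    )
    def test_printed_values(self, p, expected, places):
        assert logit(p) == pytest.approx(expected, abs=10 ** -places / 2)

    def test_inverse_values(self):
        assert inv_logit(1.0) == pytest.approx(0.73, abs=0.005)
        assert inv_logit(0.0) == 0.5

    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, p):
        assert inv_logit(logit(p)) == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_logit_domain(self, bad):
        with pytest.raises(ValueError):
            logit(bad)

    def test_inv_logit_requires_finite(self):
        with pytest.raises(ValueError):
            inv_logit(float("inf"))


class TestSelectionWeights:
    def test_uniform_limit(self):
        disp = make_display([(100, 100, "A"), (200, 100, "A"), (300, 100, "B"), (400, 100, "B")])
        state = SelectionState.initial(disp)
        w = selection_weights(state, ModelParams(), disp.width, disp.height)
        assert np.allclose(w, 0.25)

    def test_class_saturation(self):
        disp = make_display([(100, 100, "A"), (200, 100, "A"), (300, 100, "B"), (400, 100, "B")])
        state = SelectionState.initial(disp)
        w = selection_weights(state, ModelParams(b_A=10.0), disp.width, disp.height)
        a_weight = w[0] + w[1]
        assert a_weight > 0.9999

    def test_proximity_kernel_values(self):
        # last selection at the origin, remaining at 0.1/0.2/0.3 of the
        # display diagonal: weights must follow exp(-sigma_rho * d)
        diag = math.hypot(1000, 1000)
        disp = make_display(
            [(0.1 * diag, 0, "A"), (0.2 * diag, 0, "A"), (0.3 * diag, 0, "A")]
        )
        last = Item(item_id=99, x=0, y=0, item_class="A", is_target=True)
        state = SelectionState(remaining=list(disp.targets), last=last)
        w = selection_weights(
            state, ModelParams(sigma_rho=15.0), disp.width, disp.height
        )
        raw = np.exp([-1.5, -3.0, -4.5])
        assert np.allclose(w, raw / raw.sum(), atol=1e-10)
        assert w == pytest.approx([0.786, 0.175, 0.0391], abs=1e-3)

    def test_weights_normalized_and_positive(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            disp = random_small_display(rng, n_targets=int(rng.integers(2, 7)))
            params = random_params(rng)
            targets = list(disp.targets)
            last = targets.pop(int(rng.integers(len(targets))))
            prev = targets.pop(int(rng.integers(len(targets)))) if len(targets) > 1 else None
            state = SelectionState(remaining=targets, last=last, prev=prev)
            w = selection_weights(state, params, disp.width, disp.height)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w > 0).all()

    def test_empty_remaining_rejected(self):
        state = SelectionState(remaining=[])
        with pytest.raises(ValueError):
            selection_weights(state, ModelParams(), 1000, 1000)

    def test_coincident_positions_direction_neutral(self):
        # prev == last position: zero-length movement vector must not
        # produce NaNs and must leave direction out of the weights
        disp = make_display([(200, 200, "A"), (700, 700, "B")])
        anchor = Item(item_id=90, x=500, y=500, item_class="A", is_target=True)
        prev = Item(item_id=91, x=500, y=500, item_class="B", is_target=True)
        state = SelectionState(remaining=list(disp.targets), last=anchor, prev=prev)
        with_dir = selection_weights(
            state, ModelParams(sigma_d=3.0), disp.width, disp.height
        )
        without_dir = selection_weights(state, ModelParams(), disp.width, disp.height)
        assert np.allclose(with_dir, without_dir)

    def test_proximity_monotonicity(self):
        disp = make_display([(150, 100, "A"), (900, 100, "A")])
        last = Item(item_id=50, x=100, y=100, item_class="A", is_target=True)
        state = SelectionState(remaining=list(disp.targets), last=last)
        ratios = []
        for srho in (0.0, 5.0, 10.0, 20.0):
            w = selection_weights(
                state, ModelParams(sigma_rho=srho), disp.width, disp.height
            )
            ratios.append(w[0] / w[1])
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_nonspatial_reduction_ignores_positions(self):
        # with both tuning parameters zero the weights must not depend on
        # the item layout at all
        params = ModelParams(b_A=0.4, b_S=0.8)
        layouts = [
            [(100, 100, "A"), (500, 900, "A"), (900, 100, "B")],
            [(500, 500, "A"), (510, 500, "A"), (520, 500, "B")],
        ]
        weights = []
        for specs in layouts:
            disp = make_display(specs)
            last = Item(item_id=77, x=20, y=20, item_class="B", is_target=True)
            prev = Item(item_id=78, x=10, y=10, item_class="A", is_target=True)
            state = SelectionState(remaining=list(disp.targets), last=last, prev=prev)
            weights.append(selection_weights(state, params, disp.width, disp.height))
        assert np.allclose(weights[0], weights[1])


class TestSimulateTrial:
    def test_complete_permutation(self):
        rng = np.random.default_rng(0)
        disp = random_small_display(rng, n_targets=6)
        seq = simulate_trial(disp, random_params(rng), rng)
        assert sorted(seq.selected_ids) == sorted(t.item_id for t in disp.targets)

    def test_reproducible_given_seed(self):
        disp = random_small_display(np.random.default_rng(3), n_targets=6)
        params = ModelParams(b_A=0.3, b_S=0.5, sigma_rho=10.0)
        s1 = simulate_trial(disp, params, np.random.default_rng(42))
        s2 = simulate_trial(disp, params, np.random.default_rng(42))
        assert s1.selected_ids == s2.selected_ids

    def test_extreme_stickiness_two_runs(self):
        # near-certain sticking on an equal display forces one run per
        # class: exactly 2 runs in at least 99% of simulations
        rng = np.random.default_rng(7)
        specs = [(100 + 80 * i, 300, "A") for i in range(10)] + [
            (100 + 80 * i, 700, "B") for i in range(10)
        ]
        disp = make_display(specs)
        params = ModelParams(b_S=10.0)
        hits = 0
        for _ in range(1000):
            seq = simulate_trial(disp, params, rng)
            labels = seq.class_labels(disp)
            if run_stats(labels).n_runs == 2:
                hits += 1
        assert hits >= 990

    def test_uniform_ordering_frequencies(self):
        # all-zero parameters reduce to uniform sampling without
        # replacement: every ordering of a 3-target display is equally
        # likely (checked within 3 standard errors at 60k simulations)
        rng = np.random.default_rng(11)
        disp = make_display([(100, 100, "A"), (500, 500, "A"), (900, 900, "B")])
        n = 60_000
        counts = {p: 0 for p in itertools.permutations([0, 1, 2])}
        for _ in range(n):
            counts[simulate_trial(disp, ModelParams(), rng).selected_ids] += 1
        p = 1 / 6
        se = math.sqrt(p * (1 - p) / n)
        for c in counts.values():
            assert abs(c / n - p) < 3 * se


class TestTrialLoglik:
    def test_uniform_value(self):
        disp = make_display([(100, 100, "A"), (500, 500, "A"), (900, 900, "B")])
        seq = SelectionSequence((2, 0, 1))
        assert trial_loglik(disp, seq, ModelParams()) == pytest.approx(math.log(1 / 6))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            disp = random_small_display(rng, n_targets=int(rng.integers(3, 6)))
            params = random_params(rng)
            probs = enumerate_trial_probs(disp, params)
            for order, prob in itertools.islice(probs.items(), 8):
                ll = trial_loglik(disp, SelectionSequence(order), params)
                assert math.exp(ll) == pytest.approx(prob, abs=1e-10)

    def test_relabelling_symmetry(self):
        # swapping the class labels everywhere and negating b_A leaves
        # every sequence's likelihood unchanged
        rng = np.random.default_rng(33)
        disp = random_small_display(rng, n_targets=5)
        params = random_params(rng)
        swap = {"A": "B", "B": "A"}
        swapped = TrialDisplay(
            items=tuple(
                Item(it.item_id, it.x, it.y, swap[it.item_class], it.is_target)
                for it in disp.items
            ),
            width=disp.width,
            height=disp.height,
        )
        seq = simulate_trial(disp, params, rng)
        assert trial_loglik(disp, seq, params) == pytest.approx(
            trial_loglik(swapped, seq, params.relabelled()), abs=1e-12
        )

    def test_invalid_sequence_rejected(self):
        disp = make_display([(100, 100, "A"), (500, 500, "B")])
        with pytest.raises(ValueError):
            trial_loglik(disp, SelectionSequence((0, 7)), ModelParams())
        with pytest.raises(ValueError):
            SelectionSequence((0, 0))


class TestEnumerationOracle:
    def test_uniform_orderings(self):
        disp = make_display([(100, 100, "A"), (500, 500, "A"), (900, 900, "B")])
        probs = enumerate_trial_probs(disp, ModelParams())
        assert len(probs) == 6
        assert all(p == pytest.approx(1 / 6) for p in probs.values())

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        disp = random_small_display(rng, n_targets=5)
        probs = enumerate_trial_probs(disp, random_params(rng))
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-10)

    def test_first_selection_class_marginal(self):
        # per-item class weights are exp(b_A) : 1, so on a 3A/2B display
        # with b_A = logit(0.6) the chance the first pick is class A is
        # 3*1.5 / (3*1.5 + 2*1) = 9/13; with equal counts (2A/2B) it is
        # exactly p_A = 0.6
        b = logit(0.6)
        disp32 = make_display(
            [(100, 100, "A"), (300, 100, "A"), (500, 100, "A"), (700, 100, "B"), (900, 100, "B")]
        )
        probs = enumerate_trial_probs(disp32, ModelParams(b_A=b))
        first_a = sum(p for order, p in probs.items() if order[0] in (0, 1, 2))
        assert first_a == pytest.approx(9 / 13, abs=1e-10)

        disp22 = make_display(
            [(100, 100, "A"), (300, 100, "A"), (500, 100, "B"), (700, 100, "B")]
        )
        probs = enumerate_trial_probs(disp22, ModelParams(b_A=b))
        first_a = sum(p for order, p in probs.items() if order[0] in (0, 1))
        assert first_a == pytest.approx(0.6, abs=1e-10)

    def test_refuses_large_displays(self):
        rng = np.random.default_rng(9)
        disp = random_small_display(rng, n_targets=8)
        with pytest.raises(ValueError):
            enumerate_trial_probs(disp, ModelParams())

    def test_simulator_matches_oracle_frequencies(self):
        # Monte-Carlo goodness of fit of the simulator against the exact
        # enumeration probabilities on a 4-target display
        rng = np.random.default_rng(17)
        disp = make_display(
            [(200, 200, "A"), (800, 200, "A"), (200, 800, "B"), (800, 800, "B")]
        )
        params = ModelParams(b_A=0.4, b_S=0.7, sigma_rho=6.0, sigma_d=-0.5)
        probs = enumerate_trial_probs(disp, params)
        orders = list(probs)
        idx = {o: i for i, o in enumerate(orders)}
        counts = np.zeros(len(orders))
        n = 50_000
        for _ in range(n):
            counts[idx[simulate_trial(disp, params, rng).selected_ids]] += 1
        expected = n * np.array([probs[o] for o in orders])
        stat, pval = chisquare(counts, expected)
        assert pval > 0.001
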