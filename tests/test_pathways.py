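"""Memory-pathway calculus: response functions, cut-offs, retention, and
agreement with brute-force spiking simulation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetsnn import pathways as PW
from hetsnn.neurons import LEARNER, LONG_TERM, SHORT_TERM, NEURON_TYPES
from hetsnn.pathways import (
    CUTOFF_REFERENCE_G,
    CUTOFF_REFERENCE_HZ,
    CutoffModel,
    PathwaySpec,
    calibrate_leak_slope,
    calibrate_offset,
    cutoff_frequency_exact,
    cutoff_frequency_linear,
    neuron_response,
    pathway_response,
    responses_distinct,
    retention_length,
    simulate_pathway,
    simulated_cutoff,
)
from hetsnn.pathways import _dense_stage_outputs, _stage_outputs_from_inputs


def _linear_cutoff_per_ms(tag: str, G: float) -> float:
    p = NEURON_TYPES[tag]
    s = calibrate_leak_slope(CUTOFF_REFERENCE_HZ[tag], p.c, CUTOFF_REFERENCE_G)
    return cutoff_frequency_linear(s, p.c, G) / 1000.0


class TestNeuronResponse:
    def test_zero_in_zero_out(self):
        assert neuron_response(0.0, 3, 10.0) == 0.0

    def test_saturates_at_refractory_ceiling(self):
        assert neuron_response(1e9, 2, 10.0) == pytest.approx(0.1, rel=1e-6)

    def test_example_value_and_simulation(self):
        """gamma=2, r=10 ms, 100 Hz -> 33.3 Hz; spiking simulation agrees
        within 5%."""
        pred = neuron_response(0.1, 2, 10.0)
        assert pred == pytest.approx(1.0 / 30.0)
        sim = simulate_pathway(100.0, PathwaySpec(stages=(("n", 2),), r=10.0), seed=5)
        assert abs(sim - 1000.0 * pred) / (1000.0 * pred) < 0.05

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            neuron_response(-1.0, 2, 10.0)


class TestPathwayResponse:
    def test_single_stage_reduces_to_neuron_response(self):
        spec = PathwaySpec(stages=(("n", 3),), r=15.0)
        for f in np.linspace(0.005, 0.2, 25):
            assert pathway_response(f, spec) == pytest.approx(neuron_response(f, 3, 15.0))

    def test_two_stage_example(self):
        """gammas (2, 3), r=10, 100 Hz: 1/(60/f... ) = 10 Hz."""
        spec = PathwaySpec(stages=(("a", 2), ("b", 3)), r=10.0)
        assert pathway_response(0.1, spec) == pytest.approx(0.01)

    @given(
        gammas=st.lists(st.integers(1, 6), min_size=1, max_size=4),
        r=st.floats(0.0, 25.0),
        f=st.floats(0.005, 0.3),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_composition_identity(self, gammas, r, f):
        """The closed form equals the fold of single-neuron responses."""
        spec = PathwaySpec(stages=tuple(("n", g) for g in gammas), r=r)
        comp = f
        for g in gammas:
            comp = neuron_response(comp, g, r)
        assert pathway_response(f, spec) == pytest.approx(comp, rel=1e-12, abs=1e-15)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            PathwaySpec(stages=())


class TestDistinguishability:
    def test_order_swap_example(self):
        """(2,3) vs (3,2): 1/(6/f+40) vs 1/(6/f+30), distinct at 100 Hz."""
        s1 = PathwaySpec(stages=(("a", 2), ("b", 3)), r=10.0)
        s2 = PathwaySpec(stages=(("b", 3), ("a", 2)), r=10.0)
        assert pathway_response(0.1, s1) == pytest.approx(1.0 / 100.0)
        assert pathway_response(0.1, s2) == pytest.approx(1.0 / 90.0)
        distinct, witness = responses_distinct(s1, s2, grid=[0.1])
        assert distinct and witness == 0.1

    def test_identical_specs_not_distinct(self):
        s = PathwaySpec(stages=(("a", 2), ("b", 3)), r=10.0)
        assert responses_distinct(s, s) == (False, None)

    def test_all_order_permutations_distinct(self):
        """Any two specs differing only in order of distinct gammas are
        distinct (enumerated up to length 3)."""
        for values in [(2, 3), (2, 5), (2, 3, 4)]:
            specs = [
                PathwaySpec(stages=tuple(("n", g) for g in perm), r=10.0)
                for perm in itertools.permutations(values)
            ]
            for a, b in itertools.combinations(specs, 2):
                distinct, witness = responses_distinct(a, b)
                assert distinct and witness is not None


class TestCutoffs:
    def test_exact_form_reproduces_anchor(self):
        for tag, params in NEURON_TYPES.items():
            X = calibrate_offset(CUTOFF_REFERENCE_HZ[tag], params, CUTOFF_REFERENCE_G)
            f0 = cutoff_frequency_exact(CutoffModel(params, CUTOFF_REFERENCE_G, X=X))
            assert f0 == pytest.approx(CUTOFF_REFERENCE_HZ[tag], abs=1e-9)

    def test_learner_calibrated_offset_value(self):
        X = calibrate_offset(105.8, LEARNER, 0.1)
        assert X == pytest.approx(0.3127, abs=5e-4)

    def test_exact_monotone_decreasing_in_G(self):
        X = calibrate_offset(105.8, LEARNER, 0.1)
        f0s = [cutoff_frequency_exact(CutoffModel(LEARNER, G, X=X))
               for G in np.linspace(0.05, 1.0, 12)]
        assert all(b < a for a, b in zip(f0s, f0s[1:]))

    def test_vanishing_gain_diverges(self):
        X = calibrate_offset(105.8, LEARNER, 0.1)
        assert cutoff_frequency_exact(CutoffModel(LEARNER, 1e-9, X=X)) > 1e6

    def test_linear_one_over_G_scaling(self):
        s = calibrate_leak_slope(105.8, LEARNER.c, 0.1)
        assert cutoff_frequency_linear(s, LEARNER.c, 0.2) == pytest.approx(
            cutoff_frequency_linear(s, LEARNER.c, 0.1) / 2.0)

    @pytest.mark.parametrize(
        "tag,G,reference",
        [("learner", 0.6, 17.6), ("short_term", 0.2, 39.5)],
    )
    def test_linear_reproduces_reference_cells(self, tag, G, reference):
        assert _linear_cutoff_per_ms(tag, G) * 1000.0 == pytest.approx(reference, abs=0.1)

    def test_nonpositive_offset_domain_error(self):
        with pytest.raises(ValueError):
            cutoff_frequency_exact(CutoffModel(LEARNER, 0.1, X=-1.0))

    def test_simulated_cutoff_brackets_exact(self):
        """A learner at 0.9 f0 stays silent over 10 s, fires at 1.1 f0, and
        bisection lands within 2 Hz of the exact form."""
        from hetsnn.pathways import _spikes_at

        X = calibrate_offset(105.8, LEARNER, 0.1)
        f0 = cutoff_frequency_exact(CutoffModel(LEARNER, 0.1, X=X))
        p = LEARNER.with_operating_point(X, LEARNER.c * 0.1 * (1 + 1e-9))
        assert _spikes_at(p, 0.1, 0.9 * f0, 10_000.0) == 0
        assert _spikes_at(p, 0.1, 1.1 * f0, 10_000.0) > 0
        sim = simulated_cutoff(LEARNER, 0.1, X, 0.7 * f0, 1.5 * f0)
        assert abs(sim - f0) < 2.0


class TestRetention:
    def test_two_stage_reduction(self):
        """m=2, f_c=0.02/ms, r=10, gamma1=2 -> (50-10)/2 = 20 ms."""
        spec = PathwaySpec(stages=(("a", 2), ("b", 3)), r=10.0)
        assert retention_length(spec, 0.02) == pytest.approx(20.0)

    def test_deterministic(self):
        spec = PathwaySpec.from_types(("long_term", "short_term", "long_term"))
        assert retention_length(spec, 0.015) == retention_length(spec, 0.015)

    def test_length3_mixed_pathways_pairwise_distinct(self):
        ts = ["long_term", "short_term"]
        vals = []
        for combo in itertools.product(ts, repeat=3):
            spec = PathwaySpec.from_types(combo)
            vals.append(retention_length(spec, _linear_cutoff_per_ms(combo[-1], 0.5)))
        assert len(set(np.round(vals, 9))) == len(vals)

    def test_nonretaining_pathway_flagged_by_sign(self):
        spec = PathwaySpec(stages=(("a", 5), ("b", 5)), r=10.0)
        assert retention_length(spec, 0.5) < 0  # cut-off period shorter than r

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            retention_length(PathwaySpec(stages=(("a", 2),)), 0.02)

    @pytest.mark.parametrize("types", [
        ("long_term", "short_term"),
        ("short_term", "long_term", "long_term"),
        ("long_term", "short_term", "long_term"),
    ])
    def test_mapped_cutoff_is_reciprocal_of_retention(self, types):
        """Bisection inversion of the head response at the last stage's
        cut-off recovers 1/T, and feeding the mapped frequency through the
        head reproduces the cut-off."""
        from hetsnn.pathways import mapped_cutoff_frequency

        spec = PathwaySpec.from_types(types)
        fc = _linear_cutoff_per_ms(types[-1], 0.5)
        f_mapped = mapped_cutoff_frequency(spec, fc)
        assert f_mapped == pytest.approx(1.0 / retention_length(spec, fc), abs=1e-6)
        head = PathwaySpec(stages=spec.stages[:-1], r=spec.r)
        assert pathway_response(f_mapped, head) == pytest.approx(fc, abs=1e-9)


class TestSimulationOracle:
    def test_event_walk_equals_dense_lif_stepping(self):
        """The fast event-driven stage is exactly the dense LIF integrator."""
        rng = np.random.default_rng(3)
        for gamma, r in [(1, 0.0), (2, 10.0), (4, 20.0)]:
            inp = np.flatnonzero(rng.random(4000) < 0.09)
            fast = _stage_outputs_from_inputs(inp, gamma, r)
            dense = _dense_stage_outputs(inp, gamma, r, 4000)
            assert np.array_equal(fast, dense)

    def test_single_learner_stage_matches_response(self):
        spec = PathwaySpec(stages=(("learner", 4),), r=20.0)
        pred = 1000.0 * pathway_response(0.1, spec)
        sim = simulate_pathway(100.0, spec, seed=11)
        assert abs(sim - pred) / pred < 0.05

    @pytest.mark.parametrize("f_hz", [40.0, 60.0, 100.0])
    def test_two_stage_chain_matches(self, f_hz):
        spec = PathwaySpec.from_types(("long_term", "short_term"))
        pred = 1000.0 * pathway_response(f_hz / 1000.0, spec)
        sim = simulate_pathway(f_hz, spec, seed=23)
        assert abs(sim - pred) / pred < 0.05

    def test_below_cutoff_no_output(self):
        """Driving a neuron below its simulated cut-off yields zero spikes."""
        from hetsnn.pathways import _spikes_at

        X = calibrate_offset(78.9, SHORT_TERM, 0.1)
        f0 = cutoff_frequency_exact(CutoffModel(SHORT_TERM, 0.1, X=X))
        p = SHORT_TERM.with_operating_point(X, SHORT_TERM.c * 0.1 * (1 + 1e-9))
        assert _spikes_at(p, 0.1, 0.8 * f0, 10_000.0) == 0
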