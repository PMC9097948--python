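"""Division-axis cues, composition, angular objective and coefficient fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryosim import division_direction as dd
from embryosim import mechanics as mech
from embryosim import synthetic_data as synth
from embryosim.errors import DegeneracyError, UnderdeterminedFitWarning

K_TRUE = np.array([0.6, 0.3, 0.1])


def cosine(a, b):
    return float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestNeighborSqueeze:
    def test_single_overlapping_neighbor_pushes_away(self):
        cell = mech.Cell("m", [0, 0, 0], 1.0)
        nb = mech.Cell("n", [-1.5, 0, 0], 1.0)  # overlap 0.5
        assert np.allclose(dd.neighbor_squeeze_vector(cell, [nb]), [1, 0, 0])

    def test_symmetric_neighbors_cancel(self):
        cell = mech.Cell("m", [0, 0, 0], 1.0)
        nbs = [mech.Cell("a", [0, 1.5, 0], 1.0), mech.Cell("b", [0, -1.5, 0], 1.0)]
        assert np.allclose(dd.neighbor_squeeze_vector(cell, nbs), 0.0)

    def test_non_overlapping_neighbors_give_zero(self):
        cell = mech.Cell("m", [0, 0, 0], 1.0)
        nb = mech.Cell("n", [5, 0, 0], 1.0)
        assert np.allclose(dd.neighbor_squeeze_vector(cell, [nb]), 0.0)

    def test_matches_summation_oracle(self, rng):
        cell = mech.Cell("m", [0, 0, 0], 1.5)
        nbs = [
            mech.Cell(f"n{k}", rng.uniform(-2, 2, 3), rng.uniform(0.5, 1.5))
            for k in range(5)
        ]
        total = np.zeros(3)
        for nb in nbs:
            sep = cell.position - nb.position
            d = np.linalg.norm(sep)
            w = max(0.0, cell.radius + nb.radius - d)
            total += w * sep / d
        expected = total / np.linalg.norm(total)
        assert np.allclose(dd.neighbor_squeeze_vector(cell, nbs), expected, atol=1e-12)

    def test_coincident_neighbor_rejected(self):
        cell = mech.Cell("m", [0, 0, 0], 1.0)
        with pytest.raises(DegeneracyError):
            dd.neighbor_squeeze_vector(cell, [mech.Cell("n", [0, 0, 0], 1.0)])


class TestEggshellSqueeze:
    def test_cell_at_long_axis_tip_pushed_back_along_x(self, default_shell):
        cell = mech.Cell("m", [25.0, 0, 0], 2.0)
        assert np.allclose(
            dd.eggshell_squeeze_vector(cell, default_shell), [-1, 0, 0]
        )

    def test_cell_at_center_feels_nothing(self, default_shell):
        cell = mech.Cell("m", [0, 0, 0], 2.0)
        assert np.allclose(dd.eggshell_squeeze_vector(cell, default_shell), 0.0)

    def test_normal_matches_numeric_gradient_of_g(self, rng, default_shell):
        # at a random boundary contact, the squeeze direction is the inward
        # normal, i.e. the negated normalized finite-difference gradient of g
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        surface = u / default_shell.normalized_coord(u)
        cell = mech.Cell("m", surface, 2.0)
        v = dd.eggshell_squeeze_vector(cell, default_shell)
        h = 1e-7
        grad = np.array(
            [
                (
                    default_shell.normalized_coord(surface + h * np.eye(3)[m])
                    - default_shell.normalized_coord(surface - h * np.eye(3)[m])
                )
                / (2 * h)
                for m in range(3)
            ]
        )
        assert np.allclose(v, -grad / np.linalg.norm(grad), atol=1e-6)


class TestComposeAndAngle:
    def test_single_component_returns_polarity(self):
        comps = dd.DirectionComponents([1, 0, 0], [0, 1, 0], [0, 0, 1])
        model = dd.DivisionDirectionModel([1, 0, 0])
        assert np.allclose(dd.compose_direction(model, comps), [1, 0, 0])

    def test_equal_weights_bisect(self):
        comps = dd.DirectionComponents([1, 0, 0], [0, 1, 0], np.zeros(3))
        out = dd.compose_direction(np.array([0.5, 0.5, 0.0]), comps)
        assert np.allclose(out, [1 / np.sqrt(2), 1 / np.sqrt(2), 0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_output_always_unit_norm(self, seed):
        r = np.random.default_rng(seed)
        v = r.normal(size=(3, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        comps = dd.DirectionComponents(v[0], v[1], v[2])
        K = r.dirichlet(np.ones(3))
        out = dd.compose_direction(K, comps)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_combination_rejected(self):
        comps = dd.DirectionComponents([1, 0, 0], np.zeros(3), np.zeros(3))
        with pytest.raises(DegeneracyError):
            dd.compose_direction(np.array([0.0, 0.5, 0.5]), comps)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0, 0], [1, 0, 0], 0.0),
            ([1, 0, 0], [-1, 0, 0], 0.0),  # an axis is undirected
            ([1, 0, 0], [0, 1, 0], np.pi / 2),
        ],
    )
    def test_angle_error_axis_identification(self, a, b, expected):
        assert dd.angle_error(np.array(a, float), np.array(b, float)) == pytest.approx(
            expected
        )

    def test_angle_error_requires_unit_inputs(self):
        with pytest.raises(ValueError):
            dd.angle_error(np.array([2.0, 0, 0]), np.array([1.0, 0, 0]))


class TestFitCoefficients:
    def test_noiseless_recovery(self):
        obs = synth.synth_divisions(K_TRUE, n=100, noise_angle_deg=0.0, seed=7)
        model, objective = dd.fit_coefficients(obs, seed=7)
        assert cosine(model.K, K_TRUE) >= 0.999
        assert objective <= 1e-6

    def test_pure_polarity_observations_put_weight_on_polarity(self, rng):
        obs = []
        for k in range(50):
            v = rng.normal(size=(3, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            comps = dd.DirectionComponents(v[0], v[1], v[2])
            obs.append(dd.ObservedDivision(f"o{k}", comps, v[0]))
        model, _ = dd.fit_coefficients(obs, seed=0)
        assert model.K[0] >= 0.95

    def test_single_observation_fits_exactly_with_warning(self):
        comps = dd.DirectionComponents([1, 0, 0], [0, 1, 0], np.zeros(3))
        obs = [dd.ObservedDivision("o", comps, np.array([1.0, 0, 0]))]
        with pytest.warns(UnderdeterminedFitWarning):
            model, objective = dd.fit_coefficients(obs, seed=0)
        assert objective <= 1e-6

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            dd.fit_coefficients([])

    def test_objective_reproducible_from_returned_model(self):
        obs = synth.synth_divisions(K_TRUE, n=80, noise_angle_deg=5.0, seed=3)
        model, objective = dd.fit_coefficients(obs, seed=3)
        assert dd.summed_angle_error(model, obs) == pytest.approx(
            objective, abs=1e-9
        )

    def test_objective_invariant_to_axis_sign_flips(self, rng):
        obs = synth.synth_divisions(K_TRUE, n=40, noise_angle_deg=5.0, seed=5)
        model, _ = dd.fit_coefficients(obs, seed=5)
        flipped = [
            dd.ObservedDivision(o.name, o.components, -o.observed_axis) for o in obs
        ]
        assert dd.summed_angle_error(model, flipped) == pytest.approx(
            dd.summed_angle_error(model, obs), abs=1e-12
        )

    def test_fit_dominates_pure_strategies(self):
        obs = synth.synth_divisions(K_TRUE, n=60, noise_angle_deg=10.0, seed=11)
        _, objective = dd.fit_coefficients(obs, seed=11)
        for corner in np.eye(3):
            pure = dd.DivisionDirectionModel(corner)
            assert objective <= dd.summed_angle_error(pure, obs) + 1e-9


class TestPredictAxis:
    def test_isolated_cell_deep_in_shell_returns_polarity(self, default_shell):
        pol = np.array([0.0, 0.0, 1.0])
        cell = mech.Cell("m", [1.0, 0, 0], 2.0, polarity=pol)
        model = dd.DivisionDirectionModel([0.5, 0.3, 0.2])
        assert np.allclose(dd.predict_axis(model, cell, [], default_shell), pol)

    def test_shell_only_model_returns_inward_normal(self, default_shell):
        cell = mech.Cell("m", [25.0, 0, 0], 2.0, polarity=np.array([0.0, 1.0, 0.0]))
        model = dd.DivisionDirectionModel([0, 0, 1])
        assert np.allclose(
            dd.predict_axis(model, cell, [], default_shell), [-1, 0, 0]
        )

    def test_equals_manual_composition(self, rng, default_shell):
        pol = rng.normal(size=3)
        pol /= np.linalg.norm(pol)
        cell = mech.Cell("m", [22.0, 2.0, 1.0], 4.0, polarity=pol)
        nbs = [
            mech.Cell(f"n{k}", cell.position + rng.uniform(-3, 3, 3), 2.0)
            for k in range(3)
        ]
        model = dd.DivisionDirectionModel([0.4, 0.4, 0.2])
        s = dd.neighbor_squeeze_vector(cell, nbs)
        e = dd.eggshell_squeeze_vector(cell, default_shell)
        expected = dd.compose_direction(model, dd.DirectionComponents(pol, s, e))
        assert np.allclose(
            dd.predict_axis(model, cell, nbs, default_shell), expected, atol=1e-12
        )


def test_observation_table_round_trip(tmp_path):
    obs = synth.synth_divisions(K_TRUE, n=10, noise_angle_deg=5.0, seed=2)
    path = tmp_path / "obs.csv"
    dd.save_observations(obs, path)
    back = dd.load_observations(path)
    assert len(back) == len(obs)
    for a, b in zip(obs, back):
        assert a.name == b.name
        assert np.allclose(a.observed_axis, b.observed_axis, atol=1e-9)
        assert np.allclose(a.components.matrix(), b.components.matrix(), atol=1e-9)
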