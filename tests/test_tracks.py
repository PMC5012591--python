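import numpy as np
import pytest

from tumblekit.simulate import Trajectory, simulate_cells, yp_for_bias
from tumblekit.tracks import (
    BehaviorModel,
    DegenerateDataError,
    ShortTrajectoryError,
    annotate_states,
    compute_kinematics,
    fit_behavior_model,
    summarize_motility,
)


def make_traj(points, dt=1.0, cell_id="t"):
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) * dt
    return Trajectory(t=t, x=pts[:, 0], y=pts[:, 1], cell_id=cell_id)


class TestKinematics:
    def test_uniform_straight_motion(self, straight_trajectory):
        kin = compute_kinematics(straight_trajectory)
        v = kin.v[np.isfinite(kin.v)]
        assert np.allclose(v, 20.0)
        assert np.allclose(kin.a[np.isfinite(kin.a)], 0.0)
        assert np.allclose(kin.alpha[np.isfinite(kin.alpha)], 0.0)

    def test_four_point_corner(self):
        kin = compute_kinematics(make_traj([(0, 0), (1, 0), (2, 0), (2, 1)]))
        assert np.allclose(kin.v[:3], [1.0, 1.0, 1.0])
        assert kin.theta[1] == pytest.approx(0.0)
        assert kin.theta[2] == pytest.approx(np.pi / 2)

    def test_reversal_turn_angle(self):
        kin = compute_kinematics(make_traj([(0, 0), (1, 0), (0, 0), (1, 0)]))
        assert abs(kin.theta[1]) == pytest.approx(np.pi)

    def test_acceleration_formula(self):
        kin = compute_kinematics(make_traj([(0, 0), (1, 0), (3, 0), (6, 0)]))
        assert kin.v[0] == pytest.approx(1.0)
        assert kin.v[1] == pytest.approx(2.0)
        assert kin.a[0] == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(make_traj([(0, 0), (1, 0), (2, 0)]))

    def test_non_uniform_grid_rejected(self):
        tr = Trajectory(t=[0.0, 0.1, 0.3, 0.4], x=[0, 1, 2, 3], y=[0, 0, 0, 0])
        with pytest.raises(ValueError, match="non-uniform"):
            compute_kinematics(tr)

    def test_alignment_offsets(self):
        kin = compute_kinematics(make_traj(np.random.default_rng(0).normal(size=(10, 2))))
        n = 10
        assert np.isnan(kin.v[n - 1])
        assert np.isfinite(kin.v[: n - 1]).all()
        assert np.isnan(kin.theta[0])
        assert np.isfinite(kin.theta[1 : n - 1]).all()
        assert np.isfinite(kin.alpha[2 : n - 2]).all()
        assert np.isnan(kin.alpha[0]) and np.isnan(kin.alpha[1])


@pytest.fixture(scope="module")
def fitted_model_and_panel(request):
    panel = request.getfixturevalue("small_panel")
    trajs = [tr for trs in panel.values() for tr in trs]
    model = fit_behavior_model(trajs, seed=0)
    return model, panel, trajs


class TestBehaviorModel:
    def test_planted_mixture_recovery(self):
        # well-separated synthetic 3-component mixture in feature space,
        # injected through the public API via synthetic trajectories is
        # impractical; validate the mixture machinery on its own terms
        rng = np.random.default_rng(42)
        means = np.array([[1.0, 0.0, 0.0], [0.5, 0.3, 30.0], [0.05, -0.3, -30.0]])
        cov = np.diag([0.01, 0.01, 4.0])
        n = 4000
        X = np.vstack([rng.multivariate_normal(m, cov, n) for m in means])
        labels_true = np.repeat([0, 1, 2], n)
        from sklearn.mixture import GaussianMixture

        model = BehaviorModel(
            weights=np.ones(3) / 3,
            means=means,
            covariances=np.array([cov] * 3),
        )
        post = model.posterior(X)
        labels = np.argmax(post, axis=1)
        assert np.mean(labels == labels_true) >= 0.99
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_fit_recovers_separated_components(self, fitted_model_and_panel):
        model, _, _ = fitted_model_and_panel
        # S component (index 0) near normalized speed 1; T near 0
        assert model.means[0, 0] > 0.7
        assert model.means[2, 0] < 0.4
        assert model.weights.sum() == pytest.approx(1.0)

    def test_fit_deterministic(self, small_panel):
        trajs = small_panel[0.25]
        m1 = fit_behavior_model(trajs, seed=3)
        m2 = fit_behavior_model(trajs, seed=3)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.covariances, m2.covariances)

    def test_degenerate_input_raises(self):
        trajs = [
            Trajectory(
                t=np.arange(200) * 0.1,
                x=np.arange(200) * 2.0,
                y=np.zeros(200),
                cell_id=f"d{i}",
            )
            for i in range(5)
        ]
        with pytest.raises((DegenerateDataError, ValueError)):
            fit_behavior_model(trajs, seed=0)

    def test_json_roundtrip(self, fitted_model_and_panel, tmp_path):
        model, _, _ = fitted_model_and_panel
        path = tmp_path / "model.json"
        model.save(path)
        loaded = BehaviorModel.load(path)
        assert np.allclose(loaded.means, model.means)
        assert np.allclose(loaded.covariances, model.covariances)
        assert loaded.state_names == model.state_names


class TestAnnotate:
    def test_posteriors_sum_to_one(self, fitted_model_and_panel):
        model, panel, _ = fitted_model_and_panel
        ann = annotate_states(panel[0.25][0], model)
        assert np.allclose(ann.posterior.sum(axis=1), 1.0)

    def test_argmax_is_state(self, fitted_model_and_panel):
        model, panel, _ = fitted_model_and_panel
        ann = annotate_states(panel[0.4][1], model)
        names = np.array(model.state_names, dtype=object)
        assert np.array_equal(names[np.argmax(ann.posterior, axis=1)], ann.state)

    def test_component_mean_dominant_posterior(self, fitted_model_and_panel):
        model, _, _ = fitted_model_and_panel
        post = model.posterior(model.means[0][None, :])
        # at the swim mean, swim posterior dominates (components overlap
        # somewhat in real fits, so only require a clear majority)
        assert post[0, 0] > 0.5

    def test_truth_agreement_beats_chance(self, fitted_model_and_panel):
        model, panel, _ = fitted_model_and_panel
        agree = []
        for tr in panel[0.4][:5]:
            ann = annotate_states(tr, model)
            truth_tumble = tr.truth_state == "tumble"
            pred_tumble = ann.state == "T"
            agree.append(np.mean(truth_tumble == pred_tumble))
        assert np.mean(agree) > 0.8

    def test_scale_invariance_of_labels(self, fitted_model_and_panel):
        model, panel, _ = fitted_model_and_panel
        tr = panel[0.25][2]
        scaled = Trajectory(
            t=tr.t, x=3.0 * tr.x, y=3.0 * tr.y, cell_id="scaled"
        )
        a1 = annotate_states(tr, model)
        a2 = annotate_states(scaled, model)
        # speed normalization absorbs the scale; alpha is scale-free
        assert np.mean(a1.state == a2.state) > 0.95


class TestSummaries:
    def _annotation(self, n, states):
        from tumblekit.tracks import StateAnnotation

        post = np.zeros((n, 3))
        order = {"S": 0, "I": 1, "T": 2}
        for i, s in enumerate(states):
            post[i, order[s]] = 1.0
        return StateAnnotation(state=np.array(states, dtype=object), posterior=post)

    def test_all_swimming(self):
        n = 201
        tr = Trajectory(
            t=np.arange(n) * 0.1, x=np.arange(n) * 2.0, y=np.zeros(n), cell_id="s"
        )
        ann = self._annotation(n, ["S"] * n)
        summ = summarize_motility(tr, ann)
        assert summ.tumble_bias == 0.0
        assert summ.mean_run_time == pytest.approx(n * 0.1)

    def test_alternating_blocks_arithmetic(self):
        # 9 s S / 1 s T blocks at 10 Hz; raw frame fraction = 0.1
        states = (["S"] * 90 + ["T"] * 10) * 3
        n = len(states)
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.normal(size=(n, 2)), axis=0)
        tr = Trajectory(t=np.arange(n) * 0.1, x=xy[:, 0], y=xy[:, 1], cell_id="alt")
        ann = self._annotation(n, states)
        summ = summarize_motility(tr, ann, boundary_correction=False)
        assert summ.tumble_bias == pytest.approx(0.1)
        assert summ.n_tumbles == 3
        # boundary correction credits one frame per tumble block
        summ2 = summarize_motility(tr, ann, boundary_correction=True)
        assert summ2.tumble_bias == pytest.approx((30 + 3) / n)

    def test_intermediate_counting_switch(self):
        states = ["S"] * 80 + ["I"] * 10 + ["T"] * 10 + ["S"] * 100
        n = len(states)
        tr = Trajectory(
            t=np.arange(n) * 0.1, x=np.arange(n) * 1.0, y=np.zeros(n), cell_id="i"
        )
        ann = self._annotation(n, states)
        s1 = summarize_motility(tr, ann, boundary_correction=False)
        s2 = summarize_motility(
            tr, ann, boundary_correction=False, count_intermediate_as_tumble=True
        )
        assert s1.tumble_bias == pytest.approx(10 / n)
        assert s2.tumble_bias == pytest.approx(20 / n)

    def test_short_trajectory_filtered(self):
        n = 50
        tr = Trajectory(
            t=np.arange(n) * 0.1, x=np.arange(n) * 1.0, y=np.zeros(n), cell_id="sh"
        )
        ann = self._annotation(n, ["S"] * n)
        with pytest.raises(ShortTrajectoryError):
            summarize_motility(tr, ann, min_duration=10.0)

    def test_estimator_tracks_truth_on_panel(self, fitted_model_and_panel):
        model, panel, _ = fitted_model_and_panel
        means = {}
        for b, trs in panel.items():
            tbs = []
            for tr in trs:
                ann = annotate_states(tr, model)
                tbs.append(summarize_motility(tr, ann).tumble_bias)
            means[b] = np.mean(tbs)
        # monotone in the simulated bias and close to it
        assert means[0.1] < means[0.25] < means[0.4]
        for b, est in means.items():
            assert est == pytest.approx(b, abs=0.05)


class TestIdempotence:
    def test_reannotation_stable(self, fitted_model_and_panel):
        model, panel, _ = fitted_model_and_panel
        tr = panel[0.25][0]
        a1 = annotate_states(tr, model)
        a2 = annotate_states(tr, model)
        assert np.array_equal(a1.state, a2.state)
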