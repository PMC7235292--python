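"""Network simulation, evidence scoring, and two-process model selection."""

import numpy as np
import pytest
from scipy.linalg import expm

from ctxlearn import (
    AgentParams,
    ScanTimeline,
    TaskConfig,
    build_input_timecourses,
    enumerate_process1,
    enumerate_process2,
    score_model,
    select_model,
    simulate_network,
    simulate_session,
)
from ctxlearn.connectivity import (
    StabilityError,
    TRUE_P1_NAME,
    TRUE_P2_NAME,
    integrate_linear,
    posterior_probabilities,
    true_network,
    two_process_selection,
)
from ctxlearn.glm import events_from_session
import pandas as pd


@pytest.fixture(scope="module")
def timeline():
    return ScanTimeline()


@pytest.fixture(scope="module")
def session(timeline):
    return simulate_session(TaskConfig(), AgentParams(0.3, -3.0), 20)


@pytest.fixture(scope="module")
def inputs(session, timeline):
    return build_input_timecourses(session, timeline=timeline)


class TestInputs:
    def test_pain_stream_counts(self, session, inputs):
        n_pain = sum(tr.outcome for tr in session.trials)
        assert np.count_nonzero(inputs["pain"]) == n_pain
        assert np.count_nonzero(inputs["images"]) == 60

    def test_frozen_model_value_streams_vanish(self, timeline):
        s = simulate_session(TaskConfig(), AgentParams(0.5, 0.0), 2)
        streams = build_input_timecourses(s, timeline=timeline)
        assert np.all(streams["state_value"] == 0.0)
        assert np.all(streams["ape"] == 0.0)

    def test_timing_matches_event_set(self, session, inputs, timeline):
        ev = events_from_session(session)
        pain_idx = sorted(
            timeline.micro_index(t) for t in ev.events["outcome_pain"]
        )
        assert np.flatnonzero(inputs["pain"]).tolist() == pain_idx
        img_idx = sorted(
            timeline.micro_index(t)
            for t in np.concatenate(
                [ev.events["shape_A"], ev.events["shape_B"]]
            )
        )
        assert np.flatnonzero(inputs["images"]).tolist() == img_idx


class TestModelSpaces:
    def test_process1_has_24_fully_connected_candidates(self):
        space = enumerate_process1()
        assert len(space.models) == 24
        off_diag = ~np.eye(4, dtype=bool)
        for m in space.models:
            assert np.array_equal(m.a_mask, off_diag)

    def test_process1_order_stable(self):
        names1 = [m.name for m in enumerate_process1().models]
        names2 = [m.name for m in enumerate_process1().models]
        assert names1 == names2
        assert TRUE_P1_NAME in names1

    def test_process2_candidates_share_winner_inputs(self):
        winner = next(
            m for m in enumerate_process1().models if m.name == TRUE_P1_NAME
        )
        space = enumerate_process2(winner)
        assert len(space.models) == 8
        names = [m.name for m in space.models]
        assert TRUE_P2_NAME in names  # hippocampus->habenula only
        for m in space.models:
            assert np.array_equal(m.c_mask, winner.c_mask)

    def test_symmetry_classes_mirror_consistent(self):
        for m in enumerate_process2(
            enumerate_process1().models[0]
        ).models:
            for cls in m.a_classes():
                # a class either contains one self-mirrored edge or an
                # edge and its left/right mirror image
                assert len(cls) in (1, 2)
                if len(cls) == 2:
                    (i1, j1), (i2, j2) = cls
                    assert (i2, j2) == (
                        [1, 0, 3, 2][i1], [1, 0, 3, 2][j1]
                    )

    def test_unstable_self_decay_rejected(self):
        from ctxlearn.connectivity import NetworkModel

        with pytest.raises(StabilityError):
            NetworkModel(
                name="bad",
                a_mask=np.zeros((4, 4), bool),
                c_mask=np.zeros((4, 4), bool),
                self_decay=0.5,
            )

    def test_all_candidates_stable_at_moderate_weights(self):
        for m in enumerate_process1().models[:4]:
            nA = len(m.a_classes())
            nC = len(m.c_classes())
            fitted = m.with_weights(np.full(nA, 0.2), np.full(nC, 0.5))
            assert np.linalg.eigvals(fitted.A).real.max() < 0


class TestForwardModel:
    def test_single_node_impulse_matches_analytic(self):
        # dz/dt = -z driven by a unit stick: z(t) = exp(-t) after onset
        dt = 0.1
        forcing = np.zeros((200, 1))
        forcing[0, 0] = 1.0 / dt  # unit-mass stick
        z = integrate_linear(np.array([[-1.0]]), forcing, dt)
        t = np.arange(199) * dt
        assert np.abs(z[1:, 0] - np.exp(-t)).max() < 1e-4

    def test_matches_naive_propagator_loop(self, rng):
        A = -np.eye(4) + 0.25 * rng.standard_normal((4, 4)) * (
            ~np.eye(4, dtype=bool)
        )
        S = rng.standard_normal((400, 4))
        z = integrate_linear(A, S, 0.1)
        M = expm(A * 0.1)
        zn = np.zeros((400, 4))
        for k in range(1, 400):
            zn[k] = M @ zn[k - 1] + 0.1 * S[k - 1]
        assert np.abs(z - zn).max() < 1e-10

    def test_defective_feedforward_matrix_handled(self, rng):
        A = true_network().A  # -I + nilpotent coupling: defective
        S = rng.standard_normal((300, 4))
        z = integrate_linear(A, S, 0.1)
        M = expm(A * 0.1)
        zn = np.zeros((300, 4))
        for k in range(1, 300):
            zn[k] = M @ zn[k - 1] + 0.1 * S[k - 1]
        assert np.abs(z - zn).max() < 1e-10

    def test_no_input_gives_silence(self, inputs, timeline):
        model = true_network()
        model = model.with_weights(
            np.zeros(len(model.a_classes())),
            np.zeros(len(model.c_classes())),
        )
        bold = simulate_network(model, inputs, timeline)
        assert np.all(bold == 0.0)

    def test_linearity_doubling_inputs(self, inputs, timeline):
        truth = true_network()
        doubled = truth.with_weights(
            [truth.A[i, j] for cls in truth.a_classes() for i, j in cls[:1]],
            [2 * truth.C[i, k] for cls in truth.c_classes()
             for i, k in cls[:1]],
        )
        b1 = simulate_network(truth, inputs, timeline)
        b2 = simulate_network(doubled, inputs, timeline)
        assert np.abs(b2 - 2 * b1).max() < 1e-8 * np.abs(b1).max()

    def test_noise_reproducible_by_seed(self, inputs, timeline):
        truth = true_network()
        a = simulate_network(truth, inputs, timeline, noise_sd=0.1, seed=5)
        b = simulate_network(truth, inputs, timeline, noise_sd=0.1, seed=5)
        assert np.array_equal(a, b)


class TestScoring:
    def test_posteriors_hand_example(self):
        post = posterior_probabilities(np.array([0.0, -np.log(3.0)]))
        assert post == pytest.approx([0.75, 0.25], abs=1e-12)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_evidence_uniform(self):
        post = posterior_probabilities(np.zeros(5))
        assert np.allclose(post, 0.2, atol=1e-12)

    def test_select_model_reports_best_and_ties(self):
        table = pd.DataFrame(
            {"model": ["a", "b"], "log_evidence": [0.0, -np.log(3.0)]}
        )
        best, out = select_model(table)
        assert best == "a"
        assert out.attrs["n_ties"] == 1

    def test_nested_model_penalized_at_equal_fit(
        self, session, inputs, timeline
    ):
        truth = true_network()
        bold = simulate_network(truth, inputs, timeline)
        winner = next(
            m for m in enumerate_process1().models if m.name == TRUE_P1_NAME
        )
        space = enumerate_process2(winner)
        hc2hb = next(m for m in space.models if m.name == TRUE_P2_NAME)
        bidir = next(
            m for m in space.models if m.name == "p2|bidirectional"
        )
        s_simple = score_model(bold, hc2hb, inputs, timeline)
        s_complex = score_model(bold, bidir, inputs, timeline)
        # both fit the noiseless data; the smaller model must win on BIC
        assert s_simple.k < s_complex.k
        assert s_simple.log_evidence > s_complex.log_evidence

    def test_true_model_beats_wrong_inputs_by_margin(
        self, session, inputs, timeline
    ):
        truth = true_network()
        bold = simulate_network(truth, inputs, timeline)
        models = {m.name: m for m in enumerate_process1().models}
        s_true = score_model(bold, models[TRUE_P1_NAME], inputs, timeline)
        s_wrong = score_model(
            bold, models["p1|img+ape|Hb"], inputs, timeline
        )
        assert s_true.log_evidence - s_wrong.log_evidence > 3.0

    def test_evidence_invariant_to_region_order(
        self, session, inputs, timeline
    ):
        truth = true_network()
        bold = simulate_network(truth, inputs, timeline)
        m = next(
            m for m in enumerate_process1().models if m.name == TRUE_P1_NAME
        )
        s1 = score_model(bold, m, inputs, timeline)
        # swapping homologous regions and their mirrored model leaves the
        # total evidence unchanged
        perm = [1, 0, 3, 2]
        bold_perm = bold[:, perm]
        s2 = score_model(bold_perm, m, inputs, timeline)
        assert s1.log_evidence == pytest.approx(
            s2.log_evidence, abs=1e-3
        )


class TestRecovery:
    def test_noiseless_two_process_recovery(self, session, inputs, timeline):
        truth = true_network()
        bold = simulate_network(truth, inputs, timeline)
        sel = two_process_selection(bold, inputs, timeline)
        assert sel["p1_winner"] == TRUE_P1_NAME
        assert sel["p2_winner"] == TRUE_P2_NAME
        assert sel["p2_table"].attrs["best"] == TRUE_P2_NAME

    def test_recovered_hc_to_hb_weights_positive(
        self, session, inputs, timeline
    ):
        truth = true_network()
        bold = simulate_network(truth, inputs, timeline)
        winner = next(
            m for m in enumerate_process1().models if m.name == TRUE_P1_NAME
        )
        hc2hb = next(
            m for m in enumerate_process2(winner).models
            if m.name == TRUE_P2_NAME
        )
        score = score_model(bold, hc2hb, inputs, timeline)
        # generating couplings are positive; the fit must recover the sign
        assert np.all(score.a_weights > 0)

    def test_scoring_rejects_wrong_shape(self, inputs, timeline):
        truth = true_network()
        with pytest.raises(ValueError):
            score_model(
                np.zeros((timeline.n_volumes, 3)), truth, inputs, timeline
            )
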