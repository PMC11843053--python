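"""Secure aggregation server: FedAvg arithmetic, barrier semantics,
token-gated isolation, dropout recovery, finalization."""

import itertools

import numpy as np
import pytest

from conftest import random_weightset
from fedseg.aggregator import SecureAggregationServer, fedavg_aggregate
from fedseg.coordinator import TaskSpec
from fedseg.errors import (
    ConfigurationError,
    ConflictError,
    NotFoundError,
    StateError,
    TokenRejection,
    WeightCompatibilityError,
)
from fedseg.tokens import TokenClaims, issue_iteration_token
from fedseg.training import init_weights
from fedseg.unet import ModelConfig
from fedseg.weights import WeightMeta, WeightSet

NOW = 1_700_000_000.0
KEY = b"k" * 32
TINY = ModelConfig(depth=1, base_filters=1, input_shape=(8, 8))


def ws(values, n=1, name="w"):
    return WeightSet(
        [(name, np.asarray(values, dtype=np.float32))],
        WeightMeta(task_id="t", n_train_samples=n),
    )


class TestFedAvg:
    def test_single_model_is_bit_identical_passthrough(self):
        w = ws([0.1, -2.5, 3.75], n=7)
        out = fedavg_aggregate([w])
        assert np.array_equal(out.entries[0][1], w.entries[0][1])
        assert out.meta.origin == "SAS"

    def test_uniform_mean_worked_example(self):
        out = fedavg_aggregate([ws([1.0, 3.0]), ws([3.0, 5.0])], "uniform")
        assert out.entries[0][1].tolist() == [2.0, 4.0]

    def test_sample_weighted_worked_example(self):
        # (1*0 + 3*4)/4 = 3 ; (1*0 + 3*8)/4 = 6
        out = fedavg_aggregate([ws([0.0, 0.0], n=1), ws([4.0, 8.0], n=3)])
        assert out.entries[0][1].tolist() == [3.0, 6.0]
        assert out.meta.n_train_samples == 4

    def test_manifest_mismatch_rejected(self):
        with pytest.raises(WeightCompatibilityError):
            fedavg_aggregate([ws([1.0]), ws([1.0, 2.0])])

    def test_zero_samples_under_sample_weighting_rejected(self):
        with pytest.raises(ConfigurationError):
            fedavg_aggregate([ws([1.0], n=0), ws([2.0], n=0)])

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            fedavg_aggregate([])

    @pytest.mark.parametrize("weighting", ["sample_weighted", "uniform"])
    def test_matches_bruteforce_scalar_loop_over_fuzzed_inputs(self, weighting):
        """Independent oracle: flatten every entry and average scalar by
        scalar in plain Python; 120 fuzzed manifests/weights/counts must
        agree within 1e-6 max-abs."""
        rng = np.random.default_rng(99)
        for trial in range(120):
            k = int(rng.integers(1, 6))
            proto = random_weightset(rng)
            models = []
            for _ in range(k):
                entries = [
                    (nm, rng.uniform(-1, 1, size=v.shape).astype(np.float32))
                    for nm, v in proto.entries
                ]
                models.append(
                    WeightSet(
                        entries,
                        WeightMeta(task_id="t", n_train_samples=int(rng.integers(1, 100))),
                    )
                )
            out = fedavg_aggregate(models, weighting)
            counts = [
                m.meta.n_train_samples if weighting == "sample_weighted" else 1
                for m in models
            ]
            total = sum(counts)
            for j, (nm, v) in enumerate(out.entries):
                flats = [m.entries[j][1].ravel() for m in models]
                for pos in range(v.size):
                    expected = (
                        sum(c * float(f[pos]) for c, f in zip(counts, flats)) / total
                    )
                    assert abs(float(v.ravel()[pos]) - expected) <= 1e-6

    def test_convexity_of_every_output_parameter(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            proto = random_weightset(rng)
            models = []
            for _ in range(int(rng.integers(2, 5))):
                entries = [
                    (nm, rng.uniform(-10, 10, size=v.shape).astype(np.float32))
                    for nm, v in proto.entries
                ]
                models.append(
                    WeightSet(entries, WeightMeta(n_train_samples=int(rng.integers(1, 9))))
                )
            out = fedavg_aggregate(models)
            for j, (_, v) in enumerate(out.entries):
                stack = np.stack([m.entries[j][1] for m in models])
                assert np.all(v >= stack.min(axis=0) - 1e-6)
                assert np.all(v <= stack.max(axis=0) + 1e-6)


def make_task(n_stations=3, n_iterations=2, task_id="t"):
    return TaskSpec(
        task_id=task_id,
        algorithm_ref="fedseg-unet2d",
        input_params={"model_seed": 0},
        n_iterations=n_iterations,
        aggregator_id="SAS",
        station_ids=tuple(f"s{i}" for i in range(n_stations)),
    )


def make_sas(n_stations=3, n_iterations=2):
    sas = SecureAggregationServer(clock=lambda: NOW)
    task = make_task(n_stations, n_iterations)
    sas.start_task(task, TINY, signing_key=KEY)
    return sas, task


def local_update(sas, task, sid, scale=1.0, n=5):
    """A station's stand-in update: released model plus a station offset."""
    token = sas.request_token(task.task_id, sid)
    base = sas.release_global_model(task.task_id, token)
    entries = [
        (nm, v + scale * (1 + int(sid[1:]))) for nm, v in base.entries
    ]
    return token, WeightSet(entries, WeightMeta(task_id=task.task_id, n_train_samples=n))


class TestStartTask:
    def test_initial_state(self):
        sas, task = make_sas(3)
        state = sas.state_of("t")
        assert state.status == "waiting"
        assert state.expected_stations == frozenset({"s0", "s1", "s2"})
        assert state.current_iteration == 0

    def test_duplicate_task_id_conflicts(self):
        sas, task = make_sas()
        with pytest.raises(ConflictError):
            sas.start_task(task, TINY, signing_key=KEY)

    def test_initial_model_equals_seeded_init_weights(self):
        sas, task = make_sas()
        expected = init_weights(TINY, 0, task_id="t")
        assert sas.state_of("t").latest_successful_model.allclose(expected)


class TestBarrier:
    def test_partial_submissions_keep_waiting(self):
        sas, task = make_sas(3)
        for sid in ("s0", "s1"):
            token, w = local_update(sas, task, sid)
            sas.accept_model_submission("t", token, w)
        state = sas.state_of("t")
        assert state.status == "waiting"
        assert state.n_aggregations == 0

    def test_final_submission_triggers_exactly_one_aggregation(self):
        sas, task = make_sas(3)
        for sid in ("s0", "s1", "s2"):
            token, w = local_update(sas, task, sid)
            sas.accept_model_submission("t", token, w)
        state = sas.state_of("t")
        assert state.n_aggregations == 1
        assert state.current_iteration == 1
        assert state.latest_successful_model.meta.iteration == 0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_randomized_submission_orderings(self, k):
        """Aggregation fires exactly once per iteration, only when all K
        submissions are in, for every tested ordering."""
        rng = np.random.default_rng(k)
        orders = [list(rng.permutation(k)) for _ in range(8)]
        if k <= 3:
            orders = [list(p) for p in itertools.permutations(range(k))]
        for order in orders:
            sas, task = make_sas(k, n_iterations=1)
            for pos, idx in enumerate(order):
                token, w = local_update(sas, task, f"s{idx}")
                sas.accept_model_submission("t", token, w)
                agg_count = sas.state_of("t").n_aggregations
                assert agg_count == (1 if pos == k - 1 else 0)

    def test_duplicate_submission_refused_first_wins(self):
        sas, task = make_sas(3)
        token, w = local_update(sas, task, "s0")
        sas.accept_model_submission("t", token, w)
        first = sas.state_of("t").received["s0"].copy()
        token2 = sas.request_token("t", "s0")
        _, w2 = local_update(sas, task, "s1")  # different weights
        with pytest.raises(ConflictError):
            sas.accept_model_submission(
                "t", token2, WeightSet(w2.entries, WeightMeta(n_train_samples=3))
            )
        assert sas.state_of("t").received["s0"].allclose(first)

    def test_stale_token_submission_leaves_state_unchanged(self):
        sas, task = make_sas(2, n_iterations=3)
        stale = {sid: sas.request_token("t", sid) for sid in ("s0", "s1")}
        for sid in ("s0", "s1"):
            token, w = local_update(sas, task, sid)
            sas.accept_model_submission("t", token, w)  # iteration 0 done
        snapshot = sas.state_of("t").latest_successful_model.copy()
        _, w = local_update(sas, task, "s0")
        with pytest.raises(TokenRejection):
            sas.accept_model_submission("t", stale["s0"], w)
        state = sas.state_of("t")
        assert state.received == {}
        assert state.latest_successful_model.allclose(snapshot)
        assert state.n_aggregations == 1

    def test_manifest_mismatch_refused(self):
        sas, task = make_sas(2)
        token = sas.request_token("t", "s0")
        alien = init_weights(ModelConfig(depth=1, base_filters=2, input_shape=(8, 8)), 0)
        with pytest.raises(WeightCompatibilityError):
            sas.accept_model_submission("t", token, alien)
        assert sas.state_of("t").received == {}


class TestRelease:
    def test_iteration1_request_returns_iteration0_model(self):
        sas, task = make_sas(2, n_iterations=3)
        for sid in ("s0", "s1"):
            token, w = local_update(sas, task, sid)
            sas.accept_model_submission("t", token, w)
        token = sas.request_token("t", "s0")
        released = sas.release_global_model("t", token)
        assert released.meta.iteration == 0  # aggregated at iteration 0

    def test_forged_token_refused(self):
        sas, task = make_sas(2)
        claims = TokenClaims("s0", "t", 0, NOW, NOW + 600)
        forged = issue_iteration_token(claims, b"wrong-key-0000000000000000000000")
        with pytest.raises(TokenRejection):
            sas.release_global_model("t", forged)

    def test_concurrent_readers_get_identical_models(self):
        sas, task = make_sas(2)
        t0 = sas.request_token("t", "s0")
        t1 = sas.request_token("t", "s1")
        a = sas.release_global_model("t", t0)
        b = sas.release_global_model("t", t1)
        assert a.allclose(b)


class TestDropoutRecovery:
    def run_iteration(self, sas, task, exclude=()):
        for sid in task.station_ids:
            if sid in exclude:
                continue
            token, w = local_update(sas, task, sid)
            sas.accept_model_submission("t", token, w)

    def test_abort_discards_partials_and_preserves_latest_model(self):
        sas, task = make_sas(3, n_iterations=4)
        self.run_iteration(sas, task)  # iteration 0 aggregated
        snapshot = sas.state_of("t").latest_successful_model.copy()
        # iteration 1: two stations submit, third fails
        self.run_iteration(sas, task, exclude=("s2",))
        sas.report_station_failure("t", "s2")
        state = sas.state_of("t")
        assert state.status == "aborted"
        assert state.received == {}
        assert state.latest_successful_model.allclose(snapshot)

    def test_resume_reopens_same_iteration_with_fresh_tokens(self):
        sas, task = make_sas(3, n_iterations=4)
        self.run_iteration(sas, task)
        old_token = sas.request_token("t", "s0")
        sas.report_station_failure("t", "s1")
        sas.resume_iteration("t")
        # pre-abort token of the same iteration index is now a replay
        _, w = local_update(sas, task, "s0")
        with pytest.raises(TokenRejection):
            sas.accept_model_submission("t", old_token, w)
        # full re-run of the re-opened iteration aggregates at iteration 1
        self.run_iteration(sas, task)
        assert sas.state_of("t").latest_successful_model.meta.iteration == 1

    def test_unknown_station_failure_report_rejected(self):
        sas, task = make_sas(2)
        with pytest.raises(NotFoundError):
            sas.report_station_failure("t", "nobody")


class TestFinalize:
    def complete(self, sas, task):
        for _ in range(task.n_iterations):
            for sid in task.station_ids:
                token, w = local_update(sas, task, sid)
                sas.accept_model_submission("t", token, w)

    def test_finalize_returns_last_iteration_model_once_complete(self):
        sas, task = make_sas(2, n_iterations=5)
        self.complete(sas, task)
        final = sas.finalize_task("t")
        assert final.meta.iteration == 4  # 0-based indexing
        assert sas.state_of("t").status == "finished"

    def test_premature_finalize_refused(self):
        sas, task = make_sas(2, n_iterations=5)
        for _ in range(2):
            for sid in task.station_ids:
                token, w = local_update(sas, task, sid)
                sas.accept_model_submission("t", token, w)
        with pytest.raises(StateError):
            sas.finalize_task("t")
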