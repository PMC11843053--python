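"""Central coordinator: registry, auth, role matrix, task lifecycle,
status monotonicity, final-model-only persistence."""

import numpy as np
import pytest

from fedseg.coordinator import _PERMISSIONS, Coordinator, TaskSpec
from fedseg.errors import (
    AccessDeniedError,
    AuthenticationError,
    AuthorizationError,
    ChannelViolationError,
    ConfigurationError,
    ConflictError,
    NotFoundError,
    StateError,
)
from fedseg.weights import WeightMeta, WeightSet


class Clock:
    def __init__(self, t=1000.0):
        self.t = t

    def __call__(self):
        return self.t


@pytest.fixture()
def clock():
    return Clock()


@pytest.fixture()
def coord(clock):
    c = Coordinator(clock=clock)
    c.register_entity("alice", "researcher", "pw-alice")
    c.register_entity("SAS", "aggregator", "pw-sas")
    for sid in ("s0", "s1", "s2"):
        c.register_entity(sid, "station", f"pw-{sid}")
    return c


def spec(task_id="t", n_iterations=3, stations=("s0", "s1", "s2")):
    return TaskSpec(
        task_id=task_id,
        algorithm_ref="fedseg-unet2d",
        input_params={"model_seed": 0},
        n_iterations=n_iterations,
        aggregator_id="SAS",
        station_ids=tuple(stations),
    )


def final_model(iteration):
    return WeightSet(
        [("w", np.arange(3, dtype=np.float32))],
        WeightMeta(task_id="t", iteration=iteration, origin="SAS", n_train_samples=9),
    )


def run_to_completion(coord, n_iterations=3, stations=("s0", "s1", "s2")):
    researcher = coord.authenticate("alice", "pw-alice")
    sas = coord.authenticate("SAS", "pw-sas")
    coord.submit_task(researcher, spec(n_iterations=n_iterations, stations=stations))
    for it in range(n_iterations):
        for sid in stations:
            sess = coord.authenticate(sid, f"pw-{sid}")
            coord.report_status(sess, "t", it, "completed")
        coord.report_status(sas, "t", it, "completed")
    return researcher, sas


class TestRegistryAuth:
    def test_register_then_authenticate(self, coord):
        session = coord.authenticate("alice", "pw-alice")
        assert session.role == "researcher"

    def test_duplicate_registration_conflicts(self, coord):
        with pytest.raises(ConflictError):
            coord.register_entity("alice", "researcher", "other")

    def test_no_recoverable_plaintext_password_stored(self, coord):
        entity = coord._entities["alice"]
        assert b"pw-alice" not in entity.digest
        assert "pw-alice" not in repr(entity)

    def test_wrong_password_and_unknown_user_fail_identically(self, coord):
        with pytest.raises(AuthenticationError) as e1:
            coord.authenticate("alice", "wrong")
        with pytest.raises(AuthenticationError) as e2:
            coord.authenticate("nobody", "wrong")
        assert str(e1.value) == str(e2.value)

    def test_expired_session_requires_reauthentication(self, coord, clock):
        session = coord.authenticate("s0", "pw-s0")
        clock.t += 100_000
        with pytest.raises(AuthenticationError, match="re-authentication"):
            coord.pull_work(session)

    def test_unknown_role_rejected(self, coord):
        with pytest.raises(ConfigurationError):
            coord.register_entity("x", "admin", "pw")


class TestRoleMatrix:
    OPS = {
        "submit_task": lambda c, s: c.submit_task(s, spec(task_id="rm")),
        "pull_work": lambda c, s: c.pull_work(s),
        "report_status": lambda c, s: c.report_status(s, "t", 0, "completed"),
        "store_final_model": lambda c, s: c.store_final_model(s, "t", final_model(2)),
        "fetch_final_model": lambda c, s: c.fetch_final_model(s, "t"),
        "check_status": lambda c, s: c.check_status(s, "t"),
    }
    ENTITY = {"researcher": "alice", "aggregator": "SAS", "station": "s0"}

    @pytest.mark.parametrize("op", sorted(OPS))
    @pytest.mark.parametrize("role", sorted(ENTITY))
    def test_every_disallowed_role_operation_pair_is_rejected(self, coord, op, role):
        """Exhaustive sweep of the role x operation matrix: pairs outside
        the allow-list must raise AuthorizationError before any state is
        touched."""
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        session = coord.authenticate(self.ENTITY[role], f"pw-{self.ENTITY[role].lower()}"
                                     if role != "aggregator" else "pw-sas")
        if role in _PERMISSIONS[op]:
            pytest.skip("allowed pair; behaviour covered elsewhere")
        with pytest.raises(AuthorizationError):
            self.OPS[op](coord, session)


class TestTaskLifecycle:
    def test_submit_enqueues_master_plus_subtasks(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        sas = coord.authenticate("SAS", "pw-sas")
        master = coord.pull_work(sas)
        assert [i["kind"] for i in master] == ["master"]
        for sid in ("s0", "s1", "s2"):
            sess = coord.authenticate(sid, f"pw-{sid}")
            items = coord.pull_work(sess)
            assert [i["kind"] for i in items] == ["subtask"]
            assert all(i["assignee"] == sid for i in items)

    def test_unregistered_station_in_roster_rejected(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        with pytest.raises(ConfigurationError):
            coord.submit_task(researcher, spec(stations=("s0", "ghost")))

    def test_zero_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            spec(n_iterations=0)

    def test_duplicate_task_id_conflicts(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        with pytest.raises(ConflictError):
            coord.submit_task(researcher, spec())

    def test_repull_within_lease_returns_same_item_not_duplicated(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        sess = coord.authenticate("s0", "pw-s0")
        first = coord.pull_work(sess)
        second = coord.pull_work(sess)
        assert first == second and len(first) == 1


class TestStatus:
    def test_completed_row_after_all_reports(self, coord):
        run_to_completion(coord, n_iterations=1)
        sess = coord.authenticate("alice", "pw-alice")
        status = coord.check_status(sess, "t")
        assert all(v == "completed" for v in status["cells"].values())

    def test_aborted_report_flips_overall_until_reopened(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        sess = coord.authenticate("s0", "pw-s0")
        coord.report_status(sess, "t", 0, "aborted")
        assert coord.check_status(sess, "t")["overall"] == "aborted"
        coord.report_status(sess, "t", 0, "pending")
        assert coord.check_status(sess, "t")["overall"] == "running"

    def test_status_regression_refused(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        sess = coord.authenticate("s0", "pw-s0")
        coord.report_status(sess, "t", 0, "completed")
        with pytest.raises(StateError):
            coord.report_status(sess, "t", 0, "running")

    def test_weight_payload_on_status_channel_refused(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec())
        sess = coord.authenticate("s0", "pw-s0")
        with pytest.raises(ChannelViolationError):
            coord.report_status(sess, "t", 0, "completed", metrics=final_model(0))
        with pytest.raises(ChannelViolationError):
            coord.report_status(
                sess, "t", 0, "completed", metrics={"entries": [[1, 2, 3]]}
            )

    def test_unaddressed_reporter_rejected(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec(stations=("s0", "s1")))
        outsider = coord.authenticate("s2", "pw-s2")
        with pytest.raises(AuthorizationError):
            coord.report_status(outsider, "t", 0, "completed")


class TestFinalModelStore:
    def test_midtask_store_refused_and_audit_stays_zero(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        sas = coord.authenticate("SAS", "pw-sas")
        coord.submit_task(researcher, spec(n_iterations=5))
        with pytest.raises(StateError):
            coord.store_final_model(sas, "t", final_model(2))
        assert coord.audit_stored_weight_payloads() == {"t": 0}

    def test_store_after_completion_then_exactly_one_model(self, coord):
        researcher, sas = run_to_completion(coord)
        coord.store_final_model(sas, "t", final_model(2))
        assert coord.audit_stored_weight_payloads() == {"t": 1}
        with pytest.raises(ConflictError):
            coord.store_final_model(sas, "t", final_model(2))

    def test_fetch_during_run_is_access_denied_not_not_found(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        coord.submit_task(researcher, spec(n_iterations=5))
        with pytest.raises(AccessDeniedError):
            coord.fetch_final_model(researcher, "t")

    def test_fetch_after_finish_round_trips_bytes(self, coord):
        researcher, sas = run_to_completion(coord)
        stored = final_model(2)
        coord.store_final_model(sas, "t", stored)
        fetched = coord.fetch_final_model(researcher, "t")
        assert fetched.allclose(stored)
        assert fetched.meta == stored.meta

    def test_fetch_unknown_task_is_not_found(self, coord):
        researcher = coord.authenticate("alice", "pw-alice")
        with pytest.raises(NotFoundError):
            coord.fetch_final_model(researcher, "zzz")


def test_journal_records_lifecycle_and_final_model(tmp_path, clock):
    import base64
    import json as json_mod

    from fedseg.weights import deserialize_weights_bytes

    journal = tmp_path / "coordinator.jsonl"
    c = Coordinator(journal_path=journal, clock=clock)
    c.register_entity("alice", "researcher", "pw-alice")
    c.register_entity("SAS", "aggregator", "pw-sas")
    c.register_entity("s0", "station", "pw-s0")
    researcher = c.authenticate("alice", "pw-alice")
    sas = c.authenticate("SAS", "pw-sas")
    c.submit_task(researcher, spec(n_iterations=1, stations=("s0",)))
    sess = c.authenticate("s0", "pw-s0")
    c.report_status(sess, "t", 0, "completed")
    c.report_status(sas, "t", 0, "completed")
    stored = final_model(0)
    c.store_final_model(sas, "t", stored)

    events = [json_mod.loads(line) for line in journal.read_text().splitlines()]
    kinds = [e["event"] for e in events]
    assert kinds.count("register") == 3
    assert "task_submitted" in kinds and "final_model" in kinds
    blob = base64.b64decode(
        next(e for e in events if e["event"] == "final_model")["container_b64"]
    )
    assert deserialize_weights_bytes(blob).allclose(stored)
    # and no plaintext password ever reaches the journal
    assert "pw-alice" not in journal.read_text()
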