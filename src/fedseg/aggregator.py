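"""Secure aggregation server (SAS): synchronous FedAvg behind a token wall.

The SAS holds, per task, the synchronous barrier ("the averaging
algorithm waits for all the data centers"), verifies a per-iteration JWT
on *every* exchange, performs federated averaging once the barrier is
full, stores intermediate models where only token-bearing stations can
reach them, and tolerates station dropouts by re-opening the failed
iteration from the latest successful model — never rolling that model
back.

FedAvg here is the parameter-wise convex combination

    w  =  sum_k (n_k / sum_j n_j) * w_k

with ``n_k`` the submitting station's local training-sample count
(``sample_weighted``, the default) or ``n_k = 1`` for all k (``uniform``).
Accumulation is in float64 and the result is cast back to float32, so a
single-model "average" and the two-identical-models case are bit-exact
pass-throughs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .coordinator import TaskSpec
from .errors import (
    ConfigurationError,
    ConflictError,
    NotFoundError,
    RetryLater,
    StateError,
    TokenRejection,
    WeightCompatibilityError,
)
from .tokens import (
    DEFAULT_LIFETIME_S,
    TokenClaims,
    generate_signing_key,
    issue_iteration_token,
    validate_iteration_token,
)
from .training import init_weights
from .unet import ModelConfig
from .weights import WeightMeta, WeightSet, require_same_manifest

WEIGHTINGS = ("sample_weighted", "uniform")


def fedavg_aggregate(models: list[WeightSet], weighting: str = "sample_weighted") -> WeightSet:
    """Parameter-wise weighted mean of weight sets with identical manifests."""
    if weighting not in WEIGHTINGS:
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if not models:
        raise ConfigurationError("need at least one model to aggregate")
    require_same_manifest(models)
    if weighting == "sample_weighted":
        counts = [m.meta.n_train_samples for m in models]
        if any(c <= 0 for c in counts):
            raise ConfigurationError(
                "sample_weighted averaging requires n_train_samples > 0 for every model"
            )
    else:
        counts = [1] * len(models)
    total = float(sum(counts))
    coefs = [c / total for c in counts]
    entries = []
    for j, (name, _) in enumerate(models[0].entries):
        acc = np.zeros(models[0].entries[j][1].shape, dtype=np.float64)
        for coef, m in zip(coefs, models):
            acc += coef * m.entries[j][1].astype(np.float64)
        entries.append((name, acc.astype(np.float32)))
    meta = WeightMeta(
        task_id=models[0].meta.task_id,
        iteration=models[0].meta.iteration,
        origin="SAS",
        n_train_samples=int(sum(m.meta.n_train_samples for m in models)),
    )
    return WeightSet(entries, meta)


@dataclass
class AggregationState:
    """Book-keeping for one running task on the SAS."""

    task: TaskSpec
    model_config: ModelConfig
    signing_key: bytes
    weighting: str
    current_iteration: int = 0
    attempt: int = 0  # bumps when a dropped iteration is re-opened
    expected_stations: frozenset = frozenset()
    received: dict[str, WeightSet] = field(default_factory=dict)
    latest_successful_model: WeightSet | None = None
    status: str = "waiting"  # waiting | aggregating | aborted | finished
    n_aggregations: int = 0
    contributing_log: list = field(default_factory=list)  # (iteration, stations)
    token_lifetime_s: float = DEFAULT_LIFETIME_S

    def check_invariants(self) -> None:
        assert set(self.received) <= set(self.expected_stations)
        if self.latest_successful_model is not None and self.n_aggregations > 0:
            assert self.latest_successful_model.meta.iteration < self.current_iteration or (
                self.status == "finished"
            )


class SecureAggregationServer:
    """Multi-task SAS; every station-facing entry point demands a valid
    current-(iteration, attempt) token and refuses side-effect free on any
    rejection.  There is no researcher-facing route at all: intermediate
    models are isolated by construction."""

    def __init__(self, aggregator_id: str = "SAS", clock=time.time):
        self.aggregator_id = aggregator_id
        self._tasks: dict[str, AggregationState] = {}
        self._clock = clock

    # -- lifecycle -------------------------------------------------------

    def start_task(
        self,
        task: TaskSpec,
        model_config: ModelConfig,
        signing_key: bytes | None = None,
        token_lifetime_s: float = DEFAULT_LIFETIME_S,
    ) -> AggregationState:
        if task.task_id in self._tasks and self._tasks[task.task_id].status != "finished":
            raise ConflictError(f"task {task.task_id!r} is already active")
        weighting = task.input_params.get("weighting", "sample_weighted")
        if weighting not in WEIGHTINGS:
            raise ConfigurationError(f"unknown weighting {weighting!r}")
        seed = int(task.input_params.get("model_seed", 0))
        state = AggregationState(
            task=task,
            model_config=model_config,
            signing_key=signing_key or generate_signing_key(),
            weighting=weighting,
            expected_stations=frozenset(task.station_ids),
            token_lifetime_s=float(token_lifetime_s),
        )
        # the SAS creates and broadcasts the common initial model so all
        # stations start from bit-identical weights
        state.latest_successful_model = init_weights(
            model_config, seed, task_id=task.task_id
        )
        self._tasks[task.task_id] = state
        return state

    def _state(self, task_id: str) -> AggregationState:
        state = self._tasks.get(task_id)
        if state is None:
            raise NotFoundError(f"no active task {task_id!r} on this SAS")
        return state

    # -- tokens ----------------------------------------------------------

    def issue_tokens(self, task_id: str) -> dict[str, str]:
        """Mint the per-station tokens for the current (iteration, attempt)."""
        state = self._state(task_id)
        now = self._clock()
        tokens = {}
        for sid in sorted(state.expected_stations):
            claims = TokenClaims(
                station_id=sid,
                task_id=task_id,
                iteration=state.current_iteration,
                attempt=state.attempt,
                issued_at=now,
                expires_at=now + state.token_lifetime_s,
            )
            tokens[sid] = issue_iteration_token(claims, state.signing_key)
        return tokens

    def request_token(self, task_id: str, station_id: str) -> str:
        """Station-facing token fetch; roster membership is the gate, the
        transport layer is trusted to authenticate the caller."""
        state = self._state(task_id)
        if station_id not in state.expected_stations:
            raise NotFoundError(f"station {station_id!r} not on task roster")
        return self.issue_tokens(task_id)[station_id]

    def _validate(self, task_id: str, token: str) -> TokenClaims:
        state = self._state(task_id)
        return validate_iteration_token(
            token,
            state.signing_key,
            expected_task=task_id,
            expected_iteration=state.current_iteration,
            expected_attempt=state.attempt,
            known_stations=state.expected_stations,
            now=self._clock(),
        )

    # -- station-facing routes -------------------------------------------

    def release_global_model(self, task_id: str, token: str) -> WeightSet:
        """Serve the latest successful model (iteration 0: the common
        initial model) to a token-bearing station; read-only."""
        claims = self._validate(task_id, token)  # raises TokenRejection
        state = self._state(task_id)
        if state.status == "aborted":
            raise RetryLater("iteration aborted; wait for re-open")
        if state.latest_successful_model is None:
            raise RetryLater("no model available yet; retry later")
        del claims
        return state.latest_successful_model.copy()

    def accept_model_submission(self, task_id: str, token: str, weights: WeightSet) -> dict:
        """Barrier ingestion: validate token, manifest and first-submission
        policy; when the last expected station arrives, aggregate exactly
        once and advance the iteration."""
        claims = self._validate(task_id, token)  # any rejection leaves state unchanged
        state = self._state(task_id)
        if state.status == "finished":
            raise StateError("task already finished")
        if state.status == "aborted":
            raise StateError("iteration is aborted; wait for re-open")
        expected_manifest = state.latest_successful_model.manifest()
        if weights.manifest() != expected_manifest:
            raise WeightCompatibilityError("submitted weights do not match task manifest")
        if claims.station_id in state.received:
            raise ConflictError(
                f"duplicate submission from {claims.station_id!r} in iteration "
                f"{state.current_iteration} refused (first submission wins)"
            )
        state.received[claims.station_id] = weights.copy(
            task_id=task_id, iteration=state.current_iteration, origin=claims.station_id
        )
        barrier_full = set(state.received) == set(state.expected_stations)
        if barrier_full:
            self._aggregate(state)
        return {
            "accepted": True,
            "station_id": claims.station_id,
            "iteration": weights.meta.iteration,
            "barrier": f"{len(state.received)}/{len(state.expected_stations)}"
            if not barrier_full
            else "aggregated",
        }

    def _aggregate(self, state: AggregationState) -> None:
        state.status = "aggregating"
        models = [state.received[sid] for sid in sorted(state.received)]
        merged = fedavg_aggregate(models, state.weighting)
        merged = merged.copy(
            task_id=state.task.task_id,
            iteration=state.current_iteration,
            origin="SAS",
        )
        state.latest_successful_model = merged
        state.contributing_log.append((state.current_iteration, sorted(state.received)))
        state.n_aggregations += 1
        state.received = {}
        state.current_iteration += 1
        state.attempt = 0
        if state.current_iteration >= state.task.n_iterations:
            state.status = "finished"
        else:
            state.status = "waiting"
        state.check_invariants()

    # -- dropout handling --------------------------------------------------

    def report_station_failure(self, task_id: str, station_id: str) -> AggregationState:
        """Abort the current iteration: discard partial submissions; the
        latest successful model is never rolled back."""
        state = self._state(task_id)
        if station_id not in state.expected_stations:
            raise NotFoundError(f"unknown station {station_id!r}")
        if state.status == "finished":
            raise StateError("task already finished")
        state.received = {}
        state.status = "aborted"
        return state

    def resume_iteration(self, task_id: str) -> dict[str, str]:
        """Re-open the aborted iteration with fresh tokens (new attempt);
        returns the new tokens."""
        state = self._state(task_id)
        if state.status != "aborted":
            raise StateError("no aborted iteration to resume")
        state.attempt += 1
        state.status = "waiting"
        return self.issue_tokens(task_id)

    # -- completion ---------------------------------------------------------

    def finalize_task(self, task_id: str) -> WeightSet:
        """Hand the final aggregated model (and nothing else) to the caller
        for deposit at the coordinator; refused before completion."""
        state = self._state(task_id)
        if state.status != "finished":
            raise StateError(
                f"finalize refused: task at iteration {state.current_iteration} "
                f"of {state.task.n_iterations}"
            )
        return state.latest_successful_model.copy()

    def state_of(self, task_id: str) -> AggregationState:
        return self._state(task_id)
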