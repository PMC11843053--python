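"""Single-process federation driver and run history.

``simulate_federation`` wires a coordinator, a secure aggregation server
and K station nodes together over an instrumented in-memory track and
plays out the full task lifecycle of the distributed system: entity
registration and authentication, researcher task submission, master /
subtask fan-out via the pull queue, the per-iteration token - fetch -
evaluate - train - submit cycle, synchronous FedAvg at the barrier,
optional injected dropouts with iteration re-open, finalisation, and the
researcher's download of the single final global model.

Everything is seeded: under deterministic mode two runs with the same
configuration produce bit-identical final weights and (up to wall-clock
columns) identical histories.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aggregator import SecureAggregationServer
from .config import FederationConfig
from .coordinator import Coordinator, TaskSpec
from .errors import DataError
from .phantoms import PartitionedCohort, generate_partitioned_cohort
from .station import StationConfig, StationNode
from .tokens import generate_signing_key
from .transport import (
    CoordinatorClient,
    CoordinatorService,
    InMemoryTrack,
    SASClient,
    SASService,
)
from .weights import WeightSet

HISTORY_COLUMNS = [
    "iteration",
    "party",
    "event",
    "mean_train_loss",
    "val_dice_global",
    "val_dice_local",
    "wall_time",
]


@dataclass
class HistoryRecord:
    iteration: int
    party: str  # station_id or "SAS"
    event: str  # local_train | aggregate | abort | finalize
    mean_train_loss: float | None = None
    val_dice_global: float | None = None
    val_dice_local: float | None = None
    wall_time: float = 0.0


@dataclass
class FederationHistory:
    """Per-iteration, per-party records of one federated run."""

    records: list[HistoryRecord] = field(default_factory=list)
    run_metadata: dict = field(default_factory=dict)

    def add(self, **kwargs) -> None:
        self.records.append(HistoryRecord(**kwargs))

    def of_event(self, event: str) -> list[HistoryRecord]:
        return [r for r in self.records if r.event == event]

    def mean_val_dice_global(self, iteration: int) -> float:
        vals = [
            r.val_dice_global
            for r in self.records
            if r.event == "local_train"
            and r.iteration == iteration
            and r.val_dice_global is not None
        ]
        if not vals:
            raise DataError(f"no local_train records for iteration {iteration}")
        return float(sum(vals) / len(vals))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": r.iteration,
                "party": r.party,
                "event": r.event,
                "mean_train_loss": r.mean_train_loss,
                "val_dice_global": r.val_dice_global,
                "val_dice_local": r.val_dice_local,
                "wall_time": r.wall_time,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=HISTORY_COLUMNS)

    def comparable(self) -> list[tuple]:
        """History as tuples with wall_time dropped (reproducibility checks)."""
        return [
            (
                r.iteration,
                r.party,
                r.event,
                r.mean_train_loss,
                r.val_dice_global,
                r.val_dice_local,
            )
            for r in self.records
        ]


def export_history(history: FederationHistory, path) -> tuple[Path, Path]:
    """Write the per-record CSV plus a per-iteration mean summary CSV
    (``<stem>_summary.csv``) alongside; returns both paths."""
    if not history.records:
        raise DataError("cannot export an empty history")
    path = Path(path)
    df = history.to_dataframe()
    df.to_csv(path, index=False)
    local = df[df["event"] == "local_train"]
    summary = (
        local.groupby("iteration")[["mean_train_loss", "val_dice_global", "val_dice_local"]]
        .mean()
        .reset_index()
    )
    summary_path = path.with_name(path.stem + "_summary.csv")
    summary.to_csv(summary_path, index=False)
    return path, summary_path


@dataclass
class FederationResult:
    """Final model + history, with handles to the live parties for audits.

    Iterable as ``(final_weights, history)``.
    """

    final_weights: WeightSet
    history: FederationHistory
    coordinator: Coordinator
    sas: SecureAggregationServer
    track: InMemoryTrack
    cohort: PartitionedCohort
    task: TaskSpec

    def __iter__(self):
        return iter((self.final_weights, self.history))


def build_task_spec(config: FederationConfig, aggregator_id: str = "SAS") -> TaskSpec:
    return TaskSpec(
        task_id=config.task_id,
        algorithm_ref="fedseg-unet2d",
        input_params={
            "model_seed": config.seed,
            "steps_per_iteration": config.steps_per_iteration,
            "weighting": config.weighting,
            "deterministic": config.deterministic,
        },
        n_iterations=config.n_iterations,
        aggregator_id=aggregator_id,
        station_ids=tuple(s.site_id for s in config.sites),
    )


def simulate_federation(
    config: FederationConfig,
    cohort: PartitionedCohort | None = None,
    failure_plan: dict[int, str] | None = None,
    clock=time.time,
    on_iteration_end=None,
) -> FederationResult:
    """Run the whole federation end to end in one process.

    ``failure_plan`` maps an iteration index to a station that drops out
    on the first attempt of that iteration; the iteration is aborted and
    re-opened with fresh tokens, exercising the dropout-recovery path.

    ``on_iteration_end(iteration, context)`` — if given — is invoked after
    every completed aggregation with live handles
    (``coordinator``, ``sas``, ``researcher_client``, ``task``), so audits
    can run *during* the federation rather than post hoc.
    """
    failure_plan = dict(failure_plan or {})
    if cohort is None:
        cohort = generate_partitioned_cohort(config.site_profiles(), config.split_fraction)
    model_cfg = config.model_cfg()
    station_ids = [s.site_id for s in config.sites]

    track = InMemoryTrack()
    coordinator = Coordinator(clock=clock)
    sas = SecureAggregationServer(aggregator_id="SAS", clock=clock)
    track.register_endpoint("coordinator", CoordinatorService(coordinator))
    track.register_endpoint("SAS", SASService(sas))

    # registration + authentication (all parties are registered entities)
    creds = {name: f"pw-{name}-{config.seed}" for name in ["researcher", "SAS", *station_ids]}
    researcher = CoordinatorClient(track, "coordinator", "researcher")
    researcher.register("researcher", creds["researcher"])
    sas_coord = CoordinatorClient(track, "coordinator", "SAS")
    sas_coord.register("aggregator", creds["SAS"])
    station_coord = {}
    for sid in station_ids:
        client = CoordinatorClient(track, "coordinator", sid)
        client.register("station", creds[sid])
        station_coord[sid] = client
    researcher.authenticate(creds["researcher"])
    sas_coord.authenticate(creds["SAS"])
    for sid in station_ids:
        station_coord[sid].authenticate(creds[sid])

    # task submission and fan-out via the pull queue
    task = build_task_spec(config, aggregator_id="SAS")
    researcher.submit_task(task)
    master_items = sas_coord.pull_work()
    assert any(i["kind"] == "master" for i in master_items)
    signing_key = generate_signing_key()
    sas.start_task(task, model_cfg, signing_key=signing_key,
                   token_lifetime_s=config.token_lifetime_s)

    stations: dict[str, StationNode] = {}
    for sid in station_ids:
        items = station_coord[sid].pull_work()
        assert any(i["kind"] == "subtask" for i in items)
        st_config = StationConfig(
            station_id=sid,
            model_config=model_cfg,
            steps_per_iteration=config.steps_per_iteration,
            seed=config.seed,
            deterministic=config.deterministic,
            threshold=config.threshold,
        )
        stations[sid] = StationNode(
            st_config,
            SASClient(track, "SAS", sid),
            coordinator_client=station_coord[sid],
            train_cases=cohort.train[sid],
            val_cases=cohort.validation[sid],
        )

    history = FederationHistory(
        run_metadata={
            "deterministic": config.deterministic,
            "determinism_tolerance": 0.0 if config.deterministic else None,
            "task_id": task.task_id,
            "n_stations": len(station_ids),
            "weighting": config.weighting,
        }
    )

    for iteration in range(config.n_iterations):
        while True:
            failing = failure_plan.pop(iteration, None)
            aborted = False
            for sid in station_ids:
                if sid == failing:
                    # the station drops out before completing its cycle
                    station_coord[sid].report_status(
                        task.task_id, iteration, "aborted",
                        {"station_id": sid, "error": "injected dropout"},
                    )
                    sas.report_station_failure(task.task_id, sid)
                    history.add(iteration=iteration, party=sid, event="abort",
                                wall_time=clock())
                    aborted = True
                    break
                token = stations[sid].sas.request_token(task.task_id, sid)
                _, metrics = stations[sid].run_training_cycle(task, iteration, token)
                history.add(
                    iteration=iteration,
                    party=sid,
                    event="local_train",
                    mean_train_loss=metrics.mean_train_loss,
                    val_dice_global=metrics.val_dice_global,
                    val_dice_local=metrics.val_dice_local,
                    wall_time=clock(),
                )
            if aborted:
                # re-open the same iteration with fresh tokens; stations
                # that had already completed go back to pending and redo
                sas.resume_iteration(task.task_id)
                for sid in station_ids:
                    station_coord[sid].report_status(task.task_id, iteration, "pending")
                continue
            break
        sas_coord.report_status(task.task_id, iteration, "completed")
        history.add(iteration=iteration, party="SAS", event="aggregate",
                    wall_time=clock())
        if on_iteration_end is not None:
            on_iteration_end(
                iteration,
                {
                    "coordinator": coordinator,
                    "sas": sas,
                    "researcher_client": researcher,
                    "task": task,
                },
            )

    final = sas.finalize_task(task.task_id)
    sas_coord.store_final_model(task.task_id, final)
    for item in master_items:
        sas_coord.complete_work(item["item_id"])
    history.add(iteration=config.n_iterations - 1, party="SAS", event="finalize",
                wall_time=clock())
    downloaded = researcher.fetch_final_model(task.task_id)
    return FederationResult(
        final_weights=downloaded,
        history=history,
        coordinator=coordinator,
        sas=sas,
        track=track,
        cohort=cohort,
        task=task,
    )
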