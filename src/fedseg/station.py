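"""Data-station worker: local data, local training, weight-only egress.

A station holds its patients' images in persistent ``train/`` and
``validation/`` folders and communicates only by (a) pulling subtasks
from the coordinator, and (b) exchanging weight containers with the SAS
under a per-iteration token.  One training cycle is, in order:

1. fetch the previous iteration's averaged model from the SAS,
2. score that incoming model on the local validation sample
   (``val_dice_global`` — so the metric at iteration *i* always refers to
   the model aggregated at iteration *i−1*),
3. run the configured number of local minibatch steps,
4. score the freshly trained local model (``val_dice_local``),
5. submit the local weights to the SAS with the iteration token.

Raw image or mask arrays never enter any outbound payload; the
instrumented track asserts this over full runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

from .coordinator import TaskSpec
from .errors import DataError, RetryLater, TokenRejection
from .nifti_io import load_case_folder
from .phantoms import PhantomCase
from .training import (
    TrainMetrics,
    derive_seed,
    mean_validation_dice,
    train_local,
)
from .transport import SASClient
from .unet import ModelConfig

RETRY_ATTEMPTS = 3
RETRY_BACKOFF_S = 0.05  # in-memory transport; real deployments use seconds


@dataclass
class StationConfig:
    """Local configuration of one data station."""

    station_id: str
    model_config: ModelConfig
    steps_per_iteration: int
    seed: int
    deterministic: bool = True
    data_root: Path | None = None  # contains train/ and validation/
    threshold: float = 0.5

    def __post_init__(self):
        if self.steps_per_iteration < 1:
            raise DataError("steps_per_iteration must be positive")


def load_local_partition(config: StationConfig) -> tuple[list[PhantomCase], list[PhantomCase]]:
    """Load and validate every NIfTI pair under ``data_root``; both splits
    must be non-empty (local validation is mandatory)."""
    if config.data_root is None:
        raise DataError("station has no data_root configured")
    root = Path(config.data_root)
    train_cases = load_case_folder(root / "train", site_id=config.station_id)
    val_cases = load_case_folder(root / "validation", site_id=config.station_id)
    if not train_cases:
        raise DataError(f"{config.station_id}: train folder is empty")
    if not val_cases:
        raise DataError(
            f"{config.station_id}: validation folder is empty; every station "
            "must hold a local validation sample"
        )
    return train_cases, val_cases


def evaluate_global_on_validation(
    weights, val_cases, config: ModelConfig, threshold: float = 0.5
) -> float:
    """Mean Dice of a model's thresholded predictions on the validation
    cases (brute-force mean of per-case Dice)."""
    return mean_validation_dice(weights, val_cases, config, threshold)


class StationNode:
    """One station's runtime: local cases + a SAS client + a coordinator
    client (optional, for status reports)."""

    def __init__(
        self,
        config: StationConfig,
        sas_client: SASClient,
        coordinator_client=None,
        train_cases: list[PhantomCase] | None = None,
        val_cases: list[PhantomCase] | None = None,
        sleep=time.sleep,
    ):
        self.config = config
        self.sas = sas_client
        self.coordinator = coordinator_client
        self._sleep = sleep
        if train_cases is None or val_cases is None:
            train_cases, val_cases = load_local_partition(config)
        if not train_cases or not val_cases:
            raise DataError(f"{config.station_id}: empty train or validation set")
        self.train_cases = train_cases
        self.val_cases = val_cases

    # -- helpers ---------------------------------------------------------

    def _with_retry(self, fn, *args):
        last = None
        for attempt in range(RETRY_ATTEMPTS):
            try:
                return fn(*args)
            except RetryLater as exc:
                last = exc
                self._sleep(RETRY_BACKOFF_S * 2**attempt)
        raise last

    def _iteration_seed(self, task: TaskSpec, iteration: int) -> int:
        base = int(task.input_params.get("model_seed", 0))
        return derive_seed(base, self.config.seed, iteration)

    def steps_for(self, task: TaskSpec) -> int:
        # task-level parameter overrides the station default
        return int(
            task.input_params.get("steps_per_iteration", self.config.steps_per_iteration)
        )

    # -- the training cycle ----------------------------------------------

    def run_training_cycle(
        self, task: TaskSpec, iteration: int, token: str
    ) -> tuple[dict, TrainMetrics]:
        """Execute one full cycle; on token rejection or persistent SAS
        unavailability an abort is reported to the coordinator and the
        error re-raised."""
        mc = self.config.model_config
        try:
            incoming = self._with_retry(self.sas.get_global_model, task.task_id, token)
            val_dice_global = evaluate_global_on_validation(
                incoming, self.val_cases, mc, self.config.threshold
            )
            trained, mean_loss = train_local(
                incoming,
                self.train_cases,
                mc,
                steps=self.steps_for(task),
                seed=self._iteration_seed(task, iteration),
            )
            trained = trained.copy(
                iteration=iteration, origin=self.config.station_id
            )
            val_dice_local = evaluate_global_on_validation(
                trained, self.val_cases, mc, self.config.threshold
            )
            ack = self._with_retry(self.sas.submit_model, task.task_id, token, trained)
        except (TokenRejection, RetryLater) as exc:
            if self.coordinator is not None:
                self.coordinator.report_status(
                    task.task_id, iteration, "aborted",
                    {"station_id": self.config.station_id, "error": str(exc)},
                )
            raise
        metrics = TrainMetrics(
            station_id=self.config.station_id,
            iteration=iteration,
            steps_run=self.steps_for(task),
            mean_train_loss=mean_loss,
            val_dice_global=val_dice_global,
            val_dice_local=val_dice_local,
        )
        if self.coordinator is not None:
            self.coordinator.report_status(
                task.task_id, iteration, "completed", metrics.as_dict()
            )
        return ack, metrics
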