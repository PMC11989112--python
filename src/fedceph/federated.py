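"""Client-server federated averaging, simulated in process.

Each round the server broadcasts the global parameter vector to every
client; each client trains locally for a fixed number of epochs on its own
data and sends back its updated vector with its sample count; the server
forms the sample-count-weighted mean over the clients that succeeded
(fault-tolerant: failed clients are excluded and the weights renormalized).
Only model parameters cross the wire — optimizer state is client-local and
reset every round.  Clients run sequentially; results are independent of
client execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import CephNet, ModelSpec, ParameterVector, build_model, get_parameters, set_parameters
from .training import OptimizerConfig, predict_scores, train_model
from .transforms import TransformConfig

__all__ = [
    "ClientUpdate",
    "ClientSpec",
    "FLConfig",
    "RoundLog",
    "AggregationError",
    "fedavg_aggregate",
    "run_federated",
    "client_round_rng",
]


class AggregationError(RuntimeError):
    """No successful client updates to aggregate."""


@dataclass
class ClientUpdate:
    """One client's locally trained state: the unit FedAvg aggregates."""

    client_id: str
    params: ParameterVector
    n_samples: int
    success: bool = True

    def __post_init__(self) -> None:
        if self.success and self.n_samples <= 0:
            raise ValueError("successful update must carry a positive sample count")


@dataclass
class ClientSpec:
    """A simulated client: local data plus its training configuration."""

    client_id: str
    x: np.ndarray
    y: np.ndarray
    seed: int = 0
    opt: OptimizerConfig = field(default_factory=OptimizerConfig)
    transform: TransformConfig | None = None


@dataclass(frozen=True)
class FLConfig:
    """Global rounds (default 50) and local epochs per round (default 5)."""

    n_rounds: int = 50
    local_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 0 or self.local_epochs <= 0:
            raise ValueError("n_rounds must be >= 0 and local_epochs positive")


@dataclass
class RoundLog:
    round: int
    client_losses: dict[str, float]
    client_success: dict[str, bool]
    eval_accuracy: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "round": self.round,
                "client_losses": self.client_losses,
                "client_success": self.client_success,
                "eval_accuracy": self.eval_accuracy,
            }
        )


def fedavg_aggregate(updates: list[ClientUpdate]) -> ParameterVector:
    """Sample-count-weighted element-wise mean over successful updates.

    Failed clients are excluded and the weights renormalized over the
    survivors.  Raises :class:`AggregationError` when no update succeeded.
    """
    ok = [u for u in updates if u.success]
    if not ok:
        raise AggregationError("no successful client updates in this round")
    total = sum(u.n_samples for u in ok)
    names = [name for name, _ in ok[0].params]
    for u in ok[1:]:
        if [n for n, _ in u.params] != names:
            raise ValueError("client parameter vectors are not aligned")
    out: ParameterVector = []
    for i, name in enumerate(names):
        acc = np.zeros_like(ok[0].params[i][1])
        for u in ok:
            acc += (u.n_samples / total) * u.params[i][1]
        out.append((name, acc))
    return out


def client_round_rng(client_seed: int, round_index: int) -> np.random.Generator:
    """The deterministic per-client, per-round batch-shuffling stream.

    Depends only on the client's own seed and the round index, so two
    clients configured identically behave identically (symmetry), and a
    sequential re-run of the same client reproduces the federated run.
    """
    return np.random.default_rng(np.random.SeedSequence([int(client_seed), int(round_index)]))


def run_federated(
    spec: ModelSpec,
    clients: list[ClientSpec],
    cfg: FLConfig,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
    log_path: str | Path | None = None,
) -> tuple[ParameterVector, list[RoundLog]]:
    """Run the federated protocol; returns final global params and round logs.

    Per round: broadcast, local training (fresh Adam state per client per
    round), fault-tolerant weighted aggregation, optional evaluation of the
    aggregated model on ``eval_data``.  A client raising during training
    marks its update failed; a round in which every client fails aborts the
    run with :class:`AggregationError`.
    """
    if not clients or all(len(c.x) == 0 for c in clients):
        raise ValueError("need at least one client with nonempty data")
    model = build_model(spec, seed=cfg.seed)
    global_params = get_parameters(model)
    logs: list[RoundLog] = []
    log_file = open(log_path, "w") if log_path is not None else None
    try:
        for rnd in range(cfg.n_rounds):
            updates: list[ClientUpdate] = []
            losses: dict[str, float] = {}
            success: dict[str, bool] = {}
            for client in clients:
                set_parameters(model, global_params)
                try:
                    rng = client_round_rng(client.seed, rnd)
                    epoch_losses = train_model(
                        model,
                        client.x,
                        client.y,
                        epochs=cfg.local_epochs,
                        opt_cfg=client.opt,
                        rng=rng,
                        transform=client.transform,
                    )
                    updates.append(
                        ClientUpdate(client.client_id, get_parameters(model), len(client.x))
                    )
                    losses[client.client_id] = epoch_losses[-1]
                    success[client.client_id] = True
                except Exception as exc:  # fault tolerance: drop this client
                    if isinstance(exc, (KeyboardInterrupt, SystemExit)):
                        raise
                    updates.append(ClientUpdate(client.client_id, [], 0, success=False))
                    losses[client.client_id] = float("nan")
                    success[client.client_id] = False
            global_params = fedavg_aggregate(updates)
            entry = RoundLog(rnd, losses, success)
            if eval_data is not None:
                set_parameters(model, global_params)
                scores = predict_scores(model, eval_data[0])
                entry.eval_accuracy = float(
                    (np.argmax(scores, axis=1) == np.asarray(eval_data[1])).mean()
                )
            logs.append(entry)
            if log_file is not None:
                log_file.write(entry.to_json() + "\n")
    finally:
        if log_file is not None:
            log_file.close()
    return global_params, logs
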