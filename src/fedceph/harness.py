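"""The three training settings and the federation contribution analysis.

* LL (local learning): each client trains on its own data only; every model
  is evaluated on the merged test set.
* CL (centralized learning): both clients' training data are pooled into one
  run; evaluation on the merged test set.
* FL (federated learning): parameter-sharing rounds via
  :mod:`fedceph.federated`; the global model is evaluated on the merged test
  set (per-client test breakdowns are also reported).

The contribution table summarizes what federation buys: for each model
variant, the FL-minus-LL accuracy delta per client dataset (the federation
gain) and the CL-minus-FL delta on the merged test set (the price of not
pooling data; negative means FL beat CL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .estimator import CephCNNClassifier
from .federated import ClientSpec, FLConfig, RoundLog, run_federated
from .metrics import MetricsReport, compute_metrics
from .models import ModelSpec
from .training import OptimizerConfig, predict_scores
from .transforms import TransformConfig

__all__ = [
    "ClientData",
    "TwoClientData",
    "SettingConfig",
    "ContributionTable",
    "run_setting",
    "contribution_table",
]


@dataclass
class ClientData:
    """One client's train/test arrays (images in [0,1], integer targets)."""

    client_id: str
    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray


@dataclass
class TwoClientData:
    clients: list[ClientData]

    def merged_train(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.concatenate([c.x_train for c in self.clients]),
            np.concatenate([c.y_train for c in self.clients]),
        )

    def merged_test(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.concatenate([c.x_test for c in self.clients]),
            np.concatenate([c.y_test for c in self.clients]),
        )


@dataclass(frozen=True)
class SettingConfig:
    """Configuration of one LL/CL/FL run.

    ``epochs`` applies to LL and CL (full-scale default 100); the FL setting
    uses ``fl.n_rounds`` x ``fl.local_epochs`` (defaults 50 x 5).
    """

    setting: str = "cl"
    head: str = "plain"
    backbone: str = "tiny"
    input_size: int = 64
    epochs: int = 100
    opt: OptimizerConfig = field(default_factory=OptimizerConfig)
    fl: FLConfig = field(default_factory=FLConfig)
    transform: TransformConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in ("ll", "cl", "fl"):
            raise ValueError(f"setting must be 'll', 'cl' or 'fl', got {self.setting!r}")


def _evaluate(clf: CephCNNClassifier, x, y) -> MetricsReport:
    scores = clf.predict_proba(x)
    return compute_metrics(y, scores)


def run_setting(cfg: SettingConfig, data: TwoClientData) -> dict:
    """Run one setting; returns a dict of MetricsReport plus artifacts.

    LL -> ``{"per_client": {cid: report}}`` (each client's model on the
    merged test set); CL -> ``{"merged": report}``; FL -> ``{"merged":
    report, "per_client_test": {cid: report}, "rounds": [RoundLog...]}``.
    """
    for c in data.clients:
        if len(c.x_train) == 0 or len(c.x_test) == 0:
            raise ValueError(f"client {c.client_id!r} has an empty train or test split")
    x_test, y_test = data.merged_test()

    def make_clf(seed: int) -> CephCNNClassifier:
        return CephCNNClassifier(
            head=cfg.head,
            backbone=cfg.backbone,
            input_size=cfg.input_size,
            epochs=cfg.epochs,
            lr=cfg.opt.lr,
            batch_size=cfg.opt.batch_size,
            transform=cfg.transform,
            seed=seed,
        )

    if cfg.setting == "ll":
        out: dict = {"per_client": {}}
        for c in data.clients:
            clf = make_clf(cfg.seed)
            clf.fit(c.x_train, c.y_train)
            out["per_client"][c.client_id] = _evaluate(clf, x_test, y_test)
        return out

    if cfg.setting == "cl":
        x_tr, y_tr = data.merged_train()
        clf = make_clf(cfg.seed)
        clf.fit(x_tr, y_tr)
        return {"merged": _evaluate(clf, x_test, y_test)}

    # federated
    clients = [
        ClientSpec(
            client_id=c.client_id,
            x=c.x_train,
            y=c.y_train,
            seed=cfg.seed,
            opt=cfg.opt,
            transform=cfg.transform,
        )
        for c in data.clients
    ]
    spec = make_clf(cfg.seed)._make_spec(in_channels=data.clients[0].x_train.shape[1])
    fl_cfg = replace(cfg.fl, seed=cfg.seed)
    params, logs = run_federated(spec, clients, fl_cfg, eval_data=(x_test, y_test))
    from .models import build_model, set_parameters

    model = build_model(spec, seed=fl_cfg.seed)
    set_parameters(model, params)
    scores = predict_scores(model, x_test, cfg.opt.batch_size, cfg.transform)
    result = {
        "merged": compute_metrics(y_test, scores),
        "per_client_test": {},
        "rounds": logs,
    }
    for c in data.clients:
        s = predict_scores(model, c.x_test, cfg.opt.batch_size, cfg.transform)
        result["per_client_test"][c.client_id] = compute_metrics(c.y_test, s)
    return result


@dataclass(frozen=True)
class ContributionTable:
    """Federation gains and sacrifices for one model variant.

    ``fl_vs_ll``: FL accuracy minus each client's LL accuracy (merged test
    set); ``cl_vs_fl``: CL accuracy minus FL accuracy — negative means the
    federated model beat the centralized one.  All deltas are plain
    differences on the [0, 1] accuracy scale.
    """

    fl_vs_ll: dict[str, float]
    cl_vs_fl: float

    def as_dict(self) -> dict:
        return {"fl_vs_ll": dict(self.fl_vs_ll), "cl_vs_fl": self.cl_vs_fl}


def contribution_table(
    ll: dict[str, float], cl: float, fl: float
) -> ContributionTable:
    """Build the contribution/sacrifice deltas from setting accuracies."""
    for name, v in {"cl": cl, "fl": fl, **ll}.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"accuracy {name}={v} outside [0, 1]")
    return ContributionTable(
        fl_vs_ll={cid: fl - acc for cid, acc in ll.items()},
        cl_vs_fl=cl - fl,
    )
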