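"""Per-horizon classifiers and the architecture-growth training protocol.

One binary classifier is trained for each future window (>6-12, >12-18,
>18-24, >24-30 h), predicting ICU versus routine care.  Training follows a
growth protocol: start from a single small hidden layer, increase the node
count while monitoring MCC / sensitivity / specificity / precision / NPV
at cutpoints 0.15, 0.5 and 0.9 on the training and validation sets; when
the validation MCC drifts below the training MCC beyond a tolerance
(overfitting), add L1/L2 penalties and dropout and retune; when node
growth stops helping, add another hidden layer; stop when regularization
no longer rescues overfitting or the layer budget is exhausted.  The best
non-overfit candidate by validation MCC (at cutpoint 0.5) is kept.

Full-scale defaults follow the reference methodology (RMSprop, learning
rate 2e-4, minibatches of 10,000 rows, Glorot-uniform init); desk-scale
runs shrink the minibatch to ``min(10_000, n // 10)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import MLP

__all__ = [
    "TrainingProtocolConfig",
    "HorizonModel",
    "matthews_corrcoef",
    "cutpoint_metrics",
    "train_horizon_model",
    "predict_raw",
    "classify",
    "save_model",
    "load_model",
]


def matthews_corrcoef(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC from binary arrays; defined as 0 for any degenerate marginal."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = np.sum(y_true & y_pred)
    tn = np.sum(~y_true & ~y_pred)
    fp = np.sum(~y_true & y_pred)
    fn = np.sum(y_true & ~y_pred)
    denom = float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    if denom == 0:
        return 0.0
    return float((float(tp) * tn - float(fp) * fn) / np.sqrt(denom))


def classify(scores: np.ndarray, cutpoint: float) -> np.ndarray:
    """Binary labels: ICU (1) iff score strictly exceeds the cutpoint."""
    if not (0.0 < cutpoint < 1.0):
        raise ValueError(f"cutpoint must lie in (0, 1); got {cutpoint}")
    return (np.asarray(scores) > cutpoint).astype(int)


def cutpoint_metrics(scores: np.ndarray, y: np.ndarray, cutpoint: float) -> dict:
    """MCC, sensitivity, specificity, precision and NPV at one cutpoint."""
    pred = classify(scores, cutpoint)
    y = np.asarray(y, dtype=bool)
    p = pred.astype(bool)
    tp, tn = np.sum(y & p), np.sum(~y & ~p)
    fp, fn = np.sum(~y & p), np.sum(y & ~p)
    safe = lambda a, b: float(a / b) if b > 0 else np.nan
    return {
        "mcc": matthews_corrcoef(y, p),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "precision": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


@dataclass
class TrainingProtocolConfig:
    """Knobs of the growth protocol.  Rates and cutpoints as documented in
    the module docstring; ``overfit_drift_tolerance`` is the max allowed
    training-minus-validation MCC gap before a candidate counts as
    overfit."""

    learning_rate: float = 2e-4
    minibatch_size: int = 10_000
    desk_scale_minibatch: bool = True
    monitor_cutpoints: tuple[float, ...] = (0.15, 0.5, 0.9)
    selection_cutpoint: float = 0.5
    node_growth_schedule: tuple[int, ...] = (8, 16, 32, 64, 128)
    max_hidden_layers: int = 5
    regularization_ladder: tuple[dict, ...] = (
        {"l2": 1e-4, "dropout": 0.10},
        {"l2": 1e-3, "dropout": 0.25},
    )
    overfit_drift_tolerance: float = 0.02
    min_improvement: float = 0.002
    epochs: int = 30
    patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if not all(0 < c < 1 for c in self.monitor_cutpoints):
            raise ValueError("monitor_cutpoints must lie in (0, 1)")
        if self.overfit_drift_tolerance < 0:
            raise ValueError("overfit_drift_tolerance must be >= 0")


@dataclass
class HorizonModel:
    """A trained per-horizon classifier plus its training record.

    ``training_history`` has one entry per candidate architecture with
    train/validation MCC and the cutpoint metric panel; ``history_epochs``
    the per-epoch trace of the selected candidate.
    """

    horizon: int
    architecture: tuple[int, ...]
    net: MLP
    feature_names: list[str]
    protocol: TrainingProtocolConfig
    training_history: list[dict] = field(default_factory=list)
    validation_mcc: float = float("nan")
    history_epochs: list[dict] = field(default_factory=list)
    calibration: object | None = None  # CalibrationMap, attached downstream

    def predict_raw(self, X: np.ndarray, feature_names=None) -> np.ndarray:
        return predict_raw(self, X, feature_names)

    def predict_risk(self, X: np.ndarray, feature_names=None) -> np.ndarray:
        """Calibrated risk of future ICU care (requires a calibration map)."""
        raw = self.predict_raw(X, feature_names)
        if self.calibration is None:
            raise ValueError("no calibration map attached to this model")
        return self.calibration.transform(raw)


def predict_raw(model: HorizonModel, X: np.ndarray, feature_names=None) -> np.ndarray:
    """Raw network scores in (0, 1).  Rejects schema mismatches."""
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        missing = sorted(set(model.feature_names) - set(feature_names))
        extra = sorted(set(feature_names) - set(model.feature_names))
        raise ValueError(
            f"feature schema mismatch: missing={missing[:5]}..., extra={extra[:5]}..."
            if len(missing) + len(extra) > 10
            else f"feature schema mismatch: missing={missing}, extra={extra}"
        )
    X = np.asarray(X)
    if X.shape[1] != model.net.n_features:
        raise ValueError(
            f"expected {model.net.n_features} features, got {X.shape[1]}"
        )
    return model.net.predict_proba(X)


def _fit_candidate(
    X_tr, y_tr, X_va, y_va, hidden, reg, protocol: TrainingProtocolConfig,
    candidate_seed: int,
):
    """Train one candidate architecture and return (net, record, epochs)."""
    mb = protocol.minibatch_size
    if protocol.desk_scale_minibatch:
        mb = max(32, min(mb, len(y_tr) // 10))
    net = MLP(
        X_tr.shape[1], hidden, seed=candidate_seed,
        l1=reg.get("l1", 0.0), l2=reg.get("l2", 0.0),
        dropout=reg.get("dropout", 0.0),
    )
    epoch_rows: list[dict] = []

    def cb(epoch, model):
        s_va = model.predict_proba(X_va)
        mcc_va = matthews_corrcoef(y_va, s_va > protocol.selection_cutpoint)
        epoch_rows.append({"epoch": epoch, "val_mcc": mcc_va})
        return mcc_va

    net.fit(
        X_tr, y_tr, epochs=protocol.epochs, minibatch_size=mb,
        learning_rate=protocol.learning_rate, callback=cb,
        patience=protocol.patience,
    )
    s_tr = net.predict_proba(X_tr)
    s_va = net.predict_proba(X_va)
    record = {
        "architecture": tuple(hidden),
        "regularization": dict(reg),
        "train": {c: cutpoint_metrics(s_tr, y_tr, c) for c in protocol.monitor_cutpoints},
        "validation": {c: cutpoint_metrics(s_va, y_va, c) for c in protocol.monitor_cutpoints},
    }
    c0 = protocol.selection_cutpoint
    record["train_mcc"] = record["train"][c0]["mcc"]
    record["val_mcc"] = record["validation"][c0]["mcc"]
    record["overfit"] = (
        record["train_mcc"] - record["val_mcc"] > protocol.overfit_drift_tolerance
    )
    return net, record, epoch_rows


def train_horizon_model(
    train_rows: tuple[np.ndarray, np.ndarray],
    validation_rows: tuple[np.ndarray, np.ndarray],
    protocol: TrainingProtocolConfig | None = None,
    horizon: int = 1,
    feature_names: list[str] | None = None,
) -> HorizonModel:
    """Run the architecture-growth protocol for one horizon.

    ``train_rows`` / ``validation_rows`` are (X, y) pairs with binary y.
    Fully seeded: identical inputs and protocol reproduce the selected
    architecture and validation MCC.
    """
    protocol = protocol or TrainingProtocolConfig()
    protocol.validate()
    X_tr, y_tr = train_rows
    X_va, y_va = validation_rows
    for name, y in (("training", y_tr), ("validation", y_va)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} partition contains a single outcome class")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X_tr.shape[1])]

    history: list[dict] = []
    best: tuple[float, MLP, dict, list] | None = None  # only non-overfit candidates
    fallback: tuple[float, MLP, dict, list] | None = None  # best regardless of drift
    layers: list[int] = []
    candidate_idx = 0
    stop_all = False

    for _layer in range(protocol.max_hidden_layers):
        layer_best_mcc = -np.inf
        layer_best_nodes = None
        for nodes in protocol.node_growth_schedule:
            hidden = tuple(layers + [nodes])
            reg = {"l1": 0.0, "l2": 0.0, "dropout": 0.0}
            net, rec, epochs = _fit_candidate(
                X_tr, y_tr, X_va, y_va, hidden, reg, protocol,
                candidate_seed=protocol.seed * 1_000_003 + candidate_idx,
            )
            candidate_idx += 1
            # overfit: escalate regularization until the drift is within
            # tolerance or the ladder is exhausted
            rescued = not rec["overfit"]
            ladder_step = 0
            while rec["overfit"] and ladder_step < len(protocol.regularization_ladder):
                reg = dict(protocol.regularization_ladder[ladder_step])
                net, rec, epochs = _fit_candidate(
                    X_tr, y_tr, X_va, y_va, hidden, reg, protocol,
                    candidate_seed=protocol.seed * 1_000_003 + candidate_idx,
                )
                candidate_idx += 1
                ladder_step += 1
                rescued = not rec["overfit"]
            history.append(rec)
            if fallback is None or rec["val_mcc"] > fallback[0]:
                fallback = (rec["val_mcc"], net, rec, epochs)
            if rescued:
                if best is None or rec["val_mcc"] > best[0]:
                    best = (rec["val_mcc"], net, rec, epochs)
                if rec["val_mcc"] > layer_best_mcc + protocol.min_improvement:
                    layer_best_mcc = rec["val_mcc"]
                    layer_best_nodes = nodes
                else:
                    break  # node growth stopped helping at this depth
            else:
                stop_all = True  # regularization no longer rescues overfitting
                break
        if stop_all or layer_best_nodes is None:
            break
        if best is not None and layer_best_mcc < best[0] - protocol.min_improvement:
            break  # the added layer did not help
        layers.append(layer_best_nodes)

    if best is None:
        # the ladder never brought the drift inside tolerance; training still
        # returns the best candidate rather than failing on an ambitious
        # tolerance, and says so
        import warnings

        warnings.warn(
            "no candidate met the overfit drift tolerance "
            f"({protocol.overfit_drift_tolerance}); returning the "
            "best-validation-MCC candidate",
            RuntimeWarning,
        )
        best = fallback
    val_mcc, net, rec, epochs = best
    return HorizonModel(
        horizon=horizon,
        architecture=rec["architecture"],
        net=net,
        feature_names=list(feature_names),
        protocol=protocol,
        training_history=history,
        validation_mcc=val_mcc,
        history_epochs=epochs,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: HorizonModel, path: str | Path) -> None:
    """Serialize architecture, weights, protocol, seed and calibration to
    one versioned JSON file; the training history goes to a sibling CSV."""
    path = Path(path)
    payload = {
        "format_version": _FORMAT_VERSION,
        "horizon": model.horizon,
        "architecture": list(model.architecture),
        "validation_mcc": model.validation_mcc,
        "feature_names": model.feature_names,
        "protocol": asdict(model.protocol),
        "net": model.net.to_dict(),
        "calibration": (
            model.calibration.to_dict() if model.calibration is not None else None
        ),
    }
    path.write_text(json.dumps(payload))
    if model.training_history:
        rows = [
            {
                "architecture": "x".join(map(str, r["architecture"])),
                "l1": r["regularization"].get("l1", 0.0),
                "l2": r["regularization"].get("l2", 0.0),
                "dropout": r["regularization"].get("dropout", 0.0),
                "train_mcc": r["train_mcc"],
                "val_mcc": r["val_mcc"],
                "overfit": r["overfit"],
            }
            for r in model.training_history
        ]
        pd.DataFrame(rows).to_csv(path.with_suffix(".history.csv"), index=False)


def load_model(path: str | Path) -> HorizonModel:
    from .calibration import CalibrationMap  # local import to avoid a cycle

    payload = json.loads(Path(path).read_text())
    if payload["format_version"] != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {payload['format_version']}")
    proto_raw = payload["protocol"]
    proto_raw["monitor_cutpoints"] = tuple(proto_raw["monitor_cutpoints"])
    proto_raw["node_growth_schedule"] = tuple(proto_raw["node_growth_schedule"])
    proto_raw["regularization_ladder"] = tuple(proto_raw["regularization_ladder"])
    model = HorizonModel(
        horizon=payload["horizon"],
        architecture=tuple(payload["architecture"]),
        net=MLP.from_dict(payload["net"]),
        feature_names=payload["feature_names"],
        protocol=TrainingProtocolConfig(**proto_raw),
        validation_mcc=payload["validation_mcc"],
    )
    if payload["calibration"] is not None:
        model.calibration = CalibrationMap.from_dict(payload["calibration"])
    return model
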