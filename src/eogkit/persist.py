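"""Model persistence: one ``.npz`` per model with a version-stamped manifest.

* rule — the threshold set;
* knn — the exemplar memory (flattened epochs + labels) and (k, metric);
* cnn — the trained weights, standardization statistics and architecture.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cnn import CNNClassifier, CNNConfig, _Net
from .knn import KNNClassifier, KNNConfig
from .rule import RuleClassifier, ThresholdSet
from .types import ValidationError

FORMAT_VERSION = 1


def save_model(model, path: str | Path) -> None:
    path = Path(path)
    manifest = {"format_version": FORMAT_VERSION}
    if isinstance(model, RuleClassifier):
        if model.thresholds is None:
            raise ValidationError("cannot save an uncalibrated rule model")
        t = model.thresholds
        manifest["method"] = "rule"
        np.savez(
            path,
            manifest=json.dumps(manifest),
            thresholds=np.array(
                [t.horiz_thresh, t.vert_thresh, t.blink_thresh, t.blink_max_width]
            ),
        )
    elif isinstance(model, KNNClassifier):
        if model._X is None:
            raise ValidationError("cannot save an unfitted kNN model")
        manifest["method"] = "knn"
        manifest["k"] = model.config.k
        manifest["metric"] = model.config.metric
        np.savez(
            path,
            manifest=json.dumps(manifest),
            X=model._X,
            y=np.array([str(v) for v in model._y]),
        )
    elif isinstance(model, CNNClassifier):
        if model._net is None:
            raise ValidationError("cannot save an unfitted CNN model")
        cfg = model.config
        manifest["method"] = "cnn"
        manifest["config"] = {
            "module_a": list(cfg.module_a),
            "module_b": list(cfg.module_b),
            "dense_units": cfg.dense_units,
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "learning_rate": cfg.learning_rate,
            "seed": cfg.seed,
        }
        manifest["input_len"] = model._net.input_len
        arrays = {f"param_{k}": v for k, v in model._net.params.items()}
        np.savez(
            path,
            manifest=json.dumps(manifest),
            mean=model._mean,
            std=model._std,
            **arrays,
        )
    else:
        raise ValidationError(f"unknown model type {type(model).__name__}")


def load_model(path: str | Path):
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        if manifest.get("format_version") != FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {manifest.get('format_version')}"
            )
        method = manifest.get("method")
        if method == "rule":
            h, v, b, w = data["thresholds"]
            return RuleClassifier(ThresholdSet(float(h), float(v), float(b), int(w)))
        if method == "knn":
            model = KNNClassifier(KNNConfig(k=int(manifest["k"]), metric=manifest["metric"]))
            model._X = data["X"]
            model._y = data["y"].astype(object)
            return model
        if method == "cnn":
            c = manifest["config"]
            cfg = CNNConfig(
                module_a=tuple(c["module_a"]),
                module_b=tuple(c["module_b"]),
                dense_units=int(c["dense_units"]),
                epochs=int(c["epochs"]),
                batch_size=int(c["batch_size"]),
                learning_rate=float(c["learning_rate"]),
                seed=int(c["seed"]),
            )
            model = CNNClassifier(cfg)
            rng = np.random.default_rng(cfg.seed)
            net = _Net(cfg, int(manifest["input_len"]), rng)
            for k in net.params:
                net.params[k] = data[f"param_{k}"]
            model._net = net
            model._mean = data["mean"]
            model._std = data["std"]
            return model
        raise ValidationError(f"unknown model method {method!r}")
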