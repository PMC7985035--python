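"""Table and model-archive I/O with sample-id reconciliation.

Feature matrices and survival tables are delimited text (TSV default,
CSV accepted); rows are reconciled by sample id — never by position —
with an inner join and a report of dropped ids. Models are saved as
versioned, checksummed NumPy .npz archives embedding their config.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings

import numpy as np
import pandas as pd

from .model import CoxnnetModel
from .survival import SurvivalDataset
from .twostage import TwoStageModel

__all__ = ["read_table", "read_survival_table", "load_aligned",
           "save_model", "load_model", "config_hash"]

FORMAT_VERSION = 1


def _sep_for(path) -> str:
    path = str(path)
    return "," if path.endswith(".csv") else "\t"


def read_table(path) -> pd.DataFrame:
    """Read a delimited feature matrix: first column sample id, rest numeric."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from e
    return df


def read_survival_table(path) -> pd.DataFrame:
    """Read a survival table with columns (sample, time, status).

    Status must be coded 0/1 (1 = event observed); the 1/2 dialect used
    by some R exports is rejected with a message.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("sample", "time", "status") if c not in cols]
    if missing:
        raise ValueError(
            f"survival table {path} missing columns: {missing} "
            f"(found {list(df.columns)})"
        )
    out = df[[cols["sample"], cols["time"], cols["status"]]].copy()
    out.columns = ["sample", "time", "status"]
    out["sample"] = out["sample"].astype(str)
    dupes = out["sample"][out["sample"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    status = set(out["status"].unique().tolist())
    if status <= {1, 2} and 2 in status:
        raise ValueError(
            "survival status appears to use the 1/2 dialect; recode to 0/1 "
            "(1 = event observed, 0 = censored)"
        )
    if not status <= {0, 1}:
        raise ValueError(f"survival status must be 0/1, found {sorted(status)}")
    return out


def load_aligned(feature_paths, survival_path, require_events: bool = True):
    """Inner-join feature matrices with a survival table on sample id.

    Returns one :class:`SurvivalDataset` per feature path, all sharing
    the sorted intersection of sample ids. Dropped ids are reported via
    a warning. Zero-event intersections are rejected by default.
    """
    if isinstance(feature_paths, (str, bytes)) or hasattr(feature_paths, "__fspath__"):
        feature_paths = [feature_paths]
    surv = read_survival_table(survival_path)
    frames = [read_table(p) for p in feature_paths]
    ids = set(surv["sample"])
    for f in frames:
        ids &= set(f.index)
    if len(ids) < 2:
        raise ValueError(
            "empty or near-empty sample intersection across input files"
        )
    ids = sorted(ids)
    all_ids = set(surv["sample"]).union(*[set(f.index) for f in frames])
    dropped = sorted(all_ids - set(ids))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} unmatched sample id(s): "
                      f"{dropped[:10]}")
    surv = surv.set_index("sample").loc[ids]
    T = surv["time"].to_numpy(dtype=float)
    d = surv["status"].to_numpy()
    if require_events and d.sum() == 0:
        raise ValueError("no observed events in the aligned dataset")
    datasets = []
    for f in frames:
        sub = f.loc[ids]
        datasets.append(SurvivalDataset(
            ids, sub.to_numpy(dtype=float), T, d,
            feature_names=list(sub.columns),
        ))
    return datasets if len(datasets) > 1 else datasets[0]


def _model_payload(model: CoxnnetModel, prefix=""):
    arrays = {
        f"{prefix}W": model.W, f"{prefix}b": model.b,
        f"{prefix}beta": model.beta,
        f"{prefix}x_mean": model.x_mean, f"{prefix}x_std": model.x_std,
    }
    config = {
        "activation": model.activation,
        "dropout_rate": model.dropout_rate,
        "l2": model.l2,
        "feature_names": list(model.feature_names or []),
        "train_ids": list(model.train_ids or []),
    }
    return arrays, config


def _arrays_digest(arrays: dict) -> str:
    h = hashlib.sha256()
    for k in sorted(arrays):
        h.update(k.encode())
        h.update(np.ascontiguousarray(arrays[k]).tobytes())
    return h.hexdigest()


def save_model(model, path, extra_config: dict = None):
    """Save a CoxnnetModel or TwoStageModel as a checksummed .npz archive."""
    if isinstance(model, TwoStageModel):
        arrays, config = _model_payload(model.stage2, "stage2_")
        config = {"stage2": config, "kind": "twostage",
                  "n_stage1": len(model.stage1),
                  "provenance": [list(t) for t in model.provenance]}
        for i, m in enumerate(model.stage1):
            a, c = _model_payload(m, f"stage1_{i}_")
            arrays.update(a)
            config[f"stage1_{i}"] = c
    elif isinstance(model, CoxnnetModel):
        arrays, config = _model_payload(model)
        config["kind"] = "coxnnet"
    else:
        raise TypeError(f"cannot save object of type {type(model).__name__}")
    config["format_version"] = FORMAT_VERSION
    if extra_config:
        config["extra"] = extra_config
    config_json = json.dumps(config, sort_keys=True)
    config["checksum"] = _arrays_digest(arrays)
    config["config_hash"] = config_hash(config_json)
    arrays["__config__"] = np.frombuffer(
        json.dumps(config, sort_keys=True).encode(), dtype=np.uint8
    )
    _write_npz_deterministic(path, arrays)


def _write_npz_deterministic(path, arrays):
    """npz writer with fixed zip timestamps: identical input, identical bytes."""
    import zipfile

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asanyarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def _build_model(z, config, prefix=""):
    return CoxnnetModel(
        W=z[f"{prefix}W"], b=z[f"{prefix}b"], beta=z[f"{prefix}beta"],
        activation=config["activation"], dropout_rate=config["dropout_rate"],
        x_mean=z[f"{prefix}x_mean"], x_std=z[f"{prefix}x_std"],
        l2=config["l2"],
        feature_names=config["feature_names"] or None,
        train_ids=tuple(config["train_ids"]) or None,
    )


def load_model(path):
    """Load a model archive; verifies format version and array checksum."""
    with np.load(path) as z:
        config = json.loads(bytes(z["__config__"]).decode())
        if config.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"model archive format version {config.get('format_version')} "
                f"is not supported (expected {FORMAT_VERSION}); re-save the "
                "model with this version"
            )
        arrays = {k: z[k] for k in z.files if k != "__config__"}
        if _arrays_digest(arrays) != config.get("checksum"):
            raise ValueError("model archive checksum mismatch (corrupt or "
                             "tampered file)")
        if config.get("kind") == "twostage":
            stage1 = [
                _build_model(arrays, config[f"stage1_{i}"], f"stage1_{i}_")
                for i in range(config["n_stage1"])
            ]
            stage2 = _build_model(arrays, config["stage2"], "stage2_")
            return TwoStageModel(
                stage1=stage1, stage2=stage2,
                provenance=[tuple(t) for t in config["provenance"]],
            )
        return _build_model(arrays, config)


def config_hash(obj) -> str:
    """Short stable hash of a config mapping or string, for provenance."""
    if not isinstance(obj, str):
        obj = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(obj.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config=None, index=False):
    """Write a delimited table with a provenance header comment."""
    sep = _sep_for(path)
    buf = _io.StringIO()
    h = config_hash(config) if config is not None else "none"
    buf.write(f"# coxfuse v0.1.0 config_hash={h}\n")
    df.to_csv(buf, sep=sep, index=index)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
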