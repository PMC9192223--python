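"""Dataset, feature-table, density and model readers/writers.

On-disk layout for a trial dataset directory:

* ``trial_XXXX.csv`` — one file per trial; first column ``channel``, then one
  column per sample.
* ``labels.csv`` — columns ``trial_id,label``.
* ``manifest.json`` — sampling rate, channel names, provenance (seed, config
  hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import DecisionThreshold, DensityCurve, DiscriminantModel
from .errors import ConfigurationError, DegenerateInputError
from .features import CspModel
from .pipeline import TrainedDecoder
from .signals import KNOWN_LABELS, TrialSet
from .subband import SubbandSelection

__all__ = [
    "write_trials",
    "read_trials",
    "write_features",
    "write_density",
    "save_decoder",
    "load_decoder",
    "config_hash",
]


def config_hash(config) -> str:
    """Stable short hash of a (nested) configuration mapping or dataclass."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trials(trials: TrialSet, out_dir, extra_manifest: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(trials.n_trials):
        df = pd.DataFrame(trials.trials[i])
        df.insert(0, "channel", trials.channel_names)
        df.to_csv(out / f"{trials.trial_ids[i]}.csv", index=False, float_format="%.10g")
    pd.DataFrame({"trial_id": trials.trial_ids, "label": trials.labels}).to_csv(
        out / "labels.csv", index=False
    )
    manifest = {
        "sampling_rate": trials.sampling_rate,
        "channel_names": trials.channel_names,
        "n_trials": trials.n_trials,
        "n_samples": trials.n_samples,
    }
    manifest.update(extra_manifest or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _read_labels(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"trial_id", "label"} <= set(df.columns):
        raise ConfigurationError(f"{path}: need columns trial_id,label")
    labels = dict(zip(df["trial_id"], df["label"]))
    for tid, lab in labels.items():
        if lab not in KNOWN_LABELS:
            raise ConfigurationError(
                f"{path}: unknown class label {lab!r} for {tid}; "
                f"expected one of {sorted(KNOWN_LABELS)}"
            )
    return labels


def read_trials(path, format: str = "csv") -> TrialSet:
    """Load a trial dataset directory (CSV layout above, or per-trial EDF).

    For EDF, one ``*.edf`` file per trial with the same ``labels.csv``
    sidecar; sampling rate and channel names come from the EDF headers.
    """
    root = Path(path)
    if not root.is_dir():
        raise DegenerateInputError(f"{root} is not a directory")
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise DegenerateInputError(f"missing labels file {labels_path}")
    labels = _read_labels(labels_path)

    if format == "csv":
        manifest_path = root / "manifest.json"
        if not manifest_path.exists():
            raise DegenerateInputError(f"missing manifest {manifest_path}")
        manifest = json.loads(manifest_path.read_text())
        fs = float(manifest["sampling_rate"])
        channel_names = list(manifest["channel_names"])
        mats, ids = [], []
        for tid in sorted(labels):
            f = root / f"{tid}.csv"
            if not f.exists():
                raise DegenerateInputError(f"missing trial file {f}")
            df = pd.read_csv(f)
            chans = list(df["channel"])
            if chans != channel_names:
                raise DegenerateInputError(
                    f"{f}: channels {chans} do not match manifest {channel_names}"
                )
            mats.append(df.drop(columns="channel").to_numpy(dtype=np.float64))
            ids.append(tid)
    elif format == "edf":
        from .edf import read_edf

        mats, ids = [], []
        channel_names, fs = None, None
        for tid in sorted(labels):
            f = root / f"{tid}.edf"
            if not f.exists():
                raise DegenerateInputError(f"missing trial file {f}")
            data, names, file_fs = read_edf(f)
            if channel_names is None:
                channel_names, fs = names, file_fs
            elif names != channel_names:
                raise DegenerateInputError(
                    f"{f}: channels {names} differ from {channel_names}"
                )
            mats.append(data)
            ids.append(tid)
    else:
        raise ConfigurationError(f"unknown trial format {format!r}")

    if not mats:
        raise DegenerateInputError(f"no trials found under {root}")
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise DegenerateInputError(f"trial shapes differ: {sorted(shapes)}")
    return TrialSet(
        trials=np.stack(mats),
        labels=[labels[t] for t in ids],
        channel_names=channel_names,
        sampling_rate=fs,
        trial_ids=ids,
    )


def write_features(path, features: np.ndarray, labels, trial_ids=None) -> None:
    """Feature table CSV with header trial_id,label,f1..fk."""
    f = np.asarray(features)
    ids = trial_ids or [f"trial_{i:04d}" for i in range(f.shape[0])]
    df = pd.DataFrame(f, columns=[f"f{j + 1}" for j in range(f.shape[1])])
    df.insert(0, "label", list(labels))
    df.insert(0, "trial_id", ids)
    df.to_csv(path, index=False)


def write_density(path, curve: DensityCurve) -> None:
    pd.DataFrame({"score": curve.grid, "density": curve.density}).to_csv(
        path, index=False
    )


def save_decoder(decoder: TrainedDecoder, path) -> None:
    """Serialize a trained decoder as a flat JSON document."""
    doc = {
        "csp": {
            "filters": decoder.csp.filters.tolist(),
            "eigenvalues": decoder.csp.eigenvalues.tolist(),
            "n_pairs": decoder.csp.n_pairs,
        },
        "discriminant": {
            "classes": decoder.discriminant.classes,
            "class_means": {
                k: v.tolist() for k, v in decoder.discriminant.class_means.items()
            },
            "projection": decoder.discriminant.projection.tolist(),
            "gamma": decoder.discriminant.gamma.tolist(),
            "class_counts": decoder.discriminant.class_counts,
        },
        "threshold": {
            "value": decoder.threshold.value,
            "fpr_max": decoder.threshold.fpr_max,
            "achieved_fpr": decoder.threshold.achieved_fpr,
            "side": decoder.threshold.side,
        },
        "selection": {
            "wpt_level": decoder.selection.wpt_level,
            "nodes": [list(nd) for nd in decoder.selection.nodes],
            "imfs_kept": decoder.selection.imfs_kept,
            "wavelet_name": decoder.selection.wavelet_name,
            "node_order": decoder.selection.node_order,
        },
        "channels": list(decoder.channels),
        "positive_label": decoder.positive_label,
        "negative_label": decoder.negative_label,
        "denoise": decoder.denoise,
        "report": decoder.report,
    }
    doc["config_hash"] = config_hash(doc["selection"])
    Path(path).write_text(json.dumps(doc, indent=2))


def load_decoder(path) -> TrainedDecoder:
    doc = json.loads(Path(path).read_text())
    csp = CspModel(
        filters=np.asarray(doc["csp"]["filters"]),
        eigenvalues=np.asarray(doc["csp"]["eigenvalues"]),
        n_pairs=int(doc["csp"]["n_pairs"]),
    )
    disc = doc["discriminant"]
    model = DiscriminantModel(
        classes=list(disc["classes"]),
        class_means={k: np.asarray(v) for k, v in disc["class_means"].items()},
        projection=np.asarray(disc["projection"]),
        gamma=np.asarray(disc["gamma"]),
        class_counts={k: int(v) for k, v in disc["class_counts"].items()},
    )
    thr = DecisionThreshold(
        value=float(doc["threshold"]["value"]),
        fpr_max=float(doc["threshold"]["fpr_max"]),
        achieved_fpr=float(doc["threshold"]["achieved_fpr"]),
        side=doc["threshold"]["side"],
    )
    sel = SubbandSelection(
        wpt_level=int(doc["selection"]["wpt_level"]),
        nodes=tuple(tuple(nd) for nd in doc["selection"]["nodes"]),
        imfs_kept=int(doc["selection"]["imfs_kept"]),
        wavelet_name=doc["selection"]["wavelet_name"],
        node_order=doc["selection"]["node_order"],
    )
    return TrainedDecoder(
        csp=csp,
        discriminant=model,
        threshold=thr,
        selection=sel,
        channels=tuple(doc["channels"]),
        positive_label=doc["positive_label"],
        negative_label=doc["negative_label"],
        denoise=bool(doc.get("denoise", False)),
        report=dict(doc.get("report", {})),
    )
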