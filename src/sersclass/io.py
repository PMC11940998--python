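"""Readers and writers for the package's interchange formats.

Spectra travel as a wide CSV (first column ``wavenumber_cm1``, one intensity
column per spectrum id) plus a metadata CSV with ``spectrum_id, patient_id,
class_label``. Summaries are written as a CSV table plus a lossless JSON
twin; fitted models serialize to a single JSON document. Readers reject
malformed input rather than coercing it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .plsda import PLSDAModel
from .protocol import METRIC_NAMES, FoldResult, ProtocolSummary
from .synth import SpectraDataset, Spectrum, WavenumberAxis

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_summary",
    "read_summary",
    "write_folds",
    "model_to_json",
    "model_from_json",
    "config_digest",
]

WAVENUMBER_COLUMN = "wavenumber_cm1"
META_COLUMNS = ("spectrum_id", "patient_id", "class_label")


def read_spectra(path_wide_csv: str | Path, path_meta_csv: str | Path) -> SpectraDataset:
    """Load and validate a wide spectra CSV plus its metadata CSV."""
    wide = pd.read_csv(path_wide_csv)
    meta = pd.read_csv(path_meta_csv, dtype=str)
    if wide.shape[1] < 2:
        raise ValueError(f"{path_wide_csv}: need a wavenumber column and at least one spectrum column")
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"{path_meta_csv}: missing columns {missing_cols}")
    axis_vals = wide.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(axis_vals) <= 0):
        raise ValueError("wavenumbers not strictly increasing")
    dup_meta = meta["spectrum_id"][meta["spectrum_id"].duplicated()].tolist()
    if dup_meta:
        raise ValueError(f"duplicate spectrum ids in metadata: {dup_meta}")
    spec_ids = list(wide.columns[1:])
    if len(set(spec_ids)) != len(spec_ids):
        raise ValueError("duplicate spectrum columns in spectra table")
    meta_ids = set(meta["spectrum_id"])
    unmatched = sorted(set(spec_ids) - meta_ids)
    if unmatched:
        raise ValueError(f"spectra without metadata: {unmatched}")
    orphans = sorted(meta_ids - set(spec_ids))
    if orphans:
        raise ValueError(f"metadata without spectra: {orphans}")
    axis = WavenumberAxis(start=float(axis_vals[0]), end=float(axis_vals[-1]), n_points=len(axis_vals))
    meta_idx = meta.set_index("spectrum_id")
    spectra = []
    class_of_patient: dict[str, str] = {}
    for sid in spec_ids:
        row = meta_idx.loc[sid]
        pid, label = str(row["patient_id"]), str(row["class_label"])
        prev = class_of_patient.setdefault(pid, label)
        if prev != label:
            raise ValueError(f"patient {pid!r} has conflicting class labels {prev!r} and {label!r}")
        spectra.append(
            Spectrum(spectrum_id=sid, patient_id=pid, class_label=label,
                     intensities=wide[sid].to_numpy(dtype=float))
        )
    ds = SpectraDataset(axis=axis, spectra=spectra, class_of_patient=class_of_patient)
    ds.validate()
    return ds


def write_spectra(ds: SpectraDataset, path_wide_csv: str | Path, path_meta_csv: str | Path) -> None:
    wide = pd.DataFrame({WAVENUMBER_COLUMN: ds.axis.grid()})
    for s in ds.spectra:
        wide[s.spectrum_id] = s.intensities
    wide.to_csv(path_wide_csv, index=False)
    meta = pd.DataFrame(
        [(s.spectrum_id, s.patient_id, s.class_label) for s in ds.spectra],
        columns=list(META_COLUMNS),
    )
    meta.to_csv(path_meta_csv, index=False)


def summary_to_dict(summary: ProtocolSummary) -> dict:
    return {
        "stats": {
            set_name: {m: list(v) for m, v in metrics.items()}
            for set_name, metrics in summary.stats.items()
        },
        "mean_vip": summary.mean_vip.tolist(),
        "n_folds": summary.n_folds,
        "positive_label": summary.positive_label,
        "wavenumbers": None if summary.wavenumbers is None else summary.wavenumbers.tolist(),
    }


def summary_from_dict(d: dict) -> ProtocolSummary:
    return ProtocolSummary(
        stats={s: {m: tuple(v) for m, v in metrics.items()} for s, metrics in d["stats"].items()},
        mean_vip=np.asarray(d["mean_vip"], dtype=float),
        n_folds=int(d["n_folds"]),
        positive_label=d["positive_label"],
        wavenumbers=None if d["wavenumbers"] is None else np.asarray(d["wavenumbers"], dtype=float),
    )


def write_summary(summary: ProtocolSummary, path_csv: str | Path, meta: dict | None = None) -> None:
    """CSV table (rows train/test, mean/min/max per metric) plus a JSON twin
    at the same path with ``.json`` extension; ``meta`` (e.g. seed and config
    hash) is embedded in the JSON."""
    path_csv = Path(path_csv)
    frame = summary.to_frame()
    ordered = [f"{m}_{s}" for m in METRIC_NAMES for s in ("mean", "min", "max")]
    frame[ordered].to_csv(path_csv)
    doc = summary_to_dict(summary)
    if meta:
        doc["meta"] = meta
    path_csv.with_suffix(".json").write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_summary(path_json: str | Path) -> ProtocolSummary:
    return summary_from_dict(json.loads(Path(path_json).read_text()))


def write_folds(results: list[FoldResult], path_json: str | Path, meta: dict | None = None) -> None:
    """Machine-readable per-fold record: metrics, ROC points, patients, VIP."""
    docs = []
    for r in results:
        docs.append(
            {
                "fold_id": list(r.fold_id),
                "n_lv_used": r.n_lv_used,
                "train_metrics": asdict(r.train_metrics),
                "test_metrics": asdict(r.test_metrics),
                "train_auc": r.train_roc.auc,
                "test_auc": r.test_roc.auc,
                "test_roc": {
                    "thresholds": [None if not np.isfinite(t) else t for t in r.test_roc.thresholds],
                    "fpr": r.test_roc.fpr.tolist(),
                    "tpr": r.test_roc.tpr.tolist(),
                },
                "vip": r.vip.tolist(),
                "train_patient_ids": sorted(r.train_patient_ids),
                "test_patient_ids": sorted(r.test_patient_ids),
            }
        )
    Path(path_json).write_text(json.dumps({"meta": meta or {}, "folds": docs}, indent=1, sort_keys=True))


def model_to_json(model: PLSDAModel, path: str | Path) -> None:
    doc = {
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "P_load": model.P_load.tolist(),
        "q": model.q.tolist(),
        "R": model.R.tolist(),
        "b": model.b.tolist(),
        "class_codes": model.class_codes,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def model_from_json(path: str | Path) -> PLSDAModel:
    d = json.loads(Path(path).read_text())
    return PLSDAModel(
        n_lv=int(d["n_lv"]),
        x_mean=np.asarray(d["x_mean"], dtype=float),
        y_mean=float(d["y_mean"]),
        W=np.asarray(d["W"], dtype=float),
        P_load=np.asarray(d["P_load"], dtype=float),
        q=np.asarray(d["q"], dtype=float),
        R=np.asarray(d["R"], dtype=float),
        b=np.asarray(d["b"], dtype=float),
        class_codes={k: int(v) for k, v in d["class_codes"].items()},
    )


def config_digest(config_obj: object) -> str:
    """Stable SHA-256 over a config's canonical JSON form."""

    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    blob = json.dumps(config_obj, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
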