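"""Reading and writing datasets, models and reports (plain CSV/TSV + JSON)."""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import IntervalDataset, TimingModel

__all__ = [
    "ParseError",
    "read_intervals_table",
    "write_intervals_table",
    "model_to_json",
    "model_from_json",
    "write_json",
]


class ParseError(ValueError):
    """A dataset table could not be parsed into an interval dataset."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_intervals_table(path, labels_path=None) -> IntervalDataset:
    """Load a trials x intervals duration table (CSV/TSV, msec).

    The header row names the intervals; columns prefixed ``meta_`` are
    split off into per-trial metadata.  Interval labels may be supplied via
    a JSON sidecar (``labels_path``, or ``<stem>.labels.json`` next to the
    table) holding ``{"interval_labels": [...]}``.  Rows containing a
    missing or non-positive duration are rejected with a row-indexed
    warning; ragged rows, non-numeric cells and K < 3 are hard errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ParseError(f"{path}: malformed table ({err})") from err
    meta_cols = [c for c in df.columns if str(c).startswith("meta_")]
    dur_cols = [c for c in df.columns if c not in meta_cols]
    if len(dur_cols) < 3:
        raise ParseError(f"{path}: need K >= 3 interval columns, found {len(dur_cols)}")
    numeric = {}
    for c in dur_cols:
        raw = df[c]
        num = pd.to_numeric(raw, errors="coerce")
        non_numeric = num.isna() & raw.notna()
        if non_numeric.any():
            rows = df.index[non_numeric].tolist()[:10]
            raise ParseError(f"{path}: non-numeric duration in column {c!r}, row(s) {rows}")
        numeric[c] = num
    durations = pd.DataFrame(numeric)
    bad_rows = durations.isna().any(axis=1) | (durations <= 0).any(axis=1)
    if bad_rows.any():
        idx = df.index[bad_rows].tolist()
        warnings.warn(
            f"{path}: rejected {len(idx)} row(s) with missing or non-positive "
            f"durations (rows {idx[:20]}{'...' if len(idx) > 20 else ''})",
            stacklevel=2,
        )
        durations = durations.loc[~bad_rows]
        df = df.loc[~bad_rows]
    labels = None
    sidecar = Path(labels_path) if labels_path else path.with_suffix(".labels.json")
    if sidecar.exists():
        labels = json.loads(sidecar.read_text())["interval_labels"]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    return IntervalDataset(durations.to_numpy(float), interval_labels=labels, trial_meta=meta)


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_intervals_table(dataset: IntervalDataset, path, labels_sidecar: bool = True) -> None:
    """Write a dataset back to CSV/TSV (full float precision round-trip)."""
    path = Path(path)
    K = dataset.n_intervals
    cols = {f"interval_{k + 1}": dataset.durations[:, k] for k in range(K)}
    df = pd.DataFrame(cols)
    if dataset.trial_meta is not None:
        for c in dataset.trial_meta.columns:
            name = c if str(c).startswith("meta_") else f"meta_{c}"
            df[name] = dataset.trial_meta[c].to_numpy()
    _atomic_write_text(path, df.to_csv(index=False, sep=_sep_for(path)))
    if labels_sidecar and dataset.interval_labels is not None:
        _atomic_write_text(
            path.with_suffix(".labels.json"),
            json.dumps({"interval_labels": dataset.interval_labels}, indent=1),
        )


def model_to_json(model: TimingModel, path=None, seed=None, extra_metadata: dict | None = None):
    """Serialize a model to one JSON document (exact decimal round-trip)."""
    doc = model.to_dict()
    doc["metadata"] = {"seed": seed, "version": __version__, **(extra_metadata or {})}
    text = json.dumps(doc, indent=1)
    if path is not None:
        _atomic_write_text(Path(path), text)
    return doc


def model_from_json(source) -> TimingModel:
    """Load a model from a JSON path or an already parsed document.

    Accepts either a bare model document or a fit-result document that
    nests one under a ``"model"`` key, so ``diagnose`` can consume the
    output of ``fit`` directly.
    """
    doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    if "global_weights" not in doc and "model" in doc:
        doc = doc["model"]
    return TimingModel.from_dict(doc)


def write_json(doc: dict, path) -> None:
    """Atomically write a JSON document (numpy scalars/arrays coerced)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    _atomic_write_text(Path(path), json.dumps(doc, indent=1, default=default))
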