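"""Serialization: tensor archives, per-sample CSV layouts, value tables, curves.

Two dataset layouts are supported (documented in the README):

* a single-file binary tensor archive (numpy ``.npz``) holding ``signals``
  (N, W, C), ``labels`` (N,), ``split`` (N, unicode tags), optional channel
  statistics and an optional corruption record;
* a per-sample CSV directory: one ``sample_00000.csv`` per window (rows =
  timesteps, columns = channels, no header index) plus a ``labels.csv``
  sidecar with columns ``sample,label,split``.

Value tables and evaluation curves are plain CSV so they diff and round-trip
byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ChannelStats, CorruptionRecord, ValueTable, WindowedDataset
from .evaluation import CSDCurve, RHLVSCurve

__all__ = [
    "save_archive", "load_archive", "save_csv_dir", "load_csv_dir",
    "save_value_table", "load_value_table", "save_csd_curve",
    "save_rhlvs_curve", "save_report",
]


# -- binary tensor archive --------------------------------------------------

def save_archive(path, ds: WindowedDataset,
                 record: CorruptionRecord | None = None) -> None:
    payload = {
        "signals": ds.signals,
        "labels": ds.labels,
        "split": ds.split,
        "n_classes": np.int64(ds.n_classes),
    }
    if ds.channel_stats is not None:
        payload["channel_mean"] = ds.channel_stats.mean
        payload["channel_sd"] = ds.channel_stats.sd
    if record is not None:
        payload["corrupted_indices"] = record.indices
        payload["original_labels"] = record.original_labels
        payload["corruption_rate"] = np.float64(record.rate)
        payload["corruption_seed"] = np.int64(record.seed)
    np.savez(path, **payload)


def load_archive(path) -> tuple[WindowedDataset, CorruptionRecord | None]:
    with np.load(path, allow_pickle=False) as z:
        stats = None
        if "channel_mean" in z:
            stats = ChannelStats(z["channel_mean"], z["channel_sd"])
        ds = WindowedDataset(z["signals"], z["labels"], z["split"],
                             int(z["n_classes"]), channel_stats=stats)
        record = None
        if "corrupted_indices" in z:
            record = CorruptionRecord(z["corrupted_indices"],
                                      z["original_labels"],
                                      float(z["corruption_rate"]),
                                      int(z["corruption_seed"]))
    return ds, record


# -- per-sample CSV directory -----------------------------------------------

def save_csv_dir(directory, ds: WindowedDataset) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(ds.n_samples):
        pd.DataFrame(ds.signals[i],
                     columns=[f"ch{c}" for c in range(ds.n_channels)]
                     ).to_csv(directory / f"sample_{i:05d}.csv", index=False)
    pd.DataFrame({
        "sample": np.arange(ds.n_samples),
        "label": ds.labels,
        "split": ds.split,
    }).to_csv(directory / "labels.csv", index=False)


def load_csv_dir(directory) -> WindowedDataset:
    directory = Path(directory)
    sidecar = pd.read_csv(directory / "labels.csv")
    signals = np.stack([
        pd.read_csv(directory / f"sample_{i:05d}.csv").to_numpy(dtype=np.float64)
        for i in sidecar["sample"]
    ])
    labels = sidecar["label"].to_numpy(dtype=np.int64)
    return WindowedDataset(signals, labels,
                           sidecar["split"].to_numpy(dtype="U5"),
                           n_classes=int(labels.max()) + 1)


# -- value tables ------------------------------------------------------------

def save_value_table(path, table: ValueTable,
                     record: CorruptionRecord | None = None) -> None:
    df = pd.DataFrame({"index": table.sample_index,
                       "value": table.probs})
    if record is not None:
        corrupted = np.isin(table.sample_index, record.indices)
        df["is_corrupted"] = corrupted.astype(int)
    df.to_csv(path, index=False, float_format="%.12g")


def load_value_table(path) -> ValueTable:
    df = pd.read_csv(path)
    return ValueTable(df["value"].to_numpy(), df["index"].to_numpy())


# -- curves and reports -------------------------------------------------------

def save_csd_curve(path, curve: CSDCurve) -> None:
    pd.DataFrame({
        "fraction_removed": curve.removal_fractions,
        "discovery": curve.discovery,
        "optimal": curve.optimal,
    }).to_csv(path, index=False, float_format="%.12g")


def save_rhlvs_curve(path, curve: RHLVSCurve) -> None:
    pd.DataFrame({
        "fraction_removed": curve.removal_fractions,
        "remove_high_acc": curve.remove_high_acc,
        "remove_low_acc": curve.remove_low_acc,
    }).to_csv(path, index=False, float_format="%.12g")


def save_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
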