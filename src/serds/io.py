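"""Plain-text file formats and run configuration.

Raw blocks are stored as tab-delimited text with a small header (format
tag, excitation, locus, label, repeats), one wavelength column and one
column per repeat — diff-able and loadable anywhere.  Classification
reports are JSON-lines, one record per comparison.  Run configuration is a
flat ``key = value`` text file; unknown keys are rejected and every run
writes its fully-resolved configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .classify import BINARY_COMPARISONS, ClassificationReport, MulticlassReport, binary_metrics
from .core import RawBlock

BLOCK_FORMAT_TAG = "serds-block-v1"


class BlockFormatError(ValueError):
    """Malformed raw-block file."""


def write_block(path, block: RawBlock) -> None:
    path = Path(path)
    lines = [f"# {BLOCK_FORMAT_TAG}",
             f"# excitation_nm={block.excitation_nm!r}",
             f"# locus={block.locus_id}"]
    if block.label is not None:
        lines.append(f"# label={block.label}")
    lines.append(f"# repeats={block.n_repeats}")
    header = "wavelength_nm\t" + "\t".join(
        f"r{i}" for i in range(block.n_repeats))
    lines.append(header)
    body = np.column_stack([block.wavelength_nm, block.intensities.T])
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.12g", delimiter="\t")


def read_block(path) -> RawBlock:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    n_cols = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if line.startswith("wavelength_nm"):
                continue
            parts = line.split("\t")
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise BlockFormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise BlockFormatError(f"{path}:{lineno}: {exc}") from exc
    if "excitation_nm" not in meta:
        raise BlockFormatError(
            f"{path}: missing mandatory '# excitation_nm=' header "
            "(it drives the axis conversion)")
    if not rows:
        raise BlockFormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    return RawBlock(wavelength_nm=data[:, 0], intensities=data[:, 1:].T,
                    excitation_nm=float(meta["excitation_nm"]),
                    locus_id=meta.get("locus", ""),
                    label=meta.get("label"))


def _report_record(report: ClassificationReport) -> dict:
    return {
        "comparison": report.comparison,
        "positive_class": report.positive_class,
        "confusion": {"tp": report.tp, "fp": report.fp,
                      "fn": report.fn, "tn": report.tn},
        "sensitivity": round(report.sensitivity, 1),
        "specificity": round(report.specificity, 1),
        "accuracy": round(report.accuracy, 1),
        "classification_error": round(report.error, 1),
        "auc": round(report.auc, 1),
    }


def write_report(path, multiclass: MulticlassReport,
                 reports: dict[str, ClassificationReport]) -> None:
    """JSON-lines report: six binary panels plus the multiclass summary."""
    missing = set(BINARY_COMPARISONS) - set(reports)
    if missing:
        raise ValueError(f"incomplete report set, missing: {sorted(missing)}")
    path = Path(path)
    with path.open("w") as fh:
        for name in BINARY_COMPARISONS:
            fh.write(json.dumps(_report_record(reports[name])) + "\n")
        fh.write(json.dumps({
            "comparison": "multiclass",
            "accuracy": round(multiclass.accuracy, 1),
            "confusion": {truth: {pred: int(multiclass.confusion.loc[truth, pred])
                                  for pred in multiclass.confusion.columns}
                          for truth in multiclass.confusion.index},
        }) + "\n")


def read_report(path) -> list[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


def recompute_report_metrics(record: dict) -> dict[str, float]:
    """Metrics recomputed from a stored record's confusion counts."""
    c = record["confusion"]
    return binary_metrics(c["tp"], c["fp"], c["fn"], c["tn"],
                          positive_class=record.get("positive_class", ""))


# ---------------------------------------------------------------------------
# dataset matrix (rows = loci, first columns = ids/labels, then shift bins)

def write_dataset(path, data) -> None:
    """Purified-spectra matrix as tab-delimited text with a shift header."""
    import pandas as pd
    df = pd.DataFrame(data.X, columns=[f"{s:.4f}" for s in data.shift_cm1])
    df.insert(0, "specimen", data.specimen_ids)
    df.insert(0, "label", data.labels)
    df.insert(0, "locus", data.locus_ids)
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path):
    import pandas as pd

    from .classify import LabelledDataset
    df = pd.read_csv(path, sep="\t")
    meta = ["locus", "label", "specimen"]
    if df.columns[:3].tolist() != meta:
        raise ValueError(f"{path}: expected leading columns {meta}")
    bins = df.columns[3:]
    return LabelledDataset(
        X=df[bins].to_numpy(float),
        shift_cm1=np.array([float(c) for c in bins]),
        labels=df["label"].to_numpy(str),
        locus_ids=df["locus"].to_numpy(str),
        specimen_ids=df["specimen"].fillna("").to_numpy(str))


# ---------------------------------------------------------------------------
# run configuration

@dataclasses.dataclass
class RunConfig:
    """Flat key-value configuration binding the pipeline stages."""

    seed: int = 0
    repeats: int = 50
    detector_pixels: int = 1024
    loci_neurofibroma: int = 9
    loci_skin: int = 12
    loci_nerve: int = 6
    loci_fat: int = 13
    loci_bone: int = 15
    loci_mucosa: int = 27
    train_pairs: int = 2000
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    folds: int = 5
    range_low_cm1: float = 550.0
    range_high_cm1: float = 1800.0
    variance_target: float = 0.95

    def locus_counts(self) -> dict[str, int]:
        return {name: getattr(self, f"loci_{name}")
                for name in ("neurofibroma", "skin", "nerve",
                             "fat", "bone", "mucosa")}


def parse_run_config(path) -> RunConfig:
    """Parse a flat ``key = value`` file; unknown keys are an error."""
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            caster = float if fields[key] == "float" else int
            kwargs[key] = caster(value.strip())
    return RunConfig(**kwargs)


def write_run_config(path, config: RunConfig) -> None:
    with Path(path).open("w") as fh:
        for f in dataclasses.fields(RunConfig):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")
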