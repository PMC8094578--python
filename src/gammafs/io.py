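"""Readers and writers for RR tables, feature tables, rankings and reports.

CSV is the interchange format throughout (there is no domain standard for RR
feature tables); JSON outputs carry a ``schema_version`` field.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .evaluation import EvalReport
from .hrv import RRSeries
from .selection import ImportanceRanking

__all__ = [
    "read_rr_table",
    "write_rr_table",
    "read_feature_table",
    "write_feature_table",
    "write_ranking",
    "read_ranking",
    "write_ki_profile",
    "read_ki_profile",
    "write_eval_report",
    "read_eval_report",
]

SCHEMA_VERSION = 1
_LABELS = {"NSR", "AF", "unknown", ""}


def read_rr_table(path, format: str | None = None) -> list:
    """Read RR series from plain text or CSV.

    * ``txt``: one interval (ms) per line; yields a single unlabeled series
      named after the file stem.
    * ``csv``: columns ``series_id, rr_ms, label``; rows are grouped by
      ``series_id`` in order of first appearance.

    Malformed rows raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "txt")
    if fmt == "txt":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    intervals.append(float(line))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric RR interval {line!r}")
        return [RRSeries(intervals=np.asarray(intervals),
                         rhythm_label="unknown", series_id=path.stem)]
    if fmt != "csv":
        raise ValidationError(f"unknown RR table format {fmt!r} (expected txt or csv)")
    groups: dict = {}
    labels: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"series_id", "rr_ms"} <= set(reader.fieldnames):
            raise ParseError(f"{path}: CSV must have columns series_id, rr_ms[, label]")
        for lineno, row in enumerate(reader, start=2):
            sid = row["series_id"]
            try:
                rr = float(row["rr_ms"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}:{lineno}: non-numeric rr_ms {row.get('rr_ms')!r}"
                )
            label = (row.get("label") or "").strip()
            if label not in _LABELS:
                raise ParseError(f"{path}:{lineno}: unknown label {label!r}")
            groups.setdefault(sid, []).append(rr)
            labels.setdefault(sid, label or "unknown")
    return [RRSeries(intervals=np.asarray(v), rhythm_label=labels[sid], series_id=sid)
            for sid, v in groups.items()]


def write_rr_table(series_list, path) -> None:
    """Write RR series as the CSV dialect :func:`read_rr_table` accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["series_id", "rr_ms", "label"])
        for s in series_list:
            for v in s.intervals:
                w.writerow([s.series_id, repr(float(v)), s.rhythm_label])


def write_feature_table(features: pd.DataFrame, labels, path) -> None:
    """Feature table CSV: series_id index, 32 feature columns, label column."""
    out = features.copy()
    out["label"] = np.asarray(labels)
    out.to_csv(path, index=True, index_label="series_id")


def read_feature_table(path, label_col: str = "label"):
    """Read a feature table CSV back into ``(features, labels)``."""
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise ParseError(f"{path}: missing label column {label_col!r}")
    if "series_id" in df.columns:
        df = df.set_index("series_id")
    labels = df[label_col]
    return df.drop(columns=[label_col]), labels


def write_ranking(ranking: ImportanceRanking, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "importance_ranking",
        "scorer": ranking.scorer_name,
        "B": ranking.B,
        "seed": ranking.seed,
        "feature_names": list(ranking.feature_names),
        "order": list(ranking.order),
        "medians": [float(v) for v in ranking.medians],
        "scores": [[float(v) for v in row] for row in ranking.scores],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ranking(path) -> ImportanceRanking:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("kind") != "importance_ranking":
        raise ParseError(f"{path}: not an importance-ranking file")
    return ImportanceRanking(
        scores=np.asarray(d["scores"], dtype=float),
        medians=np.asarray(d["medians"], dtype=float),
        order=list(d["order"]),
        feature_names=list(d["feature_names"]),
        scorer_name=d["scorer"],
        B=int(d["B"]),
        seed=d.get("seed"),
    )


def write_ki_profile(profile: dict, path) -> None:
    """Stability profile CSV with columns ``p_prime, ki``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["p_prime", "ki"])
        for p_prime in sorted(profile):
            w.writerow([p_prime, repr(float(profile[p_prime]))])


def read_ki_profile(path) -> dict:
    out = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                out[int(row["p_prime"])] = float(row["ki"])
            except (KeyError, TypeError, ValueError):
                raise ParseError(f"{path}:{lineno}: malformed stability row")
    return out


def write_eval_report(report: EvalReport, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        report.table.to_csv(path, index=False)
        meta = {"schema_version": SCHEMA_VERSION, "kind": "eval_report",
                "scheme": report.scheme, "layout": report.layout, "seed": report.seed}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    elif format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "eval_report",
            "scheme": report.scheme,
            "layout": report.layout,
            "seed": report.seed,
            "rows": report.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_eval_report(path, format: str = "csv") -> EvalReport:
    path = Path(path)
    if format == "csv":
        table = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return EvalReport(scheme=meta.get("scheme", "unknown"), table=table,
                          layout=meta.get("layout", {}), seed=meta.get("seed"))
    if format == "json":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("kind") != "eval_report":
            raise ParseError(f"{path}: not an evaluation-report file")
        return EvalReport(scheme=d["scheme"], table=pd.DataFrame(d["rows"]),
                          layout=d.get("layout", {}), seed=d.get("seed"))
    raise ValidationError(f"unknown report format {format!r}")
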