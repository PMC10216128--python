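"""Loading, validation, filtering and reporting of tabular panel data.

The canonical on-disk form is a delimited table (CSV or TSV) of samples ×
features holding already-normalized abundance values (e.g. SomaScan RFU),
one label column, and optionally a patient-identifier column.  A minimal
reader for the SomaScan ADAT tab-delimited dialect is provided; its column
metadata supplies the human-protein flag used by :func:`filter_human_features`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "load_feature_table",
    "load_adat",
    "filter_human_features",
    "write_selection_report",
    "write_weight_table_csv",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, non-numeric cells...)."""


@dataclass
class FeatureTable:
    """A validated samples × features abundance matrix with binary labels.

    Labels are 0 for the negative class (pre-treatment) and 1 for the
    positive class (post-treatment).  Values are expected to be complete
    and already normalized; validation rejects missing entries rather than
    imputing.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    patient_ids: list[str] | None = None
    feature_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"sample_ids/labels length mismatch: matrix has {n} rows, "
                f"{len(self.sample_ids)} sample ids, {len(self.labels)} labels"
            )
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            dupes = _duplicates(self.feature_names)
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample ids: {_duplicates(self.sample_ids)[:5]}")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                "missing values are not supported; first missing entry at "
                f"sample {self.sample_ids[r]!r}, feature {self.feature_names[c]!r}"
            )
        lab = set(np.unique(self.labels).tolist())
        if not lab <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got values {sorted(lab)}")
        if lab != {0, 1}:
            raise ValueError("both classes (0 and 1) must be present")
        self.labels = self.labels.astype(int)
        if self.patient_ids is not None:
            self.patient_ids = [str(pid) for pid in self.patient_ids]
            if len(self.patient_ids) != n:
                raise ValueError("patient_ids length mismatch")
        if self.feature_meta is not None and len(self.feature_meta) != p:
            raise ValueError("feature_meta must have one row per feature")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            patient_ids=None if self.patient_ids is None
            else [self.patient_ids[i] for i in idx],
            feature_meta=self.feature_meta,
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise KeyError(f"features not in table: {missing[:5]}")
        cols = [pos[f] for f in names]
        return FeatureTable(
            values=self.values[:, cols],
            feature_names=[self.feature_names[j] for j in cols],
            sample_ids=list(self.sample_ids),
            labels=self.labels,
            patient_ids=self.patient_ids,
            feature_meta=None if self.feature_meta is None
            else self.feature_meta.iloc[cols].reset_index(drop=True),
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.feature_names)
        df.insert(0, label_column, self.labels)
        if self.patient_ids is not None:
            df.insert(1, "patient_id", self.patient_ids)
        return df


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out


def load_feature_table(
    path: str | Path,
    label_column: str,
    orientation: str = "rows-are-samples",
    patient_column: str | None = None,
    label_map: Mapping[str, int] | None = None,
    delimiter: str | None = None,
) -> FeatureTable:
    """Load a delimited samples × features table.

    Parameters
    ----------
    path
        CSV or TSV file; the delimiter is inferred from the extension
        (``.tsv``/``.txt`` → tab) unless ``delimiter`` is given.
    label_column
        Name of the column (or row, when rows-are-features) holding the
        class label.
    orientation
        ``rows-are-samples`` (default) or ``rows-are-features``; in the
        latter case the table is transposed after reading.
    patient_column
        Optional column carrying patient identifiers (pre/post pairing).
    label_map
        Mapping from string labels to {0, 1}; labels must already be
        numeric 0/1 when omitted — the positive class is never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt", ".adat"} else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "rows-are-features":
        df = df.T
    elif orientation != "rows-are-samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if label_column not in df.columns:
        raise FormatError(
            f"label column {label_column!r} not found; columns start with "
            f"{list(df.columns[:5])}"
        )
    raw_labels = df[label_column]
    if label_map is not None:
        unknown = set(raw_labels.astype(str)) - set(map(str, label_map))
        if unknown:
            raise FormatError(f"labels outside the declared mapping: {sorted(unknown)}")
        labels = raw_labels.astype(str).map({str(k): v for k, v in label_map.items()})
    else:
        labels = pd.to_numeric(raw_labels, errors="coerce")
        if labels.isna().any():
            raise FormatError(
                f"non-numeric labels in {label_column!r}; declare a label map "
                "(e.g. pre=0,post=1)"
            )
    drop = [label_column]
    patient_ids = None
    if patient_column is not None:
        if patient_column not in df.columns:
            raise FormatError(f"patient column {patient_column!r} not found")
        patient_ids = df[patient_column].astype(str).tolist()
        drop.append(patient_column)
    matrix = df.drop(columns=drop)
    numeric = matrix.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        bad = np.argwhere(numeric.isna().values)[0]
        raise FormatError(
            f"non-numeric value at sample {matrix.index[bad[0]]!r}, "
            f"feature {matrix.columns[bad[1]]!r}: "
            f"{matrix.iat[bad[0], bad[1]]!r}"
        )
    return FeatureTable(
        values=numeric.to_numpy(dtype=float),
        feature_names=[str(c) for c in matrix.columns],
        sample_ids=[str(i) for i in matrix.index],
        labels=labels.to_numpy(),
        patient_ids=patient_ids,
    )


def load_adat(
    path: str | Path,
    label_column: str,
    label_map: Mapping[str, int] | None = None,
    patient_column: str | None = None,
) -> FeatureTable:
    """Read the SomaScan ADAT tab-delimited dialect.

    Supports the header-block layout: ``^HEADER`` (ignored), ``^COL_DATA`` /
    ``^ROW_DATA`` (ignored), then ``^TABLE_BEGIN`` where column (aptamer)
    metadata rows precede the sample rows.  Aptamer metadata becomes
    ``feature_meta``; an ``is_human_protein`` flag is derived from the
    ``Organism`` and ``Type`` annotations when present (Organism == "Human"
    and Type == "Protein").  Features are named by ``SeqId``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("^TABLE_BEGIN"))
    except StopIteration:
        raise FormatError("no ^TABLE_BEGIN block found; not an ADAT file") from None
    rows = [ln.split("\t") for ln in lines[start + 1:] if ln.strip()]
    # Column-metadata rows have an empty leading block: the metadata name sits
    # just before the per-aptamer values; sample rows begin with sample fields.
    meta_rows: dict[str, list[str]] = {}
    data_start = None
    n_row_fields = None
    for i, row in enumerate(rows):
        nonempty = [j for j, cell in enumerate(row) if cell != ""]
        if not nonempty:
            continue
        first = nonempty[0]
        if first > 0 and data_start is None:
            name = row[first]
            meta_rows[name] = row[first + 1:]
            n_row_fields = first
        else:
            data_start = i if data_start is None else data_start
    if not meta_rows or data_start is None or n_row_fields is None:
        raise FormatError("could not locate aptamer metadata / sample rows")
    feature_meta = pd.DataFrame(meta_rows)
    if "SeqId" in feature_meta.columns:
        feature_names = feature_meta["SeqId"].tolist()
    else:
        feature_names = [f"Feat{j}" for j in range(len(feature_meta))]
    if {"Organism", "Type"} <= set(feature_meta.columns):
        feature_meta["is_human_protein"] = (
            (feature_meta["Organism"] == "Human") & (feature_meta["Type"] == "Protein")
        )
    header = rows[data_start][:n_row_fields]
    sample_rows = rows[data_start + 1:]
    info = pd.DataFrame([r[:n_row_fields] for r in sample_rows], columns=header)
    values = np.array(
        [[float(x) for x in r[n_row_fields:n_row_fields + len(feature_names)]]
         for r in sample_rows]
    )
    if label_column not in info.columns:
        raise FormatError(f"label column {label_column!r} not in ADAT sample fields")
    raw = info[label_column].astype(str)
    if label_map is not None:
        labels = raw.map({str(k): v for k, v in label_map.items()})
        if labels.isna().any():
            raise FormatError("labels outside the declared mapping")
        labels = labels.to_numpy()
    else:
        labels = pd.to_numeric(raw).to_numpy()
    sample_col = "SampleId" if "SampleId" in info.columns else info.columns[0]
    patient_ids = (
        info[patient_column].astype(str).tolist()
        if patient_column and patient_column in info.columns else None
    )
    return FeatureTable(
        values=values,
        feature_names=feature_names,
        sample_ids=info[sample_col].astype(str).tolist(),
        labels=labels,
        patient_ids=patient_ids,
        feature_meta=feature_meta,
    )


def filter_human_features(table: FeatureTable) -> FeatureTable:
    """Keep exactly the features flagged as human protein targets.

    Requires ``feature_meta`` with a boolean ``is_human_protein`` column;
    order of retained features is preserved and samples are untouched.
    """
    if table.feature_meta is None or "is_human_protein" not in table.feature_meta:
        raise ValueError(
            "no is_human_protein feature metadata: supply flags "
            "(e.g. via an ADAT file) or skip the human-protein filter"
        )
    mask = table.feature_meta["is_human_protein"].astype(bool).to_numpy()
    if not mask.any():
        raise ValueError("human-protein filter would remove every feature")
    keep = [f for f, m in zip(table.feature_names, mask) if m]
    return table.subset_features(keep)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_selection_report(result, path: str | Path, config: dict | None = None) -> None:
    """Serialize a sweep result as a deterministic JSON report.

    The report holds the chosen threshold/classifier/feature set, the full
    (threshold × classifier) metric grid, any baselines, and the run
    configuration.  Identical inputs produce byte-identical files.
    """
    payload = _jsonify({"config": config or {}, **result.to_dict()})
    text = json.dumps(payload, indent=2, sort_keys=True)
    Path(path).write_text(text + "\n")


def write_weight_table_csv(weight_table, path: str | Path) -> None:
    """Export accumulated per-feature weights with per-(fold, method) provenance."""
    prov_cols = sorted(weight_table.provenance)
    rows = []
    for feat in sorted(weight_table.weights,
                       key=lambda f: (-weight_table.weights[f], f)):
        row = {"feature": feat, "weight": weight_table.weights[feat]}
        for key in prov_cols:
            fold, method = key
            row[f"fold{fold}_{method}"] = int(feat in weight_table.provenance[key])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
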