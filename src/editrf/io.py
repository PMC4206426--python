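"""Delimited-text I/O for feature tables, rankings and IFS curves.

Input tables are CSV/TSV with a mandatory header row; the delimiter is
sniffed from the header unless given.  One column holds the class label
(``positive_label``, default ``"1"``, marks editing sites); an optional
column holds sample identifiers.  Everything else must be numeric and
finite — missing values are a hard error unless median imputation is
requested explicitly.

Rankings and IFS curves are written as TSV with a fixed column layout
and optional ``#``-prefixed header comments (configuration echo); both
round-trip through their ``read_*`` counterparts.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import DatasetError, FeatureTable, LabeledDataset
from .ifs import IFSCurve, IFSRecord, _optimum
from .metrics import MetricSet
from .mrmr import RankedFeatures

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_ranking",
    "read_ranking",
    "write_ifs_curve",
    "read_ifs_curve",
]

_SNIFF_DELIMITERS = ",\t;"


def _sniff_delimiter(header_line: str) -> str:
    try:
        return csv.Sniffer().sniff(header_line, delimiters=_SNIFF_DELIMITERS).delimiter
    except csv.Error:
        return ","


def _normalize_label(value) -> str:
    """Canonical string form so 1, 1.0, ' 1' and '1' all compare equal."""
    s = str(value).strip()
    try:
        f = float(s)
    except ValueError:
        return s
    if math.isfinite(f) and f == int(f):
        return str(int(f))
    return s


def read_dataset(
    path: str | Path,
    label_column: str = "label",
    delimiter: str | None = None,
    positive_label: str = "1",
    negative_label: str | None = None,
    sample_id_column: str | None = None,
    impute: str | None = None,
) -> LabeledDataset:
    """Load a labeled feature table from a delimited text file.

    The label column is removed from the feature matrix; the order of
    the remaining columns is preserved.  Values equal to
    ``positive_label`` (after numeric normalization) map to 1; with
    ``negative_label`` unset, all remaining label values must agree on a
    single negative code.  ``impute="median"`` replaces missing feature
    cells with the column median instead of erroring.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header_line = line
                break
        else:
            raise DatasetError(f"{path}: no header row found")
    delim = delimiter or _sniff_delimiter(header_line)
    header = [h.strip() for h in header_line.rstrip("\r\n").split(delim)]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise DatasetError(f"{path}: duplicate column names: {sorted(dupes)}")
    df = pd.read_csv(path, sep=delim, comment="#", float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    if label_column not in df.columns:
        raise DatasetError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    raw_labels = df.pop(label_column)
    sample_ids = None
    if sample_id_column is not None and sample_id_column in df.columns:
        sample_ids = df.pop(sample_id_column).astype(str).str.strip().tolist()

    pos = _normalize_label(positive_label)
    norm = raw_labels.map(_normalize_label)
    labels = np.where(norm == pos, 1, -1)
    neg_values = sorted(set(norm[labels == -1]))
    if negative_label is not None:
        neg = _normalize_label(negative_label)
        bad = [v for v in neg_values if v != neg]
        if bad:
            raise DatasetError(f"{path}: unmappable label values: {bad}")
    elif len(neg_values) > 1:
        raise DatasetError(
            f"{path}: ambiguous negative labels {neg_values}; "
            "set negative_label explicitly"
        )
    labels[labels == -1] = 0

    cols = {}
    for c in df.columns:
        try:
            cols[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as e:
            raise DatasetError(f"{path}: non-numeric value in feature {c!r}: {e}")
    feats = pd.DataFrame(cols)
    if feats.shape[1] == 0:
        raise DatasetError(f"{path}: no feature columns besides the label")
    if feats.isna().any().any() or not np.isfinite(feats.to_numpy()).all():
        if impute == "median":
            feats = feats.replace([np.inf, -np.inf], np.nan)
            feats = feats.fillna(feats.median())
        else:
            bad_cols = feats.columns[
                ~np.isfinite(feats.to_numpy()).all(axis=0)
            ].tolist()
            raise DatasetError(
                f"{path}: missing/non-finite values in {bad_cols}; "
                "pass impute='median' to impute"
            )
    table = FeatureTable(feats.to_numpy(float), list(feats.columns), sample_ids)
    return LabeledDataset(table, labels)


def write_dataset(
    dataset: LabeledDataset,
    path: str | Path,
    delimiter: str = ",",
    label_column: str = "label",
    sample_id_column: str | None = "sample_id",
) -> None:
    """Write a labeled table; lossless through :func:`read_dataset`."""
    df = dataset.table.to_frame().copy()
    df.insert(0, label_column, dataset.labels)
    if sample_id_column:
        df.insert(0, sample_id_column, dataset.table.sample_ids)
    df.to_csv(path, sep=delimiter, index=False)


def _write_header_comments(fh, comments: dict | None) -> None:
    for key, val in (comments or {}).items():
        fh.write(f"# {key}={val}\n")


def write_ranking(
    ranking: RankedFeatures, path: str | Path, comments: dict | None = None
) -> None:
    """TSV: rank (1-based), feature_name, scheme_score, relevance, redundancy."""
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    with open(path, "w", encoding="utf-8") as fh:
        _write_header_comments(fh, comments)
        fh.write(f"# scheme={ranking.scheme}\n")
        fh.write("rank\tfeature_name\tscheme_score\trelevance\tredundancy\n")
        for i, name in enumerate(ranking.feature_names):
            fh.write(
                f"{i + 1}\t{name}\t{float(ranking.step_score[i])!r}\t"
                f"{float(ranking.relevance[i])!r}\t{float(ranking.redundancy[i])!r}\n"
            )


def read_ranking(path: str | Path) -> RankedFeatures:
    """Rebuild a ranking from :func:`write_ranking` output.

    Original column indices are not stored in the file, so ``order`` is
    None on the returned object; the name ordering and scores are exact.
    """
    scheme = "MID"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# scheme="):
                scheme = line.split("=", 1)[1].strip()
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    expected = ["rank", "feature_name", "scheme_score", "relevance", "redundancy"]
    if list(df.columns) != expected:
        raise DatasetError(f"{path}: unexpected ranking columns {list(df.columns)}")
    df = df.sort_values("rank")
    return RankedFeatures(
        feature_names=df["feature_name"].astype(str).tolist(),
        relevance=df["relevance"].to_numpy(float),
        step_score=df["scheme_score"].to_numpy(float),
        redundancy=df["redundancy"].to_numpy(float),
        scheme=scheme,
        order=None,
    )


def _fmt(v: float) -> str:
    return "NA" if (v is None or math.isnan(v)) else f"{v:.6f}"


def write_ifs_curve(
    curve: IFSCurve, path: str | Path, comments: dict | None = None
) -> None:
    """TSV: k, Sn, Sp, Acc, MCC at 6 decimal places (one row per k)."""
    if len(curve) == 0:
        raise ValueError("empty IFS curve")
    with open(path, "w", encoding="utf-8") as fh:
        _write_header_comments(fh, comments)
        fh.write(f"# optimal_k={curve.optimal_k}\n")
        fh.write("k\tSn\tSp\tAcc\tMCC\n")
        for r in curve.records:
            m = r.metrics
            fh.write(
                f"{r.k}\t{_fmt(m.sn)}\t{_fmt(m.sp)}\t{_fmt(m.acc)}\t{_fmt(m.mcc)}\n"
            )


def read_ifs_curve(path: str | Path) -> IFSCurve:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    expected = ["k", "Sn", "Sp", "Acc", "MCC"]
    if list(df.columns) != expected:
        raise DatasetError(f"{path}: unexpected curve columns {list(df.columns)}")
    records = [
        IFSRecord(
            int(row.k),
            MetricSet(
                sn=float(row.Sn), sp=float(row.Sp), acc=float(row.Acc), mcc=float(row.MCC)
            ),
        )
        for row in df.itertuples()
    ]
    opt_k, opt_m = _optimum(records)
    return IFSCurve(records, opt_k, opt_m)
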