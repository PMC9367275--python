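"""Delimited-text readers and writers shared by all pipeline stages.

Canonical interchange is TSV with a header row whose first column is
``gene_id``; CSV is accepted on read via delimiter sniffing. Sample labels
travel in a two-column companion file (``sample_id<TAB>label``). All
writers emit plain decimal text so artifacts are diff-able and round-trip
through the readers without loss.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    if "\t" in head:
        return "\t"
    if "," in head:
        return ","
    return "\t"


def read_sample_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample->label table (header optional)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=delim)):
            if not row or not row[0].strip():
                continue
            if i == 0 and row[0].strip().lower() in {"sample_id", "sample"}:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{i + 1}: expected two columns, got {row!r}")
            labels[row[0].strip()] = row[1].strip()
    if not labels:
        raise ValueError(f"{path}: no sample labels found")
    return labels


def write_sample_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "label"])
        for sample, label in labels.items():
            writer.writerow([sample, label])


def read_expression_matrix(
    path: str | Path,
    label_path: str | Path | None = None,
    unit_label: str = "raw-count",
) -> ExpressionMatrix:
    """Parse a gene x sample expression TSV/CSV with validation.

    The header row must start with ``gene_id``. Duplicate gene or sample
    ids, non-numeric cells and negative values are rejected with the
    offending coordinates; a label file that misses a sample is rejected
    naming the sample.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delim, dtype=str)
    if frame.columns[0] != "gene_id":
        raise ValueError(
            f"{path}: first header column must be 'gene_id', got {frame.columns[0]!r}"
        )
    gene_ids = frame["gene_id"].tolist()
    data = frame.drop(columns=["gene_id"])
    parsed = np.empty(data.shape, dtype=float)
    for j, col in enumerate(data.columns):
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric value {data[col].iloc[i]!r} at gene "
                f"{gene_ids[i]!r}, sample {col!r} (line {i + 2})"
            )
        neg = np.flatnonzero((converted < 0).to_numpy())
        if neg.size:
            i = int(neg[0])
            raise ValueError(
                f"{path}: negative value {converted.iloc[i]} at gene "
                f"{gene_ids[i]!r}, sample {col!r} (line {i + 2})"
            )
        # pd.to_numeric's fast parser is not last-ulp exact; re-parse with
        # the platform strtod so writer/reader round-trips are lossless
        parsed[:, j] = data[col].to_numpy(dtype=float)
    values = pd.DataFrame(parsed, index=gene_ids, columns=list(data.columns))

    labels = None
    if label_path is not None:
        labels = read_sample_labels(label_path)
        missing = [s for s in values.columns if s not in labels]
        if missing:
            raise ValueError(f"{label_path}: label file missing samples: {missing}")
        labels = {s: labels[s] for s in values.columns}
    return ExpressionMatrix(values=values, unit_label=unit_label, sample_labels=labels)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (first column gene_id, full precision)."""
    frame = matrix.values.copy()
    frame.insert(0, "gene_id", frame.index)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not genes:
        raise ValueError(f"{path}: no gene ids found")
    return genes


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_manifest(entries: dict[str, object], path: str | Path) -> None:
    """Plain key-value manifest recording config, seed and versions."""
    lines = [f"{k} = {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")
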