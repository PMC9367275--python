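"""Expression-matrix container shared by every pipeline stage.

An :class:`ExpressionMatrix` is a gene x sample grid of non-negative
abundance values plus two pieces of metadata: a unit label saying how the
values were quantified (TPM-like, RPKM-like, raw digital counts, or
housekeeping-normalized counts) and an optional per-sample cohort/type
label map. The pipeline never compares raw values across differently
quantified cohorts -- only within-cohort ranks -- so the unit label is
carried for provenance, not arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNIT_LABELS = ("TPM-like", "RPKM-like", "raw-count", "normalized-count")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression grid with unit and cohort metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        All entries must be finite and non-negative.
    unit_label
        One of ``TPM-like``, ``RPKM-like``, ``raw-count``,
        ``normalized-count``.
    sample_labels
        Optional mapping sample id -> cohort (or tumor-type) label.
        When given it must cover every sample column.
    """

    values: pd.DataFrame
    unit_label: str
    sample_labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.unit_label not in UNIT_LABELS:
            raise ValueError(
                f"unknown unit label {self.unit_label!r}; expected one of {UNIT_LABELS}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if arr.size and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        if self.sample_labels is not None:
            missing = [s for s in cols if s not in self.sample_labels]
            if missing:
                raise ValueError(f"sample labels missing for samples: {missing}")

    # -- convenience views -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_with_label(self, label: str) -> list[str]:
        """Sample ids carrying the given cohort/type label."""
        if self.sample_labels is None:
            raise ValueError("matrix has no sample labels attached")
        return [s for s in self.sample_ids if self.sample_labels[s] == label]

    def cohorts(self) -> list[str]:
        """Distinct cohort labels in column order of first appearance."""
        if self.sample_labels is None:
            raise ValueError("matrix has no sample labels attached")
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.sample_labels[s], None)
        return list(seen)

    def with_values(self, values: pd.DataFrame, unit_label: str | None = None) -> "ExpressionMatrix":
        """Return a copy of this matrix with new values (metadata kept)."""
        return ExpressionMatrix(
            values=values,
            unit_label=unit_label or self.unit_label,
            sample_labels=dict(self.sample_labels) if self.sample_labels else None,
        )
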