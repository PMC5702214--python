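"""Cell quality control and binary genotype-matrix assembly.

Cells are retained when they were visually confirmed to contain a single
cell and at least 80% of the target SNV sites reached 10X depth — the
standard filter for whole-genome-amplified material, where amplification
failures leave large fractions of the panel uncovered. Retained cells'
SNV and SV calls are packed into one cells x assays binary matrix in which
both variant classes are equivalent contributors; a companion mask records
entries that had no usable data (stored as 0 in the matrix itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_FRACTION = 0.80
DEFAULT_MIN_DEPTH = 10
DEFAULT_MAX_MISSING_FRACTION = 0.2


@dataclass(frozen=True)
class CellRecord:
    """Per-cell QC inputs: microscopy flag and per-SNV-site depth."""

    cell_id: str
    visually_single: bool
    site_coverage: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.site_coverage.values()):
            raise ValueError(f"cell {self.cell_id!r}: negative depth")


def qc_cell(
    cell: CellRecord,
    snv_assay_ids: Sequence[str],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[bool, float]:
    """Pass/fail QC for one cell plus the covered-site fraction.

    Pass requires ``visually_single`` and that the fraction of target SNV
    sites at depth >= ``min_depth`` is at least ``min_fraction``
    (inclusive). Only SNV sites count toward coverage; SV assays do not.
    """
    if not snv_assay_ids:
        raise ValueError("SNV manifest is empty")
    covered = sum(
        1 for a in snv_assay_ids if cell.site_coverage.get(a, 0) >= min_depth
    )
    fraction = covered / len(snv_assay_ids)
    return (bool(cell.visually_single) and fraction >= min_fraction), fraction


@dataclass
class BinaryMatrix:
    """Cells x assays 0/1 genotype matrix with a missing-data mask.

    ``X[i, j]`` is the binary call for cell i at assay j; ``mask[i, j] = 1``
    marks entries with no usable data (kept as 0 in X, which is how the
    matrix is consumed by default).
    """

    cell_ids: list[str]
    assay_ids: list[str]
    X: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        n, j = len(self.cell_ids), len(self.assay_ids)
        if self.X.shape != (n, j) or self.mask.shape != (n, j):
            raise ValueError("matrix dimensions inconsistent with labels")
        if len(set(self.cell_ids)) != n or len(set(self.assay_ids)) != j:
            raise ValueError("cell and assay labels must be unique")
        if not np.isin(self.X, (0, 1)).all() or not np.isin(self.mask, (0, 1)).all():
            raise ValueError("matrix entries must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.cell_ids, columns=self.assay_ids)

    def mask_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mask, index=self.cell_ids, columns=self.assay_ids)

    def to_records(self) -> pd.DataFrame:
        """Call records for the non-masked entries (inverse of build_matrix)."""
        rows = [
            (c, a, int(self.X[i, j]))
            for i, c in enumerate(self.cell_ids)
            for j, a in enumerate(self.assay_ids)
            if self.mask[i, j] == 0
        ]
        return pd.DataFrame(rows, columns=["cell_id", "assay_id", "call"])

    def drop_assays(self, assay_ids: Sequence[str]) -> "BinaryMatrix":
        drop = set(assay_ids)
        keep = [j for j, a in enumerate(self.assay_ids) if a not in drop]
        return BinaryMatrix(
            list(self.cell_ids),
            [self.assay_ids[j] for j in keep],
            self.X[:, keep].copy(),
            self.mask[:, keep].copy(),
        )


def build_matrix(
    snv_calls: pd.DataFrame,
    sv_calls: pd.DataFrame,
    cell_ids: Sequence[str],
    snv_assay_ids: Sequence[str],
    sv_assay_ids: Sequence[str],
) -> BinaryMatrix:
    """Pack per-cell SNV and SV call records into one binary matrix.

    Call frames need columns ``cell_id, assay_id, call`` (an optional
    ``flag`` column marks ``no_data`` rows, which become masked zeros).
    Only the listed cells are included (QC happens upstream); column order
    follows the manifests, SNV assays first then SV. Missing (cell, assay)
    pairs become 0 with mask = 1; conflicting duplicates are an error.
    """
    cell_ids = list(cell_ids)
    if not cell_ids:
        raise ValueError("no QC-passing cells: cannot build a matrix")
    assay_ids = list(snv_assay_ids) + list(sv_assay_ids)
    if len(set(assay_ids)) != len(assay_ids):
        raise ValueError("SNV and SV assay ids overlap")
    row_of = {c: i for i, c in enumerate(cell_ids)}
    col_of = {a: j for j, a in enumerate(assay_ids)}
    n, j = len(cell_ids), len(assay_ids)
    X = np.zeros((n, j), dtype=np.int8)
    mask = np.ones((n, j), dtype=np.int8)
    seen: dict[tuple[int, int], int] = {}
    for frame in (snv_calls, sv_calls):
        if frame is None or len(frame) == 0:
            continue
        has_flag = "flag" in frame.columns
        for rec in frame.itertuples(index=False):
            i = row_of.get(str(rec.cell_id))
            jj = col_of.get(str(rec.assay_id))
            if i is None or jj is None:
                continue
            no_data = has_flag and rec.flag == "no_data"
            call = 0 if no_data else int(rec.call)
            prev = seen.get((i, jj))
            if prev is not None and prev != call:
                raise ValueError(
                    f"conflicting duplicate calls for "
                    f"({rec.cell_id!r}, {rec.assay_id!r})"
                )
            seen[(i, jj)] = call
            X[i, jj] = call
            mask[i, jj] = 1 if no_data else 0
    return BinaryMatrix(cell_ids, assay_ids, X, mask)


def flag_poor_assays(
    matrix: BinaryMatrix,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> list[str]:
    """Assays whose no-data fraction across cells exceeds the threshold.

    This is an optional pre-filter; poorly performing assays also surface
    post hoc as an all-absent mutation cluster during clonal inference.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    frac = matrix.mask.mean(axis=0)
    return [a for a, f in zip(matrix.assay_ids, frac) if f > max_missing_fraction]
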