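"""Single-cell SNV confirmation filters.

Variant calling itself happens upstream (alignment + pileup callers on the
amplicon reads); this module applies the single-cell confirmation rules to
per-site read counts. A site is called present in a cell when the variant
allele is supported by at least ``min_alt_reads`` reads (default 3) that
make up strictly more than ``min_vaf`` (default 1%) of all reads at the
position, and — when the observed alternate base is known — that base
matches the bulk-confirmed one. Sites without any counts row are reported
absent and flagged ``no_data`` so downstream steps can mask them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_MIN_ALT_READS = 3
DEFAULT_MIN_VAF = 0.01

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnvSite:
    """A bulk-confirmed SNV target (1-based, fully closed coordinates)."""

    assay_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site {self.assay_id!r}: pos must be >= 1")
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(f"site {self.assay_id!r}: bases must be in ACGT")
        if self.ref_base == self.alt_base:
            raise ValueError(f"site {self.assay_id!r}: ref and alt must differ")


@dataclass(frozen=True)
class SiteCounts:
    """Read-count evidence at one SNV site in one cell.

    ``depth`` is all reads at the position (the VAF denominator), not just
    ref + alt. ``observed_alt`` is the alternate base actually seen by the
    upstream caller, when available.
    """

    assay_id: str
    cell_id: str
    alt_count: int
    depth: int
    observed_alt: str | None = None

    def __post_init__(self) -> None:
        if self.alt_count < 0 or self.depth < 0:
            raise ValueError("counts must be non-negative")
        if self.alt_count > self.depth:
            raise ValueError(
                f"{self.cell_id}/{self.assay_id}: alt_count {self.alt_count} "
                f"exceeds depth {self.depth}"
            )


def call_snv_presence(
    counts: SiteCounts,
    site: SnvSite | None = None,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> int:
    """Binary SNV call for one cell at one site.

    Present iff alt_count >= min_alt_reads (inclusive) and
    alt_count / depth > min_vaf (strict), and the observed alternate base,
    if recorded, matches the bulk-confirmed site. Zero depth is absent.
    """
    if counts.depth == 0:
        return 0
    if (
        site is not None
        and counts.observed_alt is not None
        and counts.observed_alt != site.alt_base
    ):
        return 0
    if counts.alt_count < min_alt_reads:
        return 0
    return int(counts.alt_count / counts.depth > min_vaf)


def call_snv_table(
    counts: pd.DataFrame,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> pd.Series:
    """Vectorized :func:`call_snv_presence` over an alt_count/depth frame.

    Same semantics as the scalar caller (inclusive read minimum, strict
    VAF, zero depth absent); used by the pipeline for whole-run tables.
    """
    alt = counts["alt_count"].to_numpy()
    depth = counts["depth"].to_numpy()
    if (alt > depth).any():
        raise ValueError("alt_count exceeds depth in counts table")
    present = (depth > 0) & (alt >= min_alt_reads) & (alt > min_vaf * depth)
    return pd.Series(present.astype(int), index=counts.index)


def check_bulk_concordance(
    cell_site: SnvSite, bulk_manifest: Mapping[str, SnvSite]
) -> bool:
    """Accept a single-cell site only if it matches the bulk manifest exactly.

    Concordance requires identical chromosome, position, reference base and
    alternate base. The assay must exist in the manifest.
    """
    try:
        bulk = bulk_manifest[cell_site.assay_id]
    except KeyError:
        raise LookupError(
            f"assay {cell_site.assay_id!r} not in bulk manifest"
        ) from None
    return (
        cell_site.chrom == bulk.chrom
        and cell_site.pos == bulk.pos
        and cell_site.ref_base == bulk.ref_base
        and cell_site.alt_base == bulk.alt_base
    )


def genotype_snv_cell(
    counts: Sequence[SiteCounts] | pd.DataFrame,
    sites: Sequence[SnvSite],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_vaf: float = DEFAULT_MIN_VAF,
    cell_id: str = "",
) -> pd.DataFrame:
    """Apply the confirmation filters to every manifest site for one cell.

    Returns a frame with columns ``cell_id, assay_id, call, flag`` in
    manifest order. Sites with no counts row get call 0 and flag
    ``no_data``; everything else is flagged ``ok``. Duplicate
    (cell, assay) rows are an input error.
    """
    if isinstance(counts, pd.DataFrame):
        counts = [
            SiteCounts(
                assay_id=str(r.assay_id),
                cell_id=str(getattr(r, "cell_id", cell_id)),
                alt_count=int(r.alt_count),
                depth=int(r.depth),
                observed_alt=getattr(r, "observed_alt", None),
            )
            for r in counts.itertuples(index=False)
        ]
    by_assay: dict[str, SiteCounts] = {}
    for c in counts:
        if c.assay_id in by_assay:
            raise ValueError(
                f"duplicate counts row for ({c.cell_id!r}, {c.assay_id!r})"
            )
        by_assay[c.assay_id] = c
    rows = []
    for site in sites:
        c = by_assay.get(site.assay_id)
        if c is None:
            rows.append((cell_id, site.assay_id, 0, "no_data"))
        else:
            call = call_snv_presence(c, site, min_alt_reads, min_vaf)
            rows.append((c.cell_id or cell_id, site.assay_id, call, "ok"))
    return pd.DataFrame(rows, columns=["cell_id", "assay_id", "call", "flag"])
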