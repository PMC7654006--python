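"""Misplaced-SNP detection and dual-assembly map comparison.

A marker whose assembly coordinate is wrong drags down the imputation accuracy
of itself (and often of its true neighbours), so misplacement shows up as local
clusters of poorly imputed SNPs. Autosomes are partitioned into fixed-width
segments (default 100 kb) anchored at position 0; a segment with strictly more
than ``count_threshold`` poorly imputed SNPs (MAF above ``maf_min`` and R2dose
below ``r2_max``) is flagged, and every SNP it contains is reported as
putatively misplaced.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import UNMAPPED, MarkerMap
from .io import SEGMENT_COLUMNS

STATUS_VALUES = (
    "both_mapped_same_chrom",
    "chromosome_changed",
    "newly_mapped",
    "lost",
    "unmapped_both",
)


def scan_misplaced(table: pd.DataFrame, mmap: MarkerMap, width_bp: int = 100_000,
                   maf_min: float = 0.01, r2_max: float = 0.8,
                   count_threshold: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Segment scan for putatively misplaced SNPs.

    ``table`` is an accuracy table (needs marker_id, maf_true, r2_dose); every
    marker must have an autosomal position in ``mmap``. Segments are half-open
    ``[k*width, (k+1)*width)`` per chromosome, indexed by ``pos // width``. A
    SNP is poorly imputed iff ``maf_true > maf_min`` and ``r2_dose < r2_max``
    (NA r2 never counts, though such SNPs still count toward segment size).
    Returns the per-segment report (occupied segments only) and the flat list of
    markers inside flagged segments.
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    ids = table["marker_id"].to_numpy(dtype=object)
    sub = mmap.subset(ids)
    if (sub.table["chrom"] == UNMAPPED).any():
        bad = sub.table.index[sub.table["chrom"] == UNMAPPED][0]
        raise ValueError(f"marker without a map position: {bad!r}")
    chroms = sub.chrom_of(ids)
    pos = sub.pos_of(ids)
    seg_idx = pos // width_bp

    r2 = table["r2_dose"].to_numpy(dtype=float)
    mafs = table["maf_true"].to_numpy(dtype=float)
    poorly = np.isfinite(r2) & (r2 < r2_max) & (mafs > maf_min)

    df = pd.DataFrame(
        {"marker_id": ids, "chrom": chroms, "segment_index": seg_idx, "poorly": poorly}
    )
    grouped = df.groupby(["chrom", "segment_index"], sort=True).agg(
        n_snps=("marker_id", "size"), n_poorly_imputed=("poorly", "sum")
    ).reset_index()
    grouped["start_bp"] = grouped["segment_index"] * width_bp
    grouped["end_bp"] = (grouped["segment_index"] + 1) * width_bp
    grouped["flagged_misplaced"] = grouped["n_poorly_imputed"] > count_threshold
    segments = grouped[SEGMENT_COLUMNS]

    flagged_keys = set(
        map(tuple, grouped.loc[grouped["flagged_misplaced"], ["chrom", "segment_index"]].to_numpy())
    )
    in_flagged = [
        (c, s) in flagged_keys for c, s in zip(df["chrom"], df["segment_index"])
    ]
    flagged_markers = df.loc[in_flagged, "marker_id"].tolist()
    return segments, flagged_markers


def flagged_marker_table(table: pd.DataFrame, mmap: MarkerMap, flagged: list[str]) -> pd.DataFrame:
    """Convenience export of the flagged-SNP list (marker_id, chrom, pos, r2_dose)."""
    sub = table[table["marker_id"].isin(set(flagged))]
    ids = sub["marker_id"].to_numpy(dtype=object)
    return pd.DataFrame(
        {
            "marker_id": ids,
            "chrom": mmap.chrom_of(ids),
            "pos_bp": mmap.pos_of(ids),
            "r2_dose": sub["r2_dose"].to_numpy(dtype=float),
        }
    )


def compare_assemblies(map_a: MarkerMap, map_b: MarkerMap,
                       table_a: pd.DataFrame | None = None,
                       table_b: pd.DataFrame | None = None,
                       flagged_a=(), flagged_b=()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every marker by how its placement changed between assembly A and
    assembly B, and compare per-status imputation accuracy under each.

    Statuses partition the markers: mapped in both on the same chromosome,
    ``chromosome_changed`` (mapped in both, different chromosome),
    ``newly_mapped`` (unmapped in A, mapped in B), ``lost`` (mapped in A only),
    ``unmapped_both``. Markers present in only one map count as unmapped in the
    other.

    Accuracy tables (optional) contribute per-marker ``r2_dose_a``/``r2_dose_b``
    columns; the summary then reports, per status, the mean of each over markers
    where both are defined. ``flagged_a``/``flagged_b`` (marker-id sets from
    :func:`scan_misplaced` under each assembly) add two extra summary rows for
    markers flagged under one assembly only.
    """
    all_ids = list(map_a.marker_ids) + [m for m in map_b.marker_ids if m not in map_a]
    if not all_ids:
        raise ValueError("no markers to compare")
    present_b = set(map_b.marker_ids)
    present_a = set(map_a.marker_ids)
    if not (present_a & present_b):
        raise ValueError("maps share no markers")

    ca = dict(zip(map_a.marker_ids, map_a.table["chrom"]))
    cb = dict(zip(map_b.marker_ids, map_b.table["chrom"]))

    statuses = []
    for m in all_ids:
        a = ca.get(m, UNMAPPED)
        b = cb.get(m, UNMAPPED)
        if a == UNMAPPED and b == UNMAPPED:
            statuses.append("unmapped_both")
        elif a == UNMAPPED:
            statuses.append("newly_mapped")
        elif b == UNMAPPED:
            statuses.append("lost")
        elif a == b:
            statuses.append("both_mapped_same_chrom")
        else:
            statuses.append("chromosome_changed")

    per_marker = pd.DataFrame({"marker_id": all_ids, "status": statuses})

    def r2_map(table: pd.DataFrame | None) -> dict:
        if table is None:
            return {}
        return dict(zip(table["marker_id"], table["r2_dose"].astype(float)))

    ra, rb = r2_map(table_a), r2_map(table_b)
    per_marker["r2_dose_a"] = [ra.get(m, np.nan) for m in all_ids]
    per_marker["r2_dose_b"] = [rb.get(m, np.nan) for m in all_ids]

    def summary_row(name: str, mask: np.ndarray) -> dict:
        sub = per_marker[mask]
        both = sub[np.isfinite(sub["r2_dose_a"]) & np.isfinite(sub["r2_dose_b"])]
        return {
            "group": name,
            "n_markers": int(mask.sum()),
            "n_with_both_r2": len(both),
            "mean_r2_dose_a": float(both["r2_dose_a"].mean()) if len(both) else np.nan,
            "mean_r2_dose_b": float(both["r2_dose_b"].mean()) if len(both) else np.nan,
        }

    status_arr = per_marker["status"].to_numpy(dtype=object)
    rows = [summary_row(s, status_arr == s) for s in STATUS_VALUES]

    fa, fb = set(flagged_a), set(flagged_b)
    if fa or fb:
        ids_arr = per_marker["marker_id"].to_numpy(dtype=object)
        in_a = np.asarray([m in fa for m in ids_arr])
        in_b = np.asarray([m in fb for m in ids_arr])
        rows.append(summary_row("misplaced_on_a_only", in_a & ~in_b))
        rows.append(summary_row("misplaced_on_b_only", in_b & ~in_a))

    return per_marker, pd.DataFrame(rows)
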