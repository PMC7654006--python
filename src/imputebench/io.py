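"""Readers and writers: VCF (via cyvcf2), genotype-matrix TSV, marker-map TSV,
result tables and BED export.

All tables are written with full float precision (``%.17g``) and ``NA`` for
missing values so that write/read round-trips are lossless and byte-identical
across runs with the same inputs.
"""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, UNMAPPED, ArrayContent, GenotypePanel, ImputationResult, MarkerMap, PanelSplit

FLOAT_FORMAT = "%.17g"
NA_REP = "NA"

#: fixed column orders for the result tables
ACCURACY_COLUMNS = ["marker_id", "maf_true", "r2_dose", "r2_gt", "cr", "rsq_model", "n_samples"]
SEGMENT_COLUMNS = [
    "chrom", "segment_index", "start_bp", "end_bp", "n_snps", "n_poorly_imputed", "flagged_misplaced",
]

#: dosage values may exceed [0, 2] by at most this much before it is an error
DOSAGE_TOL = 1e-6


class ParseError(ValueError):
    """A record in an input file could not be interpreted."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, assembly_name: str = "default", on_multiallelic: str = "error",
             ) -> tuple[GenotypePanel, MarkerMap]:
    """Read true genotypes (GT) from a VCF into a panel plus its marker map.

    Only biallelic SNPs are accepted; multiallelic records raise a
    :class:`ParseError` or are skipped according to ``on_multiallelic``
    ("error" | "skip").
    """
    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise ParseError(
                f"multiallelic record at {variant.CHROM}:{variant.POS} ({variant.ID})"
            )
        gt = np.asarray(variant.gt_types, dtype=np.int8)  # 0/1/2 = alt count, 3 = missing
        gt[gt == 3] = MISSING
        marker_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(marker_id)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        rows.append(gt)
    vcf.close()
    if not rows:
        raise ParseError(f"no usable records in {path}")
    if len(set(marker_ids)) != len(marker_ids):
        dup = pd.Index(marker_ids)
        raise ParseError(f"duplicate marker_id: {dup[dup.duplicated()][0]!r}")
    panel = GenotypePanel(marker_ids, samples, np.vstack(rows))
    mmap = MarkerMap.from_arrays(marker_ids, chroms, positions, assembly_name)
    return panel, mmap


def read_panel(path: str, format: str = "vcf", on_multiallelic: str = "error") -> GenotypePanel:
    """Read a genotype panel from ``vcf`` or ``matrix_tsv`` input."""
    if format == "vcf":
        panel, _ = read_vcf(path, on_multiallelic=on_multiallelic)
        return panel
    if format == "matrix_tsv":
        return read_matrix_tsv(path)
    raise ValueError(f"unknown panel format {format!r}")


def _vcf_header(samples: Iterable[str], contigs: Iterable[str], extra: Iterable[str] = ()) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=imputebench"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.extend(extra)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def _ordered_contigs(mmap: MarkerMap, marker_ids) -> list[str]:
    seen: dict[str, None] = {}
    for c in mmap.chrom_of(marker_ids):
        if c not in seen:
            seen[c] = None
    return list(seen)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, mmap: MarkerMap, path: str) -> None:
    """Write a genotype panel as VCF 4.2 (GT only). Markers are written in map
    coordinate order; unmapped markers are not representable and raise."""
    sub = mmap.subset(panel.markers)
    if (~sub.is_mapped()).any():
        raise ValueError("cannot write unmapped markers to VCF")
    order = [m for m in sub.sorted_marker_ids()]
    idx = panel.marker_indexer(order)
    chroms = sub.chrom_of(order)
    poss = sub.pos_of(order)
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.samples, _ordered_contigs(sub, order)))
        for row, mid, chrom, pos in zip(panel.genotypes[idx], order, chroms, poss):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in row)
            fh.write(f"{chrom}\t{pos}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_imputed_vcf(result: ImputationResult, mmap: MarkerMap, path: str) -> None:
    """Write an imputation result as VCF with GT (best guess), DS (dosage) and
    per-marker INFO R2 (model-based quality, omitted when NaN)."""
    sub = mmap.subset(result.markers)
    if (~sub.is_mapped()).any():
        raise ValueError("cannot write unmapped markers to VCF")
    order = list(sub.sorted_marker_ids())
    res = result.subset_markers(order)
    chroms = sub.chrom_of(order)
    poss = sub.pos_of(order)
    extra = [
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Model-based imputation quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">',
    ]
    with open(path, "w") as fh:
        fh.write(_vcf_header(res.samples, _ordered_contigs(sub, order), extra))
        for i, mid in enumerate(order):
            rsq = res.rsq_reported[i]
            info = "." if not np.isfinite(rsq) else "R2=" + (FLOAT_FORMAT % rsq)
            cells = "\t".join(
                f"{_GT_STRINGS[int(b)]}:{FLOAT_FORMAT % d}"
                for b, d in zip(res.best_guess[i], res.dosages[i])
            )
            fh.write(f"{chroms[i]}\t{poss[i]}\t{mid}\tA\tG\t.\tPASS\t{info}\tGT:DS\t{cells}\n")


def read_imputed(path: str) -> tuple[ImputationResult, int]:
    """Read dosages/best-guess/Rsq from an imputed VCF.

    Returns the result and a count of dosage values that exceeded [0, 2] by at
    most ``DOSAGE_TOL`` and were clipped; larger violations raise.
    Records without a DS field raise, naming the marker. A file without INFO R2
    yields ``rsq_reported`` all-NaN.
    """
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    marker_ids, rows_d, rows_b, rsqs = [], [], [], []
    n_clipped = 0
    for variant in vcf:
        marker_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        ds = variant.format("DS")
        if ds is None:
            raise ParseError(f"missing DS (dosage) field at marker {marker_id!r}")
        d = np.asarray(ds, dtype=np.float64).reshape(-1)
        out_of_range = (d < 0) | (d > 2)
        if out_of_range.any():
            worst = float(np.max(np.maximum(-d, d - 2.0)))
            if worst > DOSAGE_TOL:
                raise ParseError(
                    f"dosage out of [0,2] by {worst:.3g} at marker {marker_id!r}"
                )
            n_clipped += int(out_of_range.sum())
            d = np.clip(d, 0.0, 2.0)
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = 0  # imputed output carries no missing best-guess; treat defensively
        rsq = variant.INFO.get("R2")
        marker_ids.append(marker_id)
        rows_d.append(d)
        rows_b.append(gt)
        rsqs.append(np.nan if rsq is None else float(rsq))
    vcf.close()
    if not marker_ids:
        raise ParseError(f"no records in {path}")
    result = ImputationResult(
        marker_ids, samples, np.vstack(rows_d), np.vstack(rows_b), np.asarray(rsqs)
    )
    return result, n_clipped


# ---------------------------------------------------------------------------
# genotype-matrix and marker-map TSV
# ---------------------------------------------------------------------------

def write_matrix_tsv(panel: GenotypePanel, path: str) -> None:
    df = pd.DataFrame(panel.genotypes, index=panel.markers, columns=panel.samples)
    df = df.replace(MISSING, np.nan)
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.0f")


def read_matrix_tsv(path: str) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col="marker_id", na_values=[NA_REP])
    geno = df.to_numpy(dtype=np.float64)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypePanel(df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object), geno)


def write_marker_map(mmap: MarkerMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#assembly={mmap.assembly_name}\n")
        tab = mmap.table.reset_index()
        tab.columns = ["marker_id", "chrom", "pos_bp"]
        tab.to_csv(fh, sep="\t", index=False)


def read_marker_map(path: str, assembly_name: str | None = None) -> MarkerMap:
    name = assembly_name
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#assembly="):
        skip = 1
        if name is None:
            name = first.strip().split("=", 1)[1]
    tab = pd.read_csv(path, sep="\t", skiprows=skip)
    return MarkerMap.from_arrays(
        tab["marker_id"], tab["chrom"], tab["pos_bp"], name or "default"
    )


# ---------------------------------------------------------------------------
# haplotype store (markers x haplotypes), used by the CLI pipeline
# ---------------------------------------------------------------------------

def write_haplotypes(haplotypes: np.ndarray, markers, samples, path: str) -> None:
    """Haplotypes as TSV; columns ``<sample>_h1``/``<sample>_h2``, rows markers.
    ``haplotypes`` has shape (2*n_samples, n_markers) with sample i owning rows
    2i and 2i+1."""
    cols = [f"{s}_h{k}" for s in samples for k in (1, 2)]
    df = pd.DataFrame(haplotypes.T.astype(np.int8), index=list(markers), columns=cols)
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t")


def read_haplotypes(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (haplotypes (2N, M), marker ids, sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col="marker_id")
    cols = list(df.columns)
    samples = []
    for c in cols[::2]:
        if not c.endswith("_h1"):
            raise ParseError(f"unexpected haplotype column {c!r}")
        samples.append(c[:-3])
    haps = df.to_numpy(dtype=np.int8).T
    return haps, df.index.to_numpy(dtype=object), np.asarray(samples, dtype=object)


# ---------------------------------------------------------------------------
# result tables, array content, splits
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str, columns: list[str] | None = None) -> None:
    """Write a result table as TSV with a fixed column order and NA convention."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    if columns is not None:
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks columns {missing}")
        table = table[columns]
    table.to_csv(path, sep="\t", index=False, na_rep=NA_REP, float_format=FLOAT_FORMAT)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)


def segments_to_bed(segments: pd.DataFrame, path: str, flagged_only: bool = False) -> None:
    """Export a segment report as BED (0-based half-open). Segment bounds are
    already 0-anchored multiples of the width, so they map onto BED directly."""
    df = segments
    if flagged_only:
        df = df[df["flagged_misplaced"]]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            name = f"seg{int(row['segment_index'])}"
            score = int(row["n_poorly_imputed"])
            fh.write(f"{row['chrom']}\t{int(row['start_bp'])}\t{int(row['end_bp'])}\t{name}\t{score}\n")


def write_array_content(content: ArrayContent, path: str) -> None:
    with open(path, "w") as fh:
        for mid in sorted(content.marker_ids):
            fh.write(f"{mid}\n")


def read_array_content(path: str, name: str | None = None) -> ArrayContent:
    with open(path) as fh:
        ids = frozenset(line.strip() for line in fh if line.strip())
    return ArrayContent(name or os.path.basename(path), ids)


def write_splits(splits: list[PanelSplit], path: str) -> None:
    rows = []
    for sp in splits:
        for role, ids in (("reference", sp.reference_ids), ("target", sp.target_ids)):
            for sid in ids:
                rows.append((sp.replicate_index, role, sid, sp.seed))
    pd.DataFrame(rows, columns=["replicate", "role", "sample_id", "seed"]).to_csv(
        path, sep="\t", index=False
    )


def read_splits(path: str) -> list[PanelSplit]:
    df = pd.read_csv(path, sep="\t")
    splits = []
    for rep, grp in df.groupby("replicate", sort=True):
        splits.append(
            PanelSplit(
                replicate_index=int(rep),
                reference_ids=tuple(grp.loc[grp["role"] == "reference", "sample_id"].astype(str)),
                target_ids=tuple(grp.loc[grp["role"] == "target", "sample_id"].astype(str)),
                seed=int(grp["seed"].iloc[0]),
            )
        )
    return splits
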