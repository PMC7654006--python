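"""Core in-memory containers for genotype panels, marker maps and imputation output.

Genotypes are stored as alternate-allele counts in {0, 1, 2}, with ``MISSING``
(-1) for no-calls; all downstream metrics are allele-label agnostic, so REF/ALT
identity is never needed beyond I/O. Marker positions are 1-based (VCF
convention); BED export converts on the way out.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
UNMAPPED: str = "UNMAPPED"

#: chromosome labels treated as non-autosomal when no explicit autosome set is given
_DEFAULT_NON_AUTOSOMES = frozenset({"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"})


def _as_str_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of identifiers")
    return arr


@dataclass
class MarkerMap:
    """Per-marker coordinates under one named genome assembly.

    ``table`` is indexed by marker_id with columns ``chrom`` (string;
    ``UNMAPPED`` for markers without a placement) and ``pos_bp`` (int64,
    1-based; -1 where unmapped).
    """

    assembly_name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos_bp"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if not self.table.index.is_unique:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate marker_id in map: {dup!r}")
        self.table = self.table.copy()
        self.table["chrom"] = self.table["chrom"].astype(str)
        self.table["pos_bp"] = self.table["pos_bp"].astype(np.int64)
        unmapped = self.table["chrom"] == UNMAPPED
        if (self.table.loc[~unmapped, "pos_bp"] < 0).any():
            raise ValueError("mapped markers must have non-negative pos_bp")
        # normalise the sentinel position of unmapped markers
        self.table.loc[unmapped, "pos_bp"] = -1

    @classmethod
    def from_arrays(cls, marker_ids, chroms, positions, assembly_name: str) -> "MarkerMap":
        table = pd.DataFrame(
            {"chrom": list(chroms), "pos_bp": np.asarray(positions, dtype=np.int64)},
            index=_as_str_array(marker_ids),
        )
        table.index.name = "marker_id"
        return cls(assembly_name=assembly_name, table=table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.table.index

    def is_mapped(self) -> pd.Series:
        return self.table["chrom"] != UNMAPPED

    def is_autosomal(self, autosomes: set[str] | None = None) -> pd.Series:
        """Boolean mask: mapped and on an autosome.

        With ``autosomes=None`` any mapped chromosome outside the conventional
        sex/mito labels counts as autosomal.
        """
        mapped = self.is_mapped()
        if autosomes is None:
            return mapped & ~self.table["chrom"].isin(_DEFAULT_NON_AUTOSOMES)
        return mapped & self.table["chrom"].isin(set(autosomes))

    def subset(self, marker_ids) -> "MarkerMap":
        ids = _as_str_array(marker_ids)
        missing = set(ids) - set(self.table.index)
        if missing:
            raise KeyError(f"markers absent from map: {sorted(missing)[:5]}")
        return MarkerMap(self.assembly_name, self.table.loc[ids])

    def chrom_of(self, marker_ids) -> np.ndarray:
        return self.table.loc[_as_str_array(marker_ids), "chrom"].to_numpy(dtype=object)

    def pos_of(self, marker_ids) -> np.ndarray:
        return self.table.loc[_as_str_array(marker_ids), "pos_bp"].to_numpy(dtype=np.int64)

    def sorted_marker_ids(self) -> np.ndarray:
        """Marker ids sorted by (chrom, pos); numeric chromosome names sort numerically,
        unmapped markers come last."""
        tab = self.table
        chroms = tab["chrom"].to_numpy(dtype=object)

        def chrom_key(c: str):
            if c == UNMAPPED:
                return (2, 0, "")
            return (0, int(c), "") if c.isdigit() else (1, 0, c)

        order = sorted(
            range(len(tab)),
            key=lambda i: (chrom_key(chroms[i]), int(tab["pos_bp"].iloc[i])),
        )
        return tab.index.to_numpy(dtype=object)[order]


def _validate_genotype_values(genotypes: np.ndarray, allow_missing: bool) -> None:
    allowed = {0, 1, 2, MISSING} if allow_missing else {0, 1, 2}
    present = set(np.unique(genotypes).tolist())
    bad = present - allowed
    if bad:
        raise ValueError(f"invalid genotype values {sorted(bad)}; allowed {sorted(allowed)}")


@dataclass
class GenotypePanel:
    """Diploid genotype matrix (markers x samples) of alternate-allele counts."""

    markers: np.ndarray
    samples: np.ndarray
    genotypes: np.ndarray  # int8, shape (n_markers, n_samples), values {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.markers = _as_str_array(self.markers)
        self.samples = _as_str_array(self.samples)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({len(self.markers)}, {len(self.samples)})"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids in panel")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in panel")
        _validate_genotype_values(self.genotypes, allow_missing=True)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def marker_indexer(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.markers)}
        try:
            return np.fromiter((lookup[m] for m in marker_ids), dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"marker not in panel: {exc.args[0]!r}") from None

    def sample_indexer(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.fromiter((lookup[s] for s in sample_ids), dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample not in panel: {exc.args[0]!r}") from None

    def subset_markers(self, marker_ids) -> "GenotypePanel":
        idx = self.marker_indexer(marker_ids)
        return GenotypePanel(self.markers[idx], self.samples.copy(), self.genotypes[idx])

    def subset_samples(self, sample_ids) -> "GenotypePanel":
        idx = self.sample_indexer(sample_ids)
        return GenotypePanel(self.markers.copy(), self.samples[idx], self.genotypes[:, idx])

    def sample_call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)

    def marker_call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker counts of genotypes (0, 1, 2) among non-missing calls; shape (M, 3)."""
        out = np.empty((self.n_markers, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.genotypes == g).sum(axis=1)
        return out

    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing genotypes (NaN if all missing)."""
        obs = self.genotypes != MISSING
        n = obs.sum(axis=1)
        alt = np.where(obs, self.genotypes, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.markers.copy(), self.samples.copy(), self.genotypes.copy())


@dataclass
class ImputationResult:
    """Imputed dosages, best-guess genotypes and (optional) model-based Rsq per marker."""

    markers: np.ndarray
    samples: np.ndarray
    dosages: np.ndarray       # float64 in [0, 2]
    best_guess: np.ndarray    # int8 in {0, 1, 2}
    rsq_reported: np.ndarray  # float64 in [0, 1], NaN = not available

    def __post_init__(self) -> None:
        self.markers = _as_str_array(self.markers)
        self.samples = _as_str_array(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.best_guess = np.asarray(self.best_guess, dtype=np.int8)
        self.rsq_reported = np.asarray(self.rsq_reported, dtype=np.float64)
        shape = (len(self.markers), len(self.samples))
        if self.dosages.shape != shape or self.best_guess.shape != shape:
            raise ValueError("dosage/best-guess shape inconsistent with marker/sample lists")
        if self.rsq_reported.shape != (len(self.markers),):
            raise ValueError("rsq_reported must be per-marker")
        if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        _validate_genotype_values(self.best_guess, allow_missing=False)
        finite = self.rsq_reported[np.isfinite(self.rsq_reported)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("rsq_reported must lie in [0, 1] or be NaN")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_samples(self, sample_ids) -> "ImputationResult":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = np.fromiter((lookup[s] for s in sample_ids), dtype=np.int64)
        return ImputationResult(
            self.markers.copy(),
            self.samples[idx],
            self.dosages[:, idx],
            self.best_guess[:, idx],
            self.rsq_reported.copy(),
        )

    def subset_markers(self, marker_ids) -> "ImputationResult":
        lookup = {m: i for i, m in enumerate(self.markers)}
        idx = np.fromiter((lookup[m] for m in marker_ids), dtype=np.int64)
        return ImputationResult(
            self.markers[idx],
            self.samples.copy(),
            self.dosages[idx],
            self.best_guess[idx],
            self.rsq_reported[idx],
        )


@dataclass(frozen=True)
class PanelSplit:
    """One cross-validation replicate: disjoint reference and target sample lists."""

    replicate_index: int
    reference_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.reference_ids) & set(self.target_ids):
            raise ValueError("reference and target panels must be disjoint")
        if self.replicate_index < 1:
            raise ValueError("replicate_index starts at 1")


@dataclass(frozen=True)
class ArrayContent:
    """Named set of marker ids, e.g. the content of a low-density genotyping array."""

    name: str
    marker_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("array content must be nonempty")

    def __len__(self) -> int:
        return len(self.marker_ids)
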