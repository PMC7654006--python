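"""Quality control for raw genotype panels.

Filters follow the usual array-QC recipe: drop unmapped/non-autosomal markers,
drop samples then markers with low call rate, fill the few remaining sporadic
missing genotypes with the per-marker mode, then drop markers out of
Hardy-Weinberg proportions and (optionally) below a MAF floor.

Filling before the HWE/MAF marker filters makes ``apply_qc`` exactly
idempotent: a second pass sees complete data with identical genotype counts and
removes nothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import MISSING, GenotypePanel, MarkerMap

#: relative tolerance used when deciding whether an outcome's probability is
#: "no larger than" the observed one (guards against ties lost to rounding)
_TIE_RTOL = 1e-10


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the same parity, the probabilities (under the hypergeometric
    null) that do not exceed the observed one — the standard exact SNP-HWE
    test. Probabilities are built by the stable two-sided recurrence from the
    modal heterozygote count.

    Returns a p-value in [0, 1]; a monomorphic sample has a single possible
    configuration and p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes observed")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    if rare == 0:
        return 1.0
    obs_het = n_Aa
    # modal heterozygote count, matched to the parity of the rare-allele count
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    if mid > rare:
        mid -= 2
    probs = {mid: 1.0}
    # downward recurrence: het -> het - 2
    het, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        hom_r += 1
        hom_c += 1
    # upward recurrence: het -> het + 2
    het, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
        hom_r -= 1
        hom_c -= 1
    total = sum(probs.values())
    p_obs = probs[obs_het]
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + _TIE_RTOL)) / total
    return min(1.0, p)


@dataclass
class QcConfig:
    """Thresholds for :func:`apply_qc`. Defaults: call rate >= 95% for both
    samples and markers, HWE exact p >= 1e-5, no MAF floor."""

    min_call_rate_sample: float = 0.95
    min_call_rate_marker: float = 0.95
    hwe_p_threshold: float = 1e-5
    autosomes: frozenset | None = None
    maf_min: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_call_rate_sample", "min_call_rate_marker", "hwe_p_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.maf_min is not None and not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.autosomes is not None:
            self.autosomes = frozenset(str(c) for c in self.autosomes)

    @classmethod
    def from_yaml(cls, path: str) -> "QcConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class QcLog:
    """Per-step accounting of what :func:`apply_qc` removed."""

    steps: list[dict] = field(default_factory=list)
    n_filled: int = 0
    fill_rule: str = "per-marker genotype mode (ties -> smaller genotype)"

    def record(self, step: int, name: str, axis: str, n_removed: int,
               n_markers: int, n_samples: int) -> None:
        self.steps.append(
            {
                "step": step,
                "name": name,
                "axis": axis,
                "n_removed": int(n_removed),
                "n_markers_after": int(n_markers),
                "n_samples_after": int(n_samples),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def removed(self, name: str) -> int:
        for s in self.steps:
            if s["name"] == name:
                return s["n_removed"]
        raise KeyError(name)


def _mode_fill(genotypes: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill MISSING cells with the per-marker modal genotype (ties go to the
    smaller genotype; an all-missing marker fills with 0)."""
    filled = genotypes.copy()
    miss = filled == MISSING
    n_filled = int(miss.sum())
    if n_filled:
        counts = np.stack([(filled == g).sum(axis=1) for g in (0, 1, 2)], axis=1)
        modes = counts.argmax(axis=1).astype(np.int8)  # argmax takes first max: tie -> smaller
        rows = np.nonzero(miss.any(axis=1))[0]
        for i in rows:
            filled[i, miss[i]] = modes[i]
    return filled, n_filled


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    """Per-marker HWE exact p-values from non-missing genotype counts."""
    counts = panel.genotype_counts()
    out = np.empty(panel.n_markers)
    for i, (n0, n1, n2) in enumerate(counts):
        total = n0 + n1 + n2
        out[i] = np.nan if total == 0 else hwe_exact_test(int(n0), int(n1), int(n2))
    return out


def apply_qc(panel: GenotypePanel, mmap: MarkerMap, cfg: QcConfig | None = None,
             ) -> tuple[GenotypePanel, QcLog]:
    """Apply the QC pipeline in a fixed, logged order.

    1. drop unmapped / non-autosomal markers,
    2. drop samples with call rate below threshold,
    3. drop markers with call rate below threshold,
    4. fill remaining sporadic missing genotypes with the per-marker mode,
    5. drop markers with HWE exact p below threshold,
    6. optionally drop markers with MAF below ``maf_min``.

    Raises if the panel empties out at any step. The map must cover all panel
    markers.
    """
    cfg = cfg or QcConfig()
    log = QcLog()
    missing_map = set(panel.markers) - set(mmap.table.index)
    if missing_map:
        raise KeyError(f"markers missing from map: {sorted(missing_map)[:5]}")

    # 1. autosomal, mapped markers only
    sub = mmap.subset(panel.markers)
    keep = sub.is_autosomal(cfg.autosomes).to_numpy()
    cur = panel.subset_markers(panel.markers[keep])
    log.record(1, "non_autosomal_or_unmapped", "markers", (~keep).sum(), cur.n_markers, cur.n_samples)
    _check_nonempty(cur, "autosome filter")

    # 2. sample call rate
    keep_s = cur.sample_call_rate() >= cfg.min_call_rate_sample
    cur = cur.subset_samples(cur.samples[keep_s])
    log.record(2, "sample_call_rate", "samples", (~keep_s).sum(), cur.n_markers, cur.n_samples)
    _check_nonempty(cur, "sample call-rate filter")

    # 3. marker call rate
    keep_m = cur.marker_call_rate() >= cfg.min_call_rate_marker
    cur = cur.subset_markers(cur.markers[keep_m])
    log.record(3, "marker_call_rate", "markers", (~keep_m).sum(), cur.n_markers, cur.n_samples)
    _check_nonempty(cur, "marker call-rate filter")

    # 4. sporadic missing-genotype fill (mode); done before the count-based
    #    marker filters so a second QC pass is a no-op
    filled, n_filled = _mode_fill(cur.genotypes)
    cur = GenotypePanel(cur.markers, cur.samples, filled)
    log.n_filled = n_filled

    # 5. HWE exact test
    pvals = hwe_pvalues(cur)
    keep_h = pvals >= cfg.hwe_p_threshold
    cur = cur.subset_markers(cur.markers[keep_h])
    log.record(5, "hwe", "markers", (~keep_h).sum(), cur.n_markers, cur.n_samples)
    _check_nonempty(cur, "HWE filter")

    # 6. optional MAF floor
    if cfg.maf_min is not None:
        af = cur.allele_freq()
        mafs = np.minimum(af, 1.0 - af)
        keep_f = mafs >= cfg.maf_min
        cur = cur.subset_markers(cur.markers[keep_f])
        log.record(6, "maf", "markers", (~keep_f).sum(), cur.n_markers, cur.n_samples)
        _check_nonempty(cur, "MAF filter")

    return cur, log


def _check_nonempty(panel: GenotypePanel, stage: str) -> None:
    if panel.n_markers == 0 or panel.n_samples == 0:
        raise ValueError(f"panel empty after {stage}")
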