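"""Per-marker imputation accuracy metrics and the model-based Rsq estimator.

Empirical metrics compare true genotypes g in {0,1,2} of the evaluated samples
against the imputer's output: R2dose is the squared Pearson correlation of g
with dosages, R2gt with best-guess genotypes, and CR the fraction of
identically imputed genotypes. Correlations are undefined (NA) when either
vector has zero variance — notably markers imputed to the major allele in every
evaluated sample — while CR is always defined; this is exactly why CR
overstates accuracy for rare variants.

The model-based score Rsq is the MaCH/minimac family estimator: the ratio of
the observed dosage variance to the variance expected under Hardy-Weinberg at
the estimated allele frequency. With diploid dosages d in [0,2]:

    p = mean(d) / 2,    Rsq = Var(d) / (2 p (1 - p)),

with the population variance (divide by N) and the result clipped to [0, 1];
undefined when p is 0 or 1. A haploid variant (denominator p(1-p)) is provided
for phased allele dosages.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypePanel, ImputationResult

NA = float("nan")


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def _check_pair(x, y, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if len(x) < min_len:
        raise ValueError(f"need at least {min_len} observations, got {len(x)}")
    return x, y


def pearson(x, y) -> float:
    """Pearson correlation via the two-pass mean-centred formula; NaN when
    either vector is constant (never coerced to 0)."""
    x, y = _check_pair(x, y, 2)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return NA
    return float(xc @ yc) / np.sqrt(sxx * syy)


def r2_dose(g, d) -> float:
    """Squared Pearson correlation between true genotypes and imputed dosages;
    NaN if either side has zero variance."""
    g_arr, d_arr = _check_pair(g, d, 2)
    _validate_genotypes(g_arr)
    if d_arr.min() < 0 or d_arr.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    r = pearson(g_arr, d_arr)
    return NA if np.isnan(r) else r * r


def r2_gt(g, b) -> float:
    """Squared Pearson correlation between true and best-guess genotypes."""
    g_arr, b_arr = _check_pair(g, b, 2)
    _validate_genotypes(g_arr)
    _validate_genotypes(b_arr)
    r = pearson(g_arr, b_arr)
    return NA if np.isnan(r) else r * r


def concordance_rate(g, b) -> float:
    """Fraction of genotypes imputed identically to truth; defined for any
    non-empty vectors, including monomorphic markers."""
    g_arr, b_arr = _check_pair(g, b, 1)
    return float(np.mean(g_arr == b_arr))


def rsq_model(d) -> float:
    """Model-based imputation quality from diploid dosages (see module docs)."""
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("need a non-empty 1-D dosage vector")
    if d.min() < 0 or d.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    p = d.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        return NA
    if np.all(d == d[0]):  # constant: exactly zero, not rounding residue
        return 0.0
    var_pop = float(np.mean((d - d.mean()) ** 2))
    return float(np.clip(var_pop / (2.0 * p * (1.0 - p)), 0.0, 1.0))


def rsq_model_haploid(hd) -> float:
    """Haploid-dosage form of the Rsq estimator, for phased allele dosages in [0, 1]."""
    hd = np.asarray(hd, dtype=np.float64)
    if hd.ndim != 1 or len(hd) == 0:
        raise ValueError("need a non-empty 1-D dosage vector")
    if hd.min() < 0 or hd.max() > 1:
        raise ValueError("haploid dosages must lie in [0, 1]")
    p = hd.mean()
    if p <= 0.0 or p >= 1.0:
        return NA
    if np.all(hd == hd[0]):
        return 0.0
    var_pop = float(np.mean((hd - p) ** 2))
    return float(np.clip(var_pop / (p * (1.0 - p)), 0.0, 1.0))


def maf(g) -> float:
    """Minor allele frequency from genotypes; missing (-1) entries are ignored."""
    g = np.asarray(g, dtype=np.float64)
    obs = g[g >= 0]
    if obs.size == 0:
        raise ValueError("no observed genotypes")
    _validate_genotypes(obs)
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def _validate_genotypes(arr: np.ndarray) -> None:
    bad = ~np.isin(arr, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError(f"genotypes must be 0, 1 or 2; saw {np.unique(arr[bad])[:4]}")


# ---------------------------------------------------------------------------
# accuracy tables
# ---------------------------------------------------------------------------

def _rowwise_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per row of two equal-shape matrices; NaN
    where either row is constant."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    syy = (yc * yc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    out = np.full(len(x), NA)
    ok = (sxx > 0) & (syy > 0)
    out[ok] = (sxy[ok] ** 2) / (sxx[ok] * syy[ok])
    return out


def build_accuracy_table(truth: GenotypePanel, imputed: ImputationResult,
                         evaluated_ids=None, rsq_source: str = "reported") -> pd.DataFrame:
    """One row per marker shared between truth and imputation, with all metrics
    computed over ``evaluated_ids`` only (defaults to all shared samples).

    ``rsq_source``: "reported" takes the imputer's per-marker Rsq (falling back
    to recomputation when none was reported); "recompute" always re-estimates it
    from the dosages of the evaluated samples.
    """
    if rsq_source not in ("reported", "recompute"):
        raise ValueError("rsq_source must be 'reported' or 'recompute'")
    imputed_set = set(imputed.markers)
    shared = [m for m in truth.markers if m in imputed_set]
    if not shared:
        raise ValueError("truth and imputation share no markers")
    if evaluated_ids is None:
        common = set(truth.samples) & set(imputed.samples)
        evaluated_ids = [s for s in truth.samples if s in common]
    evaluated_ids = list(evaluated_ids)
    if not set(evaluated_ids) <= set(truth.samples) or not set(evaluated_ids) <= set(imputed.samples):
        raise ValueError("evaluated_ids must be present in both truth and imputation")
    if not evaluated_ids:
        raise ValueError("no samples to evaluate")

    t = truth.subset_markers(shared).subset_samples(evaluated_ids)
    r = imputed.subset_markers(shared).subset_samples(evaluated_ids)
    if (t.genotypes < 0).any():
        raise ValueError("truth panel contains missing genotypes; run QC first")

    g = t.genotypes.astype(np.float64)
    d = r.dosages
    b = r.best_guess.astype(np.float64)
    n = len(evaluated_ids)

    p = g.sum(axis=1) / (2.0 * n)
    maf_true = np.minimum(p, 1.0 - p)
    cr = (t.genotypes == r.best_guess).mean(axis=1)

    if rsq_source == "reported" and np.isfinite(r.rsq_reported).any():
        rsq = r.rsq_reported.copy()
    else:
        rsq = np.array([rsq_model(row) for row in d])

    return pd.DataFrame(
        {
            "marker_id": shared,
            "maf_true": maf_true,
            "r2_dose": _rowwise_r2(g, d),
            "r2_gt": _rowwise_r2(g, b),
            "cr": cr,
            "rsq_model": rsq,
            "n_samples": n,
        }
    )


# ---------------------------------------------------------------------------
# MAF-stratified summaries and Rsq reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MafBins:
    """Left-closed MAF bins over (0, 0.5]; a marker with MAF in
    [edges[i], edges[i+1]) falls in bin i (the top bin is closed at 0.5).
    Monomorphic markers (MAF = 0) belong to no bin but still count in the
    global summary."""

    edges: tuple = (0.0, 0.02, 0.05, 0.5)
    labels: tuple = ("rare", "low_frequency", "common")

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) != len(self.labels) + 1:
            raise ValueError("need len(edges) == len(labels) + 1")
        if not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 0.5:
            raise ValueError("bins must cover (0, 0.5]")

    @classmethod
    def two_class(cls) -> "MafBins":
        """Low-frequency (MAF < 5%) vs common (MAF >= 5%)."""
        return cls(edges=(0.0, 0.05, 0.5), labels=("low_frequency", "common"))

    def assign(self, maf_values) -> np.ndarray:
        """Bin label per marker (object array; None for MAF = 0)."""
        m = np.asarray(maf_values, dtype=float)
        idx = np.digitize(m, np.asarray(self.edges)[1:-1], right=False)
        out = np.asarray(self.labels, dtype=object)[idx]
        out = np.where(m > 0, out, None)
        return out


_METRIC_COLS = ("r2_dose", "r2_gt", "cr", "rsq_model")


def summarize_by_bin(table: pd.DataFrame, bins: MafBins | None = None) -> pd.DataFrame:
    """Mean of each metric per MAF bin plus a global row; means ignore NA values
    and the per-metric non-NA counts are reported alongside."""
    if len(table) == 0:
        raise ValueError("empty accuracy table")
    bins = bins or MafBins()
    labels = bins.assign(table["maf_true"].to_numpy())
    rows = []
    for label in list(bins.labels) + ["global"]:
        sub = table if label == "global" else table[labels == label]
        row: dict = {"bin": label, "n_markers": len(sub)}
        for col in _METRIC_COLS:
            vals = sub[col].to_numpy(dtype=float) if len(sub) else np.empty(0)
            ok = np.isfinite(vals)
            row[f"mean_{col}"] = float(vals[ok].mean()) if ok.any() else NA
            row[f"n_{col}"] = int(ok.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def metric_correlations(table: pd.DataFrame, maf_min: float = 0.005) -> pd.DataFrame:
    """Pearson correlation of the model-based Rsq with each empirical metric,
    over markers with MAF >= ``maf_min``; NA pairs are dropped per metric."""
    sub = table[table["maf_true"] >= maf_min]
    if len(sub) < 2:
        raise ValueError("need at least 2 markers after the MAF filter")
    rsq = sub["rsq_model"].to_numpy(dtype=float)
    rows = []
    for col in ("r2_dose", "r2_gt", "cr"):
        vals = sub[col].to_numpy(dtype=float)
        ok = np.isfinite(rsq) & np.isfinite(vals)
        corr = pearson(rsq[ok], vals[ok]) if ok.sum() >= 2 else NA
        rows.append({"metric": col, "correlation": corr, "n_markers": int(ok.sum())})
    return pd.DataFrame(rows)
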