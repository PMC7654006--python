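"""Marker-density accounting across reference, target-truth and imputed data.

A marker "drops out" of the imputed data when every target sample is imputed to
the major allele; conversely a marker that is truly monomorphic in the target
can come back polymorphic purely through imputation error ("falsely imputed").
Correlation-based accuracy metrics see neither event, so these counts are
reported separately.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypePanel, ImputationResult

REPORT_COLUMNS = [
    "marker_id",
    "polymorphic_in_reference",
    "polymorphic_in_target_true",
    "polymorphic_in_imputed",
    "falsely_imputed",
    "rare_in_reference",
]


def polymorphism_status(g) -> bool:
    """True iff at least two distinct genotype values occur (missing ignored)."""
    g = np.asarray(g)
    obs = g[g >= 0]
    if obs.size == 0:
        raise ValueError("no observed genotypes")
    return bool(np.unique(obs).size >= 2)


def _poly_rows(genotypes: np.ndarray) -> np.ndarray:
    obs = genotypes >= 0
    gmin = np.where(obs, genotypes, 3).min(axis=1)
    gmax = np.where(obs, genotypes, -2).max(axis=1)
    return gmax > gmin


def build_density_report(reference: GenotypePanel, target_truth: GenotypePanel,
                         imputed, rare_threshold: float = 0.02,
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-marker polymorphism flags plus the summary counts of the
    reference/target/imputed accounting.

    ``imputed`` is an :class:`ImputationResult` (judged on best-guess genotypes:
    fractional dosages at a monomorphic marker do not make it polymorphic) or a
    best-guess :class:`GenotypePanel`. Marker lists of all three inputs must be
    identical and in the same order.

    Summary counts (overall and restricted to markers rare in the reference,
    i.e. reference MAF < ``rare_threshold``) are computed among markers
    polymorphic in the reference: how many are polymorphic/monomorphic in the
    target truth, polymorphic after imputation, and falsely imputed
    (monomorphic in truth yet polymorphic in the imputed data).
    """
    if isinstance(imputed, ImputationResult):
        imp_markers, imp_geno = imputed.markers, imputed.best_guess
    else:
        imp_markers, imp_geno = imputed.markers, imputed.genotypes
    if not (
        np.array_equal(reference.markers, target_truth.markers)
        and np.array_equal(reference.markers, imp_markers)
    ):
        raise ValueError("reference, target truth and imputed marker lists must be aligned")
    if not 0.0 < rare_threshold <= 0.5:
        raise ValueError("rare_threshold must be in (0, 0.5]")

    poly_ref = _poly_rows(reference.genotypes)
    poly_tgt = _poly_rows(target_truth.genotypes)
    poly_imp = _poly_rows(imp_geno)
    falsely = ~poly_tgt & poly_imp

    af = reference.allele_freq()
    ref_maf = np.minimum(af, 1.0 - af)
    rare = ref_maf < rare_threshold

    report = pd.DataFrame(
        {
            "marker_id": reference.markers,
            "polymorphic_in_reference": poly_ref,
            "polymorphic_in_target_true": poly_tgt,
            "polymorphic_in_imputed": poly_imp,
            "falsely_imputed": falsely,
            "rare_in_reference": rare,
        }
    )

    def _counts(mask: np.ndarray) -> dict:
        base = poly_ref & mask
        return {
            "polymorphic_in_reference": int(base.sum()),
            "polymorphic_in_target": int((base & poly_tgt).sum()),
            "monomorphic_in_target": int((base & ~poly_tgt).sum()),
            "polymorphic_in_imputed": int((base & poly_imp).sum()),
            "falsely_imputed": int((base & falsely).sum()),
        }

    summary = {
        "all": _counts(np.ones(len(poly_ref), dtype=bool)),
        "rare": _counts(rare),
        "rare_threshold": rare_threshold,
    }
    return report, summary
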