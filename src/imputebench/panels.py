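"""Cross-validation splits and low-density array masking.

Replicates are independent random draws of disjoint reference/target sample
sets (not a partition into folds): with reference panels as large as half the
population, disjoint folds are impossible, and re-drawing per replicate matches
randomly re-grouping animals for every fold of a cross-validation.
"""
from __future__ import annotations

import numpy as np

from .core import ArrayContent, GenotypePanel, PanelSplit


def replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Deterministic per-replicate sub-seed: the first word of
    ``SeedSequence([master_seed, replicate_index])``, truncated to 31 bits so it
    stays a portable positive int. Any replicate is reproducible in isolation."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def make_splits(sample_ids, n_reference: int, n_target: int, n_replicates: int,
                seed: int) -> list[PanelSplit]:
    """Draw ``n_replicates`` independent reference/target splits without
    replacement within each replicate."""
    ids = np.asarray(list(sample_ids), dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    if n_reference < 1 or n_target < 1 or n_replicates < 1:
        raise ValueError("panel sizes and replicate count must be positive")
    if n_reference + n_target > len(ids):
        raise ValueError(
            f"cannot draw {n_reference} reference + {n_target} target from {len(ids)} samples"
        )
    splits = []
    for rep in range(1, n_replicates + 1):
        sub = replicate_seed(seed, rep)
        rng = np.random.default_rng(sub)
        perm = rng.permutation(ids)
        splits.append(
            PanelSplit(
                replicate_index=rep,
                reference_ids=tuple(perm[:n_reference]),
                target_ids=tuple(perm[n_reference:n_reference + n_target]),
                seed=sub,
            )
        )
    return splits


def make_target_extension(sample_ids, base_ids, n_additional: int, seed: int,
                          exclude=()) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Extend a base target panel with additional samples for haplotype
    inference. Returns ``(base_ids, additional_ids)``; downstream accuracy is
    assessed on the base panel only.

    ``exclude`` (typically the reference panel) must be disjoint from the base
    panel and is never sampled from.
    """
    ids = set(sample_ids)
    base = tuple(base_ids)
    if not set(base) <= ids:
        raise ValueError("base_ids must be a subset of sample_ids")
    excl = set(exclude)
    if excl & set(base):
        raise ValueError("base panel overlaps the excluded (reference) panel")
    eligible = np.asarray(sorted(ids - set(base) - excl), dtype=object)
    if n_additional < 0:
        raise ValueError("n_additional must be >= 0")
    if n_additional > len(eligible):
        raise ValueError(
            f"requested {n_additional} additional samples but only {len(eligible)} eligible"
        )
    if n_additional == 0:
        return base, ()
    rng = np.random.default_rng(seed)
    extra = rng.choice(eligible, size=n_additional, replace=False)
    return base, tuple(extra)


def mask_to_array(panel: GenotypePanel, content: ArrayContent) -> GenotypePanel:
    """Restrict a panel to the markers on a (low-density) array, preserving the
    panel's marker order. Genotype values are untouched."""
    keep = [m for m in panel.markers if m in content.marker_ids]
    if not keep:
        raise ValueError(
            f"array content {content.name!r} shares no markers with the panel"
        )
    return panel.subset_markers(keep)
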