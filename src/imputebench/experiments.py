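"""End-to-end experimental designs over the synthetic pipeline.

Each design mirrors a standard imputation-benchmarking layout: draw replicate
reference/target splits, mask targets to a nested low-density array, impute
with the haplotype-copying imputer, and aggregate per-marker accuracy by MAF
bin together with marker-density accounting and the reliability (correlation)
of the model-based Rsq against the empirical metrics.

The target-panel-size design emulates the phasing pathway: in real pre-phasing
workflows extra target samples improve haplotype inference, which this package
cannot reproduce mechanistically since it takes simulated phase as known.
Instead the phase of the evaluated (base) samples is corrupted with a switch
error rate ``phase_error_scale / n_total_target``, so larger joint target
panels mean cleaner haplotypes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ArrayContent, GenotypePanel, MarkerMap
from .density import build_density_report
from .metrics import MafBins, build_accuracy_table, metric_correlations, summarize_by_bin
from .misplacement import scan_misplaced
from .panels import make_splits, replicate_seed
from .synthetic import (
    ImputerConfig,
    SimConfig,
    haplotypes_for_samples,
    inject_switch_errors,
    ls_impute,
    make_assembly_pair,
    simulate_population,
)


@dataclass
class ExperimentSpec:
    """Configuration of one experimental design.

    ``design`` is one of ``reference_sweep`` (vary reference-panel size),
    ``target_sweep`` (vary the cohort jointly phased with a fixed base target)
    or ``assembly_compare`` (impute under two marker maps and contrast them).
    """

    design: str = "reference_sweep"
    sizes: tuple = (25, 50, 100, 200)
    n_replicates: int = 3
    seed: int = 0
    n_target: int = 100
    base_size: int = 50
    reference_size: int = 150
    sparse_every: int = 10
    phase_error_rate: float = 0.008
    phase_error_scale: float = 1.2
    n_chrom_changes: int = 5
    n_newly_mapped: int = 3
    scan_width_bp: int = 100_000
    sim: SimConfig = field(default_factory=SimConfig)
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    bins: MafBins = field(default_factory=MafBins)

    def __post_init__(self) -> None:
        if self.design not in ("reference_sweep", "target_sweep", "assembly_compare"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def nested_sparse_content(mmap: MarkerMap, every: int = 10, name: str = "sparse",
                          exclude=()) -> ArrayContent:
    """Every ``every``-th marker in genome order — a nested lower-density array
    content. ``exclude`` ids are never included (e.g. deliberately misplaced
    markers, so they remain imputed rather than observed)."""
    order = mmap.sorted_marker_ids()
    excl = set(exclude)
    picked = [m for m in order[::every] if m not in excl]
    return ArrayContent(name, frozenset(picked))


def _impute_split(panel: GenotypePanel, mmap: MarkerMap, haplotypes: np.ndarray,
                  reference_ids, target_ids, sparse: ArrayContent,
                  imputer: ImputerConfig, switch_error_rate: float = 0.0,
                  seed: int = 0):
    """Impute one split and return (truth target panel, ImputationResult)."""
    ref_h = haplotypes_for_samples(haplotypes, panel.samples, reference_ids)
    tgt_h = haplotypes_for_samples(haplotypes, panel.samples, target_ids)
    if switch_error_rate > 0:
        order = mmap.subset(panel.markers).sorted_marker_ids()
        lookup = {m: i for i, m in enumerate(panel.markers)}
        perm = np.asarray([lookup[m] for m in order])
        chroms = mmap.chrom_of(order)
        corrupted = inject_switch_errors(tgt_h[:, perm], chroms, switch_error_rate, seed)
        tgt_h = tgt_h.copy()
        tgt_h[:, perm] = corrupted
    result = ls_impute(
        ref_h, tgt_h, panel.markers, mmap, sparse, imputer, list(target_ids)
    )
    return panel.subset_samples(list(target_ids)), result


def _replicate_outputs(panel, mmap, result, truth_tgt, reference_ids, bins):
    table = build_accuracy_table(truth_tgt, result)
    summary = summarize_by_bin(table, bins)
    ref_panel = panel.subset_samples(list(reference_ids)).subset_markers(result.markers)
    tgt_panel = truth_tgt.subset_markers(result.markers)
    _, density = build_density_report(ref_panel, tgt_panel, result)
    corr = metric_correlations(table)
    return table, summary, density, corr


def _aggregate(per_rep: list[pd.DataFrame], keys: list[str]) -> pd.DataFrame:
    stacked = pd.concat(per_rep, ignore_index=True)
    num = [c for c in stacked.columns if c not in keys]
    return stacked.groupby(keys, sort=False)[num].mean().reset_index()


def run_reference_sweep(panel: GenotypePanel, mmap: MarkerMap, haplotypes: np.ndarray,
                        spec: ExperimentSpec) -> dict:
    """Mean per-bin accuracy, density accounting and Rsq reliability for each
    reference-panel size; one fixed target size, replicated splits."""
    sparse = nested_sparse_content(mmap, spec.sparse_every)
    summaries, densities, corrs = [], [], []
    for size in spec.sizes:
        splits = make_splits(
            panel.samples, size, spec.n_target, spec.n_replicates,
            seed=replicate_seed(spec.seed, int(size)),
        )
        for sp in splits:
            truth_tgt, result = _impute_split(
                panel, mmap, haplotypes, sp.reference_ids, sp.target_ids,
                sparse, spec.imputer, switch_error_rate=spec.phase_error_rate,
                seed=replicate_seed(sp.seed, 1),
            )
            _, summary, density, corr = _replicate_outputs(
                panel, mmap, result, truth_tgt, sp.reference_ids, spec.bins
            )
            summary.insert(0, "reference_size", size)
            summary.insert(1, "replicate", sp.replicate_index)
            summaries.append(summary)
            drow = pd.DataFrame(
                [dict(reference_size=size, replicate=sp.replicate_index, group=g, **density[g])
                 for g in ("all", "rare")]
            )
            densities.append(drow)
            corr.insert(0, "reference_size", size)
            corr.insert(1, "replicate", sp.replicate_index)
            corrs.append(corr)
    return {
        "accuracy_by_bin": _aggregate(
            [s.drop(columns="replicate") for s in summaries], ["reference_size", "bin"]
        ),
        "density": _aggregate(
            [d.drop(columns="replicate") for d in densities], ["reference_size", "group"]
        ),
        "rsq_reliability": _aggregate(
            [c.drop(columns="replicate") for c in corrs], ["reference_size", "metric"]
        ),
        "replicate_accuracy": pd.concat(summaries, ignore_index=True),
    }


def run_target_sweep(panel: GenotypePanel, mmap: MarkerMap, haplotypes: np.ndarray,
                     spec: ExperimentSpec) -> dict:
    """Accuracy for a fixed base target panel when its haplotypes are inferred
    jointly with increasing numbers of additional samples. ``spec.sizes`` holds
    the *additional* sample counts; evaluation is on the base panel only."""
    sparse = nested_sparse_content(mmap, spec.sparse_every)
    splits = make_splits(
        panel.samples, spec.reference_size, spec.base_size, spec.n_replicates,
        seed=replicate_seed(spec.seed, 7),
    )
    summaries, densities = [], []
    for n_add in spec.sizes:
        n_total = spec.base_size + int(n_add)
        rate = spec.phase_error_scale / n_total  # larger joint panels phase better
        for sp in splits:
            truth_tgt, result = _impute_split(
                panel, mmap, haplotypes, sp.reference_ids, sp.target_ids,
                sparse, spec.imputer, switch_error_rate=rate,
                seed=replicate_seed(sp.seed, n_total),
            )
            _, summary, density, _ = _replicate_outputs(
                panel, mmap, result, truth_tgt, sp.reference_ids, spec.bins
            )
            summary.insert(0, "n_additional", n_add)
            summaries.append(summary)
            densities.append(pd.DataFrame(
                [dict(n_additional=n_add, group=g, **density[g]) for g in ("all", "rare")]
            ))
    return {
        "accuracy_by_bin": _aggregate(summaries, ["n_additional", "bin"]),
        "density": _aggregate(densities, ["n_additional", "group"]),
    }


def run_assembly_compare(panel: GenotypePanel, mmap: MarkerMap, haplotypes: np.ndarray,
                         spec: ExperimentSpec) -> dict:
    """Impute under two derived assembly maps and contrast per-marker accuracy,
    placement-status counts and misplacement flags between them."""
    from .misplacement import compare_assemblies

    map_a, map_b = make_assembly_pair(
        mmap, spec.n_chrom_changes, spec.n_newly_mapped, seed=replicate_seed(spec.seed, 11)
    )
    splits = make_splits(
        panel.samples, spec.reference_size, spec.n_target, 1,
        seed=replicate_seed(spec.seed, 13),
    )
    sp = splits[0]
    tables, flagged, maps = {}, {}, {"a": map_a, "b": map_b}
    for key, amap in maps.items():
        mapped = amap.table.index[amap.is_mapped()]
        keep = [m for m in panel.markers if m in set(mapped)]
        sub_panel = panel.subset_markers(keep)
        sub_haps_cols = panel.marker_indexer(keep)
        sparse = nested_sparse_content(amap.subset(keep), spec.sparse_every)
        truth_tgt, result = _impute_split(
            sub_panel, amap, haplotypes[:, sub_haps_cols], sp.reference_ids,
            sp.target_ids, sparse, spec.imputer,
            switch_error_rate=spec.phase_error_rate, seed=replicate_seed(sp.seed, 2),
        )
        tables[key] = build_accuracy_table(truth_tgt, result)
        _, fl = scan_misplaced(tables[key], amap, width_bp=spec.scan_width_bp)
        flagged[key] = fl
    per_marker, summary = compare_assemblies(
        map_a, map_b, tables["a"], tables["b"], flagged["a"], flagged["b"]
    )
    return {
        "per_marker": per_marker,
        "summary": summary,
        "accuracy_a": tables["a"],
        "accuracy_b": tables["b"],
    }


def run_misplacement_benchmark(seed: int = 0, n_blocks: int = 8, block_size: int = 10,
                               n_reference: int = 200, n_target: int = 60,
                               sparse_every: int = 5, phase_error_rate: float = 0.002,
                               sim: SimConfig | None = None,
                               imputer: ImputerConfig | None = None) -> dict:
    """Ground-truth evaluation of the misplaced-SNP scanner.

    Simulates a population, relocates ``n_blocks`` compact blocks of common,
    untyped markers to distant loci, imputes with the corrupted map from the
    largest reference panel, runs the segment scan and scores it: a block
    counts as detected when the majority of its markers are flagged, and the
    false-flag rate is the fraction of flagged segments among segments that
    contain no relocated marker.
    """
    from .synthetic import inject_misplacement

    sim = sim or SimConfig(n_samples=280, n_markers=3000, seed=seed)
    imputer = imputer or ImputerConfig()
    panel, mmap, haps = simulate_population(sim)
    sparse0 = nested_sparse_content(mmap, sparse_every)
    af = panel.allele_freq()
    pmaf = np.minimum(af, 1.0 - af)
    candidates = set(panel.markers[pmaf >= 0.05]) - sparse0.marker_ids
    bad_map, moved = inject_misplacement(
        mmap, n_blocks, block_size, seed=replicate_seed(seed, 17),
        candidate_ids=candidates,
    )
    sparse = nested_sparse_content(bad_map, sparse_every, exclude=moved)
    sp = make_splits(panel.samples, n_reference, n_target, 1,
                     seed=replicate_seed(seed, 19))[0]
    truth_tgt, result = _impute_split(
        panel, bad_map, haps, sp.reference_ids, sp.target_ids, sparse, imputer,
        switch_error_rate=phase_error_rate, seed=replicate_seed(seed, 23),
    )
    table = build_accuracy_table(truth_tgt, result)
    segments, flagged = scan_misplaced(table, bad_map)
    fl = set(flagged)
    blocks = [moved[i:i + block_size] for i in range(0, len(moved), block_size)]
    detected = sum(
        1 for b in blocks if sum(m in fl for m in b) > len(b) // 2
    )
    msub = bad_map.subset(moved)
    width = 100_000
    contaminated = {
        (msub.table.loc[m, "chrom"], msub.table.loc[m, "pos_bp"] // width) for m in moved
    }
    clean = segments[
        [(c, s) not in contaminated
         for c, s in zip(segments["chrom"], segments["segment_index"])]
    ]
    n_false = int(clean["flagged_misplaced"].sum())
    return {
        "n_blocks": len(blocks),
        "n_detected": detected,
        "sensitivity": detected / len(blocks),
        "n_clean_segments": len(clean),
        "n_falsely_flagged": n_false,
        "false_flag_rate": n_false / max(1, len(clean)),
        "segments": segments,
        "flagged_markers": flagged,
        "moved_markers": moved,
        "accuracy_table": table,
    }


def run_experiment(spec: ExperimentSpec, panel: GenotypePanel | None = None,
                   mmap: MarkerMap | None = None, haplotypes: np.ndarray | None = None,
                   ) -> dict:
    """Dispatch a design; simulates a population from ``spec.sim`` when no data
    is supplied."""
    if panel is None:
        panel, mmap, haplotypes = simulate_population(spec.sim)
    if mmap is None or haplotypes is None:
        raise ValueError("panel, map and haplotypes must be supplied together")
    runner = {
        "reference_sweep": run_reference_sweep,
        "target_sweep": run_target_sweep,
        "assembly_compare": run_assembly_compare,
    }[spec.design]
    return runner(panel, mmap, haplotypes, spec)
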