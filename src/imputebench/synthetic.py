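"""Synthetic haplotype populations and minimal imputers.

The population model is a recombination mosaic: founder haplotypes carry
alleles drawn i.i.d. per marker from a Beta allele-frequency spectrum (heavy in
rare variants by default), and each subsequent generation copies haplotypes
from the previous pool with crossovers at a Poisson rate per base pair.
Iterating the mosaic creates linkage disequilibrium that decays with physical
distance and shared recent segments between individuals — the two properties
haplotype-copying imputation exploits. There is no explicit demography;
realism is limited to those two features.

Two imputers are provided. ``ls_impute`` is a haplotype-copying hidden Markov
model (Li-Stephens): each target haplotype is modelled as an imperfect mosaic
of the reference haplotypes, with copying-error probability ``eps`` at typed
sites and switch probability ``1 - exp(-rho * dist / K)`` between adjacent
sites (K = number of reference haplotypes); posterior state probabilities from
the forward-backward algorithm give expected allele dosages at untyped sites.
Target phase is taken as known (the simulator's true haplotypes); phasing
quality can be degraded explicitly with :func:`inject_switch_errors`.
``noisy_impute`` is a calibrated error model for fast metric testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import UNMAPPED, ArrayContent, GenotypePanel, ImputationResult, MarkerMap


@dataclass
class SimConfig:
    """Parameters of the mosaic population simulator.

    Defaults give a desk-scale analogue of a large single-breed SNP-array
    cohort: a few hundred diploid samples, a few thousand biallelic autosomal
    SNPs on two 5-Mb chromosomes, a Beta(0.4, 0.4) allele-frequency spectrum
    truncated to [0.005, 0.995] (rare-variant heavy), crossover rate 1e-8 per
    bp per meiosis and 400 mosaic generations, so haplotype segments shared
    with the founders average ~250 kb and LD decays well within a chromosome.
    """

    n_haplotypes_founder: int = 300
    n_samples: int = 400
    n_markers: int = 3000
    chrom_lengths_bp: tuple = (5_000_000, 5_000_000)
    maf_beta: tuple = (0.4, 0.4)
    freq_bounds: tuple = (0.005, 0.995)
    recomb_rate_per_bp: float = 1e-8
    mosaic_generations: int = 400
    n_haplotypes_pool: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_haplotypes_founder, self.n_samples, self.n_markers,
               self.n_haplotypes_pool) < 1:
            raise ValueError("counts must be positive")
        if self.recomb_rate_per_bp < 0:
            raise ValueError("recombination rate must be >= 0")
        if self.mosaic_generations < 1:
            raise ValueError("need at least one mosaic generation")
        lo, hi = self.freq_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("freq_bounds must satisfy 0 < lo < hi < 1")


@dataclass
class ImputerConfig:
    """Parameters of the stand-in imputers.

    ``ls_hmm`` mode: ``eps`` is the copying-error probability, ``rho_per_bp``
    the population-scaled recombination rate entering the switch probability
    ``1 - exp(-rho * d / K)``. ``noise`` mode: each best-guess genotype is
    wrong (uniformly one of the other two) with probability ``noise_e`` and the
    dosage adds Gaussian jitter of sd ``noise_jitter_sd`` clipped to [0, 2].
    """

    mode: str = "ls_hmm"
    eps: float = 1e-3
    rho_per_bp: float = 1.5e-3
    noise_e: float = 0.05
    noise_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("ls_hmm", "noise"):
            raise ValueError("mode must be 'ls_hmm' or 'noise'")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        if self.rho_per_bp < 0:
            raise ValueError("rho_per_bp must be >= 0")
        if not 0 <= self.noise_e <= 1:
            raise ValueError("noise_e must be in [0, 1]")
        if self.noise_jitter_sd < 0:
            raise ValueError("noise_jitter_sd must be >= 0")


# ---------------------------------------------------------------------------
# population simulator
# ---------------------------------------------------------------------------

def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    bounds: tuple, size: int) -> np.ndarray:
    lo, hi = bounds
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _allocate_markers(n_markers: int, lengths: np.ndarray) -> np.ndarray:
    """Markers per chromosome, proportional to length, summing exactly."""
    frac = lengths / lengths.sum()
    counts = np.floor(frac * n_markers).astype(int)
    short = n_markers - counts.sum()
    order = np.argsort(-(frac * n_markers - counts))
    counts[order[:short]] += 1
    if (counts < 1).any():
        raise ValueError("too few markers to cover every chromosome")
    return counts


def _recombine_generation(pool: np.ndarray, n_out: int, chrom_bounds: list,
                          positions: np.ndarray, rate: float,
                          rng: np.random.Generator) -> np.ndarray:
    """One generation of mosaic copying: each output haplotype picks two parents
    from ``pool`` and recombines them with Poisson(rate per bp) crossovers,
    chromosomes assorting independently."""
    p1 = rng.integers(0, len(pool), size=n_out)
    p2 = rng.integers(0, len(pool), size=n_out)
    child = pool[p1].copy()
    for start, stop in chrom_bounds:
        pos = positions[start:stop]
        span = int(pos[-1] - pos[0]) if stop - start > 1 else 0
        start_p2 = rng.random(n_out) < 0.5
        n_x = rng.poisson(rate * span, size=n_out) if span > 0 else np.zeros(n_out, dtype=int)
        plain = (n_x == 0)
        # no crossovers: whole-chromosome copy from the chosen parent
        swap = plain & start_p2
        if swap.any():
            child[np.ix_(swap, np.arange(start, stop))] = pool[p2[swap], start:stop]
        for h in np.nonzero(~plain)[0]:
            cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_x[h]))
            parity = (np.searchsorted(cuts, pos, side="right") + int(start_p2[h])) % 2
            take2 = parity == 1
            if take2.any():
                child[h, start:stop][take2] = pool[p2[h], start:stop][take2]
    return child


def chrom_bounds_of(chroms: np.ndarray) -> list:
    """(start, stop) index pairs of the contiguous chromosome blocks in a
    map-ordered marker array."""
    bounds = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            bounds.append((start, i))
            start = i
    return bounds


def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, documented random substream: stream 0 = marker positions,
    1 = allele-frequency spectrum, 2 = founder haplotypes, 3 = mosaic descent."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def drawn_frequencies(cfg: SimConfig) -> np.ndarray:
    """The per-marker founder allele frequencies a simulation with this config
    draws (reproducible independently of the rest of the simulation)."""
    return _truncated_beta(_sub_rng(cfg.seed, 1), *cfg.maf_beta, cfg.freq_bounds, cfg.n_markers)


def simulate_population(cfg: SimConfig) -> tuple[GenotypePanel, MarkerMap, np.ndarray]:
    """Simulate a diploid panel; returns (panel, map, haplotypes).

    ``haplotypes`` has shape (2 * n_samples, n_markers) with sample i owning
    rows 2i and 2i+1; the panel's genotype matrix is their sum. Markers are in
    genome order (chromosomes in input order, positions increasing).
    """
    lengths = np.asarray(cfg.chrom_lengths_bp, dtype=np.int64)
    per_chrom = _allocate_markers(cfg.n_markers, lengths)

    rng_pos = _sub_rng(cfg.seed, 0)
    chroms_out, pos_out = [], []
    for c, (n_c, length) in enumerate(zip(per_chrom, lengths), start=1):
        pos = np.sort(rng_pos.choice(length, size=n_c, replace=False)) + 1
        chroms_out.append(np.full(n_c, str(c), dtype=object))
        pos_out.append(pos.astype(np.int64))
    chroms = np.concatenate(chroms_out)
    positions = np.concatenate(pos_out)
    marker_ids = np.asarray([f"snp{i + 1:06d}" for i in range(cfg.n_markers)], dtype=object)
    mmap = MarkerMap.from_arrays(marker_ids, chroms, positions, "sim")
    bounds = chrom_bounds_of(chroms)

    freqs = drawn_frequencies(cfg)
    rng_founder = _sub_rng(cfg.seed, 2)
    pool = (rng_founder.random((cfg.n_haplotypes_founder, cfg.n_markers)) < freqs).astype(np.int8)
    rng = _sub_rng(cfg.seed, 3)

    # drift in a breeding pool larger than the sampled cohort, so sampled
    # individuals are not all close relatives; the final generation draws the
    # cohort's 2N haplotypes from that pool
    n_hap = 2 * cfg.n_samples
    for _ in range(cfg.mosaic_generations - 1):
        pool = _recombine_generation(
            pool, cfg.n_haplotypes_pool, bounds, positions, cfg.recomb_rate_per_bp, rng
        )
    pool = _recombine_generation(pool, n_hap, bounds, positions, cfg.recomb_rate_per_bp, rng)

    genotypes = (pool[0::2].astype(np.int16) + pool[1::2].astype(np.int16)).T.astype(np.int8)
    samples = [f"ind{i + 1:05d}" for i in range(cfg.n_samples)]
    panel = GenotypePanel(marker_ids, samples, genotypes)
    return panel, mmap, pool


def haplotypes_for_samples(haplotypes: np.ndarray, all_samples, wanted) -> np.ndarray:
    """Rows of the haplotype store belonging to ``wanted`` samples (2 per sample,
    kept adjacent)."""
    lookup = {s: i for i, s in enumerate(all_samples)}
    rows = []
    for s in wanted:
        i = lookup[s]
        rows.extend((2 * i, 2 * i + 1))
    return haplotypes[np.asarray(rows, dtype=np.int64)]


# ---------------------------------------------------------------------------
# Li-Stephens haplotype-copying imputer
# ---------------------------------------------------------------------------

def _switch_probs(chroms: np.ndarray, positions: np.ndarray, rho: float, K: int) -> np.ndarray:
    """Per-site probability of switching copying template before site m
    (s[0] unused; 1.0 at chromosome starts = uniform reset)."""
    M = len(positions)
    s = np.empty(M)
    s[0] = 1.0
    d = np.diff(positions).astype(np.float64)
    s[1:] = 1.0 - np.exp(-rho * d / K)
    new_chrom = chroms[1:] != chroms[:-1]
    s[1:][new_chrom] = 1.0
    return s


def _ls_chunk(ref: np.ndarray, ref_f: np.ndarray, obs: np.ndarray, typed: np.ndarray,
              s: np.ndarray, eps: float, return_posteriors: bool = False):
    """Forward-backward over reference-haplotype states for a chunk of target
    haplotypes. ``ref`` (K, M) int8; ``obs`` (B, M) with observed alleles at
    typed sites; returns per-haplotype allele dosages (B, M) and optionally the
    full posterior array (B, M, K)."""
    K, M = ref.shape
    B = len(obs)
    alpha = np.empty((B, M, K), dtype=np.float32)
    cur = np.full((B, K), 1.0 / K)
    for m in range(M):
        if s[m] >= 1.0:
            pr = np.full((B, K), 1.0 / K)
        elif s[m] <= 0.0:
            pr = cur
        else:
            pr = (1.0 - s[m]) * cur + s[m] / K
        if typed[m]:
            e = np.where(ref[:, m][None, :] == obs[:, m][:, None], 1.0 - eps, eps)
            pr = pr * e
        cur = pr / pr.sum(axis=1, keepdims=True)
        alpha[:, m] = cur
    dose = np.empty((B, M))
    post = np.empty((B, M, K), dtype=np.float32) if return_posteriors else None
    beta = np.ones((B, K))
    for m in range(M - 1, -1, -1):
        gamma = alpha[:, m].astype(np.float64) * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        dose[:, m] = gamma @ ref_f[:, m]
        if return_posteriors:
            post[:, m] = gamma
        # propagate beta across the transition into site m
        v = beta
        if typed[m]:
            e = np.where(ref[:, m][None, :] == obs[:, m][:, None], 1.0 - eps, eps)
            v = v * e
        if s[m] >= 1.0:
            beta = np.repeat(v.mean(axis=1, keepdims=True), K, axis=1)
        elif s[m] <= 0.0:
            beta = v.copy()
        else:
            beta = (1.0 - s[m]) * v + s[m] * v.mean(axis=1, keepdims=True)
        beta /= beta.sum(axis=1, keepdims=True)
    return (dose, post) if return_posteriors else (dose, None)


def ls_impute(reference_haplotypes: np.ndarray, target_haplotypes: np.ndarray,
              markers, dense_map: MarkerMap, sparse_content: ArrayContent,
              cfg: ImputerConfig | None = None, target_sample_ids=None,
              ) -> ImputationResult:
    """Impute dense genotypes for targets typed only at ``sparse_content``.

    ``reference_haplotypes`` (K, M) and ``target_haplotypes`` (2T, M) are
    aligned to ``markers``; target rows 2i, 2i+1 belong to sample i (true
    simulated phase — phasing itself is out of scope here). Sites outside
    ``sparse_content`` are treated as unobserved in the targets; each target
    haplotype's posterior copying distribution over the reference haplotypes
    yields its expected allele dosage everywhere. Diploid dosage is the sum
    over the sample's two haplotypes, best-guess its rounding, and the reported
    per-marker Rsq is the model-based estimator over the imputed dosages.
    """
    cfg = cfg or ImputerConfig()
    ref = np.asarray(reference_haplotypes, dtype=np.int8)
    tgt = np.asarray(target_haplotypes, dtype=np.int8)
    if ref.ndim != 2 or ref.shape[0] < 2:
        raise ValueError("need at least 2 reference haplotypes")
    markers = np.asarray(list(markers), dtype=object)
    M = len(markers)
    if ref.shape[1] != M or tgt.shape[1] != M:
        raise ValueError("haplotype matrices must be aligned to the marker list")
    if tgt.shape[0] % 2 != 0:
        raise ValueError("target haplotypes must come in sample pairs")
    n_t = tgt.shape[0] // 2
    if target_sample_ids is None:
        target_sample_ids = [f"target{i + 1:05d}" for i in range(n_t)]
    if len(target_sample_ids) != n_t:
        raise ValueError("target_sample_ids length must match target haplotype pairs")

    # genome order according to the supplied map
    sub = dense_map.subset(markers)
    if (~sub.is_mapped()).any():
        raise ValueError("all markers need map positions for imputation")
    order_ids = sub.sorted_marker_ids()
    lookup = {m: i for i, m in enumerate(markers)}
    perm = np.asarray([lookup[m] for m in order_ids], dtype=np.int64)
    ref = ref[:, perm]
    tgt = tgt[:, perm]
    chroms = sub.chrom_of(order_ids)
    positions = sub.pos_of(order_ids)
    typed = np.asarray([m in sparse_content.marker_ids for m in order_ids])
    if not typed.any():
        raise ValueError("sparse content shares no markers with the panel")

    K = ref.shape[0]
    s = _switch_probs(chroms, positions, cfg.rho_per_bp, K)
    ref_f = ref.astype(np.float64)

    n_hap = tgt.shape[0]
    # chunk so the stored forward probabilities stay modest in memory
    chunk = max(2, min(n_hap, int(2.5e8 // max(1, M * K * 4))))
    chunk -= chunk % 2
    hap_dose = np.empty((n_hap, M))
    for lo in range(0, n_hap, chunk):
        hi = min(n_hap, lo + chunk)
        dose, _ = _ls_chunk(ref, ref_f, tgt[lo:hi], typed, s, cfg.eps)
        hap_dose[lo:hi] = dose

    dosages = np.clip(hap_dose[0::2] + hap_dose[1::2], 0.0, 2.0).T  # (M, T)
    best_guess = np.clip(np.rint(dosages), 0, 2).astype(np.int8)
    rsq = _rsq_rows(dosages)
    return ImputationResult(order_ids, list(target_sample_ids), dosages, best_guess, rsq)


def ls_posteriors(reference_haplotypes: np.ndarray, observed_alleles: np.ndarray,
                  chroms: np.ndarray, positions: np.ndarray,
                  cfg: ImputerConfig | None = None) -> np.ndarray:
    """Posterior copying probabilities (M, K) for a single target haplotype;
    ``observed_alleles`` uses -1 for untyped sites. Exposed for inspection and
    testing of the forward-backward machinery."""
    cfg = cfg or ImputerConfig()
    ref = np.asarray(reference_haplotypes, dtype=np.int8)
    obs = np.asarray(observed_alleles, dtype=np.int8)[None, :]
    typed = obs[0] >= 0
    s = _switch_probs(np.asarray(chroms, dtype=object), np.asarray(positions), cfg.rho_per_bp, len(ref))
    _, post = _ls_chunk(ref, ref.astype(np.float64), obs, typed, s, cfg.eps, return_posteriors=True)
    return post[0].astype(np.float64)


def _rsq_rows(dosages: np.ndarray) -> np.ndarray:
    p = dosages.mean(axis=1) / 2.0
    var = dosages.var(axis=1)  # population variance (divide by N)
    denom = 2.0 * p * (1.0 - p)
    out = np.full(len(dosages), np.nan)
    ok = (p > 0) & (p < 1)
    out[ok] = np.clip(var[ok] / denom[ok], 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# calibrated noise imputer
# ---------------------------------------------------------------------------

def noisy_impute(truth: GenotypePanel, cfg: ImputerConfig | None = None,
                 seed: int = 0) -> ImputationResult:
    """Corrupt true genotypes with a flat error model (see :class:`ImputerConfig`)."""
    cfg = cfg or ImputerConfig(mode="noise")
    if (truth.genotypes < 0).any():
        raise ValueError("truth panel must be complete (no missing genotypes)")
    rng = np.random.default_rng(seed)
    g = truth.genotypes.astype(np.int16)
    err = rng.random(g.shape) < cfg.noise_e
    shift = rng.integers(1, 3, size=g.shape)  # +1 or +2 mod 3: uniform over the other two
    best = np.where(err, (g + shift) % 3, g).astype(np.int8)
    dosages = np.clip(best + rng.normal(0.0, cfg.noise_jitter_sd, size=g.shape), 0.0, 2.0)
    return ImputationResult(truth.markers, truth.samples, dosages, best, _rsq_rows(dosages))


# ---------------------------------------------------------------------------
# ground-truth corruption fixtures
# ---------------------------------------------------------------------------

def inject_misplacement(mmap: MarkerMap, n_blocks: int, block_size: int, seed: int,
                        candidate_ids=None, chrom_lengths: dict | None = None,
                        min_shift_bp: int = 1_000_000,
                        ) -> tuple[MarkerMap, list[str]]:
    """Relocate ``n_blocks`` contiguous blocks of ``block_size`` markers to
    random loci (possibly other chromosomes). Genotypes stay attached to marker
    ids — only the map lies. Returns the corrupted map and the moved ids.

    Destinations on the block's own chromosome must lie at least
    ``min_shift_bp`` from the block's original midpoint: a shift within the
    population's LD range barely perturbs imputation and is not the failure
    mode this fixture represents.

    ``candidate_ids`` optionally restricts which markers may be moved (e.g. to
    keep typed array markers in place); blocks are contiguous runs *within the
    candidate set* in map order, so with a nested typed grid a moved block is a
    physically compact cluster of imputed markers. Destination spacing is the
    median marker spacing of the destination chromosome.
    """
    if n_blocks == 0:
        return MarkerMap(mmap.assembly_name, mmap.table.copy()), []
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = mmap.sorted_marker_ids()
    tab = mmap.table
    chroms_sorted = np.asarray([tab.loc[m, "chrom"] for m in order], dtype=object)
    bounds = chrom_bounds_of(chroms_sorted)

    lengths = chrom_lengths or {}
    chrom_names = [chroms_sorted[b[0]] for b in bounds]
    for name, (start, stop) in zip(chrom_names, bounds):
        if name not in lengths:
            lengths[name] = int(tab.loc[order[stop - 1], "pos_bp"])

    # candidate markers, still in map order, with their chromosome block
    if candidate_ids is not None:
        allowed = set(candidate_ids)
        cand_mask = np.asarray([m in allowed for m in order])
    else:
        cand_mask = np.ones(len(order), dtype=bool)
    cand_per_chrom = [
        np.nonzero(cand_mask[start:stop])[0] + start for start, stop in bounds
    ]

    taken: set = set()
    blocks: list[np.ndarray] = []
    attempts = 0
    while len(blocks) < n_blocks:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place the requested misplacement blocks")
        bi = rng.integers(0, len(bounds))
        cand = cand_per_chrom[bi]
        if len(cand) < block_size:
            continue
        s0 = int(rng.integers(0, len(cand) - block_size + 1))
        idx = cand[s0:s0 + block_size]
        ids = order[idx]
        if taken & set(idx):
            continue
        taken |= set(idx)
        blocks.append(ids)

    new_tab = tab.copy()
    moved: list[str] = []
    spacing = {}
    for name, (start, stop) in zip(chrom_names, bounds):
        pos = np.asarray([tab.loc[m, "pos_bp"] for m in order[start:stop]])
        spacing[name] = int(np.median(np.diff(pos))) if len(pos) > 1 else 1000
    for ids in blocks:
        origin_chrom = tab.loc[ids[0], "chrom"]
        origin_mid = int(np.median([tab.loc[m, "pos_bp"] for m in ids]))
        for _ in range(10000):
            dest = chrom_names[int(rng.integers(0, len(chrom_names)))]
            step = max(1, spacing[dest])
            span = step * (block_size - 1)
            hi = max(2, lengths[dest] - span)
            start_pos = int(rng.integers(1, hi))
            if dest != origin_chrom or abs(start_pos + span // 2 - origin_mid) >= min_shift_bp:
                break
        else:
            raise ValueError("no destination satisfies the minimum shift")
        for k, m in enumerate(ids):
            new_tab.loc[m, "chrom"] = dest
            new_tab.loc[m, "pos_bp"] = start_pos + k * step
        moved.extend(ids)
    return MarkerMap(mmap.assembly_name + "_misplaced", new_tab), moved


def make_assembly_pair(mmap: MarkerMap, n_chrom_changes: int, n_newly_mapped: int,
                       seed: int) -> tuple[MarkerMap, MarkerMap]:
    """Derive two assembly maps from a base map: assembly A has
    ``n_newly_mapped`` markers unplaced (they gain positions only in B), and B
    moves ``n_chrom_changes`` other markers to a different chromosome. With
    zero changes both maps equal the base."""
    rng = np.random.default_rng(seed)
    n_total = n_chrom_changes + n_newly_mapped
    if n_total > len(mmap):
        raise ValueError("more changes requested than markers available")
    chrom_values = sorted(set(mmap.table["chrom"]) - {UNMAPPED})
    if n_chrom_changes > 0 and len(chrom_values) < 2:
        raise ValueError("chromosome changes need at least two chromosomes")
    chosen = rng.choice(mmap.marker_ids, size=n_total, replace=False) if n_total else []
    to_unmap = list(chosen[:n_newly_mapped])
    to_change = list(chosen[n_newly_mapped:])

    tab_a = mmap.table.copy()
    tab_a.loc[to_unmap, "chrom"] = UNMAPPED
    tab_a.loc[to_unmap, "pos_bp"] = -1
    tab_b = mmap.table.copy()
    for m in to_change:
        current = tab_b.loc[m, "chrom"]
        others = [c for c in chrom_values if c != current]
        tab_b.loc[m, "chrom"] = others[int(rng.integers(0, len(others)))]
    return (
        MarkerMap(mmap.assembly_name + "_A", tab_a),
        MarkerMap(mmap.assembly_name + "_B", tab_b),
    )


def inject_switch_errors(haplotypes: np.ndarray, chroms: np.ndarray,
                         rate_per_marker: float, seed: int) -> np.ndarray:
    """Corrupt the phase of paired haplotypes: within each sample (rows 2i,
    2i+1) and chromosome, the two haplotypes are swapped from each switch point
    onward; switch points occur independently at each marker with
    ``rate_per_marker``. Emulates imperfect statistical phasing, whose error
    rate falls as the phased cohort grows."""
    if rate_per_marker < 0:
        raise ValueError("rate must be >= 0")
    haps = np.asarray(haplotypes, dtype=np.int8).copy()
    if haps.shape[0] % 2:
        raise ValueError("haplotypes must come in sample pairs")
    if rate_per_marker == 0:
        return haps
    rng = np.random.default_rng(seed)
    n_ind = haps.shape[0] // 2
    bounds = chrom_bounds_of(np.asarray(chroms, dtype=object))
    toggles = rng.random((n_ind, haps.shape[1])) < rate_per_marker
    for start, stop in bounds:
        parity = np.cumsum(toggles[:, start:stop], axis=1) % 2
        swap = parity.astype(bool)
        for i in np.nonzero(swap.any(axis=1))[0]:
            cols = np.nonzero(swap[i])[0] + start
            a, b = 2 * i, 2 * i + 1
            tmp = haps[a, cols].copy()
            haps[a, cols] = haps[b, cols]
            haps[b, cols] = tmp
    return haps
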