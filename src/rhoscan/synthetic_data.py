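"""Synthetic haplotype panels and sperm-typing assay outcomes.

The generator stands in for cohort re-sequencing data: it produces phased
haplotype panels over a few-kb segment under the neutral coalescent with
recombination (Hudson's back-in-time ancestral-recombination-graph algorithm,
infinite-sites mutation), optionally with a central recombination hotspot and
an optional positively selected derived allele (forward-time Wright–Fisher),
plus single-molecule pooled-PCR assay outcomes.

Model summary
-------------
Time is scaled in units of :math:`2N_e` generations.  With ``k`` ancestral
lineages, coalescence occurs at rate :math:`k(k-1)/2` and each lineage
recombines at rate :math:`\\rho_{\\mathrm{span}}/2`, where
:math:`\\rho_{\\mathrm{span}}` integrates the per-bp population rate
:math:`\\rho(x)` over the lineage's ancestral span.  Mutations fall on
branches as a Poisson process of intensity :math:`\\theta/2` per segment, are
mapped to discrete bp positions, and every site is biallelic
(infinite sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import (MISSING, HaplotypePanel, SnpEntry, SnpMap,
                         SUBSEGMENTS)
from .sperm_typing import AssayCounts

#: per-bp population rate equivalent to the ~0.89 cM/Mb genome average at
#: Ne = 10,000 (rho = 4 Ne r with r = 0.89e-8 per bp)
GENOME_AVG_RHO_PER_BP = 4 * 10_000 * 0.89e-8


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hotspot:
    """Interval [start, end) in segment bp with a fold-enrichment over the
    background per-bp rate."""

    start: float
    end: float
    fold: float


@dataclass(frozen=True)
class RecombProfile:
    """Piecewise-constant per-bp population recombination rate rho(x)."""

    background_per_bp: float = GENOME_AVG_RHO_PER_BP
    hotspots: tuple[Hotspot, ...] = ()

    def rates(self, seq_length: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (edges, per-bp rates) tiling [0, seq_length)."""
        cuts = {0.0, float(seq_length)}
        for h in self.hotspots:
            cuts.add(float(h.start))
            cuts.add(float(h.end))
        edges = np.array(sorted(cuts))
        rates = np.full(len(edges) - 1, self.background_per_bp, dtype=float)
        mids = 0.5 * (edges[:-1] + edges[1:])
        for h in self.hotspots:
            rates[(mids >= h.start) & (mids < h.end)] *= h.fold
        return edges, rates

    def total(self, seq_length: float) -> float:
        edges, rates = self.rates(seq_length)
        return float(np.sum(np.diff(edges) * rates))


@dataclass(frozen=True)
class Selection:
    """Additive positive selection on the derived allele of one site.

    ``s`` is the per-generation selection coefficient per derived copy;
    ``n_diploids`` the Wright–Fisher population size; haplotypes are sampled
    after ``n_generations`` of forward evolution from neutral standing
    variation.
    """

    focal_site: int
    s: float
    n_diploids: int = 100
    n_generations: int = 50


@dataclass(frozen=True)
class SimConfig:
    n_haplotypes: int
    seq_length: int = 3551
    theta: float = 5.0  # per segment
    recomb: RecombProfile = field(
        default_factory=lambda: RecombProfile(
            hotspots=(Hotspot(1525, 2025, 40.0),)))
    selection: Selection | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least two haplotypes")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if self.theta < 0 or self.recomb.background_per_bp < 0:
            raise ValueError("rates must be non-negative")
        for h in self.recomb.hotspots:
            if not (0 <= h.start < h.end <= self.seq_length):
                raise ValueError(f"hotspot {h} outside [0, seq_length)")
            if h.fold < 0:
                raise ValueError("hotspot fold must be non-negative")
        if self.selection is not None:
            sel = self.selection
            if sel.n_diploids < 1 or sel.n_generations < 0:
                raise ValueError("nonviable selection configuration")
            if self.n_haplotypes > 2 * sel.n_diploids:
                raise ValueError("cannot sample more haplotypes than the "
                                 "forward population holds")


@dataclass(frozen=True)
class PoolAssayConfig:
    """Pooled allele-specific PCR design: ``n_runs`` pools of
    ``genomes_per_run`` amplifiable genomes, a true crossover rate in cM/Mb
    over ``interval_bp``, and the fraction of recombinant molecules the
    allele-specific primer design can observe (one of the two reciprocal
    product classes gives 0.5)."""

    n_runs: int = 77
    genomes_per_run: int = 100
    true_rate: float = 129.0  # cM/Mb
    interval_bp: int = 1000
    detectable_fraction: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        if self.n_runs <= 0 or self.genomes_per_run <= 0:
            raise ValueError("counts must be positive")
        if self.interval_bp <= 0:
            raise ValueError("interval_bp must be positive")
        if not 0 < self.detectable_fraction <= 1:
            raise ValueError("detectable_fraction must be in (0, 1]")
        if self.true_rate < 0:
            raise ValueError("true_rate must be non-negative")


# ---------------------------------------------------------------------------
# Piecewise-constant rate helper
# ---------------------------------------------------------------------------


class _PiecewiseRate:
    def __init__(self, edges: np.ndarray, rates: np.ndarray):
        self.edges = edges
        self.rates = rates
        self.cum = np.concatenate([[0.0],
                                   np.cumsum(np.diff(edges) * rates)])

    def integral(self, a: float, b: float) -> float:
        return self._cum_at(b) - self._cum_at(a)

    def _cum_at(self, x: float) -> float:
        i = int(np.searchsorted(self.edges, x, side="right")) - 1
        i = min(max(i, 0), len(self.rates) - 1)
        return float(self.cum[i] + self.rates[i] * (x - self.edges[i]))

    def sample(self, a: float, b: float, rng: np.random.Generator) -> float:
        """Draw a point in (a, b) with density proportional to the rate."""
        ca, cb = self._cum_at(a), self._cum_at(b)
        u = rng.uniform(ca, cb)
        i = int(np.searchsorted(self.cum, u, side="right")) - 1
        i = min(max(i, 0), len(self.rates) - 1)
        if self.rates[i] == 0:
            return float(np.clip(self.edges[i], a, b))
        x = self.edges[i] + (u - self.cum[i]) / self.rates[i]
        return float(np.clip(x, a, b))


# ---------------------------------------------------------------------------
# Hudson ARG
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("node", "segs")

    def __init__(self, node: int, segs: list[tuple[float, float, int]]):
        self.node = node
        self.segs = segs  # sorted, disjoint (left, right, n_samples_below)

    def span(self) -> tuple[float, float]:
        return self.segs[0][0], self.segs[-1][1]


def _merge_segs(a: list[tuple[float, float, int]],
                b: list[tuple[float, float, int]],
                n: int) -> list[tuple[float, float, int]]:
    """Union two segment lists, summing sample counts on overlap and
    dropping fully coalesced (count == n) material."""
    pts = sorted({p for l, r, _ in a + b for p in (l, r)})
    out: list[tuple[float, float, int]] = []

    def count_in(segs, lo):
        for l, r, c in segs:
            if l <= lo < r:
                return c
        return 0

    for lo, hi in zip(pts[:-1], pts[1:]):
        c = count_in(a, lo) + count_in(b, lo)
        if c == 0 or c == n:
            continue
        if out and out[-1][1] == lo and out[-1][2] == c:
            out[-1] = (out[-1][0], hi, c)
        else:
            out.append((lo, hi, c))
    return out


def _simulate_arg(n: int, L: float, rate: _PiecewiseRate,
                  rng: np.random.Generator):
    """Run the back-in-time ARG; return (node_times, edges).

    Edges are (left, right, parent, child) over half-open intervals; marginal
    genealogies at any x are recovered from the edges covering x.
    """
    lineages = [_Lineage(i, [(0.0, L, 1)]) for i in range(n)]
    times = [0.0] * n
    edges: list[tuple[float, float, int, int]] = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        rec = np.array([0.5 * rate.integral(*lin.span()) if lin.segs else 0.0
                        for lin in lineages])
        total = k * (k - 1) / 2 + rec.sum()
        t += rng.exponential(1.0 / total)
        if rng.uniform(0, total) < rec.sum() and rec.sum() > 0:
            # recombination: split one lineage at a rho-weighted breakpoint
            i = int(rng.choice(k, p=rec / rec.sum()))
            lin = lineages[i]
            lo, hi = lin.span()
            x = rate.sample(lo, hi, rng)
            left = [(l, min(r, x), c) for l, r, c in lin.segs if l < x]
            right = [(max(l, x), r, c) for l, r, c in lin.segs if r > x]
            left = [s for s in left if s[1] > s[0]]
            right = [s for s in right if s[1] > s[0]]
            if not left or not right:
                continue  # breakpoint outside ancestral material: no-op
            lineages[i] = _Lineage(lin.node, left)
            lineages.append(_Lineage(lin.node, right))
        else:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            parent = len(times)
            times.append(t)
            for l, r, _ in a.segs:
                edges.append((l, r, parent, a.node))
            for l, r, _ in b.segs:
                edges.append((l, r, parent, b.node))
            merged = _merge_segs(a.segs, b.segs, n)
            lineages = [lin for idx, lin in enumerate(lineages)
                        if idx not in (int(i), int(j))]
            if merged:
                lineages.append(_Lineage(parent, merged))
    return times, edges


def _drop_mutations(n: int, L: float, theta: float, times, edges,
                    rng: np.random.Generator):
    """Poisson mutations on marginal genealogies; returns a list of
    (continuous position, frozenset of carrier sample ids)."""
    cuts = sorted({0.0, L} | {e[0] for e in edges} | {e[1] for e in edges})
    muts: list[tuple[float, frozenset[int]]] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        active = [(p, c) for l, r, p, c in edges if l <= lo and r >= hi]
        if not active:
            continue
        lengths = np.array([times[p] - times[c] for p, c in active])
        T = lengths.sum()
        m = rng.poisson(theta / (2.0 * L) * (hi - lo) * T)
        if m == 0:
            continue
        parent_of = {c: p for p, c in active}
        below: dict[int, set[int]] = {}
        for s in range(n):
            node = s
            while node in parent_of or node < n:
                below.setdefault(node, set()).add(s)
                if node not in parent_of:
                    break
                node = parent_of[node]
        probs = lengths / T
        for _ in range(m):
            e_i = int(rng.choice(len(active), p=probs))
            child = active[e_i][1]
            carriers = frozenset(below.get(child, set()))
            if 0 < len(carriers) < n:
                muts.append((rng.uniform(lo, hi), carriers))
    return muts


def _subsegment_for(pos: int, L: int) -> str:
    # synthetic quartile labelling mirroring the PreAlu/Alu/PostAlu/PostExon
    # layout of a centrally inserted element
    q = pos / L
    if q <= 0.25:
        return "PreAlu"
    if q <= 0.60:
        return "Alu"
    if q <= 0.80:
        return "PostAlu"
    return "PostExon"


def _panel_from_mutations(muts, n: int, L: int,
                          population=pd.NA, phenotype=pd.NA,
                          sex=pd.NA) -> HaplotypePanel:
    muts = sorted(muts, key=lambda m: m[0])
    positions: list[int] = []
    cols: list[frozenset[int]] = []
    prev = 0
    for x, carriers in muts:
        pos = max(int(math.floor(x)) + 1, prev + 1)
        if pos > L:
            continue  # discrete segment saturated; drop (rare)
        positions.append(pos)
        cols.append(carriers)
        prev = pos
    S = len(positions)
    matrix = np.zeros((n, S), dtype=np.int8)
    for j, carriers in enumerate(cols):
        matrix[list(carriers), j] = 1
    entries = tuple(
        SnpEntry(f"S{j + 1}", "sim", positions[j], "A", "G",
                 _subsegment_for(positions[j], L))
        for j in range(S))
    snp_map = SnpMap(entries, (1, L))
    meta = pd.DataFrame({
        "individual": [f"H{i + 1}" for i in range(n)],
        "chromosome": 1,
        "population": population, "phenotype": phenotype, "sex": sex,
    })
    return HaplotypePanel(snp_map, matrix, meta)


# ---------------------------------------------------------------------------
# Forward Wright–Fisher with selection
# ---------------------------------------------------------------------------


def _forward_wf(pop: np.ndarray, positions: np.ndarray, focal: int, s: float,
                generations: int, rate: _PiecewiseRate, L: float,
                n_diploids: int, rng: np.random.Generator) -> np.ndarray:
    """Evolve a 2N x S haplotype array forward with additive selection on the
    derived allele at column ``focal`` and crossover per the rho profile
    (per-meiosis rate r(x) = rho(x) / 4N)."""
    n2 = 2 * n_diploids
    r_total = rate.integral(0.0, L) / (4.0 * n_diploids)
    for _ in range(generations):
        w = 1.0 + s * pop[:, focal]
        p = w / w.sum()
        pa = rng.choice(n2, size=n2, p=p)
        pb = rng.choice(n2, size=n2, p=p)
        k = rng.poisson(r_total, size=n2)
        children = pop[pa].copy()
        for i in np.nonzero(k > 0)[0]:
            bps = sorted(rate.sample(0.0, L, rng) for _ in range(k[i]))
            a, b = pop[pa[i]], pop[pb[i]]
            child = a.copy()
            use_b = False
            start = 0.0
            for x in bps + [L]:
                if use_b:
                    sel = (positions > start) & (positions <= x)
                    child[sel] = b[sel]
                start, use_b = x, not use_b
            children[i] = child
        pop = children
    return pop


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def simulate_panel(cfg: SimConfig, *, population=pd.NA, phenotype=pd.NA,
                   sex=pd.NA, return_info: bool = False):
    """Simulate a phased haplotype panel under ``cfg``.

    Without selection this is the neutral coalescent with recombination;
    with selection, neutral standing variation for a Wright–Fisher population
    is generated first and then evolved forward under additive selection.
    Reproducible under a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = float(cfg.seq_length)
    rate = _PiecewiseRate(*cfg.recomb.rates(L))
    info: dict = {}
    if cfg.selection is None:
        times, edges = _simulate_arg(cfg.n_haplotypes, L, rate, rng)
        muts = _drop_mutations(cfg.n_haplotypes, L, cfg.theta, times, edges,
                               rng)
        panel = _panel_from_mutations(muts, cfg.n_haplotypes,
                                      cfg.seq_length, population, phenotype,
                                      sex)
    else:
        sel = cfg.selection
        n2 = 2 * sel.n_diploids
        times, edges = _simulate_arg(n2, L, rate, rng)
        muts = _drop_mutations(n2, L, cfg.theta, times, edges, rng)
        base = _panel_from_mutations(muts, n2, cfg.seq_length)
        if sel.focal_site >= base.n_sites:
            raise ValueError(
                f"focal site {sel.focal_site} out of range: standing "
                f"variation has {base.n_sites} segregating sites")
        positions = base.snp_map.positions.astype(float)
        pop = base.matrix.astype(np.int8)
        init_freq = float(pop[:, sel.focal_site].mean())
        pop = _forward_wf(pop, positions, sel.focal_site, sel.s,
                          sel.n_generations, rate, L, sel.n_diploids, rng)
        final_freq = float(pop[:, sel.focal_site].mean())
        info.update(init_freq=init_freq, final_freq=final_freq,
                    focal_position=int(positions[sel.focal_site]))
        take = rng.choice(n2, size=cfg.n_haplotypes, replace=False)
        sample = pop[np.sort(take)]
        poly = (sample.min(axis=0) != sample.max(axis=0))
        entries = tuple(e for j, e in enumerate(base.snp_map.entries)
                        if poly[j])
        # relabel to keep S-numbers consecutive in the output map
        entries = tuple(
            SnpEntry(f"S{j + 1}", e.rs_id, e.position, e.ancestral,
                     e.derived, e.subsegment)
            for j, e in enumerate(entries))
        snp_map = SnpMap(entries, base.snp_map.segment_span)
        meta = pd.DataFrame({
            "individual": [f"H{i + 1}" for i in range(cfg.n_haplotypes)],
            "chromosome": 1,
            "population": population, "phenotype": phenotype, "sex": sex,
        })
        panel = HaplotypePanel(snp_map, sample[:, poly], meta)
    if return_info:
        return panel, info
    return panel


def simulate_panel_n_sites(cfg: SimConfig, n_sites: int,
                           max_tries: int = 30, **kw) -> HaplotypePanel:
    """Simulate a panel with exactly ``n_sites`` polymorphic sites.

    Replicates are drawn (seed perturbed deterministically) until at least
    ``n_sites`` segregating sites appear, then sites are thinned evenly by
    position to the target count.
    """
    base_seed = 0 if cfg.seed is None else cfg.seed
    for trial in range(max_tries):
        trial_cfg = SimConfig(cfg.n_haplotypes, cfg.seq_length, cfg.theta,
                              cfg.recomb, cfg.selection,
                              seed=(base_seed + 1_000_003 * trial) % 2**31)
        panel = simulate_panel(trial_cfg, **kw)
        if panel.n_sites >= n_sites:
            keep = np.unique(np.round(
                np.linspace(0, panel.n_sites - 1, n_sites)).astype(int))
            entries = tuple(
                SnpEntry(f"S{j + 1}", e.rs_id, e.position, e.ancestral,
                         e.derived, e.subsegment)
                for j, e in enumerate(panel.snp_map.entries[i] for i in keep))
            snp_map = SnpMap(entries, panel.snp_map.segment_span)
            return HaplotypePanel(snp_map, panel.matrix[:, keep], panel.meta)
    raise RuntimeError(f"could not obtain {n_sites} segregating sites in "
                       f"{max_tries} tries; increase theta")


def pair_into_diploids(panel: HaplotypePanel,
                       seed: int | None = None) -> HaplotypePanel:
    """Randomly pair haplotypes into diploid individuals (random union of
    gametes).  Matrix content is unchanged; only metadata is rewritten."""
    n = panel.n_chromosomes
    if n % 2:
        raise ValueError("cannot pair an odd number of haplotypes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    meta = panel.meta.copy()
    individual = np.empty(n, dtype=object)
    chromosome = np.empty(n, dtype=int)
    for pair_i in range(n // 2):
        for k in range(2):
            row = perm[2 * pair_i + k]
            individual[row] = f"I{pair_i + 1}"
            chromosome[row] = k + 1
    meta["individual"] = individual
    meta["chromosome"] = chromosome
    return HaplotypePanel(panel.snp_map, panel.matrix.copy(), meta)


def simulate_pool_assay(cfg: PoolAssayConfig) -> AssayCounts:
    """Simulate pooled allele-specific PCR runs.

    Detectable recombinant molecules per run are Poisson with mean
    ``genomes_per_run * detectable_fraction * true_rate * interval_bp * 1e-8``
    (1 cM/Mb = 1e-8 crossovers per bp); a run is positive iff it contains at
    least one detectable recombinant.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lam = (cfg.genomes_per_run * cfg.detectable_fraction
           * cfg.true_rate * cfg.interval_bp * 1e-8)
    counts = rng.poisson(lam, size=cfg.n_runs)
    return AssayCounts(design="pool", n_runs=cfg.n_runs,
                       positives=int((counts >= 1).sum()),
                       genomes_per_run=cfg.genomes_per_run,
                       interval_bp=cfg.interval_bp,
                       detectable_fraction=cfg.detectable_fraction)
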