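"""Population recombination-rate estimation and crossover detection.

Three layers:

* the **four-gamete rule** and the Hudson–Kaplan lower bound ``Rm`` on the
  number of recombination events in a sample,
* a **PAC (product of approximate conditionals) copying-model** estimator of
  the local population recombination rate: each haplotype is modelled as an
  imperfect mosaic copy of the previously seen ones (Li–Stephens), with the
  copying-switch rate between adjacent SNPs proportional to the local rho;
  per-bin rates are maximised over a multiplier grid by coordinate ascent,
  with the likelihood averaged in log space over random haplotype orderings,
* unit conversion ``rho = 4 Ne r`` between the population-scaled rate and
  cM/Mb, plus hotspot classification against the ~0.89 cM/Mb genome average.

``rhohat`` for a bin is the segment-equivalent rate implied by the bin's
local per-bp intensity (intensity x segment length), so the per-bin profile
and the segment average ``rhobar`` share one scale: ``rhobar`` is the
bin-width-weighted mean of ``rhohat`` and equals the total rho of the
segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import _complete_matrix
from .formats_io import HaplotypePanel

GENOME_AVG_CMMB = 0.89
HOTSPOT_FOLD_RANGE = (10.0, 120.0)


# ---------------------------------------------------------------------------
# Four-gamete rule and Hudson–Kaplan Rm
# ---------------------------------------------------------------------------


def four_gamete(panel: HaplotypePanel, site_i: int, site_j: int,
                drop_incomplete: bool = False
                ) -> tuple[dict[str, int], bool]:
    """Census of the two-locus gamete types {00,01,10,11} and the
    incompatibility flag (True iff all four types are observed, implying
    recombination — or recurrent mutation — between the sites)."""
    sub = _complete_matrix(panel, [site_i, site_j], drop_incomplete)
    census = {"00": 0, "01": 0, "10": 0, "11": 0}
    for a, b in sub:
        census[f"{a}{b}"] += 1
    flag = all(v > 0 for v in census.values())
    return census, flag


@dataclass
class FourGameteReport:
    incompatible_pairs: list[tuple[int, int]]
    rm: int
    crossover_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        assert self.rm >= 0


def min_recomb_events(panel: HaplotypePanel,
                      drop_incomplete: bool = False) -> FourGameteReport:
    """Hudson–Kaplan minimum number of recombination events.

    Every four-gamete-incompatible site pair requires a crossover strictly
    between the sites; the minimum number of crossovers covering all such
    intervals is found by the greedy earliest-right-endpoint selection of
    disjoint intervals (optimal for interval point-cover).
    """
    sub = _complete_matrix(panel, list(range(panel.n_sites)),
                           drop_incomplete)
    S = sub.shape[1]
    incompat = []
    for i in range(S):
        for j in range(i + 1, S):
            pair = sub[:, i] * 2 + sub[:, j]
            if len(np.unique(pair)) == 4:
                incompat.append((i, j))
    chosen: list[tuple[int, int]] = []
    last_right = -1
    for i, j in sorted(incompat, key=lambda ij: ij[1]):
        if i >= last_right:
            chosen.append((i, j))
            last_right = j
    return FourGameteReport(incompat, len(chosen), chosen)


# ---------------------------------------------------------------------------
# PAC copying model
# ---------------------------------------------------------------------------


def _pac_loglik_matrix(H: np.ndarray, rho_intervals: np.ndarray,
                       orderings: np.ndarray) -> float:
    """Log PAC likelihood averaged (in log space) over haplotype orderings.

    ``H`` is (n, S) 0/1; ``rho_intervals`` the population rho between
    consecutive sites (length S-1); ``orderings`` an (O, n) array of
    permutations.  Scaled forward algorithm of the Li–Stephens copying
    model.
    """
    O, n = orderings.shape
    S = H.shape[1]
    Hord = H[orderings]  # (O, n, S)
    harmonic = np.cumsum(1.0 / np.arange(1, n + 1))
    stay_all = np.exp(-rho_intervals[None, :]
                      / np.arange(1, n, dtype=float)[:, None])  # (n-1, S-1)
    ll = np.zeros(O)
    for k in range(1, n):
        # emission probabilities for all sites at once
        theta_t = 1.0 / harmonic[k - 1]
        e_match = (k + 0.5 * theta_t) / (k + theta_t)
        e_mis = 0.5 * theta_t / (k + theta_t)
        match = Hord[:, :k, :] == Hord[:, k, None, :]
        E = (e_mis + (e_match - e_mis) * match).astype(np.float64)
        f = E[:, :, 0] / k
        c = f.sum(axis=1)
        lk = np.log(c)
        f /= c[:, None]
        stay = stay_all[k - 1]
        for j in range(1, S):
            f *= stay[j - 1]
            f += (1.0 - stay[j - 1]) / k
            f *= E[:, :, j]
            c = f.sum(axis=1)
            lk += np.log(c)
            f /= c[:, None]
        ll += lk
    # log-mean-exp across orderings
    m = ll.max()
    return float(m + np.log(np.mean(np.exp(ll - m))))


def pac_loglik(panel: HaplotypePanel, rho_intervals: np.ndarray,
               n_orderings: int = 20, seed: int | None = 0) -> float:
    """PAC log likelihood of a panel under per-interval rates
    ``rho_intervals`` (length n_sites - 1)."""
    H = _complete_matrix(panel, list(range(panel.n_sites)), False)
    rho_intervals = np.asarray(rho_intervals, dtype=float)
    if rho_intervals.shape != (panel.n_sites - 1,):
        raise ValueError("need one rho per adjacent-site interval")
    rng = np.random.default_rng(seed)
    orderings = np.array([rng.permutation(H.shape[0])
                          for _ in range(n_orderings)])
    return _pac_loglik_matrix(H, rho_intervals, orderings)


@dataclass
class RecombMap:
    """Per-bin rho profile.  ``rhohat`` is on segment scale per bin (see
    module docstring); ``rhobar`` is the width-weighted mean of ``rhohat``
    and equals the segment-total rho."""

    bin_edges: np.ndarray  # bp, length n_bins + 1, tiling the segment
    rhohat: np.ndarray
    rhobar: float
    ne: int = 10_000
    segment_length_bp: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_start": self.bin_edges[:-1].astype(int),
            "bin_end": self.bin_edges[1:].astype(int),
            "rhohat": self.rhohat,
        })
        df["cmmb"] = [rho_to_cmmb(r, self.segment_length_bp, self.ne)
                      for r in self.rhohat]
        return df

    def peak_bin(self) -> tuple[int, int]:
        """bp interval of the bin with the largest rhohat."""
        i = int(np.argmax(self.rhohat))
        return int(self.bin_edges[i]), int(self.bin_edges[i + 1])


def _make_bins(length_bp: int, bin_width: int) -> np.ndarray:
    """Tile [0, length] with ``bin_width`` bins; a trailing partial bin is
    merged into its neighbour."""
    edges = list(range(0, length_bp, bin_width)) + [length_bp]
    if len(edges) > 2 and edges[-1] - edges[-2] < bin_width:
        del edges[-2]
    return np.array(edges, dtype=float)


DEFAULT_BACKGROUND_GRID = tuple(float(2.0 ** e) for e in range(-1, 9))
DEFAULT_MULTIPLIER_GRID = (0.25, 1.0, 4.0, 16.0, 64.0)


def pac_rhomap(panel: HaplotypePanel, bin_width: int = 350,
               background_grid=DEFAULT_BACKGROUND_GRID,
               multiplier_grid=DEFAULT_MULTIPLIER_GRID,
               n_orderings: int = 20, n_sweeps: int = 1,
               seed: int | None = 0, ne: int = 10_000) -> RecombMap:
    """Maximum-PAC-likelihood per-bin recombination map.

    The fit is a two-stage grid search: first the best uniform segment-total
    rho from ``background_grid``, then coordinate ascent of per-bin
    multipliers over ``multiplier_grid`` (``n_sweeps`` sweeps).  The
    likelihood is averaged over ``n_orderings`` random haplotype orderings,
    fixed once per call, so the result is deterministic under a fixed seed.
    """
    H = _complete_matrix(panel, list(range(panel.n_sites)), False)
    poly = H.min(axis=0) != H.max(axis=0)
    if not poly.any():
        raise ValueError("all sites monomorphic; rho is unidentifiable")
    H = H[:, poly]
    positions = panel.snp_map.positions[poly].astype(float)
    lo, hi = panel.snp_map.segment_span
    L = int(hi - lo + 1)
    pos0 = positions - lo + 0.5  # site coordinates within [0, L)
    edges = _make_bins(L, bin_width)
    n_bins = len(edges) - 1
    S = H.shape[1]
    if S < 2:
        raise ValueError("need at least two polymorphic sites")
    # overlap (bp) of each adjacent-site interval with each bin
    W = np.zeros((S - 1, n_bins))
    for j in range(S - 1):
        a, b = pos0[j], pos0[j + 1]
        for bi in range(n_bins):
            W[j, bi] = max(0.0, min(b, edges[bi + 1]) - max(a, edges[bi]))
    rng = np.random.default_rng(seed)
    orderings = np.array([rng.permutation(H.shape[0])
                          for _ in range(n_orderings)])

    def loglik(rho0_per_bp: float, mult: np.ndarray) -> float:
        r = W @ (rho0_per_bp * mult)
        return _pac_loglik_matrix(H, r, orderings)

    mult = np.ones(n_bins)
    best_total, best_ll = None, -np.inf
    for total in background_grid:
        llv = loglik(total / L, mult)
        if llv > best_ll:
            best_total, best_ll = total, llv
    rho0 = best_total / L
    for _ in range(n_sweeps):
        for bi in range(n_bins):
            best_m, best_ll = mult[bi], loglik(rho0, mult)
            for m in multiplier_grid:
                if m == mult[bi]:
                    continue
                trial = mult.copy()
                trial[bi] = m
                llv = loglik(rho0, trial)
                if llv > best_ll:
                    best_m, best_ll = m, llv
            mult[bi] = best_m
    rhohat = rho0 * mult * L  # segment-equivalent rate per bin
    widths = np.diff(edges)
    rhobar = float(np.sum(rhohat * widths) / L)
    return RecombMap(edges, rhohat, rhobar, ne, L)


# ---------------------------------------------------------------------------
# Unit conversion and hotspot classification
# ---------------------------------------------------------------------------


def rho_to_cmmb(rho: float, length_bp: float, ne: int = 10_000) -> float:
    """Convert a segment-scale population rate to cM/Mb via
    ``rho = 4 Ne r``: r crossovers per segment per meiosis, then
    ``100 r / (length_bp 1e-6)`` cM/Mb."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    r = rho / (4.0 * ne)
    return 100.0 * r / (length_bp * 1e-6)


def classify_hotspot(rate_cmmb: float,
                     genome_avg: float = GENOME_AVG_CMMB
                     ) -> tuple[str, float]:
    """Fold-enrichment over the genome average and its class:
    ``below`` (< 10x), ``hotspot-range`` (10–120x) or ``above-range``."""
    if rate_cmmb < 0:
        raise ValueError("rate must be non-negative")
    fold = rate_cmmb / genome_avg
    lo, hi = HOTSPOT_FOLD_RANGE
    if fold < lo:
        cls = "below"
    elif fold <= hi:
        cls = "hotspot-range"
    else:
        cls = "above-range"
    return cls, float(fold)
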