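"""Sequence-diversity statistics and the Hd/theta sub-segment profile.

Haplotype diversity Hd (Nei's unbiased estimator), Watterson's theta and
nucleotide diversity pi over a haplotype panel or any subset of its sites.
The ratio Hd/theta serves as a first-approximation measure of recombination
strength relative to the mutational background: mutation raises both numbers,
recombination raises haplotype diversity only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import MISSING, HaplotypePanel, SnpMap, SUBSEGMENTS


def _resolve_sites(panel: HaplotypePanel,
                   region: Sequence[int] | Sequence[str] | str | None
                   ) -> list[int]:
    if region is None:
        return list(range(panel.n_sites))
    if isinstance(region, str):
        return panel.snp_map.subsegment_sites(region)
    region = list(region)
    if region and isinstance(region[0], str):
        return [panel.snp_map.index_of(lab) for lab in region]
    return [int(i) for i in region]


def _complete_matrix(panel: HaplotypePanel, sites: list[int],
                     drop_incomplete: bool) -> np.ndarray:
    sub = panel.matrix[:, sites]
    miss = (sub == MISSING).any(axis=1)
    if miss.any():
        if not drop_incomplete:
            raise ValueError("panel has missing genotypes over the region; "
                             "pass drop_incomplete=True to discard those "
                             "rows")
        sub = sub[~miss]
    return sub


def haplotype_diversity(panel: HaplotypePanel,
                        region=None, drop_incomplete: bool = False) -> float:
    """Nei's unbiased haplotype diversity ``Hd = n (1 - sum p_i^2) / (n-1)``
    over exact haplotype identity on the region's sites."""
    sites = _resolve_sites(panel, region)
    sub = _complete_matrix(panel, sites, drop_incomplete)
    n = sub.shape[0]
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 chromosomes")
    _, counts = np.unique(sub, axis=0, return_counts=True)
    p = counts / n
    return float(n * (1.0 - np.sum(p ** 2)) / (n - 1))


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def segregating_sites(panel: HaplotypePanel, region=None,
                      drop_incomplete: bool = False) -> int:
    sites = _resolve_sites(panel, region)
    sub = _complete_matrix(panel, sites, drop_incomplete)
    return int(np.sum(sub.min(axis=0) != sub.max(axis=0)))


def watterson_theta(panel: HaplotypePanel, region=None,
                    per_site: bool = False, length_bp: int | None = None,
                    drop_incomplete: bool = False) -> float:
    """Watterson's estimator ``theta_W = S / a_{n-1}``.

    Segment scale by default; ``per_site=True`` divides by the region's bp
    length (the positional span of the selected sites unless ``length_bp``
    overrides it).
    """
    sites = _resolve_sites(panel, region)
    sub = _complete_matrix(panel, sites, drop_incomplete)
    n = sub.shape[0]
    if n < 2:
        raise ValueError("theta_W needs at least 2 chromosomes")
    S = int(np.sum(sub.min(axis=0) != sub.max(axis=0)))
    theta = S / _harmonic(n)
    if per_site:
        if length_bp is None:
            if not sites:
                raise ValueError("per-site theta over a zero-length region")
            pos = panel.snp_map.positions[sites]
            length_bp = int(pos.max() - pos.min() + 1)
        if length_bp <= 0:
            raise ValueError("per-site theta over a zero-length region")
        theta /= length_bp
    return float(theta)


def nucleotide_diversity(panel: HaplotypePanel, region=None,
                         per_site: bool = False,
                         length_bp: int | None = None,
                         drop_incomplete: bool = False) -> float:
    """Mean pairwise difference pi over all chromosome pairs.

    Computed from per-site allele counts: a site with j derived copies
    contributes ``j (n - j)`` mismatching pairs.
    """
    sites = _resolve_sites(panel, region)
    sub = _complete_matrix(panel, sites, drop_incomplete)
    n = sub.shape[0]
    if n < 2:
        raise ValueError("pi needs at least 2 chromosomes")
    j = sub.sum(axis=0)
    pi = float(np.sum(j * (n - j)) / (n * (n - 1) / 2))
    if per_site:
        if length_bp is None:
            if not sites:
                raise ValueError("per-site pi over a zero-length region")
            pos = panel.snp_map.positions[sites]
            length_bp = int(pos.max() - pos.min() + 1)
        if length_bp <= 0:
            raise ValueError("per-site pi over a zero-length region")
        pi /= length_bp
    return float(pi)


@dataclass
class DiversityProfile:
    """Per-region diversity records plus the whole-segment row."""

    table: pd.DataFrame  # region, n, S, Hd, theta_W, pi, hd_theta_ratio

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.table.to_string(index=False)


def hd_theta_profile(panel: HaplotypePanel,
                     snp_map: SnpMap | None = None,
                     drop_incomplete: bool = False) -> DiversityProfile:
    """Hd, theta_W, pi and the Hd/theta ratio per sub-segment.

    theta_W enters the ratio on segment scale (per sub-segment), which keeps
    Hd/theta dimensionless and comparable across sub-segments of unequal bp
    length; per-site values can be recomputed via :func:`watterson_theta`.
    Regions with no segregating sites report an undefined (NaN) ratio.
    """
    snp_map = snp_map or panel.snp_map
    rows = []
    regions = [(name, snp_map.subsegment_sites(name)) for name in SUBSEGMENTS]
    regions.append(("Segment", list(range(snp_map.n_sites))))
    for name, sites in regions:
        if not sites:
            continue
        sub = _complete_matrix(panel, sites, drop_incomplete)
        n = sub.shape[0]
        S = int(np.sum(sub.min(axis=0) != sub.max(axis=0)))
        hd = haplotype_diversity(panel, sites, drop_incomplete)
        th = watterson_theta(panel, sites, drop_incomplete=drop_incomplete)
        pi = nucleotide_diversity(panel, sites,
                                  drop_incomplete=drop_incomplete)
        ratio = hd / th if th > 0 else float("nan")
        rows.append({"region": name, "n": n, "S": S, "Hd": hd,
                     "theta_W": th, "pi": pi, "hd_theta_ratio": ratio})
    return DiversityProfile(pd.DataFrame(rows))
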