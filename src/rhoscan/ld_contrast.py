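"""Pairwise LD (r^2) matrices and the permutation LD-contrast test.

``r^2`` between two biallelic sites is the squared Pearson correlation of
their 0/1 haplotype codes.  The LD-contrast test compares the haplotype
correlation matrices of two cohorts over a window of sites with a squared
Frobenius distance statistic; significance comes from permuting cohort labels
over the pooled chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import _complete_matrix, _resolve_sites
from .formats_io import HaplotypePanel


# ---------------------------------------------------------------------------
# r^2
# ---------------------------------------------------------------------------


def ld_r2(panel: HaplotypePanel, site_i: int | str, site_j: int | str,
          drop_incomplete: bool = False) -> float:
    """``r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B))`` from phased
    haplotype counts; NaN when either site is monomorphic."""
    sites = _resolve_sites(panel, [site_i, site_j])
    sub = _complete_matrix(panel, sites, drop_incomplete)
    a, b = sub[:, 0].astype(float), sub[:, 1].astype(float)
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        return float("nan")
    pab = np.mean(a * b)
    return float((pab - pa * pb) ** 2 / (va * vb))


@dataclass
class LdMatrix:
    labels: tuple[str, ...]
    r2: np.ndarray  # symmetric; NaN where undefined
    n_chromosomes: int
    low_ld_points: list[tuple[str, str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.labels, columns=self.labels)


def ld_matrix(panel: HaplotypePanel, low_ld_threshold: float = 0.1,
              drop_incomplete: bool = False) -> LdMatrix:
    """Full pairwise r^2 matrix plus the list of low-LD points (defined
    entries below ``low_ld_threshold``, the red-point reading of a thermal
    LD plot)."""
    if panel.n_chromosomes < 2:
        raise ValueError("LD matrix needs at least 2 chromosomes")
    sites = list(range(panel.n_sites))
    sub = _complete_matrix(panel, sites, drop_incomplete).astype(float)
    S = sub.shape[1]
    p = sub.mean(axis=0)
    var = p * (1 - p)
    poly = var > 0
    r2 = np.full((S, S), np.nan)
    if poly.any():
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub[:, poly], rowvar=False)
        corr = np.atleast_2d(corr)
        idx = np.nonzero(poly)[0]
        r2[np.ix_(idx, idx)] = corr ** 2
    np.fill_diagonal(r2, np.where(poly, 1.0, np.nan))
    labels = panel.snp_map.labels
    low = [(labels[i], labels[j], float(r2[i, j]))
           for i in range(S) for j in range(i + 1, S)
           if np.isfinite(r2[i, j]) and r2[i, j] < low_ld_threshold]
    return LdMatrix(labels, r2, sub.shape[0], low)


# ---------------------------------------------------------------------------
# D/N haplotype split
# ---------------------------------------------------------------------------


def split_by_tag_allele(panel: HaplotypePanel, tag_site: int | str
                        ) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Partition a panel by the allele carried at a tag SNP.

    Returns ``(derived-group, ancestral-group)`` — the D/N haplotype split.
    """
    [j] = _resolve_sites(panel, [tag_site])
    col = panel.matrix[:, j]
    if col.min() == col.max():
        raise ValueError("tag site is monomorphic; cannot split")
    derived = panel.take_rows(np.nonzero(col == 1)[0])
    ancestral = panel.take_rows(np.nonzero(col == 0)[0])
    return derived, ancestral


# ---------------------------------------------------------------------------
# LD contrast
# ---------------------------------------------------------------------------


@dataclass
class LdContrastResult:
    region: tuple[int, int]
    statistic: float
    n_perm: int
    p_value: float


def _corr_matrix(sub: np.ndarray) -> np.ndarray:
    """Haplotype correlation matrix with zero-variance sites contributing
    zero correlation (a monomorphic site carries no LD signal)."""
    sd = sub.std(axis=0)
    ok = sd > 0
    S = sub.shape[1]
    corr = np.zeros((S, S))
    if ok.sum() >= 2:
        c = np.corrcoef(sub[:, ok], rowvar=False)
        corr[np.ix_(np.nonzero(ok)[0], np.nonzero(ok)[0])] = c
    np.fill_diagonal(corr, 1.0)
    return corr


def ld_contrast_stat(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Squared Frobenius distance between the two groups' correlation
    matrices, summed over site pairs i < j."""
    d = _corr_matrix(mat_a) - _corr_matrix(mat_b)
    iu = np.triu_indices(d.shape[0], k=1)
    return float(np.sum(d[iu] ** 2))


def ld_contrast_test(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                     region: tuple[int, int], n_perm: int = 10_000,
                     seed: int | None = None,
                     drop_incomplete: bool = False) -> LdContrastResult:
    """Permutation contrast of LD structure between two cohorts over the
    site window ``region = (i, j)`` (inclusive site indices).

    The null distribution permutes cohort labels over the pooled
    chromosomes; ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    i, j = region
    if j - i + 1 < 2:
        raise ValueError("contrast region must span at least 2 sites")
    sites = list(range(i, j + 1))
    a = _complete_matrix(panel_a, sites, drop_incomplete).astype(float)
    b = _complete_matrix(panel_b, sites, drop_incomplete).astype(float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both cohorts need at least 2 chromosomes")
    obs = ld_contrast_stat(a, b)
    # canonical pooled order + fixed split size make the permutation null
    # exactly invariant to swapping the two groups
    pooled = np.vstack([a, b])
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n_split = max(a.shape[0], b.shape[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null = ld_contrast_stat(pooled[perm[:n_split]],
                                pooled[perm[n_split:]])
        if null >= obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return LdContrastResult((i, j), obs, n_perm, p)


def ld_contrast_exhaustive(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                           n_perm: int = 10_000, seed: int | None = None,
                           drop_incomplete: bool = False) -> pd.DataFrame:
    """Contrast every region flanked by two SNPs (all i < j windows).

    Returns a grid with the raw permutation p per region, significance bands
    at 0.05 and 0.01 (the paper-style reading), and a Bonferroni-adjusted
    column for reference (no correction is applied to the bands themselves).
    """
    S = panel_a.n_sites
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(S):
        for j in range(i + 1, S):
            res = ld_contrast_test(
                panel_a, panel_b, (i, j), n_perm=n_perm,
                seed=int(rng.integers(2 ** 31)),
                drop_incomplete=drop_incomplete)
            rows.append({"i": i, "j": j, "stat": res.statistic,
                         "p": res.p_value})
    df = pd.DataFrame(rows)
    m = len(df)
    df["band"] = np.select([df["p"] <= 0.01, df["p"] <= 0.05],
                           ["p<=0.01", "p<=0.05"], default="ns")
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
    return df
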