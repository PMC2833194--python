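"""Case-control haplotype association tests on 2x2 carrier tables.

Each haplotype form is tested carrier-vs-rest between two cohorts of phased
chromosomes (counts out of total chromosomes, i.e. 2x the subject count).
Three tests are provided:

* Pearson chi-square (uncorrected, df = 1),
* G-test (likelihood-ratio chi-square, ``G = 2 sum O ln(O/E)``, df = 1),
* a one-sided Poisson deficit test: the count in the higher-frequency group
  is scaled to the other group's chromosome total to give lambda, and the
  lower count is referred to the lower tail of Poisson(lambda).

A haplotype is *protective* when its frequency is higher among controls than
cases, *risk* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplo_network import HaplotypeSpectrum


@dataclass(frozen=True)
class HaploCountTable:
    """Carrier counts of one haplotype in two groups of chromosomes.

    Group 1 is conventionally the control (CN) cohort and group 2 the case
    (SZ) cohort.
    """

    label: str
    count1: int
    total1: int
    count2: int
    total2: int

    def __post_init__(self) -> None:
        if self.total1 <= 0 or self.total2 <= 0:
            raise ValueError("totals must be positive")
        if not (0 <= self.count1 <= self.total1
                and 0 <= self.count2 <= self.total2):
            raise ValueError("counts must lie within totals")

    def cells(self) -> np.ndarray:
        return np.array([[self.count1, self.total1 - self.count1],
                         [self.count2, self.total2 - self.count2]],
                        dtype=float)

    @property
    def direction(self) -> str:
        f1 = self.count1 / self.total1
        f2 = self.count2 / self.total2
        return "protective" if f1 > f2 else "risk"


@dataclass
class AssocResult:
    label: str
    p_pearson: float
    p_lrt: float
    p_poisson: float
    direction: str
    poisson_lambda: float


def _expected(obs: np.ndarray) -> np.ndarray:
    r = obs.sum(axis=1, keepdims=True)
    c = obs.sum(axis=0, keepdims=True)
    return r * c / obs.sum()


def pearson_chi2(table: HaploCountTable) -> float:
    """Two-sided p from the uncorrected Pearson chi-square statistic on the
    2x2 carrier table (df = 1); NaN when a margin is zero."""
    obs = table.cells()
    exp = _expected(obs)
    if (exp == 0).any():
        return float("nan")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(stat, df=1))


def g_test(table: HaploCountTable) -> float:
    """Likelihood-ratio chi-square ``G = 2 sum O ln(O/E)`` with the
    ``0 ln 0 = 0`` convention (df = 1)."""
    obs = table.cells()
    exp = _expected(obs)
    if (exp == 0).any():
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = float(2.0 * terms.sum())
    return float(stats.chi2.sf(g, df=1))


def poisson_deficit_test(table: HaploCountTable) -> tuple[float, float]:
    """One-sided Poisson test of the deficit in the lower-frequency group.

    lambda = (count in the higher-frequency group) x (chromosomes in the
    lower-count group / chromosomes in the higher-count group); the observed
    low count is referred to P(X <= observed | Poisson(lambda)).  Returns
    ``(p, lambda)``.  Unlike the chi-square tests this construction is not
    symmetric in the two groups.
    """
    f1 = table.count1 / table.total1
    f2 = table.count2 / table.total2
    if table.count1 == 0 and table.count2 == 0:
        return 1.0, 0.0
    if f1 >= f2:
        hi_count, hi_total, lo_count, lo_total = (
            table.count1, table.total1, table.count2, table.total2)
    else:
        hi_count, hi_total, lo_count, lo_total = (
            table.count2, table.total2, table.count1, table.total1)
    lam = hi_count * lo_total / hi_total
    p = float(stats.poisson.cdf(lo_count, lam)) if lam > 0 else 1.0
    return p, float(lam)


def evaluate_table(table: HaploCountTable) -> AssocResult:
    """All three tests on one carrier table."""
    p_p, lam = poisson_deficit_test(table)
    return AssocResult(table.label, pearson_chi2(table), g_test(table),
                       p_p, table.direction, lam)


def carrier_percentage(n_carriers: int, n_subjects: int) -> float:
    """Subjects carrying a haplotype, as a percentage of the cohort."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    return 100.0 * n_carriers / n_subjects


def screen_haplotypes(spectrum1: HaplotypeSpectrum,
                      spectrum2: HaplotypeSpectrum,
                      min_count: int = 3) -> pd.DataFrame:
    """Test every haplotype form with >= ``min_count`` total copies.

    Frequencies come from two cohort spectra over the same site set; results
    are sorted by the Pearson p and annotated with direction and a Sidak
    multiple-testing column (the per-table p values remain raw).
    """
    c1 = dict(zip(spectrum1.table["haplotype"], spectrum1.table["count"]))
    c2 = dict(zip(spectrum2.table["haplotype"], spectrum2.table["count"]))
    n1, n2 = spectrum1.n_chromosomes, spectrum2.n_chromosomes
    rows = []
    for hap in sorted(set(c1) | set(c2)):
        k1, k2 = c1.get(hap, 0), c2.get(hap, 0)
        if k1 + k2 < min_count:
            continue
        table = HaploCountTable(hap, k1, n1, k2, n2)
        res = evaluate_table(table)
        rows.append({"haplotype": hap, "count1": k1, "total1": n1,
                     "count2": k2, "total2": n2,
                     "p_pearson": res.p_pearson, "p_lrt": res.p_lrt,
                     "p_poisson": res.p_poisson,
                     "direction": res.direction,
                     "poisson_lambda": res.poisson_lambda})
    df = pd.DataFrame(rows, columns=[
        "haplotype", "count1", "total1", "count2", "total2", "p_pearson",
        "p_lrt", "p_poisson", "direction", "poisson_lambda"])
    if len(df):
        m = len(df)
        df["p_sidak"] = 1.0 - (1.0 - df["p_pearson"]) ** m
        df = df.sort_values("p_pearson", kind="mergesort",
                            na_position="last").reset_index(drop=True)
    else:
        df["p_sidak"] = pd.Series(dtype=float)
    return df
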