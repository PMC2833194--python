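"""Crossover-rate estimation from single-molecule sperm/somatic typing.

Two experimental designs are supported:

* **clone design** — PCR products from a sperm (or somatic) sample are cloned
  and individually haplotyped over a few marker SNPs; clones are classified
  against the two parental haplotypes, and the crossover fraction is the
  frequency of the more abundant minor (recombinant) form,
* **pool design** — allele-specific PCR runs on pools of roughly 100
  amplifiable genomes score positive when at least one detectable recombinant
  molecule is present; the per-molecule recombinant fraction is recovered
  either naively (positives over total genomes screened) or with a Poisson
  correction for multiple recombinants per positive pool.

Rates are expressed in cM/Mb (1 cM/Mb = 1e-8 crossovers per bp per meiosis).
Because an allele-specific design captures only one of the two reciprocal
recombinant product classes, the observed fraction is multiplied by a
``reciprocal_factor`` (default 2) before conversion to genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class AssayCounts:
    """Sperm-typing observations for either design.

    Clone design: ``clone_counts`` maps marker-haplotype strings (one letter
    or digit per marker, e.g. ``"GCC"``) to clone counts; ``parental`` holds
    the two non-recombinant haplotypes (inferred as the two most frequent
    clone classes when omitted).  Pool design: ``n_runs``, ``positives`` and
    ``genomes_per_run``.
    """

    design: str  # "clone" | "pool"
    interval_bp: int = 1000
    detectable_fraction: float = 1.0
    # clone design
    clone_counts: dict[str, int] = field(default_factory=dict)
    parental: tuple[str, str] | None = None
    # pool design
    n_runs: int = 0
    positives: int = 0
    genomes_per_run: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("clone", "pool"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "pool":
            if self.positives > self.n_runs:
                raise ValueError("positives exceed number of runs")
            if self.positives < 0 or self.n_runs < 0:
                raise ValueError("counts must be non-negative")
        else:
            if any(c < 0 for c in self.clone_counts.values()):
                raise ValueError("clone counts must be non-negative")
            if self.parental is not None and \
                    self.parental[0] == self.parental[1]:
                raise ValueError("parental haplotypes must be distinct")


@dataclass(frozen=True)
class RateEstimate:
    """Point estimate with a 95% confidence interval, all in cM/Mb."""

    rate_cmmb: float
    distance_cm: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.rate_cmmb
                <= self.ci_high + 1e-12):
            raise ValueError("interval does not contain the point estimate")


# ---------------------------------------------------------------------------
# Clone classification
# ---------------------------------------------------------------------------


def _infer_parentals(clone_counts: Mapping[str, int]) -> tuple[str, str]:
    ranked = sorted(clone_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < 2:
        raise ValueError("cannot infer two parental haplotypes from fewer "
                         "than two clone classes")
    return ranked[0][0], ranked[1][0]


def call_clone_classes(clones: Sequence[str] | Mapping[str, int],
                       parental: tuple[str, str] | None = None
                       ) -> dict[str, tuple[str, tuple[int, int] | None]]:
    """Classify clone haplotypes as parental / recombinant / other.

    A clone is *recombinant* when it can be written as a single crossover
    between the two parental haplotypes; the reported interval is the pair of
    marker indices flanking the switch (informative markers only, widened to
    the nearest informative markers when the switch position is ambiguous).
    Clones needing two or more switches, or carrying an allele absent from
    both parentals, are *other*.
    """
    if not isinstance(clones, Mapping):
        clones = {c: 1 for c in clones}
    if parental is None:
        parental = _infer_parentals(clones)
    p1, p2 = parental
    if p1 == p2:
        raise ValueError("parental haplotypes must be distinct")
    m = len(p1)
    if len(p2) != m:
        raise ValueError("parental haplotypes differ in length")
    informative = [i for i in range(m) if p1[i] != p2[i]]
    out: dict[str, tuple[str, tuple[int, int] | None]] = {}
    for clone in clones:
        if len(clone) != m:
            raise ValueError(f"clone {clone!r} length differs from parentals")
        if clone == p1 or clone == p2:
            out[clone] = ("parental", None)
            continue
        ok = all(clone[i] in (p1[i], p2[i]) for i in range(m))
        pattern = [0 if clone[i] == p1[i] else 1 for i in informative]
        switches = sum(a != b for a, b in zip(pattern[:-1], pattern[1:]))
        if ok and switches == 1:
            k = next(i for i in range(len(pattern) - 1)
                     if pattern[i] != pattern[i + 1])
            out[clone] = ("recombinant",
                          (informative[k], informative[k + 1]))
        else:
            out[clone] = ("other", None)
    return out


# ---------------------------------------------------------------------------
# Rate estimators
# ---------------------------------------------------------------------------


def _clopper_pearson(k: int, n: int, alpha: float = 0.05
                     ) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _to_cmmb(fraction: float, interval_bp: int) -> float:
    # genetic distance (cM) = 100 * fraction; rate = distance / (bp * 1e-6)
    return 100.0 * fraction / (interval_bp * 1e-6)


def clone_rate_estimate(counts: AssayCounts) -> RateEstimate:
    """Crossover rate from clone counts.

    The genetic distance between the two crossed-over markers is taken from
    the frequency of the more abundant of the minor (recombinant) forms; the
    binomial Clopper–Pearson interval on that count is propagated to cM/Mb.
    With zero recombinants the point estimate is 0 with a one-sided upper
    bound.
    """
    if counts.design != "clone":
        raise ValueError("clone_rate_estimate needs a clone-design assay")
    parental = counts.parental or _infer_parentals(counts.clone_counts)
    classes = call_clone_classes(counts.clone_counts, parental)
    total = sum(counts.clone_counts.values())
    if total == 0:
        raise ValueError("no clones")
    rec_counts = sorted((counts.clone_counts[c]
                         for c, (kind, _) in classes.items()
                         if kind == "recombinant"), reverse=True)
    k = rec_counts[0] if rec_counts else 0
    f = k / total
    lo, hi = _clopper_pearson(k, total)
    return RateEstimate(rate_cmmb=_to_cmmb(f, counts.interval_bp),
                        distance_cm=100.0 * f,
                        ci_low=_to_cmmb(lo, counts.interval_bp),
                        ci_high=_to_cmmb(hi, counts.interval_bp),
                        method="clone")


def pool_rate_estimate(counts: AssayCounts, poisson_correction: bool = True,
                       reciprocal_factor: float = 2.0) -> RateEstimate:
    """Crossover rate from positive/total pooled PCR runs.

    Naive: per-genome detectable fraction ``positives / (runs * genomes)``.
    Poisson-corrected: ``-ln(1 - positives/runs) / genomes`` accounts for
    pools holding more than one recombinant molecule.  Either estimate is
    multiplied by ``reciprocal_factor`` (the allele-specific design sees only
    one of the two reciprocal recombinant classes) before conversion.
    """
    if counts.design != "pool":
        raise ValueError("pool_rate_estimate needs a pool-design assay")
    if counts.n_runs <= 0 or counts.genomes_per_run <= 0:
        raise ValueError("runs and genomes_per_run must be positive")
    x = counts.positives / counts.n_runs
    if poisson_correction and counts.positives == counts.n_runs:
        raise ValueError("all runs positive: Poisson-corrected rate is "
                         "undefined (saturated design)")

    def per_genome(run_fraction: float) -> float:
        if poisson_correction:
            return -np.log1p(-run_fraction) / counts.genomes_per_run
        return run_fraction / counts.genomes_per_run

    f = reciprocal_factor * per_genome(x)
    lo, hi = _clopper_pearson(counts.positives, counts.n_runs)
    if poisson_correction and hi >= 1.0:
        hi = 1.0 - 0.5 / counts.n_runs  # keep the transform finite
    f_lo = reciprocal_factor * per_genome(lo)
    f_hi = reciprocal_factor * per_genome(hi)
    method = "pool-poisson" if poisson_correction else "pool-naive"
    return RateEstimate(rate_cmmb=_to_cmmb(f, counts.interval_bp),
                        distance_cm=100.0 * f,
                        ci_low=_to_cmmb(f_lo, counts.interval_bp),
                        ci_high=_to_cmmb(f_hi, counts.interval_bp),
                        method=method)
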