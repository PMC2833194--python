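"""Shared data model and I/O for SNP maps, haplotype panels and cohort metadata.

The package analyses phased haplotypes over a small ordered SNP panel (a few
kilobases, a few dozen biallelic sites).  Three containers are shared by every
analysis module:

* :class:`SnpMap` — the ordered site catalogue with chromosomal positions,
  ancestral/derived allele polarity and sub-segment labels,
* :class:`HaplotypePanel` — a chromosomes × sites matrix of 0/1 codes
  (0 = ancestral, 1 = derived, ``-1`` = missing) with per-chromosome cohort
  metadata,
* :class:`CohortSelector` — a population/phenotype/sex filter.

External coordinates are 1-based inclusive (the convention of genome-browser
style captions); any half-open arithmetic is confined to this module.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBSEGMENTS = ("PreAlu", "Alu", "PostAlu", "PostExon")

#: matrix code for a missing genotype
MISSING = -1

META_COLUMNS = ("individual", "chromosome", "population", "phenotype", "sex")

POPULATIONS = ("GE", "US", "JP", "AF")
PHENOTYPES = ("CN", "SZ")
SEXES = ("M", "F")


class FormatError(ValueError):
    """Malformed input file or inconsistent data model."""


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpEntry:
    label: str
    rs_id: str
    position: int  # 1-based bp on the chromosome
    ancestral: str
    derived: str
    subsegment: str


@dataclass(frozen=True)
class SnpMap:
    """Ordered catalogue of the segment's SNPs.

    ``segment_span`` is 1-based inclusive; all site positions must fall inside
    it and be strictly increasing.
    """

    entries: tuple[SnpEntry, ...]
    segment_span: tuple[int, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        prev = None
        lo, hi = self.segment_span
        if hi < lo:
            raise FormatError(f"segment span {self.segment_span} is inverted")
        for i, e in enumerate(self.entries):
            row = f"row {i + 1} ({e.label})"
            if e.label in seen:
                raise FormatError(f"duplicate SNP label in {row}")
            seen.add(e.label)
            if prev is not None and e.position <= prev:
                raise FormatError(f"non-monotone position in {row}: "
                                  f"{e.position} after {prev}")
            prev = e.position
            if not lo <= e.position <= hi:
                raise FormatError(f"position outside segment span in {row}")
            if e.ancestral == e.derived:
                raise FormatError(f"ancestral allele equals derived in {row}")
            if e.subsegment not in SUBSEGMENTS:
                raise FormatError(
                    f"unknown sub-segment {e.subsegment!r} in {row}")

    # -- convenience views ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=np.int64)

    @property
    def length_bp(self) -> int:
        lo, hi = self.segment_span
        return hi - lo + 1

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no SNP labelled {label!r}") from None

    def subsegment_sites(self, name: str) -> list[int]:
        """Site indices belonging to a named sub-segment."""
        if name not in SUBSEGMENTS:
            raise KeyError(f"unknown sub-segment {name!r}")
        return [i for i, e in enumerate(self.entries) if e.subsegment == name]

    def subsegment_length_bp(self, name: str) -> int:
        """bp span covered by a sub-segment's sites (first to last, inclusive)."""
        idx = self.subsegment_sites(name)
        if not idx:
            return 0
        pos = self.positions
        return int(pos[idx[-1]] - pos[idx[0]] + 1)


_MAP_COLUMNS = ("label", "rs_id", "position", "ancestral", "derived",
                "subsegment")


def read_snp_map(path: str | Path) -> SnpMap:
    """Read a SNP map from a tab-separated file.

    Columns: label, rs_id, position, ancestral, derived, subsegment.  A header
    comment ``#span=<start>-<end>`` fixes the segment span; otherwise the span
    defaults to the first/last site position.
    """
    path = Path(path)
    span = None
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#span="):
            a, _, b = line[len("#span="):].partition("-")
            span = (int(a.replace(",", "")), int(b.replace(",", "")))
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                         dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty SNP map file: {path}") from None
    if df.empty:
        raise FormatError(f"empty SNP map file: {path}")
    missing = set(_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"SNP map {path} lacks columns {sorted(missing)}")
    entries = []
    for _, r in df.iterrows():
        try:
            pos = int(str(r["position"]).replace(",", ""))
        except ValueError:
            raise FormatError(
                f"bad position {r['position']!r} for {r['label']}") from None
        entries.append(SnpEntry(str(r["label"]), str(r["rs_id"]), pos,
                                str(r["ancestral"]), str(r["derived"]),
                                str(r["subsegment"])))
    if span is None:
        span = (entries[0].position, entries[-1].position)
    return SnpMap(tuple(entries), span)


def write_snp_map(snp_map: SnpMap, path: str | Path) -> None:
    lo, hi = snp_map.segment_span
    with open(path, "w") as fh:
        fh.write(f"#span={lo}-{hi}\n")
        fh.write("\t".join(_MAP_COLUMNS) + "\n")
        for e in snp_map.entries:
            fh.write(f"{e.label}\t{e.rs_id}\t{e.position}\t{e.ancestral}\t"
                     f"{e.derived}\t{e.subsegment}\n")


def default_snp_map() -> SnpMap:
    """The bundled 29-SNP, 3,551-bp default map (chromosome 5q34).

    Only the segment span and a handful of rs identifiers are literature
    values; the remaining positions are evenly spaced placeholders marked as
    user-supplied in the bundled file.
    """
    with resources.files("rhoscan").joinpath("data/s1_s29_map.tsv").open() as fh:
        text = fh.read()
    span = None
    for line in text.splitlines():
        if line.startswith("#span="):
            a, _, b = line[len("#span="):].partition("-")
            span = (int(a), int(b))
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    entries = tuple(
        SnpEntry(r["label"], r["rs_id"], int(r["position"]), r["ancestral"],
                 r["derived"], r["subsegment"]) for _, r in df.iterrows())
    assert span is not None
    return SnpMap(entries, span)


# ---------------------------------------------------------------------------
# Cohort selector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSelector:
    """Optional population / phenotype / sex filters; empty selects all."""

    population: str | None = None
    phenotype: str | None = None
    sex: str | None = None

    def mask(self, meta: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(meta), dtype=bool)
        for col, val in (("population", self.population),
                         ("phenotype", self.phenotype), ("sex", self.sex)):
            if val is not None:
                m &= (meta[col] == val).to_numpy()
        return m


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased haplotypes coded against a :class:`SnpMap`.

    ``matrix`` holds one row per chromosome with codes 0 (ancestral),
    1 (derived) or :data:`MISSING`.  ``meta`` carries one row per chromosome
    with columns ``individual, chromosome, population, phenotype, sex``
    (unknown metadata is stored as missing, never dropped).
    """

    snp_map: SnpMap
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise FormatError("haplotype matrix must be 2-D")
        if self.matrix.shape[1] != self.snp_map.n_sites:
            raise FormatError(
                f"matrix has {self.matrix.shape[1]} columns but map has "
                f"{self.snp_map.n_sites} sites")
        if len(self.meta) != self.matrix.shape[0]:
            raise FormatError("metadata rows do not match matrix rows")
        bad = ~np.isin(self.matrix, (0, 1, MISSING))
        if bad.any():
            raise FormatError("haplotype codes must be 0, 1 or missing")
        self.meta = self.meta.reset_index(drop=True)

    # -- basics --------------------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(self.snp_map, self.matrix.copy(),
                              self.meta.copy())

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows without missing genotypes."""
        return ~(self.matrix == MISSING).any(axis=1)

    def haplotype_strings(self, sites: Sequence[int] | None = None
                          ) -> list[str]:
        """Rows as 0/1 strings over ``sites`` (default: all sites).

        Raises on missing data — statistics assume complete haplotypes.
        """
        sub = self.matrix if sites is None else self.matrix[:, list(sites)]
        if (sub == MISSING).any():
            raise FormatError("panel contains missing genotypes; drop "
                              "incomplete rows first")
        return ["".join("1" if v else "0" for v in row) for row in sub]

    def drop_incomplete(self) -> "HaplotypePanel":
        keep = self.complete_rows()
        return HaplotypePanel(self.snp_map, self.matrix[keep],
                              self.meta.loc[keep])

    def take_rows(self, idx: Iterable[int] | np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(list(idx) if not isinstance(idx, np.ndarray) else idx)
        return HaplotypePanel(self.snp_map, self.matrix[idx],
                              self.meta.iloc[idx])


def select_cohort(panel: HaplotypePanel,
                  sel: CohortSelector) -> HaplotypePanel:
    """Subset a panel by cohort; empty result warns rather than raising."""
    mask = sel.mask(panel.meta)
    if not mask.any():
        warnings.warn(f"cohort selection {sel} matched no chromosomes",
                      stacklevel=2)
    return HaplotypePanel(panel.snp_map, panel.matrix[mask],
                          panel.meta.loc[mask])


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-individual metadata TSV: individual, population, phenotype, sex."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "individual" not in df.columns:
        raise FormatError(f"metadata {path} lacks an 'individual' column")
    for col in ("population", "phenotype", "sex"):
        if col not in df.columns:
            df[col] = pd.NA
    return df.set_index("individual")


def _meta_for(individual: str, meta: pd.DataFrame | None) -> dict:
    rec = {"population": pd.NA, "phenotype": pd.NA, "sex": pd.NA}
    if meta is not None and individual in meta.index:
        row = meta.loc[individual]
        for k in rec:
            v = row.get(k, pd.NA)
            rec[k] = pd.NA if pd.isna(v) else v
    return rec


# ---------------------------------------------------------------------------
# Haplotype-matrix TSV dialect
# ---------------------------------------------------------------------------

# Tab-separated; id columns first, then one column per SNP label; one row per
# chromosome.  Missing genotypes written as ".".


def write_haplotypes(panel: HaplotypePanel, path: str | Path,
                     fmt: str | None = None) -> None:
    """Write a panel as haplotype TSV or phased VCF (by ``fmt`` or suffix)."""
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix.lower() == ".vcf" else "tsv")
    if fmt == "vcf":
        _write_vcf(panel, path)
        return
    cols = list(META_COLUMNS) + list(panel.snp_map.labels)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(panel.n_chromosomes):
            m = panel.meta.iloc[i]
            vals = [str(m["individual"]), str(m["chromosome"])]
            for c in ("population", "phenotype", "sex"):
                v = m[c]
                vals.append("." if pd.isna(v) else str(v))
            vals += ["." if v == MISSING else str(int(v))
                     for v in panel.matrix[i]]
            fh.write("\t".join(vals) + "\n")


def _read_haplotype_tsv(path: Path, snp_map: SnpMap,
                        meta: pd.DataFrame | None) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for lab in snp_map.labels:
        if lab not in df.columns:
            raise FormatError(f"haplotype table lacks column {lab}")
    n = len(df)
    matrix = np.full((n, snp_map.n_sites), MISSING, dtype=np.int8)
    for j, lab in enumerate(snp_map.labels):
        col = df[lab].to_numpy()
        for i, v in enumerate(col):
            if v == ".":
                continue
            if v not in ("0", "1"):
                raise FormatError(
                    f"bad haplotype code {v!r} at row {i + 1}, site {lab}")
            matrix[i, j] = int(v)
    rows = []
    for i, r in df.iterrows():
        ind = str(r.get("individual", f"H{i + 1}"))
        chrom = r.get("chromosome", "1")
        rec = {"individual": ind, "chromosome": int(chrom)}
        for c in ("population", "phenotype", "sex"):
            v = r.get(c, ".")
            if v in (".", None) or pd.isna(v):
                rec[c] = _meta_for(ind, meta)[c]
            else:
                rec[c] = v
        rows.append(rec)
    return HaplotypePanel(snp_map, matrix,
                          pd.DataFrame(rows, columns=list(META_COLUMNS)))


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


def _write_vcf(panel: HaplotypePanel, path: Path, chrom: str = "5") -> None:
    meta = panel.meta
    inds = list(dict.fromkeys(meta["individual"]))
    by_ind: dict[str, list[int]] = {k: [] for k in inds}
    for i, ind in enumerate(meta["individual"]):
        by_ind[ind].append(i)
    for ind, rows in by_ind.items():
        if len(rows) != 2:
            raise FormatError(
                f"VCF output needs diploid pairs; {ind} has {len(rows)} rows")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(inds) + "\n")
        for j, e in enumerate(panel.snp_map.entries):
            gts = []
            for ind in inds:
                a, b = by_ind[ind]
                def code(v: int) -> str:
                    return "." if v == MISSING else str(int(v))
                gts.append(f"{code(panel.matrix[a, j])}|"
                           f"{code(panel.matrix[b, j])}")
            fh.write(f"{chrom}\t{e.position}\t{e.rs_id}\t{e.ancestral}\t"
                     f"{e.derived}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def _read_vcf(path: Path, snp_map: SnpMap,
              meta: pd.DataFrame | None) -> HaplotypePanel:
    import pysam

    by_pos = {e.position: (j, e) for j, e in enumerate(snp_map.entries)}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        n = 2 * len(samples)
        matrix = np.full((n, snp_map.n_sites), MISSING, dtype=np.int8)
        for rec in vf:
            hit = by_pos.get(rec.pos)
            if hit is None:
                continue
            j, entry = hit
            alleles = rec.alleles
            for s_i, s in enumerate(samples):
                sample = rec.samples[s]
                gt = sample["GT"]
                if gt is None or len(gt) != 2:
                    raise FormatError(
                        f"sample {s} at {entry.label}: not a diploid call")
                if None not in gt and not sample.phased:
                    raise FormatError(
                        f"unphased genotype for sample {s} at {entry.label}")
                for k, g in enumerate(gt):
                    if g is None:
                        continue
                    allele = alleles[g]
                    if allele == entry.ancestral:
                        code = 0
                    elif allele == entry.derived:
                        code = 1
                    else:
                        raise FormatError(
                            f"allele {allele!r} at {entry.label} matches "
                            f"neither map allele for sample {s}")
                    matrix[2 * s_i + k, j] = code
    rows = []
    for s in samples:
        rec = _meta_for(s, meta)
        for k in (1, 2):
            rows.append({"individual": s, "chromosome": k, **rec})
    return HaplotypePanel(snp_map, matrix,
                          pd.DataFrame(rows, columns=list(META_COLUMNS)))


def read_haplotypes(path: str | Path, snp_map: SnpMap,
                    meta: pd.DataFrame | str | Path | None = None
                    ) -> HaplotypePanel:
    """Read a phased VCF or haplotype-matrix TSV into a panel.

    VCF REF/ALT alleles are remapped to the map's ancestral/derived polarity,
    so a site whose REF is the derived allele is code-inverted relative to its
    raw 0/1 genotype digits.
    """
    path = Path(path)
    if isinstance(meta, (str, Path)):
        meta = read_metadata(meta)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix.lower() == ".vcf":
        return _read_vcf(path, snp_map, meta)
    return _read_haplotype_tsv(path, snp_map, meta)
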