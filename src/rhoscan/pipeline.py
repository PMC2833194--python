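"""End-to-end orchestration: one config, all analyses, one output bundle.

A :class:`PipelineConfig` names either an input panel (haplotypes + SNP map
+ optional metadata) or a simulation block, a list of cohort selectors, and
per-module parameters.  :func:`run_pipeline` then produces, per cohort, the
diversity profile, LD matrix, PAC recombination map with hotspot
classification, median-joining network and haplotype spectrum, plus the
LD-contrast grid and haplotype association screen between a designated
cohort pair, and a JSON manifest of the parameters and seeds that suffice to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc_stats import screen_haplotypes
from .diversity import hd_theta_profile
from .formats_io import (CohortSelector, HaplotypePanel, default_snp_map,
                         read_haplotypes, read_metadata, read_snp_map,
                         select_cohort, write_haplotypes)
from .haplo_network import (build_mj_network, find_torsos,
                            haplotype_spectrum, place_ancestral_node,
                            recurrent_mutations, write_graphml)
from .ld_contrast import ld_contrast_exhaustive, ld_matrix
from .recomb_rate import classify_hotspot, pac_rhomap, rho_to_cmmb
from .synthetic_data import (Hotspot, RecombProfile, SimConfig,
                             simulate_panel_n_sites)

log = logging.getLogger("rhoscan.pipeline")


class StageError(RuntimeError):
    """Failure inside a named pipeline stage; partial outputs are kept."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class SimulationBlock:
    """Null-model demo cohorts: one neutral pool with a central hotspot,
    split at random into two phenotype groups."""

    n_group1: int = 190
    n_group2: int = 406
    n_sites: int = 29
    seq_length: int = 3551
    theta: float = 5.0
    hotspot_start: float = 1525.0
    hotspot_end: float = 2025.0
    hotspot_fold: float = 40.0
    population: str = "JP"
    sex: str = "M"


@dataclass
class PipelineConfig:
    # exactly one of (panel_path, ...) / simulation must be set
    panel_path: str | None = None
    map_path: str | None = None
    metadata_path: str | None = None
    simulation: SimulationBlock | None = None
    cohorts: list[dict] = field(default_factory=lambda: [
        {"name": "CN", "phenotype": "CN"},
        {"name": "SZ", "phenotype": "SZ"},
    ])
    contrast_pair: tuple[str, str] = ("CN", "SZ")
    output_dir: str = "rhoscan_out"
    # module parameters
    bin_width: int = 350
    ne: int = 10_000
    epsilon: int = 0
    rare_threshold: float = 0.01
    low_ld_threshold: float = 0.1
    n_perm: int = 10_000
    min_count: int = 3
    pac_orderings: int = 20
    pac_max_haplotypes: int | None = None
    # every random stage draws from an explicit seed
    seeds: dict = field(default_factory=lambda: {
        "simulate": 1, "pac": 2, "ldcontrast": 3, "subsample": 4})

    def validate(self) -> None:
        has_input = self.panel_path is not None
        has_sim = self.simulation is not None
        if has_input == has_sim:
            raise ValueError("config needs exactly one of an input panel "
                             "or a simulation block")
        if has_input and self.map_path is None:
            raise ValueError("an input panel needs a SNP map")
        for key in ("simulate", "pac", "ldcontrast", "subsample"):
            if key not in self.seeds:
                raise ValueError(f"missing explicit seed {key!r}")
        names = [c.get("name") for c in self.cohorts]
        if len(set(names)) != len(names) or None in names:
            raise ValueError("cohort selectors need unique names")
        for name in self.contrast_pair:
            if name not in names:
                raise ValueError(f"contrast cohort {name!r} not defined")


def config_to_yaml(cfg: PipelineConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["contrast_pair"] = list(cfg.contrast_pair)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("simulation") is not None:
        d["simulation"] = SimulationBlock(**d["simulation"])
    if "contrast_pair" in d:
        d["contrast_pair"] = tuple(d["contrast_pair"])
    cfg = PipelineConfig(**d)
    cfg.validate()
    return cfg


def make_demo_config(seed: int = 1,
                     output_dir: str = "rhoscan_demo") -> PipelineConfig:
    """A ready-to-run synthetic configuration sized like a re-sequencing
    study: 29 SNPs in 3,551 bp, a 40x central hotspot, and two cohorts of
    190 and 406 chromosomes drawn from one neutral pool (so they differ only
    by sampling noise)."""
    cfg = PipelineConfig(
        simulation=SimulationBlock(),
        output_dir=output_dir,
        n_perm=99,
        pac_max_haplotypes=100,
        seeds={"simulate": seed, "pac": seed + 1, "ldcontrast": seed + 2,
               "subsample": seed + 3},
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _load_or_simulate(cfg: PipelineConfig) -> HaplotypePanel:
    if cfg.panel_path is not None:
        snp_map = read_snp_map(cfg.map_path) if cfg.map_path else \
            default_snp_map()
        meta = read_metadata(cfg.metadata_path) if cfg.metadata_path else None
        return read_haplotypes(cfg.panel_path, snp_map, meta)
    sim = cfg.simulation
    n = sim.n_group1 + sim.n_group2
    sim_cfg = SimConfig(
        n_haplotypes=n, seq_length=sim.seq_length, theta=sim.theta,
        recomb=RecombProfile(hotspots=(
            Hotspot(sim.hotspot_start, sim.hotspot_end, sim.hotspot_fold),)),
        seed=cfg.seeds["simulate"])
    panel = simulate_panel_n_sites(sim_cfg, sim.n_sites,
                                   population=sim.population, sex=sim.sex)
    rng = np.random.default_rng(cfg.seeds["simulate"] + 10_007)
    phenotype = np.array(["SZ"] * n, dtype=object)
    phenotype[rng.choice(n, size=sim.n_group1, replace=False)] = "CN"
    meta = panel.meta.copy()
    meta["phenotype"] = phenotype
    return HaplotypePanel(panel.snp_map, panel.matrix, meta)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every analysis stage; returns a manifest dict (also written to
    ``manifest.json``).  Any stage failure raises :class:`StageError`;
    outputs of completed stages are retained."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "rhoscan_version": __version__,
        "seeds": dict(cfg.seeds),
        "parameters": {
            "bin_width": cfg.bin_width, "ne": cfg.ne,
            "epsilon": cfg.epsilon, "rare_threshold": cfg.rare_threshold,
            "low_ld_threshold": cfg.low_ld_threshold, "n_perm": cfg.n_perm,
            "min_count": cfg.min_count, "pac_orderings": cfg.pac_orderings,
            "pac_max_haplotypes": cfg.pac_max_haplotypes,
        },
        "cohorts": {},
    }

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage("input")
        panel = _load_or_simulate(cfg)
        if cfg.simulation is not None:
            write_haplotypes(panel, out / "panel.tsv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("input", str(exc)) from exc

    cohort_panels: dict[str, HaplotypePanel] = {}
    try:
        stage("select")
        for spec in cfg.cohorts:
            sel = CohortSelector(population=spec.get("population"),
                                 phenotype=spec.get("phenotype"),
                                 sex=spec.get("sex"))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = select_cohort(panel, sel)
            if sub.n_chromosomes == 0:
                raise ValueError(
                    f"cohort {spec['name']!r} matched no chromosomes")
            cohort_panels[spec["name"]] = sub
            manifest["cohorts"][spec["name"]] = {
                "n_chromosomes": sub.n_chromosomes}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("select", str(exc)) from exc

    try:
        stage("diversity")
        frames = []
        for name, sub in cohort_panels.items():
            prof = hd_theta_profile(sub).table
            prof.insert(0, "cohort", name)
            frames.append(prof)
        _write_tsv(pd.concat(frames, ignore_index=True),
                   out / "diversity.tsv")
    except Exception as exc:
        raise StageError("diversity", str(exc)) from exc

    try:
        stage("ld")
        for name, sub in cohort_panels.items():
            lm = ld_matrix(sub, low_ld_threshold=cfg.low_ld_threshold)
            _write_tsv(lm.to_frame().reset_index(names="site"),
                       out / f"ld_{name}.tsv")
            _write_tsv(pd.DataFrame(lm.low_ld_points,
                                    columns=["site_i", "site_j", "r2"]),
                       out / f"low_ld_points_{name}.tsv")
    except Exception as exc:
        raise StageError("ld", str(exc)) from exc

    try:
        stage("ldcontrast")
        a, b = cfg.contrast_pair
        grid = ld_contrast_exhaustive(cohort_panels[a], cohort_panels[b],
                                      n_perm=cfg.n_perm,
                                      seed=cfg.seeds["ldcontrast"])
        _write_tsv(grid, out / "ldcontrast.tsv")
    except Exception as exc:
        raise StageError("ldcontrast", str(exc)) from exc

    try:
        stage("recomb")
        rng = np.random.default_rng(cfg.seeds["subsample"])
        for name, sub in cohort_panels.items():
            fit = sub
            if (cfg.pac_max_haplotypes is not None
                    and sub.n_chromosomes > cfg.pac_max_haplotypes):
                take = np.sort(rng.choice(sub.n_chromosomes,
                                          size=cfg.pac_max_haplotypes,
                                          replace=False))
                fit = sub.take_rows(take)
            rmap = pac_rhomap(fit, bin_width=cfg.bin_width,
                              n_orderings=cfg.pac_orderings,
                              seed=cfg.seeds["pac"], ne=cfg.ne)
            _write_tsv(rmap.to_frame(), out / f"recomb_{name}.tsv")
            cmmb = rho_to_cmmb(rmap.rhobar, rmap.segment_length_bp, cfg.ne)
            cls, fold = classify_hotspot(cmmb)
            manifest["cohorts"][name].update(
                rhobar=rmap.rhobar, rate_cmmb=cmmb,
                hotspot_class=cls, fold=fold,
                pac_n_haplotypes=fit.n_chromosomes)
    except Exception as exc:
        raise StageError("recomb", str(exc)) from exc

    try:
        stage("network")
        spectra = {}
        for name, sub in cohort_panels.items():
            net = build_mj_network(sub, epsilon=cfg.epsilon)
            place_ancestral_node(net)
            write_graphml(net, out / f"network_{name}.graphml")
            spec = haplotype_spectrum(sub, cfg.rare_threshold)
            spectra[name] = spec
            _write_tsv(spec.table, out / f"spectrum_{name}.tsv")
            manifest["cohorts"][name].update(
                n_forms=spec.n_forms, rare_forms=spec.rare_forms,
                rare_share=spec.rare_share,
                n_torsos=len(find_torsos(net)),
                recurrent_snps=sorted(
                    lab for lab, c in recurrent_mutations(net).items()
                    if c > 1))
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    try:
        stage("assoc")
        a, b = cfg.contrast_pair
        screen = screen_haplotypes(spectra[a], spectra[b],
                                   min_count=cfg.min_count)
        _write_tsv(screen, out / "assoc.tsv")
    except Exception as exc:
        raise StageError("assoc", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
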