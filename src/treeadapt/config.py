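"""YAML configuration round-trip for simulation runs.

The config file mirrors the structure of :class:`engine.SimulationConfig`:
blocks for the trait architectures, site (by fixture name or explicit
values), stand statistics, phenology/growth/mortality constants, mating and
management.  Unspecified values fall back to the package defaults, so a
minimal config is just a seed and a horizon.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .climate import SiteClimate, load_sites
from .engine import SimulationConfig, default_architectures
from .genetics import TraitArchitecture
from .growth_mortality import GrowthParams, MortalityParams, StandStats
from .management import ManagementPlan
from .phenology import PhenologyParams
from .reproduction import MatingConfig

__all__ = ["load_config", "save_template", "config_from_dict", "config_to_dict"]

_ARCH_KEYS = ("n_loci", "heterozygosity", "trait_mean", "genetic_variance", "heritability")


def config_from_dict(d: dict) -> SimulationConfig:
    kw: dict = {}
    for key in ("base_seed", "years", "replicates", "plot_area_ha", "selection",
                "warming_offset", "frost_interval"):
        if key in d:
            kw[key] = d[key]
    if "site" in d:
        site = d["site"]
        if isinstance(site, str):
            kw["site"] = load_sites()[site]
        else:
            kw["site"] = SiteClimate(**site)
    if "stand" in d:
        kw["stand_stats"] = StandStats(**d["stand"])
    if "architectures" in d:
        archs = {}
        for name, spec in d["architectures"].items():
            archs[name] = TraitArchitecture.from_heterozygosity(
                name,
                n_loci=spec["n_loci"],
                heterozygosity=spec["heterozygosity"],
                trait_mean=spec["trait_mean"],
                genetic_variance=spec["genetic_variance"],
                heritability=spec["heritability"],
            )
        kw["architectures"] = archs
    if "phenology" in d:
        kw["phenology"] = PhenologyParams(**d["phenology"])
    if "growth" in d:
        kw["growth"] = GrowthParams(**d["growth"])
    if "mortality" in d:
        kw["mortality"] = MortalityParams(**d["mortality"])
    if "mating" in d:
        kw["mating"] = MatingConfig(**d["mating"])
    if "management" in d:
        m = d["management"]
        kw["plan"] = None if m in (None, "none") else ManagementPlan(**m)
    return SimulationConfig(**kw)


def config_to_dict(cfg: SimulationConfig) -> dict:
    archs = {}
    for name, a in cfg.architectures.items():
        archs[name] = {
            "n_loci": a.n_loci,
            "heterozygosity": a.heterozygosity_target,
            "trait_mean": a.trait_mean,
            "genetic_variance": a.genetic_variance,
            "heritability": a.heritability,
        }
    out = {
        "base_seed": cfg.base_seed,
        "years": cfg.years,
        "replicates": cfg.replicates,
        "plot_area_ha": cfg.plot_area_ha,
        "selection": cfg.selection,
        "warming_offset": cfg.warming_offset,
        "frost_interval": cfg.frost_interval,
        "site": cfg.site.name if cfg.site is not None else None,
        "stand": asdict(cfg.stand_stats),
        "architectures": archs,
        "phenology": asdict(cfg.phenology),
        "growth": asdict(cfg.growth),
        "mortality": asdict(cfg.mortality),
        "mating": asdict(cfg.mating),
        "management": asdict(cfg.plan) if cfg.plan is not None else None,
    }
    return out


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_template(path) -> None:
    """Write a fully populated template config with the package defaults."""
    cfg = SimulationConfig(architectures=default_architectures())
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
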