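"""Synthetic data with known generating parameters for every pipeline stage.

Provides a pure-birth ultrametric tree simulator, species traits evolving
with Brownian size and lambda-structured residuals around group-specific
allometric lines, and a specimen synthesizer that inverts the morphometric
formulas so that noise-free specimens reproduce the species targets exactly.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .morphometrics import (
    ECOTYPES,
    REGIONS,
    SpecimenRecord,
)
from .phylo import CovarianceFamily, Phylogeny

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "assign_ecotypes",
    "simulate_traits",
    "synthesize_specimens",
    "simulate_bundle",
    "write_bundle",
]

COMPONENT_TRAITS = ("head_ER", "cervical_AEI", "thoracic_AEI", "lumbar_AEI", "sacral_AEI")


@dataclass
class SimulationConfig:
    """Generating parameters; defaults mirror the study's group structure."""

    n_species: int = 87
    ecotype_sizes: tuple[int, ...] = (15, 11, 29, 32)
    ecotype_names: tuple[str, ...] = ECOTYPES
    clade_clustered: bool = True

    lambda_true: float = 0.8
    sigma: float = 0.05  # residual SD of ln shape
    size_bm_var: float = 0.3  # BM rate for ln size (tree depth 1)
    root_ln_size: float = math.log(60.0)

    # per-ecotype allometry of ln shape on ln size
    slopes: dict[str, float] = field(
        default_factory=lambda: {"chipmunk": 0.24, "gliding": 0.12, "ground": -0.11, "tree": -0.02}
    )
    intercepts: dict[str, float] = field(
        default_factory=lambda: {e: math.log(4.5) for e in ECOTYPES}
    )

    # component traits: shared intercepts (at root size), global slopes
    component_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "head_ER": math.log(2.4),
            "cervical_AEI": math.log(1.6),
            "thoracic_AEI": math.log(3.5),
            "lumbar_AEI": math.log(2.8),
            "sacral_AEI": math.log(1.2),
        }
    )
    component_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "head_ER": 0.18,
            "cervical_AEI": 0.22,
            "thoracic_AEI": 0.0,
            "lumbar_AEI": -0.09,
            "sacral_AEI": 0.0,
        }
    )
    component_sigma: float = 0.04

    # limbs: ln length ~ intercept + slope * (ln size - root)
    limb_intercepts: dict[str, float] = field(
        default_factory=lambda: {"forelimb_full": math.log(110.0), "hindlimb_full": math.log(120.0)}
    )
    limb_slopes: dict[str, float] = field(
        default_factory=lambda: {"forelimb_full": 1.0, "hindlimb_full": 1.0}
    )
    limb_sigma: float = 0.05
    limb_missing_frac: float = 0.1
    reduced_limb_frac: float = 0.6

    # specimen synthesis
    specimens_min: int = 1
    specimens_max: int = 5
    noise_cv: float = 0.03
    vertebral_counts: dict[str, int] = field(
        default_factory=lambda: {"cervical": 7, "thoracic": 12, "lumbar": 7, "sacral": 3}
    )
    head_frac: float = 0.25  # cranial length as a fraction of body length
    region_props: tuple[float, ...] = (0.15, 0.40, 0.30, 0.15)

    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(self.ecotype_sizes) != self.n_species:
            raise ValueError("ecotype sizes must sum to n_species")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")
        if min(self.sigma, self.component_sigma, self.limb_sigma, self.size_bm_var, self.noise_cv) < 0:
            raise ValueError("all SDs must be >= 0")
        if abs(sum(self.region_props) - 1.0) > 1e-9:
            raise ValueError("region proportions must sum to 1")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# tree simulation
# --------------------------------------------------------------------------

def simulate_tree(n_species: int, seed=None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, depth rescaled to 1, tips sp001..."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    birth: dict[int, float] = {}
    t = 0.0
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child()
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            child = node.new_child()
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    for node in active:
        node.edge.length = t_end - birth[id(node)]
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and t_end > 0:
            edge.length = edge.length / t_end
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(label=f"sp{i:03d}")
    return Phylogeny(tree)


def assign_ecotypes(tree: Phylogeny, config: SimulationConfig, seed=None) -> dict[str, str]:
    """Ecotype labels per tip: contiguous leaf-order blocks (clade-clustered)
    or a random assignment when ``clade_clustered`` is off."""
    rng = _rng(seed)
    taxa = tree.taxa
    order = list(taxa) if config.clade_clustered else [taxa[i] for i in rng.permutation(len(taxa))]
    out: dict[str, str] = {}
    pos = 0
    for name, size in zip(config.ecotype_names, config.ecotype_sizes):
        for sp in order[pos : pos + size]:
            out[sp] = name
        pos += size
    return out


# --------------------------------------------------------------------------
# trait simulation
# --------------------------------------------------------------------------

def _skeleton_base(
    hbER: float,
    head_ER: float,
    aeis: Mapping[str, float],
    body_size: float,
    config: SimulationConfig,
) -> dict:
    """Solve for noise-free measurements that hit the target statistics exactly.

    Regional body-length proportions and the head:body ratio are fixed
    nuisance choices; the overall scale is set so the 11-component geometric
    mean equals ``body_size``.
    """
    alpha = config.head_frac
    props = dict(zip(REGIONS, config.region_props))
    # at unit body length
    cran_l = alpha
    cran_h = alpha / head_ER
    region_l = {r: props[r] for r in REGIONS}
    region_h = {r: props[r] / aeis[r] for r in REGIONS}
    depth = (alpha + 1.0) / hbER
    comps = [cran_l, cran_h] + [region_l[r] for r in REGIONS] + [region_h[r] for r in REGIONS] + [depth]
    gm1 = math.exp(sum(math.log(c) for c in comps) / 11.0)
    B = body_size / gm1
    return {
        "cranial_length": cran_l * B,
        "cranial_height": cran_h * B,
        "region_length": {r: region_l[r] * B for r in REGIONS},
        "region_height": {r: region_h[r] * B for r in REGIONS},
        "body_depth": depth * B,
    }


def simulate_traits(
    tree: Phylogeny, config: SimulationConfig, seed=None
) -> tuple[pd.DataFrame, dict]:
    """Species trait table plus the truth record of generating parameters.

    ln size evolves by Brownian motion; ln shape and each component follow
    group/global allometric lines with multivariate-normal residuals whose
    covariance is ``sigma^2 * V(lambda_true)``.
    """
    rng = _rng(seed if seed is not None else config.seed)
    family = CovarianceFamily.from_tree(tree)
    taxa = family.taxa
    n = len(taxa)
    ecotypes = assign_ecotypes(tree, config, rng)
    eco = np.array([ecotypes[t] for t in taxa])

    L_bm = family.sqrt(1.0) * math.sqrt(config.size_bm_var)
    ln_size = config.root_ln_size + L_bm @ rng.standard_normal(n)
    centered = ln_size - config.root_ln_size

    L_lam = family.sqrt(config.lambda_true)
    a = np.array([config.intercepts[e] for e in eco])
    b = np.array([config.slopes[e] for e in eco])
    ln_hber = a + b * centered + config.sigma * (L_lam @ rng.standard_normal(n))

    comp_ln = {}
    for trait in COMPONENT_TRAITS:
        comp_ln[trait] = (
            config.component_intercepts[trait]
            + config.component_slopes[trait] * centered
            + config.component_sigma * (L_lam @ rng.standard_normal(n))
        )

    limb_ln = {}
    for limb in ("forelimb_full", "hindlimb_full"):
        limb_ln[limb] = (
            config.limb_intercepts[limb]
            + config.limb_slopes[limb] * centered
            + config.limb_sigma * (L_lam @ rng.standard_normal(n))
        )

    df = pd.DataFrame(index=pd.Index(taxa, name="species"))
    df["ecotype"] = eco
    df["n_specimens"] = 1
    df["hbER"] = np.exp(ln_hber)
    df["head_ER"] = np.exp(comp_ln["head_ER"])
    for r in REGIONS:
        df[f"{r}_AEI"] = np.exp(comp_ln[f"{r}_AEI"])
    df["body_size"] = np.exp(ln_size)
    df["forelimb_full"] = np.exp(limb_ln["forelimb_full"])
    df["hindlimb_full"] = np.exp(limb_ln["hindlimb_full"])
    df["forelimb_reduced"] = df["forelimb_full"] * config.reduced_limb_frac
    df["hindlimb_reduced"] = df["hindlimb_full"] * config.reduced_limb_frac

    # body depth / rib length follows from the deterministic skeleton solve
    ribs = []
    for sp in taxa:
        row = df.loc[sp]
        base = _skeleton_base(
            row["hbER"], row["head_ER"], {r: row[f"{r}_AEI"] for r in REGIONS},
            row["body_size"], config,
        )
        ribs.append(base["body_depth"])
    df["rib_length"] = ribs

    for col in df.columns:
        if col not in ("ecotype", "n_specimens"):
            df[f"ln_{col}"] = np.log(df[col].astype(float))

    truth = {
        "lambda_true": config.lambda_true,
        "sigma": config.sigma,
        "size_bm_var": config.size_bm_var,
        "root_ln_size": config.root_ln_size,
        "slopes": dict(config.slopes),
        "intercepts": dict(config.intercepts),
        "component_slopes": dict(config.component_slopes),
        "component_sigma": config.component_sigma,
        "limb_slopes": dict(config.limb_slopes),
        "ecotypes": ecotypes,
        "ln_size": dict(zip(taxa, map(float, ln_size))),
        "ln_hbER": dict(zip(taxa, map(float, ln_hber))),
    }
    return df, truth


# --------------------------------------------------------------------------
# specimen synthesis
# --------------------------------------------------------------------------

def synthesize_specimens(
    species: pd.DataFrame, config: SimulationConfig, seed=None
) -> tuple[list[SpecimenRecord], dict[str, str]]:
    """Specimen-level records whose indices hit the species targets exactly
    before multiplicative lognormal measurement noise (CV ``noise_cv``)."""
    rng = _rng(seed if seed is not None else config.seed)
    sigma_ln = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    def noisy(x: float) -> float:
        if sigma_ln == 0:
            return x
        return x * math.exp(sigma_ln * rng.standard_normal())

    records: list[SpecimenRecord] = []
    ecotypes: dict[str, str] = {}
    for sp, row in species.iterrows():
        ecotypes[sp] = row["ecotype"]
        base = _skeleton_base(
            row["hbER"], row["head_ER"], {r: row[f"{r}_AEI"] for r in REGIONS},
            row["body_size"], config,
        )
        has_limbs = (
            pd.notna(row.get("forelimb_full"))
            and rng.random() >= config.limb_missing_frac
        )
        bones: dict[str, float] = {}
        if has_limbs:
            F, Rd = float(row["forelimb_full"]), float(row["forelimb_reduced"])
            hF, hRd = float(row["hindlimb_full"]), float(row["hindlimb_reduced"])
            bones = {
                "humerus": Rd / 2, "radius": Rd / 2,
                "scapula": 0.75 * (F - Rd), "metacarpal3": 0.25 * (F - Rd),
                "femur": hRd / 2, "tibia": hRd / 2, "metatarsal3": hF - hRd,
            }
        n_spec = int(rng.integers(config.specimens_min, config.specimens_max + 1))
        for k in range(1, n_spec + 1):
            vertebrae = {}
            for r in REGIONS:
                count = config.vertebral_counts[r]
                lv = base["region_length"][r] / count
                hv = base["region_height"][r]
                vertebrae[r] = [(noisy(lv), noisy(hv)) for _ in range(count)]
            d = base["body_depth"]
            ribs = [noisy(d) for _ in range(4)] + [noisy(0.85 * d), noisy(0.7 * d)]
            records.append(
                SpecimenRecord(
                    specimen_id=f"{sp}_{k:02d}",
                    species_id=str(sp),
                    cranial_length=noisy(base["cranial_length"]),
                    cranial_height=noisy(base["cranial_height"]),
                    vertebrae=vertebrae,
                    rib_lengths=ribs,
                    limb_bones={b: noisy(v) for b, v in bones.items()},
                )
            )
    return records, ecotypes


# --------------------------------------------------------------------------
# bundles
# --------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig | None = None, seed: int | None = None):
    """Tree + species table + truth + specimens, all from one seed."""
    config = config or SimulationConfig()
    root_seed = seed if seed is not None else config.seed
    rng = _rng(root_seed)
    tree = simulate_tree(config.n_species, rng)
    species, truth = simulate_traits(tree, config, rng)
    specimens, ecotypes = synthesize_specimens(species, config, rng)
    return tree, species, truth, specimens, ecotypes


def write_bundle(outdir: str | Path, config: SimulationConfig | None = None, seed: int | None = None) -> dict:
    """Write measurement CSV, species CSV, Newick tree and truth JSON."""
    from .morphometrics import RIB_COLUMNS, LIMB_BONES

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig()
    tree, species, truth, specimens, ecotypes = simulate_bundle(config, seed)

    rows = []
    for rec in specimens:
        common = {
            "specimen_id": rec.specimen_id,
            "species": rec.species_id,
            "ecotype": ecotypes[rec.species_id],
            "cranial_length": rec.cranial_length,
            "cranial_height": rec.cranial_height,
        }
        for i, rib in enumerate(rec.rib_lengths[:6], start=1):
            common[f"rib{i}"] = rib
        for bone in LIMB_BONES:
            common[bone] = rec.limb_bones.get(bone, np.nan)
        for region in REGIONS:
            for j, (lv, hv) in enumerate(rec.vertebrae[region], start=1):
                rows.append({**common, "region": region, "vertebra_index": j,
                             "centrum_length": lv, "vertebral_height": hv})
    meas = pd.DataFrame(rows)

    paths = {
        "measurements": outdir / "measurements.csv",
        "species": outdir / "species.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    meas.to_csv(paths["measurements"], index=False)
    species.to_csv(paths["species"])
    tree.write(paths["tree"])
    with open(paths["truth"], "w") as fh:
        json.dump({"config": _config_json(config), "seed": seed, "truth": truth}, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def _config_json(config: SimulationConfig) -> dict:
    d = asdict(config)
    return d
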