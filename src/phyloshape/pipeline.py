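"""End-to-end orchestration: traits -> covariance -> allometry -> limbs -> RRPP.

Every stochastic step draws its seed deterministically from the configured
base seed, so identical configurations produce byte-identical output tables.
Output CSVs carry a comment header with the seed, package version and input
checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .morphometrics import (
    REGIONS,
    aggregate_species,
    read_measurements_csv,
    read_species_csv,
    species_frame,
)
from .pgls import (
    ModelSpec,
    bootstrap_cis,
    classify_allometry,
    compare_group_slopes,
    fit_pgls,
    group_mean_comparison,
    per_group_slopes,
    size_correct,
    type2_anova,
)
from .phylo import CovarianceFamily, parse_newick, taxa_overlap_report
from .rrpp import rrpp_multiple_regression

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

COMPONENT_RESPONSES = ("head_ER", "cervical_AEI", "thoracic_AEI", "lumbar_AEI", "sacral_AEI")
RRPP_PREDICTORS = (
    "ln_head_ER",
    "ln_cervical_AEI",
    "ln_thoracic_AEI",
    "ln_lumbar_AEI",
    "ln_sacral_AEI",
    "sc_rib_length",
)


class PipelineError(RuntimeError):
    """Fatal, actionable validation failure."""


@dataclass
class PipelineConfig:
    tree: str
    species_csv: str | None = None
    measurements_csv: str | None = None
    outdir: str = "results"
    run_allometry: bool = True
    run_components: bool = True
    run_limbs: bool = True
    run_rrpp: bool = True
    bootstrap_reps: int = 1000
    rrpp_iters: int = 1000
    isometric_slope: float = 0.0
    limb_mode: str = "both"  # full | reduced | both
    aggregation: str = "mean_of_indices"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.species_csv is None and self.measurements_csv is None:
            raise ValueError("either species_csv or measurements_csv is required")
        if self.bootstrap_reps < 1 or self.rrpp_iters < 1:
            raise ValueError("bootstrap reps and RRPP iterations must be >= 1")
        if self.limb_mode not in ("full", "reduced", "both"):
            raise ValueError(f"invalid limb_mode {self.limb_mode!r}")

    # flat key=value serialization -----------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items() if v is not None]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        bools = {"run_allometry", "run_components", "run_limbs", "run_rrpp"}
        ints = {"bootstrap_reps", "rrpp_iters", "seed"}
        floats = {"isometric_slope"}
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, value = raw.partition("=")
            key, value = key.strip(), value.strip()
            if key in bools:
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ints:
                kwargs[key] = int(value)
            elif key in floats:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, header: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)


def _seed_for(base: int, tag: str) -> int:
    digest = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _allometry_row(model, group, fit, slope, ci, iso):
    call = classify_allometry(slope, ci, isometric_slope=iso, group=group)
    return {
        "model": model,
        "group": group,
        "slope": slope,
        "ci_lower": ci[0],
        "ci_upper": ci[1],
        "lambda": fit.lambda_hat,
        "adjusted_r2": fit.adjusted_r2,
        "call": call.call,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analyses; returns a machine-readable summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phyloshape")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    checksums = {}
    # ---- traits ----------------------------------------------------------
    if config.species_csv:
        if not Path(config.species_csv).exists():
            raise PipelineError(f"species CSV not found: {config.species_csv}")
        checksums["species_csv"] = _checksum(config.species_csv)
        df = read_species_csv(config.species_csv)
        logger.info("loaded %d species from %s", len(df), config.species_csv)
    else:
        if not Path(config.measurements_csv).exists():
            raise PipelineError(f"measurement CSV not found: {config.measurements_csv}")
        checksums["measurements_csv"] = _checksum(config.measurements_csv)
        records, ecotypes = read_measurements_csv(config.measurements_csv)
        traits = aggregate_species(records, ecotypes, rule=config.aggregation)
        df = species_frame(traits)
        logger.info("aggregated %d specimens into %d species", len(records), len(df))

    # ---- tree and covariance --------------------------------------------
    if not Path(config.tree).exists():
        raise PipelineError(f"tree file not found: {config.tree}")
    checksums["tree"] = _checksum(config.tree)
    tree = parse_newick(Path(config.tree))
    report = taxa_overlap_report(df.index, tree.taxa)
    (outdir / "taxa_overlap.txt").write_text(report["text"] + "\n")
    if not report["shared"]:
        raise PipelineError("no species shared between trait table and tree")
    if report["data_only"]:
        raise PipelineError(
            f"species in data but missing from tree: {', '.join(report['data_only'])}"
        )
    shared = report["shared"]
    pruned = tree.prune(shared)
    family = CovarianceFamily.from_tree(pruned)
    df = df.loc[family.taxa]
    if df["ecotype"].isna().any():
        raise PipelineError("missing ecotype labels")
    empty = [e for e in df["ecotype"].unique() if (df["ecotype"] == e).sum() == 0]
    if empty:
        raise PipelineError(f"empty ecotype groups: {empty}")

    header = [
        f"phyloshape {__version__}",
        f"seed = {config.seed}",
        *(f"checksum {k} = {v}" for k, v in sorted(checksums.items())),
    ]
    _write_table(df, outdir / "species_traits.csv", header)

    summary: dict = {
        "n_species": len(df),
        "seed": config.seed,
        "version": __version__,
        "checksums": checksums,
    }
    iso = config.isometric_slope

    # size-corrected rib length: used as a shape component and a response
    df = df.copy()
    sc_rib, _ = size_correct(df, "ln_rib_length", "ln_body_size", family)
    df["sc_rib_length"] = sc_rib

    allometry_rows = []
    anova_tables = []

    def run_allometry_for(trait_ln: str, label: str) -> dict:
        out: dict = {}
        fit_all = fit_pgls(ModelSpec(trait_ln, ["ln_body_size"]), df, family)
        boot = bootstrap_cis(
            fit_all, n_reps=config.bootstrap_reps,
            seed=_seed_for(config.seed, f"allometry:{label}:all"),
        )
        slope = fit_all.coefficients["ln_body_size"]
        ci = boot.ci["ln_body_size"]
        allometry_rows.append(_allometry_row(label, "all", fit_all, slope, ci, iso))
        out["overall"] = {"slope": slope, "ci": ci, "lambda": fit_all.lambda_hat,
                          "adjusted_r2": fit_all.adjusted_r2}

        fit_int = fit_pgls(
            ModelSpec.from_formula(f"{trait_ln} ~ ln_body_size * ecotype"), df, family
        )
        anova = type2_anova(fit_int)
        anova_tables.append(anova.assign(model=label))
        slopes = per_group_slopes(fit_int)
        boot_int = bootstrap_cis(
            fit_int, n_reps=config.bootstrap_reps,
            seed=_seed_for(config.seed, f"allometry:{label}:interaction"),
        )
        for g, s in slopes.items():
            allometry_rows.append(
                _allometry_row(f"{label} x ecotype", g, fit_int, s, boot_int.group_slope_ci[g], iso)
            )
        out["by_ecotype"] = {
            "slopes": slopes,
            "ci": boot_int.group_slope_ci,
            "replicate_mean_slopes": boot_int.group_slope_replicate_mean,
            "lambda": fit_int.lambda_hat,
            "adjusted_r2": fit_int.adjusted_r2,
            "slope_comparison": compare_group_slopes(slopes, boot_int.group_slope_ci).to_dict("records"),
        }
        return out

    if config.run_allometry:
        summary["hbER_allometry"] = run_allometry_for("ln_hbER", "hbER")

    if config.run_components:
        comp_summary = {}
        for comp in COMPONENT_RESPONSES:
            comp_summary[comp] = run_allometry_for(f"ln_{comp}", comp)
        comp_summary["sc_rib_length"] = run_allometry_for("sc_rib_length", "sc_rib_length")
        summary["component_allometry"] = comp_summary

    # ---- limbs -----------------------------------------------------------
    if config.run_limbs:
        modes = ("full", "reduced") if config.limb_mode == "both" else (config.limb_mode,)
        limb_summary: dict = {}
        limb_mean_rows = []
        for mode in modes:
            for limb in ("forelimb", "hindlimb"):
                col = f"ln_{limb}_{mode}"
                if col not in df.columns:
                    logger.warning("no column %s; skipping", col)
                    continue
                have = df.index[df[col].notna()].tolist()
                excluded = len(df) - len(have)
                logger.info("%s (%s): %d species with limb data, %d excluded", limb, mode, len(have), excluded)
                if len(have) < 5:
                    logger.warning("too few species with limb data for %s", col)
                    continue
                sub_family = family.subset(have)
                sub = df.loc[have].copy()
                sc, _ = size_correct(sub, col, "ln_body_size", sub_family)
                sub["sc_limb"] = sc
                fit_int = fit_pgls(
                    ModelSpec.from_formula("sc_limb ~ ln_hbER * ecotype"), sub, sub_family
                )
                boot = bootstrap_cis(
                    fit_int, n_reps=config.bootstrap_reps,
                    seed=_seed_for(config.seed, f"limb:{limb}:{mode}"),
                )
                slopes = per_group_slopes(fit_int)
                for g, s in slopes.items():
                    allometry_rows.append(
                        _allometry_row(f"{limb}_{mode} ~ shape", g, fit_int, s, boot.group_slope_ci[g], iso)
                    )
                means = group_mean_comparison(
                    sub["sc_limb"], sub["ecotype"], sub_family,
                    n_reps=config.bootstrap_reps,
                    seed=_seed_for(config.seed, f"limbmeans:{limb}:{mode}"),
                )
                for g in means.means:
                    limb_mean_rows.append({
                        "limb": limb, "mode": mode, "ecotype": g,
                        "mean": means.means[g],
                        "ci_lower": means.ci[g][0], "ci_upper": means.ci[g][1],
                    })
                limb_summary[f"{limb}_{mode}"] = {
                    "n_species": len(have),
                    "n_excluded": excluded,
                    "slopes": slopes,
                    "slope_ci": boot.group_slope_ci,
                    "lambda": fit_int.lambda_hat,
                    "adjusted_r2": fit_int.adjusted_r2,
                    "group_means": means.means,
                    "group_mean_ci": means.ci,
                    "mean_flags": means.flags.to_dict("records"),
                }
        summary["limbs"] = limb_summary
        if limb_mean_rows:
            _write_table(pd.DataFrame(limb_mean_rows), outdir / "limb_group_means.csv", header)

    if allometry_rows:
        _write_table(pd.DataFrame(allometry_rows), outdir / "allometry.csv", header)
    if anova_tables:
        _write_table(pd.concat(anova_tables), outdir / "ancova_type2.csv", header)

    # ---- RRPP decomposition ---------------------------------------------
    if config.run_rrpp:
        rrpp_rows = []
        rrpp_summary = {}
        groups = ["all"] + sorted(df["ecotype"].unique())
        for group in groups:
            sub = df if group == "all" else df[df["ecotype"] == group]
            if len(sub) < len(RRPP_PREDICTORS) + 2:
                logger.warning("group %s too small for the six-component model", group)
                continue
            sub_family = family if group == "all" else family.subset(sub.index.tolist())
            res = rrpp_multiple_regression(
                "ln_hbER", list(RRPP_PREDICTORS), sub, sub_family,
                n_iter=config.rrpp_iters,
                seed=_seed_for(config.seed, f"rrpp:{group}"),
            )
            table = res.table().assign(group=group)
            rrpp_rows.append(table)
            rrpp_summary[group] = {
                "r2": res.r2,
                "p": res.p_perm,
                "p_adjusted": res.p_adjusted,
                "top_component": max(res.r2, key=res.r2.get),
            }
        if rrpp_rows:
            _write_table(pd.concat(rrpp_rows), outdir / "rrpp_decomposition.csv", header)
        summary["rrpp"] = rrpp_summary

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline complete: %s", outdir)
    return summary
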