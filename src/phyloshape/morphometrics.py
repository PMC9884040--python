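"""Skeletal elongation statistics computed from specimen measurements.

All statistics are simple ratios or sums of linear measurements:

* whole-body elongation: (cranial length + summed centrum lengths) / body depth
* head elongation: cranial length / cranial height
* regional axial elongation: summed centrum lengths / mean vertebral height
* body size: geometric mean of 11 cranial/axial measurements
* limb lengths: sums of long-bone (and optionally girdle/metapodial) lengths

Specimen-level statistics are averaged arithmetically within species and the
species means are ln-transformed for downstream modeling.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "ECOTYPES",
    "FULL_FORELIMB_BONES",
    "FULL_HINDLIMB_BONES",
    "REDUCED_FORELIMB_BONES",
    "REDUCED_HINDLIMB_BONES",
    "SpecimenRecord",
    "SpeciesTraits",
    "InvalidMeasurementError",
    "MissingRegionError",
    "InsufficientRibsError",
    "EcotypeLabelError",
    "compute_hbER",
    "compute_body_length",
    "compute_body_depth",
    "compute_head_ER",
    "compute_AEI",
    "compute_geometric_mean",
    "compute_limb_lengths",
    "size_components",
    "specimen_indices",
    "aggregate_species",
    "species_frame",
    "read_measurements_csv",
    "write_species_csv",
    "read_species_csv",
]

REGIONS = ("cervical", "thoracic", "lumbar", "sacral")
ECOTYPES = ("chipmunk", "gliding", "ground", "tree")

FULL_FORELIMB_BONES = ("scapula", "humerus", "radius", "metacarpal3")
FULL_HINDLIMB_BONES = ("femur", "tibia", "metatarsal3")
REDUCED_FORELIMB_BONES = ("humerus", "radius")
REDUCED_HINDLIMB_BONES = ("femur", "tibia")
LIMB_BONES = FULL_FORELIMB_BONES + FULL_HINDLIMB_BONES

CONTINUOUS_TRAITS = (
    "hbER",
    "head_ER",
    "cervical_AEI",
    "thoracic_AEI",
    "lumbar_AEI",
    "sacral_AEI",
    "rib_length",
    "body_size",
    "forelimb_full",
    "forelimb_reduced",
    "hindlimb_full",
    "hindlimb_reduced",
)


class InvalidMeasurementError(ValueError):
    def __init__(self, name: str, value):
        super().__init__(f"measurement {name!r} must be strictly positive, got {value!r}")
        self.name = name


class MissingRegionError(ValueError):
    def __init__(self, region: str):
        super().__init__(f"vertebral region {region!r} has no vertebrae")
        self.region = region


class InsufficientRibsError(ValueError):
    def __init__(self, n: int):
        super().__init__(f"need at least 4 rib lengths, got {n}")
        self.n = n


class EcotypeLabelError(KeyError):
    def __init__(self, species: Iterable[str]):
        self.species = sorted(species)
        super().__init__(f"no ecotype label for species: {', '.join(self.species)}")


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InvalidMeasurementError(name, value)
    return value


@dataclass
class SpecimenRecord:
    """Raw skeletal measurements for one museum specimen.

    ``vertebrae`` maps each region to an ordered list of
    ``(centrum_length, vertebral_height)`` pairs in mm. ``limb_bones`` may
    omit any bone; missingness is a legal value.
    """

    specimen_id: str
    species_id: str
    cranial_length: float
    cranial_height: float
    vertebrae: dict[str, list[tuple[float, float]]]
    rib_lengths: list[float]
    limb_bones: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        _check_positive("cranial_length", self.cranial_length)
        _check_positive("cranial_height", self.cranial_height)
        for region in REGIONS:
            verts = self.vertebrae.get(region, [])
            if not verts:
                raise MissingRegionError(region)
            for i, (lv, hv) in enumerate(verts):
                _check_positive(f"{region}[{i}].centrum_length", lv)
                _check_positive(f"{region}[{i}].vertebral_height", hv)
        if len(self.rib_lengths) < 4:
            raise InsufficientRibsError(len(self.rib_lengths))
        for i, r in enumerate(self.rib_lengths):
            _check_positive(f"rib[{i}]", r)
        for bone, length in self.limb_bones.items():
            _check_positive(bone, length)


@dataclass
class SpeciesTraits:
    """Per-species trait means (raw scale) plus their natural logs."""

    species_id: str
    ecotype: str
    n_specimens: int
    values: dict[str, float]  # raw-scale traits; limb entries may be absent

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        for k, v in self.values.items():
            if v is not None and v <= 0:
                raise InvalidMeasurementError(k, v)

    @property
    def ln_values(self) -> dict[str, float]:
        return {f"ln_{k}": math.log(v) for k, v in self.values.items() if v is not None}


# --------------------------------------------------------------------------
# formula-defined statistics
# --------------------------------------------------------------------------

def compute_hbER(cranial_length: float, body_length: float, body_depth: float) -> float:
    """Whole-body elongation: (cranial length + body length) / body depth."""
    lh = _check_positive("cranial_length", cranial_length)
    lb = _check_positive("body_length", body_length)
    lr = _check_positive("body_depth", body_depth)
    return (lh + lb) / lr


def compute_body_length(vertebrae: Mapping[str, Sequence[tuple[float, float]]]) -> float:
    """Sum of centrum lengths across the four vertebral regions."""
    total = 0.0
    for region in REGIONS:
        verts = vertebrae.get(region, [])
        if not verts:
            raise MissingRegionError(region)
        total += sum(lv for lv, _ in verts)
    return total


def compute_body_depth(rib_lengths: Sequence[float]) -> float:
    """Mean of the four longest rib lengths."""
    if len(rib_lengths) < 4:
        raise InsufficientRibsError(len(rib_lengths))
    top4 = sorted(rib_lengths, reverse=True)[:4]
    return float(sum(top4) / 4.0)


def compute_head_ER(cranial_length: float, cranial_height: float) -> float:
    """Head elongation: cranial length / cranial height."""
    lh = _check_positive("cranial_length", cranial_length)
    hh = _check_positive("cranial_height", cranial_height)
    return lh / hh


def compute_AEI(region_vertebrae: Sequence[tuple[float, float]]) -> float:
    """Regional axial elongation: summed centrum lengths / mean height."""
    if not region_vertebrae:
        raise MissingRegionError("<region>")
    lengths = [_check_positive("centrum_length", lv) for lv, _ in region_vertebrae]
    heights = [_check_positive("vertebral_height", hv) for _, hv in region_vertebrae]
    return sum(lengths) / (sum(heights) / len(heights))


def compute_geometric_mean(components: Sequence[float]) -> float:
    """Geometric mean of exactly 11 strictly positive measurements."""
    if len(components) != 11:
        raise InvalidMeasurementError("size_components", f"expected 11 values, got {len(components)}")
    vals = [_check_positive(f"size_component[{i}]", v) for i, v in enumerate(components)]
    return float(np.exp(np.mean(np.log(vals))))


def compute_limb_lengths(
    limb_bones: Mapping[str, float], mode: Literal["full", "reduced"]
) -> tuple[float | None, float | None]:
    """(forelimb, hindlimb) sums for the requested mode; None if a bone is absent."""
    if mode == "full":
        fore, hind = FULL_FORELIMB_BONES, FULL_HINDLIMB_BONES
    elif mode == "reduced":
        fore, hind = REDUCED_FORELIMB_BONES, REDUCED_HINDLIMB_BONES
    else:
        raise ValueError(f"mode must be 'full' or 'reduced', got {mode!r}")

    def _sum(bones: Sequence[str]) -> float | None:
        vals = [limb_bones.get(b) for b in bones]
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
            return None
        return float(sum(vals))

    return _sum(fore), _sum(hind)


def size_components(record: SpecimenRecord) -> list[float]:
    """The 11 body-size components: cranial length & height, the four regional
    summed centrum lengths, the four regional mean vertebral heights, and body
    depth."""
    comps = [record.cranial_length, record.cranial_height]
    for region in REGIONS:
        verts = record.vertebrae.get(region, [])
        if not verts:
            raise MissingRegionError(region)
        comps.append(sum(lv for lv, _ in verts))
    for region in REGIONS:
        verts = record.vertebrae[region]
        comps.append(sum(hv for _, hv in verts) / len(verts))
    comps.append(compute_body_depth(record.rib_lengths))
    return comps


def specimen_indices(record: SpecimenRecord) -> dict[str, float | None]:
    """All derived statistics for a single specimen."""
    record.validate()
    body_length = compute_body_length(record.vertebrae)
    body_depth = compute_body_depth(record.rib_lengths)
    out: dict[str, float | None] = {
        "hbER": compute_hbER(record.cranial_length, body_length, body_depth),
        "head_ER": compute_head_ER(record.cranial_length, record.cranial_height),
        "rib_length": body_depth,
        "body_size": compute_geometric_mean(size_components(record)),
    }
    for region in REGIONS:
        out[f"{region}_AEI"] = compute_AEI(record.vertebrae[region])
    for mode in ("full", "reduced"):
        fore, hind = compute_limb_lengths(record.limb_bones, mode)
        out[f"forelimb_{mode}"] = fore
        out[f"hindlimb_{mode}"] = hind
    return out


# --------------------------------------------------------------------------
# species aggregation
# --------------------------------------------------------------------------

def aggregate_species(
    records: Sequence[SpecimenRecord],
    ecotypes: Mapping[str, str],
    rule: Literal["mean_of_indices", "indices_of_means"] = "mean_of_indices",
) -> list[SpeciesTraits]:
    """Aggregate specimen records to one trait vector per species.

    ``mean_of_indices`` (default): compute each statistic per specimen, then
    average arithmetically across a species' specimens. The alternative
    ``indices_of_means`` averages each raw measurement first and computes the
    statistics from the species-mean skeleton (only defined when all
    specimens share vertebral counts); it is provided for sensitivity checks.

    Specimens that fail validation are excluded with a logged warning rather
    than aborting the run. Limb statistics come from the subset of specimens
    possessing the needed bones; a species with no usable limb specimens
    carries missing limb fields.
    """
    by_species: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)

    missing_labels = [s for s in by_species if s not in ecotypes]
    if missing_labels:
        raise EcotypeLabelError(missing_labels)

    out = []
    for species in by_species:
        usable: list[dict[str, float | None]] = []
        kept_records = []
        for rec in by_species[species]:
            try:
                usable.append(specimen_indices(rec))
                kept_records.append(rec)
            except (InvalidMeasurementError, MissingRegionError, InsufficientRibsError) as exc:
                logger.warning("excluding specimen %s (%s): %s", rec.specimen_id, species, exc)
        if not usable:
            logger.warning("species %s has no usable specimens; dropped", species)
            continue
        if rule == "mean_of_indices":
            values = _mean_of_indices(usable)
        elif rule == "indices_of_means":
            values = _indices_of_mean_skeleton(kept_records)
        else:
            raise ValueError(f"unknown aggregation rule {rule!r}")
        out.append(
            SpeciesTraits(
                species_id=species,
                ecotype=ecotypes[species],
                n_specimens=len(usable),
                values=values,
            )
        )
    return out


def _mean_of_indices(per_specimen: list[dict[str, float | None]]) -> dict[str, float]:
    values: dict[str, float] = {}
    for key in CONTINUOUS_TRAITS:
        vals = [d[key] for d in per_specimen if d.get(key) is not None]
        if vals:
            values[key] = float(np.mean(vals))
    return values


def _indices_of_mean_skeleton(records: list[SpecimenRecord]) -> dict[str, float]:
    counts = {r: len(records[0].vertebrae[r]) for r in REGIONS}
    for rec in records:
        for r in REGIONS:
            if len(rec.vertebrae[r]) != counts[r]:
                raise ValueError(
                    "indices_of_means requires identical vertebral counts across specimens"
                )
    n_ribs = min(len(r.rib_lengths) for r in records)
    mean_rec = SpecimenRecord(
        specimen_id="<species-mean>",
        species_id=records[0].species_id,
        cranial_length=float(np.mean([r.cranial_length for r in records])),
        cranial_height=float(np.mean([r.cranial_height for r in records])),
        vertebrae={
            reg: [
                (
                    float(np.mean([r.vertebrae[reg][i][0] for r in records])),
                    float(np.mean([r.vertebrae[reg][i][1] for r in records])),
                )
                for i in range(counts[reg])
            ]
            for reg in REGIONS
        },
        rib_lengths=[
            float(np.mean([sorted(r.rib_lengths, reverse=True)[i] for r in records]))
            for i in range(n_ribs)
        ],
        limb_bones={},
    )
    values = {k: v for k, v in specimen_indices(mean_rec).items() if v is not None}
    # limbs still use per-specimen sums over the subset possessing them
    limb_stats = _mean_of_indices([specimen_indices(r) for r in records])
    for key in ("forelimb_full", "forelimb_reduced", "hindlimb_full", "hindlimb_reduced"):
        if key in limb_stats:
            values[key] = limb_stats[key]
    return values


def species_frame(traits: Sequence[SpeciesTraits]) -> pd.DataFrame:
    """Tidy species table: raw traits plus ``ln_``-prefixed columns."""
    rows = []
    for t in traits:
        row = {"species": t.species_id, "ecotype": t.ecotype, "n_specimens": t.n_specimens}
        row.update({k: t.values.get(k) for k in CONTINUOUS_TRAITS})
        row.update(t.ln_values)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("species").sort_index()
    return df


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

RIB_COLUMNS = tuple(f"rib{i}" for i in range(1, 7))


def read_measurements_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> tuple[list[SpecimenRecord], dict[str, str]]:
    """Read the long-form measurement CSV.

    One row per (specimen, vertebra); specimen-level columns
    (``specimen_id, species, ecotype, cranial_length, cranial_height``, ribs
    ``rib1..rib6`` and the seven limb-bone columns) repeat across a
    specimen's rows. ``column_map`` renames source columns to the canonical
    names so alternative wide layouts can be consumed.

    Returns (records, ecotype map).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {
        "specimen_id",
        "species",
        "ecotype",
        "cranial_length",
        "cranial_height",
        "region",
        "vertebra_index",
        "centrum_length",
        "vertebral_height",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")

    records: list[SpecimenRecord] = []
    ecotypes: dict[str, str] = {}
    for specimen_id, grp in df.groupby("specimen_id", sort=True):
        head = grp.iloc[0]
        species = str(head["species"]).strip().replace(" ", "_")
        ecotypes[species] = str(head["ecotype"]).strip()
        vertebrae: dict[str, list[tuple[float, float]]] = {r: [] for r in REGIONS}
        for _, row in grp.sort_values(["region", "vertebra_index"]).iterrows():
            vertebrae[str(row["region"])].append(
                (float(row["centrum_length"]), float(row["vertebral_height"]))
            )
        ribs = [
            float(head[c]) for c in RIB_COLUMNS if c in grp.columns and pd.notna(head[c])
        ]
        limbs = {
            b: float(head[b]) for b in LIMB_BONES if b in grp.columns and pd.notna(head[b])
        }
        records.append(
            SpecimenRecord(
                specimen_id=str(specimen_id),
                species_id=species,
                cranial_length=float(head["cranial_length"]),
                cranial_height=float(head["cranial_height"]),
                vertebrae=vertebrae,
                rib_lengths=ribs,
                limb_bones=limbs,
            )
        )
    return records, ecotypes


def write_species_csv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh)


def read_species_csv(path: str | Path) -> pd.DataFrame:
    """Read a species-level trait table; ensures ``ln_`` columns exist."""
    df = pd.read_csv(path, comment="#")
    if "species" not in df.columns:
        raise ValueError("species CSV must have a 'species' column")
    df["species"] = df["species"].astype(str).str.strip().str.replace(" ", "_")
    df = df.set_index("species")
    for col in CONTINUOUS_TRAITS:
        if col in df.columns and f"ln_{col}" not in df.columns:
            with np.errstate(invalid="ignore", divide="ignore"):
                df[f"ln_{col}"] = np.log(df[col])
    return df
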