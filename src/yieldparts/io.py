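"""Trait-table and phylogeny input/output.

The package's tabular currency is a per-plant trait table (CSV, one row per
harvested plant) and a rooted ultrametric phylogeny (Newick) whose tip labels
match the table's taxa. Seed masses travel in mg in files and records (they
are weighed in mg); whole-plant masses are in g. Conversion to g happens in
one place, when yield components are derived (:mod:`yieldparts.components`).

Species means are computed *after* applying each trait's analysis-scale
transform (natural log for sizes, masses and counts; identity for rates,
fractions and durations), so that log-trait means are geometric means on the
natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

STATUSES = ("crop", "progenitor")
FAMILIES = ("grass", "legume")

#: mass-consistency slack for validation, relative to the larger operand
_MASS_RTOL = 1e-9


class TraitTableError(ValueError):
    """Raised when a trait table is malformed or rows break invariants."""


class TreeError(ValueError):
    """Raised when a phylogeny is unusable (labels, branch lengths, shape)."""


@dataclass(slots=True)
class PlantRecord:
    """One harvested plant's measured traits.

    Masses: ``seed_mass_sown`` / ``seed_mass_harvest`` are mean individual
    seed masses in **mg**; all other masses are dry above-ground masses in
    **g**. ``mass_reproductive`` includes culm and chaff; by the package's
    bookkeeping convention culm is folded into ``mass_chaff`` so that
    ``mass_chaff + mass_grain == mass_reproductive`` exactly.

    Packaging counts (``n_seeds_per_infructescence``, ``n_infructescences``)
    are measured for cereals only and are ``None`` for pulses. Counts are
    stored as floats because they are means over sub-sampled infructescences.
    """

    species_id: str
    status: str
    family: str
    accession_id: str
    experiment_id: int
    block_id: str
    seed_mass_sown: float        # mg
    biomass_total: float         # g
    mass_vegetative: float       # g
    mass_reproductive: float     # g
    mass_chaff: float            # g
    mass_grain: float            # g, total seed yield Y
    seed_mass_harvest: float     # mg
    n_seeds_total: float
    duration_days: float
    n_seeds_per_infructescence: float | None = None
    n_infructescences: float | None = None
    height: float | None = None  # cm

    @property
    def is_pulse_style(self) -> bool:
        """True when per-infructescence packaging counts were not measured."""
        return self.n_seeds_per_infructescence is None or self.n_infructescences is None

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if self.status not in STATUSES:
            errs.append(f"status {self.status!r} not in {STATUSES}")
        if self.family not in FAMILIES:
            errs.append(f"family {self.family!r} not in {FAMILIES}")
        for name in ("seed_mass_sown", "biomass_total", "mass_vegetative",
                     "mass_reproductive", "mass_chaff", "mass_grain",
                     "seed_mass_harvest", "n_seeds_total"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v < 0:
                errs.append(f"{name}={v!r} must be finite and >= 0")
        slack = _MASS_RTOL * max(self.mass_reproductive, self.mass_chaff + self.mass_grain, 1e-300)
        if self.mass_chaff + self.mass_grain > self.mass_reproductive + slack:
            errs.append(
                f"mass_chaff + mass_grain = {self.mass_chaff + self.mass_grain:g} "
                f"exceeds mass_reproductive = {self.mass_reproductive:g}"
            )
        if self.mass_reproductive > self.biomass_total * (1 + _MASS_RTOL):
            errs.append(
                f"mass_reproductive = {self.mass_reproductive:g} exceeds "
                f"biomass_total = {self.biomass_total:g}"
            )
        if not (self.duration_days is not None and self.duration_days > 0):
            errs.append(f"duration_days={self.duration_days!r} must be > 0")
        if (self.n_seeds_per_infructescence is None) != (self.n_infructescences is None):
            errs.append("packaging counts must be both present or both absent")
        return errs


#: CSV column name for each PlantRecord field (units encoded in the header)
COLUMNS: dict[str, str] = {
    "species_id": "species_id",
    "status": "status",
    "family": "family",
    "accession_id": "accession_id",
    "experiment_id": "experiment_id",
    "block_id": "block_id",
    "seed_mass_sown": "seed_mass_sown_mg",
    "biomass_total": "biomass_total_g",
    "mass_vegetative": "mass_vegetative_g",
    "mass_reproductive": "mass_reproductive_g",
    "mass_chaff": "mass_chaff_g",
    "mass_grain": "mass_grain_g",
    "seed_mass_harvest": "seed_mass_harvest_mg",
    "n_seeds_total": "n_seeds_total",
    "n_seeds_per_infructescence": "n_seeds_per_infructescence",
    "n_infructescences": "n_infructescences",
    "duration_days": "duration_days",
    "height": "height_cm",
}

_OPTIONAL_COLUMNS = {"n_seeds_per_infructescence", "n_infructescences", "height"}
_MANDATORY_COLUMNS = [c for f, c in COLUMNS.items() if f not in _OPTIONAL_COLUMNS]

#: analysis-scale transform per derived trait ("log" = natural log, "identity")
TRAIT_TRANSFORMS: dict[str, str] = {
    "Y": "log",
    "Ms_sown": "log",
    "Ms_harvest": "log",
    "Md": "log",
    "infructescence_mass": "log",
    "N_total": "log",
    "Ns": "log",
    "Ni": "log",
    "height": "log",
    "d": "identity",
    "Ar": "identity",
    "c": "identity",
    "lambda_bar": "identity",
    "lambda_s": "identity",
    "harvest_index": "identity",
    "seeds_per_gram": "log",
}


def read_trait_table(path: str | Path) -> list[PlantRecord]:
    """Read and validate a per-plant trait CSV.

    Raises :class:`TraitTableError` naming every offending row if any record
    breaks the mass or count invariants, and on missing mandatory columns.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records: list[PlantRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        kwargs = {}
        for field, col in COLUMNS.items():
            if col not in df.columns:
                kwargs[field] = None
                continue
            v = getattr(row, col)
            if field in _OPTIONAL_COLUMNS and (v is None or (isinstance(v, float) and math.isnan(v))):
                kwargs[field] = None
            elif field in ("species_id", "status", "family", "accession_id", "block_id"):
                kwargs[field] = str(v)
            elif field == "experiment_id":
                kwargs[field] = int(v)
            else:
                kwargs[field] = float(v)
        rec = PlantRecord(**kwargs)
        errs = rec.validation_errors()
        if errs:
            problems.append(f"row {i} ({rec.species_id}): " + "; ".join(errs))
        else:
            records.append(rec)
    if problems:
        raise TraitTableError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return records


def records_to_frame(records: Iterable[PlantRecord]) -> pd.DataFrame:
    """Plant records as a DataFrame with the canonical CSV column names."""
    rows = []
    for r in records:
        rows.append({col: getattr(r, field) for field, col in COLUMNS.items()})
    return pd.DataFrame(rows, columns=list(COLUMNS.values()))


def write_trait_table(records: Iterable[PlantRecord], path: str | Path) -> None:
    """Write records as CSV. Float formatting uses shortest round-trip repr,
    so read→write→read is lossless."""
    records_to_frame(records).to_csv(path, index=False)


def read_tree(path: str | Path, expected_taxa: Sequence[str] | None = None,
              ultrametric_tol: float = 1e-6) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Checks every edge has a length, that the tree is ultrametric within
    ``ultrametric_tol`` (relative to root depth), and — when
    ``expected_taxa`` is given — that tip labels match it exactly.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError(f"{path}: edge above "
                            f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'} "
                            "has no branch length")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if expected_taxa is not None:
        expected = set(expected_taxa)
        only_tree = sorted(tips - expected)
        only_table = sorted(expected - tips)
        if only_tree or only_table:
            raise TreeError(
                f"{path}: tip/table mismatch: "
                f"in tree only: {only_tree or '[]'}; in table only: {only_table or '[]'}"
            )
    check_ultrametric(tree, tol=ultrametric_tol)
    return tree


def check_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> float:
    """Assert root-to-tip depths agree within ``tol`` (relative); return depth."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    depth = max(depths)
    if depth <= 0:
        raise TreeError("tree has zero depth")
    if (depth - min(depths)) / depth > tol:
        raise TreeError(
            f"tree is not ultrametric: tip depths span [{min(depths):g}, {depth:g}]"
        )
    return depth


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def species_means(plant_traits: pd.DataFrame, scale: str = "analysis",
                  transforms: dict[str, str] | None = None,
                  by_accession: bool = False) -> pd.DataFrame:
    """Aggregate a per-plant component table to species means.

    Parameters
    ----------
    plant_traits
        Output of :func:`yieldparts.components.components_frame`: one row per
        plant with ``species_id``, ``status``, ``family`` and trait columns.
    scale
        ``"analysis"`` transforms each trait first (log traits are averaged
        on the log scale and the mean is *returned on the log scale*);
        ``"natural"`` averages raw values (used for the variance
        decomposition, which differentiates yield in natural units).
    by_accession
        Average plants within accessions first, then accessions within
        species, instead of pooling all plants of a species.

    Returns one row per taxon, indexed by ``species_id``. Missing trait cells
    (e.g. packaging counts for pulses) yield NaN means, which downstream
    consumers must tolerate.
    """
    if scale not in ("analysis", "natural"):
        raise ValueError(f"scale must be 'analysis' or 'natural', got {scale!r}")
    transforms = TRAIT_TRANSFORMS if transforms is None else transforms
    meta_cols = ["status", "family"]
    trait_cols = [c for c in plant_traits.columns if c in transforms]
    df = plant_traits.copy()
    if scale == "analysis":
        for c in trait_cols:
            if transforms[c] == "log":
                with np.errstate(divide="ignore", invalid="ignore"):
                    df[c] = np.log(df[c].astype(float))
    grouping = ["species_id", "accession_id"] if by_accession else ["species_id"]
    agg = df.groupby(grouping, sort=True)[trait_cols].mean()
    if by_accession:
        agg = agg.groupby(level="species_id", sort=True).mean()
    meta = plant_traits.groupby("species_id", sort=True)[meta_cols].first()
    out = meta.join(agg)
    return out
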