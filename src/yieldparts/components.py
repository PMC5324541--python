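"""Yield-component decomposition for individual plants.

Total seed yield Y (g of grain per plant) is decomposed in two equivalent
ways:

* growth/allocation:  Y = Ms · exp(λ̃·d) · Ar · (1 − c)
* seed packaging:     Y = Ms(harvest) · Ns · Ni      (cereals)
                      Y = Ms(harvest) · N_total      (pulses)

where Ms is individual seed mass (g; sown for the first decomposition,
harvested for the second), λ̃ = ln(Md/Ms)/d is the average relative growth
rate over the growing period d (days), Md is final above-ground dry mass,
Ar is the fraction of Md allocated to reproductive tissue, c is the chaff
(or pod-wall) fraction of reproductive mass, Ns is seeds per infructescence
and Ni infructescences per plant. Because λ̃ is defined from the same Md,
the first decomposition collapses to the exact identity Y = Md·Ar·(1−c).

The harvest index is Y/Md.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PlantRecord, records_to_frame

log = logging.getLogger(__name__)

MG_PER_G = 1000.0


class ComponentError(ValueError):
    """Raised for arithmetically undefined component values."""


@dataclass(slots=True)
class YieldComponents:
    """The trait vector θ for one plant (or one species mean), in g/days.

    ``Ns``/``Ni`` are ``None`` for pulse-style records. ``N_total`` is the
    directly counted total seed number and is *not* reconciled with Ns×Ni
    when sub-sampling makes them disagree. ``seeds_per_gram`` = N_total/Md
    is reported as a supplementary trait outside both decompositions.
    """

    species_id: str
    status: str
    family: str
    Ms_sown: float       # g
    Ms_harvest: float    # g
    lambda_bar: float    # g g^-1 day^-1
    d: float             # days
    Ar: float            # fraction of Md
    c: float             # chaff fraction of reproductive mass
    Y: float             # g, recorded grain mass
    Md: float            # g, final above-ground mass
    N_total: float
    harvest_index: float
    seeds_per_gram: float
    Ns: float | None = None
    Ni: float | None = None


def chaff_fraction(mass_chaff: float, mass_grain: float, percent: bool = False) -> float:
    """Chaff (or pod material) as a proportion of reproductive mass,
    c = chaff/(chaff + grain)."""
    if mass_chaff < 0 or mass_grain < 0:
        raise ComponentError("chaff and grain masses must be >= 0")
    total = mass_chaff + mass_grain
    if total == 0:
        raise ComponentError("chaff fraction undefined: chaff + grain = 0")
    c = mass_chaff / total
    return 100.0 * c if percent else c


def relative_reduction(progenitor_value: float, crop_value: float) -> float:
    """Percent reduction of a crop trait relative to its progenitor,
    100·(progenitor − crop)/progenitor. E.g. chaff percentages 39.0 → 24.2
    give a 38% reduction (nearest integer)."""
    if progenitor_value == 0:
        raise ComponentError("relative reduction undefined for zero progenitor value")
    return 100.0 * (progenitor_value - crop_value) / progenitor_value


def average_rgr(Ms_sown: float, Md: float, d: float) -> float:
    """Average relative growth rate λ̃ = ln(Md/Ms)/d over the growing period.

    Valid even when growth is not exponential; substituting back gives
    Ms·exp(λ̃·d) = Md exactly. A final mass below the sown seed mass yields a
    negative rate — biologically odd but data-possible, so it is logged as a
    warning rather than rejected.
    """
    if Ms_sown <= 0 or Md <= 0:
        raise ComponentError(f"masses must be > 0 (Ms_sown={Ms_sown}, Md={Md})")
    if d <= 0:
        raise ComponentError(f"duration must be > 0 (d={d})")
    lam = math.log(Md / Ms_sown) / d
    if lam < 0:
        log.warning("negative average RGR: Md=%g g below sown seed mass %g g", Md, Ms_sown)
    return lam


def yield_eqn1(Ms_sown: float, lambda_bar: float, d: float, Ar: float, c: float) -> float:
    """Growth/allocation yield: Y = Ms·exp(λ̃·d)·Ar·(1−c)."""
    if not 0 <= Ar <= 1:
        raise ComponentError(f"Ar={Ar} outside [0, 1]")
    if not 0 <= c <= 1:
        raise ComponentError(f"c={c} outside [0, 1]")
    return Ms_sown * math.exp(lambda_bar * d) * Ar * (1.0 - c)


def yield_eqn2(Ms_harvest: float, Ns: float | None = None, Ni: float | None = None,
               N_total: float | None = None) -> float:
    """Packaging yield: Y = Ms·Ns·Ni (cereals) or Y = Ms·N_total (pulses)."""
    if Ms_harvest <= 0:
        raise ComponentError(f"Ms_harvest={Ms_harvest} must be > 0")
    if Ns is not None and Ni is not None:
        if Ns < 0 or Ni < 0:
            raise ComponentError("counts must be >= 0")
        return Ms_harvest * Ns * Ni
    if N_total is not None:
        if N_total < 0:
            raise ComponentError("N_total must be >= 0")
        return Ms_harvest * N_total
    raise ComponentError("provide either (Ns, Ni) or N_total")


def derive_components(record: PlantRecord) -> YieldComponents:
    """Assemble the full component vector from one plant record.

    Seed masses are converted mg → g here (the single conversion point).
    """
    try:
        Ms_sown = record.seed_mass_sown / MG_PER_G
        Ms_harvest = record.seed_mass_harvest / MG_PER_G
        Md = record.biomass_total
        Ar = record.mass_reproductive / Md if Md > 0 else math.nan
        c = chaff_fraction(record.mass_chaff, record.mass_grain)
        lam = average_rgr(Ms_sown, Md, record.duration_days)
        Y = record.mass_grain
        return YieldComponents(
            species_id=record.species_id,
            status=record.status,
            family=record.family,
            Ms_sown=Ms_sown,
            Ms_harvest=Ms_harvest,
            lambda_bar=lam,
            d=record.duration_days,
            Ar=Ar,
            c=c,
            Y=Y,
            Md=Md,
            N_total=record.n_seeds_total,
            harvest_index=Y / Md if Md > 0 else math.nan,
            seeds_per_gram=record.n_seeds_total / Md if Md > 0 else math.nan,
            Ns=record.n_seeds_per_infructescence,
            Ni=record.n_infructescences,
        )
    except ComponentError as e:
        raise ComponentError(
            f"{record.species_id}/{record.accession_id}/block {record.block_id}: {e}"
        ) from e


def components_frame(records) -> pd.DataFrame:
    """Per-plant component table: one row per plant, trait columns named as
    in :data:`yieldparts.io.TRAIT_TRANSFORMS`, plus identifiers.

    ``infructescence_mass`` (g of seed per infructescence, Y/Ni) is included
    for cereals; packaging columns are NaN for pulses.
    """
    raw = records_to_frame(records)
    comps = [derive_components(r) for r in records]
    df = pd.DataFrame(
        {
            "species_id": [c.species_id for c in comps],
            "status": [c.status for c in comps],
            "family": [c.family for c in comps],
            "accession_id": raw["accession_id"].to_numpy(),
            "experiment_id": raw["experiment_id"].to_numpy(),
            "block_id": raw["block_id"].to_numpy(),
            "Y": [c.Y for c in comps],
            "Ms_sown": [c.Ms_sown for c in comps],
            "Ms_harvest": [c.Ms_harvest for c in comps],
            "Md": [c.Md for c in comps],
            "lambda_bar": [c.lambda_bar for c in comps],
            "d": [c.d for c in comps],
            "Ar": [c.Ar for c in comps],
            "c": [c.c for c in comps],
            "N_total": [c.N_total for c in comps],
            "Ns": [np.nan if c.Ns is None else c.Ns for c in comps],
            "Ni": [np.nan if c.Ni is None else c.Ni for c in comps],
            "harvest_index": [c.harvest_index for c in comps],
            "seeds_per_gram": [c.seeds_per_gram for c in comps],
            "height": raw["height_cm"].to_numpy(dtype=float),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["infructescence_mass"] = df["Y"] / df["Ni"]
    return df
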