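"""Redox-zone assignment from O2 and NO3 penetration depths.

Hadal sediment cores are vertically stratified by the dominant terminal
electron acceptor: an oxic zone (O2 present), a nitrogenous zone (nitrate /
nitrite / Mn oxides), and a ferruginous zone below nitrate penetration where
dissolved Fe(II) accumulates.  A sample slice ``[top, bottom)`` is assigned by
its depth midpoint ``m``::

    m <  o2_penetration                    -> oxic
    o2_penetration <= m < no3_penetration  -> nitrogenous
    m >= no3_penetration                   -> ferruginous

Ties at a boundary go to the deeper zone.  Because the in situ boundaries are
only known to roughly +/- 2 cm, ``annotate_zones`` can additionally flag
samples whose midpoint falls within ``boundary_buffer`` cm of either boundary
as transitional, so that downstream zone means can exclude them.
"""

from __future__ import annotations

import logging

import pandas as pd

from .tables_io import SAMPLE_METADATA, ValidationError, ZONES

__all__ = ["assign_zone", "annotate_zones"]

logger = logging.getLogger(__name__)


def assign_zone(
    depth_top_cm: float,
    depth_bottom_cm: float,
    o2_penetration_cm: float,
    no3_penetration_cm: float,
) -> str:
    """Assign one depth interval to oxic / nitrogenous / ferruginous."""
    if not 0 <= depth_top_cm < depth_bottom_cm:
        raise ValidationError(
            f"invalid depth interval [{depth_top_cm}, {depth_bottom_cm})"
        )
    if not 0 < o2_penetration_cm < no3_penetration_cm:
        raise ValidationError(
            f"inconsistent penetration depths: o2={o2_penetration_cm} cm, "
            f"no3={no3_penetration_cm} cm (need 0 < o2 < no3)"
        )
    midpoint = 0.5 * (depth_top_cm + depth_bottom_cm)
    if midpoint < o2_penetration_cm:
        return "oxic"
    if midpoint < no3_penetration_cm:
        return "nitrogenous"
    return "ferruginous"


def annotate_zones(
    metadata: pd.DataFrame, boundary_buffer: float = 0.0
) -> pd.DataFrame:
    """Return a copy of the metadata with the ``zone`` column populated.

    ``boundary_buffer`` > 0 adds a boolean ``transitional`` column marking
    samples whose midpoint lies within that many cm of the O2 or NO3
    penetration depth of their site.
    """
    SAMPLE_METADATA.validate(metadata)
    out = metadata.copy()
    zones = []
    for _, row in out.iterrows():
        if pd.isna(row["no3_penetration_cm"]) or pd.isna(row["o2_penetration_cm"]):
            raise ValidationError(
                f"site {row['site_id']}: missing penetration depth for sample "
                f"{row['sample_id']}"
            )
        try:
            zones.append(
                assign_zone(
                    row["depth_top_cm"],
                    row["depth_bottom_cm"],
                    row["o2_penetration_cm"],
                    row["no3_penetration_cm"],
                )
            )
        except ValidationError as err:
            raise ValidationError(f"site {row['site_id']}: {err}") from err
    out["zone"] = pd.array(zones, dtype="string")
    if boundary_buffer > 0:
        mid = 0.5 * (out["depth_top_cm"] + out["depth_bottom_cm"])
        near_o2 = (mid - out["o2_penetration_cm"]).abs() <= boundary_buffer
        near_no3 = (mid - out["no3_penetration_cm"]).abs() <= boundary_buffer
        out["transitional"] = (near_o2 | near_no3).astype("boolean")
    counts = out["zone"].value_counts()
    logger.info(
        "zone assignment: %s",
        ", ".join(f"{z}={int(counts.get(z, 0))}" for z in ZONES),
    )
    return out
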