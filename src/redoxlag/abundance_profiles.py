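"""Relative abundances and abundance-weighted depth profiles.

Coverage is converted to within-sample relative abundance
``p[i, s] = c[i, s] / sum_j c[j, s]`` and then aggregated to groups (phyla,
guilds, secreted-CAZyme strata, ...).  Depth profiles report, per aligned
depth horizon, the mean and standard error of a group's relative abundance
across sites.  CAZyme-family abundance is presence-weighted: the family's
abundance in a sample is the summed relative abundance of the MAGs that carry
at least one copy, irrespective of copy number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    CAZYME_TABLE,
    COVERAGE_MATRIX,
    SAMPLE_METADATA,
    ValidationError,
)

__all__ = [
    "StrataScheme",
    "DEFAULT_STRATA",
    "relative_abundance",
    "aggregate_groups",
    "depth_profile",
    "cazyme_family_abundance",
    "secreted_cazyme_strata",
]

logger = logging.getLogger(__name__)


def relative_abundance(coverage: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a coverage matrix to relative abundances.

    Input is the wide ``coverage_matrix`` layout (``mag_id`` column + one
    column per sample).  Output is indexed by mag_id with sample columns
    summing to 1; an all-zero sample stays all-zero (with a warning) rather
    than becoming NaN.
    """
    COVERAGE_MATRIX.validate(coverage)
    mat = coverage.set_index("mag_id").astype(float)
    totals = mat.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        logger.warning(
            "%d sample(s) with zero total coverage left as all-zero columns: %s",
            len(zero_cols),
            ", ".join(map(str, zero_cols[:5])),
        )
    safe = totals.replace(0, 1.0)
    return mat.div(safe, axis=1)


def aggregate_groups(
    relabund: pd.DataFrame, mapping: Mapping[str, str | Sequence[str]]
) -> pd.DataFrame:
    """Sum member relative abundances per group label.

    ``mapping`` takes each mag_id to one label or a sequence of labels; a MAG
    with several labels contributes its full abundance to each (guild groups
    may therefore sum above 1 within a sample, while any partition sums to
    the column totals exactly).  MAGs missing from the mapping are pooled
    under ``"unassigned"``.
    """
    labels: dict[str, list[str]] = {}
    for mag in relabund.index:
        lab = mapping.get(mag, "unassigned")
        if isinstance(lab, str):
            labels[mag] = [lab]
        else:
            labels[mag] = list(lab) if len(lab) else ["unassigned"]
    all_groups = sorted({g for labs in labels.values() for g in labs})
    out = pd.DataFrame(
        0.0, index=pd.Index(all_groups, name="group"), columns=relabund.columns
    )
    for mag, labs in labels.items():
        for g in labs:
            out.loc[g] += relabund.loc[mag]
    return out


@dataclass(frozen=True)
class DepthProfileRow:
    group: str
    depth_top_cm: float
    depth_bottom_cm: float
    mean: float
    se: float | None
    n_sites: int


def depth_profile(
    group_abund: pd.DataFrame,
    metadata: pd.DataFrame,
    sites: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-horizon mean and standard error of group abundance across sites.

    Horizons are aligned across sites by their exact ``(top, bottom)``
    interval.  The standard error is ``sd / sqrt(n)`` over the sites that
    possess the horizon; horizons present at fewer than two sites report a
    missing SE and are flagged via ``n_sites``.
    """
    SAMPLE_METADATA.validate(metadata)
    meta = metadata
    if sites is not None:
        meta = meta[meta["site_id"].isin(list(sites))]
        if meta.empty:
            raise ValidationError("no metadata rows for the requested sites")
    horizons = sorted(
        {(t, b) for t, b in zip(meta["depth_top_cm"], meta["depth_bottom_cm"])}
    )
    if not horizons:
        raise ValidationError("no overlapping horizons across the requested sites")
    sample_by_site_horizon = {
        (row["site_id"], (row["depth_top_cm"], row["depth_bottom_cm"])): row["sample_id"]
        for _, row in meta.iterrows()
    }
    records = []
    site_ids = sorted(meta["site_id"].unique())
    for group, row in group_abund.iterrows():
        for top, bottom in horizons:
            vals = [
                row[sample_by_site_horizon[(s, (top, bottom))]]
                for s in site_ids
                if (s, (top, bottom)) in sample_by_site_horizon
                and sample_by_site_horizon[(s, (top, bottom))] in row.index
            ]
            n = len(vals)
            if n == 0:
                continue
            mean = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else np.nan
            records.append(
                {
                    "group": group,
                    "depth_top_cm": top,
                    "depth_bottom_cm": bottom,
                    "depth_mid_cm": 0.5 * (top + bottom),
                    "mean": mean,
                    "se": se,
                    "n_sites": n,
                }
            )
    return pd.DataFrame.from_records(records)


def cazyme_family_abundance(
    relabund: pd.DataFrame, cazyme_table: pd.DataFrame
) -> pd.DataFrame:
    """Family x sample table of summed abundance of carrier MAGs.

    Presence-weighted: a MAG with five copies of a family contributes exactly
    as much as a MAG with one copy.
    """
    CAZYME_TABLE.validate(cazyme_table)
    families = sorted(cazyme_table["cazyme_family"].unique())
    out = pd.DataFrame(
        0.0, index=pd.Index(families, name="cazyme_family"), columns=relabund.columns
    )
    for fam, grp in cazyme_table.groupby("cazyme_family"):
        carriers = [m for m in grp["mag_id"].unique() if m in relabund.index]
        if carriers:
            out.loc[fam] = relabund.loc[carriers].sum(axis=0)
    return out


@dataclass(frozen=True)
class StrataScheme:
    """Ordered, disjoint count bins covering 0..infinity.

    ``bins`` is a sequence of ``(lo, hi, label)`` with inclusive integer
    bounds; the last ``hi`` may be ``None`` (unbounded).
    """

    bins: tuple[tuple[int, int | None, str], ...]

    def __post_init__(self) -> None:
        expect = 0
        for k, (lo, hi, _label) in enumerate(self.bins):
            if lo != expect:
                raise ValidationError(
                    f"strata bins must tile 0..inf without gaps/overlaps "
                    f"(bin {k} starts at {lo}, expected {expect})"
                )
            if hi is None:
                if k != len(self.bins) - 1:
                    raise ValidationError("only the last stratum may be unbounded")
                return
            if hi < lo:
                raise ValidationError(f"empty stratum bin ({lo}, {hi})")
            expect = hi + 1
        raise ValidationError("last stratum must be unbounded (hi=None)")

    def label_for(self, count: int) -> str:
        for lo, hi, label in self.bins:
            if count >= lo and (hi is None or count <= hi):
                return label
        raise AssertionError("unreachable: bins cover 0..inf")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label in self.bins)


#: Eight strata of secreted-CAZyme richness, "none" up to "more than eight".
DEFAULT_STRATA = StrataScheme(
    bins=(
        (0, 0, "0"),
        (1, 1, "1"),
        (2, 2, "2"),
        (3, 3, "3"),
        (4, 4, "4"),
        (5, 5, "5"),
        (6, 8, "6-8"),
        (9, None, ">8"),
    )
)


def secreted_cazyme_strata(
    cazyme_table: pd.DataFrame,
    mag_ids: Sequence[str],
    scheme: StrataScheme = DEFAULT_STRATA,
    count_copies: bool = False,
) -> pd.Series:
    """Assign every MAG to one secreted-CAZyme stratum.

    By default the count is the number of DISTINCT families with at least one
    secreted copy; ``count_copies=True`` counts secreted gene copies instead.
    MAGs without any CAZyme rows count as 0.
    """
    CAZYME_TABLE.validate(cazyme_table)
    secreted = cazyme_table[cazyme_table["secreted_copies"] >= 1]
    if count_copies:
        counts = secreted.groupby("mag_id")["secreted_copies"].sum()
    else:
        counts = secreted.groupby("mag_id")["cazyme_family"].nunique()
    out = pd.Series(
        [scheme.label_for(int(counts.get(m, 0))) for m in mag_ids],
        index=pd.Index(mag_ids, name="mag_id"),
        name="stratum",
        dtype="string",
    )
    return out
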