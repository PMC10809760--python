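"""Rule-based classification of MAGs into respiratory guilds.

Capabilities are inferred from annotated marker genes:

* **aerobic** — any of three terminal-oxidase KEGG-style modules (cytochrome
  *c* oxidase, *cbb3*-type cytochrome *c* oxidase, cytochrome *bd* ubiquinol
  oxidase) at >= 50% module completeness, OR membership in a configured
  override family.  The default override family is *Nitrosopumilaceae*,
  whose divergent Complex IV escapes the standard module definitions but
  which are bona fide aerobic ammonia oxidizers.
* **nitrogen** — any step of dissimilatory nitrogen-oxide reduction:
  nitrate reductases napAB (both subunits) or narGHI (>= 2 of the three
  subunits); nitrite reductases nrfAH (both), nirBD (both), nirK/nirS
  (either); nitric-oxide reductase norBC (either); nitrous-oxide reductase
  nosZ.  A "full denitrifier" additionally requires a nitrate reductase plus
  nirK/S, norBC, and nosZ.
* **sulfur** — dissimilatory sulfite reductase dsrAB.  Both subunits are
  required by default (single-subunit hits are commonly fragments); the flag
  records gene presence only and deliberately does not decide between
  reductive and oxidative use of the enzyme.
* **metal** — porin-cytochrome homologs flagged upstream (FeGenie-style).

A MAG with none of the above capabilities is operationally a **fermenter**.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

from .tables_io import (
    GENE_TABLE,
    MAG_CATALOG,
    METAL_FLAGS,
    ModuleDefinition,
    SchemaError,
    taxonomy_rank,
)

__all__ = [
    "ClassifierConfig",
    "OXIDASE_MODULE_KEYS",
    "CAPABILITIES",
    "module_completeness",
    "classify_aerobic",
    "classify_nitrogen",
    "classify_sulfur",
    "classify_guilds",
    "guild_overlap",
]

logger = logging.getLogger(__name__)

#: Required keys into the oxidase module mapping, in reporting order.
OXIDASE_MODULE_KEYS = ("cytc", "cbb3", "bd")

#: Respiratory capability columns, in reporting order.
CAPABILITIES = ("aerobic", "nitrogen", "sulfur_resp", "metal_resp")

NITROGEN_FLAGS = ("napAB", "narGHI", "nrfAH", "nirBD", "nirKS", "norBC", "nosZ")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the rule engine.

    ``completeness_threshold`` is compared with >= (a module at exactly 50%
    completeness counts); ``override_families`` lists family-rank names whose
    members are called aerobic regardless of oxidase annotation;
    ``dsr_require_both`` toggles between requiring both dsrA and dsrB
    (default) or either subunit.
    """

    completeness_threshold: Fraction = Fraction(1, 2)
    override_families: tuple[str, ...] = ("Nitrosopumilaceae",)
    dsr_require_both: bool = True


def module_completeness(genes: Iterable[str], module: ModuleDefinition) -> Fraction:
    """Fraction of module steps with at least one alternative present.

    Exact rational arithmetic so that threshold comparisons (e.g. 2/4 >= 1/2)
    are never subject to rounding.
    """
    gene_set = set(genes)
    hit = sum(1 for step in module.steps if gene_set & step)
    return Fraction(hit, len(module.steps))


def classify_aerobic(
    genes: Iterable[str],
    modules: Mapping[str, ModuleDefinition],
    taxonomy: str,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict[str, bool]:
    """Terminal-oxidase flags plus the taxon override.

    ``modules`` must supply definitions under the keys ``cytc``, ``cbb3``
    and ``bd``.
    """
    missing = [k for k in OXIDASE_MODULE_KEYS if k not in modules]
    if missing:
        raise SchemaError(f"missing oxidase module definition(s): {', '.join(missing)}")
    gene_set = set(genes)
    flags = {
        "has_cytc_oxidase": module_completeness(gene_set, modules["cytc"])
        >= config.completeness_threshold,
        "has_cbb3": module_completeness(gene_set, modules["cbb3"])
        >= config.completeness_threshold,
        "has_bd": module_completeness(gene_set, modules["bd"])
        >= config.completeness_threshold,
    }
    family = taxonomy_rank(taxonomy, "family")
    flags["taxon_override_aerobic"] = family in config.override_families
    return flags


def classify_nitrogen(genes: Iterable[str]) -> dict[str, bool]:
    """Seven nitrogen-respiration flags plus the full-denitrifier call."""
    g = set(genes)
    flags = {
        "napAB": {"napA", "napB"} <= g,
        "narGHI": len(g & {"narG", "narH", "narI"}) >= 2,
        "nrfAH": {"nrfA", "nrfH"} <= g,
        "nirBD": {"nirB", "nirD"} <= g,
        "nirKS": bool(g & {"nirK", "nirS"}),
        "norBC": bool(g & {"norB", "norC"}),
        "nosZ": "nosZ" in g,
    }
    flags["full_denitrifier"] = (
        (flags["napAB"] or flags["narGHI"])
        and flags["nirKS"]
        and flags["norBC"]
        and flags["nosZ"]
    )
    return flags


def classify_sulfur(
    genes: Iterable[str], config: ClassifierConfig = ClassifierConfig()
) -> bool:
    """dsrAB presence flag (both subunits by default)."""
    g = set(genes)
    if config.dsr_require_both:
        return {"dsrA", "dsrB"} <= g
    return bool(g & {"dsrA", "dsrB"})


def _derive(flags: dict[str, bool], metal: bool) -> dict[str, bool]:
    derived = {
        "aerobic": flags["has_cytc_oxidase"]
        or flags["has_cbb3"]
        or flags["has_bd"]
        or flags["taxon_override_aerobic"],
        "nitrogen": any(flags[k] for k in NITROGEN_FLAGS),
        "sulfur_resp": flags["dsrAB"],
        "metal_resp": bool(metal),
    }
    derived["fermenter"] = not any(derived[c] for c in CAPABILITIES)
    return derived


def classify_guilds(
    catalog: pd.DataFrame,
    gene_table: pd.DataFrame,
    metal_flags: pd.DataFrame,
    modules: Mapping[str, ModuleDefinition],
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Classify every MAG in the catalog; one row per MAG.

    MAGs absent from the gene table are classified from an empty gene set
    (with a warning), so an unannotated genome comes out as a fermenter
    unless rescued by the taxon override or the metal flag.
    """
    MAG_CATALOG.validate(catalog)
    GENE_TABLE.validate(gene_table)
    METAL_FLAGS.validate(metal_flags)
    genes_by_mag = {
        mag: set(grp["feature_id"]) for mag, grp in gene_table.groupby("mag_id")
    }
    metal_by_mag = dict(
        zip(metal_flags["mag_id"], metal_flags["porin_cytochrome_homolog"])
    )
    missing = [m for m in catalog["mag_id"] if m not in genes_by_mag]
    if missing:
        logger.warning(
            "%d MAG(s) absent from the gene table; classified from empty gene sets "
            "(first: %s)",
            len(missing),
            missing[0],
        )
    rows = []
    for _, rec in catalog.iterrows():
        mag = rec["mag_id"]
        genes = genes_by_mag.get(mag, set())
        flags: dict[str, bool] = {"mag_id": mag}
        flags.update(classify_aerobic(genes, modules, rec["taxonomy"], config))
        flags.update(classify_nitrogen(genes))
        flags["dsrAB"] = classify_sulfur(genes, config)
        flags.update(_derive(flags, bool(metal_by_mag.get(mag, False))))
        rows.append(flags)
    return pd.DataFrame(rows)


def guild_overlap(assignments: pd.DataFrame) -> dict[str, int]:
    """Counts for every nonempty capability subset plus the fermenter count.

    Region keys join capability names with ``+`` in the fixed order
    ``aerobic, nitrogen, sulfur_resp, metal_resp``; each non-fermenter MAG
    falls in exactly one region, so region counts plus the fermenter count
    partition the catalog.
    """
    counts: dict[str, int] = {}
    for r in range(1, len(CAPABILITIES) + 1):
        for combo in itertools.combinations(CAPABILITIES, r):
            counts["+".join(combo)] = 0
    counts["fermenter"] = 0
    for _, row in assignments.iterrows():
        if row["fermenter"]:
            counts["fermenter"] += 1
            continue
        combo = tuple(c for c in CAPABILITIES if row[c])
        counts["+".join(combo)] += 1
    return counts
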