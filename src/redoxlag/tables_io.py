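"""Schemas, validation, and TSV round-trip I/O for the pipeline's tabular data.

All pipeline stages exchange plain UTF-8 TSV files with a header row; the
decimal separator is "." and the empty string denotes a missing value.  Each
table kind has a :class:`TableSchema` that is the single source of truth for
its columns and invariants:

``MAG_CATALOG``
    One row per metagenome-assembled genome (MAG): id, 7-rank taxonomy
    string, completeness and redundancy percentages, optional genome size.
``GENE_TABLE``
    Sparse (mag_id, feature_id, copies) triples of annotated KEGG orthologs
    or gene symbols (narG, nosZ, dsrA, ...).
``METAL_FLAGS``
    Per-MAG boolean for the presence of porin-cytochrome homologs, i.e. the
    marker used to call iron/manganese (metal) respiration.
``CAZYME_TABLE``
    Sparse (mag_id, cazyme_family, copies, secreted_copies) rows; families
    use the standard GH/PL/CBM/GT/CE/AA nomenclature and ``secreted_copies``
    counts genes of the family carrying a secretion signal peptide.
``COVERAGE_MATRIX``
    Wide matrix of mean read coverage, one row per MAG, one column per
    sample.
``SAMPLE_METADATA``
    Per-sample core geometry (depth interval in cm below the sediment
    surface, half-open ``[top, bottom)``; midpoint is the representative
    depth), site, water depth, O2 and NO3 penetration depths, sedimentation
    rate in mm/yr, and an optional derived redox-zone label.

KEGG-style module definitions (ordered steps, each a set of alternative
orthologs) are handled by :class:`ModuleDefinition` and its own TSV dialect
``(module_id, step_index, alternatives comma-joined)``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "TableSchema",
    "ModuleDefinition",
    "MAG_CATALOG",
    "GENE_TABLE",
    "METAL_FLAGS",
    "CAZYME_TABLE",
    "COVERAGE_MATRIX",
    "SAMPLE_METADATA",
    "SCHEMAS",
    "ZONES",
    "read_table",
    "write_table",
    "read_module_definitions",
    "write_module_definitions",
    "split_taxonomy",
    "taxonomy_rank",
]


class SchemaError(ValueError):
    """A file does not have the columns the schema requires."""


class ValidationError(ValueError):
    """A table violates one of its schema's invariants."""


#: Redox-zone labels in order of increasing sediment depth.
ZONES = ("oxic", "nitrogenous", "ferruginous")

CAZYME_FAMILY_RE = re.compile(r"^(GH|PL|CBM|GT|CE|AA)[0-9]+$")

#: Plausibility band for lead-210-derived sedimentation rates (mm/yr).
SEDIMENTATION_RATE_BAND = (0.01, 10.0)

_TAX_PREFIX_RE = re.compile(r"^[dpcofgs]__")


def split_taxonomy(taxonomy: str) -> list[str]:
    """Split a 7-rank, semicolon-delimited lineage into bare rank names.

    GTDB-style rank prefixes (``d__``, ``p__``, ... ``s__``) are accepted and
    stripped; empty ranks stay empty strings.
    """
    parts = [p.strip() for p in str(taxonomy).split(";")]
    return [_TAX_PREFIX_RE.sub("", p) for p in parts]


def taxonomy_rank(taxonomy: str, rank: str) -> str:
    """Return one named rank (``domain`` ... ``species``) of a lineage string."""
    names = ("domain", "phylum", "class", "order", "family", "genus", "species")
    parts = split_taxonomy(taxonomy)
    if len(parts) != 7:
        raise ValidationError(
            f"taxonomy {taxonomy!r} has {len(parts)} rank slots, expected 7"
        )
    return parts[names.index(rank)]


@dataclass(frozen=True)
class TableSchema:
    """Column layout plus invariant checks for one table kind."""

    name: str
    key_columns: tuple[str, ...]
    #: column -> pandas dtype used on read/write ("string", "Int64", "float64", "boolean")
    columns: dict[str, str]
    optional: tuple[str, ...] = ()
    #: extra columns beyond ``columns`` allowed (wide matrices)
    open_columns: bool = False
    validator: Callable[[pd.DataFrame], None] | None = None

    def required_columns(self) -> list[str]:
        return [c for c in self.columns if c not in self.optional]

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        """Check columns and invariants; return the (unmodified) frame."""
        missing = [c for c in self.required_columns() if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{self.name}: missing required column(s) {', '.join(missing)}"
            )
        if not self.open_columns:
            unknown = [c for c in df.columns if c not in self.columns]
            if unknown:
                raise SchemaError(
                    f"{self.name}: unexpected column(s) {', '.join(unknown)}"
                )
        if self.validator is not None:
            self.validator(df)
        return df


def _require_unique(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    dup = df.duplicated(subset=list(cols))
    if dup.any():
        row = df.loc[dup.idxmax(), list(cols)].tolist()
        raise ValidationError(f"{name}: duplicate key {tuple(row)!r}")


def _require_numeric_range(
    series: pd.Series,
    lo: float,
    hi: float,
    name: str,
    label: str,
    lo_open: bool = False,
    hi_open: bool = False,
) -> None:
    vals = series.astype(float)
    if vals.isna().any():
        raise ValidationError(f"{name}: missing {label} in row {int(vals.isna().idxmax())}")
    bad_lo = vals <= lo if lo_open else vals < lo
    bad_hi = vals >= hi if hi_open else vals > hi
    bad = bad_lo | bad_hi | ~np.isfinite(vals)
    if bad.any():
        i = bad.idxmax()
        raise ValidationError(
            f"{name}: {label}={vals[i]!r} out of range in row {int(i)}"
        )


def _validate_mag_catalog(df: pd.DataFrame) -> None:
    _require_unique(df, ["mag_id"], "mag_catalog")
    _require_numeric_range(df["completeness"], 75.0, 100.0, "mag_catalog", "completeness")
    _require_numeric_range(
        df["redundancy"], 0.0, 10.0, "mag_catalog", "redundancy", hi_open=True
    )
    for i, tax in df["taxonomy"].items():
        if len(split_taxonomy(tax)) != 7:
            raise ValidationError(
                f"mag_catalog: taxonomy {tax!r} in row {int(i)} does not have 7 rank slots"
            )
    if "genome_size" in df.columns:
        sizes = df["genome_size"].dropna()
        if (sizes <= 0).any():
            raise ValidationError("mag_catalog: genome_size must be > 0")


def _validate_gene_table(df: pd.DataFrame) -> None:
    _require_unique(df, ["mag_id", "feature_id"], "gene_table")
    copies = df["copies"]
    if copies.isna().any() or (copies < 1).any():
        i = (copies.isna() | (copies < 1)).idxmax()
        raise ValidationError(f"gene_table: copies must be an integer >= 1 (row {int(i)})")


def _validate_metal_flags(df: pd.DataFrame) -> None:
    _require_unique(df, ["mag_id"], "metal_flags")
    if df["porin_cytochrome_homolog"].isna().any():
        raise ValidationError("metal_flags: porin_cytochrome_homolog must be true/false")


def _validate_cazyme_table(df: pd.DataFrame) -> None:
    _require_unique(df, ["mag_id", "cazyme_family"], "cazyme_table")
    for i, fam in df["cazyme_family"].items():
        if not CAZYME_FAMILY_RE.match(str(fam)):
            raise ValidationError(
                f"cazyme_table: family {fam!r} in row {int(i)} does not match "
                "GH/PL/CBM/GT/CE/AA naming"
            )
    if (df["copies"] < 1).any():
        raise ValidationError("cazyme_table: copies must be >= 1")
    if (df["secreted_copies"] < 0).any():
        raise ValidationError("cazyme_table: secreted_copies must be >= 0")
    bad = df["secreted_copies"] > df["copies"]
    if bad.any():
        i = bad.idxmax()
        raise ValidationError(
            f"cazyme_table: secreted_copies > copies for "
            f"({df.loc[i, 'mag_id']}, {df.loc[i, 'cazyme_family']})"
        )


def _validate_coverage_matrix(df: pd.DataFrame) -> None:
    _require_unique(df, ["mag_id"], "coverage_matrix")
    sample_cols = [c for c in df.columns if c != "mag_id"]
    if len(set(sample_cols)) != len(sample_cols):
        raise ValidationError("coverage_matrix: duplicate sample columns")
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            i = bad.idxmax()
            raise ValidationError(
                f"coverage_matrix: invalid coverage at (mag {df.loc[i, 'mag_id']}, "
                f"sample {col}): {df.loc[i, col]!r}"
            )


def _validate_sample_metadata(df: pd.DataFrame) -> None:
    _require_unique(df, ["sample_id"], "sample_metadata")
    _require_numeric_range(
        df["depth_top_cm"], 0.0, math.inf, "sample_metadata", "depth_top_cm"
    )
    if (df["depth_bottom_cm"] <= df["depth_top_cm"]).any():
        bad = (df["depth_bottom_cm"] <= df["depth_top_cm"]).idxmax()
        raise ValidationError(
            f"sample_metadata: depth_bottom_cm <= depth_top_cm for sample "
            f"{df.loc[bad, 'sample_id']}"
        )
    _require_numeric_range(
        df["water_depth_m"], 0.0, math.inf, "sample_metadata", "water_depth_m", lo_open=True
    )
    for site, grp in df.groupby("site_id"):
        o2 = grp["o2_penetration_cm"]
        no3 = grp["no3_penetration_cm"]
        if (o2 <= 0).any():
            raise ValidationError(f"sample_metadata: o2_penetration_cm <= 0 at site {site}")
        if (no3 <= o2).any():
            raise ValidationError(
                f"sample_metadata: no3_penetration_cm <= o2_penetration_cm at site {site}"
            )
        g = grp.sort_values("depth_top_cm")
        overlap = g["depth_top_cm"].values[1:] < g["depth_bottom_cm"].values[:-1]
        if overlap.any():
            raise ValidationError(
                f"sample_metadata: overlapping depth intervals at site {site}"
            )
    rates = df["sedimentation_rate_mm_yr"]
    if (rates <= 0).any():
        raise ValidationError("sample_metadata: sedimentation_rate_mm_yr must be > 0")
    lo, hi = SEDIMENTATION_RATE_BAND
    if ((rates < lo) | (rates > hi)).any():
        warnings.warn(
            f"sample_metadata: sedimentation rate outside the plausibility band "
            f"{SEDIMENTATION_RATE_BAND} mm/yr",
            stacklevel=3,
        )
    if "zone" in df.columns:
        known = df["zone"].dropna()
        bad = ~known.isin(ZONES)
        if bad.any():
            raise ValidationError(
                f"sample_metadata: unknown zone label {known[bad.idxmax()]!r}"
            )


MAG_CATALOG = TableSchema(
    name="mag_catalog",
    key_columns=("mag_id",),
    columns={
        "mag_id": "string",
        "taxonomy": "string",
        "completeness": "float64",
        "redundancy": "float64",
        "genome_size": "Int64",
    },
    optional=("genome_size",),
    validator=_validate_mag_catalog,
)

GENE_TABLE = TableSchema(
    name="gene_table",
    key_columns=("mag_id", "feature_id"),
    columns={"mag_id": "string", "feature_id": "string", "copies": "Int64"},
    validator=_validate_gene_table,
)

METAL_FLAGS = TableSchema(
    name="metal_flags",
    key_columns=("mag_id",),
    columns={"mag_id": "string", "porin_cytochrome_homolog": "boolean"},
    validator=_validate_metal_flags,
)

CAZYME_TABLE = TableSchema(
    name="cazyme_table",
    key_columns=("mag_id", "cazyme_family"),
    columns={
        "mag_id": "string",
        "cazyme_family": "string",
        "copies": "Int64",
        "secreted_copies": "Int64",
    },
    validator=_validate_cazyme_table,
)

COVERAGE_MATRIX = TableSchema(
    name="coverage_matrix",
    key_columns=("mag_id",),
    columns={"mag_id": "string"},
    open_columns=True,
    validator=_validate_coverage_matrix,
)

SAMPLE_METADATA = TableSchema(
    name="sample_metadata",
    key_columns=("sample_id",),
    columns={
        "sample_id": "string",
        "site_id": "string",
        "depth_top_cm": "float64",
        "depth_bottom_cm": "float64",
        "water_depth_m": "float64",
        "o2_penetration_cm": "float64",
        "no3_penetration_cm": "float64",
        "sedimentation_rate_mm_yr": "float64",
        "zone": "string",
    },
    optional=("zone",),
    validator=_validate_sample_metadata,
)

SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        MAG_CATALOG,
        GENE_TABLE,
        METAL_FLAGS,
        CAZYME_TABLE,
        COVERAGE_MATRIX,
        SAMPLE_METADATA,
    )
}


def _dtype_map(schema: TableSchema, columns: Sequence[str]) -> dict[str, str]:
    if schema.open_columns:
        out = {c: schema.columns.get(c, "float64") for c in columns}
    else:
        out = {c: schema.columns[c] for c in columns if c in schema.columns}
    return out


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read one TSV table and validate it against ``schema``.

    Row order is preserved.  Raises :class:`SchemaError` for missing/unknown
    columns and :class:`ValidationError` for invariant violations, naming the
    offending column or row.
    """
    path = Path(path)
    header = pd.read_csv(path, sep="\t", nrows=0)
    dtypes = _dtype_map(schema, header.columns)
    # boolean columns are serialised as true/false strings; read as strings
    read_dtypes = {c: ("string" if d == "boolean" else d) for c, d in dtypes.items()}
    df = pd.read_csv(
        path, sep="\t", dtype=read_dtypes, keep_default_na=True, na_values=[""]
    )
    for col, dt in dtypes.items():
        if dt == "boolean":
            df[col] = (
                df[col]
                .map({"true": True, "false": False, "True": True, "False": False})
                .astype("boolean")
            )
    return schema.validate(df.reset_index(drop=True))


def write_table(df: pd.DataFrame, schema: TableSchema, path: str | Path) -> Path:
    """Validate and write ``df`` as TSV; inverse of :func:`read_table`.

    Booleans are serialised as ``true``/``false`` and missing values as the
    empty string so that ``read_table(write_table(t)) == t``.
    """
    schema.validate(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if str(out[col].dtype) == "boolean" or out[col].dtype == bool:
            out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, na_rep="")
    return path


# ---------------------------------------------------------------------------
# KEGG-style module definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleDefinition:
    """An ordered sequence of reaction steps, each a set of alternative features.

    Module completeness of a genome is the fraction of steps for which at
    least one alternative feature is annotated; a step therefore acts as an
    OR over its alternatives and the module as an (unordered) AND over steps.
    """

    module_id: str
    steps: tuple[frozenset[str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValidationError(f"module {self.module_id}: needs >= 1 step")
        for k, step in enumerate(self.steps):
            if not step:
                raise ValidationError(f"module {self.module_id}: step {k} is empty")


def read_module_definitions(path: str | Path) -> dict[str, ModuleDefinition]:
    """Read module definitions from TSV (module_id, step_index, alternatives).

    ``alternatives`` is a comma-joined set of feature ids; step indices must
    start at 0 (or 1) and be consecutive within a module.
    """
    df = pd.read_csv(path, sep="\t", dtype={"module_id": str, "alternatives": str})
    for col in ("module_id", "step_index", "alternatives"):
        if col not in df.columns:
            raise SchemaError(f"module_definitions: missing required column(s) {col}")
    modules: dict[str, ModuleDefinition] = {}
    for mod_id, grp in df.groupby("module_id", sort=False):
        grp = grp.sort_values("step_index")
        idx = grp["step_index"].tolist()
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValidationError(f"module {mod_id}: step indices not consecutive")
        steps = tuple(
            frozenset(a.strip() for a in str(alts).split(",") if a.strip())
            for alts in grp["alternatives"]
        )
        modules[str(mod_id)] = ModuleDefinition(str(mod_id), steps)
    return modules


def write_module_definitions(
    modules: dict[str, ModuleDefinition], path: str | Path
) -> Path:
    rows = []
    for mod in modules.values():
        for k, step in enumerate(mod.steps):
            rows.append(
                {
                    "module_id": mod.module_id,
                    "step_index": k,
                    "alternatives": ",".join(sorted(step)),
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
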