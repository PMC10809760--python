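"""Synthetic hadal-sediment community generator with planted ground truth.

Emulates the seven tables an upstream metagenomic workflow would produce
(MAG catalog, gene annotations, metal-reduction flags, CAZyme table,
coverage matrix, sample metadata, module definitions) for a multi-site
sediment-core study, while recording exactly which guild each MAG belongs to
and which kinetic parameters govern each guild's depth trajectory.

MAGs are drawn from archetypes whose gene content is sufficient and
necessary to trigger the intended classifier flags:

========================  =============================================
archetype                 intended capability flags
========================  =============================================
``strict_aerobe``         aerobic (full cytochrome c oxidase module)
``aerobe_nitrogen``       aerobic + nitrogen (cytc module + narG, narH)
``nitrifier``             aerobic via the *Nitrosopumilaceae* override
``anammox``               aerobic (cbb3 module) + nitrogen (nirS)
``sulfur``                sulfur (dsrA + dsrB)
``metal``                 metal (porin-cytochrome flag)
``fermenter``             none -> fermenter; carries secreted CAZymes
``subsurface_sulfur``     sulfur; absorbs the community balance at depth
========================  =============================================

Depth trajectories are piecewise log-linear in sediment age with C0
continuity at zone boundaries: aerobic/nitrogen archetypes hold a constant
share through the oxic and nitrogenous zones and decay exponentially below
the nitrate penetration depth with a per-site half-life; fermenters hold a
low plateau, grow exponentially (fixed doubling distance in cm) inside a
configured depth window, and plateau again below it.  The
``subsurface_sulfur`` pool takes up whatever share remains, so the total
community coverage is constant across depth by construction (mirroring the
constant-total-cell-abundance assumption under which relative abundances are
read as cell densities).  Observed coverage multiplies the expected value by
lognormal noise, ``exp(sigma * Z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    CAZYME_TABLE,
    COVERAGE_MATRIX,
    GENE_TABLE,
    MAG_CATALOG,
    METAL_FLAGS,
    SAMPLE_METADATA,
    ModuleDefinition,
    ValidationError,
)

__all__ = [
    "ARCHETYPES",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "default_oxidase_modules",
    "simulate_catalog",
    "simulate_core",
    "simulate_all",
]

LN2 = math.log(2.0)

ARCHETYPES = (
    "strict_aerobe",
    "aerobe_nitrogen",
    "nitrifier",
    "anammox",
    "sulfur",
    "metal",
    "fermenter",
    "subsurface_sulfur",
)

#: archetypes whose share decays exponentially in the ferruginous zone
_DECAYING = ("strict_aerobe", "aerobe_nitrogen", "nitrifier", "anammox")

_TAXONOMY = {
    "strict_aerobe": "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Woeseiales;f__Woeseiaceae;g__;s__",
    "aerobe_nitrogen": "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhodobacterales;f__Rhodobacteraceae;g__;s__",
    "nitrifier": "d__Archaea;p__Thermoproteota;c__Nitrososphaeria;o__Nitrosopumilales;f__Nitrosopumilaceae;g__;s__",
    "anammox": "d__Bacteria;p__Planctomycetota;c__Brocadiae;o__Brocadiales;f__Brocadiaceae;g__;s__",
    "sulfur": "d__Bacteria;p__Desulfobacterota;c__Desulfobacteria;o__Desulfobacterales;f__Desulfobacteraceae;g__;s__",
    "metal": "d__Bacteria;p__Zixibacteria;c__MSB-5A5;o__;f__;g__;s__",
    "fermenter": "d__Bacteria;p__Chloroflexota;c__Anaerolineae;o__Anaerolineales;f__Anaerolineaceae;g__;s__",
    "subsurface_sulfur": "d__Bacteria;p__Desulfobacterota;c__Desulfobacteria;o__Desulfatiglandales;f__Desulfatiglandaceae;g__;s__",
}

_GENES = {
    "strict_aerobe": ("coxA", "coxB", "coxC"),
    "aerobe_nitrogen": ("coxA", "coxB", "coxC", "narG", "narH"),
    "nitrifier": ("amoA", "amoB"),
    "anammox": ("ccoN", "ccoO", "ccoP", "nirS", "hzsA"),
    "sulfur": ("dsrA", "dsrB"),
    "metal": ("mtrA",),
    "fermenter": ("hydA",),
    "subsurface_sulfur": ("dsrA", "dsrB"),
}

#: intended capability flags per archetype (the classifier must reproduce these)
_TRUTH_FLAGS = {
    "strict_aerobe": dict(aerobic=True, nitrogen=False, sulfur_resp=False, metal_resp=False),
    "aerobe_nitrogen": dict(aerobic=True, nitrogen=True, sulfur_resp=False, metal_resp=False),
    "nitrifier": dict(aerobic=True, nitrogen=False, sulfur_resp=False, metal_resp=False),
    "anammox": dict(aerobic=True, nitrogen=True, sulfur_resp=False, metal_resp=False),
    "sulfur": dict(aerobic=False, nitrogen=False, sulfur_resp=True, metal_resp=False),
    "metal": dict(aerobic=False, nitrogen=False, sulfur_resp=False, metal_resp=True),
    "fermenter": dict(aerobic=False, nitrogen=False, sulfur_resp=False, metal_resp=False),
    "subsurface_sulfur": dict(aerobic=False, nitrogen=False, sulfur_resp=True, metal_resp=False),
}

_CAZYME_POOL = (
    "GH23",
    "GH103",
    "GH102",
    "GH5",
    "GH6",
    "GH15",
    "GH16",
    "GH29",
    "GH109",
    "PL7",
    "PL12",
    "CBM44",
)


def default_oxidase_modules() -> dict[str, ModuleDefinition]:
    """Illustrative three-step definitions of the three oxidase modules."""
    return {
        "cytc": ModuleDefinition(
            "M_CYTC",
            (frozenset({"coxA"}), frozenset({"coxB"}), frozenset({"coxC", "coxD"})),
        ),
        "cbb3": ModuleDefinition(
            "M_CBB3", (frozenset({"ccoN"}), frozenset({"ccoO"}), frozenset({"ccoP"}))
        ),
        "bd": ModuleDefinition(
            "M_BD", (frozenset({"cydA"}), frozenset({"cydB"}), frozenset({"cydX", "appX"}))
        ),
    }


def _per_site(value, n_sites: int, name: str) -> np.ndarray:
    """Broadcast a scalar / (lo, hi) band / explicit sequence to one value per site."""
    if np.isscalar(value):
        return np.full(n_sites, float(value))
    vals = np.asarray(value, dtype=float)
    if vals.shape == (2,) and n_sites != 2:
        return np.linspace(vals[0], vals[1], n_sites)
    if vals.shape == (n_sites,):
        return vals
    raise ValidationError(
        f"{name}: expected a scalar, a (lo, hi) band, or {n_sites} per-site values"
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and planted dynamics of the synthetic cores.

    Defaults mirror the hadal study layout: six sites, slices of 1 cm down
    to 10 cm and 2.5 cm below, O2 penetration spanning 2.6-4.1 cm, NO3
    penetration ~8 cm, sedimentation rates spanning 0.29-0.76 mm/yr,
    respiratory decay half-lives spanning 135-367 yr across sites, a
    fermenter doubling distance of 1.4 cm inside a 6.5-9.5 cm growth window,
    and lognormal coverage noise of sigma = 0.3.
    """

    n_mags: Mapping[str, int] = field(
        default_factory=lambda: {
            "strict_aerobe": 12,
            "aerobe_nitrogen": 20,
            "nitrifier": 6,
            "anammox": 4,
            "sulfur": 5,
            "metal": 5,
            "fermenter": 12,
            "subsurface_sulfur": 8,
        }
    )
    n_sites: int = 6
    max_depth_cm: float = 20.0
    fine_resolution_cm: float = 1.0
    fine_to_cm: float = 10.0
    coarse_resolution_cm: float = 2.5
    o2_penetration_cm: float | Sequence[float] = (2.6, 4.1)
    no3_penetration_cm: float | Sequence[float] = 8.0
    sedimentation_rate_mm_yr: float | Sequence[float] = (0.29, 0.76)
    water_depth_m: float | Sequence[float] = (7720.0, 8085.0)
    respiratory_half_life_yr: float | Sequence[float] = (135.0, 367.0)
    fermenter_doubling_distance_cm: float = 1.4
    growth_window_cm: tuple[float, float] = (6.5, 9.5)
    surface_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "strict_aerobe": 0.20,
            "aerobe_nitrogen": 0.30,
            "nitrifier": 0.12,
            "anammox": 0.02,
            "sulfur": 0.03,
            "metal": 0.02,
            "fermenter": 0.03,
        }
    )
    noise_sigma: float = 0.3
    total_coverage: float = 100.0

    def validate(self) -> None:
        for arch, n in self.n_mags.items():
            if arch not in ARCHETYPES:
                raise ValidationError(f"unknown archetype {arch!r}")
            if n < 1:
                raise ValidationError(f"archetype {arch!r} requests {n} MAGs (need >= 1)")
        if "subsurface_sulfur" not in self.n_mags:
            raise ValidationError("the subsurface_sulfur balance pool is required")
        if self.n_sites < 1:
            raise ValidationError("need >= 1 site")
        o2 = _per_site(self.o2_penetration_cm, self.n_sites, "o2_penetration_cm")
        no3 = _per_site(self.no3_penetration_cm, self.n_sites, "no3_penetration_cm")
        if np.any(o2 <= 0) or np.any(no3 <= o2):
            raise ValidationError("need 0 < o2_penetration < no3_penetration per site")
        for name in ("sedimentation_rate_mm_yr", "respiratory_half_life_yr"):
            if np.any(_per_site(getattr(self, name), self.n_sites, name) <= 0):
                raise ValidationError(f"{name} must be > 0")
        if self.fermenter_doubling_distance_cm <= 0:
            raise ValidationError("fermenter_doubling_distance_cm must be > 0")
        if not 0 <= self.noise_sigma:
            raise ValidationError("noise_sigma must be >= 0")
        g0, g1 = self.growth_window_cm
        if not 0 <= g0 < g1 <= self.max_depth_cm:
            raise ValidationError("growth window must lie within the core")
        if sum(self.surface_shares.values()) >= 1.0:
            raise ValidationError("surface shares must sum to < 1 (balance pool)")

    def horizon_grid(self) -> list[tuple[float, float]]:
        """Half-open depth intervals [top, bottom) of one core."""
        if self.fine_resolution_cm <= 0 or self.coarse_resolution_cm <= 0:
            raise ValidationError("slice resolutions must be > 0")
        bounds = [0.0]
        while bounds[-1] + self.fine_resolution_cm <= self.fine_to_cm + 1e-9:
            bounds.append(round(bounds[-1] + self.fine_resolution_cm, 6))
        while bounds[-1] + self.coarse_resolution_cm <= self.max_depth_cm + 1e-9:
            bounds.append(round(bounds[-1] + self.coarse_resolution_cm, 6))
        if len(bounds) < 2:
            raise ValidationError("horizon grid is empty")
        if any(b <= a for a, b in zip(bounds, bounds[1:])) or bounds[0] < 0:
            raise ValidationError("horizon grid must start at 0 and increase")
        return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class GroundTruth:
    """What the simulator planted, keyed the same way the pipeline reports.

    ``guild_flags``: per-MAG archetype and capability flags.
    ``kinetics``: per site x guild planted rate constants and
    half-life/doubling times with the depth windows where they apply.
    ``zones``: true redox-zone label per sample (filled by the core
    simulation).
    """

    guild_flags: pd.DataFrame
    kinetics: pd.DataFrame | None = None
    zones: pd.DataFrame | None = None


@dataclass
class SimulatedDataset:
    catalog: pd.DataFrame
    gene_table: pd.DataFrame
    metal_flags: pd.DataFrame
    cazyme_table: pd.DataFrame
    coverage: pd.DataFrame
    metadata: pd.DataFrame
    modules: dict[str, ModuleDefinition]
    truth: GroundTruth


def _secreted_family_count(rng: np.random.Generator, archetype: str) -> int:
    if archetype in ("fermenter", "subsurface_sulfur"):
        # zero-inflated geometric spanning all secretion strata (0..12)
        if rng.random() < 0.12:
            return 0
        return int(min(rng.geometric(0.25), 12))
    if archetype in ("strict_aerobe", "aerobe_nitrogen"):
        return int(rng.choice([1, 2, 3], p=[0.2, 0.5, 0.3]))
    if archetype == "nitrifier":
        return 0
    return int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2]))


def simulate_catalog(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the MAG catalog, gene/CAZyme content, metal flags, and truth flags."""
    config.validate()
    rng = np.random.default_rng(seed)
    catalog_rows, gene_rows, metal_rows, caz_rows, truth_rows = [], [], [], [], []
    mag_no = 0
    for arch in ARCHETYPES:
        n = int(config.n_mags.get(arch, 0))
        for _ in range(n):
            mag_no += 1
            mag = f"MAG_{mag_no:04d}"
            catalog_rows.append(
                {
                    "mag_id": mag,
                    "taxonomy": _TAXONOMY[arch],
                    "completeness": round(float(rng.uniform(75.0, 100.0)), 1),
                    "redundancy": round(float(rng.uniform(0.0, 9.8)), 1),
                    "genome_size": int(rng.integers(1_500_000, 8_000_000)),
                }
            )
            for gene in _GENES[arch]:
                gene_rows.append(
                    {"mag_id": mag, "feature_id": gene, "copies": int(rng.integers(1, 4))}
                )
            metal_rows.append(
                {"mag_id": mag, "porin_cytochrome_homolog": arch == "metal"}
            )
            n_secreted = _secreted_family_count(rng, arch)
            # secreted families first, then a few strictly intracellular ones
            n_plain = int(rng.integers(0, 3))
            fams = rng.choice(
                _CAZYME_POOL, size=min(n_secreted + n_plain, len(_CAZYME_POOL)), replace=False
            )
            for k, fam in enumerate(fams):
                secreted = k < n_secreted
                copies = int(rng.integers(1, 4))
                caz_rows.append(
                    {
                        "mag_id": mag,
                        "cazyme_family": str(fam),
                        "copies": copies,
                        "secreted_copies": int(rng.integers(1, copies + 1)) if secreted else 0,
                    }
                )
            flags = _TRUTH_FLAGS[arch]
            truth_rows.append(
                {
                    "mag_id": mag,
                    "archetype": arch,
                    **flags,
                    "fermenter": not any(flags.values()),
                }
            )
    catalog = pd.DataFrame(catalog_rows).astype({"mag_id": "string", "taxonomy": "string"})
    gene_table = pd.DataFrame(gene_rows).astype({"mag_id": "string", "feature_id": "string"})
    metal_flags = pd.DataFrame(metal_rows).astype(
        {"mag_id": "string", "porin_cytochrome_homolog": "boolean"}
    )
    cazyme_table = pd.DataFrame(caz_rows).astype(
        {"mag_id": "string", "cazyme_family": "string"}
    )
    MAG_CATALOG.validate(catalog)
    GENE_TABLE.validate(gene_table)
    METAL_FLAGS.validate(metal_flags)
    CAZYME_TABLE.validate(cazyme_table)
    truth = GroundTruth(guild_flags=pd.DataFrame(truth_rows))
    return catalog, gene_table, metal_flags, cazyme_table, truth


def _expected_share(
    arch: str,
    z_mid: float,
    site: dict[str, float],
    config: SimulationConfig,
) -> float:
    """Noise-free relative abundance of one archetype at one depth."""
    base = float(config.surface_shares.get(arch, 0.0))
    if arch in _DECAYING:
        z_fe = site["no3"]
        if z_mid <= z_fe:
            return base
        years = 10.0 * (z_mid - z_fe) / site["omega"]
        return base * 2.0 ** (-years / site["half_life"])
    if arch == "fermenter":
        g0, g1 = config.growth_window_cm
        d = config.fermenter_doubling_distance_cm
        if z_mid <= g0:
            return base
        if z_mid <= g1:
            return base * 2.0 ** ((z_mid - g0) / d)
        return base * 2.0 ** ((g1 - g0) / d)
    if arch in ("sulfur", "metal"):
        return base
    raise AssertionError(f"no planted trajectory for {arch}")


def simulate_core(
    catalog: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate coverage and metadata; fills the truth's kinetics and zones.

    Expected per-archetype shares follow the planted piecewise trajectories;
    the ``subsurface_sulfur`` pool absorbs ``1 - sum(focal shares)`` so the
    noise-free total is constant at ``total_coverage`` in every sample.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    horizons = config.horizon_grid()
    n_sites = config.n_sites
    o2 = _per_site(config.o2_penetration_cm, n_sites, "o2_penetration_cm")
    no3 = _per_site(config.no3_penetration_cm, n_sites, "no3_penetration_cm")
    omega = _per_site(config.sedimentation_rate_mm_yr, n_sites, "sedimentation_rate_mm_yr")
    wdepth = _per_site(config.water_depth_m, n_sites, "water_depth_m")
    half_life = _per_site(
        config.respiratory_half_life_yr, n_sites, "respiratory_half_life_yr"
    )

    by_arch = truth.guild_flags.groupby("archetype")["mag_id"].apply(list).to_dict()
    # fixed per-MAG weights within each archetype (uneven but reproducible)
    weights: dict[str, float] = {}
    for arch in ARCHETYPES:
        mags = by_arch.get(arch, [])
        if mags:
            w = rng.dirichlet(np.full(len(mags), 5.0))
            weights.update(zip(mags, w))

    arch_of = truth.guild_flags.set_index("mag_id")["archetype"]
    mag_arch = [str(arch_of[m]) for m in catalog["mag_id"]]
    mag_w = np.array([weights[m] for m in catalog["mag_id"]])

    meta_rows, zone_rows, kin_rows = [], [], []
    cov = pd.DataFrame({"mag_id": catalog["mag_id"]})
    for s in range(n_sites):
        site_id = f"S{s + 1}"
        site = {"o2": o2[s], "no3": no3[s], "omega": omega[s], "half_life": half_life[s]}
        rate = LN2 / half_life[s]
        for guild in ("aerobic", "narGHI"):
            kin_rows.append(
                {
                    "site_id": site_id,
                    "guild": guild,
                    "direction": "decay",
                    "rate_per_yr": rate,
                    "time_yr": half_life[s],
                    "window_top_cm": no3[s],
                    "window_bottom_cm": config.max_depth_cm,
                }
            )
        doubling_yr = 10.0 * config.fermenter_doubling_distance_cm / omega[s]
        kin_rows.append(
            {
                "site_id": site_id,
                "guild": "fermenter",
                "direction": "growth",
                "rate_per_yr": LN2 / doubling_yr,
                "time_yr": doubling_yr,
                "window_top_cm": config.growth_window_cm[0],
                "window_bottom_cm": config.growth_window_cm[1],
            }
        )
        for k, (top, bottom) in enumerate(horizons):
            sample_id = f"{site_id}_{k:02d}"
            mid = 0.5 * (top + bottom)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "site_id": site_id,
                    "depth_top_cm": top,
                    "depth_bottom_cm": bottom,
                    "water_depth_m": round(float(wdepth[s]), 1),
                    "o2_penetration_cm": round(float(o2[s]), 2),
                    "no3_penetration_cm": round(float(no3[s]), 2),
                    "sedimentation_rate_mm_yr": round(float(omega[s]), 3),
                }
            )
            if mid < o2[s]:
                zone = "oxic"
            elif mid < no3[s]:
                zone = "nitrogenous"
            else:
                zone = "ferruginous"
            zone_rows.append({"sample_id": sample_id, "site_id": site_id, "zone": zone})
            shares = {
                arch: _expected_share(arch, mid, site, config)
                for arch in ARCHETYPES
                if arch != "subsurface_sulfur"
            }
            balance = 1.0 - sum(shares.values())
            if balance <= 0:
                raise ValidationError(
                    f"planted shares exceed 1 at {site_id} depth {mid} cm; "
                    "lower surface_shares or the growth amplitude"
                )
            shares["subsurface_sulfur"] = balance
            expected = config.total_coverage * mag_w * np.array(
                [shares[a] for a in mag_arch]
            )
            if config.noise_sigma > 0:
                noise = np.exp(config.noise_sigma * rng.standard_normal(len(expected)))
            else:
                noise = 1.0
            cov[sample_id] = expected * noise
    metadata = pd.DataFrame(meta_rows).astype({"sample_id": "string", "site_id": "string"})
    cov = cov.astype({"mag_id": "string"})
    SAMPLE_METADATA.validate(metadata)
    COVERAGE_MATRIX.validate(cov)
    truth.kinetics = pd.DataFrame(kin_rows)
    truth.zones = pd.DataFrame(zone_rows)
    return cov, metadata


def simulate_all(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """End-to-end convenience wrapper emitting the full seven-table bundle.

    The catalog and the core use decorrelated child seeds spawned from
    ``seed``; the same (config, seed) pair always reproduces the same
    dataset byte-for-byte.
    """
    config = config or SimulationConfig()
    master = np.random.default_rng(seed)
    catalog_seed = int(master.integers(0, 2**31 - 1))
    core_seed = int(master.integers(0, 2**31 - 1))
    catalog, genes, metal, caz, truth = simulate_catalog(config, catalog_seed)
    coverage, metadata = simulate_core(catalog, truth, config, core_seed)
    return SimulatedDataset(
        catalog=catalog,
        gene_table=genes,
        metal_flags=metal,
        cazyme_table=caz,
        coverage=coverage,
        metadata=metadata,
        modules=default_oxidase_modules(),
        truth=truth,
    )
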