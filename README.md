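# redoxlag

Respiratory-guild succession and decay/growth kinetics across redox zones in
deep-sea sediment metagenome collections.

## The problem

Undisturbed, hardly bioturbated sediment cores (for example from hadal
trenches) develop a sharp vertical redox zonation: an **oxic** zone where O2
is consumed, a **nitrogenous** zone dominated by nitrate/nitrite (and Mn)
respiration, and a **ferruginous** zone below nitrate penetration where
Fe(II) accumulates. If electron-acceptor availability selects on microbial
genomes, the community's *genomic* respiratory potential should track these
zones — but with a lag set by how slowly buried cells decay and subsurface
specialists grow.

`redoxlag` implements the downstream analysis that quantifies this lag from
a catalog of metagenome-assembled genomes (MAGs):

1. **Rule-based guild classification.** Each MAG's annotated gene content is
   mapped to capability flags: aerobic respiration (cytochrome *c*,
   *cbb3*-type, or *bd* oxidase modules at >= 50% KEGG-style module
   completeness, plus a configurable taxon override for *Nitrosopumilaceae*,
   whose divergent Complex IV escapes the module definitions); nitrogen
   respiration (napAB, narGHI with >= 2 subunits, nrfAH, nirBD, nirK/S,
   norBC, nosZ); sulfur respiration (dsrAB); metal respiration
   (porin-cytochrome homolog flags). MAGs with none of these are putative
   **fermenters**.
2. **Redox-zone assignment** of each core slice by its depth midpoint
   against per-site O2 and NO3 penetration depths.
3. **Abundance profiles.** Mean coverages are normalized within samples,
   `p[i,s] = c[i,s] / Σ_j c[j,s]`, and aggregated per guild, taxon, CAZyme
   family (presence-weighted), or secreted-CAZyme stratum; depth profiles
   report cross-site means with standard errors per aligned horizon.
4. **Kinetics under a sediment age model.** Depth converts to age via the
   lead-210 sedimentation rate ω (mm/yr): `age = 10·z/ω` years. Within a
   zone window the guild abundance is fitted as `a(t) = a0·e^(−λt)` by OLS
   on `ln a`; the half-life (or doubling time, for growth) is `ln 2/λ`, and
   cross-site results are reported as (min, max) ranges.
5. **Ordination statistics.** Bray–Curtis + PCoA, Hellinger + PCA, global
   and pairwise PERMANOVA (Anderson's pseudo-F, add-one permutation
   p-values, Benjamini–Hochberg adjustment), Welch's t-test, and Ward
   clustering for heatmap ordering.

Because real coverage profiles require a sequencing campaign, the package
ships a first-class **synthetic community simulator** that emits all seven
input tables with planted guild memberships, zone boundaries, and kinetic
constants, so every stage can be validated against known ground truth.

## Worked example

```python
from redoxlag.synthetic_data import SimulationConfig, simulate_all
from redoxlag.guild_classifier import classify_guilds, guild_overlap
from redoxlag.abundance_profiles import relative_abundance, aggregate_groups
from redoxlag.redox_zones import annotate_zones
from redoxlag.kinetics import fit_guild_kinetics, doubling_from_distance

data = simulate_all(SimulationConfig(noise_sigma=0.0), seed=11)
assignments = classify_guilds(data.catalog, data.gene_table,
                              data.metal_flags, data.modules)
print({k: v for k, v in guild_overlap(assignments).items() if v})

mapping = {}
for _, r in assignments.iterrows():
    labs = [c for c in ("aerobic", "nitrogen", "sulfur_resp", "metal_resp") if r[c]]
    if r["fermenter"]:
        labs.append("fermenter")
    mapping[r["mag_id"]] = labs
guilds = aggregate_groups(relative_abundance(data.coverage), mapping)
meta = annotate_zones(data.metadata)

decay = fit_guild_kinetics(guilds, meta, "aerobic", "decay")
print("aerobic half-life range (yr):", decay.half_life_range_yr)
growth = fit_guild_kinetics(guilds, meta, "fermenter", "growth", window_cm=(6.5, 9.5))
print("fermenter doubling range (yr):", growth.half_life_range_yr)
print("1.4 cm at 0.76 mm/yr ->", round(doubling_from_distance(1.4, 0.76), 1), "yr")
```

prints

```
{'aerobic': 18, 'sulfur_resp': 13, 'metal_resp': 5, 'aerobic+nitrogen': 24, 'fermenter': 12}
aerobic half-life range (yr): (135.0, 367.0)
fermenter doubling range (yr): (18.4, 48.3)
1.4 cm at 0.76 mm/yr -> 18.4 yr
```

The overlap counts show the Venn regions of the four respiratory
capabilities (24 of the 42 aerobic MAGs are also nitrogen respirers, and 12
MAGs lacking every marker are fermenters). On this noise-free core the
kinetics module recovers the planted per-site half-lives exactly, so the
cross-site aerobic range equals the planted 135–367 yr band, and the
fermenter doubling times span 18.4–48.3 yr — the direct conversion of a
1.4 cm doubling distance through the 0.76 and 0.29 mm/yr sedimentation-rate
extremes.

The same pipeline is available from the shell:

```sh
redoxlag simulate --seed 11 --outdir run/
redoxlag zones --metadata run/sample_metadata.tsv --out run/meta_zoned.tsv
redoxlag classify --catalog run/mag_catalog.tsv --genes run/gene_table.tsv \
    --metal-flags run/metal_flags.tsv --modules run/module_definitions.tsv \
    --out-prefix run/guild
redoxlag run --config config.yaml --outdir bundle/   # full pipeline + manifest
```

Input schemas (UTF-8 TSV with header; `redoxlag.tables_io` is the single
source of truth) cover the MAG catalog, gene table, metal-homolog flags,
CAZyme table, coverage matrix, sample metadata, and KEGG-style module
definitions.

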