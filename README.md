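# metallome

Reconstruct a cell's relative metallome from its expressed proteome, and
compare it with directly measured metal quotas.

Trace-metal physiology in phytoplankton is usually measured bulk (ICP-MS
quotas, mmol metal per mol C) — which cannot say *which proteins* use the
metal — or inferred protein-by-protein, which misses free ion pools.
This package implements the bridge between the two views:

1. **Structure annotation** — template structures (PDB/mmCIF) are scanned
   for metal ions; each ion's first coordination sphere (N/O/S atoms within
   a 3.0 Å cutoff) is resolved, buffer ions with no polymer donor are
   flagged adventitious, and the remaining ions yield a per-chain metal
   stoichiometry.
2. **Homology transfer** — fold-recognition matches (query protein →
   template, confidence %) are filtered at a strict `> 95%` confidence
   threshold and the template's stoichiometry is copied onto the expressed
   protein (best-confidence match per protein).
3. **Quantification** — label-free intensity tables (MaxQuant
   proteinGroups or plain TSV) are normalized per sample to the median
   (for differential tests) and per group to the total (for relative
   abundances `pᵢ` with `Σᵢ pᵢ = 1`).
4. **Metallome reconstruction** — the relative abundance of metal *m* is

   `A(m) = Σᵢ pᵢ · nᵢ(m)`

   where `nᵢ(m)` is the number of ions of *m* bound by protein *i*.
   The unit is arbitrary (intensities are relative), so profiles are
   comparable across metals within a species, not across species.
5. **Comparison** — Pearson *r*² between `log₁₀ A(m)` and `log₁₀ quota(m)`;
   between-strain ratios with delta-method error propagation,
   `SD(b/a) = (b/a)·√((SDₐ/a)² + (SD_b/b)²)`; per-protein Student t-tests
   on median-normalized intensities (volcano-plot view). A metal whose
   quota ratio exceeds 1 while its metallome ratio stays near 1 is the
   signature of luxury uptake; quota ≫ metallome across the board marks
   free-ion-dominated elements (Ca, Mg, K).

A seeded synthetic-data generator produces coupled inputs for all four
stages — structures with planted sites, match tables straddling the
confidence threshold, log-normal replicate intensities, and quota tables
decomposed as `scale · (bound + free) · luxury · (1 + ε)` — so the whole
pipeline is testable against known ground truth.

## Worked example

```sh
metallome simulate --n-proteins 300 --n-templates 20 --seed 1 -o demo/sim
metallome annotate demo/sim/templates/*.pdb -o demo/store.json
metallome transfer demo/sim/matches.tsv demo/store.json -o demo/annotations.json
metallome metallome demo/sim/intensities.tsv demo/annotations.json \
    --group OA1 -o demo/oa1
metallome compare demo/sim/intensities.tsv demo/annotations.json \
    demo/sim/quotas.tsv --group-a OA1 --group-b OA16 -o demo/cmp
```

prints

```
synthetic dataset (300 proteins, 111 metalloproteins) -> demo/sim
annotated 20 templates -> demo/store.json
127 annotated (111 metalloproteins) -> demo/annotations.json
111/300 metalloproteins (37.0%), 10 distinct metals
{
 "alpha": 0.05,
 "r_squared_OA1": 0.8379487240194634,
 "n_metals_OA1": 10,
 "excluded_metals_OA1": [],
 "r_squared_OA16": 0.7890944260118627,
 "n_metals_OA16": 10,
 "excluded_metals_OA16": [],
 "n_significant": 20
}
```

Reading the numbers: 111 of 300 simulated proteins carry a transferred
metal stoichiometry (37.0% — the generator's default metalloproteome
fraction); 127 proteins had a passing match (16 to apo templates, hence
not metalloproteins). The quota–metallome correlation lands at
*r*² ≈ 0.84/0.79 rather than 1.0 because the generator's default quota
model includes free Ca/Mg/K pools and Fe/Mo luxury uptake that the
proteome cannot see; switching those off (`free_pool={}, luxury={}` in
the library API) drives *r*² above 0.99. `demo/cmp.report.json`
additionally contains the per-metal OA16/OA1 ratio pairs: Fe shows a
quota ratio near 2 with a metallome ratio near 1 — planted luxury uptake
recovered — and `demo/cmp.de.tsv` holds the per-protein fold
changes and p-values (20 significant at α = 0.05 here).

The same five subcommands run on real data: PHYRE2-style match tables,
MaxQuant proteinGroups tables (`--dialect maxquant`), and ICP-MS quota
TSVs (`strain, metal, mean_mmol_per_molC, sd, n`).

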