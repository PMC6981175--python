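# adfield

Assemblage dispersion fields, asymmetry-vector symmetry diagrams, and
spreading-dye null models for gridded species presence–absence data.

## The problem

Continental species-richness maps correlate with climate, but the
correlation alone cannot distinguish *why*: is richness set locally by
available energy, or does it emerge from the large-scale overlap of
cohesive species ranges whose expansion tracks habitat (ecoregion)
structure?  The two mechanisms leave different fingerprints not in
richness itself but in the *turnover of species composition* between grid
cells.  `adfield` implements the dispersion-field toolkit that extracts
those fingerprints from a binary species-by-cell matrix, for
macroecologists and biogeographers working with gridded range data (or
fully synthetic study systems).

## The method

Occurrences of S species over N lattice cells sit in a binary matrix
**P** (rows species, columns cells), with row sums the range sizes
r_i and column sums the cell richness s_j.  The core objects:

* **Dispersion-field matrix** — D = PᵀP, the symmetric site-by-site
  matrix whose entry D[j,k] counts species shared by cells j and k.  Row
  j is the assemblage dispersion field (ADF) of focal cell j: the surface
  obtained by overlaying the ranges of all species present in j.
* **Volume and cosmopolitanism** — the row sum of D at j equals
  Σ_i p_ij·r_i (the summed range sizes of the local assemblage); divided
  by s_j it gives the mean range size of the locally present species.
* **Asymmetry vector** — cells sharing fewer than a fraction c of the
  focal assemblage (D[j,k]/s_j < c) are trimmed away; the vector from the
  focal cell's center to the count-weighted centroid of the surviving
  central region measures the direction and degree of the field's
  deviation from radial symmetry.  One vector per cell forms a
  **symmetry diagram**, a continental vector field of biotic turnover.
* **Spreading-dye null model** — cohesive pseudo-ranges grown by
  repeatedly annexing a random cell adjacent to the range.  A per-size
  sampling population (every cell intersected by ≥100 stored ranges of
  each size) lets each cell's empirical asymmetry be compared against
  null fields that preserve its own range-size frequency distribution,
  as a standardized effect size SES = (ν − μ(λ))/σ(λ) over (by default)
  1000 replicates.
* **Predictive assembly models** — energy-weighted origination,
  richness-ceiling simultaneous growth, and ecoregion-constrained
  expansion where crossing a boundary is 30× less likely than a
  same-region step.
* **Ecotone regression** — within one ecoregion, OLS of per-cell SES on
  graph-step distance to the region boundary, with a KS normality check
  on the residuals.

Everything runs on synthetic lattice continents (`adfield.synth`):
rectangle/disc/two-lobe domains, contiguous random ecoregions, log-series
range-size distributions, and faunas generated by any of the assembly
models with a ground-truth manifest.

## Worked example

```python
import adfield as adf

scenario = adf.SynthScenario(
    shape="rectangle", n_cells=196, n_ecoregions=2, n_species=300,
    mean_range_size=20, model="ecoregion", boundary_penalty=30.0, seed=0,
)
result = adf.make_fauna(scenario)
P, domain = result.pab, result.domain

j = P.cell_index(0)
print("richness of cell 0:", int(P.richness[j]))
print("dispersion-field volume of cell 0:", adf.df_volume(P, j))
print("mean cosmopolitanism of cell 0:", round(adf.mean_cosmopolitanism(P, j), 1))

diagram = adf.symmetry_diagram(P, domain, cutoff=0.5)
print("mean asymmetry-vector length (deg):", round(diagram.table.length.mean(), 2))
```

prints

```
richness of cell 0: 21
dispersion-field volume of cell 0: 1252
mean cosmopolitanism of cell 0: 59.6
mean asymmetry-vector length (deg): 2.45
```

Cell 0 (a corner cell of a two-ecoregion continent) hosts 21 species
whose ranges jointly cover 1252 cell-occurrences, i.e. the average
species present there occupies ~60 of the 196 cells.  The mean vector
length of 2.45° says dispersion fields on this penalised fauna are
strongly asymmetric — near-boundary vectors point away from the ecotone
into their own region, the signature of habitat-constrained range
expansion.

The same pipeline is scriptable from a shell:

```sh
adfield synth --shape rectangle --cells 196 --regions 2 --species 300 \
        --model ecoregion --penalty 30 --seed 0 --out run/
adfield symmetry --matrix run/matrix.csv --grid run/grid.csv \
        --cutoff 0.5 --out run/sym/
adfield null --matrix run/matrix.csv --grid run/grid.csv \
        --reps 1000 --coverage 100 --seed 0 --out run/ses/
```

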