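# hexanematic

Multiscale orientational-order analysis of confluent epithelial monolayers.

Epithelial tissue is a liquid crystal whose symmetry depends on the scale at
which you look: individual cells in a confluent sheet are approximately
six-fold (hexatic order, inherited from honeycomb-like packing), while at
larger scales the weak elongation of cells builds up two-fold (nematic)
order. The length where one gives way to the other — the **hexanematic
crossover scale R×** — is a mesoscale fingerprint of the tissue that tracks
density and cell–cell adhesion. This package implements the full analysis
chain for junction-marker images (ZO-1-like) or pre-segmented cell polygons,
plus a synthetic-monolayer generator so every stage is testable without
microscopy data. It is aimed at quantitative cell biologists and active
matter physicists working with epithelial monolayer images.

## The quantities

For a cell with vertices **r**_v (relative to its centre of mass, polar
angles φ_v), the *p*-fold shape function is

    γ_p = Σ_v |r_v|^p e^{i p φ_v} / Σ_v |r_v|^p ,

a complex number with |γ_p| ≤ 1. |γ_6| = 1 for a regular hexagon, |γ_2| = 0;
for an elongated hexagon both are finite, and Arg(γ_p)/p is the cell's
p-fold orientation. The scalar shape index is p₀ = P/√A.

Coarse-graining averages γ_p over cells within a disk of radius R around
each node **r**_n of a square grid with spacing R_cc/2 (R_cc = mean
cell–cell distance):

    Γ_p(r, R) = (1/N_disk) Σ_c γ_p(r_c) Θ(R − |r − r_c|) ,

and the grid mean of |Γ_p| as a function of R gives the order profile. R× is
the radius where the hexatic profile |Γ₆| first drops to the nematic one
|Γ₂|. Topological defects of either field are plaquette winding numbers
s = (1/2π) ∮ dθ of the director θ = Arg(Γ_p)/p, quantized in units of 1/p
(±1/2 nematic, ±1/6 hexatic), reported per 100 cells.

## Worked example

```python
import hexanematic as hx

cfg = hx.study_config(16.2, elongation=1.2, seed=1, noise_sd=0.1)
ml = hx.generate_monolayer(cfg)            # ~200-cell confluent tiling
img = hx.render_junction_image(ml, cfg)    # noisy ZO-1-like image

seg = hx.segment_image(img, cfg.pixel_size)
rcc = hx.mean_cell_cell_distance(seg)
records = hx.compute_shape_records(seg)
g6, g2 = hx.ensemble_average(records, 6), hx.ensemble_average(records, 2)
radii, p6, p2, cross = hx.hexanematic_profile(seg, records)
print(f"R_cc = {rcc:.1f} um  <|g6|> = {g6:.2f}  <|g2|> = {g2:.2f}  "
      f"Rx/R_cc = {cross.r_cross:.2f}")
```

prints

```
R_cc = 16.7 um  <|g6|> = 0.38  <|g2|> = 0.37  Rx/R_cc = 0.58
```

meaning: the re-segmented monolayer has a 16.7 μm mean cell–cell distance;
at the single-cell scale the hexatic shape function still edges out the
nematic one (vertex-detection noise narrows the margin relative to the
ground-truth polygons, where the same fixture gives 0.43 vs 0.40); and for
this moderately elongated fixture hexatic order yields to nematic order
already below one cell diameter.

The numbered drivers under `analysis/` run the full study on synthetic
ensembles and write tables to `results/`:

```bash
python analysis/01_generate_monolayers.py   # the ensemble (3 densities x 4 elongations)
python analysis/02_segmentation_roundtrip.py
python analysis/03_shape_and_crossover.py
python analysis/04_defect_statistics.py
python analysis/05_density_report.py
```

Representative output (2 seeds per condition): segmentation recovers 100%
of interior cells with ≤0.25 μm median centroid error and neighbour-F1 ≈
0.98; the pooled crossover R×/R_cc falls from 1.7 to 0.7 as the base cell
aspect ratio grows from 1.1 to 1.4, and (at low elongation) from 1.7 to
1.0 as the mean cell–cell distance grows from 13.6 to 21.4 μm; defect
densities per 100 cells decrease with the coarse-graining radius (Spearman
ρ ≈ −0.7 nematic, −0.9 hexatic); and cell-level |γ₂| differs between the
densest and sparsest groups (two-sided Wilcoxon rank-sum p ≈ 4e−4).

A CLI mirrors the pipeline for shell use:

```bash
hexanematic segment image.tif --pixel-size-um 0.5 --out seg/
hexanematic crossover seg/monolayer.json --out cross/
hexanematic defects seg/monolayer.json --p 2,6 --at-crossover --out defects/
hexanematic report results/ --out report/
```

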