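# osteomorph

3D bone morphometry from micro- and nano-CT image stacks, for skeletal
phenotyping studies in small animals: cortical and trabecular indices,
osteocyte-lacunar and vascular-canal porosity with best-fit-ellipsoid
shape statistics, hydroxyapatite-phantom-calibrated tissue mineral
density (TMD), and genotype × age significance mapping along the bone
length. A synthetic-data module generates every input the pipeline
needs — shells, pore fields, lattices, phantoms and cohort tables —
with analytic ground truth, so the whole chain is testable without scan
data.

## What it computes

**Cortical cross-sections.** For each transverse binary section: bone
area (CSA/B.Ar), second moments of area about the principal centroidal
axes (Imin ≤ Imax, each voxel a unit square with its 1/12 self-moment),
polar moment MMI = Imin + Imax, mean 2D local thickness, inertia-ellipse
eccentricity √(1 − Imin/Imax), and total porosity 100·(1 − B.Ar/TV)
within the cortical envelope. Whole-bone profiles evaluate these at
percent-length stations over the 10–90% diaphyseal window.

**Intracortical porosity.** Enclosed void space is extracted from a
binarized cortical slab (complement components not reaching the slab
faces; the axial ends are open, so the marrow cavity is excluded and
end-censored pores are counted separately), labeled, and classified
purely by physical volume:

- `< 13 μm³` → noise, `> 1500 μm³` → vascular canal, the inclusive band
  between → osteocyte lacuna.

Per class the report gives counts, number densities (per mm³ of
cortical tissue volume Ct.TV), mean and fractional volumes,
sphere-fitting local thickness and separation, and connectivity density
(1 − χ)/Ct.TV from the 3D Euler characteristic χ.

**Lacunar shape.** Each lacuna is summarised by the ellipsoid sharing
its central second moments; for a uniform solid the semi-axes follow
from the inertia eigenvalues mᵢ as λᵢ = √((5/2)(mⱼ + mₖ − mᵢ)). With
λ1 ≥ λ2 ≥ λ3:

    Eq = λ3/λ1,  El = 1 − λ2/λ1,  Fl = 1 − λ3/λ2,  Eq = (1−El)(1−Fl)

plus Flinn-diagram coordinates (λ2/λ3, λ1/λ2) separating prolate from
oblate shapes.

**Trabecular morphometry.** BV/TV, Tb.Th and Tb.Sp by 3D local
thickness, Tb.N = (BV/TV)/Tb.Th, and Conn.Dn = (1 − χ)/TV on a
user-supplied metaphyseal ROI (5% of bone length from the trabecular
bridge reference slice).

**Statistics.** Each index is fitted as a two-way ANOVA with
interaction, `y ~ genotype * age` (age categorical, Type-II sums of
squares), with Shapiro–Wilk residual checks, Welch per-age post-hoc
contrasts (Bonferroni or unadjusted), and per-station significance
bands (red p ≤ 0.001, yellow ≤ 0.01, green ≤ 0.05, blue > 0.05) along
the 10–90% profile.

## Worked example

Generate a nano-CT-scale porous cortical shell (0.6 μm voxels, 50
planted lacunae, 4 canals, 15 single-voxel specks) and analyse it:

```python
import osteomorph as om

vol, manifest, _ = om.make_porous_shell(seed=3)
report, particles, classes = om.analyze_cortical_porosity(vol)
print(report.to_series().round(3).to_string())
```

```
Ct.TV (mm^3)               0.000
Ct.Th (mm)                 0.012
N.Lc                      50.000
N.Lc/Ct.TV (mm^-3)    207274.884
Lc.V (um^3)              311.973
Lc.V/Ct.TV (%)             6.466
Lc.Th (um)                 4.645
Lc.Sp (um)                14.051
Lc.Con.Dnn (mm^-3)   -203129.386
N.Ca                       4.000
N.Ca/Ct.TV (mm^-3)     16581.991
Ca.V (um^3)             2882.790
Ca.V/Ct.TV (%)             4.780
Ca.Th (um)                 8.245
Ca.Sp (um)                17.093
Ca.Con.Dnn (mm^-3)    -12436.493
n_noise                   15.000
n_excluded                 0.000
```

All 50 planted lacunae, 4 canals and 15 noise specks are recovered with
their planted classes (`classes.value_counts()`), the mean canal
thickness (8.2 μm) matches the planted 4–4.5 μm cylinder radii, and the
negative connectivity densities reflect 50 and 4 disjoint
simply-connected pores ((1 − N)/Ct.TV). Lacunar shape follows from the
best-fit ellipsoids:

```python
lacunae = particles.select((classes == "lacuna").to_numpy())
shapes = om.particle_shape_table(lacunae)
print(shapes[["lambda1_um", "lambda2_um", "lambda3_um",
              "Lc.Eq", "Lc.El", "Lc.Fl"]].mean().round(3).to_string())
```

```
lambda1_um    7.597
lambda2_um    3.902
lambda3_um    2.248
Lc.Eq         0.318
Lc.El         0.466
Lc.Fl         0.409
```

i.e. the planted tri-axial lacunae (λ1 ≈ 7.6, λ2 ≈ 3.9, λ3 ≈ 2.2 μm,
elongation ≈ 0.47) are recovered per particle.

The same functionality is scriptable from the shell:

```sh
osteomorph synth pores --seed 3 --out demo/
osteomorph porosity demo/porous_shell.tif --voxel-size 0.6 --out demo/report.csv
osteomorph run --preset cohort-null --outdir demo/stats
```

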