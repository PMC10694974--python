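# mycomat

Microstructure quantification and EN-norm material-property analysis for
fungal (mycelium–hemp) composite materials.

The package has two halves:

1. **µCT microstructure pipeline** — segmentation of hemp-shive substrate
   and fungal hyphae from grayscale tomography volumes, followed by
   skeleton-based morphometry:
   * slice-wise non-local-means denoising, adaptive binarization and
     foreground masking;
   * multilevel Otsu classing; shive extraction with a 140,000 µm³
     minimum-object rule; apparent (pore-filled) substrate volume via
     per-slice disk closing and vessel filling;
   * substrate solid fraction ε = V_solid / V_solid+pores and apparent
     density ε × ρ_solid (default 1450 kg m⁻³);
   * hyphae extraction (single Otsu on the shive-removed volume, 280 µm³
     minimum-object rule), 3D skeletonization, mean hyphal diameter from
     the Euclidean distance transform, total length l = 4V/(πd²),
     branch/tip counts, and the branching-frequency profile in 50 µm
     distance shells around the substrate.
2. **EN-norm material-property calculators** — compression (stress at 10%
   strain), three-point bending (flexural strength, modulus of
   elasticity), transverse tension, raw density, water soak, cup-method
   vapour diffusion (G → g → W → δ → µ), guarded two-plate thermal
   conductivity, and rule-based small-flame flammability classing.

Because no public CT volumes or raw test records accompany the method,
`mycomat.synthetic` generates voxel phantoms (porous shive slab with two
vessel-radius classes + a stochastically branching tubular hyphal network,
with exact ground truth) and synthetic test records (compression curves,
vapour mass series, bending records) so every stage is testable offline.

## CLI

One entry point, `mycomat`, with task subcommands:

```bash
# synthetic data
mycomat simulate volume --config cfg.yaml --seed 1 --out phantom/
mycomat simulate vapour --w-true 8.22 --delta-p 2390 --out series.csv
mycomat simulate compression --density 80 --out curve.csv
mycomat simulate bending --f-m 6.0 --t-n 10 --out bend.csv

# microstructure
mycomat segment --in phantom/volume.tif --out seg/
mycomat hyphae-metrics --masks seg/ --shell-um 50 --out metrics/
mycomat pipeline --seed 1 --size 96 --out run/   # phantom -> segment -> metrics -> report

# material properties
mycomat mech compress --in curve.csv --a0 10000 --d0 100 --out res.json
mycomat mech bend --in bend.csv --t-n 10 --out res.json
mycomat mech tensile --f-max 250
mycomat mech density --m 30 --a 50 --b 50 --t 10
mycomat mech soak --t1 10 --t2 15 --m1 10 --m2 60
mycomat vapour --in series.csv --out vap.json
mycomat thermal --phi 9 --d 0.05 --area 0.25 --t1 298 --t2 288
mycomat flammability --spread-mm 120 --smoke s2
mycomat report --shell-csv metrics/shell_profile.csv --out figures/
```

Volumes are multi-page TIFF stacks with a YAML sidecar carrying the voxel
size (mandatory — never inferred from TIFF tags); tables are CSV, scalar
results JSON, and every output directory receives a manifest with a config
hash, the seed, and library versions.

## Layout

```
src/mycomat/
  core.py          value types (VoxelVolume) and exceptions
  synthetic/       phantom + record generators with exact ground truth
  segmentation.py  CT pipeline (denoise/threshold/classes/shive/apparent/hyphae)
  morphometry.py   skeleton, diameter, length, shell profile
  properties.py    EN-norm record types and calculators
  io.py            TIFF/CSV/JSON/YAML readers and writers, manifests
  report.py        figures (stress-strain, shells, density maps)
  cli.py           command-line interface
```
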