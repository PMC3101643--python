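# densvar

Density-space sparse estimation of conformational variability in
crystallographic ensembles.

Given a base conformer and an ensemble of alternative models, densvar
expresses the base conformer's electron density map as an L1-regularized
(Lasso) linear combination of the ensemble members' densities. Members
whose coefficients shrink to (effectively) zero contribute nothing to
representing the base and are classified as **truly variable** — genuine
conformational change; members with significant non-zero coefficients are
**noise variants** of the base. The package also ships a synthetic
two-conformer crystal simulator with known truth labels, so the whole
statistical test is verifiable without external data.

## What's inside

| module | contents |
| --- | --- |
| `densvar.structures` | `Atom`/`Conformer`/`Ensemble`, PDB read/write, Kabsch superposition, RMSD |
| `densvar.density` | Gaussian-atom density maps, structure factors, Fourier map synthesis, complex structure-factor mixing, R/R_free, grid regions, reflection CSV and CCP4 export (P1, orthorhombic cells) |
| `densvar.simulate` | ideal-geometry toy proteins, seeded coordinate noise, RMSD-targeted neighborhood sampling, two-conformer crystals, labeled ensembles, R_free filtering, redundancy pruning |
| `densvar.sparse` | the statistical test: coordinate-descent Lasso with KKT certification, regularization paths, cross-validated λ (1-SE rule), post-selection OLS t-tests, classification, sliding-window and fragment profiles |
| `densvar.report` | baseline comparators: per-residue RMSD, normalized RMSD, B-factor profiles |
| `densvar.cli` | `densvar simulate | classify | path | profile` |

## Quick start (CLI)

Simulate a crystal containing two conformations (~1 Å apart, B = 30 Å²,
d_min = 2 Å) whose structure factors are averaged at equal weight, plus a
four-member ensemble with known truth labels:

```sh
densvar simulate run/fixture --n-residues 8 --sigma 0.1 --seed 7
```

Classify the ensemble (R_free filter, dedup, Lasso with cross-validated λ,
post-selection t-test):

```sh
densvar classify run/fixture/base.pdb run/fixture/members \
    --out run/cls \
    --fixture-json run/fixture/fixture.json \
    --reflections run/fixture/reflections.csv
```

`run/cls/report.csv` lists per-member weight, t, p and label
(`noise_variant` / `truly_variable`). Add `--window 5 --lam 10` for a
per-residue sliding-window profile. `densvar path ...` writes the
regularization path; `densvar profile ...` writes the RMSD/B-factor
baseline comparators.

The same pipeline is available programmatically:

```python
import densvar as dv
from densvar.density import density_map, fragment_box

base = dv.make_toy_protein(8, "helix")
alt = dv.sample_neighborhood(base, (0.8, 1.2), n=1, seed=1)[0]
crystal = dv.make_two_conformer_crystal(base, alt, d_min=2.0)
ens = dv.make_labeled_ensemble(crystal, n_noise=2, n_variable=2,
                               noise=dv.NoiseModel(0.1, seed=2))
shape = crystal.mixed_map.shape
y = density_map(crystal.base, crystal.cell, crystal.spacing, shape=shape)
X = [density_map(m, crystal.cell, crystal.spacing, shape=shape)
     for m in ens.members]
region = fragment_box(crystal.base, (1, 8), margin=2.0, grid=y)
report = dv.classify_ensemble(y, X, region, lam="cv")
print(report.to_frame())
```

## Conventions

Space group P1 with orthorhombic cells; B = 8π²⟨u²⟩ (atoms are normalized
isotropic Gaussians of per-axis variance B/(8π²), total weight = electron
count); F(h) = Σ f_j exp(+2πi h·x); ρ = (1/V) Σ F exp(−2πi h·x); lengths in
Å, B in Å², density in e/Å³.
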