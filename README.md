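# cryoflex

Protein flexibility prediction from cryo-EM density maps and fitted atomic
models.

## The problem

A cryo-EM reconstruction averages many instantaneous conformations of the
imaged particles, so flexible parts of a protein appear blurred while rigid
parts stay sharp.  cryoflex turns that physical signal into a quantitative
prediction of local structural dynamics: the root-mean-square fluctuation

```
RMSF_i = sqrt( (1/T) Σ_t ‖ x_i(t) − x̃_i ‖² )
```

of every atom *i* about its mean position x̃_i — the quantity normally
obtained from long molecular-dynamics trajectories — inferred in seconds
from a density map and its fitted model.  It is aimed at structural
biologists who have an EMDB-style map plus a PDB/mmCIF model and want a
per-residue flexibility profile without running MD.

## The method

The map is resampled to 1.5 Å voxels; the atomic model is rendered as a
simulated density (mass-weighted Gaussians of width 0.225 × resolution).
Both grids are cut into 40³ boxes on a stride-10 lattice; boxes whose 10³
central subbox contains no atoms are screened out, and box densities are
normalized to [0, 1].  A 3D UNet++(L3) with a pointwise regression head maps
each C×40³ box (C = 1 or 2 input channels depending on the variant) to the
RMSF of its central 10³ subbox; subbox predictions are merged into an RMSF
map and read out per atom and per residue.  Training minimizes a masked MSE
on ensemble-derived RMSF labels (Adam, lr 0.004, lr halving after 10
stagnant validation epochs, early stop after 30, eightfold mirror
augmentation).  An auxiliary occupancy classifier (`occ`) and its two-stage
composition (`occ2rmsf`) expose what the map-only route learns.  The
networks and their training run on a compact numpy autograd engine, so the
whole pipeline is CPU-only and deterministic given a seed.

Because MD-labelled experimental data cannot ship with a package, cryoflex
includes a first-class synthetic generator: pseudo-proteins (self-avoiding
3.8 Å chains), fluctuation ensembles with closed-form ground truth
(RMSF = σ√3), and heterogeneity-blurred noisy maps.  See
`docs/methods.md` for the model, the generator's scope and its limits.

## Worked example

```python
import cryoflex as cf
from cryoflex import FlexibilityModel

# ten synthetic entries: map + model + known per-atom RMSF
entries = cf.make_dataset(10, cf.SyntheticSpec(), seed=101)

model = FlexibilityModel(entries, variant="dual", base_channels=8, seed=1)
results = model.fit(cf.TrainConfig(epochs=10, batch_size=16, augment=False,
                                   seed=1),
                    train_entries=entries[:7], val_entries=entries[7:8])
results.evaluate(entries[8:])          # held-out entries
print(results.summary())
```

prints (about two minutes of generation plus a few minutes of training on
one CPU core):

```
Flexibility model fit
============================================
variant:          dual
base channels:    8
train entries:    7
val entries:      1
epochs run:       10
best epoch:       9
best val loss:    0.039024
lr halvings at stagnant epochs: none
--------------------------------------------
voxel-level CC:   0.870 (median 0.870, std 0.003, n=2)
residue-level CC: 0.870 (median 0.870, std 0.003)
```

`voxel-level CC` is the Pearson correlation between predicted and true RMSF
on atom-occupied voxels of the held-out maps (0.87 here: the network has
learned the blur-flexibility relation from eight entries); the residue level
averages atoms within each residue first.  `results.predict_entry(e)`
returns the merged RMSF map plus per-atom and per-residue profiles, and
`results.save("weights.npz")` writes a reusable checkpoint.

The same loop is available from the shell:

```
cryoflex synth --n-entries 5 --seed 1 --out data/
cryoflex train --variant dual --seed 1 --out run/
cryoflex predict --map data/entry000_map.mrc --model data/entry000_model.pdb \
                 --weights run/dual_weights.npz --variant dual --out pred/
cryoflex evaluate --pred pred/ --truth truth/ --out eval/
```

`predict` writes the RMSF map (MRC), per-atom and per-residue tables, and a
copy of the model with RMSF in the B-factor column for coloring in molecular
viewers.

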