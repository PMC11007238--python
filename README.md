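# voxbind

Structure-based prediction of RNA–small-molecule binding affinity.

Small molecules that bind structured RNAs (riboswitches, viral elements
such as HIV-1 TAR, regulatory non-coding RNAs) are an emerging class of
therapeutics, but very few computational tools score how *strongly* a
ligand binds its RNA target. `voxbind` addresses that gap for users who
have 3D structures of RNA–ligand complexes and experimental dissociation
constants for some of them: it learns a map from the binding-pocket
geometry to the affinity and predicts kd for new complexes.

## Method in brief

Given a complex (RNA as polymer `ATOM` records, ligand as `HETATM`
records in one PDB file), the pipeline:

1. **Curates**: rejects complexes with protein chains, RNAs shorter than
   10 nucleotides, ion or artifact ligands, or no RNA–ligand heavy-atom
   contact below 4 Å.
2. **Extracts the pocket**: receptor heavy atoms within a k-d-tree query
   radius (10 Å default, 6 Å supported) of any ligand atom, then centres
   all coordinates on the ligand centroid.
3. **Voxelizes**: deposits pocket + ligand atoms on an N×N×N×8 grid
   (41 Å box, 1 Å resolution by default; 31 Å supported) with one channel
   per element (C, N, O, P, F, Cl, Br, I), each atom filling the voxels
   inside its van der Waals radius, followed by a σ=1 Gaussian blur.
4. **Pre-trains (optional)**: a 3D residual encoder R maps grids to
   23×23×23×32 latents; two rigid-transform views S_i, S_j of each pocket
   are projected by a small MLP P to embeddings z_i = P(R(S_i)), and
   encoder and projector are trained with the NT-Xent loss
   ℓ(i,j) = −log [exp(s(z_i,z_j)/τ) / Σ_{k≠i} exp(s(z_i,z_k)/τ)],
   s = cosine similarity, pulling views of the same complex together and
   views of different complexes apart.
5. **Regresses**: a 3D CNN (four convolutions with dropout and ReLU, max
   pooling after the second and fourth, fully connected head, sigmoid
   output) is trained with MSE + Adam on labels y = min–max-normalized
   pKd, where pKd = −log10(kd); the min–max range comes from the training
   split only. The regressor reads either raw grids ("raw" mode) or the
   frozen pre-trained latents ("encoder" mode).
6. **Evaluates**: Pearson (PCC) and Spearman (SPCC) correlations, RMSE
   and absolute error, over repeated seeded train/validation/test splits
   (default 10 repeats of 100/29/13).

Everything runs on plain numpy/scipy — the networks, including training,
are implemented in the package (`voxbind.nn`) and verified against
finite-difference gradients. See `docs/methods.md` for assumptions,
parameter tables and limitations.

## Worked example

No external data is needed: the package generates curated synthetic
RNA–ligand complexes (an idealized helix with a docked random ligand) in
which pKd is planted as 2.0 + 0.1 × (number of RNA atoms within 4 Å of
the ligand). The full shell workflow:

```bash
voxbind synth --n 50 --seed 1 --out data/           # 50 PDB files + labels.csv
voxbind featurize --input-dir data --out run --box-size 41 --pocket-radius 10
voxbind train --input-dir data --labels data/labels.csv --out run \
        --epochs 20 --seed 1
voxbind predict --input-dir data --out run
voxbind evaluate --input-dir data --labels data/labels.csv --out run \
        --repeats 2 --split-sizes 30,10,10 --epochs 10 --seed 1
```

Or from Python, the parameter-recovery experiment the test suite runs:

```python
import numpy as np, voxbind as vb
from voxbind.regression import TrainConfig, train_regressor, predict_affinity
from voxbind.networks import RegressorSpec
from voxbind.evaluation import make_splits, compute_metrics
from voxbind.pocket import extract_pocket, center_on_ligand

recs = vb.generate_dataset(150, seed=1)            # planted, zero-noise labels
pockets = [center_on_ligand(extract_pocket(r.pair, 10.0)) for r in recs]
split = make_splits(150, (120, 30, 0), repeats=1, master_seed=1)[0]
sub = lambda idx: [(pockets[i], recs[i].label) for i in idx]

cfg = TrainConfig(learning_rate=2e-3, batch_size=16, epochs=45, seed=1,
                  mode="raw", lr_decay_epoch=30,
                  regressor=RegressorSpec(dropout=0.15))
result = train_regressor(sub(split.train), sub(split.val), cfg)
pred = predict_affinity([(recs[i].complex_id, pockets[i]) for i in split.val],
                        result.model, result.transform, mode="raw")
truth = np.array([recs[i].label.pkd for i in split.val])
m = compute_metrics(truth, pred["pkd"].to_numpy())
print(f"held-out PCC {m.pcc:.2f}  RMSE(pKd) {m.rmse:.2f}")
```

which prints (takes a few minutes; exact values can shift slightly with
the platform's BLAS):

```
held-out PCC 0.83  RMSE(pKd) 0.20
```

meaning the trained network recovers the planted interface-size signal on
the 30 complexes held out of training: predicted and true pKd correlate
at 0.83, and the typical pKd error (0.20, about two contacts' worth
of signal) is small against the ~1.8-unit label range. `pred` also carries
each complex's predicted kd in molar units (kd = 10^−pKd).

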