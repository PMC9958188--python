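# rnpscore

Deep-learning scoring of RNA-protein complex docking decoys from voxelized
interface features. The pipeline parses PDB coordinate files, assigns atom
types (mass + partial charge) from tabular typing files, extracts the
RNA-protein interaction interface at a 6 Å cutoff, builds a rigid-motion-
invariant local coordinate frame per interface nucleotide/residue, bins the
complex into 3-channel (occupancy / mass / charge) 32 Å voxel grids, and
scores poses with a sequence+spatial ("4D") convolutional network trained to
regress interface RMSD. A rigid-body decoy generator provides synthetic
training/evaluation fixtures with exact RMSD labels, and the evaluation
module implements Kabsch superposition, interface RMSD, top-N success rates
at the 4.0 Å native-likeness threshold, and a distance-based intermolecular
hydrogen-bond detector.

The network stack is implemented in pure NumPy (explicit forward/backward
passes, validated against finite differences), so no GPU or deep-learning
framework is required. The default configuration follows the published
schedule: channels [64, 128, 256, 512, 512], sequence strides [2, 2, 2, 1, 1]
with kernel 3, 2×2×2 spatial max-pooling, a global spatial average after the
last block (flattened representation length 8,192 for L = 128), and an
independent per-unit 3D baseline (64→1024 channels, 32³→1³).

## Command-line usage

```bash
# 1. generate a toy native + rigid-body decoy set (PDBs + manifest.csv)
rnpscore decoys --seed 1 --n-nt 6 --n-aa 8 --n-decoys 10 --out-dir work/decoys

# 2. featurize arbitrary PDBs into HDF5 tensor caches
rnpscore featurize work/decoys/native.pdb --out-dir work/cache

# 3. train a scoring model (config YAML controls grid/network/training)
rnpscore train --decoy-dir work/decoys --config config.yaml --seed 1 \
    --steps 300 --out-dir work/run

# 4. score the decoys with the trained checkpoint
rnpscore score --checkpoint work/run/checkpoint.npz --decoy-dir work/decoys \
    --config config.yaml --out work/scores.tsv

# 5. success@N report (JSON summary + per-decoy CSV)
rnpscore evaluate --scores work/scores.tsv --decoy-dir work/decoys \
    --config config.yaml --out-dir work/report
```

A config file is optional; defaults reproduce the published settings
(6 Å cutoff, L = 128, 32³ grids of 1 Å voxels, learning rate 1e-4, batch
size 1). Example reduced config for quick runs:

```yaml
L: 8
grid_size: 8
network:
  L: 8
  grid_size: 8
  batch_norm: false
training:
  learning_rate: 1.0e-4
  momentum: 0.9
  max_steps: 300
```

Atom typing ships as two TSV files
(`src/rnpscore/data/{rna,protein}_atom_types.tsv`; columns
residue_code / atom_name / type_id / mass / charge) and can be replaced via
the `rna_table` / `protein_table` config keys. The canonical RNA table has
exactly 85 entries (A, G, C, U heavy atoms with a full 5'-phosphate
backbone).

## Layout

- `src/rnpscore/structures.py` — PDB parsing, typing tables, interface extraction
- `src/rnpscore/featurize.py` — local frames, voxelization, tensor assembly
- `src/rnpscore/network/` — NumPy layers, 4D/3D models, shape tracer, checkpoints
- `src/rnpscore/training.py` — labeling, SGD training loop, decoy scoring
- `src/rnpscore/decoygen.py` — toy complexes and rigid-body decoy sets
- `src/rnpscore/evaluate.py` — RMSD, superposition, I_rmsd, success rates, H-bonds
- `src/rnpscore/cli.py` — the `rnpscore` command group
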