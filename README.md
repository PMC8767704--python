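# leafhair

Ordinal scoring of leaf hairiness (pubescence) from microscope images.
The pipeline has four stages: a data-augmentation module, a residual
feature-extraction network with a single fully connected scoring head, a
training loop, and a leaf-level scoring module producing three accuracies —
per image (IA), per first image (FIA, the most proximal image of each leaf)
and per leaf (LA, majority vote with a smallest-score tie-break).

Because the execution environment is CPU-only with no deep-learning runtime,
the network stack (convolutions, batch norm, pooling, backprop, Adam/AdamW/
RMSProp/SGD) is implemented in NumPy. The five canonical residual depths
(18/34/50/101/152) are available headless — the depth-34 backbone counts
exactly 21,284,672 trainable parameters — plus a `tiny` backbone for
desk-scale training.

Everything is testable without the original dataset: `leafhair.synth`
procedurally renders labelled microscope-style leaf images (a mid-vein cut by
the left/right borders, hair-stroke density and length increasing with the
9-level ordinal score, year/environment style shifts).

## Layout

| module | role |
|---|---|
| `leafhair.manifest` | score scale, image records, manifest CSV I/O |
| `leafhair.deidentify` | genotype→colorname mapping, metadata stripping |
| `leafhair.synth` | synthetic leaf-image generator |
| `leafhair.augment` | resize/normalize + flips, random crop/rotation, Gaussian noise |
| `leafhair.net` | headless residual backbones + Kaiming-Uniform linear head |
| `leafhair.nn` | NumPy layer/optimizer framework backing `net` |
| `leafhair.splits` | leaf-group-exclusive splits: whole, mixed/intra/inter per factor, fold pairs |
| `leafhair.train` | cross-entropy training loop, multi-run experiments |
| `leafhair.score` | IA/FIA/LA, confusion matrices, adjacency analysis, noise sweep |
| `leafhair.cli` | `leafhair` command-line entry point |

## CLI

```sh
# generate a synthetic dataset (desk scale, 256x192)
leafhair generate --out data/synth --seed 0

# write splits: whole 80/20, per-factor sextets, fold pairs
leafhair split --manifest data/synth/manifest.csv --out data/splits --whole
leafhair split --manifest data/synth/manifest.csv --out data/splits --factor year
leafhair split --manifest data/synth/manifest.csv --out data/splits --kfold 10

# train (multi-run) and evaluate
leafhair --config config.yaml train --data data/synth \
    --split data/splits/whole.json --out runs/whole --runs 5 --seed 0
leafhair --config config.yaml evaluate --data data/synth \
    --split data/splits/whole.json --out runs/report.json --noise-sweep

# de-identify a manifest (master map goes to a separate directory)
leafhair deidentify --manifest data/raw/manifest.csv \
    --out data/public --map-out data/secret --seed 0
```

A YAML config can preset any block (`synth`, `genotypes`, `augmentation`,
`network`, `train`); flags override. See `tests/test_cli.py` for a worked
example.

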