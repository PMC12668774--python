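# schicenh

Single-cell Hi-C (scHi-C) contact-matrix enhancement toolkit. A dual-branch
GAN generator imputes sparsely captured contacts in per-cell, per-chromosome
matrices while preserving matrix symmetry by construction: features are
collapsed to per-channel vectors with (n x 1) kernels and rebuilt as weighted
outer products, with squeeze-and-excitation channel gating to keep the output
from over-smoothing. The package also ships the full evaluation stack
(MAE, binarized macro F1, stratum-adjusted correlation, graph random-walk
concordance, shift-tolerant structural matching), downstream A/B-compartment
and insulation-score TAD-boundary callers, and a synthetic scHi-C simulator
with planted structure so everything is testable offline.

The network runs on a small built-in NumPy autodiff engine (`schicenh.nn`) —
no deep-learning framework is required; everything trains on one CPU at
desk scale.

## CLI

All commands take a `--seed`; fixed seeds give byte-identical outputs.

```sh
# simulate a cohort (triplet text per cell + ground_truth.json)
schicenh simulate --cells 60 --bins 120 --depth 30000 --seed 1 --out cohort/

# train the enhancement GAN on downsampled copies of the cohort
schicenh train --data cohort/ --bins 120 --ratio 9 --epochs 30 \
    --out model.npz --log-out train_log.tsv

# enhance sparse matrices with a trained checkpoint
schicenh enhance --checkpoint model.npz --data sparse/ --bins 120 --out enhanced/

# score predictions against truth (per-cell TSV + cohort summary)
schicenh evaluate --truth cohort/ --pred enhanced/ --bins 120 --out report.tsv

# structure callers
schicenh compartments --data enhanced/ --bins 120 --out compartments.bed
schicenh tads --data enhanced/ --bins 120 --out boundaries.bed

# end-to-end desk-scale demo (simulate -> train -> enhance -> evaluate)
schicenh demo --workdir demo/ --seed 7
```

Matrices are exchanged as upper-triangle `bin_i<TAB>bin_j<TAB>count` text
(0-based bins, gzip-transparent, `#` comments).

## Layout

- `schicenh.synthetic` — planted-structure simulator, binomial downsampling
- `schicenh.matio` — triplet I/O, log-cap normalization, diagonal-band tiling
- `schicenh.nn` — NumPy reverse-mode autodiff + Adam
- `schicenh.model` — generator/discriminator, rank-one + SE blocks, checkpoints
- `schicenh.training` — pair construction, LSGAN training loop, enhancement
- `schicenh.metrics` — similarity metrics and structural matching
- `schicenh.structure` — compartment and TAD-boundary callers
- `schicenh.cli` — `schicenh` command
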