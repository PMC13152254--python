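# hamgnn

Physics-informed graph neural networks for single-cell multi-omics
classification.

Cell–cell k-nearest-neighbor graphs make graph convolutional networks
(GCNs) a natural classifier for paired single-cell RNA + ATAC data, but
plain GCNs over-smooth with depth (all embeddings collapse toward one
point), degrade sharply under feature or graph corruption, and offer
little mechanistic insight. `hamgnn` implements a Hamiltonian alternative:
each cell's embedding is split into position and momentum coordinates
`(q, p)` and evolved by symplectic Euler integration of a learnable scalar
energy `H_θ(q, p)`,

    p' = p − Δt ∂H/∂q(q, p),    q' = q + Δt ∂H/∂p(q, p'),

so representations are transported along energy-bounded trajectories
instead of repeatedly averaged. The package is aimed at computational
biologists who want a self-contained, CPU-friendly reference
implementation of this model family together with the full surrounding
workflow:

- **preprocessing** — RNA log-normalization (counts-per-10k, log1p),
  scaling, variance-stabilized highly-variable-gene selection; ATAC QC
  (nucleosome signal ≤ 2, TSS enrichment ≥ 2), TF-IDF, LSI; training-set-
  only Wilcoxon differential feature selection with BH correction;
- **graph construction** — per-modality k-NN (k = 20), simplified
  weighted-nearest-neighbor modality weights, consensus k = 15 graph;
- **models** — the Hamiltonian graph network (per-node MLP energy or
  graph-convolutional tanh-bounded energy) and a matched plain-GCN
  baseline of configurable depth, trained with Adam (lr 0.01, weight decay
  5e-4, dropout 0.5, early stopping, patience 50), all on a built-in numpy
  autodiff engine (no torch required);
- **diagnostics** — per-step energy traces and drift, mean pairwise cosine
  similarity, Dirichlet energy, inter/intra-class similarity, phase-space
  PCA, depth/horizon ablation sweeps;
- **perturbation harness** — seeded feature bit-flip / shift / dropout and
  edge removal + injection, with a combined-intensity robustness sweep;
- **synthetic data** — seeded generators for a paired multiome cohort
  (8 cell types × 2 disease states, donors nested in state, negative-
  binomial RNA, zero-inflated-Poisson ATAC) and stochastic-block-model
  graph benchmarks, so everything is testable without downloads.

See `docs/methods.md` for the model, its assumptions, and all numerical
conventions.

## Worked example

```python
from hamgnn.model import ModelConfig
from hamgnn.pipeline import PipelineConfig, run_pipeline
from hamgnn.synthetic import SyntheticSpec, make_multiome

data = make_multiome(SyntheticSpec(seed=1))          # 2,000 cells, 16 classes
cfg = PipelineConfig(model=ModelConfig(hidden_dim=16, epochs=50, patience=50))
out = run_pipeline(data["rna"], data["atac"], data["labels"], data["qc"],
                   cfg, seed=1)
for part in ("train", "val", "test"):
    m = out["metrics"][part]
    print(f"{part}: accuracy={m['accuracy']:.4f} f1_macro={m['f1_macro']:.4f}")
```

prints

```
train: accuracy=1.0000 f1_macro=1.0000
val: accuracy=1.0000 f1_macro=1.0000
test: accuracy=0.9974 f1_macro=0.9973
```

i.e. after QC (~5% of cells removed), feature selection on training cells
only, consensus-graph construction and training, the 16-way composite
cell-type × disease-state classifier labels 99.7% of held-out cells
correctly on the synthetic cohort. The same workflow is available as a
CLI:

```sh
hamgnn simulate   --config cfg.yaml --out sim/
hamgnn preprocess --rna sim/rna.mtx --atac sim/atac.mtx \
                  --labels sim/labels.tsv --qc sim/qc.tsv \
                  --config cfg.yaml --out pre/
hamgnn build-graph --rna-embed pre/rna_embed.tsv \
                   --atac-embed pre/atac_embed.tsv --config cfg.yaml --out g/
hamgnn train --features pre/features.tsv --graph g/graph.tsv \
             --labels pre/labels.tsv --split pre/split.json \
             --config cfg.yaml --out run/
hamgnn diagnose --features pre/features.tsv --graph g/graph.tsv \
                --labels pre/labels.tsv --checkpoint run/model.npz \
                --energy-trace run/energy_trace.json --config cfg.yaml --out d/
```

Every stage writes a `manifest.json` (config echo, seed, version, input
hashes); identical manifests reproduce outputs bit for bit. `perturb-sweep`
and `depth-sweep` run the robustness and over-smoothing ablation grids and
emit tidy CSV.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main end-to-end result from scratch — generates
the default synthetic cohort under the given seed, runs QC, preprocessing,
weighted-nearest-neighbor graph fusion and Hamiltonian-model training, and
prints the split-wise accuracy/F1 to stderr — then writes the results
JSON to `--out`.
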