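# perturbcycle

Cycle-consistent, latent-additive modeling of cellular responses to
chemical and genetic perturbations.

The package predicts perturbed expression (or proteomic) profiles from
unperturbed ones. Control profiles are encoded into a latent space in which
a perturbation acts as vector addition: the forward path decodes
`enc_control(x) + d_j` into a treated profile, and the reverse path decodes
`enc_treated(y) - d_j` back into a control profile. The perturbation vector
`d_j` comes from a two-layer graph-attention encoder over the drug's
molecular graph (SMILES), from a one-layer fully connected encoder over a
one-hot target gene for genetic perturbations, and can be modulated by a
learned dose embedding (elementwise product).

Two training regimes are supported:

* **paired** (bulk data): joint minimization of the autoencoder
  reconstruction loss and a two-term paired MSE (forward prediction +
  reverse restoration).
* **unpaired** (single-cell data): adversarial alignment with two
  discriminators (one per domain), a bidirectional cycle-consistency loss,
  and identity regularization, weighted as
  `alpha*L_reco + beta*L_GAN + lambda*L_cyc (+ identity)`.

Everything runs on a small numpy-based reverse-mode autodiff engine
(`perturbcycle._nn`) — no GPU framework is required.

## Layout

| module | contents |
| --- | --- |
| `perturbcycle.data_io` | dataset container, H5AD / MatrixMarket / delimited I/O, perturbation-level splits, pair assembly |
| `perturbcycle.drug_encoder` | SMILES → molecular graph, graph-attention layers, genetic encoder, dose embedding |
| `perturbcycle.model_core` | dual encoder–decoder model, discriminators, latent arithmetic, checkpoints |
| `perturbcycle.losses` | reconstruction, paired MSE, adversarial, cycle, identity, total objectives |
| `perturbcycle.training` | paired and adversarial training loops, batch prediction |
| `perturbcycle.evaluation` | r², explained variance, top-DEG selection, per-condition reports |
| `perturbcycle.synthetic` | additive-latent synthetic data generator with ground truth, recovery experiments |
| `perturbcycle.cli` | `perturbcycle` command-line interface incl. the six-variant ablation |
| `perturbcycle._nn` | autodiff tensors, MLP/batch-norm layers, Adam |

## CLI

```bash
# synthetic benchmark with known ground truth
perturbcycle simulate --config sim.yaml --out data/

# fit a model (paired or unpaired per the YAML config)
perturbcycle train --config train.yaml --train data/expression.csv --out ckpt/

# predict treated profiles for every treated record
perturbcycle predict --model ckpt/ --data data/expression.csv --out pred.csv

# per-condition r2 / EV / DEG report
perturbcycle evaluate --pred pred.csv --truth data/expression.csv \
    --report report.csv --summary-json summary.json --log-space

# single/dual autoencoder x loss-term ablation table
perturbcycle ablate --sim-config sim.yaml --train-config train.yaml --out ablation.csv
```

YAML config keys mirror `TrainingConfig` / `SyntheticConfig` fields
(`mode`, `epochs`, `batch_size`, `latent_dim`, `weights: {alpha, beta, lam,
identity_weight}`, ...). A global `--seed` overrides config seeds.

## Data conventions

* Delimited form: comma-separated (tab autodetected), header row of gene
  ids, first column `sample_id`; perturbation metadata either embedded
  (`perturbation_id`, `kind`, `smiles`, `target_gene`, `dose`,
  `context_id` columns) or in a `<stem>_obs.csv` sidecar.
* MatrixMarket form: `.mtx` plus `<stem>_features.txt`,
  `<stem>_barcodes.txt` and `<stem>_obs.csv` sidecars.
* H5AD form: `X` matrix, metadata in `obs`, gene ids in `var`.
* Expression values are consumed as provided; `preprocess()` offers
  optional log1p + per-gene standardization (off by default).
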