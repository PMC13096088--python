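# greensentry

Early disease warning for greenhouse crops from joint visual + environmental
sensing. The package implements, end to end on plain CPU numpy (autodiff via
HIPS `autograd`):

- **`greensentry.synthdata`** — a synthetic greenhouse simulator: minute-resolution
  environmental streams (temperature, RH, VPD via the Magnus formula, CO₂),
  per-plant disease events whose onset follows sustained high-humidity episodes
  with a configurable lag, and procedurally rendered frames whose lesion coverage
  tracks the ground-truth stage (`healthy` → `early` at <5% coverage →
  `symptomatic` within 1–3 days).
- **`greensentry.preprocess`** — multimodal temporal alignment: closed ±30 min
  window mean aggregation, EWMA smoothing (α=0.2), z-score normalization with
  train-only statistics, minimal-perturbation augmentation (±10% brightness /
  contrast, ≥95% area crops), and event-bounded sequence windowing.
- **`greensentry.model`** — the dual-branch network: hierarchical windowed-attention
  visual backbone (stage resolutions H/8·96, H/16·192, H/32·384), a sensor branch
  producing per-stage environmental embeddings, environment-guided channel gating
  (`F̃ = F · σ(W_c[f_avg;f_max]) · σ(W_e s)` + spatial map + 1×1 residual),
  per-frame spatial saliency attention (3×3 conv on channel-pooled maps), and a
  bidirectional temporal encoder (6 blocks, 8 heads, 4d FFN, d=256 by default).
- **`greensentry.losses`** — the four-term objective
  `L = L_sup + 0.5·L_early + 0.1·L_align + 0.3·L_ds` (cross-entropy, early-stage
  upweighting, cosine environment–vision alignment, deep supervision).
- **`greensentry.evaluation`** — accuracy/recall/precision/F1, early-stage
  one-vs-rest metrics, lead time with a 3-consecutive->0.5 hysteresis rule
  (positive lead = warning before reference onset), and leakage-free
  event-grouped K-fold splits.
- **`greensentry.cli` / `greensentry.train`** — AdamW + cosine annealing training
  loop, Xavier-uniform init, run manifests, and a vision-only ablation switch.

## CLI

```bash
greensentry simulate --out data/ --seed 0                  # synthetic dataset
greensentry train    --data data/ --out run/ --seed 0      # train (desk profile)
greensentry train    --data data/ --out run_abl/ --no-env-guidance
greensentry evaluate --checkpoint run/checkpoint.npz --data data/ --out eval/
greensentry crossval --data data/ --out cv/ --folds 5      # event-isolated 5-fold
```

Configuration is one YAML file with `sim`/`align`/`model`/`loss`/`train`/`eval`
sections (`--config cfg.yaml`); `--profile paper` selects the published
hyperparameters (d=256, batch 16, lr 1e-4, weight decay 1e-4), `--profile desk`
(default) a reduced-width profile with identical structure for CPU-scale runs.

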