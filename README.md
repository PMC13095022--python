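# dscanet

Dual-branch encoder–decoder network for **colorectal polyp segmentation**
in colonoscopy images, as a tested, pure-NumPy library and CLI.

Polyps are the precursor lesions of most colorectal cancers; segmenting
them in endoscopy frames is hard because their boundaries blur into the
surrounding mucosa and their size and color vary wildly. DSCANet attacks
both problems with two cooperating encoders and three fusion modules:

- an **edge encoder** built from *pixel-difference convolutions* —
  y = Σ₍ᵢ,ᵢ′₎∈P ωᵢ·(xᵢ − xᵢ′), a convolution over pixel-pair differences
  that responds to gradients and is exactly zero on constant regions —
  with a deeply supervised edge map per stage;
- a **body encoder**: a four-stage shifted-window transformer
  (ẑ = W-MSA(LN(z)) + z; z = MLP(LN(ẑ)) + ẑ, alternating with shifted
  windows) producing the pyramid H/4×C … H/32×8C;
- **SCA** (spatial cross-attention): all four edge stages tokenized to a
  common token count and refined by one shared attention map
  Softmax(QKᵀ/√d_k) applied to every scale's values;
- **BF** (bipolar fusion): class tokens CLS = GAP(Norm(P)) of the
  shallowest and deepest levels are exchanged through single-query
  cross-attention, y_s = f_s(CLS_s) + MCA(LN([f_s(CLS_s) ∥ P_l])), which
  runs in time linear in the token count;
- an **FAA decoder**: gated axial attention along height then width,
  y_ij = Σ_w softmax(q_ijᵀk_iw + G_Q q_ijᵀr^q_iw + G_K k_iwᵀr^k_iw)
  (G_V1 v_iw + G_V2 r^v_iw), whose learnable gates suppress badly
  learned positional terms.

Training combines a hybrid body loss L_body = λ1·BCE + λ2·Dice
(λ1 = 0.6, λ2 = 0.4) with an annotator-robust edge loss (γ = 0.6,
β = 0.8, λ = 2.0) as L = L_body + ω·L_edge, ω = 0.3. Reported metrics
are DSC, IoU, Precision, Recall and F1 from pixel confusion counts.

Everything — including a compact reverse-mode autodiff engine with
convolutions, window/axial attention, Adam and LR scheduling — runs on
NumPy/SciPy; there is no GPU dependency. Synthetic polyp data (blurred
boundaries, tiny/large blobs, variable color on textured mucosa) makes
the whole pipeline exercisable end-to-end with no dataset download;
Kvasir-SEG / CVC-ClinicDB-style folders (`images/`, `masks/`) load
through the same interface.

## Worked example

Overfitting the reduced-width model (C = 24, depths (1,1,2,1)) on eight
synthetic 64×64 samples — the package's desk-scale sanity check:

```python
from dscanet import (SyntheticConfig, generate_dataset, tiny_config,
                     build_model, train, evaluate, TrainConfig)

samples = generate_dataset(SyntheticConfig(image_size=64, seed=11), 8)
model = build_model(tiny_config(input_size=64, seed=0))
tcfg = TrainConfig(lr=2e-3, batch_size=2, epochs=30, input_size=64,
                   seed=0, weight_decay=0.0, grad_clip=5.0)
result = train(model, samples, tcfg)
model.load_state_dict(result["best"])
report = evaluate(model, samples)
print(f"best training DSC over 30 epochs: {result['best_dsc']:.2f}%")
print("final per-image-mean metrics on the training set:")
for k, v in report.as_dict().items():
    print(f"  {k:>9}: {v:6.2f}%")
```

prints (a few minutes on one CPU core):

```
best training DSC over 30 epochs: 95.27%
final per-image-mean metrics on the training set:
        dsc:  95.27%
        iou:  91.02%
  precision:  96.80%
     recall:  93.92%
         f1:  96.10%
```

DSC is the Dice overlap 2TP/(2TP+FP+FN) between predicted and true
polyp masks in percent; >90% here means the training pipeline can drive
the full architecture to near-pixel-perfect masks on data it has seen —
a correctness check of the machinery, not a clinical claim.

## CLI

```bash
dscanet generate --out data/ --n 64 --size 224 --seed 0   # synthetic dataset
dscanet train --out run/ --data data/ --size 224          # train (Adam, plateau LR)
dscanet eval run/best.npz --data data/ --out eval/        # metrics TSV + PNG masks
dscanet ablate --out ablation.json --size 64              # M1…M7 + full grid
dscanet complexity                                        # params (M) / FLOPs (G)
```

`dscanet complexity` prints the analytic accounting of the default
224×224 model — 31.28 M trainable parameters and 58.33 GFLOPs
(2·MACs over convolutions, linear layers and attention matmuls) —
matching the method's reference budget of ~31.25 M / ~58.63 G.

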