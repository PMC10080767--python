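# mhamfd

Hierarchical-attention graph learning for health-insurance fraud detection.

Medical claims involve patients, departments, dispensed medicines and visit
dates, and fraud tends to be *collective*: rings of card holders show up in
the same department on the same day or cycle the same prescriptions.
Single-visit attributes miss this; the structure of repeated co-visits does
not.  `mhamfd` models a claim table as an attributed heterogeneous
information network over four node types (Patient, Time, Medicine,
Department), derives seven patient–patient **behavioural relation graphs**
— PDP, PTP, PMP (one shared entity type), PDTP, PDMP, PTMP (two,
simultaneously, within one visit pair), PDTMP (all three) — and classifies
patients with a three-tier attention network:

1. **intra-relation**: multi-head graph attention over a patient's
   neighbours in one relation graph,
   α<sub>ij</sub><sup>l</sup> = softmax<sub>j</sub> LeakyReLU(a<sub>l</sub>·[W<sub>l</sub>x<sub>i</sub> ‖ W<sub>l</sub>x<sub>j</sub>]);
2. **inter-relation**: attention over the relation embeddings of each
   level, β = softmax over ω<sub>l</sub> = mean<sub>i</sub> q₀·tanh(W₀x<sub>i</sub><sup>l</sup>+b₀);
3. **hierarchical**: attention over the level embeddings, weights γ, final
   embedding H = Σ γ<sub>m</sub> x<sub>m</sub>.

Training is semi-supervised and transductive (weighted cross-entropy on the
labelled patients only), and the fitted β and γ weights are reported — they
say *which* behavioural relationships drive the classification, which is
the interpretability the setting demands.

The model is trained with a small reverse-mode autodiff engine over numpy
that ships with the package; there is no deep-learning framework
dependency.

## Worked example

Real claim data of this kind is private, so the package includes a
simulator that plants fraud rings (shared department+date co-visits) in a
population whose patient features carry **no** label signal — anything the
model learns must come from graph structure:

```python
from mhamfd import MHAMFD, SynthConfig, TrainConfig, generate_claims, generate_features

cfg = SynthConfig(seed=0)                      # 100 fraud : 200 normal, rings of 6
claims, labels = generate_claims(cfg)
features = generate_features(labels, cfg)      # pure N(0,1) noise (mu = 0)
model = MHAMFD.from_claims(claims, features=features,
                           config=TrainConfig(split_ratio=(3, 1, 1), seed=0))
results = model.fit()
print(results.summary())
```

```
MHAMFD fitted model
=======================================================
patients: 300   relations: 7   best epoch: 162/212

split        n      acc     prec   recall       f1
train      180   0.9667   0.9091   1.0000   0.9524
val         60   0.9833   0.9524   1.0000   0.9756
test        60   0.8833   0.7407   1.0000   0.8511

attention over relationship levels:
  single   0.305
  dual     0.633
  triple   0.062
attention over behavioural relationships (within level):
  PDP      0.438
  PMP      0.230
  PTP      0.332
  PDMP     0.180
  PDTP     0.698
  PTMP     0.122
  PDTMP    1.000
```

Reading the output: held-out test F1 is 0.85 even though the features are
noise — the planted co-visit structure is recovered.  The level attention γ
concentrates on the **dual** level (0.633): sharing a department *and* a
date in one visit pair is rare by coincidence but guaranteed inside a ring,
so those graphs carry the class signal.  Within the dual level, β singles
out PDTP (0.698).  The triple level has a single relation (PDTMP), so its
β is exactly 1 by construction.

A features-only logistic regression on the same split stays near chance
(F1 ≈ 0.34), and a single-level-only ablation (PDP/PTP/PMP graphs alone)
reaches only F1 ≈ 0.58 — the multilevel hierarchy is what extracts the
signal.  `results.lift_table()` reproduces the classic observational check:
patients with at least one fraudulent PDTMP neighbour have a fraud rate
several times the zero-neighbour group's.

The same objects are scriptable from the shell:

```bash
mhamfd simulate --seed 0 --out-dir runs/sim
mhamfd build-graphs --claims runs/sim/claims.csv --out-dir runs/graphs
mhamfd train --claims runs/sim/claims.csv --features runs/sim/features.csv \
             --seed 0 --out-dir runs/fit
mhamfd report --claims runs/sim/claims.csv \
              --attention runs/fit/attention.json --out-dir runs/report
```

Every run directory receives the resolved configuration (`config.yaml`), a
log, metrics and attention reports as JSON, the training history as CSV and
the patient embeddings as TSV.

## Layout

| module | contents |
| --- | --- |
| `mhamfd.claims` | claim/feature table I/O, validation, structural fallback features |
| `mhamfd.hetero` | AHIN construction and composition summary |
| `mhamfd.relations` | behavioural path enumeration and relation adjacencies |
| `mhamfd.attention` | the three-tier attention network, loss, attention report |
| `mhamfd.training` | splits, training loop, metrics, fraud-lift analysis |
| `mhamfd.model` | `MHAMFD` / `MHAMFDResults` model–results interface |
| `mhamfd.synth` | planted-ring claim simulator |
| `mhamfd.cli` | `mhamfd simulate / build-graphs / train / evaluate / report` |

See `docs/methods.md` for the model's assumptions, parameter defaults and
known limitations.
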