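# pirbind

Identification of piRNA target sites on mRNAs from CLASH chimeric reads,
with a deep multi-head attention classifier.

In *C. elegans*, PIWI-clade Argonautes use ~21-nt piRNAs to find and silence
mRNA targets, tolerating imperfect pairing outside a seed region (piRNA
positions 2–7). CLASH experiments record these interactions as chimeric
reads — a piRNA ligated to a fragment of the mRNA it was bound to. `pirbind`
provides the full analysis path:

- **Ground truth from chimeras** (`pirbind.clash_prep`): five rigorous
  filters (read count ≥ 7, fragment ≥ 14 nt, perfect unique transcriptome
  placement, duplex energy < 0) produce verified positive pairs; a loose
  binding set (LBS) defines per-piRNA negative candidates
  `NCS_i = U − {x | (i,x) ∈ LBS}` from which balanced negatives are sampled.
- **Model** (`pirbind.attention_net`): one-hot piRNA (21×4) and mRNA window
  (31×4) → convolution (128 kernels, width 5) + batch norm + PReLU +
  squeeze-and-excitation → 16-head scaled dot-product attention
  `H_t = softmax(M W_Q (P W_K)ᵀ / √d) P W_V` with d = 21 (the piRNA length)
  → residual feed-forward with layer norm → fully connected classifier
  (32·31 → 8·31 → 2, softmax). A pure-CNN ablation removes the attention.
  The network runs on a small NumPy autodiff engine (`pirbind.nn`); no
  deep-learning framework is required.
- **Evaluation** (`pirbind.train_eval`): repeated stratified 8:1:1 splits,
  sensitivity/specificity/precision/F1, rank-based AUC (equal to the
  trapezoidal ROC area), one-tailed rank-sum model comparison.
- **Baselines** (`pirbind.baselines`): 18 whole-sequence features (CG
  content, composition, k-mer tandem repeats for k = 2,3,4, duplex energy)
  as single-score ROCs and as a small MLP.
- **Rule extraction** (`pirbind.rule_viz`): head-averaged attention
  matrices, per-position salience and consensus regions.
- **Synthetic worlds** (`pirbind.synthetic`): transcriptomes with target
  sites planted under the worm targeting rule (perfect 2–7 seed
  complement, few non-seed mismatches, free first base), chimera libraries
  with a low-count noise spike, and direct labeled pair sets — everything
  is testable without downloads.

See `docs/methods.md` for the model, filters and design choices in detail.

## Worked example

```python
import numpy as np
import pirbind as pb
from pirbind.train_eval import TrainConfig, encode_pairs, roc_auc, train_model

world = pb.gen_world(pb.SynthSpec(n_transcripts=150, n_pirnas=100,
                                  n_planted_sites=900, seed=2))
gt = pb.gen_pair_dataset(world, 800, 800, seed=2)      # balanced planted pairs
p_oh, m_oh, y = encode_pairs(gt.examples)
perm = np.random.default_rng(0).permutation(len(y))
model, log = train_model("full", (p_oh, m_oh, y),
                         split=(perm[:1200], perm[1200:1400]),
                         train_cfg=TrainConfig(epochs=10, batch_size=256, seed=0))
test = perm[1400:]
print(roc_auc(y[test], model.predict_proba(p_oh[test], m_oh[test])[:, 1]).auc)
```

Running this (`python examples/02_train_attention_model.py`) prints

```
epoch  7: train acc 0.777, val acc 0.685
epoch  8: train acc 0.772, val acc 0.685
epoch  9: train acc 0.762, val acc 0.700

test AUC 0.822  precision 0.727 recall 0.881  F1 0.797
```

i.e. at this deliberately small demo scale (1,200 training pairs, ten
epochs) the model already ranks a random positive above a random negative
82% of the time; on the default 7,000-pair dataset the same architecture
reaches test AUC ≈ 0.95 after 14 epochs and ≈ 0.99 with continued
training. The other scripts in `examples/` walk through ground-truth
construction with its attrition report, attention-rule extraction
(salience peaking over the seed), and the baseline comparison.

A thin CLI mirrors the library: `pirbind simulate | prep | train | eval |
predict | baseline` (see `pirbind --help`).

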