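"""Compare whole-sequence baseline scores against the planted signal.

Computes the 18 per-pair features (CG content, base composition,
tandem-repeat summaries, duplex energy), ranks pairs by single features,
and fits the small feature MLP.  Duplex energy separates planted antisense
pairs from random ones; composition alone is near chance.
"""

import numpy as np

import pirbind as pb
from pirbind.baselines import (
    MLPConfig, feature_matrix, single_feature_auc, train_mlp_baseline,
)
from pirbind.train_eval import roc_auc

world = pb.gen_world(pb.SynthSpec(n_transcripts=100, n_pirnas=60,
                                  n_planted_sites=400, seed=3))
gt = pb.gen_pair_dataset(world, 400, 400, seed=3)
pairs = gt.examples
labels = np.array([p.label for p in pairs])

print("single-feature AUCs (sign-oriented):")
for name in ("duplex_energy", "cg_content", "comp_A", "comp_G", "k2_n_loci"):
    print(f"  {name:>14}: {single_feature_auc(pairs, name).auc:.3f}")

X = feature_matrix(pairs)
rng = np.random.default_rng(0)
perm = rng.permutation(len(pairs))
tr, te = perm[:600], perm[600:]
mlp = train_mlp_baseline(X[tr], labels[tr], MLPConfig(epochs=30, seed=0))
auc = roc_auc(labels[te], mlp.predict_proba(X[te])[:, 1]).auc
print(f"\n18-feature MLP test AUC: {auc:.3f}")
print("Energy dominates the baselines here because planted targets are "
      "antisense matches; composition features carry only weak signal.")
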