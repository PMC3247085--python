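"""One break-tie active-learning round on an overlapping mixture.

Trains a calibrated SVM on four labels, scores the unlabeled pool,
splits it by confidence, and shows which instances the break-tie
criterion sends to the oracle.
"""

import numpy as np

from ppispotter import (
    ClusterSpec,
    class_probability,
    fit_calibration,
    make_clusters,
    select_queries,
    split_by_confidence,
    train_linear_svm,
)

spec = ClusterSpec(centers=[(-1.0, 0.0), (1.0, 0.0)], sigmas=[0.8, 0.8],
                   class_of_cluster=[-1, 1], n_labeled=4, n_unlabeled=200,
                   n_test=0, seed=3)
labeled, pool, _ = make_clusters(spec)

model = train_linear_svm(labeled.X, labeled.y, C=1.0)
calib = fit_calibration(model, labeled.X, labeled.y)
p_pos, _ = class_probability(model, calib, pool.X)

fuzzy, confident, machine_labels = split_by_confidence(p_pos, theta=0.9)
batch = select_queries(p_pos[fuzzy], budget=10)

print(f"pool size                : {len(pool.X)}")
print(f"high-confidence instances: {len(confident)}")
print(f"fuzzy instances          : {len(fuzzy)}")
print("queried (tie score, P+):")
for loc, score in zip(batch.indices, batch.tie_scores_):
    idx = fuzzy[loc]
    print(f"  pool[{idx:3d}]  tie={score:.3f}  P+={p_pos[idx]:.3f}")

# The queried instances all have P+ near 0.5 — the model's genuinely
# ambiguous cases, exactly where an expert label buys the most
# information.  High-confidence instances keep their machine labels and
# later warm-start the semi-supervised stage.
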