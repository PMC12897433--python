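"""Rank the window statistics with the from-scratch random forest and
validate the fibrosis labels with from-scratch K-means.

Run:  python examples/02_feature_selection_and_clustering.py
(takes a minute or two: it extracts windows from 120 images)
"""

import shgquant as sq
from shgquant.clustering import cluster_image_features, label_agreement
from shgquant.features import image_feature_table, window_feature_table
from shgquant.selection import rank_features

# a half-size dataset keeps the window table small for the demo
cohorts = [
    sq.CohortSpec("C", 6, 5, 0.08, 26.0),
    sq.CohortSpec("A", 6, 5, 0.24, 24.0),
    sq.CohortSpec("S", 6, 5, 0.40, 16.0),
    sq.CohortSpec("AS", 6, 5, 0.62, 2.8),
]
dataset = sq.generate_dataset(cohorts, seed=1)

# window-level features, stride 10 (stride 1 would give 6561 rows/image)
wtab = window_feature_table(dataset.images, window_size=20, stride=10)
label_map = dict(zip(dataset.manifest["image_id"], dataset.labels))
labels = wtab["image_id"].map(label_map).to_numpy(dtype=int)
print(f"{len(wtab)} window rows from {len(dataset)} images")

# random-forest mean-decrease-in-impurity ranking of the 8 features
ranking = rank_features(wtab, labels, n_trees=50, seed=0)
print(ranking.as_frame().to_string(index=False))
print(f"top feature: {ranking.ranked_names[0]}")

# K-means (k=2) on the image-level features; does unsupervised structure
# agree with the fibrosis labels?
itab = image_feature_table(dataset.images)
assignment = cluster_image_features(itab, seed=0, n_init=3)
agreement = label_agreement(assignment, dataset.labels)
print(f"k-means converged in {assignment.iterations} iterations, "
      f"inertia {assignment.inertia:.1f}")
print(f"cluster/label agreement: {agreement:.3f}")
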