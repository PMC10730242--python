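"""Endotype discovery: hierarchical clustering of the embedding, data-driven
choice of the number of clusters, and severity-ordered relabelling.

Clusters are cut from a Ward / Euclidean agglomeration of the encoder
embedding; k is chosen as the silhouette argmax over a grid with a
no-structure guard; labels are then renumbered so that mean baseline
c-IMT_mean-max increases with the endotype index (endotype 1 mildest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

__all__ = ["cluster_embedding", "select_k", "order_endotypes", "EndotypeAssignment", "KSelection"]


def _check_embedding(Z) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if not np.all(np.isfinite(Z)):
        raise ValueError("embedding must be finite")
    if float(Z.std(axis=0).max()) < 1e-3:
        # collapsed bottleneck: variation is numerical residue, not structure
        raise ValueError("degenerate embedding: no usable variation")
    return Z


def cluster_embedding(embedding, k: int) -> np.ndarray:
    """Agglomerative (Ward linkage, Euclidean) clustering cut at k clusters."""
    Z = _check_embedding(embedding)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(Z):
        raise ValueError("k exceeds the number of subjects")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(Z)


@dataclass
class KSelection:
    k: int
    profile: dict            # k -> mean silhouette
    no_structure: bool
    threshold: float

    @property
    def max_silhouette(self) -> float:
        return max(self.profile.values())


def select_k(embedding, kmin: int = 2, kmax: int = 8, threshold: float = 0.15) -> KSelection:
    """Silhouette argmax over k in [kmin, kmax] with a no-structure guard.

    The guard flags the result when even the best silhouette stays below the
    threshold, in which case no defined cluster should be reported.
    """
    Z = _check_embedding(embedding)
    if len(Z) <= kmax:
        raise ValueError("need more subjects than kmax")
    profile = {}
    for k in range(kmin, kmax + 1):
        labels = cluster_embedding(Z, k)
        profile[k] = float(silhouette_score(Z, labels))
    best_k = max(profile, key=lambda k: (profile[k], -k))
    return KSelection(k=best_k, profile=profile,
                      no_structure=profile[best_k] < threshold, threshold=threshold)


@dataclass
class EndotypeAssignment:
    """Severity-ordered endotype labels 1..K (1 = mildest mean c-IMT_mean-max)."""

    labels: np.ndarray
    k: int
    relabel_map: dict          # raw cluster id -> endotype
    mean_severity: np.ndarray  # per endotype, ascending

    def __post_init__(self):
        if np.any(np.diff(self.mean_severity) < -1e-12):
            raise ValueError("mean severity must be non-decreasing in the endotype index")


def write_assignment(assignment: "EndotypeAssignment", subject_ids, csv_path,
                     tree_path=None, linkage=None) -> None:
    """Two-column delimited text (subject_id, endotype); optional tree as JSON."""
    import json

    import pandas as pd
    pd.DataFrame({"subject_id": np.asarray(subject_ids),
                  "endotype": assignment.labels}).to_csv(csv_path, index=False)
    if tree_path is not None and linkage is not None:
        with open(tree_path, "w", encoding="utf-8") as fh:
            json.dump({"linkage": np.asarray(linkage).tolist(),
                       "relabel_map": {str(k): v for k, v in assignment.relabel_map.items()}},
                      fh)


def order_endotypes(raw_labels, severity) -> EndotypeAssignment:
    """Relabel raw clusters so mean severity is ascending; ties -> larger cluster first."""
    raw = np.asarray(raw_labels)
    sev = np.asarray(severity, dtype=float)
    if raw.shape != sev.shape:
        raise ValueError("labels and severity must align")
    uniq = np.unique(raw)
    means, sizes = [], []
    for c in uniq:
        members = sev[raw == c]
        if members.size == 0:
            raise ValueError(f"empty cluster {c}")
        means.append(members.mean())
        sizes.append(members.size)
    means = np.asarray(means)
    sizes = np.asarray(sizes)
    order = np.lexsort((-sizes, means))   # ascending mean, ties -> descending size
    relabel = {int(uniq[orig]): rank + 1 for rank, orig in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    return EndotypeAssignment(labels=labels, k=len(uniq), relabel_map=relabel,
                              mean_severity=means[order])
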