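"""Clustering quality control for merged expression matrices."""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression import ExpressionMatrix

__all__ = ["cluster_qc"]


def cluster_qc(m: ExpressionMatrix, n_groups: int = 3) -> dict:
    """Hierarchical clustering (Euclidean, complete linkage) of the samples.

    The tree is cut into ``n_groups``; each group takes its majority
    phenotype as its label.  Returns, per phenotype, the fraction of its
    samples falling in groups labeled with that phenotype.
    """
    if m.phenotype is None:
        raise ValueError("cluster_qc requires phenotype labels")
    if n_groups > m.n_samples:
        raise ValueError("n_groups exceeds the number of samples")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    link = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    groups = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")

    phenotypes = m.phenotype.to_numpy()
    group_label = {}
    for grp in np.unique(groups):
        counts = Counter(phenotypes[groups == grp])
        group_label[grp] = counts.most_common(1)[0][0]

    accuracy = {}
    for phen in dict.fromkeys(phenotypes):
        idx = phenotypes == phen
        in_own = sum(1 for grp in groups[idx] if group_label[grp] == phen)
        accuracy[phen] = in_own / idx.sum()
    return accuracy
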