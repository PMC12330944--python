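"""Pathway correlation structure: axes from clusters of correlated pathways.

Pathway enrichment scores are correlated across samples (Pearson), pathways
are agglomeratively clustered on the distance 1 - r, and each cluster whose
members carry prognostic signal is collapsed into a composite axis score —
the per-sample unweighted mean of its prognostic member pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "pathway_correlation",
    "cluster_pathways",
    "composite_scores",
    "composite_matrix",
    "PathwayClustering",
    "CompositeScore",
    "AXIS_LABELS",
]

#: canonical axis labels, in the order (protective, adverse, adverse, adverse)
AXIS_LABELS = ("Luminal_AR", "Proliferation", "mTOR_glycolysis", "NEPC")


def pathway_correlation(s: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of pathway scores across samples."""
    if s.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate pathways")
    sd = s.std(axis=1, ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant pathways cannot be correlated: {constant}")
    r = np.corrcoef(s.to_numpy(dtype=float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=s.index, columns=s.index)


@dataclass
class PathwayClustering:
    """Result of cutting the pathway dendrogram into k clusters."""

    correlation: pd.DataFrame
    linkage_method: str
    k: int
    assignment: pd.Series  # pathway -> cluster id (1..k)

    def members(self, cluster_id: int) -> list[str]:
        return self.assignment.index[self.assignment == cluster_id].tolist()


def cluster_pathways(
    corr: pd.DataFrame, k: int, linkage_method: str = "average"
) -> PathwayClustering:
    """Agglomerative clustering of pathways on correlation distance 1 - r.

    Pathways are sorted lexicographically before linkage so the result is
    invariant to input order; the dendrogram is cut at exactly ``k``
    clusters, and cluster ids are relabeled 1..k in order of each cluster's
    lexicographically first member.
    """
    n = corr.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    names = sorted(corr.index)
    c = corr.loc[names, names].to_numpy(dtype=float)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    z = linkage(condensed, method=linkage_method)
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel deterministically by first-member order
    seen: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        labels[i] = seen[lab]
    assignment = pd.Series(labels, index=names, name="cluster")
    return PathwayClustering(
        correlation=corr, linkage_method=linkage_method, k=k, assignment=assignment
    )


@dataclass
class CompositeScore:
    """One axis: the mean of a cluster's prognostic member pathways."""

    cluster_id: int
    members: list[str]
    values: pd.Series  # per sample
    label: str = ""
    direction: str = ""  # "favorable" (HR < 1) or "adverse" (HR > 1)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a composite needs at least one member pathway")


def composite_scores(
    s: pd.DataFrame,
    clustering: PathwayClustering,
    prognostic_flags: pd.Series,
    labels: dict[int, str] | None = None,
    directions: pd.Series | None = None,
    standardize: bool = False,
) -> list[CompositeScore]:
    """Build one composite per cluster from its prognostic members.

    ``prognostic_flags`` marks pathways significant in the univariate
    survival screen (BH-adjusted p < 0.05); clusters with no flagged member
    yield no composite. Members enter unstandardized by default (enrichment
    scores already share the [-1, 1] scale); ``standardize=True`` z-scores
    each member first.
    """
    out: list[CompositeScore] = []
    labels = labels or {}
    for cid in sorted(clustering.assignment.unique()):
        members = [
            m for m in clustering.members(cid) if bool(prognostic_flags.get(m, False))
        ]
        if not members:
            continue
        block = s.loc[members]
        if standardize:
            block = block.sub(block.mean(axis=1), axis=0).div(
                block.std(axis=1, ddof=0), axis=0
            )
        values = block.mean(axis=0)
        direction = ""
        if directions is not None:
            dirs = {directions.get(m) for m in members}
            direction = dirs.pop() if len(dirs) == 1 else "mixed"
        out.append(
            CompositeScore(
                cluster_id=int(cid),
                members=members,
                values=values,
                label=labels.get(int(cid), f"cluster_{cid}"),
                direction=direction,
            )
        )
    return out


def composite_matrix(composites: list[CompositeScore]) -> pd.DataFrame:
    """Stack composites into an axis-by-sample DataFrame (rows = labels)."""
    if not composites:
        raise ValueError("no composites to stack")
    return pd.DataFrame({c.label: c.values for c in composites}).T
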