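"""Pairwise colocalization of crosslink sites and UPGMA clustering.

For an ordered factor pair (A, B): take A's strongest ``n`` crosslink
sites by occupancy, find B's maximum unsmoothed occupancy within +-w nt of
each site on the same strand, average those maxima (c), and compare with
B's background, the median of all defined B occupancies (b). The score is
log2(c/b): ~0 for unrelated factors, positive when B concentrates around
A's sites. The full (asymmetric) score matrix is row-normalized, turned
into Euclidean distances and clustered by average linkage (UPGMA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .annotation import GenomeLayout
from .normalize import OccupancyTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocScore:
    factor_a: str
    factor_b: str
    c: float       # mean over A's top sites of B's local max occupancy
    b: float       # median of all defined B occupancies
    score: float   # log2(c / b)
    n_sites: int
    w: int


@dataclass(frozen=True)
class ColocMatrix:
    scores: pd.DataFrame      # factors x factors, entry (A, B) = score(A -> B)
    normalized: pd.DataFrame  # after row normalization (input to clustering)
    linkage: np.ndarray       # scipy linkage matrix (n - 1 merges)


def coloc_score(
    sites_a: pd.DataFrame,
    occ_b: OccupancyTrack,
    layout: GenomeLayout,
    n: int = 3000,
    w: int = 20,
    factor_a: str = "A",
    factor_b: str = "B",
) -> ColocScore:
    """Colocalization of factor B around factor A's strongest sites.

    ``sites_a`` needs columns chrom/pos/strand/occupancy (unsmoothed).
    Fewer than ``n`` sites means all are used, recorded in ``n_sites``.
    Windows never cross to the opposite strand; windows where B is
    entirely undefined contribute 0.
    """
    if len(sites_a) == 0:
        raise ValueError(f"factor {factor_a!r} has no crosslink sites")
    b_vals = occ_b.values()
    if len(b_vals) == 0:
        raise ValueError(f"factor {factor_b!r} has no defined occupancies")
    b = float(np.median(b_vals))
    if b == 0:
        raise ValueError(
            f"median occupancy of {factor_b!r} is 0; apply an occupancy floor "
            "or a denominator mask before colocalization"
        )
    # deterministic top-n: occupancy descending, then genomic coordinate
    top = sites_a.sort_values(["occupancy", "chrom", "strand", "pos"],
                              ascending=[False, True, True, True],
                              kind="stable").head(n)
    dense_b = occ_b.to_dense(layout)
    maxima = np.zeros(len(top))
    for i, row in enumerate(top.itertuples(index=False)):
        arr = dense_b.get((row.chrom, row.strand))
        if arr is None:
            continue
        lo, hi = max(row.pos - w, 0), min(row.pos + w + 1, len(arr))
        window = arr[lo:hi]
        if np.any(np.isfinite(window)):
            maxima[i] = np.nanmax(window)
    c = float(maxima.mean())
    score = float(np.log2(c / b)) if c > 0 else -np.inf
    return ColocScore(factor_a=factor_a, factor_b=factor_b, c=c, b=b,
                      score=score, n_sites=len(top), w=w)


def average_linkage(dist: np.ndarray) -> np.ndarray:
    """UPGMA linkage from a square distance matrix (symmetric, zero
    diagonal, finite); returns the scipy linkage matrix of n-1 merges."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return hierarchy.average(squareform(d, checks=False))


def coloc_matrix(
    factors: dict[str, tuple[pd.DataFrame, OccupancyTrack]],
    layout: GenomeLayout,
    n: int = 3000,
    w: int = 20,
    normalize: bool = True,
) -> ColocMatrix:
    """All-pairs colocalization scores and their UPGMA clustering.

    ``factors`` maps factor name -> (called sites with occupancy, full
    occupancy track). Entry (A, B) of the score matrix is the A -> B score
    (not symmetric). Rows are z-score normalized before the Euclidean
    distance unless ``normalize`` is off.
    """
    names = list(factors)
    if len(names) < 3:
        raise ValueError("colocalization clustering needs >= 3 factors")
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    failures = []
    for a in names:
        for bn in names:
            try:
                mat.loc[a, bn] = coloc_score(
                    factors[a][0], factors[bn][1], layout, n=n, w=w,
                    factor_a=a, factor_b=bn).score
            except ValueError as exc:
                failures.append((a, bn, str(exc)))
                mat.loc[a, bn] = np.nan
    if failures or not np.all(np.isfinite(mat.to_numpy())):
        raise ValueError(f"colocalization failed for pairs: {failures}; "
                         "clustering aborted")
    norm = mat.copy()
    if normalize:
        vals = mat.to_numpy()
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        norm = pd.DataFrame((vals - mu) / sd, index=names, columns=names)
    link = hierarchy.average(pdist(norm.to_numpy(), metric="euclidean"))
    return ColocMatrix(scores=mat, normalized=norm, linkage=link)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Newick string (with branch lengths) for a scipy linkage matrix."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"
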