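"""Intrinsic gene-expression subset machinery.

Skin biopsies from systemic sclerosis patients fall into reproducible
molecular subsets (inflammatory, fibroproliferative, normal-like) defined
by an intrinsic gene list on a labeled reference cohort.  This module
builds per-subset centroids (gene-wise mean expression over the reference
samples of each subset), assigns new samples by the highest Spearman rank
correlation against those centroids, scores per-sample signature averages,
and provides the hierarchical clustering used for array trees.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetCall",
    "build_subset_centroids",
    "spearman_with_p",
    "assign_intrinsic_subset",
    "assign_all_samples",
    "score_signature",
    "hierarchical_cluster",
    "linkage_to_newick",
]

#: exact-permutation threshold for the Spearman p-value; above this the
#: t-approximation is used
EXACT_SPEARMAN_N = 9


@dataclass
class SubsetCall:
    """Assignment of one sample to an intrinsic subset."""

    sample_id: str
    rho: dict[str, float]
    p: dict[str, float]
    call: str
    margin: float
    warning: str | None = None


def build_subset_centroids(
    expression: pd.DataFrame,
    labels: dict[str, str],
    genes: list[str] | None = None,
    exclude: set[str] = frozenset({"limited"}),
) -> pd.DataFrame:
    """Average reference expression per subset over an intrinsic gene list.

    Parameters
    ----------
    expression : genes x reference-samples matrix.
    labels : sample_id -> subset label for the reference cohort.
    genes : intrinsic gene list; genes absent from the reference are
        dropped with a logged count. Defaults to all reference genes.
    exclude : subset labels to leave out (the 'limited' subset by default,
        matching a diffuse-disease study population).

    Returns a genes x subsets DataFrame of centroid vectors.
    """
    labeled = [s for s in expression.columns if s in labels and labels[s] not in exclude]
    if not labeled:
        raise ValueError("no labeled reference samples after exclusions")
    if genes is None:
        shared = list(expression.index)
    else:
        present = set(expression.index)
        shared = [g for g in genes if g in present]
        dropped = len(genes) - len(shared)
        if dropped:
            logger.info("dropped %d of %d intrinsic genes absent from reference", dropped, len(genes))
    if not shared:
        raise ValueError("no shared intrinsic genes")
    sub = expression.loc[shared, labeled]
    subset_of = pd.Series({s: labels[s] for s in labeled})
    centroids = sub.T.groupby(subset_of).mean().T
    if centroids.isna().any().any():
        raise ValueError("centroids contain missing values; impute the reference first")
    return centroids


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of one rank vector."""
    n = len(xr)
    xc = xr - xr.mean()
    sx = math.sqrt((xc**2).sum())
    yc = yr - yr.mean()
    sy = math.sqrt((yc**2).sum())
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(xc, yc[list(perm)])) / (sx * sy)
        if abs(r) >= abs(rho_obs) - tol:
            count += 1
        total += 1
    return count / total


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Ranks use midranks for ties. The p-value is exact (full permutation
    enumeration) for n <= 9 and otherwise uses the t-distribution
    approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations for Spearman correlation")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= EXACT_SPEARMAN_N:
        p = _exact_spearman_p(xr, yr, rho)
    else:
        if abs(rho) >= 1.0:
            p = float(np.nextafter(0, 1))
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(max(p, np.nextafter(0, 1)), 1.0)


def assign_intrinsic_subset(sample: pd.Series, centroids: pd.DataFrame) -> SubsetCall:
    """Call the intrinsic subset of one sample by nearest centroid.

    The sample is correlated (Spearman) with each subset centroid over
    their shared genes; the call is the subset with the highest rho.  The
    study procedure uses the highest coefficient and the lowest p-value as
    a joint criterion; these coincide when every centroid shares the same
    gene overlap, so rho wins with a recorded warning if they ever differ.
    """
    shared = centroids.index.intersection(sample.dropna().index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared with the centroids")
    vec = sample.loc[shared].to_numpy(dtype=float)
    if np.ptp(stats.rankdata(vec)) == 0:
        raise ValueError("zero rank variance")
    rhos: dict[str, float] = {}
    ps: dict[str, float] = {}
    for subset in centroids.columns:
        rhos[subset], ps[subset] = spearman_with_p(vec, centroids.loc[shared, subset].to_numpy())
    # argmax rho; ties broken by smaller p then alphabetical
    ordered = sorted(rhos, key=lambda s: (-rhos[s], ps[s], s))
    call = ordered[0]
    warning = None
    best_p = min(ps, key=lambda s: (ps[s], s))
    if best_p != call and not math.isclose(ps[best_p], ps[call]):
        warning = (
            f"highest-rho subset {call!r} differs from lowest-p subset {best_p!r}; rho wins"
        )
        logger.warning("%s: %s", sample.name, warning)
    margin = rhos[ordered[0]] - rhos[ordered[1]] if len(ordered) > 1 else float("nan")
    return SubsetCall(sample_id=str(sample.name), rho=rhos, p=ps, call=call, margin=margin, warning=warning)


def assign_all_samples(m: pd.DataFrame, centroids: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Assign every (or the given) sample; returns a tidy call table."""
    cols = samples if samples is not None else list(m.columns)
    rows = []
    for s in cols:
        call = assign_intrinsic_subset(m[s], centroids)
        row = {"sample_id": s, "call": call.call, "margin": call.margin}
        for subset in centroids.columns:
            row[f"rho_{subset}"] = call.rho[subset]
            row[f"p_{subset}"] = call.p[subset]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def score_signature(
    m: pd.DataFrame,
    gene_set: list[str],
    samples: list[str] | None = None,
    set_name: str = "signature",
) -> pd.DataFrame:
    """Per-sample signature score: mean expression over the set's genes.

    The matrix is expected to be centered (log2 ratios, median-centered
    platform-wide), so a score of 0 means signature expression at the
    cohort-typical level. Returns a table with score and n_genes_used.
    """
    present = [g for g in dict.fromkeys(gene_set) if g in m.index]
    if not present:
        raise ValueError("gene set disjoint from the expression matrix")
    cols = samples if samples is not None else list(m.columns)
    scores = m.loc[present, cols].mean(axis=0)
    out = pd.DataFrame({
        "sample_id": cols,
        "gene_set": set_name,
        "score": scores.values,
        "n_genes_used": len(present),
    })
    return out.set_index("sample_id")


def _correlation_distance(X: np.ndarray, centered: bool = True) -> np.ndarray:
    """Pairwise 1 - Pearson correlation over rows; constant rows get
    correlation 0 (distance 1) to everything, with a warning."""
    X = np.asarray(X, dtype=float)
    if centered:
        Xc = X - X.mean(axis=1, keepdims=True)
    else:
        Xc = X.copy()
    norms = np.sqrt((Xc**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        logger.warning("%d constant item(s); correlation to them defined as 0", int(zero.sum()))
    norms[zero] = 1.0
    Xn = Xc / norms[:, None]
    corr = Xn @ Xn.T
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return 1.0 - corr


def hierarchical_cluster(
    m: pd.DataFrame,
    axis: str = "columns",
    centered: bool = True,
) -> dict:
    """Average-linkage agglomerative clustering on correlation distance.

    Distance is 1 - Pearson correlation (set ``centered=False`` for the
    uncentered-correlation variant used by classic clustering tools).
    Ties in merge distance are resolved deterministically by input order
    (the condensed-distance convention). Returns the linkage matrix, leaf
    order, leaf labels, a Newick string, and the reordered matrix.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = m.to_numpy(dtype=float) if axis == "rows" else m.to_numpy(dtype=float).T
    labels = list(m.index) if axis == "rows" else list(m.columns)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _correlation_distance(data, centered=centered)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    order = hierarchy.leaves_list(Z).tolist()
    reordered = m.loc[[labels[i] for i in order]] if axis == "rows" else m[[labels[i] for i in order]]
    return {
        "linkage": Z,
        "leaf_order": order,
        "leaf_labels": [labels[i] for i in order],
        "newick": linkage_to_newick(Z, labels),
        "reordered": reordered,
    }


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return str(labels[node.id]).replace(",", "_").replace("(", "_").replace(")", "_")
        left = render(node.get_left())
        right = render(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return render(tree) + ";"


def write_cdt(m: pd.DataFrame, path) -> None:
    """Write a clustered data table (CDT-style tab-delimited export)."""
    out = m.copy()
    out.insert(0, "NAME", out.index)
    out.insert(0, "GID", [f"GENE{i}X" for i in range(len(out))])
    out.to_csv(path, sep="\t", index_label="GID0")
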