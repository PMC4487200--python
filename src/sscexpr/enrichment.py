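"""Gene-set level statistics.

Three routes from genes to pathways:

* :func:`gsea` — cohort-level enrichment of a ranked gene list against a
  collection of gene sets, using the weighted Kolmogorov–Smirnov running
  sum, a gene-set permutation null (sample permutation is unsound at the
  class sizes of a ten-patient trial), and the standard signed-pool FDR.
* :func:`ssgsea_project` — single-sample projection: per sample, the
  integrated difference of weighted empirical CDFs of in-set versus
  out-of-set genes along the expression-ranked list.
* :func:`overrepresentation_test` — a self-contained hypergeometric
  over-representation test with Benjamini–Hochberg correction, for
  annotating a discrete gene signature against functional term sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import ClassAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes_signal_to_noise",
    "enrichment_score",
    "gsea",
    "ssgsea_project",
    "overrepresentation_test",
]


def rank_genes_signal_to_noise(
    m: pd.DataFrame, classes: ClassAssignment, metric: str = "s2n"
) -> pd.Series:
    """Per-gene class-separation metric, sorted descending.

    's2n' is the signal-to-noise ratio (meanA - meanB)/(sdA + sdB) with the
    usual floor on each sd (max(sd, 0.2*|mean|, eps)) to keep
    low-variance genes from dominating; 't' is the pooled two-sample t.
    """
    A = m[classes.class_a].to_numpy(dtype=float)
    B = m[classes.class_b].to_numpy(dtype=float)
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    if metric == "s2n":
        sa = np.maximum.reduce([A.std(axis=1, ddof=1), 0.2 * np.abs(ma), np.full_like(ma, 0.2)])
        sb = np.maximum.reduce([B.std(axis=1, ddof=1), 0.2 * np.abs(mb), np.full_like(mb, 0.2)])
        score = (ma - mb) / (sa + sb)
    elif metric == "t":
        n1, n2 = A.shape[1], B.shape[1]
        sp2 = ((n1 - 1) * A.var(axis=1, ddof=1) + (n2 - 1) * B.var(axis=1, ddof=1)) / (n1 + n2 - 2)
        sp2 = np.maximum(sp2, 1e-12)
        score = (ma - mb) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ranked = pd.Series(score, index=m.index).sort_values(ascending=False, kind="stable")
    return ranked


def enrichment_score(
    ranked: pd.Series, gene_set: set[str] | list[str], weight: float = 1.0
) -> tuple[float, int, list[str]]:
    """Weighted KS enrichment score for one gene set on a ranked list.

    ``ranked`` is the metric sorted descending. Hits increment the running
    sum by |metric|^weight normalized over the set's hits; misses decrement
    by 1/(N - Nh). The ES is the running-sum value of largest magnitude.
    Returns (ES, extremum position, core-enrichment genes: the set members
    at or before the extremum on the ES's sign side).
    """
    genes = ranked.index
    in_set = genes.isin(set(gene_set)).astype(bool)
    N = len(genes)
    Nh = int(in_set.sum())
    if Nh == 0:
        raise ValueError("gene set disjoint from the ranked universe")
    if Nh == N:
        raise ValueError("gene set covers the entire universe; miss pool empty")
    r = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit = np.where(in_set, r, 0.0)
    nr = hit.sum()
    if nr == 0:
        # all in-set metrics are exactly 0 under positive weight; fall back
        # to equal hit weights so the score stays defined
        hit = in_set.astype(float)
        nr = hit.sum()
    steps = hit / nr - (~in_set) / (N - Nh)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        pos = i_max
        core = [g for g, s in zip(genes[: pos + 1], in_set[: pos + 1]) if s]
    else:
        pos = i_min
        core = [g for g, s in zip(genes[pos:], in_set[pos:]) if s]
    return float(es), pos, core


def _null_es(
    ranked: pd.Series,
    set_size: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-set permutation null: ES of random same-size sets."""
    genes = list(ranked.index)
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm_set = rng.choice(genes, size=set_size, replace=False)
        out[i], _, _ = enrichment_score(ranked, set(perm_set), weight)
    return out


def _nes(es: float, null: np.ndarray) -> float:
    same = null[null >= 0] if es >= 0 else null[null < 0]
    denom = np.abs(same).mean() if same.size else np.nan
    return es / denom if denom and np.isfinite(denom) else np.nan


def gsea(
    m: pd.DataFrame,
    classes: ClassAssignment,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    metric: str = "s2n",
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Gene Set Enrichment Analysis with a gene-set permutation null.

    Genes are ranked by the class metric (signal-to-noise by default, A
    over B), each set's ES is computed from the weighted running sum, and
    significance comes from random same-size gene sets: the nominal p is
    the same-sign tail fraction, NES divides the ES by the mean |null ES|
    of its sign, and the FDR q follows the signed-pool procedure over all
    sets' normalized nulls. Sets significant at q < ``fdr_threshold``
    (10% by default) are flagged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    ranked = rank_genes_signal_to_noise(m, classes, metric=metric)
    universe = set(ranked.index)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in sets.items():
        members = [g for g in dict.fromkeys(genes) if g in universe]
        if not members:
            logger.info("gene set %r entirely outside the universe; skipped", name)
            continue
        if not (min_size <= len(members) <= max_size):
            logger.info("gene set %r outside size filter (%d genes); skipped", name, len(members))
            continue
        es, pos, core = enrichment_score(ranked, members, weight)
        size = len(members)
        if size not in null_cache:
            null_cache[size] = _null_es(ranked, size, weight, n_perm, rng)
        null = null_cache[size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        p = (np.sum(np.abs(same) >= abs(es)) + 1) / (same.size + 1) if same.size else 1.0
        nes = _nes(es, null)
        null_nes = np.array([_nes(e, null) for e in null])
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        rows.append({
            "set": name, "size": size, "ES": es, "NES": nes,
            "p": float(p), "core_enrichment": core,
        })
    if not rows:
        return pd.DataFrame(columns=["set", "size", "ES", "NES", "p", "q", "core_enrichment", "significant"])
    table = pd.DataFrame(rows)
    pool = np.concatenate(null_nes_pool)
    obs = table["NES"].to_numpy()

    qs = np.empty(len(table))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            qs[i] = 1.0
            continue
        if nes >= 0:
            pos_pool = pool[pool >= 0]
            num = np.mean(pos_pool >= nes) if pos_pool.size else 1.0
            den = np.mean(obs[obs >= 0] >= nes)
        else:
            neg_pool = pool[pool < 0]
            num = np.mean(neg_pool <= nes) if neg_pool.size else 1.0
            den = np.mean(obs[obs < 0] <= nes)
        qs[i] = min(1.0, num / den) if den > 0 else 1.0
    # enforce monotone non-increasing q in |NES| within each sign pool
    for sign in (1, -1):
        mask = (obs >= 0) if sign == 1 else (obs < 0)
        idx = np.where(mask)[0]
        order = idx[np.argsort(-np.abs(obs[idx]), kind="stable")]
        qs[order] = np.minimum.accumulate(qs[order][::-1])[::-1]
    table["q"] = qs
    table["significant"] = table["q"] < fdr_threshold
    return table.sort_values("NES", ascending=False, kind="stable").reset_index(drop=True)


def ssgsea_project(
    m: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.75,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample GSEA projection: sets x samples score matrix.

    Per sample, genes are ordered by decreasing expression (ties broken by
    stable input order) and assigned rank values N..1 from the top. The set
    score integrates the difference between the weighted ECDF of in-set
    genes (weight rank^alpha) and the uniform ECDF of out-of-set genes
    along the list. A constant sample carries no ordering information and
    scores 0 with a warning. With ``normalize`` the whole projection is
    divided by its score range.
    """
    if m.index.has_duplicates:
        raise ValueError("ssGSEA requires unique gene symbols")
    N = m.shape[0]
    genes = m.index
    scores = pd.DataFrame(index=list(sets), columns=m.columns, dtype=float)
    membership = {name: genes.isin(set(gs)) for name, gs in sets.items()}
    for name, mask in membership.items():
        if not mask.any():
            raise ValueError(f"gene set {name!r} disjoint from the matrix")
        if mask.all():
            raise ValueError(f"gene set {name!r} covers all genes")
    for sample in m.columns:
        x = m[sample].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("sample %r constant; ssGSEA scores set to 0", sample)
            scores[sample] = 0.0
            continue
        order = np.argsort(-x, kind="stable")
        rank_value = np.arange(N, 0, -1, dtype=float)  # N at the top of the list
        for name, mask in membership.items():
            in_set = mask[order]
            w = np.where(in_set, rank_value**alpha, 0.0)
            ecdf_in = np.cumsum(w) / w.sum()
            n_out = N - in_set.sum()
            ecdf_out = np.cumsum(~in_set) / n_out
            scores.loc[name, sample] = float(np.sum(ecdf_in - ecdf_out))
    if normalize:
        rng_ = scores.to_numpy().max() - scores.to_numpy().min()
        if rng_ > 0:
            scores = scores / rng_
    return scores


def overrepresentation_test(
    query: list[str],
    universe: list[str],
    sets: dict[str, list[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene signature in term sets.

    For each set, the one-sided upper-tail hypergeometric probability of
    drawing at least the observed overlap when sampling |query| genes from
    the universe; Benjamini-Hochberg q across all tested sets; significant
    at q < 5% by default.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    uni = set(universe)
    if not query_set <= uni:
        raise ValueError("query must be a subset of the universe")
    N = len(uni)
    n = len(query_set)
    rows = []
    for name, genes in sets.items():
        members = set(genes) & uni
        K = len(members)
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["q"] < fdr_threshold
    return table.sort_values("p", kind="stable").reset_index(drop=True)
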