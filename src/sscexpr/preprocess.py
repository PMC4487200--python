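"""Expression preprocessing: missingness filter, KNN imputation, median
centering, and probe-to-gene collapse.

The chain mirrors standard two-color microarray practice: probes with more
than ``max_missing_frac`` missing data are dropped, remaining gaps are
filled by row-wise k-nearest-neighbour imputation, each probe is
median-centered across arrays, and probes are collapsed to gene symbols by
taking the probe with the highest mean expression as the gene's
representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "filter_probes_by_missingness",
    "impute_missing_knn",
    "median_center_rows",
    "collapse_probes_to_genes",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    max_missing_frac : rows with a strictly greater missing fraction are
        removed (a row at exactly the threshold is retained).
    knn_k : neighbours used for imputation.
    collapse_rule : 'max' keeps the probe with the highest mean expression
        as the gene's single representative; 'mean'/'median' aggregate
        per-cell across a gene's probes.
    center : whether to median-center rows.
    center_before_collapse : center at the probe level (then collapse) or
        after collapsing to genes.
    """

    max_missing_frac: float = 0.2
    knn_k: int = 10
    collapse_rule: str = "max"
    center: bool = True
    center_before_collapse: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.collapse_rule not in ("max", "mean", "median"):
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")


def filter_probes_by_missingness(m: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Drop rows whose fraction of missing entries exceeds the threshold.

    The rule is strict: a row with missing fraction exactly equal to
    ``max_missing_frac`` is retained.
    """
    if m.shape[0] == 0:
        raise ValueError("no probes")
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.isna().mean(axis=1)
    return m.loc[frac <= max_missing_frac]


def impute_missing_knn(m: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells with the mean over the k nearest rows.

    Distance between two rows is the Euclidean distance computed over the
    columns observed in both. For a missing cell (row i, column j), only
    rows with an observed value in column j are eligible neighbours; the
    fill is the unweighted mean of their column-j values over the k nearest
    such rows (fewer if fewer exist). Observed cells are never touched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = m.index[~obs.any(axis=1)].tolist()
        raise ValueError(f"rows with no observed values: {bad}")
    if not obs.any(axis=0).all():
        bad = m.columns[~obs.any(axis=0)].tolist()
        raise ValueError(f"column unimputable: {bad}")
    if obs.all():
        return m.copy()

    out = X.copy()
    n = X.shape[0]
    rows_missing = np.where(~obs.all(axis=1))[0]
    for i in rows_missing:
        both = obs & obs[i]  # (n, p) columns observed in both i and each row
        diff = X - X[i]
        diff[~both] = 0.0
        n_shared = both.sum(axis=1)
        d2 = (diff**2).sum(axis=1)
        d2[i] = np.inf
        d2[n_shared == 0] = np.inf
        for j in np.where(~obs[i])[0]:
            cand = np.where(obs[:, j] & np.isfinite(d2))[0]
            if cand.size == 0:
                raise ValueError(f"column unimputable: {m.columns[j]!r}")
            nearest = cand[np.argsort(d2[cand], kind="stable")[:k]]
            out[i, j] = X[nearest, j].mean()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def median_center_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's median (over observed entries) from the row."""
    med = m.median(axis=1, skipna=True)
    return m.sub(med, axis=0)


def collapse_probes_to_genes(
    m: pd.DataFrame,
    annotation: dict[str, str],
    rule: str = "max",
) -> tuple[pd.DataFrame, dict]:
    """Collapse a probe-level matrix to one row per gene symbol.

    rule='max' picks, per gene, the single probe with the highest mean
    expression across samples as the representative row (not a per-cell
    max). 'mean' and 'median' aggregate per cell over the gene's probes.
    Probes without an annotation entry are dropped. Returns the collapsed
    matrix and a report of input/output row counts.
    """
    if rule not in ("max", "mean", "median"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    symbols = pd.Series({p: annotation.get(p) for p in m.index}, dtype=object)
    mapped = symbols.dropna()
    if mapped.empty:
        raise ValueError("annotation covers none of the probes")
    sub = m.loc[mapped.index]
    if rule == "max":
        means = sub.mean(axis=1, skipna=True)
        # stable: on equal means the earlier probe wins
        order = pd.DataFrame({"gene": mapped.values, "mean": means.values}, index=sub.index)
        rep = (
            order.reset_index(names="probe")
            .sort_values(["gene", "mean"], kind="stable", ascending=[True, False])
            .drop_duplicates("gene", keep="first")
        )
        collapsed = sub.loc[rep["probe"]]
        collapsed.index = rep["gene"].values
        collapsed = collapsed.sort_index()
    else:
        grouped = sub.groupby(mapped.values, sort=True)
        collapsed = grouped.mean() if rule == "mean" else grouped.median()
    collapsed.index.name = m.index.name
    report = {
        "n_probes_in": int(m.shape[0]),
        "n_probes_mapped": int(mapped.size),
        "n_genes_out": int(collapsed.shape[0]),
        "rule": rule,
    }
    return collapsed, report


def run_preprocess(
    m: pd.DataFrame,
    annotation: dict[str, str] | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full chain: filter -> impute -> (center) -> collapse -> (center).

    Returns the processed matrix and a JSON-serializable run report with
    row counts at each stage.
    """
    cfg = config or PreprocessConfig()
    report: dict = {"stages": [], "config": {
        "max_missing_frac": cfg.max_missing_frac,
        "knn_k": cfg.knn_k,
        "collapse_rule": cfg.collapse_rule,
        "center": cfg.center,
        "center_before_collapse": cfg.center_before_collapse,
    }}

    def log(stage: str, mat: pd.DataFrame) -> None:
        report["stages"].append({"stage": stage, "n_rows": int(mat.shape[0]), "n_cols": int(mat.shape[1])})

    log("input", m)
    m = filter_probes_by_missingness(m, cfg.max_missing_frac)
    log("filter_missingness", m)
    if m.isna().any().any():
        m = impute_missing_knn(m, cfg.knn_k)
    log("impute", m)
    if cfg.center and cfg.center_before_collapse:
        m = median_center_rows(m)
        log("median_center_probes", m)
    if annotation is not None:
        m, collapse_report = collapse_probes_to_genes(m, annotation, cfg.collapse_rule)
        report["collapse"] = collapse_report
        log("collapse", m)
    if cfg.center and not cfg.center_before_collapse:
        m = median_center_rows(m)
        log("median_center_genes", m)
    return m, report
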