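"""Two-class marker selection between phenotype classes.

Supports paired designs (baseline vs post-treatment in the same patients)
and unpaired designs (drug vs placebo) with Student t-tests.  At a trial of
this size uncorrected p-values are the primary readout; Benjamini-Hochberg
q-values are reported alongside for information, and a permutation p-value
is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ClassAssignment", "two_class_marker_selection", "compare_signature_groups"]

_TINY_P = float(np.nextafter(0, 1))


@dataclass
class ClassAssignment:
    """Sample -> class mapping with optional pairing.

    classes maps sample_id to 'A' or 'B'. pairing, when given, maps each
    class-A sample to its class-B partner (a bijection).
    """

    classes: dict[str, str]
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        bad = {v for v in self.classes.values()} - {"A", "B"}
        if bad:
            raise ValueError(f"classes must be 'A' or 'B', got {bad}")
        if self.pairing is not None:
            a = [s for s, c in self.classes.items() if c == "A"]
            b = [s for s, c in self.classes.items() if c == "B"]
            values = list(self.pairing.values())
            if (set(self.pairing) != set(a) or set(values) != set(b)
                    or len(set(values)) != len(values)):
                raise ValueError("pairing must be a bijection between class A and class B")

    @property
    def class_a(self) -> list[str]:
        return [s for s, c in self.classes.items() if c == "A"]

    @property
    def class_b(self) -> list[str]:
        return [s for s, c in self.classes.items() if c == "B"]


def _paired_t(diffs: np.ndarray) -> tuple[float, float, bool]:
    n = len(diffs)
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, True
        return float(np.sign(mean)) * np.inf, _TINY_P, True
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return float(np.sign(a.mean() - b.mean())) * np.inf, _TINY_P, True
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p), False


def two_class_marker_selection(
    m: pd.DataFrame,
    classes: ClassAssignment,
    paired: bool = False,
    alpha: float = 0.05,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene Student t between two phenotype classes.

    Paired designs test the per-pair differences (A minus B); unpaired
    designs use the pooled-variance two-sample t.  Genes with zero variance
    get p = 1 (no difference) or the smallest representable p (constant
    nonzero difference) and are flagged ``degenerate`` rather than dropped.
    If ``n_perm`` > 0 a label-permutation p-value column is added.

    Returns the full marker table sorted by p then decreasing |t|:
    columns gene, t, p, q (Benjamini-Hochberg), mean_diff (A minus B),
    direction, significant, degenerate.
    """
    a_samples = classes.class_a
    b_samples = classes.class_b
    if paired:
        if classes.pairing is None:
            raise ValueError("paired design requires a pairing")
        if len(classes.pairing) < 2:
            raise ValueError("need at least 2 pairs")
        a_samples = list(classes.pairing.keys())
        b_samples = [classes.pairing[s] for s in a_samples]
    else:
        if len(a_samples) < 2 or len(b_samples) < 2:
            raise ValueError("need at least 2 samples per class")

    A = m[a_samples].to_numpy(dtype=float)
    B = m[b_samples].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(m.index):
        if paired:
            t, p, degenerate = _paired_t(A[i] - B[i])
        else:
            t, p, degenerate = _pooled_t(A[i], B[i])
        mean_diff = float(A[i].mean() - B[i].mean())
        rows.append({
            "gene": gene,
            "t": t,
            "p": p,
            "mean_diff": mean_diff,
            "direction": "up_in_A" if mean_diff >= 0 else "up_in_B",
            "degenerate": degenerate,
        })
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p"] < alpha

    if n_perm > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        obs_abs_t = np.abs(table["t"].to_numpy())
        exceed = np.zeros(len(table))
        X = np.hstack([A, B])
        nA = A.shape[1]
        for _ in range(n_perm):
            perm = rng.permutation(X.shape[1])
            Ap, Bp = X[:, perm[:nA]], X[:, perm[nA:]]
            for i in range(X.shape[0]):
                if paired:
                    t, _, _ = _paired_t(Ap[i] - Bp[i])
                else:
                    t, _, _ = _pooled_t(Ap[i], Bp[i])
                if abs(t) >= obs_abs_t[i]:
                    exceed[i] += 1
        table["p_perm"] = (exceed + 1) / (n_perm + 1)

    table = table.sort_values(
        ["p", "t"], key=lambda s: s if s.name == "p" else -s.abs(), kind="stable"
    ).reset_index(drop=True)
    return table


def compare_signature_groups(
    scores_a: pd.Series | np.ndarray,
    scores_b: pd.Series | np.ndarray,
    paired: bool = False,
) -> dict:
    """Single t-test on per-sample signature scores (centroid vectors).

    For a paired design the two score vectors must be aligned per patient
    (baseline vs post-treatment). Returns t, p, group means and the design.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired design requires aligned score vectors")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        t, p, degenerate = _paired_t(a - b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 samples per group")
        t, p, degenerate = _pooled_t(a, b)
    return {
        "t": t,
        "p": p,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "design": "paired" if paired else "unpaired",
        "degenerate": degenerate,
    }
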