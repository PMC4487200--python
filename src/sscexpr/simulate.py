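"""Synthetic cohorts with known ground truth.

Two generators cover the study design end to end:

* :func:`generate_reference_cohort` — a labeled reference cohort with
  inflammatory / fibroproliferative / normal-like subset structure, the
  role a previously published intrinsic-subset cohort plays for
  nearest-centroid classification.
* :func:`generate_trial_cohort` — a paired baseline/post-treatment trial:
  per-patient skin expression drawn from the patient's subset model, an
  mRSS trajectory over the eight-visit schedule from a linear
  random-intercept model with arm and disease-duration effects, responder
  flags derived from the generated trajectories, and a post-treatment loss
  of the signature in treated responders.

Expression values emulate log2 ratios on a two-color array: background
genes are Gaussian around zero and each subset's signature block is
shifted upward by a fixed log2 effect in that subset's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import VISIT_DAYS

__all__ = ["SimulationConfig", "generate_reference_cohort", "generate_trial_cohort", "inject_missing"]

SUBSETS = ["inflammatory", "fibroproliferative", "normal-like"]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic study.

    Expression: ``n_genes`` total genes of which each subset owns
    ``n_signature_genes``; subset samples have their signature block
    shifted by ``effect`` log2 units over Gaussian noise with sd
    ``noise_sd``.  Trial: treated responders lose ``decay`` log2 units of
    their signature post-treatment, non-responders and placebo drift by
    ``nonimprover_drift`` (mild increase mirrors the observed placebo
    behaviour).  mRSS follows
    ``intercept + slope*duration + effect*drug + trend*visit +
    interaction*visit*drug + patient intercept + noise`` rounded and
    clipped to the 0-51 scale; defaults take the trial's printed estimates
    (drug effect -9.8, duration slope -0.9) as the generating truth.
    """

    seed: int = 0
    # expression
    n_genes: int = 2000
    n_signature_genes: int = 100
    effect: float = 2.0
    noise_sd: float = 0.5
    heavy_tail: bool = False
    missing_rate: float = 0.0
    # reference cohort
    n_reference_per_subset: int = 10
    # trial cohort
    n_abatacept: int = 7
    n_placebo: int = 3
    n_healthy: int = 4
    subset_probs: tuple[float, float, float] = (0.5, 0.15, 0.35)  # matches SUBSETS order
    decay: float = 1.5
    nonimprover_drift: float = 0.2
    force_improver_fraction: dict | None = None
    # mRSS model
    mrss_intercept: float = 30.0
    mrss_duration_slope: float = -0.9
    mrss_drug_effect: float = -9.8
    mrss_visit_trend: float = -0.1
    mrss_drug_visit_trend: float = -0.9
    mrss_intercept_sd: float = 6.0
    mrss_residual_sd: float = 3.0
    # disease duration (years from first non-Raynaud symptom), per arm
    duration_mean_abatacept: float = 2.4
    duration_sd_abatacept: float = 1.6
    duration_mean_placebo: float = 8.8
    duration_sd_placebo: float = 3.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if 3 * self.n_signature_genes > self.n_genes:
            raise ValueError("signature genes exceed total genes")
        for name in ("noise_sd", "mrss_intercept_sd", "mrss_residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if abs(sum(self.subset_probs) - 1.0) > 1e-9:
            raise ValueError("subset_probs must sum to 1")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def signature_sets(self) -> dict[str, list[str]]:
        """The true signature gene sets, GMT-ready."""
        ids = self.gene_ids
        k = self.n_signature_genes
        return {
            f"{name}_signature": ids[i * k:(i + 1) * k] for i, name in enumerate(SUBSETS)
        }


def _noise(rng: np.random.Generator, size, cfg: SimulationConfig) -> np.ndarray:
    if cfg.heavy_tail:
        return cfg.noise_sd * rng.standard_t(df=5, size=size)
    return rng.normal(0.0, cfg.noise_sd, size=size)


def _expression_for(
    rng: np.random.Generator, cfg: SimulationConfig, subset: str | None, sig_shift: dict[str, float] | None = None
) -> np.ndarray:
    """One sample's expression vector: background noise plus the subset's
    signature shift (optionally overridden per subset via ``sig_shift``)."""
    x = _noise(rng, cfg.n_genes, cfg)
    k = cfg.n_signature_genes
    shifts = dict.fromkeys(SUBSETS, 0.0)
    if subset is not None:
        shifts[subset] = cfg.effect
    if sig_shift:
        shifts.update(sig_shift)
    for i, name in enumerate(SUBSETS):
        if shifts[name]:
            x[i * k:(i + 1) * k] += shifts[name]
    return x


def inject_missing(m: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Set entries missing completely at random at the given rate, keeping
    at least one observed value per row and per column."""
    if rate == 0:
        return m.copy()
    X = m.to_numpy(dtype=float).copy()
    mask = rng.random(X.shape) < rate
    # keep every row and column imputable
    for i in range(X.shape[0]):
        if mask[i].all():
            mask[i, rng.integers(X.shape[1])] = False
    for j in range(X.shape[1]):
        if mask[:, j].all():
            mask[rng.integers(X.shape[0]), j] = False
    X[mask] = np.nan
    return pd.DataFrame(X, index=m.index, columns=m.columns)


def generate_reference_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Labeled reference cohort for centroid building.

    Returns (expression genes x samples, sample -> subset labels, ground
    truth). Reproducible: the same config yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    samples, labels = [], {}
    columns = {}
    for subset in SUBSETS:
        for j in range(cfg.n_reference_per_subset):
            sid = f"REF_{subset[:4]}_{j:02d}"
            columns[sid] = _expression_for(rng, cfg, subset)
            labels[sid] = subset
            samples.append(sid)
    m = pd.DataFrame(columns, index=cfg.gene_ids)
    if cfg.missing_rate:
        m = inject_missing(m, cfg.missing_rate, rng)
    truth = {
        "labels": dict(labels),
        "signature_sets": cfg.signature_sets(),
        "params": {"effect": cfg.effect, "noise_sd": cfg.noise_sd},
    }
    return m, labels, truth


def generate_trial_cohort(cfg: SimulationConfig) -> dict:
    """Paired baseline/post trial expression plus clinical trajectories.

    Order of generation: arms and disease durations, patient subsets, mRSS
    trajectories from the linear random-intercept model, responder flags
    derived from the trajectories (unless ``force_improver_fraction``
    overrides the flags per arm), then expression — baseline from the
    patient's subset model and post-treatment with the signature decayed
    toward zero for treated responders (others drift mildly upward).

    Returns a dict with ``expression`` (genes x samples; ``<pid>_base`` /
    ``<pid>_post`` columns plus healthy controls), ``clinical`` (long
    format), and ``truth``.
    """
    if cfg.n_abatacept < 1 or cfg.n_placebo < 1:
        raise ValueError("need at least one patient per arm")
    rng = np.random.default_rng(cfg.seed)
    patients = []
    for i in range(cfg.n_abatacept):
        patients.append((f"A{i + 1:02d}", "abatacept"))
    for i in range(cfg.n_placebo):
        patients.append((f"P{i + 1:02d}", "placebo"))

    durations, subsets = {}, {}
    for pid, arm in patients:
        if arm == "abatacept":
            mu, sd = cfg.duration_mean_abatacept, cfg.duration_sd_abatacept
        else:
            mu, sd = cfg.duration_mean_placebo, cfg.duration_sd_placebo
        durations[pid] = max(0.3, rng.normal(mu, sd))
        subsets[pid] = SUBSETS[rng.choice(len(SUBSETS), p=cfg.subset_probs)]

    # mRSS trajectories over the visit schedule
    rows = []
    for pid, arm in patients:
        drug = 1.0 if arm == "abatacept" else 0.0
        b_i = rng.normal(0.0, cfg.mrss_intercept_sd)
        for v, day in enumerate(VISIT_DAYS):
            mu = (cfg.mrss_intercept
                  + cfg.mrss_duration_slope * durations[pid]
                  + cfg.mrss_drug_effect * drug
                  + cfg.mrss_visit_trend * v
                  + cfg.mrss_drug_visit_trend * v * drug
                  + b_i)
            val = mu + rng.normal(0.0, cfg.mrss_residual_sd)
            rows.append({
                "patient_id": pid, "arm": arm, "visit_day": day,
                "mrss": int(np.clip(round(val), 0, 51)),
                "disease_duration": durations[pid],
            })
    clinical = pd.DataFrame(rows)

    # responder flags derived from the generated trajectories
    improver: dict[str, bool] = {}
    rel_change: dict[str, float] = {}
    for pid, arm in patients:
        traj = clinical[clinical["patient_id"] == pid].sort_values("visit_day")["mrss"]
        base, final = float(traj.iloc[0]), float(traj.iloc[-1])
        base = max(base, 1.0)
        rel_change[pid] = (base - final) / base
        improver[pid] = rel_change[pid] >= 0.30
    if cfg.force_improver_fraction is not None:
        for arm, frac in cfg.force_improver_fraction.items():
            arm_pids = [pid for pid, a in patients if a == arm]
            k = int(round(frac * len(arm_pids)))
            ranked = sorted(arm_pids, key=lambda p: -rel_change[p])
            for pid in arm_pids:
                improver[pid] = pid in ranked[:k]

    # paired expression
    columns = {}
    for pid, arm in patients:
        subset = subsets[pid]
        columns[f"{pid}_base"] = _expression_for(rng, cfg, subset)
        if arm == "abatacept" and improver[pid]:
            post_shift = {subset: max(cfg.effect - cfg.decay, 0.0)}
        else:
            post_shift = {subset: cfg.effect + cfg.nonimprover_drift}
        columns[f"{pid}_post"] = _expression_for(rng, cfg, None, sig_shift=post_shift)
    for h in range(cfg.n_healthy):
        columns[f"HC{h + 1:02d}"] = _expression_for(rng, cfg, None)
    expression = pd.DataFrame(columns, index=cfg.gene_ids)
    if cfg.missing_rate:
        expression = inject_missing(expression, cfg.missing_rate, rng)

    clinical["baseline_sample"] = clinical["patient_id"] + "_base"
    clinical["post_sample"] = clinical["patient_id"] + "_post"

    truth = {
        "subsets": subsets,
        "improver": improver,
        "relative_change": rel_change,
        "signature_sets": cfg.signature_sets(),
        "params": {
            "effect": cfg.effect, "noise_sd": cfg.noise_sd, "decay": cfg.decay,
            "mrss_drug_effect": cfg.mrss_drug_effect,
            "mrss_duration_slope": cfg.mrss_duration_slope,
            "mrss_visit_trend": cfg.mrss_visit_trend,
            "mrss_drug_visit_trend": cfg.mrss_drug_visit_trend,
        },
    }
    return {"expression": expression, "clinical": clinical, "truth": truth}
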