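"""Weighted-effect-size synthesis across studies (fixed-form meta-analysis).

Each study contributes one effect M_j (a flux as % of added C, or a scenario
response) with weight W*_j = n_j / s_j^2, i.e. an inverse squared standard
error built from the study's replicate count and its posterior SD.  The
pooled estimate is M = sum(W* M) / sum(W*) with variance V = 1 / sum(W*) and
CI = M +/- 1.96 sqrt(V).  Significance is judged purely on 95% CIs: an
effect is significant when its CI excludes zero, and two groups differ
significantly when their CIs do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EffectSize", "SynthesisResult", "weighted_mean_ci",
           "group_synthesis"]

Z95 = 1.96


@dataclass(frozen=True)
class EffectSize:
    """One study's contribution to the synthesis."""

    study_id: str
    metric: str
    mean: float
    weight: float              # W*_j > 0
    n: int = 1                 # replicate count
    nc_category: str = "none"

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")

    @classmethod
    def from_posterior(cls, study_id: str, metric: str, mean: float,
                       sd: float, n: int = 1,
                       nc_category: str = "none") -> "EffectSize":
        """Weight from the study's posterior SD and replicate count:
        W* = n / s^2 (an inverse squared standard error)."""
        if sd <= 0:
            raise ValueError("posterior SD must be positive to weight")
        return cls(study_id=study_id, metric=metric, mean=mean,
                   weight=n / sd ** 2, n=n, nc_category=nc_category)


@dataclass(frozen=True)
class SynthesisResult:
    """Pooled weighted mean with its 95% CI."""

    mean: float
    variance: float
    ci_low: float
    ci_high: float
    k: int                     # number of studies
    significant: bool          # CI excludes zero

    def to_dict(self) -> dict:
        return {"mean": self.mean, "variance": self.variance,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "k": self.k, "significant": self.significant}


def weighted_mean_ci(effects: list[EffectSize]) -> SynthesisResult:
    """Fixed-form weighted mean, variance 1/sum(W*), and 95% CI."""
    if not effects:
        raise ValueError("no effects to synthesize")
    w = np.array([e.weight for e in effects])
    m = np.array([e.mean for e in effects])
    mw = float(np.sum(w * m) / np.sum(w))
    vw = float(1.0 / np.sum(w))
    half = Z95 * np.sqrt(vw)
    lo, hi = mw - half, mw + half
    return SynthesisResult(mean=mw, variance=vw, ci_low=lo, ci_high=hi,
                           k=len(effects), significant=not (lo <= 0.0 <= hi))


def group_synthesis(effects: list[EffectSize], grouping: str = "nc_category"):
    """Per-group weighted means plus pairwise CI-overlap significance.

    Returns (per-group dict of SynthesisResult, {(a, b): bool} for group
    pairs flagged significantly different when their 95% CIs do not overlap).
    """
    known = ("none", "low", "high")
    groups: dict[str, list[EffectSize]] = {}
    for e in effects:
        g = getattr(e, grouping)
        if grouping == "nc_category" and g not in known:
            raise ValueError(f"unknown N:C category {g!r}")
        groups.setdefault(g, []).append(e)
    per_group = {g: weighted_mean_ci(es) for g, es in groups.items()}
    names = sorted(per_group)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ra, rb = per_group[a], per_group[b]
            disjoint = ra.ci_high < rb.ci_low or rb.ci_high < ra.ci_low
            pairwise[(a, b)] = disjoint
    return per_group, pairwise


def synthesis_frame(results: dict[str, SynthesisResult]) -> pd.DataFrame:
    """Tabulate {label: SynthesisResult} as a tidy frame."""
    rows = [{"group": k, **r.to_dict()} for k, r in results.items()]
    return pd.DataFrame(rows)
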