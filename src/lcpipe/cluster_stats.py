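"""Statistics for clustered measurements (ROIs nested in animals).

Calcium-imaging screens measure many ROIs per slice from few animals, so
per-ROI values are not independent.  This module provides:

* :func:`icc_oneway` — the one-way random-effects ANOVA intraclass
  correlation, ICC = (MSB − MSW) / (MSB + (m̄ − 1)·MSW), with the standard
  unbalanced-design adjustment m̄ = (N − Σmᵢ²/N)/(k − 1);
* :func:`effective_sample_size` — the design-effect correction
  n_eff = N / (1 + (m̄ − 1)·ICC), the theoretical sample size if there were
  no clustering;
* :func:`fit_group_comparison` — a thin delegation layer over a
  random-intercept linear mixed model (statsmodels MixedLM) for group
  comparisons, recording the exact fixed/random specification used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import t as _t
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusteredSample",
    "IccResult",
    "GroupComparisonResult",
    "icc_oneway",
    "effective_sample_size",
    "n_eff_from_sample",
    "fit_group_comparison",
]


@dataclass
class ClusteredSample:
    """Measurements with a cluster (animal) label and optional group label."""

    values: np.ndarray
    cluster: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.cluster = np.asarray(self.cluster).ravel()
        if self.values.shape != self.cluster.shape:
            raise ValueError("values and cluster labels must align")
        if self.group is not None:
            self.group = np.asarray(self.group).ravel()
            if self.group.shape != self.values.shape:
                raise ValueError("group labels must align with values")


@dataclass
class IccResult:
    icc: float
    ms_between: float
    ms_within: float
    k_clusters: int
    n_total: int
    m_bar: float  # unbalanced-adjusted mean cluster size


def icc_oneway(s: ClusteredSample) -> IccResult:
    """One-way random-effects intraclass correlation.

    The estimate can be negative (down to −1/(m̄−1)) when clusters are more
    homogeneous between than within; it is reported as-is.
    """
    values, cluster = s.values, s.cluster
    labels, inverse = np.unique(cluster, return_inverse=True)
    k = labels.shape[0]
    n = values.shape[0]
    if k < 2:
        raise ValueError("ICC requires at least 2 clusters")
    if n - k < 1:
        raise ValueError("no residual degrees of freedom (need n > k)")
    sizes = np.bincount(inverse)
    sums = np.bincount(inverse, weights=values)
    means = sums / sizes
    grand = values.mean()
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(np.sum((values - means[inverse]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    m_bar = (n - np.sum(sizes**2) / n) / (k - 1)
    denom = msb + (m_bar - 1) * msw
    icc = 1.0 if denom == 0 else (msb - msw) / denom
    return IccResult(
        icc=float(icc),
        ms_between=msb,
        ms_within=msw,
        k_clusters=int(k),
        n_total=int(n),
        m_bar=float(m_bar),
    )


def effective_sample_size(n_total: int, m_bar: float, icc: float) -> float:
    """Design-effect effective sample size n_eff = N / (1 + (m̄ − 1)·ICC).

    A negative ICC estimate is clipped to 0 (the design effect is undefined
    for negative clustering), and ICC > 1 to 1, so n_eff ∈ [k, N].
    """
    if m_bar < 1:
        raise ValueError(f"mean cluster size {m_bar} < 1")
    icc = float(np.clip(icc, 0.0, 1.0))
    return n_total / (1.0 + (m_bar - 1.0) * icc)


def n_eff_from_sample(s: ClusteredSample) -> tuple[IccResult, float]:
    """Estimate the ICC and the implied effective sample size in one call."""
    res = icc_oneway(s)
    return res, effective_sample_size(res.n_total, res.m_bar, res.icc)


@dataclass
class GroupComparisonResult:
    """Random-intercept mixed-model comparison report."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    wald_f: float
    wald_p: float
    pairwise: pd.DataFrame  # estimate, p_raw, p_adj per group pair
    spec: dict = field(default_factory=dict)
    converged: bool = True
    singular: bool = False


def fit_group_comparison(
    s: ClusteredSample,
    *,
    adjust: str = "holm",
) -> GroupComparisonResult:
    """Compare group means with a random intercept per cluster.

    Delegates fitting to ``statsmodels`` MixedLM (`value ~ C(group)` with a
    per-cluster random intercept); this module only owns the specification
    and bookkeeping.  Pairwise group contrasts are Wald tests on the fitted
    fixed effects with p-values adjusted by ``adjust`` (any method accepted
    by statsmodels ``multipletests``).  A singular or non-converged fit is
    reported through the result flags, never masked.
    """
    if s.group is None:
        raise ValueError("fit_group_comparison requires group labels")
    data = pd.DataFrame(
        {"value": s.values, "cluster": s.cluster, "group": s.group}
    )
    groups = sorted(pd.unique(data["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    singular = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm("value ~ C(group)", data, groups=data["cluster"])
        fit = model.fit(reml=True)
        for w in caught:
            msg = str(w.message).lower()
            if "singular" in msg or "boundary" in msg:
                singular = True
            if "converge" in msg and "fail" in msg:
                converged = False
    converged = converged and bool(getattr(fit, "converged", True))

    fe_names = [p for p in fit.fe_params.index if p != "Intercept"]
    # Wald F over all group terms (joint null: all group effects zero).
    contrast = np.zeros((len(fe_names), len(fit.params)))
    for i, name in enumerate(fe_names):
        contrast[i, list(fit.params.index).index(name)] = 1.0
    wald = fit.wald_test(contrast, scalar=True, use_f=True)
    wald_f = float(np.squeeze(wald.statistic))
    wald_p = float(np.squeeze(wald.pvalue))

    # Pairwise contrasts between group levels on the fixed-effect scale.
    fe_index = list(fit.fe_params.index)

    def _coef(level):
        vec = np.zeros(len(fe_index))
        if level != groups[0]:
            vec[fe_index.index(f"C(group)[T.{level}]")] = 1.0
        return vec

    # Between-cluster degrees of freedom for group contrasts: the group
    # effect is estimated against cluster-to-cluster variation, so normal
    # (z) intervals undercover with few animals.  Use t with k - g df, as
    # mixed-model software with small-sample corrections does.
    k = int(data["cluster"].nunique())
    ddf = max(k - len(groups), 1)
    tcrit = _t.ppf(0.975, ddf)

    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        vec = (_coef(gb) - _coef(ga)).reshape(1, -1)
        tt = fit.t_test(vec)
        stat = float(np.squeeze(tt.effect)) / float(np.squeeze(tt.sd))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "estimate": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "p_raw": float(2.0 * _t.sf(abs(stat), ddf)),
            }
        )
    pairwise = pd.DataFrame(rows)
    if len(pairwise) > 1:
        pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=adjust)[1]
    else:
        pairwise["p_adj"] = pairwise["p_raw"]

    return GroupComparisonResult(
        params=fit.fe_params,
        bse=fit.bse_fe,
        conf_int=pd.DataFrame(
            {
                0: fit.fe_params - tcrit * fit.bse_fe,
                1: fit.fe_params + tcrit * fit.bse_fe,
            },
            index=fit.fe_params.index,
        ),
        wald_f=wald_f,
        wald_p=wald_p,
        pairwise=pairwise,
        spec={
            "fixed": "group",
            "random": "random intercept per cluster",
            "formula": "value ~ C(group)",
            "adjust": adjust,
            "contrast_df": ddf,
            "n": int(len(data)),
            "k_clusters": int(data["cluster"].nunique()),
        },
        converged=converged,
        singular=singular,
    )
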