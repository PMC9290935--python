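"""Empirical checks for cross-lag signatures in a panel.

A cross-lag makes the predictor at time t depend on the response at time
t-1, so a first exploratory step on real data is the within-subject
correlation between ``X[t]`` and ``Y[t-1]``.  A significant correlation is
a *necessary but not sufficient* condition for a causal cross-lag
(measurement error or confounding can in principle produce one too), which
is how the result is labelled in the returned record.

The second diagnostic profiles ``Var(X[t])`` over time from a degenerate
start: cross-lagged dynamics make the variance of X grow with series
length and level off at its stationary value, which is also why static
regression bias fades in long series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .procsim import Panel, ProcessSpec, simulate

__all__ = ["CrossLagCorrelation", "crosslag_correlation", "variance_growth"]


@dataclass
class CrossLagCorrelation:
    """Within-subject correlation of X[t] with Y[t-1]."""

    r: float
    n_pairs: int
    ci: Tuple[float, float]
    p_value: float
    note: str = ("a significant cross-lag correlation is a necessary, "
                 "not a sufficient, condition for a causal cross-lag")

    def to_dict(self) -> dict:
        return {"r": self.r, "n_pairs": self.n_pairs, "ci_lower": self.ci[0],
                "ci_upper": self.ci[1], "p_value": self.p_value,
                "note": self.note}


def crosslag_correlation(panel: Panel, x: str = "X", y: str = "Y"
                         ) -> CrossLagCorrelation:
    """Correlate X[t] with Y[t-1] on within-subject-centred values.

    Pairs are formed strictly within subjects at consecutive time steps;
    both members of each pair are centred on their subject's mean over the
    contributing pairs, so the statistic is invariant to per-subject
    additive shifts of either variable.  The confidence interval uses the
    Fisher z transform with the number of pairs as effective sample size.
    """
    for col in (x, y):
        if col not in panel.data.columns:
            raise KeyError(f"unknown variable {col!r}")
    d = panel.data.sort_values(["subject", "time"])
    g = d.groupby("subject")
    ylag = g[y].shift(1)
    contiguous = (g["time"].diff() == 1).fillna(False)
    ok = contiguous & ylag.notna()
    pairs = pd.DataFrame({
        "subject": d["subject"][ok],
        "xt": d[x][ok].astype(float),
        "ylag": ylag[ok].astype(float),
    })
    n = len(pairs)
    if n < 3:
        raise ValueError(f"insufficient data: only {n} usable within-subject "
                         "pairs (need >= 3)")
    gp = pairs.groupby("subject")
    xt = pairs["xt"] - gp["xt"].transform("mean")
    yl = pairs["ylag"] - gp["ylag"].transform("mean")
    r, p = stats.pearsonr(xt, yl)
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (np.nan, np.nan)
    return CrossLagCorrelation(r=float(r), n_pairs=n, ci=ci, p_value=float(p))


def variance_growth(spec: ProcessSpec, n_reps: int, seed: int | None = None
                    ) -> pd.DataFrame:
    """Across-replicate variance of X at each time step from a cold start.

    ``burn_in`` is forced to zero so every replicate starts at the
    deterministic stationary mean; the returned profile shows how Var(X[t])
    rises from (near) zero and plateaus at the stationary variance.
    """
    spec = spec.replace(burn_in=0, seed=spec.seed if seed is None else seed)
    xs = []
    for r in range(n_reps):
        panel = simulate(spec.replace(seed=spec.seed + r))
        xs.append(panel.data["X"].to_numpy(float)
                  .reshape(spec.n_subjects, spec.n_time))
    X = np.concatenate(xs, axis=0)          # (n_reps * S, T)
    var_t = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(spec.n_time)
    return pd.DataFrame({"time": np.arange(1, spec.n_time + 1),
                         "var_x": var_t,
                         "n_series": X.shape[0]})
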