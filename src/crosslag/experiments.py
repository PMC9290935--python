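"""Monte-Carlo bias and power engine.

Replicates the grid / sweep design used to characterize estimator bias:
for every design cell, ``n_reps`` panels are simulated and *every*
requested model is fitted to the identical panel (a paired-replicate
design, so model contrasts are not diluted by simulation noise).  Cell
summaries report the mean estimate, relative bias (absolute bias where the
true effect is zero), the Monte-Carlo standard error, the rejection rate
of the Wald test of b = 0 at ``alpha`` (power, or type-I error when the
true effect is zero) and the convergence rate.  Non-converged fits are
excluded from the summaries, with counts reported.

Replicate ``r`` of a cell simulates with ``seed + r``, so reruns with the
same seed reproduce every summary bit-for-bit and replicates remain
independent scheduling units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .procsim import MeasurementErrorSpec, Panel, ProcessSpec, simulate, add_measurement_error

__all__ = ["ExperimentResult", "run_cells", "run_grid", "run_sweep",
           "power_analysis", "MODELS"]

_ME_SEED_OFFSET = 1_000_003  # decorrelates error draws from process draws


def _fit_model(name: str, panel: Panel, structure: str,
               error_variances=None) -> est.FitResult:
    if name == "STAT_OVERALL":
        return est.fit_stat_overall(panel)
    if name == "STAT_WITHIN":
        return est.fit_stat_within(panel)
    if name == "DYN_LDVM":
        return est.fit_dyn_ldvm(panel)
    if name == "DYN_SEM":
        return est.fit_dyn_sem(panel, structure)
    if name == "DYN_SEM_PLUS":
        return est.fit_dyn_sem_plus(panel, structure, error_variances,
                                    compute_se=False)
    raise ValueError(f"unknown model {name!r}")

MODELS = ("STAT_OVERALL", "STAT_WITHIN", "DYN_LDVM", "DYN_SEM", "DYN_SEM_PLUS")


@dataclass
class ExperimentResult:
    """Replicate-level estimates plus per-cell summaries."""

    estimates: pd.DataFrame   # one row per (cell, model, replicate)
    summary: pd.DataFrame     # one row per (cell, model)
    b_true: float

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def _summarize(raw: pd.DataFrame, cell_cols: Sequence[str], b_true: float,
               alpha: float) -> pd.DataFrame:
    rows = []
    for key, grp in raw.groupby(list(cell_cols) + ["model"], sort=False):
        ok = grp[grp["converged"] & np.isfinite(grp["b_hat"])]
        n_used = len(ok)
        mean_b = ok["b_hat"].mean() if n_used else np.nan
        sd_b = ok["b_hat"].std(ddof=1) if n_used > 1 else np.nan
        rec = dict(zip(list(cell_cols) + ["model"], key))
        rec.update(
            n_reps=len(grp),
            n_used=n_used,
            n_excluded=len(grp) - n_used,
            mean_b_hat=mean_b,
            abs_bias=mean_b - b_true,
            rel_bias_pct=(100.0 * (mean_b - b_true) / b_true
                          if b_true != 0 else np.nan),
            rel_bias_defined=b_true != 0,
            mc_se=sd_b / np.sqrt(n_used) if n_used > 1 else np.nan,
            power=(ok["p_value_b"] < alpha).mean() if n_used else np.nan,
            convergence_rate=n_used / len(grp) if len(grp) else np.nan,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def run_cells(cells: Sequence[dict], models: Sequence[str], n_reps: int,
              alpha: float = 0.05,
              measurement_error: Optional[MeasurementErrorSpec] = None,
              cell_cols: Sequence[str] = ("S", "T")) -> ExperimentResult:
    """Run the paired Monte-Carlo over explicit design cells.

    Each cell dict must contain a ``spec`` (ProcessSpec) plus the labelling
    keys in ``cell_cols``.  With ``measurement_error``, panels are
    contaminated and all models except DYN_SEM_PLUS are fitted to the
    observed values; DYN_SEM_PLUS receives the realized error variances as
    known quantities.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    records = []
    b_true = cells[0]["spec"].b
    for cell in cells:
        spec: ProcessSpec = cell["spec"]
        for m in models:
            if m == "DYN_SEM_PLUS" and measurement_error is None:
                raise ValueError("DYN_SEM_PLUS requires a measurement_error spec")
        for r in range(n_reps):
            panel = simulate(spec.replace(seed=spec.seed + r))
            if measurement_error is not None:
                panel = add_measurement_error(
                    panel, MeasurementErrorSpec(
                        frac_x=measurement_error.frac_x,
                        frac_y=measurement_error.frac_y,
                        seed=measurement_error.seed + _ME_SEED_OFFSET + r))
                fit_panel = panel.using_observed()
            else:
                fit_panel = panel
            for m in models:
                rec = {k: cell[k] for k in cell_cols}
                rec.update(model=m, rep=r)
                try:
                    if m == "DYN_SEM_PLUS":
                        ev = (panel.error_variances["X"],
                              panel.error_variances["Y"])
                        fr = _fit_model(m, panel, spec.structure, ev)
                    else:
                        fr = _fit_model(m, fit_panel, spec.structure)
                    rec.update(b_hat=fr.b_hat, se_b=fr.se_b,
                               p_value_b=fr.p_value_b, converged=fr.converged)
                except Exception as exc:  # recorded, not fatal
                    rec.update(b_hat=np.nan, se_b=np.nan, p_value_b=np.nan,
                               converged=False, error=str(exc))
                records.append(rec)
    raw = pd.DataFrame(records)
    summary = _summarize(raw, cell_cols, b_true, alpha)
    return ExperimentResult(estimates=raw, summary=summary, b_true=b_true)


def run_grid(base: ProcessSpec, subjects: Sequence[int], lengths: Sequence[int],
             models: Sequence[str], n_reps: int, seed: Optional[int] = None,
             alpha: float = 0.05,
             measurement_error: Optional[MeasurementErrorSpec] = None
             ) -> ExperimentResult:
    """Bias/power surface over a (number of subjects) x (series length) grid."""
    seed = base.seed if seed is None else seed
    cells = []
    for S in subjects:
        for T in lengths:
            spec = base.replace(n_subjects=int(S), n_time=int(T), seed=seed)
            cells.append({"spec": spec, "S": int(S), "T": int(T)})
    return run_cells(cells, models, n_reps, alpha, measurement_error)


def _apply_sweep(base: ProcessSpec, parameter: str, value: float) -> ProcessSpec:
    if parameter == "d":
        return base.replace(d=float(value))
    if parameter == "b":
        return base.replace(b=float(value))
    if parameter == "omega_cov":
        om = np.array(base.omega, float).copy()
        bound = np.sqrt(om[0, 0] * om[1, 1])
        if abs(value) > bound:
            raise ValueError("omega_cov exceeds the PSD bound given the variances")
        om[0, 1] = om[1, 0] = float(value)
        return base.replace(omega=om)
    raise ValueError("parameter must be one of 'd', 'omega_cov', 'b'")


def run_sweep(base: ProcessSpec, parameter: str, values: Sequence[float],
              S: int, T: int, models: Sequence[str], n_reps: int,
              seed: Optional[int] = None, alpha: float = 0.05,
              measurement_error: Optional[MeasurementErrorSpec] = None
              ) -> ExperimentResult:
    """One-dimensional sensitivity sweep (cross-lag d, among-subject
    covariance, or effect size b) at fixed S and T."""
    seed = base.seed if seed is None else seed
    cells = []
    for v in values:
        spec = _apply_sweep(base, parameter, v).replace(
            n_subjects=int(S), n_time=int(T), seed=seed)
        cells.append({"spec": spec, "S": int(S), "T": int(T), parameter: float(v)})
    res = run_cells(cells, models, n_reps, alpha, measurement_error,
                    cell_cols=("S", "T", parameter))
    if parameter == "b":
        # per-cell truth varies; recompute bias columns per swept value
        raw = res.estimates
        parts = []
        for v in values:
            sub = raw[raw[parameter] == float(v)]
            parts.append(_summarize(sub, ("S", "T", parameter), float(v), alpha))
        res.summary = pd.concat(parts, ignore_index=True)
    return res


def power_analysis(base: ProcessSpec, designs: Sequence[tuple], model: str,
                   alpha: float = 0.05, n_reps: int = 200,
                   seed: Optional[int] = None) -> pd.DataFrame:
    """Power and bias per candidate (S, T) design for one model.

    A study-design tool: how do added subjects trade off against added
    seasons for detecting the contemporaneous effect?
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    res = run_grid(base, sorted({int(s) for s, _ in designs}),
                   sorted({int(t) for _, t in designs}),
                   [model], n_reps, seed=seed, alpha=alpha)
    want = {(int(s), int(t)) for s, t in designs}
    summ = res.summary
    mask = [(int(r.S), int(r.T)) in want for r in summ.itertuples()]
    return summ[mask].reset_index(drop=True)
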