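"""Two-process (Process S) model fitting.

Given a scored hypnogram and the hourly NREM delta-power series it
produced, recover the homeostat's time constants: sleep pressure S rises
exponentially toward an upper asymptote with time constant ``tau_i``
during wake/REM and discharges toward a lower asymptote with ``tau_d``
during NREM sleep, and NREM delta power is proportional to S.

The forward model composes the per-epoch exponential update exactly over
runs of constant branch, predicts the mean S over each hour's NREM
epochs, and scales by a gain solved in closed form (ordinary least
squares given the taus).  Only the two time constants are free; the
asymptotes and the initial pressure are taken as known (they set the
units of S and are absorbed by the gain up to the rise/fall curvature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import NREM, Hypnogram
from .simulate import ProcessSParams, _branch_runs


def _s_scan(starts, lengths, is_nrem, tau_i, tau_d, lower, upper, s0, dt):
    """Per-epoch S by exact composition over constant-branch runs."""
    n = int(lengths.sum())
    s = np.empty(n)
    cur = s0
    for st, m, dn in zip(starts, lengths, is_nrem):
        if dn:
            asym, tau = lower, tau_d
        else:
            asym, tau = upper, tau_i
        seg = asym + (cur - asym) * np.exp(-np.arange(1, m + 1) * dt / tau)
        s[st : st + m] = seg
        cur = seg[-1]
    return s


class ProcessSModel:
    """Fit Process-S time constants to an hourly NREM delta series.

    Parameters
    ----------
    hypnogram : the scored state sequence driving the homeostat.
    hourly_delta : Series indexed by hour (from recording start) of mean
        NREM delta power; hours without NREM sleep are NaN and ignored.
    params : asymptotes / initial value held fixed during the fit (the
        defaults of the synthetic generator); only tau_i and tau_d are
        estimated, together with a closed-form proportionality gain.
    """

    def __init__(self, hypnogram: Hypnogram, hourly_delta: pd.Series,
                 params: ProcessSParams = ProcessSParams()):
        self.hypnogram = hypnogram
        self.params = params
        self.dt = hypnogram.epoch_s / 3600.0
        self._runs = _branch_runs(hypnogram.states)

        hour_of = hypnogram.epoch_start_h().astype(int)
        nrem = hypnogram.states == NREM
        obs_hours, targets, masks = [], [], []
        for h, v in hourly_delta.items():
            if not np.isfinite(v):
                continue
            rows = nrem & (hour_of == int(h))
            if rows.any():
                obs_hours.append(int(h))
                targets.append(float(v))
                masks.append(np.flatnonzero(rows))
        if len(obs_hours) < 4:
            raise ValueError("need at least 4 observed hours to fit two time constants")
        self.hours = np.array(obs_hours)
        self.y = np.array(targets)
        self._masks = masks

    def _predict_mean_s(self, tau_i: float, tau_d: float) -> np.ndarray:
        p = self.params
        s = _s_scan(*self._runs, tau_i, tau_d, p.lower, p.upper, p.s0, self.dt)
        return np.array([s[m].mean() for m in self._masks])

    def _residuals(self, log_taus: np.ndarray) -> np.ndarray:
        tau_i, tau_d = np.exp(log_taus)
        m = self._predict_mean_s(tau_i, tau_d)
        gain = float(m @ self.y) / float(m @ m)
        return gain * m - self.y

    def fit(self, tau_i0: float = 6.0, tau_d0: float = 1.5,
            bounds_h: tuple[float, float] = (0.2, 100.0)) -> "ProcessSResults":
        lb, ub = np.log(bounds_h[0]), np.log(bounds_h[1])
        sol = optimize.least_squares(
            self._residuals,
            x0=np.log([tau_i0, tau_d0]),
            bounds=([lb, lb], [ub, ub]),
            xtol=1e-10,
            ftol=1e-10,
        )
        tau_i, tau_d = np.exp(sol.x)
        m = self._predict_mean_s(tau_i, tau_d)
        gain = float(m @ self.y) / float(m @ m)
        resid = gain * m - self.y
        return ProcessSResults(
            tau_i=float(tau_i),
            tau_d=float(tau_d),
            gain=gain,
            sse=float(resid @ resid),
            n_hours=self.y.size,
            converged=bool(sol.success),
            fitted=pd.Series(gain * m, index=pd.Index(self.hours, name="hour")),
            observed=pd.Series(self.y, index=pd.Index(self.hours, name="hour")),
        )


@dataclass
class ProcessSResults:
    """Estimated Process-S time constants and fit diagnostics."""

    tau_i: float
    tau_d: float
    gain: float
    sse: float
    n_hours: int
    converged: bool
    fitted: pd.Series
    observed: pd.Series

    def summary(self) -> str:
        rmse = np.sqrt(self.sse / self.n_hours)
        return "\n".join(
            [
                "Process-S fit",
                f"  tau_i (build, h):     {self.tau_i:8.3f}",
                f"  tau_d (discharge, h): {self.tau_d:8.3f}",
                f"  gain:                 {self.gain:8.4f}",
                f"  hours fitted: {self.n_hours}; RMSE: {rmse:.4f}; "
                f"converged: {self.converged}",
            ]
        )


__all__ = ["ProcessSModel", "ProcessSResults"]
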