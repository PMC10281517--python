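"""Latent kinase-activity kinetics for the translocation-reporter generator.

A kinase translocation reporter (KTR) shuttles between nucleus and cytoplasm
depending on its phosphorylation state: with the kinase inhibited the
fluorescence is nuclear-enriched (C/N ratio below 1), and on stimulation the
reporter relocates to the cytoplasm.  The generator models the per-cell
cytoplasm/nucleus ratio ``r(t)`` as first-order relaxation towards an
activity-dependent steady state::

    dr/dt = (r_inf(a) - r) / tau,      r_inf(a) = r_min + (r_max - r_min) * a

with latent activity ``a(t)`` in [0, 1].  This is a deliberately simple
stand-in for the translocation phenomenology (no claim about reporter
biochemistry) chosen so that the trace has a closed-form solution for
piecewise-constant activity and the whole analysis pipeline can be verified
against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KineticsParams", "ActivityTrace", "simulate_ktr_kinetics", "step_activity"]


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the first-order C/N relaxation model.

    Attributes
    ----------
    r_min : float
        Baseline C/N ratio with the kinase fully inactive (nuclear-enriched,
        so < 1).  Dimensionless.
    r_max : float
        Saturated C/N ratio with the kinase fully active (cytoplasm-enriched).
    tau : float
        Relaxation time constant in minutes.
    noise_sd : float
        Multiplicative Gaussian intensity-noise scale used at render time.
    """

    r_min: float = 0.4
    r_max: float = 2.5
    tau: float = 15.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError(
                f"require 0 < r_min < r_max, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def r_inf(self, activity):
        """Steady-state ratio for a given activity level."""
        a = np.asarray(activity, dtype=float)
        return self.r_min + (self.r_max - self.r_min) * a


@dataclass(frozen=True)
class ActivityTrace:
    """Latent kinase activity sampled at strictly increasing times (minutes)."""

    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        activity = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "activity", activity)
        if times.ndim != 1 or activity.ndim != 1 or times.size != activity.size:
            raise ValueError("times and activity must be 1-D arrays of equal length")
        if times.size == 0:
            raise ValueError("activity trace must contain at least one sample")
        if times[0] != 0:
            raise ValueError(f"times must start at 0, got {times[0]}")
        diffs = np.diff(times)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            i = int(bad[0]) + 1
            raise ValueError(
                f"times must be strictly increasing; offending index {i} "
                f"(t[{i - 1}]={times[i - 1]}, t[{i}]={times[i]})"
            )
        if np.any(activity < 0) or np.any(activity > 1):
            raise ValueError("activity must be bounded in [0, 1]")


def step_activity(times, t_on: float = 0.0, low: float = 0.0, high: float = 1.0) -> ActivityTrace:
    """Step stimulation: activity jumps from `low` to `high` at ``t_on``.

    Mirrors the experimental design of adding ligand at T0 to an
    inhibitor-pretreated culture.
    """
    times = np.asarray(times, dtype=float)
    activity = np.where(times >= t_on, high, low)
    return ActivityTrace(times=times, activity=activity)


def simulate_ktr_kinetics(
    activity: ActivityTrace, params: KineticsParams, r0: float
) -> np.ndarray:
    """True C/N ratio at the trace's sample times.

    Activity is held constant on each interval ``[t_i, t_{i+1})`` at its left
    value, for which the linear relaxation has the exact solution

        r(t_{i+1}) = r_inf_i + (r(t_i) - r_inf_i) * exp(-dt/tau)

    applied interval by interval; the result is therefore exact (up to
    floating point) for piecewise-constant activity, continuous in time, and
    bounded in [r_min, r_max] whenever r0 is.
    """
    if not (params.r_min <= r0 <= params.r_max):
        raise ValueError(
            f"r0={r0} outside [r_min, r_max]=[{params.r_min}, {params.r_max}]"
        )
    times = activity.times
    r_inf = params.r_inf(activity.activity)
    out = np.empty_like(times)
    out[0] = r0
    decay = np.exp(-np.diff(times) / params.tau)
    for i in range(times.size - 1):
        out[i + 1] = r_inf[i] + (out[i] - r_inf[i]) * decay[i]
    return out
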