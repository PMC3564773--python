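"""Numerical integration of the closure model and derived outputs.

Trajectories are integrated with a stiff-capable adaptive solver (LSODA)
from the all-100 percent-of-control initial state.  AOX2 is supplied as a
closed-form forcing function rather than a sixth ODE.  The aperture proxy
is the cytosolic K+ series ([AP] = [K+]).

The default horizon of interest is the first two hours after stimulation;
the model describes transient signal transduction only, not the long-term
stationary behaviour governed by transcriptional regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.integrate import solve_ivp

from .model import (
    CONTROL_LEVEL,
    ModelParameters,
    StimulusDose,
    VARIANTS,
    aox2_level,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "ResponseMap",
    "TimescaleReport",
    "simulate",
    "aperture_series",
    "dose_response",
    "timescales",
    "trajectory_frame",
    "response_map_frame",
]

#: Snapshot times (min) used for dose-response maps.
DEFAULT_MAP_TIMES = (15.0, 30.0, 45.0, 60.0)


class IntegrationError(RuntimeError):
    """The ODE solver failed (stiffness, step underflow, ...)."""


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course of all six model variables.

    All series share the time grid; ros/aox1/no/kout/k are percent of
    control, aox2 is dimensionless in [0, 1).  The aperture series is the
    k series.
    """

    times: np.ndarray
    ros: np.ndarray
    aox1: np.ndarray
    aox2: np.ndarray
    no: np.ndarray
    kout: np.ndarray
    k: np.ndarray
    dose: StimulusDose
    variant: str

    @property
    def aperture(self) -> np.ndarray:
        return self.k

    def at(self, variable: str, time: float) -> float:
        """Series value at a grid time (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, time))
        if idx.size == 0:
            raise KeyError(f"time {time} not on the trajectory grid")
        return float(getattr(self, variable)[idx[0]])


@dataclass(frozen=True)
class ResponseMap:
    """Aperture on an (ABA dose) x (ACC dose) x (time) grid, % of control."""

    aba_grid: np.ndarray
    acc_grid: np.ndarray
    times: np.ndarray
    aperture: np.ndarray  # shape (n_aba, n_acc, n_times)


@dataclass(frozen=True)
class TimescaleReport:
    """Effective delays of the two antioxidant cascades, minutes."""

    tau1: float  # OR-gated AOX1 cascade: n1 / alpha23
    tau2: float  # AND-gated AOX2 cascade: n2 / beta13


def _make_rhs(params: ModelParameters, dose: StimulusDose, variant: str):
    """Build a fast RHS closure with dose-dependent constants precomputed."""
    p = params
    aba, acc = dose.aba, dose.acc
    ros_prod = p.alpha10 + (p.alpha11 * p.k12 * aba + p.alpha12 * p.k11 * acc) / (
        p.k11 * p.k12 + p.k12 * aba + p.k11 * acc
    )
    aox1_mm = (p.alpha21 * p.k22 * aba + p.alpha22 * p.k21 * acc) / (
        p.k21 * p.k22 + p.k22 * aba + p.k21 * acc
    )
    aox2_gate = (aba * acc) / ((p.k11 + aba) * (p.k12 + acc))
    no_from_acc = 0.0 if variant == "ph_variant" else p.alpha32 * acc / (p.k12 + acc)
    kout_const = p.alpha40 + p.alpha41 * aba / (p.k11 + aba)
    if variant == "ph_variant":
        kout_const += p.alpha43 * acc / (p.k12 + acc)
    n1, a23, n2, b13 = p.n1, p.alpha23, p.n2, p.beta13
    b11, b12, b20 = p.beta11, p.beta12, p.beta20
    a20, a31, k31, b30 = p.alpha20, p.alpha31, p.k31, p.beta30
    a42, b40, a51, k51, b50 = p.alpha42, p.beta40, p.alpha51, p.k51, p.beta50
    gammainc = special.gammainc

    def rhs(t, y):
        ros, aox1, no, kout, k = y
        aox2 = aox2_gate * gammainc(n2, b13 * t) if aox2_gate > 0 else 0.0
        return (
            ros_prod - (b11 * aox1 + b12 * aox2) * ros,
            a20 + aox1_mm * gammainc(n1, a23 * t) - b20 * aox1,
            a31 * ros / (k31 + ros) + no_from_acc - b30 * no,
            kout_const + a42 * no - b40 * kout,
            a51 / (k51 + no) - b50 * kout * k,
        )

    return rhs


def simulate(params: ModelParameters, dose: StimulusDose, times,
             variant: str = "primary", rtol: float = 1e-8,
             atol: float = 1e-10) -> Trajectory:
    """Integrate the five ODEs over an ascending time grid starting at 0.

    Returns a :class:`Trajectory` evaluated exactly at ``times``.  The
    initial state is 100 for every variable (percent-of-control
    convention) and AOX2(0) = 0.

    Raises
    ------
    IntegrationError
        if the solver fails; the message carries the solver diagnostic.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0 (stimulus onset)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly ascending")

    rhs = _make_rhs(params, dose, variant)
    y0 = np.full(5, CONTROL_LEVEL)
    if times[-1] == 0.0:  # degenerate grid: only the initial instant
        return Trajectory(times=times, ros=y0[:1].copy(), aox1=y0[1:2].copy(),
                          aox2=np.zeros(1), no=y0[2:3].copy(),
                          kout=y0[3:4].copy(), k=y0[4:5].copy(),
                          dose=dose, variant=variant)
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), y0, method="LSODA",
        t_eval=times, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for dose (aba={dose.aba}, acc={dose.acc}), "
            f"variant={variant}: {sol.message}"
        )
    ros, aox1, no, kout, k = sol.y
    return Trajectory(
        times=times, ros=ros, aox1=aox1,
        aox2=np.asarray(aox2_level(params, dose, times)),
        no=no, kout=kout, k=k, dose=dose, variant=variant,
    )


def aperture_series(traj: Trajectory) -> np.ndarray:
    """Stomatal aperture as percent of control: the K+ series itself."""
    return traj.k


def dose_response(params: ModelParameters, aba_grid, acc_grid,
                  times=DEFAULT_MAP_TIMES, variant: str = "primary",
                  rtol: float = 1e-8, atol: float = 1e-10) -> ResponseMap:
    """Aperture response map over a grid of (ABA, ACC) dose combinations.

    Each dose pair is simulated independently from the control state; the
    map holds the aperture (K+) value at every snapshot time.  Row/column
    zero give the single-stimulus dose-response curves.
    """
    aba_grid = np.asarray(aba_grid, dtype=float)
    acc_grid = np.asarray(acc_grid, dtype=float)
    snap = np.asarray(times, dtype=float)
    if aba_grid.size == 0 or acc_grid.size == 0:
        raise ValueError("dose grids must be non-empty")
    if np.any(aba_grid < 0) or np.any(acc_grid < 0):
        raise ValueError("doses must be non-negative")
    grid = np.concatenate([[0.0], snap]) if snap[0] > 0 else snap
    aperture = np.empty((aba_grid.size, acc_grid.size, snap.size))
    for i, aba in enumerate(aba_grid):
        for j, acc in enumerate(acc_grid):
            try:
                traj = simulate(params, StimulusDose(aba, acc), grid,
                                variant=variant, rtol=rtol, atol=atol)
            except IntegrationError as err:
                raise IntegrationError(
                    f"dose pair (aba={aba}, acc={acc}): {err}"
                ) from err
            aperture[i, j] = [traj.at("k", t) for t in snap]
    return ResponseMap(aba_grid=aba_grid, acc_grid=acc_grid, times=snap,
                       aperture=aperture)


def timescales(params: ModelParameters) -> TimescaleReport:
    """Effective antioxidant cascade delays tau1 = n1/alpha23, tau2 = n2/beta13."""
    if params.alpha23 <= 0 or params.beta13 <= 0:
        raise ValueError("cascade rates alpha23 and beta13 must be > 0")
    return TimescaleReport(tau1=params.n1 / params.alpha23,
                           tau2=params.n2 / params.beta13)


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy long-format view: columns time, variable, value, aba, acc, variant."""
    parts = []
    for var in ("ros", "aox1", "aox2", "no", "kout", "k"):
        parts.append(pd.DataFrame({
            "time": traj.times, "variable": var,
            "value": getattr(traj, var),
        }))
    out = pd.concat(parts, ignore_index=True)
    out["aba"] = traj.dose.aba
    out["acc"] = traj.dose.acc
    out["variant"] = traj.variant
    return out


def response_map_frame(rmap: ResponseMap) -> pd.DataFrame:
    """Tidy long-format view of a dose-response map."""
    aba, acc, t = np.meshgrid(rmap.aba_grid, rmap.acc_grid, rmap.times,
                              indexing="ij")
    return pd.DataFrame({
        "aba": aba.ravel(), "acc": acc.ravel(), "time": t.ravel(),
        "aperture": rmap.aperture.ravel(),
    })
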