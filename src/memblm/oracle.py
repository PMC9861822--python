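"""Exact reference solutions of the nonlinear circuit ODE.

The single state variable is the viscoelastic branch voltage ``Utilde``:

    dUtilde/dt = (U(t) - Utilde) / (tau * (1 + beta * Utilde**2))

integrated half-period by half-period (the ramp corner makes ``dU/dt``
discontinuous at ``t = n*T/2``, so each half is a smooth subproblem and the
integrator is restarted at every slope reversal).  The periodic steady state
is detected as a fixed point of the period map on ``Utilde`` at the ramp
foot.  Branch currents follow algebraically:

    i1 = (1-kappa) * C0 * (U - Utilde) / tau      (viscoelastic)
    i2 = kappa * C0 * dU/dt = +-kappa * C0 * k    (elastic)
    i3 = g*U + gamma*U**9                         (ionic)

The same machinery integrates the inverse ("ferroelectric") charge law,
``tau * dv/dt = U(t) - v - (beta/3) * v**3`` with ``v = q/((1-kappa)*C0)``
and ``i1 = (1-kappa)*C0*dv/dt``, used as the oracle for the sign of the
insertion conductance under that law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.integrate import solve_ivp

from .analytic import ResponseCurves
from .model import DriveSpec, MembraneParams, command_voltage, ionic_current

Law = Literal["membrane", "ferroelectric"]


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached within the period budget."""


@dataclass
class OracleSolution:
    """One steady period of the exact circuit solution."""

    t: np.ndarray
    utilde: np.ndarray
    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    I0: np.ndarray
    n_periods_to_converge: int
    params: MembraneParams
    drive: DriveSpec
    residual: float


def _rhs_factory(
    params: MembraneParams, law: Law
) -> Callable[[float, np.ndarray, float, float], np.ndarray]:
    beta, tau = params.beta, params.tau

    if law == "membrane":

        def rhs(t: float, y: np.ndarray, u0: float, slope: float) -> np.ndarray:
            return (u0 + slope * t - y) / (tau * (1.0 + beta * y * y))

    elif law == "ferroelectric":

        def rhs(t: float, y: np.ndarray, u0: float, slope: float) -> np.ndarray:
            return (u0 + slope * t - y - beta * y**3 / 3.0) / tau

    else:
        raise ValueError(f"unknown law {law!r}")
    return rhs


def _half_segments(drive: DriveSpec, n_half: int, t0: float = 0.0):
    """Yield (t_start, t_end, U_at_start, slope) for successive half periods."""
    Th = drive.T / 2.0
    for n in range(n_half):
        up = n % 2 == 0
        yield (
            t0 + n * Th,
            t0 + (n + 1) * Th,
            -drive.Umax if up else drive.Umax,
            drive.k if up else -drive.k,
        )


def _integrate_half(rhs, t0, t1, y0, u_start, slope, rel_tol, abs_tol, t_eval=None):
    sol = solve_ivp(
        lambda t, y: rhs(t - t0, y, u_start, slope),
        (t0, t1),
        [y0],
        method="LSODA",
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def integrate_to_steady_state(
    params: MembraneParams,
    drive: DriveSpec,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
    max_periods: int = 100,
    n_eval: int = 2001,
    law: Law = "membrane",
) -> OracleSolution:
    """Integrate the circuit ODE to its periodic steady state.

    Returns one steady period sampled on ``2*n_eval - 1`` points.  ``abs_tol``
    (volts) doubles as the fixed-point tolerance of the period map; starting
    from the linear-lag steady value the map typically converges in a few
    periods when ``T >= 20*tau``.

    For ``tau == 0`` the branch voltage equals the command voltage and the
    solution is algebraic.
    """
    if params.tau == 0.0:
        te = np.linspace(0.0, drive.T / 2.0, n_eval)
        t = np.concatenate([te, te + drive.T / 2.0])
        U = np.concatenate(
            [-drive.Umax + drive.k * te, drive.Umax - drive.k * te]
        )
        slope = np.concatenate(
            [np.full(n_eval, drive.k), np.full(n_eval, -drive.k)]
        )
        i1 = (1.0 - params.kappa) * params.C0 * slope
        i2 = params.kappa * params.C0 * slope
        i3 = ionic_current(U, params)
        return OracleSolution(
            t=t,
            utilde=U.copy(),
            i1=i1,
            i2=i2,
            i3=i3,
            I0=i1 + i2 + i3,
            n_periods_to_converge=0,
            params=params,
            drive=drive,
            residual=0.0,
        )

    rhs = _rhs_factory(params, law)
    # start from the linear-lag steady value at the ramp foot
    y = -drive.Umax + drive.k * params.tau
    tol = max(abs_tol, 1e-15)
    n_conv = -1
    residual = np.inf
    for period in range(max_periods):
        y_prev = y
        for t0, t1, u0, slope in _half_segments(drive, 2):
            y = float(
                _integrate_half(rhs, t0, t1, y, u0, slope, rel_tol, abs_tol).y[0, -1]
            )
        residual = abs(y - y_prev)
        if residual < tol:
            n_conv = period + 1
            break
    if n_conv < 0:
        raise ConvergenceError(
            f"no periodic fixed point within {max_periods} periods "
            f"(residual {residual:.3e} V > {tol:.3e} V)"
        )

    # one more period, densely sampled
    te = np.linspace(0.0, drive.T / 2.0, n_eval)
    segs = []
    for t0, t1, u0, slope in _half_segments(drive, 2):
        sol = _integrate_half(rhs, t0, t1, y, u0, slope, rel_tol, abs_tol, t0 + te)
        segs.append((sol.t, sol.y[0], u0, slope))
        y = float(sol.y[0, -1])

    # the apex sample is kept twice, once per slope: i2 jumps there and each
    # half-cycle branch needs its own one-sided value
    t = np.concatenate([segs[0][0], segs[1][0]])
    utilde = np.concatenate([segs[0][1], segs[1][1]])
    U = command_voltage(t % drive.T, drive)
    U[: n_eval] = -drive.Umax + drive.k * t[:n_eval]  # exact apex endpoint
    U[n_eval :] = drive.Umax - drive.k * (t[n_eval:] - drive.T / 2.0)
    slope_arr = np.concatenate(
        [
            np.full(n_eval, drive.k),
            np.full(n_eval, -drive.k),
        ]
    )
    i1 = _branch_current(params, U, utilde, law)
    i2 = params.kappa * params.C0 * slope_arr
    i3 = ionic_current(U, params)
    return OracleSolution(
        t=t,
        utilde=utilde,
        i1=i1,
        i2=i2,
        i3=i3,
        I0=i1 + i2 + i3,
        n_periods_to_converge=n_conv,
        params=params,
        drive=drive,
        residual=float(residual),
    )


def _branch_current(
    params: MembraneParams, U: np.ndarray, state: np.ndarray, law: Law
) -> np.ndarray:
    pre = (1.0 - params.kappa) * params.C0 / params.tau
    if law == "membrane":
        return pre * (U - state)
    return pre * (U - state - params.beta * state**3 / 3.0)


def steady_current_vs_voltage(sol: OracleSolution) -> ResponseCurves:
    """Fold one steady period into I_up(U) and time-inverted I_down_inv(U).

    Both branches are linearly interpolated onto a common ascending voltage
    grid whose endpoints are the ramp turning points.
    """
    n = sol.t.size // 2
    T, k, Umax = sol.drive.T, sol.drive.k, sol.drive.Umax
    t_up = sol.t[:n]
    U_up = -Umax + k * t_up
    I_up = sol.I0[:n]
    t_dn = sol.t[n:] - T / 2.0
    # time inversion tp -> T/2 - tp maps the down branch onto ascending U
    U_dn_inv = -Umax + k * (T / 2.0 - t_dn)[::-1]
    I_dn_inv = sol.I0[n:][::-1]

    U_grid = np.linspace(-Umax, Umax, n)
    return ResponseCurves(
        U=U_grid,
        I_up=np.interp(U_grid, U_up, I_up),
        I_down_inv=np.interp(U_grid, U_dn_inv, I_dn_inv),
        C_up=np.interp(U_grid, U_up, I_up) / k,
        C_down=np.interp(U_grid, U_dn_inv, I_dn_inv) / (-k),
    )


def simulate_trajectory(
    params: MembraneParams,
    drive: DriveSpec,
    fs: float,
    n_periods: int,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
    law: Law = "membrane",
    utilde0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full multi-period trajectory sampled at rate ``fs`` from a cold start.

    The membrane rests equilibrated at the ramp foot before the sweep begins
    (``Utilde(0) = U(0) = -Umax``), so the first cycles carry the genuine
    startup transient, as a real recording would.

    Returns ``(t, i_total, utilde)``.
    """
    t = np.arange(int(round(n_periods * drive.T * fs))) / fs
    if params.tau == 0.0:
        U = command_voltage(t, drive)
        slope = np.where(np.mod(t, drive.T) < drive.T / 2.0, drive.k, -drive.k)
        i = params.C0 * slope + ionic_current(U, params)
        return t, i, U.copy()

    rhs = _rhs_factory(params, law)
    y = -drive.Umax if utilde0 is None else float(utilde0)
    state = np.empty_like(t)
    Th = drive.T / 2.0
    for t0, t1, u0, slope in _half_segments(drive, 2 * n_periods):
        m = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
        t_eval = np.clip(np.append(t[m], t1), t0, t1)
        sol = _integrate_half(rhs, t0, t1, y, u0, slope, rel_tol, abs_tol, t_eval)
        state[m] = sol.y[0, : m.sum()]
        y = float(sol.y[0, -1])

    U = command_voltage(t, drive)
    slope_arr = np.where(np.mod(t, drive.T) < Th, drive.k, -drive.k)
    i1 = _branch_current(params, U, state, law)
    i2 = params.kappa * params.C0 * slope_arr
    i = i1 + i2 + ionic_current(U, params)
    return t, i, state


def energy_balance(sol: OracleSolution) -> tuple[float, float, float]:
    """Per-period energy bookkeeping of a steady solution.

    Returns ``(w_source, w_ionic, w_series)``: total source work, ionic
    dissipation, and series-resistance dissipation ``r * integral(i1**2)``.
    Over a steady period the capacitors are conservative, so
    ``w_source == w_ionic + w_series`` up to integration error.
    """
    U = command_voltage(sol.t % sol.drive.T, sol.drive)
    w_source = float(np.trapezoid(sol.I0 * U, sol.t))
    w_ionic = float(np.trapezoid(sol.i3 * U, sol.t))
    w_series = float(np.trapezoid(sol.params.r * sol.i1**2, sol.t))
    return w_source, w_ionic, w_series
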