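"""Voltage-clamp amplifier feedback model.

The amplifier output voltage follows the membrane current through a
first-order lag, ``dUout/dt + Uout/tau_out = I0 * Rout / tau_out``, so the
recorded quantity ``Uout/Rout`` is the low-pass filtered current.  Around a
ramp reversal this splits the current step into two exponentials — the slow
membrane relaxation (amplitude ``2*(1-kappa)*k*C0``, time constant ``tau``)
and the fast instrument response (amplitude ``2*kappa*k*C0``, time constant
``tau_out``) — which is how the elastic fraction ``kappa`` becomes visible
in recordings.
"""

from __future__ import annotations

import numpy as np

from .model import AmplifierParams, DriveSpec, MembraneParams, Trace


def filter_current(
    i: np.ndarray | Trace,
    amp: AmplifierParams,
    fs: float | None = None,
    y0: float | None = None,
) -> np.ndarray:
    """First-order low-pass of a uniformly sampled current.

    Exact zero-order-hold update: the input is held constant over each
    sample interval, for which the lag has the closed-form step
    ``y[n+1] = a*y[n] + (1-a)*x[n]`` with ``a = exp(-1/(fs*tau_out))``.
    Euler would be badly wrong here: typical ``tau_out`` (~0.8 ms) is close
    to a 1 kHz sample interval.

    ``y0`` sets the initial output (defaults to the first input sample — a
    filter already settled on the pre-trigger level); DC gain is exactly 1
    and the update is linear in the input, and ``tau_out = 0`` is the
    identity.
    """
    if isinstance(i, Trace):
        fs = i.fs
        x = i.i
    else:
        x = np.asarray(i, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    if amp.tau_out == 0.0:
        return x.copy()
    a = float(np.exp(-1.0 / (fs * amp.tau_out)))
    y = np.empty_like(x)
    y[0] = x[0] if y0 is None else y0
    for n in range(x.size - 1):
        y[n + 1] = a * y[n] + (1.0 - a) * x[n]
    return y


def analytic_output_transient(
    t: float | np.ndarray,
    params: MembraneParams,
    drive: DriveSpec,
    amp: AmplifierParams,
) -> float | np.ndarray:
    """Closed-form amplifier output after an up-ramp reversal.

    For the linear membrane (``beta = gamma = g = 0``) the input current is
    ``I0 = k*C0*(1 - 2*(1-kappa)*exp(-t/tau))`` and the settled output of
    the previous half cycle is ``-k*C0``, giving

        Uout/Rout = k*C0
                    - 2*(1-kappa)*k*C0/(1 - tau_out/tau)
                      * (exp(-t/tau) - exp(-t/tau_out))
                    - 2*k*C0*exp(-t/tau_out)

    which starts at ``-k*C0``, settles to ``+k*C0`` and for
    ``tau_out << tau`` reduces to the two-exponential form with amplitudes
    ``2*(1-kappa)*k*C0`` and ``2*kappa*k*C0``.  The confluent limit
    ``tau_out == tau`` is handled explicitly.
    """
    t = np.asarray(t, dtype=float)
    kC0 = drive.k * params.C0
    kap, tau, tau_out = params.kappa, params.tau, amp.tau_out
    if tau_out == 0.0:
        out = kC0 * (1.0 - 2.0 * (1.0 - kap) * np.exp(-t / tau)) if tau > 0 else (
            np.full_like(t, kC0)
        )
        return out if out.ndim else float(out)
    if tau == 0.0 or kap == 1.0:
        out = kC0 * (1.0 - 2.0 * np.exp(-t / tau_out))
        return out if out.ndim else float(out)
    if abs(1.0 - tau_out / tau) < 1e-12:
        # confluent limit: (e^{-t/tau} - e^{-t/tau_out})/(1 - tau_out/tau)
        # -> (t/tau) e^{-t/tau}
        mid = 2.0 * (1.0 - kap) * kC0 * (t / tau) * np.exp(-t / tau)
    else:
        mid = (
            2.0
            * (1.0 - kap)
            * kC0
            / (1.0 - tau_out / tau)
            * (np.exp(-t / tau) - np.exp(-t / tau_out))
        )
    out = kC0 - mid - 2.0 * kC0 * np.exp(-t / tau_out)
    return out if out.ndim else float(out)


def two_exponential_amplitudes(
    params: MembraneParams, drive: DriveSpec
) -> tuple[float, float]:
    """Slow and fast transient amplitudes ``(2*(1-kappa)*k*C0, 2*kappa*k*C0)``.

    Valid in the ``tau_out << tau`` regime; the amplitudes always sum to
    ``2*k*C0`` (the full current step at a ramp reversal).
    """
    kC0 = drive.k * params.C0
    return 2.0 * (1.0 - params.kappa) * kC0, 2.0 * params.kappa * kC0
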