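"""Drive waveform, equivalent-circuit parameter sets, and memoryless branch currents.

The membrane is modelled as three parallel branches under voltage clamp:

1. a *viscoelastic* branch — series resistance ``r`` (solvent viscosity) feeding
   the nonlinear capacitance ``C1 = (1 - kappa) * C0 * (1 + beta * Utilde**2)``,
   where ``Utilde`` is the lagging voltage across ``C1``;
2. a purely *elastic* branch of capacitance ``kappa * C0`` (its own nonlinearity
   is negligible for the solvent-free fraction and is fixed at zero);
3. an *ionic* branch ``i3 = g*U + gamma*U**9``.

Everything internal is SI (V, A, F, S, s).  Display/JSON I/O uses the
conventional laboratory units (mV, pF, nS, ms) with explicit unit-suffixed
keys; the ninth-order conductance coefficient in particular is trapped by
units (0.5e-18 nS/mV^8 == 5e-4 S/V^8), so conversion happens in exactly one
place, here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ValidityWarning(UserWarning):
    """Raised when an operation is used outside its comfortable regime."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriveSpec:
    """Periodic triangular command voltage.

    Each period starts at ``U = -Umax`` on the up ramp, reaches ``+Umax`` at
    ``T/2`` and returns.  The sweep rate is ``k = 4 * Umax * f`` so that
    ``k * (T/2) == 2 * Umax`` exactly.

    Parameters
    ----------
    Umax : float
        Voltage amplitude in volts, > 0.
    f : float
        Frequency in hertz, > 0.
    """

    Umax: float
    f: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.Umax) and self.Umax > 0):
            raise ValueError(f"Umax must be finite and > 0, got {self.Umax}")
        if not (np.isfinite(self.f) and self.f > 0):
            raise ValueError(f"f must be finite and > 0, got {self.f}")

    @property
    def T(self) -> float:
        """Period in seconds."""
        return 1.0 / self.f

    @property
    def k(self) -> float:
        """Sweep rate ``4 * Umax * f`` in V/s."""
        return 4.0 * self.Umax * self.f

    def to_dict(self) -> dict[str, float]:
        return {"Umax_mV": self.Umax * 1e3, "f_Hz": self.f}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "DriveSpec":
        _check_keys(d, {"Umax_mV", "f_Hz"}, "DriveSpec")
        return cls(Umax=d["Umax_mV"] * 1e-3, f=d["f_Hz"])


@dataclass(frozen=True)
class MembraneParams:
    """Lumped equivalent-circuit parameters of the membrane (SI units).

    Attributes
    ----------
    C0 : float
        Zero-voltage capacitance of the whole membrane (F), > 0.
    beta : float
        Capacitance nonlinearity of the viscoelastic fraction (V^-2), >= 0.
        This is the *intrinsic* coefficient; the paired-ramp protocol sees
        the effective ``beta_exp = beta * (1 - kappa)``.
    kappa : float
        Purely elastic fraction of the membrane, in [0, 1].
    tau : float
        Polarization lag time ``tau = (1 - kappa) * r * C0`` (s), >= 0.
        The series resistance ``r`` is derived, never stored.
    g : float
        Linear ionic conductance (S), >= 0.
    gamma : float
        Ninth-order ionic conductance coefficient (S V^-8), >= 0.
    """

    C0: float
    beta: float = 0.0
    kappa: float = 0.0
    tau: float = 0.0
    g: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C0) and self.C0 > 0):
            raise ValueError(f"C0 must be finite and > 0, got {self.C0}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.kappa == 1.0 and self.tau != 0.0:
            raise ValueError("kappa = 1 (no viscoelastic branch) forces tau = 0")
        if self.g < 0 or self.gamma < 0:
            raise ValueError("g and gamma must be >= 0")

    @property
    def beta_exp(self) -> float:
        """Effective nonlinearity ``beta * (1 - kappa)`` seen by the protocol."""
        return self.beta * (1.0 - self.kappa)

    @property
    def r(self) -> float:
        """Implied series resistance of the viscoelastic branch (Ohm)."""
        if self.kappa == 1.0:
            return 0.0
        return self.tau / ((1.0 - self.kappa) * self.C0)

    def to_dict(self) -> dict[str, float]:
        return {
            "C0_pF": self.C0 * 1e12,
            "beta_per_V2": self.beta,
            "kappa": self.kappa,
            "tau_ms": self.tau * 1e3,
            "g_nS": self.g * 1e9,
            "gamma_nS_per_mV8": self.gamma / GAMMA_SI_PER_LAB,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "MembraneParams":
        _check_keys(
            d,
            {"C0_pF", "beta_per_V2", "kappa", "tau_ms", "g_nS", "gamma_nS_per_mV8"},
            "MembraneParams",
            required={"C0_pF"},
        )
        return cls(
            C0=d["C0_pF"] * 1e-12,
            beta=d.get("beta_per_V2", 0.0),
            kappa=d.get("kappa", 0.0),
            tau=d.get("tau_ms", 0.0) * 1e-3,
            g=d.get("g_nS", 0.0) * 1e-9,
            gamma=d.get("gamma_nS_per_mV8", 0.0) * GAMMA_SI_PER_LAB,
        )


#: 1 nS/mV^8 expressed in S/V^8:  1e-9 S / (1e-3 V)^8 = 1e15 S V^-8.
GAMMA_SI_PER_LAB = 1e15


@dataclass(frozen=True)
class AmplifierParams:
    """Voltage-clamp amplifier feedback loop (first-order low-pass).

    ``tau_out = Rout * Cout`` where ``Rout`` is the feedback resistance and
    ``Cout`` its parasitic capacitance; ``Cout`` is derived, not stored.
    """

    Rout: float
    tau_out: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.Rout) and self.Rout > 0):
            raise ValueError(f"Rout must be finite and > 0, got {self.Rout}")
        if self.tau_out < 0:
            raise ValueError(f"tau_out must be >= 0, got {self.tau_out}")

    @property
    def Cout(self) -> float:
        return self.tau_out / self.Rout

    def to_dict(self) -> dict[str, float]:
        return {"Rout_MOhm": self.Rout * 1e-6, "tau_out_ms": self.tau_out * 1e3}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AmplifierParams":
        _check_keys(d, {"Rout_MOhm", "tau_out_ms"}, "AmplifierParams")
        return cls(Rout=d["Rout_MOhm"] * 1e6, tau_out=d["tau_out_ms"] * 1e-3)


@dataclass
class Trace:
    """Uniformly sampled voltage-clamp current record tied to a drive.

    Attributes
    ----------
    t : ndarray
        Sample times (s), strictly increasing with uniform spacing ``1/fs``.
    i : ndarray
        Current samples (A).
    drive : DriveSpec
        The command waveform the record answers to.
    fs : float
        Sampling rate (Hz).
    u : ndarray or None
        Recorded command voltage (V), if available.
    """

    t: np.ndarray
    i: np.ndarray
    drive: DriveSpec
    fs: float
    u: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.i.shape:
            raise ValueError("t and i must be 1-D arrays of equal length")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.shape != self.t.shape:
                raise ValueError("u must match t in shape")
        dt = np.diff(self.t)
        if dt.size and (np.any(dt <= 0) or np.any(np.abs(dt * self.fs - 1.0) > 1e-9)):
            raise ValueError("t must increase in uniform steps of 1/fs (1e-9 rel)")
        if self.t.size < 2 * self.drive.T * self.fs:
            raise ValueError("trace must cover at least 2 drive periods")

    @property
    def n_periods(self) -> float:
        return self.t.size / (self.drive.T * self.fs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def command_voltage(t: float | np.ndarray, drive: DriveSpec) -> float | np.ndarray:
    """Triangular command voltage ``U(t)``.

    The phase convention is ``U(0) = -Umax`` at the foot of the up ramp:
    ``U = -Umax + k*t`` for ``0 <= t < T/2`` and mirrored on the down half.
    ``t`` may be any real (reduced modulo the period).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("command_voltage: non-finite time")
    tm = np.mod(t, drive.T)
    up = tm < drive.T / 2.0
    u = np.where(
        up,
        -drive.Umax + drive.k * tm,
        drive.Umax - drive.k * (tm - drive.T / 2.0),
    )
    return u if u.ndim else float(u)


def sweep_rate(drive: DriveSpec) -> float:
    """Magnitude of the voltage ramp slope, ``k = 4 * Umax * f`` (V/s)."""
    return drive.k


def ionic_current(U: float | np.ndarray, params: MembraneParams) -> float | np.ndarray:
    """Ionic branch current ``g*U + gamma*U**9`` (odd in U)."""
    U = np.asarray(U, dtype=float)
    i = params.g * U + params.gamma * U**9
    return i if i.ndim else float(i)


def warn_if_fast_drive(params: MembraneParams, drive: DriveSpec) -> None:
    """Warn when the half period is short against the lag time.

    The closed-form responses assume the reversal transient has decayed
    within each half cycle; below ``T/2 = 5*tau`` that degrades.
    """
    if params.tau > 0 and drive.T / 2.0 < 5.0 * params.tau:
        warnings.warn(
            f"half period T/2 = {drive.T / 2:.4g} s is below 5*tau = "
            f"{5 * params.tau:.4g} s; transient-decayed closed forms degrade",
            ValidityWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# JSON plumbing
# ---------------------------------------------------------------------------


def _check_keys(
    d: dict[str, Any],
    allowed: set[str],
    name: str,
    required: set[str] | None = None,
) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
    missing = (required if required is not None else allowed) - set(d)
    if missing:
        raise ValueError(f"{name}: missing keys {sorted(missing)}")


def params_to_json(
    params: MembraneParams,
    drive: DriveSpec | None = None,
    amp: AmplifierParams | None = None,
) -> str:
    """Serialize parameter sets to a JSON object with unit-suffixed keys."""
    obj: dict[str, Any] = {"membrane": params.to_dict()}
    if drive is not None:
        obj["drive"] = drive.to_dict()
    if amp is not None:
        obj["amplifier"] = amp.to_dict()
    return json.dumps(obj, indent=2)


def params_from_json(
    text: str,
) -> tuple[MembraneParams, DriveSpec | None, AmplifierParams | None]:
    obj = json.loads(text)
    params = MembraneParams.from_dict(obj["membrane"])
    drive = DriveSpec.from_dict(obj["drive"]) if "drive" in obj else None
    amp = AmplifierParams.from_dict(obj["amplifier"]) if "amplifier" in obj else None
    return params, drive, amp
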