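"""Synthetic voltage-clamp recordings with the structure of real protocols.

The generator plays the exact circuit ODE forward from a cold start (the
membrane equilibrated at the ramp foot), optionally passes the current
through the amplifier lag, and adds white Gaussian current noise.  Defaults
mirror the published recording protocol: 1 kHz sampling, 25 periods of a
triangular command, noise at the few-pA scale visible on nF membranes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import oracle
from .instrument import filter_current
from .model import (
    AmplifierParams,
    DriveSpec,
    MembraneParams,
    Trace,
    ValidityWarning,
    command_voltage,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic recording."""

    params: MembraneParams
    drive: DriveSpec
    amp: AmplifierParams | None = None
    fs: float = 1000.0
    n_periods: int = 25
    noise_sd: float = 5e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.n_periods < 2:
            raise ValueError("need at least 2 periods")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        scales = [x for x in (self.params.tau, self.amp.tau_out if self.amp else None) if x]
        if scales and self.fs * min(scales) < 2.0:
            warnings.warn(
                "sampling rate under-resolves the fastest time constant "
                f"(fs*min(tau) = {self.fs * min(scales):.2f} < 2)",
                ValidityWarning,
                stacklevel=3,
            )


def generate_trace(spec: SyntheticSpec) -> Trace:
    """Simulate one recording; bit-reproducible for a fixed seed."""
    t, i, _ = oracle.simulate_trajectory(
        spec.params, spec.drive, spec.fs, spec.n_periods
    )
    if spec.amp is not None:
        i = filter_current(i, spec.amp, fs=spec.fs)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        i = i + rng.normal(0.0, spec.noise_sd, size=i.size)
    u = command_voltage(t, spec.drive)
    return Trace(
        t=t,
        i=i,
        drive=spec.drive,
        fs=spec.fs,
        u=u,
        meta={
            "generator": "memblm.synth",
            "seed": spec.seed,
            "noise_sd_A": spec.noise_sd,
            "n_periods": spec.n_periods,
            "membrane": spec.params.to_dict(),
            "drive": spec.drive.to_dict(),
            "amplifier": spec.amp.to_dict() if spec.amp else None,
        },
    )


@dataclass(frozen=True)
class ReferenceSet:
    params: MembraneParams
    drive: DriveSpec
    note: str = ""


def reference_parameter_sets() -> dict[str, ReferenceSet]:
    """Published equivalent-circuit parameter sets, in SI units.

    ``azolectin_200mV_1Hz`` is the azolectin membrane characterised under a
    200 mV, 1 Hz triangular drive (C0 = 897 pF, effective nonlinearity
    beta_exp = 11 V^-2 so intrinsic beta = 11/0.8 = 13.75 V^-2 at
    kappa = 0.2, tau = 19 ms, g = 0.05 nS, gamma = 0.5e-18 nS/mV^8).

    The three ``regime_*`` sets share C0 = 1120 pF, tau = 10 ms, effective
    beta_exp = 15 V^-2 under 200 mV / 2 Hz, and differ only in the ionic
    conductance: g = 0 (negative apparent conductance, pinched loop),
    g = 1.72 nS (= g*, zero loop width) and g = 8 nS (open loop).  The
    quoted nonlinearity is interpreted as effective: with k = 1.6 V/s,
    4 * 15 * k**2 * C0 * tau reproduces the quoted 1.72 nS exactly, while
    the intrinsic reading would not.
    """
    azo = MembraneParams(
        C0=897e-12, beta=13.75, kappa=0.2, tau=19e-3, g=0.05e-9, gamma=5e-4
    )
    drive_azo = DriveSpec(Umax=0.2, f=1.0)

    def regime(g: float) -> ReferenceSet:
        return ReferenceSet(
            params=MembraneParams(
                C0=1120e-12, beta=15.0 / 0.8, kappa=0.2, tau=10e-3, g=g, gamma=0.0
            ),
            drive=DriveSpec(Umax=0.2, f=2.0),
        )

    return {
        "azolectin_200mV_1Hz": ReferenceSet(params=azo, drive=drive_azo),
        "regime_negative_gapp": regime(0.0),
        "regime_zero_gapp": regime(1.72e-9),
        "regime_positive_gapp": regime(8e-9),
    }
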