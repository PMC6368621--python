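"""qPlus-sensor signal layer: frequency-shift/stiffness conversion and
experimental artifacts (measurement noise, premature tip-bond rupture).

At sub-ångström oscillation amplitude the frequency shift of a stiff tuning
fork tracks the gradient of the conservative tip–sample force, k ≈ 2k0·Δf/f0.
The small-amplitude relation is taken as exact here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .trace import Trace

__all__ = [
    "SensorParams",
    "stiffness_from_freq_shift",
    "freq_shift_from_stiffness",
    "apply_rupture",
    "add_noise",
]


@dataclass
class SensorParams:
    """qPlus deflection sensor: stiffness k0 (N m⁻¹), resonance f0 (Hz),
    oscillation amplitude A (pm)."""

    k0: float = 1800.0
    f0: float = 26000.0
    A: float = 50.0

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.f0 <= 0 or self.A <= 0:
            raise InvalidParameterError("k0, f0 and A must all be > 0")


def stiffness_from_freq_shift(dfreq, sensor: SensorParams = SensorParams()):
    """Effective stiffness k = 2·k0·Δf/f0 (N m⁻¹); linear and sign-preserving."""
    return 2.0 * sensor.k0 * np.asarray(dfreq, dtype=float) / sensor.f0


def freq_shift_from_stiffness(k, sensor: SensorParams = SensorParams()):
    """Frequency shift Δf = k·f0/(2·k0) (Hz); exact inverse of the above."""
    return np.asarray(k, dtype=float) * sensor.f0 / (2.0 * sensor.k0)


def apply_rupture(trace: Trace, rupture_force: float, seed: int = 0) -> Trace:
    """Sever the tip–molecule bond at the first sample where F reaches
    ``rupture_force`` (nN); all later samples get a zero-force tail.

    Emulates the premature end of the experimental retraction while the
    molecule stays on the surface.  Samples before the rupture point are kept
    bit-exactly; the trace length never grows.  ``rupture_force = inf`` leaves
    the trace unchanged.  ``seed`` is accepted for interface symmetry with the
    other artifact operations (rupture itself is deterministic).
    """
    if rupture_force is None or not rupture_force > 0:
        raise InvalidParameterError("rupture_force must be > 0")
    if trace.F is None:
        raise InvalidParameterError("trace has no force channel")
    hit = np.where(trace.F >= rupture_force)[0]
    if len(hit) == 0:
        return trace
    i0 = int(hit[0])
    out = Trace(Z=trace.Z, meta=dict(trace.meta, rupture_z=float(trace.Z[i0])))
    for name, ch in trace.channels().items():
        new = ch.copy()
        if name in ("F", "k", "dfreq"):
            new[i0:] = 0.0
        setattr(out, name, new)
    return out


def add_noise(trace: Trace, sigma_k: float, seed: int = 0) -> Trace:
    """Add zero-mean Gaussian white noise (sd ``sigma_k``, N m⁻¹) to the
    stiffness channel; deterministic for fixed seed."""
    if sigma_k < 0:
        raise InvalidParameterError("sigma_k must be >= 0")
    if trace.k is None:
        raise InvalidParameterError("trace has no stiffness channel")
    if sigma_k == 0:
        return trace
    rng = np.random.default_rng(seed)
    noisy = trace.k + rng.normal(0.0, sigma_k, len(trace))
    out = trace.with_channel("k", noisy)
    out.meta = dict(trace.meta, sigma_k=sigma_k, noise_seed=seed)
    return out
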