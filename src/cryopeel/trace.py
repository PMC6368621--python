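"""Retraction trace container shared by the simulator, signal and analysis layers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError

CHANNELS = ("F", "k", "dfreq", "energy", "dissipation", "n_adsorbed", "zP")


@dataclass
class Trace:
    """Sampled retraction record on a strictly increasing tip-displacement grid.

    ``Z`` is the tip displacement from the retraction start (nm).  Channels:
    ``F`` tip force k_tip·(Z − Z_P) in nN; ``k`` effective stiffness d⟨F⟩/dZ in
    N m⁻¹; ``dfreq`` sensor frequency shift in Hz; ``energy`` relaxed total
    energy (nN·nm); ``dissipation`` per-step energy released by slips (nN·nm);
    ``n_adsorbed`` adsorbed-base count; ``zP`` vertical displacement of the
    pulled bead (nm).  ``meta`` carries speed, seed, smoothing window, k_tip
    and sensor parameters.
    """

    Z: np.ndarray
    F: np.ndarray | None = None
    k: np.ndarray | None = None
    dfreq: np.ndarray | None = None
    energy: np.ndarray | None = None
    dissipation: np.ndarray | None = None
    n_adsorbed: np.ndarray | None = None
    zP: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 1 or len(self.Z) == 0:
            raise InvalidParameterError("Z must be a non-empty 1-D array")
        if len(self.Z) > 1 and not np.all(np.diff(self.Z) > 0):
            raise InvalidParameterError("Z must be strictly increasing")
        for name in CHANNELS:
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.Z.shape:
                    raise InvalidParameterError(
                        f"channel {name!r} length {ch.shape} != Z {self.Z.shape}"
                    )
                setattr(self, name, ch)

    def __len__(self) -> int:
        return len(self.Z)

    def channels(self) -> dict[str, np.ndarray]:
        """Present channels as an ordered name → array mapping."""
        return {n: getattr(self, n) for n in CHANNELS if getattr(self, n) is not None}

    def with_channel(self, name: str, values: np.ndarray) -> "Trace":
        """Return a copy with one channel replaced/added."""
        if name not in CHANNELS:
            raise InvalidParameterError(f"unknown channel {name!r}")
        return replace(self, **{name: np.asarray(values, dtype=float)})
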