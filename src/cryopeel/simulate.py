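"""Quasi-static steered retraction of the adsorbed chain.

The tip anchor starts at the attachment bead and moves vertically in steps of
``dz``.  At every step all bead coordinates are relaxed to a *local* energy
minimum, warm-started from the previous step.  Warm-starting is what produces
hysteretic stick-slip: the system rides a metastable branch until it
disappears, then drops — the abrupt force drops seen as dips in k(Z).  At 5 K
thermal energy is negligible against the nN·nm barriers, so this
zero-temperature limit stands in for thermostatted steered pulling; the pulling
speed is metadata only.

Energy bookkeeping: moving the tip at frozen bead coordinates does external
work exactly equal to the tip-spring energy change; the subsequent relaxation
at fixed tip releases ``dissipation`` ≥ 0.  Hence
``∫F dZ ≈ ΔE_total + Σ dissipation`` up to quadrature error, which
:func:`work_energy_residual` measures.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .chain import ChainConformation, SurfaceModel, TipModel, energy_and_gradient
from .errors import InvalidParameterError, StepError
from .trace import Trace

__all__ = [
    "retract",
    "relax",
    "smooth_force",
    "stiffness_from_force",
    "detachment_distance",
    "work_energy_residual",
]

_GTOL = 1e-6  # nN, target residual gradient
_GTOL_ACCEPT = 5e-3  # nN, accept threshold before declaring a step failure
# (5e-3 nN is an order below the force floor and any dip depth; the
# post-detachment dangling chain has nearly flat modes where L-BFGS stops on
# ftol first)


def relax(
    positions: np.ndarray,
    chain: ChainConformation,
    surface: SurfaceModel,
    tip: TipModel,
    tip_position: np.ndarray | None,
    free_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Locally minimize the energy over the free bead coordinates.

    Returns (relaxed positions, energy, residual gradient inf-norm).
    ``free_mask`` is a per-bead boolean; ``False`` beads stay frozen.
    """
    pos0 = np.asarray(positions, dtype=float).copy()
    n = pos0.shape[0]
    if free_mask is None:
        free_mask = np.ones(n, dtype=bool)
    idx = np.where(free_mask)[0]

    def fun(x):
        p = pos0.copy()
        p[idx] = x.reshape(-1, 3)
        e, g = energy_and_gradient(p, chain, surface, tip, tip_position)
        return e, g[idx].ravel()

    res = minimize(
        fun,
        pos0[idx].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": _GTOL},
    )
    out = pos0.copy()
    out[idx] = res.x.reshape(-1, 3)
    resid = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    return out, float(res.fun), resid


def retract(
    chain: ChainConformation,
    surface: SurfaceModel,
    tip: TipModel,
    z_max: float,
    dz: float = 0.002,
    seed: int = 0,
    jitter: float = 0.0,
    fixed_beads: tuple[int, ...] = (),
    snapshot_every: int = 0,
) -> Trace | tuple[Trace, list[tuple[float, np.ndarray]]]:
    """Quasi-static retraction producing a force–distance trace.

    Parameters
    ----------
    z_max, dz
        Final tip displacement and step (nm); ``dz`` must resolve the lattice
        (``dz < lattice_period/4``).
    jitter
        RMS amplitude (nm) of a Gaussian coordinate kick applied before each
        relaxation — a small 5-K-scale thermal perturbation.  0 keeps the run
        strictly deterministic-quasi-static (required for the work–energy
        identity).
    fixed_beads
        Bead indices frozen in place (e.g. to pin the far end of the chain).
    snapshot_every
        If > 0, also return conformation snapshots every that many steps.

    Deterministic for fixed ``seed``.
    """
    if dz <= 0 or z_max <= 0:
        raise InvalidParameterError("z_max and dz must be > 0")
    if dz >= surface.lattice_period / 4:
        raise InvalidParameterError("dz must be below lattice_period/4")
    att = tip.attachment_bead
    if att >= chain.n_bases:
        raise InvalidParameterError("attachment_bead out of range")

    rng = np.random.default_rng(seed)
    free = np.ones(chain.n_bases, dtype=bool)
    for i in fixed_beads:
        free[i] = False

    pos = chain.positions.copy()
    anchor = pos[att].copy()
    z_p0 = pos[att, 2]

    # settle into the Z = 0 minimum before recording
    pos, e_prev, resid = relax(pos, chain, surface, tip, anchor, free)
    if resid > _GTOL_ACCEPT:
        raise StepError(0.0, resid)

    n_steps = int(round(z_max / dz)) + 1
    Z = dz * np.arange(n_steps)
    F = np.empty(n_steps)
    E = np.empty(n_steps)
    D = np.zeros(n_steps)
    zP = np.empty(n_steps)
    nads = np.empty(n_steps)
    snapshots: list[tuple[float, np.ndarray]] = []

    for i, z in enumerate(Z):
        tip_pos = anchor + np.array([0.0, 0.0, z])
        if i > 0:
            e_frozen, _ = energy_and_gradient(pos, chain, surface, tip, tip_pos)
            trial = pos
            if jitter > 0:
                trial = pos + rng.normal(0.0, jitter, pos.shape) * free[:, None]
            pos, e, resid = relax(trial, chain, surface, tip, tip_pos, free)
            if resid > _GTOL_ACCEPT:
                # one retry from a slightly perturbed point, then give up
                bump = pos + rng.normal(0.0, 1e-4, pos.shape) * free[:, None]
                pos, e, resid = relax(bump, chain, surface, tip, tip_pos, free)
                if resid > _GTOL_ACCEPT:
                    raise StepError(float(z), resid)
            # frozen tip move overshoots the reversible work by exactly
            # ½·k_tip·dz² (protocol arithmetic); remove it so smooth steps
            # carry no spurious dissipation
            D[i] = max(e_frozen - e - 0.5 * tip.k_tip * dz**2, 0.0)
        else:
            e = e_prev
        E[i] = e
        zP[i] = pos[att, 2] - z_p0
        F[i] = tip.k_tip * (z - zP[i])
        nads[i] = int(np.sum(pos[:, 2] < surface.adsorption_cutoff_height))
        if snapshot_every and i % snapshot_every == 0:
            snapshots.append((float(z), pos.copy()))

    meta = {
        "speed_nm_per_s": tip.speed,
        "seed": seed,
        "k_tip": tip.k_tip,
        "dz": dz,
        "jitter": jitter,
        "n_bases": chain.n_bases,
        "b": chain.b,
        "contour_length": chain.contour_length,
    }
    trace = Trace(Z=Z, F=F, energy=E, dissipation=D, zP=zP, n_adsorbed=nads, meta=meta)
    if snapshot_every:
        return trace, snapshots
    return trace


def smooth_force(trace: Trace, window: float) -> Trace:
    """Centered running average of the force channel over ``window`` (nm).

    Endpoints use symmetrically shrunken windows, so linear segments are
    reproduced exactly everywhere.  The running average stands in for the
    thermal average ⟨F(Z)⟩ of the steered-pulling protocol; the window should
    be wide enough to be smooth yet narrow against the event spacing.
    """
    if trace.F is None:
        raise InvalidParameterError("trace has no force channel")
    dz = np.min(np.diff(trace.Z)) if len(trace) > 1 else window
    if window < dz:
        raise InvalidParameterError("window must be at least the grid step")
    half = max(int(round(window / dz)) // 2, 1)
    n = len(trace)
    csum = np.concatenate([[0.0], np.cumsum(trace.F)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    new = trace.with_channel("F", out)
    new.meta = dict(trace.meta, smoothing_window=window)
    return new


def stiffness_from_force(trace: Trace) -> Trace:
    """Effective stiffness k = d⟨F⟩/dZ by finite differences (N m⁻¹).

    Central differences on the interior, one-sided at the ends; negative
    excursions at force drops are preserved.
    """
    if trace.F is None:
        raise InvalidParameterError("trace has no force channel")
    if len(trace) < 3:
        raise InvalidParameterError("need at least 3 samples to differentiate")
    k = np.gradient(trace.F, trace.Z)
    return trace.with_channel("k", k)


def detachment_distance(trace: Trace, force_floor: float) -> float | None:
    """Smallest Z after which |F| stays below ``force_floor`` to the trace end.

    Returns ``None`` when no such terminal regime exists (no detachment
    within the trace).
    """
    if trace.F is None:
        raise InvalidParameterError("trace has no force channel")
    below = np.abs(trace.F) < force_floor
    if not below[-1]:
        return None
    # first index of the terminal all-below run
    above = np.where(~below)[0]
    start = 0 if len(above) == 0 else above[-1] + 1
    return float(trace.Z[start])


def work_energy_residual(trace: Trace) -> float:
    """Relative mismatch between ∫F dZ and ΔE + Σ dissipation.

    Zero for an exactly quasi-static, jitter-free run up to quadrature error on
    the force integral.
    """
    if trace.F is None or trace.energy is None or trace.dissipation is None:
        raise InvalidParameterError("trace needs F, energy and dissipation channels")
    work = float(np.trapezoid(trace.F, trace.Z))
    balance = float(trace.energy[-1] - trace.energy[0] + trace.dissipation.sum())
    scale = max(abs(work), abs(balance), 1e-12)
    return abs(work - balance) / scale
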