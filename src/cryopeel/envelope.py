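"""Springs-in-series analysis of the decaying stiffness envelope.

While the chain peels, the lifted segment of n detached repeats (per-repeat
stiffness k1), the tip–molecule bond (k_tip) and the pinning at the adsorbed
part (k_pin) act as springs in series, so the upper envelope of the measured
stiffness obeys

    k(Z) = [1/k_ends + n/k1]^(-1),   1/k_ends = 1/k_tip + 1/k_pin,

with n = floor(Z / (b cosθ)) the number of detached nucleotides and b cosθ the
projected repeat length along the pulling axis (θ the inclination of the
straight lifted segment).  In the reciprocal domain the model is *linear* in n
(1/k = 1/k_ends + n/k1), so for a candidate b cosθ the fit is an exact linear
least-squares problem; b cosθ itself is found by grid search because the floor
makes the model piecewise constant in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import FitError, InsufficientEventsError, InvalidParameterError
from .trace import Trace

__all__ = [
    "EventSet",
    "EnvelopeFit",
    "SpacingStats",
    "find_events",
    "spacing_stats",
    "envelope_value",
    "fit_envelope",
    "derived_quantities",
    "synthetic_peak_set",
]


@dataclass
class EventSet:
    """Dips (stick-slip/detachment events) and the k maxima between them."""

    dip_positions: np.ndarray
    peak_positions: np.ndarray
    peak_heights: np.ndarray
    prominence_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.dip_positions = np.asarray(self.dip_positions, dtype=float)
        self.peak_positions = np.asarray(self.peak_positions, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if np.any(np.diff(self.dip_positions) <= 0) or np.any(
            np.diff(self.peak_positions) <= 0
        ):
            raise InvalidParameterError("event positions must be sorted ascending")
        if self.peak_positions.shape != self.peak_heights.shape:
            raise InvalidParameterError("peak positions/heights length mismatch")


@dataclass
class SpacingStats:
    mean: float
    sd: float
    spacings: np.ndarray


@dataclass
class EnvelopeFit:
    """Fitted springs-in-series envelope with delta-method uncertainties."""

    k1: float
    k_pin: float
    b_cos_theta: float
    k_tip_fixed: float
    k1_err: float
    k_pin_err: float
    b_cos_theta_err: float
    n_assignment: np.ndarray
    peak_positions: np.ndarray
    peak_heights: np.ndarray
    fit_range: tuple[int, int]
    residual_norm: float
    meta: dict = field(default_factory=dict)

    @property
    def k_ends(self) -> float:
        return 1.0 / (1.0 / self.k_tip_fixed + 1.0 / self.k_pin)

    def predict(self, Z) -> np.ndarray:
        return envelope_value(Z, self.k1, self.k_pin, self.k_tip_fixed, self.b_cos_theta)


def find_events(trace: Trace, prominence: float) -> EventSet:
    """Locate stiffness dips (local minima of k with at least the given
    prominence, N m⁻¹) and the maximum of k between consecutive dips,
    including the stretches before the first and after the last dip."""
    if trace.k is None:
        raise InvalidParameterError("trace has no stiffness channel")
    k = trace.k
    if len(k) == 0 or np.ptp(k) == 0:
        if len(k) == 0:
            return EventSet(np.empty(0), np.empty(0), np.empty(0), prominence)
        return EventSet(
            np.empty(0), trace.Z[:1], k[:1], prominence_threshold=prominence
        )
    dips, _ = find_peaks(-k, prominence=prominence)
    bounds = np.concatenate([[0], dips, [len(k)]])
    peak_idx = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = slice(lo + 1 if lo in dips else lo, hi)
        if seg.start < seg.stop:
            peak_idx.append(seg.start + int(np.argmax(k[seg])))
    peak_idx = np.asarray(sorted(set(peak_idx)), dtype=int)
    return EventSet(
        dip_positions=trace.Z[dips],
        peak_positions=trace.Z[peak_idx],
        peak_heights=k[peak_idx],
        prominence_threshold=prominence,
    )


def spacing_stats(events: EventSet) -> SpacingStats | None:
    """Mean and sample sd of consecutive dip spacings; ``None`` (insufficient
    events) with fewer than two dips."""
    if len(events.dip_positions) < 2:
        return None
    spac = np.diff(events.dip_positions)
    sd = float(np.std(spac, ddof=1)) if len(spac) > 1 else 0.0
    return SpacingStats(mean=float(np.mean(spac)), sd=sd, spacings=spac)


def envelope_value(Z, k1: float, k_pin: float, k_tip: float, b_cos_theta: float):
    """Model stiffness envelope k(Z) = [1/k_ends + n/k1]⁻¹, n = floor(Z/(b cosθ))."""
    if k1 <= 0 or k_pin <= 0 or k_tip <= 0 or b_cos_theta <= 0:
        raise InvalidParameterError("all stiffnesses and b_cos_theta must be > 0")
    n = np.floor(np.asarray(Z, dtype=float) / b_cos_theta)
    inv_k_ends = 1.0 / k_tip + 1.0 / k_pin
    return 1.0 / (inv_k_ends + n / k1)


def _reciprocal_ls(n: np.ndarray, y: np.ndarray):
    """Exact LS of 1/k = c0 + n/k1; returns (c0, slope, rss, cov or None)."""
    X = np.column_stack([np.ones_like(n, dtype=float), n.astype(float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    m = len(y)
    cov = None
    if m > 2:
        sigma2 = rss / (m - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(beta[0]), float(beta[1]), rss, cov


def fit_envelope(
    events: EventSet,
    k_tip: float,
    b_cos_theta_grid: tuple[float, float, float] = (0.40, 0.90, 0.005),
    n_range: tuple[int, int] = (1, 18),
) -> EnvelopeFit:
    """Fit the springs-in-series envelope to the k maxima with k_tip fixed.

    For every candidate b cosθ on the grid, peaks are assigned
    n = floor(Z/(b cosθ)) (ties at exact multiples go to the lower n via
    floor), peaks with n outside ``n_range`` are excluded, and the linear
    least-squares problem 1/k = 1/k_ends + n/k1 is solved exactly.

    Candidate selection: a candidate retaining more peaks always wins (a
    period whose assignment pushes peaks out of ``n_range`` discards data and
    trivially shrinks the residual).  Among equals the score is the height
    residual inflated by plateau misalignment, RSS·(1 + P) with
    P = 12·mean((Z/c − n − ½)²): the model puts every k maximum inside its
    plateau [n·c, (n+1)·c), so P compares the observed scatter of peak
    positions around plateau centres against a uniform-within-plateau spread
    (variance 1/12 in plateau units).  Peak heights alone leave b cosθ nearly
    unidentified once noise exceeds the integer-assignment staircase; the
    positions carry that information.  Exact score ties resolve to the
    smallest P.  k_pin is recovered from the fitted k_ends and the fixed
    k_tip; uncertainties come from the regression covariance propagated
    through the reciprocals.
    """
    if k_tip <= 0:
        raise InvalidParameterError("k_tip must be > 0")
    lo, hi, step = b_cos_theta_grid
    if not (0 < lo < hi) or step <= 0:
        raise InvalidParameterError("invalid b_cos_theta grid")
    n_min, n_max = n_range
    Z = events.peak_positions
    K = events.peak_heights
    pos = K > 0
    Z, K = Z[pos], K[pos]
    if len(Z) < 4:
        raise InsufficientEventsError("need at least 4 positive peaks to fit")
    y = 1.0 / K

    grid = np.arange(lo, hi + 0.5 * step, step)
    best = None  # (count, score, misalign, c, n_sel, sel)
    for c in grid:
        n = np.floor(Z / c).astype(int)
        sel = (n >= n_min) & (n <= n_max)
        count = int(sel.sum())
        if count < 4 or len(np.unique(n[sel])) < 2:
            continue
        c0, slope, rss, _ = _reciprocal_ls(n[sel], y[sel])
        misalign = 12.0 * float(np.mean((Z[sel] / c - n[sel] - 0.5) ** 2))
        score = rss * (1.0 + misalign)
        if (
            best is None
            or count > best[0]
            or (
                count == best[0]
                and (
                    score < best[1] * (1 - 1e-9)
                    or (
                        abs(score - best[1]) <= 1e-9 * max(best[1], 1e-30)
                        and misalign < best[2]
                    )
                )
            )
        ):
            best = (count, score, misalign, c, n[sel], sel)
    if best is None:
        raise FitError(
            "degenerate peak assignment: no grid value yields >=4 peaks on >=2 "
            "distinct n within n_range"
        )
    _, _, _, c, n_sel, sel = best
    c0, slope, rss, cov = _reciprocal_ls(n_sel, y[sel])
    if slope <= 0:
        raise FitError("non-positive fitted slope implies non-positive k1")
    inv_kpin = c0 - 1.0 / k_tip
    if inv_kpin <= 0:
        raise FitError(
            "fitted k_ends >= k_tip implies non-positive k_pin; k_tip inconsistent"
        )
    k1 = 1.0 / slope
    k_pin = 1.0 / inv_kpin
    if cov is not None:
        se_c0, se_slope = np.sqrt(np.diag(cov))
        k1_err = se_slope / slope**2
        k_pin_err = se_c0 / inv_kpin**2
    else:
        k1_err = k_pin_err = float("nan")
    return EnvelopeFit(
        k1=k1,
        k_pin=k_pin,
        b_cos_theta=float(c),
        k_tip_fixed=float(k_tip),
        k1_err=float(k1_err),
        k_pin_err=float(k_pin_err),
        b_cos_theta_err=float(step),
        n_assignment=n_sel,
        peak_positions=Z[sel],
        peak_heights=K[sel],
        fit_range=(n_min, n_max),
        residual_norm=float(np.sqrt(rss)),
    )


def derived_quantities(
    fit: EnvelopeFit, n_bases: int, trace: Trace | None = None
) -> dict:
    """Mechanical quantities derived from a fit.

    ``k_dna`` = k1/(n_bases − 1): stiffness of the fully stretched oligomer
    (springs in series over all repeats).  With a trace, ``avg_tension`` is the
    mean force over the Z range spanned by the fitted peaks.
    """
    if n_bases < 2:
        raise InvalidParameterError("n_bases must be >= 2")
    out = {
        "k_dna": fit.k1 / (n_bases - 1),
        "k1": fit.k1,
        "k_pin": fit.k_pin,
        "k_ends": fit.k_ends,
        "b_cos_theta": fit.b_cos_theta,
    }
    if trace is not None and trace.F is not None and len(fit.peak_positions) > 0:
        z_lo, z_hi = fit.peak_positions.min(), fit.peak_positions.max()
        m = (trace.Z >= z_lo) & (trace.Z <= z_hi)
        if m.any():
            out["avg_tension"] = float(np.mean(trace.F[m]))
    return out


def synthetic_peak_set(
    k1: float = 32.6,
    k_pin: float = 18.3,
    k_tip: float = 35.0,
    b_cos_theta: float = 0.64,
    n_range: tuple[int, int] = (1, 18),
    noise: float = 0.0,
    seed: int | None = None,
) -> EventSet:
    """Peaks drawn exactly from the envelope model at plateau centres
    Z_n = (n+½)·b cosθ, optionally with multiplicative Gaussian noise on the
    heights.  The reference generator for self-consistency refits."""
    n = np.arange(n_range[0], n_range[1] + 1)
    Z = (n + 0.5) * b_cos_theta
    k = envelope_value(Z, k1, k_pin, k_tip, b_cos_theta)
    if noise > 0:
        rng = np.random.default_rng(seed)
        k = k * (1.0 + noise * rng.standard_normal(len(k)))
    return EventSet(dip_positions=np.empty(0), peak_positions=Z, peak_heights=k)
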