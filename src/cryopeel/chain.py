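"""Coarse-grained energy model: ssDNA bead chain, corrugated gold surface, tip spring.

One bead per nucleotide; beads are joined by stiff harmonic bonds whose spring
constant is the per-repeat stiffness of the fully stretched backbone.  Each bead
adheres to the substrate plane through a Morse well in height and feels an
in-plane sinusoidal corrugation with the substrate lattice period (0.28 nm for
Au(111)) that decays with height.  The probe is a harmonic spring between a
virtual tip point and the attachment bead; retracting the tip vertically peels
the chain off the surface base by base.

Units throughout: lengths in nm, forces in nN, energies in nN·nm.  With this
choice a stiffness in nN/nm is numerically equal to N/m, so fitted values can be
compared directly with stiffnesses quoted in N m⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ChainConformation",
    "SurfaceModel",
    "TipModel",
    "build_chain",
    "count_counterions",
    "total_energy",
    "energy_and_gradient",
    "write_xyz",
    "read_xyz",
]


@dataclass
class SurfaceModel:
    """Adhesive, corrugated substrate plane at z = 0.

    Parameters
    ----------
    lattice_period
        In-plane period of the corrugation (nm).  0.28 nm for Au(111).
    corrugation_amplitude
        Peak-to-valley height of the in-plane diffusion barrier per base
        (nN·nm).  Controls stick-slip of the peel-front base.
    adhesion_depth
        Depth of the per-base contact well (nN·nm).  An *effective* value:
        in the coarse-grained picture it absorbs base adhesion plus the
        unfolding work per repeat, and is calibrated so the peeling tension
        is of the nN order.
    adsorption_cutoff_height
        A base counts as adsorbed when its height above the well minimum is
        below this cutoff (nm).
    well_inverse_width
        Morse inverse width a (nm⁻¹); the maximum vertical holding force of
        the contact well is a·adhesion_depth/2.
    corrugation_decay
        Gaussian decay length of the corrugation with height (nm).
    shelf_depth, shelf_height, shelf_width
        Secondary (Gaussian) binding shelf above the contact well: the
        partially-detached state of a nucleotide whose base has peeled but
        whose backbone still binds the surface.  Each repeat therefore
        detaches through intermediate stages — peeling, lifting, final
        detachment — rather than in one jump, and the lattice registry
        (corrugation) acts in both the contact and the shelf state.  Maximum
        vertical holding force of the shelf is √2·e^(−1/2)·shelf_depth/shelf_width.
    """

    lattice_period: float = 0.28
    corrugation_amplitude: float = 0.08
    adhesion_depth: float = 0.22
    adsorption_cutoff_height: float = 0.15
    well_inverse_width: float = 8.0
    corrugation_decay: float = 0.12
    shelf_depth: float = 0.08
    shelf_height: float = 0.2
    shelf_width: float = 0.18

    def __post_init__(self) -> None:
        if self.lattice_period <= 0:
            raise InvalidParameterError("lattice_period must be > 0")
        if self.adhesion_depth < 0:
            raise InvalidParameterError("adhesion_depth must be >= 0")
        if self.corrugation_amplitude > self.adhesion_depth:
            raise InvalidParameterError(
                "corrugation_amplitude must not exceed adhesion_depth"
            )
        if self.well_inverse_width <= 0 or self.corrugation_decay <= 0:
            raise InvalidParameterError("length scales must be > 0")
        if self.shelf_depth < 0 or self.shelf_width <= 0:
            raise InvalidParameterError("invalid shelf parameters")


@dataclass
class TipModel:
    """Harmonic tip–molecule bond retracted at constant speed.

    ``k_tip`` in N m⁻¹ (= nN/nm); ``speed`` is metadata only — the simulator is
    quasi-static.  ``rupture_force`` of ``None`` means an unbreakable bond.
    ``attachment_bead`` is the index of the pulled node; the default is bead 1,
    the node closest to the backbone phosphate between the first two
    nucleotides, so the terminal base hangs below the attachment point and the
    lifted span to the far end is n_bases − 2 repeats.
    """

    k_tip: float = 35.0
    speed: float = 1.0e8  # nm/s; the steered-pulling value 0.1 m/s
    rupture_force: float | None = None
    attachment_bead: int = 1

    def __post_init__(self) -> None:
        if self.k_tip <= 0:
            raise InvalidParameterError("k_tip must be > 0")
        if self.speed <= 0:
            raise InvalidParameterError("speed must be > 0")
        if self.attachment_bead < 0:
            raise InvalidParameterError("attachment_bead must be a valid index")


@dataclass
class ChainConformation:
    """Bead-per-nucleotide conformation of a single-stranded oligomer.

    Each of the ``n_bases - 1`` phosphodiester linkages carries one negative
    unit charge; overall neutrality therefore requires exactly ``n_bases - 1``
    monovalent counterions (19 Na⁺ for a 20-mer).
    """

    positions: np.ndarray  # (n_bases, 3), nm
    b: float  # backbone repeat length, nm
    bond_stiffness: float = 32.6  # per-repeat stiffness of the stretched chain, N/m
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidParameterError("positions must be an (n, 3) array")
        if self.n_bases < 2:
            raise InvalidParameterError("a chain needs at least 2 bases")
        if self.b <= 0:
            raise InvalidParameterError("repeat length b must be > 0")
        if self.bond_stiffness <= 0:
            raise InvalidParameterError("bond_stiffness must be > 0")

    @property
    def n_bases(self) -> int:
        return self.positions.shape[0]

    @property
    def n_links(self) -> int:
        return self.n_bases - 1

    @property
    def link_charges(self) -> np.ndarray:
        """One negative unit charge per phosphodiester linkage."""
        return -np.ones(self.n_links)

    @property
    def contour_length(self) -> float:
        """Fully stretched backbone length, (n_bases − 1)·b."""
        return self.n_links * self.b

    def adsorbed_flags(self, surface: SurfaceModel) -> np.ndarray:
        return self.positions[:, 2] < surface.adsorption_cutoff_height

    def in_plane_extent(self) -> float:
        """Maximal pairwise in-plane distance between beads (nm)."""
        xy = self.positions[:, :2]
        d = xy[:, None, :] - xy[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).max())


def count_counterions(chain: ChainConformation) -> int:
    """Number of monovalent counterions neutralizing the backbone.

    Equal to the number of charged linkages, ``n_bases − 1``.
    """
    return chain.n_links


def build_chain(
    n_bases: int,
    b: float = 0.63,
    seed: int = 0,
    fold: bool = True,
    max_extent: float = 4.0,
    min_separation: float = 0.35,
    bond_stiffness: float = 32.6,
) -> ChainConformation:
    """Generate a folded, adsorbed starting conformation on the surface plane.

    The conformation is a self-avoiding planar walk with fixed step length
    ``b``, confined to a disc of diameter ``max_extent`` so that the in-plane
    extent of the folded oligomer stays well below the contour length —
    emulating the compact ~4-nm adsorbed structures a 20-mer collapses into.
    The walk starts on the *edge* of the confinement disc: the probe picks the
    oligomer up at one extremity of the folded blob, so the adsorbed train
    lies to one side of the pulling axis and the lifted segment stays
    inclined while peeling.  Deterministic for a fixed ``seed``.

    With ``fold=False`` the chain is laid out straight along x.
    """
    if n_bases < 2:
        raise InvalidParameterError("n_bases must be >= 2")
    if b <= 0:
        raise InvalidParameterError("b must be > 0")
    if n_bases == 2 or not fold:
        pts = np.zeros((n_bases, 3))
        pts[:, 0] = b * np.arange(n_bases)
        return ChainConformation(pts, b=b, bond_stiffness=bond_stiffness, seed=seed)

    rng = np.random.default_rng(seed)
    radius = max_extent / 2.0
    center = np.array([radius, 0.0])  # bead 0 sits on the disc boundary
    for _restart in range(200):
        pts = [np.zeros(2)]
        heading = rng.uniform(-np.pi / 3, np.pi / 3)  # walk into the disc
        failed = False
        for _ in range(n_bases - 1):
            # sample a few valid continuations; drift away from the pick-up
            # point so the chain mass lies on the far side of the pulling axis
            cands: list[tuple[np.ndarray, float]] = []
            for _attempt in range(120):
                turn = rng.uniform(-2.4, 2.4)
                cand_heading = heading + turn
                cand = pts[-1] + b * np.array(
                    [np.cos(cand_heading), np.sin(cand_heading)]
                )
                if np.linalg.norm(cand - center) > radius:
                    continue
                # drift outward: successive bases sit no closer to the
                # pick-up point than their predecessor (small slack), so the
                # peel front's lateral offset grows with the lifted length
                # and the lifted segment keeps a steady inclination
                if np.linalg.norm(cand) < np.linalg.norm(pts[-1]) - 0.25:
                    continue
                if len(pts) > 1:
                    prev = np.asarray(pts[:-1])
                    if np.min(np.linalg.norm(prev - cand, axis=1)) < min_separation:
                        continue
                cands.append((cand, cand_heading))
                if len(cands) == 3:
                    break
            if not cands:
                failed = True
                break
            if rng.random() < 0.7:
                pick = max(range(len(cands)), key=lambda j: np.linalg.norm(cands[j][0]))
            else:
                pick = 0
            cand, heading = cands[pick]
            pts.append(cand)
        if not failed:
            xy = np.asarray(pts)
            pos = np.column_stack([xy, np.zeros(len(xy))])
            return ChainConformation(
                pos, b=b, bond_stiffness=bond_stiffness, seed=seed
            )
    raise RuntimeError(
        "self-avoiding walk generation failed; relax max_extent or min_separation"
    )


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------


def energy_and_gradient(
    positions: np.ndarray,
    chain: ChainConformation,
    surface: SurfaceModel,
    tip: TipModel,
    tip_position: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    """Total energy (nN·nm) and gradient (nN) at arbitrary bead positions.

    Terms: harmonic backbone bonds with per-repeat stiffness
    ``chain.bond_stiffness``; per-base Morse adhesion well in height; in-plane
    sinusoidal corrugation decaying with height; 3-D harmonic tip spring on the
    attachment bead (omitted when ``tip_position`` is None).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    grad = np.zeros_like(pos)

    # backbone bonds
    d = pos[1:] - pos[:-1]
    lengths = np.linalg.norm(d, axis=1)
    stretch = lengths - chain.b
    e_bond = 0.5 * chain.bond_stiffness * float(np.sum(stretch**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(lengths[:, None] > 0, d / lengths[:, None], 0.0)
    f_bond = chain.bond_stiffness * stretch[:, None] * unit
    grad[1:] += f_bond
    grad[:-1] -= f_bond

    # per-base adhesion in z: Morse contact well plus Gaussian shelf
    # (the partially-detached intermediate state of a repeat)
    z = pos[:, 2]
    a = surface.well_inverse_width
    D = surface.adhesion_depth
    with np.errstate(over="ignore", invalid="ignore"):
        ez = np.exp(-a * z)
        e_adh = float(np.sum(D * ((1.0 - ez) ** 2 - 1.0)))
        grad[:, 2] += 2.0 * a * D * ez * (1.0 - ez)
    if not np.isfinite(e_adh):  # deep-overlap probe during line search
        e_adh = np.inf
        grad[:, 2] = np.where(np.isfinite(grad[:, 2]), grad[:, 2], -1e30)
    D2, z2, w2 = surface.shelf_depth, surface.shelf_height, surface.shelf_width
    if D2 > 0:
        u = (z - z2) / w2
        shelf = np.exp(-(u**2))
        e_adh += float(np.sum(-D2 * shelf))
        grad[:, 2] += D2 * shelf * 2.0 * u / w2

    # in-plane corrugation: lattice registry in the contact and shelf states
    A = surface.corrugation_amplitude
    if A > 0:
        q = 2.0 * np.pi / surface.lattice_period
        zc = surface.corrugation_decay
        w = np.exp(-((z / zc) ** 2))
        dw = w * (-2.0 * z / zc**2)
        if D2 > 0:
            u = (z - z2) / w2
            ws = np.exp(-(u**2))
            w = w + ws
            dw = dw + ws * (-2.0 * u / w2)
        g = 0.25 * A * (2.0 - np.cos(q * pos[:, 0]) - np.cos(q * pos[:, 1]))
        e_corr = float(np.sum(g * w))
        grad[:, 0] += 0.25 * A * q * np.sin(q * pos[:, 0]) * w
        grad[:, 1] += 0.25 * A * q * np.sin(q * pos[:, 1]) * w
        grad[:, 2] += g * dw
    else:
        e_corr = 0.0

    # tip spring
    e_tip = 0.0
    if tip_position is not None:
        i = tip.attachment_bead
        dr = pos[i] - np.asarray(tip_position, dtype=float)
        e_tip = 0.5 * tip.k_tip * float(dr @ dr)
        grad[i] += tip.k_tip * dr

    return e_bond + e_adh + e_corr + e_tip, grad


def total_energy(
    chain: ChainConformation,
    surface: SurfaceModel,
    tip: TipModel,
    tip_height: float,
    tip_anchor: np.ndarray | None = None,
) -> float:
    """Energy of the conformation with the tip raised by ``tip_height`` (nm).

    The tip sits at ``tip_anchor + (0, 0, tip_height)``; the anchor defaults to
    the current position of the attachment bead, so at ``tip_height = 0`` the
    tip spring is unstretched.
    """
    if tip_anchor is None:
        tip_anchor = chain.positions[tip.attachment_bead]
    tip_pos = np.asarray(tip_anchor, dtype=float) + np.array([0.0, 0.0, tip_height])
    e, _ = energy_and_gradient(chain.positions, chain, surface, tip, tip_pos)
    return e


# ---------------------------------------------------------------------------
# XYZ-style plain-text serialization
# ---------------------------------------------------------------------------


def write_xyz(chain: ChainConformation, path) -> None:
    """Serialize a conformation as XYZ-style text (element tag + coordinates)."""
    lines = [str(chain.n_bases)]
    seed = "none" if chain.seed is None else chain.seed
    lines.append(f"n_bases={chain.n_bases} b={chain.b!r} seed={seed}")
    for p in chain.positions:
        lines.append(f"C {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> ChainConformation:
    with open(path) as fh:
        raw = [ln.strip() for ln in fh if ln.strip()]
    n = int(raw[0])
    meta = dict(kv.split("=", 1) for kv in raw[1].split())
    pos = np.array([[float(x) for x in ln.split()[1:4]] for ln in raw[2 : 2 + n]])
    seed = None if meta.get("seed") in (None, "none") else int(meta["seed"])
    return ChainConformation(pos, b=float(meta["b"]), seed=seed)
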