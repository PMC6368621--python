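"""Quasi-static retraction: signal operations, small-chain oracles, and the
stick-slip phenomenology of the default 20-mer run."""

import numpy as np
import pytest
from scipy.optimize import minimize

import cryopeel as cp
from cryopeel import (
    ChainConformation,
    InvalidParameterError,
    SurfaceModel,
    TipModel,
    Trace,
    build_chain,
    detachment_distance,
    retract,
    smooth_force,
    stiffness_from_force,
    work_energy_residual,
)


class TestSmoothForce:
    def test_constant_force_unchanged(self):
        z = np.linspace(0, 1, 101)
        tr = Trace(Z=z, F=np.full_like(z, 2.0))
        out = smooth_force(tr, 0.05)
        assert np.allclose(out.F, 2.0)

    def test_linear_force_reproduced_exactly(self):
        z = np.linspace(0, 1, 101)
        tr = Trace(Z=z, F=3.0 * z)
        out = smooth_force(tr, 0.05)
        # symmetric (shrunken at the ends) windows keep linear data exact
        assert np.allclose(out.F, tr.F, atol=1e-12)

    def test_single_spike_reduced_to_h_over_window(self):
        z = np.arange(100) * 0.01
        F = np.zeros_like(z)
        F[50] = 1.0
        tr = Trace(Z=z, F=F)
        out = smooth_force(tr, 0.05)  # 5-sample window
        assert out.F[50] == pytest.approx(1.0 / 5.0)

    def test_window_below_grid_step_rejected(self):
        z = np.arange(10) * 0.01
        with pytest.raises(InvalidParameterError):
            smooth_force(Trace(Z=z, F=np.zeros_like(z)), 0.001)


class TestStiffnessFromForce:
    def test_linear_force_gives_constant_stiffness(self):
        z = np.linspace(0, 2, 201)
        tr = Trace(Z=z, F=35.0 * (z - 0.3))
        out = stiffness_from_force(tr)
        assert np.allclose(out.k, 35.0)

    def test_constant_force_gives_zero(self):
        z = np.linspace(0, 2, 201)
        out = stiffness_from_force(Trace(Z=z, F=np.full_like(z, 1.5)))
        assert np.allclose(out.k, 0.0)

    def test_sawtooth_slope_and_negative_spikes(self):
        dz, period, slope = 0.01, 0.5, 8.0
        z = np.arange(0, 3, dz)
        F = slope * (z % period)
        out = stiffness_from_force(Trace(Z=z, F=F))
        drops = np.where(np.diff(F) < 0)[0]
        interior = np.ones(len(z), dtype=bool)
        for i in drops:  # finite differences smear one sample each side
            interior[max(i - 1, 0) : i + 2] = False
        interior[[0, -1]] = False
        assert np.allclose(out.k[interior], slope, atol=1e-9)
        assert np.all(out.k[drops] < 0)  # dips preserved, not clipped

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            stiffness_from_force(Trace(Z=np.array([0.0, 0.1]), F=np.array([0.0, 1.0])))


class TestDetachmentDistance:
    def test_all_zero_force(self):
        z = np.linspace(0, 1, 11)
        assert detachment_distance(Trace(Z=z, F=np.zeros_like(z)), 0.05) == 0.0

    def test_positive_then_exact_zero(self):
        z = np.linspace(0, 10, 101)
        F = np.where(z < 5.0, 1.0, 0.0)
        assert detachment_distance(Trace(Z=z, F=F), 0.05) == pytest.approx(5.0)

    def test_noisy_floor_threshold_scan(self):
        rng = np.random.default_rng(1)
        z = np.round(np.arange(0, 10.01, 0.1), 10)
        F = np.where(z < 7.2, 1.0 + rng.uniform(0, 0.5, len(z)), 0.0)
        F[z >= 7.2] = rng.uniform(-0.01, 0.01, (z >= 7.2).sum())
        tr = Trace(Z=z, F=F)
        # oracle: scan every grid point for the first index after which |F|
        # never exceeds the floor again
        expected = next(
            z[i] for i in range(len(z)) if np.all(np.abs(F[i:]) < 0.05)
        )
        assert expected == pytest.approx(7.2)
        assert detachment_distance(tr, 0.05) == pytest.approx(expected)

    def test_no_detachment_sentinel(self):
        z = np.linspace(0, 1, 11)
        assert detachment_distance(Trace(Z=z, F=np.ones_like(z)), 0.05) is None


def interevent_force_changes(raw, z_lo, z_hi):
    """Net force change of each stretch between dissipative events inside
    [z_lo, z_hi], plus the per-step force changes on those stretches."""
    d = np.diff(raw.F)
    diss = raw.dissipation[1:]
    inside = (raw.Z[1:] >= z_lo) & (raw.Z[1:] <= z_hi)
    events = diss > 1e-4
    nets, steps = [], []
    acc = None
    for i in range(len(d)):
        if not inside[i]:
            acc = None
            continue
        if events[i]:
            if acc is not None:
                nets.append(acc)
            acc = 0.0
            continue
        if acc is None:
            acc = 0.0
        acc += d[i]
        steps.append(d[i])
    if acc is not None:
        nets.append(acc)
    return np.array(nets), np.array(steps)


def smooth_surface(**kw):
    """Surface without corrugation or shelf: single-basin landscape."""
    base = dict(
        corrugation_amplitude=0.0,
        shelf_depth=0.0,
        adhesion_depth=0.1,
        well_inverse_width=2.0,
    )
    base.update(kw)
    return SurfaceModel(**base)


class TestRetractSmallChains:
    def test_zero_adhesion_smooth_rise_to_series_spring(self):
        chain = build_chain(4, 0.63, seed=0, fold=False)
        surf = smooth_surface(adhesion_depth=0.0)
        tip = TipModel(k_tip=35.0, attachment_bead=0)
        tr = retract(
            chain, surf, tip, z_max=2.5, dz=0.02, seed=0, fixed_beads=(3,)
        )
        assert np.all(np.diff(tr.F) > -1e-6)  # no drops without pinning sites
        taut = tr.F > 0.5
        slope = np.gradient(tr.F, tr.Z)[taut]
        k_series = 1.0 / (1.0 / 35.0 + 3.0 / 32.6)
        assert np.all(slope <= k_series + 1e-6)
        assert slope[-1] > 0.5 * k_series  # approaches the series-spring line

    def test_deterministic_for_fixed_seed(self):
        chain = build_chain(5, 0.63, seed=2)
        surf = SurfaceModel()
        tip = TipModel()
        a = retract(chain, surf, tip, z_max=1.0, dz=0.01, seed=3)
        b = retract(chain, surf, tip, z_max=1.0, dz=0.01, seed=3)
        assert np.array_equal(a.F, b.F)

    def test_step_grid_validation(self):
        chain = build_chain(3, 0.63, seed=0)
        with pytest.raises(InvalidParameterError):
            retract(chain, SurfaceModel(), TipModel(), z_max=1.0, dz=0.1)

    def test_work_energy_consistency_small_chain(self):
        chain = build_chain(6, 0.63, seed=4)
        tr = retract(chain, SurfaceModel(), TipModel(), z_max=5.0, dz=0.002, seed=4)
        assert work_energy_residual(tr) < 0.01


def batched_energy(x0z0x1z1x2z2, b, k1, surf, k_tip, tip_x, tip_z):
    """Independent vectorized energy for a 3-bead chain confined to y = 0.

    Written from the model definition (bond + Morse adhesion + tip spring),
    not by calling the package's energy function.
    """
    x0, z0, x1, z1, x2, z2 = x0z0x1z1x2z2
    a, D = surf.well_inverse_width, surf.adhesion_depth
    e = 0.0
    for (xa, za, xb, zb) in [(x0, z0, x1, z1), (x1, z1, x2, z2)]:
        L = np.sqrt((xb - xa) ** 2 + (zb - za) ** 2)
        e = e + 0.5 * k1 * (L - b) ** 2
    for zz in (z0, z1, z2):
        ez = np.exp(-a * zz)
        e = e + D * ((1.0 - ez) ** 2 - 1.0)
    e = e + 0.5 * k_tip * ((x0 - tip_x) ** 2 + (z0 - tip_z) ** 2)
    return e


class TestExhaustiveMinimizationOracle:
    def test_three_bead_trace_matches_global_minimum(self):
        """On a single-basin landscape the warm-started quasi-static trace
        must coincide with exhaustive minimization at every Z."""
        b = 0.63
        surf = smooth_surface()
        tip = TipModel(k_tip=35.0, attachment_bead=0)
        chain = build_chain(3, b, seed=0, fold=False)
        dz = 0.05
        tr = retract(chain, surf, tip, z_max=0.75, dz=dz, seed=0)

        grids = [
            np.linspace(-0.3, 0.9, 11),  # x0
            None,  # z0 set per Z
            np.linspace(0.2, 1.4, 11),  # x1
            None,
            np.linspace(0.8, 2.0, 11),  # x2
            None,
        ]
        for i, z_tip in enumerate(tr.Z):
            zmax = z_tip + 0.3
            zg = np.linspace(-0.1, zmax, 13)
            mesh = np.meshgrid(
                grids[0], zg, grids[2], zg, grids[4], zg, indexing="ij"
            )
            flat = [m.ravel() for m in mesh]
            e = batched_energy(flat, b, 32.6, surf, 35.0, 0.0, z_tip)
            best = np.argmin(e)
            x0 = [f[best] for f in flat]
            res = minimize(
                lambda x: batched_energy(x, b, 32.6, surf, 35.0, 0.0, z_tip),
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 20000},
            )
            F_oracle = 35.0 * (z_tip - res.x[1])
            assert tr.F[i] == pytest.approx(F_oracle, abs=1e-3), f"Z={z_tip}"


class TestDefaultRunPhenomenology:
    """Properties of the reference 20-mer retraction (session fixture)."""

    def test_force_scale_nanonewton_range(self, default_run):
        raw = default_run["raw"]
        mid = (raw.Z > 0.5) & (raw.Z < 10.5)
        assert 0.5 <= raw.F[mid].mean() <= 5.0
        assert raw.F.max() < 10.0

    def test_detachment_events_bounded_by_base_count(self, default_run):
        # cannot detach more bases than exist: one contact-well departure per
        # base, each a discrete event, plus sub-events that do not change the
        # adsorbed count
        raw = default_run["raw"]
        na = raw.n_adsorbed
        assert na[0] == 20 and na[-1] == 0
        # irreversible departures from the contact well (flicker across the
        # adsorption cutoff does not count twice)
        run_min = np.minimum.accumulate(na)
        assert np.sum(np.diff(run_min) < 0) <= 20

    def test_monotone_load_between_events(self, default_run):
        """In the sequential-peeling regime the load builds between events:
        any residual smooth decline is an order of magnitude below the
        event-drop scale.  (The initial correlated-unfolding phase, where the
        force requirement rises and falls non-monotonically, is excluded —
        that is the regime where the experiment ends by premature rupture.)
        """
        raw = default_run["raw"]
        z_off = detachment_distance(raw, 0.05)
        nets, steps = interevent_force_changes(raw, z_lo=1.5, z_hi=z_off)
        assert len(nets) > 20  # plenty of inter-event stretches
        assert min(nets) > -0.1  # net declines far below ~0.5 nN event drops
        assert min(steps) > -0.06  # no hidden drop-sized single steps

    def test_full_detachment_below_contour_length(self, default_run):
        raw = default_run["raw"]
        z_off = detachment_distance(raw, 0.05)
        assert z_off is not None
        assert 0.0 < z_off < default_run["chain"].contour_length

    def test_work_energy_consistency_one_percent(self, default_run):
        assert work_energy_residual(default_run["raw"]) < 0.01

    def test_dip_spacing_in_sub_nanometer_band(self, default_run):
        ev = cp.find_events(default_run["trace"], prominence=2.0)
        st = cp.spacing_stats(ev)
        assert st is not None
        assert 0.2 <= st.mean <= 0.3

    def test_lifted_segment_straight_and_inclined(self, default_run):
        """Once >=8 repeats are lifted the segment is collinear within 5 deg
        and keeps a stable non-zero inclination."""
        tip = default_run["tip"]
        inclinations = []
        for z, pos in default_run["snapshots"]:
            seg = pos[tip.attachment_bead :]
            lifted = seg[seg[:, 2] > 0.45]
            if len(lifted) < 8 or len(lifted) > 18:
                continue
            bonds = np.diff(lifted, axis=0)
            bonds /= np.linalg.norm(bonds, axis=1)[:, None]
            mean_dir = bonds.mean(axis=0)
            mean_dir /= np.linalg.norm(mean_dir)
            angles = np.degrees(np.arccos(np.clip(bonds @ mean_dir, -1, 1)))
            assert np.max(angles) < 5.0
            incl = np.degrees(
                np.arctan2(np.linalg.norm(mean_dir[:2]), abs(mean_dir[2]))
            )
            inclinations.append(incl)
        assert len(inclinations) >= 3
        # the tilt stays in a moderate band while peeling: it neither
        # collapses to vertical (which would overshoot the contour length at
        # detachment) nor flattens out, and averages a few tens of degrees
        assert np.all((np.asarray(inclinations) > 8.0))
        assert np.all((np.asarray(inclinations) < 40.0))
        assert 10.0 < np.mean(inclinations) < 30.0
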