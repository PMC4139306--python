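"""Finite-difference PB solver: media maps, analytic limits, focusing."""

import numpy as np
import pytest

from memesp import GridSpec, StructureModel
from memesp.pb import (
    PBConfig,
    build_media_maps,
    dh_potential_at,
    focus_solve,
    solve,
)


def ion(charge=-1.0, radius=0.5, pos=(0.0, 0.0, 0.0), name="P1"):
    return StructureModel(coords=[pos], charges=[charge], radii=[radius],
                          names=[name], resnames=["ION"], resids=[1],
                          roles={"P1": 0} if name == "P1" else {})


def uniform_cfg(**kw):
    defaults = dict(solute_dielectric=80.0, solvent_dielectric=80.0,
                    ionic_strength=0.1, tolerance=1e-6)
    defaults.update(kw)
    return PBConfig(**defaults)


class TestMediaMaps:
    def test_empty_structure_uniform_maps(self):
        st = StructureModel(coords=np.zeros((0, 3)), charges=[], radii=[],
                            names=[], resnames=[], resids=[])
        cfg = PBConfig()
        spec = GridSpec((8, 8, 8), 1.0)
        maps = build_media_maps(st, spec, cfg)
        assert np.all(maps.dielectric == cfg.solvent_dielectric)
        assert np.allclose(maps.kappa2, cfg.solvent_dielectric * cfg.kappa**2)
        assert np.count_nonzero(maps.charge) == 0

    def test_solute_voxel_count_brute_force(self):
        spec = GridSpec((15, 15, 15), 0.7, (-4.9, -4.9, -4.9))
        cfg = PBConfig()
        # atom centered exactly on a voxel
        center = np.asarray(spec.origin) + 7 * spec.spacing
        maps = build_media_maps(ion(radius=2.0, pos=tuple(center)), spec, cfg)
        x, y, z = spec.meshgrid()
        inside = ((x - center[0])**2 + (y - center[1])**2 + (z - center[2])**2) <= 4.0
        assert np.count_nonzero(maps.dielectric == cfg.solute_dielectric) == inside.sum()
        # screening zeroed within the inflated sphere
        inflated = ((x - center[0])**2 + (y - center[1])**2
                    + (z - center[2])**2) <= (2.0 + cfg.ion_exclusion_radius)**2
        assert np.array_equal(maps.kappa2 == 0.0, inflated)

    def test_charge_conservation(self, rng):
        coords = rng.uniform(-3, 3, size=(10, 3))
        st = StructureModel(coords=coords, charges=rng.normal(size=10),
                            radii=np.full(10, 1.0), names=["X"] * 10,
                            resnames=["UNK"] * 10, resids=np.arange(10))
        maps = build_media_maps(st, GridSpec((12, 12, 12), 1.0, (-5.5, -5.5, -5.5)),
                                PBConfig())
        assert maps.charge.sum() == pytest.approx(st.charges.sum(), abs=1e-9)

    def test_atom_outside_grid_warns_zero_radius_errors(self):
        spec = GridSpec((6, 6, 6), 1.0)
        with pytest.warns(UserWarning, match="outside"):
            maps = build_media_maps(ion(pos=(40.0, 0.0, 0.0)), spec, PBConfig())
        assert maps.charge.sum() == pytest.approx(-1.0)  # clipped, still conserved
        with pytest.raises(ValueError, match="zero-radius"):
            build_media_maps(ion(radius=0.0), spec, PBConfig())


class TestSolve:
    def test_zero_charges_zero_boundary(self):
        st = StructureModel(coords=np.zeros((0, 3)), charges=[], radii=[],
                            names=[], resnames=[], resids=[])
        cfg = PBConfig()
        maps = build_media_maps(st, GridSpec((9, 9, 9), 1.0), cfg)
        g = solve(maps, cfg, boundary="zero")
        assert np.count_nonzero(g.values) == 0

    def test_single_ion_debye_huckel_limit(self):
        cfg = uniform_cfg()
        spec = GridSpec.centered((0, 0, 0), (33, 33, 33), 0.5)
        maps = build_media_maps(ion(), spec, cfg)
        g = solve(maps, cfg)
        x, y, z = spec.meshgrid()
        r = np.sqrt(x**2 + y**2 + z**2)
        exact = dh_potential_at(ion(), np.column_stack([x.ravel(), y.ravel(), z.ravel()]),
                                cfg).reshape(spec.dims)
        sel = (r >= 2.0) & (r <= 6.0)
        rel = np.abs(g.values[sel] - exact[sel]) / np.abs(exact[sel])
        assert rel.max() < 0.05

    def test_superposition_and_sign_flip(self, rng):
        cfg = PBConfig(tolerance=1e-8)
        spec = GridSpec.centered((0, 0, 0), (17, 17, 17), 1.0)

        def solve_for(charges):
            st = StructureModel(coords=[[-2, 0, 0], [2.5, 0.5, 0]], charges=charges,
                                radii=[1.5, 2.0], names=["A", "B"],
                                resnames=["UNK"] * 2, resids=[1, 2])
            return solve(build_media_maps(st, spec, cfg), cfg).values

        pa = solve_for([-1.0, 0.0])
        pb_ = solve_for([0.0, 2.0])
        pab = solve_for([-1.0, 2.0])
        assert np.allclose(pa + pb_, pab, atol=1e-4 * np.abs(pab).max())
        assert np.allclose(solve_for([1.0, -2.0]), -pab, rtol=1e-9, atol=1e-12)

    def test_error_shrinks_with_spacing(self):
        cfg = uniform_cfg()

        def max_rel(spacing, n):
            spec = GridSpec.centered((0, 0, 0), (n, n, n), spacing)
            g = solve(build_media_maps(ion(), spec, cfg), cfg)
            x, y, z = spec.meshgrid()
            r = np.sqrt(x**2 + y**2 + z**2)
            exact = dh_potential_at(
                ion(), np.column_stack([x.ravel(), y.ravel(), z.ravel()]), cfg
            ).reshape(spec.dims)
            sel = (r >= 2.0) & (r <= 6.0)
            return np.max(np.abs(g.values[sel] - exact[sel]) / np.abs(exact[sel]))

        coarse = max_rel(1.0, 17)
        fine = max_rel(0.5, 33)
        assert fine < coarse

    def test_nonlinear_agrees_with_linear_at_small_potential(self):
        spec = GridSpec.centered((0, 0, 0), (25, 25, 25), 0.75)
        lin_cfg = uniform_cfg()
        nl_cfg = uniform_cfg(nonlinear=True)
        maps = build_media_maps(ion(radius=2.0), spec, lin_cfg)
        lin = solve(maps, lin_cfg).values
        nl = solve(maps, nl_cfg).values
        sel = (np.abs(lin) < 0.5) & (np.abs(lin) > 1e-3)
        rel = np.abs(nl[sel] - lin[sel]) / np.abs(lin[sel])
        assert rel.max() < 0.02


class TestFocusing:
    def test_zero_problem_gives_zero_inner(self):
        st = StructureModel(coords=[[0.0, 0.0, 0.0]], charges=[0.0], radii=[1.0],
                            names=["P1"], resnames=["ION"], resids=[1], roles={"P1": 0})
        cfg = PBConfig(outer_dims=(17, 17, 17), outer_spacing=2.0,
                       inner_dims=(17, 17, 17), inner_spacing=0.5)
        g = focus_solve(st, cfg)
        assert np.allclose(g.values, 0.0)
        assert g.metadata["focused"]

    def test_focused_matches_direct_fine_solve(self):
        cfg = PBConfig(outer_dims=(33, 33, 33), outer_spacing=2.0,
                       inner_dims=(33, 33, 33), inner_spacing=0.5,
                       solute_dielectric=2.0)
        st = ion(charge=-3.0, radius=1.9)
        focused = focus_solve(st, cfg)
        inner_spec = GridSpec.centered((0, 0, 0), cfg.inner_dims, cfg.inner_spacing)
        direct = solve(build_media_maps(st, inner_spec, cfg), cfg, boundary="dh_analytic")
        q = len(focused.values) // 4
        interior = (slice(q, -q),) * 3
        mad = np.abs(focused.values[interior] - direct.values[interior]).mean()
        assert mad < 0.05

    def test_default_config_echoes_focusing_protocol(self):
        cfg = PBConfig()
        assert cfg.inner_dims == (201, 201, 201) and cfg.inner_spacing == 0.5
        assert cfg.outer_dims == (271, 271, 222) and cfg.outer_spacing == 2.0

    def test_inner_outside_outer_raises(self):
        cfg = PBConfig(outer_dims=(9, 9, 9), outer_spacing=1.0,
                       inner_dims=(9, 9, 9), inner_spacing=2.0)
        with pytest.raises(ValueError, match="not contained"):
            focus_solve(ion(), cfg)
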