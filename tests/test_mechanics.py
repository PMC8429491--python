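import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from myoregen import generate_synthetic_bundle
from myoregen.mechanics import (
    ActiveParams,
    ConstitutiveParams,
    ECM_PARAMS,
    FIBER_PARAMS,
    MechanicsError,
    StrainField,
    active_tension,
    expand_necrosis,
    export_strain_table,
    fiber_energy,
    fiber_stress_response,
    import_strain_table,
    select_damage,
    surrogate_strain_field,
)
from conftest import make_symmetric_four_fiber_grid


class TestFiberStress:
    def test_zero_below_identity_stretch(self):
        p = ConstitutiveParams()
        assert fiber_stress_response(0.9, p) == 0.0
        assert fiber_stress_response(1.0, p) == 0.0

    def test_toe_branch_closed_form(self):
        # c3 (e^{c4 (lam-1)} - 1) at lam=1.1, c3=2, c4=60 -> 2(e^6 - 1)
        p = ConstitutiveParams(c3=2.0, c4=60.0, lambda_m=1.2)
        expected = 2.0 * (math.exp(6.0) - 1.0)
        assert fiber_stress_response(1.1, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(804.858, abs=1e-3)

    @given(
        c3=st.floats(0.5, 10.0),
        c4=st.floats(5.0, 80.0),
        c5=st.floats(100.0, 1200.0),
        lm=st.floats(1.01, 1.15),
    )
    @settings(max_examples=60, deadline=None)
    def test_continuous_at_branch_points(self, c3, c4, c5, lm):
        p = ConstitutiveParams(c3=c3, c4=c4, c5=c5, lambda_m=lm)
        eps = 1e-9
        at_one = fiber_stress_response(1.0 + eps, p)
        assert abs(at_one) < 1e-4 * max(1.0, c3 * c4)
        below = fiber_stress_response(lm - eps, p)
        above = fiber_stress_response(lm + eps, p)
        scale = max(1.0, abs(below))
        assert abs(above - below) / scale < 1e-5

    def test_negative_stretch_rejected(self):
        with pytest.raises(MechanicsError):
            fiber_stress_response(-1.0, ConstitutiveParams())


class TestFiberEnergy:
    def test_zero_at_and_below_identity(self):
        p = ConstitutiveParams()
        assert fiber_energy(1.0, p) == 0.0
        assert fiber_energy(0.8, p) == 0.0

    def test_energy_matches_quadrature_of_stress(self):
        # F2(lam) = integral from 1 to lam of stress(s)/s ds
        p = ConstitutiveParams(c3=2.0, c4=60.0, lambda_m=1.2)
        val, _ = quad(lambda s: fiber_stress_response(s, p) / s, 1.0, 1.05)
        assert fiber_energy(1.05, p) == pytest.approx(val, rel=1e-6)

    def test_stress_is_lambda_times_energy_derivative(self):
        p = ConstitutiveParams()
        h = 1e-6
        for lam in np.linspace(1.001, p.lambda_m - 0.001, 100):
            dF = (fiber_energy(lam + h, p) - fiber_energy(lam - h, p)) / (2 * h)
            assert lam * dF == pytest.approx(
                fiber_stress_response(lam, p), rel=1e-5
            )

    def test_zero_ei_argument_is_domain_error(self):
        with pytest.raises(MechanicsError):
            fiber_energy(1.05, ConstitutiveParams(c4=0.0))

    def test_c6_continuity_constant(self):
        p = ConstitutiveParams()
        lhs = p.c5 * p.lambda_m + p.c6
        rhs = p.c3 * (math.exp(p.c4 * (p.lambda_m - 1.0)) - 1.0)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestActiveTension:
    def test_zero_at_slack_length(self):
        a = ActiveParams()
        assert active_tension(a.l0, a) == 0.0
        assert active_tension(a.l0 - 0.1, a) == 0.0

    def test_zero_without_activation(self):
        a = ActiveParams(Ct=0.0)
        assert active_tension(2.0, a) == 0.0

    def test_reference_length_value_bounded(self):
        a = ActiveParams(Ct=1.0)
        ta = active_tension(a.refl, a)
        assert 0.0 < ta <= a.Tmax
        # independent evaluation of the elastance formula
        eca50 = a.Ca0_max / math.sqrt(math.exp(a.B * (a.refl - a.l0)) - 1.0)
        expected = a.Tmax * a.Ca0_max**2 / (a.Ca0_max**2 + eca50**2)
        assert ta == pytest.approx(expected, rel=1e-12)

    def test_monotone_on_working_range(self):
        a = ActiveParams()
        lengths = np.linspace(a.l0 + 1e-6, a.refl, 50)
        values = [active_tension(l, a) for l in lengths]
        assert all(v2 >= v1 for v1, v2 in zip(values, values[1:]))

    def test_literal_rendering_flag(self):
        a = ActiveParams()
        lit = active_tension(2.0, a, literal_eca50=True)
        std = active_tension(2.0, a)
        assert lit != std and 0.0 <= lit <= a.Tmax


class TestSurrogateStrain:
    def test_symmetric_bundle_gives_symmetric_field(self):
        g = make_symmetric_four_fiber_grid()
        fld = surrogate_strain_field(g, noise_sigma=0.0, seed=0)
        v = fld.values
        assert np.allclose(v, v[::-1, :], atol=1e-12)
        assert np.allclose(v, v[:, ::-1], atol=1e-12)

    def test_corner_fiber_strains_exceed_center(self, bundle):
        fld = surrogate_strain_field(bundle, seed=0)
        centroids = {}
        for fid in range(1, 21):
            ys, xs = np.nonzero(bundle.fiber_id == fid)
            centroids[fid] = (xs.mean(), ys.mean())
        cx = bundle.width / 2, bundle.height / 2
        dist = {f: math.hypot(c[0] - cx[0], c[1] - cx[1])
                for f, c in centroids.items()}
        corner = max(dist, key=dist.get)
        center = min(dist, key=dist.get)
        mean = lambda f: fld.values[bundle.fiber_id == f].mean()
        assert mean(corner) > mean(center)

    def test_c5_softening_raises_max_strain(self, bundle):
        base = surrogate_strain_field(bundle, seed=0)
        soft = surrogate_strain_field(
            bundle, seed=0,
            p_fiber=FIBER_PARAMS.replace(c5=0.9 * FIBER_PARAMS.c5),
            p_ecm=ECM_PARAMS.replace(c5=0.9 * ECM_PARAMS.c5),
        )
        stiff = surrogate_strain_field(
            bundle, seed=0,
            p_fiber=FIBER_PARAMS.replace(c5=1.1 * FIBER_PARAMS.c5),
            p_ecm=ECM_PARAMS.replace(c5=1.1 * ECM_PARAMS.c5),
        )
        assert soft.max() > base.max() > stiff.max()

    def test_rejects_fibril_free_grid(self, bundle):
        g = bundle.copy()
        g.fiber_id[:] = 0
        with pytest.raises(MechanicsError):
            surrogate_strain_field(g)


class TestImportStrain:
    def test_identity_table_round_trips(self, small_bundle, tmp_path):
        fld = surrogate_strain_field(small_bundle, seed=4)
        path = tmp_path / "strain.csv"
        export_strain_table(fld, path)
        back = import_strain_table(path, small_bundle)
        assert np.allclose(back.values, fld.values)

    def test_single_center_gives_uniform_field(self, small_bundle, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("x,y,strain\n5,5,0.42\n")
        fld = import_strain_table(path, small_bundle)
        assert np.allclose(fld.values[fld.mask], 0.42)

    def test_two_centers_split_at_bisector(self, small_bundle, tmp_path):
        g = small_bundle
        x1, x2 = 2, g.width - 3
        ymid = g.height // 2
        path = tmp_path / "two.csv"
        path.write_text(f"x,y,strain\n{x1},{ymid},0.1\n{x2},{ymid},0.9\n")
        fld = import_strain_table(path, g)
        ys, xs = np.nonzero(g.fibril_mask)
        for x, y in zip(xs, ys):
            d1 = (x - x1) ** 2 + (y - ymid) ** 2
            d2 = (x - x2) ** 2 + (y - ymid) ** 2
            expected = 0.1 if d1 < d2 else (0.9 if d2 < d1 else fld.values[y, x])
            assert fld.values[y, x] == pytest.approx(expected)

    def test_empty_table_errors(self, small_bundle, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("x,y,strain\n")
        with pytest.raises(MechanicsError, match="empty"):
            import_strain_table(path, small_bundle)

    def test_out_of_bounds_centers_listed(self, small_bundle, tmp_path):
        path = tmp_path / "oob.csv"
        path.write_text("x,y,strain\n5,5,0.1\n9999,2,0.2\n")
        with pytest.raises(MechanicsError, match="rows 1"):
            import_strain_table(path, small_bundle)


class TestSelectDamage:
    def test_exact_cardinality_and_top_strains(self, small_bundle):
        fld = surrogate_strain_field(small_bundle, seed=2)
        n_fib = small_bundle.fibril_count
        chosen = select_damage(fld, small_bundle, 0.10)
        assert len(chosen) == math.ceil(0.10 * n_fib)
        cutoff = min(fld.values[y, x] for x, y in chosen)
        ys, xs = np.nonzero(small_bundle.fibril_mask)
        higher = sum(fld.values[y, x] > cutoff for x, y in zip(xs, ys))
        assert higher <= len(chosen)

    def test_zero_fraction_is_empty(self, small_bundle):
        fld = surrogate_strain_field(small_bundle, seed=2)
        assert select_damage(fld, small_bundle, 0.0) == set()

    def test_ties_break_in_row_major_order(self, small_bundle):
        g = small_bundle
        uniform = StrainField(
            values=np.where(g.fibril_mask, 1.0, 0.0),
            mask=g.fibril_mask.copy(),
        )
        n = math.ceil(0.05 * g.fibril_count)
        chosen = select_damage(uniform, g, 0.05)
        ys, xs = np.nonzero(g.fibril_mask)
        expected = set(
            (int(x), int(y)) for x, y in
            sorted(zip(xs, ys), key=lambda p: (p[1], p[0]))[:n]
        )
        assert chosen == expected


class TestExpandNecrosis:
    def test_interior_seed_gains_von_neumann_halo(self, small_bundle):
        g = small_bundle.copy()
        # find an interior fibril pixel whose 4-neighbors are all fibril
        ys, xs = np.nonzero(g.fibril_mask)
        seed = None
        for x, y in zip(xs, ys):
            nbrs = [(x, y - 1), (x + 1, y), (x, y + 1), (x - 1, y)]
            if all(g.fiber_id[ny, nx] > 0 for nx, ny in nbrs):
                seed, nbrs_found = (x, y), nbrs
                break
        out = expand_necrosis(g, {seed})
        assert out == {seed, *nbrs_found}
        assert g.damaged[seed[1], seed[0]]

    def test_edge_seed_clips_to_occupied(self):
        g = generate_synthetic_bundle(1, 100, 0.3, seed=0)
        ys, xs = np.nonzero(g.fibril_mask)
        # a fibril pixel adjacent to the canvas-border ECM ring
        x, y = int(xs[0]), int(ys[0])
        out = expand_necrosis(g, {(x, y)})
        assert (x, y) in out
        assert all(g.occupied[yy, xx] for xx, yy in out)

    def test_adjacent_seeds_union_is_eight_pixels(self, small_bundle):
        g = small_bundle.copy()
        ys, xs = np.nonzero(g.fibril_mask)
        seed = None
        for x, y in zip(xs, ys):
            box = [(x + dx, y + dy) for dx in (-1, 0, 1, 2) for dy in (-1, 0, 1)]
            if all(g.fiber_id[ny, nx] > 0 for nx, ny in box):
                seed = (x, y)
                break
        s1, s2 = seed, (seed[0] + 1, seed[1])
        oracle = set()
        for sx, sy in (s1, s2):
            oracle.add((sx, sy))
            oracle.update([(sx, sy - 1), (sx + 1, sy), (sx, sy + 1), (sx - 1, sy)])
        out = expand_necrosis(g, {s1, s2})
        assert out == oracle
        assert len(out) == 8

    def test_idempotent_without_new_seeds(self, small_bundle):
        g = small_bundle.copy()
        ys, xs = np.nonzero(g.fibril_mask)
        first = expand_necrosis(g, {(int(xs[40]), int(ys[40]))})
        again = expand_necrosis(g, first)
        assert again == first

    def test_ecm_neighbors_lose_collagen(self, small_bundle):
        g = small_bundle.copy()
        border = g.fibril_mask & np.roll(g.ecm, 1, axis=0)
        ys, xs = np.nonzero(border)
        x, y = int(xs[0]), int(ys[0])
        out = expand_necrosis(g, {(x, y)})
        ecm_members = [(xx, yy) for xx, yy in out if g.ecm[yy, xx]]
        assert ecm_members
        for xx, yy in ecm_members:
            assert g.collagen[yy, xx] == pytest.approx(0.2)


class TestSensitivityOrdering:
    def test_c5_dominates_surrogate_sensitivity(self, bundle):
        from myoregen import material_sensitivity

        table = material_sensitivity(bundle, seed=0)
        mags = (
            table.assign(mag=table.pct_change_max_strain.abs())
            .groupby("parameter")["mag"].max()
        )
        assert mags["c5"] > mags.drop("c5").max()
        assert mags["density"] == 0.0
        c5 = table[table.parameter == "c5"]
        up = c5[c5.delta > 0].pct_change_max_strain.iloc[0]
        down = c5[c5.delta < 0].pct_change_max_strain.iloc[0]
        assert up < 0 < down
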