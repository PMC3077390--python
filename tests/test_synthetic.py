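"""Phantom generator, forward signal model, and cohort construction."""

import numpy as np
import pytest

import limbictract as lt
from limbictract.synthetic import (CohortSpec, arc_centerline, design_matrix,
                                   simulate_profile_cohort, straight_centerline)


class TestGradientScheme:
    def test_default_acquisition_layout(self, scheme):
        """One b=0 baseline plus 15 diffusion-weighted volumes at b=800."""
        assert scheme.n_volumes == 16
        assert int((scheme.bvalues == 800.0).sum()) == 15
        assert int(scheme.b0_mask.sum()) == 1

    def test_directions_unit_norm_and_spread(self, scheme):
        dirs = scheme.directions[~scheme.b0_mask]
        norms = np.linalg.norm(dirs, axis=1)
        assert np.all(np.abs(norms - 1.0) <= 1e-6)
        # exhaustive pairwise angle check: a usable DTI set is well spread
        min_angle = 180.0
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                c = np.clip(np.dot(dirs[i], dirs[j]), -1, 1)
                min_angle = min(min_angle, np.degrees(np.arccos(c)))
        assert min_angle > 20.0

    def test_roundtrip_through_fsl_files(self, scheme, tmp_path):
        scheme.save(tmp_path / "x.bvec", tmp_path / "x.bval")
        back = lt.GradientScheme.load(tmp_path / "x.bvec", tmp_path / "x.bval")
        assert np.allclose(back.directions, scheme.directions, atol=1e-7)
        assert np.allclose(back.bvalues, scheme.bvalues)

    def test_rejects_collinear_directions(self):
        dirs = np.vstack([np.zeros(3)] + [[1.0, 0.0, 0.0]] * 6)
        with pytest.raises(ValueError, match="collinear"):
            lt.GradientScheme(directions=dirs, bvalues=[0] + [800] * 6)

    def test_rejects_missing_baseline(self):
        dirs = lt.default_scheme().directions[1:]
        with pytest.raises(ValueError, match="baseline"):
            lt.GradientScheme(directions=dirs, bvalues=[800.0] * 15)


class TestMakePhantom:
    def test_straight_tube_principal_axis(self, tube):
        """Inside a straight x-axis tube the principal eigenvector is x."""
        evals, evecs = lt.eigendecompose(tube["tensors"].coeffs[tube["mask"]])
        e1 = evecs[..., :, 0]
        assert np.allclose(np.abs(e1[:, 0]), 1.0, atol=1e-10)
        assert np.allclose(evals, np.array([1.5e-3, 0.3e-3, 0.3e-3]), atol=1e-12)

    def test_outside_is_isotropic(self, tube):
        fa = tube["maps"]["fa"].data
        assert np.max(fa[~tube["mask"]]) < 1e-9

    def test_curved_tube_tangent_continuity(self):
        """Adjacent along-tube voxels of a wide arc differ by < 5 degrees."""
        cl = arc_centerline(center=(40, 10, 12), radius=28.0,
                            theta0=np.pi * 0.15, theta1=np.pi * 0.85)
        spec = lt.PhantomSpec(grid_shape=(40, 28, 12), voxel_size=(2, 2, 2),
                              centerline=cl, tube_radius=3.0)
        tensors, mask, truth = lt.make_phantom(spec)
        e1 = lt.principal_directions(tensors)
        frac = truth["voxel_arc_fraction"]
        # order tube voxels along the tube and compare successive axes
        idx = np.argwhere(mask)
        order = np.argsort(frac[mask])
        axes = e1[tuple(idx[order].T)]
        cos = np.abs(np.einsum("ij,ij->i", axes[:-1], axes[1:]))
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert angles.max() < 5.0

    def test_tube_exiting_grid_is_rejected(self):
        cl = straight_centerline([0.0, 16.0, 16.0], [80.0, 16.0, 16.0])
        with pytest.raises(ValueError, match="exits the grid"):
            lt.make_phantom(lt.PhantomSpec(grid_shape=(40, 16, 16),
                                           voxel_size=(2, 2, 2), centerline=cl))

    def test_invalid_eigenvalue_order_rejected(self):
        with pytest.raises(ValueError):
            lt.PhantomSpec(inside_eigenvalues=(0.3e-3, 1.5e-3, 0.3e-3))


class TestSimulateDwi:
    def test_baseline_equals_s0(self, tube, scheme):
        b0 = tube["dwi"][..., scheme.b0_mask][..., 0]
        assert np.allclose(b0, 1000.0, atol=1e-9)

    def test_isotropic_signal_direction_independent(self, scheme):
        d = 0.7e-3
        grid = lt.ImageGrid(shape=(3, 3, 3), voxel_size=(1, 1, 1))
        coeffs = np.zeros((3, 3, 3, 6))
        coeffs[..., :3] = d
        sig = lt.simulate_dwi(lt.TensorVolume(coeffs=coeffs, grid=grid), scheme,
                              s0=1000.0)
        dw = sig[..., ~scheme.b0_mask]
        expected = 1000.0 * np.exp(-800.0 * d)
        # directions are unit to ~1e-8, so b*d*|g|^2 carries that error
        assert np.allclose(dw, expected, rtol=1e-7)

    def test_known_attenuation_along_principal_axis(self):
        """diag(1.5,0.3,0.3)e-3, g=x, b=800, s0=1000 -> 1000 exp(-1.2)."""
        grid = lt.ImageGrid(shape=(1, 1, 1), voxel_size=(1, 1, 1))
        coeffs = np.array([[[[1.5e-3, 0.3e-3, 0.3e-3, 0, 0, 0]]]])
        sch = lt.GradientScheme(
            directions=np.array([[0, 0, 0], [1, 0, 0]] + [[0, 1, 0], [0, 0, 1],
                                [0.70710678, 0.70710678, 0], [0.70710678, 0, 0.70710678],
                                [0, 0.70710678, 0.70710678],
                                [0.57735027, 0.57735027, 0.57735027]]),
            bvalues=[0] + [800] * 7,
        )
        sig = lt.simulate_dwi(lt.TensorVolume(coeffs=coeffs, grid=grid), sch, s0=1000.0)
        assert sig[0, 0, 0, 1] == pytest.approx(1000.0 * np.exp(-1.2), rel=1e-12)
        assert sig[0, 0, 0, 1] == pytest.approx(301.19, abs=0.01)

    def test_log_signal_identity(self, tube, scheme):
        """Noise-free log(S/S0) equals -b g^T D g to machine precision."""
        B = design_matrix(scheme.directions, scheme.bvalues)
        q = np.einsum("...c,nc->...n", tube["tensors"].coeffs, B)
        assert np.allclose(np.log(tube["dwi"] / 1000.0), -q, atol=1e-12)

    def test_noise_reproducible_and_nonnegative(self, tube, scheme):
        a = lt.simulate_dwi(tube["tensors"], scheme, s0=1000.0, noise_sigma=0.05, seed=3)
        b = lt.simulate_dwi(tube["tensors"], scheme, s0=1000.0, noise_sigma=0.05, seed=3)
        c = lt.simulate_dwi(tube["tensors"], scheme, s0=1000.0, noise_sigma=0.05, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.all(a >= 0)  # Rician magnitude signal

    def test_invalid_inputs_rejected(self, tube, scheme):
        with pytest.raises(ValueError):
            lt.simulate_dwi(tube["tensors"], scheme, s0=-1.0)
        with pytest.raises(ValueError):
            lt.simulate_dwi(tube["tensors"], scheme, s0=1000.0, noise_sigma=-0.1)


class TestMakeCohort:
    def test_default_group_sizes(self):
        """The emulated sample: 31 controls and 33 patients, 64 records."""
        cohort = lt.make_cohort(lt.PhantomSpec(), CohortSpec(seed=1))
        assert len(cohort.subjects) == 64
        counts = cohort.subjects["group"].value_counts()
        assert counts["control"] == 31 and counts["patient"] == 33

    def test_null_effect_groups_identical_given_subject(self):
        """With effect_delta = 0, patient status does not alter the field."""
        spec = lt.PhantomSpec(effect_delta=0.0)
        t_pat, _, _ = lt.make_phantom(spec, effect_delta=0.0, radial_shift=1e-5)
        t_con, _, _ = lt.make_phantom(spec, effect_delta=0.0, radial_shift=1e-5)
        assert np.array_equal(t_pat.coeffs, t_con.coeffs)

    def test_effect_confined_to_segment(self):
        """Patient and control tensors agree outside the effect segment."""
        spec = lt.PhantomSpec(effect_segment=(0.4, 0.6), effect_delta=0.3e-3)
        t_con, mask, truth = lt.make_phantom(spec, effect_delta=0.0)
        t_pat, _, _ = lt.make_phantom(spec)
        frac = truth["voxel_arc_fraction"]
        outside = mask & ((frac < 0.4) | (frac > 0.6))
        inside = mask & (frac >= 0.4) & (frac <= 0.6)
        assert np.array_equal(t_pat.coeffs[outside], t_con.coeffs[outside])
        assert not np.array_equal(t_pat.coeffs[inside], t_con.coeffs[inside])

    def test_excessive_effect_delta_rejected(self):
        with pytest.raises(ValueError, match="effect_delta"):
            lt.PhantomSpec(effect_delta=1.5e-3)

    def test_negative_coupling_gives_negative_correlation(self):
        """PANSS coupled negatively to locus FA: the generated scores must
        correlate negatively with true locus FA in a large draw."""
        cohort = lt.make_cohort(
            lt.PhantomSpec(effect_delta=0.0),
            CohortSpec(n_control=2, n_patient=1000, seed=11,
                       panss_coupling={"panss_total": -0.6}),
        )
        pats = cohort.subjects[cohort.subjects["group"] == "patient"]
        r = np.corrcoef(pats["fa_locus_true"], pats["panss_total"])[0, 1]
        assert r < -0.4

    def test_determinism_under_seed(self):
        a = lt.make_cohort(lt.PhantomSpec(), CohortSpec(seed=5, n_control=3, n_patient=3))
        b = lt.make_cohort(lt.PhantomSpec(), CohortSpec(seed=5, n_control=3, n_patient=3))
        assert a.subjects.equals(b.subjects)
        sid = a.subjects["id"].iloc[0]
        assert np.array_equal(a.subject_dwi(sid), b.subject_dwi(sid))

    def test_covariates_follow_group_distributions(self):
        cohort = lt.make_cohort(lt.PhantomSpec(),
                                CohortSpec(n_control=400, n_patient=400, seed=2))
        s = cohort.subjects
        con = s[s["group"] == "control"]
        pat = s[s["group"] == "patient"]
        assert con["duration"].eq(0).all()
        assert con["age"].mean() == pytest.approx(35.4, abs=1.5)
        assert pat["age"].mean() == pytest.approx(39.4, abs=1.5)
        assert pat["education"].mean() == pytest.approx(11.6, abs=0.5)
        assert con["panss_total"].isna().all()
        assert pat["panss_total"].notna().all()


class TestProfileCohort:
    def test_shapes_and_determinism(self):
        p1, s1, t1 = simulate_profile_cohort(CohortSpec(seed=9))
        p2, s2, t2 = simulate_profile_cohort(CohortSpec(seed=9))
        assert len(s1) == 64 and len(p1) == 64 * 30
        assert p1.equals(p2) and s1.equals(s2)

    def test_effect_localized_in_mean_difference(self):
        p, s, truth = simulate_profile_cohort(
            CohortSpec(seed=21, n_control=400, n_patient=400), effect_d=1.2)
        wide = p.pivot(index="subject", columns="point", values="value")
        groups = s.set_index("id")["group"]
        diff = (wide.loc[groups == "patient"].mean()
                - wide.loc[groups == "control"].mean())
        lo, hi = truth["effect_points"]
        assert diff[list(range(lo, hi + 1))].max() < -0.03  # FA down in segment
        outside = [j for j in range(30) if j < lo or j > hi]
        assert diff[outside].abs().max() < 0.01

    def test_coupling_produces_raw_profile_correlation(self):
        p, s, truth = simulate_profile_cohort(
            CohortSpec(seed=33, n_control=2, n_patient=2000,
                       panss_coupling={"panss_total": -0.6}))
        wide = p.pivot(index="subject", columns="point", values="value")
        pats = s[s["group"] == "patient"].set_index("id")
        x = wide.loc[pats.index, truth["locus"]]
        r = np.corrcoef(x, pats["panss_total"])[0, 1]
        assert r == pytest.approx(-0.6, abs=0.06)

    def test_unattainable_coupling_rejected(self):
        with pytest.raises(ValueError, match="unattainable"):
            simulate_profile_cohort(
                CohortSpec(seed=1, panss_coupling={"panss_total": -0.9}),
                subject_icc=0.4)
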