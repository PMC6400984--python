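"""FCLS unmixing: exact recovery, oracle equivalence, constraint
satisfaction, and plot-level aggregation."""

import numpy as np
import pytest

from paddysma import AbundanceMap, BandSet, EndmemberLibrary, MultibandImage, \
    PlotLayout, PlotROI, aggregate_abundance, fcls_pixel, unmix_image
from paddysma.raster import KIND_DN, KIND_REFLECTANCE
from paddysma.unmix import UnmixingError
from .oracles import grid_min_objective


def _objective(spectrum, library, a):
    r = spectrum - library.matrix.T @ a
    return float(r @ r)


class TestFclsPixel:
    def test_pure_pixel_gives_abundance_one(self, library):
        for name in library.names:
            a, resid = fcls_pixel(library.row(name), library)
            assert a[library.names.index(name)] == pytest.approx(1.0, abs=1e-9)
            assert resid < 1e-9

    def test_exact_binary_mixture(self, library):
        spec = 0.5 * library.row("TL") + 0.5 * library.row("DS")
        a, resid = fcls_pixel(spec, library)
        expect = {"TL": 0.5, "DS": 0.5}
        for name, ai in zip(library.names, a):
            assert ai == pytest.approx(expect.get(name, 0.0), abs=1e-9)
        assert resid < 1e-9

    @pytest.mark.parametrize("n_em,step", [(3, 0.01), (6, 0.02)])
    def test_noisy_spectra_beat_simplex_grid_oracle(self, library, n_em, step):
        rng = np.random.default_rng(12)
        sub = EndmemberLibrary(names=library.names[:n_em],
                               matrix=library.matrix[:n_em], bands=library.bands)
        for _ in range(20):
            w = rng.dirichlet(np.ones(n_em))
            spec = w @ sub.matrix + rng.normal(0, 0.005, size=6)
            a, resid = fcls_pixel(spec, sub)
            assert resid ** 2 <= grid_min_objective(spec, sub.matrix, step) + 1e-6
            assert a.min() >= -1e-9 and abs(a.sum() - 1) < 1e-9

    def test_permutation_equivariance(self, library):
        rng = np.random.default_rng(5)
        spec = rng.dirichlet(np.ones(6)) @ library.matrix + rng.normal(0, 0.01, 6)
        a, _ = fcls_pixel(spec, library)
        perm = [3, 1, 5, 0, 2, 4]
        plib = EndmemberLibrary(names=tuple(library.names[i] for i in perm),
                                matrix=library.matrix[perm], bands=library.bands)
        ap, _ = fcls_pixel(spec, plib)
        assert np.allclose(ap, a[perm], atol=1e-8)

    def test_matches_unconstrained_fit_when_feasible(self, library):
        # interior mixture: the sum-to-one-only LS solution is feasible,
        # so FCLS must attain the same residual
        rng = np.random.default_rng(8)
        for _ in range(10):
            w = rng.dirichlet(np.full(6, 20.0))  # well inside the simplex
            spec = w @ library.matrix + rng.normal(0, 1e-4, 6)
            a, resid = fcls_pixel(spec, library)
            # sum-to-one-only LS via KKT system
            E = library.matrix
            G = E @ E.T
            kkt = np.block([[2 * G, np.ones((6, 1))], [np.ones((1, 6)), np.zeros((1, 1))]])
            rhs = np.concatenate([2 * E @ spec, [1.0]])
            sol = np.linalg.solve(kkt, rhs)[:6]
            if sol.min() >= 0:
                ls_resid = np.linalg.norm(spec - E.T @ sol)
                assert resid == pytest.approx(ls_resid, abs=1e-6)

    def test_input_validation(self, library):
        with pytest.raises(UnmixingError, match="two endmembers"):
            fcls_pixel(np.zeros(6), EndmemberLibrary(
                names=("TL",), matrix=library.matrix[:1], bands=library.bands))
        with pytest.raises(UnmixingError, match="finite"):
            fcls_pixel(np.full(6, np.nan), library)
        with pytest.raises(UnmixingError, match="shape"):
            fcls_pixel(np.zeros(4), library)


class TestUnmixImage:
    def test_constant_endmember_image(self, library):
        img = MultibandImage(values=np.broadcast_to(library.row("TP"), (3, 4, 6)).copy(),
                             bands=library.bands, kind=KIND_REFLECTANCE)
        out = unmix_image(img, library)
        assert out.values.shape == (3, 4, 6)
        assert np.allclose(out.plane("TP"), 1.0, atol=1e-9)

    def test_agrees_with_per_pixel_solver(self, library):
        rng = np.random.default_rng(2)
        vals = rng.dirichlet(np.ones(6), size=(4, 5)) @ library.matrix \
            + rng.normal(0, 0.005, size=(4, 5, 6))
        img = MultibandImage(values=vals, bands=library.bands, kind=KIND_REFLECTANCE)
        out = unmix_image(img, library)
        out.validate()
        for i in range(4):
            for j in range(5):
                a, r = fcls_pixel(vals[i, j], library)
                assert np.allclose(out.values[i, j], a, atol=1e-10)
                assert out.residual_norm[i, j] == pytest.approx(r, abs=1e-10)

    def test_zero_noise_scene_recovers_truth(self, noiseless_scene, library):
        out = unmix_image(noiseless_scene.reflectance_image, noiseless_scene.library)
        rois = noiseless_scene.layout.plots
        r0, c0, nr, nc = rois[0].rect
        err = np.abs(out.values[r0:r0 + nr, c0:c0 + nc]
                     - noiseless_scene.true_abundance.values[r0:r0 + nr, c0:c0 + nc])
        assert err.max() < 1e-6

    def test_kind_and_band_checks(self, library):
        dn = MultibandImage(values=np.zeros((2, 2, 6)), bands=library.bands,
                            kind=KIND_DN)
        with pytest.raises(UnmixingError, match="reflectance"):
            unmix_image(dn, library)
        img4 = MultibandImage(values=np.zeros((2, 2, 4)),
                              bands=BandSet(centers=(490., 550., 670., 720.)),
                              kind=KIND_REFLECTANCE)
        with pytest.raises(UnmixingError, match="bands"):
            unmix_image(img4, library)


class TestAggregation:
    def _map(self, values, names=("TL", "BL", "TP", "BP", "DS", "WS")):
        return AbundanceMap(values=values,
                            residual_norm=np.zeros(values.shape[:2]), names=names)

    def test_uniform_map_gives_constants(self):
        const = np.array([0.60, 0.33, 0.03, 0.01, 0.02, 0.01])
        amap = self._map(np.broadcast_to(const, (6, 8, 6)).copy())
        layout = PlotLayout(plots=[PlotROI("p1", 0.0, (1, 1, 4, 5))])
        t = aggregate_abundance(amap, layout)
        assert t.loc[0, "TL"] == pytest.approx(0.60)
        assert t.loc[0, "Abd_L"] == pytest.approx(0.93)   # 0.60 + 0.33
        assert t.loc[0, "Abd_P"] == pytest.approx(0.04)
        assert t.loc[0, "Abd_L-P"] == pytest.approx(0.89)

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.dirichlet(np.ones(6), size=(10, 12))
        amap = self._map(vals)
        layout = PlotLayout(plots=[PlotROI("a", 0.0, (2, 3, 5, 6)),
                                   PlotROI("b", 3.0, (0, 0, 4, 4))])
        t = aggregate_abundance(amap, layout).set_index("plot_id")
        # oracle: direct masked means
        for pid, (r0, c0, nr, nc) in [("a", (2, 3, 5, 6)), ("b", (0, 0, 4, 4))]:
            sub = vals[r0:r0 + nr, c0:c0 + nc]
            assert t.loc[pid, "TL"] == pytest.approx(sub[:, :, 0].mean(), abs=1e-12)
            assert t.loc[pid, "Abd_L"] == pytest.approx(
                sub[:, :, 0].mean() + sub[:, :, 1].mean(), abs=1e-12)

    def test_abundance_closure_per_plot(self, small_scene):
        t = small_scene.true_plot_table
        soil = t["DS"] + t["WS"]
        assert np.allclose(t["Abd_L"] + t["Abd_P"] + soil, 1.0, atol=1e-6)
        assert t["Abd_L-P"].between(-1, 1).all()

    def test_out_of_bounds_roi_rejected(self):
        amap = self._map(np.full((4, 4, 6), 1 / 6))
        layout = PlotLayout(plots=[PlotROI("p", 0.0, (2, 2, 5, 5))])
        with pytest.raises(ValueError, match="outside"):
            aggregate_abundance(amap, layout)

    def test_duplicate_plot_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PlotLayout(plots=[PlotROI("p", 0.0, (0, 0, 2, 2)),
                              PlotROI("p", 3.0, (2, 2, 2, 2))])
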