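import numpy as np
import pytest
from sklearn.decomposition import PCA

from varidyn import (
    call_pc_shift,
    displacement_field,
    fit_modes,
    project,
    superpose_ensemble,
)
from varidyn import synthetic as syn
from varidyn.modes import ProjectionSeries
from varidyn.structure_io import TrajectoryEnsemble


@pytest.fixture(scope="module")
def fitted_ensemble(template, planted_modes, chain_a_sel):
    sc = syn.VariantScenario(name="WT", seed=20, n_frames=2000)
    modes = syn.default_planted_modes(noise_sd=0.05)
    ens = syn.sample_ensemble(template, modes, sc)
    return superpose_ensemble(ens, template, chain_a_sel), modes


class TestFitModes:
    def test_identical_frames_have_zero_variance(self, template, chain_b_sel):
        frames = np.tile(template.coordinates, (5, 1, 1))
        ens = TrajectoryEnsemble(atoms=template.atoms, frames=frames)
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        assert np.allclose(basis.eigenvalues, 0.0, atol=1e-12)

    def test_planted_modes_recovered(self, fitted_ensemble, chain_b_sel):
        ens, modes = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        for k in range(3):
            cos = abs(basis.eigenvectors[k] @ modes.mode_vectors[k])
            assert cos >= 0.99
            assert basis.eigenvalues[k] == pytest.approx(modes.mode_sds[k] ** 2, rel=0.15)

    def test_total_variance_equals_covariance_trace(self, fitted_ensemble, chain_b_sel):
        ens, _ = fitted_ensemble
        x = ens.frames[:, chain_b_sel.resolved_indices, :].reshape(ens.n_frames, -1)
        trace = np.cov(x, rowvar=False).trace()
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        assert basis.total_variance == pytest.approx(trace, abs=1e-6)

    def test_matches_sklearn_pca(self, fitted_ensemble, chain_b_sel):
        ens, _ = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        x = ens.frames[:, chain_b_sel.resolved_indices, :].reshape(ens.n_frames, -1)
        ref = PCA(n_components=3).fit(x)
        for k in range(3):
            assert abs(basis.eigenvectors[k] @ ref.components_[k]) == pytest.approx(1.0, abs=1e-8)
            assert basis.eigenvalues[k] == pytest.approx(ref.explained_variance_[k], rel=1e-8)

    def test_frame_order_permutation_invariant(self, fitted_ensemble, chain_b_sel):
        ens, _ = fitted_ensemble
        rng = np.random.default_rng(0)
        shuffled = TrajectoryEnsemble(
            atoms=ens.atoms, frames=ens.frames[rng.permutation(ens.n_frames)]
        )
        a = fit_modes(ens, chain_b_sel, n_modes=3)
        b = fit_modes(shuffled, chain_b_sel, n_modes=3)
        assert np.allclose(a.eigenvectors, b.eigenvectors, atol=1e-8)

    def test_single_frame_rejected(self, template, chain_b_sel):
        ens = TrajectoryEnsemble(atoms=template.atoms, frames=template.coordinates[None])
        with pytest.raises(ValueError, match="at least 2"):
            fit_modes(ens, chain_b_sel)


class TestProject:
    def test_fitting_pool_centered(self, fitted_ensemble, chain_b_sel):
        ens, _ = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        proj = project(ens, basis, chain_b_sel)
        assert np.abs(proj.scores.mean(axis=0)).max() <= 1e-6

    def test_unit_displacement_along_mode(self, fitted_ensemble, chain_b_sel, template):
        ens, _ = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        frame = np.array(template.coordinates)[None].repeat(1, axis=0).copy()
        flat = basis.mean_conformation + 2.0 * basis.eigenvectors[0]
        frame[0, chain_b_sel.resolved_indices, :] = flat.reshape(-1, 3)
        one = TrajectoryEnsemble(atoms=template.atoms, frames=frame)
        scores = project(one, basis, chain_b_sel).scores[0]
        assert scores[0] == pytest.approx(2.0, abs=1e-8)
        assert np.abs(scores[1:]).max() <= 1e-8

    def test_dimension_mismatch(self, fitted_ensemble, chain_a_sel, chain_b_sel):
        ens, _ = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        with pytest.raises(ValueError, match="dimension"):
            project(ens, basis, chain_a_sel)


class TestPcShiftCall:
    @staticmethod
    def _series(values):
        return [ProjectionSeries(scores=np.asarray(values, dtype=float)[:, None])]

    def test_variant_equal_to_wt_is_none(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=3000)
        call = call_pc_shift(self._series(w), self._series(w), 1)
        assert call.call == "none"

    def test_two_sigma_separation_called(self):
        rng = np.random.default_rng(2)
        w = rng.normal(0, 1, 3000)
        v = rng.normal(2, 1, 3000)
        assert call_pc_shift(self._series(v), self._series(w), 1).call == "+PC1"
        assert call_pc_shift(self._series(-v), self._series(w), 1).call == "-PC1"

    def test_threshold_boundary_is_inclusive(self):
        rng = np.random.default_rng(3)
        w = rng.normal(0, 1, 5001)
        sd = np.std(w, ddof=1)
        med = np.median(w)
        below = call_pc_shift(self._series(w + (0.999 * sd)), self._series(w), 1)
        above = call_pc_shift(self._series(w + (1.001 * sd)), self._series(w), 1)
        assert below.call == "none"
        assert above.call == "+PC1"
        assert above.variant_median == pytest.approx(med + 1.001 * sd)

    def test_planted_shift_scores_near_two_sigma(self, template, planted_modes, chain_a_sel, chain_b_sel):
        wt_sc = syn.VariantScenario(name="WT", seed=30, n_frames=600)
        v_sc = syn.VariantScenario(name="v", mode_shifts={1: 2.0}, seed=31, n_frames=600)
        wt = superpose_ensemble(
            syn.sample_ensemble(template, planted_modes, wt_sc), template, chain_a_sel
        )
        var = superpose_ensemble(
            syn.sample_ensemble(template, planted_modes, v_sc), template, chain_a_sel
        )
        basis = fit_modes([wt, var], chain_b_sel, n_modes=3)
        pw = [project(wt, basis, chain_b_sel)]
        pv = [project(var, basis, chain_b_sel)]
        call = call_pc_shift(pv, pw, 1)
        assert call.call == "+PC1"
        sd1 = planted_modes.mode_sds[0]
        assert call.shift == pytest.approx(2.0 * sd1, rel=0.15)


class TestDisplacementField:
    def test_zero_eigenvalue_gives_zero_field(self, template, chain_b_sel):
        frames = np.tile(template.coordinates, (4, 1, 1))
        ens = TrajectoryEnsemble(atoms=template.atoms, frames=frames)
        basis = fit_modes(ens, chain_b_sel, n_modes=2)
        assert np.all(displacement_field(basis, 1) == 0.0)

    def test_field_parallel_to_planted_mode(self, fitted_ensemble, chain_b_sel):
        ens, modes = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        field = displacement_field(basis, 1).ravel()
        cos = abs(field @ modes.mode_vectors[0]) / np.linalg.norm(field)
        assert cos >= 0.99

    def test_squared_norms_sum_to_eigenvalue(self, fitted_ensemble, chain_b_sel):
        ens, _ = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        field = displacement_field(basis, 2)
        assert (field**2).sum() == pytest.approx(basis.eigenvalues[1], abs=1e-6)

    def test_invalid_index(self, fitted_ensemble, chain_b_sel):
        ens, _ = fitted_ensemble
        basis = fit_modes(ens, chain_b_sel, n_modes=3)
        with pytest.raises(ValueError):
            displacement_field(basis, 4)
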