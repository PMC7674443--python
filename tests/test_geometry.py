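"""Superposition, RMSD and representative-selection checks against oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from glucnmr import geometry, synthetic
from glucnmr.geometry import kabsch_superpose, select_representative


def random_coords(rng, n=8, scale=5.0):
    return rng.normal(size=(n, 3)) * scale


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        assert kabsch_superpose(x, x).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = random_coords(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(x, y)
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.apply(x), y, atol=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_errors(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rotation_proper_and_rmsd_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_coords(rng), random_coords(rng)
        res = kabsch_superpose(x, y)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd == pytest.approx(kabsch_superpose(y, x).rmsd, abs=1e-9)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_coords(rng), random_coords(rng)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        x2 = x @ rot.T + rng.normal(size=3)
        assert kabsch_superpose(x2, y).rmsd == pytest.approx(
            kabsch_superpose(x, y).rmsd, abs=1e-8
        )

    def test_agrees_with_scipy_align_vectors(self):
        # independent route through scipy's own superposition
        rng = np.random.default_rng(7)
        x, y = random_coords(rng, 12), random_coords(rng, 12)
        ours = kabsch_superpose(x, y).rmsd
        rot, rssd = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        theirs = rssd / np.sqrt(len(x))
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestPairwiseMatrix:
    def test_identical_models_zero(self, tiny_ensemble):
        m = geometry.pairwise_rmsd_matrix(tiny_ensemble, "CA", [(1, 10)])
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    def test_rigid_moved_model_zero_entry(self):
        spec = synthetic.EnsembleSpec(
            n_models=2, n_residues=8, rigid_ranges=((1, 8),), flexible_ranges=(),
            sigma_core=0.3, seed=4,
        )
        ens = synthetic.make_ensemble(spec)
        # append a rigidly moved copy of model 1
        from glucnmr.structure_io import Atom, Ensemble, Model, ResidueRecord

        rot = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        moved = Model(
            model_id=3,
            residues=[
                ResidueRecord(
                    r.seq_id, r.aa,
                    [Atom(a.name, a.element, a.coords @ rot.T + 2.0) for a in r.atoms],
                )
                for r in ens.models[0].residues
            ],
        )
        ens3 = Ensemble(models=[ens.models[0], ens.models[1], moved])
        m = geometry.pairwise_rmsd_matrix(ens3, "CA", [(1, 8)])
        assert m.values[0, 2] == pytest.approx(0.0, abs=1e-6)
        # symmetry, zero diagonal
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(m.values), 0.0)

    def test_noise_scaling_matches_direct_simulation(self):
        """Off-diagonal mean tracks a Monte-Carlo oracle built from raw numpy."""
        sigma = 1.0
        spec = synthetic.EnsembleSpec(
            n_models=19, n_residues=40, rigid_ranges=((1, 40),), flexible_ranges=(),
            sigma_core=sigma, seed=11,
        )
        ens = synthetic.make_ensemble(spec)
        m = geometry.pairwise_rmsd_matrix(ens, "CA", [(1, 40)])
        measured = m.values[np.triu_indices(19, 1)].mean()

        rng = np.random.default_rng(99)
        base = rng.normal(size=(40, 3)) * 10
        sims = []
        for _ in range(200):
            a = base + rng.normal(0, sigma, size=(40, 3))
            b = base + rng.normal(0, sigma, size=(40, 3))
            rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            sims.append(rssd / np.sqrt(40))
        expected = float(np.mean(sims))
        assert measured == pytest.approx(expected, rel=0.15)


class TestRepresentative:
    def test_tie_breaks_to_lowest_index(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        assert select_representative(m) == 0

    def test_forced_by_row_means(self):
        m = np.array([[0, 2, 2], [2, 0, 0], [2, 0, 0]], dtype=float)
        # row means: 2.0, 1.0, 1.0 -> index 1 (tie with 2, lowest wins)
        assert select_representative(m) == 1

    @pytest.mark.parametrize("n", [2, 5, 10, 12])
    def test_matches_exhaustive_argmin(self, n):
        rng = np.random.default_rng(n)
        m = rng.uniform(0.1, 5.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        best = min(
            range(n), key=lambda i: sum(m[i, j] for j in range(n) if j != i) / (n - 1)
        )
        assert select_representative(m) == best


class TestReferenceStats:
    def test_identical_models(self, tiny_ensemble):
        mean, sd = geometry.rmsd_to_reference_stats(tiny_ensemble, 0, "CA", [(1, 10)])
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_recomputation(self, gluc_ensemble, gluc_spec):
        from glucnmr.structure_io import select_coords

        m = geometry.pairwise_rmsd_matrix(gluc_ensemble, "CA", gluc_spec.rigid_ranges)
        rep = select_representative(m)
        mean, sd = geometry.rmsd_to_reference_stats(
            gluc_ensemble, rep, "CA", gluc_spec.rigid_ranges
        )
        coords = select_coords(gluc_ensemble, "CA", gluc_spec.rigid_ranges)
        ref = coords[rep]
        direct = []
        for i in range(coords.shape[0]):
            if i == rep:
                continue
            rot, rssd = Rotation.align_vectors(
                ref - ref.mean(0), coords[i] - coords[i].mean(0)
            )
            direct.append(rssd / np.sqrt(coords.shape[1]))
        assert mean == pytest.approx(np.mean(direct), rel=1e-6)
        assert sd == pytest.approx(np.std(direct), rel=1e-6)

    def test_heavy_atom_variant_runs(self, gluc_ensemble, gluc_spec):
        mean, sd = geometry.rmsd_to_reference_stats_heavy(
            gluc_ensemble, 0, gluc_spec.rigid_ranges
        )
        assert mean > 0 and sd >= 0


class TestDisplacement:
    def test_identical_models_zero_profile(self, tiny_ensemble):
        prof = geometry.per_residue_displacement(tiny_ensemble, 0, "CA", [(1, 10)])
        np.testing.assert_allclose(prof.mean, 0.0, atol=1e-9)

    def test_flexible_tails_exceed_core(self):
        spec = synthetic.EnsembleSpec(
            n_models=10, n_residues=60, rigid_ranges=((11, 50),),
            flexible_ranges=((1, 10), (51, 60)), sigma_core=0.5, sigma_flex=5.0, seed=3,
        )
        ens = synthetic.make_ensemble(spec)
        prof = geometry.per_residue_displacement(ens, 0, "CA", [(11, 50)])
        core = (prof.seq_ids >= 11) & (prof.seq_ids <= 50)
        assert prof.mean[~core].mean() > prof.mean[core].mean()

    def test_single_flexible_residue_is_local_maximum(self):
        spec = synthetic.EnsembleSpec(
            n_models=12, n_residues=30, rigid_ranges=((1, 14), (16, 30)),
            flexible_ranges=((15, 15),), sigma_core=0.3, sigma_flex=3.0, seed=8,
        )
        ens = synthetic.make_ensemble(spec)
        prof = geometry.per_residue_displacement(
            ens, 0, "CA", [(1, 14), (16, 30)]
        )
        i15 = int(np.nonzero(prof.seq_ids == 15)[0][0])
        assert prof.mean[i15] > prof.mean[i15 - 1]
        assert prof.mean[i15] > prof.mean[i15 + 1]
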