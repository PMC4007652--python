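"""Elastic network model: energy, Hessian, modes, conformer ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoconform import enm_nma as enm


@pytest.fixture(scope="module")
def tetra_model():
    coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                       [0.0, 5.0, 0.0], [0.0, 0.0, 5.0]])
    return enm.build_enm(coords)


@pytest.fixture(scope="module")
def helix_model(helix50):
    return enm.build_enm(helix50)


def test_contact_counting_under_cutoff():
    coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                       [30.0, 0.0, 0.0], [42.0, 0.0, 1.0]])
    model = enm.build_enm(coords)
    assert len(model.contacts) == 1  # only the 5 Å pair; 12 Å is beyond R_C
    assert model.d0[0] == pytest.approx(5.0)


def test_contacts_match_brute_force(helix_model, helix50):
    coords = helix_model.ca_coords
    brute = {(i, j) for i in range(len(coords))
             for j in range(i + 1, len(coords))
             if np.linalg.norm(coords[i] - coords[j]) < 10.0}
    assert set(map(tuple, helix_model.contacts)) == brute


def test_too_few_residues_rejected():
    with pytest.raises(ValueError):
        enm.build_enm(np.zeros((3, 3)) + np.arange(3)[:, None])


def test_energy_zero_at_reference(helix_model):
    assert enm.enm_energy(helix_model.ca_coords, helix_model) == 0.0


def test_energy_single_stretched_contact(tetra_model):
    # stretch the (0,1) contact by delta along x; keep others out of range
    coords = tetra_model.ca_coords.copy()
    delta = 0.3
    model = enm.build_enm(coords, cutoff=6.0)
    moved = coords.copy()
    moved[1, 0] += delta
    stretched_pairs = [(i, j) for (i, j) in map(tuple, model.contacts)]
    e = enm.enm_energy(moved, model)
    expected = sum(0.5 * (np.linalg.norm(moved[i] - moved[j])
                          - np.linalg.norm(coords[i] - coords[j])) ** 2
                   for i, j in stretched_pairs)
    assert e == pytest.approx(expected, rel=1e-12)


def test_energy_matches_brute_force_sum(helix_model, rng):
    coords = helix_model.ca_coords + rng.normal(0, 0.1,
                                                helix_model.ca_coords.shape)
    brute = 0.0
    for (i, j), d0 in zip(helix_model.contacts, helix_model.d0):
        d = np.linalg.norm(coords[i] - coords[j])
        brute += 0.5 * (d - d0) ** 2
    assert enm.enm_energy(coords, helix_model) == pytest.approx(brute,
                                                                rel=1e-12)


def test_energy_shape_mismatch(helix_model):
    with pytest.raises(ValueError):
        enm.enm_energy(np.zeros((3, 3)), helix_model)


def test_hessian_symmetric_and_psd(helix_model):
    h = enm.hessian(helix_model)
    assert np.abs(h - h.T).max() == 0.0
    eig = np.linalg.eigvalsh(h)
    assert eig.min() > -1e-10


def test_hessian_matches_finite_differences(tetra_model):
    """Second derivatives of the printed energy, via central differences."""
    model = tetra_model
    n = model.n_residues
    h_analytic = enm.hessian(model)
    step = 1e-5
    x0 = model.ca_coords.flatten()

    def energy(x):
        return enm.enm_energy(x.reshape(n, 3), model)

    h_num = np.zeros((3 * n, 3 * n))
    for a in range(3 * n):
        for b in range(3 * n):
            xpp = x0.copy(); xpp[a] += step; xpp[b] += step
            xpm = x0.copy(); xpm[a] += step; xpm[b] -= step
            xmp = x0.copy(); xmp[a] -= step; xmp[b] += step
            xmm = x0.copy(); xmm[a] -= step; xmm[b] -= step
            h_num[a, b] = (energy(xpp) - energy(xpm) - energy(xmp)
                           + energy(xmm)) / (4 * step ** 2)
    scale = max(np.abs(h_analytic).max(), 1.0)
    assert np.abs(h_analytic - h_num).max() / scale < 1e-4


def test_exactly_six_zero_modes(helix_model, tetra_model):
    for model in (helix_model, tetra_model):
        modes = enm.normal_modes(model)
        assert modes.n_zero == 6


def test_nonzero_mode_count_3n_minus_6():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 8, size=(10, 3))
    model = enm.build_enm(coords, cutoff=12.0)
    modes = enm.normal_modes(model)
    assert modes.nonzero_modes.shape[1] == 3 * 10 - 6 == 24


def test_eigenvectors_orthonormal(helix_model):
    modes = enm.normal_modes(helix_model)
    v = modes.eigenvectors
    assert np.abs(v.T @ v - np.eye(v.shape[1])).max() < 1e-8


def test_spectrum_invariant_under_isometry(helix_model):
    from phosphoconform.geometry import rotation_matrix

    rot = rotation_matrix([1.0, 1.0, 0.0], 73.0)
    moved = helix_model.ca_coords @ rot.T + np.array([3.0, -2.0, 8.0])
    model2 = enm.build_enm(moved)
    e1 = enm.normal_modes(helix_model).eigenvalues
    e2 = enm.normal_modes(model2).eigenvalues
    np.testing.assert_allclose(e1, e2, atol=1e-8)


def test_disconnected_network_raises():
    coords = np.vstack([np.random.default_rng(1).uniform(0, 6, (5, 3)),
                        np.random.default_rng(2).uniform(50, 56, (5, 3))])
    model = enm.build_enm(coords)
    with pytest.raises(enm.DisconnectedNetworkError):
        enm.normal_modes(model)


def test_default_ensemble_is_401(helix_model):
    modes = enm.normal_modes(helix_model)
    ensemble = enm.generate_conformers(helix_model, modes)
    assert len(ensemble) == 20 * 20 + 1 == 401
    assert ensemble.provenance[0] == (-1, -1)


@settings(deadline=None, max_examples=10, derandomize=True)
@given(n_modes=st.integers(1, 8), n_steps=st.integers(1, 8))
def test_ensemble_size_law(n_modes, n_steps):
    coords = np.random.default_rng(5).uniform(0, 9, size=(8, 3))
    model = enm.build_enm(coords, cutoff=16.0)
    modes = enm.normal_modes(model)
    ensemble = enm.generate_conformers(model, modes, n_modes=n_modes,
                                       n_steps=n_steps, max_amp=1.0)
    assert len(ensemble) == n_modes * n_steps + 1


def test_small_ensemble_1x2(helix_model):
    modes = enm.normal_modes(helix_model)
    assert len(enm.generate_conformers(helix_model, modes, n_modes=1,
                                       n_steps=2)) == 3


def test_amplitudes_symmetric_and_energy_quadratic(helix_model):
    """Along one mode at small amplitude the energy is ½ λ a² and symmetric
    in ±a."""
    modes = enm.normal_modes(helix_model)
    ensemble = enm.generate_conformers(helix_model, modes, n_modes=3,
                                       n_steps=4, max_amp=0.25)
    n = helix_model.n_residues
    for conf, (m, s) in zip(ensemble.conformers[1:],
                            ensemble.provenance[1:]):
        disp = (conf - helix_model.ca_coords).flatten()
        amp = np.linalg.norm(disp)
        lam = modes.nonzero_eigenvalues[m]
        expected = 0.5 * lam * amp ** 2
        actual = enm.enm_energy(conf, helix_model)
        assert actual == pytest.approx(expected, rel=0.05)
    # symmetry of ±amplitude energies per mode
    by_mode = {}
    for conf, (m, s) in zip(ensemble.conformers[1:],
                            ensemble.provenance[1:]):
        by_mode.setdefault(m, []).append(enm.enm_energy(conf, helix_model))
    # symmetric to harmonic order; anharmonic corrections are O(a³)
    for energies in by_mode.values():
        energies = sorted(energies)
        assert energies[0] == pytest.approx(energies[1], rel=0.01)


def test_excess_modes_warns(tetra_model):
    modes = enm.normal_modes(tetra_model)
    with pytest.warns(UserWarning, match="non-zero modes"):
        ensemble = enm.generate_conformers(tetra_model, modes, n_modes=50,
                                           n_steps=2)
    assert len(ensemble) == modes.nonzero_modes.shape[1] * 2 + 1


def test_nonpositive_amplitude_rejected(helix_model):
    modes = enm.normal_modes(helix_model)
    with pytest.raises(ValueError):
        enm.generate_conformers(helix_model, modes, max_amp=0.0)


def test_singleton_ensemble_max_equals_input(helix_model, fast_params):
    ensemble = enm.ConformerEnsemble(
        conformers=[helix_model.ca_coords.copy()], provenance=[(-1, -1)])
    values, mx = enm.ensemble_rsasa(ensemble, helix_model,
                                    helix_model.seq_nums[5:13], fast_params)
    assert mx == values[0]
    anchored, mx2 = enm.ensemble_rsasa(ensemble, helix_model,
                                       helix_model.seq_nums[5:13],
                                       fast_params, anchor_rsasa=0.42)
    assert mx2 == pytest.approx(0.42)


def test_floppy_arm_gains_accessibility(arm_fixture):
    """The verified arm fixture exposes its site in some conformer."""
    assert arm_fixture.ensemble_max > arm_fixture.input_rsasa
    assert arm_fixture.input_rsasa < 0.2 < arm_fixture.ensemble_max


def test_reclassification_rules():
    allowed, rescued = enm.reclassify_by_dynamics(0.15, np.array([0.1, 0.25]))
    assert allowed and rescued
    allowed, rescued = enm.reclassify_by_dynamics(0.05,
                                                  np.array([0.04, 0.08]))
    assert not allowed and not rescued
    allowed, rescued = enm.reclassify_by_dynamics(0.30, np.array([0.1]))
    assert allowed and not rescued


def test_missing_ca_named_in_error():
    from phosphoconform.synthetic_data import build_ideal_helix

    helix = build_ideal_helix("A" * 10)
    res = helix.chains[0].residue_at(4)
    res.atoms = [a for a in res.atoms if a.name != "CA"]
    with pytest.raises(enm.MissingCAError, match="4"):
        enm.build_enm(helix)


def test_short_gap_interpolated():
    from phosphoconform.structure_io import Residue
    from phosphoconform.synthetic_data import build_ideal_helix

    helix = build_ideal_helix("A" * 12)
    helix.chains[0].residues[5] = Residue(chain_id="A", seq_num=6, aa="A",
                                          atoms=[], is_observed=False)
    coords, aas, nums = enm.ca_model_from_structure(helix)
    assert len(coords) == 12 and nums == list(range(1, 13))
    # interpolated point lies between its neighbours
    mid = coords[5]
    assert np.linalg.norm(mid - coords[4]) < 4.0
    assert np.linalg.norm(mid - coords[6]) < 4.0


def test_ensemble_pdb_has_all_models(helix_model):
    modes = enm.normal_modes(helix_model)
    ensemble = enm.generate_conformers(helix_model, modes, n_modes=1,
                                       n_steps=2)
    text = enm.write_ensemble_pdb(ensemble, helix_model)
    assert text.count("MODEL") == text.count("ENDMDL") == 3
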