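"""Surface-area engine: closed forms, oracles, normalization, depth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from phosphoconform import sasa_engine as se
from phosphoconform import structure_io as sio
from phosphoconform.aminoacids import VDW_RADII, coarse_radius
from phosphoconform.site_mapper import OctapeptideSite, StructureRef
from phosphoconform.synthetic_data import build_extended_peptide


def test_isolated_carbon_matches_closed_form():
    areas, _ = se.shrake_rupley(np.zeros((1, 3)), np.array([1.70]),
                                probe=1.4, n_points=960)
    assert areas[0] == pytest.approx(4 * np.pi * 3.10 ** 2, rel=1e-9)


def test_fully_enclosed_atom_has_zero_area():
    from phosphoconform.geometry import fibonacci_sphere

    shell = 2.0 * fibonacci_sphere(80)
    coords = np.vstack([[0.0, 0.0, 0.0], shell])
    radii = np.full(len(coords), 1.7)
    areas, _ = se.shrake_rupley(coords, radii, probe=1.4, n_points=960)
    assert areas[0] == 0.0


def _two_sphere_closed_form(r1, r2, probe, d):
    """Exact accessible area of sphere 1 (expanded radius R1) occluded by
    sphere 2 (expanded radius R2) at center distance d."""
    rr1, rr2 = r1 + probe, r2 + probe
    if d >= rr1 + rr2:
        return 4 * np.pi * rr1 ** 2
    # spherical cap removed from sphere 1
    cos_theta = (d ** 2 + rr1 ** 2 - rr2 ** 2) / (2 * d * rr1)
    h = rr1 * (1 - cos_theta)
    return 4 * np.pi * rr1 ** 2 - 2 * np.pi * rr1 * h


@pytest.mark.parametrize("d", [3.0, 4.0, 5.0, 6.0, 6.5])
def test_two_atom_pair_matches_cap_integral(d):
    coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    radii = np.array([1.7, 1.55])
    areas, _ = se.shrake_rupley(coords, radii, probe=1.4, n_points=960)
    expected = _two_sphere_closed_form(1.7, 1.55, 1.4, d)
    assert areas[0] == pytest.approx(expected, rel=0.02)


def test_residue_additivity(globule, fast_params):
    atoms = se.atom_sasa(globule.structure, fast_params)
    residues = se.residue_sasa(globule.structure, fast_params)
    assert sum(residues.values()) == pytest.approx(atoms.sum(), rel=1e-9)


def test_core_residue_below_surface_residue(globule, fast_params):
    pct = se.residue_percent_sasa(globule.structure, fast_params)
    cores = [p for p, lab in globule.labels.items() if lab == "core"]
    surfs = [p for p, lab in globule.labels.items() if lab == "surface"]
    assert max(pct[("A", p)].percent_sasa for p in cores) < \
        min(pct[("A", p)].percent_sasa for p in surfs)


def test_reference_values_deterministic_and_ordered(default_params):
    a1 = se.reference_sasa("W", default_params)
    a2 = se.reference_sasa("W", default_params)
    assert a1 == a2
    assert se.reference_sasa("W", default_params) > \
        se.reference_sasa("G", default_params)
    with pytest.raises(ValueError):
        se.reference_sasa("B", default_params)


def test_reference_tripeptide_against_biotite():
    """The extended Gly-Ala-Gly reference reproduces an independent
    Shrake-Rupley implementation on identical coordinates and radii."""
    import biotite.structure as struc

    coords, radii, central = se._build_reference_tripeptide("A", "G", "full")
    arr = struc.AtomArray(len(coords))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = 1
    arr.res_name[:] = "ALA"
    arr.atom_name[:] = [f"X{i}" for i in range(len(coords))]
    arr.element[:] = "C"
    ours, _ = se.shrake_rupley(coords, radii, 1.4, 960)
    theirs = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                        vdw_radii=np.asarray(radii, dtype=float))
    assert ours[central].sum() == pytest.approx(theirs[central].sum(),
                                                rel=0.05)


def test_per_residue_oracle_equivalence(globule, helix20, extended12):
    """Per-residue SASA within 5% of biotite on every fixture."""
    import biotite.structure as struc

    for structure in (globule.structure, helix20, extended12):
        pairs = structure.atoms()
        coords = np.array([a.coord for _, a in pairs])
        radii = np.array([VDW_RADII[a.element] for _, a in pairs])
        res_ids = np.array([r.seq_num for r, _ in pairs])
        arr = struc.AtomArray(len(coords))
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id = res_ids
        arr.res_name[:] = "ALA"
        arr.atom_name = np.array([a.name for _, a in pairs])
        arr.element = np.array([a.element for _, a in pairs])
        ours_atoms, _ = se.shrake_rupley(coords, radii, 1.4, 960)
        theirs_atoms = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                                  vdw_radii=radii.astype(float))
        for num in np.unique(res_ids):
            mask = res_ids == num
            ours = ours_atoms[mask].sum()
            theirs = theirs_atoms[mask].sum()
            # 5% relative, with an absolute floor for nearly buried
            # residues where point-lattice noise dominates
            assert ours == pytest.approx(theirs, rel=0.05, abs=2.0)


def _site_on(structure, seq_nums, sequence8="AAASAAAA"):
    return OctapeptideSite(sequence8=sequence8,
                           structure_ref=StructureRef(
                               structure_id=structure.id, chain_id="A",
                               seq_nums=list(seq_nums)))


def test_octapeptide_rsasa_is_plain_mean(helix20, default_params):
    site = _site_on(helix20, range(5, 13))
    percent = {("A", n): se.ResidueSASA(sasa=(i + 1) * 10.0, ref_sasa=100.0)
               for i, n in enumerate(range(5, 13))}
    value = se.octapeptide_rsasa(helix20, site, default_params,
                                 percent=percent)
    assert value == pytest.approx(0.45)
    assert site.rsasa == pytest.approx(0.45)
    zero = {("A", n): se.ResidueSASA(sasa=0.0, ref_sasa=100.0)
            for n in range(5, 13)}
    assert se.octapeptide_rsasa(helix20, site, default_params,
                                percent=zero) == 0.0


def test_incomplete_octapeptide_raises(default_params):
    from phosphoconform.synthetic_data import build_ideal_helix

    helix = build_ideal_helix("A" * 12)
    chain = helix.chains[0]
    chain.residues[6] = sio.Residue(chain_id="A", seq_num=7, aa="A",
                                    atoms=[], is_observed=False)
    site = _site_on(helix, range(3, 11))
    with pytest.raises(se.IncompleteOctapeptideError):
        se.octapeptide_rsasa(helix, site, default_params)


def test_extended_octapeptide_rsasa_near_one(default_params):
    """An isolated fully extended octapeptide is its own reference state up
    to end effects."""
    peptide = build_extended_peptide("A" * 8)
    site = _site_on(peptide, range(1, 9))
    value = se.octapeptide_rsasa(peptide, site, default_params)
    assert value == pytest.approx(1.0, rel=0.15)


def test_buried_site_rsasa_near_zero(globule):
    assert globule.core_rsasa < 0.1


def test_coarse_isolated_sphere_closed_form(fast_params):
    aas = ["W"]
    areas = se.shrake_rupley(np.zeros((1, 3)),
                             np.array([coarse_radius("W")]),
                             fast_params.probe_radius,
                             fast_params.n_sphere_points)[0]
    expected = 4 * np.pi * (coarse_radius("W")
                            + fast_params.probe_radius) ** 2
    assert areas[0] == pytest.approx(expected, rel=1e-9)


def test_coarse_duplicate_positions_rejected(fast_params):
    coords = np.zeros((2, 3))
    with pytest.raises(ValueError, match="duplicate"):
        se.coarse_residue_sasa(coords, ["A", "A"], fast_params)


def test_coarse_tracks_all_atom_burial(globule, fast_params):
    """Coarse and all-atom per-residue accessibility agree ordinally."""
    structure = globule.structure
    chain = structure.chains[0]
    ca = np.array([r.atom("CA").coord for r in chain.observed])
    aas = [r.aa for r in chain.observed]
    coarse = se.coarse_residue_sasa(ca, aas, fast_params)
    pct = se.residue_percent_sasa(structure, fast_params)
    allatom = np.array([pct[("A", r.seq_num)].percent_sasa
                        for r in chain.observed])
    rho = spearmanr(coarse, allatom).statistic
    assert rho > 0.7
    cores = [i for i, r in enumerate(chain.observed)
             if globule.labels.get(r.seq_num) == "core"]
    surfs = [i for i, r in enumerate(chain.observed)
             if globule.labels.get(r.seq_num) == "surface"]
    assert coarse[cores].mean() < coarse[surfs].mean()


def test_depth_orders_core_above_surface(globule, fast_params):
    """The designated core octapeptide lies deeper than every surface
    residue."""
    depths = se.all_residue_depths(globule.structure, fast_params)
    cores = [depths[("A", p)] for p in globule.core_window]
    surfs = [depths[("A", p)] for p, lab in globule.labels.items()
             if lab == "surface"]
    assert min(cores) > max(surfs)


def test_depth_small_for_isolated_residue(fast_params):
    from phosphoconform.synthetic_data import build_extended_peptide

    peptide = build_extended_peptide("AAAA")
    res = peptide.chains[0].residue_at(2)
    depth = se.residue_depth(peptide, res, fast_params)
    assert depth <= 2 * fast_params.probe_radius


def test_isometry_invariance(globule, fast_params):
    """Rigid-body transforms leave SASA and depth unchanged."""
    from phosphoconform.geometry import rotation_matrix

    import copy

    structure = globule.structure
    before_sasa = se.residue_sasa(structure, fast_params)
    before_depth = se.all_residue_depths(structure, fast_params)
    rot = rotation_matrix([1.0, 2.0, 3.0], 67.0)
    moved = copy.deepcopy(structure)
    for _, atom in moved.atoms():
        atom.coord = rot @ atom.coord + np.array([11.0, -5.0, 42.0])
    after_sasa = se.residue_sasa(moved, fast_params)
    after_depth = se.all_residue_depths(moved, fast_params)
    for key in before_sasa:
        assert after_sasa[key] == pytest.approx(before_sasa[key],
                                                rel=1e-6, abs=1e-6)
        assert after_depth[key] == pytest.approx(before_depth[key],
                                                 rel=1e-4, abs=2e-3)


def test_occlusion_monotonicity(rng):
    """Adding an atom never increases any existing atom's area."""
    coords = rng.uniform(-4, 4, size=(12, 3))
    radii = np.full(12, 1.7)
    # fixed lattice: canonical orientation would re-align with the new atom
    base, _ = se.shrake_rupley(coords, radii, 1.4, 384, canonical=False)
    extra = np.vstack([coords, rng.uniform(-4, 4, size=(1, 3))])
    more, _ = se.shrake_rupley(extra, np.full(13, 1.7), 1.4, 384,
                               canonical=False)
    assert np.all(more[:12] <= base + 1e-9)


def test_point_count_convergence(helix20):
    p1 = se.SASAParams(n_sphere_points=480)
    p2 = se.SASAParams(n_sphere_points=960)
    t1 = se.atom_sasa(helix20, p1).sum()
    t2 = se.atom_sasa(helix20, p2).sum()
    assert abs(t1 - t2) / t2 < 0.01


def test_unknown_element_raises(helix20):
    helix = sio.parse_structure(sio.write_structure(helix20))
    helix.chains[0].residue_at(1).atoms[0].element = "Q?"
    with pytest.raises(se.RadiusLookupError, match="Q?"):
        se.atom_sasa(helix)


def test_params_validation():
    with pytest.raises(ValueError):
        se.SASAParams(probe_radius=0.0)
    with pytest.raises(ValueError):
        se.SASAParams(n_sphere_points=50)
    with pytest.raises(ValueError):
        se.SASAParams(reference_flank="P")
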