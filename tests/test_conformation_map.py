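"""Threshold semantics, rescue rules, A_rel, histograms and compositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoconform import conformation_map as cm
from phosphoconform.synthetic_data import build_ideal_helix


@pytest.mark.parametrize("rsasa,expected", [
    (0.11, "disallowed"),    # buried actin-like site
    (0.30, "allowed"),       # moderately accessible
    (0.73, "allowed"),       # well accessible
    (0.20, "allowed"),       # boundary inclusive
    (0.19999, "disallowed"),
])
def test_classification_threshold(rsasa, expected):
    assert cm.classify_site(rsasa) == expected


def test_stringent_threshold():
    assert cm.classify_site(0.30, threshold=0.3) == "allowed"
    assert cm.classify_site(0.29, threshold=0.3) == "disallowed"


def test_negative_rsasa_rejected():
    with pytest.raises(cm.NegativeRSASAError):
        cm.classify_site(-0.01)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(rsasa=st.floats(0, 1.5), delta=st.floats(0, 0.5))
def test_classification_monotone_in_threshold(rsasa, delta):
    """Raising the threshold never turns a disallowed site allowed."""
    low = cm.classify_site(rsasa, threshold=0.2)
    high = cm.classify_site(rsasa, threshold=0.2 + delta)
    assert not (low == "disallowed" and high == "allowed")


def test_interface_rescue_flips_buried_site():
    result = cm.classify(0.15)
    cm.rescue_interface(result, monomer_rsasa=0.45)
    assert result.label == "allowed" and result.rescue == "interface"
    assert result.rsasa == pytest.approx(0.45)


def test_interface_rescue_needs_exposed_monomer():
    result = cm.classify(0.15)
    cm.rescue_interface(result, monomer_rsasa=0.16)
    assert result.label == "disallowed" and result.rescue == "none"


@pytest.mark.parametrize("values,expected", [
    ({"closed": 0.19, "open": 0.39}, "allowed"),
    ({"ordered": 0.16, "disordered_loop": 0.35}, "allowed"),
    ({"a": 0.05, "b": 0.12}, "disallowed"),
])
def test_alternate_structure_rescue(values, expected):
    result = cm.classify(min(values.values()))
    cm.rescue_alternate(result, values)
    assert result.label == expected
    if expected == "allowed":
        assert result.rescue == "alternate_structure"


def test_alternate_rescue_empty_map():
    with pytest.raises(ValueError):
        cm.rescue_alternate(cm.classify(0.1), {})


@pytest.mark.parametrize("octa,expected", [
    ("AAASPAKA", True),      # S-P-x-K
    ("AAATPGRA", True),      # T-P-x-R
    ("AAASAAKA", False),     # no proline at +1
    ("AAAYPAKA", False),     # Y is not part of the S/T motif
    ("AAASPAAA", False),     # no basic residue at +3
])
def test_cdk_consensus_motif(octa, expected):
    assert cm.consensus_override(octa) is expected


def test_rescues_never_demote():
    result = cm.classify(0.5)
    assert result.label == "allowed"
    cm.rescue_interface(result, monomer_rsasa=0.05)
    cm.rescue_alternate(result, {"x": 0.01})
    assert result.label == "allowed" and result.rescue == "none"


def test_rescue_precedence_ordering():
    result = cm.classify(0.1)
    result.apply_rescue("consensus_motif")
    result.apply_rescue("dynamics")
    result.apply_rescue("interface")
    assert result.rescue == "interface"


def test_predicted_sasa_formula_exact():
    assert cm.predicted_sasa(10_000.0) == pytest.approx(
        4.44 * 10_000.0 ** 0.77, rel=1e-15)
    record = cm.FlexibilityRecord(mass=12_345.0,
                                  observed_sasa=4.44 * 12_345.0 ** 0.77)
    assert record.a_rel == pytest.approx(1.0, rel=1e-12)


def test_a_rel_filters(fast_params):
    from phosphoconform.structure_io import Residue

    helix = build_ideal_helix("A" * 40)
    flex = cm.compute_a_rel(helix, fast_params)
    assert flex is not None and flex.a_rel > 0
    # more than five disordered residues -> filtered out
    chain = helix.chains[0]
    for i in range(6):
        chain.residues[i] = Residue(chain_id="A", seq_num=i + 1, aa="A",
                                    atoms=[], is_observed=False)
    assert cm.compute_a_rel(helix, fast_params) is None


def test_a_rel_excludes_multimers(dimer, fast_params):
    assembly, _ = dimer
    assert cm.compute_a_rel(assembly, fast_params) is None


def test_histogram_mode_median_and_conservation():
    counts, edges, mode_bin, median = cm.bin_and_summarize([0.45] * 7)
    assert (edges[mode_bin], edges[mode_bin + 1]) == pytest.approx((0.4, 0.5))
    assert counts.sum() == 7
    _, _, _, med = cm.bin_and_summarize([0.1, 0.2, 0.3])
    assert med == pytest.approx(0.2)
    counts, *_ = cm.bin_and_summarize([0.05, 1.7, 0.95])
    assert counts.sum() == 3 and counts[-1] == 2  # >1 clamped into last bin
    with pytest.raises(ValueError):
        cm.bin_and_summarize([])


def test_histogram_recovers_planted_mode(rng):
    values = np.concatenate([rng.uniform(0.2, 0.3, 400),
                             rng.uniform(0.0, 1.0, 200)])
    _, edges, mode_bin, _ = cm.bin_and_summarize(values)
    assert (edges[mode_bin], edges[mode_bin + 1]) == pytest.approx((0.2, 0.3))


def test_composition_identical_sets_zero_difference():
    octas = ["AVLIKDES", "KKDDEEAA"]
    comp = cm.composition_compare(octas, list(octas))
    assert comp["hydrophobic_difference"] == pytest.approx(0.0)
    assert comp["charged_difference"] == pytest.approx(0.0)
    assert sum(comp["allowed"].values()) == pytest.approx(1.0)


def test_composition_extreme_case():
    comp = cm.composition_compare(["KKKKKKKK"], ["LLLLLLLL"])
    assert comp["hydrophobic_difference"] == pytest.approx(1.0)


def test_composition_recovers_planted_enrichment(rng):
    """A 10% leucine enrichment planted in the disallowed set is recovered
    within sampling error at n=500 octapeptides."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    base = rng.choice(aas, size=(500, 8))
    allowed = ["".join(row) for row in base]
    enriched = base.copy()
    mask = rng.random(enriched.shape) < 0.10
    enriched[mask] = "L"
    disallowed = ["".join(row) for row in enriched]
    comp = cm.composition_compare(allowed, disallowed)
    planted = 0.10 * (1 - 1 / len(aas))  # replacements that were not L
    diff = comp["disallowed"]["L"] - comp["allowed"]["L"]
    assert diff == pytest.approx(planted, abs=0.02)


def test_depth_consistency_fraction():
    sites = [(0.5, 3.0), (0.05, 40.0)]
    assert cm.depth_consistency(sites) == 1.0
    sites = [(0.5, 50.0), (0.05, 40.0)]  # exposed but deep -> discordant
    assert cm.depth_consistency(sites) == 0.5
    assert cm.depth_consistency([(0.5, 3.0)], depth_cutoff=2.0) == 0.0


def test_depth_consistency_on_globule(globule, fast_params):
    """rSASA and depth agree on the generated globule when the cutoff
    matches the fixture's physical scale."""
    from phosphoconform.sasa_engine import (all_residue_depths,
                                            residue_percent_sasa)

    pct = residue_percent_sasa(globule.structure, fast_params)
    depths = all_residue_depths(globule.structure, fast_params)
    sites = []
    for window in (globule.core_window, globule.surface_window):
        rs = float(np.mean([pct[("A", p)].percent_sasa for p in window]))
        dp = float(np.mean([depths[("A", p)] for p in window]))
        sites.append((rs, dp))
    # surface octapeptide shallow, core octapeptide deep
    assert cm.depth_consistency(sites, depth_cutoff=0.25) == 1.0


def test_protein_mass_sums_residues():
    helix = build_ideal_helix("AG" * 5)
    expected = 5 * (71.08 + 57.05) + 18.02
    assert cm.protein_mass(helix) == pytest.approx(expected)
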