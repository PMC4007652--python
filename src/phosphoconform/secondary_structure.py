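"""Per-residue secondary structure in a four-class vocabulary (H/E/T/C).

Backbone hydrogen bonds are detected with the Kabsch-Sander electrostatic
model (amide H rebuilt from the preceding carbonyl; bond when the
interaction energy is below -0.5 kcal/mol).  Labels:

* ``H`` helix: helical φ/ψ inside an i→i+4 hydrogen-bonded stretch,
* ``E`` sheet: extended φ/ψ with a cross-strand hydrogen bond,
* ``T`` turn: enclosed by an i→i+3 hydrogen bond that is not helical,
* ``C`` otherwise (including residues with missing backbone atoms).

Precedence when several patterns apply: H > E > T > C.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import dihedral_angle
from .structure_io import Chain, Structure

HB_ENERGY_CUTOFF = -0.5          # kcal/mol, Kabsch-Sander threshold
_KS_FACTOR = 0.084 * 332.0       # kcal/mol * Å, electrostatic prefactor
PEPTIDE_BOND_MAX = 2.5           # Å, C(i)-N(i+1) distance for contiguity

HELICAL_PHI = (-120.0, -20.0)
HELICAL_PSI = (-90.0, 10.0)
EXTENDED_PHI = (-180.0, -45.0)
EXTENDED_PSI_A = (45.0, 180.0)
EXTENDED_PSI_B = (-180.0, -150.0)

#: minimum sequence separation for a hydrogen bond to count as cross-strand
STRAND_MIN_SEP = 5


def _backbone(chain: Chain):
    """Backbone coordinate arrays for observed residues; None where absent."""
    frames = []
    for res in chain.observed:
        atoms = {}
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            atoms[name] = None if a is None else a.coord
        if any(v is None for v in atoms.values()):
            frames.append(None)
        else:
            frames.append(atoms)
    return frames


def _contiguous(chain: Chain, i: int, j: int, frames) -> bool:
    """True if observed residues i and j (=i+1) are bonded neighbours."""
    ri, rj = chain.observed[i], chain.observed[j]
    if rj.seq_num - ri.seq_num != 1:
        return False
    if frames[i] is None or frames[j] is None:
        return False
    return float(np.linalg.norm(frames[j]["N"] - frames[i]["C"])) \
        <= PEPTIDE_BOND_MAX


def _hydrogen_bonds(chain: Chain, frames) -> set[tuple[int, int]]:
    """(acceptor, donor) index pairs with Kabsch-Sander energy < cutoff."""
    n = len(frames)
    h_pos: list[np.ndarray | None] = [None] * n
    for j in range(1, n):
        if frames[j] is None or not _contiguous(chain, j - 1, j, frames):
            continue
        if chain.observed[j].aa == "P":     # proline has no amide H
            continue
        co = frames[j - 1]["C"] - frames[j - 1]["O"]
        h_pos[j] = frames[j]["N"] + co / np.linalg.norm(co)
    bonds: set[tuple[int, int]] = set()
    for i in range(n):          # acceptor: C=O of residue i
        if frames[i] is None:
            continue
        for j in range(n):      # donor: N-H of residue j
            if abs(i - j) < 2 or frames[j] is None or h_pos[j] is None:
                continue
            r_on = np.linalg.norm(frames[i]["O"] - frames[j]["N"])
            r_ch = np.linalg.norm(frames[i]["C"] - h_pos[j])
            r_oh = np.linalg.norm(frames[i]["O"] - h_pos[j])
            r_cn = np.linalg.norm(frames[i]["C"] - frames[j]["N"])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue        # colliding atoms: not a hydrogen bond
            energy = _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < HB_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def _phi_psi(chain: Chain, frames):
    n = len(frames)
    phi = [None] * n
    psi = [None] * n
    for i in range(n):
        if frames[i] is None:
            continue
        if i > 0 and _contiguous(chain, i - 1, i, frames):
            phi[i] = dihedral_angle(frames[i - 1]["C"], frames[i]["N"],
                                    frames[i]["CA"], frames[i]["C"])
        if i < n - 1 and _contiguous(chain, i, i + 1, frames):
            psi[i] = dihedral_angle(frames[i]["N"], frames[i]["CA"],
                                    frames[i]["C"], frames[i + 1]["N"])
    return phi, psi


def _in(value, lo_hi) -> bool:
    return value is not None and lo_hi[0] <= value <= lo_hi[1]


def _assign_chain(chain: Chain) -> dict[int, str]:
    """Labels keyed by author seq_num, for observed residues only."""
    frames = _backbone(chain)
    if any(f is None for f in frames):
        warnings.warn(f"chain {chain.chain_id}: residues with missing "
                      "backbone atoms labeled C", stacklevel=3)
    bonds = _hydrogen_bonds(chain, frames)
    phi, psi = _phi_psi(chain, frames)
    n = len(frames)
    labels = ["C"] * n

    helix_candidate = [False] * n
    for (i, j) in bonds:
        if j - i == 4:
            for k in range(i + 1, j + 1):
                helix_candidate[k] = True
    turn_candidate = [False] * n
    for (i, j) in bonds:
        if j - i == 3:
            for k in range(i + 1, j):
                turn_candidate[k] = True
    strand_partner = [False] * n
    for (i, j) in bonds:
        if abs(i - j) >= STRAND_MIN_SEP:
            strand_partner[i] = strand_partner[j] = True

    for k in range(n):
        helical = _in(phi[k], HELICAL_PHI) and _in(psi[k], HELICAL_PSI)
        extended = _in(phi[k], EXTENDED_PHI) and (
            _in(psi[k], EXTENDED_PSI_A) or _in(psi[k], EXTENDED_PSI_B))
        if helix_candidate[k] and helical:
            labels[k] = "H"
        elif strand_partner[k] and extended:
            labels[k] = "E"
        elif turn_candidate[k]:
            labels[k] = "T"
    return {chain.observed[k].seq_num: labels[k] for k in range(n)}


def assign_secondary_structure(structure: Structure) -> dict[str, str]:
    """Per-chain label strings over observed residues."""
    return {ch.chain_id: "".join(_assign_chain(ch)[r.seq_num]
                                 for r in ch.observed)
            for ch in structure.chains}


def label_map(structure: Structure) -> dict[tuple[str, int], str]:
    """Labels keyed by (chain_id, author seq_num)."""
    out = {}
    for ch in structure.chains:
        for num, lab in _assign_chain(ch).items():
            out[(ch.chain_id, num)] = lab
    return out


def octapeptide_ss(structure: Structure, site) -> str:
    """The 8-label string over a mapped site's window residues."""
    ref = site.structure_ref
    if ref is None:
        raise ValueError("site is not mapped onto a structure")
    chain = structure.chain(ref.chain_id)
    labels = _assign_chain(chain)
    out = []
    for num in ref.seq_nums:
        if num not in labels:
            raise ValueError(
                f"residue {ref.chain_id}{num} unobserved; the site belongs "
                "in the disordered category")
        out.append(labels[num])
    return "".join(out)


CLASS_PRIORITY = "HETC"


def dominant_class(ss8: str) -> str:
    """Majority label of an octapeptide string; ties resolved H > E > T > C."""
    if len(ss8) != 8:
        raise ValueError("octapeptide label string must have length 8")
    counts = {c: ss8.count(c) for c in set(ss8)}
    best = max(counts.values())
    for c in CLASS_PRIORITY:
        if counts.get(c, 0) == best:
            return c
    raise ValueError(f"unexpected labels in {ss8!r}")


def ss_composition(ss_strings: list[str]) -> dict[str, float]:
    """Fraction of sites per dominant class; fractions sum to 1."""
    if not ss_strings:
        raise ValueError("no sites supplied")
    doms = [dominant_class(s) for s in ss_strings]
    return {c: doms.count(c) / len(doms) for c in CLASS_PRIORITY}
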