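"""Synthetic structures and phosphosite cohorts with known ground truth.

Every generated fixture is verified at generation time with the package's
own surface machinery (rejection sampling with seeded jitter), so planted
labels — buried core, exposed surface, interface-buried, dynamics-rescuable
— are measured facts about the emitted coordinates, not hopes.

Generated proteins are idealized helix bundles: a buried core octapeptide
helix wrapped by a ring of helices and two axial caps, plus a partially
exposed "display" helix on the outside carrying the surface octapeptide.
Residues carry backbone + Cβ atoms only; %SASA on these fixtures therefore
uses the matching reduced-atom reference convention.  The random sequence
alphabet excludes proline so the CDK consensus motif (S/T-P-X-K/R) can only
occur where it is planted deliberately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geo
from .enm_nma import build_enm, ensemble_rsasa, generate_conformers, normal_modes
from .sasa_engine import SASAParams, residue_percent_sasa
from .structure_io import Atom, Chain, Residue, Structure, write_structure

#: no proline (prevents accidental kinase motifs and broken H-bond donors)
SEQUENCE_ALPHABET = "ADEFGHIKLMNQRSTVWY"

#: coarse surface params used for conformer ensembles (big spheres need
#: fewer sample points than atoms do)
ENSEMBLE_SASA_PARAMS = SASAParams(n_sphere_points=240)


class PackingError(RuntimeError):
    """Fixture geometry could not satisfy its guarantees within the retry
    budget."""


# ---------------------------------------------------------------------------
# Frame-level builders


def _helix_frames(n: int) -> list[dict[str, np.ndarray]]:
    """Ideal α-helix frames centered at the origin with axis along +z."""
    frames = geo.build_backbone(n, (geo.HELIX_PHI, geo.HELIX_PSI))
    ca = np.array([f["CA"] for f in frames])
    axis = np.linalg.svd(ca - ca.mean(axis=0))[2][0]
    if (ca[-1] - ca[0]) @ axis < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = float(np.linalg.norm(v))
    if s < 1e-9:
        rot = np.eye(3)
    else:
        c = float(axis @ z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    center = ca.mean(axis=0)
    return [{k: rot @ (p - center) for k, p in f.items()} for f in frames]


def _place(frames, rot: np.ndarray, trans: np.ndarray):
    return [{k: rot @ p + trans for k, p in f.items()} for f in frames]


def _frames_to_structure(frames, sequence: str, structure_id: str,
                         chain_id: str = "A",
                         unobserved: frozenset[int] = frozenset()
                         ) -> Structure:
    """One residue per frame, numbered from 1.  ``unobserved`` holds
    1-based positions whose coordinates are withheld (disordered)."""
    if len(frames) != len(sequence):
        raise ValueError("one frame per sequence letter required")
    residues = []
    serial = 1
    for pos, (frame, aa) in enumerate(zip(frames, sequence), start=1):
        if pos in unobserved:
            residues.append(Residue(chain_id=chain_id, seq_num=pos, aa=aa,
                                    atoms=[], is_observed=False))
            continue
        atoms = []
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CB" and aa == "G":
                continue
            elem = "N" if name == "N" else "O" if name == "O" else "C"
            atoms.append(Atom(name=name, element=elem,
                              coord=frame[name], serial=serial))
            serial += 1
        residues.append(Residue(chain_id=chain_id, seq_num=pos, aa=aa,
                                atoms=atoms))
    return Structure(id=structure_id, chains=[Chain(chain_id=chain_id,
                                                    residues=residues)])


def _check_sequence(sequence: str) -> None:
    from .aminoacids import ONE_TO_THREE

    bad = sorted(set(sequence) - set(ONE_TO_THREE))
    if bad:
        raise ValueError(f"non-canonical residues {bad}")


def build_ideal_helix(sequence: str, structure_id: str = "helix") -> Structure:
    """Idealized α-helix (φ=−57°, ψ=−47°) with backbone + Cβ atoms."""
    if len(sequence) < 6:
        raise ValueError("helix needs at least 6 residues")
    _check_sequence(sequence)
    return _frames_to_structure(_helix_frames(len(sequence)), sequence,
                                structure_id)


def build_extended_peptide(sequence: str,
                           structure_id: str = "extended") -> Structure:
    """Fully extended (φ=−120°, ψ=+120°) peptide."""
    _check_sequence(sequence)
    frames = geo.build_backbone(len(sequence),
                                (geo.EXTENDED_PHI, geo.EXTENDED_PSI))
    return _frames_to_structure(frames, sequence, structure_id)


def build_beta_hairpin(n_per_strand: int = 6,
                       structure_id: str = "hairpin") -> Structure:
    """Two-stranded antiparallel β-hairpin.

    The second strand's rigid placement is chosen by a deterministic grid
    scan maximizing the number of Kabsch-Sander cross-strand hydrogen
    bonds; the two connecting loop residues are interpolated and are not
    part of any guarantee.
    """
    from .secondary_structure import _backbone, _hydrogen_bonds

    strand = geo.build_backbone(n_per_strand,
                                (geo.STRAND_PHI, geo.STRAND_PSI))
    flips = {"y": geo.rotation_matrix([0.0, 1.0, 0.0], 180.0),
             "z": geo.rotation_matrix([0.0, 0.0, 1.0], 180.0)}

    def assemble(flip: str, dx: float, dy: float) -> Structure:
        # 180° rotation keeps the strand's internal geometry but makes it
        # run antiparallel; the chain then reads strand1 -> loop -> strand2
        s2 = _place(strand, flips[flip], np.array([dx, dy, 0.0]))
        a_end, b_start = strand[-1]["C"], s2[0]["N"]
        loop = []
        for t in (1 / 3, 2 / 3):
            mid = a_end + t * (b_start - a_end)
            loop.append({"N": mid + [0, 0, 1.2], "CA": mid,
                         "C": mid + [1.0, 0, -0.8],
                         "O": mid + [1.0, 1.1, -0.9],
                         "CB": mid + [0, -1.3, 0]})
        frames = list(strand) + loop + s2
        return _frames_to_structure(frames, "A" * len(frames), structure_id)

    best, best_count = None, -1
    span = float(strand[-1]["CA"][0] - strand[0]["CA"][0])
    for flip in flips:
        for dx in np.arange(span - 3.0, span + 3.01, 0.5):
            for dy in np.arange(4.2, 5.81, 0.2):
                chain = assemble(flip, float(dx), float(dy)).chains[0]
                frames = _backbone(chain)
                cross = sum(1 for (i, j) in _hydrogen_bonds(chain, frames)
                            if abs(i - j) >= 5)
                if cross > best_count:
                    best, best_count = (flip, float(dx), float(dy)), cross
    if best_count < 2:
        raise PackingError("hairpin scan found no hydrogen-bonded registry")
    return assemble(*best)


# ---------------------------------------------------------------------------
# Helix-bundle globule


@dataclass
class GlobuleFixture:
    structure: Structure
    core_window: list[int]          # seq_nums of the buried octapeptide
    surface_window: list[int]       # seq_nums of the exposed octapeptide
    core_rsasa: float
    surface_rsasa: float
    labels: dict[int, str] = field(default_factory=dict)


#: bundle geometry constants (Å)
RING_RADIUS = 8.0
CAP_Z = 11.5
DISPLAY_RADIUS = 14.2
DISPLAY_ANGLE = math.pi / 6

CORE_MAX_RSASA = 0.1
SURFACE_MIN_RSASA = 0.4
MIN_SEGMENT_CLEARANCE = 0.9


def _bundle_layout(n_residues: int):
    """Split ``n_residues`` into (cap length, ring helix lengths); the core
    contributes 8 and the display helix 9 residues."""
    if n_residues < 50:
        raise ValueError("bundle fixtures need at least 50 residues")
    remaining = n_residues - 17
    cap_len = min(8, max(5, remaining // 8))
    ring_budget = remaining - 2 * cap_len
    n_ring = max(5, round(ring_budget / 9))
    base, extra = divmod(ring_budget, n_ring)
    ring_lengths = [base + (1 if i < extra else 0) for i in range(n_ring)]
    if min(ring_lengths) < 5:
        raise ValueError(f"cannot lay out {n_residues} residues")
    return cap_len, ring_lengths


def _jitter(rng: np.random.Generator, scale: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = geo.rotation_matrix(axis, float(rng.normal(0.0, 3.0 * scale)))
    trans = rng.normal(0.0, 0.3 * scale, size=3)
    return rot, trans


def _bundle_segments(n_residues: int, rng: np.random.Generator,
                     jitter_scale: float,
                     display_radius: float = DISPLAY_RADIUS):
    """Rigid helical segments of the bundle with chain roles."""
    cap_len, ring_lengths = _bundle_layout(n_residues)
    n_ring = len(ring_lengths)
    half = (n_ring + 1) // 2
    ring_places = []
    for i, length in enumerate(ring_lengths):
        theta = 2 * math.pi * i / n_ring
        rot = (geo.rotation_matrix([1.0, 0.0, 0.0], 180.0) if i % 2
               else np.eye(3))
        trans = np.array([RING_RADIUS * math.cos(theta),
                          RING_RADIUS * math.sin(theta), 0.0])
        ring_places.append(("ring", length, rot, trans))
    u = np.array([math.cos(DISPLAY_ANGLE), math.sin(DISPLAY_ANGLE), 0.0])
    order = list(ring_places[:half])
    order.append(("core", 8, np.eye(3), np.zeros(3)))
    order.append(("display", 9, np.eye(3), display_radius * u))
    order.extend(ring_places[half:])
    # caps sit just above/below the ring helix ends
    cap_z = min(CAP_Z, max(8.5, CAP_Z - 0.75 * (9 - max(ring_lengths))))
    for sign, ang in ((+1.0, 0.0), (-1.0, 90.0)):
        rot = (geo.rotation_matrix([0.0, 0.0, 1.0], ang)
               @ geo.rotation_matrix([0.0, 1.0, 0.0], 90.0))
        order.append(("cap", cap_len, rot,
                      np.array([0.0, 0.0, sign * cap_z])))
    segments, roles = [], []
    for role, length, rot, trans in order:
        jrot, jtrans = _jitter(rng, jitter_scale)
        segments.append(_place(_helix_frames(length), jrot @ rot,
                               trans + jtrans))
        roles.append(role)
    return segments, roles


def _segment_clearance(segments) -> float:
    from scipy.spatial import cKDTree

    coords = [np.array([p for f in seg for p in f.values()])
              for seg in segments]
    best = math.inf
    for i in range(len(coords)):
        tree = cKDTree(coords[i])
        for j in range(i + 1, len(coords)):
            best = min(best, float(tree.query(coords[j])[0].min()))
    return best


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SEQUENCE_ALPHABET), size=n))


def _window_positions(roles, lengths, role: str, size: int = 8) -> list[int]:
    """1-based chain positions of the first ``size`` residues of a role's
    segment."""
    offset = 0
    for r, length in zip(roles, lengths):
        if r == role:
            return list(range(offset + 1, offset + 1 + size))
        offset += length
    raise ValueError(f"no {role} segment")


def build_globule(n_residues: int = 87, seed: int = 0,
                  motif: bool = False, phospho: str = "S",
                  params: SASAParams | None = None,
                  max_attempts: int = 8) -> GlobuleFixture:
    """Compact helix bundle with a buried core octapeptide and an exposed
    surface octapeptide, both verified by the surface engine at generation
    time (regenerated with fresh jitter on violation).

    ``motif=True`` plants the CDK consensus S/T-P-X-K/R in the core
    window; ``phospho`` (S/T/Y) sits at position 4 of both windows.
    """
    params = params or SASAParams()
    rng = np.random.default_rng(seed)
    last = "no attempt"
    for attempt in range(max_attempts):
        scale = 0.7 ** attempt
        segments, roles = _bundle_segments(n_residues, rng, scale)
        lengths = [len(s) for s in segments]
        core_win = _window_positions(roles, lengths, "core")
        surf_win = _window_positions(roles, lengths, "display")
        seq = list(_random_sequence(rng, n_residues))
        core_phospho = phospho if phospho in "ST" else "S"
        seq[core_win[3] - 1] = core_phospho if motif else phospho
        if motif:
            seq[core_win[4] - 1] = "P"
            seq[core_win[6] - 1] = "K"
        seq[surf_win[3] - 1] = phospho
        structure = _frames_to_structure(
            [f for s in segments for f in s], "".join(seq),
            f"globule{seed}")
        if _segment_clearance(segments) < MIN_SEGMENT_CLEARANCE:
            last = "segment clash"
            continue
        pct = residue_percent_sasa(structure, params)
        core = float(np.mean([pct[("A", p)].percent_sasa for p in core_win]))
        surf = float(np.mean([pct[("A", p)].percent_sasa for p in surf_win]))
        if core >= CORE_MAX_RSASA:
            last = f"core rSASA {core:.3f}"
            continue
        if surf <= SURFACE_MIN_RSASA:
            last = f"surface rSASA {surf:.3f}"
            continue
        labels = {}
        for p in range(1, n_residues + 1):
            v = pct[("A", p)].percent_sasa
            if v < CORE_MAX_RSASA:
                labels[p] = "core"
            elif v > SURFACE_MIN_RSASA:
                labels[p] = "surface"
        return GlobuleFixture(structure=structure, core_window=core_win,
                              surface_window=surf_win, core_rsasa=core,
                              surface_rsasa=surf, labels=labels)
    raise PackingError(
        f"globule guarantees not met in {max_attempts} attempts ({last})")


# ---------------------------------------------------------------------------
# Oligomers


ASSEMBLY_MAX_RSASA = 0.2
MONOMER_MIN_RSASA = 0.3
CHAIN_CLEARANCE = 1.8
#: partner nestings tried first: (roll about the contact axis, z shift)
_NESTING_ORDER = tuple((g, dz) for dz in (-3.0, 0.0, 3.0)
                       for g in range(0, 360, 30))
_FAST_SCAN_PARAMS = SASAParams(n_sphere_points=240)


def make_multimer(monomer: Structure, n_copies: int,
                  interface_window: list[int],
                  params: SASAParams | None = None) -> Structure:
    """Homo-oligomer in which a partner chain buries the given surface
    window of chain A.

    The partner is the monomer flipped to face the window and pressed
    against it along the window's outward direction at the closest
    clash-free distance; rolls about the contact axis and axial shifts are
    scanned until the window is occluded (rSASA < 0.2 in the assembly
    while ≥ 0.3 in the monomer, both verified).  Copies beyond the second
    are parked on the far side and take no part in the occlusion
    guarantee.
    """
    params = params or SASAParams()
    if n_copies == 1:
        return monomer
    chain = monomer.chains[0]
    pct = residue_percent_sasa(monomer, params)
    mono_rsasa = float(np.mean([pct[(chain.chain_id, p)].percent_sasa
                                for p in interface_window]))
    if mono_rsasa < MONOMER_MIN_RSASA:
        raise PackingError(
            f"window rSASA {mono_rsasa:.3f} in the monomer; an interface "
            "fixture needs an exposed window")
    all_coords = monomer.coords()
    centroid = all_coords.mean(axis=0)
    win_atoms = np.array([a.coord for p in interface_window
                          for a in chain.residue_at(p).atoms])
    u = win_atoms.mean(axis=0) - centroid
    u /= np.linalg.norm(u)
    w = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(u, [1.0, 0.0, 0.0])
    w /= np.linalg.norm(w)

    from scipy.spatial import cKDTree

    tree = cKDTree(all_coords)
    chain_ids = "BCDEFGH"
    z = np.array([0.0, 0.0, 1.0])

    def place(gamma: float, dz: float):
        rot = geo.rotation_matrix(u, gamma) @ geo.rotation_matrix(w, 180.0)
        base = (all_coords - centroid) @ rot.T + centroid + dz * z
        for d in np.arange(10.0, 60.0, 0.25):
            if tree.query(base + d * u)[0].min() >= CHAIN_CLEARANCE:
                return rot, centroid + d * u + dz * z
        return None, None

    def assembly_rsasa(asm: Structure, p: SASAParams) -> float:
        pct2 = residue_percent_sasa(asm, p)
        return float(np.mean([pct2[(chain.chain_id, q)].percent_sasa
                              for q in interface_window]))

    for gamma, dz in _NESTING_ORDER:
        rot, new_pivot = place(float(gamma), dz)
        if rot is None:
            continue
        partner = _transform_chain(chain, chain_ids[0], rot, centroid,
                                   new_pivot)
        assembly = Structure(id=f"{monomer.id}_x{n_copies}",
                             chains=[chain, partner])
        if assembly_rsasa(assembly, _FAST_SCAN_PARAMS) >= \
                ASSEMBLY_MAX_RSASA - 0.01:
            continue
        if assembly_rsasa(assembly, params) < ASSEMBLY_MAX_RSASA:
            for extra in range(n_copies - 2):
                assembly.chains.append(_transform_chain(
                    chain, chain_ids[extra + 1], np.eye(3), centroid,
                    centroid - (26.0 + 20.0 * extra) * u))
            return assembly
    raise PackingError("could not occlude the interface window")


INTERFACE_DISPLAY_RADIUS = 11.8


def build_interface_dimer(seed: int = 0, phospho: str = "S",
                          n_residues: int = 87,
                          params: SASAParams | None = None
                          ) -> tuple[Structure, list[int]]:
    """Homodimer fixture: a bundle whose site helix sits low enough on the
    surface that a nested partner chain can bury it.

    Returns (assembly, window seq_nums); the window is exposed (≥ 0.3) on
    the monomer and occluded (< 0.2) in the dimer, both measured.
    """
    params = params or SASAParams()
    rng = np.random.default_rng(seed)
    last = "no attempt"
    for attempt in range(6):
        scale = 0.7 ** attempt
        segments, roles = _bundle_segments(
            n_residues, rng, scale,
            display_radius=INTERFACE_DISPLAY_RADIUS)
        lengths = [len(s) for s in segments]
        window = _window_positions(roles, lengths, "display")
        seq = list(_random_sequence(rng, n_residues))
        seq[window[3] - 1] = phospho
        monomer = _frames_to_structure(
            [f for s in segments for f in s], "".join(seq), f"iface{seed}")
        try:
            assembly = make_multimer(monomer, 2, window, params)
        except PackingError as exc:
            last = str(exc)
            continue
        return assembly, window
    raise PackingError(f"no occludable dimer found ({last})")


def _transform_chain(chain: Chain, new_id: str, rot: np.ndarray,
                     pivot: np.ndarray, new_pivot: np.ndarray) -> Chain:
    residues = []
    for res in chain.residues:
        atoms = [Atom(name=a.name, element=a.element,
                      coord=rot @ (a.coord - pivot) + new_pivot,
                      occupancy=a.occupancy, serial=a.serial)
                 for a in res.atoms]
        residues.append(Residue(chain_id=new_id, seq_num=res.seq_num,
                                aa=res.aa, atoms=atoms,
                                is_observed=res.is_observed,
                                modified=res.modified, icode=res.icode))
    return Chain(chain_id=new_id, residues=residues)


# ---------------------------------------------------------------------------
# Dynamics fixtures (floppy arm / rigid cage)


@dataclass
class ArmFixture:
    structure: Structure
    window: list[int]               # seq_nums of the covered site
    input_rsasa: float              # all-atom, with the arm in place
    ensemble_max: float             # anchored coarse maximum over conformers
    arm_positions: list[int]


ARM_LENGTH = 10
#: (display radius, arm offset) candidates, scanned in order
ARM_CANDIDATES = ((11.4, 5.5), (11.0, 6.0), (11.2, 5.8), (11.0, 6.5),
                  (11.6, 5.5), (11.4, 6.0), (10.8, 6.2))
ARM_INPUT_MAX = 0.195
ARM_RESCUE_MIN = 0.205


def build_floppy_arm(n_residues: int = 97, seed: int = 0, phospho: str = "S",
                     params: SASAParams | None = None,
                     enm_kwargs: dict | None = None,
                     verify_dynamics: bool = True) -> ArmFixture:
    """Bundle whose surface octapeptide is buried under a terminal helical
    arm, verified to be rescuable by the normal-mode ensemble.

    The site helix sits sunk toward the bundle and the arm hovers just
    outside it; candidate geometries are scanned until the site's all-atom
    rSASA falls below the classification threshold while some low-energy
    conformer's anchored coarse rSASA exceeds it.
    """
    params = params or SASAParams()
    enm_kwargs = enm_kwargs or {}
    body_n = n_residues - ARM_LENGTH
    rng = np.random.default_rng(seed)
    last = "no candidate"
    for r_disp, arm_d in ARM_CANDIDATES:
        for attempt in range(3):
            scale = 0.5 * 0.7 ** attempt
            segments, roles = _bundle_segments(body_n, rng, scale,
                                               display_radius=r_disp)
            u = np.array([math.cos(DISPLAY_ANGLE),
                          math.sin(DISPLAY_ANGLE), 0.0])
            jrot, jtrans = _jitter(rng, scale)
            segments.append(_place(_helix_frames(ARM_LENGTH), jrot,
                                   (r_disp + arm_d) * u + jtrans))
            roles.append("arm")
            lengths = [len(s) for s in segments]
            window = _window_positions(roles, lengths, "display")
            arm_start = sum(lengths[:-1]) + 1
            seq = list(_random_sequence(rng, n_residues))
            seq[window[3] - 1] = phospho
            structure = _frames_to_structure(
                [f for s in segments for f in s], "".join(seq), f"arm{seed}")
            pct = residue_percent_sasa(structure, params)
            rsasa_in = float(np.mean([pct[("A", p)].percent_sasa
                                      for p in window]))
            if not 0.10 < rsasa_in < ARM_INPUT_MAX:
                last = f"input rSASA {rsasa_in:.3f}"
                continue
            if not verify_dynamics:
                return ArmFixture(structure=structure, window=window,
                                  input_rsasa=rsasa_in,
                                  ensemble_max=float("nan"),
                                  arm_positions=list(range(
                                      arm_start, n_residues + 1)))
            model = build_enm(structure)
            ensemble = generate_conformers(model, normal_modes(model),
                                           **enm_kwargs)
            _, mx = ensemble_rsasa(ensemble, model, window,
                                   ENSEMBLE_SASA_PARAMS,
                                   anchor_rsasa=rsasa_in)
            if mx < ARM_RESCUE_MIN:
                last = f"ensemble max {mx:.3f}"
                continue
            return ArmFixture(structure=structure, window=window,
                              input_rsasa=rsasa_in, ensemble_max=mx,
                              arm_positions=list(range(arm_start,
                                                       n_residues + 1)))
    raise PackingError(f"no rescuable arm geometry found ({last})")


CAGE_ENSEMBLE_MAX = 0.1


def verify_rigid_cage(fixture: GlobuleFixture,
                      enm_kwargs: dict | None = None) -> float:
    """Negative control: the core octapeptide of a globule must stay
    inaccessible (< 0.1) in every conformer of the default ensemble.
    Returns the ensemble maximum; raises on violation."""
    model = build_enm(fixture.structure)
    ensemble = generate_conformers(model, normal_modes(model),
                                   **(enm_kwargs or {}))
    _, mx = ensemble_rsasa(ensemble, model, fixture.core_window,
                           ENSEMBLE_SASA_PARAMS,
                           anchor_rsasa=fixture.core_rsasa)
    if mx >= CAGE_ENSEMBLE_MAX:
        raise PackingError(f"cage conformer reached rSASA {mx:.3f}")
    return mx


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Planted-truth cohort description.

    ``rates`` maps category names to fractions summing to 1; counts follow
    largest-remainder rounding.  Categories: exposed, buried,
    interface_buried, motif_buried, alternate, dynamics, disordered,
    mutated, terminal, low_coverage.
    """

    n_proteins: int = 50
    seed: int = 0
    rates: dict[str, float] = field(default_factory=lambda: {
        "exposed": 0.18, "buried": 0.12, "interface_buried": 0.12,
        "motif_buried": 0.10, "alternate": 0.10, "dynamics": 0.08,
        "disordered": 0.10, "mutated": 0.08, "terminal": 0.06,
        "low_coverage": 0.06,
    })

    def counts(self) -> dict[str, int]:
        if abs(sum(self.rates.values()) - 1.0) > 1e-9:
            raise ValueError("rates must sum to 1")
        raw = {k: v * self.n_proteins for k, v in self.rates.items()}
        counts = {k: int(math.floor(v)) for k, v in raw.items()}
        shortfall = self.n_proteins - sum(counts.values())
        for k in sorted(raw, key=lambda k: raw[k] - counts[k],
                        reverse=True)[:shortfall]:
            counts[k] += 1
        return counts


#: expected downstream behaviour per category:
#: (match status, final label, rescue rule)
CATEGORY_TRUTH = {
    "exposed": ("matched", "allowed", "none"),
    "buried": ("matched", "disallowed", "none"),
    "interface_buried": ("matched", "allowed", "interface"),
    "motif_buried": ("matched", "allowed", "consensus_motif"),
    "alternate": ("matched", "allowed", "alternate_structure"),
    "dynamics": ("matched", "allowed", "dynamics"),
    "disordered": ("disordered", "", ""),
    "mutated": ("mutated", "", ""),
    "terminal": ("terminal", "", ""),
    "low_coverage": ("low_coverage", "", ""),
}

LOW_COVERAGE_FRACTION = 0.31


def _window15(sequence: str, position: int) -> str:
    """PhosphoSitePlus-style window: 7 residues either side, X-padded."""
    return "".join(sequence[i] if 0 <= i < len(sequence) else "X"
                   for i in range(position - 8, position + 7))


def generate_cohort(spec: CohortSpec, out_dir: str | Path,
                    params: SASAParams | None = None) -> dict:
    """Write a fully verified cohort: PDB structures, a phosphosite table
    and a planted-truth table.  Deterministic for a fixed spec."""
    params = params or SASAParams()
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts()
    site_rows, truth_rows, manifest = [], [], []
    index = 0
    for category in spec.rates:
        for _ in range(counts.get(category, 0)):
            index += 1
            acc = f"SYN{index:04d}"
            # a handful of derived seeds so one unlucky geometry draw
            # cannot sink the whole cohort
            child_seeds = [int(rng.integers(0, 2**31 - 1))
                           for _ in range(5)]
            for attempt, child_seed in enumerate(child_seeds):
                try:
                    files, row = _make_protein(acc, category, child_seed,
                                               out, params)
                    break
                except PackingError:
                    if attempt == len(child_seeds) - 1:
                        raise
            site_rows.append(row)
            status, label, rescue = CATEGORY_TRUTH[category]
            truth_rows.append((acc, category, status, label, rescue,
                               row[1]))
            manifest.append((acc, category, ";".join(files)))
    _write_tsv(out / "phosphosites.tsv",
               ("accession", "position", "residue", "window15", "kinase"),
               site_rows)
    _write_tsv(out / "truth.tsv",
               ("accession", "category", "status", "label", "rescue",
                "position"), truth_rows)
    _write_tsv(out / "manifest.tsv", ("accession", "category", "files"),
               manifest)
    return {"counts": counts, "out_dir": str(out)}


def _write_tsv(path: Path, header, rows) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def _save(out: Path, name: str, structure: Structure) -> str:
    path = out / "structures" / f"{name}.pdb"
    path.write_text(write_structure(structure))
    return path.name


def _unobserve(chain: Chain, gone: set[int]) -> None:
    chain.residues = [
        Residue(chain_id=chain.chain_id, seq_num=r.seq_num, aa=r.aa,
                atoms=[], is_observed=False) if r.seq_num in gone else r
        for r in chain.residues]


def _make_protein(acc: str, category: str, seed: int, out: Path,
                  params: SASAParams):
    """Build, verify and write one protein; returns (files, phosphosite
    table row)."""
    rng = np.random.default_rng(seed)
    phospho = str(rng.choice(list("STY")))
    kinase = "0"

    if category == "terminal":
        seq = _random_sequence(rng, 30)
        pos = 2
        seq = seq[:pos - 1] + phospho + seq[pos:]
        structure = build_ideal_helix(seq, structure_id=acc)
        return ([_save(out, acc, structure)],
                (acc, pos, phospho, _window15(seq, pos), kinase))

    if category in ("dynamics", "alternate"):
        fixture = build_floppy_arm(seed=seed, phospho=phospho, params=params,
                                   verify_dynamics=category == "dynamics")
        fixture.structure.id = acc
        seq = fixture.structure.chains[0].sequence
        pos = fixture.window[3]
        files = [_save(out, acc, fixture.structure)]
        if category == "alternate":
            # open form: the covering arm undergoes an order -> disorder
            # transition, exposing the site in the alternate structure
            open_form = Structure(id=f"{acc}_alt", chains=[_transform_chain(
                fixture.structure.chains[0], "A", np.eye(3),
                np.zeros(3), np.zeros(3))])
            _unobserve(open_form.chains[0], set(fixture.arm_positions))
            pct = residue_percent_sasa(open_form, params)
            open_rsasa = float(np.mean([pct[("A", p)].percent_sasa
                                        for p in fixture.window]))
            if open_rsasa < ASSEMBLY_MAX_RSASA:
                raise PackingError(
                    f"open form rSASA {open_rsasa:.3f}; not an alternate")
            files.append(_save(out, f"{acc}__alt", open_form))
        return files, (acc, pos, phospho, _window15(seq, pos), kinase)

    if category == "interface_buried":
        assembly, window = build_interface_dimer(seed=seed, phospho=phospho,
                                                 params=params)
        assembly.id = acc
        seq = assembly.chains[0].sequence
        pos = window[3]
        return ([_save(out, acc, assembly)],
                (acc, pos, seq[pos - 1], _window15(seq, pos), kinase))

    motif = category == "motif_buried"
    fixture = build_globule(seed=seed, motif=motif, phospho=phospho,
                            params=params)
    fixture.structure.id = acc
    seq = fixture.structure.chains[0].sequence
    window = (fixture.core_window if category in ("buried", "motif_buried")
              else fixture.surface_window)
    pos = window[3]
    phospho = seq[pos - 1]

    if category == "buried":
        verify_rigid_cage(fixture)

    if category == "disordered":
        _unobserve(fixture.structure.chains[0], set(window[4:6]))

    if category == "mutated":
        res = fixture.structure.chains[0].residue_at(window[5])
        res.aa = next(a for a in SEQUENCE_ALPHABET
                      if a not in (res.aa, "G"))

    if category == "low_coverage":
        chain = fixture.structure.chains[0]
        n_gone = math.ceil(LOW_COVERAGE_FRACTION * len(chain.residues))
        removable = [r.seq_num for r in chain.residues
                     if r.seq_num not in set(window)]
        _unobserve(chain, set(removable[:n_gone]))

    return ([_save(out, acc, fixture.structure)],
            (acc, pos, phospho, _window15(seq, pos), kinase))
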