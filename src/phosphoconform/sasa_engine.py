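"""Solvent accessible surface area (SASA) computations.

Implements the Shrake-Rupley rolling-probe algorithm with a deterministic
generalized-spiral point lattice (no RNG), normalization of per-residue
areas against extended Gly-X-Gly (or Ala-X-Ala) tripeptide references
(%SASA), octapeptide averaging (rSASA), a coarse single-sphere-per-residue
variant for Cα-only conformers, and residue depth measured from the
retained accessible surface points.

%SASA is the ratio of a residue's area in the folded structure to the area
of the same residue in an extended tripeptide; it is deliberately not
clamped at 1 (normalization is a convention, and the classification
thresholds operate on raw ratios).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .aminoacids import ONE_TO_THREE, VDW_RADII, coarse_radius
from .structure_io import Residue, Structure

#: atom names that exist in the reduced (backbone + CB) representation
REDUCED_ATOMS = {"N", "CA", "C", "O", "CB"}


class RadiusLookupError(KeyError):
    """An atom's element has no entry in the radius table."""


class IncompleteOctapeptideError(ValueError):
    """One or more of the eight window residues has no coordinates."""


class NoSurfaceError(ValueError):
    """The structure exposes no accessible surface at all."""


@dataclass
class SASAParams:
    """Parameters of the surface calculation.

    probe_radius : solvent probe radius in Å (water, 1.4 Å).
    n_sphere_points : test points per atom; more points, finer resolution.
    radii_set : name of the van der Waals radius table (only "bondi" ships).
    reference_flank : flanking residue of the extended tripeptide reference,
        "G" or "A".
    reference_atoms : atom convention for the reference state: "full"
        (all heavy atoms), "reduced" (backbone + CB, matching generated
        fixtures), or "auto" (reduced iff the query structure itself
        contains only backbone + CB atoms).
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_set: str = "bondi"
    reference_flank: str = "G"
    reference_atoms: str = "auto"

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be at least 92")
        if self.reference_flank not in ("G", "A"):
            raise ValueError("reference_flank must be 'G' or 'A'")
        if self.reference_atoms not in ("full", "reduced", "auto"):
            raise ValueError("reference_atoms must be full/reduced/auto")


@dataclass
class ResidueSASA:
    sasa: float
    ref_sasa: float
    percent_sasa: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sasa < 0:
            raise ValueError("negative SASA")
        if self.ref_sasa <= 0:
            raise ValueError("reference SASA must be positive")
        self.percent_sasa = self.sasa / self.ref_sasa


def element_radius(element: str, atom_label: str = "?") -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise RadiusLookupError(
            f"no van der Waals radius for element {element!r} "
            f"(atom {atom_label})") from None


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Proper rotation aligning the molecule's principal axes, with signs
    fixed deterministically.  Sampling sphere lattices in this frame makes
    the surface computation invariant under rigid-body transforms of the
    input (up to floating-point noise)."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    for k in range(3):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float,
                  n_points: int, collect_surface: bool = False,
                  canonical: bool = True
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-atom accessible areas; optionally the retained surface points.

    Each atom is covered by a deterministic spiral lattice of ``n_points``
    on its probe-expanded sphere; points not occluded by any other expanded
    sphere are accessible, and the area is the accessible fraction of the
    expanded-sphere area.  With ``canonical=True`` the lattice is oriented
    along the molecule's principal axes, making results invariant under
    rigid-body transforms of the input.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    expanded = np.asarray(radii, dtype=float) + probe
    unit = geometry.fibonacci_sphere(n_points)
    if canonical and n > 1:
        unit = unit @ _canonical_orientation(coords).T
    areas = np.zeros(n)
    surface_pts: list[np.ndarray] = []
    if n == 0:
        return areas, (np.zeros((0, 3)) if collect_surface else None)
    tree = cKDTree(coords)
    r_max = expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        nbr = tree.query_ball_point(coords[i], expanded[i] + r_max)
        nbr = [j for j in nbr if j != i]
        if nbr:
            diff = pts[:, None, :] - coords[nbr][None, :, :]
            d2 = np.einsum("pjk,pjk->pj", diff, diff)
            accessible = ~np.any(d2 < expanded[nbr][None, :] ** 2, axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        frac = accessible.mean()
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
        if collect_surface and accessible.any():
            surface_pts.append(pts[accessible])
    if collect_surface:
        surface = (np.vstack(surface_pts) if surface_pts
                   else np.zeros((0, 3)))
        return areas, surface
    return areas, None


def _structure_arrays(structure: Structure):
    pairs = structure.atoms()
    coords = np.array([a.coord for _, a in pairs]) if pairs else np.zeros((0, 3))
    radii = np.array([element_radius(a.element, a.name) for _, a in pairs])
    return pairs, coords, radii


def atom_sasa(structure: Structure, params: SASAParams | None = None
              ) -> np.ndarray:
    """Accessible area (Å²) per atom, ordered as ``structure.atoms()``."""
    params = params or SASAParams()
    _, coords, radii = _structure_arrays(structure)
    areas, _ = shrake_rupley(coords, radii, params.probe_radius,
                             params.n_sphere_points)
    return areas


def residue_sasa(structure: Structure, params: SASAParams | None = None
                 ) -> dict[tuple[str, int], float]:
    """Per-residue areas keyed by (chain_id, author seq_num).

    A residue's area is the sum of its member atoms' areas, so the total
    over residues equals the total over atoms.
    """
    params = params or SASAParams()
    pairs, coords, radii = _structure_arrays(structure)
    areas, _ = shrake_rupley(coords, radii, params.probe_radius,
                             params.n_sphere_points)
    out: dict[tuple[str, int], float] = {}
    for (res, _), area in zip(pairs, areas):
        key = (res.chain_id, res.seq_num)
        out[key] = out.get(key, 0.0) + float(area)
    return out


def _build_reference_tripeptide(aa: str, flank: str, atom_set: str):
    """Extended tripeptide coordinates; returns (coords, radii, central_mask)."""
    backbone = geometry.build_backbone(
        3, (geometry.EXTENDED_PHI, geometry.EXTENDED_PSI), include_cb=True)
    coords: list[np.ndarray] = []
    radii: list[float] = []
    central: list[bool] = []
    seq = (flank, aa, flank)
    for i, (res_aa, frame) in enumerate(zip(seq, backbone)):
        names = ["N", "CA", "C", "O"]
        if res_aa != "G":
            names.append("CB")
        for name in names:
            coords.append(frame[name])
            radii.append(VDW_RADII["N" if name == "N" else
                                   "O" if name == "O" else "C"])
            central.append(i == 1)
        if i == 1 and atom_set == "full" and res_aa not in ("G", "A"):
            for coord, elem in _ccd_side_chain(res_aa, frame):
                coords.append(coord)
                radii.append(element_radius(elem, f"{res_aa} side chain"))
                central.append(True)
    return np.array(coords), np.array(radii), np.array(central)


def _ccd_side_chain(aa: str, frame: dict[str, np.ndarray]):
    """Ideal-geometry side-chain heavy atoms (beyond CB) grafted onto the
    extended backbone frame via superposition of N/CA/C."""
    from biotite.structure.info import residue as ccd_residue

    template = ccd_residue(ONE_TO_THREE[aa])
    template = template[template.element != "H"]
    names = list(template.atom_name)
    tmpl_bb = np.array([template.coord[names.index(n)] for n in ("N", "CA", "C")])
    target_bb = np.array([frame["N"], frame["CA"], frame["C"]])
    rot, trans = geometry.kabsch(tmpl_bb, target_bb)
    out = []
    for name, elem, coord in zip(template.atom_name, template.element,
                                 template.coord):
        if name in ("N", "CA", "C", "O", "CB", "OXT"):
            continue
        out.append((coord @ rot.T + trans, str(elem)))
    return out


@functools.lru_cache(maxsize=256)
def _reference_sasa_cached(aa: str, flank: str, atom_set: str,
                           probe: float, n_points: int) -> float:
    coords, radii, central = _build_reference_tripeptide(aa, flank, atom_set)
    areas, _ = shrake_rupley(coords, radii, probe, n_points)
    return float(areas[central].sum())


def reference_sasa(aa: str, params: SASAParams | None = None,
                   flank: str | None = None, atom_set: str = "full") -> float:
    """Central-residue SASA of a programmatically built extended
    (φ≈−120°, ψ≈+120°) flank-X-flank tripeptide.  Cached; deterministic."""
    params = params or SASAParams()
    flank = flank or params.reference_flank
    if aa not in ONE_TO_THREE:
        raise ValueError(f"non-canonical amino acid {aa!r}")
    if atom_set == "auto":
        atom_set = "full"
    return _reference_sasa_cached(aa, flank, atom_set,
                                  params.probe_radius, params.n_sphere_points)


def _effective_atom_set(structure: Structure, params: SASAParams) -> str:
    if params.reference_atoms != "auto":
        return params.reference_atoms
    names = {a.name for _, a in structure.atoms()}
    return "reduced" if names <= REDUCED_ATOMS else "full"


def residue_percent_sasa(structure: Structure,
                         params: SASAParams | None = None
                         ) -> dict[tuple[str, int], ResidueSASA]:
    """%SASA (folded/reference ratio) for every observed residue."""
    params = params or SASAParams()
    atom_set = _effective_atom_set(structure, params)
    raw = residue_sasa(structure, params)
    out = {}
    for ch in structure.chains:
        for res in ch.observed:
            key = (ch.chain_id, res.seq_num)
            aa = res.aa if res.aa in ONE_TO_THREE else "G"
            ref = reference_sasa(aa, params, atom_set=atom_set)
            out[key] = ResidueSASA(sasa=raw.get(key, 0.0), ref_sasa=ref)
    return out


def octapeptide_rsasa(structure: Structure, site,
                      params: SASAParams | None = None,
                      percent: dict[tuple[str, int], ResidueSASA] | None = None
                      ) -> float:
    """rSASA of a site: the mean %SASA of its eight window residues.

    ``site`` must carry a ``structure_ref`` with the chain id and the eight
    author residue numbers.  Raises :class:`IncompleteOctapeptideError` if
    any of the eight residues lacks coordinates (such sites belong in the
    disordered category, not here).
    """
    params = params or SASAParams()
    ref = site.structure_ref
    chain = structure.chain(ref.chain_id)
    by_num = {r.seq_num: r for r in chain.residues}
    for num in ref.seq_nums:
        res = by_num.get(num)
        if res is None or not res.is_observed:
            raise IncompleteOctapeptideError(
                f"residue {ref.chain_id}{num} of site {site.sequence8} "
                "has no coordinates")
    if percent is None:
        percent = residue_percent_sasa(structure, params)
    values = [percent[(ref.chain_id, num)].percent_sasa
              for num in ref.seq_nums]
    rsasa = float(np.mean(values))
    site.rsasa = rsasa
    return rsasa


# ---------------------------------------------------------------------------
# Coarse (Cα-only) model


@functools.lru_cache(maxsize=64)
def _coarse_reference(aa: str, probe: float, n_points: int) -> float:
    """Central-sphere SASA of an extended three-sphere 'tripeptide':
    Gly-sized flank spheres at the ±3.8 Å Cα positions."""
    coords = np.array([[-3.8, 0, 0], [0, 0, 0], [3.8, 0, 0]])
    radii = np.array([coarse_radius("G"), coarse_radius(aa),
                      coarse_radius("G")])
    areas, _ = shrake_rupley(coords, radii, probe, n_points)
    return float(areas[1])


def coarse_residue_sasa(ca_coords: np.ndarray, aas: str | list[str],
                        params: SASAParams | None = None) -> np.ndarray:
    """Per-residue %SASA of a Cα-only model.

    Each residue is a single sphere at its Cα with a volume-derived radius;
    areas are normalized by coarse extended-tripeptide references, so the
    output is on the same 0-1-ish scale as the all-atom %SASA.
    """
    params = params or SASAParams()
    ca_coords = np.asarray(ca_coords, dtype=float)
    if len(ca_coords) != len(aas):
        raise ValueError("one Cα coordinate per residue required")
    if len(np.unique(ca_coords.round(6), axis=0)) != len(ca_coords):
        raise ValueError("duplicate residue positions in Cα model")
    radii = np.array([coarse_radius(a) for a in aas])
    areas, _ = shrake_rupley(ca_coords, radii, params.probe_radius,
                             params.n_sphere_points)
    refs = np.array([_coarse_reference(a, params.probe_radius,
                                       params.n_sphere_points) for a in aas])
    return areas / refs


def coarse_rsasa(ca_coords: np.ndarray, aas: str | list[str],
                 window_indices: list[int],
                 params: SASAParams | None = None) -> float:
    """Mean coarse %SASA over the 0-based ``window_indices``."""
    per_res = coarse_residue_sasa(ca_coords, aas, params)
    return float(np.mean(per_res[window_indices]))


# ---------------------------------------------------------------------------
# Residue depth


def all_residue_depths(structure: Structure,
                       params: SASAParams | None = None
                       ) -> dict[tuple[str, int], float]:
    """Depth (Å) of every observed residue.

    Per atom: distance to the nearest solvent-accessible surface point,
    minus the atom's own probe-contact radius (so a fully exposed atom has
    depth ≈ 0); the residue depth is the mean over its atoms.  The farther
    a residue from the protein surface, the larger the value.
    """
    params = params or SASAParams()
    pairs, coords, radii = _structure_arrays(structure)
    _, surface = shrake_rupley(coords, radii, params.probe_radius,
                               params.n_sphere_points, collect_surface=True)
    if surface is None or len(surface) == 0:
        raise NoSurfaceError("structure exposes no accessible surface")
    surface = _outer_surface(surface)
    tree = cKDTree(surface)
    dists, _ = tree.query(coords)
    depths = np.maximum(dists - (radii + params.probe_radius), 0.0)
    out: dict[tuple[str, int], list[float]] = {}
    for (res, _), d in zip(pairs, depths):
        out.setdefault((res.chain_id, res.seq_num), []).append(float(d))
    return {k: float(np.mean(v)) for k, v in out.items()}


def _outer_surface(points: np.ndarray, eps: float = 1.5) -> np.ndarray:
    """Largest connected patch of surface points.

    Pairwise sphere occlusion retains sample points lining interior voids
    that bulk solvent can never reach; those patches are disconnected from
    the outer envelope and are discarded so depth is measured from the
    real protein surface.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(points)
    if n < 2:
        return points
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp == 1:
        return points
    counts = np.bincount(labels)
    return points[labels == np.argmax(counts)]


def residue_depth(structure: Structure, residue: Residue,
                  params: SASAParams | None = None) -> float:
    """Depth of a single residue; the farther from the surface, the larger."""
    if not residue.is_observed:
        raise ValueError("depth undefined for a residue without coordinates")
    depths = all_residue_depths(structure, params)
    return depths[(residue.chain_id, residue.seq_num)]
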