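"""Cα elastic network model (ENM) normal-mode analysis and conformers.

Each residue is a single node at its Cα position; nodes closer than a
cutoff R_C (default 10 Å) are joined by identical harmonic springs with the
crystal-structure distance as the rest length:

    E = ½ k Σ_{d0_ij < R_C} (d_ij − d0_ij)²

Masses are uniform (unit) and k is an arbitrary unit constant, since only
mode shapes and their ordering matter here.  Diagonalizing the 3N×3N
Hessian yields 3N−6 non-zero modes for a connected three-dimensional
network; the six near-zero eigenvalues are rigid-body motions.  Low-energy
conformer ensembles are built by displacing the structure at evenly spaced
amplitudes along each of the lowest-frequency modes — by default 20 modes ×
20 conformers per mode + the input structure = 401 conformers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .structure_io import Structure

DEFAULT_CUTOFF = 10.0      # Å, R_C
DEFAULT_N_MODES = 20
DEFAULT_N_STEPS = 20
DEFAULT_MAX_AMP = 2.0      # Å, largest per-Cα displacement of a conformer

#: eigenvalues below this fraction of the largest are rigid-body modes
ZERO_EIGENVALUE_REL_TOL = 1e-8


class MissingCAError(ValueError):
    """Residues without a Cα atom; named in the message."""


class DisconnectedNetworkError(ValueError):
    """More than six near-zero eigenvalues: the spring network has
    disconnected or degenerate components."""


@dataclass
class ENMModel:
    ca_coords: np.ndarray            # N×3 Å reference (crystal) coordinates
    contacts: np.ndarray             # (M, 2) int pairs i<j within R_C
    d0: np.ndarray                   # (M,) reference distances
    k: float = 1.0
    cutoff: float = DEFAULT_CUTOFF
    aas: list[str] = field(default_factory=list)
    seq_nums: list[int] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.ca_coords)


@dataclass
class ModeSet:
    eigenvalues: np.ndarray          # ascending, length 3N
    eigenvectors: np.ndarray         # (3N, 3N), columns matching eigenvalues
    n_zero: int

    @property
    def nonzero_modes(self) -> np.ndarray:
        """Columns of the non-rigid-body modes, lowest frequency first."""
        return self.eigenvectors[:, self.n_zero:]

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]


@dataclass
class ConformerEnsemble:
    conformers: list[np.ndarray]                 # each N×3
    provenance: list[tuple[int, int]]            # (mode idx, step idx); the
                                                 # input structure is (-1, -1)

    def __len__(self) -> int:
        return len(self.conformers)


def ca_model_from_structure(structure: Structure, chain_id: str | None = None,
                            max_gap: int = 2):
    """Extract (coords, aas, seq_nums) for the Cα trace of one chain.

    Interior coordinate gaps of at most ``max_gap`` residues are linearly
    interpolated between the flanking Cα positions, keeping the elastic
    network connected; larger gaps raise :class:`MissingCAError`.
    """
    chain = (structure.chain(chain_id) if chain_id
             else structure.chains[0])
    coords, aas, nums = [], [], []
    gap: list = []
    started = False
    for res in chain.residues:
        ca = res.atom("CA") if res.is_observed else None
        if ca is None:
            if started:
                gap.append(res)
            continue
        if gap:
            if len(gap) > max_gap:
                raise MissingCAError(
                    f"chain {chain.chain_id}: gap of {len(gap)} residues "
                    f"ending at {res.seq_num} exceeds {max_gap}")
            prev = np.asarray(coords[-1])
            for g, gres in enumerate(gap, start=1):
                t = g / (len(gap) + 1)
                coords.append(prev + t * (ca.coord - prev))
                aas.append(gres.aa)
                nums.append(gres.seq_num)
            gap = []
        coords.append(ca.coord)
        aas.append(res.aa)
        nums.append(res.seq_num)
        started = True
    missing = [r.seq_num for r in chain.residues
               if r.is_observed and r.atom("CA") is None]
    if missing:
        raise MissingCAError(
            f"chain {chain.chain_id}: residues without Cα: {missing}")
    return np.array(coords), aas, nums


def build_enm(structure_or_coords, cutoff: float = DEFAULT_CUTOFF,
              k: float = 1.0, chain_id: str | None = None) -> ENMModel:
    """Build the elastic network: all Cα pairs within the cutoff.

    Accepts either a :class:`Structure` (first chain unless ``chain_id``)
    or a bare N×3 coordinate array.
    """
    if isinstance(structure_or_coords, Structure):
        coords, aas, nums = ca_model_from_structure(structure_or_coords,
                                                    chain_id)
    else:
        coords = np.asarray(structure_or_coords, dtype=float)
        aas, nums = ["X"] * len(coords), list(range(1, len(coords) + 1))
    if len(coords) < 4:
        raise ValueError("elastic network needs at least 4 residues")
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(cutoff))
    contacts = np.array(pairs, dtype=int).reshape(-1, 2)
    d0 = np.linalg.norm(coords[contacts[:, 0]] - coords[contacts[:, 1]],
                        axis=1)
    return ENMModel(ca_coords=coords, contacts=contacts, d0=d0, k=k,
                    cutoff=cutoff, aas=aas, seq_nums=nums)


def enm_energy(coords: np.ndarray, model: ENMModel) -> float:
    """Harmonic energy ½k Σ (d_ij − d0_ij)² over the contact set."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != model.ca_coords.shape:
        raise ValueError(
            f"coordinate shape {coords.shape} does not match model "
            f"{model.ca_coords.shape}")
    d = np.linalg.norm(coords[model.contacts[:, 0]]
                       - coords[model.contacts[:, 1]], axis=1)
    return float(0.5 * model.k * np.sum((d - model.d0) ** 2))


def hessian(model: ENMModel) -> np.ndarray:
    """The 3N×3N second-derivative matrix of the pairwise potential at the
    reference coordinates: off-diagonal blocks −k/d0² · (r ⊗ r)."""
    n = model.n_residues
    h = np.zeros((3 * n, 3 * n))
    for (i, j), d0 in zip(model.contacts, model.d0):
        rij = model.ca_coords[j] - model.ca_coords[i]
        block = model.k * np.outer(rij, rij) / d0 ** 2
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
    return h


def normal_modes(model: ENMModel) -> ModeSet:
    """Diagonalize the Hessian; exactly six near-zero (rigid-body)
    eigenvalues are expected for a connected 3D network."""
    h = hessian(model)
    eigenvalues, eigenvectors = scipy.linalg.eigh(h)
    tol = ZERO_EIGENVALUE_REL_TOL * max(eigenvalues[-1], 1e-30)
    n_zero = int(np.sum(eigenvalues < tol))
    if n_zero > 6:
        raise DisconnectedNetworkError(
            f"{n_zero} near-zero eigenvalues; the network is disconnected "
            "(increase the cutoff or reject the structure)")
    eigenvalues = np.maximum(eigenvalues, 0.0)   # clip numerical negatives
    return ModeSet(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                   n_zero=n_zero)


def _step_amplitudes(n_steps: int) -> np.ndarray:
    """Evenly spaced fractional amplitudes in [−1, 1] excluding 0,
    symmetric for even ``n_steps`` (the last negative step is dropped when
    ``n_steps`` is odd)."""
    half = (n_steps + 1) // 2
    pos = np.arange(1, half + 1) / half
    amps = np.concatenate([-pos[::-1], pos])
    if len(amps) > n_steps:
        amps = amps[1:]
    return amps


def generate_conformers(model: ENMModel, mode_set: ModeSet,
                        n_modes: int = DEFAULT_N_MODES,
                        n_steps: int = DEFAULT_N_STEPS,
                        max_amp: float = DEFAULT_MAX_AMP) -> ConformerEnsemble:
    """Deterministic conformer ensemble along the lowest-frequency modes.

    Each of the ``n_modes`` lowest non-zero modes contributes ``n_steps``
    conformers at evenly spaced amplitudes spanning both signs; amplitudes
    are scaled so the largest per-Cα displacement of the extreme conformer
    is ``max_amp`` Å.  The input structure is included, giving
    ``n_modes × n_steps + 1`` conformers.
    """
    if max_amp <= 0:
        raise ValueError("max_amp must be positive")
    available = mode_set.nonzero_modes.shape[1]
    if n_modes > available:
        warnings.warn(f"only {available} non-zero modes available; "
                      f"using all of them", stacklevel=2)
        n_modes = available
    n = model.n_residues
    conformers = [model.ca_coords.copy()]
    provenance: list[tuple[int, int]] = [(-1, -1)]
    fractions = _step_amplitudes(n_steps)
    for m in range(n_modes):
        vec = mode_set.nonzero_modes[:, m].reshape(n, 3)
        per_ca = np.linalg.norm(vec, axis=1)
        scale = max_amp / per_ca.max()
        for s, frac in enumerate(fractions):
            conformers.append(model.ca_coords + frac * scale * vec)
            provenance.append((m, s))
    return ConformerEnsemble(conformers=conformers, provenance=provenance)


def ensemble_rsasa(ensemble: ConformerEnsemble, model: ENMModel,
                   window_seq_nums: list[int], params=None,
                   anchor_rsasa: float | None = None
                   ) -> tuple[np.ndarray, float]:
    """Coarse rSASA of a site in every conformer; returns (values, max).

    The site is given by the author numbers of its eight window residues;
    accessibility on the Cα-only conformers uses the coarse
    single-sphere-per-residue surface model.

    When ``anchor_rsasa`` (the site's all-atom rSASA in the input
    structure) is given, the coarse values are anchored to the all-atom
    scale by the constant offset that maps the input conformer's coarse
    value onto ``anchor_rsasa``.  The coarse model then contributes only
    the *change* in accessibility along each mode, which removes the
    systematic offset between the two surface conventions; the input
    conformer's anchored value equals the site's classification rSASA
    exactly.
    """
    from .sasa_engine import coarse_rsasa

    idx = [model.seq_nums.index(num) for num in window_seq_nums]
    values = np.array([coarse_rsasa(coords, model.aas, idx, params)
                       for coords in ensemble.conformers])
    if anchor_rsasa is not None:
        values = values + (anchor_rsasa - values[0])
    return values, float(values.max())


def reclassify_by_dynamics(input_rsasa: float, conformer_rsasa: np.ndarray,
                           threshold: float = 0.2):
    """Dynamics rescue: a site initially disallowed becomes allowed iff any
    low-energy conformer exceeds the accessibility threshold.

    Returns (allowed, rescued): ``rescued`` is True only when the input
    structure itself was below threshold but some conformer was not.
    """
    conformer_rsasa = np.asarray(conformer_rsasa)
    if input_rsasa >= threshold:
        return True, False
    if conformer_rsasa.size and conformer_rsasa.max() > threshold:
        return True, True
    return False, False


def write_ensemble_pdb(ensemble: ConformerEnsemble, model: ENMModel,
                       chain_id: str = "A") -> str:
    """Multi-model PDB text of the Cα-only conformer ensemble."""
    from .aminoacids import ONE_TO_THREE

    lines = []
    for m, coords in enumerate(ensemble.conformers, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (xyz, aa, num) in enumerate(zip(coords, model.aas,
                                               model.seq_nums), start=1):
            resname = ONE_TO_THREE.get(aa, "UNK")
            lines.append(
                f"ATOM  {i:5d}  CA  {resname:>3s} {chain_id}{num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           C")
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
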