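"""Read and write PDB-format structures into a validated hierarchical model.

The model keeps explicit bookkeeping of residues that are present in the
primary sequence (SEQRES) but have no coordinates ("disordered" residues),
author residue numbering, and the number of chain copies in the deposited
assembly.  Only the first MODEL of a multi-model file is used.  Alternate
locations are reduced to the highest-occupancy conformer (ties broken by
first alphabetical altloc identifier).

Numbering policy: author residue numbers are kept verbatim; internal
positions are 1-based over the primary sequence, and an observed residue
with author number *k* is assigned primary-sequence position
``k - first_author_number + 1``.  Insertion codes are preserved as opaque
suffixes and never used for arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aminoacids import MODIFIED_PARENT, ONE_TO_THREE, THREE_TO_ONE


class PDBParseError(ValueError):
    """Malformed fixed-column line; message names the offending line."""


class EmptyStructureError(ValueError):
    """No ATOM/HETATM records were found."""


class ChainLookupError(KeyError):
    """Requested chain id does not exist."""


class CoverageUndefinedError(ValueError):
    """Coverage requested for a chain with an empty primary sequence."""


class PDBFormatError(ValueError):
    """Value does not fit the fixed-column PDB format."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    serial: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    is_observed: bool = True
    modified: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        if self.aa not in THREE_TO_ONE.values() and self.aa != "X":
            raise ValueError(f"unknown amino acid code {self.aa!r}")
        if self.is_observed and not self.atoms:
            raise ValueError(
                f"residue {self.chain_id}{self.seq_num} marked observed "
                "but has no atoms")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_ca(self) -> bool:
        return self.atom("CA") is not None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]  # one entry per primary-sequence position

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def observed(self) -> list[Residue]:
        return [r for r in self.residues if r.is_observed]

    def residue_at(self, position: int) -> Residue:
        """Residue at 1-based primary-sequence position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside chain "
                             f"{self.chain_id} (length {len(self.residues)})")
        return self.residues[position - 1]


@dataclass
class Structure:
    id: str
    chains: list[Chain]

    @property
    def assembly_size(self) -> int:
        return len(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise ChainLookupError(
            f"chain {chain_id!r} not in structure {self.id} "
            f"(has {[c.chain_id for c in self.chains]})")

    def atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for ch in self.chains for r in ch.observed
                for a in r.atoms]

    def coords(self) -> np.ndarray:
        pairs = self.atoms()
        if not pairs:
            return np.zeros((0, 3))
        return np.array([a.coord for _, a in pairs])


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in ("SE", "CL", "BR"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _resname_to_aa(resname: str) -> tuple[str, bool] | None:
    """Map a 3-letter residue name to (one-letter, modified_flag)."""
    resname = resname.strip().upper()
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname], False
    if resname in MODIFIED_PARENT:
        return MODIFIED_PARENT[resname], True
    return None


def parse_structure(pdb_text: str, structure_id: str = "struct",
                    fasta_sequences: dict[str, str] | None = None) -> Structure:
    """Parse PDB-format text into the hierarchical model.

    SEQRES (when present) defines the primary sequence of each chain; when
    absent, the sequence for a chain may be supplied via
    ``fasta_sequences[chain_id]``, and otherwise it is inferred from the
    span of author residue numbers with coordinate-less positions marked
    unknown.  Residues present in the primary sequence but absent from
    coordinate records are marked ``is_observed=False``.
    """
    seqres: dict[str, list[str]] = {}
    # raw[(chain, resseq, icode)] -> {"resname", "atoms": {name: [(altloc, Atom)]}}
    raw: dict[tuple[str, int, str], dict] = {}
    chain_order: list[str] = []
    in_first_model = True
    n_models_seen = 0
    has_atom_record = False

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            n_models_seen += 1
            in_first_model = n_models_seen == 1
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if rec == "SEQRES":
            chain_id = line[11:12].strip() or "A"
            names = line[19:].split()
            seqres.setdefault(chain_id, []).extend(names)
            continue
        if rec not in ("ATOM", "HETATM") or not in_first_model:
            continue
        has_atom_record = True
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16:17]
            resname = line[17:20]
            chain_id = line[21:22].strip() or "A"
            resseq = int(line[22:26])
            icode = line[26:27].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
        except (ValueError, IndexError) as exc:
            raise PDBParseError(
                f"malformed {rec} record at line {lineno}: {line!r}") from exc
        mapped = _resname_to_aa(resname)
        if mapped is None:
            continue  # water, ligands, unknown hetero groups
        element = line[76:78].strip().upper() or _infer_element(name)
        key = (chain_id, resseq, icode)
        if chain_id not in chain_order:
            chain_order.append(chain_id)
        entry = raw.setdefault(key, {"resname": mapped, "atoms": {}})
        entry["atoms"].setdefault(name, []).append(
            (altloc, Atom(name=name, element=element, coord=(x, y, z),
                          occupancy=min(max(occupancy, 0.0), 1.0),
                          serial=serial)))

    if not has_atom_record:
        raise EmptyStructureError("no ATOM/HETATM records in input")

    chains: list[Chain] = []
    for chain_id in chain_order:
        keys = sorted((k for k in raw if k[0] == chain_id),
                      key=lambda k: (k[1], k[2]))
        observed: dict[int, Residue] = {}
        for (_, resseq, icode) in keys:
            entry = raw[(chain_id, resseq, icode)]
            aa, modified = entry["resname"]
            atoms = []
            for name, variants in entry["atoms"].items():
                # highest occupancy wins; ties -> first alphabetical altloc
                best = max(variants, key=lambda v: (v[1].occupancy,
                                                    _altloc_rank(v[0])))
                atoms.append(best[1])
            atoms.sort(key=lambda a: a.serial)
            if resseq in observed:
                continue  # insertion-coded duplicates: keep the first
            observed[resseq] = Residue(chain_id=chain_id, seq_num=resseq,
                                       aa=aa, atoms=atoms, is_observed=True,
                                       modified=modified, icode=icode)
        # with an explicit primary sequence, author number k is primary
        # position k; otherwise positions span the observed numbering
        has_primary = (chain_id in seqres
                       or (fasta_sequences and chain_id in fasta_sequences))
        first = 1 if has_primary else min(observed)
        primary = _primary_sequence(chain_id, observed, first,
                                    seqres, fasta_sequences)
        residues: list[Residue] = []
        for pos, aa in enumerate(primary, start=1):
            author_num = first + pos - 1
            if author_num in observed:
                residues.append(observed[author_num])
            else:
                residues.append(Residue(chain_id=chain_id, seq_num=author_num,
                                        aa=aa, atoms=[], is_observed=False))
        # observed residues beyond the primary sequence are appended verbatim
        for num in sorted(observed):
            if not first <= num < first + len(primary):
                residues.append(observed[num])
        residues.sort(key=lambda r: r.seq_num)
        chains.append(Chain(chain_id=chain_id, residues=residues))

    return Structure(id=structure_id, chains=chains)


def _altloc_rank(altloc: str) -> float:
    # used as a max() tiebreak, so earlier alphabetical must rank higher
    return -ord(altloc) if altloc.strip() else 1.0


def _primary_sequence(chain_id, observed, first, seqres, fasta_sequences):
    if chain_id in seqres:
        return "".join(THREE_TO_ONE.get(n.upper(),
                                        MODIFIED_PARENT.get(n.upper(), "X"))
                       for n in seqres[chain_id])
    if fasta_sequences and chain_id in fasta_sequences:
        return fasta_sequences[chain_id].upper()
    last = max(observed)
    return "".join(observed[n].aa if n in observed else "X"
                   for n in range(first, last + 1))


def extract_monomer(structure: Structure, chain_id: str) -> Structure:
    """Return a single-chain structure; coordinates are untouched."""
    ch = structure.chain(chain_id)
    new_chain = Chain(chain_id=ch.chain_id,
                      residues=[replace(r, atoms=list(r.atoms))
                                for r in ch.residues])
    return Structure(id=f"{structure.id}_{chain_id}", chains=[new_chain])


def sequence_coverage(structure: Structure, chain_id: str) -> float:
    """Fraction of the primary sequence with observed coordinates."""
    ch = structure.chain(chain_id)
    if not ch.residues:
        raise CoverageUndefinedError(
            f"chain {chain_id} has an empty primary sequence")
    return len(ch.observed) / len(ch.residues)


def write_structure(structure: Structure) -> str:
    """Serialize to PDB-format text.

    Unobserved residues are omitted from ATOM records but retained in
    SEQRES, so a parse/write round trip reproduces the model (coordinates
    to the 0.001 Å column precision).
    """
    lines: list[str] = []
    for ch in structure.chains:
        names = [ONE_TO_THREE.get(r.aa, "UNK") for r in ch.residues]
        for i in range(0, len(names), 13):
            block = names[i:i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {ch.chain_id:1.1s} "
                f"{len(names):4d}  " + " ".join(f"{n:>3s}" for n in block))
    serial = 1
    for ch in structure.chains:
        for res in ch.observed:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                if np.any(np.abs(atom.coord) >= 10000):
                    raise PDBFormatError(
                        f"coordinate {atom.coord} exceeds PDB column width")
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:4.4s} {resname:>3s} "
                    f"{ch.chain_id:1.1s}{res.seq_num:4d}{res.icode:1.1s}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}"
                    f"{atom.coord[2]:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2.2s}")
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_fasta(text: str) -> dict[str, str]:
    """Read FASTA text, returning {record id: sequence} (id = first token)."""
    import io

    from biotite.sequence.io.fasta import FastaFile

    fasta = FastaFile.read(io.StringIO(text))
    return {header.split()[0]: str(seq).upper()
            for header, seq in fasta.items()}
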