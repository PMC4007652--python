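"""Map phosphosite sequence windows onto structure chains.

Phosphosite databases export each site as a 15-residue window with the
phosphorylated residue at position 8, padded with ``X`` at protein termini.
The window is trimmed to an octapeptide with the phosphoresidue at position
4, located on the structure's primary sequence by exact anchored matching,
and failures are discriminated into disordered (sequence matches but
coordinates are missing), mutated (exactly one single-residue substitution
restores a match), terminal, low-coverage, or no-structure categories.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import pandas as pd

from .aminoacids import CANONICAL
from .structure_io import Chain, Structure, sequence_coverage

CONVENTIONAL_PHOSPHO = frozenset("STY")
UNCONVENTIONAL_PHOSPHO = frozenset("HCD")

#: residues before / after the phosphosite inside the octapeptide
N_BEFORE, N_AFTER = 3, 4

#: anchoring tolerance (residues) when locating octapeptides, absorbing
#: small isoform numbering drift without allowing matches in distant repeats
ANCHOR_TOLERANCE = 2


class MatchStatus(str, enum.Enum):
    MATCHED = "matched"
    DISORDERED = "disordered"
    MUTATED = "mutated"
    TERMINAL = "terminal"
    LOW_COVERAGE = "low_coverage"
    NO_STRUCTURE = "no_structure"


class AmbiguousMatchError(ValueError):
    """Several distinct anchored matches; the site cannot be mapped."""


class SchemaError(ValueError):
    """Phosphosite table is missing a required column."""


@dataclass
class PhosphoSiteRecord:
    accession: str
    position: int            # 1-based index in the full protein sequence
    residue: str             # S/T/Y conventional; H/C/D unconventional
    window15: str
    kinase_site: bool = False  # site lies on a kinase (autophosphorylation
                               # candidates are annotated, never inferred)

    def __post_init__(self) -> None:
        self.window15 = self.window15.upper()
        self.residue = self.residue.upper()
        if len(self.window15) != 15:
            raise ValueError("window length")
        if self.residue not in CONVENTIONAL_PHOSPHO | UNCONVENTIONAL_PHOSPHO:
            raise ValueError(f"residue type {self.residue!r}")
        if self.window15[7] != self.residue:
            raise ValueError("window center mismatch")
        if self.position < 1:
            raise ValueError("position must be 1-based")

    @property
    def conventional(self) -> bool:
        return self.residue in CONVENTIONAL_PHOSPHO


@dataclass
class StructureRef:
    structure_id: str
    chain_id: str
    seq_nums: list[int]      # author numbers of the eight mapped residues


@dataclass
class OctapeptideSite:
    sequence8: str
    phospho_index: int = 4   # 1-based, fixed by construction
    structure_ref: StructureRef | None = None
    rsasa: float | None = None
    terminal: bool = False

    def __post_init__(self) -> None:
        self.sequence8 = self.sequence8.upper()
        if len(self.sequence8) != 8:
            raise ValueError("octapeptide must have length 8")
        if self.phospho_index != 4:
            raise ValueError("phosphoresidue is fixed at position 4")

    @property
    def phospho_residue(self) -> str:
        return self.sequence8[self.phospho_index - 1]


@dataclass
class MatchResult:
    status: MatchStatus
    detail: tuple[int, str] | None = None  # mutated: (octa position, residue)
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.detail is not None) != (self.status is MatchStatus.MUTATED):
            raise ValueError("detail present iff status is mutated")


def parse_phosphosite_table(tsv_text: str
                            ) -> tuple[list[PhosphoSiteRecord],
                                       list[tuple[int, str]]]:
    """Parse a tab-separated phosphosite table.

    Requires columns ``accession``, ``position``, ``residue``, ``window15``;
    an optional boolean ``kinase`` column marks sites on kinases.  Returns
    the valid records plus a list of (row index, reason) for rejected rows.
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"accession", "position", "residue", "window15"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    records: list[PhosphoSiteRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            records.append(PhosphoSiteRecord(
                accession=str(row["accession"]).strip(),
                position=int(row["position"]),
                residue=str(row["residue"]),
                window15=str(row["window15"]),
                kinase_site=str(row.get("kinase", "")).strip().lower()
                in ("1", "true", "yes"),
            ))
        except (ValueError, TypeError) as exc:
            rejected.append((int(idx), str(exc)))
    return records, rejected


def trim_to_octapeptide(window15: str) -> OctapeptideSite:
    """Trim the 15-mer to the octapeptide: characters 5-12 (1-based), which
    places the phosphoresidue at octapeptide position 4.  A pad character
    ``X`` inside the window marks a terminal site."""
    window15 = window15.upper()
    if len(window15) != 15:
        raise ValueError("window must have length 15")
    octa = window15[4:12]
    return OctapeptideSite(sequence8=octa, terminal="X" in octa)


def _anchored_occurrences(chain_sequence: str, octa: str,
                          site_position: int) -> list[int]:
    """0-based start indices of exact occurrences within the anchoring
    tolerance of the expected offset."""
    expected = site_position - 1 - N_BEFORE
    starts = []
    start = chain_sequence.find(octa)
    while start != -1:
        starts.append(start)
        start = chain_sequence.find(octa, start + 1)
    return [s for s in starts if abs(s - expected) <= ANCHOR_TOLERANCE]


def locate_octapeptide(chain_sequence: str, octa: str,
                       site_position: int) -> list[int] | None:
    """Locate the octapeptide on the chain's primary sequence.

    Returns the eight 1-based sequence positions on success, ``None`` when
    the octapeptide is absent near the expected offset, and raises
    :class:`AmbiguousMatchError` when several distinct anchored matches
    exist (the site is excluded rather than guessed).
    """
    if not chain_sequence:
        raise ValueError("empty chain sequence")
    anchored = _anchored_occurrences(chain_sequence, octa.upper(),
                                     site_position)
    if not anchored:
        return None
    if len(set(anchored)) > 1:
        raise AmbiguousMatchError(
            f"octapeptide {octa} matches at offsets {sorted(anchored)}")
    start = anchored[0]
    return list(range(start + 1, start + 9))


def classify_failure(octa: str, chain_sequence: str, chain: Chain,
                     site_position: int) -> MatchResult:
    """Discriminate why an octapeptide failed to map.

    If the sequence matches but one of the eight residues has no
    coordinates, the site is disordered.  Otherwise every one of the 8x19
    single-substitution variants of the octapeptide is searched; a match
    through exactly one substitution position means the structure carries a
    mutant sequence there.  Matches through two or more positions are
    ambiguous and the site stays unmatched.
    """
    octa = octa.upper()
    anchored = _anchored_occurrences(chain_sequence, octa, site_position)
    if anchored:
        start = anchored[0]
        window = chain.residues[start:start + 8]
        if any(not r.is_observed for r in window):
            return MatchResult(status=MatchStatus.DISORDERED)
        return MatchResult(status=MatchStatus.MATCHED,
                           positions=list(range(start + 1, start + 9)))

    hit_positions: dict[int, str] = {}
    for pos in range(8):
        for sub in sorted(CANONICAL - {octa[pos]}):
            variant = octa[:pos] + sub + octa[pos + 1:]
            if _anchored_occurrences(chain_sequence, variant, site_position):
                hit_positions[pos + 1] = sub
                break
    if len(hit_positions) == 1:
        pos, sub = next(iter(hit_positions.items()))
        return MatchResult(status=MatchStatus.MUTATED, detail=(pos, sub))
    return MatchResult(status=MatchStatus.NO_STRUCTURE)


def is_terminal(site_position: int, sequence_length: int) -> bool:
    """True iff the octapeptide cannot be formed: fewer than 3 residues
    precede or fewer than 4 follow the site."""
    if not 1 <= site_position <= sequence_length:
        raise ValueError(
            f"position {site_position} outside sequence of length "
            f"{sequence_length}")
    return (site_position - 1 < N_BEFORE
            or sequence_length - site_position < N_AFTER)


def filter_by_coverage(sites: list[OctapeptideSite], structure: Structure,
                       threshold: float = 0.7
                       ) -> tuple[list[OctapeptideSite],
                                  list[OctapeptideSite]]:
    """Split mapped sites into (retained, low_coverage) by chain coverage.

    A chain qualifies when at least ``threshold`` of its primary sequence
    has coordinates (boundary inclusive: exactly 70% is retained).
    """
    retained, low = [], []
    for site in sites:
        if site.structure_ref is None:
            raise ValueError("site has no structure mapping")
        cov = sequence_coverage(structure, site.structure_ref.chain_id)
        (retained if cov >= threshold else low).append(site)
    return retained, low


def best_chain(structure: Structure) -> Chain:
    """Of several chains, the one with the highest sequence coverage
    (ties: first in file order)."""
    return max(structure.chains,
               key=lambda ch: (len(ch.observed) / max(len(ch.residues), 1),))
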