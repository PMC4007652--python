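"""Allowed/disallowed phosphoconformation classification and rescues.

A phosphosite is *allowed* (accessible to a kinase) when its octapeptide
rSASA reaches the threshold (default 0.2; a stringent variant uses 0.3 —
the boundary is inclusive, so exactly 0.2 classifies as allowed), and
*disallowed* otherwise.  Disallowed sites may be rescued by:

* **interface** — the site is buried by a partner chain of an oligomer and
  becomes accessible on the extracted monomer;
* **alternate_structure** — another deposited structure of the same protein
  shows the site accessible;
* **dynamics** — a low-energy elastic-network conformer exposes the site;
* **consensus_motif** — the octapeptide matches a kinase consensus
  (S/T-P-X-K/R for cyclin-dependent kinases), arguing that the site is
  accessible in some cellular conformation even though the crystal buries
  it.

Rescues only ever move sites disallowed → allowed.  When several rules
fire, all are recorded and the site is labeled by the first in the
precedence interface > alternate_structure > dynamics > consensus_motif.

Also provided: the mass-based flexibility index A_rel (observed whole-chain
SASA over the empirical prediction 4.44·M^0.77), rSASA histograms, residue
composition comparisons, and the rSASA/depth consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aminoacids import CANONICAL, CHARGED, HYDROPHOBIC, RESIDUE_MASS
from .sasa_engine import SASAParams, residue_sasa
from .structure_io import Structure

DEFAULT_THRESHOLD = 0.2
STRINGENT_THRESHOLD = 0.3
DEPTH_CUTOFF = 30.0           # configurable; consistency is ordinal

RESCUE_PRECEDENCE = ("interface", "alternate_structure", "dynamics",
                     "consensus_motif", "autophosphorylation_flag")

#: empirical whole-protein SASA prediction constants (Å², Da)
AREL_COEFF = 4.44
AREL_EXPONENT = 0.77
AREL_MAX_DISORDERED = 5


class NegativeRSASAError(ValueError):
    pass


@dataclass
class ClassificationResult:
    label: str                       # "allowed" | "disallowed"
    rsasa: float
    threshold_used: float = DEFAULT_THRESHOLD
    rescues: list[str] = field(default_factory=list)

    @property
    def rescue(self) -> str:
        """First fired rescue rule in precedence order, or "none"."""
        for rule in RESCUE_PRECEDENCE:
            if rule in self.rescues:
                return rule
        return "none"

    def apply_rescue(self, rule: str, new_rsasa: float | None = None) -> None:
        """Record a rescue; flips the label to allowed, never the reverse."""
        if rule not in RESCUE_PRECEDENCE:
            raise ValueError(f"unknown rescue rule {rule!r}")
        self.rescues.append(rule)
        self.label = "allowed"
        if new_rsasa is not None:
            self.rsasa = max(self.rsasa, new_rsasa)


@dataclass
class FlexibilityRecord:
    mass: float                      # Da
    observed_sasa: float             # Å², whole chain
    predicted_sasa: float = field(init=False)
    a_rel: float = field(init=False)

    def __post_init__(self) -> None:
        self.predicted_sasa = predicted_sasa(self.mass)
        self.a_rel = self.observed_sasa / self.predicted_sasa


def classify_site(rsasa: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """"allowed" iff rSASA ≥ threshold (boundary inclusive)."""
    if rsasa < 0:
        raise NegativeRSASAError(f"rSASA {rsasa} is negative")
    return "allowed" if rsasa >= threshold else "disallowed"


def classify(rsasa: float, threshold: float = DEFAULT_THRESHOLD
             ) -> ClassificationResult:
    return ClassificationResult(label=classify_site(rsasa, threshold),
                                rsasa=rsasa, threshold_used=threshold)


def rescue_interface(result: ClassificationResult, monomer_rsasa: float
                     ) -> ClassificationResult:
    """Interface rescue: recompute on the extracted monomer; allowed iff
    the monomeric rSASA reaches the threshold."""
    if result.label == "disallowed" and \
            monomer_rsasa >= result.threshold_used:
        result.apply_rescue("interface", monomer_rsasa)
    return result


def rescue_alternate(result: ClassificationResult,
                     rsasa_by_structure: dict[str, float]
                     ) -> ClassificationResult:
    """Alternate-structure rescue: allowed iff the maximum rSASA over all
    deposited structures of the protein reaches the threshold."""
    if not rsasa_by_structure:
        raise ValueError("no structures supplied")
    best = max(rsasa_by_structure.values())
    if result.label == "disallowed" and best >= result.threshold_used:
        result.apply_rescue("alternate_structure", best)
    return result


def consensus_override(octa: str) -> bool:
    """CDK consensus S/T-P-X-K/R anchored at the phosphosite: position 4 is
    S or T, position 5 is P, position 7 is K or R."""
    octa = octa.upper()
    if len(octa) != 8:
        raise ValueError("octapeptide must have length 8")
    return octa[3] in "ST" and octa[4] == "P" and octa[6] in "KR"


def protein_mass(structure: Structure, chain_id: str | None = None) -> float:
    """Chain mass in Da from residue masses over the primary sequence
    (plus one water for the free termini)."""
    chain = structure.chain(chain_id) if chain_id else structure.chains[0]
    return sum(RESIDUE_MASS.get(r.aa, RESIDUE_MASS["X"])
               for r in chain.residues) + 18.02


def predicted_sasa(mass: float) -> float:
    """Empirical whole-protein SASA prediction 4.44·M^0.77 (Å²)."""
    return AREL_COEFF * mass ** AREL_EXPONENT


def compute_a_rel(structure: Structure, params: SASAParams | None = None
                  ) -> FlexibilityRecord | None:
    """Flexibility index of a monomeric structure.

    Returns ``None`` (filtered out) for multimers and for chains with more
    than five residues lacking coordinates; otherwise the ratio of the
    observed total SASA to the mass-based prediction.  Values above 1
    indicate a more extended or flexible conformation.
    """
    if structure.assembly_size != 1:
        return None
    chain = structure.chains[0]
    n_disordered = sum(1 for r in chain.residues if not r.is_observed)
    if n_disordered > AREL_MAX_DISORDERED:
        return None
    observed = sum(residue_sasa(structure, params).values())
    return FlexibilityRecord(mass=protein_mass(structure),
                             observed_sasa=observed)


def bin_and_summarize(values, width: float = 0.1):
    """Histogram of rSASA values in ten half-open bins [x, x+0.1) with the
    last bin closed; values above 1 are clamped into the last bin for
    display only.  Returns (counts, bin_edges, modal bin index, median)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no values to bin")
    edges = np.arange(0.0, 1.0 + width / 2, width)
    clamped = np.clip(values, 0.0, np.nextafter(1.0, 0.0))
    counts, _ = np.histogram(clamped, bins=edges)
    mode_bin = int(np.argmax(counts))
    return counts, edges, mode_bin, float(np.median(values))


def composition_compare(allowed_octas: list[str],
                        disallowed_octas: list[str]):
    """Per-amino-acid frequency tables for the two sets plus class-level
    differences (disallowed − allowed) for hydrophobic and polar/charged
    residues."""
    if not allowed_octas or not disallowed_octas:
        raise ValueError("both sets must be non-empty")

    def freqs(octas):
        counts = {aa: 0 for aa in sorted(CANONICAL)}
        total = 0
        for octa in octas:
            for ch in octa.upper():
                if ch in counts:
                    counts[ch] += 1
                    total += 1
        return {aa: c / total for aa, c in counts.items()}

    fa, fd = freqs(allowed_octas), freqs(disallowed_octas)
    hydro_diff = (sum(fd[a] for a in HYDROPHOBIC)
                  - sum(fa[a] for a in HYDROPHOBIC))
    charged_diff = (sum(fd[a] for a in CHARGED)
                    - sum(fa[a] for a in CHARGED))
    return {"allowed": fa, "disallowed": fd,
            "hydrophobic_difference": hydro_diff,
            "charged_difference": charged_diff}


def depth_consistency(sites, depth_cutoff: float = DEPTH_CUTOFF,
                      rsasa_threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of sites where rSASA and residue depth agree: accessible
    sites shallow (depth < cutoff), inaccessible sites deep (≥ cutoff).

    ``sites`` is an iterable of (rsasa, depth) pairs.
    """
    sites = list(sites)
    if not sites:
        return float("nan")
    agree = sum(1 for rsasa, depth in sites
                if (rsasa >= rsasa_threshold and depth < depth_cutoff)
                or (rsasa < rsasa_threshold and depth >= depth_cutoff))
    return agree / len(sites)
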