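# Methods

This note documents the models, conventions and numerical choices behind
`phosphoconform`, in the spirit of a methods supplement: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Octapeptide relative solvent accessibility (rSASA)

A kinase can only phosphorylate a residue it can reach. The package
quantifies reachability through the solvent accessible surface area (SASA)
of the octapeptide spanning the phosphosite: residues −3 … +4 around the
phosphoresidue, which sits at octapeptide position 4.

Per-residue SASA is computed with the Shrake–Rupley rolling-probe
algorithm: each atom's probe-expanded sphere (van der Waals radius + probe
radius, water probe 1.4 Å) is covered with a deterministic golden-spiral
lattice of test points (default 960 per atom), and the accessible area is
the fraction of points not occluded by any neighbouring expanded sphere.
Van der Waals radii follow the Bondi element table (C 1.70, N 1.55, O
1.52, S/P 1.80 Å). Two deliberate numerical choices:

* **No randomness.** The spiral lattice is deterministic, so repeated runs
  are bit-identical.
* **Isometry invariance.** The lattice is oriented along the molecule's
  principal axes (signs fixed deterministically), so rotating or
  translating the input changes results only at floating-point noise.
  Without this, rotations would perturb areas by ~0.5 Å² of sampling
  noise. One consequence: adding an atom re-orients the lattice, so strict
  occlusion monotonicity holds only for a fixed lattice
  (`shrake_rupley(..., canonical=False)`).

Per-residue areas are normalized into **%SASA** by the same residue's area
in a programmatically built extended (φ = −120°, ψ = +120°) Gly-X-Gly
tripeptide (Ala flanks available by configuration). Full side-chain
reference coordinates are produced by grafting ideal-geometry residues
from the chemical component dictionary onto the extended backbone frame.
%SASA is not clamped at 1 — normalization is a convention, and the
classification thresholds below operate on raw ratios. **rSASA** is the
arithmetic mean of the eight window residues' %SASA.

Synthetic structures generated by this package carry backbone + Cβ atoms
only; for them the reference state uses the matching reduced-atom
convention (`reference_atoms="auto"` detects this per structure), keeping
%SASA calibrated so that an isolated extended peptide scores ≈ 1.

The per-residue areas agree with an independent Shrake–Rupley
implementation (biotite) to within 5% on identical coordinates and radii,
with an absolute floor of 2 Å² for nearly buried residues where
point-lattice noise dominates any relative measure.

## Site mapping and failure taxonomy

Phosphosite databases export each site as a 15-residue window with the
phosphoresidue at position 8, `X`-padded at protein termini. The window is
trimmed to the octapeptide (window characters 5–12) and located on the
structure's primary sequence by exact matching **anchored** within ±2
residues of the reported position — wide enough to absorb minor isoform
numbering drift, narrow enough to reject matches in sequence repeats.
Ambiguous anchored matches exclude the site rather than guess.

Failures are discriminated exactly as the octapeptide scan prescribes:

* **disordered** — the sequence matches but at least one window residue
  has no coordinates;
* **mutated** — no exact match, but exactly one of the 8 × 19
  single-substitution variants of the octapeptide matches (the position
  and substituting residue are reported); matches through two or more
  substitution positions remain unmatched;
* **terminal** — fewer than 3 residues precede or fewer than 4 follow the
  site, so no octapeptide exists;
* **low_coverage** — the matched chain's structure covers less than 70%
  of its primary sequence (boundary inclusive: exactly 70% is kept);
* **no_structure** — everything else.

When a protein has several matched structures, the first file is the
primary structure and per-site values from all structures feed the
alternate-structure rescue. Within a multi-chain structure the chain with
the highest sequence coverage is used.

## Conformational map and rescue rules

A site is **allowed** (accessible to a kinase) when rSASA ≥ 0.2 and
**disallowed** otherwise; a stringent variant uses 0.3. The boundary is
inclusive — reported accessibilities of exactly 0.2/0.3 classify as
allowed. Disallowed sites are re-examined by four rescue rules, applied in
this precedence when several fire: **interface** (recompute on the
extracted monomer of an oligomeric assembly) > **alternate_structure**
(maximum rSASA over all deposited structures of the protein) >
**dynamics** (conformer ensemble, below) > **consensus_motif** (the
octapeptide matches the cyclin-dependent-kinase consensus S/T-P-X-K/R
anchored at the phosphosite, arguing for accessibility in some cellular
conformation). An **autophosphorylation** annotation supplied in the input
table (never inferred) ranks with consensus. Rescues only ever move sites
from disallowed to allowed.

## Cα elastic-network conformer ensembles

Each chain is reduced to one node per residue at its Cα. Nodes closer than
R_C = 10 Å are joined by identical harmonic springs with the
crystal-structure distance d⁰ᵢⱼ as rest length:

    E = ½ k Σ_{d⁰ᵢⱼ < R_C} (dᵢⱼ − d⁰ᵢⱼ)²

with uniform unit masses and k = 1 (only mode shapes and orderings
matter). Diagonalizing the 3N×3N Hessian yields exactly six near-zero
eigenvalues (rigid-body motions; tolerance 10⁻⁸ of the largest eigenvalue,
more flagged as a disconnected network) and 3N−6 genuine modes. Interior
coordinate gaps of at most two residues are bridged by linear
interpolation of the flanking Cα positions to keep the network connected;
larger gaps make the chain ineligible.

The low-energy ensemble displaces the structure along each of the 20
lowest-frequency modes at 20 evenly spaced amplitudes spanning both signs,
plus the input structure: 20 × 20 + 1 = 401 conformers. The unstated scale
of "small" displacements is resolved by normalizing each mode so the
largest per-Cα displacement of its extreme conformer is `max_amp`
(default 2.0 Å) — large enough to sample breathing of weakly packed
surface elements, small enough that single-mode conformers stay near the
harmonic regime (conformer energies match ½λa² within 5% at small
amplitudes).

### Coarse accessibility of conformers, and anchoring

Conformers are Cα-only, so their accessibility uses a coarse surface
model: one sphere per residue at the Cα with a radius derived from the
residue's mean volume (r = (3V/4π)^⅓; Gly 2.43 Å … Trp 3.79 Å),
normalized by coarse extended three-sphere references. This coarse %SASA
ranks burial correctly (rank correlation > 0.7 against the all-atom values
on the same structure) but sits systematically ~0.05–0.1 *below* the
all-atom %SASA for surface sites, because the Cα sphere centre is recessed
beneath the residue's true surface. The original coarse-grained surface
programs dealt with this by fitting their coarse parameters against
all-atom areas; we instead **anchor** the ensemble: conformer values are
shifted by the constant that maps the input conformer's coarse value onto
the site's all-atom rSASA. The input structure's anchored value therefore
equals the classification rSASA exactly, and conformers contribute only
the *change* in accessibility along each mode — which is the quantity the
rescue question actually needs. Raw coarse values remain available
(`anchor_rsasa=None`).

A disallowed site is rescued by dynamics when any of the 401 anchored
conformer values exceeds the classification threshold.

## Residue depth

As an independent burial measure, each atom's depth is its distance to the
nearest solvent-accessible surface point minus its own probe-contact
radius (so fully exposed atoms score ≈ 0); residue depth is the mean over
atoms. Surface points retained by pairwise occlusion also line interior
voids that bulk solvent cannot reach; these disconnected patches are
removed by keeping only the largest connected component of surface points
(points linked within 1.5 Å). This approximates depth-from-water
definitions ordinally — buried cores score strictly deeper than surface
residues on every fixture — but absolute values depend on structure size,
so the consistency cutoff between rSASA and depth is configurable
(default 30, matching the literature convention for full-size proteins;
synthetic fixtures are far smaller and need correspondingly smaller
cutoffs).

## Secondary structure

A four-class assigner (H helix, E sheet, T turn, C coil): backbone amide
hydrogens are rebuilt from the preceding carbonyl, hydrogen bonds are
detected with the Kabsch–Sander electrostatic energy (bond when
E < −0.5 kcal/mol), and labels combine hydrogen-bond patterns (i→i+4
helical, i→i+3 turn, sequence separation ≥ 5 cross-strand) with φ/ψ
windows. Ties resolve H > E > T > C, and the dominant class of an
octapeptide is its majority label under the same priority. Proline donates
no hydrogen bond; residues with missing backbone atoms are labeled C with
a warning.

## A_rel flexibility index

For monomeric chains with at most five unobserved residues, the observed
whole-chain SASA is compared with the empirical mass-based prediction
4.44·M^0.77 Å² (M in Da, from average residue masses plus one water);
A_rel = observed/predicted, with values above 1 indicating extended or
flexible conformations. Multimers and poorly observed chains are filtered
out rather than reported.

## Synthetic data: what it emulates, and what it does not

All validation runs on generated fixtures with *measured* ground truth:
every guarantee (core octapeptide rSASA < 0.1, surface octapeptide > 0.4,
interface occlusion < 0.2 in the assembly vs ≥ 0.3 on the monomer,
dynamics rescue and rigid-cage non-rescue under the default ensemble) is
verified with the package's own engines at generation time, with seeded
jitter and rejection sampling; fixtures that cannot meet their guarantee
raise instead of silently shipping.

The generated proteins are idealized helix bundles — a central buried
octapeptide wrapped in a ring of helices with axial caps, plus a partially
exposed display helix carrying the surface octapeptide; the dynamics
fixture adds a terminal helical arm hovering over a sunken site, and the
oligomer fixture nests a flipped copy against the site. Residues carry
backbone + Cβ atoms only, helices are ideal, segments are rigid, and the
random sequence alphabet excludes proline so the CDK motif occurs only
where planted. Consequently the synthetic cohort demonstrates that the
*pipeline logic* — mapping, taxonomy, thresholds, rescue rules, ensemble
mechanics — behaves exactly as specified on inputs with known answers. It
does not demonstrate accuracy on real crystal structures, where side-chain
packing, irregular loops, crystallographic artifacts and genuine
conformational heterogeneity enter; published per-site accessibility
values from real structures should be expected to match this
implementation approximately (the original surface program's exact
parametrization is not reproduced), not digit for digit.

Cohort categories and their planted outcomes: exposed (allowed), buried
(disallowed, ensemble-negative), interface_buried (allowed via interface),
motif_buried (allowed via consensus), alternate (allowed via a second
structure whose covering arm is disordered — an order-to-disorder
transition), dynamics (allowed via the ensemble), disordered, mutated
(single substitution at window position 6), terminal, and low_coverage
(31% of residues unobserved). Category counts follow largest-remainder
rounding of the requested rates; everything is byte-identical under a
fixed seed.

## Default problem sizes

Generated bundles default to 87 residues (97 with the arm), the validation
cohort to 50 proteins, and surface sampling to 960 points per atom
(240 for the big coarse spheres of conformer ensembles, where the
integrand is far smoother). These sizes keep a full cohort
generation-plus-pipeline run in the minutes range on a single core while
leaving every guarantee comfortably measurable.
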