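"""End-to-end orchestration: map sites, run dynamics rescue, summarize.

The pipeline wires the analysis stages in their natural order: parse
structures and phosphosite windows, trim to octapeptides and locate them on
chains, filter by sequence coverage, compute octapeptide rSASA, classify
into allowed/disallowed phosphoconformation with the static rescue rules
(interface, alternate structure, consensus motif, autophosphorylation
annotation), then optionally re-examine buried sites against the
normal-mode conformer ensemble, and finally produce distribution and
composition summaries.

All stages are deterministic; randomness exists only in the synthetic-data
generator.  Reports are TSV files plus a JSON summary per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformation_map as cmap
from . import enm_nma, secondary_structure, site_mapper
from .sasa_engine import (SASAParams, all_residue_depths, octapeptide_rsasa,
                          residue_percent_sasa)
from .site_mapper import MatchStatus, OctapeptideSite, StructureRef
from .structure_io import Structure, extract_monomer, parse_structure, \
    read_fasta, sequence_coverage

log = logging.getLogger("phosphoconform")


@dataclass
class RunConfig:
    """All run parameters in one place; round-trips through YAML."""

    structures_dir: str = "structures"
    phosphosites: str = "phosphosites.tsv"
    fasta: str | None = None
    out_dir: str = "results"
    rsasa_threshold: float = 0.2
    stringent_threshold: float = 0.3
    coverage_threshold: float = 0.7
    depth_cutoff: float = 30.0
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    reference_flank: str = "G"
    reference_atoms: str = "auto"
    enm_cutoff: float = 10.0
    enm_n_modes: int = 20
    enm_n_steps: int = 20
    enm_max_amp: float = 2.0
    ensemble_sphere_points: int = 240
    seed: int = 0

    def sasa_params(self) -> SASAParams:
        return SASAParams(probe_radius=self.probe_radius,
                          n_sphere_points=self.n_sphere_points,
                          reference_flank=self.reference_flank,
                          reference_atoms=self.reference_atoms)

    def ensemble_params(self) -> SASAParams:
        return SASAParams(probe_radius=self.probe_radius,
                          n_sphere_points=self.ensemble_sphere_points)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_structures(config: RunConfig) -> dict[str, list[Structure]]:
    """Structures grouped by accession.

    Accessions come from file names: ``<accession>.pdb`` is the primary
    structure and ``<accession>__<tag>.pdb`` are alternates; the primary
    sorts first within each group.
    """
    fasta_seqs: dict[str, str] = {}
    if config.fasta:
        fasta_seqs = read_fasta(Path(config.fasta).read_text())
    grouped: dict[str, list[Structure]] = {}
    for path in sorted(Path(config.structures_dir).glob("*.pdb")):
        accession = path.stem.split("__")[0]
        fallback = ({"A": fasta_seqs[accession]}
                    if accession in fasta_seqs else None)
        structure = parse_structure(path.read_text(), structure_id=path.stem,
                                    fasta_sequences=fallback)
        grouped.setdefault(accession, []).append(structure)
    return grouped


class _StructureCache:
    """Per-structure memo of the expensive surface computations."""

    def __init__(self, params: SASAParams):
        self.params = params
        self._pct: dict[str, dict] = {}
        self._depth: dict[str, dict] = {}
        self._ss: dict[str, dict] = {}

    def percent(self, structure: Structure):
        if structure.id not in self._pct:
            self._pct[structure.id] = residue_percent_sasa(structure,
                                                           self.params)
        return self._pct[structure.id]

    def depths(self, structure: Structure):
        if structure.id not in self._depth:
            self._depth[structure.id] = all_residue_depths(structure,
                                                           self.params)
        return self._depth[structure.id]

    def ss_labels(self, structure: Structure):
        if structure.id not in self._ss:
            self._ss[structure.id] = secondary_structure.label_map(structure)
        return self._ss[structure.id]


def _map_on_structure(record, octa, structure: Structure, config: RunConfig,
                      cache: _StructureCache):
    """Try to map one site on one structure; returns a dict describing the
    outcome on this structure."""
    chain = site_mapper.best_chain(structure)
    try:
        positions = site_mapper.locate_octapeptide(
            chain.sequence, octa.sequence8, record.position)
    except site_mapper.AmbiguousMatchError as exc:
        return {"status": "ambiguous", "reason": str(exc)}
    if positions is None:
        result = site_mapper.classify_failure(
            octa.sequence8, chain.sequence, chain, record.position)
        return {"status": result.status.value, "detail": result.detail}
    window = [chain.residues[p - 1] for p in positions]
    if any(not r.is_observed for r in window):
        return {"status": MatchStatus.DISORDERED.value}
    coverage = sequence_coverage(structure, chain.chain_id)
    if coverage < config.coverage_threshold:
        return {"status": MatchStatus.LOW_COVERAGE.value,
                "coverage": coverage}
    seq_nums = [r.seq_num for r in window]
    site = OctapeptideSite(
        sequence8=octa.sequence8,
        structure_ref=StructureRef(structure_id=structure.id,
                                   chain_id=chain.chain_id,
                                   seq_nums=seq_nums))
    rsasa = octapeptide_rsasa(structure, site, cache.params,
                              percent=cache.percent(structure))
    return {"status": MatchStatus.MATCHED.value, "rsasa": rsasa,
            "chain": chain.chain_id, "seq_nums": seq_nums,
            "coverage": coverage, "site": site}


_FAILURE_PRIORITY = ("disordered", "mutated", "low_coverage", "ambiguous",
                     "no_structure")


def run_map(config: RunConfig) -> pd.DataFrame:
    """Stage 1: map every phosphosite and classify the matched ones.

    Writes ``sites.tsv`` (one row per input site), ``proteins.tsv``
    (per-structure bookkeeping incl. the A_rel flexibility index) and
    ``map_summary.json`` to the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.sasa_params()
    cache = _StructureCache(params)
    structures = load_structures(config)
    text = Path(config.phosphosites).read_text()
    records, rejected = site_mapper.parse_phosphosite_table(text)
    if rejected:
        log.warning("rejected %d malformed phosphosite rows", len(rejected))
    log.info("run_map: %d sites, %d proteins with structures, config %s",
             len(records), len(structures), config.digest())

    rows = []
    for record in records:
        row = {"accession": record.accession, "position": record.position,
               "residue": record.residue, "octa8": "",
               "status": MatchStatus.NO_STRUCTURE.value, "structure_id": "",
               "chain": "", "rsasa": np.nan, "label": "", "rescue": "",
               "rescues": "", "ss8": "", "depth": np.nan,
               "mutation_detail": ""}
        rows.append(row)
        avail = structures.get(record.accession, [])
        octa = site_mapper.trim_to_octapeptide(record.window15)
        row["octa8"] = octa.sequence8

        if avail:
            seq_len = len(site_mapper.best_chain(avail[0]).residues)
            terminal = octa.terminal or (
                record.position <= seq_len
                and site_mapper.is_terminal(record.position, seq_len))
        else:
            terminal = octa.terminal
        if terminal:
            row["status"] = MatchStatus.TERMINAL.value
            continue
        if not avail:
            continue

        outcomes = [(s, _map_on_structure(record, octa, s, config, cache))
                    for s in avail]
        matched = [(s, o) for s, o in outcomes
                   if o["status"] == MatchStatus.MATCHED.value]
        if not matched:
            statuses = {o["status"] for _, o in outcomes}
            for status in _FAILURE_PRIORITY:
                if status in statuses:
                    row["status"] = status
                    break
            detail = next((o.get("detail") for _, o in outcomes
                           if o.get("detail")), None)
            if detail:
                row["mutation_detail"] = f"pos{detail[0]}:{detail[1]}"
            continue

        primary_structure, primary = matched[0]
        row.update(status=MatchStatus.MATCHED.value,
                   structure_id=primary_structure.id,
                   chain=primary["chain"], rsasa=primary["rsasa"])
        rsasa_by_structure = {s.id: o["rsasa"] for s, o in matched}

        result = cmap.classify(primary["rsasa"],
                               threshold=config.rsasa_threshold)
        if result.label == "disallowed" and \
                primary_structure.assembly_size > 1:
            monomer = extract_monomer(primary_structure, primary["chain"])
            mono_pct = residue_percent_sasa(monomer, params)
            mono_rsasa = float(np.mean(
                [mono_pct[(primary["chain"], n)].percent_sasa
                 for n in primary["seq_nums"]]))
            cmap.rescue_interface(result, mono_rsasa)
        if result.label == "disallowed" and len(matched) >= 2:
            cmap.rescue_alternate(result, rsasa_by_structure)
        if result.label == "disallowed" and \
                cmap.consensus_override(octa.sequence8):
            result.apply_rescue("consensus_motif")
        if result.label == "disallowed" and record.kinase_site:
            result.apply_rescue("autophosphorylation_flag")

        row.update(label=result.label, rescue=result.rescue,
                   rescues=",".join(result.rescues))
        depths = cache.depths(primary_structure)
        row["depth"] = float(np.mean(
            [depths[(primary["chain"], n)] for n in primary["seq_nums"]]))
        labels = cache.ss_labels(primary_structure)
        row["ss8"] = "".join(labels.get((primary["chain"], n), "C")
                             for n in primary["seq_nums"])

    columns = ["accession", "position", "residue", "octa8", "status",
               "structure_id", "chain", "rsasa", "label", "rescue",
               "rescues", "ss8", "depth", "mutation_detail"]
    frame = pd.DataFrame(rows, columns=columns)
    if frame.empty:
        log.warning("no phosphosite records; writing empty report")
    frame.to_csv(out / "sites.tsv", sep="\t", index=False)
    _write_proteins_table(structures, cache, params, out)
    summary = {
        "n_sites": len(frame),
        "n_rejected_rows": len(rejected),
        "status_counts": frame["status"].value_counts().to_dict(),
        "label_counts": frame.loc[frame.label != "", "label"]
        .value_counts().to_dict(),
        "rescue_counts": frame.loc[frame.rescue.isin(
            cmap.RESCUE_PRECEDENCE), "rescue"].value_counts().to_dict(),
        "config": config.digest(),
        "seed": config.seed,
    }
    (out / "map_summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
    return frame


def _write_proteins_table(structures, cache, params, out: Path) -> None:
    rows = []
    for accession, group in sorted(structures.items()):
        primary = group[0]
        chain = site_mapper.best_chain(primary)
        flex = cmap.compute_a_rel(primary, params)
        rows.append({
            "accession": accession,
            "structure_id": primary.id,
            "n_chains": primary.assembly_size,
            "coverage": sequence_coverage(primary, chain.chain_id),
            "mass": cmap.protein_mass(primary, chain.chain_id),
            "a_rel": np.nan if flex is None else flex.a_rel,
            "arel_filtered": flex is None,
        })
    pd.DataFrame(rows).to_csv(out / "proteins.tsv", sep="\t", index=False)


#: rescue rules that rank below dynamics; their sites are re-examined
_BELOW_DYNAMICS = ("consensus_motif", "autophosphorylation_flag")


def run_dynamics(config: RunConfig,
                 site_ids: list[tuple[str, int]] | None = None
                 ) -> pd.DataFrame:
    """Stage 2: conformer-ensemble rescue of buried sites.

    Eligible sites are the matched ones still disallowed after the static
    rules (plus those rescued only by rules ranking below dynamics, so the
    precedence ordering holds).  Each eligible site gets the full
    normal-mode ensemble; the anchored coarse rSASA of every conformer is
    compared against the classification threshold.  Updates ``sites.tsv``
    in place and writes ``dynamics.tsv``.
    """
    out = Path(config.out_dir)
    frame = pd.read_csv(out / "sites.tsv", sep="\t",
                        keep_default_na=False,
                        dtype={"rescues": str, "rescue": str})
    structures = load_structures(config)
    eligible = frame[(frame.status == MatchStatus.MATCHED.value)
                     & ((frame.label == "disallowed")
                        | frame.rescue.isin(_BELOW_DYNAMICS))]
    if site_ids is not None:
        wanted = set(site_ids)
        skipped = eligible.index[~eligible.apply(
            lambda r: (r.accession, r.position) in wanted, axis=1)]
        eligible = eligible.drop(index=skipped)
    dyn_rows = []
    conformer_rows = []
    for idx, row in eligible.iterrows():
        entry = {"accession": row.accession, "position": row.position,
                 "n_conformers": 0, "max_rsasa": np.nan, "rescued": False,
                 "reason": ""}
        dyn_rows.append(entry)
        structure = next(s for s in structures[row.accession]
                         if s.id == row.structure_id)
        try:
            model = enm_nma.build_enm(structure, cutoff=config.enm_cutoff,
                                      chain_id=row.chain)
            modes = enm_nma.normal_modes(model)
        except (enm_nma.MissingCAError,
                enm_nma.DisconnectedNetworkError, ValueError) as exc:
            entry["reason"] = f"ENM ineligible: {exc}"
            continue
        ensemble = enm_nma.generate_conformers(
            model, modes, n_modes=config.enm_n_modes,
            n_steps=config.enm_n_steps, max_amp=config.enm_max_amp)
        seq_nums = _window_seq_nums(structure, row, config)
        values, mx = enm_nma.ensemble_rsasa(
            ensemble, model, seq_nums, config.ensemble_params(),
            anchor_rsasa=float(row.rsasa))
        entry["n_conformers"] = len(ensemble)
        entry["max_rsasa"] = mx
        for (mode, step), value in zip(ensemble.provenance, values):
            conformer_rows.append((row.accession, row.position, mode, step,
                                   round(float(value), 4)))
        allowed, rescued = enm_nma.reclassify_by_dynamics(
            float(row.rsasa), values, threshold=config.rsasa_threshold)
        entry["rescued"] = bool(rescued)
        if rescued:
            rescues = [r for r in str(row.rescues).split(",") if r]
            rescues.append("dynamics")
            result = cmap.ClassificationResult(
                label="allowed", rsasa=float(row.rsasa),
                threshold_used=config.rsasa_threshold, rescues=rescues)
            frame.loc[idx, ["label", "rescue", "rescues"]] = \
                ["allowed", result.rescue, ",".join(rescues)]
    frame.to_csv(out / "sites.tsv", sep="\t", index=False)
    dyn = pd.DataFrame(dyn_rows, columns=["accession", "position",
                                          "n_conformers", "max_rsasa",
                                          "rescued", "reason"])
    dyn.to_csv(out / "dynamics.tsv", sep="\t", index=False)
    pd.DataFrame(conformer_rows,
                 columns=["accession", "position", "mode", "step",
                          "rsasa"]).to_csv(out / "dynamics_conformers.tsv",
                                           sep="\t", index=False)
    return dyn


def _window_seq_nums(structure: Structure, row, config: RunConfig):
    chain = structure.chain(row.chain)
    positions = site_mapper.locate_octapeptide(chain.sequence, row.octa8,
                                               int(row.position))
    return [chain.residues[p - 1].seq_num for p in positions]


def run_summaries(config: RunConfig) -> dict:
    """Stage 3: distribution and composition summaries.

    Produces rSASA histograms (overall and per phosphoresidue type),
    octapeptide secondary-structure composition, the amino-acid
    composition comparison between allowed and disallowed octapeptides,
    the A_rel distribution and the rSASA/depth consistency fraction.
    """
    out = Path(config.out_dir)
    frame = pd.read_csv(out / "sites.tsv", sep="\t", keep_default_na=False)
    matched = frame[frame.status == MatchStatus.MATCHED.value].copy()
    matched["rsasa"] = matched["rsasa"].astype(float)
    if matched.empty:
        raise ValueError("no matched sites; run the map stage first")

    summary: dict = {"n_matched": len(matched)}
    hist_rows = []
    counts, edges, mode_bin, median = cmap.bin_and_summarize(matched.rsasa)
    summary["rsasa_mode_bin"] = [round(edges[mode_bin], 1),
                                 round(edges[mode_bin + 1], 1)]
    summary["rsasa_median"] = median
    hist_rows.append(["all", *counts.tolist()])
    for res in sorted(matched.residue.unique()):
        sub = matched[matched.residue == res]
        c, _, _, _ = cmap.bin_and_summarize(sub.rsasa)
        hist_rows.append([res, *c.tolist()])
    bins = [f"{edges[i]:.1f}-{edges[i+1]:.1f}" for i in range(10)]
    pd.DataFrame(hist_rows, columns=["subset", *bins]).to_csv(
        out / "rsasa_histograms.tsv", sep="\t", index=False)

    with_ss = matched[matched.ss8 != ""]
    if not with_ss.empty:
        summary["ss_composition"] = secondary_structure.ss_composition(
            list(with_ss.ss8))

    allowed = matched[matched.label == "allowed"]
    disallowed = matched[matched.label == "disallowed"]
    if not allowed.empty and not disallowed.empty:
        comp = cmap.composition_compare(list(allowed.octa8),
                                        list(disallowed.octa8))
        summary["hydrophobic_difference"] = comp["hydrophobic_difference"]
        summary["charged_difference"] = comp["charged_difference"]
        pd.DataFrame({"aa": sorted(comp["allowed"]),
                      "allowed": [comp["allowed"][a]
                                  for a in sorted(comp["allowed"])],
                      "disallowed": [comp["disallowed"][a]
                                     for a in sorted(comp["disallowed"])]
                      }).to_csv(out / "composition.tsv", sep="\t",
                                index=False)

    with_depth = matched[matched.depth != ""]
    pairs = [(float(r.rsasa), float(r.depth))
             for r in with_depth.itertuples() if str(r.depth) != ""]
    if pairs:
        summary["depth_consistency"] = cmap.depth_consistency(
            pairs, depth_cutoff=config.depth_cutoff,
            rsasa_threshold=config.rsasa_threshold)

    proteins = pd.read_csv(out / "proteins.tsv", sep="\t")
    arel = proteins.a_rel.dropna()
    if len(arel):
        summary["a_rel_mean"] = float(arel.mean())
        summary["n_arel_proteins"] = int(len(arel))

    (out / "summaries.json").write_text(json.dumps(summary, indent=2,
                                                   sort_keys=True))
    return summary
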