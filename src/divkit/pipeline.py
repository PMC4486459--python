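"""End-to-end orchestration: distances -> tree -> loci/CNV -> selection ->
PBR tables, with plain-file stage handoff, config-hash caching, and a
machine-readable run report.

Stages exchange FASTA/Newick/TSV files under the output directory; each
stage directory carries the hash of the configuration slice it depends on,
so a rerun with an unchanged config reuses cached outputs and any parameter
change invalidates exactly the downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codeml, locus, pbr, phylo
from .alignment import AlignedSequenceSet
from .distance import group_distance, mcl_distances
from .simulate import LocusSpec, PopulationSimConfig, simulate_population_alleles


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # input: either a synthetic population block or explicit files
    synthetic: dict | None = None  # kwargs for PopulationSimConfig (minus seed)
    alignment_fasta: str | None = None
    genotype_tsv: str | None = None
    bootstrap_reps: int = 100
    tree_bootstrap_reps: int = 100
    max_alleles: int = 2
    run_selection: bool = False
    selection_models: tuple[str, ...] = ("M2a", "M3", "M8")
    selection_threshold: float = 0.9
    selection_min_models: int = 2
    leader_offset: int = pbr.DEFAULT_LEADER_OFFSET

    def __post_init__(self):
        if self.synthetic is None and self.alignment_fasta is None:
            raise ValueError("config needs a synthetic block or an alignment_fasta")
        for path in (self.alignment_fasta, self.genotype_tsv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def stage_hash(self, *fields_used: str) -> str:
        payload = {f: getattr(self, f) for f in sorted(fields_used)}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _log(msg: str) -> None:
    print(f"[divkit] {msg}", file=sys.stderr)


def _stage(out_dir: Path, name: str, h: str):
    d = out_dir / name
    marker = d / ".hash"
    cached = marker.exists() and marker.read_text() == h
    d.mkdir(parents=True, exist_ok=True)
    return d, cached, lambda: marker.write_text(h)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run report (also written to
    ``report.json``/``report.tsv`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.stage_hash(*vars(config))}

    # ---- stage 1: input -------------------------------------------------
    h1 = config.stage_hash("seed", "synthetic", "alignment_fasta", "genotype_tsv")
    d1, cached, done = _stage(out, "01_input", h1)
    aln_path, gm_path = d1 / "alleles.fasta", d1 / "genotypes.tsv"
    truth = None
    if config.synthetic is not None:
        raw = dict(config.synthetic)
        if "loci" in raw:
            raw["loci"] = [LocusSpec(**l) if isinstance(l, dict) else l for l in raw["loci"]]
        sim = simulate_population_alleles(PopulationSimConfig(**raw, seed=config.seed))
        truth = sim
        if not cached:
            sim.alleles.to_fasta(aln_path)
            sim.genotype.astype(int).to_csv(gm_path, sep="\t")
            pd.Series(sim.locus_of).to_csv(d1 / "true_loci.tsv", sep="\t", header=["locus"])
            done()
        aln = sim.alleles
        gm = sim.genotype
    else:
        aln = AlignedSequenceSet.from_fasta(config.alignment_fasta)
        gm = (
            pd.read_csv(config.genotype_tsv, sep="\t", index_col=0).astype(bool)
            if config.genotype_tsv
            else None
        )
        if not cached:
            aln.to_fasta(aln_path)
            done()
    _log(f"input: {len(aln)} sequences x {aln.length} columns")
    report["n_sequences"] = len(aln)
    report["alignment_length"] = aln.length

    # ---- stage 2: distances --------------------------------------------
    h2 = h1 + config.stage_hash("bootstrap_reps")
    d2, cached, done = _stage(out, "02_distance", h2)
    dm = mcl_distances(aln, bootstrap_reps=config.bootstrap_reps, seed=config.seed)
    if not cached:
        dm.to_tsv(d2 / "distances.tsv")
        done()
    iu = np.triu_indices(len(dm.labels), 1)
    report["mean_distance"] = float(np.nanmean(dm.d[iu]))
    report["mean_distance_se"] = float(np.nanmean(dm.se[iu]))
    _log(f"mean pairwise distance {report['mean_distance']:.4f}")

    # ---- stage 3: tree --------------------------------------------------
    h3 = h2 + config.stage_hash("tree_bootstrap_reps")
    d3, cached, done = _stage(out, "03_tree", h3)
    tree = phylo.bootstrap_support(aln, reps=config.tree_bootstrap_reps, seed=config.seed)
    if not cached:
        tree.write(path=str(d3 / "nj_supported.nwk"), schema="newick")
        done()
    report["tree_length"] = float(sum(e.length or 0 for e in tree.edges() if e.head_node.parent_node))

    # ---- stage 4: loci + CNV -------------------------------------------
    if gm is not None:
        h4 = h3 + config.stage_hash("max_alleles")
        d4, cached, done = _stage(out, "04_loci", h4)
        part = locus.assign_loci(tree, gm, max_alleles=config.max_alleles)
        cnv = locus.detect_cnv(part, gm)
        if not cached:
            rows = [(g, s) for g, mem in sorted(part.groups.items()) for s in sorted(mem)]
            pd.DataFrame(rows, columns=["group", "sequence"]).to_csv(
                d4 / "partition.tsv", sep="\t", index=False
            )
            cnv.carries_locus.astype(int).to_csv(d4 / "presence_matrix.tsv", sep="\t")
            done()
        report["n_locus_groups"] = len(part.groups)
        report["partition_valid"] = part.valid
        report["haplotypic_variation"] = cnv.haplotypic_variation
        report["group_sizes"] = {g: len(m) for g, m in sorted(part.groups.items())}
        _log(
            f"loci: {len(part.groups)} groups, gene-content variation="
            f"{cnv.haplotypic_variation}"
        )
        groups_map = {s: g for g, mem in part.groups.items() for s in mem}
        within = {}
        for g, mem in sorted(part.groups.items()):
            if len(mem) >= 2:
                m, se = group_distance(dm, groups_map, "within", select=g)
                within[g] = {"mean": m, "se": se}
        report["within_group_distance"] = within
        if truth is not None:
            report["true_loci"] = sorted(set(truth.locus_of.values()))

    # ---- stage 5: selection --------------------------------------------
    sel = None
    if config.run_selection:
        h5 = h3 + config.stage_hash("selection_models", "selection_threshold", "selection_min_models")
        d5, cached, done = _stage(out, "05_selection", h5)
        models = tuple(dict.fromkeys(("M0", "M1a") + tuple(config.selection_models)))
        fits = codeml.fit_models(aln, tree, models=models)
        lrts = {}
        for null, alt in (("M1a", "M2a"), ("M1a", "M8"), ("M0", "M3")):
            if null in fits and alt in fits:
                r = codeml.lrt(fits[null], fits[alt])
                lrts[f"{null}_vs_{alt}"] = {"stat": r.stat, "df": r.df, "p": r.p_value}
        sel = codeml.selected_sites(
            fits, threshold=config.selection_threshold, min_models=config.selection_min_models
        )
        if not cached:
            pd.DataFrame(
                [
                    {"model": m, "lnL": f.lnL, "kappa": f.kappa, "scale": f.branch_scale}
                    for m, f in fits.items()
                ]
            ).to_csv(d5 / "model_fits.tsv", sep="\t", index=False)
            pd.DataFrame(
                [{"codon": s.position, **s.posteriors} for s in sel.sites]
            ).to_csv(d5 / "selected_sites.tsv", sep="\t", index=False)
            done()
        report["lrt"] = lrts
        report["selected_codons"] = sel.positions
        _log(f"selection: {len(sel.positions)} consensus sites")

    # ---- stage 6: PBR variability --------------------------------------
    if gm is not None:
        d6, cached, done = _stage(out, "06_pbr", h3 + config.stage_hash("leader_offset"))
        try:
            proteins = pbr.translate_and_number(aln, numbering_offset=config.leader_offset)
            cmap = pbr.ContactMap.load()
            kirset = pbr.KirContactSet.load()
            lineages = {s: g for g, mem in part.groups.items() for s in mem}
            table = pbr.tabulate_variability(proteins, lineages, cmap, selected=sel, kir=kirset)
            if not cached:
                table.to_csv(d6 / "variability.tsv", sep="\t")
                done()
            covered = table[table["covered"]]
            report["pbr_positions_covered"] = int(covered.shape[0])
            report["pbr_positions_variable"] = int(covered["variable"].sum())
        except ValueError as exc:
            report["pbr_error"] = str(exc)
            _log(f"pbr stage skipped: {exc}")

    body = json.dumps(report, indent=2, sort_keys=True, default=str)
    (out / "report.json").write_text(body + "\n")
    flat = {k: v for k, v in report.items() if not isinstance(v, (dict, list))}
    pd.Series(flat).to_csv(out / "report.tsv", sep="\t", header=["value"])
    return report
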