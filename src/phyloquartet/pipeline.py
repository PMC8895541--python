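"""Pipeline orchestration: one config drives curation, concatenation,
tier compilation, SRH screening, and the quartet analyses (FcLM, QS, AU),
writing all artifacts plus a machine-readable run report.

Every stochastic stage derives its own substream from the mandatory
top-level seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import curation, fclm, io, qs, simulate, srh, topotest
from .alignment import Supermatrix
from .curation import DatasetTier, GroupDefinitions
from .models import SubstModel, empirical_synthetic_model, poisson_model, read_paml_matrix
from .trees import PhyloTree

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report", "load_config"]


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    genes_dir: str | None = None
    simulate: dict | None = None
    model: dict = field(default_factory=lambda: {"type": "poisson"})
    curation: dict = field(default_factory=dict)
    tiers: list[str] = field(default_factory=lambda: ["unreduced"])
    groups: dict[str, list[str]] | None = None
    srh: dict | None = None
    fclm: dict | None = None
    qs: dict | None = None
    au: dict | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if (self.genes_dir is None) == (self.simulate is None):
            raise ValueError("configure exactly one of genes_dir / simulate")
        for t in self.tiers:
            DatasetTier(t)
        if "intermediate" in self.tiers and not self.groups:
            raise ValueError("intermediate tier requires group definitions")
        if self.fclm is not None and not self.groups:
            raise ValueError("FcLM requires group definitions")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "stages": self.stages}


def _build_model(spec: dict) -> SubstModel:
    kind = spec.get("type", "poisson")
    gamma = spec.get("gamma_shape")
    ncat = spec.get("categories", 4)
    if kind == "poisson":
        return poisson_model(gamma_shape=gamma, n_rate_categories=ncat)
    if kind == "empirical_synthetic":
        return empirical_synthetic_model(gamma_shape=gamma, n_rate_categories=ncat)
    if kind == "paml":
        return read_paml_matrix(spec["path"], gamma_shape=gamma, n_rate_categories=ncat)
    raise ValueError(f"unknown model type {kind!r}")


def _load_genes(cfg: PipelineConfig, rng_seed: int):
    if cfg.genes_dir is not None:
        paths = sorted(Path(cfg.genes_dir).glob("*.fa*"))
        if not paths:
            raise ValueError(f"no FASTA files in {cfg.genes_dir}")
        return [(p.stem, io.read_fasta(p)) for p in paths], None
    sim = dict(cfg.simulate)
    sim.setdefault("seed", rng_seed)
    het = sim.pop("het", None)
    if het is not None:
        het = simulate.HeterogeneitySpec(
            set(het["affected_taxa"]), np.asarray(het["freqs_alt"], dtype=float),
            het.get("fraction", 1.0))
    miss = sim.pop("missingness", None)
    if miss is not None:
        miss = simulate.MissingnessSpec(**miss)
    outl = sim.pop("outliers", None)
    if outl is not None:
        outl = simulate.OutlierSpec(**outl)
    fx = simulate.make_fourgroup_fixture(het=het, miss=miss, outliers=outl, **sim)
    return fx.genes, fx


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(cfg))
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: s for name, s in zip(
        ("simulate", "curation", "fclm", "qs", "au"), ss.spawn(5))}
    model = _build_model(cfg.model)

    genes, fixture = _load_genes(cfg, seeds["simulate"].generate_state(1)[0] % 2**31)
    report.stages["input"] = {"n_genes": len(genes),
                              "n_taxa": len({t for _, a in genes for t in a.labels}),
                              "source": "simulate" if fixture else "genes_dir"}
    if fixture is not None and fixture.presence is not None:
        fixture.presence.to_csv(out / "presence_matrix.tsv", sep="\t")

    # -- curation ------------------------------------------------------------
    cur = cfg.curation
    cur_rng = np.random.default_rng(seeds["curation"])
    stage: dict[str, Any] = {}
    if cur.get("drop_taxa"):
        genes = curation.drop_taxa(genes, cur["drop_taxa"])
        stage["dropped_taxa"] = list(cur["drop_taxa"])
    if cur.get("detect_outliers", False):
        removed = []
        cleaned = []
        for g, aln in genes:
            flags = curation.detect_outlier_sequences(
                aln, cutoff=cur.get("outlier_cutoff", 3.5))
            removed += [(g, t) for t in flags]
            cleaned.append((g, aln.drop_taxa(flags) if flags else aln))
        genes = cleaned
        stage["outlier_sequences_removed"] = len(removed)
        pd.DataFrame(removed, columns=["gene", "taxon"]).to_csv(
            out / "removed_outliers.tsv", sep="\t", index=False)
    if cur.get("mask") is not None:
        mask_cfg = cur["mask"] or {}
        total_masked = 0
        masked_genes = []
        for g, aln in genes:
            cols = curation.mask_ambiguous_sites(
                aln, window=mask_cfg.get("window", 6),
                reps=mask_cfg.get("reps", 100),
                seed=cur_rng.integers(2**31))
            keep = np.setdiff1d(np.arange(aln.n_sites), cols)
            total_masked += cols.size
            if keep.size:
                masked_genes.append((g, aln.select_columns(keep)))
        genes = masked_genes
        stage["sites_masked"] = int(total_masked)
    all_species = sorted({t for _, aln in genes for t in aln.labels})
    table = pd.DataFrame(False, index=[g for g, _ in genes],
                         columns=all_species)  # genes x species
    for g, aln in genes:
        table.loc[g, aln.labels] = True
    if cur.get("species_coverage") is not None:
        retained, excluded = curation.filter_species_by_coverage(
            table, ortholog_set_size=cur.get("ortholog_set_size", len(genes)),
            threshold=cur.get("species_coverage", 0.60))
        if excluded:
            genes = curation.drop_taxa(genes, list(excluded))
            table = table[retained]
        stage["species_excluded"] = sorted(excluded)
    if cur.get("gene_coverage") is not None:
        kept = set(curation.filter_genes_by_coverage(
            table, threshold=cur.get("gene_coverage", 0.50)))
        genes = [(g, a) for g, a in genes if g in kept]
        stage["genes_kept"] = len(genes)
    report.stages["curation"] = stage

    # -- concatenation + tiers -----------------------------------------------
    sm = curation.concatenate(genes)
    io.write_supermatrix(sm, out / "supermatrix_unreduced.fasta",
                         out / "partitions_unreduced.txt")
    groups = GroupDefinitions(cfg.groups) if cfg.groups else None
    tiers: dict[str, Supermatrix] = {}
    tier_stage = {}
    for t in cfg.tiers:
        tiers[t] = curation.compile_dataset(sm, t, groups)
        io.write_supermatrix(tiers[t], out / f"supermatrix_{t}.fasta",
                             out / f"partitions_{t}.txt")
        rep = curation.completeness(tiers[t])
        tier_stage[t] = {"n_genes": len(tiers[t].partitions),
                         "n_sites": tiers[t].alignment.n_sites,
                         "n_taxa": tiers[t].alignment.n_taxa,
                         "completeness": round(rep.overall_completeness, 6)}
    report.stages["tiers"] = tier_stage

    def pick_tier(section: dict) -> Supermatrix:
        t = section.get("tier", cfg.tiers[0])
        return tiers.get(t) or curation.compile_dataset(sm, t, groups)

    # -- SRH -------------------------------------------------------------
    if cfg.srh is not None:
        alpha = cfg.srh.get("alpha", 0.05)
        srh_sm = pick_tier(cfg.srh)
        pmat = srh.all_pairs(srh_sm)
        pmat.to_csv(out / "bowker_pvalues.tsv", sep="\t")
        offenders = srh.rank_offenders(pmat, alpha)
        offenders.to_csv(out / "bowker_offenders.tsv", sep="\t", index=False)
        report.stages["srh"] = {
            "alpha": alpha,
            "percent_violating": round(srh.percent_violating(pmat, alpha), 4),
            "worst_offender": offenders.iloc[0]["taxon"],
        }

    # -- FcLM ------------------------------------------------------------
    if cfg.fclm is not None:
        fc = cfg.fclm
        fgroups = fclm.FourGroups.from_dict(
            {k: cfg.groups[k] for k in fc.get("group_names", sorted(cfg.groups)[:4])})
        res = fclm.run_fclm(
            pick_tier(fc), fgroups, model,
            cap=fc.get("cap", 1000),
            seed=int(seeds["fclm"].generate_state(1)[0] % 2**31),
            schemes=fc.get("schemes", ["I"]),
            n_permutation_replicates=fc.get("n_permutation_replicates", 1),
            min_sites=fc.get("min_sites", 50))
        fclm.summary_frame(res).to_csv(out / "fclm_summary.tsv", sep="\t", index=False)
        quartet_rows = []
        for dataset, evals in res.evals.items():
            for e in evals:
                row = {"dataset": dataset, "taxa": ",".join(e.taxa),
                       "region": e.region, "n_sites": e.n_sites}
                if e.weights is not None:
                    row.update({f"w{k + 1}": float(w) for k, w in enumerate(e.weights)})
                quartet_rows.append(row)
        pd.DataFrame(quartet_rows).to_csv(out / "fclm_quartets.tsv", sep="\t", index=False)
        fclm_stage = {"original_corner_pct":
                      [round(float(x), 3) for x in res.original.corner_percentages()]}
        for scheme, summ in res.permuted.items():
            fclm_stage[f"scheme_{scheme}_corner_pct"] = [
                round(float(x), 3) for x in summ.corner_percentages()]
            fclm_stage[f"net_{scheme}"] = [round(float(x), 3) for x in res.net(scheme)]
        report.stages["fclm"] = fclm_stage

    # -- Quartet Sampling -------------------------------------------------
    if cfg.qs is not None:
        qs_cfg = cfg.qs
        tree = _resolve_tree(qs_cfg.get("tree"), fixture)
        config = qs.QSConfig(
            n_per_branch=qs_cfg.get("n_per_branch", 100),
            delta=qs_cfg.get("delta", 2.0),
            seed=int(seeds["qs"].generate_state(1)[0] % 2**31),
            min_sites=qs_cfg.get("min_sites", 50))
        table_qs, qf, annotated = qs.run_qs(pick_tier(qs_cfg), tree, model, config)
        table_qs.to_csv(out / "qs_branch_scores.tsv", sep="\t", index=False)
        qf.rename("QF").to_csv(out / "qs_taxon_fidelity.tsv", sep="\t")
        io.write_tree(annotated, out / "qs_annotated.nwk", decimals=5)
        report.stages["qs"] = {
            "n_branches": int(len(table_qs)),
            "min_qc": None if table_qs["QC"].dropna().empty
            else round(float(table_qs["QC"].dropna().min()), 4),
        }

    # -- AU placement tests ------------------------------------------------
    if cfg.au is not None:
        au_cfg = cfg.au
        backbone = _resolve_tree(au_cfg["tree"], fixture)
        placements = topotest.build_placements(
            backbone, au_cfg["focal"], au_cfg["edges"],
            labels=au_cfg.get("labels"))
        au_sm = pick_tier(au_cfg)
        table = topotest.site_lnl_table(
            [p.tree for p in placements], au_sm, model,
            optimize_branches=au_cfg.get("optimize_branches", True))
        res = topotest.au_test(
            table, scales=au_cfg.get("scales", topotest.DEFAULT_SCALES),
            n_boot=au_cfg.get("n_boot", 10000),
            seed=int(seeds["au"].generate_state(1)[0] % 2**31),
            labels=[p.label for p in placements])
        df = pd.DataFrame({"p_au": res.p_values, "d": res.d, "c": res.c,
                           "degenerate": res.degenerate,
                           "total_lnL": table.sum(axis=1)})
        df.to_csv(out / "au_results.tsv", sep="\t")
        report.stages["au"] = {
            "p_values": {k: round(float(v), 6) for k, v in res.p_values.items()}}

    write_report(report, out)
    return report


def _resolve_tree(spec, fixture) -> PhyloTree:
    if spec == "truth":
        if fixture is None:
            raise ValueError("tree 'truth' requires a simulator-backed run")
        t1 = fixture.truth[fixture.truth.topology == "T1"]
        if t1.empty:
            raise ValueError("no concordant gene in fixture to take a tree from")
        return PhyloTree.from_newick(t1.iloc[0]["newick"])
    if isinstance(spec, str) and spec.endswith((";", ")")):
        return PhyloTree.from_newick(spec)
    return io.read_tree(spec)


def write_report(report: RunReport, out_dir) -> Path:
    """YAML report plus a short human-readable summary; round-trippable."""
    out = Path(out_dir)
    path = out / "run_report.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(report.to_dict()), fh, sort_keys=True)
    lines = [f"pipeline run (seed {report.config['seed']})"]
    for stage, info in report.stages.items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    (out / "run_report.txt").write_text("\n".join(lines) + "\n")
    return path


def read_report(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively convert numpy scalars/arrays for clean YAML."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
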