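"""End-to-end orchestration of the synthetic demo workflow.

Runs the stages in order — simulate, filter, estimate, core calling,
species-tree extraction, ancestral reconstruction, comparative analysis —
writing every stage's outputs as TSV/JSON plus a manifest of SHA-256 hashes.
Reruns with an identical configuration and seed are bit-identical.

The demo is entirely synthetic: a genome-level phylogeny with known species
membership, orthogroup content evolved down the species tree (so the
ancestral root set is known), per-species Bernoulli pangenome matrices, and
QC metadata correlated with the true recovery rates.
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

from . import ancestral, comparative, freq, phylo, qc, simulate

logger = logging.getLogger("pancore")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters.

    Defaults are the production values: contamination < 10%, completeness
    > 80%, contig count within 3x the species median, length within 3 SD,
    >= 50 genomes per species; estimation floor 0.10, q initialized at 0.99;
    core threshold 0.9999; g-grid 0.1 to 2.0 in 0.05 steps.
    """

    seed: int = 1
    threads: int = 1

    # synthetic-cohort shape
    n_species: int = 12
    genomes_per_species: int = 60
    scramble: float = 0.0
    n_root_ogs: int = 60
    n_pool_ogs: int = 120
    gain_rate: float = 0.05
    loss_rate: float = 0.15
    n_accessory: int = 40
    recovery_low: float = 0.9
    recovery_high: float = 1.0
    metadata_noise_sd: float = 2.0

    # filtering
    max_contamination: float = 10.0
    min_completeness: float = 80.0
    contig_fold: float = 3.0
    length_sd: float = 3.0
    min_genomes: int = 50

    # frequency estimation / core calling
    estimation_floor: float = 0.10
    q_init: float = 0.99
    tol: float = 1e-9
    max_iter: int = 15000
    core_threshold: float = 0.9999

    # ancestral reconstruction
    grid_start: float = 0.1
    grid_stop: float = 2.0
    grid_step: float = 0.05

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all stages; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    outputs: list[Path] = []

    def _record(path: Path) -> Path:
        outputs.append(path)
        return path

    # ------------------------------------------------------------------ simulate
    logger.info("stage simulate: %d species x %d genomes", config.n_species,
                config.genomes_per_species)
    genome_tree, species_map = simulate.simulate_species_genome_tree(
        config.n_species, config.genomes_per_species, seed=seed, scramble=config.scramble
    )
    phylo.write_newick(genome_tree, _record(outdir / "genome_tree.nwk"))
    phylo.write_species_map(species_map, _record(outdir / "species_map.tsv"))

    # true species tree for evolving orthogroup content
    true_species_tree = phylo.extract_species_tree(genome_tree, species_map)
    pool = [f"OG{i:04d}" for i in range(config.n_pool_ogs)]
    root_set = set(pool[: config.n_root_ogs])
    evo = simulate.simulate_gene_content_evolution(
        true_species_tree.tree.clone(depth=1), root_set, set(pool),
        config.gain_rate, config.loss_rate, seed=seed,
    )
    truth_rows = [
        {"node": label, "ogs": ";".join(sorted(ogs))}
        for label, ogs in sorted(evo.node_states.items())
    ]
    pd.DataFrame(truth_rows).to_csv(
        _record(outdir / "truth_node_states.tsv"), sep="\t", index=False
    )

    rng = np.random.default_rng([seed, 0xC0FE])
    leaf_states = evo.leaf_states()
    matrices: dict[str, object] = {}
    truths: dict[str, simulate.PangenomeTruth] = {}
    metadata_frames = []
    for si, sp in enumerate(sorted(species_map)):
        core_ogs = sorted(leaf_states[sp])
        non_core = [og for og in pool if og not in leaf_states[sp]]
        k_acc = min(config.n_accessory, len(non_core))
        acc = sorted(rng.choice(non_core, size=k_acc, replace=False)) if k_acc else []
        genes = core_ogs + list(acc)
        p = np.concatenate([np.ones(len(core_ogs)), rng.uniform(0.1, 0.9, len(acc))])
        genomes = sorted(species_map[sp])
        mat, truth = simulate.simulate_pangenome(
            len(genes), len(genomes),
            freq_sampler=p,
            recovery_sampler=("uniform", config.recovery_low, config.recovery_high),
            seed=seed + 1000 + si,
            gene_ids=genes, genome_ids=genomes,
        )
        matrices[sp] = mat
        truths[sp] = truth
        mat.to_tsv(_record(outdir / f"matrix_{sp}.tsv"))
        metadata_frames.append(
            simulate.simulate_metadata(
                truth, noise_sd=config.metadata_noise_sd, seed=seed + 2000 + si,
                genome_ids=genomes, species_ids=[sp] * len(genomes),
            )
        )
    metadata = pd.concat(metadata_frames, ignore_index=True)
    metadata.to_csv(_record(outdir / "metadata.tsv"), sep="\t", index=False)

    # ------------------------------------------------------------------ filter
    logger.info("stage filter")
    report = qc.filter_genomes(
        metadata,
        max_contamination=config.max_contamination,
        min_completeness=config.min_completeness,
        contig_fold=config.contig_fold,
        length_sd=config.length_sd,
        min_genomes=config.min_genomes,
    )
    report.to_tsv(_record(outdir / "filter_report.tsv"))
    report.to_json(_record(outdir / "filter_summary.json"))
    qualifying = sorted(report.qualifying_species)
    if not qualifying:
        raise RuntimeError("stage filter: no species qualified")

    # ------------------------------------------------------------------ estimate + core
    logger.info("stage estimate: %d species", len(qualifying))
    core_sets: dict[str, set] = {}
    gene_frames = []
    genome_frames = []
    for sp in qualifying:
        kept = sorted(report.kept[sp])
        mat = matrices[sp].select_genomes(kept)
        est = freq.estimate(
            mat,
            estimation_floor=config.estimation_floor,
            q_init=config.q_init,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        core_sets[sp] = freq.call_core(est, config.core_threshold)
        gf = est.gene_frame()
        gf.insert(0, "species_id", sp)
        gene_frames.append(gf)
        qf = est.genome_frame()
        qf.insert(0, "species_id", sp)
        genome_frames.append(qf)
    pd.concat(gene_frames, ignore_index=True).to_csv(
        _record(outdir / "gene_estimates.tsv"), sep="\t", index=False
    )
    pd.concat(genome_frames, ignore_index=True).to_csv(
        _record(outdir / "genome_estimates.tsv"), sep="\t", index=False
    )
    core_rows = [
        {"species_id": sp, "core_ogs": ";".join(sorted(core_sets[sp]))} for sp in qualifying
    ]
    pd.DataFrame(core_rows).to_csv(_record(outdir / "core_genomes.tsv"), sep="\t", index=False)

    # ------------------------------------------------------------------ species tree
    logger.info("stage species-tree")
    kept_map = {sp: report.kept[sp] for sp in qualifying}
    sp_tree = phylo.extract_species_tree(genome_tree, kept_map)
    phylo.write_newick(sp_tree.tree, _record(outdir / "species_tree.nwk"))
    sp_tree.diagnostics_frame().to_csv(
        _record(outdir / "species_tree_diagnostics.tsv"), sep="\t", index=False
    )

    # ------------------------------------------------------------------ ancestral
    logger.info("stage ancestral")
    og_table = pd.DataFrame(
        {sp: [1 if og in core_sets[sp] else 0 for og in pool] for sp in qualifying},
        index=pool,
    )
    og_table.to_csv(_record(outdir / "og_table.tsv"), sep="\t", index_label="og_id")
    recon = ancestral.AncestralReconstruction(
        sp_tree.tree, config.grid_start, config.grid_stop, config.grid_step
    ).fit(og_table)
    ancestral.profiles_frame(recon.profiles_, recon.grid_).to_csv(
        _record(outdir / "ancestral_profiles.tsv"), sep="\t", index=False
    )

    # ------------------------------------------------------------------ comparative
    logger.info("stage analyze")
    g_mid = min(recon.grid_, key=lambda g: abs(g - 1.0))
    g_max = recon.grid_[-1]
    lbca_mid = recon.core_at(g_mid)
    lbca_max = recon.core_at(g_max)
    jaccards = {sp: comparative.jaccard(lbca_mid, core_sets[sp]) for sp in qualifying}
    corr = comparative.threshold_prevalence_correlation(recon.profiles_)
    truth_root = set(evo.root_state)
    summary = {
        "qualifying_species": qualifying,
        "core_sizes": {sp: len(core_sets[sp]) for sp in qualifying},
        "lbca_core_size_at_g1": len(lbca_mid),
        "lbca_core_size_at_gmax": len(lbca_max),
        "jaccard_lbca_vs_modern": jaccards,
        "root_jaccard_vs_truth_at_g1": comparative.jaccard(lbca_mid, truth_root),
        "min_g_prevalence_spearman": corr.rho if corr.ok else None,
    }
    _write_json(summary, _record(outdir / "analysis_summary.json"))

    # ------------------------------------------------------------------ manifest
    cfg = config.to_dict()
    cfg.pop("threads", None)  # worker count never changes results
    manifest = {
        "config": cfg,
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    _write_json(manifest, outdir / "manifest.json")
    return outdir
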