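"""Configuration-driven orchestration of the full synthetic-data pipeline.

``run_pipeline`` executes every stage in dependency order on a simulated
multi-species dataset: karyotype + landscape simulation, windowing and
quartile tracks, conserved-region calling, projection onto the ancestral
karyotype, gene retention, pathway skew, and a toy region-phylogenomics
comparison. Every output file carries the configuration hash; rerunning
with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as aio
from .conserved import call_conserved_regions, calls_to_frame
from .evaluate import planted_recovery, recovery_rate
from .genes import (
    apply_symbol_resolution,
    assign_gene_categories,
    genes_in_calls,
    resolve_loc_symbols,
    retention_summary,
    shared_gene_set,
)
from .pathways import analyze_pathway_skew
from .phylo import compare_trees, filter_columns_by_missingness, nj_tree, subsample_columns
from .ratemaps import assign_quartiles, make_windows, map_rates_to_windows, sliding_average
from .simulate import (
    SimConfig,
    Simulation,
    simulate_alignment_pair,
    simulate_genes_and_pathways,
    simulate_karyotypes,
    simulate_recombination_landscape,
    write_simulation,
)

logger = logging.getLogger("ancrecomb")

DEFAULT_PHYLO_TREE = (
    "((((t1:0.05,t2:0.05):0.04,(t3:0.04,t4:0.06):0.03):0.05,"
    "(t5:0.08,t6:0.07):0.06):0.04,(t7:0.12,t8:0.1):0.05);"
)


@dataclass
class RunConfig:
    """All pipeline parameters; the defaults are the standard analysis values
    (1.5 Mb windows, 2 Mb / 50 kb sliding blocks, 3-of-4 consensus, 1 Mb
    merge gap, alpha 0.05)."""

    sim: SimConfig = field(default_factory=SimConfig)
    window_size: int = 1_500_000
    sliding: bool = False  # tracks from the simulator are already map-level
    sliding_block: int = 2_000_000
    sliding_step: int = 50_000
    length_weighted: bool = False
    min_support: int = 3
    min_run: int = 2
    merge_gap: int = 1_000_000
    alpha: float = 0.05
    phylo_columns: int = 2_000
    phylo_rate_multiplier: float = 2.0
    phylo_missing_fraction: float = 0.05
    phylo_tree: str = DEFAULT_PHYLO_TREE

    def validate(self) -> None:
        self.sim.validate()
        if self.min_support > self.sim.n_species:
            raise ValueError(
                f"min_support ({self.min_support}) exceeds n_species ({self.sim.n_species})"
            )
        if self.window_size <= 0 or self.merge_gap < 0 or not (0 < self.alpha < 1):
            raise ValueError("invalid analysis parameters")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["ancestral_chromosomes"] = [list(t) for t in self.sim.ancestral_chromosomes]
        d["sim"]["pathway_spec"] = [list(t) for t in self.sim.pathway_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        sim["ancestral_chromosomes"] = tuple(
            (str(n), int(length)) for n, length in sim.get("ancestral_chromosomes", SimConfig().ancestral_chromosomes)
        )
        sim["pathway_spec"] = tuple(
            (str(n), int(k), float(f)) for n, k, f in sim.get("pathway_spec", SimConfig().pathway_spec)
        )
        return cls(sim=SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha1(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Run every stage and write all artefacts under ``out_dir``.

    Returns a results dict with the in-memory objects and summary metrics.
    """
    config.validate()
    aio.ensure_dir(out_dir)
    header = f"ancrecomb run config={config.digest()}"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    config.to_yaml(f"{out_dir}/config.yaml")
    log(f"stage simulate: seed={config.sim.seed} n_species={config.sim.n_species}")
    sim = simulate_karyotypes(config.sim)
    maps = simulate_recombination_landscape(sim)
    gsim = simulate_genes_and_pathways(sim)
    write_simulation(sim, maps, gsim, f"{out_dir}/dataset")

    log("stage quartiles: windowing and genome-wide ranking per species")
    tracks = {}
    for g in sim.species:
        rmap = maps[g.name]
        if config.sliding:
            rmap = sliding_average(rmap, config.sliding_block, config.sliding_step, g.chrom_sizes)
        windows = make_windows(g.chrom_sizes, config.window_size)
        windowed = map_rates_to_windows(rmap, windows, config.length_weighted)
        tracks[g.name] = assign_quartiles(windowed)
        aio.write_bed(
            tracks[g.name].entries.dropna().rename(columns={"category": "name"}),
            f"{out_dir}/{g.name}.quartiles.bed",
            header=header,
        )

    log("stage call-regions: consensus across species")
    ref_to_species = {
        g.name: g.to_reference.invert() for g in sim.species if g.name != sim.reference
    }
    alr, ahr, call_log = call_conserved_regions(
        tracks,
        sim.reference,
        ref_to_species,
        min_support=config.min_support,
        n_species=config.sim.n_species,
        min_run=config.min_run,
        max_gap=config.merge_gap,
    )
    log_lines.extend(call_log)
    aio.write_bed(calls_to_frame(alr), f"{out_dir}/calls_alr.bed", header=header)
    aio.write_bed(calls_to_frame(ahr), f"{out_dir}/calls_ahr.bed", header=header)

    log("stage project-ancestor: mapping calls onto the ancestral karyotype")
    ref_to_anc = sim.genome(sim.reference).to_ancestor
    anc_rows = []
    for call in alr + ahr:
        mapped, _ = ref_to_anc.project_region(call.chrom, call.start, call.end, warn_unmapped=False)
        for m in mapped:
            anc_rows.append(
                (m["dst_chrom"], m["dst_start"], m["dst_end"],
                 f"{call.region_class}:{call.support}", call.support, m["src_fragment"])
            )
    anc_df = pd.DataFrame(
        anc_rows, columns=["chrom", "start", "end", "name", "score", "provenance"]
    ).sort_values(["chrom", "start"])
    anc_df.to_csv(f"{out_dir}/calls_ancestor.bed", sep="\t", index=False, header=False)

    log("stage genes: LOC resolution, categories, shared set, retention")
    mapping, unresolved = resolve_loc_symbols(gsim.orthogroups, anchor_species=(sim.reference,))
    if unresolved:
        log(f"unresolved LOC symbols: {len(unresolved)}")
    species_genes = {
        sp: apply_symbol_resolution(df, mapping) for sp, df in gsim.species_genes.items()
    }
    categories = {}
    for k, (sp, df) in enumerate(sorted(species_genes.items())):
        df = df.copy()
        df["category"] = assign_gene_categories(df, tracks[sp], seed=config.sim.seed * 1000 + k)
        species_genes[sp] = df
        categories[sp] = dict(zip(df["symbol"], df["category"]))
    shared, shared_log = shared_gene_set(species_genes)
    log_lines.extend(shared_log)
    ref_genes = species_genes[sim.reference]
    class_sets = genes_in_calls(ref_genes[ref_genes["symbol"].isin(shared)], alr, ahr)
    retention = None
    if class_sets["ALR"] and class_sets["AHR"]:
        retention = retention_summary(class_sets, categories)
        retention.table.to_csv(f"{out_dir}/retention.tsv", sep="\t", index=False)
        for cls, members in retention.intersections.items():
            with open(f"{out_dir}/intersection_{cls.lower()}.txt", "w") as fh:
                fh.write("\n".join(sorted(members)) + "\n")
    else:
        log("gene retention skipped: a class gene set is empty")

    log("stage skew: pathway chi-squared with BH correction")
    skew = analyze_pathway_skew(
        class_sets["AHR"], class_sets["ALR"], gsim.pathways, alpha=config.alpha
    )
    skew.to_csv(f"{out_dir}/pathway_skew.tsv", sep="\t", index=False)

    log("stage phylo: toy alignment pair, NJ fits, tree comparison")
    aln_a, aln_b, _tree = simulate_alignment_pair(
        config.phylo_tree,
        config.phylo_columns,
        rate_multiplier=config.phylo_rate_multiplier,
        missing_fraction=config.phylo_missing_fraction,
        seed=config.sim.seed,
    )
    filt_a = filter_columns_by_missingness(aln_a)
    filt_b = filter_columns_by_missingness(aln_b)
    n_sub = min(filt_a.n_columns, filt_b.n_columns)
    comparison = compare_trees(
        nj_tree(subsample_columns(filt_a, n_sub, config.sim.seed)),
        nj_tree(subsample_columns(filt_b, n_sub, config.sim.seed)),
    )
    comparison["branches"].to_csv(f"{out_dir}/phylo_branches.tsv", sep="\t", index=False)
    comparison["heights"].to_csv(f"{out_dir}/phylo_heights.tsv", sep="\t", index=False)

    recovery = planted_recovery(sim.truth, alr, ahr, sim.reference)
    recovery.to_csv(f"{out_dir}/planted_recovery.tsv", sep="\t", index=False)
    summary = {
        "config_digest": config.digest(),
        "n_alr_calls": len(alr),
        "n_ahr_calls": len(ahr),
        "planted_recovery_rate": recovery_rate(recovery),
        "mean_planted_jaccard": float(recovery["best_jaccard"].mean()),
        "n_shared_genes": len(shared),
        "n_alr_genes": len(class_sets["ALR"]),
        "n_ahr_genes": len(class_sets["AHR"]),
        "min_retention_percent": (
            float(retention.table["percent"].min()) if retention is not None else None
        ),
        "significant_pathways": skew.loc[skew["direction"].isin(["high", "low"]), "pathway"].tolist(),
        "phylo_median_branch_ratio": comparison["summary"]["median_ratio"],
    }
    with open(f"{out_dir}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(f"{out_dir}/run.log", "w") as fh:
        fh.write(f"# {header}\n" + "\n".join(log_lines) + "\n")
    return {
        "sim": sim,
        "maps": maps,
        "tracks": tracks,
        "alr": alr,
        "ahr": ahr,
        "genes": species_genes,
        "class_sets": class_sets,
        "retention": retention,
        "skew": skew,
        "phylo": comparison,
        "recovery": recovery,
        "summary": summary,
    }
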