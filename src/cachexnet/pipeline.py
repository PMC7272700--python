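"""End-to-end orchestration of the miRNA-mRNA integration pipeline.

Two entry points: :func:`simulate_bundle` writes a complete synthetic
input bundle (counts, sample sheet, promoter genome, motif library, gene
sets, target tables, micrographs, ground truth) and :func:`run_pipeline`
executes normalization -> differential expression (mRNA and miRNA) ->
stability clustering -> promoter motif enrichment (up- and down-regulated
promoters separately) -> gene-set enrichment -> target-network
integration -> optional histology, writing per-stage TSVs and a run
manifest with input hashes and record counts. All randomness flows from
the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cluster import (
    cluster_stability,
    cumulative_fc_distribution,
    fold_change_cv,
    kmeans_cluster,
    nearest_subgroup,
    sample_pca,
    subgroup_degs,
    zscore_rows,
)
from .de import call_degs, run_de
from .enrich import GeneSetCollection, hypergeom_enrich, read_gmt, updown_fractions, write_gmt
from .histology import binarize, box_count_dimension, group_compare, stained_area_fraction
from .motifs import (
    MotifModel,
    enrich_motifs,
    extract_promoters,
    match_background,
    read_jaspar,
    write_jaspar,
)
from .network import (
    anticorrelation_filter,
    build_network,
    coregulation_table,
    export_edges_tsv,
    export_graphml,
    export_sif,
    union_targets,
    write_target_map,
)
from .normalize import (
    CASE,
    CountMatrix,
    abundance_class,
    filter_expressed_mirnas,
    normalize,
    per_sample_fold_change,
    to_cpm,
    to_rpkm,
)
from .simulate import (
    SimulationConfig,
    child_rng,
    embed_promoters_in_genome,
    simulate_fractal_image,
    simulate_gene_sets,
    simulate_paired_counts,
    simulate_promoters,
    simulate_target_tables,
)

PLANTED_CONSENSUS = "GGGACTTTCC"  # kB-site-like 10-mer


def default_motif_library(config: SimulationConfig, n_decoys: int = 5) -> list[MotifModel]:
    """The planted motif plus random-consensus decoy motifs."""
    rng = child_rng(config.seed, "promoters")
    motifs = [MotifModel.from_consensus(PLANTED_CONSENSUS, "MPLANT", "planted")]
    for i in range(n_decoys):
        cons = "".join("ACGT"[j] for j in rng.integers(0, 4, size=10))
        motifs.append(
            MotifModel.from_consensus(cons, f"MDECOY{i + 1}", f"decoy {i + 1}")
        )
    return motifs


def simulate_bundle(
    config: SimulationConfig, outdir, subgroup_mode: bool = True
) -> dict:
    """Write every input the pipeline consumes, with planted truth.

    Returns a small dict of the paths written. Micrographs emulate the
    histology arm: case images carry a lower stained-area fraction than
    controls (reduced collagen), with per-image cell densities in a TSV.
    """
    out = io.ensure_dir(outdir)
    cm_mrna, cm_mirna, truth = simulate_paired_counts(config, subgroup_mode)
    io.write_counts(cm_mrna.counts.astype(int), out / "mrna_counts.tsv")
    io.write_counts(cm_mirna.counts.astype(int), out / "mirna_counts.tsv")
    io.write_sample_sheet(cm_mrna.groups, out / "samples.tsv")
    cm_mrna.feature_lengths.rename("length_bp").to_frame().to_csv(
        out / "gene_lengths.tsv", sep="\t"
    )

    motifs = default_motif_library(config)
    write_jaspar(motifs, out / "motifs.jaspar")
    fg = set(truth.genes_of("up"))
    promoters, planted = simulate_promoters(
        list(truth.de_status.index), fg, motifs[0], config
    )
    truth.planted_motif_genes = planted
    genome, tss_bed = embed_promoters_in_genome(promoters, config)
    io.write_fasta(genome, out / "genome.fasta")
    io.write_bed(tss_bed, out / "tss.bed")

    terms = simulate_gene_sets(truth, config)
    write_gmt(terms, out / "gene_sets.gmt")

    tm = simulate_target_tables(truth, config)
    write_target_map(tm, out / "targets")

    # micrographs: reduced stained area in the case group
    img_dir = io.ensure_dir(out / "images")
    rng = child_rng(config.seed, "images")
    density_rows = []
    for group, n, frac, dens in (
        ("control", config.n_control, 0.30, 2.0),
        ("case", config.n_case, 0.15, 1.2),
    ):
        for i in range(n):
            img, _ = simulate_fractal_image(
                "random_fiber", 256, area_fraction=frac, rng=rng
            )
            name = f"{group}_{i + 1}"
            _write_png(img.mask, img_dir / f"{name}.png")
            density_rows.append(
                {"image_id": name, "group": group,
                 "cell_density": round(dens + rng.normal(0, 0.05), 4)}
            )
    pd.DataFrame(density_rows).to_csv(
        out / "cell_density.tsv", sep="\t", index=False
    )

    truth_json = {
        "de_status": truth.de_status.to_dict(),
        "regulation_class": {
            k: v for k, v in truth.regulation_class.dropna().to_dict().items()
        },
        "mirna_de_status": truth.mirna_de_status.to_dict(),
        "target_pairs": sorted(map(list, truth.target_pairs)),
        "planted_motif_genes": sorted(truth.planted_motif_genes),
        "subgroup_samples": truth.subgroup_samples,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return {"outdir": str(out)}


def _write_png(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.astype(np.uint8) * 255))


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for a pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    fc_threshold: float = 1.5
    alpha: float = 0.05
    use_fdr: bool = True
    motif_alpha: float = 0.01
    mirna_floor: int = 32
    k: int = 4
    n_init: int = 100
    pseudocount: float = 1.0
    cpg_tolerance: float = 0.02
    run_histology: bool = True

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "alpha", "motif_alpha", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on an input bundle; returns the manifest."""
    ind = Path(config.input_dir)
    out = io.ensure_dir(config.output_dir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fc": config.fc_threshold, "alpha": config.alpha,
            "use_fdr": config.use_fdr, "motif_alpha": config.motif_alpha,
            "mirna_floor": config.mirna_floor, "k": config.k,
        },
        "inputs": {},
        "stages": {},
    }
    for f in sorted(ind.rglob("*")):
        if f.is_file():
            manifest["inputs"][str(f.relative_to(ind))] = _sha256(f)

    stage = "normalize"
    try:
        cm_mrna = io.read_count_matrix(
            ind / "mrna_counts.tsv", ind / "samples.tsv", ind / "gene_lengths.tsv"
        )
        cm_mirna = io.read_count_matrix(
            ind / "mirna_counts.tsv", ind / "samples.tsv"
        )
        nm = normalize(cm_mrna)
        fc = per_sample_fold_change(nm, pseudocount=config.pseudocount)
        io.write_counts(nm.normalized.round(4), out / "mrna_normalized.tsv")
        io.write_counts(fc.round(4), out / "mrna_fold_changes.tsv")
        io.write_counts(to_cpm(cm_mrna).round(4), out / "mrna_cpm.tsv")
        io.write_counts(to_rpkm(cm_mrna).round(4), out / "mrna_rpkm.tsv")
        kept = filter_expressed_mirnas(cm_mirna, config.mirna_floor)
        cm_mirna_f = cm_mirna.subset_features(kept)
        manifest["stages"][stage] = {
            "n_genes": cm_mrna.counts.shape[0],
            "n_mirnas_raw": cm_mirna.counts.shape[0],
            "n_mirnas_expressed": len(kept),
        }

        stage = "differential_expression"
        de_mrna = run_de(
            cm_mrna, fc_threshold=config.fc_threshold, alpha=config.alpha,
            use_fdr=config.use_fdr, pseudocount=config.pseudocount,
        )
        de_mirna = run_de(
            cm_mirna_f, fc_threshold=config.fc_threshold, alpha=config.alpha,
            use_fdr=config.use_fdr, pseudocount=config.pseudocount,
        )
        de_mrna["abundance_class"] = abundance_class(de_mrna["base_mean"])
        de_mirna["abundance_class"] = abundance_class(de_mirna["base_mean"])
        _write_de(de_mrna, out / "de_mrna.tsv")
        _write_de(de_mirna, out / "de_mirna.tsv")
        up, down = call_degs(de_mrna, config.fc_threshold, config.alpha, config.use_fdr)
        degs = sorted(up | down)
        mir_up, mir_down = call_degs(
            de_mirna, config.fc_threshold, config.alpha, config.use_fdr
        )
        manifest["stages"][stage] = {
            "degs_up": len(up), "degs_down": len(down),
            "de_mirnas_up": len(mir_up), "de_mirnas_down": len(mir_down),
        }

        stage = "cluster_variability"
        z = zscore_rows(nm.normalized.loc[degs])
        res = kmeans_cluster(
            z, k=config.k, n_init=config.n_init, seed=config.seed,
            order_by=de_mrna["log2fc"],
        )
        case_samples = cm_mrna.samples_of(CASE)
        stab = cluster_stability(res, fc, case_samples)
        res.labels.rename("cluster").to_frame().to_csv(
            out / "clusters.tsv", sep="\t"
        )
        stab.round(4).to_csv(out / "cluster_stability.tsv", sep="\t")
        ecdf = cumulative_fc_distribution(de_mrna["log2fc"].loc[degs], res.labels)
        pd.concat(
            [df.assign(cluster=c) for c, df in sorted(ecdf.items())]
        ).round(4).to_csv(out / "fc_ecdf.tsv", sep="\t", index=False)
        scores, varfrac = sample_pca(nm.normalized)
        scores.round(4).to_csv(out / "pca_scores.tsv", sep="\t")
        subgroup = nearest_subgroup(z, cm_mrna.groups)
        uniform_set, _ = subgroup_degs(
            cm_mrna, set(degs), subgroup,
            config.fc_threshold, config.alpha, config.use_fdr,
        )
        pd.Series(sorted(uniform_set), name="gene_id").to_csv(
            out / "uniform_degs.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "clusters": {int(c): int(n) for c, n in res.sizes.items()},
            "subgroup_samples": subgroup,
            "uniform_degs": len(uniform_set),
            "pc_variance": [round(float(v), 4) for v in varfrac],
        }

        stage = "motif_enrichment"
        genome = io.read_fasta(ind / "genome.fasta")
        tss = io.read_bed(ind / "tss.bed")
        promoters = extract_promoters(tss, genome)
        motif_lib = read_jaspar(ind / "motifs.jaspar")
        rng = np.random.default_rng(config.seed)
        motif_counts = {}
        for label, gene_set in (("up", up), ("down", down)):
            fg = promoters.subset(sorted(gene_set & set(promoters.genes)))
            pool = promoters.subset(
                sorted(set(promoters.genes) - set(fg.genes))
            )
            bg = match_background(fg, pool, config.cpg_tolerance, rng)
            table = enrich_motifs(fg, bg, motif_lib)
            table.round(6).to_csv(
                out / f"motif_enrichment_{label}.tsv", sep="\t", index=False
            )
            motif_counts[label] = int((table["p_value"] < config.motif_alpha).sum())
        manifest["stages"][stage] = {"significant_motifs": motif_counts}

        stage = "functional_enrichment"
        collection = GeneSetCollection(
            read_gmt(ind / "gene_sets.gmt"), set(cm_mrna.features)
        )
        enr = hypergeom_enrich(degs, collection)
        enr = updown_fractions(enr, collection.harmonized(), up, down)
        enr.round(6).to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "terms_tested": len(enr),
            "terms_significant": int((enr["q_value"] <= config.alpha).sum()),
        }

        stage = "mirna_integration"
        from .simulate import TargetMap

        sources = {}
        validated = set()
        for f in sorted((ind / "targets").glob("targets_*.tsv")):
            src = f.stem.replace("targets_", "")
            df = pd.read_csv(f, sep="\t", dtype=str)
            sources[src] = set(zip(df["mirna_id"], df["gene_id"]))
            if src == "validated":
                validated.add(src)
        tm = TargetMap(sources, validated)
        de_mirs = mir_up | mir_down
        _, provenance = union_targets(tm, de_mirs)
        retained = anticorrelation_filter(provenance, de_mrna, de_mirna)
        net = build_network(
            retained, tm.validated, de_mirna["direction"], de_mrna["direction"]
        )
        export_edges_tsv(net, out / "network_edges.tsv")
        export_graphml(net, out / "network.graphml")
        export_sif(net, out / "network.sif")
        coregulation_table(net).to_csv(
            out / "coregulation.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "candidate_pairs": len(provenance),
            "interactions": net.n_interactions,
            "mirnas": len(net.mirnas),
            "genes": len(net.genes),
        }

        if config.run_histology and (ind / "images").is_dir():
            stage = "histology"
            import imageio.v3 as iio

            dens = pd.read_csv(ind / "cell_density.tsv", sep="\t").set_index(
                "image_id"
            )
            rows = []
            for f in sorted((ind / "images").glob("*.png")):
                img = iio.imread(str(f))
                bin_img = binarize(img, threshold_method=127, source_id=f.stem)
                est = box_count_dimension(bin_img)
                rows.append(
                    {"image_id": f.stem,
                     "group": dens.loc[f.stem, "group"],
                     "area_fraction": round(bin_img.foreground_fraction, 6),
                     "pra_cd": round(
                         stained_area_fraction(
                             bin_img, dens.loc[f.stem, "cell_density"]
                         ), 6),
                     "fractal_dimension": round(est.dimension, 4),
                     "r_squared": round(est.r_squared, 4)}
                )
            hist = pd.DataFrame(rows)
            hist.to_csv(out / "histology.tsv", sep="\t", index=False)
            ctrl = hist[hist["group"] == "control"]
            case = hist[hist["group"] == "case"]
            t_pra, p_pra = group_compare(ctrl["pra_cd"], case["pra_cd"])
            t_fd, p_fd = group_compare(
                ctrl["fractal_dimension"], case["fractal_dimension"]
            )
            manifest["stages"][stage] = {
                "n_images": len(hist),
                "pra_cd_t": round(t_pra, 4), "pra_cd_p": round(p_pra, 6),
                "fractal_t": round(t_fd, 4), "fractal_p": round(p_fd, 6),
            }
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _write_de(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "feature_id"
    for col in ("base_mean", "log2fc", "se", "stat"):
        out[col] = out[col].round(4)
    out.to_csv(path, sep="\t")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
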