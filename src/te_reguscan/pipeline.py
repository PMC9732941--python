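"""End-to-end pipeline driver: simulate -> annotate -> enrich -> tfbs ->
phylo -> associate -> responsiveness -> reporter.

A single YAML config names the output directory, the global seed, the
analysis constants (alpha 0.05, min fold 1.5, 10,000 shuffle replicates,
TPM >= 2, merge gap 100 bp — all surfaced as named defaults, never
hard-coded in stage logic), and optional overrides for the synthetic
generator. Every artifact is written under the output directory and
recorded in ``manifest.json`` with its SHA-256; reruns with the same
config and seed are byte-identical.

With the ``simulate`` stage enabled (the default), all inputs are
generated with planted ground truth; otherwise file paths for peaks, TE
annotation, tree, TPM matrix, links, DE table, and plates must be given
under ``inputs:``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from te_reguscan import annotation, association, enrichment, io, phylo, reporter, sim

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "annotate", "enrich", "tfbs",
    "phylo", "associate", "responsiveness", "reporter",
]


@dataclass
class RunConfig:
    outdir: str = "te_reguscan_run"
    seed: int = 1
    stages: list = field(default_factory=lambda: list(STAGES))
    alpha: float = 0.05
    min_fold: float = 1.5
    n_reps: int = 10_000
    tpm_threshold: float = 2.0
    merge_gap: int = 100
    mds_dims: int = 4
    kmeans_k: int = 4
    n_tf_factors: int = 4
    focal_tip: str = "Human"
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    inputs: dict = field(default_factory=dict)     # file paths when not simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "simulate" not in self.stages:
            need = {
                "annotate": ["peaks", "tes", "chrom_sizes"],
                "enrich": ["peaks", "tes", "chrom_sizes"],
                "phylo": ["tree", "tpm"],
                "associate": ["links", "promoters"],
                "responsiveness": ["de_table"],
                "reporter": ["plates"],
            }
            for stage, keys in need.items():
                if stage in self.stages:
                    missing = [k for k in keys if k not in self.inputs]
                    if missing:
                        raise ValueError(
                            f"stage {stage!r} enabled without simulate: "
                            f"missing inputs {missing}"
                        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_sim_config(cfg: RunConfig) -> sim.SimConfig:
    over = dict(cfg.simulate)
    kwargs = {"seed": cfg.seed}
    for key in ("genome_chrom_sizes", "tree_newick", "max_fragment_gap"):
        if key in over:
            kwargs[key] = over.pop(key)
    sub = {
        "peak_spec": sim.PeakSpec, "expression_spec": sim.ExpressionSpec,
        "link_spec": sim.LinkSpec, "de_spec": sim.DESpec,
        "reporter_spec": sim.ReporterSpec,
    }
    for key, klass in sub.items():
        if key in over:
            kwargs[key] = klass(**over.pop(key))
    if "te_family_specs" in over:
        kwargs["te_family_specs"] = [
            sim.TEFamilySpec(**d) for d in over.pop("te_family_specs")
        ]
    if over:
        raise ValueError(f"unknown simulate keys: {sorted(over)}")
    return sim.SimConfig(**kwargs)


def run_all(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    state: dict = {}

    def emit(name: str, writer, obj) -> None:
        path = out / name
        writer(obj, path)
        outputs[name] = path

    ran = []
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, state, emit)
        except Exception:
            logger.error("stage %s failed", stage)
            for name, path in outputs.items():
                path.rename(path.with_suffix(path.suffix + ".partial"))
            raise
        ran.append(stage)

    manifest = {
        "version": 1,
        "seed": cfg.seed,
        "stages": ran,
        "parameters": {
            "alpha": cfg.alpha, "min_fold": cfg.min_fold, "n_reps": cfg.n_reps,
            "tpm_threshold": cfg.tpm_threshold, "merge_gap": cfg.merge_gap,
            "mds_dims": cfg.mds_dims, "kmeans_k": cfg.kmeans_k,
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, state, emit):
    sc = _build_sim_config(cfg)
    state["sim_config"] = sc
    state["genome"] = sc.genome_chrom_sizes
    tes = sim.gen_te_annotation(sc)
    peaks = sim.gen_peaks(sc, tes, assay="reg")
    tfbs = {
        f"TF{i + 1}": sim.gen_peaks(sc, tes, assay=f"TF{i + 1}", stream=i + 1)
        for i in range(cfg.n_tf_factors)
    }
    tpm, event_log, _ = sim.gen_expression_phylo(sc)
    genes = list(tpm.index[: max(50, len(tpm) // 4)])
    promoters = sim.gen_promoters(sc, genes)
    ov = annotation.overlap_peaks_tes(peaks, tes, genome=sc.genome_chrom_sizes)
    te_mask = np.zeros(len(peaks), dtype=bool)
    if len(ov.pairs):
        te_mask[ov.pairs["peak_index"].unique()] = True
    links, link_truth = sim.gen_reg_links(sc, peaks, promoters, te_mask)
    te_genes = list(link_truth[link_truth].index)
    other_genes = list(link_truth[~link_truth].index)
    de = sim.gen_de_table(sc, te_genes, other_genes)
    plates, plate_truth = sim.gen_reporter_plates(sc)

    state.update(
        tes=tes, peaks=peaks, tfbs=tfbs, tpm=tpm, tree_newick=sc.tree_newick,
        promoters=promoters, links=links, de=de, plates=plates,
        link_truth=link_truth, event_log=event_log, plate_truth=plate_truth,
    )
    emit("chrom_sizes.tsv", lambda o, p: io.write_chrom_sizes(o, p), sc.genome_chrom_sizes)
    emit("tes.bed", lambda o, p: io.write_te_bed(o, p), tes)
    emit("peaks.bed", lambda o, p: io.write_bed(o, p), peaks)
    for name, fp in tfbs.items():
        emit(f"tfbs_{name}.bed", lambda o, p: io.write_bed(o, p), fp)
    emit("tree.nwk", lambda o, p: Path(p).write_text(o), sc.tree_newick)
    emit("tpm.tsv", lambda o, p: io.write_expression_matrix(o, p), tpm)
    emit("links.bedpe", lambda o, p: io.write_bedpe(o, p), links)
    emit("de_table.tsv", lambda o, p: io.write_de_table(o, p), de)
    emit("plates.csv", lambda o, p: io.write_plates(o, p), plates)
    emit("truth_events.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), event_log)
    emit("truth_links.tsv",
         lambda o, p: o.rename("te_linked").to_csv(p, sep="\t", index_label="gene"),
         link_truth)
    emit("truth_plates.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), plate_truth)


def _load_inputs(cfg, state):
    inp = cfg.inputs
    if "genome" not in state and "chrom_sizes" in inp:
        state["genome"] = io.read_chrom_sizes(inp["chrom_sizes"])
    if "tes" not in state and "tes" in inp:
        state["tes"] = io.read_te_bed(inp["tes"])
    if "peaks" not in state and "peaks" in inp:
        state["peaks"] = io.read_bed(inp["peaks"])


def _stage_annotate(cfg, state, emit):
    _load_inputs(cfg, state)
    tes = annotation.merge_fragmented_copies(state["tes"], max_gap=cfg.merge_gap)
    state["tes_merged"] = tes
    ov = annotation.overlap_peaks_tes(state["peaks"], tes, genome=state["genome"])
    state["overlap"] = ov
    gfrac = annotation.genome_age_fractions(tes, state["genome"])
    summary = annotation.summarize_te_content(ov, gfrac)
    state["content_summary"] = summary
    pct = summary.percent_te_containing
    tbl = pd.DataFrame(
        {
            "age_class": summary.age_distribution_peaks.index,
            "fraction_in_peaks": summary.age_distribution_peaks.values,
            "fraction_in_genome": summary.age_distribution_genome.values,
        }
    )
    tbl.insert(0, "percent_peaks_with_te", "" if pct is None else pct)
    emit("te_content.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), tbl)
    emit("overlap_pairs.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), ov.pairs)


def _stage_enrich(cfg, state, emit):
    res = enrichment.family_enrichment(
        state["peaks"], state.get("tes_merged", state["tes"]), state["genome"],
        n_reps=cfg.n_reps, seed=cfg.seed, min_fold=cfg.min_fold, alpha=cfg.alpha,
    )
    frame = enrichment.family_enrichment_frame(res)
    state["family_enrichment"] = frame
    emit("family_enrichment.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), frame)


def _stage_tfbs(cfg, state, emit):
    if "tfbs" not in state:
        state["tfbs"] = {
            name: io.read_bed(path)
            for name, path in cfg.inputs.get("tfbs", {}).items()
        }
    if not state["tfbs"]:
        logger.info("no TFBS peak sets; skipping tfbs stage body")
        return
    segs, non_te = annotation.peak_te_partition(
        state["peaks"], state.get("tes_merged", state["tes"])
    )
    res = enrichment.tfbs_enrichment(
        segs, non_te, state["tfbs"], state["genome"],
        n_reps=cfg.n_reps, seed=cfg.seed,
    )
    frame = enrichment.tfbs_enrichment_frame(res)
    state["tfbs_enrichment"] = frame
    emit("tfbs_enrichment.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), frame)


def _stage_phylo(cfg, state, emit):
    if "tpm" not in state:
        state["tpm"] = io.read_expression_matrix(cfg.inputs["tpm"])
        state["tree_newick"] = Path(cfg.inputs["tree"]).read_text()
    tree = phylo.parse_tree(state["tree_newick"], min_tips=3)
    binmat = phylo.binarize_expression(state["tpm"], threshold=cfg.tpm_threshold)
    recon = phylo.reconstruct_matrix(tree, binmat)
    focal = cfg.focal_tip if cfg.focal_tip in tree.tip_labels else tree.tip_labels[0]
    gl = phylo.call_gain_loss(recon, focal_tip=focal)
    state["gain_loss"] = gl
    state["recruitment"] = gl.recruitment
    emit("branch_events.tsv",
         lambda o, p: o.to_csv(p, sep="\t", index=False), gl.branch_counts)
    emit("gene_events.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), gl.events)
    emit("recruitment.tsv",
         lambda o, p: o.to_csv(p, sep="\t", index_label="gene", header=True),
         gl.recruitment)


def _stage_associate(cfg, state, emit):
    if "links" not in state:
        state["links"] = io.read_bedpe(cfg.inputs["links"])
        state["promoters"] = pd.read_csv(cfg.inputs["promoters"], sep="\t")
    ov = state.get("overlap")
    elements = association.flag_elements(
        state["peaks"], ov.pairs if ov is not None else pd.DataFrame()
    )
    assoc = association.associate_genes(state["links"], elements, state["promoters"])
    state["gene_assoc"] = assoc
    emit("gene_elements.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), assoc)


def _stage_responsiveness(cfg, state, emit):
    if "de" not in state:
        state["de"] = io.read_de_table(cfg.inputs["de_table"])
    de = state["de"]
    assoc = state.get("gene_assoc")
    flagged = set(assoc.loc[assoc["te_derived"], "gene"]) if assoc is not None else set()
    genes = de["gene"]
    flags = pd.Series([g in flagged for g in genes], index=genes)
    recruitment = state.get("recruitment")
    if recruitment is not None:
        strata = pd.Series(
            [recruitment.get(g, None) or "unassigned" for g in genes], index=genes
        )
    else:
        strata = pd.Series(["all"] * len(genes), index=genes)
    # genes absent from the phylo matrix fall into one pooled stratum
    table = association.stratified_responsiveness(de, flags, strata)
    state["responsiveness"] = table
    emit("responsiveness.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), table)


def _stage_reporter(cfg, state, emit):
    if "plates" not in state:
        state["plates"] = io.read_plates(cfg.inputs["plates"])
    norm = reporter.normalize_plates(state["plates"])
    calls = reporter.classify_constructs(norm, alpha=cfg.alpha)
    state["reporter_calls"] = calls
    emit("reporter_calls.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), calls)

    summaries = []
    for (ct, tr), sub in calls.groupby(["cell_type", "treatment"]):
        ex = reporter.repressor_excess_test(sub)
        summaries.append((ct, tr, ex.k, ex.n, round(ex.fraction, 3), ex.p))
    excess = pd.DataFrame(
        summaries,
        columns=["cell_type", "treatment", "n_repressors", "n_constructs",
                 "fraction", "p_binomial"],
    )
    state["repressor_excess"] = excess
    emit("repressor_excess.tsv", lambda o, p: o.to_csv(p, sep="\t", index=False), excess)

    tsa_rows = []
    for ct in calls["cell_type"].unique():
        unt = calls[(calls["cell_type"] == ct) & (calls["treatment"] == "none")]
        tsa = calls[(calls["cell_type"] == ct) & (calls["treatment"] == "TSA")]
        if len(unt) == 0 or len(tsa) == 0:
            continue
        d = reporter.tsa_derepression(unt, tsa)
        tsa_rows.append((ct, len(d.derepressed), d.n_untreated_repressors,
                         "" if d.percent is None else d.percent))
    tsa_tbl = pd.DataFrame(
        tsa_rows, columns=["cell_type", "n_derepressed", "n_repressors", "percent"]
    )
    state["tsa"] = tsa_tbl
    emit("tsa_derepression.tsv",
         lambda o, p: o.to_csv(p, sep="\t", index=False), tsa_tbl)

    mat = reporter.activity_matrix(calls[calls["call"] != "control"])
    if len(mat) >= cfg.mds_dims + 1:
        mk = reporter.mds_kmeans(mat, dims=cfg.mds_dims, k=cfg.kmeans_k, seed=cfg.seed)
        state["mds"] = mk
        coords = mk.coordinates.copy()
        coords["cluster"] = mk.labels
        emit("mds_clusters.tsv",
             lambda o, p: o.to_csv(p, sep="\t", index_label="construct"), coords)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
    "tfbs": _stage_tfbs,
    "phylo": _stage_phylo,
    "associate": _stage_associate,
    "responsiveness": _stage_responsiveness,
    "reporter": _stage_reporter,
}
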