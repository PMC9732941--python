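"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of the study system —
TE families with controlled genomic density and planted peak enrichment,
fragmented TE copies, binary expression characters evolving on a species
tree, pcHiC-style promoter-element links, differential-expression tables
with planted variance ratios, and dual-luciferase plates with planted
enhancer/repressor effects and transfection noise — without simulating
any nucleotide sequence (the downstream statistics operate purely on
intervals and tables).

Every generator is a pure function of ``(config, seed)``: the global
integer seed is split into fixed per-generator substreams, so rerunning
with the same config gives byte-identical output files, and ground-truth
logs record every planted signal so downstream calls can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from te_reguscan.io import LINK_COLUMNS, PLATE_COLUMNS
from te_reguscan.phylo import parse_tree
from te_reguscan.enrichment import bh_adjust
from te_reguscan.reporter import EMPTY_VECTOR, POSITIVE_CONTROL

logger = logging.getLogger(__name__)

#: ordered clade labels, oldest first, mirroring lineage-specificity bins
DEFAULT_AGE_CLASSES = (
    "Amniota", "Mammalia", "Theria", "Eutheria", "Primates", "Catarrhini",
)

# fixed substream ids so generators are independent and order-insensitive
_STREAMS = {"te": 1, "peaks": 2, "phylo": 3, "links": 4, "de": 5, "reporter": 6}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


@dataclass
class TEFamilySpec:
    family_name: str
    te_class: str                     # LTR, LINE, SINE, DNA
    age_class: str
    copy_count: int
    mean_length: int                  # bp
    fragmentation_rate: float = 0.0   # probability a copy is emitted split


@dataclass
class PeakSpec:
    n_peaks: int = 1000
    mean_length: int = 300
    # family -> multiplier on the family's genomic fraction (1 = uniform)
    per_family_enrichment_multiplier: dict = field(default_factory=dict)


@dataclass
class ExpressionSpec:
    n_genes: int = 2000
    # events per unit branch length; at the default tree's total length this
    # keeps planted events quasi-independent (<10% share a gene), the regime
    # in which parsimony polarization is identifiable
    gain_rate: float = 0.005
    loss_rate: float = 0.005
    # natural-log scale; chosen so the TPM>=2 threshold misclassifies a tip
    # with probability ~1e-4 (silent and expressed populations separable)
    expressed_TPM_logmean: float = float(np.log(100.0))
    silent_TPM_logmean: float = float(np.log(0.1))
    TPM_logsd: float = 0.8
    root_expressed_prob: float = 0.5


@dataclass
class LinkSpec:
    te_linked_fraction: float = 0.5   # genes given >=1 link to a TE-overlapping peak
    links_per_gene: int = 1


@dataclass
class DESpec:
    variance_ratio_planted: float = 4.0
    n_genes_per_set: int = 200
    base_sd: float = 1.0              # log2FC SD of the reference set


@dataclass
class ReporterSpec:
    n_constructs: int = 89
    frac_repressor: float = 0.6
    frac_enhancer: float = 0.15
    repressor_effect: float = 0.3     # multiplicative on firefly
    enhancer_effect: float = 3.0
    positive_control_effect: float = 5.0
    n_replicates: int = 5             # study used 4-6 independent replicates
    tsa_derepression_prob: float = 0.86
    noise_sd: float = 0.1             # lognormal sigma of measurement noise
    transfection_sd: float = 0.3      # lognormal sigma of renilla
    renilla_mean: float = 1000.0
    baseline_ratio: float = 1.0
    cell_types: tuple = ("ESF", "DSC")
    treatments: tuple = ("none", "TSA")


#: a 10-taxon amniote-like default tree with the focal taxon "Human".
#: The two root-adjacent branches are deliberately short: single changes on
#: them are unpolarizable by parsimony (see te_reguscan.phylo), so keeping
#: their share of total length small makes the planted events recoverable.
DEFAULT_TREE = (
    "((((((((Human:1,Macaque:1):1,Marmoset:1):1,Mouse:1):1,Dog:1):1,"
    "Cow:1):1,Opossum:1):1,Platypus:1):0.2,(Chicken:1,Lizard:1):0.2);"
)


def _default_families() -> list:
    classes = ("LTR", "LINE", "SINE", "DNA")
    fams = []
    for i in range(10):
        fams.append(
            TEFamilySpec(
                family_name=f"FAM{i + 1}",
                te_class=classes[i % 4],
                age_class=DEFAULT_AGE_CLASSES[i % len(DEFAULT_AGE_CLASSES)],
                copy_count=60,
                mean_length=250,
                fragmentation_rate=0.1,
            )
        )
    return fams


@dataclass
class SimConfig:
    """Full parameterization of the synthetic study system."""

    genome_chrom_sizes: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    te_family_specs: list = field(default_factory=_default_families)
    peak_spec: PeakSpec = field(default_factory=PeakSpec)
    tree_newick: str = DEFAULT_TREE
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    link_spec: LinkSpec = field(default_factory=LinkSpec)
    de_spec: DESpec = field(default_factory=DESpec)
    reporter_spec: ReporterSpec = field(default_factory=ReporterSpec)
    age_classes: tuple = DEFAULT_AGE_CLASSES
    max_fragment_gap: int = 80        # bp between emitted fragments of one copy
    seed: int = 0

    def __post_init__(self):
        for chrom, length in self.genome_chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for fs in self.te_family_specs:
            if fs.copy_count <= 0 or fs.mean_length <= 0:
                raise ValueError(f"family {fs.family_name}: counts/lengths must be > 0")
            if not 0 <= fs.fragmentation_rate <= 1:
                raise ValueError(f"family {fs.family_name}: fragmentation_rate not in [0,1]")
            if fs.age_class not in self.age_classes:
                raise ValueError(
                    f"family {fs.family_name}: age_class {fs.age_class!r} not in "
                    f"configured clade list"
                )
        ps = self.peak_spec
        if ps.n_peaks < 0 or ps.mean_length <= 0:
            raise ValueError("peak_spec: n_peaks >= 0 and mean_length > 0 required")
        for m in ps.per_family_enrichment_multiplier.values():
            if m < 0:
                raise ValueError("enrichment multipliers must be >= 0")
        if not 0 <= self.link_spec.te_linked_fraction <= 1:
            raise ValueError("te_linked_fraction must be in [0,1]")
        if self.de_spec.variance_ratio_planted < 0:
            raise ValueError("variance_ratio_planted must be >= 0")
        rs = self.reporter_spec
        if rs.frac_repressor + rs.frac_enhancer > 1:
            raise ValueError("frac_repressor + frac_enhancer must be <= 1")
        if rs.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (Wilcoxon undefined below)")
        if not 0 <= rs.tsa_derepression_prob <= 1:
            raise ValueError("tsa_derepression_prob must be in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# TE annotation


def gen_te_annotation(config: SimConfig) -> pd.DataFrame:
    """Place TE copies uniformly; fragmented copies are emitted split.

    Copies may overlap each other (real genomes nest TEs). A fragmented
    copy becomes two records sharing ``copy_id``, separated by a gap of at
    most ``config.max_fragment_gap`` bp. Requesting more than 90% of the
    genome in TE bp is a capacity error.
    """
    rng = _rng(config, "te")
    genome_bp = sum(config.genome_chrom_sizes.values())
    requested = sum(fs.copy_count * fs.mean_length for fs in config.te_family_specs)
    if requested > 0.9 * genome_bp:
        raise ValueError(
            f"requested TE bp ({requested}) exceeds 90% of the genome ({genome_bp} bp)"
        )
    chroms = list(config.genome_chrom_sizes)
    chrom_len = np.array([config.genome_chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()
    min_chrom = int(chrom_len.min())

    rows = []
    for fs in config.te_family_specs:
        if fs.mean_length >= min_chrom:
            raise ValueError(
                f"family {fs.family_name}: mean_length >= shortest chromosome"
            )
        lengths = np.maximum(
            10, np.round(rng.lognormal(np.log(fs.mean_length), 0.2, fs.copy_count))
        ).astype(int)
        cidx = rng.choice(len(chroms), size=fs.copy_count, p=chrom_p)
        frag = rng.random(fs.copy_count) < fs.fragmentation_rate
        for i in range(fs.copy_count):
            chrom = chroms[cidx[i]]
            L = min(int(lengths[i]), config.genome_chrom_sizes[chrom] - 1)
            copy_id = f"{fs.family_name}_{i}"
            if frag[i] and L >= 20:
                gap = int(rng.integers(1, config.max_fragment_gap + 1))
                span = L + gap
                span = min(span, config.genome_chrom_sizes[chrom] - 1)
                start = int(rng.integers(0, config.genome_chrom_sizes[chrom] - span + 1))
                cut = int(rng.integers(L // 4, 3 * L // 4))
                rows.append((chrom, start, start + cut, fs.family_name, fs.te_class,
                             fs.age_class, copy_id, 0, "."))
                s2 = start + cut + (span - L)
                rows.append((chrom, s2, start + span, fs.family_name, fs.te_class,
                             fs.age_class, copy_id, 1, "."))
            else:
                start = int(rng.integers(0, config.genome_chrom_sizes[chrom] - L + 1))
                rows.append((chrom, start, start + L, fs.family_name, fs.te_class,
                             fs.age_class, copy_id, 0, "."))
    tes = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "family", "te_class", "age_class",
                 "copy_id", "fragment_index", "strand"],
    )
    return tes.sort_values(["chrom", "start", "copy_id", "fragment_index"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# peaks


def gen_peaks(
    config: SimConfig, tes: pd.DataFrame, assay: str = "sim", stream: int = 0
) -> pd.DataFrame:
    """Place peaks with planted per-family enrichment.

    With multiplier ``m`` for a family occupying genomic fraction ``q``,
    the expected fraction of peaks overlapping that family is
    ``min(1, m*q)``: a fraction ``t = q*(m-1)/(1-q)`` of peaks is targeted
    to overlap a random copy of the family, the rest are uniform (which
    contributes ``q`` by itself). All multipliers 1 gives pure uniform
    placement. Multipliers implying an expected fraction > 1 are capped
    with a logged warning. ``stream`` separates independent peak sets
    (e.g. one per simulated assay or factor) under one global seed.
    """
    rng = np.random.default_rng([config.seed, _STREAMS["peaks"], stream])
    ps = config.peak_spec
    mult = ps.per_family_enrichment_multiplier
    missing = set(mult) - set(tes["family"])
    if missing:
        raise ValueError(f"multipliers reference unknown families: {sorted(missing)}")

    chroms = list(config.genome_chrom_sizes)
    chrom_len = np.array([config.genome_chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()
    genome_bp = chrom_len.sum()

    # baseline probability that a uniformly placed peak of the configured
    # mean length overlaps the family: (merged bp + n_intervals*(L-1)) / G.
    # This reduces to the family's genomic fraction for short peaks and is
    # the quantity a shuffle null estimates, so a planted multiplier m is
    # recovered as an m-fold enrichment downstream.
    L = ps.mean_length
    fam_frac = {}
    for fam, sub in tes.groupby("family"):
        bp, n_iv = 0, 0
        for _, csub in sub.groupby("chrom"):
            iv = csub[["start", "end"]].sort_values("start").to_numpy()
            last = -1
            for s, e in iv:
                if s > last:
                    n_iv += 1
                s = max(s, last)
                bp += max(0, e - s)
                last = max(last, e)
        fam_frac[fam] = min(1.0, (bp + n_iv * (L - 1)) / genome_bp)

    targeted_frac = {}
    for fam, m in mult.items():
        q = fam_frac[fam]
        if m * q > 1:
            logger.warning(
                "family %s: multiplier %g implies expected fraction %.2f > 1; capped",
                fam, m, m * q,
            )
            m = 1 / q
        t = q * (m - 1) / (1 - q) if q < 1 else 0.0
        if t > 0:
            targeted_frac[fam] = t
    total_t = sum(targeted_frac.values())
    if total_t > 1:
        logger.warning("targeted fractions sum to %.2f > 1; renormalized", total_t)
        targeted_frac = {f: t / total_t for f, t in targeted_frac.items()}
        total_t = 1.0

    fams = list(targeted_frac)
    probs = [targeted_frac[f] for f in fams] + [1 - total_t]
    fam_rows = {f: tes[tes["family"] == f].reset_index(drop=True) for f in fams}

    rows = []
    lengths = np.maximum(
        20, np.round(rng.lognormal(np.log(ps.mean_length), 0.25, ps.n_peaks))
    ).astype(int)
    choice = rng.choice(len(fams) + 1, size=ps.n_peaks, p=probs)
    for i in range(ps.n_peaks):
        L = int(lengths[i])
        if choice[i] < len(fams):
            fam = fams[choice[i]]
            copies = fam_rows[fam]
            r = copies.iloc[int(rng.integers(0, len(copies)))]
            chrom = r["chrom"]
            clen = config.genome_chrom_sizes[chrom]
            L = min(L, clen - 1)
            lo = max(0, int(r["start"]) - L + 1)
            hi = min(clen - L, int(r["end"]) - 1)
            start = int(rng.integers(lo, max(lo, hi) + 1))
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            clen = config.genome_chrom_sizes[chrom]
            L = min(L, clen - 1)
            start = int(rng.integers(0, clen - L + 1))
        rows.append((chrom, start, start + L, f"{assay}_peak_{i}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# expression evolution on the tree


def gen_expression_phylo(config: SimConfig):
    """Evolve binary expression on the tree and draw tip TPMs.

    Per gene, a root state (Bernoulli ``root_expressed_prob``) evolves
    along each branch by a two-state Markov jump process: when silent,
    gains arrive at ``gain_rate`` per unit branch length; when expressed,
    losses at ``loss_rate``. Tip TPMs are lognormal around the expressed
    or silent log-mean. Returns ``(tpm, event_log, tip_states)`` where
    ``event_log`` rows are (gene, branch child label, direction) for every
    planted event.
    """
    rng = _rng(config, "phylo")
    es = config.expression_spec
    tree = parse_tree(config.tree_newick, min_tips=3)

    genes = [f"g{i:05d}" for i in range(es.n_genes)]
    preorder = tree.postorder[::-1]
    tip_states = np.zeros((es.n_genes, len(tree.tip_indices)), dtype=np.int8)
    tip_pos = {v: j for j, v in enumerate(tree.tip_indices)}
    events = []

    root_state = (rng.random(es.n_genes) < es.root_expressed_prob).astype(np.int8)
    state = np.zeros((tree.n_nodes, es.n_genes), dtype=np.int8)
    state[tree.root] = root_state
    for v in preorder:
        u = tree.parent[v]
        if u == -1:
            continue
        blen = tree.edge_lengths[v]
        s = state[u].copy()
        for g in range(es.n_genes):
            t, cur = 0.0, int(s[g])
            while True:
                rate = es.gain_rate if cur == 0 else es.loss_rate
                if rate <= 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= blen:
                    break
                cur = 1 - cur
                events.append(
                    (genes[g], tree.labels[v], "gain" if cur == 1 else "loss")
                )
            s[g] = cur
        state[v] = s
        if v in tip_pos:
            tip_states[:, tip_pos[v]] = s

    logmeans = np.where(
        tip_states == 1, es.expressed_TPM_logmean, es.silent_TPM_logmean
    )
    tpm = np.exp(rng.normal(logmeans, es.TPM_logsd))
    tpm_df = pd.DataFrame(tpm, index=genes,
                          columns=[tree.labels[v] for v in tree.tip_indices])
    event_log = pd.DataFrame(events, columns=["gene", "branch", "direction"])
    states_df = pd.DataFrame(tip_states, index=genes, columns=tpm_df.columns)
    return tpm_df, event_log, states_df


# ---------------------------------------------------------------------------
# pcHiC links


def gen_promoters(config: SimConfig, genes: list, width: int = 2000) -> pd.DataFrame:
    """Deterministic promoter intervals evenly spaced along the genome."""
    chroms = list(config.genome_chrom_sizes)
    rows = []
    n = len(genes)
    per_chrom = int(np.ceil(n / len(chroms)))
    gi = 0
    for chrom in chroms:
        clen = config.genome_chrom_sizes[chrom]
        step = max(width + 1, clen // (per_chrom + 1))
        for j in range(per_chrom):
            if gi >= n:
                break
            start = min(clen - width - 1, (j + 1) * step)
            rows.append((genes[gi], chrom, start, start + width))
            gi += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def gen_reg_links(
    config: SimConfig,
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    te_peak_mask: np.ndarray,
):
    """Link promoters to distal peaks, planting TE-linked genes.

    A fraction ``link_spec.te_linked_fraction`` of genes receives links to
    TE-overlapping peaks (``te_peak_mask`` marks them); the rest link to
    TE-free peaks when available. Returns ``(links, truth)`` with truth
    mapping gene -> planted te_linked flag.
    """
    rng = _rng(config, "links")
    ls = config.link_spec
    te_idx = np.nonzero(te_peak_mask)[0]
    free_idx = np.nonzero(~np.asarray(te_peak_mask))[0]
    rows, truth = [], {}
    for _, g in promoters.iterrows():
        want_te = rng.random() < ls.te_linked_fraction
        pool = te_idx if want_te and len(te_idx) else free_idx
        if len(pool) == 0:
            pool = np.arange(len(peaks))
            want_te = bool(te_peak_mask[pool[0]]) if len(pool) else False
        truth[g["gene"]] = bool(want_te and len(te_idx))
        for _ in range(ls.links_per_gene):
            p = peaks.iloc[int(rng.choice(pool))]
            rows.append((g["chrom"], g["start"], g["end"],
                         p["chrom"], p["start"], p["end"], g["gene"]))
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return links, pd.Series(truth, name="te_linked")


# ---------------------------------------------------------------------------
# DE table


def gen_de_table(config: SimConfig, te_linked, other):
    """Planted variance-ratio DE table for two disjoint gene sets.

    log2FC for TE-linked genes ~ Normal(0, sd^2 * r) and for the others
    ~ Normal(0, sd^2), r = ``de_spec.variance_ratio_planted``. The p-value
    column is the two-sided normal tail of log2FC under the reference SD
    (a plausible stand-in for a DE fit; downstream tests use log2FC only).
    """
    from scipy import stats as _st

    te_linked, other = list(te_linked), list(other)
    if set(te_linked) & set(other):
        raise ValueError("gene sets must be disjoint")
    if len(te_linked) == 0 or len(other) == 0:
        raise ValueError("both gene sets must be nonempty")
    ds = config.de_spec
    rng = _rng(config, "de")
    sd = ds.base_sd
    fc_te = rng.normal(0, sd * np.sqrt(ds.variance_ratio_planted), len(te_linked))
    fc_ot = rng.normal(0, sd, len(other))
    genes = te_linked + other
    fc = np.concatenate([fc_te, fc_ot])
    p = 2 * _st.norm.sf(np.abs(fc) / sd)
    de = pd.DataFrame({"gene": genes, "log2FC": fc, "pvalue": p,
                       "padj": bh_adjust(p)})
    return de


# ---------------------------------------------------------------------------
# reporter plates


def gen_reporter_plates(config: SimConfig):
    """Simulate dual-luciferase plates with planted construct effects.

    Per well: renilla ~ lognormal transfection noise; firefly =
    renilla x baseline x construct effect x condition effect x lognormal
    measurement noise. The empty vector (effect 1) and a positive-control
    enhancer are always included. Under TSA, each repressor is fully
    de-repressed (effect -> 1) with probability
    ``tsa_derepression_prob``, decided once per construct and recorded in
    the ground truth. Returns ``(wells, truth)``.
    """
    rs = config.reporter_spec
    rng = _rng(config, "reporter")
    n = rs.n_constructs
    n_rep = int(round(n * rs.frac_repressor))
    n_enh = int(round(n * rs.frac_enhancer))
    classes = (["repressor"] * n_rep + ["enhancer"] * n_enh
               + ["neutral"] * (n - n_rep - n_enh))
    order = rng.permutation(n)
    constructs = [f"conTE_{i + 1:03d}" for i in range(n)]
    cls = {constructs[i]: classes[order[i]] for i in range(n)}
    effect = {
        c: {"repressor": rs.repressor_effect, "enhancer": rs.enhancer_effect,
            "neutral": 1.0}[cls[c]]
        for c in constructs
    }
    tsa_flag = {
        c: bool(cls[c] == "repressor" and rng.random() < rs.tsa_derepression_prob)
        for c in constructs
    }

    all_constructs = [EMPTY_VECTOR, POSITIVE_CONTROL] + constructs
    cls[EMPTY_VECTOR], cls[POSITIVE_CONTROL] = "control", "control"
    effect[EMPTY_VECTOR] = 1.0
    effect[POSITIVE_CONTROL] = rs.positive_control_effect
    tsa_flag[EMPTY_VECTOR] = tsa_flag[POSITIVE_CONTROL] = False

    rows = []
    for ct in rs.cell_types:
        for tr in rs.treatments:
            for c in all_constructs:
                e = effect[c]
                if tr == "TSA" and tsa_flag[c]:
                    e = 1.0
                for rep in range(rs.n_replicates):
                    renilla = rng.lognormal(np.log(rs.renilla_mean), rs.transfection_sd)
                    noise = rng.lognormal(0.0, rs.noise_sd) if rs.noise_sd > 0 else 1.0
                    firefly = renilla * rs.baseline_ratio * e * noise
                    rows.append((c, ct, tr, rep, firefly, renilla))
    wells = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    truth = pd.DataFrame(
        {
            "construct": all_constructs,
            "effect_class": [cls[c] for c in all_constructs],
            "effect": [effect[c] for c in all_constructs],
            "tsa_derepressed": [tsa_flag[c] for c in all_constructs],
        }
    )
    return wells, truth
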