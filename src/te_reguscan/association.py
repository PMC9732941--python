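"""Gene-element association via pcHiC links, responsiveness F-tests, and ORA.

Promoter-capture Hi-C links connect a gene promoter to a distal element.
A gene is associated with a regulatory element when one link endpoint
overlaps the promoter interval and the other endpoint overlaps the
element (>=1 bp, half-open). Element flags (TE derivation, TE age
category, PGR binding) propagate to the gene.

Responsiveness comparisons use a two-sample F-test on log2 fold changes:
genes linked to TE-derived elements are contrasted with unlinked genes
within each recruitment-age stratum; the statistic is the ratio of
sample variances and the two-sided p comes from the F distribution.

Over-representation analysis is the standard hypergeometric upper-tail
test of a hit set against pathway gene sets with BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from te_reguscan.enrichment import bh_adjust

logger = logging.getLogger(__name__)

# age-category binning of TE age classes; clade membership is configurable
ANCIENT_MAMMALIAN_CLADES = frozenset({"Mammalia", "Theria", "Eutheria"})
PRIMATE_SPECIFIC_CLADES = frozenset({"Primates", "Catarrhini"})


def flag_elements(
    peaks: pd.DataFrame,
    overlap_pairs: pd.DataFrame,
    pgr_peaks: pd.DataFrame | None = None,
    ancient_clades=ANCIENT_MAMMALIAN_CLADES,
    primate_clades=PRIMATE_SPECIFIC_CLADES,
) -> pd.DataFrame:
    """Annotate each peak with TE-derivation, age category, and PGR flags.

    ``overlap_pairs`` is the ``pairs`` frame of an
    :class:`~te_reguscan.annotation.OverlapTable` for these peaks. The age
    category is ``primate_specific`` if any overlapping TE is in a primate
    clade (a peak hit by both categories counts as primate-specific),
    else ``ancient_mammalian`` if any TE is in an ancient mammalian
    clade, else ``none``.
    """
    out = peaks.copy().reset_index(drop=True)
    te_derived = np.zeros(len(out), dtype=bool)
    category = np.array(["none"] * len(out), dtype=object)
    if len(overlap_pairs):
        for pi, grp in overlap_pairs.groupby("peak_index"):
            pi = int(pi)
            te_derived[pi] = True
            ages = set(grp["age_class"])
            if ages & set(primate_clades):
                category[pi] = "primate_specific"
            elif ages & set(ancient_clades):
                category[pi] = "ancient_mammalian"
    out["te_derived"] = te_derived
    out["te_age_category"] = category
    out["pgr_bound"] = False
    if pgr_peaks is not None and len(pgr_peaks):
        trees = {}
        for chrom, sub in pgr_peaks.groupby("chrom", sort=False):
            trees[chrom] = IntervalTree.from_tuples(
                (s, e) for s, e in zip(sub["start"], sub["end"]) if e > s
            )
        out["pgr_bound"] = [
            bool(trees.get(c) and trees[c].overlap(s, e))
            for c, s, e in zip(out["chrom"], out["start"], out["end"])
        ]
    return out


def promoters_from_tss(tss: pd.DataFrame, flank: int = 1000) -> pd.DataFrame:
    """Promoter intervals as TSS +/- ``flank`` bp (clipped at 0).

    ``tss`` columns: gene, chrom, pos.
    """
    return pd.DataFrame(
        {
            "gene": tss["gene"],
            "chrom": tss["chrom"],
            "start": np.maximum(0, tss["pos"] - flank),
            "end": tss["pos"] + flank,
        }
    )


def associate_genes(
    links: pd.DataFrame,
    elements: pd.DataFrame,
    promoters: pd.DataFrame,
) -> pd.DataFrame:
    """Map genes to regulatory elements through pcHiC links.

    A gene is linked to an element iff one endpoint of a link overlaps the
    gene's promoter interval and the *other* endpoint overlaps the element
    (>=1 bp each). Link orientation is not assumed: both endpoint
    assignments are tried. Genes named in ``links`` but absent from
    ``promoters`` are skipped with a log message.

    Returns one row per (gene, element) association with the element's
    flag columns (``te_derived``, ``te_age_category``, ``pgr_bound`` when
    present).
    """
    prom = promoters.set_index("gene")
    etrees: dict[str, IntervalTree] = {}
    elements = elements.reset_index(drop=True)
    for chrom, sub in elements.groupby("chrom", sort=False):
        etrees[chrom] = IntervalTree.from_tuples(
            (s, e, i) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
            if e > s
        )

    def _hits(chrom, s, e):
        t = etrees.get(chrom)
        return {iv.data for iv in t.overlap(s, e)} if t is not None else set()

    rows = []
    seen_missing = set()
    for _, ln in links.iterrows():
        gene = ln["gene"]
        if gene not in prom.index:
            if gene not in seen_missing:
                logger.warning("gene %s has no promoter interval; skipped", gene)
                seen_missing.add(gene)
            continue
        p = prom.loc[gene]
        endA = (ln["chromA"], ln["startA"], ln["endA"])
        endB = (ln["chromB"], ln["startB"], ln["endB"])
        for prom_end, dist_end in ((endA, endB), (endB, endA)):
            c, s, e = prom_end
            if c == p["chrom"] and min(e, p["end"]) - max(s, p["start"]) >= 1:
                for ei in _hits(*dist_end):
                    rows.append((gene, ei))
    if not rows:
        return pd.DataFrame(columns=["gene", "element_index"] + [
            c for c in ("name", "te_derived", "te_age_category", "pgr_bound")
            if c in elements.columns
        ])
    assoc = pd.DataFrame(sorted(set(rows)), columns=["gene", "element_index"])
    keep = [c for c in ("name", "te_derived", "te_age_category", "pgr_bound")
            if c in elements.columns]
    assoc = assoc.join(elements[keep], on="element_index")
    return assoc.reset_index(drop=True)


@dataclass
class FTestResult:
    """Two-sample variance-ratio test: F = s2_A / s2_B, df = (nA-1, nB-1)."""

    F: float
    df: tuple
    p: float
    n_A: int
    n_B: int


def variance_ratio_test(log2fc_A, log2fc_B) -> FTestResult:
    """Two-sided F-test comparing the variances of two log2FC samples.

    F is the ratio of (n-1)-denominator sample variances (A over B);
    p = 2 * min(P(F_dist >= F), P(F_dist <= F)), capped at 1. Groups need
    >= 2 values each; zero variance in B is an error (undefined ratio).
    """
    a = np.asarray(log2fc_A, dtype=float)
    b = np.asarray(log2fc_B, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in group B: F undefined")
    F = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    dist = stats.f(dfa, dfb)
    p = min(1.0, 2 * min(dist.sf(F), dist.cdf(F)))
    return FTestResult(F=float(F), df=(dfa, dfb), p=float(p), n_A=len(a), n_B=len(b))


def significance_marker(p: float) -> str:
    """Stars at the study's thresholds: * P<0.01, ** P<1e-5."""
    if p < 1.0e-5:
        return "**"
    if p < 0.01:
        return "*"
    return ""


def stratified_responsiveness(
    de: pd.DataFrame,
    gene_flags: pd.Series,
    strata: pd.Series,
    min_group: int = 2,
) -> pd.DataFrame:
    """F-test of +flag vs -flag genes' log2FC within each stratum.

    ``gene_flags`` (gene -> bool) marks genes linked to TE-derived
    elements; ``strata`` (gene -> label) is typically the recruitment age.
    Genes missing from either series are dropped. Contrasts with fewer
    than ``min_group`` genes on either side are reported with missing
    statistics rather than omitted.
    """
    df = de.set_index("gene")
    genes = df.index.intersection(gene_flags.index).intersection(strata.index)
    df = df.loc[genes]
    flags = gene_flags.loc[genes].astype(bool)
    strat = strata.loc[genes]

    rows = []
    for stratum in sorted(strat.dropna().unique(), key=str):
        sel = strat == stratum
        pos = df.loc[sel & flags, "log2FC"].to_numpy()
        neg = df.loc[sel & ~flags, "log2FC"].to_numpy()
        if len(pos) < min_group or len(neg) < min_group:
            rows.append((stratum, len(pos), len(neg), np.nan, np.nan, ""))
            continue
        res = variance_ratio_test(pos, neg)
        rows.append((stratum, len(pos), len(neg), res.F, res.p,
                     significance_marker(res.p)))
    return pd.DataFrame(
        rows, columns=["stratum", "n_flagged", "n_unflagged", "F", "p", "marker"]
    )


def ora_hypergeometric(
    hits: set, background: set, pathways: dict
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis of a gene hit set.

    Per pathway with k = |hits ∩ pathway ∩ background| and
    m = |pathway ∩ background|: enrichment ratio = (k/|hits|)/(m/|background|),
    p = upper-tail hypergeometric P(X >= k), q by BH across pathways.
    Requires ``hits ⊆ background`` and a nonempty background.
    """
    if not background:
        raise ValueError("empty background")
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    N, n = len(background), len(hits)
    rows = []
    for name in sorted(pathways):
        pw = set(pathways[name]) & background
        m = len(pw)
        k = len(pw & hits)
        ratio = (k / n) / (m / N) if n and m else np.nan
        # P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(stats.hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        rows.append((name, k, m, ratio, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["pathway", "k", "pathway_size", "ratio", "p"])
    out["q_BH"] = bh_adjust(out["p"])
    return out
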