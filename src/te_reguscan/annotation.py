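"""Peak/TE intersection, fragment merging, and TE-content summaries.

RepeatMasker-style annotations frequently split one TE insertion into
several records (nested insertions, deletions, assembly gaps).
:func:`merge_fragmented_copies` restores one record per copy before any
counting. :func:`overlap_peaks_tes` records every peak-TE pair with at
least 1 bp of intersection under the 0-based half-open convention, and
:func:`summarize_te_content` reduces the pair table to the headline
quantities: the percentage of peaks containing a TE and the age-class
distribution of TE-derived basepairs inside peaks.

Strand is ignored throughout: regulatory peaks are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree


@dataclass
class OverlapTable:
    """Peak-TE intersection result for one assay's peak set.

    Attributes
    ----------
    pairs : DataFrame
        One row per (peak, TE record) pair with >=1 bp intersection:
        ``peak_index, peak_name, family, te_class, age_class, copy_id,
        overlap_bp``.
    n_peaks_total, n_peaks_with_te : int
        A peak overlapping several TE copies counts once in
        ``n_peaks_with_te``.
    per_family : DataFrame
        ``family, n_peaks_overlapped, total_overlap_bp`` (a peak counts
        once per family).
    """

    pairs: pd.DataFrame
    n_peaks_total: int
    n_peaks_with_te: int
    per_family: pd.DataFrame = field(repr=False)

    @property
    def te_containing_fraction(self) -> float | None:
        if self.n_peaks_total == 0:
            return None
        return self.n_peaks_with_te / self.n_peaks_total


@dataclass
class ContentSummary:
    """TE content of one peak set: percent TE-containing and age profile."""

    percent_te_containing: float | None   # rounded to 1 decimal; None if no peaks
    age_distribution_peaks: pd.Series     # TE bp in peaks by age class, sums to 1
    age_distribution_genome: pd.Series    # same normalization, whole genome
    age_distribution_missing: bool        # True when no TE bp fell in peaks


def _validate_chroms(df: pd.DataFrame, genome: dict | None, what: str) -> None:
    if genome is None:
        return
    bad = df.loc[~df["chrom"].isin(genome), "chrom"]
    if len(bad):
        first = df.loc[bad.index[0]]
        raise ValueError(
            f"{what} record on unknown chromosome {first['chrom']!r}: "
            f"{first['chrom']}:{first['start']}-{first['end']}"
        )


def merge_fragmented_copies(tes: pd.DataFrame, max_gap: int = 100) -> pd.DataFrame:
    """Merge TE records of the same copy separated by small gaps.

    Records sharing (chrom, family, copy_id) whose gap is <= ``max_gap`` bp
    are replaced by a single record spanning min(start)-max(end). The merge
    is transitive (a chain of close fragments collapses to one record) and
    idempotent. Records from different copies never merge.

    Parameters
    ----------
    tes : DataFrame with the TE annotation columns.
    max_gap : maximum tolerated gap in bp between consecutive fragments.

    Returns
    -------
    DataFrame with merged records, ``fragment_index`` reset to 0 and
    sorted by (chrom, start).
    """
    if len(tes) == 0:
        return tes.copy()
    df = tes.sort_values(["chrom", "family", "copy_id", "start"], kind="mergesort")
    key = (
        (df["chrom"] != df["chrom"].shift())
        | (df["family"] != df["family"].shift())
        | (df["copy_id"].astype(str) != df["copy_id"].astype(str).shift())
    )
    # new run whenever the copy changes or the gap to the previous fragment
    # exceeds max_gap (cummax guards against contained fragments)
    prev_end = df.groupby(key.cumsum())["end"].cummax().shift()
    gap_break = df["start"] - prev_end > max_gap
    run = (key | gap_break.fillna(True)).cumsum()
    agg = {
        "chrom": "first",
        "start": "min",
        "end": "max",
        "family": "first",
        "te_class": "first",
        "age_class": "first",
        "copy_id": "first",
        "strand": "first",
    }
    agg = {k: v for k, v in agg.items() if k in df.columns}
    out = df.groupby(run, sort=False).agg(agg).reset_index(drop=True)
    out["fragment_index"] = 0
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def overlap_peaks_tes(
    peaks: pd.DataFrame, tes: pd.DataFrame, genome: dict | None = None
) -> OverlapTable:
    """Record every peak-TE pair with >=1 bp intersection.

    Half-open convention: peak [100,200) and TE [200,300) do not overlap.
    When ``genome`` (chrom -> length) is given, records on chromosomes
    absent from it raise a :class:`ValueError` naming the record.
    """
    _validate_chroms(peaks, genome, "peak")
    _validate_chroms(tes, genome, "TE")

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in tes.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, i) for i, (s, e) in enumerate(zip(sub["start"], sub["end"]), 0)
            if e > s
        )
        trees[chrom].indices = sub.index.to_numpy()  # type: ignore[attr-defined]

    rows = []
    for pi, (chrom, ps, pe, pname) in enumerate(
        zip(peaks["chrom"], peaks["start"], peaks["end"], peaks["name"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(ps, pe):
            ti = tree.indices[iv.data]
            ov = min(pe, iv.end) - max(ps, iv.begin)
            if ov >= 1:
                rows.append((pi, pname, ti, ov))
    if rows:
        pairs = pd.DataFrame(rows, columns=["peak_index", "peak_name", "_ti", "overlap_bp"])
        te_cols = tes.loc[pairs["_ti"], ["family", "te_class", "age_class", "copy_id"]]
        pairs = pd.concat([pairs.drop(columns="_ti").reset_index(drop=True),
                           te_cols.reset_index(drop=True)], axis=1)
        pairs = pairs[["peak_index", "peak_name", "family", "te_class",
                       "age_class", "copy_id", "overlap_bp"]]
        pairs = pairs.sort_values(["peak_index", "family", "copy_id"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        pairs = pd.DataFrame(
            columns=["peak_index", "peak_name", "family", "te_class",
                     "age_class", "copy_id", "overlap_bp"]
        )
    n_with = pairs["peak_index"].nunique()
    per_family = (
        pairs.groupby("family")
        .agg(n_peaks_overlapped=("peak_index", "nunique"),
             total_overlap_bp=("overlap_bp", "sum"))
        .reset_index()
        if len(pairs)
        else pd.DataFrame(columns=["family", "n_peaks_overlapped", "total_overlap_bp"])
    )
    return OverlapTable(
        pairs=pairs,
        n_peaks_total=len(peaks),
        n_peaks_with_te=int(n_with),
        per_family=per_family,
    )


def genome_age_fractions(tes: pd.DataFrame, genome: dict) -> pd.Series:
    """Fraction of TE-derived genomic bp per age class (sums to 1)."""
    bp = tes.assign(length=tes["end"] - tes["start"]).groupby("age_class")["length"].sum()
    total = bp.sum()
    if total == 0:
        return bp.astype(float)
    return bp / total


def summarize_te_content(
    ov: OverlapTable, genome_fractions: pd.Series | None = None
) -> ContentSummary:
    """Reduce an :class:`OverlapTable` to headline TE-content numbers.

    Returns the percent of peaks containing at least one TE (1-decimal
    rounding: 5344/8510 -> 62.8), the distribution of TE-derived bp within
    peaks across age classes (normalized to sum to 1), and the genome-wide
    distribution for comparison. With zero peaks the percentage is missing
    (``None``), never 0.
    """
    if ov.n_peaks_total == 0:
        pct = None
    else:
        pct = round(100.0 * ov.n_peaks_with_te / ov.n_peaks_total, 1)
    bp = ov.pairs.groupby("age_class")["overlap_bp"].sum() if len(ov.pairs) else pd.Series(dtype=float)
    total = bp.sum()
    missing = total == 0
    dist = bp / total if total > 0 else bp.astype(float)
    if genome_fractions is None:
        genome_fractions = pd.Series(dtype=float)
    dist, gdist = dist.align(genome_fractions, fill_value=0.0)
    return ContentSummary(
        percent_te_containing=pct,
        age_distribution_peaks=dist,
        age_distribution_genome=gdist,
        age_distribution_missing=bool(missing),
    )


def peak_te_partition(
    peaks: pd.DataFrame, tes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split peaks into TE-derived segments and wholly TE-free peaks.

    Returns ``(segments, non_te_peaks)`` where segments are the merged
    per-peak intersections of the peak with any TE record, and
    ``non_te_peaks`` are peaks with no TE overlap at all.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in tes.groupby("chrom", sort=False):
        t = IntervalTree.from_tuples(
            (s, e) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
        t.merge_overlaps()
        trees[chrom] = t
    seg_rows, free_idx = [], []
    for i, (chrom, ps, pe, name) in enumerate(
        zip(peaks["chrom"], peaks["start"], peaks["end"], peaks["name"])
    ):
        tree = trees.get(chrom)
        hits = sorted(tree.overlap(ps, pe)) if tree is not None else []
        if not hits:
            free_idx.append(i)
            continue
        merged: list[list[int]] = []
        for iv in hits:
            s, e = max(ps, iv.begin), min(pe, iv.end)
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for j, (s, e) in enumerate(merged):
            seg_rows.append((chrom, s, e, f"{name}_te{j}"))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "name"])
    return segments, peaks.iloc[free_idx].reset_index(drop=True)
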