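"""TE-family and TFBS enrichment against resampling nulls.

A TE family is called enriched (eTE) in a peak set when the number of
peaks overlapping at least one of its copies exceeds the shuffle
expectation by >=1.5-fold at P <= 0.05. Two p-values are computed:

* an empirical p from ``n_reps`` placement shuffles that preserve peak
  count, peak lengths, and chromosome assignment, with a +1 pseudo-count
  so p is never 0;
* an exact two-sided binomial p (minimum-likelihood two-sidedness, as in
  :func:`scipy.stats.binomtest`) with per-peak success probability
  estimated from the shuffle expectation.

The eTE flag uses the binomial p by default (``p_rule="binomial"``); the
empirical p or the smaller of the two can be selected instead.

TFBS enrichment contrasts the density of a factor's binding peaks inside
TE-derived peak segments with the density inside TE-free peaks, with an
empirical p from factor-peak reshuffling and BH correction across factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# shuffle machinery


def _check_fit(peaks: pd.DataFrame, genome: dict) -> None:
    for chrom, sub in peaks.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        too_long = sub["end"] - sub["start"] > genome[chrom]
        if too_long.any():
            r = sub[too_long].iloc[0]
            raise ValueError(
                f"peak {r['name']} ({r['end'] - r['start']} bp) longer than "
                f"chromosome {chrom} ({genome[chrom]} bp)"
            )


def shuffle_peaks(
    peaks: pd.DataFrame, genome: dict, n_reps: int, seed=None
) -> Iterator[pd.DataFrame]:
    """Yield ``n_reps`` placement shuffles of a peak set.

    Each replicate keeps every peak's length and chromosome and draws a new
    start uniformly on the valid range [0, chrom_length - peak_length].
    """
    _check_fit(peaks, genome)
    rng = np.random.default_rng(seed)
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    maxstart = np.array([genome[c] for c in peaks["chrom"]]) - lengths
    for _ in range(n_reps):
        starts = rng.integers(0, maxstart + 1)
        rep = peaks.copy()
        rep["start"] = starts
        rep["end"] = starts + lengths
        yield rep


@dataclass
class _FamilyIndex:
    """Merged, sorted per-(family, chrom) interval arrays for fast stabbing."""

    families: list
    starts: dict   # (family, chrom) -> sorted np.ndarray of merged starts
    ends: dict     # (family, chrom) -> matching merged ends (also sorted)

    @classmethod
    def build(cls, tes: pd.DataFrame) -> "_FamilyIndex":
        starts, ends = {}, {}
        fams = sorted(tes["family"].unique())
        for (fam, chrom), sub in tes.groupby(["family", "chrom"], sort=False):
            iv = sub[["start", "end"]].sort_values("start").to_numpy()
            ms, me = [], []
            for s, e in iv:
                if me and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            starts[(fam, chrom)] = np.asarray(ms)
            ends[(fam, chrom)] = np.asarray(me)
        return cls(families=fams, starts=starts, ends=ends)

    def count_overlapping(self, fam, chrom, starts, ends) -> np.ndarray:
        """Boolean array: does each [start, end) hit any merged interval.

        ``starts``/``ends`` may be any shape; merged intervals are disjoint
        and sorted, so the only candidate is the interval with the largest
        start < end, found by searchsorted.
        """
        fs = self.starts.get((fam, chrom))
        if fs is None or len(fs) == 0:
            return np.zeros(np.shape(starts), dtype=bool)
        fe = self.ends[(fam, chrom)]
        idx = np.searchsorted(fs, ends, side="left")
        hit = idx > 0
        hit[hit] = fe[idx[hit] - 1] > np.asarray(starts)[hit]
        return hit


def _family_counts(
    index: _FamilyIndex, chroms: np.ndarray, starts: np.ndarray, lengths: np.ndarray
) -> dict:
    """Per family: number of peaks (rows of ``starts``) overlapping >=1 copy.

    ``starts`` has shape (n_reps, n_peaks); returns family -> (n_reps,) counts.
    """
    ends = starts + lengths
    out = {}
    for fam in index.families:
        hit = np.zeros(starts.shape, dtype=bool)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            hit[:, sel] = index.count_overlapping(
                fam, chrom, starts[:, sel], ends[:, sel]
            )
        out[fam] = hit.sum(axis=1)
    return out


@dataclass
class FamilyEnrichment:
    family: str
    observed_count: int
    expected_count: float
    fold: float | None          # None when expected_count == 0
    p_empirical: float
    p_binomial: float
    is_eTE: bool


def family_enrichment(
    peaks: pd.DataFrame,
    tes: pd.DataFrame,
    genome: dict,
    n_reps: int = 10_000,
    seed=None,
    min_fold: float = 1.5,
    alpha: float = 0.05,
    p_rule: str = "binomial",
) -> list[FamilyEnrichment]:
    """Call enriched TE families (eTEs) in a peak set against a shuffle null.

    Per family: observed = peaks overlapping >=1 copy; expected = mean count
    over ``n_reps`` placement shuffles; p_empirical =
    (1 + #{shuffles with count >= observed}) / (n_reps + 1); p_binomial =
    exact two-sided binomial with per-peak success probability
    expected / n_peaks. The eTE flag is
    ``fold >= min_fold and p <= alpha`` with p chosen by ``p_rule``
    ("binomial", "empirical", or "min").

    Requires ``n_reps >= 100`` for a usable empirical null.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if p_rule not in ("binomial", "empirical", "min"):
        raise ValueError(f"unknown p_rule {p_rule!r}")
    _check_fit(peaks, genome)
    index = _FamilyIndex.build(tes)
    n_peaks = len(peaks)

    chroms = peaks["chrom"].to_numpy()
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    obs = _family_counts(index, chroms, peaks["start"].to_numpy()[None, :], lengths)

    rng = np.random.default_rng(seed)
    maxstart = np.array([genome[c] for c in chroms]) - lengths
    # all shuffles at once: (n_reps, n_peaks) start matrix
    null_starts = rng.integers(0, maxstart + 1, size=(n_reps, n_peaks))
    null = _family_counts(index, chroms, null_starts, lengths)

    results = []
    for fam in index.families:
        o = int(obs[fam][0])
        counts = null[fam]
        expected = float(counts.mean())
        p_emp = (1 + int((counts >= o).sum())) / (n_reps + 1)
        phat = min(expected / n_peaks, 1.0) if n_peaks else 0.0
        if n_peaks and 0.0 < phat < 1.0:
            p_binom = stats.binomtest(o, n_peaks, phat).pvalue
        else:
            p_binom = 1.0
        fold = o / expected if expected > 0 else None
        p_used = {"binomial": p_binom, "empirical": p_emp,
                  "min": min(p_binom, p_emp)}[p_rule]
        is_ete = fold is not None and fold >= min_fold and p_used <= alpha
        results.append(
            FamilyEnrichment(
                family=fam, observed_count=o, expected_count=expected,
                fold=fold, p_empirical=p_emp, p_binomial=float(p_binom),
                is_eTE=bool(is_ete),
            )
        )
    return results


def family_enrichment_frame(results: list[FamilyEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [r.family for r in results],
            "observed": [r.observed_count for r in results],
            "expected": [r.expected_count for r in results],
            "fold": [np.nan if r.fold is None else r.fold for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "p_binomial": [r.p_binomial for r in results],
            "is_eTE": [r.is_eTE for r in results],
        }
    )


# ---------------------------------------------------------------------------
# TFBS enrichment


@dataclass
class TFBSEnrichment:
    factor: str
    density_in_te_segments: float   # factor peaks per bp of TE-derived segment
    density_in_non_te_peaks: float
    ratio: float                    # inf sentinel when non-TE density is 0
    p_empirical: float
    q_BH: float | None = None


def _interval_arrays(df: pd.DataFrame) -> dict:
    """chrom -> (sorted merged starts, ends) for a generic interval frame."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        iv = sub[["start", "end"]].sort_values("start").to_numpy()
        ms, me = [], []
        for s, e in iv:
            if me and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        out[chrom] = (np.asarray(ms), np.asarray(me))
    return out


def _count_hits(target: dict, chroms, starts, ends) -> np.ndarray:
    """Number of query intervals overlapping the merged target set.

    starts/ends shape (n_reps, n_queries); returns (n_reps,) counts.
    """
    hit = np.zeros(starts.shape, dtype=bool)
    for chrom in np.unique(chroms):
        arr = target.get(chrom)
        if arr is None:
            continue
        ms, me = arr
        if len(ms) == 0:
            continue
        sel = chroms == chrom
        idx = np.searchsorted(ms, ends[:, sel], side="left")
        h = idx > 0
        h[h] = me[idx[h] - 1] > starts[:, sel][h]
        hit[:, sel] = h
    return hit.sum(axis=1)


def tfbs_enrichment(
    te_segments: pd.DataFrame,
    non_te_peaks: pd.DataFrame,
    tfbs: dict,
    genome: dict,
    n_reps: int = 10_000,
    seed=None,
) -> list[TFBSEnrichment]:
    """Test each factor's binding-site density in TE-derived peak segments.

    For each factor: density = (factor peaks overlapping the target) /
    (target bp), computed for the TE-derived segments and for TE-free
    peaks; the statistic is the density ratio (TE / non-TE, ``inf`` when
    the non-TE density is 0). The empirical p reshuffles the factor's
    peaks uniformly over the genome ``n_reps`` times and counts null
    ratios >= observed (+1 pseudo-count). q_BH is computed across all
    factors tested.
    """
    te_bp = int((te_segments["end"] - te_segments["start"]).sum())
    non_bp = int((non_te_peaks["end"] - non_te_peaks["start"]).sum())
    if te_bp == 0 or non_bp == 0:
        raise ValueError("zero target bp in TE segments or non-TE peaks")
    te_idx = _interval_arrays(te_segments)
    non_idx = _interval_arrays(non_te_peaks)
    rng = np.random.default_rng(seed)

    results = []
    for factor in sorted(tfbs):
        fp = tfbs[factor]
        _check_fit(fp, genome)
        chroms = fp["chrom"].to_numpy()
        lengths = (fp["end"] - fp["start"]).to_numpy()
        starts = fp["start"].to_numpy()[None, :]
        d_te = _count_hits(te_idx, chroms, starts, starts + lengths)[0] / te_bp
        d_non = _count_hits(non_idx, chroms, starts, starts + lengths)[0] / non_bp
        ratio = d_te / d_non if d_non > 0 else float("inf")

        maxstart = np.array([genome[c] for c in chroms]) - lengths
        null_starts = rng.integers(0, maxstart + 1, size=(n_reps, len(fp)))
        n_te = _count_hits(te_idx, chroms, null_starts, null_starts + lengths) / te_bp
        n_non = _count_hits(non_idx, chroms, null_starts, null_starts + lengths) / non_bp
        with np.errstate(divide="ignore", invalid="ignore"):
            null_ratio = np.where(n_non > 0, n_te / n_non,
                                  np.where(n_te > 0, np.inf, np.nan))
        # a null replicate with 0/0 carries no evidence either way; treat as < obs
        ge = np.nansum(null_ratio >= ratio) if np.isfinite(ratio) else np.nansum(
            np.isinf(null_ratio)
        )
        p_emp = (1 + int(ge)) / (n_reps + 1)
        results.append(
            TFBSEnrichment(
                factor=factor,
                density_in_te_segments=float(d_te),
                density_in_non_te_peaks=float(d_non),
                ratio=float(ratio),
                p_empirical=float(p_emp),
            )
        )
    qs = bh_adjust([r.p_empirical for r in results])
    for r, q in zip(results, qs):
        r.q_BH = float(q)
    return results


def tfbs_enrichment_frame(results: list[TFBSEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "factor": [r.factor for r in results],
            "density_te": [r.density_in_te_segments for r in results],
            "density_non_te": [r.density_in_non_te_peaks for r in results],
            "ratio": [r.ratio for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "q_BH": [r.q_BH for r in results],
        }
    )
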