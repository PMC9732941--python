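"""Dual-luciferase reporter statistics and the activity landscape.

Firefly luminescence is standardized by the co-transfected renilla signal
(controls transfection efficiency) and by the empty reporter vector
(controls baseline promoter activity): per well,
``relative_activity = (firefly/renilla) / mean(empty-vector firefly/renilla)``
within the same cell type and treatment. A construct is called an
enhancer or repressor in a condition by an exact two-sample Wilcoxon
rank-sum test of its replicate activities against the empty-vector
replicates, BH-corrected across constructs within the condition, with
the call direction given by the median relative activity.

Higher-level statistics: an exact binomial test for an excess of
repressors among constructs, the fraction of repressors de-repressed by
the HDAC inhibitor trichostatin A (TSA), and a classical (Torgerson) MDS
embedding of mean log activities with k-means clustering of constructs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from te_reguscan.enrichment import bh_adjust

logger = logging.getLogger(__name__)

EMPTY_VECTOR = "Basic_minP"     # empty reporter vector reference
POSITIVE_CONTROL = "TAP2_C"     # progesterone-responsive enhancer control
CONTROL_CONSTRUCTS = (EMPTY_VECTOR, POSITIVE_CONTROL)


def normalize_plates(wells: pd.DataFrame) -> pd.DataFrame:
    """Renilla- and empty-vector-normalize reporter wells.

    Adds ``ratio`` (firefly/renilla), ``relative_activity`` (ratio over
    the mean empty-vector ratio of the same cell_type x treatment), and
    ``log2_activity``. Wells with renilla = 0 are dropped with a log
    message; a condition without empty-vector wells is an error.
    """
    df = wells.copy()
    bad = df["renilla"] <= 0
    if bad.any():
        logger.warning("dropping %d wells with renilla <= 0", int(bad.sum()))
        df = df[~bad].copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    ev = df[df["construct"] == EMPTY_VECTOR]
    baseline = ev.groupby(["cell_type", "treatment"])["ratio"].mean()
    conditions = df.groupby(["cell_type", "treatment"]).groups.keys()
    missing = [c for c in conditions if c not in baseline.index]
    if missing:
        raise ValueError(f"conditions without empty-vector wells: {missing}")
    base = baseline.loc[
        pd.MultiIndex.from_frame(df[["cell_type", "treatment"]])
    ].to_numpy()
    df["relative_activity"] = df["ratio"] / base
    df["log2_activity"] = np.log2(df["relative_activity"])
    return df


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p.

    Exact null (all rank assignments equally likely) when both groups have
    <= 10 values and there are no ties across the pooled sample; normal
    approximation with tie correction otherwise. A fully tied sample
    (every value equal) gives p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(x), len(y)) <= 10) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def classify_constructs(
    activities: pd.DataFrame,
    alpha: float = 0.05,
    controls=CONTROL_CONSTRUCTS,
    fdr_family: str = "condition",
) -> pd.DataFrame:
    """Call enhancer/repressor/neutral per construct x condition.

    Each construct's replicate ``relative_activity`` values are compared
    with the empty-vector replicates of the same cell_type x treatment by
    an exact two-sided Wilcoxon rank-sum test; BH correction is applied
    across constructs within each condition (``fdr_family="all"`` pools
    all conditions into one family instead). Control constructs are
    tested but excluded from the FDR family and from downstream counting.

    Returns one row per construct x condition: ``construct, cell_type,
    treatment, n_replicates, median_activity, median_log2, p, q_BH, call``.
    """
    if fdr_family not in ("condition", "all"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    rows = []
    for (ct, tr), cond in activities.groupby(["cell_type", "treatment"]):
        ev = cond.loc[cond["construct"] == EMPTY_VECTOR, "relative_activity"].to_numpy()
        for construct, grp in cond.groupby("construct"):
            if construct == EMPTY_VECTOR:
                continue
            vals = grp["relative_activity"].to_numpy()
            if len(vals) < 2 or len(ev) < 2:
                raise ValueError(
                    f"construct {construct} in {ct}/{tr}: need >= 2 replicates"
                )
            p = _wilcoxon_rank_sum(vals, ev)
            rows.append(
                {
                    "construct": construct,
                    "cell_type": ct,
                    "treatment": tr,
                    "n_replicates": len(vals),
                    "median_activity": float(np.median(vals)),
                    "median_log2": float(np.median(np.log2(vals))),
                    "p": p,
                    "is_control": construct in controls,
                }
            )
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls
    calls["q_BH"] = np.nan
    tested = ~calls["is_control"]
    if fdr_family == "condition":
        for _, idx in calls[tested].groupby(["cell_type", "treatment"]).groups.items():
            calls.loc[idx, "q_BH"] = bh_adjust(calls.loc[idx, "p"])
    else:
        calls.loc[tested, "q_BH"] = bh_adjust(calls.loc[tested, "p"])

    def _call(r):
        if not (r["q_BH"] <= alpha):
            return "neutral"
        if r["median_activity"] > 1:
            return "enhancer"
        if r["median_activity"] < 1:
            return "repressor"
        return "neutral"

    calls["call"] = calls.apply(_call, axis=1)
    calls.loc[calls["is_control"], "call"] = "control"
    return calls.drop(columns="is_control")


@dataclass
class BinomialExcess:
    k: int          # repressors
    n: int          # constructs considered
    fraction: float
    p: float        # exact two-sided binomial


def repressor_excess_test(
    calls: pd.DataFrame, null_prob: float = 0.5
) -> BinomialExcess:
    """Exact two-sided binomial test for an excess of repressor calls.

    k = number of repressors among all non-control constructs in
    ``calls`` (one condition's rows), tested against ``null_prob``.
    """
    considered = calls[calls["call"] != "control"]
    if len(considered) == 0:
        raise ValueError("no constructs to test")
    k = int((considered["call"] == "repressor").sum())
    n = len(considered)
    p = float(stats.binomtest(k, n, null_prob).pvalue)
    return BinomialExcess(k=k, n=n, fraction=k / n, p=p)


@dataclass
class TSADerepression:
    derepressed: list        # constructs repressor untreated, not under TSA
    n_untreated_repressors: int
    fraction: float | None   # missing when no untreated repressors
    percent: int | None      # rounded to nearest integer


def tsa_derepression(
    calls_untreated: pd.DataFrame, calls_tsa: pd.DataFrame
) -> TSADerepression:
    """Fraction of untreated repressors that lose the repressor call under TSA.

    Both inputs are call frames for one cell type (treatment ``none`` vs
    ``TSA``); constructs must match.
    """
    unt = calls_untreated.set_index("construct")
    tsa = calls_tsa.set_index("construct")
    missing = set(unt.index) ^ set(tsa.index)
    if missing:
        raise ValueError(f"constructs not present in both conditions: {sorted(missing)}")
    repressors = unt.index[unt["call"] == "repressor"]
    dere = [c for c in repressors if tsa.loc[c, "call"] != "repressor"]
    n = len(repressors)
    if n == 0:
        return TSADerepression(derepressed=[], n_untreated_repressors=0,
                               fraction=None, percent=None)
    frac = len(dere) / n
    return TSADerepression(
        derepressed=sorted(dere), n_untreated_repressors=n,
        fraction=frac, percent=round(100 * frac),
    )


@dataclass
class MDSResult:
    coordinates: pd.DataFrame   # constructs x dims
    eigenvalues: np.ndarray     # all eigenvalues, descending
    labels: pd.Series           # construct -> cluster id
    chosen_k: int
    silhouette_by_k: dict


def classical_mds(D: np.ndarray, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-center -1/2 D^2, eigendecompose, and keep the top ``dims``
    nonnegative eigendirections; coordinate scale is sqrt(eigenvalue).
    Returns (coordinates n x dims, all eigenvalues descending).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    pos = np.clip(evals[:dims], 0, None)
    coords[:, : len(pos)] = evecs[:, :dims] * np.sqrt(pos)
    return coords, evals


def mds_kmeans(
    activity_matrix: pd.DataFrame,
    dims: int = 4,
    k: int | None = 4,
    k_range=range(2, 7),
    n_restarts: int = 50,
    seed: int | None = 0,
) -> MDSResult:
    """Embed constructs by classical MDS and cluster with k-means.

    ``activity_matrix``: constructs x conditions of mean log2 activities;
    missing cells are imputed by the condition mean (logged). Euclidean
    distances feed the Torgerson embedding; k-means (``n_restarts``
    restarts, best inertia, fixed seed) runs on the MDS coordinates for
    each k in ``k_range``, scored by silhouette. ``k=4`` is the default
    (the landscape's strong/moderate/weak-enhancer vs repressor
    structure); pass ``k=None`` to pick k by silhouette instead.
    """
    X = activity_matrix.to_numpy(dtype=float)
    if X.shape[0] < dims + 1:
        raise ValueError(f"need >= {dims + 1} constructs for a {dims}-D embedding")
    if np.isnan(X).any():
        logger.info("imputing %d missing cells by condition mean",
                    int(np.isnan(X).sum()))
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    coords, evals = classical_mds(D, dims)

    sil, fits = {}, {}
    for kk in k_range:
        if kk >= len(X):
            continue
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(coords)
        fits[kk] = lab
        sil[kk] = float(silhouette_score(coords, lab)) if len(set(lab)) > 1 else -1.0
    chosen = k if k is not None else max(sil, key=sil.get)
    if chosen not in fits:
        km = KMeans(n_clusters=chosen, n_init=n_restarts, random_state=seed)
        fits[chosen] = km.fit_predict(coords)
    return MDSResult(
        coordinates=pd.DataFrame(
            coords, index=activity_matrix.index,
            columns=[f"dim{i + 1}" for i in range(dims)],
        ),
        eigenvalues=evals,
        labels=pd.Series(fits[chosen], index=activity_matrix.index, name="cluster"),
        chosen_k=int(chosen),
        silhouette_by_k=sil,
    )


def activity_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Constructs x (cell_type, treatment) matrix of median log2 activities."""
    mat = calls.pivot_table(
        index="construct", columns=["cell_type", "treatment"],
        values="median_log2",
    )
    mat.columns = [f"{ct}:{tr}" for ct, tr in mat.columns]
    return mat
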