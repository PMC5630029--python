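"""Promoter-level binding "share" statistics and ROC discrimination.

The *share* of a promoter is its fraction of the total transcription-factor
signal bound across the gene universe.  Because a global increase in binding
is normalized out, the share isolates gene-specific gains and losses: a gene
increases its share exactly when its own log2 binding change exceeds the
log2 change of the cohort total (the *share-neutral threshold*).  These
statistics, together with ROC analysis of the binding change as a predictor
of transcriptional induction vs repression, form the first analysis stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_share",
    "share_neutral_threshold",
    "share_table",
    "classify_regulation",
    "RocResult",
    "roc_induced_vs_repressed",
    "youden_optimum",
    "trend_correlation",
    "stratified_neutral_threshold",
]


# ------------------------------------------------------------------- shares

def compute_share(binding, pseudocount: float = 0.0) -> np.ndarray:
    """Fraction of total binding attributable to each gene.

    ``share_i = (b_i + pc) / sum_j (b_j + pc)``; the result sums to 1.
    """
    b = np.asarray(binding, float)
    if np.any(b < 0):
        raise ValueError("binding values must be non-negative")
    tot = np.sum(b + pseudocount)
    if tot <= 0:
        raise ValueError("total binding is zero; use a positive pseudocount")
    return (b + pseudocount) / tot


def share_neutral_threshold(b_before, b_after, pseudocount: float = 0.0) -> float:
    """Log2 binding change at which a gene's share is unchanged.

    Equals ``log2(total_after / total_before)`` (pseudocounted).  A gene
    gains share iff its own log2 change exceeds this threshold.
    """
    tb = np.sum(np.asarray(b_before, float) + pseudocount)
    ta = np.sum(np.asarray(b_after, float) + pseudocount)
    if tb <= 0 or ta <= 0:
        raise ValueError("totals must be positive")
    return float(np.log2(ta / tb))


def share_table(b_before, b_after, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene binding change and share change between two conditions.

    ``share_change`` satisfies ``share_change = delta - delta*`` exactly,
    with ``delta*`` the share-neutral threshold.
    """
    b0 = np.asarray(b_before, float)
    b1 = np.asarray(b_after, float)
    s0 = compute_share(b0, pseudocount)
    s1 = compute_share(b1, pseudocount)
    delta = np.log2(b1 + pseudocount) - np.log2(b0 + pseudocount)
    return pd.DataFrame(
        dict(
            b_before=b0,
            b_after=b1,
            delta=delta,
            share_before=s0,
            share_after=s1,
            share_change=np.log2(s1) - np.log2(s0),
        )
    )


# ----------------------------------------------------------- classification

def classify_regulation(
    responses, up_thresh: float = 1.0, down_thresh: float = -1.0
) -> np.ndarray:
    """Label genes induced / repressed / unresponsive from log2 responses.

    ``responses`` is (genes, timepoints) of log2 ratios to untreated.
    Induced if the maximum response reaches ``up_thresh``, repressed if the
    minimum reaches ``down_thresh``; a gene meeting both is labeled by the
    larger absolute excursion, with exact ties unresponsive.
    """
    r = np.atleast_2d(np.asarray(responses, float))
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    hi = r.max(axis=1)
    lo = r.min(axis=1)
    up = hi >= up_thresh
    down = lo <= down_thresh
    labels = np.full(r.shape[0], "unresponsive", dtype=object)
    labels[up & ~down] = "induced"
    labels[down & ~up] = "repressed"
    both = up & down
    labels[both & (hi > -lo)] = "induced"
    labels[both & (-lo > hi)] = "repressed"
    return labels


# ---------------------------------------------------------------------- ROC

@dataclass
class RocResult:
    """ROC curve for discriminating induced (positive) from repressed genes."""

    thresholds: np.ndarray  # descending; point i = classify positive if score > thresholds[i]
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    neutral_threshold: float | None = None
    neutral_point: tuple | None = None  # (fpr, tpr) at the share-neutral threshold

    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc_induced_vs_repressed(scores, labels, neutral_threshold=None) -> RocResult:
    """ROC of a per-gene score for induced (positive) vs repressed genes.

    Every distinct score is swept as a threshold ("score > t" calls
    induced), so the trapezoidal AUC equals the Mann-Whitney pair statistic
    with ties counted half.  Unresponsive genes are excluded.
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels, dtype=object)
    mask = (lab == "induced") | (lab == "repressed")
    s, lab = s[mask], lab[mask]
    pos = lab == "induced"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one induced and one repressed gene")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    # collapse tied scores so both counts jump together
    distinct = np.nonzero(np.r_[True, np.diff(s_sorted) != 0])[0]
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(~pos_sorted)
    ends = np.r_[distinct[1:] - 1, s_sorted.size - 1]
    tpr = np.r_[0.0, tp[ends] / n_pos]
    fpr = np.r_[0.0, fp[ends] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[ends]]
    auc = float(np.trapezoid(tpr, fpr))
    neutral_point = None
    if neutral_threshold is not None:
        neutral_point = (
            float(np.mean(s[~pos] > neutral_threshold)),
            float(np.mean(s[pos] > neutral_threshold)),
        )
    return RocResult(thresholds, tpr, fpr, auc, neutral_threshold, neutral_point)


def youden_optimum(roc: RocResult) -> tuple[float, float]:
    """Return (threshold, J) maximizing Youden's J = tpr - fpr."""
    j = roc.youden()
    i = int(np.argmax(j))
    return float(roc.thresholds[i]), float(j[i])


# ------------------------------------------------------------------- trends

def _tricube_local_quadratic(x, y, grid, span):
    """Tricube-weighted local quadratic regression evaluated on ``grid``."""
    n = x.size
    k = max(int(np.ceil(span * n)), 5)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        X = np.column_stack([np.ones(use.sum()), xs[use] - g, (xs[use] - g) ** 2])
        W = w[use]
        beta, *_ = np.linalg.lstsq(X * W[:, None], ys[use] * W, rcond=None)
        out[i] = beta[0]
    return out


def _spearman(x, y):
    """Spearman rho with an exact permutation p-value at very small n."""
    n = x.size
    rho, p = stats.spearmanr(x, y)
    if n <= 8:  # exact enumeration is cheap here
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def trend_correlation(
    x,
    y,
    labels=None,
    trim: tuple = (2.0, 98.0),
    span: float = 0.5,
    n_grid: int = 100,
) -> dict:
    """Smoothed trend of response vs binding change, with Spearman rho.

    Data points outside the ``trim`` percentile band of ``x`` are excluded
    from both the trend and the correlation.  The trend is a tricube-weighted
    local quadratic fit evaluated on an even grid over the trimmed x-range.
    Returns a dict of per-group results (groups from ``labels`` plus
    ``"all"``), each with keys ``grid``, ``trend``, ``rho``, ``p``, ``n``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lab = np.asarray(labels, dtype=object) if labels is not None else None
    lo, hi = np.percentile(x, trim)
    keep = (x >= lo) & (x <= hi)
    groups = {"all": keep}
    if lab is not None:
        for g in ("induced", "repressed"):
            groups[g] = keep & (lab == g)
    out = {}
    for name, m in groups.items():
        if m.sum() < 10:
            if name == "all":
                raise ValueError("fewer than 10 points after trimming")
            continue
        xg, yg = x[m], y[m]
        grid = np.linspace(xg.min(), xg.max(), n_grid)
        rho, p = _spearman(xg, yg)
        out[name] = dict(
            grid=grid,
            trend=_tricube_local_quadratic(xg, yg, grid, span),
            rho=rho,
            p=p,
            n=int(m.sum()),
        )
    return out


# -------------------------------------------------- stratified thresholds

def stratified_neutral_threshold(
    delta,
    labels,
    cofactor,
    n_bins: int = 4,
    min_per_class: int = 20,
) -> pd.DataFrame:
    """Per-cofactor-bin Youden-optimal discrimination threshold.

    Genes are split into ``n_bins`` quantile bins of ``cofactor`` (e.g.
    ZBTB17 promoter binding); within each bin the binding-change threshold
    maximizing Youden's J for induced-vs-repressed is located.  Bins with
    fewer than ``min_per_class`` genes of either class are flagged rather
    than failing.
    """
    delta = np.asarray(delta, float)
    lab = np.asarray(labels, dtype=object)
    cof = np.asarray(cofactor, float)
    edges = np.quantile(cof, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.inf
    rows = []
    for i in range(n_bins):
        m = (cof >= edges[i]) & (cof < edges[i + 1])
        n_ind = int(np.sum(m & (lab == "induced")))
        n_rep = int(np.sum(m & (lab == "repressed")))
        ok = n_ind >= min_per_class and n_rep >= min_per_class
        thr = j = np.nan
        if ok:
            roc = roc_induced_vs_repressed(delta[m], lab[m])
            thr, j = youden_optimum(roc)
        rows.append(
            dict(
                bin=i + 1,
                cofactor_low=edges[i],
                cofactor_high=edges[i + 1],
                n_induced=n_ind,
                n_repressed=n_rep,
                threshold=thr,
                youden_j=j,
                flagged=not ok,
            )
        )
    return pd.DataFrame(rows).set_index("bin")
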