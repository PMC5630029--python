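import numpy as np
import pytest

from mycflux import (
    classify_regulation,
    compute_share,
    roc_induced_vs_repressed,
    share_neutral_threshold,
    share_table,
    stratified_neutral_threshold,
    trend_correlation,
    youden_optimum,
)


# ------------------------------------------------------------------ shares

def test_compute_share_basic():
    assert np.allclose(compute_share([2, 3, 5]), [0.2, 0.3, 0.5])
    assert np.allclose(compute_share(np.ones(7)), np.full(7, 1 / 7))
    b = np.array([1.0, 4.0, 9.0])
    assert np.allclose(compute_share(b), compute_share(10 * b))
    with pytest.raises(ValueError):
        compute_share([0.0, 0.0])


def test_neutral_threshold_closed_form():
    b0 = np.full(10, 100.0)
    assert share_neutral_threshold(b0, 4 * b0) == pytest.approx(2.0, abs=1e-12)
    assert share_neutral_threshold(b0, b0) == pytest.approx(0.0, abs=1e-12)


def test_threshold_partitions_share_gainers():
    """delta > delta* if and only if the gene's share increased."""
    rng = np.random.default_rng(3)
    b0 = rng.lognormal(3, 1, 1000)
    b1 = b0 * rng.lognormal(0.5, 0.8, 1000)
    for pc in (0.0, 1.0):
        tab = share_table(b0, b1, pc)
        ds = share_neutral_threshold(b0, b1, pc)
        assert np.array_equal(tab.delta > ds, tab.share_after > tab.share_before)
        # share_change identity: exactly delta - delta*
        assert np.allclose(tab.share_change, tab.delta - ds, atol=1e-12)
        assert tab.share_before.sum() == pytest.approx(1.0, abs=1e-9)
        assert tab.share_after.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------- classification

def test_classify_regulation_rules():
    resp = np.array(
        [
            [0.2, 1.5, 0.8],     # peaks above threshold -> induced
            [0.0, 0.0, 0.0],     # flat -> unresponsive
            [1.2, -1.2, 0.3],    # tie in excursion -> unresponsive
            [-0.1, -1.4, -0.2],  # repressed
            [2.0, -1.1, 0.0],    # both, larger positive -> induced
        ]
    )
    labels = classify_regulation(resp, up_thresh=1.0, down_thresh=-1.0)
    assert list(labels) == ["induced", "unresponsive", "unresponsive", "repressed", "induced"]


# ---------------------------------------------------------------------- ROC

def mwu_auc(scores, labels):
    """Exhaustive pairwise Mann-Whitney oracle (ties count half)."""
    pos = scores[labels == "induced"]
    neg = scores[labels == "repressed"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def test_auc_equals_pairwise_oracle_including_ties():
    rng = np.random.default_rng(11)
    for trial in range(20):
        n = rng.integers(10, 120)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = np.where(rng.random(n) < 0.5, "induced", "repressed")
        if len(set(labels)) < 2:
            continue
        roc = roc_induced_vs_repressed(scores, labels)
        assert roc.auc == pytest.approx(mwu_auc(scores, labels), abs=1e-12)


def test_auc_perfect_separation_and_monotone_invariance():
    scores = np.r_[np.zeros(5), np.ones(5)]
    labels = np.array(["repressed"] * 5 + ["induced"] * 5, dtype=object)
    assert roc_induced_vs_repressed(scores, labels).auc == 1.0
    rng = np.random.default_rng(5)
    s = rng.normal(size=80)
    lab = np.where(rng.random(80) < 0.4, "induced", "repressed")
    a1 = roc_induced_vs_repressed(s, lab).auc
    a2 = roc_induced_vs_repressed(np.exp(3 * s) + 7, lab).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_auc_centered_under_label_permutation():
    rng = np.random.default_rng(19)
    s = rng.normal(size=2000)
    labels = np.array(["induced"] * 1000 + ["repressed"] * 1000, dtype=object)
    aucs = []
    for _ in range(200):
        rng.shuffle(labels)
        aucs.append(roc_induced_vs_repressed(s, labels).auc)
    assert abs(np.mean(aucs) - 0.5) < 0.03


def test_roc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_induced_vs_repressed([1.0, 2.0], ["induced", "induced"])


def test_unresponsive_genes_excluded_from_roc():
    s = np.array([0.0, 1.0, 99.0])
    lab = np.array(["repressed", "induced", "unresponsive"], dtype=object)
    roc = roc_induced_vs_repressed(s, lab)
    assert roc.auc == 1.0


# ------------------------------------------------------------------- trends

def test_trend_recovers_linear_relation():
    rng = np.random.default_rng(2)
    x = rng.uniform(-2, 2, 400)
    y = 2 * x
    res = trend_correlation(x, y)
    g = res["all"]
    assert g["rho"] == pytest.approx(1.0)
    interior = (g["grid"] > -1.2) & (g["grid"] < 1.2)
    slope = np.gradient(g["trend"], g["grid"])[interior]
    assert np.allclose(slope, 2.0, atol=0.05)


def test_trimming_makes_rho_outlier_robust():
    rng = np.random.default_rng(4)
    x = rng.normal(size=500)
    y = x + 0.1 * rng.normal(size=500)
    base = trend_correlation(x, y)["all"]["rho"]
    x_out = np.r_[x, np.full(5, 40.0)]       # beyond the 98th percentile
    y_out = np.r_[y, np.full(5, -40.0)]
    trimmed = trend_correlation(x_out, y_out)["all"]["rho"]
    assert trimmed == pytest.approx(base, abs=0.01)


def test_rho_rank_invariance_and_small_n_exact_p():
    x = np.arange(20.0)
    res = trend_correlation(x, np.exp(x / 3))["all"]
    assert res["rho"] == pytest.approx(1.0)
    tiny = trend_correlation(np.arange(12.0), np.arange(12.0) ** 3, trim=(0, 100))
    assert tiny["all"]["rho"] == pytest.approx(1.0)


def test_trend_requires_enough_points():
    with pytest.raises(ValueError):
        trend_correlation(np.arange(5.0), np.arange(5.0))


# -------------------------------------------------- stratified thresholds

def _labeled_deltas(rng, n, boundary=0.0, margin=1.0, noise=0.3):
    lab = np.where(rng.random(n) < 0.5, "induced", "repressed")
    d = np.where(lab == "induced", boundary + margin, boundary - margin)
    return d + noise * rng.normal(size=n), lab


def test_stratified_threshold_flat_when_cofactor_independent():
    rng = np.random.default_rng(6)
    d, lab = _labeled_deltas(rng, 1200)
    cof = rng.lognormal(size=1200)  # independent of class
    out = stratified_neutral_threshold(d, lab, cof, n_bins=4)
    assert not out["flagged"].any()
    assert out["threshold"].max() - out["threshold"].min() < 0.35


def test_stratified_threshold_recovers_shifted_boundary():
    rng = np.random.default_rng(8)
    n = 2000
    cof = rng.uniform(0, 1, n)
    top = cof > 0.75
    d = np.empty(n)
    lab = np.empty(n, dtype=object)
    d[~top], lab[~top] = _labeled_deltas(rng, int((~top).sum()), boundary=0.0)
    d[top], lab[top] = _labeled_deltas(rng, int(top.sum()), boundary=0.5)
    out = stratified_neutral_threshold(d, lab, cof, n_bins=4)
    assert out["threshold"].iloc[3] - out["threshold"].iloc[:3].mean() == pytest.approx(
        0.5, abs=0.25
    )


def test_single_bin_reduces_to_global_youden():
    rng = np.random.default_rng(9)
    d, lab = _labeled_deltas(rng, 500)
    roc = roc_induced_vs_repressed(d, lab)
    thr, _ = youden_optimum(roc)
    out = stratified_neutral_threshold(d, lab, rng.normal(size=500), n_bins=1)
    assert out["threshold"].iloc[0] == pytest.approx(thr, abs=1e-12)


def test_underpopulated_bin_flagged():
    rng = np.random.default_rng(10)
    d, lab = _labeled_deltas(rng, 60)
    out = stratified_neutral_threshold(d, lab, rng.normal(size=60), n_bins=4,
                                       min_per_class=20)
    assert out["flagged"].any()
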