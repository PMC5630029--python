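"""Synthetic cohorts with known transcriptional and RNAPII kinetics.

The generator emulates the statistical structure of an acute
transcription-factor activation time course: a cohort of genes split into
induced / repressed / unresponsive classes, factor binding at promoters
whose genomic total rises upon activation (induced genes gaining more than
the cohort, repressed genes less, so share gains track class by
construction), RNAPII densities produced by the four-parameter compartment
model, and RNA abundances produced by the synthesis/processing/degradation
ODE with a short metabolic-labeling window — all with known ground truth
for recovery testing.

Conventions: rates are defined by impulse-family time courses for t >= 0
and held at their untreated value before treatment (t < 0 matters only for
the labeling pulse preceding the first collection).  Every gene starts at
the steady state of both the RNA and the compartment model.  Promoter-flux
gains of induced genes are budget-balanced against the losses of repressed
genes so the cohort's total chromatin-bound RNAPII stays within a stated
tolerance, reflecting a limiting pool of polymerase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import impulse_eval, _logistic
from .signal import SignalTable, TimeGrid
from .kinetics import _quad_trajectory as _rna_quad

__all__ = ["NoiseModel", "GroundTruth", "generate_ground_truth",
           "simulate_rna_tables", "simulate_chip_tables", "simulate_cohort",
           "synthetic_annotation"]

CLASSES = ("induced", "repressed", "unresponsive")
_RATE_NAMES = ("k1", "k2", "k3", "p1", "p2", "p3", "p4", "b", "zbtb17")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal count noise, optionally Poisson-resampled.

    ``cv`` is the coefficient of variation of the lognormal factor;
    ``depth`` the expected library size used to convert normalized signal
    into raw counts (and as the Poisson intensity scale when
    ``scheme='poisson_lognormal'``).
    """

    scheme: str = "lognormal"
    cv: float = 0.2
    depth: float = 2e7

    def __post_init__(self):
        if self.scheme not in ("lognormal", "poisson_lognormal"):
            raise ValueError(f"unknown noise scheme {self.scheme!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def apply(self, expected, n_replicates, rng):
        """Expected normalized signal (G, T) -> raw counts (G, T, R)."""
        e = np.asarray(expected, float)[:, :, None]
        counts = np.broadcast_to(e * (self.depth / 1e6), e.shape[:2] + (n_replicates,)).copy()
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            counts = counts * rng.lognormal(-0.5 * sigma**2, sigma, size=counts.shape)
        if self.scheme == "poisson_lognormal":
            counts = rng.poisson(counts).astype(float)
        return counts


@dataclass
class GroundTruth:
    """True per-gene kinetics, RNAPII parameters, binding, and class labels.

    All rate time courses are stored as impulse parameters
    (baseline, peak, plateau, t_onset, t_offset, slope); constants are flat
    impulses.  ``eval(name, t)`` returns a (genes, times) array, with t < 0
    mapped to the untreated value.
    """

    gene_ids: np.ndarray
    classes: np.ndarray
    params: dict                      # rate name -> (n, 6) impulse parameters
    grid: TimeGrid
    seed: int
    global_gain: float
    flags: dict = field(default_factory=dict)   # e.g. k2_dip, p3_dip, p1_negative

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def eval(self, name: str, t) -> np.ndarray:
        t = np.maximum(np.atleast_1d(np.asarray(t, float)), 0.0)
        P = self.params[name]
        return impulse_eval(t[None, :], *(P[:, j : j + 1] for j in range(6)))

    def rates_at(self, name: str, gene: int, t):
        return self.eval(name, t)[gene]

    def to_frame(self) -> pd.DataFrame:
        cols = {"class": self.classes}
        for name, P in self.params.items():
            for j, p in enumerate(("baseline", "peak", "plateau", "t_on", "t_off", "slope")):
                cols[f"{name}_{p}"] = P[:, j]
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene_id"))


def _flat(values):
    """Impulse parameters encoding a constant rate."""
    v = np.asarray(values, float)
    P = np.empty((v.size, 6))
    P[:, 0] = P[:, 1] = P[:, 2] = v
    P[:, 3], P[:, 4], P[:, 5] = 0.0, 1.0, 1.0
    return P


def generate_ground_truth(
    n_genes: int = 1500,
    fractions: tuple = (0.2, 0.2, 0.6),
    grid: TimeGrid | None = None,
    seed: int = 0,
    effect_log2: tuple = (1.0, 2.5),
    binding_margin_log2: tuple = (0.5, 2.0),
    global_gain: float = 3.0,
    k2_dip_fraction: float = 0.45,
    p3_dip_fraction: float = 0.45,
    rnapii_budget_tolerance: float = 0.10,
) -> GroundTruth:
    """Draw a synthetic cohort with known kinetics.

    ``fractions`` are the induced / repressed / unresponsive proportions;
    ``effect_log2`` the range of |log2| synthesis fold-changes of responsive
    genes; ``binding_margin_log2`` the range of per-gene log2 binding
    changes *beyond* (induced) or *short of* (repressed) the cohort-wide
    ``global_gain``.  A ``k2_dip_fraction`` of induced genes additionally
    receives a transient processing-rate decrease and a
    ``p3_dip_fraction`` a transient elongation-rate decrease (mirrored with
    opposite sign in a subset of repressed genes).  Deterministic given
    ``seed``.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError("fractions must be three non-negative numbers summing to 1")
    grid = grid or TimeGrid()
    rng = np.random.default_rng(seed)

    n_ind = int(round(fractions[0] * n_genes))
    n_rep = int(round(fractions[1] * n_genes))
    classes = np.array(
        ["induced"] * n_ind + ["repressed"] * n_rep
        + ["unresponsive"] * (n_genes - n_ind - n_rep),
        dtype=object,
    )
    rng.shuffle(classes)
    ind = classes == "induced"
    rep = classes == "repressed"
    responsive = ind | rep

    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)], dtype=object)

    # baseline kinetics (units: abundance/h for k1, 1/h otherwise)
    k1_0 = rng.lognormal(np.log(10.0), 0.8, n_genes)
    k2_0 = rng.lognormal(np.log(4.0), 0.6, n_genes)
    k3_0 = rng.lognormal(np.log(0.5), 0.5, n_genes)

    lo, hi = effect_log2
    fold = np.ones(n_genes)
    fold[ind] = 2.0 ** rng.uniform(lo, hi, n_ind)
    fold[rep] = 2.0 ** -rng.uniform(lo, hi, n_rep)

    # --- k1: impulse response with mild overshoot, onset within ~10-25 min
    k1 = _flat(k1_0)
    r = responsive
    n_r = int(r.sum())
    k1[r, 2] = k1_0[r] * fold[r]
    overshoot = np.where(ind[r], 1.0 + rng.uniform(0.0, 0.4, n_r), 1.0)
    k1[r, 1] = k1[r, 2] * overshoot
    k1[r, 3] = rng.uniform(0.15, 0.4, n_r)
    k1[r, 4] = rng.uniform(1.0, 2.5, n_r)
    k1[r, 5] = rng.uniform(6.0, 12.0, n_r)

    # --- k2: transient processing-rate dip in a subset of induced genes,
    # transient rise in a subset of repressed genes
    k2 = _flat(k2_0)
    k2_dip = np.zeros(n_genes, bool)
    k2_dip[ind] = rng.random(n_ind) < k2_dip_fraction
    k2_dip[rep] = rng.random(n_rep) < 0.3
    nd = int(k2_dip.sum())
    sign = np.where(ind[k2_dip], -1.0, 1.0)
    k2[k2_dip, 1] = k2_0[k2_dip] * 2.0 ** (sign * rng.uniform(0.7, 1.7, nd))
    k2[k2_dip, 2] = k2_0[k2_dip] * rng.uniform(0.85, 1.0, nd)
    k2[k2_dip, 3] = rng.uniform(0.1, 0.4, nd)
    k2[k2_dip, 4] = rng.uniform(0.7, 1.5, nd)
    k2[k2_dip, 5] = rng.uniform(4.0, 10.0, nd)

    # --- k3: degradation changes, the least prevalent effect
    k3 = _flat(k3_0)
    k3_var = np.zeros(n_genes, bool)
    k3_var[responsive] = rng.random(n_r) < 0.15
    nv = int(k3_var.sum())
    k3[k3_var, 1] = k3[k3_var, 2] = k3_0[k3_var] * 2.0 ** (
        rng.choice([-1.0, 1.0], nv) * rng.uniform(0.5, 1.2, nv)
    )
    k3[k3_var, 3] = rng.uniform(0.3, 1.0, nv)
    k3[k3_var, 4] = k3[k3_var, 3] + 10.0  # sigmoid-like: offset far beyond course
    k3[k3_var, 5] = rng.uniform(2.0, 6.0, nv)

    # --- RNAPII parameters; p1 baseline tied to synthesis so the
    # compartment steady state matches transcriptional output scale
    p2_0 = rng.lognormal(np.log(2.0), 0.4, n_genes)
    p3_0 = rng.lognormal(np.log(3.0), 0.4, n_genes)
    p4_0 = rng.lognormal(np.log(6.0), 0.4, n_genes)
    p1_0 = k1_0.copy()

    # promoter-flux fold changes, budget-balanced: induced gains are scaled
    # so that (weighted by per-gene pool size) they offset repressed losses,
    # keeping total chromatin-bound RNAPII near-constant
    w = 1.0 / p2_0 + 1.0 / p3_0 + 1.0 / p4_0
    gain_raw = 2.0 ** rng.uniform(lo, hi, n_ind) - 1.0
    loss = 1.0 - 2.0 ** -rng.uniform(lo, hi, n_rep)
    denom = float(np.sum(w[ind] * p1_0[ind] * gain_raw))
    kappa = float(np.sum(w[rep] * p1_0[rep] * loss)) / denom if denom > 0 else 1.0
    p1_fold = np.ones(n_genes)
    p1_fold[ind] = 1.0 + kappa * gain_raw
    p1_fold[rep] = 1.0 - loss

    p1 = _flat(p1_0)
    p1[r, 2] = p1_0[r] * p1_fold[r]
    burst = np.where(ind[r], 1.0 + rng.uniform(0.3, 1.0, n_r), 1.0)
    p1[r, 1] = p1[r, 2] * burst
    # loading responds immediately: onset within minutes, steep but with a
    # negligible leading tail at t=0 (onset * slope >> 1)
    p1[r, 3] = rng.uniform(0.08, 0.14, n_r)
    p1[r, 4] = rng.uniform(0.5, 1.5, n_r)
    p1[r, 5] = rng.uniform(50.0, 80.0, n_r)
    # strongly repressed genes transiently lose polymerase (negative flux)
    p1_neg = rep & (p1_fold < 2.0**-1.2)
    p1[p1_neg, 1] = -p1_0[p1_neg] * rng.uniform(0.1, 0.5, int(p1_neg.sum()))

    p2 = _flat(p2_0)
    sgn = np.where(ind[r], 1.0, -1.0)
    p2[r, 1] = p2[r, 2] = p2_0[r] * 2.0 ** (sgn * rng.uniform(0.3, 0.8, n_r))
    p2[r, 3] = rng.uniform(0.2, 0.6, n_r)
    p2[r, 4] = p2[r, 3] + 10.0
    p2[r, 5] = rng.uniform(4.0, 10.0, n_r)

    p3 = _flat(p3_0)
    p3_dip = np.zeros(n_genes, bool)
    p3_dip[ind] = rng.random(n_ind) < p3_dip_fraction
    p3_dip[rep] = rng.random(n_rep) < 0.3
    np3 = int(p3_dip.sum())
    sgn3 = np.where(ind[p3_dip], -1.0, 1.0)
    p3[p3_dip, 1] = p3_0[p3_dip] * 2.0 ** (sgn3 * rng.uniform(0.5, 1.2, np3))
    p3[p3_dip, 2] = p3_0[p3_dip] * rng.uniform(0.85, 1.0, np3)
    p3[p3_dip, 3] = rng.uniform(0.1, 0.4, np3)
    p3[p3_dip, 4] = rng.uniform(0.7, 1.5, np3)
    p3[p3_dip, 5] = rng.uniform(4.0, 10.0, np3)

    p4 = _flat(p4_0)

    # --- promoter binding: induced genes gain more than the cohort-wide
    # fold-change, repressed genes less, by the stated log2 margin.  The
    # margins are made exact relative to the realized (binding-weighted)
    # cohort fold-change by letting unresponsive promoters absorb the share
    # imbalance: induced promoters gain more share mass than repressed ones
    # release, so the passive pool is diluted by a common factor, computed
    # in closed form so the weighted mean fold equals the global gain.
    b0 = rng.lognormal(np.log(50.0), 0.8, n_genes)
    mlo, mhi = binding_margin_log2
    rel = np.ones(n_genes)
    rel[ind] = 2.0 ** rng.uniform(mlo, mhi, n_ind)
    rel[rep] = 2.0 ** -rng.uniform(mlo, mhi, n_rep)
    jitter = 2.0 ** rng.normal(0.0, 0.15, n_genes)
    unresp = ~responsive
    resp_mass = float(np.sum(b0[responsive] * rel[responsive])) / float(np.sum(b0))
    unresp_mass = float(np.sum(b0[unresp] * jitter[unresp])) / float(np.sum(b0))
    if unresp_mass > 0 and resp_mass < 0.95:
        rel[unresp] = (1.0 - resp_mass) / unresp_mass * jitter[unresp]
    else:
        import warnings

        warnings.warn(
            "cannot balance binding shares (no/too-small unresponsive pool); "
            "margins are relative to the unresponsive level only"
        )
        rel[unresp] = jitter[unresp]
    b_fold = global_gain * rel
    b = _flat(b0)
    b[:, 1] = b[:, 2] = b0 * b_fold
    b[:, 3] = rng.uniform(0.08, 0.12, n_genes)   # binding within minutes
    b[:, 4] = b[:, 3] + 10.0
    b[:, 5] = 80.0

    # cofactor (ZBTB17-style) promoter binding: static over the course and
    # independent of class; stratified-threshold analyses bin on it
    z = _flat(rng.lognormal(np.log(30.0), 0.8, n_genes))

    return GroundTruth(
        gene_ids=gene_ids,
        classes=classes,
        params={"k1": k1, "k2": k2, "k3": k3, "p1": p1, "p2": p2, "p3": p3,
                "p4": p4, "b": b, "zbtb17": z},
        grid=grid,
        seed=int(seed),
        global_gain=float(global_gain),
        flags={"k2_dip": k2_dip, "p3_dip": p3_dip, "k3_var": k3_var,
               "p1_negative": p1_neg,
               "rnapii_budget_tolerance": float(rnapii_budget_tolerance)},
    )


# ------------------------------------------------------------- simulation

def _fine_times(grid: TimeGrid, dt: float = 0.01, t_min: float = 0.0):
    t = np.arange(t_min, grid.times[-1] + dt / 2, dt)
    extra = np.asarray(grid.times)
    extra = np.r_[extra, extra - grid.labeling_duration]
    return np.union1d(np.round(t, 9), np.round(extra[extra >= t_min], 9))


def rna_trajectories(gt: GroundTruth, dt: float = 0.01):
    """Noiseless P(t), M(t) and labeling-window synthesis, on the grid.

    Returns dict with P, M (genes x timepoints) and ``nascent`` (amount of
    RNA synthesized in the labeling window preceding each timepoint).
    """
    grid = gt.grid
    tau = grid.labeling_duration
    times = grid.as_array()
    if np.any((times > 0) & (times < tau)):
        raise ValueError("labeling window would precede t=0 for an early timepoint")
    tf = _fine_times(grid, dt)
    k1 = gt.eval("k1", tf)
    k2 = gt.eval("k2", tf)
    k3 = gt.eval("k3", tf)
    P0 = k1[:, 0] / k2[:, 0]
    M0 = k1[:, 0] / k3[:, 0]
    P, M = _rna_quad(k1, k2, k3, P0[:, None], M0[:, None], tf)
    idx = np.searchsorted(tf, np.round(times, 9))
    # integral of k1 over [t - tau, t]; rates are flat before t=0
    K1 = np.concatenate(
        [np.zeros((gt.n_genes, 1)),
         np.cumsum(0.5 * (k1[:, 1:] + k1[:, :-1]) * np.diff(tf)[None, :], axis=1)],
        axis=1,
    )
    idx_lo = np.searchsorted(tf, np.round(np.maximum(times - tau, 0.0), 9))
    nascent = K1[:, idx] - K1[:, idx_lo]
    pre = np.clip(tau - times, 0.0, tau)          # pre-treatment part of the window
    nascent = nascent + pre[None, :] * k1[:, [0]]
    return {"P": P[:, idx], "M": M[:, idx], "nascent": nascent,
            "k2_grid": gt.eval("k2", times)}


def simulate_rna_tables(
    gt: GroundTruth,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
    nascent_scale: float = 1.0,
) -> dict:
    """Total and nascent exonic/intronic SignalTables from the RNA ODE.

    Intronic total signal tracks pre-mRNA P, exonic total tracks P + M.
    The nascent signal equals the RNA synthesized during the labeling
    window, partitioned into intronic/exonic parts by the unprocessed
    fraction implied by k2 (mean survival of labeled molecules across the
    window).  ``nascent_scale`` deliberately mis-scales the nascent tables
    to exercise inference-side rescaling.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)
    tr = rna_trajectories(gt)
    tau = gt.grid.labeling_duration
    k2g = tr["k2_grid"]
    u = -np.expm1(-k2g * tau) / (k2g * tau)       # unprocessed fraction
    expected = {
        "total_intron": tr["P"],
        "total_exon": tr["P"] + tr["M"],
        "nascent_intron": nascent_scale * u * tr["nascent"],
        "nascent_exon": nascent_scale * (1.0 - u) * tr["nascent"],
    }
    out = {}
    for assay, e in expected.items():
        counts = noise.apply(e, n_replicates, rng)
        out[assay] = SignalTable(
            assay=assay,
            gene_ids=gt.gene_ids.copy(),
            values=counts,
            grid=gt.grid,
            library_sizes=np.full((gt.grid.n_times, n_replicates), noise.depth),
        )
    return out


def polii_trajectories(gt: GroundTruth, dt: float = 0.01):
    """Noiseless compartment densities on the sampling grid (genes x T)."""
    tf = _fine_times(gt.grid, dt)
    p1 = gt.eval("p1", tf)
    p2 = gt.eval("p2", tf)
    p3 = gt.eval("p3", tf)
    p4 = gt.eval("p4", tf)
    from ._num import expstep_solve

    init = (p1[:, :1] / p2[:, :1], p1[:, :1] / p3[:, :1], p1[:, :1] / p4[:, :1])
    out = []
    src = p1
    for rate, y0 in zip((p2, p3, p4), init):
        y = expstep_solve(rate, src, y0, tf)
        out.append(y)
        src = rate * y
    idx = np.searchsorted(tf, np.round(gt.grid.as_array(), 9))
    Pr, Gb, Te = (np.clip(y[:, idx], 0.0, None) for y in out)
    return {"Pr": Pr, "Gb": Gb, "Te": Te, "k1_implied": gt.eval("p3", gt.grid.as_array()) * Gb}


def simulate_chip_tables(
    gt: GroundTruth,
    noise: NoiseModel | None = None,
    global_gain: float | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
) -> dict:
    """MYC-binding and RNAPII-density SignalTables.

    MYC expected counts are rescaled per timepoint so that the cohort total
    follows ``1 + (global_gain - 1) * s(t)`` with s the fast activation
    sigmoid — the genome-wide increase in bound factor.  Library sizes are
    held constant across the course (quantitative, spike-in-like scaling),
    so the global gain survives CPM normalization.  RNAPII tables sample
    the compartment-model trajectories.
    """
    noise = noise or NoiseModel()
    if global_gain is None:
        global_gain = gt.global_gain
    if global_gain <= 0:
        raise ValueError("global_gain must be positive")
    rng = np.random.default_rng(gt.seed + 2 if seed is None else seed)
    times = gt.grid.as_array()

    b = gt.eval("b", times)
    s = _logistic(30.0 * (times - 0.055))
    s = (s - s[0]) / (1.0 - s[0])                 # 0 at t=0, -> 1 once activated
    target = b[:, 0].sum() * (1.0 + (global_gain - 1.0) * s)
    b = b * (target / b.sum(axis=0))[None, :]

    tr = polii_trajectories(gt)
    expected = {
        "MYC": b,
        "ZBTB17": gt.eval("zbtb17", times),
        "RNAPII_promoter": tr["Pr"],
        "RNAPII_genebody": tr["Gb"],
        "RNAPII_tes": tr["Te"],
    }
    out = {}
    for assay, e in expected.items():
        counts = noise.apply(e, n_replicates, rng)
        out[assay] = SignalTable(
            assay=assay,
            gene_ids=gt.gene_ids.copy(),
            values=counts,
            grid=gt.grid,
            library_sizes=np.full((gt.grid.n_times, n_replicates), noise.depth),
        )
    return out


def simulate_cohort(
    n_genes: int = 1500,
    seed: int = 0,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    **gt_kwargs,
):
    """Generate ground truth plus all RNA and ChIP tables in one call."""
    gt = generate_ground_truth(n_genes=n_genes, seed=seed, **gt_kwargs)
    noise = noise or NoiseModel()
    tables = simulate_rna_tables(gt, noise, n_replicates)
    tables.update(simulate_chip_tables(gt, noise, n_replicates=n_replicates))
    return gt, tables


def synthetic_annotation(gt: GroundTruth, rng=None) -> pd.DataFrame:
    """A plausible BED12 gene annotation for the cohort (synthetic layout)."""
    rng = rng or np.random.default_rng(gt.seed + 3)
    lengths = rng.lognormal(np.log(2e4), 0.6, gt.n_genes).astype(int) + 2000
    starts = 10_000 + np.cumsum(lengths + 10_000) - lengths
    strands = rng.choice(["+", "-"], gt.n_genes)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths,
            "name": gt.gene_ids,
            "score": 0,
            "strand": strands,
        }
    )
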