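"""Population statistics over lineage tables and trajectory snapshots.

Covers the quantities used to characterise cell-cycle variability:
coefficients of variation, number-doubling-time estimation from culture
count series, the binned size-control regression (μ·T_unbud against
ln(V_bir/⟨V_bud⟩)), Poisson and two-component-Poisson fits to mRNA count
histograms, product-moment correlations, and per-cell Sic1 decay fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp


# ---------------------------------------------------------------------------
# elementary descriptors
# ---------------------------------------------------------------------------

def cv(values) -> float:
    """Coefficient of variation: sample sd (n−1 denominator) / sample mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("cv needs at least two values")
    m = x.mean()
    if m == 0:
        return np.nan
    return float(x.std(ddof=1) / m)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("pearson_r needs at least three pairs")
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(sps.pearsonr(x, y)[0])


@dataclass
class SummaryStat:
    variable: str
    group: str
    mean: float
    sd: float
    cv: float
    n: int


def summarize(values, variable: str, group: str = "all") -> SummaryStat:
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite values")
    m, s = float(x.mean()), float(x.std(ddof=1))
    return SummaryStat(variable, group, m, s, s / m if m else np.nan, x.size)


# ---------------------------------------------------------------------------
# culture growth
# ---------------------------------------------------------------------------

def ndt_estimate(t, counts, discard: float = 0.0) -> float:
    """Number doubling time from a culture's count-versus-time series.

    Fits ln(count) against time by least squares (after discarding an
    initial transient) and returns ln2/slope in minutes.
    """
    t = np.asarray(t, float)
    n = np.asarray(counts, float)
    keep = (t >= discard) & (n >= 2)
    t, n = t[keep], n[keep]
    if t.size < 3:
        raise ValueError("need at least three usable time points")
    if n[-1] <= n[0]:
        raise ValueError("counts do not increase over the fitted range")
    slope = np.polyfit(t, np.log(n), 1)[0]
    return float(np.log(2.0) / slope)


# ---------------------------------------------------------------------------
# size control
# ---------------------------------------------------------------------------

def size_control_slope(v_bir, t_unbud, mu: float, n_bins: int = 10,
                       v_bud_mean: float | None = None) -> float:
    """Slope of the binned size-control regression.

    x = ln(V_bir/⟨V_bud⟩), y = μ·T_unbud; x is split into equal-count bins,
    bin means are fitted with a straight line and its slope returned.
    A slope near −1 is a strict sizer (pre-Start growth exactly compensates
    birth size); near 0 there is no size control.
    """
    v = np.asarray(v_bir, float)
    tu = np.asarray(t_unbud, float)
    ok = np.isfinite(v) & np.isfinite(tu)
    v, tu = v[ok], tu[ok]
    if v_bud_mean is None:
        v_bud_mean = float(np.mean(v * np.exp(mu * tu)))
    x = np.log(v / v_bud_mean)
    y = mu * tu
    order = np.argsort(x)
    x, y = x[order], y[order]
    edges = np.linspace(0, x.size, n_bins + 1).astype(int)
    bx, by = [], []
    for i in range(n_bins):
        sl = slice(edges[i], edges[i + 1])
        if edges[i + 1] - edges[i] > 0:
            bx.append(x[sl].mean())
            by.append(y[sl].mean())
    if len(bx) < 3:
        raise ValueError("fewer than three non-empty bins")
    return float(np.polyfit(bx, by, 1)[0])


# ---------------------------------------------------------------------------
# mRNA count distribution fits
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Poisson or two-component-Poisson fit of a count histogram."""

    model: str                      # "poisson" | "two_component_poisson"
    params: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    aic: float = np.nan
    n: int = 0
    converged: bool = True


def _poisson_logpmf(k, lam):
    lam = max(lam, 1e-12)
    return k * np.log(lam) - lam - gammaln(k + 1.0)


def fit_poisson(counts) -> MixtureFit:
    """Maximum-likelihood Poisson fit (λ = sample mean)."""
    k = np.asarray(counts)
    if k.size < 1 or np.any(k < 0):
        raise ValueError("counts must be non-negative")
    lam = float(k.mean())
    ll = float(np.sum(_poisson_logpmf(k.astype(float), lam)))
    return MixtureFit("poisson", {"lam": lam}, ll, 2 * 1 - 2 * ll, k.size)


def fit_two_component_poisson(counts, n_restarts: int = 5,
                              tol: float = 1e-8, max_iter: int = 2000,
                              seed: int = 0) -> MixtureFit:
    """Two-component Poisson mixture fit by expectation-maximisation.

    Runs EM from several random starts, keeps the best log-likelihood.
    The mixture is w·Poisson(λ₁) + (1−w)·Poisson(λ₂).
    """
    k = np.asarray(counts, dtype=float)
    if k.size < 2 or np.any(k < 0):
        raise ValueError("need at least two non-negative counts")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if r == 0:
            lam1, lam2 = np.percentile(k, 25) + 0.1, np.percentile(k, 75) + 0.2
            w = 0.5
        else:
            lam1, lam2 = sorted(rng.uniform(0.1, max(k.max(), 1.0), 2))
            lam2 += 0.1
            w = rng.uniform(0.2, 0.8)
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            la = np.log(w) + _poisson_logpmf(k, lam1)
            lb = np.log1p(-w) + _poisson_logpmf(k, lam2)
            norm = logsumexp([la, lb], axis=0)
            ra = np.exp(la - norm)
            ll = float(norm.sum())
            w = float(np.clip(ra.mean(), 1e-9, 1 - 1e-9))
            sa = ra.sum()
            lam1 = float((ra * k).sum() / sa) if sa > 0 else lam1
            sb = (1 - ra).sum()
            lam2 = float(((1 - ra) * k).sum() / sb) if sb > 0 else lam2
            if ll - ll_prev < tol and ll_prev > -np.inf:
                converged = True
                break
            ll_prev = ll
        fit = MixtureFit("two_component_poisson",
                         {"w": w, "lam1": lam1, "lam2": lam2},
                         ll, 2 * 3 - 2 * ll, k.size, converged)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def prefers_mixture(counts, seed: int = 0) -> bool:
    """Model choice between Poisson and the mixture by AIC."""
    return (fit_two_component_poisson(counts, seed=seed).aic
            < fit_poisson(counts).aic)


# ---------------------------------------------------------------------------
# Sic1 decay
# ---------------------------------------------------------------------------

def sic1_halflife(t, sic1_total, floor: float = 0.01,
                  shoulder: float = 0.8, min_points: int = 4) -> float | None:
    """Per-cell Sic1 decay timescale from one single-cycle trajectory.

    Total Sic1 is high through G1 (a plateau), collapses abruptly at Start,
    and is re-synthesised in telophase.  The exponential N(t) = N₀·e^{−t/τ}
    is fitted to the collapse only: the pre-trough peak is located, and the
    fit runs from the last time the signal is above ``shoulder``·peak down
    to max(5, ``floor``·peak) molecules.  Returns the half-life τ·ln2 in
    minutes, or None (flagged) when the series never decays below half its
    peak, so no decay segment exists.
    """
    t = np.asarray(t, float)
    n = np.asarray(sic1_total, float)
    if n.size < min_points:
        return None
    itrough = int(np.argmin(n))
    if itrough < 2:
        return None
    ipk = int(np.argmax(n[:itrough]))
    peak = n[ipk]
    if peak <= 0 or n[itrough] > 0.5 * peak:
        return None
    cutoff = max(5.0, floor * peak)
    below = np.nonzero(n[ipk:itrough + 1] <= cutoff)[0]
    iend = ipk + int(below[0]) if below.size else itrough
    # start at the shoulder: last point still near the plateau level
    above = np.nonzero(n[ipk:iend] >= shoulder * peak)[0]
    istart = ipk + int(above[-1]) if above.size else ipk
    seg_t = t[istart:iend + 1]
    seg_n = n[istart:iend + 1]
    ok = seg_n > 0
    if ok.sum() < min_points:
        return None
    slope = np.polyfit(seg_t[ok], np.log(seg_n[ok]), 1)[0]
    if slope >= 0:
        return None
    return float(-np.log(2.0) / slope)


# ---------------------------------------------------------------------------
# population snapshots
# ---------------------------------------------------------------------------

def snapshot_counts(records, species_groups: dict[str, list[int]],
                    t_stop: float) -> dict[str, np.ndarray]:
    """Per-cell species totals at ``t_stop`` from stored trajectories.

    ``records`` are extant EventRecords whose ``extra['trajectory']`` holds
    the sampled (t, V, bud, dna, counts) arrays; ``species_groups`` maps an
    output name to the list of species indices to sum (e.g. all phospho forms
    and complexes of one protein).  Returns name -> vector over cells.
    """
    out = {name: [] for name in species_groups}
    for r in records:
        traj = r.extra.get("trajectory")
        if traj is None:
            continue
        t_s, v_s, _, _, counts_s = traj
        age = t_stop - r.t_birth
        i = int(np.clip(np.searchsorted(t_s, age), 0, len(t_s) - 1))
        for name, idxs in species_groups.items():
            out[name].append(counts_s[i, idxs].sum())
    return {k: np.asarray(v) for k, v in out.items()}


def activation_cdf(ages) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of gene-activation ages (NaNs dropped)."""
    a = np.asarray(ages, float)
    a = np.sort(a[np.isfinite(a)])
    if a.size == 0:
        return a, a
    return a, np.arange(1, a.size + 1) / a.size


def joint_histogram(x, y, x_max: int | None = None,
                    y_max: int | None = None) -> np.ndarray:
    """2-D count histogram (joint distribution of two mRNA species)."""
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    if x_max is None:
        x_max = int(x.max())
    if y_max is None:
        y_max = int(y.max())
    h = np.zeros((x_max + 1, y_max + 1), dtype=int)
    for xi, yi in zip(x, y):
        if xi <= x_max and yi <= y_max:
            h[xi, yi] += 1
    return h
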