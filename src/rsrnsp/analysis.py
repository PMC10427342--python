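"""Synaptic-connection statistics of the trained network.

Cortical synapses show three robust statistical signatures: lognormal-like
weight distributions, power-law-like distributions of connection
lifetimes, and greater stability of stronger connections.  This module
measures all three on a trained network and its structural-plasticity
event log: connection-fraction bookkeeping, distribution fits
(maximum-likelihood, with Kolmogorov-Smirnov goodness of fit), lifecycle
extraction from birth/death events, and survival-by-strength tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .network import ContractError


class InsufficientDataError(ValueError):
    """Raised when too few samples are available for a distribution fit."""


class LogCorruptionError(ValueError):
    """Raised when a structural-event log is internally inconsistent."""


@dataclass
class ConnectivityLog:
    """Birth/death events of E-E connections over one training run."""

    events: list
    initial_mask: np.ndarray
    final_weights: np.ndarray | None = None

    def replay(self) -> np.ndarray:
        """Apply all events to the initial mask; returns the final mask."""
        mask = self.initial_mask.copy().astype(bool)
        for ev in self.events:
            if ev.kind == "birth":
                mask[ev.i, ev.j] = True
            elif ev.kind == "death":
                mask[ev.i, ev.j] = False
            else:
                raise LogCorruptionError(f"unknown event kind {ev.kind!r}")
        return mask


@dataclass
class DistributionFit:
    """Result of a maximum-likelihood distribution fit."""

    family: str                  # "lognormal" | "powerlaw"
    params: dict = field(default_factory=dict)
    gof: float = 0.0             # Kolmogorov-Smirnov distance
    n_samples: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0.0 <= self.gof <= 1.0:
            raise ValueError("gof must lie in [0, 1]")


def connection_fraction(mask: np.ndarray) -> float:
    """Fraction of possible off-diagonal pairs that are connected."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ContractError("mask must be square")
    if np.any(np.diagonal(mask)):
        raise ContractError("mask has nonzero diagonal (self-connections)")
    n = mask.shape[0]
    return float(np.count_nonzero(mask)) / (n * (n - 1))


def lifecycles(log: ConnectivityLog, horizon: int
               ) -> tuple[list[int], list[int]]:
    """Lifetimes of newly formed connections.

    For each birth the duration until the matching death of the same
    ``(i, j)`` pair; connections still alive at ``horizon`` are
    right-censored and returned separately (censored durations are
    excluded from power-law fitting by default).  Deaths of initial
    (t = 0) connections are not lifecycles; a death with neither a prior
    birth nor an initial connection is log corruption.

    Returns ``(completed, censored)`` duration lists.
    """
    open_birth: dict[tuple[int, int], int] = {}
    alive_initial = {tuple(ij) for ij in np.argwhere(log.initial_mask)}
    completed: list[int] = []
    for ev in log.events:
        key = (ev.i, ev.j)
        if ev.kind == "birth":
            if key in open_birth:
                raise LogCorruptionError(f"double birth for pair {key}")
            open_birth[key] = ev.t
        elif ev.kind == "death":
            if key in open_birth:
                completed.append(ev.t - open_birth.pop(key))
            elif key in alive_initial:
                alive_initial.discard(key)
            else:
                raise LogCorruptionError(f"death without birth for {key}")
        else:
            raise LogCorruptionError(f"unknown event kind {ev.kind!r}")
    censored = [horizon - t0 for t0 in open_birth.values()]
    return completed, censored


def fit_lognormal(weights: np.ndarray) -> DistributionFit:
    """Maximum-likelihood lognormal fit to positive synaptic weights.

    The MLE of a lognormal is the sample mean/std of the log weights; the
    returned ``gof`` is the KS distance between the sample and the fitted
    distribution.  An (almost) all-equal sample is flagged degenerate.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 10:
        raise InsufficientDataError(
            f"need at least 10 positive weights, got {w.size}"
        )
    if np.any(w <= 0):
        raise ContractError("weights must be strictly positive")
    logs = np.log(w)
    mu = float(logs.mean())
    sigma = float(logs.std())
    if sigma < 1e-12:
        return DistributionFit("lognormal",
                               {"mu": mu, "sigma": sigma}, gof=1.0,
                               n_samples=w.size, degenerate=True)
    ks = stats.kstest(w, stats.lognorm(s=sigma, scale=np.exp(mu)).cdf)
    return DistributionFit("lognormal", {"mu": mu, "sigma": sigma},
                           gof=float(ks.statistic), n_samples=w.size)


def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def _powerlaw_mle_alpha(x: np.ndarray, xmin: int) -> float:
    """Discrete power-law exponent by maximising the zeta likelihood."""
    slog = float(np.log(x).sum()) / x.size

    def nll(alpha: float) -> float:
        return np.log(_zeta(alpha, xmin)) + alpha * slog

    res = optimize.minimize_scalar(nll, bounds=(1.01, 12.0),
                                   method="bounded")
    return float(res.x)


def _powerlaw_ks(x: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance of the tail sample against the fitted discrete law."""
    tail = np.sort(x[x >= xmin])
    values = np.unique(tail)
    z = _zeta(alpha, xmin)
    # model CDF at v: 1 - zeta(alpha, v+1)/zeta(alpha, xmin)
    # both CDFs are right-continuous step functions on the integers, so
    # the sup-distance is attained at observed values
    cdf_model = 1.0 - np.array([_zeta(alpha, int(v) + 1) for v in values]) / z
    cdf_emp = np.searchsorted(tail, values, side="right") / tail.size
    return float(np.max(np.abs(cdf_emp - cdf_model)))


def fit_powerlaw(lifetimes, xmin: int | None = None,
                 max_xmin_candidates: int = 50) -> DistributionFit:
    """Discrete power-law MLE for connection lifetimes.

    The exponent maximises the Hurwitz-zeta likelihood; when ``xmin`` is
    not given it is chosen to minimise the KS distance over candidate
    lower cutoffs (the standard tail-selection recipe).  All-identical
    samples are flagged degenerate.
    """
    x = np.asarray(lifetimes, dtype=float)
    if x.size < 50:
        raise InsufficientDataError(
            f"need at least 50 lifetimes, got {x.size}"
        )
    if np.any(x < 1) or np.any(x != np.floor(x)):
        raise ContractError("lifetimes must be positive integers")
    x = x.astype(int)
    if np.unique(x).size == 1:
        return DistributionFit("powerlaw",
                               {"alpha": np.inf, "xmin": int(x[0])},
                               gof=1.0, n_samples=x.size, degenerate=True)
    if xmin is not None:
        alpha = _powerlaw_mle_alpha(x[x >= xmin], xmin)
        return DistributionFit(
            "powerlaw", {"alpha": alpha, "xmin": int(xmin)},
            gof=_powerlaw_ks(x, alpha, xmin), n_samples=int((x >= xmin).sum()))
    candidates = np.unique(x)[:-1]  # need at least 2 distinct tail values
    if candidates.size > max_xmin_candidates:
        idx = np.linspace(0, candidates.size - 1,
                          max_xmin_candidates).astype(int)
        candidates = candidates[idx]
    best = None
    for xm in candidates:
        tail = x[x >= xm]
        if tail.size < 50 or np.unique(tail).size < 2:
            continue
        alpha = _powerlaw_mle_alpha(tail, int(xm))
        ks = _powerlaw_ks(x, alpha, int(xm))
        if best is None or ks < best[0]:
            best = (ks, alpha, int(xm), tail.size)
    if best is None:
        raise InsufficientDataError("no viable tail for power-law fitting")
    ks, alpha, xm, ntail = best
    return DistributionFit("powerlaw", {"alpha": alpha, "xmin": xm},
                           gof=ks, n_samples=ntail)


def survival_by_strength(cohort_weights, survived, n_bins: int = 5):
    """Survival fraction by weight-quantile bin, plus rank association.

    ``cohort_weights`` are connection weights observed at a reference
    time; ``survived`` flags whether each connection was still present at
    the horizon.  Returns ``(table, rank_correlation)`` where ``table``
    has one row per bin: (bin index, median weight, n, survival
    fraction).  The rank correlation (Spearman) is computed between the
    individual weights and survival indicators, so it is meaningful even
    when some bins are constant.
    """
    w = np.asarray(cohort_weights, dtype=float)
    s = np.asarray(survived, dtype=bool)
    if w.size == 0:
        raise ContractError("empty cohort")
    if w.shape != s.shape:
        raise ContractError("weights/survival length mismatch")
    qs = np.quantile(w, np.linspace(0, 1, n_bins + 1))
    qs[-1] = np.inf
    table = []
    for b in range(n_bins):
        in_bin = (w >= qs[b]) & (w < qs[b + 1])
        if not in_bin.any():
            continue
        table.append((b, float(np.median(w[in_bin])), int(in_bin.sum()),
                      float(s[in_bin].mean())))
    if np.unique(w).size < 2 or np.unique(s).size < 2:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(w, s).statistic)
    return table, rho


def plot_weight_distribution(weights, path, n_bins: int = 40) -> None:
    """Histogram of positive weights on log-spaced bins with the fitted
    lognormal curve overlaid; saved to ``path`` (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    edges, counts = weight_histogram(w, n_bins)
    fit = fit_lognormal(w)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    widths = np.diff(edges)
    ax.bar(edges[:-1], counts / (w.size * widths), width=widths,
           align="edge", alpha=0.7, label="synaptic weights")
    if not fit.degenerate:
        xs = np.logspace(np.log10(edges[0]), np.log10(edges[-1]), 200)
        pdf = stats.lognorm(s=fit.params["sigma"],
                            scale=np.exp(fit.params["mu"])).pdf(xs)
        ax.plot(xs, pdf, "r-", label="lognormal fit")
    ax.set_xscale("log")
    ax.set_xlabel("weight")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lifecycle_distribution(lifetimes, path) -> None:
    """Survival-style log-log plot of connection lifetimes with the
    fitted power law overlaid; saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.sort(np.asarray(lifetimes, dtype=int))
    ccdf = 1.0 - np.arange(1, x.size + 1) / x.size
    fit = fit_powerlaw(x)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.loglog(x[:-1], ccdf[:-1], ".", ms=3, label="lifetimes")
    if not fit.degenerate:
        alpha, xmin = fit.params["alpha"], fit.params["xmin"]
        xs = np.unique(x[x >= xmin])
        z = _zeta(alpha, xmin)
        model = np.array([_zeta(alpha, int(v) + 1) for v in xs]) / z
        scale = float(np.mean(x >= xmin))
        ax.loglog(xs, scale * model, "r-",
                  label=f"power law (alpha={alpha:.2f})")
    ax.set_xlabel("lifetime (steps)")
    ax.set_ylabel("P(lifetime > t)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def weight_histogram(weights: np.ndarray, n_bins: int = 40):
    """Log-spaced histogram of positive weights (for weight-distribution
    plots); returns (bin_edges, counts)."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ContractError("no positive weights")
    lo, hi = w.min(), w.max()
    if lo == hi:
        lo, hi = lo * 0.9, hi * 1.1
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[0] = min(edges[0], lo)
    edges[-1] = max(edges[-1], np.nextafter(hi, np.inf))
    counts, _ = np.histogram(w, bins=edges)
    return edges, counts
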