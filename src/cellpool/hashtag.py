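"""Hashtag (cell-hashing) demultiplexing via per-hashtag Gaussian mixtures.

Each hashtag's log10(count+1) distribution over all cells of a run is
bimodal: a low "noise" peak (ambient / non-specific binding across the
pool) and a high "signal" peak (cells actually barcoded with that
hashtag). A two-component univariate Gaussian mixture is fitted per
hashtag by EM, and a cell is called positive for a hashtag when the
odds of the signal component over the noise component reach
``ratio_threshold`` (default 3, inclusive). Cells positive for exactly
one hashtag are assigned to that donor; cells with zero or multiple
positive hashtags are left unassigned (multiplets are labeled, not
silently dropped).

By default the odds are mixing-proportion-weighted posterior odds
pi*N(x; mu_hi, s_hi) / ((1-pi)*N(x; mu_lo, s_lo)), reflecting that a
donor's signal population is a minority of the pooled cells; the
unweighted density ratio is available via ``weighted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DegenerateInputError",
    "HashtagMixtureFit",
    "fit_hashtag_gmm",
    "fit_all_hashtags",
    "hashtag_log_odds",
    "assign_by_hashtag",
    "summarize_hashtag_positivity",
    "log10p1",
]

_SIGMA_FLOOR = 1e-3


class DegenerateInputError(ValueError):
    """Raised when the data cannot support a two-component fit."""


@dataclass
class HashtagMixtureFit:
    """Two-component Gaussian mixture fitted to one hashtag's log-counts.

    Components are relabeled after fitting so that ``mu_hi >= mu_lo``;
    ``pi_hi`` is the signal (high-mean) mixing proportion.
    """

    hashtag_id: str
    mu_lo: float
    sigma_lo: float
    mu_hi: float
    sigma_hi: float
    pi_hi: float
    converged: bool
    n_iter: int
    log_likelihood: float


def log10p1(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """log10(count + 1) transform used throughout the demultiplexer."""
    return np.log10(np.asarray(counts, dtype=float) + 1.0)


def fit_hashtag_gmm(
    log_counts: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    hashtag_id: str = "",
) -> HashtagMixtureFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialization is deterministic and tailored to minority-signal
    mixtures: the noise mean starts at the 25th percentile, the signal mean
    at the 95th, both sds at half the pooled sd, and pi_hi at 0.1. The EM
    log-likelihood is monotone nondecreasing; the fit is flagged converged
    when successive log-likelihood change falls below ``tol``.

    Raises
    ------
    DegenerateInputError
        Fewer than 20 observations or zero variance.
    """
    x = np.asarray(log_counts, dtype=float).ravel()
    n = x.size
    if n < 20:
        raise DegenerateInputError(f"need >= 20 observations, got {n}")
    sd = float(np.std(x))
    if np.ptp(x) == 0.0 or sd == 0.0:
        raise DegenerateInputError("constant input: zero variance")

    mu = np.array([np.percentile(x, 25.0), np.percentile(x, 95.0)])
    if mu[1] - mu[0] < 1e-8:  # heavily skewed data; nudge apart
        mu = np.array([mu[0] - 0.5 * sd, mu[1] + 0.5 * sd])
    sigma = np.array([0.5 * sd, 0.5 * sd])
    sigma = np.maximum(sigma, _SIGMA_FLOOR)
    pi = np.array([0.9, 0.1])

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step (log domain)
        logp = (np.log(pi)[:, None]
                + norm.logpdf(x[None, :], mu[:, None], sigma[:, None]))
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        r = np.exp(logp - lse)  # responsibilities, 2 x n
        # M step
        nk = r.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (r @ x) / nk
        var = (r @ (x * x)) / nk - mu**2
        sigma = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        pi = nk / n
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)  # relabel: component 0 = noise (low mean)
    mu, sigma, pi = mu[order], sigma[order], pi[order]
    return HashtagMixtureFit(
        hashtag_id=hashtag_id,
        mu_lo=float(mu[0]), sigma_lo=float(sigma[0]),
        mu_hi=float(mu[1]), sigma_hi=float(sigma[1]),
        pi_hi=float(pi[1]),
        converged=converged, n_iter=n_iter, log_likelihood=ll,
    )


def fit_all_hashtags(
    counts: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> dict[str, HashtagMixtureFit]:
    """Fit the mixture for every hashtag column of a cells x hashtags matrix."""
    return {
        h: fit_hashtag_gmm(log10p1(counts[h].to_numpy()), tol=tol,
                           max_iter=max_iter, hashtag_id=str(h))
        for h in counts.columns
    }


def hashtag_log_odds(
    x: np.ndarray,
    fit: HashtagMixtureFit,
    weighted: bool = True,
) -> np.ndarray:
    """Log odds of the signal vs noise component at log-count x.

    With ``weighted=True`` (default) this is the posterior odds
    log[pi * N(x; hi)] - log[(1-pi) * N(x; lo)]; otherwise the plain
    density log-ratio.
    """
    x = np.asarray(x, dtype=float)
    lo = norm.logpdf(x, fit.mu_lo, fit.sigma_lo)
    hi = norm.logpdf(x, fit.mu_hi, fit.sigma_hi)
    out = hi - lo
    if weighted:
        out = out + (np.log(fit.pi_hi) - np.log1p(-fit.pi_hi))
    return out


def assign_by_hashtag(
    counts: pd.DataFrame,
    fits: dict[str, HashtagMixtureFit],
    ratio_threshold: float = 3.0,
    weighted: bool = True,
    keep_odds: bool = False,
) -> pd.DataFrame:
    """Call each cell's donor from its positive hashtags.

    Hashtag h is positive for a cell iff its (weighted) signal/noise odds at
    x = log10(count+1) are at least ``ratio_threshold``. ``donor_call`` is
    set only when exactly one hashtag is positive; zero positives yield
    status "negative" and two or more "multiplet", both with a null call.

    Returns a DataFrame indexed like ``counts`` with columns donor_call
    (nullable), n_positive, positive_hashtags (comma-joined), status, and —
    when ``keep_odds`` — one log-odds column per hashtag.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    fits = {str(k): v for k, v in fits.items()}
    missing = [h for h in counts.columns if str(h) not in fits]
    if missing:
        raise KeyError(f"no mixture fit for hashtag(s): {missing}")

    hashtags = list(counts.columns)
    log_thr = np.log(ratio_threshold)
    logodds = np.column_stack([
        hashtag_log_odds(log10p1(counts[h].to_numpy()), fits[str(h)],
                         weighted=weighted)
        for h in hashtags
    ])
    positive = logodds >= log_thr
    n_pos = positive.sum(axis=1)

    ht = np.asarray([str(h) for h in hashtags], dtype=object)
    donor_call = np.where(n_pos == 1, ht[positive.argmax(axis=1)], None)
    status = np.where(n_pos == 0, "negative",
                      np.where(n_pos == 1, "singlet", "multiplet"))
    pos_join = [",".join(ht[row]) for row in positive]

    out = pd.DataFrame({
        "cell_id": counts.index.astype(str),
        "donor_call": donor_call,
        "n_positive": n_pos,
        "positive_hashtags": pos_join,
        "status": status,
    })
    if keep_odds:
        for j, h in enumerate(hashtags):
            out[f"logodds_{h}"] = logodds[:, j]
    return out


def summarize_hashtag_positivity(calls: pd.DataFrame) -> pd.Series:
    """Histogram of the number of positive hashtags per cell.

    Returns a Series indexed by n_positive (0, 1, 2, ...) whose values sum
    to the number of cells.
    """
    if len(calls) == 0:
        return pd.Series(dtype=int, name="n_cells")
    h = calls["n_positive"].value_counts().sort_index()
    h.index.name = "n_positive"
    h.name = "n_cells"
    return h
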