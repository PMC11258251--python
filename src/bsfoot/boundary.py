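"""Single-changepoint estimation on binomial conversion profiles.

The chromatin boundary is formalized as the position where the per-base
conversion probability switches between two regimes.  With per-position
converted counts c_i out of depth d_i, the two-regime model assigns one
binomial proportion to positions before the candidate boundary and another
from the boundary on; the estimator is an exhaustive scan maximizing the
binomial log likelihood over all candidate boundaries (profiles are a few kb,
so the O(n^2) scan is exact and cheap).  Significance against the one-regime
null comes from a permutation test on the scan-max log-likelihood ratio
(exact under exchangeability of positions) or, optionally, a chi-square
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bsmap import ConversionProfile


@dataclass(frozen=True)
class BoundaryCall:
    """Estimated changepoint: first position of the downstream regime."""

    position: int
    p_up_hat: float
    p_down_hat: float
    log_likelihood_ratio: float
    p_value: float
    n_positions_used: int
    plateau: bool  # other candidates within 1 log-likelihood unit of the best
    method: str

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "p_up_hat": self.p_up_hat,
            "p_down_hat": self.p_down_hat,
            "log_likelihood_ratio": self.log_likelihood_ratio,
            "p_value": self.p_value,
            "n_positions_used": self.n_positions_used,
            "plateau": self.plateau,
            "method": self.method,
        }


@dataclass(frozen=True)
class RegimeSummary:
    upstream_max: float
    upstream_mean: float
    downstream_min: float
    downstream_mean: float
    upstream_window: tuple[int, int]
    downstream_window: tuple[int, int]
    n_upstream: int
    n_downstream: int


def _profile_counts(
    profile: ConversionProfile | pd.DataFrame,
    pool_strands: bool,
    strand: str | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    table = profile.table if isinstance(profile, ConversionProfile) else profile
    t = table[table["depth"] > 0]
    if strand is not None:
        t = t[t["strand"] == strand]
    if pool_strands or strand is not None:
        g = t.groupby("pos", as_index=False)[["n_converted", "depth"]].sum()
        pos = g["pos"].to_numpy()
        return pos, g["n_converted"].to_numpy(float), g["depth"].to_numpy(float)
    raise ValueError("set pool_strands=True or pick a strand")


def _binom_ll(c: np.ndarray | float, d: np.ndarray | float) -> np.ndarray | float:
    """Profile log likelihood of pooled counts at the MLE proportion c/d."""
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(c > 0, c * np.log(c / d), 0.0)
        t2 = np.where(d - c > 0, (d - c) * np.log(1.0 - c / d), 0.0)
    return t1 + t2


def _scan_llr(conv: np.ndarray, depth: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Log-likelihood ratio of the two-regime model for every candidate split.

    Candidate k means positions [0, k) are upstream and [k, n) downstream;
    returns LLR for k in [lo, hi).
    """
    c_cum = np.concatenate([[0.0], np.cumsum(conv)])
    d_cum = np.concatenate([[0.0], np.cumsum(depth)])
    ks = np.arange(lo, hi)
    c_up, d_up = c_cum[ks], d_cum[ks]
    c_dn, d_dn = c_cum[-1] - c_up, d_cum[-1] - d_up
    ll2 = _binom_ll(c_up, d_up) + _binom_ll(c_dn, d_dn)
    ll0 = _binom_ll(c_cum[-1], d_cum[-1])
    return ll2 - ll0


def detect_boundary(
    profile: ConversionProfile | pd.DataFrame,
    search_interval: tuple[int, int] | None = None,
    pool_strands: bool = True,
    strand: str | None = None,
    min_side: int = 10,
    method: str = "permutation",
    n_permutations: int = 199,
    seed: int = 0,
) -> BoundaryCall:
    """Locate the conversion-rate changepoint.

    ``search_interval`` restricts candidate boundary positions (1-based,
    inclusive).  Every candidate needs at least ``min_side`` informative
    (depth > 0) positions on each side.  ``method`` is 'permutation' (exact
    under exchangeability; default) or 'chi2' (2*LLR against chi-square df 2,
    a fast approximation that ignores the scan maximization).
    Raises ValueError when too few informative positions remain.
    """
    pos, conv, depth = _profile_counts(profile, pool_strands, strand)
    n = len(pos)
    lo, hi = min_side, n - min_side + 1
    if search_interval is not None:
        s, e = search_interval
        lo = max(lo, int(np.searchsorted(pos, s, side="left")))
        hi = min(hi, int(np.searchsorted(pos, e, side="right")))
    if hi <= lo:
        raise ValueError(
            f"too few informative positions ({n}) for min_side={min_side} "
            f"in the search interval"
        )
    llr = _scan_llr(conv, depth, lo, hi)
    k_rel = int(np.argmax(llr))
    best = float(llr[k_rel])
    k = lo + k_rel
    plateau = bool(np.sum(llr >= best - 1.0) > 1)

    c_cum, d_cum = float(conv.sum()), float(depth.sum())
    c_up, d_up = float(conv[:k].sum()), float(depth[:k].sum())
    p_up_hat = c_up / d_up
    p_down_hat = (c_cum - c_up) / (d_cum - d_up)

    if method == "chi2":
        p_value = float(stats.chi2.sf(2.0 * best, df=2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if float(np.max(_scan_llr(conv[perm], depth[perm], lo, hi))) >= best:
                count += 1
        p_value = (1 + count) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    return BoundaryCall(
        position=int(pos[k]),
        p_up_hat=p_up_hat,
        p_down_hat=p_down_hat,
        log_likelihood_ratio=best,
        p_value=float(p_value),
        n_positions_used=n,
        plateau=plateau,
        method=method,
    )


def regime_summary(
    profile: ConversionProfile | pd.DataFrame,
    boundary_position: int,
    windows: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> RegimeSummary:
    """Max/mean conversion rate upstream and min/mean downstream of a boundary.

    ``windows`` gives explicit 1-based inclusive (upstream, downstream)
    windows; by default the whole profile splits at ``boundary_position``
    (upstream excludes it, downstream includes it).  Only non-NA rates are
    used; an all-NA or empty window raises ValueError.
    """
    table = profile.table if isinstance(profile, ConversionProfile) else profile
    pmin, pmax = int(table["pos"].min()), int(table["pos"].max())
    if not pmin <= boundary_position <= pmax:
        raise ValueError(f"boundary {boundary_position} outside profile {pmin}-{pmax}")
    if windows is None:
        windows = ((pmin, boundary_position - 1), (boundary_position, pmax))
    (u0, u1), (d0, d1) = windows
    rates = {}
    for name, (a, b) in (("upstream", (u0, u1)), ("downstream", (d0, d1))):
        sel = table[(table["pos"] >= a) & (table["pos"] <= b)]["rate_pct"].dropna()
        if sel.empty:
            raise ValueError(f"{name} window {a}-{b} has no usable positions")
        rates[name] = sel
    return RegimeSummary(
        upstream_max=float(rates["upstream"].max()),
        upstream_mean=float(rates["upstream"].mean()),
        downstream_min=float(rates["downstream"].min()),
        downstream_mean=float(rates["downstream"].mean()),
        upstream_window=(u0, u1),
        downstream_window=(d0, d1),
        n_upstream=int(len(rates["upstream"])),
        n_downstream=int(len(rates["downstream"])),
    )
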