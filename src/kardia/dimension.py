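"""Correlation dimension (D2) of an RR series, Grassberger–Procaccia style.

The RR sequence is delay-embedded into m-dimensional vectors
``u_j = (RR_j, RR_{j+τ}, …, RR_{j+(m−1)τ})`` and the correlation integral

    C(r) = (2 / P) · #{(j, k) : k − j > w, ‖u_j − u_k‖ < r}

is evaluated on a log-spaced radius grid, with a Theiler window ``w``
excluding temporally adjacent pairs and
``P = (N_v − w)(N_v − w − 1)`` admissible ordered-pair slots.  D2 is the
slope of log C against log r over the scaling region, found as the
contiguous run of curve points whose local slopes have minimal variance.

Defaults follow short-term HRV practice: embedding dimension m = 10,
delay τ = 1 beat, Euclidean norm, Theiler window m·τ, and a radius grid
scaled by the dispersion of the embedded components so the estimate is
invariant under affine rescaling of the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .io import RRSeries
from .preprocess import InsufficientDataError

__all__ = [
    "EmbeddingConfig",
    "D2Result",
    "embed",
    "correlation_sum",
    "estimate_d2",
    "d2",
]

#: curve points with C above this are the saturated large-r tail (log C
#: flattens towards 0) and are excluded from the plateau search
SATURATION_C = 0.9
#: minimum admissible pair count for a curve point to enter the plateau
#: search (below this the small-r statistics are too sparse to trust)
MIN_PAIRS = 10
#: candidate scaling runs scoring within this factor of the best relative
#: slope dispersion are considered equivalent; the largest-radius one wins
PLATEAU_TOLERANCE = 5.0


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding and correlation-integral parameters.

    ``theiler=None`` resolves to ``m·tau``.  The radius grid is log-spaced
    over ``[r_lo_sigma·σ, r_hi_sigma·σ]`` where σ is the SD of the embedded
    vector components.
    """

    m: int = 10
    tau: int = 1
    theiler: int | None = None
    norm: str = "euclidean"
    r_grid: int = 30
    r_lo_sigma: float = 0.05
    r_hi_sigma: float = 2.5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be ≥ 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"delay tau must be ≥ 1, got {self.tau}")
        if self.theiler is not None and self.theiler < 0:
            raise ValueError("theiler window must be ≥ 0")
        if self.norm not in {"euclidean", "chebyshev"}:
            raise ValueError(f"norm must be 'euclidean' or 'chebyshev', got {self.norm!r}")
        if self.r_grid < 10:
            raise ValueError("r_grid must have ≥ 10 radii")

    @property
    def theiler_resolved(self) -> int:
        return self.m * self.tau if self.theiler is None else self.theiler


@dataclass
class D2Result:
    """Correlation-dimension estimate with its diagnostic curve.

    ``quality_flag`` is ``"ok"`` when a scaling plateau was found,
    ``"no_plateau"`` when the global mid-half fallback fit was used, and
    ``"degenerate"`` for (near-)constant series where D2 is reported as 0.
    """

    d2: float
    log_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    log_c: np.ndarray = field(default_factory=lambda: np.empty(0))
    local_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    scaling_region: tuple[int, int] | None = None
    quality_flag: str = "ok"
    config: EmbeddingConfig | None = None


def embed(series: RRSeries | np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed a series into an ``(N_v, m)`` array of state vectors.

    ``N_v = N − (m−1)·τ``; at least two vectors are required.
    """
    x = series.intervals if isinstance(series, RRSeries) else np.asarray(series, float)
    n = x.size
    n_v = n - (m - 1) * tau
    if n_v < 2:
        raise InsufficientDataError(
            f"series of length {n} yields {max(n_v, 0)} embedded vectors; "
            f"need N ≥ {(m - 1) * tau + 2} for m={m}, tau={tau}"
        )
    idx = np.arange(n_v)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _radius_grid(vectors: np.ndarray, config: EmbeddingConfig) -> np.ndarray:
    sigma = float(np.std(vectors))
    if sigma == 0:
        sigma = 1.0  # degenerate cloud; grid value is immaterial
    return np.logspace(
        np.log10(config.r_lo_sigma * sigma),
        np.log10(config.r_hi_sigma * sigma),
        config.r_grid,
    )


def correlation_sum(
    vectors: np.ndarray,
    r_grid: np.ndarray,
    theiler: int = 0,
    norm: str = "euclidean",
) -> np.ndarray:
    """Correlation integral C(r) for each radius in ``r_grid``.

    Counts ordered pairs ``(j, k)`` with ``k − j > theiler`` and distance
    strictly below r, normalised by ``(N_v − w)(N_v − w − 1)`` so that a
    fully recurrent cloud reaches C = 1.  Monotone non-decreasing in r.
    """
    n_v = vectors.shape[0]
    if n_v < 2:
        raise InsufficientDataError("correlation sum needs ≥ 2 vectors")
    w = theiler
    p_slots = (n_v - w) * (n_v - w - 1)
    if p_slots <= 0:
        return np.full(len(r_grid), np.nan)
    metric = "euclidean" if norm == "euclidean" else "chebyshev"
    dists = pdist(vectors, metric=metric)
    if w > 0:
        # condensed-form index separation |j-k| for each pdist entry
        j, k = np.triu_indices(n_v, k=1)
        dists = dists[(k - j) > w]
    dists = np.sort(dists)
    counts = np.searchsorted(dists, r_grid, side="left")  # strict '<'
    return 2.0 * counts / p_slots


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def estimate_d2(
    log_r: np.ndarray,
    log_c: np.ndarray,
    m_cap: float = np.inf,
    min_run: int = 5,
    pair_counts: np.ndarray | None = None,
) -> D2Result:
    """Fit D2 from a correlation-integral curve.

    Local slopes come from centred finite differences on the finite part of
    the curve.  The scaling region is the contiguous run of at least
    ``min_run`` points minimising the variance of the local slopes, searched
    over the usable part of the curve — points with C > 0, below the
    saturation level ``C = 0.9`` (where log C flattens toward zero) and with
    at least 10 counted pairs (when ``pair_counts`` is given).  D2 is the
    least-squares slope over that run, clipped to ``[0, m_cap]``.

    Fallbacks: no usable run → ``no_plateau`` flag with a fit over the
    middle half of the finite curve; fewer than 2 finite points →
    ``degenerate`` with D2 = 0.
    """
    log_r = np.asarray(log_r, float)
    log_c = np.asarray(log_c, float)
    finite = np.isfinite(log_c) & np.isfinite(log_r)
    c_vals = np.exp(log_c)
    usable = finite & (c_vals <= SATURATION_C)
    if pair_counts is not None:
        usable &= np.asarray(pair_counts) >= MIN_PAIRS
    if finite.sum() < 2 or usable.sum() < 2:
        return D2Result(d2=0.0, log_r=log_r, log_c=log_c,
                        quality_flag="degenerate")

    ur, uc = log_r[usable], log_c[usable]
    order = np.argsort(ur)
    ur, uc = ur[order], uc[order]
    slopes = np.gradient(uc, ur)

    # Runs are scored by the *relative* dispersion of their local slopes,
    # var/mean²: a plain variance minimum is hijacked by lacunarity steps of
    # periodic attractors, whose flat (slope ≈ 0) stretches have tiny
    # variance but carry no scaling information.  Runs with non-positive
    # mean slope are never scaling regions (C is non-decreasing).  Among
    # runs scoring within a factor 2 of the best, the one ending at the
    # largest radius wins: measurement noise inflates distances below its
    # own scale, so the attractor's scaling region sits above the noise
    # floor, at the large-r end of the comparable candidates.
    candidates: list[tuple[float, int, int]] = []  # (score, start, length)
    n = ur.size
    if n >= min_run:
        for length in range(min_run, n + 1):
            for start in range(0, n - length + 1):
                run = slopes[start:start + length]
                mean = float(np.mean(run))
                if mean <= 1e-3:
                    continue
                score = float(np.var(run)) / mean**2
                candidates.append((score, start, length))
    if candidates:
        best_score = min(c[0] for c in candidates)
        threshold = max(PLATEAU_TOLERANCE * best_score, best_score + 1e-3)
        score_, start, length = max(
            (c for c in candidates if c[0] <= threshold),
            key=lambda c: (c[1] + c[2], c[2]),  # latest end, then longest
        )
        stop = start + length
        slope = _ols_slope(ur[start:stop], uc[start:stop])
        flag = "ok"
        region = (start, stop)
    else:
        # mid-half fallback over the finite curve
        fr, fc = log_r[finite], log_c[finite]
        lo, hi = fr.size // 4, max(fr.size // 4 + 2, (3 * fr.size) // 4)
        slope = _ols_slope(fr[lo:hi], fc[lo:hi])
        flag = "no_plateau"
        region = None
        slopes = np.gradient(fc, fr) if fr.size > 1 else np.empty(0)

    d2_val = float(np.clip(slope, 0.0, m_cap))
    if not np.isclose(slope, d2_val) and slope > m_cap:
        flag = "no_plateau"
    return D2Result(d2=d2_val, log_r=log_r, log_c=log_c, local_slopes=slopes,
                    scaling_region=region, quality_flag=flag)


def d2(series: RRSeries | np.ndarray,
       config: EmbeddingConfig | None = None) -> D2Result:
    """Correlation dimension of an RR series (embed → C(r) → slope fit).

    A constant (or numerically constant) series is a single-point attractor:
    D2 = 0 with the ``degenerate`` flag.  The estimate is capped at the
    embedding dimension m — larger values are estimation artifacts.
    """
    config = config or EmbeddingConfig()
    x = series.intervals if isinstance(series, RRSeries) else np.asarray(series, float)
    if float(np.std(x)) < 1e-12 * max(1.0, abs(float(np.mean(x)))):
        return D2Result(d2=0.0, quality_flag="degenerate", config=config)
    vectors = embed(x, config.m, config.tau)
    r_grid = _radius_grid(vectors, config)
    c_vals = correlation_sum(vectors, r_grid, theiler=config.theiler_resolved,
                             norm=config.norm)
    if not np.any(c_vals > 0):
        return D2Result(d2=0.0, quality_flag="degenerate", config=config)
    with np.errstate(divide="ignore"):
        log_c = np.log(c_vals)
    n_v = vectors.shape[0]
    w = config.theiler_resolved
    pair_counts = c_vals * (n_v - w) * (n_v - w - 1) / 2.0
    result = estimate_d2(np.log(r_grid), log_c, m_cap=float(config.m),
                         pair_counts=pair_counts)
    result.config = config
    return result
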