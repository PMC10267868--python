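"""Genetic-map functions: evaluation, least-squares fitting and selection.

A genetic-map function relates map distance d (Morgan) to recombination
fraction θ under an assumed model of crossover interference.  Four
single-parameter families are supported:

``haldane_scaled``
    θ = ½(1 − e^{−2ad}), a > 0.  Haldane's no-interference function with a
    free rate scale; a = 1 is classical Haldane.
``karlin_binomial``
    θ = ½[1 − (1 − 2d/N)^N] for d ≤ N/2, else ½; the count-location model
    with at most N crossovers.  N ∈ {2, 3, 4, 5} by grid search when
    fitting; N → ∞ recovers Haldane.
``felsenstein``
    θ = (1 − e^{−2(2−K)d}) / (2[1 − (K−1)e^{−2(2−K)d}]), K ∈ [0, 2);
    K = 0 is Kosambi, K = 1 is Haldane.
``rao``
    Rao's interpolation system, a ∈ [0, 1], expressed as a distance
    function d(θ | a); the forward value θ(d) is obtained by bracketed
    root finding.  Special cases: a = 0 Morgan (complete interference),
    a = ¼ Carter–Falconer, a = ½ Kosambi, a = 1 Haldane.

Fitting minimises the sum of squared deviations Σ (θ̂_ij − f(d_ij | a))²
over marker pairs, by bounded scalar minimisation (Brent) for the
continuous families and exhaustive search over N for the binomial family.
The family with the smallest SSE is the "best" map function.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

log = logging.getLogger(__name__)

#: fixed family order used for reporting and tie-breaking
FAMILIES = ("haldane_scaled", "rao", "felsenstein", "karlin_binomial")

#: fitting domains; the binomial family is a discrete grid
DOMAINS = {
    "haldane_scaled": (1e-6, 100.0),
    "rao": (0.0, 1.0),
    "felsenstein": (0.0, 2.0 - 1e-6),
}
KARLIN_GRID = (2, 3, 4, 5)

_RAO_THETA_SUP = 0.5 - 1e-13


def _check_d(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance d must be non-negative")
    return d


def haldane_scaled_theta(d, a) -> np.ndarray:
    if not a > 0:
        raise ValueError("haldane_scaled requires a > 0")
    return 0.5 * (1.0 - np.exp(-2.0 * a * _check_d(d)))


def karlin_theta(d, n) -> np.ndarray:
    if n != int(n) or n < 2:
        raise ValueError("karlin_binomial requires integer N >= 2")
    n = int(n)
    d = _check_d(d)
    base = np.clip(1.0 - 2.0 * d / n, 0.0, None)
    return 0.5 * (1.0 - base ** n)


def felsenstein_theta(d, k) -> np.ndarray:
    if not (0.0 <= k < 2.0):
        raise ValueError("felsenstein requires K in [0, 2)")
    d = _check_d(d)
    e = np.exp(-2.0 * (2.0 - k) * d)
    return (1.0 - e) / (2.0 * (1.0 - (k - 1.0) * e))


def rao_distance(theta, a) -> np.ndarray:
    """Rao's map distance d(θ | a), the inverse of the map function.

    Interpolates Morgan (a=0), Carter–Falconer (a=¼), Kosambi (a=½) and
    Haldane (a=1).  Defined for θ ∈ [0, ½).
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError("rao requires a in [0, 1]")
    theta = np.asarray(theta, dtype=float)
    if (theta < 0).any() or (theta >= 0.5).any():
        raise ValueError("rao_distance requires theta in [0, 0.5)")
    t2 = 2.0 * theta
    c_log = a * (2 * a - 1) * (1 - 4 * a) / 6.0
    c_atan = 8 * a * (a - 1) * (2 * a - 1) / 3.0
    c_atanh = 2 * a * (1 - a) * (4 * a + 1) / 3.0
    c_lin = (1 - a) * (1 - 2 * a) * (1 - 4 * a)
    return (
        c_log * np.log1p(-t2)
        + c_atan * np.arctan(t2)
        + c_atanh * np.arctanh(t2)
        + c_lin * theta
    )


def _rao_distance_scalar(theta: float, a: float) -> float:
    """Scalar Rao distance via :mod:`math`, the root-finder workhorse."""
    t2 = 2.0 * theta
    return (
        a * (2 * a - 1) * (1 - 4 * a) / 6.0 * math.log1p(-t2)
        + 8 * a * (a - 1) * (2 * a - 1) / 3.0 * math.atan(t2)
        + 2 * a * (1 - a) * (4 * a + 1) / 3.0 * math.atanh(t2)
        + (1 - a) * (1 - 2 * a) * (1 - 4 * a) * theta
    )


def rao_theta(d, a) -> np.ndarray:
    """Forward Rao map function θ(d | a) by bracketed root finding.

    ``rao_distance`` is strictly increasing in θ for a ∈ [0, 1], so each
    value is found by Brent's method on [0, ½) to absolute tolerance 1e−10
    (the root finder is run to 1e−12).  Distances beyond the representable
    range saturate at ½.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError("rao requires a in [0, 1]")
    d = _check_d(d)
    scalar = d.ndim == 0
    flat = np.atleast_1d(d).ravel()
    d_sup = _rao_distance_scalar(_RAO_THETA_SUP, a)
    out = np.empty(flat.shape)
    # cache roots: fitting evaluates the same distances repeatedly
    seen: dict[float, float] = {}
    for i, di in enumerate(flat):
        di = float(di)
        if di in seen:
            out[i] = seen[di]
            continue
        if di <= 0:
            val = 0.0
        elif di >= d_sup:
            val = 0.5
        else:
            val = optimize.brentq(
                lambda t: _rao_distance_scalar(t, a) - di, 0.0, _RAO_THETA_SUP,
                xtol=1e-12, maxiter=200,
            )
        seen[di] = val
        out[i] = val
    if scalar:
        return float(out[0])
    return out.reshape(d.shape)


_THETA_FUNCS = {
    "haldane_scaled": haldane_scaled_theta,
    "rao": rao_theta,
    "felsenstein": felsenstein_theta,
    "karlin_binomial": karlin_theta,
}


def theta(family: str, d, param) -> np.ndarray:
    """Evaluate a map-function family at distance d (Morgan)."""
    try:
        fn = _THETA_FUNCS[family]
    except KeyError:
        raise ValueError(f"unknown map-function family {family!r}; "
                         f"choose from {FAMILIES}") from None
    return fn(d, param)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class MapFunctionFit:
    """Result of fitting one family to (d, θ̂) pairs."""

    family: str
    parameter: float
    sse: float
    mse: float
    n_pairs: int
    converged: bool
    at_boundary: bool = False
    pairs_key: str = ""

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def _pairs_key(d: np.ndarray, th: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(d, dtype=float).tobytes())
    h.update(np.ascontiguousarray(th, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _clean_pairs(d, theta_hat, weights):
    d = np.asarray(d, dtype=float)
    th = np.asarray(theta_hat, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    if d.shape != th.shape:
        raise ValueError("d and theta_hat must have the same length")
    keep = np.isfinite(d) & np.isfinite(th)
    dropped = int((~keep).sum())
    if dropped:
        log.info("fit: skipping %d pairs with non-finite values", dropped)
    d, th = d[keep], th[keep]
    if w is not None:
        w = w[keep]
    if d.size == 0:
        raise ValueError("no finite (d, theta) pairs to fit")
    if (d < 0).any():
        raise ValueError("map distances must be non-negative")
    return d, th, w


def sse(family: str, d, theta_hat, param, weights=None) -> float:
    """Sum of squared deviations Σ w (θ̂ − f(d | a))²."""
    resid = np.asarray(theta_hat, dtype=float) - theta(family, d, param)
    if weights is not None:
        resid = resid * np.sqrt(np.asarray(weights, dtype=float))
    return float(np.dot(resid, resid))


def fit(d, theta_hat, family: str, weights=None, xatol: float = 1e-10) -> MapFunctionFit:
    """Fit one map-function family by least squares.

    Continuous families use bounded Brent minimisation over the family's
    admissible domain; the binomial family is an exhaustive grid over
    N ∈ {2, 3, 4, 5}.  The fit is unweighted unless per-pair weights (for
    example informative-meiosis counts) are supplied.  Deterministic.
    """
    d, th, w = _clean_pairs(d, theta_hat, weights)
    key = _pairs_key(d, th)
    n = d.size
    if family == "karlin_binomial":
        sses = [sse(family, d, th, N, w) for N in KARLIN_GRID]
        best = int(np.argmin(sses))
        return MapFunctionFit(family, float(KARLIN_GRID[best]), sses[best],
                              sses[best] / n, n, True, False, key)
    if family not in DOMAINS:
        raise ValueError(f"unknown map-function family {family!r}")
    lo, hi = DOMAINS[family]
    res = optimize.minimize_scalar(
        lambda a: sse(family, d, th, a, w),
        bounds=(lo, hi), method="bounded", options={"xatol": xatol},
    )
    # bounded Brent never evaluates the endpoints themselves; when the
    # minimum sits on the domain boundary the exact endpoint is better
    candidates = [(float(res.fun), float(res.x))]
    for edge in (lo, hi):
        try:
            candidates.append((sse(family, d, th, edge, w), edge))
        except (ValueError, FloatingPointError):  # pragma: no cover
            pass
    val, a_hat = min(candidates)
    span = hi - lo
    at_boundary = (a_hat - lo) < 1e-5 * span or (hi - a_hat) < 1e-5 * span
    return MapFunctionFit(family, a_hat, val, val / n, n,
                          bool(res.success) and not at_boundary, at_boundary, key)


def fit_all(d, theta_hat, families=FAMILIES, weights=None) -> list[MapFunctionFit]:
    return [fit(d, theta_hat, fam, weights=weights) for fam in families]


def select_best(fits: list[MapFunctionFit]) -> tuple[str, list[MapFunctionFit]]:
    """Pick the family with minimal SSE; return (winner, ranked fits).

    All fits must come from the identical pair set.  Exact SSE ties are
    broken by the fixed family order (haldane_scaled, rao, felsenstein,
    karlin_binomial); a tie is logged.
    """
    if len(fits) < 2:
        raise ValueError("select_best needs at least 2 fits")
    keys = {f.pairs_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different pair sets")
    order = {fam: i for i, fam in enumerate(FAMILIES)}
    ranked = sorted(fits, key=lambda f: (f.sse, order.get(f.family, 99)))
    if len(ranked) > 1 and ranked[0].sse == ranked[1].sse:
        log.warning("SSE tie between %s and %s; fixed order applied",
                    ranked[0].family, ranked[1].family)
    return ranked[0].family, ranked


# ---------------------------------------------------------------------------
# Scatter thinning
# ---------------------------------------------------------------------------

def thin_scatter(points, n_keep: int = 200_000):
    """Thin an ordered (d, θ̂) scatter by consecutive Euclidean distance.

    Points must already be ordered (pairwise tables use the column-major
    vectorisation of the upper triangle of the SNP × SNP matrix).  Each
    point scores the Euclidean distance to its predecessor (the first point
    scores +∞ so it is always kept); the ``n_keep`` highest-scoring points
    are retained, ties broken toward the earlier index, and returned in the
    original order.  Inputs of at most ``n_keep`` points pass through
    unchanged.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d, theta)")
    n = pts.shape[0]
    if n <= n_keep:
        return pts.copy(), np.arange(n)
    dist = np.empty(n)
    dist[0] = np.inf
    dist[1:] = np.hypot(*(pts[1:] - pts[:-1]).T)
    # stable sort on -dist keeps earlier indices first among ties
    chosen = np.sort(np.argsort(-dist, kind="stable")[:n_keep])
    return pts[chosen], chosen
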