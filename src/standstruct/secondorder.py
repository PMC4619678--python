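"""Uni- and bivariate Ripley K/L functions, envelopes, scale classification.

The univariate estimator is

    K(r) = (A / n^2) * sum_{i != j} w_ij * 1(d_ij < r)

with ``A`` the window area and ``w_ij`` an edge-correction weight.  Its
variance-stabilised transform L(r) = sqrt(K(r)/pi) - r is 0 under complete
spatial randomness (CSR), positive where the pattern is clustered and
negative where it is regular.

The bivariate (cross-type) estimator for point types i and j is

    K_ij(r) = (A / (n_i * n_j)) * sum_{k in i, l in j} w_kl * 1(d_kl < r)

and, because K_ij and K_ji differ only through edge effects, the symmetric
combination K_B = (n_i K_ij + n_j K_ji) / (n_i + n_j) is used.  Its L
transform is 0 under independence of the two types, positive for
aggregation, negative for repulsion.

Departure from the null is read off pointwise Monte-Carlo envelopes: CSR
re-scatters of the same point count for the univariate function, and
Lotwick-Silverman toroidal shifts of one type against the other for the
bivariate one.

Edge corrections: ``isotropic`` (Ripley's circumference-fraction weight,
default), ``translation``, or ``none``.  The isotropic weight for a
rectangle is the reciprocal of the fraction of the circle of radius d_ij
around point i that lies inside the window; it is exact for r up to half
the shorter window side, which bounds the distance grid anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .pattern import PatternError, PlotPattern, PlotWindow

#: Default distance grid: 0-12 m in 0.25 m steps (upper bound from the
#: 50 x 50 m plots: r_max must stay below half the shorter side).
R_MAX_DEFAULT = 12.0
R_STEP_DEFAULT = 0.25

CORRECTIONS = ("isotropic", "translation", "none")


def distance_grid(r_max: float = R_MAX_DEFAULT,
                  step: float = R_STEP_DEFAULT,
                  window: PlotWindow | None = None) -> np.ndarray:
    """Strictly increasing grid of distances (step, 2*step, ..., r_max)."""
    if r_max <= 0 or step <= 0:
        raise PatternError("r_max and step must be positive")
    if window is not None and r_max > window.shorter_side / 2:
        raise PatternError(
            f"r_max={r_max} exceeds half the shorter window side "
            f"({window.shorter_side / 2})"
        )
    return np.arange(step, r_max + step / 2, step)


@dataclass(frozen=True)
class SecondOrderResult:
    """K or L values on a distance grid."""

    kind: str                 # "K_U", "L_U", "K_B", "L_B"
    grid: np.ndarray
    values: np.ndarray
    correction: str
    n: int | None = None          # univariate point count
    n_i: int | None = None        # bivariate type counts
    n_j: int | None = None
    k_ij: np.ndarray | None = None
    k_ji: np.ndarray | None = None


@dataclass(frozen=True)
class Envelope:
    """Pointwise Monte-Carlo envelope of an L function."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sim: int
    level: float
    null: str                 # "CSR" or "independence-shift"
    seed: int | None = None


@dataclass(frozen=True)
class ScaleClassification:
    """Per-distance envelope comparison and its verbal verdict."""

    grid: np.ndarray
    labels: np.ndarray        # "below" / "inside" / "above" per grid point
    verdict: str


@dataclass(frozen=True)
class DCutScan:
    """Scan of the small/large diameter split threshold."""

    thresholds: np.ndarray    # candidate d_cut values (cm)
    scores: np.ndarray        # aggregation-excess score per candidate
    chosen: float             # arg-max threshold (ties -> smallest)
    significant: bool         # False when no candidate shows any excess


# ---------------------------------------------------------------------------
# Edge-correction weights
# ---------------------------------------------------------------------------

def _isotropic_weight(xy_i: np.ndarray, d: np.ndarray,
                      window: PlotWindow) -> np.ndarray:
    """Ripley's isotropic weight per ordered pair, centred on point i.

    Reciprocal of the fraction of the circle of radius ``d`` around point i
    inside the rectangular window.  Valid for d < half the shorter side,
    where at most one corner of the rectangle can fall inside the circle.
    """
    d = np.asarray(d, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dl = xy_i[:, 0] - window.x_min
        dr = window.x_max - xy_i[:, 0]
        db = xy_i[:, 1] - window.y_min
        dt = window.y_max - xy_i[:, 1]
        out = np.zeros_like(d)
        for e in (dl, dr, db, dt):
            ratio = np.clip(e / d, -1.0, 1.0)
            out += np.where(e < d, 2.0 * np.arccos(ratio), 0.0)
        # subtract the double-counted arc beyond each corner
        for ex, ey in ((dl, db), (dl, dt), (dr, db), (dr, dt)):
            inside = ex**2 + ey**2 < d**2
            corner = (np.pi / 2
                      - np.arcsin(np.clip(ex / d, -1.0, 1.0))
                      - np.arcsin(np.clip(ey / d, -1.0, 1.0)))
            out -= np.where(inside, corner, 0.0)
    return 2.0 * np.pi / (2.0 * np.pi - out)


def _translation_weight(dxy: np.ndarray, window: PlotWindow) -> np.ndarray:
    """Translation-correction weight A / ((W-|dx|) (H-|dy|)) per pair."""
    wx = window.width - np.abs(dxy[:, 0])
    wy = window.height - np.abs(dxy[:, 1])
    return window.area / (wx * wy)


def _pair_weights(xy_a: np.ndarray, xy_b: np.ndarray, window: PlotWindow,
                  correction: str):
    """Flattened ordered-pair distances and weights between two point sets.

    When the two sets are the same object, self-pairs are excluded.
    """
    diff = xy_a[:, None, :] - xy_b[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    if xy_a is xy_b:
        mask = ~np.eye(len(xy_a), dtype=bool)
    else:
        mask = np.ones(d.shape, dtype=bool)
    ii, jj = np.nonzero(mask)
    dist = d[ii, jj]
    if correction == "none":
        w = np.ones_like(dist)
    elif correction == "translation":
        w = _translation_weight(diff[ii, jj], window)
    elif correction == "isotropic":
        w = _isotropic_weight(xy_a[ii], dist, window)
    else:
        raise PatternError(f"unknown edge correction {correction!r}; "
                           f"choose from {CORRECTIONS}")
    return dist, w


def _k_from_pairs(dist: np.ndarray, weights: np.ndarray, grid: np.ndarray,
                  norm: float) -> np.ndarray:
    """K(r) = norm * sum w * 1(d < r), evaluated on the whole grid at once."""
    order = np.argsort(dist)
    d_sorted = dist[order]
    cum = np.concatenate([[0.0], np.cumsum(weights[order])])
    pos = np.searchsorted(d_sorted, grid, side="left")   # strict d < r
    return norm * cum[pos]


def _k_univariate_xy(xy: np.ndarray, window: PlotWindow, grid: np.ndarray,
                     correction: str) -> np.ndarray:
    dist, w = _pair_weights(xy, xy, window, correction)
    return _k_from_pairs(dist, w, grid, window.area / len(xy) ** 2)


def _k_bivariate_xy(xy_i: np.ndarray, xy_j: np.ndarray, window: PlotWindow,
                    grid: np.ndarray, correction: str):
    """(K_ij, K_ji, K_B) for two disjoint point sets."""
    n_i, n_j = len(xy_i), len(xy_j)
    d_ij, w_ij = _pair_weights(xy_i, xy_j, window, correction)
    k_ij = _k_from_pairs(d_ij, w_ij, grid, window.area / (n_i * n_j))
    d_ji, w_ji = _pair_weights(xy_j, xy_i, window, correction)
    k_ji = _k_from_pairs(d_ji, w_ji, grid, window.area / (n_i * n_j))
    k_b = (n_i * k_ij + n_j * k_ji) / (n_i + n_j)
    return k_ij, k_ji, k_b


def _l_transform(k: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.sqrt(k / np.pi) - grid


# ---------------------------------------------------------------------------
# Public estimators
# ---------------------------------------------------------------------------

def ripley_k_univariate(pattern: PlotPattern, grid: np.ndarray | None = None,
                        correction: str = "isotropic") -> SecondOrderResult:
    """Univariate Ripley K on a distance grid."""
    if pattern.n < 2:
        raise PatternError(f"plot {pattern.code}: K needs at least 2 trees")
    grid = distance_grid(window=pattern.window) if grid is None else np.asarray(grid)
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise PatternError("distance grid must be non-negative and increasing")
    values = _k_univariate_xy(pattern.xy, pattern.window, grid, correction)
    return SecondOrderResult("K_U", grid, values, correction, n=pattern.n)


def l_univariate(result: SecondOrderResult) -> SecondOrderResult:
    """Besag's L transform of a univariate K result."""
    if result.kind != "K_U":
        raise PatternError(f"expected a K_U result, got {result.kind}")
    if np.any(result.values < 0):
        raise PatternError("negative K values cannot be L-transformed")
    return replace(result, kind="L_U",
                   values=_l_transform(result.values, result.grid))


def _resolve_group(pattern: PlotPattern, selector) -> np.ndarray:
    """Boolean tree mask from a species label, a label set, or a mask."""
    if isinstance(selector, str) or (isinstance(selector, (set, frozenset, list, tuple))
                                     and all(isinstance(s, str) for s in selector)):
        return pattern.species_mask(selector)
    mask = np.asarray(selector)
    if mask.dtype != bool:
        out = np.zeros(pattern.n, dtype=bool)
        out[mask] = True
        return out
    return mask


def ripley_k_bivariate(pattern: PlotPattern, type_i, type_j,
                       grid: np.ndarray | None = None,
                       correction: str = "isotropic") -> SecondOrderResult:
    """Cross-type Ripley K between two disjoint tree groups.

    ``type_i``/``type_j`` may be species labels, label sets, or boolean/index
    masks over the trees.  Returns the symmetric combination ``K_B`` with the
    directional estimates ``k_ij``/``k_ji`` attached.
    """
    mask_i = _resolve_group(pattern, type_i)
    mask_j = _resolve_group(pattern, type_j)
    if np.any(mask_i & mask_j):
        raise PatternError("type_i and type_j overlap; groups must be disjoint")
    for name, m in (("type_i", mask_i), ("type_j", mask_j)):
        if not m.any():
            raise PatternError(f"plot {pattern.code}: {name} selects no trees")
    grid = distance_grid(window=pattern.window) if grid is None else np.asarray(grid)
    xy = pattern.xy
    k_ij, k_ji, k_b = _k_bivariate_xy(xy[mask_i], xy[mask_j], pattern.window,
                                      grid, correction)
    return SecondOrderResult("K_B", grid, k_b, correction,
                             n_i=int(mask_i.sum()), n_j=int(mask_j.sum()),
                             k_ij=k_ij, k_ji=k_ji)


def l_bivariate(result: SecondOrderResult) -> SecondOrderResult:
    """L transform of a bivariate K_B result."""
    if result.kind != "K_B":
        raise PatternError(f"expected a K_B result, got {result.kind}")
    if np.any(result.values < 0):
        raise PatternError("negative K values cannot be L-transformed")
    return replace(result, kind="L_B",
                   values=_l_transform(result.values, result.grid))


# ---------------------------------------------------------------------------
# Envelopes
# ---------------------------------------------------------------------------

def _envelope_from_sims(sims: np.ndarray, grid, n_sim, level, null, seed) -> Envelope:
    k = int(np.ceil(n_sim * (1.0 - level) / 2.0))
    k = max(k, 1)
    sims_sorted = np.sort(sims, axis=0)
    return Envelope(grid=grid, lower=sims_sorted[k - 1],
                    upper=sims_sorted[n_sim - k], n_sim=n_sim, level=level,
                    null=null, seed=seed)


def csr_envelope(pattern: PlotPattern, grid: np.ndarray | None = None,
                 n_sim: int = 1000, level: float = 0.99, seed=None,
                 correction: str = "isotropic") -> Envelope:
    """Pointwise CSR envelope of the univariate L function.

    ``n_sim`` uniform patterns with the same point count in the same window;
    bounds at the k-th extreme ranks with k = ceil(n_sim*(1-level)/2)
    (rank 5 from each tail at n_sim = 1000 and level 0.99).
    """
    if pattern.n < 2:
        raise PatternError(f"plot {pattern.code}: envelope needs >= 2 trees")
    grid = distance_grid(window=pattern.window) if grid is None else np.asarray(grid)
    rng = np.random.default_rng(seed)
    w = pattern.window
    sims = np.empty((n_sim, len(grid)))
    for s in range(n_sim):
        xy = np.column_stack([rng.uniform(w.x_min, w.x_max, pattern.n),
                              rng.uniform(w.y_min, w.y_max, pattern.n)])
        sims[s] = _l_transform(_k_univariate_xy(xy, w, grid, correction), grid)
    return _envelope_from_sims(
        sims, grid, n_sim, level, "CSR",
        int(seed) if isinstance(seed, (int, np.integer)) else None)


def independence_envelope(pattern: PlotPattern, type_i, type_j,
                          grid: np.ndarray | None = None,
                          n_sim: int = 1000, level: float = 0.99, seed=None,
                          correction: str = "isotropic") -> Envelope:
    """Toroidal-shift envelope of L_B under the independence null.

    The type-i pattern is held fixed; in each simulation the type-j points
    are shifted by a uniform random offset with wrap-around on the window
    (Lotwick-Silverman randomisation of relative position).
    """
    mask_i = _resolve_group(pattern, type_i)
    mask_j = _resolve_group(pattern, type_j)
    for name, m in (("type_i", mask_i), ("type_j", mask_j)):
        if not m.any():
            raise PatternError(f"plot {pattern.code}: {name} selects no trees")
    if mask_j.sum() < 2:
        warnings.warn(
            f"plot {pattern.code}: type_j has {int(mask_j.sum())} point(s); "
            "the independence envelope is degenerate", stacklevel=2)
    grid = distance_grid(window=pattern.window) if grid is None else np.asarray(grid)
    rng = np.random.default_rng(seed)
    w = pattern.window
    xy = pattern.xy
    xy_i, xy_j = xy[mask_i], xy[mask_j]
    n_i, n_j = len(xy_i), len(xy_j)
    sims = np.empty((n_sim, len(grid)))
    for s in range(n_sim):
        shift = rng.uniform([0.0, 0.0], [w.width, w.height])
        xy_js = np.column_stack([
            (xy_j[:, 0] - w.x_min + shift[0]) % w.width + w.x_min,
            (xy_j[:, 1] - w.y_min + shift[1]) % w.height + w.y_min,
        ])
        _, _, k_b = _k_bivariate_xy(xy_i, xy_js, w, grid, correction)
        sims[s] = _l_transform(k_b, grid)
    return _envelope_from_sims(
        sims, grid, n_sim, level, "independence-shift",
        int(seed) if isinstance(seed, (int, np.integer)) else None)


# ---------------------------------------------------------------------------
# Classification and the diameter-threshold scan
# ---------------------------------------------------------------------------

_VOCAB = {
    "univariate": {"above": "clustering", "below": "regularity",
                   "inside": "CSR"},
    "bivariate": {"above": "aggregation", "below": "repulsion",
                  "inside": "Independence"},
}


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs (stop inclusive)."""
    out = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def classify_scales(l_result: SecondOrderResult, envelope: Envelope,
                    mode: str = "univariate") -> ScaleClassification:
    """Label every grid distance against the envelope and phrase a verdict.

    Verdicts follow the conventional vocabulary: excursions above the upper
    bound read "clustering" (univariate) or "aggregation" (bivariate),
    below the lower bound "regularity"/"repulsion", and a curve inside the
    band everywhere reads "CSR"/"Independence".  Runs are reported with
    their distance bounds in metres.
    """
    if mode not in _VOCAB:
        raise PatternError(f"mode must be 'univariate' or 'bivariate', got {mode!r}")
    if len(l_result.grid) != len(envelope.grid) or \
            not np.allclose(l_result.grid, envelope.grid):
        raise PatternError("L result and envelope are on different grids")
    v = l_result.values
    labels = np.where(v > envelope.upper, "above",
                      np.where(v < envelope.lower, "below", "inside"))
    words = _VOCAB[mode]
    grid = l_result.grid
    phrases = []
    for direction in ("above", "below"):
        for start, stop in _runs(labels == direction):
            if start == stop:
                phrases.append(f"{words[direction]} at r = {grid[start]:g} m")
            else:
                phrases.append(
                    f"{words[direction]} at {grid[start]:g} <= r <= "
                    f"{grid[stop]:g} m")
    verdict = "; ".join(phrases) if phrases else words["inside"]
    return ScaleClassification(grid=grid, labels=labels, verdict=verdict)


def dcut_scan(pattern: PlotPattern, dbh_range: tuple[float, float] = (7.0, 40.0),
              step: float = 0.1, n_sim: int = 199, seed=None,
              grid: np.ndarray | None = None,
              correction: str = "isotropic") -> DCutScan:
    """Scan the small/large DBH split for the most aggregated bivariate pattern.

    For each candidate threshold the trees are split into small (dbh < t) and
    large (dbh >= t) groups, the bivariate L and its toroidal-shift
    independence envelope are computed, and the candidate is scored by the
    integrated excess of L_B above the upper envelope bound
    (sum of max(0, L_B - upper) * dr).  The chosen threshold maximises this
    score, ties resolved towards the smaller threshold; a zero maximum is
    flagged non-significant.  Candidates yielding the same group membership
    are evaluated once.
    """
    lo, hi = dbh_range
    thresholds = np.arange(lo + step, hi, step)
    dbh = pattern.dbh
    valid = [(t, (dbh < t)) for t in thresholds
             if 0 < (dbh < t).sum() < pattern.n]
    if not valid:
        raise PatternError(
            f"plot {pattern.code}: no threshold in ({lo}, {hi}) splits the "
            "trees into two non-empty groups")
    grid = distance_grid(window=pattern.window) if grid is None else np.asarray(grid)
    dr = np.diff(grid, prepend=0.0)
    ss = np.random.SeedSequence(seed)
    scores = np.full(len(thresholds), np.nan)
    cache: dict[int, float] = {}
    child_iter = iter(ss.spawn(len(valid)))
    for t, small in valid:
        key = int(small.sum())         # group membership is determined by
        child = next(child_iter)       # the count under a sorted-dbh split
        if key not in cache:
            k_res = ripley_k_bivariate(pattern, small, ~small, grid, correction)
            l_res = l_bivariate(k_res)
            env = independence_envelope(pattern, small, ~small, grid,
                                        n_sim=n_sim, seed=child,
                                        correction=correction)
            cache[key] = float(np.sum(np.maximum(0.0, l_res.values - env.upper) * dr))
        scores[np.searchsorted(thresholds, t)] = cache[key]
    best = np.nanmax(scores)
    chosen = float(thresholds[np.nanargmax(scores)])   # first max = smallest t
    return DCutScan(thresholds=thresholds, scores=scores, chosen=chosen,
                    significant=bool(best > 0.0))
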