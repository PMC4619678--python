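"""Marked tree point patterns: windows, neighbour geometry, stand parameters.

The basic object is a :class:`PlotPattern`: a rectangular observation window
plus one row per tree (coordinates in metres, species label, diameter at
breast height in cm, optionally total height in m).  Everything downstream —
nearest-neighbour indices, Ripley functions, dominance stratification —
consumes this object.

Trees below the 7 cm DBH calliper threshold are outside the population of
interest and are rejected at load time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Minimum diameter at breast height (cm) for a tree to enter the pattern.
DBH_MIN = 7.0

#: Width of the diameter classes (cm) used for stand tables, first class
#: starting at the calliper threshold: [7, 17), [17, 27), ...
DBH_CLASS_WIDTH = 10.0


class PatternError(ValueError):
    """Invalid pattern construction or an operation's precondition failed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotWindow:
    """Rectangular observation window, coordinates in metres."""

    x_min: float = 0.0
    x_max: float = 50.0
    y_min: float = 0.0
    y_max: float = 50.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise PatternError(
                f"degenerate window [{self.x_min},{self.x_max}]x"
                f"[{self.y_min},{self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Window area in m^2."""
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    def boundary_distance(self, x, y) -> np.ndarray:
        """Distance from each point to the nearest window edge (m)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.minimum.reduce(
            [x - self.x_min, self.x_max - x, y - self.y_min, self.y_max - y]
        )


@dataclass
class PlotPattern:
    """One plot: window plus marked trees.

    ``trees`` holds one row per tree with columns ``x``, ``y``, ``species``,
    ``dbh`` and optionally ``height``; the row order is the canonical tree
    index used by all neighbour tables and stratifications.
    """

    code: str
    window: PlotWindow
    trees: pd.DataFrame
    lat: float | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        required = {"x", "y", "species", "dbh"}
        missing = required - set(self.trees.columns)
        if missing:
            raise PatternError(f"plot {self.code}: missing columns {sorted(missing)}")
        t = self.trees.reset_index(drop=True)
        if len(t):
            inside = self.window.contains(t["x"].to_numpy(), t["y"].to_numpy())
            if not inside.all():
                bad = int(np.flatnonzero(~inside)[0])
                raise PatternError(
                    f"plot {self.code}: tree in row {bad} at "
                    f"({t.at[bad, 'x']}, {t.at[bad, 'y']}) lies outside the window"
                )
            dbh = t["dbh"].to_numpy(dtype=float)
            if np.any(~np.isfinite(dbh)):
                bad = int(np.flatnonzero(~np.isfinite(dbh))[0])
                raise PatternError(f"plot {self.code}: non-numeric dbh in row {bad}")
            if np.any(dbh < DBH_MIN):
                bad = int(np.flatnonzero(dbh < DBH_MIN)[0])
                raise PatternError(
                    f"plot {self.code}: dbh {dbh[bad]} < {DBH_MIN} cm in row {bad}; "
                    "filter undersized trees before constructing the pattern"
                )
            species = t["species"].astype(str)
            if (species.str.len() == 0).any():
                raise PatternError(f"plot {self.code}: empty species label")
            if "height" in t.columns:
                h = t["height"].to_numpy(dtype=float)
                if np.any(np.isfinite(h) & (h <= 0)):
                    bad = int(np.flatnonzero(np.isfinite(h) & (h <= 0))[0])
                    raise PatternError(f"plot {self.code}: height <= 0 in row {bad}")
        self.trees = t

    @property
    def n(self) -> int:
        return len(self.trees)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of tree coordinates."""
        return self.trees[["x", "y"]].to_numpy(dtype=float)

    @property
    def dbh(self) -> np.ndarray:
        return self.trees["dbh"].to_numpy(dtype=float)

    @property
    def species(self) -> np.ndarray:
        return self.trees["species"].astype(str).to_numpy()

    def subset(self, mask, code_suffix: str = "") -> "PlotPattern":
        """Pattern restricted to ``mask`` (boolean or index array), same window."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = self.trees.iloc[idx]
        return replace(
            self,
            code=self.code + code_suffix,
            trees=sub.reset_index(drop=True),
            n_excluded=0,
        )

    def species_mask(self, labels) -> np.ndarray:
        if isinstance(labels, str):
            labels = {labels}
        return np.isin(self.species, sorted(labels))


@dataclass(frozen=True)
class StandSummary:
    """Per-hectare stand parameters for one plot (optionally one species)."""

    n_trees: int
    N: float          # stems per hectare
    G: float          # basal area, m^2 per hectare
    dg: float         # quadratic mean diameter, cm
    d: float          # arithmetic mean diameter, cm
    h: float          # mean height, m (nan when heights absent)
    d_max: float      # cm
    h_max: float      # m (nan when heights absent)
    class_edges: np.ndarray = field(repr=False)
    class_freq: np.ndarray = field(repr=False)

    @property
    def fcd(self) -> float:
        """Relative frequency of the first 10-cm diameter class."""
        return float(self.class_freq[0])


@dataclass(frozen=True)
class DiversityProfile:
    """Hill-number diversity profile: richness, inverse Simpson, inverse
    Berger-Parker (effective number of prevalent species)."""

    upsilon_0: float
    upsilon_2: float
    upsilon_inf: float


@dataclass(frozen=True)
class DominanceSplit:
    """Dominant/suppressed stratification by a basal-area prefix rule."""

    dominant: np.ndarray
    suppressed: np.ndarray
    threshold_fraction: float = 0.5


@dataclass(frozen=True)
class NeighbourTable:
    """k nearest neighbours of every tree.

    ``indices``/``distances``/``azimuths`` have shape (n, k), neighbour rank
    ascending by distance (ties broken by lower tree index).  Azimuths are in
    degrees, 0 = north (+y axis), increasing clockwise.  ``boundary`` is the
    distance from each tree to the nearest window edge.
    """

    indices: np.ndarray
    distances: np.ndarray
    azimuths: np.ndarray
    boundary: np.ndarray

    @property
    def k(self) -> int:
        return self.indices.shape[1]


# ---------------------------------------------------------------------------
# Geometry kernels (array in, array out; used by the index and null machinery)
# ---------------------------------------------------------------------------

def _knn(xy: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbours by exhaustive pairwise distances.

    Ties are broken by ascending tree index (stable sort on distance), which
    keeps every downstream statistic deterministic.  Plots hold at most a few
    hundred trees, so the O(n^2) table is cheap and exact; larger inputs
    (e.g. lattice calibration patterns) take a blocked argpartition path
    with a generous tie buffer.
    """
    n = len(xy)
    if n <= 1500:
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        return order, np.take_along_axis(d, order, axis=1)
    m = min(k + 32, n - 1)   # candidate buffer absorbs distance ties
    order = np.empty((n, k), dtype=np.intp)
    dist = np.empty((n, k))
    for start in range(0, n, 512):
        block = slice(start, min(start + 512, n))
        d = np.hypot(xy[block, None, 0] - xy[None, :, 0],
                     xy[block, None, 1] - xy[None, :, 1])
        d[np.arange(block.stop - block.start), np.arange(start, block.stop)] \
            = np.inf
        cand = np.argpartition(d, m - 1, axis=1)[:, :m]
        cd = np.take_along_axis(d, cand, axis=1)
        for r in range(cand.shape[0]):
            sub = np.lexsort((cand[r], cd[r]))[:k]
            order[start + r] = cand[r][sub]
            dist[start + r] = cd[r][sub]
    return order, dist


def azimuth_deg(dx, dy) -> np.ndarray:
    """Azimuth of the vector (dx, dy): 0 deg = +y (north), clockwise."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def nearest_neighbours(pattern: PlotPattern, k: int) -> NeighbourTable:
    """Table of each tree's ``k`` nearest neighbours with distances and azimuths."""
    if k < 1:
        raise PatternError("k must be >= 1")
    if k >= pattern.n:
        raise PatternError(
            f"plot {pattern.code}: k={k} neighbours requested but only "
            f"{pattern.n} trees present (need k <= n-1)"
        )
    xy = pattern.xy
    idx, dist = _knn(xy, k)
    diff = xy[idx] - xy[:, None, :]
    az = azimuth_deg(diff[..., 0], diff[..., 1])
    boundary = pattern.window.boundary_distance(xy[:, 0], xy[:, 1])
    return NeighbourTable(idx, dist, az, boundary)


def nn1_reference_set(pattern: PlotPattern, n_neighbours: int = 1) -> np.ndarray:
    """Trees usable as reference trees under the NN1 edge rule.

    A tree qualifies when its ``n_neighbours``-th nearest-neighbour distance
    does not exceed its distance to the nearest window edge, i.e. its whole
    neighbour search disc lies inside the plot.  All trees remain candidate
    neighbours and enter the density estimate; only the averaging set shrinks.
    """
    if pattern.n < 2:
        raise PatternError(f"plot {pattern.code}: need at least 2 trees")
    nt = nearest_neighbours(pattern, min(n_neighbours, pattern.n - 1))
    return np.flatnonzero(nt.distances[:, -1] <= nt.boundary)


# ---------------------------------------------------------------------------
# Stand parameters, diversity, dominance
# ---------------------------------------------------------------------------

def basal_area_m2(dbh_cm) -> np.ndarray:
    """Cross-sectional area at breast height (m^2) from DBH in cm."""
    return np.pi * (np.asarray(dbh_cm, dtype=float) / 200.0) ** 2


def stand_summary(pattern: PlotPattern, species=None) -> StandSummary:
    """Per-hectare stand parameters, optionally for one species (or label set).

    N = stems/ha, G = basal area m^2/ha, dg = quadratic mean diameter
    (so that G = pi/4 * (dg/100)^2 * N), d/h arithmetic means, plus relative
    diameter-class frequencies over 10-cm bins starting at 7 cm.
    """
    trees = pattern.trees
    if species is not None:
        trees = trees[pattern.species_mask(species)]
    if len(trees) == 0:
        raise PatternError(
            f"plot {pattern.code}: no trees"
            + (f" of species {species!r}" if species is not None else "")
        )
    dbh = trees["dbh"].to_numpy(dtype=float)
    scale = 10_000.0 / pattern.window.area   # per-hectare expansion factor
    n = len(dbh)
    heights = trees["height"].to_numpy(dtype=float) if "height" in trees else None
    has_h = heights is not None and np.isfinite(heights).any()
    edges = np.arange(DBH_MIN, dbh.max() + DBH_CLASS_WIDTH, DBH_CLASS_WIDTH)
    counts, _ = np.histogram(dbh, bins=edges)
    return StandSummary(
        n_trees=n,
        N=n * scale,
        G=float(basal_area_m2(dbh).sum() * scale),
        dg=float(np.sqrt(np.mean(dbh**2))),
        d=float(dbh.mean()),
        h=float(np.nanmean(heights)) if has_h else float("nan"),
        d_max=float(dbh.max()),
        h_max=float(np.nanmax(heights)) if has_h else float("nan"),
        class_edges=edges,
        class_freq=counts / n,
    )


def hill_diversity(abundances, order) -> float:
    """Effective species number of a given order (0, 2 or inf).

    order 0: species richness; order 2: inverse Simpson concentration
    1/sum(p_i^2); order inf: reciprocal of the largest relative abundance.
    """
    counts = np.asarray(abundances, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise PatternError("hill_diversity: no positive abundances")
    if np.any(counts < 0):
        raise PatternError("hill_diversity: negative abundance")
    p = counts / counts.sum()
    p = p[p > 0]
    if order == 0:
        return float(len(p))
    if order == 2:
        return float(1.0 / np.sum(p**2))
    if order in (np.inf, float("inf"), "inf"):
        return float(1.0 / p.max())
    raise PatternError(f"unsupported Hill order {order!r}")


def diversity_profile(pattern: PlotPattern) -> DiversityProfile:
    counts = pattern.trees["species"].value_counts().to_numpy(dtype=float)
    return DiversityProfile(
        hill_diversity(counts, 0),
        hill_diversity(counts, 2),
        hill_diversity(counts, np.inf),
    )


def dominance_split(pattern: PlotPattern,
                    threshold_fraction: float = 0.5) -> DominanceSplit:
    """Split trees into dominant and suppressed by descending-DBH basal area.

    The dominant class is the smallest prefix of trees, in descending DBH
    order (ties by ascending tree index), whose cumulative basal area reaches
    ``threshold_fraction`` of the stand total; the suppressed class is the
    remainder.  Loosely follows the basal-area-of-larger-trees competition
    logic used in forest mensuration.
    """
    if pattern.n == 0:
        raise PatternError(f"plot {pattern.code}: empty pattern")
    dbh = pattern.dbh
    order = np.lexsort((np.arange(pattern.n), -dbh))
    ba = basal_area_m2(dbh[order])
    cum = np.cumsum(ba)
    cut = int(np.searchsorted(cum, threshold_fraction * cum[-1] - 1e-12)) + 1
    return DominanceSplit(
        dominant=np.sort(order[:cut]),
        suppressed=np.sort(order[cut:]),
        threshold_fraction=threshold_fraction,
    )


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise corrected significance level alpha/m."""
    if not 0 < alpha < 1:
        raise PatternError(f"alpha={alpha} outside (0, 1)")
    if m < 1:
        raise PatternError(f"m={m} must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("code", "x", "y", "species", "dbh")


def _read_table(source) -> pd.DataFrame:
    """Comma- or tab-delimited table with a header row, decimal point."""
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(str(source))
    df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PatternError(f"input table missing required column(s) {missing}")
    return df


def _build_pattern(code: str, rows: pd.DataFrame, window: PlotWindow,
                   lat: float | None) -> PlotPattern:
    for col in ("x", "y", "dbh"):
        vals = pd.to_numeric(rows[col], errors="coerce")
        bad = vals.isna() & rows[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PatternError(
                f"plot {code}: non-numeric {col} value "
                f"{rows[col].iloc[row]!r} in row {row}"
            )
        rows = rows.assign(**{col: vals})
    undersized = rows["dbh"] < DBH_MIN
    kept = rows.loc[~undersized]
    cols = ["x", "y", "species", "dbh"] + (["height"] if "height" in rows else [])
    return PlotPattern(
        code=code,
        window=window,
        trees=kept[cols].reset_index(drop=True),
        lat=lat,
        n_excluded=int(undersized.sum()),
    )


def load_plots(source, window: PlotWindow | None = None,
               lat: dict[str, float] | None = None) -> dict[str, PlotPattern]:
    """Load every plot from a delimited-text tree table, grouped by code.

    The table needs columns ``code, x, y, species, dbh`` (``height`` optional),
    metres / centimetres, decimal points.  Rows below the 7 cm DBH threshold
    are dropped and counted in each pattern's ``n_excluded``.
    """
    window = window or PlotWindow()
    df = _read_table(source)
    out: dict[str, PlotPattern] = {}
    for code, rows in df.groupby("code", sort=False):
        out[str(code)] = _build_pattern(
            str(code), rows, window, (lat or {}).get(str(code))
        )
    return out


def load_plot(source, window: PlotWindow | None = None,
              code: str | None = None) -> PlotPattern:
    """Load a single plot; ``code`` selects one when the file holds several."""
    plots = load_plots(source, window)
    if code is not None:
        if code not in plots:
            raise PatternError(f"plot code {code!r} not present in input")
        return plots[code]
    if len(plots) != 1:
        raise PatternError(
            f"input holds {len(plots)} plots {sorted(plots)}; pass code= to pick one"
        )
    return next(iter(plots.values()))


def write_plots(plots, path, sep: str = "\t") -> None:
    """Write patterns back to the same delimited format ``load_plots`` reads."""
    frames = []
    for p in (plots.values() if isinstance(plots, dict) else plots):
        t = p.trees.copy()
        t.insert(0, "code", p.code)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
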