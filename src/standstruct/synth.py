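"""Generators of point patterns and marked stands used as study inputs.

The generators emulate the statistical structure of uneven-aged mixed
conifer stands measured on 0.25 ha (50 x 50 m) plots: 38-133 trees per
plot, 4-9 species, reverse-J diameter distributions (many small stems,
few large), and optionally small trees clustered around large ones.

Every generator is a pure function of its parameters and seed: the same
seed reproduces the same pattern bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pattern import DBH_MIN, PatternError, PlotPattern, PlotWindow

#: Plot codes of the 12-location study fixture.
STUDY_CODES = ("TN", "RC", "CV", "TY", "TR", "VN",
               "LQ", "PPR", "QD", "CB", "SJ", "LP")

#: Label used for the focal species in generated stands.
FOCAL_SPECIES = "PCH"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _as_pattern(code: str, window: PlotWindow, x, y, species=None, dbh=None,
                height=None, lat=None) -> PlotPattern:
    n = len(x)
    trees = pd.DataFrame({
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
        "species": np.asarray(species) if species is not None
        else np.full(n, "SP1"),
        "dbh": np.asarray(dbh, dtype=float) if dbh is not None
        else np.full(n, 20.0),
    })
    if height is not None:
        trees["height"] = np.asarray(height, dtype=float)
    return PlotPattern(code=code, window=window, trees=trees, lat=lat)


# ---------------------------------------------------------------------------
# Point processes
# ---------------------------------------------------------------------------

def gen_csr(n: int, window: PlotWindow | None = None, seed=None,
            code: str = "CSR") -> PlotPattern:
    """Binomial (conditioned-Poisson) pattern: n points uniform in the window."""
    window = window or PlotWindow()
    rng = _rng(seed)
    x = rng.uniform(window.x_min, window.x_max, n)
    y = rng.uniform(window.y_min, window.y_max, n)
    return _as_pattern(code, window, x, y)


def _thomas_xy(rng, kappa_per_ha, mu, sigma, window):
    area_ha = window.area / 10_000.0
    n_parents = rng.poisson(kappa_per_ha * area_ha)
    px = rng.uniform(window.x_min, window.x_max, n_parents)
    py = rng.uniform(window.y_min, window.y_max, n_parents)
    xs, ys = [], []
    for k in range(n_parents):
        n_off = rng.poisson(mu)
        placed = 0
        while placed < n_off:
            # rejection keeps true parent-offspring displacements near edges
            cand = rng.normal([px[k], py[k]], sigma, size=(n_off - placed, 2))
            ok = window.contains(cand[:, 0], cand[:, 1])
            for cx, cy in cand[ok]:
                xs.append(cx)
                ys.append(cy)
            placed += int(ok.sum())
    return np.array(xs), np.array(ys)


def gen_thomas(kappa: float, mu: float, sigma: float,
               window: PlotWindow | None = None, seed=None,
               code: str = "THOMAS") -> PlotPattern:
    """Thomas cluster process.

    ``kappa`` parents per hectare (Poisson), each with Poisson(``mu``)
    offspring displaced by an isotropic Gaussian of scale ``sigma`` metres;
    offspring falling outside the window are re-drawn (rejection), so the
    displacement distribution is honest near the edges.
    """
    if kappa <= 0 or mu <= 0 or sigma <= 0:
        raise PatternError("kappa, mu and sigma must be positive")
    window = window or PlotWindow()
    x, y = _thomas_xy(_rng(seed), kappa, mu, sigma, window)
    return _as_pattern(code, window, x, y)


def gen_hardcore(n: int, r_min: float, window: PlotWindow | None = None,
                 seed=None, max_tries_per_point: int = 1000,
                 code: str = "HARDCORE") -> PlotPattern:
    """Simple sequential inhibition: uniform proposals kept at >= r_min apart.

    Raises when the proposal budget is exhausted before ``n`` points are
    placed, reporting how many were achieved.
    """
    if r_min < 0:
        raise PatternError("r_min must be >= 0")
    window = window or PlotWindow()
    rng = _rng(seed)
    pts = np.empty((n, 2))
    placed = 0
    budget = max_tries_per_point * max(n, 1)
    while placed < n and budget > 0:
        cand = np.array([rng.uniform(window.x_min, window.x_max),
                         rng.uniform(window.y_min, window.y_max)])
        budget -= 1
        if placed == 0 or r_min == 0 or \
                np.min(np.hypot(*(pts[:placed] - cand).T)) >= r_min:
            pts[placed] = cand
            placed += 1
    if placed < n:
        raise PatternError(
            f"hard-core sampler exhausted its budget: placed {placed} of "
            f"{n} points at r_min={r_min}")
    return _as_pattern(code, window, pts[:, 0], pts[:, 1])


# ---------------------------------------------------------------------------
# Marked stands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandSpec:
    """Recipe for one synthetic marked stand.

    ``spatial`` selects the position process: ``("csr",)``,
    ``("thomas", kappa_per_ha, mu, sigma_m)`` or ``("hardcore", r_min_m)``.
    ``size_link`` = (threshold_cm, sigma_m) places every tree below the
    threshold as a Gaussian offspring of a random tree above it, producing
    the small-around-large aggregation typical of gap regeneration.
    DBH follows a truncated exponential on [7, dbh_max] with the given rate
    (cm^-1), i.e. a reverse-J distribution; heights follow the allometry
    h = a * dbh^b with multiplicative lognormal noise and are only carried
    as summary marks.
    """

    n_trees: int = 80
    window: PlotWindow = field(default_factory=PlotWindow)
    species_labels: tuple = (FOCAL_SPECIES, "SP2", "SP3", "SP4", "SP5")
    species_probs: tuple = (0.35, 0.25, 0.2, 0.1, 0.1)
    dbh_rate: float = 0.08
    dbh_max: float = 90.0
    height_a: float = 1.3
    height_b: float = 0.75
    height_sigma: float = 0.15
    spatial: tuple = ("csr",)
    size_link: tuple | None = None
    seed: int | None = None
    code: str = "SYN"
    lat: float | None = None

    def __post_init__(self) -> None:
        if len(self.species_labels) != len(self.species_probs):
            raise PatternError("species labels and probabilities differ in length")
        if abs(sum(self.species_probs) - 1.0) > 1e-9:
            raise PatternError("species probabilities must sum to 1")
        if self.dbh_rate <= 0 or self.dbh_max <= DBH_MIN:
            raise PatternError("invalid DBH law parameters")


def _truncated_exponential_dbh(rng, n, rate, d_max):
    u = rng.uniform(size=n)
    span = 1.0 - np.exp(-rate * (d_max - DBH_MIN))
    return DBH_MIN - np.log(1.0 - u * span) / rate


def _positions(rng, spec: StandSpec, n: int) -> np.ndarray:
    w = spec.window
    kind = spec.spatial[0]
    if kind == "csr":
        return np.column_stack([rng.uniform(w.x_min, w.x_max, n),
                                rng.uniform(w.y_min, w.y_max, n)])
    if kind == "thomas":
        _, kappa, mu, sigma = spec.spatial
        x, y = _thomas_xy(rng, kappa, mu, sigma, w)
        # condition the process on the requested count
        while len(x) < n:
            x2, y2 = _thomas_xy(rng, kappa, mu, sigma, w)
            x = np.concatenate([x, x2])
            y = np.concatenate([y, y2])
        pick = rng.choice(len(x), size=n, replace=False)
        return np.column_stack([x[pick], y[pick]])
    if kind == "hardcore":
        _, r_min = spec.spatial
        p = gen_hardcore(n, r_min, w, seed=rng)
        return p.xy
    raise PatternError(f"unknown spatial process {kind!r}")


def gen_marked_stand(spec: StandSpec) -> PlotPattern:
    """Generate a marked stand (positions, species, DBH, height) from a spec."""
    rng = _rng(spec.seed)
    n = spec.n_trees
    dbh = _truncated_exponential_dbh(rng, n, spec.dbh_rate, spec.dbh_max)
    species = rng.choice(np.asarray(spec.species_labels), size=n,
                         p=np.asarray(spec.species_probs))
    if spec.size_link is not None:
        threshold, sigma = spec.size_link
        large = dbh >= threshold
        if not large.any() or large.all():
            raise PatternError(
                f"size_link threshold {threshold} leaves a group empty")
        xy = np.empty((n, 2))
        xy[large] = _positions(rng, spec, int(large.sum()))
        parents = xy[large][rng.integers(0, int(large.sum()),
                                         size=int((~large).sum()))]
        w = spec.window
        small_idx = np.flatnonzero(~large)
        for row, parent in zip(small_idx, parents):
            while True:
                cand = rng.normal(parent, sigma, size=2)
                if w.contains(cand[0], cand[1]):
                    xy[row] = cand
                    break
    else:
        xy = _positions(rng, spec, n)
    log_noise = rng.normal(0.0, spec.height_sigma, size=n)
    height = spec.height_a * dbh**spec.height_b * np.exp(log_noise)
    return _as_pattern(spec.code, spec.window, xy[:, 0], xy[:, 1],
                       species=species, dbh=dbh, height=height, lat=spec.lat)


def gen_study_fixture(seed=None) -> dict[str, PlotPattern]:
    """Twelve synthetic plots shaped like the field study's 12 locations.

    Per plot: total tree count uniform on [38, 133] (152-532 stems/ha on
    0.25 ha), focal-species count on [11, 35], 4-9 species, reverse-J DBH,
    and a mix of CSR and size-linked clustered position processes.  Plot
    latitudes span the community's 23-29 deg N range, decreasing along the
    plot order so latitude-index covariations are exercised.
    """
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(STUDY_CODES))
    plots: dict[str, PlotPattern] = {}
    lats = np.linspace(23.5, 28.8, len(STUDY_CODES))
    for i, (code, child) in enumerate(zip(STUDY_CODES, children)):
        rng = np.random.default_rng(child)
        n = int(rng.integers(38, 134))
        n_species = int(rng.integers(4, 10))
        n_focal = int(min(rng.integers(11, 36), n - (n_species - 1)))
        other = n - n_focal
        labels = [FOCAL_SPECIES] + [f"SP{k}" for k in range(2, n_species + 1)]
        clustered = i % 2 == 1   # alternate CSR and clustered plots
        spec = StandSpec(
            n_trees=n,
            species_labels=tuple(labels),
            species_probs=tuple([1 / n_species] * n_species),
            size_link=(25.0, 2.0) if clustered else None,
            seed=int(rng.integers(2**31 - 1)),
            code=code,
            lat=float(lats[len(STUDY_CODES) - 1 - i]),
        )
        p = gen_marked_stand(spec)
        # realise the exact composition: n_focal focal trees, every other
        # species present at least once, remainder spread at random
        counts = np.ones(n_species - 1, dtype=int)
        extra = rng.multinomial(other - (n_species - 1),
                                np.full(n_species - 1, 1 / (n_species - 1)))
        composition = np.repeat(labels, np.concatenate([[n_focal],
                                                        counts + extra]))
        p.trees["species"] = rng.permutation(composition)
        plots[code] = p
    return plots
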