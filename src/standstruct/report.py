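"""Study orchestration: run every analysis over a set of plots, emit tables.

``run_study`` composes the whole pipeline on a collection of plots:
stand summaries, the three neighbourhood indices with Monte-Carlo CSR tests
for the focal species / all species / dominance strata, univariate and
bivariate L functions with envelope verdicts, covariation of plot-level
variables with the indices, and group mean-difference permutation tests —
with Bonferroni family corrections applied per test family.

Every Monte-Carlo stage draws its generator from a seed derived
deterministically from the master seed and the (plot, stage) key, so a rerun
with the same configuration reproduces the bundle exactly, regardless of
which optional stages are enabled.  Stages that fail on a plot (too few
trees, empty strata) are recorded as "-" cells, mirroring field reports, and
never abort the bundle.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import apply_family_correction, covariation_test, \
    group_mean_diff_test
from .indices import csr_index_test
from .pattern import PatternError, PlotPattern, PlotWindow, diversity_profile, \
    dominance_split, load_plots, stand_summary
from .secondorder import classify_scales, csr_envelope, dcut_scan, \
    distance_grid, independence_envelope, l_bivariate, l_univariate, \
    ripley_k_bivariate, ripley_k_univariate
from .synth import FOCAL_SPECIES, gen_study_fixture

log = logging.getLogger("standstruct")

MISSING = "-"

INDEX_NAMES = ("CE", "W", "R")

#: Tail-probability column label per index (small = clustering for all three).
TAIL_LABEL = {"CE": "1-P(Z>=CE)", "W": "P(Z>=W)", "R": "P(Z>=R)"}


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    input: str | None = None          # delimited tree table; None -> fixture
    focal_species: str = FOCAL_SPECIES
    n_sim_env: int = 1000             # envelope simulations
    n_sim_perm: int = 10_000          # index-test / permutation draws
    r_max: float = 12.0
    r_step: float = 0.25
    alpha: float = 0.05
    m_indices: int | None = None      # family sizes; None -> tests run
    m_covariation: int | None = None
    m_diff: int | None = None
    dcut_all: float = 23.2            # small/large split, all species (cm)
    dcut_focal: float = 29.3          # split within the focal species (cm)
    scan_dcut: bool = False           # re-estimate the splits per plot
    dcut_step: float = 1.0
    dcut_n_sim: int = 199
    correction: str = "isotropic"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_sim_env < 99 or self.n_sim_perm < 99:
            raise PatternError("n_sim must be at least 99")
        if not 0 < self.alpha < 1:
            raise PatternError("alpha must lie in (0, 1)")


def _stage_seed(master_seed: int, *key: str) -> np.random.SeedSequence:
    """Deterministic per-(plot, stage) seed, independent of execution order."""
    digest = zlib.crc32("/".join(key).encode())
    return np.random.SeedSequence([int(master_seed), digest])


def _logged(stage: str, plot: str, seed_key, n_sim: int, t0: float) -> None:
    log.info("plot=%s stage=%s seed=%s n_sim=%d elapsed=%.2fs",
             plot, stage, seed_key, n_sim, time.monotonic() - t0)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _stand_rows(code: str, pattern: PlotPattern, focal: str) -> dict:
    row = {"code": code, "n": pattern.n, "lat": pattern.lat}
    for label, species in (("total", None), ("focal", focal)):
        try:
            s = stand_summary(pattern, species)
            row.update({f"N_{label}": s.N, f"G_{label}": s.G,
                        f"dg_{label}": s.dg, f"d_{label}": s.d,
                        f"h_{label}": s.h, f"dmax_{label}": s.d_max,
                        f"hmax_{label}": s.h_max})
            if label == "total":
                row["fcd"] = s.fcd
        except PatternError:
            for c in ("N", "G", "dg", "d", "h", "dmax", "hmax"):
                row[f"{c}_{label}"] = np.nan
    div = diversity_profile(pattern)
    row.update({"upsilon_0": div.upsilon_0, "upsilon_2": div.upsilon_2,
                "upsilon_inf": div.upsilon_inf})
    return row


def _index_row(pattern: PlotPattern, code: str, group: str,
               cfg: StudyConfig) -> dict:
    row: dict = {"code": code, "group": group, "n": pattern.n}
    for index in INDEX_NAMES:
        t0 = time.monotonic()
        ss = _stage_seed(cfg.seed, code, group, index)
        try:
            res = csr_index_test(pattern, index, n_sim=cfg.n_sim_perm, seed=ss)
            row[index] = res.value
            row[f"{index}_tail"] = res.p_tail
            row[f"{index}_verdict"] = res.verdict
        except PatternError:
            row[index] = np.nan
            row[f"{index}_tail"] = np.nan
            row[f"{index}_verdict"] = MISSING
        _logged(f"index-{index}-{group}", code, ss.entropy, cfg.n_sim_perm, t0)
    return row


def _univariate_verdict(pattern: PlotPattern, grid, cfg: StudyConfig,
                        code: str, stage: str) -> str:
    if pattern.n < 2:
        return MISSING
    ss = _stage_seed(cfg.seed, code, stage)
    l_obs = l_univariate(ripley_k_univariate(pattern, grid, cfg.correction))
    env = csr_envelope(pattern, grid, n_sim=cfg.n_sim_env, seed=ss,
                       correction=cfg.correction)
    return classify_scales(l_obs, env, "univariate").verdict


def _bivariate_verdict(pattern: PlotPattern, mask_i, mask_j, grid,
                       cfg: StudyConfig, code: str, stage: str) -> str:
    if not np.any(mask_i) or not np.any(mask_j):
        return MISSING
    ss = _stage_seed(cfg.seed, code, stage)
    try:
        l_obs = l_bivariate(
            ripley_k_bivariate(pattern, mask_i, mask_j, grid, cfg.correction))
        env = independence_envelope(pattern, mask_i, mask_j, grid,
                                    n_sim=cfg.n_sim_env, seed=ss,
                                    correction=cfg.correction)
    except PatternError:
        return MISSING
    return classify_scales(l_obs, env, "bivariate").verdict


# ---------------------------------------------------------------------------
# The study driver
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig,
              plots: dict[str, PlotPattern] | None = None) -> dict:
    """Run the complete analysis bundle over the configured plots.

    ``plots`` overrides loading: otherwise ``config.input`` is read, or the
    synthetic 12-plot study fixture is generated when no input is given.
    Returns a dict of DataFrames plus a ``metadata`` entry.
    """
    cfg = config
    if plots is None:
        if cfg.input is None:
            plots = gen_study_fixture(
                _stage_seed(cfg.seed, "fixture").generate_state(1)[0] % 2**31)
        else:
            plots = load_plots(cfg.input)
    focal = cfg.focal_species
    grid = distance_grid(cfg.r_max, cfg.r_step)
    errors: list[str] = []

    stand = pd.DataFrame([_stand_rows(c, p, focal) for c, p in plots.items()])

    # --- neighbourhood indices per group -----------------------------------
    def group_patterns(code: str, p: PlotPattern):
        focal_mask = p.species_mask(focal)
        yield "all", p
        if focal_mask.any():
            yield "focal", p.subset(focal_mask)
        else:
            errors.append(f"{code}: focal species {focal!r} absent")
        try:
            split = dominance_split(p)
            yield "suppressed_all", p.subset(split.suppressed)
            yield "dominant_all", p.subset(split.dominant)
        except PatternError as e:
            errors.append(str(e))
        if focal_mask.any():
            fp = p.subset(focal_mask)
            try:
                fsplit = dominance_split(fp)
                yield "suppressed_focal", fp.subset(fsplit.suppressed)
                yield "dominant_focal", fp.subset(fsplit.dominant)
            except PatternError as e:
                errors.append(str(e))

    index_rows = []
    for code, p in plots.items():
        for group, gp in group_patterns(code, p):
            if gp.n < 2:
                index_rows.append(
                    {"code": code, "group": group, "n": gp.n,
                     **{c: np.nan for i in INDEX_NAMES
                        for c in (i, f"{i}_tail")},
                     **{f"{i}_verdict": MISSING for i in INDEX_NAMES}})
            else:
                index_rows.append(_index_row(gp, code, group, cfg))
    indices = pd.DataFrame(index_rows)
    tail_cols = [f"{i}_tail" for i in INDEX_NAMES]
    tails = indices[tail_cols].to_numpy().ravel()
    m_idx = cfg.m_indices or int(np.isfinite(tails).sum())
    thr_idx = cfg.alpha / m_idx
    for i in INDEX_NAMES:
        indices[f"{i}_bonferroni"] = indices[f"{i}_tail"].apply(
            lambda p: bool(p < thr_idx or p > 1 - thr_idx)
            if np.isfinite(p) else False)

    # --- second-order verdicts ---------------------------------------------
    so_rows = []
    dcut_rows = []
    for code, p in plots.items():
        cut_all, cut_focal = cfg.dcut_all, cfg.dcut_focal
        if cfg.scan_dcut:
            for label, pat in (("all", p),
                               ("focal", p.subset(p.species_mask(focal)))):
                try:
                    scan = dcut_scan(pat, step=cfg.dcut_step,
                                     n_sim=cfg.dcut_n_sim,
                                     seed=_stage_seed(cfg.seed, code,
                                                      f"dcut-{label}"),
                                     grid=grid, correction=cfg.correction)
                    dcut_rows.append({"code": code, "group": label,
                                      "d_cut": scan.chosen,
                                      "significant": scan.significant})
                    if scan.significant:
                        if label == "all":
                            cut_all = scan.chosen
                        else:
                            cut_focal = scan.chosen
                except PatternError as e:
                    errors.append(f"{code}: d_cut scan ({label}): {e}")
        focal_mask = p.species_mask(focal)
        small = p.dbh < cut_all
        t0 = time.monotonic()
        row = {"code": code,
               "univariate_all": _univariate_verdict(p, grid, cfg, code,
                                                     "L-all"),
               "univariate_small": _univariate_verdict(
                   p.subset(small), grid, cfg, code, "L-small")
               if small.any() else MISSING,
               "univariate_large": _univariate_verdict(
                   p.subset(~small), grid, cfg, code, "L-large")
               if (~small).any() else MISSING,
               "bivariate_focal_vs_others": _bivariate_verdict(
                   p, focal_mask, ~focal_mask, grid, cfg, code, "LB-focal"),
               "bivariate_small_vs_large": _bivariate_verdict(
                   p, small, ~small, grid, cfg, code, "LB-size"),
               }
        fsmall = focal_mask & (p.dbh < cut_focal)
        flarge = focal_mask & (p.dbh >= cut_focal)
        row["bivariate_small_vs_large_focal"] = _bivariate_verdict(
            p, fsmall, flarge, grid, cfg, code, "LB-size-focal")
        so_rows.append(row)
        _logged("second-order", code, "-", cfg.n_sim_env, t0)
    second_order = pd.DataFrame(so_rows)

    # --- covariation of plot variables with the all-species indices --------
    all_idx = indices[indices["group"] == "all"].set_index("code")
    cov_rows = []
    xvars = {"N": stand.set_index("code")["N_total"],
             "G": stand.set_index("code")["G_total"],
             "fcd": stand.set_index("code")["fcd"],
             "upsilon_0": stand.set_index("code")["upsilon_0"],
             "upsilon_2": stand.set_index("code")["upsilon_2"],
             "upsilon_inf": stand.set_index("code")["upsilon_inf"]}
    lat = stand.set_index("code")["lat"]
    if lat.notna().all():
        xvars["lat"] = lat.astype(float)
    else:
        errors.append("latitude absent for some plots; C[lat x .] skipped")
    for xname, xs in xvars.items():
        for index in INDEX_NAMES:
            ys = all_idx[index]
            ok = xs.notna() & ys.notna()
            if ok.sum() < 2:
                continue
            ss = _stage_seed(cfg.seed, "covariation", xname, index)
            try:
                res = covariation_test(xs[ok].to_numpy(), ys[ok].to_numpy(),
                                       n_perm=cfg.n_sim_perm, seed=ss,
                                       name_x=xname, name_y=index)
                cov_rows.append({"x": xname, "y": index, "n": int(ok.sum()),
                                 "C": res.c, "p": res.p})
            except PatternError:
                cov_rows.append({"x": xname, "y": index, "n": int(ok.sum()),
                                 "C": np.nan, "p": np.nan})
    covariation = pd.DataFrame(cov_rows)
    if len(covariation):
        finite = covariation["p"].notna()
        m_cov = cfg.m_covariation or int(finite.sum())
        flags, thr_cov = apply_family_correction(
            covariation["p"].fillna(1.0).to_numpy(), cfg.alpha, m_cov)
        covariation["bonferroni"] = flags & finite.to_numpy()
    else:
        thr_cov = np.nan

    # --- group mean-difference tests ---------------------------------------
    diff_rows = []
    pairs = (("focal", "all"), ("suppressed_focal", "dominant_focal"),
             ("suppressed_all", "dominant_all"))
    for ga, gb in pairs:
        for index in INDEX_NAMES:
            va = indices.loc[indices["group"] == ga, index].dropna().to_numpy()
            vb = indices.loc[indices["group"] == gb, index].dropna().to_numpy()
            if len(va) == 0 or len(vb) == 0:
                diff_rows.append({"group_a": ga, "group_b": gb, "index": index,
                                  "diff": np.nan, "p": np.nan})
                continue
            ss = _stage_seed(cfg.seed, "diff", ga, gb, index)
            res = group_mean_diff_test(va, vb, n_perm=cfg.n_sim_perm, seed=ss,
                                       label_a=ga, label_b=gb, method="perm")
            diff_rows.append({"group_a": ga, "group_b": gb, "index": index,
                              "diff": res.diff, "p": res.p})
    diff = pd.DataFrame(diff_rows)
    finite = diff["p"].notna()
    m_diff = cfg.m_diff or max(int(finite.sum()), 1)
    flags, thr_diff = apply_family_correction(
        diff["p"].fillna(1.0).to_numpy(), cfg.alpha, m_diff)
    diff["bonferroni"] = flags & finite.to_numpy()

    bundle = {
        "stand_summary": stand,
        "indices": indices,
        "second_order_verdicts": second_order,
        "covariation": covariation,
        "diff_tests": diff,
        "metadata": {
            "package_version": __version__,
            "config": asdict(cfg),
            "bonferroni_thresholds": {
                "indices": thr_idx, "covariation": float(thr_cov),
                "diff": thr_diff},
            "errors": errors,
            "plots": list(plots),
        },
    }
    if dcut_rows:
        bundle["dcut"] = pd.DataFrame(dcut_rows)
    if cfg.out_dir:
        write_tables(bundle, cfg.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Tallies and output
# ---------------------------------------------------------------------------

def tally_verdicts(tail_values, low: float = 0.01, high: float = 0.99) -> dict:
    """Count plots reading clustering / CSR / regularity from tail values.

    ``tail_values`` are the clustering-direction tail probabilities (e.g.
    1 - P(Z >= CE)); values below ``low`` count as clustering, above
    ``high`` as regularity, the rest as CSR.  Percentages are reported to
    one decimal.
    """
    t = np.asarray(pd.Series(tail_values).dropna(), dtype=float)
    if t.size == 0:
        raise PatternError("no tail values to tally")
    if np.any((t < 0) | (t > 1)):
        raise PatternError("tail values must lie in [0, 1]")
    counts = {
        "clustering": int(np.sum(t < low)),
        "regularity": int(np.sum(t > high)),
    }
    counts["CSR"] = int(t.size - counts["clustering"] - counts["regularity"])
    return {
        "n": int(t.size),
        "counts": counts,
        "percent": {k: round(100.0 * v / t.size, 1) for k, v in counts.items()},
    }


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if "tail" in col or col in ("p", "fcd"):
            out[col] = out[col].map(lambda v: f"{v:.4f}" if pd.notna(v)
                                    else MISSING)
        else:
            out[col] = out[col].map(lambda v: f"{v:.3f}" if pd.notna(v)
                                    else MISSING)
    return out


def write_tables(bundle: dict, path, formats=("tsv", "json")) -> list[Path]:
    """Write the bundle as TSV tables plus a JSON metadata/record file.

    Column order is the construction order of each table and numeric cells
    are formatted at fixed precision (indices 3 dp, probabilities 4 dp), so
    identical bundles produce byte-identical files.
    """
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            if "tsv" in formats:
                f = out_dir / f"{name}.tsv"
                _format_frame(obj).to_csv(f, sep="\t", index=False)
                written.append(f)
            if "json" in formats:
                f = out_dir / f"{name}.json"
                f.write_text(json.dumps(
                    json.loads(_format_frame(obj).to_json(orient="records")),
                    indent=1) + "\n")
                written.append(f)
    meta = out_dir / "run_metadata.json"
    meta.write_text(json.dumps(bundle.get("metadata", {}), indent=1,
                               default=str) + "\n")
    written.append(meta)
    return written
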