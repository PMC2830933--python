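"""Readers, writers and run manifests.

Everything on disk is plain CSV (records, posterior samples in long
format, summaries) plus a small YAML manifest per run recording the
configuration and seeds, so that any output is reproducible from its
manifest alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FIXED_EFFECT_LEVELS, RECORD_COLUMNS, GLCategoryMap
from .gibbs import MCMCConfig, PosteriorSamples

DEFAULT_GL_WINDOW = (240, 310)


class RecordValidationError(ValueError):
    pass


def validate_records(df: pd.DataFrame, c_cd: int = 3,
                     gl_window: tuple[int, int] = DEFAULT_GL_WINDOW) -> pd.DataFrame:
    """Validate a record table in place; errors name the offending rows."""
    if len(df) == 0:
        raise RecordValidationError("empty input: no records")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing column(s): {', '.join(missing)}")

    def bad_rows(mask) -> str:
        rows = df.index[mask].tolist()[:10]
        return ", ".join(str(r) for r in rows)

    for col in RECORD_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.integer):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                raise RecordValidationError(
                    f"non-integer {col} at row(s) {bad_rows(bad)}")
            df[col] = coerced.astype(int)
    lo, hi = gl_window
    bad = (df["gl_days"] < lo) | (df["gl_days"] > hi)
    if bad.any():
        raise RecordValidationError(
            f"gl_days outside [{lo}, {hi}] at row(s) {bad_rows(bad)}")
    bad = (df["cd_score"] < 1) | (df["cd_score"] > c_cd)
    if bad.any():
        raise RecordValidationError(
            f"cd_score outside 1..{c_cd} at row(s) {bad_rows(bad)}")
    bad = ~df["sb_score"].isin([1, 2])
    if bad.any():
        raise RecordValidationError(f"sb_score not in {{1, 2}} at row(s) {bad_rows(bad)}")
    for col, n_levels in FIXED_EFFECT_LEVELS.items():
        bad = (df[col] < 1) | (df[col] > n_levels)
        if bad.any():
            raise RecordValidationError(
                f"{col} outside 1..{n_levels} at row(s) {bad_rows(bad)}")
    return df


def read_records(path, c_cd: int = 3,
                 gl_window: tuple[int, int] = DEFAULT_GL_WINDOW) -> pd.DataFrame:
    """Read and validate a records CSV; row order is preserved."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise RecordValidationError(f"empty input file: {path}") from None
    return validate_records(df, c_cd=c_cd, gl_window=gl_window)


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(RECORD_COLUMNS))


def write_manifest(path, **entries) -> None:
    clean = {}
    for k, v in entries.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        clean[k] = v
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Fit persistence
# ---------------------------------------------------------------------------

_SCALAR_PARAMS = ("lambda", "G0", "H0", "R0", "b", "thresholds")


def _flatten(name: str, arr: np.ndarray):
    """Yield (label, 1-d values) per scalar component of one chain's draws."""
    if arr.ndim == 1:
        yield name, arr
        return
    if name in ("G0", "H0", "R0"):
        d = arr.shape[1]
        for i in range(d):
            for j in range(i, d):
                yield f"{name}[{i},{j}]", arr[:, i, j]
    else:
        flat = arr.reshape(arr.shape[0], -1)
        idx = [np.unravel_index(i, arr.shape[1:]) for i in range(flat.shape[1])]
        for col, ix in enumerate(idx):
            yield f"{name}[{','.join(map(str, ix))}]", flat[:, col]


def save_fit(samples: PosteriorSamples, out_dir, version: str = "") -> None:
    """Persist a fit: long-format sample CSVs (one per chain), record-level
    posterior means, posterior-mean effects, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = samples.config
    for c in range(cfg.n_chains):
        frames = []
        ret = samples.draws["lambda"].shape[1]
        iters = cfg.burn_in + cfg.thin * np.arange(1, ret + 1)
        for name in _SCALAR_PARAMS:
            for label, values in _flatten(name, samples.draws[name][c]):
                frames.append(pd.DataFrame(
                    {"iteration": iters, "parameter": label, "value": values}))
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"samples_chain{c + 1}.csv", index=False)
    liab = samples.record_means["liab"].mean(axis=0)
    eta = samples.record_means["eta"].mean(axis=0)
    pd.DataFrame({
        "eta_gl": eta[:, 0], "eta_cd": eta[:, 1], "eta_sb": eta[:, 2],
        "liab_cd": liab[:, 1], "liab_sb": liab[:, 2],
    }).to_csv(out / "record_means.csv", index=False)
    h_mean = samples.posterior_mean("h")
    u_mean = samples.posterior_mean("u")
    pd.DataFrame({"herd_year_id": samples.herd_ids,
                  "h_gl": h_mean[:, 0], "h_cd": h_mean[:, 1],
                  "h_sb": h_mean[:, 2]}).to_csv(out / "herd_means.csv", index=False)
    pd.DataFrame({"bull_id": samples.bull_ids,
                  "s_gl": u_mean[:, 0], "s_cd": u_mean[:, 1], "s_sb": u_mean[:, 2],
                  "mgs_gl": u_mean[:, 3], "mgs_cd": u_mean[:, 4],
                  "mgs_sb": u_mean[:, 5]}).to_csv(out / "bull_means.csv", index=False)
    write_manifest(out / "manifest.yaml",
                   variant=samples.variant,
                   n_chains=cfg.n_chains, n_iterations=cfg.n_iterations,
                   burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed,
                   gl_reference=samples.gl_reference,
                   category_boundaries=list(samples.cat_map.boundaries),
                   c_cd=samples.c_cd, version=version)


def load_fit(fit_dir) -> PosteriorSamples:
    """Rebuild a :class:`PosteriorSamples` from a saved fit.

    Scalar parameter draws are restored exactly; the herd and bull effects
    are restored as their posterior means only (sufficient for prediction,
    summaries and comparison).
    """
    fit_dir = Path(fit_dir)
    man = read_manifest(fit_dir / "manifest.yaml")
    cfg = MCMCConfig(n_chains=man["n_chains"], n_iterations=man["n_iterations"],
                     burn_in=man["burn_in"], thin=man["thin"], seed=man["seed"])
    chains = []
    for c in range(cfg.n_chains):
        chains.append(pd.read_csv(fit_dir / f"samples_chain{c + 1}.csv"))
    nk = len(man["category_boundaries"]) + 1
    c_cd = man["c_cd"]
    shapes = {"lambda": (nk, 3), "G0": (6, 6), "H0": (3, 3), "R0": (3, 3),
              "b": (16, 3), "thresholds": (c_cd - 1,)}
    draws = {}
    ret = cfg.retained_per_chain
    for name, shape in shapes.items():
        draws[name] = np.zeros((cfg.n_chains, ret) + shape)
    for c, df in enumerate(chains):
        for label, sub in df.groupby("parameter", sort=False):
            name = label.split("[")[0]
            if name not in shapes:
                continue
            vals = sub["value"].to_numpy()
            if "[" in label:
                ix = tuple(int(t) for t in label[label.index("[") + 1:-1].split(","))
            else:
                ix = ()
            draws[name][(c, slice(None)) + ix] = vals
            if name in ("G0", "H0", "R0") and len(ix) == 2 and ix[0] != ix[1]:
                draws[name][(c, slice(None)) + (ix[1], ix[0])] = vals
    rm = pd.read_csv(fit_dir / "record_means.csv")
    n = len(rm)
    liab = np.zeros((1, n, 3))
    eta = np.zeros((1, n, 3))
    eta[0, :, 0] = rm["eta_gl"]
    eta[0, :, 1] = rm["eta_cd"]
    eta[0, :, 2] = rm["eta_sb"]
    liab[0, :, 1] = rm["liab_cd"]
    liab[0, :, 2] = rm["liab_sb"]
    herd = pd.read_csv(fit_dir / "herd_means.csv")
    bull = pd.read_csv(fit_dir / "bull_means.csv")
    # single pseudo-draw holding the posterior mean of each effect
    draws["h"] = herd[["h_gl", "h_cd", "h_sb"]].to_numpy()[None, None]
    draws["u"] = bull[["s_gl", "s_cd", "s_sb", "mgs_gl", "mgs_cd",
                       "mgs_sb"]].to_numpy()[None, None]
    return PosteriorSamples(
        variant=man["variant"], config=cfg, draws=draws,
        record_means={"liab": liab, "eta": eta},
        herd_ids=herd["herd_year_id"].to_numpy(),
        bull_ids=bull["bull_id"].to_numpy(),
        gl_reference=man["gl_reference"],
        cat_map=GLCategoryMap(tuple(man["category_boundaries"])),
        c_cd=c_cd,
    )
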