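"""Posterior summaries: means, HPD intervals, Monte-Carlo error, convergence
checks, and the per-category genetic-parameter transformation of every
retained draw."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    N_TRAITS, TRAITS, DispersionSet, GLCategoryMap, StructuralCoefficients,
    genetic_parameters, overall_effect_sb_from_gl,
)
from .gibbs import PosteriorSamples


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    n = draws.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    d = np.sort(draws)
    m = int(np.ceil(mass * n))
    widths = d[m - 1:] - d[:n - m + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m - 1])


def mcse(draws: np.ndarray) -> float:
    """Batch-means Monte-Carlo standard error with floor(sqrt(n)) batches."""
    draws = np.asarray(draws, dtype=float).ravel()
    n = draws.size
    if n < 100:
        raise ValueError("need at least 100 draws for an MCSE")
    n_batches = int(np.floor(np.sqrt(n)))
    batch_size = n // n_batches
    used = n_batches * batch_size
    means = draws[:used].reshape(n_batches, batch_size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def ess_rhat(chains: np.ndarray) -> tuple[float, float]:
    """Effective sample size and split-Rhat for (n_chains, n_draws) draws."""
    import warnings

    import arviz as az
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    data = az.convert_to_dataset({"x": chains})
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        ess = float(az.ess(data)["x"].values)
        if chains.shape[0] * chains.shape[1] < 4 or chains.shape[1] < 4:
            return ess, np.nan
        rhat = float(az.rhat(data)["x"].values)
    return ess, rhat


@dataclass
class SummaryTable:
    """Long-format per-parameter posterior summary."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _summary_row(name: str, category, chains: np.ndarray,
                 rhat_threshold: float = 1.05) -> dict:
    pooled = chains.ravel()
    h95 = hpd_interval(pooled, 0.95)
    h90 = hpd_interval(pooled, 0.90)
    ess, rhat = ess_rhat(chains)
    return {
        "parameter": name, "category": category,
        "mean": float(pooled.mean()), "sd": float(pooled.std(ddof=1)),
        "hpd95_lo": h95[0], "hpd95_hi": h95[1],
        "hpd90_lo": h90[0], "hpd90_hi": h90[1],
        "mcse": mcse(pooled), "ess": ess, "rhat": rhat,
    }


def scalar_summaries(samples: PosteriorSamples) -> SummaryTable:
    """Summaries of structural coefficients and dispersion components."""
    rows = []
    lam = samples.draws["lambda"]                # (C, R, K, 3)
    lam_names = ("lambda_cd_gl", "lambda_sb_gl", "lambda_sb_cd")
    nk = lam.shape[2]
    for k in range(nk):
        for j, nm in enumerate(lam_names):
            rows.append(_summary_row(nm, k + 1, lam[:, :, k, j]))
        overall = lam[:, :, k, 1] + lam[:, :, k, 0] * lam[:, :, k, 2]
        rows.append(_summary_row("overall_sb_gl", k + 1, overall))
    for mat, dim in (("G0", 6), ("H0", 3), ("R0", 3)):
        a = samples.draws[mat]
        for i in range(dim):
            for j in range(i, dim):
                rows.append(_summary_row(f"{mat}[{i},{j}]", None, a[:, :, i, j]))
    table = pd.DataFrame(rows)
    table["category"] = table["category"].astype("Int64")
    return SummaryTable(table)


# ---------------------------------------------------------------------------
# Per-draw genetic-parameter transformation
# ---------------------------------------------------------------------------

def transform_draws(samples: PosteriorSamples,
                    cat_map: GLCategoryMap | None = None,
                    include_herd_in_phenotypic: bool = False
                    ) -> tuple[pd.DataFrame, SummaryTable, int]:
    """Reduced-form genetic parameters of every retained draw, per category.

    Each draw's (G0, H0, R0, lambda) is pushed through the reduced-form
    transformation and the sire-MGS -> direct/maternal conversion, giving
    posterior draws (not transforms of posterior means) of heritabilities,
    correlations and the overall GL -> SB effect.  Returns the per-draw
    long table, a summary table, and the count of draws whose implied
    per-trait (direct, maternal) matrix failed the PSD check (a warning
    count, never an error).
    """
    if cat_map is None:
        cat_map = samples.cat_map
    g0 = samples.pooled("G0")
    h0 = samples.pooled("H0")
    r0 = samples.pooled("R0")
    lam = samples.pooled("lambda")
    n_draws = g0.shape[0]
    nk = lam.shape[1]
    psd_warnings = 0
    rows = []
    for d in range(n_draws):
        coeffs = StructuralCoefficients.from_matrix(lam[d])
        disp = DispersionSet.__new__(DispersionSet)  # skip mask validation per draw
        disp.G0, disp.H0, disp.R0 = g0[d], h0[d], r0[d]
        disp.variant = samples.variant
        for k in range(1, nk + 1):
            s = genetic_parameters(disp, coeffs, k,
                                   include_herd_in_phenotypic=include_herd_in_phenotypic)
            if not s.willham.psd_ok.all():
                psd_warnings += 1
            row = {"draw": d, "category": k,
                   "overall_sb_gl": overall_effect_sb_from_gl(coeffs, k)}
            for t, trait in enumerate(TRAITS):
                row[f"h2_direct_{trait}"] = s.h2_direct[t]
                row[f"h2_maternal_{trait}"] = s.h2_maternal[t]
            for a in range(N_TRAITS):
                for b in range(N_TRAITS):
                    if a < b:
                        row[f"r_direct_{TRAITS[a]}_{TRAITS[b]}"] = s.corr_direct[a, b]
                        row[f"r_maternal_{TRAITS[a]}_{TRAITS[b]}"] = s.corr_maternal[a, b]
                        row[f"r_herd_{TRAITS[a]}_{TRAITS[b]}"] = s.corr_herd[a, b]
                        row[f"r_residual_{TRAITS[a]}_{TRAITS[b]}"] = s.corr_residual[a, b]
                    row[f"r_dm_{TRAITS[a]}_{TRAITS[b]}"] = s.corr_direct_maternal[a, b]
            rows.append(row)
    per_draw = pd.DataFrame(rows)
    srows = []
    for k in range(1, nk + 1):
        sub = per_draw[per_draw["category"] == k]
        for col in per_draw.columns:
            if col in ("draw", "category"):
                continue
            srows.append(_summary_row_pooled(col, k, sub[col].to_numpy()))
    return per_draw, SummaryTable(pd.DataFrame(srows)), psd_warnings


def _summary_row_pooled(name: str, category, pooled: np.ndarray) -> dict:
    h95 = hpd_interval(pooled, 0.95)
    h90 = hpd_interval(pooled, 0.90)
    return {
        "parameter": name, "category": category,
        "mean": float(pooled.mean()), "sd": float(pooled.std(ddof=1)),
        "hpd95_lo": h95[0], "hpd95_hi": h95[1],
        "hpd90_lo": h90[0], "hpd90_hi": h90[1],
        "mcse": mcse(pooled), "ess": np.nan, "rhat": np.nan,
    }
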