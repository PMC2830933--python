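"""Synthetic calving-trait records with the structure the models assume.

The real analysis data (US national calving-ease records: tens of thousands
of primiparous cows, hundreds of sires/maternal grandsires, herd-year
contemporary groups) are not public; this module generates datasets with
the same statistical skeleton at configurable (default: reduced) scale so
that every downstream stage can be exercised end to end.

Records are generated under the recursive threshold model: herd-year,
sire and MGS effects and residuals are drawn from H0, G0 and R0, GL is the
continuous trait (rounded to integer days, never truncated — the outer GL
categories absorb the tails), the CD and SB liabilities then accumulate the
category-dependent recursion terms, and ordinal scores arise by
thresholding.  The recursion covariate is GL expressed as a deviation from
a fixed reference day (``gl_reference``, default the design's mean), which
anchors the piecewise-linear category slopes at a common point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CD, GL, SB, FIXED_EFFECT_LEVELS, GLCategoryMap, DispersionSet,
    StructuralCoefficients, Thresholds,
)

#: Category-wise recursion rates used as the default simulation truth.
#: lam_cd_gl and lam_sb_cd follow the magnitudes reported for recursive
#: analyses of US Holstein calving records; lam_sb_gl is the direct rate
#: implied by the reported overall GL->SB effects minus the mediated part.
DEFAULT_LAM_CD_GL = np.array([0.005, 0.020, 0.032, 0.040])
DEFAULT_LAM_SB_CD = np.array([0.339, 0.331, 0.330, 0.3311])
DEFAULT_OVERALL_SB_GL = np.array([-0.044, -0.021, -0.008, 0.024])
DEFAULT_LAM_SB_GL = DEFAULT_OVERALL_SB_GL - DEFAULT_LAM_CD_GL * DEFAULT_LAM_SB_CD


@dataclass
class SimulationDesign:
    """Shape of a simulated dataset (ids, levels, no phenotype values)."""

    n_records: int = 5000
    n_sires: int = 60
    n_mgs: int = 120
    n_herd_years: int = 40
    gl_mean: float = 278.0
    mgs_sire_overlap: float = 0.3  # fraction of MGS ids that are also sires
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_records", "n_sires", "n_mgs", "n_herd_years"):
            if getattr(self, name) < 0 or (name != "n_records" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.mgs_sire_overlap <= 1.0:
            raise ValueError("mgs_sire_overlap must lie in [0, 1]")


def default_true_parameters(variant: str = "RMM3",
                            n_categories: int = 4,
                            c_cd: int = 3) -> "TrueParameters":
    """Simulation truth with realistic magnitudes for calving traits.

    Variance components are chosen so that on the reduced-form scale the
    direct heritability of GL is about 0.37 and those of the CD and SB
    liabilities fall below 0.1, with GL phenotypic SD near 5 days —
    magnitudes typical of primiparous Holstein calving data.  Herd-year
    variances are scale guesses (only correlations of these are reported in
    the literature this emulates).
    """
    lam = StructuralCoefficients(
        DEFAULT_LAM_CD_GL[:n_categories].copy(),
        DEFAULT_LAM_SB_GL[:n_categories].copy(),
        DEFAULT_LAM_SB_CD[:n_categories].copy(),
    )
    s_var = np.array([2.0, 0.02, 0.015])
    mgs_var = np.array([1.0, 0.02, 0.02])
    s_mgs_cov = np.array([0.7, 0.008, 0.006])
    g0 = np.zeros((6, 6))
    for t in range(3):
        g0[t, t] = s_var[t]
        g0[t + 3, t + 3] = mgs_var[t]
        g0[t, t + 3] = g0[t + 3, t] = s_mgs_cov[t]
    h0 = np.diag([2.0, 0.03, 0.03])
    r0 = np.diag([18.0, 0.8, 1.0])
    if variant in ("SMM", "RMM1", "RMM2"):
        # mild cross-trait structure so unstructured blocks are exercised
        g0[GL, CD + 3] = g0[CD + 3, GL] = 0.02
        g0[GL, CD] = g0[CD, GL] = 0.06
        if variant in ("SMM", "RMM1"):
            h0[CD, SB] = h0[SB, CD] = 0.012
        if variant == "SMM":
            r0[GL, CD] = r0[CD, GL] = 0.9
            r0[CD, SB] = r0[SB, CD] = 0.35
            lam = StructuralCoefficients.zeros(n_categories)
    disp = DispersionSet(g0, h0, r0, variant=variant)
    b = _default_fixed_effects()
    return TrueParameters(b=b, coeffs=lam, dispersion=disp,
                          thresholds=Thresholds.default(c_cd), c_cd=c_cd)


def _default_fixed_effects() -> np.ndarray:
    """(16, 3) coefficient matrix: intercept + corner-coded sex/age/year-season.

    Intercepts place mean GL at the design reference and the liabilities
    near their thresholds (roughly 70/24/6% CD scores and ~8% stillbirth);
    the level contrasts are small shifts of plausible sign (male calves:
    longer gestation, harder calving).
    """
    b = np.zeros((16, 3))
    b[0] = [0.0, -0.5, -1.35]          # intercepts (GL intercept on top of gl_mean)
    b[1] = [1.2, 0.25, 0.12]           # sex: male vs female
    b[2:5, GL] = [-0.4, 0.2, 0.5]      # age-at-first-calving classes 2..4
    b[2:5, CD] = [-0.05, -0.1, -0.15]
    b[2:5, SB] = [-0.02, -0.05, -0.08]
    rng = np.random.default_rng(20100125)
    b[5:16, GL] = rng.normal(0.0, 0.5, 11)      # year-season classes 2..12
    b[5:16, CD] = rng.normal(0.0, 0.05, 11)
    b[5:16, SB] = rng.normal(0.0, 0.05, 11)
    return b


@dataclass
class TrueParameters:
    """Everything the generator needs: fixed effects, recursion, dispersion."""

    b: np.ndarray                      # (16, 3) corner-coded fixed effects
    coeffs: StructuralCoefficients
    dispersion: DispersionSet
    thresholds: Thresholds
    c_cd: int = 3
    category_map: GLCategoryMap = field(default_factory=GLCategoryMap)

    def __post_init__(self) -> None:
        if self.thresholds.n_cd_categories != self.c_cd:
            raise ValueError("thresholds inconsistent with C_cd")
        self.dispersion.validate()


def design_matrix(sex: np.ndarray, age_class: np.ndarray,
                  year_season: np.ndarray) -> np.ndarray:
    """Corner-constrained fixed-effect design: intercept + levels 2..L."""
    n = len(sex)
    x = np.zeros((n, 16))
    x[:, 0] = 1.0
    x[:, 1] = (sex == 2)
    for j in range(2, 5):
        x[:, j] = (age_class == j)
    for j in range(2, 13):
        x[:, 3 + j] = (year_season == j)
    return x


def generate_design(design: SimulationDesign) -> pd.DataFrame:
    """Record skeleton: ids and fixed-effect levels, no phenotypes.

    Sires are bulls 1..n_sires.  A fraction ``mgs_sire_overlap`` of the MGS
    id list is drawn from the sires (so the sire-MGS covariance is
    identifiable); the rest are additional bulls.  Assignments are uniform.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_records
    n_overlap = int(round(design.mgs_sire_overlap * design.n_mgs))
    n_overlap = min(n_overlap, design.n_sires)
    overlap_ids = rng.choice(np.arange(1, design.n_sires + 1), size=n_overlap,
                             replace=False)
    extra_ids = design.n_sires + 1 + np.arange(design.n_mgs - n_overlap)
    mgs_pool = np.concatenate([overlap_ids, extra_ids])
    smallest_pool = min(design.n_sires, design.n_mgs, design.n_herd_years)
    if 0 < n < smallest_pool:
        warnings.warn("fewer records than levels: some sire/MGS/herd levels "
                      "will be empty", stacklevel=2)
    df = pd.DataFrame({
        "record_id": np.arange(1, n + 1),
        "sire_id": rng.integers(1, design.n_sires + 1, size=n),
        "mgs_id": rng.choice(mgs_pool, size=n),
        "herd_year_id": rng.integers(1, design.n_herd_years + 1, size=n),
        "sex": rng.integers(1, FIXED_EFFECT_LEVELS["sex"] + 1, size=n),
        "age_class": rng.integers(1, FIXED_EFFECT_LEVELS["age_class"] + 1, size=n),
        "year_season": rng.integers(1, FIXED_EFFECT_LEVELS["year_season"] + 1, size=n),
    })
    return df


def simulate_records(skeleton: pd.DataFrame, truth: TrueParameters, seed: int,
                     gl_mean: float = 278.0,
                     gl_reference: float | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes + latent truth for a record skeleton.

    Returns ``(records, latent)``.  ``records`` has the observable columns
    only; ``latent`` carries the liabilities, realized effects and residuals
    and must never be read by the fitting pipeline (test use only).

    The GL category of each record is determined from its realized,
    rounded GL, exactly as in the phenotypic recursion being modelled.
    """
    rng = np.random.default_rng(seed)
    n = len(skeleton)
    if gl_reference is None:
        gl_reference = gl_mean
    disp = truth.dispersion
    bulls = np.union1d(skeleton["sire_id"].to_numpy(),
                       skeleton["mgs_id"].to_numpy()) if n else np.array([], dtype=int)
    bull_index = {b: i for i, b in enumerate(bulls)}
    # joint 6-vector per bull: (s_GL, s_CD, s_SB, mgs_GL, mgs_CD, mgs_SB)
    u = rng.multivariate_normal(np.zeros(6), disp.G0, size=len(bulls),
                                method="cholesky") if len(bulls) else np.zeros((0, 6))
    herd_ids = np.unique(skeleton["herd_year_id"].to_numpy()) if n else np.array([], dtype=int)
    herd_index = {h: i for i, h in enumerate(herd_ids)}
    h = rng.multivariate_normal(np.zeros(3), disp.H0, size=len(herd_ids),
                                method="cholesky") if len(herd_ids) else np.zeros((0, 3))
    eps = rng.multivariate_normal(np.zeros(3), disp.R0, size=n,
                                  method="cholesky") if n else np.zeros((0, 3))

    if n == 0:
        empty = skeleton.copy()
        for c in ("gl_days", "cd_score", "sb_score"):
            empty[c] = np.array([], dtype=int)
        return empty, pd.DataFrame()

    x = design_matrix(skeleton["sex"].to_numpy(), skeleton["age_class"].to_numpy(),
                      skeleton["year_season"].to_numpy())
    fixed = x @ truth.b                                   # (n, 3)
    s_idx = skeleton["sire_id"].map(bull_index).to_numpy()
    m_idx = skeleton["mgs_id"].map(bull_index).to_numpy()
    h_idx = skeleton["herd_year_id"].map(herd_index).to_numpy()
    mu = fixed + h[h_idx] + u[s_idx, :3] + u[m_idx, 3:]   # (n, 3)

    gl_cont = gl_mean + mu[:, GL] + eps[:, GL]
    gl_days = np.rint(gl_cont).astype(int)
    k = truth.category_map.category(gl_days)              # 1-based
    g_dev = gl_days - gl_reference

    lam_cd = truth.coeffs.lam_cd_gl[k - 1]
    lam_sbg = truth.coeffs.lam_sb_gl[k - 1]
    lam_sbc = truth.coeffs.lam_sb_cd[k - 1]
    l_cd = lam_cd * g_dev + mu[:, CD] + eps[:, CD]
    l_sb = lam_sbg * g_dev + lam_sbc * l_cd + mu[:, SB] + eps[:, SB]

    cd_edges = np.concatenate([[-np.inf], truth.thresholds.cd, [np.inf]])
    cd_score = np.digitize(l_cd, cd_edges[1:-1], right=True) + 1
    sb_score = np.where(l_sb <= truth.thresholds.sb, 1, 2)

    records = skeleton.copy()
    records["gl_days"] = gl_days
    records["cd_score"] = cd_score.astype(int)
    records["sb_score"] = sb_score.astype(int)

    latent = skeleton[["record_id"]].copy()
    latent["gl_continuous"] = gl_cont
    latent["gl_category"] = k
    latent["liab_cd"] = l_cd
    latent["liab_sb"] = l_sb
    for t, name in enumerate(("gl", "cd", "sb")):
        latent[f"mu_{name}"] = mu[:, t]
        latent[f"eps_{name}"] = eps[:, t]
    return records, latent


def simulate_dataset(design: SimulationDesign, truth: TrueParameters | None = None,
                     variant: str = "RMM3"
                     ) -> tuple[pd.DataFrame, pd.DataFrame, TrueParameters]:
    """Convenience wrapper: skeleton + phenotypes under default truth."""
    if truth is None:
        truth = default_true_parameters(variant)
    skeleton = generate_design(design)
    records, latent = simulate_records(skeleton, truth, seed=design.seed + 1,
                                       gl_mean=design.gl_mean)
    return records, latent, truth
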