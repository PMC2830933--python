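"""Gibbs sampling for the standard and recursive threshold mixed models.

All full conditionals are closed-form: truncated normals for the CD/SB
liabilities, multivariate normals for location effects and structural
coefficients, inverted Wisharts / scaled inverse chi-squares for the
dispersion components, and uniforms for free thresholds.  The scan order
per iteration is liabilities -> fixed effects + structural coefficients ->
herd-year effects -> bull (sire, MGS) effects -> thresholds -> dispersion.

For the recursive variants the structural coefficients of a trait equation
are drawn *jointly* with that equation's fixed effects: the lambda's
multiply a covariate (GL deviation) whose mean is absorbed by the
intercept, so single-site updates of lambda given the intercept would walk
a near-degenerate ridge.  The joint draw is an exact Gibbs blocking of the
same posterior.  Standalone single-block updates are also provided
(:func:`sample_location_effects`, :func:`sample_structural_coefficients`)
and are used by the unit tests.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CD, GL, SB, N_TRAITS, VARIANTS, DispersionSet, GLCategoryMap,
    StructuralCoefficients, Thresholds, variant_masks,
)
from .distributions import (
    sample_cond_invwishart_fixed_corner, sample_invwishart,
    sample_mvn_from_precision, scaled_inv_chi2, truncated_normal,
)
from .simulate import design_matrix

N_FIXED = 16  # intercept + sex + 3 age + 11 year-season contrasts


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Chain bookkeeping: 5 x 10,000 iterations, 1,000 burn-in, thin 10
    retains 4,500 draws with the defaults."""

    n_chains: int = 5
    n_iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the closed-form priors.

    Inverted-Wishart blocks use df = dimension + 1 and scale 0.1 I by
    default; diagonal variances use Scale-inv-chi2(nu=4, s2=0.1); the
    structural coefficients get N(0, 1e4) (proper but effectively flat);
    fixed effects get N(0, 1e6) per coefficient (numerically flat, keeps
    the conditional proper if a design column is empty).
    """

    iw_scale: float = 0.1
    iw_df_extra: float = 1.0      # df = dim + iw_df_extra
    sic_nu: float = 4.0
    sic_s2: float = 0.1
    lambda_mean: float = 0.0
    lambda_var: float = 1.0e4
    b_var: float = 1.0e6

    def iw_df(self, dim: int) -> float:
        df = dim + self.iw_df_extra
        if df <= dim - 1:
            raise ValueError("inverted-Wishart df too small for a proper prior")
        return df


# ---------------------------------------------------------------------------
# Data preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Design arrays extracted once from a record table."""

    n: int
    x: np.ndarray            # (n, N_FIXED) fixed-effect design
    g: np.ndarray            # (n,) GL deviation from gl_reference
    kcat: np.ndarray         # (n,) 0-based GL category
    cd_score: np.ndarray
    sb_score: np.ndarray
    h_idx: np.ndarray        # (n,) herd level index
    s_idx: np.ndarray        # (n,) bull index of the sire
    m_idx: np.ndarray        # (n,) bull index of the MGS
    herd_ids: np.ndarray
    bull_ids: np.ndarray
    cat_map: GLCategoryMap
    c_cd: int
    gl_reference: float
    # per-bull record index lists and sire/MGS-coincidence counts
    sire_recs: list = field(repr=False, default_factory=list)
    mgs_recs: list = field(repr=False, default_factory=list)
    n_both: np.ndarray = field(repr=False, default_factory=lambda: np.zeros(0, int))

    @property
    def n_herds(self) -> int:
        return len(self.herd_ids)

    @property
    def n_bulls(self) -> int:
        return len(self.bull_ids)

    @property
    def n_categories(self) -> int:
        return self.cat_map.n_categories


def build_model_data(records: pd.DataFrame, c_cd: int = 3,
                     cat_map: GLCategoryMap | None = None,
                     gl_reference: float | None = None) -> ModelData:
    """Preprocess a validated record table for sampling.

    ``gl_reference`` anchors the recursion covariate (GL deviation); by
    default the rounded sample mean of GL is used and recorded so that a
    fitted model can be applied to new records consistently.
    """
    if cat_map is None:
        cat_map = GLCategoryMap()
    if len(records) == 0:
        raise ValueError("no records")
    gl = records["gl_days"].to_numpy(dtype=float)
    if gl_reference is None:
        gl_reference = float(np.round(gl.mean()))
    herd_ids, h_idx = np.unique(records["herd_year_id"].to_numpy(), return_inverse=True)
    bull_ids = np.union1d(records["sire_id"].to_numpy(), records["mgs_id"].to_numpy())
    lookup = {b: i for i, b in enumerate(bull_ids)}
    s_idx = records["sire_id"].map(lookup).to_numpy()
    m_idx = records["mgs_id"].map(lookup).to_numpy()
    x = design_matrix(records["sex"].to_numpy(), records["age_class"].to_numpy(),
                      records["year_season"].to_numpy())
    data = ModelData(
        n=len(records), x=x, g=gl - gl_reference,
        kcat=np.asarray(cat_map.category(records["gl_days"].to_numpy())) - 1,
        cd_score=records["cd_score"].to_numpy(),
        sb_score=records["sb_score"].to_numpy(),
        h_idx=h_idx, s_idx=s_idx, m_idx=m_idx,
        herd_ids=herd_ids, bull_ids=bull_ids,
        cat_map=cat_map, c_cd=c_cd, gl_reference=gl_reference,
    )
    nb = data.n_bulls
    data.sire_recs = [np.flatnonzero(s_idx == q) for q in range(nb)]
    data.mgs_recs = [np.flatnonzero(m_idx == q) for q in range(nb)]
    data.n_both = np.array([int(np.intersect1d(s, m, assume_unique=True).size)
                            for s, m in zip(data.sire_recs, data.mgs_recs)])
    return data


# ---------------------------------------------------------------------------
# Chain state
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """Current values of every unknown.  ``y`` holds the working phenotype
    triple per record: column 0 is the (observed, fixed) GL deviation and
    columns 1-2 the augmented CD and SB liabilities."""

    b: np.ndarray                 # (N_FIXED, 3)
    h: np.ndarray                 # (n_herds, 3)
    u: np.ndarray                 # (n_bulls, 6), (sire | MGS) x traits
    y: np.ndarray                 # (n, 3)
    coeffs: StructuralCoefficients
    disp: DispersionSet
    thresholds: Thresholds

    def random_part(self, data: ModelData) -> np.ndarray:
        """(n, 3) herd + sire + MGS contribution per record."""
        return (self.h[data.h_idx] + self.u[data.s_idx, :3]
                + self.u[data.m_idx, 3:])

    def mu(self, data: ModelData) -> np.ndarray:
        """(n, 3) linear predictor X b + herd + sire + MGS."""
        return data.x @ self.b + self.random_part(data)

    def lam_per_record(self, data: ModelData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k = data.kcat
        c = self.coeffs
        return c.lam_cd_gl[k], c.lam_sb_gl[k], c.lam_sb_cd[k]

    def working(self, data: ModelData) -> np.ndarray:
        """w = Lambda_k y per record: structural-equation left-hand side."""
        lcg, lsg, lsc = self.lam_per_record(data)
        w = self.y.copy()
        w[:, CD] -= lcg * self.y[:, GL]
        w[:, SB] -= lsg * self.y[:, GL] + lsc * self.y[:, CD]
        return w


def cd_edges(thresholds: Thresholds) -> np.ndarray:
    return np.concatenate([[-np.inf], thresholds.cd, [np.inf]])


def initial_state(data: ModelData, variant: str,
                  rng: np.random.Generator) -> ChainState:
    """Dispersed but sane starting values."""
    vg = max(float(np.var(data.g)), 1.0)
    g0 = np.diag([0.05 * vg, 0.05, 0.05, 0.05 * vg, 0.05, 0.05])
    h0 = np.diag([0.1 * vg, 0.05, 0.05])
    r0 = np.diag([0.8 * vg, 0.8, 1.0])
    disp = DispersionSet(g0, h0, r0, variant=variant)
    thresholds = Thresholds.default(data.c_cd)
    y = np.zeros((data.n, 3))
    y[:, GL] = data.g
    edges = cd_edges(thresholds)
    lo, hi = edges[data.cd_score - 1], edges[data.cd_score]
    mid = np.where(np.isfinite(lo) & np.isfinite(hi), 0.5 * (lo + hi),
                   np.where(np.isfinite(lo), lo + 0.5, hi - 0.5))
    y[:, CD] = mid
    y[:, SB] = np.where(data.sb_score == 1, -0.5, 0.5)
    b = np.zeros((N_FIXED, 3))
    coeffs = StructuralCoefficients.zeros(data.n_categories)
    state = ChainState(b=b, h=np.zeros((data.n_herds, 3)),
                       u=np.zeros((data.n_bulls, 6)), y=y,
                       coeffs=coeffs, disp=disp, thresholds=thresholds)
    return state


# ---------------------------------------------------------------------------
# Full-conditional updates
# ---------------------------------------------------------------------------

def sample_liabilities(state: ChainState, data: ModelData, variant: str,
                       rng: np.random.Generator) -> None:
    """Truncated-normal refresh of the CD and SB liabilities (in place).

    RMM variants (diagonal R0): the CD conditional combines the CD
    structural equation with the information flowing back from the SB
    equation, in which l_CD is a predictor; the SB conditional is then a
    plain truncated normal around its structural mean.  SMM: each
    liability's residual is conditioned on the other two traits' residuals
    through the unstructured R0.
    """
    m = state.mu(data)
    edges = cd_edges(state.thresholds)
    lo_cd, hi_cd = edges[data.cd_score - 1], edges[data.cd_score]
    sb_thr = state.thresholds.sb
    lo_sb = np.where(data.sb_score == 1, -np.inf, sb_thr)
    hi_sb = np.where(data.sb_score == 1, sb_thr, np.inf)
    y = state.y
    if variant == "SMM":
        q = np.linalg.inv(state.disp.R0)
        e0 = y[:, GL] - m[:, GL]
        e2 = y[:, SB] - m[:, SB]
        mean_cd = m[:, CD] - (q[CD, GL] * e0 + q[CD, SB] * e2) / q[CD, CD]
        y[:, CD] = truncated_normal(mean_cd, 1.0 / np.sqrt(q[CD, CD]),
                                    lo_cd, hi_cd, rng)
        e1 = y[:, CD] - m[:, CD]
        mean_sb = m[:, SB] - (q[SB, GL] * e0 + q[SB, CD] * e1) / q[SB, SB]
        y[:, SB] = truncated_normal(mean_sb, 1.0 / np.sqrt(q[SB, SB]),
                                    lo_sb, hi_sb, rng)
        return
    lcg, lsg, lsc = state.lam_per_record(data)
    r_cd = state.disp.R0[CD, CD]
    r_sb = state.disp.R0[SB, SB]
    g = y[:, GL]
    m_cd_struct = lcg * g + m[:, CD]
    m_sb_base = lsg * g + m[:, SB]
    prec = 1.0 / r_cd + lsc ** 2 / r_sb
    mean_cd = (m_cd_struct / r_cd + lsc * (y[:, SB] - m_sb_base) / r_sb) / prec
    y[:, CD] = truncated_normal(mean_cd, np.sqrt(1.0 / prec), lo_cd, hi_cd, rng)
    y[:, SB] = truncated_normal(m_sb_base + lsc * y[:, CD], np.sqrt(r_sb),
                                lo_sb, hi_sb, rng)


def _draw_regression(ctc: np.ndarray, ctr: np.ndarray, resid_var: float,
                     prior_prec: np.ndarray, prior_mean_term: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    prec = ctc / resid_var + prior_prec
    lin = ctr / resid_var + prior_mean_term
    return sample_mvn_from_precision(prec, lin, rng)


def _fixed_prior(n_cols: int, priors: PriorSpec, n_lambda: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    d = np.full(n_cols, 1.0 / priors.b_var)
    if n_lambda:
        d[-n_lambda:] = 1.0 / priors.lambda_var
    mean_term = np.zeros(n_cols)
    if n_lambda and priors.lambda_mean:
        mean_term[-n_lambda:] = priors.lambda_mean / priors.lambda_var
    return np.diag(d), mean_term


def _lambda_design(data: ModelData, y_cd: np.ndarray | None = None
                   ) -> np.ndarray:
    """Category-indicator covariate columns g*1{k} (and l_CD*1{k})."""
    nk = data.n_categories
    onehot = np.eye(nk)[data.kcat]                       # (n, K)
    cols = [data.g[:, None] * onehot]
    if y_cd is not None:
        cols.append(y_cd[:, None] * onehot)
    return np.hstack(cols)


def sample_fixed_and_structural(state: ChainState, data: ModelData, variant: str,
                                priors: PriorSpec, rng: np.random.Generator
                                ) -> None:
    """Joint draw of b (and, for RMMs, lambda) per trait equation."""
    rand = state.random_part(data)
    y = state.y
    if variant == "SMM":
        _sample_b_smm(state, data, priors, rng, rand)
        return
    nk = data.n_categories
    r = np.diag(state.disp.R0)
    # GL equation: fixed effects only
    prior_prec, prior_mean = _fixed_prior(N_FIXED, priors)
    resp = y[:, GL] - rand[:, GL]
    beta = _draw_regression(data.x.T @ data.x, data.x.T @ resp, r[GL],
                            prior_prec, prior_mean, rng)
    state.b[:, GL] = beta
    # CD equation: b_CD with the K lambdas on the GL-deviation covariate
    c_cd = np.hstack([data.x, _lambda_design(data)])
    prior_prec, prior_mean = _fixed_prior(N_FIXED + nk, priors, n_lambda=nk)
    resp = y[:, CD] - rand[:, CD]
    beta = _draw_regression(c_cd.T @ c_cd, c_cd.T @ resp, r[CD],
                            prior_prec, prior_mean, rng)
    state.b[:, CD] = beta[:N_FIXED]
    state.coeffs.lam_cd_gl[:] = beta[N_FIXED:]
    # SB equation: b_SB with 2K lambdas (GL deviation and current l_CD)
    c_sb = np.hstack([data.x, _lambda_design(data, y_cd=y[:, CD])])
    prior_prec, prior_mean = _fixed_prior(N_FIXED + 2 * nk, priors,
                                          n_lambda=2 * nk)
    resp = y[:, SB] - rand[:, SB]
    beta = _draw_regression(c_sb.T @ c_sb, c_sb.T @ resp, r[SB],
                            prior_prec, prior_mean, rng)
    state.b[:, SB] = beta[:N_FIXED]
    state.coeffs.lam_sb_gl[:] = beta[N_FIXED:N_FIXED + nk]
    state.coeffs.lam_sb_cd[:] = beta[N_FIXED + nk:]


def _sample_b_smm(state: ChainState, data: ModelData, priors: PriorSpec,
                  rng: np.random.Generator, rand: np.ndarray) -> None:
    """Matrix-normal draw of all fixed effects under unstructured R0.

    With a common R0 across records and the same design for every trait,
    the GLS solution coincides with trait-wise OLS and the conditional is
    matrix normal with row covariance (X'X)^-1 and column covariance R0.
    """
    resp = state.y - rand
    xtx = data.x.T @ data.x + np.eye(N_FIXED) / priors.b_var
    mean = np.linalg.solve(xtx, data.x.T @ resp)
    l_row = np.linalg.cholesky(np.linalg.inv(xtx))
    l_col = np.linalg.cholesky(state.disp.R0)
    state.b[:] = mean + l_row @ rng.standard_normal((N_FIXED, 3)) @ l_col.T


def sample_location_effects(state: ChainState, data: ModelData, variant: str,
                            priors: PriorSpec, rng: np.random.Generator,
                            include_fixed: bool = True) -> None:
    """Draw b, then herd-year vectors, then per-bull (sire, MGS) 6-vectors.

    Operates on the working variables w = Lambda_k y, under which the model
    is an ordinary multi-trait mixed model with residual covariance R0.
    Herd levels are conditionally independent given everything else and are
    drawn in a single vectorized pass; bulls share records (one bull's sire
    records are another's MGS records) and are scanned sequentially with an
    incrementally maintained residual.
    """
    if include_fixed:
        if variant == "SMM":
            _sample_b_smm(state, data, priors, rng, state.random_part(data))
        else:
            # b given current lambda: regress working variables on X alone
            w = state.working(data)
            rand = state.random_part(data)
            r = np.diag(state.disp.R0)
            for t in range(N_TRAITS):
                prior_prec, prior_mean = _fixed_prior(N_FIXED, priors)
                resp = w[:, t] - rand[:, t]
                state.b[:, t] = _draw_regression(
                    data.x.T @ data.x, data.x.T @ resp, r[t],
                    prior_prec, prior_mean, rng)
    sample_herd_effects(state, data, rng)
    sample_bull_effects(state, data, rng)


def sample_herd_effects(state: ChainState, data: ModelData,
                        rng: np.random.Generator) -> None:
    w = state.working(data)
    res = w - data.x @ state.b - state.u[data.s_idx, :3] - state.u[data.m_idx, 3:]
    r0_inv = np.linalg.inv(state.disp.R0)
    h0_inv = np.linalg.inv(state.disp.H0)
    nh = data.n_herds
    sums = np.zeros((nh, 3))
    np.add.at(sums, data.h_idx, res)
    counts = np.bincount(data.h_idx, minlength=nh).astype(float)
    prec = counts[:, None, None] * r0_inv + h0_inv           # (nh, 3, 3)
    lin = sums @ r0_inv.T                                    # (nh, 3)
    mean = np.linalg.solve(prec, lin[..., None])[..., 0]
    chol = np.linalg.cholesky(prec)
    z = rng.standard_normal((nh, 3))
    noise = np.linalg.solve(np.swapaxes(chol, 1, 2), z[..., None])[..., 0]
    state.h[:] = mean + noise


def sample_bull_effects(state: ChainState, data: ModelData,
                        rng: np.random.Generator) -> None:
    w = state.working(data)
    res = w - data.x @ state.b - state.h[data.h_idx]
    res -= state.u[data.s_idx, :3]
    res -= state.u[data.m_idx, 3:]
    r0_inv = np.linalg.inv(state.disp.R0)
    g0_inv = np.linalg.inv(state.disp.G0)
    u = state.u
    for q in range(data.n_bulls):
        sr = data.sire_recs[q]
        mr = data.mgs_recs[q]
        res[sr] += u[q, :3]
        res[mr] += u[q, 3:]
        n_s, n_m = len(sr), len(mr)
        n_b = int(data.n_both[q]) if data.n_both.size else 0
        prec = g0_inv.copy()
        prec[:3, :3] += n_s * r0_inv
        prec[3:, 3:] += n_m * r0_inv
        if n_b:
            prec[:3, 3:] += n_b * r0_inv
            prec[3:, :3] += n_b * r0_inv
        lin = np.concatenate([r0_inv @ res[sr].sum(axis=0) if n_s else np.zeros(3),
                              r0_inv @ res[mr].sum(axis=0) if n_m else np.zeros(3)])
        u[q] = sample_mvn_from_precision(prec, lin, rng)
        res[sr] -= u[q, :3]
        res[mr] -= u[q, 3:]


def sample_structural_coefficients(state: ChainState, data: ModelData,
                                   variant: str, priors: PriorSpec,
                                   rng: np.random.Generator) -> None:
    """Category-wise normal draw of the lambdas given everything else.

    Requires diagonal R0 (true for every RMM), under which the CD- and
    SB-equation coefficients are conditionally independent regression
    slopes of structural residuals on the GL deviation (and, in the SB
    equation, on the current CD liability).
    """
    if variant == "SMM":
        raise ValueError("SMM has no structural coefficients")
    m = state.mu(data)
    y = state.y
    r_cd = state.disp.R0[CD, CD]
    r_sb = state.disp.R0[SB, SB]
    pv, pm = priors.lambda_var, priors.lambda_mean
    import warnings
    for k in range(data.n_categories):
        idx = np.flatnonzero(data.kcat == k)
        if idx.size == 0:
            warnings.warn(f"GL category {k + 1} has no records; structural "
                          "coefficients drawn from their prior", stacklevel=2)
            state.coeffs.lam_cd_gl[k] = rng.normal(pm, np.sqrt(pv))
            draw = rng.normal(pm, np.sqrt(pv), size=2)
            state.coeffs.lam_sb_gl[k], state.coeffs.lam_sb_cd[k] = draw
            continue
        g = y[idx, GL]
        # CD equation: slope of (l_CD - mu_CD) on g
        resp = y[idx, CD] - m[idx, CD]
        prec = g @ g / r_cd + 1.0 / pv
        lin = g @ resp / r_cd + pm / pv
        state.coeffs.lam_cd_gl[k] = sample_mvn_from_precision(
            np.array([[prec]]), np.array([lin]), rng)[0]
        # SB equation: joint slopes on (g, l_CD)
        c = np.column_stack([g, y[idx, CD]])
        resp = y[idx, SB] - m[idx, SB]
        prec = c.T @ c / r_sb + np.eye(2) / pv
        lin = c.T @ resp / r_sb + pm / pv
        draw = sample_mvn_from_precision(prec, lin, rng)
        state.coeffs.lam_sb_gl[k], state.coeffs.lam_sb_cd[k] = draw


def sample_thresholds(state: ChainState, data: ModelData,
                      rng: np.random.Generator) -> None:
    """Uniform draw of each free CD threshold between the extreme
    liabilities of its adjacent categories (no-op when C_cd = 3)."""
    thr = state.thresholds
    if thr.n_free == 0:
        return
    l_cd = state.y[:, CD]
    cd = thr.cd.copy()
    for j in range(2, cd.size):            # free thresholds: tau_3, ...
        below = l_cd[data.cd_score == j + 1]
        above = l_cd[data.cd_score == j + 2]
        lo = below.max() if below.size else cd[j - 1]
        hi = above.min() if above.size else (cd[j + 1] if j + 1 < cd.size else lo)
        lo = max(lo, cd[j - 1])
        if j + 1 < cd.size:
            hi = min(hi, cd[j + 1])
        cd[j] = lo if hi <= lo else rng.uniform(lo, hi)
        if cd[j] <= cd[j - 1]:
            cd[j] = np.nextafter(cd[j - 1], np.inf)
    state.thresholds = Thresholds(cd, thr.sb)


def sample_dispersion(state: ChainState, data: ModelData, variant: str,
                      priors: PriorSpec, rng: np.random.Generator) -> None:
    """Inverted-Wishart / scaled-inverse-chi-square refresh of G0, H0, R0."""
    w = state.working(data)
    eps = w - state.mu(data)
    n = data.n
    masks = variant_masks(variant)

    # --- R0 ---
    if variant == "SMM":
        scale = priors.iw_scale * np.eye(3) + eps.T @ eps
        r0 = sample_cond_invwishart_fixed_corner(priors.iw_df(3) + n, scale,
                                                 corner=1.0, rng=rng)
    else:
        r0 = np.zeros((3, 3))
        for t in (GL, CD):
            ss = float(eps[:, t] @ eps[:, t])
            nu = priors.sic_nu + n
            r0[t, t] = scaled_inv_chi2(nu, (priors.sic_nu * priors.sic_s2 + ss) / nu,
                                       rng)
        r0[SB, SB] = 1.0

    # --- H0 ---
    h = state.h
    if masks["H0"].all():
        scale = priors.iw_scale * np.eye(3) + h.T @ h
        h0 = sample_invwishart(priors.iw_df(3) + data.n_herds, scale, rng)
    else:
        h0 = np.zeros((3, 3))
        for t in range(3):
            ss = float(h[:, t] @ h[:, t])
            nu = priors.sic_nu + data.n_herds
            h0[t, t] = scaled_inv_chi2(nu, (priors.sic_nu * priors.sic_s2 + ss) / nu,
                                       rng)

    # --- G0 ---
    u = state.u
    if masks["G0"].all():
        scale = priors.iw_scale * np.eye(6) + u.T @ u
        g0 = sample_invwishart(priors.iw_df(6) + data.n_bulls, scale, rng)
    else:
        g0 = np.zeros((6, 6))
        for t in range(3):
            pair = u[:, [t, t + 3]]
            scale = priors.iw_scale * np.eye(2) + pair.T @ pair
            block = sample_invwishart(priors.iw_df(2) + data.n_bulls, scale, rng)
            g0[t, t] = block[0, 0]
            g0[t + 3, t + 3] = block[1, 1]
            g0[t, t + 3] = g0[t + 3, t] = block[0, 1]

    state.disp = DispersionSet(g0, h0, r0, variant=variant)


# ---------------------------------------------------------------------------
# Posterior container and chain driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained draws across chains, plus per-record posterior means.

    ``draws`` maps parameter names to arrays of shape
    (n_chains, retained_per_chain, ...).  ``record_means`` holds the
    per-chain running means over retained draws of the augmented
    liabilities (``liab``: columns GL deviation, l_CD, l_SB) and of the
    reduced-form expected phenotypes (``eta`` = Lambda_k^{-1} mu).
    """

    variant: str
    config: MCMCConfig
    draws: dict
    record_means: dict
    herd_ids: np.ndarray
    bull_ids: np.ndarray
    gl_reference: float
    cat_map: GLCategoryMap
    c_cd: int

    @property
    def n_retained(self) -> int:
        return self.draws["lambda"].shape[0] * self.draws["lambda"].shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws with the chain axis flattened away."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.pooled(name).mean(axis=0)

    def mean_liabilities(self) -> np.ndarray:
        """(n, 3) posterior mean of the augmented record triples."""
        return self.record_means["liab"].mean(axis=0)

    def mean_eta(self) -> np.ndarray:
        """(n, 3) posterior mean reduced-form expectations (GL centered)."""
        return self.record_means["eta"].mean(axis=0)

    def coeffs_mean(self) -> StructuralCoefficients:
        lam = self.posterior_mean("lambda")
        return StructuralCoefficients.from_matrix(lam)

    def thresholds_mean(self) -> Thresholds:
        cd = self.posterior_mean("thresholds")
        cd[0], cd[1] = 0.0, 1.0
        return Thresholds(cd)


def _eta(state: ChainState, data: ModelData) -> np.ndarray:
    mu = state.mu(data)
    lcg, lsg, lsc = state.lam_per_record(data)
    eta = mu.copy()
    eta[:, CD] = lcg * mu[:, GL] + mu[:, CD]
    eta[:, SB] = (lsg + lsc * lcg) * mu[:, GL] + lsc * mu[:, CD] + mu[:, SB]
    return eta


def run_chains(records: pd.DataFrame | ModelData, variant: str,
               priors: PriorSpec | None = None,
               config: MCMCConfig | None = None,
               c_cd: int = 3, cat_map: GLCategoryMap | None = None,
               gl_reference: float | None = None,
               progress: bool = False) -> PosteriorSamples:
    """Run the full Gibbs sampler and return retained draws.

    Deterministic given ``config.seed`` (chain seeds are spawned from it).
    One progress line per 1,000 iterations is written to stderr when
    ``progress`` is set.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if priors is None:
        priors = PriorSpec()
    if config is None:
        config = MCMCConfig()
    data = records if isinstance(records, ModelData) else build_model_data(
        records, c_cd=c_cd, cat_map=cat_map, gl_reference=gl_reference)
    nk = data.n_categories
    ret = config.retained_per_chain
    draws = {
        "b": np.empty((config.n_chains, ret, N_FIXED, 3)),
        "h": np.empty((config.n_chains, ret, data.n_herds, 3)),
        "u": np.empty((config.n_chains, ret, data.n_bulls, 6)),
        "lambda": np.empty((config.n_chains, ret, nk, 3)),
        "G0": np.empty((config.n_chains, ret, 6, 6)),
        "H0": np.empty((config.n_chains, ret, 3, 3)),
        "R0": np.empty((config.n_chains, ret, 3, 3)),
        "thresholds": np.empty((config.n_chains, ret, data.c_cd - 1)),
    }
    record_means = {
        "liab": np.zeros((config.n_chains, data.n, 3)),
        "eta": np.zeros((config.n_chains, data.n, 3)),
    }
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        state = initial_state(data, variant, rng)
        r = 0
        for it in range(1, config.n_iterations + 1):
            sample_liabilities(state, data, variant, rng)
            sample_fixed_and_structural(state, data, variant, priors, rng)
            sample_herd_effects(state, data, rng)
            sample_bull_effects(state, data, rng)
            sample_thresholds(state, data, rng)
            sample_dispersion(state, data, variant, priors, rng)
            if progress and it % 1000 == 0:
                print(f"[{variant}] chain {c + 1}/{config.n_chains} "
                      f"iteration {it}/{config.n_iterations}", file=sys.stderr)
            if it > config.burn_in and (it - config.burn_in) % config.thin == 0 \
                    and r < ret:
                draws["b"][c, r] = state.b
                draws["h"][c, r] = state.h
                draws["u"][c, r] = state.u
                draws["lambda"][c, r] = state.coeffs.as_matrix()
                draws["G0"][c, r] = state.disp.G0
                draws["H0"][c, r] = state.disp.H0
                draws["R0"][c, r] = state.disp.R0
                draws["thresholds"][c, r] = state.thresholds.cd
                record_means["liab"][c] += state.y
                record_means["eta"][c] += _eta(state, data)
                r += 1
        record_means["liab"][c] /= max(r, 1)
        record_means["eta"][c] /= max(r, 1)
    return PosteriorSamples(
        variant=variant, config=config, draws=draws, record_means=record_means,
        herd_ids=data.herd_ids, bull_ids=data.bull_ids,
        gl_reference=data.gl_reference, cat_map=data.cat_map, c_cd=data.c_cd,
    )
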