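"""Core model algebra for recursive multi-trait threshold mixed models.

Three calving traits are modelled jointly: gestation length (GL, continuous,
days), calving difficulty (CD, ordinal liability) and stillbirth (SB, binary
liability).  The structural system is strictly recursive, GL -> CD -> SB,
with rates of change (structural coefficients) that depend on the category
of the realized GL phenotype:

    Lambda_k y_i = mu_i + eps_i,      eps_i ~ N(0, R0)

where y_i = (GL_i - g_ref, l_CD_i, l_SB_i), k = k(GL_i) is the GL category
and Lambda_k is unit lower triangular.  Observed ordinal scores arise by
thresholding the liabilities.

This module holds the domain types, the Lambda_k algebra, the GL category
map, the model-variant constraint masks and free-parameter counts, the
reduced-form covariance transformation, and the sire/maternal-grandsire to
direct/maternal (Willham) conversion with derived genetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRAITS = ("GL", "CD", "SB")
N_TRAITS = 3
VARIANTS = ("SMM", "RMM1", "RMM2", "RMM3")

# trait indices
GL, CD, SB = 0, 1, 2


# ---------------------------------------------------------------------------
# GL categories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCategoryMap:
    """Partition of gestation length (integer days) into categories.

    A day equal to a boundary belongs to the *lower* category, i.e. the
    default boundaries (267, 273, 279) give the four classes
    <=267, 268-273, 274-279 and >=280 days.
    """

    boundaries: tuple[int, ...] = (267, 273, 279)

    def __post_init__(self) -> None:
        b = tuple(self.boundaries)
        if len(b) == 0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be non-empty and strictly increasing")

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1

    def category(self, gl_days):
        """Vectorized 1-based category index for integer day(s)."""
        return np.searchsorted(np.asarray(self.boundaries), np.asarray(gl_days),
                               side="left") + 1


def gl_category(gl_days: int, cat_map: GLCategoryMap | None = None) -> int:
    """Category index k in 1..n_categories for a gestation length in days."""
    if cat_map is None:
        cat_map = GLCategoryMap()
    return int(cat_map.category(int(gl_days)))


# ---------------------------------------------------------------------------
# Structural coefficients and Lambda_k
# ---------------------------------------------------------------------------

@dataclass
class StructuralCoefficients:
    """The category-dependent recursion rates lambda.

    ``lam_cd_gl[k-1]`` is the change of CD liability per extra day of GL in
    category k, ``lam_sb_gl`` the direct change of SB liability per day GL,
    and ``lam_sb_cd`` the change of SB liability per unit of CD liability.
    """

    lam_cd_gl: np.ndarray
    lam_sb_gl: np.ndarray
    lam_sb_cd: np.ndarray

    def __post_init__(self) -> None:
        self.lam_cd_gl = np.atleast_1d(np.asarray(self.lam_cd_gl, dtype=float))
        self.lam_sb_gl = np.atleast_1d(np.asarray(self.lam_sb_gl, dtype=float))
        self.lam_sb_cd = np.atleast_1d(np.asarray(self.lam_sb_cd, dtype=float))
        n = len(self.lam_cd_gl)
        if not (len(self.lam_sb_gl) == len(self.lam_sb_cd) == n):
            raise ValueError("coefficient vectors must share one length per category")
        if not (np.isfinite(self.lam_cd_gl).all() and np.isfinite(self.lam_sb_gl).all()
                and np.isfinite(self.lam_sb_cd).all()):
            raise ValueError("structural coefficients must be finite")

    @property
    def n_categories(self) -> int:
        return len(self.lam_cd_gl)

    @classmethod
    def zeros(cls, n_categories: int = 4) -> "StructuralCoefficients":
        z = np.zeros(n_categories)
        return cls(z.copy(), z.copy(), z.copy())

    def as_matrix(self) -> np.ndarray:
        """(n_categories, 3) array, columns (cd<-gl, sb<-gl, sb<-cd)."""
        return np.column_stack([self.lam_cd_gl, self.lam_sb_gl, self.lam_sb_cd])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "StructuralCoefficients":
        m = np.asarray(m, dtype=float)
        return cls(m[:, 0].copy(), m[:, 1].copy(), m[:, 2].copy())


def build_lambda(coeffs: StructuralCoefficients, k: int) -> np.ndarray:
    """Unit lower-triangular structural matrix Lambda_k.

    Encodes the system Lambda_k y = mu + eps: off-diagonals are the negated
    recursion rates, and the GL row is (1, 0, 0) because GL is upstream of
    both liabilities.
    """
    if not 1 <= k <= coeffs.n_categories:
        raise ValueError(f"category {k} outside 1..{coeffs.n_categories}")
    i = k - 1
    return np.array([
        [1.0, 0.0, 0.0],
        [-coeffs.lam_cd_gl[i], 1.0, 0.0],
        [-coeffs.lam_sb_gl[i], -coeffs.lam_sb_cd[i], 1.0],
    ])


def overall_effect_sb_from_gl(coeffs: StructuralCoefficients, k: int) -> float:
    """Total (direct + mediated) rate of change of SB liability per day GL.

    Equals lam_sb_gl + lam_cd_gl * lam_sb_cd, i.e. the (SB, GL) entry of
    Lambda_k^{-1} applied to a unit GL perturbation.
    """
    if not 1 <= k <= coeffs.n_categories:
        raise ValueError(f"category {k} outside 1..{coeffs.n_categories}")
    i = k - 1
    return float(coeffs.lam_sb_gl[i] + coeffs.lam_cd_gl[i] * coeffs.lam_sb_cd[i])


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass
class Thresholds:
    """Cutpoints mapping liabilities to ordinal scores.

    For CD the first threshold is fixed at 0 and the second at 1 (these two
    identify location and scale of the CD liability); thresholds beyond the
    second, present when C_cd > 3, are free.  The single SB threshold is
    fixed at 0.
    """

    cd: np.ndarray
    sb: float = 0.0

    def __post_init__(self) -> None:
        self.cd = np.asarray(self.cd, dtype=float)
        if self.cd.size < 2:
            raise ValueError("CD needs at least 3 categories (2 thresholds)")
        if self.cd[0] != 0.0 or self.cd[1] != 1.0:
            raise ValueError("first two CD thresholds are fixed at 0 and 1")
        if np.any(np.diff(self.cd) <= 0):
            raise ValueError("CD thresholds must be strictly increasing")
        if self.sb != 0.0:
            raise ValueError("SB threshold is fixed at 0")

    @property
    def n_cd_categories(self) -> int:
        return self.cd.size + 1

    @property
    def n_free(self) -> int:
        return self.cd.size - 2

    @classmethod
    def default(cls, c_cd: int = 3) -> "Thresholds":
        if c_cd < 3:
            raise ValueError("C_cd must be >= 3")
        # free thresholds initialized on an even grid above 1
        extra = 1.0 + np.arange(1, c_cd - 2) * 0.5
        return cls(np.concatenate([[0.0, 1.0], extra]))


# ---------------------------------------------------------------------------
# Dispersion structures and variant masks
# ---------------------------------------------------------------------------

def variant_masks(variant: str, n_traits: int = N_TRAITS) -> dict[str, np.ndarray]:
    """Boolean masks of *allowed* (possibly non-zero) entries per matrix.

    G0 is 2*n_traits square over (sire block, MGS block) with traits in
    order inside each block; H0 and R0 are n_traits square.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    t = n_traits
    full_g = np.ones((2 * t, 2 * t), dtype=bool)
    full = np.ones((t, t), dtype=bool)
    diag = np.eye(t, dtype=bool)
    if variant == "SMM":
        return {"G0": full_g, "H0": full, "R0": full}
    if variant == "RMM1":
        return {"G0": full_g, "H0": full, "R0": diag}
    if variant == "RMM2":
        return {"G0": full_g, "H0": diag, "R0": diag}
    # RMM3: G0 non-zero only in per-trait 2x2 (sire, MGS) blocks
    g = np.zeros((2 * t, 2 * t), dtype=bool)
    for i in range(t):
        for a, b in ((i, i), (i, i + t), (i + t, i), (i + t, i + t)):
            g[a, b] = True
    return {"G0": g, "H0": diag, "R0": diag}


@dataclass
class DispersionSet:
    """Structural-scale covariance components and the variant they obey.

    ``G0`` is the 6x6 joint (co)variance of a bull's sire-of-record and
    maternal-grandsire-of-record effects across the three traits, ordered
    (s_GL, s_CD, s_SB, mgs_GL, mgs_CD, mgs_SB); ``H0`` the herd-year and
    ``R0`` the residual 3x3 matrices.  R0[SB, SB] is fixed at 1 for
    identification of the SB liability scale.
    """

    G0: np.ndarray
    H0: np.ndarray
    R0: np.ndarray
    variant: str = "SMM"

    def __post_init__(self) -> None:
        self.G0 = np.asarray(self.G0, dtype=float)
        self.H0 = np.asarray(self.H0, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        self.validate()

    @property
    def S0(self) -> np.ndarray:
        """Sire 3x3 block."""
        return self.G0[:N_TRAITS, :N_TRAITS]

    @property
    def M0(self) -> np.ndarray:
        """Maternal-grandsire 3x3 block."""
        return self.G0[N_TRAITS:, N_TRAITS:]

    @property
    def C_sm(self) -> np.ndarray:
        """Sire x MGS 3x3 cross block (rows sire, columns MGS)."""
        return self.G0[:N_TRAITS, N_TRAITS:]

    def validate(self, atol: float = 1e-8) -> None:
        for name, m in (("G0", self.G0), ("H0", self.H0), ("R0", self.R0)):
            if not np.allclose(m, m.T, atol=atol):
                raise ValueError(f"{name} must be symmetric")
        if abs(self.R0[SB, SB] - 1.0) > atol:
            raise ValueError("R0[SB, SB] is fixed at 1")
        masks = variant_masks(self.variant)
        for name, m in (("G0", self.G0), ("H0", self.H0), ("R0", self.R0)):
            if np.any(np.abs(m[~masks[name]]) > atol):
                raise ValueError(f"{name} violates the {self.variant} constraint mask")
        for name, m in (("G0", self.G0), ("H0", self.H0), ("R0", self.R0)):
            free = m[np.ix_(np.diag(m) > 0, np.diag(m) > 0)]
            if free.size and np.linalg.eigvalsh(free).min() <= -atol:
                raise ValueError(f"{name} is not positive semidefinite on its free part")


def count_free_parameters(variant: str, n_categories: int = 4,
                          c_cd: int = 3) -> int:
    """Number of free dispersion + structural-coefficient parameters.

    Counts free entries of S0/M0/C_sm, H0 and R0 under the variant's
    constraint mask (R0[SB, SB] is never free) plus 3 structural
    coefficients per GL category for the recursive variants.  Location
    parameters and free thresholds (present only when ``c_cd`` > 3) are not
    counted.
    """
    masks = variant_masks(variant)
    t = N_TRAITS

    def sym_free(mask: np.ndarray) -> int:
        # free entries of a symmetric matrix = upper triangle incl. diagonal
        return int(np.triu(mask).sum())

    n_g = sym_free(masks["G0"])
    n_h = sym_free(masks["H0"])
    n_r = sym_free(masks["R0"]) - 1  # R0[SB,SB] fixed
    n_lam = 0 if variant == "SMM" else 3 * n_categories
    return n_g + n_h + n_r + n_lam


# ---------------------------------------------------------------------------
# Reduced form
# ---------------------------------------------------------------------------

def reduced_form_covariances(disp: DispersionSet, coeffs: StructuralCoefficients,
                             k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category-k reduced-form (genetic 6x6, herd 3x3, residual 3x3) matrices.

    Solving the recursion out premultiplies every random term by
    Lambda_k^{-1}, so each structural covariance block Sigma becomes
    Lambda_k^{-1} Sigma Lambda_k^{-T} (the genetic 6x6 transforms blockwise).
    """
    lam = build_lambda(coeffs, k)
    lam_inv = np.linalg.inv(lam)
    assert np.isfinite(lam_inv).all()
    t_big = np.kron(np.eye(2), lam_inv)
    genetic = t_big @ disp.G0 @ t_big.T
    herd = lam_inv @ disp.H0 @ lam_inv.T
    residual = lam_inv @ disp.R0 @ lam_inv.T
    # enforce exact symmetry against round-off
    genetic = 0.5 * (genetic + genetic.T)
    herd = 0.5 * (herd + herd.T)
    residual = 0.5 * (residual + residual.T)
    return genetic, herd, residual


# ---------------------------------------------------------------------------
# Willham direct/maternal transformation
# ---------------------------------------------------------------------------

@dataclass
class WillhamParams:
    """Direct/maternal genetic (co)variances implied by sire-MGS components.

    ``direct`` and ``maternal`` are symmetric 3x3 matrices over traits;
    ``direct_maternal``[t, u] = cov(a_d of trait t, a_m of trait u) and is
    not symmetric in general.  ``psd_ok``[t] flags whether the per-trait
    (direct, maternal) 2x2 matrix is positive semidefinite; a violated flag
    is a warning (it can happen for individual posterior draws), not an
    error.
    """

    direct: np.ndarray
    maternal: np.ndarray
    direct_maternal: np.ndarray
    psd_ok: np.ndarray = field(default_factory=lambda: np.ones(N_TRAITS, dtype=bool))


def willham_transform(S0: np.ndarray, M0: np.ndarray,
                      C_sm: np.ndarray) -> WillhamParams:
    """Convert sire/MGS (co)variance blocks to direct/maternal ones.

    Under s = (1/2) a_d and mgs = (1/4) a_d + (1/2) a_m per trait:

        direct          D  = 4 S0
        direct-maternal DM = 4 C_sm - 2 S0
        maternal        Mm = 4 M0 + S0 - 2 (C_sm + C_sm')

    (per-trait diagonals reduce to sigma2_d = 4 sigma2_s,
    sigma_dm = 4 sigma_s,mgs - 2 sigma2_s and
    sigma2_m = 4 sigma2_mgs + sigma2_s - 4 sigma_s,mgs).
    """
    S0 = np.asarray(S0, dtype=float)
    M0 = np.asarray(M0, dtype=float)
    C_sm = np.asarray(C_sm, dtype=float)
    direct = 4.0 * S0
    dm = 4.0 * C_sm - 2.0 * S0
    maternal = 4.0 * M0 + S0 - 2.0 * (C_sm + C_sm.T)
    n = direct.shape[0]
    psd_ok = np.empty(n, dtype=bool)
    for t in range(n):
        two = np.array([[direct[t, t], dm[t, t]], [dm[t, t], maternal[t, t]]])
        psd_ok[t] = np.linalg.eigvalsh(two).min() >= -1e-10
    return WillhamParams(direct, maternal, dm, psd_ok)


def willham_inverse(params: WillhamParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic inverse of :func:`willham_transform` (direct/maternal -> sire/MGS)."""
    d = params.direct
    dm = params.direct_maternal
    m = params.maternal
    S0 = d / 4.0
    C_sm = (dm + d / 2.0) / 4.0
    M0 = (m - S0 + 2.0 * (C_sm + C_sm.T)) / 4.0
    return S0, M0, C_sm


# ---------------------------------------------------------------------------
# Derived genetic parameters
# ---------------------------------------------------------------------------

def _corr(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = cov / np.outer(sd, sd)
    c[~np.isfinite(c)] = 0.0
    return np.clip(c, -1.0, 1.0)


@dataclass
class ReducedFormSummary:
    """Genetic parameters on the reduced-form scale for one GL category."""

    category: int
    genetic: np.ndarray            # 6x6 reduced sire/MGS covariance
    herd: np.ndarray               # 3x3
    residual: np.ndarray           # 3x3
    willham: WillhamParams
    phenotypic_var: np.ndarray     # (3,)
    h2_direct: np.ndarray          # (3,)
    h2_maternal: np.ndarray        # (3,)
    corr_direct: np.ndarray        # 3x3 correlations among direct effects
    corr_maternal: np.ndarray      # 3x3
    corr_direct_maternal: np.ndarray  # 3x3, [t, u] = corr(a_d t, a_m u)
    corr_herd: np.ndarray          # 3x3
    corr_residual: np.ndarray      # 3x3


def genetic_parameters(disp: DispersionSet, coeffs: StructuralCoefficients, k: int,
                       include_herd_in_phenotypic: bool = False) -> ReducedFormSummary:
    """Heritabilities and correlations for GL category ``k``.

    The phenotypic variance per trait is sigma2_s + sigma2_mgs + sigma_s,mgs
    + sigma2_e on the reduced-form scale (plus the herd-year variance when
    ``include_herd_in_phenotypic``), the usual convention in sire-MGS
    analyses of calving traits.
    """
    genetic, herd, residual = reduced_form_covariances(disp, coeffs, k)
    s0 = genetic[:N_TRAITS, :N_TRAITS]
    m0 = genetic[N_TRAITS:, N_TRAITS:]
    c_sm = genetic[:N_TRAITS, N_TRAITS:]
    wp = willham_transform(s0, m0, c_sm)
    pvar = np.diag(s0) + np.diag(m0) + np.diag(c_sm) + np.diag(residual)
    if include_herd_in_phenotypic:
        pvar = pvar + np.diag(herd)
    if np.any(pvar <= 0):
        raise ValueError("non-positive phenotypic variance")
    h2_d = np.diag(wp.direct) / pvar
    h2_m = np.diag(wp.maternal) / pvar
    sd_d = np.sqrt(np.clip(np.diag(wp.direct), 0.0, None))
    sd_m = np.sqrt(np.clip(np.diag(wp.maternal), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr_dm = wp.direct_maternal / np.outer(sd_d, sd_m)
    corr_dm[~np.isfinite(corr_dm)] = 0.0
    return ReducedFormSummary(
        category=k,
        genetic=genetic, herd=herd, residual=residual, willham=wp,
        phenotypic_var=pvar,
        h2_direct=h2_d, h2_maternal=h2_m,
        corr_direct=_corr(wp.direct), corr_maternal=_corr(wp.maternal),
        corr_direct_maternal=np.clip(corr_dm, -1.0, 1.0),
        corr_herd=_corr(herd), corr_residual=_corr(residual),
    )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitRecord:
    """One calf record: identifiers, fixed-effect levels and phenotypes."""

    record_id: int
    sire_id: int
    mgs_id: int
    herd_year_id: int
    sex: int           # 1..2
    age_class: int     # 1..4
    year_season: int   # 1..12
    gl_days: int
    cd_score: int      # 1..C_cd
    sb_score: int      # 1..2


RECORD_COLUMNS = ("record_id", "sire_id", "mgs_id", "herd_year_id", "sex",
                  "age_class", "year_season", "gl_days", "cd_score", "sb_score")

FIXED_EFFECT_LEVELS = {"sex": 2, "age_class": 4, "year_season": 12}
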