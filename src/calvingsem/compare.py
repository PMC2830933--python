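"""Goodness of fit, 3-fold cross-validated predictive ability, and
between-model fitted-value concordance.

Fitted/predicted ordinal scores are expected scores under the probit
measurement model: the probability of each category is a difference of
standard-normal CDFs at the thresholds minus the (posterior-mean)
liability, and the score is the probability-weighted category index.
Models are compared per trait by mean squared error and Pearson
correlation between fitted (or cross-validation predicted) and observed
phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import CD, GL, SB, GLCategoryMap, StructuralCoefficients
from .gibbs import MCMCConfig, PosteriorSamples, PriorSpec, run_chains
from .simulate import design_matrix


# ---------------------------------------------------------------------------
# Eq-level primitives
# ---------------------------------------------------------------------------

def category_probabilities(liability_mean, thresholds, n_categories: int
                           ) -> np.ndarray:
    """P(category c) = Phi(tau_c - lhat) - Phi(tau_{c-1} - lhat), c = 1..C.

    ``liability_mean`` may be scalar or an array (categories on the last
    axis of the result); ``thresholds`` has length C - 1.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size != n_categories - 1:
        raise ValueError("need C - 1 thresholds")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    lhat = np.asarray(liability_mean, dtype=float)
    edges = np.concatenate([[-np.inf], thresholds, [np.inf]])
    cdf = ndtr(edges - lhat[..., None])
    return np.diff(cdf, axis=-1)


def expected_score(probabilities) -> np.ndarray:
    """Probability-weighted category score, categories coded 1..C."""
    p = np.asarray(probabilities, dtype=float)
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    c = np.arange(1, p.shape[-1] + 1)
    out = p @ c
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fit metrics
# ---------------------------------------------------------------------------

@dataclass
class FitMetrics:
    """Per-trait MSE and Pearson correlation of fitted vs observed values."""

    mse: dict
    pearson: dict

    def as_frame(self) -> pd.DataFrame:
        rows = [{"trait": t, "mse": self.mse[t], "pearson": self.pearson[t]}
                for t in self.mse]
        return pd.DataFrame(rows)


def fit_metrics(observed: dict, fitted: dict) -> FitMetrics:
    """MSE and Pearson r per trait; r is missing when either side is constant."""
    mse, pearson = {}, {}
    for t in observed:
        o = np.asarray(observed[t], dtype=float)
        f = np.asarray(fitted[t], dtype=float)
        mse[t] = float(np.mean((o - f) ** 2))
        if o.std() == 0 or f.std() == 0:
            pearson[t] = np.nan
        else:
            pearson[t] = float(np.corrcoef(o, f)[0, 1])
    return FitMetrics(mse, pearson)


def _expected_scores_from_liab(liab_cd, liab_sb, thresholds) -> tuple[np.ndarray, np.ndarray]:
    c_cd = thresholds.n_cd_categories
    p_cd = category_probabilities(liab_cd, thresholds.cd, c_cd)
    p_sb = category_probabilities(liab_sb, [thresholds.sb], 2)
    return expected_score(p_cd), expected_score(p_sb)


def goodness_of_fit(samples: PosteriorSamples, records: pd.DataFrame
                    ) -> FitMetrics:
    """In-sample fit evaluated at the posterior means of the unknowns.

    Fitted values are the model's expected phenotypes given the location
    effects: for GL the linear predictor (no residual), for CD/SB the
    expected liabilities (driven, in the recursive variants, by the
    record's observed GL) pushed through the probit measurement model.
    The augmented liabilities are deliberately not used here — being
    truncated to the observed category they would track the data almost
    perfectly and measure nothing about the model.
    """
    if len(records) != samples.record_means["liab"].shape[1]:
        raise ValueError("records do not match the fitted sample")
    p = predict_records(samples, records)
    observed = {"GL": records["gl_days"].to_numpy(dtype=float),
                "CD": records["cd_score"].to_numpy(dtype=float),
                "SB": records["sb_score"].to_numpy(dtype=float)}
    fitted = {"GL": p["gl_pred"].to_numpy(), "CD": p["cd_pred"].to_numpy(),
              "SB": p["sb_pred"].to_numpy()}
    return fit_metrics(observed, fitted)


# ---------------------------------------------------------------------------
# Prediction for new records (plug-in posterior means)
# ---------------------------------------------------------------------------

def predict_records(samples: PosteriorSamples, records: pd.DataFrame
                    ) -> pd.DataFrame:
    """Plug-in predictions for (possibly unseen) records.

    Uses posterior means of b, h, s, mgs, lambda and thresholds from the
    fit; herd or bull levels absent from training predict with effect 0.
    For the recursive variants the CD/SB liabilities accumulate the
    recursion terms driven by the record's *observed* GL (its category and
    deviation), with the unobserved CD liability replaced by its expected
    value in the SB equation; for SMM the liabilities are the plain linear
    predictors.
    """
    b = samples.posterior_mean("b")
    h = samples.posterior_mean("h")
    u = samples.posterior_mean("u")
    lam = StructuralCoefficients.from_matrix(samples.posterior_mean("lambda"))
    thr = samples.thresholds_mean()

    x = design_matrix(records["sex"].to_numpy(), records["age_class"].to_numpy(),
                      records["year_season"].to_numpy())
    herd_lookup = {hid: i for i, hid in enumerate(samples.herd_ids)}
    bull_lookup = {bid: i for i, bid in enumerate(samples.bull_ids)}

    def effect(ids, table, cols):
        out = np.zeros((len(ids), len(cols)))
        lookup = herd_lookup if table is h else bull_lookup
        idx = np.array([lookup.get(i, -1) for i in ids])
        hit = idx >= 0
        out[hit] = table[np.ix_(idx[hit], cols)] if table.ndim == 2 else table[idx[hit]]
        return out

    mu = x @ b
    mu += effect(records["herd_year_id"].to_numpy(), h, [0, 1, 2])
    mu += effect(records["sire_id"].to_numpy(), u, [0, 1, 2])
    mu += effect(records["mgs_id"].to_numpy(), u, [3, 4, 5])

    g = records["gl_days"].to_numpy(dtype=float) - samples.gl_reference
    k = np.asarray(samples.cat_map.category(records["gl_days"].to_numpy())) - 1
    if samples.variant == "SMM":
        liab_cd = mu[:, CD]
        liab_sb = mu[:, SB]
    else:
        liab_cd = lam.lam_cd_gl[k] * g + mu[:, CD]
        liab_sb = lam.lam_sb_gl[k] * g + lam.lam_sb_cd[k] * liab_cd + mu[:, SB]
    cd_fit, sb_fit = _expected_scores_from_liab(liab_cd, liab_sb, thr)
    return pd.DataFrame({
        "record_id": records["record_id"].to_numpy(),
        "gl_pred": mu[:, GL] + samples.gl_reference,
        "liab_cd": liab_cd, "liab_sb": liab_sb,
        "cd_pred": cd_fit, "sb_pred": sb_fit,
    })


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Random disjoint partition of records into (nearly) equal folds."""

    fold: np.ndarray          # (n,) fold index 0..n_folds-1
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold, minlength=self.n_folds)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")


def make_cv_plan(n_records: int, seed: int, n_folds: int = 3) -> CVPlan:
    rng = np.random.default_rng(seed)
    fold = np.arange(n_records) % n_folds
    rng.shuffle(fold)
    return CVPlan(fold=fold, n_folds=n_folds, seed=seed)


def cross_validate(records: pd.DataFrame, variant: str,
                   priors: PriorSpec | None = None,
                   config: MCMCConfig | None = None,
                   plan: CVPlan | None = None, seed: int = 0,
                   c_cd: int = 3, cat_map: GLCategoryMap | None = None,
                   progress: bool = False) -> FitMetrics:
    """K-fold predictive ability: fit on K-1 folds, predict the held-out
    fold, compute MSE / Pearson r once on the concatenated test sets."""
    if plan is None:
        plan = make_cv_plan(len(records), seed)
    obs = {"GL": [], "CD": [], "SB": []}
    pred = {"GL": [], "CD": [], "SB": []}
    for f in range(plan.n_folds):
        test = records.loc[plan.fold == f]
        train = records.loc[plan.fold != f]
        if len(test) == 0 or len(train) == 0:
            raise ValueError(f"fold {f} leaves an empty train or test set")
        fit = run_chains(train, variant, priors=priors, config=config,
                         c_cd=c_cd, cat_map=cat_map, progress=progress)
        p = predict_records(fit, test)
        obs["GL"].append(test["gl_days"].to_numpy(dtype=float))
        obs["CD"].append(test["cd_score"].to_numpy(dtype=float))
        obs["SB"].append(test["sb_score"].to_numpy(dtype=float))
        pred["GL"].append(p["gl_pred"].to_numpy())
        pred["CD"].append(p["cd_pred"].to_numpy())
        pred["SB"].append(p["sb_pred"].to_numpy())
    observed = {t: np.concatenate(obs[t]) for t in obs}
    fitted = {t: np.concatenate(pred[t]) for t in pred}
    return fit_metrics(observed, fitted)


# ---------------------------------------------------------------------------
# Between-model concordance
# ---------------------------------------------------------------------------

def concordance(samples_a: PosteriorSamples, samples_b: PosteriorSamples,
                records: pd.DataFrame) -> dict:
    """Pearson correlations of fitted values between two models.

    Compares the posterior means of the expected GL and of the expected CD
    and SB liabilities (reduced-form expectations) on an identical record
    set.
    """
    n = len(records)
    if (samples_a.record_means["eta"].shape[1] != n
            or samples_b.record_means["eta"].shape[1] != n):
        raise ValueError("both fits must cover the same records")
    eta_a = samples_a.mean_eta()
    eta_b = samples_b.mean_eta()
    out = {}
    for t, name in ((GL, "GL"), (CD, "CD"), (SB, "SB")):
        a, b = eta_a[:, t], eta_b[:, t]
        if t == GL:
            a = a + samples_a.gl_reference
            b = b + samples_b.gl_reference
        out[name] = float(np.corrcoef(a, b)[0, 1])
    return out
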