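"""Mixed-effects comparison of per-fold decoding performance.

Per-fold Pearson correlations are modeled with linear mixed-effects
regression: fixed condition factors, a random intercept per recording
(file), and maximum-likelihood estimation so that nested fixed-effect
structures can be compared with likelihood-ratio tests. The stepwise
ladder (intercept-only → main effects → interaction) reproduces the
structure of the published model-comparison tables: Δ AIC and
Δ log-likelihood against the previous model and the χ² LRT p-value.

The response is modeled untransformed (matching the use of raw
correlation coefficients as the dependent variable); ``fisher_z=True``
applies the variance-stabilizing transform instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class ModelComparison:
    """Result of a stepwise mixed-model comparison."""

    ladder: pd.DataFrame              # one row per model in the sequence
    fits: list                        # MixedLMResults, same order
    formulas: list[str]
    factors: list[str]
    response: str
    group: str
    family_size: int                  # Bonferroni adjustment factor
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def best_index(self) -> int:
        return int(self.ladder["aic"].idxmin())

    @property
    def best_fit(self):
        return self.fits[self.best_index]

    @property
    def best_formula(self) -> str:
        return self.formulas[self.best_index]

    def fixed_effects(self) -> pd.DataFrame:
        """β, SE, t and Bonferroni-adjusted p for the winning model."""
        fit = self.best_fit
        fe = fit.fe_params
        se = fit.bse_fe
        t = fe / se
        p = 2 * sps.norm.sf(np.abs(t))
        return pd.DataFrame({"beta": fe, "se": se, "t": t,
                             "p_adj": np.minimum(p * self.family_size, 1.0)})

    def contrast(self, factor: str, pair: tuple[str, str]):
        """Pairwise fixed-effect contrast ``pair[0] − pair[1]``.

        Treatment coding: the factor's reference level has an implicit
        coefficient of 0; in models with interactions the contrast refers
        to the reference level of the other factors. Returns
        ``(beta, t, p_adj)`` with Bonferroni-adjusted p.
        """
        fit = self.best_fit
        names = list(fit.fe_params.index)
        levels = sorted(self.data[factor].astype(str).unique())

        def basis(level: str) -> np.ndarray:
            v = np.zeros(len(names))
            term = f"C({factor})[T.{level}]"
            if term in names:
                v[names.index(term)] = 1.0
            elif level not in levels:
                raise KeyError(f"unknown level {level!r} of factor {factor!r}")
            return v  # reference level -> all zeros

        c = basis(str(pair[0])) - basis(str(pair[1]))
        beta = float(c @ fit.fe_params.to_numpy())
        cov = np.asarray(fit.cov_params())[:len(names), :len(names)]
        se = float(np.sqrt(c @ cov @ c))
        if se == 0:
            return 0.0, 0.0, 1.0
        t = beta / se
        p = min(2 * sps.norm.sf(abs(t)) * self.family_size, 1.0)
        return beta, float(t), float(p)

    def report(self) -> str:
        lines = ["Mixed-model comparison (ML, random intercept per "
                 f"{self.group})", "=" * 60]
        lines.append(self.ladder.to_string(index=False,
                                           float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append(f"Winning model: {self.best_formula}")
        lines.append(self.fixed_effects().to_string(
            float_format=lambda v: f"{v:.4g}"))
        lines.append(f"(p-values Bonferroni-adjusted, family size "
                     f"{self.family_size})")
        return "\n".join(lines)


class _BoundaryFit:
    """ML mixed-model fit at the zero random-variance boundary.

    When the file-intercept variance estimate collapses to zero the mixed
    model's maximum likelihood coincides with OLS; statsmodels' MixedLM
    cannot represent that boundary (singular Hessian), so the OLS fit
    stands in, with identical log-likelihood and fixed-effect inference.
    """

    def __init__(self, formula: str, data: pd.DataFrame) -> None:
        self._fit = smf.ols(formula, data).fit()
        self.llf = float(self._fit.llf)
        self.fe_params = self._fit.params
        self.bse_fe = self._fit.bse

    def cov_params(self) -> pd.DataFrame:
        return self._fit.cov_params()


def _fit_ml(formula: str, data: pd.DataFrame, group: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[group])
        fit = None
        for method in (None, "lbfgs", "cg"):
            try:
                kw = {} if method is None else {"method": method}
                fit = model.fit(reml=False, **kw)
                if np.isfinite(fit.llf):
                    break
                fit = None
            except (np.linalg.LinAlgError, ValueError):
                fit = None
        if fit is None:
            fit = _BoundaryFit(formula, data)
    # parameters: fixed effects + random-intercept variance + residual variance
    k = len(fit.fe_params) + 2
    return fit, k


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, −2·logLik + 2·k."""
    return -2.0 * loglik + 2.0 * k


def compare_models(results: pd.DataFrame, factors: list[str],
                   response: str = "r", group: str = "file",
                   family_size: int | None = None,
                   fisher_z: bool = False) -> ModelComparison:
    """Stepwise mixed-model ladder over condition factors.

    Fits, by maximum likelihood with a random intercept per ``group``:
    the intercept-only model, the main-effects model, and (for two
    factors) the interaction model. Each step reports Δ AIC and
    Δ log-likelihood against the previous model and a χ² LRT p-value on
    the added fixed-effect degrees of freedom.
    """
    data = results.copy()
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 grouping levels (files) for a "
                         "random intercept; design is degenerate")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        data[f] = data[f].astype(str)
    if fisher_z:
        data = data.assign(**{response: np.arctanh(
            np.clip(data[response], -0.999999, 0.999999))})
    if family_size is None:
        # planned pairwise comparisons per factor: one per level pair
        family_size = sum(len(set(data[f])) * (len(set(data[f])) - 1) // 2
                          for f in factors)

    terms = [f"C({f})" for f in factors]
    formulas = [f"{response} ~ 1"]
    if terms:
        formulas.append(f"{response} ~ 1 + " + " + ".join(terms))
    if len(terms) == 2:
        formulas.append(f"{response} ~ 1 + {terms[0]} * {terms[1]}")

    fits, ks = [], []
    for fml in formulas:
        fit, k = _fit_ml(fml, data, group)
        fits.append(fit)
        ks.append(k)

    rows = []
    for i, (fml, fit, k) in enumerate(zip(formulas, fits, ks)):
        row = {"model": fml, "k": k, "loglik": fit.llf, "aic": aic(fit.llf, k)}
        if i == 0:
            row.update(delta_aic=np.nan, delta_loglik=np.nan,
                       lrt_df=np.nan, lrt_p=np.nan)
        else:
            d_ll = fit.llf - fits[i - 1].llf
            d_df = ks[i] - ks[i - 1]
            stat = max(2.0 * d_ll, 0.0)
            row.update(delta_aic=row["aic"] - rows[i - 1]["aic"],
                       delta_loglik=d_ll, lrt_df=d_df,
                       lrt_p=float(sps.chi2.sf(stat, d_df)))
        rows.append(row)
    ladder = pd.DataFrame(rows)
    return ModelComparison(ladder, fits, formulas, list(factors), response,
                           group, family_size, data)


def simulate_fold_results(offsets: dict[str, float], n_files: int,
                          n_folds: int, file_sd: float = 0.02,
                          resid_sd: float = 0.05,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate a per-fold decoding table with known condition offsets and
    file-level random intercepts — the ground-truth model the mixed-effects
    machinery assumes. Used for estimator-recovery and calibration checks."""
    rng = np.random.default_rng(seed)
    levels = list(offsets)
    intercepts = rng.normal(0.0, file_sd, n_files)
    rows = []
    for f in range(n_files):
        for j in range(n_folds):
            for lv in levels:
                rows.append({"file": f, "fold": j, "condition": lv,
                             "r": offsets[lv] + intercepts[f]
                             + rng.normal(0.0, resid_sd)})
    return pd.DataFrame(rows)
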