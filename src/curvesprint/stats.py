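"""Statistical comparison layer: mixed models, pruning and post hocs.

The study design is quantified with linear mixed-effects models (LMEM):
categorical fixed effects (condition / curve radius, inside vs outside
leg, sprinting direction), a random intercept per athlete, restricted
maximum likelihood estimation.  Models start with interaction terms;
non-significant interactions are pruned by Wald p-value (main effects are
retained).  When a significant interaction survives, simple effects are
probed with estimated-marginal-mean contrasts under a Bonferroni-corrected
per-comparison alpha (0.05 divided by the family size).  Model-vs-data
agreement for predicted curve v_max uses paired t-tests.

Estimation is delegated to statsmodels (MixedLM / OLS); the pruning
order, marginal-mean contrast construction and reporting conventions
live here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
import statsmodels.formula.api as smf

ALPHA = 0.05


@dataclass
class LmemSpec:
    response: str
    fixed: list[str]
    interactions: list[tuple[str, str]] = field(default_factory=list)
    group: str = "athlete"

    def formula(self) -> str:
        terms = [f"C({f})" for f in self.fixed]
        terms += [f"C({a}):C({b})" for a, b in self.interactions]
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class LmemResult:
    spec: LmemSpec
    coefficients: pd.DataFrame  # name, estimate, se, p
    random_intercept_var: float
    converged: bool
    fallback_fixed_blocks: bool
    pruning_log: list[str]
    data: pd.DataFrame
    _fit: object  # statsmodels results object

    def coef(self, name_fragment: str) -> pd.Series:
        hit = self.coefficients[self.coefficients["name"].str.contains(name_fragment, regex=False)]
        if len(hit) != 1:
            raise KeyError(f"{name_fragment!r} matches {len(hit)} coefficients")
        return hit.iloc[0]


def _fit_formula(formula: str, data: pd.DataFrame, group: str):
    """REML mixed fit with an OLS fixed-blocks fallback on singular fits."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=data[group])
            fit = model.fit(reml=True)
            if np.isfinite(fit.params).all() and fit.converged:
                return fit, False
        except (np.linalg.LinAlgError, ValueError):
            pass
        warnings.warn("singular mixed fit; falling back to athlete fixed blocks")
        ols = smf.ols(formula + f" + C({group})", data).fit()
        return ols, True


def fit_lmem(data: pd.DataFrame, spec: LmemSpec) -> LmemResult:
    """Fit the mixed model described by ``spec``.

    Requires at least two athletes and two levels of each included factor.
    Reports fixed-effect coefficients with Wald p-values and the random
    intercept variance.
    """
    if data[spec.group].nunique() < 2:
        raise ValueError("need >= 2 athletes")
    for f in spec.fixed:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f} needs >= 2 levels")
    fit, fallback = _fit_formula(spec.formula(), data, spec.group)

    if fallback:
        names = [n for n in fit.params.index if not n.startswith(f"C({spec.group})")]
        rand_var = float("nan")
    else:
        names = list(fit.fe_params.index)
        rand_var = float(np.asarray(fit.cov_re)[0, 0])
    coefficients = pd.DataFrame(
        {
            "name": names,
            "estimate": [fit.params[n] for n in names],
            "se": [fit.bse[n] for n in names],
            "p": [fit.pvalues[n] for n in names],
        }
    )
    return LmemResult(
        spec=spec,
        coefficients=coefficients,
        random_intercept_var=rand_var,
        converged=bool(getattr(fit, "converged", True)),
        fallback_fixed_blocks=fallback,
        pruning_log=[],
        data=data,
        _fit=fit,
    )


def _interaction_pvalues(result: LmemResult) -> dict[tuple[str, str], float]:
    """Worst (largest) Wald p among each interaction term's coefficients."""
    out = {}
    for a, b in result.spec.interactions:
        mask = result.coefficients["name"].str.contains(f"C({a})", regex=False) & result.coefficients[
            "name"
        ].str.contains(f"C({b})", regex=False)
        ps = result.coefficients.loc[mask, "p"]
        if len(ps):
            out[(a, b)] = float(ps.max())
    return out


def prune(result: LmemResult) -> LmemResult:
    """Iteratively drop non-significant interaction terms and refit.

    The interaction with the largest non-significant (p >= 0.05) Wald p is
    removed first; ties break lexicographically.  Main effects are always
    retained.  Already-pruned specs are returned unchanged (fixed point).
    """
    spec = LmemSpec(
        response=result.spec.response,
        fixed=list(result.spec.fixed),
        interactions=list(result.spec.interactions),
        group=result.spec.group,
    )
    current = result
    log = list(result.pruning_log)
    while True:
        pvals = _interaction_pvalues(current)
        removable = {k: p for k, p in pvals.items() if p >= ALPHA}
        if not removable:
            break
        worst = sorted(removable.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        log.append(f"removed C({worst[0]}):C({worst[1]}) (p={removable[worst]:.4f})")
        spec.interactions = [t for t in spec.interactions if t != worst]
        current = fit_lmem(result.data, spec)
    current.pruning_log = log
    return current


def _emm_row(result: LmemResult, cell: dict[str, object]) -> np.ndarray:
    """Design row for one cell's estimated marginal mean.

    The cell fixes some factors; every remaining categorical in the model
    (including athlete blocks in the fallback) is averaged over its
    observed levels with equal weight.
    """
    fit = result._fit
    design_info = fit.model.data.design_info
    free = [f for f in result.spec.fixed if f not in cell]
    if result.fallback_fixed_blocks:
        free.append(result.spec.group)
    levels = {f: sorted(result.data[f].unique()) for f in free}
    combos = list(itertools.product(*levels.values())) or [()]
    rows = []
    for combo in combos:
        rec = dict(cell)
        rec.update(dict(zip(levels.keys(), combo)))
        rows.append(rec)
    (X,) = build_design_matrices([design_info], pd.DataFrame(rows))
    return np.asarray(X).mean(axis=0)


def posthoc_bonferroni(
    result: LmemResult, family: list[tuple[str, dict, dict]]
) -> pd.DataFrame:
    """Estimated-marginal-mean contrasts with Bonferroni-corrected alpha.

    ``family`` lists (label, cell_a, cell_b) contrasts; each cell maps
    factor names to levels.  The corrected per-comparison alpha is
    0.05 / len(family) and is reported beside each p-value.
    """
    if not family:
        raise ValueError("empty contrast family")
    fit = result._fit
    if result.fallback_fixed_blocks:
        param_names = list(fit.params.index)
    else:
        param_names = list(fit.fe_params.index)
    beta = np.array([fit.params[n] for n in param_names])
    cov = pd.DataFrame(fit.cov_params()).loc[param_names, param_names].to_numpy()

    alpha_corr = ALPHA / len(family)
    rows = []
    for label, cell_a, cell_b in family:
        xa = _emm_row(result, cell_a)
        xb = _emm_row(result, cell_b)
        c = (xa - xb)[: len(beta)]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = est / se
            p = 2 * sps.norm.sf(abs(z))
        rows.append(
            {
                "contrast": label,
                "estimate": est,
                "se": se,
                "p": p,
                "alpha_corrected": alpha_corr,
                "significant": p < alpha_corr,
            }
        )
    return pd.DataFrame(rows)


def leg_radius_family(
    radii=(17.2, 36.5), legs=("inside", "outside"), radius_col="radius", leg_col="role"
) -> list[tuple[str, dict, dict]]:
    """The four-contrast family used for leg-specific GRF and kinematic
    post hocs: leg within each radius and radius within each leg
    (corrected alpha 0.0125)."""
    fam = []
    for r in radii:
        fam.append(
            (
                f"{legs[0]} vs {legs[1]} @ r={r}",
                {radius_col: r, leg_col: legs[0]},
                {radius_col: r, leg_col: legs[1]},
            )
        )
    for leg in legs:
        fam.append(
            (
                f"r={radii[0]} vs r={radii[1]} @ {leg}",
                {radius_col: radii[0], leg_col: leg},
                {radius_col: radii[1], leg_col: leg},
            )
        )
    return fam


def compare_models_ttest(
    measured: np.ndarray, predicted: np.ndarray, model: str
) -> dict:
    """Paired t-test between measured and model-predicted percent slowing.

    Zero-variance difference vectors are reported as exact ties (p = 1
    when the mean difference is also zero) rather than crashing.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.size < 3:
        raise ValueError("need >= 3 paired values")
    diff = measured - predicted
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0):
        p = 1.0 if np.isclose(mean_diff, 0) else 0.0
        t_stat = 0.0 if np.isclose(mean_diff, 0) else np.inf * np.sign(mean_diff)
        exact_tie = True
    else:
        t_stat, p = sps.ttest_rel(measured, predicted)
        exact_tie = False
    return {
        "model": model,
        "n": int(measured.size),
        "mean_difference": mean_diff,
        "t": float(t_stat),
        "p": float(p),
        "exact_tie": exact_tie,
    }
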