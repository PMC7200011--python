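"""Per-class regression of stability metrics on temperature variability.

For each interaction class, each stability response (λ1, λ2 or the
size-normalized feasibility Ω^{1/S}) is regressed by ordinary least
squares on temperature variability with community size S and connectance
C as covariates.  All variables are standardized (zero mean, unit sample
variance) before fitting, so coefficients are comparable across
responses and classes; intervals at 1 and 2 standard errors are exported
for forest-style plots.  Separate per-class fits (rather than a pooled
model) keep the class-specific effect directions directly readable; a
pooled model with a class interaction is available as a robustness
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from envnet.errors import ValidationError
from envnet.network_io import DEFAULT_ENV_VAR, NetworkSet, prune_isolated
from envnet.null_models import er_randomize
from envnet.stability import CompetitionSpec, stability_bundle

RESPONSES = ("lambda1", "lambda2", "omega_norm")
PREDICTORS = (DEFAULT_ENV_VAR, "size_S", "connectance_C")

_SEED_MAX = 2**31 - 1


@dataclass
class RegressionFit:
    """A standardized OLS fit for one response in one interaction class."""

    response: str
    interaction_class: str
    coefficients: dict[str, float]  # includes "intercept"
    standard_errors: dict[str, float]
    adj_r2: float
    n: int

    def coefficient(self, name: str = DEFAULT_ENV_VAR) -> float:
        return self.coefficients[name]

    def se(self, name: str = DEFAULT_ENV_VAR) -> float:
        return self.standard_errors[name]

    def intervals(self) -> pd.DataFrame:
        """1-SE and 2-SE intervals per coefficient (for interval plots)."""
        rows = []
        for name, b in self.coefficients.items():
            s = self.standard_errors[name]
            rows.append({"term": name, "estimate": b,
                         "lo_1se": b - s, "hi_1se": b + s,
                         "lo_2se": b - 2 * s, "hi_2se": b + 2 * s})
        return pd.DataFrame(rows).set_index("term")


def stability_table(network_set: NetworkSet, spec: CompetitionSpec | None = None,
                    method: str = "orthant", n_draws: int = 20_000, seed: int = 0,
                    env_var: str = DEFAULT_ENV_VAR) -> pd.DataFrame:
    """Per-network stability metrics joined with size, connectance and env."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for net, child in zip(network_set, ss.spawn(len(network_set))):
        sb = stability_bundle(net, spec=spec, method=method, n_draws=n_draws,
                              seed=int(child.generate_state(1)[0] % _SEED_MAX))
        m, n = net.incidence.shape
        rows.append({
            "id": net.id,
            "interaction_class": net.interaction_class,
            "lambda1": sb.lambda1, "lambda2": sb.lambda2,
            "omega_raw": sb.omega_raw, "omega_norm": sb.omega_norm,
            "size_S": m + n, "connectance_C": float(net.incidence.mean()),
            env_var: net.environment(env_var),
        })
    return pd.DataFrame(rows).set_index("id")


def _standardize(x: pd.Series) -> np.ndarray:
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValidationError(f"constant column {x.name!r}: cannot standardize")
    return ((x - x.mean()) / sd).to_numpy(dtype=float)


def fit_effects(data: pd.DataFrame, response: str, class_filter: str | None = None,
                predictors: tuple[str, ...] = PREDICTORS) -> RegressionFit:
    """Standardized OLS of one stability response on the predictors.

    ``data`` needs the response, predictor and ``interaction_class``
    columns (see :func:`stability_table`).  Requires >= 10 rows in the
    class after filtering; rank-deficient designs raise a
    :class:`ValidationError` naming the columns involved.
    """
    df = data
    if class_filter is not None:
        df = df[df["interaction_class"] == class_filter]
    if len(df) < 10:
        raise ValidationError(f"need >= 10 networks, got {len(df)}")
    if not np.isfinite(df[[response, *predictors]].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite values in regression variables")
    y = _standardize(df[response])
    X = np.column_stack([_standardize(df[p]) for p in predictors])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"collinear predictors among {list(predictors)}")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["intercept", *predictors]
    return RegressionFit(
        response=response,
        interaction_class=class_filter or "pooled",
        coefficients=dict(zip(names, (float(v) for v in res.params))),
        standard_errors=dict(zip(names, (float(v) for v in res.bse))),
        adj_r2=float(res.rsquared_adj),
        n=int(res.nobs),
    )


def fit_pooled_interaction(data: pd.DataFrame, response: str,
                           env_var: str = DEFAULT_ENV_VAR) -> pd.DataFrame:
    """Robustness variant: pooled OLS with a class × temperature interaction."""
    df = data.copy()
    z = pd.DataFrame({p: _standardize(df[p]) for p in (env_var, "size_S", "connectance_C")},
                     index=df.index)
    z["is_mutualistic"] = (df["interaction_class"] == "mutualistic").astype(float)
    z[f"{env_var}:mutualistic"] = z[env_var] * z["is_mutualistic"]
    y = _standardize(df[response])
    res = sm.OLS(y, sm.add_constant(z.to_numpy())).fit()
    names = ["intercept", *z.columns]
    return pd.DataFrame({"estimate": res.params, "se": res.bse}, index=names)


@dataclass
class OppositeSignResult:
    opposite: bool
    summary: dict


def opposite_sign_check(fit_a: RegressionFit, fit_b: RegressionFit,
                        term: str = DEFAULT_ENV_VAR) -> OppositeSignResult:
    """True iff the two classes' temperature coefficients have opposite
    signs and each exceeds 2 standard errors in magnitude."""
    if fit_a.response != fit_b.response:
        raise ValidationError("fits must share a response")
    if fit_a.interaction_class == fit_b.interaction_class:
        raise ValidationError("fits must come from different classes")
    ba, bb = fit_a.coefficient(term), fit_b.coefficient(term)
    sa, sb = fit_a.se(term), fit_b.se(term)
    opposite = bool(ba * bb < 0 and abs(ba) > 2 * sa and abs(bb) > 2 * sb)
    return OppositeSignResult(opposite, {
        fit_a.interaction_class: {"coef": ba, "se": sa},
        fit_b.interaction_class: {"coef": bb, "se": sb},
        "response": fit_a.response,
    })


def class_fits(data: pd.DataFrame, response: str) -> dict[str, RegressionFit]:
    return {cls: fit_effects(data, response, class_filter=cls)
            for cls in ("mutualistic", "antagonistic")}


def randomized_control(network_set: NetworkSet, seed: int = 0,
                       spec: CompetitionSpec | None = None,
                       responses: tuple[str, ...] = ("lambda1", "omega_norm"),
                       n_draws: int = 20_000) -> dict[str, dict[str, RegressionFit]]:
    """Refit the per-class regressions on ER-randomized architectures.

    Randomization severs the environment → architecture path, so the
    temperature coefficients are expected to lose significance and the
    opposite-sign pattern to disappear.
    """
    rng = np.random.default_rng(seed)
    randomized = []
    for net in network_set:
        B = er_randomize(net.incidence, seed=int(rng.integers(_SEED_MAX)))
        if B.sum(axis=1).max() == 0 or B.sum(axis=0).max() == 0:  # pragma: no cover
            continue
        clone = net.__class__(id=net.id, incidence=B,
                              interaction_class=net.interaction_class,
                              sub_class=net.sub_class, env=dict(net.env))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            randomized.append(prune_isolated(clone))
    rand_set = NetworkSet(randomized, provenance="er-randomized")
    table = stability_table(rand_set, spec=spec, n_draws=n_draws,
                            seed=int(rng.integers(_SEED_MAX)))
    return {resp: class_fits(table, resp) for resp in responses}
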