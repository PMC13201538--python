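"""Log-linear Boltzmann-Arrhenius scaling models with AICc selection.

The central model for a biological rate ``I`` (metabolic rate, feeding
rate, or energetic efficiency) of an individual of body mass ``M`` at
absolute temperature ``T``, from source group ``S``, is

    I = I0 * M**b * exp(E * (T - T0) / (k * T * T0)) * S

which on the natural-log scale is an ordinary linear regression of
``ln I`` on ``ln M`` (allometric exponent ``b``), the Arrhenius
temperature (activation energy ``E`` [eV]) and the categorical source
term, with all marginality-respecting combinations of main effects and
interactions as the candidate set. The most parsimonious candidate is
chosen by the small-sample corrected Akaike criterion (AICc).

The source factor is data, not code: the same machinery fits the pooled
two-level (cold/warm) analysis and the three-level per-stream variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .constants import DEFAULT_CONTEXT, ArrheniusContext, celsius_to_kelvin

arrhenius_transform = DEFAULT_CONTEXT.transform

#: canonical term order; interactions use ':' between constituent names
TERMS_FULL = (
    "log_mass",
    "arrhenius_x",
    "source",
    "log_mass:arrhenius_x",
    "log_mass:source",
    "arrhenius_x:source",
    "log_mass:arrhenius_x:source",
)


def _factors(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


ModelSpec = tuple  # ordered tuple of term strings; () is intercept-only


def enumerate_models(
    predictors: tuple[str, ...] = ("log_mass", "arrhenius_x", "source"),
    max_order: int = 3,
) -> list[ModelSpec]:
    """All marginality-respecting model specs over the given predictors.

    A spec is a tuple of terms in canonical order; an interaction may only
    appear when every lower-order term nested inside it is also present
    (strong heredity). The intercept-only spec ``()`` is always included,
    and the order of the returned list is deterministic.
    """
    predictors = tuple(predictors)
    unknown = set(predictors) - set(TERMS_FULL[:3])
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    candidates = [
        t
        for t in TERMS_FULL
        if _factors(t) <= set(predictors) and len(_factors(t)) <= max_order
    ]
    specs: list[ModelSpec] = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            present = {_factors(t) for t in combo}
            hierarchical = all(
                all(
                    frozenset(sub) in present
                    for k in range(1, len(fs))
                    for sub in itertools.combinations(sorted(fs), k)
                )
                for fs in present
            )
            if hierarchical:
                specs.append(tuple(combo))
    return specs


@dataclass
class ScalingFit:
    """A fitted log-linear scaling model.

    ``coefficients``/``std_errors`` are indexed by design-matrix column
    name (patsy convention, e.g. ``source[T.warm]``). ``aicc`` counts the
    residual variance as a parameter: q = p + 1 regression coefficients
    plus sigma^2.
    """

    spec: ModelSpec
    coefficients: pd.Series
    std_errors: pd.Series
    r2: float
    f_statistic: float
    f_df: tuple[float, float]
    aicc: float
    n: int
    n_params: int
    response: str
    source_levels: tuple[str, ...] = ()
    _results: object = field(default=None, repr=False, compare=False)
    _data_key: int = field(default=0, repr=False, compare=False)

    def coefficient(self, name: str) -> float:
        """Coefficient by design-column name, or by plain term name when unique."""
        if name in self.coefficients.index:
            return float(self.coefficients[name])
        hits = [c for c in self.coefficients.index if c.startswith(name)]
        if len(hits) == 1:
            return float(self.coefficients[hits[0]])
        raise KeyError(f"{name!r} not uniquely found among {list(self.coefficients.index)}")


def _formula(spec: ModelSpec, response: str) -> str:
    if not spec:
        return f"{response} ~ 1"
    return f"{response} ~ " + " + ".join(spec)


def make_design(
    mass_mg,
    temp_C,
    source,
    response=None,
    ctx: ArrheniusContext = DEFAULT_CONTEXT,
) -> pd.DataFrame:
    """Assemble the design frame: ln mass, Arrhenius temperature, source factor.

    ``response`` (if given) is the rate on its natural scale and is stored
    as ``ln_rate``. Temperatures are in Celsius.
    """
    df = pd.DataFrame(
        {
            "log_mass": np.log(np.asarray(mass_mg, dtype=float)),
            "arrhenius_x": ctx.transform(celsius_to_kelvin(temp_C)),
            "source": pd.Categorical(source),
        }
    )
    if response is not None:
        resp = np.asarray(response, dtype=float)
        if np.any(resp <= 0):
            raise ValueError("responses must be positive to take logs")
        df["ln_rate"] = np.log(resp)
    return df


def _ordered_source(df: pd.DataFrame, reference: str = "cold") -> pd.DataFrame:
    """Put the reference level (default 'cold') first so it absorbs the intercept."""
    if "source" not in df:
        return df
    levels = list(pd.Categorical(df["source"]).categories)
    if reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    df = df.copy()
    df["source"] = pd.Categorical(df["source"], categories=levels)
    return df


def fit(spec: ModelSpec, rows: pd.DataFrame, response: str = "ln_rate") -> ScalingFit:
    """OLS fit of one candidate spec on a design frame.

    Reports coefficients with standard errors, r^2, the overall F test with
    (p-1, n-p) degrees of freedom, and Gaussian AICc with the residual
    variance counted as a parameter. Fails loudly on rank deficiency,
    naming the aliased design columns.
    """
    rows = _ordered_source(rows)
    res = smf.ols(_formula(spec, response), data=rows).fit()
    n = int(res.nobs)
    p = len(res.params)  # regression coefficients incl. intercept
    if n <= p + 2:  # AICc needs n > q + 1 with q = p + 1
        raise ValueError(f"n={n} too small for {p} parameters")
    if res.df_model + 1 < p or np.linalg.matrix_rank(res.model.exog) < p:
        u, s, vt = np.linalg.svd(res.model.exog)
        aliased = [
            res.model.exog_names[i]
            for i in np.argsort(np.abs(vt[-1]))[::-1][:2]
        ]
        raise ValueError(f"rank-deficient design; aliased terms near {aliased}")
    q = p + 1  # + residual variance
    aicc = -2 * res.llf + 2 * q + 2 * q * (q + 1) / (n - q - 1)
    levels = ()
    if "source" in rows:
        levels = tuple(pd.Categorical(rows["source"]).categories)
    return ScalingFit(
        spec=spec,
        coefficients=res.params,
        std_errors=res.bse,
        r2=float(res.rsquared),
        f_statistic=float(res.fvalue) if p > 1 else float("nan"),
        f_df=(float(res.df_model), float(res.df_resid)),
        aicc=float(aicc),
        n=n,
        n_params=q,
        response=response,
        source_levels=levels,
        _results=res,
        _data_key=int(pd.util.hash_pandas_object(rows[response]).sum() & 0x7FFFFFFF),
    )


def select(fits: list[ScalingFit]) -> ScalingFit:
    """Most parsimonious fit: minimum AICc.

    Ties are broken by fewer parameters, then by the lexicographic order of
    the term tuple, making the choice invariant to input ordering. All fits
    must have been computed on identical rows.
    """
    if not fits:
        raise ValueError("no candidate fits supplied")
    keys = {(f.n, f._data_key) for f in fits}
    if len(keys) > 1:
        raise ValueError("candidate fits were computed on differing data")
    return min(fits, key=lambda f: (f.aicc, f.n_params, f.spec))


def fit_all(
    rows: pd.DataFrame,
    predictors: tuple[str, ...] = ("log_mass", "arrhenius_x", "source"),
    response: str = "ln_rate",
) -> tuple[ScalingFit, list[ScalingFit]]:
    """Fit every hierarchical candidate and return (selected, all fits).

    Candidates with too many parameters for the sample size are dropped
    from the comparison (their AICc is undefined).
    """
    fits = []
    for spec in enumerate_models(predictors):
        try:
            fits.append(fit(spec, rows, response))
        except ValueError as err:
            if "too small" not in str(err):
                raise
    return select(fits), fits


def predict(
    fit_: ScalingFit,
    mass_mg,
    temp_C,
    source,
    ctx: ArrheniusContext = DEFAULT_CONTEXT,
):
    """Predicted rate on the natural scale, ``exp`` of the linear predictor.

    No retransformation (smearing) correction is applied; predictions are
    conditional medians under log-normal errors. Unknown source levels are
    rejected.
    """
    scalar = np.isscalar(mass_mg) and np.isscalar(temp_C) and isinstance(source, str)
    mass = np.atleast_1d(np.asarray(mass_mg, dtype=float))
    temp = np.atleast_1d(np.asarray(temp_C, dtype=float))
    src = np.atleast_1d(np.asarray(source, dtype=object))
    mass, temp, src = np.broadcast_arrays(mass, temp, src)
    if fit_.source_levels:
        unseen = set(src) - set(fit_.source_levels)
        if unseen:
            raise ValueError(f"unseen source level(s): {sorted(unseen)}")
    new = pd.DataFrame(
        {
            "log_mass": np.log(mass),
            "arrhenius_x": ctx.transform(celsius_to_kelvin(temp)),
            "source": pd.Categorical(src, categories=fit_.source_levels or None),
        }
    )
    out = np.exp(np.asarray(fit_._results.predict(new)))
    return float(out[0]) if scalar else out


def model_table(fits: list[ScalingFit]) -> list[dict]:
    """JSON-ready summary of a candidate set: terms, AICc, dAICc, coefficients."""
    best = min(f.aicc for f in fits)
    table = [
        {
            "terms": list(f.spec),
            "aicc": f.aicc,
            "delta_aicc": f.aicc - best,
            "n_params": f.n_params,
            "r2": f.r2,
            "coefficients": {k: float(v) for k, v in f.coefficients.items()},
        }
        for f in fits
    ]
    return sorted(table, key=lambda d: d["aicc"])
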