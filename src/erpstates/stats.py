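"""Inferential models for vocal RTs and microstate map durations.

Linear mixed models with mode of articulation (fricative vs stop), place
of articulation (p/t/k) and their interaction as fixed effects, and
crossed random intercepts for subjects and items.  Degenerate fits fall
back to a subject-aggregated fixed-effects analysis, and the fallback is
flagged in the result.  Planned pairwise place contrasts are reported
without multiplicity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "ModelResult", "prepare_table", "fit_model", "planned_contrasts"]

PLACES = ("p", "t", "k")


class ModelDesignError(ValueError):
    """The factor structure cannot support the requested model."""


@dataclass
class ModelSpec:
    """What to model: the response and the fixed/random structure."""

    response: str = "rt_ms"  # or "duration_tf"
    fixed: tuple = ("mode", "place", "mode:place")
    random: tuple = ("subject", "item")


@dataclass
class ModelResult:
    """Fixed-effect terms, tests, and bookkeeping about the fit."""

    terms: pd.DataFrame  # term, statistic, df_num, df_den, p
    coefficients: pd.DataFrame  # name, estimate, se, stat, p
    method: str  # "mixedlm-reml" or "ols-subject-aggregated"
    converged: bool
    fallback: bool
    random_variances: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = [f"method: {self.method} (converged={self.converged})"]
        if self.random_variances:
            lines.append(
                "random-effect variances: "
                + ", ".join(f"{k}={v:.3g}" for k, v in self.random_variances.items())
            )
        lines.append(self.terms.to_string(index=False))
        lines.append(self.coefficients.to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "converged": self.converged,
            "fallback": self.fallback,
            "random_variances": self.random_variances,
            "terms": self.terms.to_dict(orient="records"),
            "coefficients": self.coefficients.to_dict(orient="records"),
        }


def prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derive mode/place factors from the phoneme column.

    mode: 'stop' for p/t/k, 'fricative' for sp/st/sk; place: the base
    stop consonant (p/t/k) in either mode.
    """
    t = table.copy()
    if "phoneme" not in t:
        raise ModelDesignError("table needs a 'phoneme' column")
    phon = t["phoneme"].astype(str)
    t["mode"] = np.where(phon.str.startswith("s"), "fricative", "stop")
    t["place"] = phon.str.lstrip("s")
    bad = ~t["place"].isin(PLACES)
    if bad.any():
        raise ModelDesignError(
            f"unknown phonemes: {sorted(phon[bad].unique())}"
        )
    return t


def _check_design(t: pd.DataFrame, response: str) -> None:
    if response not in t:
        raise ModelDesignError(f"response column {response!r} missing")
    for col in ("mode", "place", "subject"):
        if col not in t:
            raise ModelDesignError(f"factor column {col!r} missing")
        if t[col].nunique() < 2 and col != "subject":
            raise ModelDesignError(f"factor {col!r} needs >= 2 levels")
    if t["subject"].nunique() < 2:
        raise ModelDesignError("need >= 2 subjects")


def _wald_terms(res, formula_terms: list[str]) -> pd.DataFrame:
    """Wald F tests per model term from a fitted formula model."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test_terms(scalar=True)
    table = wt.table
    for term in table.index:
        if term == "Intercept":
            continue
        row = table.loc[term]
        stat = row.get("F", row.get("statistic", np.nan))
        if "F" in table.columns:
            stat_name = "F"
        else:
            stat_name = "chi2"
        rows.append(
            {
                "term": term,
                "statistic": float(stat),
                "stat_name": stat_name,
                "df_num": float(row.get("df_constraint", np.nan)),
                "df_den": float(row.get("df_denom", np.nan)),
                "p": float(row.get("P>F", row.get("pvalue", np.nan))),
            }
        )
    return pd.DataFrame(rows)


def _coef_frame(res) -> pd.DataFrame:
    params = res.params
    bse = res.bse
    tvals = res.tvalues
    pvals = res.pvalues
    names = [
        n
        for n in params.index
        if not n.startswith("Group") and not n.endswith(" Var") and n != "_all Var"
    ]
    return pd.DataFrame(
        {
            "name": names,
            "estimate": [float(params[n]) for n in names],
            "se": [float(bse[n]) for n in names],
            "stat": [float(tvals[n]) for n in names],
            "p": [float(pvals[n]) for n in names],
        }
    )


def _fit_mixed(t: pd.DataFrame, response: str, fixed_formula: str):
    """Crossed random intercepts via variance components on one group."""
    data = t.copy()
    data["_all"] = 1
    vc = {"subject": "0 + C(subject)"}
    if "item" in data.columns and data["item"].nunique() > 1:
        vc["item"] = "0 + C(item)"
    model = smf.mixedlm(
        f"{response} ~ {fixed_formula}",
        data,
        groups="_all",
        re_formula="0",
        vc_formula=vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "bfgs", "powell", "nm"])
    return res, vc


def fit_model(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> ModelResult:
    """Fit the mixed model for RTs or map durations.

    REML linear mixed model with mode * place fixed effects and crossed
    subject/item random intercepts (variance components).  If the fit
    does not converge or every random-effect variance collapses to ~0,
    the model is refit as OLS on subject-cell means with subject fixed
    effects, and ``fallback=True`` is set.
    """
    spec = spec or ModelSpec()
    t = prepare_table(table) if "mode" not in table.columns else table.copy()
    _check_design(t, spec.response)
    fixed_formula = " + ".join(
        ":".join(f"C({f})" for f in term.split(":")) for term in spec.fixed
    )

    try:
        res, vc = _fit_mixed(t, spec.response, fixed_formula)
        converged = bool(getattr(res, "converged", True))
        rv = {k: float(res.vcomp[i]) for i, k in enumerate(vc)}
        degenerate = all(v < 1e-8 for v in rv.values())
        if converged and not degenerate:
            return ModelResult(
                terms=_wald_terms(res, list(spec.fixed)),
                coefficients=_coef_frame(res),
                method="mixedlm-reml",
                converged=converged,
                fallback=False,
                random_variances=rv,
            )
        reason = "degenerate random-effect variances" if degenerate else "non-convergence"
    except (np.linalg.LinAlgError, ValueError) as exc:  # rank deficiency etc.
        if "rank" in str(exc).lower():
            raise ModelDesignError(f"rank-deficient design: {exc}") from exc
        reason = f"mixed fit failed ({exc})"
    logger.warning("mixed model fallback: %s", reason)

    # Subject-aggregated analysis: cell means per subject x mode x place,
    # OLS with subject fixed effects (the within-subject paired analysis).
    agg = (
        t.groupby(["subject", "mode", "place"], sort=True)[spec.response]
        .mean()
        .reset_index()
    )
    ols = smf.ols(
        f"{spec.response} ~ {fixed_formula} + C(subject)", agg
    ).fit()
    terms = _wald_terms(ols, list(spec.fixed))
    terms = terms[~terms["term"].str.contains("subject")].reset_index(drop=True)
    coefs = _coef_frame(ols)
    coefs = coefs[~coefs["name"].str.contains("subject")].reset_index(drop=True)
    return ModelResult(
        terms=terms,
        coefficients=coefs,
        method="ols-subject-aggregated",
        converged=True,
        fallback=True,
        random_variances={},
    )


def planned_contrasts(
    table: pd.DataFrame,
    mode: str,
    pairs: list[tuple[str, str]] | None = None,
    response: str = "rt_ms",
) -> pd.DataFrame:
    """Pairwise place contrasts within one mode of articulation.

    Refits the model on the mode subset with place as the fixed factor
    (subject/item random intercepts, with the same aggregated fallback)
    and reports each pair's estimated difference (first minus second),
    SE, t and uncorrected p.
    """
    pairs = pairs or [("k", "p"), ("k", "t"), ("p", "t")]
    t = prepare_table(table) if "mode" not in table.columns else table.copy()
    sub = t[t["mode"] == mode]
    if sub.empty:
        raise ModelDesignError(f"no rows for mode {mode!r}")
    levels = sorted(sub["place"].unique())
    for a, b in pairs:
        if a not in levels or b not in levels:
            raise ModelDesignError(f"place level missing for contrast {a}-{b}")

    try:
        res, _ = _fit_mixed(sub, response, "C(place)")
        if not getattr(res, "converged", True):
            raise ValueError("non-convergence")
        exog_names = res.model.exog_names
    except (np.linalg.LinAlgError, ValueError):
        agg = (
            sub.groupby(["subject", "place"], sort=True)[response]
            .mean()
            .reset_index()
        )
        res = smf.ols(f"{response} ~ C(place) + C(subject)", agg).fit()
        exog_names = res.model.exog_names

    ref = levels[0]

    n_fe = getattr(res, "k_fe", len(exog_names))

    def coef_vector(level: str) -> np.ndarray:
        v = np.zeros(n_fe)
        if level == ref:
            return v
        name = f"C(place)[T.{level}]"
        v[exog_names.index(name)] = 1.0
        return v

    rows = []
    for a, b in pairs:
        c = np.atleast_2d(coef_vector(a) - coef_vector(b))
        tt = res.t_test(c)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "estimate": float(np.ravel(tt.effect)[0]),
                "se": float(np.ravel(tt.sd)[0]),
                "t": float(np.ravel(tt.tvalue)[0]),
                "p": float(np.ravel(tt.pvalue)[0]),
            }
        )
    return pd.DataFrame(rows)
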