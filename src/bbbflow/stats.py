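"""Mixed-model inference on leakage slopes and the cognition models.

The main analyses are linear mixed models of per-tissue enhancement slopes
with a random patient intercept, fitted with statsmodels' ``MixedLM``:

* tissue-specific covariate effects (age per 5 years, WMH burden per
  Fazekas point, lacunar vs cortical subtype, vascular risk factors), each
  interaction family fitted in its own model while adjusting for the others
  plus blood-pool level and pre-contrast tissue T1;
* the penumbra gradient: leakage per one-contour step toward the WMH edge;
* age-adjusted contour profiles stratified by WMH-burden group;
* ordinary least squares for the 1-year cognition (ACE-R) models with a
  leakage x subtype interaction, optionally conditioning on baseline ACE-R
  (the "change" model).

Coefficients are reported on the x 1e-3 slope scale with Wald 95% CIs and
normal-approximation p-values; no degrees-of-freedom correction and no
multiple-testing adjustment are applied (each table reports unadjusted
per-term tests).  Missing covariates are handled complete-case per model,
with counts logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import labels as L

log = logging.getLogger(__name__)

Z95 = 1.959963984540054

#: the three interaction families (age, WMH burden, subtype) adjust for each
#: other as main effects, plus blood-pool level, within-tissue T10 deviation
#: and the vascular risk factors
DEFAULT_ADJUSTERS = ("age5", "fazekas_score", "lacunar", "sinus_level",
                     "t10_dev", "map_c", "hypertension", "pp_c", "smoker")

#: WMH-burden grouping used for the stratified contour profiles
FAZEKAS_GROUPS = {"low": (0, 2), "medium": (3, 4), "high": (5, 6)}


@dataclass(frozen=True)
class ModelSpec:
    """One leakage mixed model: response, term of interest (interacted with
    tissue), adjustment set, tissue strata, and the reporting scale."""

    covariate: str
    response: str = "slope_1e3"
    adjusters: tuple[str, ...] = DEFAULT_ADJUSTERS
    tissues: tuple[str, ...] = L.MODEL_TISSUES
    reporting_scale: float = 1.0   # response already carries x1e-3

    def __post_init__(self) -> None:
        # the term of interest never adjusts for itself
        object.__setattr__(self, "adjusters", tuple(
            a for a in self.adjusters if a != self.covariate))


def _complete_case(df: pd.DataFrame, cols) -> pd.DataFrame:
    cols = [c for c in cols if c in df.columns]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"covariates absent from table: {missing}")
    out = df.dropna(subset=cols)
    n_drop = len(df) - len(out)
    if n_drop:
        log.info("complete-case: %d rows dropped for missing values", n_drop)
    return out


def prepare_model_frame(table: pd.DataFrame, tissues) -> pd.DataFrame:
    """Restrict to the requested strata and derive the within-tissue
    T10 deviation adjuster (raw T10 is nearly collinear with tissue)."""
    df = table[table.tissue.isin(tissues)].copy()
    if df.empty:
        raise ValueError(f"no rows for tissues {tuple(tissues)}")
    df["t10_dev"] = df.t10_ms - df.groupby("tissue").t10_ms.transform("mean")
    return df


def _check_rank(exog: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(exog)
    if r < exog.shape[1]:
        # a column is implicated if dropping it restores full column rank
        bad = [n for i, n in enumerate(names)
               if np.linalg.matrix_rank(np.delete(exog, i, axis=1)) == r]
        raise ValueError(f"rank-deficient design (rank {r} of "
                         f"{exog.shape[1]}); collinear terms: {bad}")


def _wald_table(params, bse, names, scale=1.0) -> pd.DataFrame:
    from scipy import stats as sps

    est = np.asarray(params) * scale
    se = np.asarray(bse) * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "term": names, "estimate": est,
        "ci95_low": est - Z95 * se, "ci95_high": est + Z95 * se,
        "p_value": p,
    })


def _mixedlm(formula: str, df: pd.DataFrame):
    if df.patient_id.nunique() < 2:
        raise ValueError("mixed model needs >= 2 patients (the random "
                         "intercept is undefined otherwise)")
    model = smf.mixedlm(formula, df, groups=df["patient_id"])
    _check_rank(model.exog, model.exog_names)
    return _fit_mixed(model)


def _fit_mixed(model):
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # boundary variance estimates are routine (e.g. noiseless cohorts)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            return model.fit(reml=True)
        except np.linalg.LinAlgError:
            return model.fit(reml=True, method="powell", maxiter=500)


_TISSUE_RE = re.compile(r"C\(tissue[^\)]*\)\[(?:T\.)?([^\]]+)\]")


def _tissue_of_term(term: str) -> str | None:
    m = _TISSUE_RE.search(term)
    return m.group(1) if m else None


def fit_leakage_model(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-tissue coefficients of one covariate on the leakage slope.

    Fits ``response ~ C(tissue) + adjusters + C(tissue):covariate`` with a
    random patient intercept and returns one coefficient row per tissue
    stratum (columns: term, tissue, estimate, ci95_low/high, p_value).
    """
    df = prepare_model_frame(table, spec.tissues)
    needed = [spec.response, spec.covariate, "patient_id", *spec.adjusters]
    df = _complete_case(df, needed)
    adj = " + ".join(spec.adjusters)
    formula = (f"{spec.response} ~ C(tissue) + {adj} "
               f"+ C(tissue):{spec.covariate}")
    res = _mixedlm(formula, df)

    fe = res.fe_params
    tab = _wald_table(fe.values, res.bse_fe.values, list(fe.index),
                      spec.reporting_scale)
    tab["tissue"] = [_tissue_of_term(t) for t in tab.term]
    keep = tab.term.str.contains(f":{re.escape(spec.covariate)}", regex=True) \
        | tab.term.str.contains(f"{re.escape(spec.covariate)}:", regex=True)
    out = tab[keep].copy()
    out["covariate"] = spec.covariate
    return out.reset_index(drop=True)


def fit_leakage_models(table: pd.DataFrame,
                       covariates=("age5", "fazekas_score", "lacunar"),
                       **kwargs) -> pd.DataFrame:
    """The headline coefficient table: one separate interaction model per
    covariate family (simultaneous interaction fitting is deliberately not
    attempted), stacked into one tidy table."""
    out = [fit_leakage_model(table, ModelSpec(covariate=c, **kwargs))
           for c in covariates]
    return pd.concat(out, ignore_index=True)


def contour_index(tissue: pd.Series) -> pd.Series:
    """Contour number k from the label (NaN for non-contour strata)."""
    return tissue.str.extract(r"contour_(\d+)")[0].astype(float)


def fit_contour_gradient(table: pd.DataFrame,
                         adjusters=("age5", "fazekas_score", "map_c",
                                    "pp_c", "lacunar", "smoker"),
                         response: str = "slope_1e3",
                         n_contours: int = 10) -> pd.DataFrame:
    """Linear leakage gradient across the NAWM penumbra.

    The predictor is the number of one-contour steps toward the WMH edge
    (contour ``n`` -> 0, contour 1 -> ``n - 1``), so a positive estimate
    means more leakage closer to the WMH.  Requires >= 3 populated contour
    levels.
    """
    df = table[table.tissue.str.startswith("contour_")].copy()
    if df.empty:
        raise ValueError("no contour strata in the table")
    k = contour_index(df.tissue)
    levels = sorted(k.unique())
    if len(levels) < 3:
        raise ValueError(f"need >= 3 contour levels, found {levels}")
    df["steps_toward_wmh"] = n_contours - k
    df = _complete_case(df, [response, "patient_id", *adjusters])
    adj = " + ".join(adjusters)
    res = _mixedlm(f"{response} ~ steps_toward_wmh + {adj}", df)
    fe = res.fe_params
    tab = _wald_table(fe.values, res.bse_fe.values, list(fe.index))
    out = tab[tab.term == "steps_toward_wmh"].copy()
    out["term"] = "leakage_per_contour_toward_wmh"
    return out.reset_index(drop=True)


def fazekas_group(scores: pd.Series,
                  grouping: dict | None = None) -> pd.Series:
    grouping = FAZEKAS_GROUPS if grouping is None else grouping
    covered = sorted(s for lo, hi in grouping.values()
                     for s in range(lo, hi + 1))
    if covered != list(range(7)):
        raise ValueError(f"grouping must cover scores 0..6, covers {covered}")
    def assign(s):
        for name, (lo, hi) in grouping.items():
            if lo <= s <= hi:
                return name
        return None
    return scores.map(assign)


def profile_by_fazekas_group(table: pd.DataFrame, value_col: str,
                             grouping: dict | None = None,
                             age_col: str = "age5") -> pd.DataFrame:
    """Age-adjusted group means of ``value_col`` per contour / WMH stratum.

    Per stratum, fits ``value ~ C(group) + age`` by OLS and reports each
    group's adjusted mean at the overall mean age with a Wald 95% CI.
    Strata keep their natural spatial order (contour n .. contour 1, then
    less-intense and intense WMH).  Empty groups are omitted with a warning.
    """
    grouping = FAZEKAS_GROUPS if grouping is None else grouping
    df = table.copy()
    df["faz_group"] = fazekas_group(df.fazekas_score, grouping)
    strata = [t for t in df.tissue.unique()
              if t.startswith("contour_") or t.startswith("wmh")]
    strata.sort(key=_stratum_order)
    rows = []
    for tissue in strata:
        sub = df[df.tissue == tissue].dropna(subset=[value_col, age_col])
        present = [g for g in grouping if (sub.faz_group == g).any()]
        absent = [g for g in grouping if g not in present]
        if absent:
            log.warning("profile_by_fazekas_group: %s: empty groups %s "
                        "omitted", tissue, absent)
        for g in present:
            gsub = sub[sub.faz_group == g]
            x = sm.add_constant(gsub[age_col] - df[age_col].mean())
            res = sm.OLS(gsub[value_col], x).fit()
            est = float(res.params.iloc[0])
            se = float(res.bse.iloc[0])
            rows.append({"tissue": tissue, "faz_group": g,
                         "adjusted_mean": est,
                         "ci95_low": est - Z95 * se,
                         "ci95_high": est + Z95 * se,
                         "n": len(gsub)})
    return pd.DataFrame(rows)


def _stratum_order(tissue: str) -> float:
    if tissue.startswith("contour_"):
        return -int(tissue.split("_")[1])           # contour 10 first
    return {"wmh": 0.5, "wmh_less_intense": 1.0, "wmh_intense": 2.0}[tissue]


def standardize_leakage(values: pd.Series) -> pd.Series:
    sd = values.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("WMH leakage has zero variance; cannot standardise")
    return (values - values.mean()) / sd


def fit_cognition_model(cohort_table: pd.DataFrame,
                        include_baseline_acer: bool = False,
                        leak_col: str = "wmh_slope_1e3",
                        min_patients: int = 20) -> pd.DataFrame:
    """1-year ACE-R on standardised WMH leakage, by stroke subtype.

    Without the baseline flag this is the cross-sectional 1-year model with
    a leakage x subtype interaction (separate lacunar / cortical leakage
    coefficients).  With ``include_baseline_acer`` the 1-3-month ACE-R
    enters as a covariate, making the leakage term a predictor of one-year
    *change*; that model reports a single pooled leakage coefficient.
    Both adjust for NART, Fazekas score, age and hypertension.
    """
    needed = ["acer_1yr", leak_col, "nart", "fazekas_score", "age5",
              "hypertension", "lacunar"]
    if include_baseline_acer:
        needed.append("acer_baseline")
    df = _complete_case(cohort_table, needed).copy()
    if len(df) < min_patients:
        raise ValueError(f"cognition model needs >= {min_patients} patients "
                         f"with 1-year ACE-R and WMH leakage, have {len(df)}")
    df["leak_z"] = standardize_leakage(df[leak_col])
    base = "nart + fazekas_score + age5 + hypertension"
    if include_baseline_acer:
        formula = f"acer_1yr ~ leak_z + acer_baseline + {base}"
    else:
        formula = f"acer_1yr ~ leak_z:C(lacunar) + C(lacunar) + {base}"
    model = smf.ols(formula, df)
    _check_rank(model.exog, model.exog_names)
    res = model.fit()
    tab = _wald_table(res.params.values, res.bse.values,
                      list(res.params.index))
    keep = tab.term.str.contains("leak_z")
    out = tab[keep].copy()
    out["term"] = out.term.map({
        "leak_z": "wmh_leakage_z",
        "leak_z:C(lacunar)[0]": "wmh_leakage_z[cortical]",
        "leak_z:C(lacunar)[1]": "wmh_leakage_z[lacunar]",
    }).fillna(out.term)
    out["n"] = len(df)
    return out.reset_index(drop=True)


def fit_longitudinal_model(curves: pd.DataFrame, covariate: str,
                           tissues=L.MODEL_TISSUES,
                           response: str = "enhancement_1e3") -> pd.DataFrame:
    """Direct longitudinal mode: enhancement ~ time x tissue (x covariate)
    with a random slope on time per patient.

    The covariate's per-tissue interaction with time is the slope effect on
    the same x 1e-3 / min scale as the two-stage models; the two modes must
    agree in sign and approximate magnitude.
    """
    df = curves[curves.tissue.isin(tissues)].copy()
    df = _complete_case(df, [response, "time_min", covariate, "patient_id"])
    if df.patient_id.nunique() < 2:
        raise ValueError("mixed model needs >= 2 patients")
    formula = (f"{response} ~ C(tissue) + C(tissue):time_min "
               f"+ C(tissue):time_min:{covariate}")
    model = smf.mixedlm(formula, df, groups=df["patient_id"],
                        re_formula="~time_min")
    res = _fit_mixed(model)
    fe = res.fe_params
    tab = _wald_table(fe.values, res.bse_fe.values, list(fe.index))
    tab["tissue"] = [_tissue_of_term(t) for t in tab.term]
    keep = tab.term.str.contains("time_min:") \
        & tab.term.str.contains(re.escape(covariate))
    out = tab[keep].copy()
    out["covariate"] = covariate
    return out.reset_index(drop=True)
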