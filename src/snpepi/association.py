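"""Logistic-regression association analysis: crude and adjusted odds ratios,
block likelihood-ratio p-values, data-driven confounder selection, scan
drivers for the report tables, and mediation re-analysis.

Every fit is a maximum-likelihood binary logistic regression on complete
cases.  A genetic exposure enters either as reference-coded indicator
columns (categorical encodings) or as a single numeric column (ordinal
encodings); the model's single p-value is the likelihood-ratio test of
all exposure terms jointly ("block p").  Confidence intervals are Wald
intervals on the log-odds scale.  Following the study's convention,
p < 0.05 is classed significant and 0.05 <= p < 0.10 marginal.

Confounder selection is stepwise-backward: starting from all candidate
covariates, the non-locked covariate with the largest likelihood-ratio
p-value is removed while that p-value is at or above the critical
threshold (default 0.2), refitting after each removal.  Skin colour is
locked by convention (population-stratification control).  The selection
is run against each outcome (binary logistic) and against each genetic
exposure (multinomial logistic); the covariates adjusted for in a given
exposure-outcome analysis are those retained on both sides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from . import encodings
from .cohort import Cohort, OUTCOME_COLS
from .encodings import (
    COMBOS,
    EpistaticModel,
    GeneticModel,
    category_display,
    combo_label,
    single_category_display,
)

logger = logging.getLogger(__name__)

Z975 = norm.ppf(0.975)
#: |log OR| beyond which a contrast is flagged as separated/unstable
SEPARATION_LOG_OR = 15.0
ALPHA = 0.05
MARGINAL = 0.10


class FitError(RuntimeError):
    """Raised when a regression cannot be fitted at all."""


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

class SingleSnpExposure:
    """One SNP under one of the five genetic models."""

    def __init__(self, locus: int, model: GeneticModel):
        if locus not in (1, 2):
            raise ValueError("locus must be 1 or 2")
        self.locus = locus
        self.model = model

    kind = property(lambda self: self.model.kind)
    required_columns = property(lambda self: (f"g{self.locus}",))

    def name(self, snp_defs) -> str:
        return f"{snp_defs[self.locus - 1].name}:{self.model.name}"

    @property
    def categories(self):
        return self.model.categories

    def encoded(self, df: pd.DataFrame) -> pd.Series:
        g = df[f"g{self.locus}"]
        return g.map(lambda v: self.model.mapping[int(v)])

    def contrast_display(self, category, snp_defs) -> str:
        return single_category_display(self.model, category, snp_defs[self.locus - 1])

    def reference_display(self, snp_defs) -> str:
        if self.model.kind == "ordinal":
            return ""
        return single_category_display(self.model, encodings.REF, snp_defs[self.locus - 1])


class EpistaticExposure:
    """The combined genotype under one epistatic model."""

    def __init__(self, model: EpistaticModel):
        self.model = model

    kind = property(lambda self: self.model.kind)
    required_columns = ("g1", "g2")

    def name(self, snp_defs) -> str:
        return f"epistasis:{self.model.id}"

    @property
    def categories(self):
        return self.model.categories

    def encoded(self, df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [self.model.mapping[(int(a), int(b))] for a, b in zip(df["g1"], df["g2"])],
            index=df.index,
        )

    def contrast_display(self, category, snp_defs) -> str:
        return category_display(self.model, category, snp_defs)

    def reference_display(self, snp_defs) -> str:
        if self.model.kind == "ordinal":
            return ""
        return category_display(self.model, self.model.reference, snp_defs)


class ComboExposure:
    """The saturated 9-level combined genotype (reference wild/wild)."""

    kind = "categorical"
    required_columns = ("g1", "g2")
    categories = COMBOS  # reference first

    def name(self, snp_defs) -> str:
        return "combined genotype"

    def encoded(self, df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [(int(a), int(b)) for a, b in zip(df["g1"], df["g2"])], index=df.index
        )

    def contrast_display(self, category, snp_defs) -> str:
        return combo_label(*category, snp_defs)

    def reference_display(self, snp_defs) -> str:
        return combo_label(0, 0, snp_defs)


def single_snp_exposure(locus: int, model_name: str) -> SingleSnpExposure:
    return SingleSnpExposure(locus, encodings.GENETIC_MODELS[model_name])


def epistatic_exposure(model_id: str) -> EpistaticExposure:
    return EpistaticExposure(encodings.EPISTATIC_MODELS[model_id])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    """One non-reference exposure category (or the per-unit ordinal term)."""

    label: str
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    n: int = 0
    undefined: bool = False
    unstable: bool = False

    def format_or(self, digits: int = 2) -> str:
        if self.undefined:
            return "undefined"
        return f"{self.or_:.{digits}f} ({self.ci_low:.{digits}f}-{self.ci_high:.{digits}f})"


def classify_significance(p: float, alpha: float = ALPHA, marginal: float = MARGINAL) -> str:
    if p != p:  # NaN
        return "null"
    if p < alpha:
        return "significant"
    if p < marginal:
        return "marginal"
    return "null"


@dataclass
class AssocResult:
    """Result of one logistic association fit."""

    exposure_name: str
    outcome: str
    contrasts: list = field(default_factory=list)
    reference_label: str = ""
    block_p: float = float("nan")
    block_df: int = 0
    n_used: int = 0
    covariates_used: tuple = ()
    converged: bool = True

    @property
    def significance(self) -> str:
        return classify_significance(self.block_p)

    def odds_ratios(self) -> dict:
        return {c.label: c.or_ for c in self.contrasts}


# ---------------------------------------------------------------------------
# design matrices and ML fitting
# ---------------------------------------------------------------------------

def _covariate_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Reference-coded indicators; most frequent level is the reference."""
    cols = {}
    for var in covariates:
        vals = df[var]
        levels = vals.value_counts()
        ref = levels.index[0]
        for level in levels.index[1:]:
            cols[f"{var}={level}"] = (vals == level).astype(float).to_numpy()
    return pd.DataFrame(cols, index=df.index)


def _fit_binary_ml(y: np.ndarray, X: pd.DataFrame):
    """Newton ML fit of a binary logistic model; returns the fitted result."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X.to_numpy(dtype=float))
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except Exception:
            try:
                res = model.fit(method="bfgs", maxiter=500, disp=0)
            except Exception as exc:  # pragma: no cover - pathological designs
                raise FitError(f"logistic fit failed: {exc}") from exc
    return res


@dataclass
class DesignSpec:
    """What to fit: outcome, encoded genetic exposure, covariates."""

    outcome: str
    exposure: object
    covariates: tuple = ()

    def __post_init__(self):
        self.covariates = tuple(self.covariates)


def fit_logistic(cohort: Cohort, spec: DesignSpec) -> AssocResult:
    """Crude or adjusted logistic fit of an outcome on a genetic exposure.

    Complete-case analysis: subjects missing the outcome, a genotype the
    exposure needs, or any covariate are dropped (and excluded from
    ``n_used``).  Empty exposure categories are reported as undefined
    contrasts; coefficients diverging beyond ``|log OR| > 15`` flag the
    fit as non-converged (separation), mirroring how extremely sparse
    categories behave rather than penalising them.
    """
    exposure = spec.exposure
    need = [spec.outcome, *exposure.required_columns, *spec.covariates]
    df = cohort.data.dropna(subset=need)
    n_used = len(df)
    result = AssocResult(
        exposure_name=exposure.name(cohort.snp_defs),
        outcome=spec.outcome,
        n_used=n_used,
        covariates_used=tuple(spec.covariates),
        reference_label=exposure.reference_display(cohort.snp_defs),
    )
    if n_used == 0:
        raise FitError("no complete-case subjects")
    y = df[spec.outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise FitError(f"outcome {spec.outcome} is constant on complete cases")

    enc = exposure.encoded(df)
    X_parts = {}
    if exposure.kind == "categorical":
        cats = [c for c in exposure.categories]
        ref = cats[0]
        for cat in cats[1:]:
            label = exposure.contrast_display(cat, cohort.snp_defs)
            n_cat = int((enc == cat).sum())
            if n_cat == 0:
                result.contrasts.append(Contrast(label=label, n=0, undefined=True))
            else:
                X_parts[label] = (enc == cat).astype(float).to_numpy()
                result.contrasts.append(Contrast(label=label, n=n_cat))
    else:
        score = enc.astype(float)
        label = exposure.contrast_display(None, cohort.snp_defs) or "per unit score"
        if score.nunique() < 2:
            result.contrasts.append(Contrast(label=label, n=n_used, undefined=True))
        else:
            X_parts[label] = score.to_numpy()
            result.contrasts.append(Contrast(label=label, n=n_used))

    X_exp = pd.DataFrame(X_parts, index=df.index)
    X_cov = _covariate_design(df, spec.covariates)
    const = pd.DataFrame({"const": np.ones(n_used)}, index=df.index)

    if X_exp.shape[1] == 0:
        result.block_p = float("nan")
        return result

    X_full = pd.concat([const, X_exp, X_cov], axis=1)
    X_red = pd.concat([const, X_cov], axis=1)
    res_full = _fit_binary_ml(y, X_full)
    res_red = _fit_binary_ml(y, X_red)

    lr = max(0.0, 2.0 * (res_full.llf - res_red.llf))
    result.block_df = X_exp.shape[1]
    result.block_p = float(chi2_dist.sf(lr, result.block_df))

    names = list(X_full.columns)
    converged = bool(res_full.mle_retvals.get("converged", True))
    defined = [c for c in result.contrasts if not c.undefined]
    for contrast in defined:
        i = names.index(contrast.label)
        b, se = float(res_full.params[i]), float(res_full.bse[i])
        with np.errstate(over="ignore"):
            contrast.or_ = float(np.exp(b))
            contrast.ci_low = float(np.exp(b - Z975 * se))
            contrast.ci_high = float(np.exp(b + Z975 * se))
        contrast.p = float(2 * norm.sf(abs(b) / se)) if se > 0 else float("nan")
        if abs(b) > SEPARATION_LOG_OR:
            contrast.unstable = True
            converged = False
    result.converged = converged
    return result


# ---------------------------------------------------------------------------
# confounder selection
# ---------------------------------------------------------------------------

@dataclass
class ConfounderSelection:
    """Outcome of a stepwise-backward covariate selection."""

    target: str
    retained: tuple
    removal_trace: list = field(default_factory=list)
    locked: tuple = ()
    threshold: float = 0.2


def _selection_response(cohort: Cohort, target: str) -> pd.Series:
    """Response used on the selection side: binary outcome or exposure levels."""
    df = cohort.data
    if target in OUTCOME_COLS:
        return df[target]
    if target in ("g1", "g2"):
        return df[target]
    if target == "combo":
        ok = df["g1"].notna() & df["g2"].notna()
        out = pd.Series(pd.NA, index=df.index, dtype="Int64")
        out[ok] = (3 * df.loc[ok, "g1"] + df.loc[ok, "g2"]).astype("Int64")
        return out
    raise ValueError(f"unknown selection target {target!r}")


def _fit_selection_ll(y: np.ndarray, X: pd.DataFrame, multinomial: bool) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr = X.to_numpy(dtype=float)
        if multinomial:
            model = sm.MNLogit(y, arr)
        else:
            model = sm.Logit(y, arr)
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-8, disp=0)
        except Exception:
            res = model.fit(method="bfgs", maxiter=1000, disp=0)
    return float(res.llf)


def select_confounders(
    cohort: Cohort,
    target: str,
    candidates,
    locked=("skin_color",),
    threshold: float = 0.2,
) -> ConfounderSelection:
    """Stepwise-backward covariate selection against one target.

    ``target`` is an outcome name (binary logistic) or a genetic
    exposure — ``"g1"``, ``"g2"`` (three genotype levels) or ``"combo"``
    (nine combined-genotype levels) — fitted by multinomial logistic
    regression with the wild/wild level as reference.  At each step the
    removable covariate with the largest likelihood-ratio p-value is
    dropped if that p-value is at or above ``threshold``; locked
    covariates are never removed.  Complete cases over the target plus
    all candidates are used throughout so every step sees the same
    subjects.
    """
    locked = tuple(locked)
    candidates = [c for c in candidates if c not in locked]
    # variables with no observed values cannot be adjusted for at all
    observed = set()
    for var in list(locked) + candidates:
        if cohort.data[var].notna().any():
            observed.add(var)
        else:
            logger.warning("select_confounders: %s entirely missing, dropped", var)
    locked = tuple(v for v in locked if v in observed)
    candidates = [v for v in candidates if v in observed]
    y_all = _selection_response(cohort, target)
    df = cohort.data.copy()
    df["_y"] = y_all
    keep_cols = ["_y", *locked, *candidates]
    cc = df.dropna(subset=keep_cols)
    if len(cc) == 0:
        raise FitError("no complete-case subjects for selection")
    y_ser = cc["_y"].astype(int)
    if y_ser.nunique() < 2:
        raise FitError(f"selection target {target} is constant")
    multinomial = y_ser.nunique() > 2
    codes = pd.Categorical(y_ser, categories=sorted(y_ser.unique())).codes
    n_eq = y_ser.nunique() - 1

    usable = []
    for var in list(locked) + candidates:
        if cc[var].nunique() < 2:
            logger.warning("select_confounders: %s has a single level, dropped", var)
        else:
            usable.append(var)
    locked_use = tuple(v for v in usable if v in locked)
    current = [v for v in usable if v not in locked]

    trace = []
    while True:
        X_base = _covariate_design(cc, list(locked_use) + current)
        X_full = pd.concat(
            [pd.DataFrame({"const": np.ones(len(cc))}, index=cc.index), X_base], axis=1
        )
        ll_full = _fit_selection_ll(codes, X_full, multinomial)
        worst, worst_p = None, -1.0
        for var in current:
            others = [v for v in list(locked_use) + current if v != var]
            X_wo = pd.concat(
                [
                    pd.DataFrame({"const": np.ones(len(cc))}, index=cc.index),
                    _covariate_design(cc, others),
                ],
                axis=1,
            )
            ll_wo = _fit_selection_ll(codes, X_wo, multinomial)
            df_term = (X_full.shape[1] - X_wo.shape[1]) * n_eq
            lr = max(0.0, 2.0 * (ll_full - ll_wo))
            p = float(chi2_dist.sf(lr, df_term))
            if p > worst_p:
                worst, worst_p = var, p
        if worst is None or worst_p < threshold:
            break
        current.remove(worst)
        trace.append((worst, worst_p))
    return ConfounderSelection(
        target=target,
        retained=tuple(locked_use) + tuple(current),
        removal_trace=trace,
        locked=locked_use,
        threshold=threshold,
    )


def confounders_for_pair(
    selection_outcome: ConfounderSelection,
    selection_exposure: ConfounderSelection,
    locked=("skin_color",),
) -> tuple:
    """Covariates adjusted for in one exposure-outcome analysis.

    The union of the locked covariates with the intersection of the two
    retained sets, ordered as in the outcome-side selection.
    """
    both = set(selection_outcome.retained) & set(selection_exposure.retained)
    out, seen = [], set()
    for var in tuple(locked) + selection_outcome.retained:
        if (var in both or var in locked) and var not in seen:
            out.append(var)
            seen.add(var)
    return tuple(out)


# ---------------------------------------------------------------------------
# scan drivers
# ---------------------------------------------------------------------------

@dataclass
class ScanRow:
    model: str
    crude: AssocResult | None = None
    adjusted: AssocResult | None = None
    error: str | None = None


@dataclass
class ScanResult:
    """Crude + adjusted results over a family of models for one outcome."""

    outcome: str
    rows: list = field(default_factory=list)
    covariates: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        """Report table mirroring the published layout: one row per contrast."""
        out = []
        for row in self.rows:
            if row.error is not None:
                out.append({"model": row.model, "category": "", "error": row.error})
                continue
            crude, adj = row.crude, row.adjusted
            if crude.reference_label:
                out.append(
                    {
                        "model": row.model,
                        "category": crude.reference_label,
                        "crude_or_ci": "1 (Reference)",
                        "crude_p": round(crude.block_p, 4),
                        "adjusted_or_ci": "1 (Reference)",
                        "adjusted_p": round(adj.block_p, 4) if adj else "",
                    }
                )
            for c_crude, c_adj in zip(crude.contrasts, adj.contrasts if adj else crude.contrasts):
                rec = {
                    "model": row.model,
                    "category": c_crude.label,
                    "crude_or_ci": c_crude.format_or(),
                    "adjusted_or_ci": c_adj.format_or() if adj else "",
                }
                if not crude.reference_label:
                    rec["crude_p"] = round(crude.block_p, 4)
                    rec["adjusted_p"] = round(adj.block_p, 4) if adj else ""
                out.append(rec)
        cols = ["model", "category", "crude_or_ci", "crude_p", "adjusted_or_ci", "adjusted_p", "error"]
        frame = pd.DataFrame(out)
        return frame.reindex(columns=[c for c in cols if c in frame.columns]).fillna("")


def _scan(cohort, outcome, exposures, covariates) -> ScanResult:
    scan = ScanResult(outcome=outcome, covariates=tuple(covariates))
    for name, exposure in exposures:
        row = ScanRow(model=name)
        try:
            row.crude = fit_logistic(cohort, DesignSpec(outcome, exposure, ()))
            row.adjusted = fit_logistic(cohort, DesignSpec(outcome, exposure, covariates))
        except (FitError, ValueError) as exc:
            row.error = str(exc)
            logger.warning("scan %s / %s failed: %s", outcome, name, exc)
        scan.rows.append(row)
    return scan


def run_single_snp_scan(cohort: Cohort, locus: int, outcome: str, covariates=()) -> ScanResult:
    """Crude and adjusted fits of one SNP under all five genetic models."""
    exposures = [
        (name, SingleSnpExposure(locus, encodings.GENETIC_MODELS[name]))
        for name in encodings.GENETIC_MODEL_ORDER
    ]
    return _scan(cohort, outcome, exposures, covariates)


def run_epistasis_scan(cohort: Cohort, outcome: str, models=None, covariates=()) -> ScanResult:
    """Crude and adjusted fits of the epistatic model catalog."""
    if models is None:
        models = encodings.list_epistatic_models()
    exposures = [(m.id, EpistaticExposure(m)) for m in models]
    return _scan(cohort, outcome, exposures, covariates)


# ---------------------------------------------------------------------------
# mediation re-analysis
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Covariate-inclusion mediation check: the same fit with and without
    the putative mediator, plus the per-contrast attenuation fraction
    ``1 - log(OR_with) / log(OR_without)`` (0 = no attenuation, 1 = the
    association vanishes entirely once the mediator is adjusted for)."""

    without: AssocResult
    with_mediator: AssocResult
    mediator: str
    attenuation: dict = field(default_factory=dict)


def mediation_check(cohort: Cohort, spec: DesignSpec, mediator: str) -> MediationResult:
    """Refit an adjusted model adding a putative mediator as a covariate."""
    if mediator == spec.outcome:
        raise ValueError("mediator cannot equal the outcome")
    if mediator in spec.covariates:
        raise ValueError("mediator already among the covariates")
    med_vals = cohort.data[mediator].dropna()
    if med_vals.nunique() < 2:
        raise ValueError(f"mediator {mediator} is constant")
    base_need = [spec.outcome, *spec.exposure.required_columns, *spec.covariates, mediator]
    sub = Cohort(
        cohort.data.dropna(subset=base_need), snp_defs=cohort.snp_defs
    )  # same subjects in both fits
    without = fit_logistic(sub, spec)
    with_med = fit_logistic(
        sub, DesignSpec(spec.outcome, spec.exposure, tuple(spec.covariates) + (mediator,))
    )
    attenuation = {}
    for c0, c1 in zip(without.contrasts, with_med.contrasts):
        if c0.undefined or c1.undefined or c0.or_ <= 0 or c1.or_ <= 0:
            continue
        denom = np.log(c0.or_)
        if abs(denom) > 1e-12:
            attenuation[c0.label] = float(1.0 - np.log(c1.or_) / denom)
    return MediationResult(
        without=without, with_mediator=with_med, mediator=mediator, attenuation=attenuation
    )


# ---------------------------------------------------------------------------
# fast aggregated fitters (shared with the power module; equivalence with
# fit_logistic is pinned by tests)
# ---------------------------------------------------------------------------

def block_p_categorical_counts(counts) -> float:
    """Block LRT p for a saturated categorical exposure from a k x 2 table.

    ``counts[:, 0]`` are controls and ``counts[:, 1]`` cases per exposure
    level.  For a saturated categorical logistic fit the block LRT equals
    the likelihood-ratio (G) statistic of the k x 2 table with
    df = (observed levels) - 1.
    """
    t = np.asarray(counts, dtype=float)
    t = t[t.sum(axis=1) > 0]
    k = t.shape[0]
    if k < 2 or (t.sum(axis=0) == 0).any():
        return float("nan")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    g = 2.0 * terms.sum()
    return float(chi2_dist.sf(max(g, 0.0), k - 1))


def fit_ordinal_counts(scores, controls, cases, tol=1e-10, maxiter=50):
    """Aggregated logistic fit of case status on a numeric score.

    Data arrive collapsed by score level (``cases[i]`` events out of
    ``cases[i] + controls[i]`` trials at ``scores[i]``).  Returns
    ``(beta, block_p)`` where ``beta`` is the per-unit log odds ratio and
    ``block_p`` the 1-df likelihood-ratio p-value.
    """
    s = np.asarray(scores, dtype=float)
    events = np.asarray(cases, dtype=float)
    trials = events + np.asarray(controls, dtype=float)
    keep = trials > 0
    s, events, trials = s[keep], events[keep], trials[keep]
    if len(s) < 2 or np.ptp(s) == 0 or events.sum() == 0 or events.sum() == trials.sum():
        return float("nan"), float("nan")
    X = np.column_stack([np.ones_like(s), s])
    beta = np.array([np.log(events.sum() / (trials.sum() - events.sum())), 0.0])

    def loglik(b):
        eta = X @ b
        return float(events @ eta - trials @ np.logaddexp(0.0, eta))

    ll = loglik(beta)
    for _ in range(maxiter):
        mu = expit(X @ beta)
        w = trials * mu * (1 - mu)
        grad = X.T @ (events - trials * mu)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        ll_new = loglik(beta)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new
    p_null = events.sum() / trials.sum()
    ll0 = float(events.sum() * np.log(p_null) + (trials.sum() - events.sum()) * np.log(1 - p_null))
    lr = max(0.0, 2.0 * (ll - ll0))
    return float(beta[1]), float(chi2_dist.sf(lr, 1))
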