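"""Synthetic cohort generation.

Generates case-control cohorts with the statistical structure the
analysis assumes: per-stratum genotype frequencies at two biallelic
loci (independent by default, with an optional log-linear dependence
parameter), per-stratum categorical covariate distributions with
missing-completely-at-random masking, and binary outcomes drawn from
logistic models over genotypes, covariates and stratum membership.

:func:`mimic_params` is a preset that emulates the marginal genotype,
covariate and outcome distributions of the motivating cervical-screening
study (250 women in one HIV stratum, 100 in the other).  The preset
reproduces printed marginal distributions; the joint two-locus
distribution within stratum is not published, so loci are generated
independently unless a joint override is supplied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort, DEFAULT_SNP_DEFS
from .encodings import COMBOS, EpistaticModel, GeneticModel

STRATA = ("neg", "pos")  # hiv = 0 and 1


# ---------------------------------------------------------------------------
# study count constants (inputs to the mimic preset and the worked examples)
# ---------------------------------------------------------------------------

#: per-stratum counts of the study sample; strata are (HIV-negative n=250,
#: HIV-positive n=100) and every distribution is over non-missing subjects
STUDY_COUNTS = {
    "n": {"neg": 250, "pos": 100},
    "g1": {"neg": (27, 118, 105), "pos": (18, 43, 39)},
    "g2": {"neg": (35, 101, 114), "pos": (16, 45, 39)},
    "skin_color": {
        "levels": ("white", "black", "brown"),
        "neg": (164, 31, 55),
        "pos": (51, 26, 23),
    },
    "age_group": {
        "levels": ("18-24", "25-30", "31-35", "36-39", "40-45"),
        "neg": (43, 55, 45, 50, 57),
        "pos": (3, 10, 17, 17, 53),
    },
    "schooling": {
        "levels": ("illiterate", "1-4", "5-8", "9-10", ">=11"),
        "neg": (4, 32, 93, 36, 81),
        "pos": (0, 22, 43, 0, 30),
    },
    "income": {
        "levels": ("<=1", ">1-2", ">2-3", ">=4"),
        "neg": (50, 80, 46, 12),
        "pos": (27, 33, 18, 10),
    },
    "hpv_pos": {"neg": (176, 250), "pos": (32, 100)},
    "hpv_high_risk": {"neg": (62, 69), "pos": (19, 57)},
}

#: three-way partition of the blocked-recessive model (9.1) as printed for
#: the worked example: (reference, middle, blocked) counts per stratum.
#: These counts are internally inconsistent with the marginal genotype
#: table above (a known discrepancy of the source data); the worked
#: example follows them verbatim.
DISCUSSION_PARTITION = {"neg": (50, 180, 20), "pos": (8, 70, 22)}


def study_contingency_tables() -> dict:
    """The printed between-strata contingency tables, rows x (neg, pos)."""
    tables = {}
    for var in ("g1", "g2"):
        tables[var] = [
            [STUDY_COUNTS[var]["neg"][i], STUDY_COUNTS[var]["pos"][i]] for i in range(3)
        ]
    for var in ("skin_color", "age_group", "schooling", "income"):
        neg, pos = STUDY_COUNTS[var]["neg"], STUDY_COUNTS[var]["pos"]
        tables[var] = [[neg[i], pos[i]] for i in range(len(neg))]
    hp = STUDY_COUNTS["hpv_pos"]
    tables["hpv"] = [
        [hp["neg"][0], hp["pos"][0]],
        [hp["neg"][1] - hp["neg"][0], hp["pos"][1] - hp["pos"][0]],
    ]
    return tables


def pooled_genotype_counts(locus: int) -> tuple[int, int, int]:
    """Genotype counts pooled over both strata ("total sample")."""
    var = f"g{locus}"
    return tuple(
        STUDY_COUNTS[var]["neg"][i] + STUDY_COUNTS[var]["pos"][i] for i in range(3)
    )


# ---------------------------------------------------------------------------
# outcome models
# ---------------------------------------------------------------------------

@dataclass
class BinaryTerm:
    """Contribution ``coef * value`` of a binary column (e.g. hiv)."""

    var: str
    coef: float

    def linpred(self, df, snp_defs):
        return self.coef * df[self.var].astype(float).to_numpy()

    def to_dict(self):
        return {"kind": "binary", "var": self.var, "coef": self.coef}


@dataclass
class CategoricalTerm:
    """Per-level log-odds contributions of a categorical covariate."""

    var: str
    coefs: dict  # level -> log OR (reference levels implicit 0)

    def linpred(self, df, snp_defs):
        return df[self.var].map(lambda v: self.coefs.get(v, 0.0)).astype(float).to_numpy()

    def to_dict(self):
        return {"kind": "categorical", "var": self.var, "coefs": dict(self.coefs)}


@dataclass
class GeneticTerm:
    """Log-odds contribution of a single-SNP genetic-model encoding."""

    locus: int
    model: GeneticModel
    coefs: object  # dict category -> log OR, or float per unit for ordinal

    def linpred(self, df, snp_defs):
        g = df[f"g{self.locus}"]
        if self.model.kind == "ordinal":
            return float(self.coefs) * g.astype(float).to_numpy()
        enc = g.map(lambda v: self.model.mapping[int(v)])
        return enc.map(lambda c: self.coefs.get(c, 0.0)).astype(float).to_numpy()

    def combo_values(self):
        if self.model.kind == "ordinal":
            return {c: float(self.coefs) * self.model.mapping[c[self.locus - 1]] for c in COMBOS}
        return {
            c: self.coefs.get(self.model.mapping[c[self.locus - 1]], 0.0) for c in COMBOS
        }

    def to_dict(self):
        return {
            "kind": "genetic",
            "locus": self.locus,
            "model": self.model.name,
            "coefs": self.coefs if isinstance(self.coefs, float) else dict(self.coefs),
        }


@dataclass
class EpistaticTerm:
    """Log-odds contribution of an epistatic-model encoding."""

    model: EpistaticModel
    coefs: object  # dict category -> log OR, or float per unit for ordinal

    def linpred(self, df, snp_defs):
        vals = self.combo_values()
        return np.array(
            [vals[(int(a), int(b))] for a, b in zip(df["g1"], df["g2"])], dtype=float
        )

    def combo_values(self):
        if self.model.kind == "ordinal":
            return {c: float(self.coefs) * self.model.mapping[c] for c in COMBOS}
        return {c: self.coefs.get(self.model.mapping[c], 0.0) for c in COMBOS}

    def to_dict(self):
        return {
            "kind": "epistatic",
            "model": self.model.id,
            "coefs": self.coefs if isinstance(self.coefs, float) else dict(self.coefs),
        }


@dataclass
class LogisticOutcome:
    """A logistic outcome model: intercept plus additive log-odds terms."""

    intercept: float
    terms: list = field(default_factory=list)

    def linpred(self, df, snp_defs):
        eta = np.full(len(df), self.intercept, dtype=float)
        for term in self.terms:
            eta += term.linpred(df, snp_defs)
        return eta

    def to_dict(self):
        return {"intercept": self.intercept, "terms": [t.to_dict() for t in self.terms]}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Full specification of a synthetic cohort.

    ``genotype_freqs[stratum][locus]`` are 3-vectors over genotype
    classes; ``ld`` tilts the within-stratum joint genotype distribution
    as ``P(g1, g2) \\propto P(g1) P(g2) exp(ld * g1 * g2)`` (0 keeps the
    loci independent); ``joint_override[stratum]`` may replace the joint
    3 x 3 distribution outright.  ``missing_rates`` are MCAR proportions,
    scalar or per-stratum ``(neg, pos)`` pairs.
    """

    n_controls: int = 250
    n_cases: int = 100
    genotype_freqs: dict = field(default_factory=dict)
    ld: float = 0.0
    joint_override: dict = field(default_factory=dict)
    covariate_dists: dict = field(default_factory=dict)
    missing_rates: dict = field(default_factory=dict)
    outcome_models: dict = field(default_factory=dict)
    snp_defs: tuple = DEFAULT_SNP_DEFS

    def validate(self) -> None:
        if self.n_controls < 1 or self.n_cases < 1:
            raise ValueError("both strata need at least one subject")
        for stratum in STRATA:
            for locus in (1, 2):
                p = np.asarray(self.genotype_freqs[stratum][locus], dtype=float)
                if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ValueError(f"invalid genotype frequencies {stratum}/g{locus}")
        for var, dist in self.covariate_dists.get("neg", {}).items():
            for stratum in STRATA:
                probs = np.asarray(
                    list(self.covariate_dists[stratum][var].values()), dtype=float
                )
                if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
                    raise ValueError(f"invalid covariate distribution {stratum}/{var}")
        for rate in self.missing_rates.values():
            pair = rate if isinstance(rate, (tuple, list)) else (rate, rate)
            if not all(0 <= r < 1 for r in pair):
                raise ValueError("missing rates must be in [0, 1)")

    def joint_genotype_probs(self, stratum: str) -> np.ndarray:
        """Joint 3 x 3 genotype distribution for one stratum."""
        if stratum in self.joint_override:
            joint = np.asarray(self.joint_override[stratum], dtype=float).reshape(3, 3)
            if abs(joint.sum() - 1.0) > 1e-9 or (joint < 0).any():
                raise ValueError("invalid joint genotype override")
            return joint
        p1 = np.asarray(self.genotype_freqs[stratum][1], dtype=float)
        p2 = np.asarray(self.genotype_freqs[stratum][2], dtype=float)
        joint = np.outer(p1, p2)
        if self.ld != 0.0:
            g = np.arange(3)
            joint = joint * np.exp(self.ld * np.outer(g, g))
            joint /= joint.sum()
        return joint

    def pooled_combo_probs(self) -> np.ndarray:
        """Population distribution over the 9 combos, strata pooled by size."""
        w = np.array([self.n_controls, self.n_cases], dtype=float)
        w /= w.sum()
        joint = w[0] * self.joint_genotype_probs("neg") + w[1] * self.joint_genotype_probs("pos")
        return joint.reshape(-1)

    def to_dict(self) -> dict:
        return {
            "n_controls": self.n_controls,
            "n_cases": self.n_cases,
            "genotype_freqs": {
                s: {locus: list(map(float, self.genotype_freqs[s][locus])) for locus in (1, 2)}
                for s in STRATA
            },
            "ld": self.ld,
            "joint_override": {
                s: np.asarray(j, dtype=float).reshape(-1).tolist()
                for s, j in self.joint_override.items()
            },
            "covariate_dists": self.covariate_dists,
            "missing_rates": {
                k: list(v) if isinstance(v, (tuple, list)) else v
                for k, v in self.missing_rates.items()
            },
            "outcome_models": {k: m.to_dict() for k, m in self.outcome_models.items()},
            "snps": [(s.name, s.wild_allele, s.variant_allele) for s in self.snp_defs],
        }

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class GeneratorReceipt:
    """Provenance of one generated cohort (same seed + params => same cohort)."""

    seed: int
    params_digest: str
    realized_counts: dict = field(default_factory=dict)


def _proportions(counts) -> tuple:
    total = sum(counts)
    return tuple(c / total for c in counts)


def mimic_params(n_controls: int = 250, n_cases: int = 100) -> CohortParams:
    """Preset emulating the study's marginal distributions.

    Genotype and covariate distributions per HIV stratum follow the
    published descriptive table; income and schooling missingness match
    its reduced denominators; HPV status and oncogenic risk are logistic
    in HIV status with per-stratum prevalences as printed.  Sample sizes
    default to the study's 250/100 but may be scaled.
    """
    sc = STUDY_COUNTS
    genotype_freqs = {
        s: {1: _proportions(sc["g1"][s]), 2: _proportions(sc["g2"][s])} for s in STRATA
    }
    covariate_dists = {
        s: {
            var: dict(zip(sc[var]["levels"], _proportions(sc[var][s])))
            for var in ("skin_color", "age_group", "schooling", "income")
            if sum(sc[var][s]) > 0
        }
        for s in STRATA
    }
    # drop zero-probability levels (e.g. empty schooling categories)
    for s in STRATA:
        for var in list(covariate_dists[s]):
            covariate_dists[s][var] = {
                k: v for k, v in covariate_dists[s][var].items() if v > 0
            }
    missing_rates = {
        "income": (
            1 - sum(sc["income"]["neg"]) / sc["n"]["neg"],
            1 - sum(sc["income"]["pos"]) / sc["n"]["pos"],
        ),
        "schooling": (
            1 - sum(sc["schooling"]["neg"]) / sc["n"]["neg"],
            1 - sum(sc["schooling"]["pos"]) / sc["n"]["pos"],
        ),
    }
    p_hpv = {s: sc["hpv_pos"][s][0] / sc["hpv_pos"][s][1] for s in STRATA}
    p_hr = {s: sc["hpv_high_risk"][s][0] / sc["hpv_high_risk"][s][1] for s in STRATA}
    outcome_models = {
        "hpv": LogisticOutcome(
            intercept=float(logit(p_hpv["neg"])),
            terms=[BinaryTerm("hiv", float(logit(p_hpv["pos"]) - logit(p_hpv["neg"])))],
        ),
        "hpv_high_risk": LogisticOutcome(
            intercept=float(logit(p_hr["neg"])),
            terms=[BinaryTerm("hiv", float(logit(p_hr["pos"]) - logit(p_hr["neg"])))],
        ),
    }
    params = CohortParams(
        n_controls=n_controls,
        n_cases=n_cases,
        genotype_freqs=genotype_freqs,
        covariate_dists=covariate_dists,
        missing_rates=missing_rates,
        outcome_models=outcome_models,
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(params: CohortParams, seed: int) -> tuple[Cohort, GeneratorReceipt]:
    """Draw a cohort from ``params`` (deterministic given ``seed``).

    Genotypes are drawn from the per-stratum joint distribution,
    covariates independently from their per-stratum categorical
    distributions, outcomes from the configured logistic models on the
    complete latent data, and missingness is applied last (so it is
    independent of everything unobserved — MCAR).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for hiv, stratum, n in (
        (0, "neg", params.n_controls),
        (1, "pos", params.n_cases),
    ):
        joint = params.joint_genotype_probs(stratum).reshape(-1)
        combo_idx = rng.choice(9, size=n, p=joint)
        df = pd.DataFrame(
            {
                "id": [f"S{offset + i + 1:06d}" for i in range(n)],
                "g1": combo_idx // 3,
                "g2": combo_idx % 3,
                "hiv": hiv,
            }
        )
        for var, dist in params.covariate_dists.get(stratum, {}).items():
            levels = list(dist)
            probs = np.array([dist[k] for k in levels], dtype=float)
            df[var] = rng.choice(levels, size=n, p=probs / probs.sum())
        frames.append(df)
        offset += n
    df = pd.concat(frames, ignore_index=True)

    for outcome in ("hpv", "hpv_high_risk"):
        model = params.outcome_models.get(outcome)
        if model is None:
            df[outcome] = pd.NA
            continue
        eta = model.linpred(df, params.snp_defs)
        draw = (rng.random(len(df)) < expit(eta)).astype(int)
        if outcome == "hpv_high_risk":
            vals = pd.Series(draw, dtype="Int64")
            vals[df["hpv"] != 1] = pd.NA  # nested outcome: defined among HPV+ only
            df[outcome] = vals
        else:
            df[outcome] = draw

    hiv_arr = df["hiv"].to_numpy()
    for var, rate in params.missing_rates.items():
        pair = tuple(rate) if isinstance(rate, (tuple, list)) else (rate, rate)
        p_miss = np.where(hiv_arr == 0, pair[0], pair[1])
        mask = rng.random(len(df)) < p_miss
        col = df[var].astype(object)
        col[mask] = pd.NA
        df[var] = col

    cohort = Cohort(df, snp_defs=params.snp_defs)
    realized = {
        "n": {"neg": params.n_controls, "pos": params.n_cases},
        "g1": {
            s: cohort.genotype_counts(1, cohort.data["hiv"] == h)
            for s, h in (("neg", 0), ("pos", 1))
        },
        "g2": {
            s: cohort.genotype_counts(2, cohort.data["hiv"] == h)
            for s, h in (("neg", 0), ("pos", 1))
        },
        "hpv_positive": int(cohort.data["hpv"].fillna(0).sum()),
    }
    receipt = GeneratorReceipt(seed=seed, params_digest=params.digest(), realized_counts=realized)
    return cohort, receipt


# ---------------------------------------------------------------------------
# effect injection
# ---------------------------------------------------------------------------

def _effect_term(exposure_model, or_values):
    """Build the outcome-model term for an injected effect."""
    from .association import EpistaticExposure, SingleSnpExposure  # cycle guard

    if isinstance(exposure_model, EpistaticModel):
        model = exposure_model
        if model.kind == "ordinal":
            return EpistaticTerm(model, float(np.log(np.atleast_1d(or_values)[0])))
        cats = [c for c in model.categories if c != model.reference]
        ors = np.atleast_1d(or_values).astype(float)
        if len(ors) == 1:
            ors = np.repeat(ors, len(cats))
        if len(ors) != len(cats):
            raise ValueError(f"model {model.id} needs {len(cats)} odds ratios")
        return EpistaticTerm(model, dict(zip(cats, np.log(ors))))
    if isinstance(exposure_model, (SingleSnpExposure,)):
        locus, model = exposure_model.locus, exposure_model.model
        if model.kind == "ordinal":
            return GeneticTerm(locus, model, float(np.log(np.atleast_1d(or_values)[0])))
        cats = [c for c in model.categories if c != "ref"]
        ors = np.atleast_1d(or_values).astype(float)
        if len(ors) == 1:
            ors = np.repeat(ors, len(cats))
        if len(ors) != len(cats):
            raise ValueError(f"model {model.name} needs {len(cats)} odds ratios")
        return GeneticTerm(locus, model, dict(zip(cats, np.log(ors))))
    if isinstance(exposure_model, EpistaticExposure):
        return _effect_term(exposure_model.model, or_values)
    raise TypeError(f"unsupported exposure {exposure_model!r}")


def solve_intercept(combo_probs, combo_linpred, target_prevalence: float) -> float:
    """Intercept giving a target marginal outcome prevalence.

    Solves ``sum_c p_c expit(b0 + eta_c) = target`` by root bracketing to
    1e-6 on the probability scale.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    p = np.asarray(combo_probs, dtype=float)
    eta = np.asarray(combo_linpred, dtype=float)

    def f(b0):
        return float(p @ expit(b0 + eta)) - target_prevalence

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence unattainable under the given effects")
    return float(brentq(f, lo, hi, xtol=1e-8))


def inject_effect(
    params: CohortParams,
    exposure_model,
    or_values,
    target_prevalence: float = 0.3,
    outcome: str = "hpv",
) -> CohortParams:
    """Return params whose ``outcome`` follows a logistic model in the
    given genetic/epistatic encoding, with log-OR coefficients
    ``log(or_values)`` and the intercept re-solved so the marginal
    prevalence over the pooled genotype distribution hits
    ``target_prevalence``.  The previous outcome model is replaced.
    """
    term = _effect_term(exposure_model, or_values)
    combo_probs = params.pooled_combo_probs()
    combo_eta = np.array([term.combo_values()[c] for c in COMBOS])
    b0 = solve_intercept(combo_probs, combo_eta, target_prevalence)
    new = CohortParams(
        n_controls=params.n_controls,
        n_cases=params.n_cases,
        genotype_freqs=params.genotype_freqs,
        ld=params.ld,
        joint_override=dict(params.joint_override),
        covariate_dists=params.covariate_dists,
        missing_rates=dict(params.missing_rates),
        outcome_models={**params.outcome_models, outcome: LogisticOutcome(b0, [term])},
        snp_defs=params.snp_defs,
    )
    new.validate()
    return new


def inject_epistatic_effect(
    params: CohortParams,
    model: EpistaticModel,
    or_per_category,
    target_prevalence: float = 0.3,
    outcome: str = "hpv",
) -> CohortParams:
    """Inject an epistatic effect on ``outcome`` (see :func:`inject_effect`)."""
    return inject_effect(params, model, or_per_category, target_prevalence, outcome)


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

def cohort_from_category_counts(
    model: EpistaticModel,
    control_counts,
    case_counts,
    outcome: str = "hiv",
    snp_defs=DEFAULT_SNP_DEFS,
) -> Cohort:
    """Expand per-category case/control counts into a subject-level cohort.

    Each category of the (categorical) model is represented by its first
    genotype combination in row-major order; any combination in the
    category encodes identically, so fits on the expanded cohort
    reproduce fits on the collapsed table exactly.
    """
    cats = model.categories
    if len(control_counts) != len(cats) or len(case_counts) != len(cats):
        raise ValueError(f"model {model.id} has {len(cats)} categories")
    reps = {cat: min(model.combos_in(cat)) for cat in cats}
    rows = []
    for status, counts in ((0, control_counts), (1, case_counts)):
        for cat, n in zip(cats, counts):
            g1, g2 = reps[cat]
            rows += [{"g1": g1, "g2": g2, outcome: status}] * int(n)
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"T{i + 1:05d}" for i in range(len(df))])
    return Cohort(df, snp_defs=snp_defs)


def discussion_cohort(snp_defs=DEFAULT_SNP_DEFS) -> Cohort:
    """The worked-example cohort: blocked-recessive three-way partition
    counts (controls 50/180/20, cases 8/70/22) expanded to subjects."""
    from .encodings import EPISTATIC_MODELS

    return cohort_from_category_counts(
        EPISTATIC_MODELS["9.1"],
        DISCUSSION_PARTITION["neg"],
        DISCUSSION_PARTITION["pos"],
        outcome="hiv",
        snp_defs=snp_defs,
    )
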