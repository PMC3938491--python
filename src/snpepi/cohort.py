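"""Cohort data model, delimited-file I/O and stratified descriptive tables.

The native input of the pipeline is a per-subject delimited table with
two biallelic genotypes, three binary outcomes (HIV status, HPV status
and — among HPV-positives only — HPV oncogenic risk) and four
categorical covariates (skin colour, age group, schooling, family
income), any of which may be missing.  Genotypes are stored ordinally
(0 = homozygous wild, 1 = heterozygous, 2 = homozygous variant) but may
be written in files either as codes or as allele-pair labels such as
``R72P``; the two naming conventions are interchangeable on input.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from . import exact_tests
from .exact_tests import TestResult

logger = logging.getLogger(__name__)

OUTCOME_COLS = ("hiv", "hpv", "hpv_high_risk")
COVARIATE_COLS = ("skin_color", "age_group", "schooling", "income")
GENOTYPE_COLS = ("g1", "g2")
ALL_COLS = ("id",) + GENOTYPE_COLS + OUTCOME_COLS + COVARIATE_COLS
MANDATORY_COLS = ("id",) + GENOTYPE_COLS + ("hiv", "hpv")

_TRUE = {"1", "positive", "pos", "yes", "true", "high", "high-risk", "high_risk"}
_FALSE = {"0", "negative", "neg", "no", "false", "low", "low-risk", "low_risk"}


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


class ValidationError(ValueError):
    """The cohort violates a structural invariant."""


@dataclass(frozen=True)
class SnpDef:
    """Definition of one biallelic SNP: its name and allele labels."""

    name: str
    wild_allele: str
    variant_allele: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("SNP name must be nonempty")
        if self.wild_allele == self.variant_allele:
            raise ValueError("wild and variant alleles must differ")

    @property
    def _position(self) -> str:
        m = re.search(r"\d+", self.name)
        return m.group(0) if m else ""

    def genotype_label(self, g) -> str:
        """Label of a genotype class, e.g. 0 -> ``"R72R"`` for TP53 R72P."""
        w, v, p = self.wild_allele, self.variant_allele, self._position
        return {0: f"{w}{p}{w}", 1: f"{w}{p}{v}", 2: f"{v}{p}{v}"}[int(g)]

    def set_label(self, genotypes: frozenset) -> str:
        """Label of a genotype subset, using ``_`` for "any allele"."""
        w, v, p = self.wild_allele, self.variant_allele, self._position
        key = frozenset(genotypes)
        named = {
            frozenset({0, 1, 2}): f"_{p}_",
            frozenset({1, 2}): f"{v}{p}_",
            frozenset({0, 1}): f"{w}{p}_",
        }
        if key in named:
            return named[key]
        return "/".join(self.genotype_label(g) for g in sorted(key))

    def parse_genotype(self, value):
        """Parse a genotype cell: 0/1/2 codes or allele-pair labels.

        Returns the ordinal code, or ``None`` when unparseable.
        """
        if value is None or value is pd.NA or value != value:
            return None
        text = str(value).strip()
        if text == "":
            return None
        if text in {"0", "1", "2"}:
            return int(text)
        try:
            num = float(text)
        except ValueError:
            num = None
        if num is not None:
            return int(num) if num in (0.0, 1.0, 2.0) else None
        letters = re.sub(r"[\d\s/|:;,_-]", "", text)
        w, v = self.wild_allele, self.variant_allele
        forms = {w + w: 0, w + v: 1, v + w: 1, v + v: 2}
        return forms.get(letters)


DEFAULT_SNP_DEFS = (SnpDef("R72P", "R", "P"), SnpDef("T309G", "T", "G"))


def _parse_binary(value):
    if value is None or value is pd.NA or value != value:
        return None
    text = str(value).strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return 1
    if text in _FALSE:
        return 0
    try:
        num = float(text)
    except ValueError:
        return None
    return int(num) if num in (0.0, 1.0) else None


@dataclass
class Cohort:
    """An ordered collection of subjects plus the two SNP definitions.

    ``data`` holds one row per subject with the canonical columns
    (``id, g1, g2, hiv, hpv, hpv_high_risk, skin_color, age_group,
    schooling, income``); genotypes and binary outcomes use the nullable
    ``Int64`` dtype so missingness propagates.
    """

    data: pd.DataFrame
    snp_defs: tuple = DEFAULT_SNP_DEFS

    def __post_init__(self):
        df = self.data.copy()
        for col in ALL_COLS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[list(ALL_COLS)]
        for col in GENOTYPE_COLS + OUTCOME_COLS:
            df[col] = df[col].astype("Int64")
        df["id"] = df["id"].astype(str)
        self.data = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if len(df) < 1:
            raise ValidationError("cohort must contain at least one subject")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].unique()[:5]
            raise ValidationError(f"duplicate subject ids: {list(dups)}")
        bad_g = df[list(GENOTYPE_COLS)].stack().dropna()
        if len(bad_g) and not bad_g.isin([0, 1, 2]).all():
            raise ValidationError("genotypes must be 0, 1, 2 or missing")
        bad_hr = df["hpv_high_risk"].notna() & (df["hpv"].isna() | (df["hpv"] != 1))
        if bad_hr.any():
            ids = df.loc[bad_hr, "id"].tolist()[:5]
            raise ValidationError(
                "hpv_high_risk defined for subjects without positive HPV status: "
                f"{ids}"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def genotype_counts(self, locus: int, subset=None) -> tuple[int, int, int]:
        """Genotype class counts ``(hom-wild, het, hom-variant)`` at a locus."""
        col = self.data[f"g{locus}"]
        if subset is not None:
            col = col[subset]
        vc = col.value_counts()
        return tuple(int(vc.get(g, 0)) for g in (0, 1, 2))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_cohort(path, schema=None, sep=None, snp_defs=DEFAULT_SNP_DEFS) -> Cohort:
    """Read a delimited cohort file.

    ``schema`` remaps canonical column names to the file's headers,
    e.g. ``{"hiv": "hiv_status"}``.  Genotype cells may hold 0/1/2 codes
    or allele-pair labels; binary cells accept 0/1 and common textual
    forms (positive/negative, high/low...).  Unparseable cells become
    missing; their count is logged as a warning.
    """
    schema = dict(schema or {})
    if sep is None:
        sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    raw.columns = [c.strip() for c in raw.columns]
    colmap = {canon: schema.get(canon, canon) for canon in ALL_COLS}
    missing = [colmap[c] for c in MANDATORY_COLS if colmap[c] not in raw.columns]
    if missing:
        raise SchemaError(f"mandatory columns absent from {path}: {missing}")

    n_bad = 0

    def parse_col(canon, parser):
        nonlocal n_bad
        name = colmap[canon]
        if name not in raw.columns:
            return pd.Series([pd.NA] * len(raw))
        vals, bad = [], 0
        for cell in raw[name]:
            out = parser(cell)
            if out is None and str(cell).strip() != "":
                bad += 1
            vals.append(pd.NA if out is None else out)
        n_bad += bad
        return pd.Series(vals)

    df = pd.DataFrame({"id": raw[colmap["id"]].astype(str)})
    df["g1"] = parse_col("g1", snp_defs[0].parse_genotype)
    df["g2"] = parse_col("g2", snp_defs[1].parse_genotype)
    for col in OUTCOME_COLS:
        df[col] = parse_col(col, _parse_binary)
    for col in COVARIATE_COLS:
        name = colmap[col]
        if name in raw.columns:
            vals = raw[name].astype(str).str.strip()
            df[col] = vals.where(vals != "", pd.NA)
        else:
            df[col] = pd.NA
    if n_bad:
        logger.warning("read_cohort: %d unparseable cells set to missing", n_bad)
    return Cohort(df, snp_defs=snp_defs)


def write_cohort(cohort: Cohort, path, sep: str = ",", genotype_labels: bool = True) -> None:
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    df = cohort.data.copy()
    if genotype_labels:
        for locus, snp in zip((1, 2), cohort.snp_defs):
            col = f"g{locus}"
            df[col] = df[col].map(
                lambda g, s=snp: s.genotype_label(g) if pd.notna(g) else pd.NA
            )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------

#: default between-strata test per variable; Fisher unless stated otherwise
DEFAULT_DESCRIBE_TESTS = {"age_group": "chi2", "skin_color": "chi2"}

_CATEGORY_ORDER = {
    "age_group": None,  # sorted lexicographically (labels are ordered ranges)
    "skin_color": ("white", "black", "brown"),
}


@dataclass
class DescriptiveTable:
    """Per-variable counts and percentages by stratum plus a test p-value."""

    table: pd.DataFrame
    tests: dict = field(default_factory=dict)
    stratify_by: str = "hiv"
    strata: tuple = (0, 1)

    def to_delimited(self, path, sep: str = ",") -> None:
        out = self.table.copy()
        out["p_value"] = out["variable"].map(
            lambda v: f"{self.tests[v].p_value:.4f}" if v in self.tests else ""
        ).astype(object)
        out.loc[out.duplicated("variable"), "p_value"] = ""
        out.to_csv(path, sep=sep, index=False)

    def to_text(self) -> str:
        lines = []
        s0, s1 = self.strata
        head = (
            f"{'variable':<18}{'category':<16}"
            f"{self.stratify_by + '=' + str(s0):>16}{self.stratify_by + '=' + str(s1):>16}"
            f"{'p':>10}"
        )
        lines.append(head)
        lines.append("-" * len(head))
        for var, grp in self.table.groupby("variable", sort=False):
            res = self.tests.get(var)
            ptxt = f"{res.p_value:.3f}" if res else ""
            for i, (_, row) in enumerate(grp.iterrows()):
                lines.append(
                    f"{var if i == 0 else '':<18}{str(row['category']):<16}"
                    f"{f'{row.n0} ({row.pct0:.1f}%)':>16}"
                    f"{f'{row.n1} ({row.pct1:.1f}%)':>16}"
                    f"{ptxt if i == 0 else '':>10}"
                )
        return "\n".join(lines)


def _variable_categories(cohort: Cohort, var: str) -> list:
    if var in GENOTYPE_COLS:
        return [0, 1, 2]
    if var in OUTCOME_COLS:
        return [1, 0]
    order = _CATEGORY_ORDER.get(var)
    observed = [v for v in cohort.data[var].dropna().unique()]
    if order:
        known = [c for c in order if c in observed]
        return known + sorted(v for v in observed if v not in order)
    return sorted(observed)


def _category_label(cohort: Cohort, var: str, cat) -> str:
    if var in GENOTYPE_COLS:
        snp = cohort.snp_defs[int(var[1]) - 1]
        return snp.genotype_label(cat)
    if var == "hpv_high_risk":
        return {1: "high-risk", 0: "low-risk"}[cat]
    if var in OUTCOME_COLS:
        return {1: "positive", 0: "negative"}[cat]
    return str(cat)


def describe(
    cohort: Cohort,
    stratify_by: str = "hiv",
    variables=None,
    tests=None,
) -> DescriptiveTable:
    """Stratified descriptive table with between-strata tests.

    Counts and percentages are computed per variable over the subjects
    with a non-missing value (complete cases per variable), separately
    within each stratum of the binary ``stratify_by`` outcome.  The
    between-strata comparison uses the Fisher exact test by default and
    the Pearson chi-square where configured via ``tests`` (a mapping
    ``variable -> "fisher" | "chi2"``).
    """
    if stratify_by not in OUTCOME_COLS:
        raise ValueError(f"stratify_by must be one of {OUTCOME_COLS}")
    strat = cohort.data[stratify_by]
    strata = (0, 1)
    masks = {s: (strat == s).fillna(False) for s in strata}
    for s, mask in masks.items():
        if mask.sum() == 0:
            raise ValueError(f"stratum {stratify_by}={s} has zero subjects")

    if variables is None:
        variables = [v for v in OUTCOME_COLS if v != stratify_by]
        variables += list(COVARIATE_COLS) + list(GENOTYPE_COLS)
    test_for = dict(DEFAULT_DESCRIBE_TESTS)
    test_for.update(tests or {})

    rows = []
    results: dict[str, TestResult] = {}
    for var in variables:
        cats = _variable_categories(cohort, var)
        if not cats:
            continue
        col = cohort.data[var]
        counts = {
            s: [int(((col == c) & masks[s]).sum()) for c in cats] for s in strata
        }
        denom = {s: sum(counts[s]) for s in strata}
        for c, label in zip(cats, (_category_label(cohort, var, c) for c in cats)):
            i = cats.index(c)
            rows.append(
                {
                    "variable": var,
                    "category": label,
                    "n0": counts[0][i],
                    "pct0": 100.0 * counts[0][i] / denom[0] if denom[0] else float("nan"),
                    "n1": counts[1][i],
                    "pct1": 100.0 * counts[1][i] / denom[1] if denom[1] else float("nan"),
                }
            )
        table = [[counts[0][i], counts[1][i]] for i in range(len(cats))]
        nonzero_rows = [r for r in table if sum(r) > 0]
        if len(nonzero_rows) < 2:
            results[var] = TestResult(
                p_value=1.0, method="degenerate (single observed category)"
            )
        elif test_for.get(var, "fisher") == "chi2":
            results[var] = exact_tests.chi_square(nonzero_rows)
        else:
            results[var] = exact_tests.fisher_exact(nonzero_rows)
    return DescriptiveTable(
        table=pd.DataFrame(rows), tests=results, stratify_by=stratify_by, strata=strata
    )


def hwe_report(cohort: Cohort, strata_var: str = "skin_color") -> pd.DataFrame:
    """Exact HWE p-values per SNP, overall and within covariate strata.

    Pools both outcome groups ("total sample") for the overall rows,
    then repeats the test within each level of ``strata_var``.
    """
    rows = []
    for locus, snp in zip((1, 2), cohort.snp_defs):
        counts = cohort.genotype_counts(locus)
        res = exact_tests.hwe_exact(counts)
        rows.append(
            {"snp": snp.name, "stratum": "total", "n": sum(counts), "p_value": res.p_value}
        )
    levels = _variable_categories(cohort, strata_var)
    for level in levels:
        mask = cohort.data[strata_var] == level
        for locus, snp in zip((1, 2), cohort.snp_defs):
            counts = cohort.genotype_counts(locus, subset=mask)
            if sum(counts) == 0:
                continue
            res = exact_tests.hwe_exact(counts)
            rows.append(
                {
                    "snp": snp.name,
                    "stratum": str(level),
                    "n": sum(counts),
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
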