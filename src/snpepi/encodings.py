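"""Genotype encodings: single-SNP genetic models and two-locus epistatic models.

A biallelic genotype is coded ordinally as 0 (homozygous wild), 1
(heterozygous) or 2 (homozygous variant).  A *genetic model* recodes the
three genotype classes of one SNP into regression terms; an *epistatic
model* recodes the nine two-locus genotype combinations.  Categorical
models partition the combinations into a reference category plus one or
two effect categories; ordinal models assign a numeric score that enters
regression as a single linear term.

The catalog below is fixed at two biallelic loci.  Locus 1 and locus 2
are interchangeable roles (for the study they are TP53 R72P and MDM2
T309G); paired model ids (1.1/1.2, 2.1/2.2, 3.1/3.2) are mirror images
under swapping the loci.  Models are data, not code: custom categorical
models can be built with :func:`make_categorical_model`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

GENOTYPES = (0, 1, 2)
REF = "ref"
CAT1 = "cat1"
CAT2 = "cat2"

#: all nine two-locus genotype combinations, row-major in (g1, g2)
COMBOS = tuple(itertools.product(GENOTYPES, GENOTYPES))

# genotype subsets used to write model categories as products of per-locus
# sets, mirroring the underscore ("any allele") notation of the field
ANY = frozenset(GENOTYPES)
WILD = frozenset({0})
HET = frozenset({1})
HOMVAR = frozenset({2})
CARRIER = frozenset({1, 2})       # variant carrier: "v_"
NONHOMVAR = frozenset({0, 1})     # not homozygous variant: "w_"


class EncodingError(ValueError):
    """Raised for malformed model definitions."""


# ---------------------------------------------------------------------------
# single-SNP genetic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticModel:
    """One of the five standard single-SNP genetic models.

    ``mapping`` is indexed by the ordinal genotype and yields a category
    label (categorical kind) or an integer score (ordinal kind).  The
    reference category is always the one containing the homozygous-wild
    genotype.
    """

    name: str
    kind: str  # "categorical" | "ordinal"
    mapping: tuple

    def encode(self, g):
        """Encode a single genotype; ``None``/missing propagates."""
        if g is None or g is pd.NA or g != g:
            return None
        return self.mapping[int(g)]

    @property
    def categories(self) -> tuple:
        if self.kind != "categorical":
            raise EncodingError(f"model {self.name} is ordinal")
        seen = []
        for lab in self.mapping:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    @property
    def non_ref_categories(self) -> tuple:
        if self.kind == "ordinal":
            return ("score",)
        return tuple(c for c in self.categories if c != REF)

    def genotypes_in(self, category) -> frozenset:
        return frozenset(g for g in GENOTYPES if self.mapping[g] == category)


GENETIC_MODELS: dict[str, GeneticModel] = {
    m.name: m
    for m in (
        GeneticModel("codominant", "categorical", (REF, CAT1, CAT2)),
        GeneticModel("overdominant", "categorical", (REF, CAT1, REF)),
        GeneticModel("additive", "ordinal", (0, 1, 2)),
        GeneticModel("dominant", "categorical", (REF, CAT1, CAT1)),
        GeneticModel("recessive", "categorical", (REF, REF, CAT1)),
    )
}

#: presentation order used by the single-SNP report tables
GENETIC_MODEL_ORDER = ("codominant", "overdominant", "additive", "dominant", "recessive")


def encode_single(g, model: GeneticModel):
    """Encode one genotype under a genetic model (missing propagates)."""
    return model.encode(g)


# ---------------------------------------------------------------------------
# two-locus epistatic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpistaticModel:
    """A named map from the 9 two-locus genotype combinations to categories.

    ``mapping`` sends every ``(g1, g2)`` pair to a category label
    (categorical kind) or an integer score (ordinal kind).  For
    categorical models ``display_blocks`` documents each category as a
    union of per-locus product sets — e.g. category 1 of the double
    recessive model is ``[(HOMVAR, ANY), (ANY, HOMVAR)]``, read
    "homozygous variant at either locus".  These blocks are what the
    report tables render with the actual allele names.
    """

    id: str
    kind: str  # "categorical" | "ordinal"
    mapping: dict = field(compare=False)
    description: str = ""
    display_blocks: dict = field(default_factory=dict, compare=False)
    reference: str = REF

    def encode(self, g1, g2):
        if g1 is None or g2 is None or g1 is pd.NA or g2 is pd.NA:
            return None
        if g1 != g1 or g2 != g2:  # NaN
            return None
        return self.mapping[(int(g1), int(g2))]

    @property
    def categories(self) -> tuple:
        if self.kind != "categorical":
            raise EncodingError(f"model {self.id} is ordinal")
        seen = []
        for combo in COMBOS:
            lab = self.mapping[combo]
            if lab not in seen:
                seen.append(lab)
        order = [c for c in (REF, CAT1, CAT2) if c in seen]
        extra = [c for c in seen if c not in order]
        return tuple(order + extra)

    @property
    def non_ref_categories(self) -> tuple:
        if self.kind == "ordinal":
            return ("score",)
        return tuple(c for c in self.categories if c != self.reference)

    def combos_in(self, category) -> frozenset:
        return frozenset(c for c in COMBOS if self.mapping[c] == category)


def validate_partition(model: EpistaticModel) -> None:
    """Check that a categorical model's categories partition all 9 combos."""
    if model.kind == "ordinal":
        missing = [c for c in COMBOS if c not in model.mapping]
        if missing:
            raise EncodingError(f"model {model.id}: unmapped combos {missing}")
        return
    cats = model.categories
    if not 2 <= len(cats) <= 3:
        raise EncodingError(f"model {model.id}: {len(cats)} categories (need 2 or 3)")
    covered = set()
    for cat in cats:
        combos = model.combos_in(cat)
        if covered & combos:
            raise EncodingError(f"model {model.id}: overlapping category {cat}")
        covered |= combos
    if covered != set(COMBOS):
        raise EncodingError(f"model {model.id}: categories do not cover all 9 combos")
    if model.reference not in cats:
        raise EncodingError(f"model {model.id}: reference {model.reference} missing")
    if model.display_blocks:
        for cat in cats:
            blocks = model.display_blocks.get(cat)
            if blocks is None:
                raise EncodingError(f"model {model.id}: no display blocks for {cat}")
            union = set()
            for s1, s2 in blocks:
                union |= set(itertools.product(s1, s2))
            if union != set(model.combos_in(cat)):
                raise EncodingError(
                    f"model {model.id}: display blocks for {cat} do not match combos"
                )


def make_categorical_model(
    id: str,
    description: str,
    blocks: dict,
    reference: str = REF,
) -> EpistaticModel:
    """Build and validate a categorical epistatic model.

    ``blocks`` maps each category label to a list of ``(set1, set2)``
    per-locus product sets; the category's combinations are their union.
    """
    mapping = {}
    for cat, blist in blocks.items():
        for s1, s2 in blist:
            for combo in itertools.product(s1, s2):
                prev = mapping.get(combo)
                if prev is not None and prev != cat:
                    raise EncodingError(
                        f"model {id}: combo {combo} assigned to both {prev} and {cat}"
                    )
                mapping[combo] = cat
    model = EpistaticModel(
        id=id,
        kind="categorical",
        mapping=mapping,
        description=description,
        display_blocks={k: tuple(v) for k, v in blocks.items()},
        reference=reference,
    )
    validate_partition(model)
    return model


def _ordinal_model(id: str, description: str, score: dict) -> EpistaticModel:
    model = EpistaticModel(id=id, kind="ordinal", mapping=dict(score), description=description)
    validate_partition(model)
    return model


def _build_catalog() -> dict[str, EpistaticModel]:
    m = {}
    m["1.1"] = make_categorical_model(
        "1.1",
        "dominant epistasis, locus 1 over locus 2",
        {
            REF: [(WILD, WILD)],
            CAT1: [(WILD, CARRIER)],
            CAT2: [(CARRIER, ANY)],
        },
    )
    m["1.2"] = make_categorical_model(
        "1.2",
        "dominant epistasis, locus 2 over locus 1",
        {
            REF: [(WILD, WILD)],
            CAT1: [(CARRIER, WILD)],
            CAT2: [(ANY, CARRIER)],
        },
    )
    m["2.1"] = make_categorical_model(
        "2.1",
        "recessive epistasis, locus 1 over locus 2",
        {
            REF: [(NONHOMVAR, NONHOMVAR)],
            CAT1: [(NONHOMVAR, HOMVAR)],
            CAT2: [(HOMVAR, ANY)],
        },
    )
    m["2.2"] = make_categorical_model(
        "2.2",
        "recessive epistasis, locus 2 over locus 1",
        {
            REF: [(NONHOMVAR, NONHOMVAR)],
            CAT1: [(HOMVAR, NONHOMVAR)],
            CAT2: [(ANY, HOMVAR)],
        },
    )
    m["3.1"] = make_categorical_model(
        "3.1",
        "dominant (locus 1) and recessive (locus 2) epistasis",
        {
            REF: [(ANY, NONHOMVAR), (WILD, ANY)],
            CAT1: [(CARRIER, HOMVAR)],
        },
    )
    m["3.2"] = make_categorical_model(
        "3.2",
        "recessive (locus 1) and dominant (locus 2) epistasis",
        {
            REF: [(NONHOMVAR, ANY), (ANY, WILD)],
            CAT1: [(HOMVAR, CARRIER)],
        },
    )
    m["4"] = make_categorical_model(
        "4",
        "double dominant epistasis without cumulative effect",
        {
            REF: [(WILD, WILD)],
            CAT1: [(CARRIER, ANY), (ANY, CARRIER)],
        },
    )
    m["5"] = make_categorical_model(
        "5",
        "double recessive epistasis without cumulative effect",
        {
            REF: [(NONHOMVAR, NONHOMVAR)],
            CAT1: [(HOMVAR, ANY), (ANY, HOMVAR)],
        },
    )
    m["6"] = make_categorical_model(
        "6",
        "double dominant epistasis with cumulative effect",
        {
            REF: [(WILD, WILD)],
            CAT1: [(WILD, CARRIER), (CARRIER, WILD)],
            CAT2: [(CARRIER, CARRIER)],
        },
    )
    m["7"] = make_categorical_model(
        "7",
        "double recessive epistasis with cumulative effect",
        {
            REF: [(NONHOMVAR, NONHOMVAR)],
            CAT1: [(HOMVAR, NONHOMVAR), (NONHOMVAR, HOMVAR)],
            CAT2: [(HOMVAR, HOMVAR)],
        },
    )
    m["8"] = _ordinal_model(
        "8",
        "quantitative: total number of variant alleles at the two loci",
        {(g1, g2): g1 + g2 for g1, g2 in COMBOS},
    )
    m["9.1"] = make_categorical_model(
        "9.1",
        "double dominant epistasis with blocked recessive effects (categorical)",
        {
            REF: [(WILD, WILD)],
            CAT1: [(HET, ANY), (ANY, HET), (HOMVAR, HOMVAR)],
            CAT2: [(WILD, HOMVAR), (HOMVAR, WILD)],
        },
    )
    cat_index = {REF: 0, CAT1: 1, CAT2: 2}
    m["9.2"] = _ordinal_model(
        "9.2",
        "double dominant epistasis with blocked recessive effects (linear score)",
        {combo: cat_index[m["9.1"].mapping[combo]] for combo in COMBOS},
    )
    return m


EPISTATIC_MODELS: dict[str, EpistaticModel] = _build_catalog()
EPISTATIC_MODEL_ORDER = tuple(EPISTATIC_MODELS)


def list_epistatic_models() -> list[EpistaticModel]:
    """Return the ordered catalog of the 13 epistatic models (validated)."""
    models = [EPISTATIC_MODELS[i] for i in EPISTATIC_MODEL_ORDER]
    for model in models:
        validate_partition(model)
    return models


def encode_epistatic(g1, g2, model: EpistaticModel):
    """Encode a two-locus genotype pair (missing propagates)."""
    return model.encode(g1, g2)


def encode_epistatic_series(g1: pd.Series, g2: pd.Series, model: EpistaticModel) -> pd.Series:
    """Vectorised :func:`encode_epistatic` over aligned genotype columns."""
    out = pd.Series([None] * len(g1), index=g1.index, dtype=object)
    ok = g1.notna() & g2.notna()
    out[ok] = [model.mapping[(int(a), int(b))] for a, b in zip(g1[ok], g2[ok])]
    return out


# ---------------------------------------------------------------------------
# human-readable labels
# ---------------------------------------------------------------------------

def combo_label(g1, g2, snp_defs) -> str:
    """Deterministic label of a genotype pair, e.g. ``"R72R G309G"``."""
    return f"{snp_defs[0].genotype_label(g1)} {snp_defs[1].genotype_label(g2)}"


def all_combo_labels(snp_defs) -> dict:
    return {combo: combo_label(*combo, snp_defs) for combo in COMBOS}


def parse_combo_label(label: str, snp_defs):
    """Inverse of :func:`combo_label`."""
    part1, part2 = label.split()
    g1 = snp_defs[0].parse_genotype(part1)
    g2 = snp_defs[1].parse_genotype(part2)
    if g1 is None or g2 is None:
        raise ValueError(f"unparseable combination label {label!r}")
    return (g1, g2)


def category_display(model: EpistaticModel, category, snp_defs) -> str:
    """Render a category of a categorical model with the SNPs' allele names.

    Uses the model's per-locus product blocks, e.g. category 2 of model
    1.1 renders as ``"P72_ _309_"`` for the R72P/T309G pair.
    """
    if model.kind == "ordinal":
        return "per-unit score"
    blocks = model.display_blocks.get(category)
    if not blocks:
        combos = sorted(model.combos_in(category))
        return " - ".join(combo_label(*c, snp_defs) for c in combos)
    parts = [
        f"{snp_defs[0].set_label(frozenset(s1))} {snp_defs[1].set_label(frozenset(s2))}"
        for s1, s2 in blocks
    ]
    return " - ".join(parts)


def single_category_display(model: GeneticModel, category, snp_def) -> str:
    """Render a category of a single-SNP genetic model, e.g. ``"R72R-P72P"``."""
    if model.kind == "ordinal":
        return f"number of {snp_def.variant_allele} alleles"
    gs = sorted(model.genotypes_in(category))
    return "-".join(snp_def.genotype_label(g) for g in gs)


def catalog_table(snp_defs=None) -> pd.DataFrame:
    """Export the epistatic catalog as a tidy table (model x combination).

    One row per model per genotype combination, with the assigned
    category or score; suitable for documentation and cross-language
    reuse of the maps.
    """
    rows = []
    for model in list_epistatic_models():
        for g1, g2 in COMBOS:
            row = {
                "model": model.id,
                "kind": model.kind,
                "g1": g1,
                "g2": g2,
                "value": model.mapping[(g1, g2)],
            }
            if snp_defs is not None:
                row["combination"] = combo_label(g1, g2, snp_defs)
            rows.append(row)
    return pd.DataFrame(rows)
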