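"""OR-pattern-driven model discovery over the combined genotypes.

The procedure profiles the adjusted odds ratio of each of the eight
non-reference two-locus genotype combinations against the wild/wild
reference in a single saturated logistic fit, then applies an explicit
decision rule to the profile: combinations whose OR clearly exceeds the
rest ("elevation") and resemble one another ("similarity") are flagged.
When the flagged set is exactly the two wild-homozygote x
variant-homozygote combinations — the signature of a double dominant
effect that masks an otherwise hidden recessive effect — the procedure
proposes the blocked-recessive models (categorical 9.1 and its linear
score 9.2).

The underlying published procedure was a visual inspection of the OR
plot; the thresholds here make that judgment explicit, reproducible and
auditable (the rule trace records every comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import ComboExposure, DesignSpec, fit_logistic
from .cohort import Cohort
from .encodings import EPISTATIC_MODELS, combo_label, validate_partition

#: the two wild-homozygote x variant-homozygote combinations
BLOCKED_PAIR = frozenset({(0, 2), (2, 0)})


@dataclass
class ComboEntry:
    combo: tuple
    label: str
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_controls: int = 0
    n_cases: int = 0
    undefined: bool = False


@dataclass
class ComboProfile:
    """Adjusted ORs of the 8 non-reference genotype combinations."""

    entries: list
    covariates_used: tuple = ()
    outcome: str = "hiv"
    n_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "combination": e.label,
                    "or": e.or_,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n_controls": e.n_controls,
                    "n_cases": e.n_cases,
                    "undefined": e.undefined,
                }
                for e in self.entries
            ]
        )


def combination_or_profile(cohort: Cohort, outcome: str, covariates=()) -> ComboProfile:
    """One adjusted logistic fit of the 9-level combined genotype.

    Reference is the wild/wild combination; each entry carries the OR,
    Wald 95% CI and per-stratum subject counts of one combination.
    Empty combinations are flagged undefined, never dropped silently.
    """
    exposure = ComboExposure()
    result = fit_logistic(cohort, DesignSpec(outcome, exposure, tuple(covariates)))
    need = [outcome, "g1", "g2", *covariates]
    cc = cohort.data.dropna(subset=need)
    y = cc[outcome].astype(int)
    entries = []
    by_label = {c.label: c for c in result.contrasts}
    for combo in exposure.categories[1:]:
        label = combo_label(*combo, cohort.snp_defs)
        contrast = by_label[label]
        mask = (cc["g1"] == combo[0]) & (cc["g2"] == combo[1])
        entries.append(
            ComboEntry(
                combo=combo,
                label=label,
                or_=contrast.or_,
                ci_low=contrast.ci_low,
                ci_high=contrast.ci_high,
                n_controls=int((mask & (y == 0)).sum()),
                n_cases=int((mask & (y == 1)).sum()),
                undefined=contrast.undefined,
            )
        )
    return ComboProfile(
        entries=entries,
        covariates_used=tuple(covariates),
        outcome=outcome,
        n_used=result.n_used,
    )


@dataclass
class PatternProposal:
    """Outcome of the blocked-recessive pattern rule."""

    flagged_combos: frozenset
    proposed_models: tuple | None
    rule_trace: str
    elevation: float = 2.0
    similarity: float = 1.5


def propose_blocked_recessive(
    profile: ComboProfile, elevation: float = 2.0, similarity: float = 1.5
) -> PatternProposal:
    """Apply the blocked-recessive pattern rule to an OR profile.

    A combination is flagged when its OR exceeds ``elevation`` times the
    median OR of the remaining combinations; flagged combinations must
    additionally be mutually similar (largest/smallest ratio at most
    ``similarity``).  The blocked-recessive models (9.1, 9.2) are
    proposed only when the flagged set is exactly the wild-homozygote x
    variant-homozygote pair; any other pattern yields no proposal, with
    the reasoning recorded in the rule trace.  The rule compares only OR
    ratios, so rescaling every OR by a constant leaves it unchanged.
    """
    lines = [f"rule: OR > {elevation} x median(others); mutual ratio <= {similarity}"]
    defined = [e for e in profile.entries if not e.undefined and e.or_ > 0]
    undefined = [e for e in profile.entries if e.undefined]
    for e in undefined:
        lines.append(f"  {e.label}: OR undefined, excluded from the rule")
    flagged = []
    for e in defined:
        others = [o.or_ for o in defined if o is not e]
        med = float(np.median(others)) if others else float("nan")
        hit = e.or_ > elevation * med
        lines.append(
            f"  {e.label}: OR={e.or_:.2f}, median(others)={med:.2f} -> "
            f"{'flagged' if hit else 'not flagged'}"
        )
        if hit:
            flagged.append(e)
    flagged_set = frozenset(e.combo for e in flagged)
    if len(flagged) >= 2:
        ors = [e.or_ for e in flagged]
        ratio = max(ors) / min(ors)
        similar = ratio <= similarity
        lines.append(
            f"  flagged mutual ratio {ratio:.2f} "
            f"{'<=' if similar else '>'} {similarity}"
        )
        if not similar:
            lines.append("  no proposal: flagged ORs are not similar to one another")
            return PatternProposal(flagged_set, None, "\n".join(lines), elevation, similarity)
    if flagged_set == BLOCKED_PAIR:
        lines.append(
            "  pattern matches the wild-homozygote x variant-homozygote pair: "
            "proposing blocked-recessive models 9.1 (categorical) and 9.2 (score)"
        )
        models = (EPISTATIC_MODELS["9.1"], EPISTATIC_MODELS["9.2"])
        for m in models[:1]:
            validate_partition(m)
        return PatternProposal(flagged_set, models, "\n".join(lines), elevation, similarity)
    if not flagged_set:
        lines.append("  no proposal: no combination is elevated")
    else:
        lines.append(
            "  no proposal: flagged set "
            f"{sorted(flagged_set)} is not the wild x variant-homozygote pair"
        )
    return PatternProposal(flagged_set, None, "\n".join(lines), elevation, similarity)


def plot_profile(profile: ComboProfile, path) -> None:
    """Optional rendered figure of the OR profile (never load-bearing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = profile.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(frame))
    ax.errorbar(
        x,
        frame["or"],
        yerr=[frame["or"] - frame["ci_low"], frame["ci_high"] - frame["or"]],
        fmt="o",
        capsize=3,
    )
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xticks(x, frame["combination"], rotation=45, ha="right")
    ax.set_ylabel(f"OR vs wild/wild ({profile.outcome})")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
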