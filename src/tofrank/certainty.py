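"""Diagnostic-certainty binning of clinical exome findings.

Each individual's reported variant findings in a gene are binned into a
``definitive``, ``probable`` or ``provisional`` diagnosis (or ``none``)
according to a rule table keyed on the ACMG variant class, the inheritance
mode of the associated disorder, phase for biallelic findings, and whether
the individual's phenotype is suggestive of the disorder.

The base table is configurable (YAML), but two autosomal-recessive rules are
fixed and cannot be overridden:

* P + VUS in trans, suggestive phenotype  -> probable
* LP + VUS in trans, suggestive phenotype -> provisional

Likely-benign and benign findings are ignored.  When the phase of a
qualifying biallelic pair is unknown the diagnosis is demoted one bin
relative to its in-trans bin, with provisional as the floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

ACMG_CLASSES = ("P", "LP", "VUS", "LB", "B")
INHERITANCE_MODES = ("AD", "AR", "XL")
PHASES = ("in_trans", "in_cis", "unknown", "n/a")

_ACMG_RANK = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}


class Certainty(IntEnum):
    """Ordered diagnostic certainty: definitive > probable > provisional > none."""

    NONE = 0
    PROVISIONAL = 1
    PROBABLE = 2
    DEFINITIVE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Certainty":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown certainty label {label!r}") from None


@dataclass(frozen=True)
class VariantFinding:
    """One reported variant in one gene of one individual."""

    individual_id: str
    gene: str
    acmg_class: str
    inheritance_mode: str
    phase: str = "n/a"
    phenotype_suggestive: bool = True

    def __post_init__(self) -> None:
        if self.acmg_class not in ACMG_CLASSES:
            raise ValueError(f"unknown acmg_class {self.acmg_class!r}")
        if self.inheritance_mode not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance_mode {self.inheritance_mode!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class Diagnosis:
    individual_id: str
    gene: str
    certainty: Certainty
    triggering_rule: str


# Monoallelic (AD/XL) bins for a phenotype-suggestive finding.
DEFAULT_MONOALLELIC: dict[str, Certainty] = {
    "P": Certainty.DEFINITIVE,
    "LP": Certainty.PROBABLE,
    "VUS": Certainty.PROVISIONAL,
}

# Biallelic (AR) in-trans bins for a phenotype-suggestive pair, keyed by the
# sorted pair of ACMG classes.
DEFAULT_BIALLELIC_IN_TRANS: dict[tuple[str, str], Certainty] = {
    ("P", "P"): Certainty.DEFINITIVE,
    ("LP", "P"): Certainty.DEFINITIVE,
    ("LP", "LP"): Certainty.DEFINITIVE,
    ("P", "VUS"): Certainty.PROBABLE,
    ("LP", "VUS"): Certainty.PROVISIONAL,
}

# Fixed rules; any override attempting to change these is rejected.
_FIXED_BIALLELIC: dict[tuple[str, str], Certainty] = {
    ("P", "VUS"): Certainty.PROBABLE,
    ("LP", "VUS"): Certainty.PROVISIONAL,
}


@dataclass(frozen=True)
class RuleSet:
    """Configurable certainty rule table."""

    monoallelic: Mapping[str, Certainty]
    biallelic_in_trans: Mapping[tuple[str, str], Certainty]

    @classmethod
    def default(cls) -> "RuleSet":
        return cls(dict(DEFAULT_MONOALLELIC), dict(DEFAULT_BIALLELIC_IN_TRANS))

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        """Load overrides from YAML; the two fixed AR compound-het rules
        (P+VUS -> probable, LP+VUS -> provisional) cannot be changed."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mono = dict(DEFAULT_MONOALLELIC)
        for cls_, label in (raw.get("monoallelic") or {}).items():
            if cls_ not in DEFAULT_MONOALLELIC:
                raise ValueError(f"monoallelic rule for unknown class {cls_!r}")
            mono[cls_] = Certainty.from_label(label)
        bi = dict(DEFAULT_BIALLELIC_IN_TRANS)
        for key, label in (raw.get("biallelic_in_trans") or {}).items():
            pair = tuple(sorted(str(key).split("+")))
            if len(pair) != 2 or any(c not in ("P", "LP", "VUS") for c in pair):
                raise ValueError(f"bad biallelic rule key {key!r}")
            cert = Certainty.from_label(label)
            if pair in _FIXED_BIALLELIC and cert != _FIXED_BIALLELIC[pair]:
                raise ValueError(
                    f"rule {key!r} is fixed to "
                    f"{_FIXED_BIALLELIC[pair].label!r} and cannot be overridden"
                )
            bi[pair] = cert
        return cls(mono, bi)


def _demote(cert: Certainty) -> Certainty:
    """One bin lower, floored at provisional."""
    if cert is Certainty.NONE:
        return cert
    return Certainty(max(cert - 1, Certainty.PROVISIONAL))


def classify(
    findings: Sequence[VariantFinding],
    rules: RuleSet | None = None,
) -> Diagnosis:
    """Bin the findings of one (individual, gene) pair into a Diagnosis.

    For autosomal-recessive disorders every in-trans or phase-unknown pair of
    qualifying variants is evaluated and the highest-certainty outcome kept;
    in-cis pairs do not qualify.  For AD/XL disorders the best single finding
    decides.  Findings without a suggestive phenotype yield no diagnosis.
    """
    if not findings:
        raise ValueError("no findings supplied")
    if len({(f.individual_id, f.gene) for f in findings}) != 1:
        raise ValueError("findings must share one individual and one gene")
    rules = rules or RuleSet.default()

    individual, gene = findings[0].individual_id, findings[0].gene
    usable = [f for f in findings if f.acmg_class not in ("LB", "B")]
    best = (Certainty.NONE, "no_qualifying_finding")

    modes = {f.inheritance_mode for f in usable}
    if len(modes) > 1:
        raise ValueError(
            f"conflicting inheritance modes for {individual}/{gene}: {sorted(modes)}"
        )

    if usable and usable[0].inheritance_mode == "AR":
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                f1, f2 = usable[i], usable[j]
                if "in_cis" in (f1.phase, f2.phase):
                    continue
                if not (f1.phenotype_suggestive and f2.phenotype_suggestive):
                    continue
                pair = tuple(sorted((f1.acmg_class, f2.acmg_class)))
                cert = rules.biallelic_in_trans.get(pair, Certainty.NONE)
                if cert is Certainty.NONE:
                    continue
                if f1.phase == "in_trans" and f2.phase == "in_trans":
                    rule_id = f"AR_{pair[0]}+{pair[1]}_in_trans"
                else:
                    cert = _demote(cert)
                    rule_id = f"AR_{pair[0]}+{pair[1]}_phase_unknown"
                if cert > best[0]:
                    best = (cert, rule_id)
    else:
        for f in usable:
            if not f.phenotype_suggestive:
                continue
            cert = rules.monoallelic.get(f.acmg_class, Certainty.NONE)
            if cert > best[0]:
                best = (cert, f"{f.inheritance_mode}_{f.acmg_class}_suggestive")

    return Diagnosis(individual, gene, best[0], best[1])


def classify_cohort(
    cohort: pd.DataFrame,
    rules: RuleSet | None = None,
) -> list[Diagnosis]:
    """Classify every (individual, gene) group of a cohort table.

    Expects columns ``individual_id, gene, acmg_class, inheritance_mode,
    phase, phenotype_suggestive``.  Malformed rows are rejected with their
    (0-based) row number.
    """
    findings: dict[tuple[str, str], list[VariantFinding]] = {}
    for i, row in enumerate(cohort.itertuples(index=False)):
        try:
            f = VariantFinding(
                individual_id=str(row.individual_id),
                gene=str(row.gene),
                acmg_class=str(row.acmg_class),
                inheritance_mode=str(row.inheritance_mode),
                phase=str(row.phase),
                phenotype_suggestive=_as_bool(row.phenotype_suggestive),
            )
        except ValueError as e:
            raise ValueError(f"cohort row {i}: {e}") from None
        findings.setdefault((f.individual_id, f.gene), []).append(f)

    return [classify(fs, rules) for fs in findings.values()]


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {v!r}")


def best_per_individual(diagnoses: Iterable[Diagnosis]) -> dict[str, Certainty]:
    """Highest certainty per individual (used for diagnostic efficacy)."""
    best: dict[str, Certainty] = {}
    for d in diagnoses:
        cur = best.get(d.individual_id, Certainty.NONE)
        if d.certainty > cur:
            best[d.individual_id] = d.certainty
        else:
            best.setdefault(d.individual_id, cur)
    return best


def diagnoses_to_frame(diagnoses: Iterable[Diagnosis]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": d.individual_id,
                "gene": d.gene,
                "certainty": d.certainty.label,
                "triggering_rule": d.triggering_rule,
            }
            for d in diagnoses
        ]
    )
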