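"""Diagnostic-efficacy and gene-panel-coverage accounting.

Efficacy is the fraction of cohort individuals whose highest-certainty
diagnosis is definitive or probable.  Diagnosis counts are gene-level: an
autosomal-recessive diagnosis supported by two variants in one gene is one
diagnosis, and one individual may hold several diagnoses in distinct genes.

Panel coverage asks how many definitive/probable diagnoses (and how many of
the unique genes behind them) fall inside each commercial panel's gene set;
the cross-panel minimum and maximum are reported as a range.

Exact fractions are the ground truth throughout; percentages are rounded
half-up to one decimal only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from ._format import pct
from .certainty import Certainty, Diagnosis

DIAGNOSTIC = (Certainty.DEFINITIVE, Certainty.PROBABLE)


@dataclass
class CohortSummary:
    n_individuals: int
    n_definitive: int
    n_probable: int
    n_provisional: int
    n_dx_individuals: int
    n_dx_diagnoses: int

    @property
    def efficacy_fraction(self) -> Fraction:
        return Fraction(self.n_dx_individuals, self.n_individuals)

    @property
    def efficacy_pct(self) -> float:
        return pct(self.n_dx_individuals, self.n_individuals)

    @property
    def definitive_pct(self) -> float:
        return pct(self.n_definitive, self.n_individuals)

    @property
    def probable_pct(self) -> float:
        return pct(self.n_probable, self.n_individuals)

    @property
    def provisional_pct(self) -> float:
        return pct(self.n_provisional, self.n_individuals)

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_definitive": self.n_definitive,
            "n_probable": self.n_probable,
            "n_provisional": self.n_provisional,
            "n_dx_individuals": self.n_dx_individuals,
            "n_dx_diagnoses": self.n_dx_diagnoses,
            "efficacy_fraction": f"{self.n_dx_individuals}/{self.n_individuals}",
            "efficacy_pct": self.efficacy_pct,
            "definitive_pct": self.definitive_pct,
            "probable_pct": self.probable_pct,
            "provisional_pct": self.provisional_pct,
        }


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class PanelCoverage:
    panel_name: str
    genes: frozenset[str]
    dx_covered: int
    dx_total: int
    unique_genes_covered: int
    unique_genes_total: int

    @property
    def dx_pct(self) -> float:
        return pct(self.dx_covered, self.dx_total)

    @property
    def gene_pct(self) -> float:
        return pct(self.unique_genes_covered, self.unique_genes_total)


def summarize_cohort(
    best: Mapping[str, Certainty],
    diagnoses: Iterable[Diagnosis],
    n_individuals: int,
) -> CohortSummary:
    """Per-bin individual counts, diagnosis counts, and efficacy.

    ``best`` maps each individual to their highest certainty (see
    :func:`tofrank.certainty.best_per_individual`); ``diagnoses`` supplies the
    gene-level records for the definitive/probable diagnosis count.
    """
    diagnosed = {i for i, c in best.items() if c is not Certainty.NONE}
    if n_individuals < len(diagnosed):
        raise ValueError(
            f"n_individuals={n_individuals} is less than the "
            f"{len(diagnosed)} distinct diagnosed individuals"
        )
    n_def = sum(1 for c in best.values() if c is Certainty.DEFINITIVE)
    n_prob = sum(1 for c in best.values() if c is Certainty.PROBABLE)
    n_prov = sum(1 for c in best.values() if c is Certainty.PROVISIONAL)
    n_dx_dx = sum(1 for d in diagnoses if d.certainty in DIAGNOSTIC)
    return CohortSummary(
        n_individuals=n_individuals,
        n_definitive=n_def,
        n_probable=n_prob,
        n_provisional=n_prov,
        n_dx_individuals=n_def + n_prob,
        n_dx_diagnoses=n_dx_dx,
    )


def panel_coverage(
    diagnoses: Sequence[Diagnosis],
    panels: Sequence[PanelDefinition],
) -> tuple[list[PanelCoverage], dict[str, float]]:
    """Coverage of definitive/probable diagnoses by each panel, plus the
    cross-panel min/max range at diagnosis and unique-gene level."""
    if not panels:
        raise ValueError("no panels supplied")
    dx = [d for d in diagnoses if d.certainty in DIAGNOSTIC]
    if not dx:
        raise ValueError("no definitive or probable diagnoses to cover")
    genes = {d.gene for d in dx}

    out = []
    for p in panels:
        out.append(
            PanelCoverage(
                panel_name=p.name,
                genes=p.genes,
                dx_covered=sum(1 for d in dx if d.gene in p.genes),
                dx_total=len(dx),
                unique_genes_covered=len(genes & p.genes),
                unique_genes_total=len(genes),
            )
        )
    rng = {
        "dx_pct_min": min(c.dx_pct for c in out),
        "dx_pct_max": max(c.dx_pct for c in out),
        "gene_pct_min": min(c.gene_pct for c in out),
        "gene_pct_max": max(c.gene_pct for c in out),
    }
    return out, rng
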