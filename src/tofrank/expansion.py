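"""Rule-based evidence integration for phenotypic expansion.

Candidate genes are those carrying a definitive or probable diagnosis in the
cohort but not already known to cause the phenotype.  For each candidate,
three lines of evidence are combined:

1. the gene's rank annotation score — positive (>50%) or high (>=85%);
2. previously published cases linking the gene (or its syndrome) to the
   phenotype;
3. congenital heart defects in mouse models of the gene's homolog
   (recorded as supportive annotation, not required for support).

Default verdict rule: ``supported`` iff score > 50% AND literature cases
exist.  The thresholds and the literature requirement are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .certainty import Certainty, Diagnosis
from .genes import known_tof_genes

SCORE_BANDS = ("high", "positive", "non-positive")


@dataclass(frozen=True)
class KnownGeneRegistry:
    """Genes already established to cause the phenotype; candidates must not
    be members."""

    known_phenotype_genes: frozenset[str] = field(
        default_factory=known_tof_genes
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "known_phenotype_genes", frozenset(self.known_phenotype_genes)
        )

    def __contains__(self, gene: str) -> bool:
        return gene in self.known_phenotype_genes


@dataclass(frozen=True)
class ExpansionRule:
    positive_threshold: float = 50.0
    high_threshold: float = 85.0
    require_literature: bool = True


@dataclass
class ExpansionEvidence:
    gene: str
    rank_score: float
    score_band: str
    literature_cases: bool
    mouse_chd: bool
    verdict: str
    diagnosis_certainty: Certainty | None = None


def identify_candidates(
    diagnoses: Iterable[Diagnosis],
    registry: KnownGeneRegistry | None = None,
) -> list[str]:
    """Genes with at least one definitive/probable diagnosis that are not in
    the known-gene registry; sorted, unique."""
    registry = registry or KnownGeneRegistry()
    hits = {
        d.gene
        for d in diagnoses
        if d.certainty in (Certainty.DEFINITIVE, Certainty.PROBABLE)
    }
    return sorted(hits - registry.known_phenotype_genes)


def evaluate(
    gene: str,
    rank_score: float,
    literature_cases: bool,
    mouse_chd: bool,
    diagnosis_certainty: Certainty | None = None,
    rule: ExpansionRule | None = None,
) -> ExpansionEvidence:
    """Apply the evidence rule to one candidate gene."""
    rule = rule or ExpansionRule()
    if not 0.0 <= rank_score <= 100.0:
        raise ValueError(f"rank score {rank_score} outside [0, 100]")
    if rank_score >= rule.high_threshold:
        band = "high"
    elif rank_score > rule.positive_threshold:
        band = "positive"
    else:
        band = "non-positive"
    supported = rank_score > rule.positive_threshold and (
        literature_cases or not rule.require_literature
    )
    return ExpansionEvidence(
        gene=gene,
        rank_score=float(rank_score),
        score_band=band,
        literature_cases=bool(literature_cases),
        mouse_chd=bool(mouse_chd),
        verdict="supported" if supported else "not_supported",
        diagnosis_certainty=diagnosis_certainty,
    )


def evaluate_candidates(
    candidates: Sequence[str],
    scores: dict[str, float],
    evidence: dict[str, tuple[bool, bool]],
    rule: ExpansionRule | None = None,
) -> list[ExpansionEvidence]:
    """Evaluate many candidates; ``evidence`` maps gene -> (literature_cases,
    mouse_chd)."""
    out = []
    for g in candidates:
        lit, mouse = evidence.get(g, (False, False))
        out.append(evaluate(g, scores[g], lit, mouse, rule=rule))
    return out
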