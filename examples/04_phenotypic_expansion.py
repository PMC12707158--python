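"""Evidence integration for phenotypic expansion candidates.

Takes the four TOF candidate genes with their published rank-annotation
scores and evidence flags, identifies candidates from diagnosis records
(novel genes with a definitive/probable diagnosis), and applies the decision
rule: supported iff score > 50% AND published TOF cases exist; mouse CHD is
recorded as supportive annotation only.
"""

from tofrank import (
    Certainty,
    KnownGeneRegistry,
    evaluate,
    identify_candidates,
    summarize_scores,
)
from tofrank.certainty import Diagnosis

diagnoses = [
    Diagnosis("BG45", "DVL3", Certainty.PROBABLE, "AD_LP_suggestive"),
    Diagnosis("D2", "MED13L", Certainty.DEFINITIVE, "AD_P_suggestive"),
    Diagnosis("BG61", "PUF60", Certainty.DEFINITIVE, "AD_P_suggestive"),
    Diagnosis("BG31", "MEIS2", Certainty.PROBABLE, "AD_LP_suggestive"),
    Diagnosis("BG1", "JAG1", Certainty.DEFINITIVE, "AD_P_suggestive"),  # known
]
candidates = identify_candidates(diagnoses, KnownGeneRegistry())
print("candidate genes (novel, definitive/probable):", candidates)

# gene -> (rank score %, literature TOF cases, CHD in mouse models)
evidence = {"DVL3": (96.8, True, True), "MED13L": (85.1, True, False),
            "PUF60": (79.9, True, False), "MEIS2": (61.9, True, True)}
for gene in candidates:
    score, lit, mouse = evidence[gene]
    ev = evaluate(gene, score, lit, mouse)
    print(f"{gene:7s} score {score:5.1f}% ({ev.score_band:12s}) "
          f"literature={lit} mouse_chd={mouse} -> {ev.verdict}")

summary = summarize_scores({g: e[0] for g, e in evidence.items()},
                           evidence.keys(), label="candidates")
print(f"median candidate score: {summary.median:.1f}%  (chance = 50%)")
# All four candidates are supported: each scores above chance and has
# published TOF cases, so TOF is added to each gene's phenotypic spectrum.
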