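"""Synthetic knowledge sources, cohorts and fixtures.

The real inputs of this analysis — genome-scale annotation sources and a
clinically classified exome cohort — are not redistributable, so this module
generates structurally faithful stand-ins:

* :func:`simulate_sources` builds K gene x feature matrices of independent
  Gaussian noise in which a designated training-gene set has its mean shifted
  by ``enrichment`` on a fixed 20% of each source's features (a planted,
  tunable disease-gene signal; ``enrichment = 0`` makes genes exchangeable).
* :func:`simulate_cohort` builds a variant-finding table that, when
  classified with the default certainty rules, reproduces a requested
  definitive/probable/provisional composition *exactly* (constructive
  generation, not rejection sampling), including individuals holding multiple
  diagnoses in distinct genes.

All randomness flows from explicit seeds; identical configs reproduce
byte-identical TSV output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import TOF_TRAINING_GENES
from .ranking import FeatureSource

_EXTRA_POOL = ("DVL3", "MED13L", "PUF60", "MEIS2", "DLG2", "CUL3", "TAB2",
               "SON", "POGZ", "ARID1B", "ANKRD11", "EHMT1", "SETD5", "AUTS2")


@dataclass
class SimConfig:
    """Configuration for synthetic knowledge sources.

    ``training_genes=None`` selects the first ``min(20, n_genes // 5)``
    genome genes.  ``gene_symbols=None`` generates ``G000001...``; supply
    real symbols (e.g. the TOF training genes) via ``gene_symbols``.
    """

    n_genes: int = 1000
    n_sources: int = 3
    n_features_per_source: int = 50
    training_genes: Sequence[str] | None = None
    enrichment: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    gene_symbols: Sequence[str] | None = None
    enriched_feature_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_sources", "n_features_per_source"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 < self.enriched_feature_fraction <= 1:
            raise ValueError("enriched_feature_fraction must be in (0, 1]")
        if self.gene_symbols is not None and len(self.gene_symbols) != self.n_genes:
            raise ValueError("gene_symbols length must equal n_genes")

    @property
    def genome(self) -> list[str]:
        if self.gene_symbols is not None:
            return list(self.gene_symbols)
        return [f"G{i + 1:06d}" for i in range(self.n_genes)]

    def resolved_training_genes(self) -> list[str]:
        genome = self.genome
        if self.training_genes is None:
            return genome[: min(20, max(1, self.n_genes // 5))]
        genome_set = set(genome)
        for g in self.training_genes:
            if g not in genome_set:
                raise ValueError(f"training gene {g!r} is not in the genome")
        return list(self.training_genes)

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_sources": self.n_sources,
            "n_features_per_source": self.n_features_per_source,
            "training_genes": self.resolved_training_genes(),
            "enrichment": self.enrichment,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "enriched_feature_fraction": self.enriched_feature_fraction,
        }


def simulate_sources(config: SimConfig) -> list[FeatureSource]:
    """Generate K knowledge sources with a planted training-gene signal.

    Entries are iid Normal(0, noise_sd); for training genes the first
    ``ceil(enriched_feature_fraction * n_features)`` features of every source
    are additively shifted by ``enrichment``.  Each source draws from its own
    substream of the global seed, so sources are independent but jointly
    reproducible.
    """
    genome = config.genome
    training = config.resolved_training_genes()
    pos = {g: i for i, g in enumerate(genome)}
    train_idx = [pos[g] for g in training]
    n_enriched = math.ceil(config.enriched_feature_fraction
                           * config.n_features_per_source)
    children = np.random.SeedSequence(config.seed).spawn(config.n_sources)

    sources = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        m = rng.normal(0.0, config.noise_sd,
                       size=(config.n_genes, config.n_features_per_source))
        m[np.asarray(train_idx), :n_enriched] += config.enrichment
        sources.append(FeatureSource(name=f"source{k + 1:02d}",
                                     genes=list(genome), matrix=m))
    return sources


def write_sources(sources: Sequence[FeatureSource], out_dir, config: SimConfig | None = None) -> None:
    """One TSV per source (gene first column) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for src in sources:
        src.to_frame().to_csv(out / f"{src.name}.tsv", sep="\t",
                              index=False, float_format="%.6f")
    if config is not None:
        (out / "manifest.json").write_text(
            json.dumps({"sim_config": config.to_dict()}, indent=2) + "\n"
        )


def read_sources(in_dir) -> list[FeatureSource]:
    paths = sorted(Path(in_dir).glob("source*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no source*.tsv files under {in_dir}")
    return [
        FeatureSource.from_frame(p.stem, pd.read_csv(p, sep="\t"))
        for p in paths
    ]


@dataclass
class CohortSpec:
    """Requested composition of a synthetic clinical exome cohort.

    ``multi_diagnosis`` lists ``(individual_index, extra_count)`` pairs: the
    individual at that (0-based) index receives ``extra_count`` additional
    distinct-gene diagnoses of its own certainty bin, so per-individual bin
    counts stay exact while the diagnosis-level count grows.

    ``n_unique_dx_genes`` fixes how many distinct genes the definitive and
    probable diagnoses span (genes are reused cyclically across individuals);
    by default every such diagnosis gets its own gene.
    """

    n_individuals: int
    n_definitive: int = 0
    n_probable: int = 0
    n_provisional: int = 0
    multi_diagnosis: Sequence[tuple[int, int]] = field(default_factory=tuple)
    seed: int = 0
    n_unique_dx_genes: int | None = None

    @property
    def n_dx_diagnoses(self) -> int:
        return (self.n_definitive + self.n_probable
                + sum(e for _, e in self.multi_diagnosis))

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        for name in ("n_definitive", "n_probable", "n_provisional"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.n_definitive + self.n_probable + self.n_provisional
                > self.n_individuals):
            raise ValueError("bin counts exceed the number of individuals")
        n_dx = self.n_definitive + self.n_probable
        for idx, extra in self.multi_diagnosis:
            if extra < 1:
                raise ValueError("extra diagnosis counts must be >= 1")
            if not 0 <= idx < n_dx:
                raise ValueError(
                    f"multi-diagnosis individual index {idx} must fall in the "
                    f"definitive/probable stratum (0..{n_dx - 1})"
                )
        if self.n_unique_dx_genes is not None:
            per_ind_max = 1 + max((e for _, e in self.multi_diagnosis),
                                  default=0)
            if not per_ind_max <= self.n_unique_dx_genes <= self.n_dx_diagnoses:
                raise ValueError(
                    "n_unique_dx_genes must lie between the largest "
                    "per-individual diagnosis count and the total number of "
                    "definitive/probable diagnoses"
                )

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_definitive": self.n_definitive,
            "n_probable": self.n_probable,
            "n_provisional": self.n_provisional,
            "multi_diagnosis": [list(t) for t in self.multi_diagnosis],
            "seed": self.seed,
        }


# (acmg classes, inheritance, phase) templates per certainty bin; the
# biallelic variants exercise the AR compound-het rules.
_TEMPLATES = {
    "definitive": (
        (("P",), "AD", "n/a"),
        (("P", "P"), "AR", "in_trans"),
    ),
    "probable": (
        (("LP",), "AD", "n/a"),
        (("P", "VUS"), "AR", "in_trans"),
    ),
    "provisional": (
        (("VUS",), "AD", "n/a"),
        (("LP", "VUS"), "AR", "in_trans"),
    ),
}

_COLUMNS = ("individual_id", "gene", "acmg_class", "inheritance_mode",
            "phase", "phenotype_suggestive")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Variant-finding table whose default-rules classification reproduces
    the requested bin composition exactly.

    Individuals are ``BG1..BGn``; the first ``n_definitive`` receive a
    definitive diagnosis, the next ``n_probable`` a probable one, the next
    ``n_provisional`` a provisional one.  Roughly 40% of diagnoses are
    autosomal-recessive compound heterozygotes, the rest monoallelic.
    Undiagnosed individuals may carry non-qualifying findings (a VUS without
    a suggestive phenotype, or a likely-benign variant).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pool = list(TOF_TRAINING_GENES) + list(_EXTRA_POOL)
    extras = dict(spec.multi_diagnosis)

    # diagnostic (definitive/probable) genes cycle through a shuffled pool of
    # exactly n_unique_dx_genes symbols so the unique-gene count is exact
    n_unique = spec.n_unique_dx_genes or min(spec.n_dx_diagnoses, len(pool))
    dx_pool = [pool[i] for i in rng.permutation(len(pool))[:n_unique]]
    dx_slot = 0

    bins = (["definitive"] * spec.n_definitive
            + ["probable"] * spec.n_probable
            + ["provisional"] * spec.n_provisional)
    rows: list[tuple] = []

    def add_diagnosis(ind_id: str, gene: str, bin_label: str) -> None:
        templates = _TEMPLATES[bin_label]
        classes, mode, phase = templates[int(rng.random() < 0.4)]
        for c in classes:
            rows.append((ind_id, gene, c, mode, phase, True))

    for i in range(spec.n_individuals):
        ind_id = f"BG{i + 1}"
        if i < len(bins):
            n_dx_here = 1 + extras.get(i, 0)
            if bins[i] == "provisional":
                genes = list(rng.choice(pool, size=n_dx_here, replace=False))
            else:
                genes = []
                for _ in range(n_dx_here):
                    genes.append(dx_pool[dx_slot % n_unique])
                    dx_slot += 1
            for g in genes:
                add_diagnosis(ind_id, str(g), bins[i])
        else:
            u = rng.random()
            if u < 0.5:
                g = str(rng.choice(pool))
                rows.append((ind_id, g, "VUS", "AD", "n/a", False))
            elif u < 0.7:
                g = str(rng.choice(pool))
                rows.append((ind_id, g, "LB", "AD", "n/a", True))

    return pd.DataFrame(rows, columns=_COLUMNS)


def write_cohort(cohort: pd.DataFrame, path, spec: CohortSpec | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, sep="\t", index=False)
    if spec is not None:
        path.with_suffix(".manifest.json").write_text(
            json.dumps({"cohort_spec": spec.to_dict()}, indent=2) + "\n"
        )


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
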