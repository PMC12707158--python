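"""Phenotype-specific rank-annotation scoring with leave-one-out validation.

Every gene in a genome is scored against a training set of established
disease genes, separately within each genome-scale knowledge source, and the
per-source results are combined into a single *rank annotation score* on a
0–100% percentile scale (genome-wide median 50% by construction).

The scoring chain is:

1. :func:`score_source` — within one source, z-score each feature across the
   genome, form the centroid of the (standardized) training-gene vectors and
   take the cosine similarity of every gene to that centroid.
2. :func:`percentile_ranks` — convert raw similarities to midrank
   percentiles in [0, 100].
3. :func:`omnibus_scores` — average per-source percentiles gene-wise and
   re-percentile, yielding the omnibus score.
4. :func:`loocv_roc` — leave-one-out cross-validation: each training gene is
   removed from the centroid, re-scored, and its recovered percentile
   recorded; an ROC-style curve (genome fraction called positive vs fraction
   of held-out training genes recovered) and its area above the diagonal
   summarize discrimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

Curve = list[tuple[float, float]]


@dataclass
class FeatureSource:
    """One knowledge source: a gene × feature annotation matrix.

    Parameters
    ----------
    name : str
        Source label (e.g. an expression atlas or ontology).
    genes : list of str
        Gene symbols, one per matrix row; no duplicates.
    matrix : ndarray of shape (n_genes, n_features)
        Quantitative annotations; at least 2 features.
    """

    name: str
    genes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"source {self.name!r}: matrix must be 2-D")
        if len(self.genes) != self.matrix.shape[0]:
            raise ValueError(
                f"source {self.name!r}: {len(self.genes)} genes but "
                f"{self.matrix.shape[0]} matrix rows"
            )
        if self.matrix.shape[1] < 2:
            raise ValueError(f"source {self.name!r}: need at least 2 features")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise ValueError(f"source {self.name!r}: duplicate gene symbol {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def standardized(self) -> np.ndarray:
        """Per-feature z-scores; zero-variance features are dropped with a warning."""
        mu = self.matrix.mean(axis=0)
        sd = self.matrix.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "source %r: dropping %d zero-variance feature(s)",
                self.name, int((~keep).sum()),
            )
            if not keep.any():
                raise ValueError(f"source {self.name!r}: all features have zero variance")
        return (self.matrix[:, keep] - mu[keep]) / sd[keep]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{j + 1:03d}" for j in range(self.matrix.shape[1])]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "gene", self.genes)
        return df

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "FeatureSource":
        genes = df.iloc[:, 0].astype(str).tolist()
        return cls(name=name, genes=genes, matrix=df.iloc[:, 1:].to_numpy(float))


@dataclass(frozen=True)
class TrainingSet:
    """A phenotype-specific set of established disease genes."""

    phenotype_label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError("training set is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RankAnnotation:
    """Genome-wide 0–100% rank annotation scores plus per-source percentiles."""

    scores: dict[str, float]
    per_source_scores: dict[tuple[str, str], float]
    training_set: TrainingSet

    def to_frame(self) -> pd.DataFrame:
        sources = sorted({s for s, _ in self.per_source_scores})
        rows = []
        for g in self.scores:
            row = {"gene": g, "omnibus_score": self.scores[g]}
            for s in sources:
                row[s] = self.per_source_scores[(s, g)]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RocResult:
    """Leave-one-out ROC-style validation of a rank annotation."""

    per_source_curves: dict[str, Curve]
    omnibus_curve: Curve
    auc_above_diagonal: float
    loo_percentiles: dict[str, float]
    per_source_auc: dict[str, float] = field(default_factory=dict)


def _check_training(source: FeatureSource, training: TrainingSet) -> None:
    missing = sorted(training.genes - set(source.genes))
    if missing:
        raise ValueError(
            f"training gene(s) absent from source {source.name!r}: "
            + ", ".join(missing)
        )


def score_source(
    source: FeatureSource,
    training: TrainingSet,
    exclude: str | None = None,
) -> dict[str, float]:
    """Cosine similarity of every gene to the standardized training centroid.

    ``exclude`` removes one training gene from the centroid (used by LOOCV);
    the gene itself is still scored.
    """
    _check_training(source, training)
    if exclude is not None and exclude not in training.genes:
        raise ValueError(f"exclude gene {exclude!r} not in training set")
    train = training.genes - ({exclude} if exclude else set())
    if not train:
        raise ValueError("training set is empty after exclusion")

    Z = source.standardized()
    idx = {g: i for i, g in enumerate(source.genes)}
    centroid = Z[[idx[g] for g in sorted(train)]].mean(axis=0)
    raw = _cosine_to_centroid(Z, centroid)
    return dict(zip(source.genes, raw))


def _cosine_to_centroid(Z: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    cnorm = float(np.linalg.norm(centroid))
    norms = np.linalg.norm(Z, axis=1)
    denom = norms * cnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (Z @ centroid) / denom
    return np.where(denom > 0, raw, 0.0)


def percentile_ranks(raw: Mapping[str, float]) -> dict[str, float]:
    """Midrank percentiles in [0, 100]; ties share a value, median 50.

    ``score(g) = 100 * (rank_avg(g) - 0.5) / N`` where ``rank_avg`` is the
    average (midrank) rank of the raw value.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 genes to percentile-rank")
    genes = list(raw)
    values = np.array([raw[g] for g in genes], dtype=float)
    pct = 100.0 * (rankdata(values, method="average") - 0.5) / len(values)
    return dict(zip(genes, pct))


def _common_universe(sources: Sequence[FeatureSource]) -> list[str]:
    universe = set(sources[0].genes)
    for s in sources[1:]:
        if set(s.genes) != universe:
            diff = sorted(universe ^ set(s.genes))
            raise ValueError(
                f"gene universes differ between {sources[0].name!r} and "
                f"{s.name!r}; symmetric difference: " + ", ".join(diff)
            )
    return list(sources[0].genes)


def omnibus_scores(
    sources: Sequence[FeatureSource],
    training: TrainingSet,
) -> RankAnnotation:
    """Combine per-source percentiles into omnibus 0–100% scores.

    Per-source raw similarities are percentile-ranked, averaged gene-wise
    across sources, and re-percentiled so the genome median returns to 50%.
    """
    if not sources:
        raise ValueError("need at least one source")
    genes = _common_universe(sources)

    per_source: dict[tuple[str, str], float] = {}
    mean_pct = np.zeros(len(genes))
    for src in sources:
        pct = percentile_ranks(score_source(src, training))
        for g in src.genes:
            per_source[(src.name, g)] = pct[g]
        mean_pct += np.array([pct[g] for g in genes])
    mean_pct /= len(sources)

    final = percentile_ranks(dict(zip(genes, mean_pct)))
    scores = {g: final[g] for g in genes}
    return RankAnnotation(scores=scores, per_source_scores=per_source,
                          training_set=training)


def _roc_curve(
    all_scores: np.ndarray,
    positive_scores: np.ndarray,
    thresholds: np.ndarray,
) -> Curve:
    """Sweep thresholds high→low: x = fraction of the genome at or above the
    threshold, y = fraction of held-out training genes at or above it."""
    n, t = len(all_scores), len(positive_scores)
    curve: Curve = [(0.0, 0.0)]
    for thr in thresholds:
        x = float(np.count_nonzero(all_scores >= thr)) / n
        y = float(np.count_nonzero(positive_scores >= thr)) / t
        curve.append((x, y))
    return curve


def _trapezoid_auc(curve: Curve) -> float:
    xs = np.array([p[0] for p in curve])
    ys = np.array([p[1] for p in curve])
    return float(np.trapezoid(ys, xs))


def loocv_roc(
    sources: Sequence[FeatureSource],
    training: TrainingSet,
) -> RocResult:
    """Leave-one-out cross-validation with ROC-style curves.

    For each training gene the centroid is re-fit without it and the gene's
    recovered omnibus percentile recorded.  The omnibus curve ranks the whole
    genome on one list in which each training gene carries its leave-one-out
    percentile (all other genes their full-fit percentile); the area under
    that curve minus 0.5 (chance) is ``auc_above_diagonal``.
    """
    if len(training) < 3:
        raise ValueError("leave-one-out validation needs at least 3 training genes")
    genes = _common_universe(sources)
    n = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    held_out = sorted(training.genes)

    # Precompute per-source standardized matrices and training-row sums so each
    # exclusion is a rank-one update of the centroid.
    Zs, sums = [], []
    for src in sources:
        _check_training(src, training)
        Z = src.standardized()
        if src.genes != genes:
            src_idx = {g: i for i, g in enumerate(src.genes)}
            Z = Z[[src_idx[g] for g in genes]]
        Zs.append(Z)
        sums.append(Z[[gi[g] for g in held_out]].sum(axis=0))

    full = omnibus_scores(sources, training)
    full_pct_per_source = {
        s.name: np.array([full.per_source_scores[(s.name, g)] for g in genes])
        for s in sources
    }

    loo_pct: dict[str, float] = {}
    loo_pct_per_source: dict[str, dict[str, float]] = {s.name: {} for s in sources}
    t_count = len(held_out)
    for t in held_out:
        mean_pct = np.zeros(n)
        for src, Z, S in zip(sources, Zs, sums):
            centroid = (S - Z[gi[t]]) / (t_count - 1)
            raw = _cosine_to_centroid(Z, centroid)
            pct = 100.0 * (rankdata(raw, method="average") - 0.5) / n
            loo_pct_per_source[src.name][t] = float(pct[gi[t]])
            mean_pct += pct
        mean_pct /= len(sources)
        omni = 100.0 * (rankdata(mean_pct, method="average") - 0.5) / n
        loo_pct[t] = float(omni[gi[t]])

    train_mask = np.array([g in training.genes for g in genes])

    def build(scores_full: np.ndarray, loo: Mapping[str, float]) -> tuple[Curve, float]:
        combined = scores_full.copy()
        for t, v in loo.items():
            combined[gi[t]] = v
        pos = np.array([loo[t] for t in held_out])
        thresholds = np.unique(np.concatenate([pos, [0.0, 100.0]]))[::-1]
        curve = _roc_curve(combined, pos, thresholds)
        return curve, _trapezoid_auc(curve) - 0.5

    omni_full = np.array([full.scores[g] for g in genes])
    omnibus_curve, auc = build(omni_full, loo_pct)

    per_source_curves: dict[str, Curve] = {}
    per_source_auc: dict[str, float] = {}
    for src in sources:
        curve, a = build(full_pct_per_source[src.name], loo_pct_per_source[src.name])
        per_source_curves[src.name] = curve
        per_source_auc[src.name] = a

    return RocResult(
        per_source_curves=per_source_curves,
        omnibus_curve=omnibus_curve,
        auc_above_diagonal=auc,
        loo_percentiles=loo_pct,
        per_source_auc=per_source_auc,
    )
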