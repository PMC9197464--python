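"""Evaluation of rankings and community partitions against synthetic truth.

A ranking is scored for its ability to recover the *non-seed* genes of the
planted disease modules. The evaluation universe is every gene of the truth
except the seed CAGs (seeds are the method's input, not its discoveries):
positives are the remaining disease-module genes, negatives all other genes.
Genes absent from the ranking — those whose communities were filtered out —
are placed tied below every ranked gene, so exclusion counts as a (correct or
incorrect) negative call rather than being ignored.

AUROC is computed by the Wilcoxon/Mann-Whitney rank-sum identity with
half-credit for ties, which equals the fraction of (positive, negative) pairs
ordered correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .exceptions import InputError
from .ranking import GeneRanking
from .synthdata import SyntheticTruth


@dataclass
class EvaluationReport:
    auroc: float
    precision_at_10: float
    precision_at_50: float
    median_rank_disease: float
    median_rank_background: float
    rank_sum_statistic: float
    n_positives: int
    n_negatives: int
    n_ranked: int

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "precision_at_10": self.precision_at_10,
            "precision_at_50": self.precision_at_50,
            "median_rank_disease": self.median_rank_disease,
            "median_rank_background": self.median_rank_background,
            "rank_sum_statistic": self.rank_sum_statistic,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
            "n_ranked": self.n_ranked,
        }


def auroc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the rank-sum identity; ties get half credit.

    ``scores``: higher means ranked better; ``labels``: 1 positive, 0 negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # ascending, average ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_ranking(ranking: GeneRanking, truth: SyntheticTruth
                     ) -> EvaluationReport:
    """Score a gene ranking against the planted disease modules."""
    if truth.seed_cags is None:
        raise InputError("truth carries no seed CAG set")
    seeds = truth.seed_cags.symbols
    universe = [g for g in truth.genes if g not in seeds]
    if not universe:
        raise InputError("empty evaluation universe")
    disease = truth.disease_genes()
    labels = np.array([g in disease for g in universe])
    if not labels.any():
        raise InputError("no positive genes remain after excluding seed CAGs")
    if labels.all():
        raise InputError("no negative genes in the evaluation universe")

    rank_by_gene = {e.gene: e.rank for e in ranking.entries}
    n_ranked = len(ranking)
    # score: ranked genes by decreasing rank, unranked tied below everything
    scores = np.array([
        -rank_by_gene.get(g, n_ranked + 1) for g in universe
    ], dtype=float)

    auroc = auroc_from_scores(scores, labels)

    # positions in the combined ordering (1 = best), ties averaged
    positions = rankdata(-scores)
    median_disease = float(np.median(positions[labels]))
    median_background = float(np.median(positions[~labels]))
    rank_sum = float(positions[labels].sum())

    ranked_universe = [e.gene for e in ranking.entries if e.gene not in seeds]

    def precision_at(k: int) -> float:
        top = ranked_universe[:k]
        if not top:
            return 0.0
        return sum(g in disease for g in top) / float(k)

    return EvaluationReport(
        auroc=auroc,
        precision_at_10=precision_at(10),
        precision_at_50=precision_at(50),
        median_rank_disease=median_disease,
        median_rank_background=median_background,
        rank_sum_statistic=rank_sum,
        n_positives=int(labels.sum()),
        n_negatives=int((~labels).sum()),
        n_ranked=n_ranked,
    )


def community_recovery_ari(assignment: dict[str, int],
                           truth: SyntheticTruth) -> float:
    """Adjusted Rand index between detected communities and planted blocks.

    Only genes present in the assignment are compared (genes dropped as
    isolated or unexpressed carry no community label).
    """
    genes = [g for g in truth.genes if g in assignment]
    if not genes:
        raise InputError("no overlap between assignment and truth genes")
    planted = [truth.block_labels[g] for g in genes]
    found = [assignment[g] for g in genes]
    return float(adjusted_rand_score(planted, found))
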