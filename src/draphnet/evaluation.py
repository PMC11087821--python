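"""Validation machinery: similarity premises, drug-held-out CV, ROC/AUC.

Three kinds of checks support the modeling premise and measure the fitted
model:

* **pairwise similarity** — do drugs with more correlated endpoint
  profiles share more phenotype associations (Jaccard of their binary
  rows), and do phenotypes with more correlated gene scores share more
  drugs? Association is summarized by a rank correlation across pairs, a
  least-squares fit accounting for the number of shared endpoints, and a
  permutation p-value from shuffling the pairing between the two sources;
* **drug-held-out cross-validation** — drugs are partitioned into folds,
  the model fitted on in-fold drugs and scored on held-out drugs, compared
  against a nearest-neighbor baseline by per-drug Jaccard distance (paired
  one-sided Wilcoxon signed-rank) and by pooled ROC/AUC;
* **group similarity** — rank-sum comparison of pairwise profile
  correlations between drug pairs that share an attribute (e.g. a target)
  and pairs that do not.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import InvalidInputError
from .matrices import AssociationMatrix, EndpointMatrix, GeneScoreMatrix
from .model import FittedModel, ModelConfig, decompose_gene_matrix, fit, predict
from .softimpute import drug_factors as _drug_factors, soft_impute

logger = logging.getLogger(__name__)


def jaccard(set_a: set, set_b: set) -> float:
    """Jaccard index |A n B| / |A u B|; NaN when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return float("nan")
    return len(set_a & set_b) / union


def jaccard_distance(set_a: set, set_b: set) -> float:
    return 1.0 - jaccard(set_a, set_b)


def _row_set(binary_row: np.ndarray) -> set[int]:
    return set(np.flatnonzero(binary_row).tolist())


@dataclass
class PairSimilarityRecord:
    id_a: str
    id_b: str
    jaccard: float
    profile_correlation: float
    n_shared_features: int


@dataclass
class SimilarityStats:
    """Association between profile correlation and Jaccard across pairs."""

    spearman_rho: float
    spearman_p: float
    ols_coef: float
    ols_p: float
    permutation_p: float
    n_pairs: int
    n_excluded: int = 0


def _association_stats(
    records: list[PairSimilarityRecord],
    n_perm: int,
    seed: int,
    n_excluded: int,
    with_shared_covariate: bool,
) -> SimilarityStats:
    jac = np.array([r.jaccard for r in records])
    cor = np.array([r.profile_correlation for r in records])
    shared = np.array([r.n_shared_features for r in records], dtype=float)
    ok = ~np.isnan(jac) & ~np.isnan(cor)
    jac, cor, shared = jac[ok], cor[ok], shared[ok]
    if jac.size < 3:
        raise InvalidInputError("need at least 3 valid pairs")
    rho, rho_p = stats.spearmanr(jac, cor)
    X = np.column_stack([cor, shared]) if with_shared_covariate else cor[:, None]
    ols = sm.OLS(jac, sm.add_constant(X)).fit()
    ols_coef, ols_p = float(ols.params[1]), float(ols.pvalues[1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_rho = stats.spearmanr(jac, rng.permutation(cor)).statistic
        if perm_rho >= rho:
            exceed += 1
    perm_p = (1.0 + exceed) / (n_perm + 1.0)
    return SimilarityStats(
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        ols_coef=ols_coef,
        ols_p=ols_p,
        permutation_p=perm_p,
        n_pairs=int(jac.size),
        n_excluded=n_excluded,
    )


def drug_pair_similarity(
    D: EndpointMatrix,
    Y: AssociationMatrix,
    min_shared_endpoints: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[PairSimilarityRecord], SimilarityStats]:
    """Per drug pair: Jaccard of association rows vs Spearman correlation of
    endpoint scores over mutually observed endpoints.

    Pairs with fewer than ``min_shared_endpoints`` mutually observed
    endpoints are excluded (count logged and reported).
    """
    if D.drug_ids != Y.drug_ids:
        raise InvalidInputError("D and Y must be aligned on drugs")
    records: list[PairSimilarityRecord] = []
    n_excluded = 0
    for i, j in combinations(range(len(D.drug_ids)), 2):
        both = D.mask[i] & D.mask[j]
        n_shared = int(both.sum())
        if n_shared < min_shared_endpoints:
            n_excluded += 1
            continue
        cor = stats.spearmanr(D.values[i, both], D.values[j, both]).statistic
        records.append(
            PairSimilarityRecord(
                id_a=D.drug_ids[i],
                id_b=D.drug_ids[j],
                jaccard=jaccard(_row_set(Y.values[i]), _row_set(Y.values[j])),
                profile_correlation=float(cor),
                n_shared_features=n_shared,
            )
        )
    if n_excluded:
        logger.info("excluded %d drug pairs with < %d shared endpoints",
                    n_excluded, min_shared_endpoints)
    stats_out = _association_stats(records, n_perm, seed, n_excluded, True)
    return records, stats_out


def phenotype_pair_similarity(
    G: GeneScoreMatrix,
    Y: AssociationMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[PairSimilarityRecord], SimilarityStats]:
    """Mirror of :func:`drug_pair_similarity` with phenotypes in the pair
    role: Jaccard of drug sets vs Spearman correlation of gene-score
    columns (complete, so no shared-feature filtering)."""
    if G.phenotype_ids != Y.phenotype_ids:
        raise InvalidInputError("G and Y must be aligned on phenotypes")
    records = []
    n_genes = G.shape[0]
    for i, j in combinations(range(len(G.phenotype_ids)), 2):
        cor = stats.spearmanr(G.values[:, i], G.values[:, j]).statistic
        records.append(
            PairSimilarityRecord(
                id_a=G.phenotype_ids[i],
                id_b=G.phenotype_ids[j],
                jaccard=jaccard(_row_set(Y.values[:, i]), _row_set(Y.values[:, j])),
                profile_correlation=float(cor),
                n_shared_features=n_genes,
            )
        )
    return records, _association_stats(records, n_perm, seed, 0, False)


def nearest_neighbor_baseline(
    drug_factors: np.ndarray,
    Y: AssociationMatrix,
    held_out_drug: int,
    in_fold: np.ndarray | None = None,
) -> set[int]:
    """Predict a held-out drug's associations as the profile of its nearest
    Euclidean neighbor in factor space among in-fold drugs; distance ties
    break toward the lower drug index (drug-id order)."""
    n = drug_factors.shape[0]
    if in_fold is None:
        in_fold = np.array([i for i in range(n) if i != held_out_drug])
    in_fold = np.asarray(in_fold)
    if in_fold.size == 0:
        raise InvalidInputError("need at least one in-fold drug")
    d = np.linalg.norm(
        drug_factors[in_fold] - drug_factors[held_out_drug], axis=1
    )
    neighbor = int(in_fold[int(np.argmin(d))])  # argmin is stable: first minimum
    return _row_set(Y.values[neighbor])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve points and AUC (Mann-Whitney normalization, ties count 1/2).

    Raises when only one class is present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        raise InvalidInputError("AUC undefined with a single label class")
    fpr, tpr, thresh = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return points, auc


@dataclass
class CvReport:
    """Drug-held-out cross-validation results."""

    per_drug: pd.DataFrame
    roc_points: pd.DataFrame
    auc: float
    ranksum_stat: float
    ranksum_p: float
    probabilities: np.ndarray
    n_folds: int

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "ranksum_stat": self.ranksum_stat,
            "ranksum_p": self.ranksum_p,
            "median_model_distance": float(
                self.per_drug["jaccard_distance_model"].median()
            ),
            "median_baseline_distance": float(
                self.per_drug["jaccard_distance_baseline"].median()
            ),
            "n_folds": self.n_folds,
            "n_drugs": int(len(self.per_drug)),
        }


def _fold_assignment(n_drugs: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n_drugs)
    folds = np.empty(n_drugs, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def cv_evaluate(
    D: EndpointMatrix,
    G: GeneScoreMatrix,
    Y: AssociationMatrix,
    config: ModelConfig,
    n_folds: int = 20,
    binarize_threshold: float = 0.5,
    seed: int = 0,
    *,
    si_lambda: float = 0.0,
    binarize: str = "threshold",
) -> CvReport:
    """Drug-held-out cross-validation against the nearest-neighbor baseline.

    Drug factors come from one soft-impute fit of the full ``D`` (the
    molecular input is unsupervised; only association rows are held out).
    Predictions are binarized at ``binarize_threshold`` (or, with
    ``binarize='topk'``, by taking the same number of phenotypes as the
    nearest neighbor's profile) for the per-drug Jaccard comparison; the
    paired one-sided Wilcoxon signed-rank tests whether model distances are
    lower than baseline distances. ROC/AUC pools all (drug, phenotype)
    pairs using predicted probabilities as scores.
    """
    n_drugs, n_phenos = Y.shape
    if n_folds > n_drugs:
        raise InvalidInputError("more folds than drugs")
    dec = soft_impute(D, rank=min(config.r_D, min(D.shape)), lam=si_lambda)
    DF = _drug_factors(dec)
    if DF.shape[1] < config.r_D:
        config = ModelConfig(
            r_D=DF.shape[1], r_P=config.r_P, l1_strength=config.l1_strength,
            cv_fold_count=config.cv_fold_count, intercept=config.intercept,
            seed=config.seed, max_iter=config.max_iter, tol=config.tol,
        )
    gd = decompose_gene_matrix(G, config.r_P)

    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n_drugs, n_folds, rng)
    # a fold whose training labels are degenerate is re-drawn once
    for attempt in range(2):
        ok = all(
            Y.values[folds != f].min() != Y.values[folds != f].max()
            for f in range(n_folds)
        )
        if ok:
            break
        if attempt == 1:
            raise InvalidInputError("degenerate training labels after fold re-draw")
        folds = _fold_assignment(n_drugs, n_folds, rng)

    probs = np.empty((n_drugs, n_phenos))
    rows = []
    for f in range(n_folds):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        model = fit(DF, gd, Y, config, drug_subset=train_idx)
        probs[test_idx] = predict(model, DF[test_idx, : config.r_D])
        for i in test_idx:
            true_set = _row_set(Y.values[i])
            baseline_set = nearest_neighbor_baseline(
                DF[:, : config.r_D], Y, int(i), in_fold=train_idx
            )
            if binarize == "topk":
                k = len(baseline_set)
                pred_set = set(np.argsort(-probs[i], kind="stable")[:k].tolist())
            else:
                pred_set = _row_set(probs[i] > binarize_threshold)
            rows.append(
                {
                    "drug_id": Y.drug_ids[i],
                    "fold": f,
                    "n_true": len(true_set),
                    "jaccard_distance_model": jaccard_distance(pred_set, true_set),
                    "jaccard_distance_baseline": jaccard_distance(
                        baseline_set, true_set
                    ),
                }
            )
    per_drug = pd.DataFrame(rows)
    valid = per_drug.dropna(
        subset=["jaccard_distance_model", "jaccard_distance_baseline"]
    )
    diffs = (
        valid["jaccard_distance_model"] - valid["jaccard_distance_baseline"]
    ).to_numpy()
    if np.allclose(diffs, 0):
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(diffs, alternative="less")
        stat, p = float(res.statistic), float(res.pvalue)
    roc_points, auc = roc_auc(probs.ravel(), Y.values.ravel())
    return CvReport(
        per_drug=per_drug,
        roc_points=roc_points,
        auc=auc,
        ranksum_stat=stat,
        ranksum_p=p,
        probabilities=probs,
        n_folds=n_folds,
    )


def similarity_by_group(
    vectors: np.ndarray, share_attribute: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Rank-sum comparison of pairwise Spearman correlations between pairs
    that share an attribute and pairs that do not.

    ``share_attribute`` is a symmetric boolean matrix over items (diagonal
    ignored). Returns (statistic, two-sided p, shared correlations,
    unshared correlations).
    """
    vectors = np.asarray(vectors, dtype=float)
    share = np.asarray(share_attribute, dtype=bool)
    n = vectors.shape[0]
    if share.shape != (n, n):
        raise InvalidInputError("share_attribute must be items x items")
    shared, unshared = [], []
    for i, j in combinations(range(n), 2):
        cor = stats.spearmanr(vectors[i], vectors[j]).statistic
        (shared if share[i, j] else unshared).append(cor)
    if not shared or not unshared:
        raise InvalidInputError("both groups must be non-empty")
    res = stats.mannwhitneyu(shared, unshared, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), np.asarray(shared), np.asarray(unshared)
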