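"""Projections of drugs onto phenome and disease-genome space, with
permutation-based significance.

From a fitted bilinear model, each drug's compressed effect over the
phenotype factors is the **phenome effect matrix** ``U_D S_D W_DP``. Using
the orthonormality of the gene-side singular vectors, that effect is mapped
back onto individual genes as the **disease genome matrix**

    (U_D S_D W_DP) S_P^{-1} U_P^t

giving each drug a score over every disease-associated gene. Because the
truncation discards phenotype-factor directions, this is the minimum-norm
gene-space preimage of the phenome effect.

Significance of each drug-gene connection is assessed against a permutation
null: the association labels ``Y`` are shuffled (the molecular inputs stay
fixed), the model is refitted, and the drug-gene score recomputed. The
two-sided empirical p-value counts null scores at least as extreme in
absolute value, with an add-one correction; per-drug adjustment uses the
Benjamini-Yekutieli step-up, which is valid under arbitrary dependence of
the gene-wise tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InvalidInputError
from .matrices import AssociationMatrix
from .model import FittedModel, ModelConfig, fit
from .softimpute import Decomposition


@dataclass
class PhenomeEffectMatrix:
    """Drugs x r_P compressed phenome-effect coordinates."""

    values: np.ndarray
    drug_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.drug_ids) != self.values.shape[0]:
            raise InvalidInputError("drug_ids must match row count")


@dataclass
class DiseaseGenomeResult:
    """Drug x gene effect scores with permutation p-values and BY q-values."""

    scores: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    n_perm: int
    drug_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not (self.scores.shape == self.pvalues.shape == self.qvalues.shape):
            raise InvalidInputError("score/p/q shapes must match")
        lo = 1.0 / (self.n_perm + 1)
        if (self.pvalues < lo - 1e-12).any() or (self.pvalues > 1 + 1e-12).any():
            raise InvalidInputError("p-values outside [1/(n_perm+1), 1]")
        if (self.qvalues + 1e-12 < self.pvalues).any():
            raise InvalidInputError("q-values must dominate p-values")


PermutationMode = Literal["entries", "rows", "within_columns"]


@dataclass
class NullEnsemble:
    """Per-permutation drug x gene score matrices under shuffled labels.

    ``scores`` stacks the retained permutations (n_valid x drugs x genes);
    permutations whose refit failed are dropped and counted in
    ``n_failed``. Every permutation reuses the identical molecular inputs.
    """

    scores: np.ndarray
    n_perm: int
    seed: int
    mode: PermutationMode = "entries"
    n_failed: int = 0

    @property
    def n_valid(self) -> int:
        return self.scores.shape[0]


def phenome_effect(model: FittedModel) -> PhenomeEffectMatrix:
    """Compressed per-drug phenome effect ``U_D S_D W_DP``."""
    return PhenomeEffectMatrix(
        values=model.drug_factors @ model.W_DP, drug_ids=list(model.drug_ids)
    )


def disease_genome(model: FittedModel) -> np.ndarray:
    """Per-drug gene-space effect ``(U_D S_D W_DP) S_P^{-1} U_P^t``."""
    gd = model.gene_decomp
    if (gd.S <= 0).any():
        raise InvalidInputError("gene decomposition has a non-positive singular value")
    pe = model.drug_factors @ model.W_DP
    return (pe / gd.S) @ gd.U.T


def drug_disease_score(drug_gene_row: np.ndarray, gene_pheno_column: np.ndarray) -> float:
    """Dot product of a drug's gene-effect vector with a phenotype's
    gene-score vector: the model's drug-disease effect estimate."""
    a = np.asarray(drug_gene_row, dtype=float).ravel()
    b = np.asarray(gene_pheno_column, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidInputError("vector lengths must match")
    return float(a @ b)


def permute_labels(
    Y: np.ndarray, rng: np.random.Generator, mode: PermutationMode = "entries"
) -> np.ndarray:
    """Shuffle a binary label matrix. ``entries`` permutes the flattened
    matrix globally (preserving the total count of ones); ``rows`` permutes
    whole drug rows; ``within_columns`` shuffles independently inside each
    phenotype column."""
    if mode == "entries":
        flat = rng.permutation(Y.ravel())
        return flat.reshape(Y.shape)
    if mode == "rows":
        return Y[rng.permutation(Y.shape[0])]
    if mode == "within_columns":
        out = Y.copy()
        for j in range(Y.shape[1]):
            out[:, j] = rng.permutation(Y[:, j])
        return out
    raise InvalidInputError(f"unknown permutation mode {mode!r}")


def null_ensemble(
    D_factors: np.ndarray,
    gene_decomp: Decomposition,
    Y: AssociationMatrix,
    config: ModelConfig,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    mode: PermutationMode = "entries",
) -> NullEnsemble:
    """Refit the model on ``n_perm`` label shuffles and project each refit
    to gene space. Deterministic under ``seed``; permutation ``k`` uses the
    substream ``(seed, k)`` so the index range can be split across workers.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    mats = []
    n_failed = 0
    for k in range(n_perm):
        rng = np.random.default_rng([seed, k])
        Y_perm = AssociationMatrix(
            values=permute_labels(Y.values, rng, mode),
            drug_ids=list(Y.drug_ids),
            phenotype_ids=list(Y.phenotype_ids),
            polarity=Y.polarity,
        )
        try:
            m = fit(D_factors, gene_decomp, Y_perm, config)
        except InvalidInputError:
            n_failed += 1
            continue
        mats.append(disease_genome(m))
    if n_failed > 0.01 * n_perm:
        warnings.warn(
            f"{n_failed}/{n_perm} permutations failed to fit and were excluded"
        )
    if not mats:
        raise InvalidInputError("every permutation failed to fit")
    return NullEnsemble(
        scores=np.stack(mats), n_perm=n_perm, seed=seed, mode=mode, n_failed=n_failed
    )


def empirical_pvalues(true_scores: np.ndarray, null: NullEnsemble) -> np.ndarray:
    """Two-sided add-one empirical p-values:
    ``p = (1 + #{perm: |null| >= |true|}) / (n_valid + 1)``."""
    true_scores = np.asarray(true_scores, dtype=float)
    if true_scores.shape != null.scores.shape[1:]:
        raise InvalidInputError("true score shape must match null ensemble")
    exceed = (np.abs(null.scores) >= np.abs(true_scores)[None]).sum(axis=0)
    return (1.0 + exceed) / (null.n_valid + 1.0)


def by_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment of a p-value vector.

    ``q(k) = min_{j>=k} p(j) * m * c(m) / j`` on the ascending sort, with
    ``c(m)`` the m-th harmonic number, capped at 1, returned in the input
    order.
    """
    p = np.asarray(p, dtype=float).ravel()
    if ((p < 0) | (p > 1)).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def disease_genome_result(
    model: FittedModel, null: NullEnsemble
) -> DiseaseGenomeResult:
    """Assemble scores, empirical p-values, and per-drug BY q-values."""
    scores = disease_genome(model)
    pvals = empirical_pvalues(scores, null)
    qvals = np.vstack([by_adjust(row) for row in pvals])
    return DiseaseGenomeResult(
        scores=scores,
        pvalues=pvals,
        qvalues=qvals,
        n_perm=null.n_valid,
        drug_ids=list(model.drug_ids),
        gene_ids=list(model.gene_ids),
    )


def significant_genes(
    result: DiseaseGenomeResult, alpha: float = 0.05
) -> dict[str, set[str]]:
    """Per-drug sets of genes with BY q-value below ``alpha``."""
    if not (0 <= alpha < 1):
        raise InvalidInputError("alpha must lie in [0, 1)")
    gene_arr = np.array(result.gene_ids, dtype=object)
    return {
        drug: set(gene_arr[result.qvalues[i] < alpha])
        for i, drug in enumerate(result.drug_ids)
    }
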