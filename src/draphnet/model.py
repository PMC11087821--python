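"""Bilinear logistic ("affinity regression") model of drug-phenotype association.

The model explains the binary association matrix ``Y`` (drugs x phenotypes)
by an interaction between two molecular feature spaces:

    logit p(Y) = D W G^t

with ``D`` the drug endpoint matrix and ``G`` the gene-major gene-score
matrix (genes x phenotypes; ``G^t`` maps phenotype to gene space). The
full interaction matrix ``W`` (endpoints x genes) is never formed; both
sides are reduced. With ``D ~ U_D S_D V_D^t`` (soft-impute) and
``G = U_P S_P V_P^t`` (SVD), the model becomes

    logit p(Y) = (U_D S_D) W_DP V_P^t,     W_DP = V_D^t W U_P S_P,

so only the small ``r_D x r_P`` matrix ``W_DP`` is learned. Vectorizing
column-major turns this into an ordinary sparse (L1) logistic regression
through the identity ``vec(A X B^t) = (B kron A) vec(X)``: each
(drug i, phenotype j) pair contributes one design row
``V_P[j, :] kron drug_factors[i, :]``.

Hyperparameters (the two truncation ranks and the lasso strength) are tuned
by cross-validation that holds out whole drugs, scoring predicted
probabilities for the held-out drugs' association rows by AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .errors import ConvergenceWarning, InvalidInputError
from .matrices import AssociationMatrix, EndpointMatrix, GeneScoreMatrix
from .softimpute import Decomposition, drug_factors as _drug_factors, soft_impute


@dataclass
class ModelConfig:
    """Hyperparameters of the bilinear logistic model.

    ``l1_strength`` multiplies the L1 penalty in the per-sample objective
    ``mean(logloss) + l1_strength * ||vec(W_DP)||_1``, so the fit is
    invariant to duplicating training pairs.
    """

    r_D: int
    r_P: int
    l1_strength: float
    cv_fold_count: int = 10
    intercept: bool = True
    seed: int = 0
    max_iter: int = 5000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.r_D < 1 or self.r_P < 1:
            raise InvalidInputError("ranks must be >= 1")
        if self.l1_strength <= 0:
            raise InvalidInputError("l1_strength must be > 0")


#: Operating points used for the full-scale public data in the original
#: analysis, kept as documented defaults for that data size.
FULL_SCALE_CONFIGS = {
    "indications": ModelConfig(r_D=95, r_P=131, l1_strength=1.0),
    "side_effects": ModelConfig(r_D=246, r_P=197, l1_strength=0.1),
}


@dataclass
class PairDesign:
    """Expanded design over (drug, phenotype) pairs.

    Rows follow column-major order over ``Y`` (drug index varies fastest)
    restricted to ``pairs``; columns are the ``r_D * r_P`` interaction
    features ordered as column-major ``vec(W_DP)``.
    """

    X: np.ndarray
    pairs: list[tuple[int, int]]
    labels: np.ndarray | None = None


@dataclass
class FittedModel:
    """A trained bilinear model and the factorizations defining it."""

    W_DP: np.ndarray
    intercept: float
    drug_factors: np.ndarray
    gene_decomp: Decomposition
    drug_ids: list[str]
    phenotype_ids: list[str]
    gene_ids: list[str]
    polarity: str = "side_effects"
    config: ModelConfig | None = None

    def __post_init__(self) -> None:
        r_D, r_P = self.W_DP.shape
        if self.drug_factors.shape[1] != r_D:
            raise InvalidInputError("drug_factors width must equal r_D")
        if self.gene_decomp.rank != r_P:
            raise InvalidInputError("gene decomposition rank must equal r_P")


def truncate_decomposition(dec: Decomposition, r: int) -> Decomposition:
    """Keep the top ``r`` components of a decomposition."""
    if r > dec.rank:
        warnings.warn(
            f"requested rank {r} exceeds available rank {dec.rank}; truncating",
            ConvergenceWarning,
        )
        r = dec.rank
    return Decomposition(
        U=dec.U[:, :r], S=dec.S[:r], V=dec.V[:, :r], rank=r, lam=dec.lam
    )


def decompose_gene_matrix(G: GeneScoreMatrix, r_P: int) -> Decomposition:
    """Truncated SVD ``G = U_P S_P V_P^t`` of the gene-major score matrix.

    ``U_P`` is gene-side (genes x r_P), ``V_P`` phenotype-side. If ``r_P``
    exceeds the numerical rank the result is truncated with a warning.
    """
    n_genes, n_phenos = G.shape
    if r_P < 1 or r_P > min(n_genes, n_phenos):
        raise InvalidInputError(f"r_P must lie in [1, {min(n_genes, n_phenos)}]")
    U, s, Vt = np.linalg.svd(G.values, full_matrices=False)
    num_rank = int(np.count_nonzero(s > s[0] * max(n_genes, n_phenos) * np.finfo(float).eps))
    if r_P > num_rank:
        warnings.warn(
            f"r_P={r_P} exceeds numerical rank {num_rank}; truncating",
            ConvergenceWarning,
        )
        r_P = num_rank
    return Decomposition(U=U[:, :r_P], S=s[:r_P], V=Vt[:r_P].T, rank=r_P, lam=0.0)


def build_design(
    drug_factors: np.ndarray,
    V_P: np.ndarray,
    pair_subset: list[tuple[int, int]] | None = None,
    labels: np.ndarray | None = None,
) -> PairDesign:
    """Expanded Kronecker design for (drug, phenotype) pairs.

    Satisfies ``design.X @ W_DP.ravel(order='F') ==
    (drug_factors @ W_DP @ V_P.T)[pairs]`` exactly.
    """
    n_drugs, r_D = drug_factors.shape
    n_phenos, r_P = V_P.shape
    if pair_subset is None:
        pairs = [(i, j) for j in range(n_phenos) for i in range(n_drugs)]
        X = np.kron(V_P, drug_factors)
    else:
        pairs = list(pair_subset)
        for i, j in pairs:
            if not (0 <= i < n_drugs and 0 <= j < n_phenos):
                raise InvalidInputError(f"pair ({i}, {j}) out of range")
        di = np.array([p[0] for p in pairs])
        pj = np.array([p[1] for p in pairs])
        # row = V_P[j, :] kron drug_factors[i, :], column-major over W_DP
        X = (V_P[pj][:, :, None] * drug_factors[di][:, None, :]).reshape(
            len(pairs), r_P * r_D
        )
    lab = None
    if labels is not None:
        lab = np.asarray(labels).ravel()
        if lab.shape[0] != X.shape[0]:
            raise InvalidInputError("labels length must match pair count")
    return PairDesign(X=X, pairs=pairs, labels=lab)


def _fit_logistic(
    X: np.ndarray, y: np.ndarray, config: ModelConfig
) -> tuple[np.ndarray, float]:
    if y.min() == y.max():
        raise InvalidInputError(
            "degenerate labels: all associations are identical"
        )
    # per-sample objective: C = 1 / (n * l1_strength)
    n = X.shape[0]
    C = 1.0 / (n * config.l1_strength)
    # liblinear penalizes the (scaled) intercept coefficient; scaling with
    # the penalty strength keeps that contribution negligible at any
    # l1_strength, so an extreme penalty still recovers the base rate
    scaling = 100.0 * max(1.0, n * config.l1_strength)
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        fit_intercept=config.intercept,
        intercept_scaling=scaling,
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    clf.fit(X, y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= config.max_iter:
        warnings.warn(
            f"lasso-logistic solver hit max_iter={config.max_iter}",
            ConvergenceWarning,
        )
    intercept = float(clf.intercept_[0]) if config.intercept else 0.0
    return clf.coef_.ravel(), intercept


def fit(
    D_factors: np.ndarray,
    gene_decomp: Decomposition,
    Y: AssociationMatrix,
    config: ModelConfig,
    *,
    drug_subset: np.ndarray | None = None,
    drug_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> FittedModel:
    """Fit ``W_DP`` by L1-penalized logistic regression on the pair design.

    ``D_factors`` (drugs x >= r_D) and ``gene_decomp`` are truncated to the
    configured ranks. ``drug_subset`` restricts the training pairs to those
    drug row indices (used for drug-held-out validation); the returned
    model still carries factor rows for all drugs so any drug can be scored.
    """
    if D_factors.shape[1] < config.r_D:
        raise InvalidInputError(
            f"drug factors provide {D_factors.shape[1]} dims < r_D={config.r_D}"
        )
    DF = np.asarray(D_factors, dtype=float)[:, : config.r_D]
    gd = truncate_decomposition(gene_decomp, config.r_P)
    r_P = gd.rank
    n_drugs, n_phenos = Y.shape
    if DF.shape[0] != n_drugs:
        raise InvalidInputError("drug factor rows must match Y rows")
    if gd.V.shape[0] != n_phenos:
        raise InvalidInputError("gene decomposition phenotype side must match Y columns")

    if drug_subset is None:
        pairs = None
        labels = Y.values.ravel(order="F").astype(float)
        design = build_design(DF, gd.V)
    else:
        rows = np.asarray(drug_subset)
        pairs = [(int(i), j) for j in range(n_phenos) for i in rows]
        labels = Y.values[rows].ravel(order="F").astype(float)
        design = build_design(DF, gd.V, pair_subset=pairs)

    coef, intercept = _fit_logistic(design.X, labels, config)
    W_DP = coef.reshape((config.r_D, r_P), order="F")
    return FittedModel(
        W_DP=W_DP,
        intercept=intercept,
        drug_factors=DF,
        gene_decomp=gd,
        drug_ids=drug_ids if drug_ids is not None else list(Y.drug_ids),
        phenotype_ids=list(Y.phenotype_ids),
        gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(gd.U.shape[0])],
        polarity=Y.polarity,
        config=config,
    )


def predict(model: FittedModel, drug_factor_rows: np.ndarray) -> np.ndarray:
    """Association probabilities ``sigmoid(b + F W_DP V_P^t)`` for the given
    drug factor rows (one row per drug, width r_D)."""
    F = np.atleast_2d(np.asarray(drug_factor_rows, dtype=float))
    if F.shape[1] != model.W_DP.shape[0]:
        raise InvalidInputError(
            f"factor rows have width {F.shape[1]}, expected {model.W_DP.shape[0]}"
        )
    logits = model.intercept + F @ model.W_DP @ model.gene_decomp.V.T
    return 1.0 / (1.0 + np.exp(-logits))


def predict_matrix(model: FittedModel) -> np.ndarray:
    """Probabilities for every (drug, phenotype) pair of the fitted model."""
    return predict(model, model.drug_factors)


@dataclass
class TuneResult:
    best: ModelConfig
    table: "object"  # pandas.DataFrame; avoided in the annotation to keep imports light


def tune(
    D: EndpointMatrix,
    G: GeneScoreMatrix,
    Y: AssociationMatrix,
    r_d_grid: list[int],
    r_p_grid: list[int],
    l1_grid: list[float],
    *,
    cv_fold_count: int = 10,
    seed: int = 0,
    si_lambda: float = 0.0,
    base_config: ModelConfig | None = None,
) -> TuneResult:
    """Drug-held-out CV over the (r_D, r_P, l1) grid, maximizing mean AUC.

    Folds partition drugs. The drug factor matrix comes from a single
    soft-impute fit of the full ``D`` at the largest requested rank; each
    candidate truncates it (nested SVD ranks truncate consistently). Folds
    whose held-out labels are single-class are skipped with a warning.
    """
    import pandas as pd

    if not r_d_grid or not r_p_grid or not l1_grid:
        raise InvalidInputError("grids must be non-empty")
    n_drugs = Y.shape[0]
    if cv_fold_count > n_drugs:
        raise InvalidInputError("more folds than drugs")
    dec_D = soft_impute(D, rank=max(r_d_grid), lam=si_lambda)
    DF_full = _drug_factors(dec_D)
    gd_full = decompose_gene_matrix(G, min(max(r_p_grid), min(G.shape)))

    kf = KFold(n_splits=cv_fold_count, shuffle=True, random_state=seed)
    rows = []
    for r_D, r_P, l1 in product(r_d_grid, r_p_grid, l1_grid):
        cfg = ModelConfig(
            r_D=min(r_D, DF_full.shape[1]),
            r_P=min(r_P, gd_full.rank),
            l1_strength=l1,
            cv_fold_count=cv_fold_count,
            seed=seed,
            **(
                {"intercept": base_config.intercept, "max_iter": base_config.max_iter,
                 "tol": base_config.tol}
                if base_config is not None
                else {}
            ),
        )
        aucs = []
        for fold, (train_idx, test_idx) in enumerate(kf.split(np.arange(n_drugs))):
            y_test = Y.values[test_idx].ravel(order="F")
            if y_test.min() == y_test.max():
                warnings.warn(
                    f"fold {fold}: held-out labels single-class; AUC skipped",
                    ConvergenceWarning,
                )
                continue
            model = fit(DF_full, gd_full, Y, cfg, drug_subset=train_idx)
            probs = predict(model, DF_full[test_idx, : cfg.r_D]).ravel(order="F")
            aucs.append(roc_auc_score(y_test, probs))
        rows.append(
            {
                "r_D": cfg.r_D,
                "r_P": cfg.r_P,
                "l1_strength": l1,
                "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                "n_folds_scored": len(aucs),
            }
        )
    table = pd.DataFrame(rows)
    best_row = table.loc[table["mean_auc"].idxmax()]
    best = ModelConfig(
        r_D=int(best_row["r_D"]),
        r_P=int(best_row["r_P"]),
        l1_strength=float(best_row["l1_strength"]),
        cv_fold_count=cv_fold_count,
        seed=seed,
    )
    return TuneResult(best=best, table=table)


# ---------------------------------------------------------------------------
# Serialization: a model is a directory of TSVs plus a JSON of scalars.
# ---------------------------------------------------------------------------


def save_model(model: FittedModel, outdir: str | Path) -> None:
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def _write(name: str, arr: np.ndarray, index, columns) -> None:
        import pandas as pd

        pd.DataFrame(arr, index=index, columns=columns).to_csv(
            out / name, sep="\t", index_label="id"
        )

    r_D, r_P = model.W_DP.shape
    d_cols = [f"d{k}" for k in range(r_D)]
    p_cols = [f"p{k}" for k in range(r_P)]
    _write("W_DP.tsv", model.W_DP, d_cols, p_cols)
    _write("drug_factors.tsv", model.drug_factors, model.drug_ids, d_cols)
    _write("U_P.tsv", model.gene_decomp.U, model.gene_ids, p_cols)
    _write("V_P.tsv", model.gene_decomp.V, model.phenotype_ids, p_cols)
    _write("S_P.tsv", model.gene_decomp.S[:, None], p_cols, ["s"])
    meta = {
        "intercept": model.intercept,
        "polarity": model.polarity,
        "r_D": r_D,
        "r_P": r_P,
        "gene_lam": model.gene_decomp.lam,
    }
    if model.config is not None:
        meta["config"] = {
            "r_D": model.config.r_D,
            "r_P": model.config.r_P,
            "l1_strength": model.config.l1_strength,
            "cv_fold_count": model.config.cv_fold_count,
            "intercept": model.config.intercept,
            "seed": model.config.seed,
            "max_iter": model.config.max_iter,
            "tol": model.config.tol,
        }
    (out / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_model(indir: str | Path) -> FittedModel:
    import json

    import pandas as pd

    src = Path(indir)
    meta = json.loads((src / "model.json").read_text())

    def _read(name: str) -> pd.DataFrame:
        return pd.read_csv(src / name, sep="\t", index_col=0)

    W = _read("W_DP.tsv")
    DF = _read("drug_factors.tsv")
    UP = _read("U_P.tsv")
    VP = _read("V_P.tsv")
    SP = _read("S_P.tsv")
    gd = Decomposition(
        U=UP.to_numpy(),
        S=SP.to_numpy().ravel(),
        V=VP.to_numpy(),
        rank=int(meta["r_P"]),
        lam=float(meta.get("gene_lam", 0.0)),
    )
    config = None
    if "config" in meta:
        config = ModelConfig(**meta["config"])
    return FittedModel(
        W_DP=W.to_numpy(),
        intercept=float(meta["intercept"]),
        drug_factors=DF.to_numpy(),
        gene_decomp=gd,
        drug_ids=[str(i) for i in DF.index],
        phenotype_ids=[str(i) for i in VP.index],
        gene_ids=[str(i) for i in UP.index],
        polarity=meta["polarity"],
        config=config,
    )
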