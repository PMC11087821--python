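"""Synthetic inputs from a planted ground-truth interaction model.

The generator emulates the statistical structure of the real inputs while
remaining fully self-contained:

* ``D`` — a low-rank drug x endpoint matrix (latent drug factors times
  endpoint loadings plus Gaussian noise), squashed through the logistic
  map so entries live in [0, 1] like hit-fraction scores, then masked
  uniformly at a configurable missingness rate (every drug keeps at least
  one observed endpoint);
* ``G`` — a low-rank signed gene x phenotype matrix on a z-score-like
  scale;
* ``W`` — a sparse endpoints x genes interaction matrix with +-1 entries,
  rescaled so the logits ``D W G`` have a requested standard deviation;
* ``Y`` — Bernoulli draws of ``sigmoid(D W G + b)`` where the intercept
  ``b`` is calibrated by bisection to a requested association density;
* targets — groups of drugs loading on a common latent direction, each
  with a planted gene set (the top genes of that direction's propagated
  effect), mimicking shared-mechanism drug groups.

All randomness derives from one seed through named substreams, so every
matrix is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .matrices import AssociationMatrix, EndpointMatrix, GeneScoreMatrix
from .enrichment import TargetMap


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    n_drugs: int = 120
    n_endpoints: int = 200
    n_genes: int = 400
    n_phenotypes: int = 40
    latent_rank_D: int = 4
    latent_rank_G: int = 4
    w_sparsity: float = 0.05
    signal_scale: float = 2.0
    missing_fraction_D: float = 0.2
    noise_sd_D: float = 0.5
    y_density: float = 0.10
    n_targets: int = 8
    drugs_per_target: int = 6
    genes_per_target: int = 20
    gene_score_sd: float = 2.0
    squash: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank_D > min(self.n_drugs, self.n_endpoints):
            raise InvalidInputError("latent_rank_D exceeds matrix dimensions")
        if self.latent_rank_G > min(self.n_genes, self.n_phenotypes):
            raise InvalidInputError("latent_rank_G exceeds matrix dimensions")
        if not (0 <= self.missing_fraction_D < 1):
            raise InvalidInputError("missing_fraction_D must lie in [0, 1)")
        if not (0 < self.w_sparsity <= 1):
            raise InvalidInputError("w_sparsity must lie in (0, 1]")
        if not (0 < self.y_density < 1):
            raise InvalidInputError("y_density must lie in (0, 1)")
        if self.drugs_per_target > self.n_drugs:
            raise InvalidInputError("drugs_per_target exceeds n_drugs")
        if self.squash not in ("logistic", "none"):
            raise InvalidInputError(f"unknown squash mode {self.squash!r}")


@dataclass
class SimTruth:
    """Planted ground truth behind one simulated data set."""

    drug_latents: np.ndarray          # n_drugs x latent_rank_D
    endpoint_loadings: np.ndarray     # n_endpoints x latent_rank_D
    W: np.ndarray                     # endpoints x genes, sparse +-scaled
    D_complete: np.ndarray            # pre-mask squashed endpoint matrix
    logits: np.ndarray                # drugs x phenotypes (incl. intercept)
    intercept: float
    target_gene_sets: dict[str, set[str]]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _substream(seed: int, name: str) -> np.random.Generator:
    tag = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng([seed, tag])


def _calibrate_intercept(raw_logits: np.ndarray, density: float) -> float:
    """Bisection on b so that mean(sigmoid(raw + b)) == density."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(raw_logits + mid).mean() < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(
    config: SimConfig,
) -> tuple[EndpointMatrix, GeneScoreMatrix, AssociationMatrix, TargetMap, SimTruth]:
    """Draw one complete synthetic data set from the planted model."""
    seed = config.seed
    drug_ids = [f"drug{i:03d}" for i in range(config.n_drugs)]
    endpoint_ids = [f"ep{j:03d}" for j in range(config.n_endpoints)]
    gene_ids = [f"gene{g:04d}" for g in range(config.n_genes)]
    pheno_ids = [f"pheno{p:02d}" for p in range(config.n_phenotypes)]

    # --- endpoint matrix -------------------------------------------------
    rng_d = _substream(seed, "endpoints")
    A = rng_d.standard_normal((config.n_drugs, config.latent_rank_D))
    B = rng_d.standard_normal((config.n_endpoints, config.latent_rank_D))
    raw_D = A @ B.T + config.noise_sd_D * rng_d.standard_normal(
        (config.n_drugs, config.n_endpoints)
    )
    D_complete = _sigmoid(raw_D) if config.squash == "logistic" else raw_D

    rng_mask = _substream(seed, "mask")
    for _ in range(100):
        mask = rng_mask.random((config.n_drugs, config.n_endpoints)) >= (
            config.missing_fraction_D
        )
        if mask.any(axis=1).all():
            break
    else:
        raise InvalidInputError(
            "missing_fraction_D too high to keep every drug observed"
        )
    D = EndpointMatrix(
        values=np.where(mask, D_complete, np.nan),
        drug_ids=drug_ids,
        endpoint_ids=endpoint_ids,
        mask=mask,
    )

    # --- gene-score matrix ----------------------------------------------
    rng_g = _substream(seed, "genes")
    Ug = rng_g.standard_normal((config.n_genes, config.latent_rank_G))
    Vg = rng_g.standard_normal((config.n_phenotypes, config.latent_rank_G))
    G_vals = Ug @ Vg.T
    G_vals *= config.gene_score_sd / G_vals.std()
    G = GeneScoreMatrix(values=G_vals, gene_ids=gene_ids, phenotype_ids=pheno_ids)

    # --- planted interaction and labels ----------------------------------
    rng_w = _substream(seed, "interaction")
    W = np.zeros((config.n_endpoints, config.n_genes))
    n_nonzero = max(1, int(round(config.w_sparsity * W.size)))
    idx = rng_w.choice(W.size, size=n_nonzero, replace=False)
    W.ravel()[idx] = rng_w.choice([-1.0, 1.0], size=n_nonzero)
    raw_logits = D_complete @ W @ G_vals
    if config.signal_scale > 0:
        sd = raw_logits.std()
        if sd > 0:
            W *= config.signal_scale / sd
            raw_logits *= config.signal_scale / sd
    else:
        W[:] = 0.0
        raw_logits[:] = 0.0
    intercept = _calibrate_intercept(raw_logits, config.y_density)
    logits = raw_logits + intercept

    rng_y = _substream(seed, "labels")
    Y_vals = (rng_y.random(logits.shape) < _sigmoid(logits)).astype(np.int8)
    Y = AssociationMatrix(
        values=Y_vals, drug_ids=drug_ids, phenotype_ids=pheno_ids,
        polarity="side_effects",
    )

    # --- targets: drug groups sharing a latent direction ------------------
    rng_t = _substream(seed, "targets")
    targets: dict[str, set[str]] = {}
    target_gene_sets: dict[str, set[str]] = {}
    for t in range(config.n_targets):
        direction = rng_t.standard_normal(config.latent_rank_D)
        direction /= np.linalg.norm(direction)
        loading = A @ direction
        members = np.argsort(-loading, kind="stable")[: config.drugs_per_target]
        gene_effect = np.abs((B @ direction) @ W)
        top_genes = np.argsort(-gene_effect, kind="stable")[: config.genes_per_target]
        name = f"target{t:02d}"
        targets[name] = {drug_ids[i] for i in members}
        target_gene_sets[name] = {gene_ids[g] for g in top_genes}

    truth = SimTruth(
        drug_latents=A,
        endpoint_loadings=B,
        W=W,
        D_complete=D_complete,
        logits=logits,
        intercept=intercept,
        target_gene_sets=target_gene_sets,
    )
    return D, G, Y, TargetMap(targets), truth


def truth_metrics(
    truth: SimTruth,
    model,
    genome_result=None,
    *,
    alpha: float = 0.05,
) -> dict:
    """Recovery diagnostics of a fitted model against the planted truth.

    Reports the correlation and sign agreement between the planted
    gene-space effects (``D W`` per drug and gene) and the model's
    disease-genome scores, AUC of predicted probabilities against the truth
    logits' Bernoulli means, and, when a significance result is supplied,
    precision/recall of each drug's significant gene set against the
    planted support (genes with a non-zero propagated effect).
    """
    from sklearn.metrics import roc_auc_score

    from .model import predict_matrix
    from .projections import disease_genome, significant_genes

    true_gene_effect = truth.D_complete @ truth.W  # drugs x genes
    est_gene_effect = disease_genome(model)
    # the model can only resolve gene effects inside the span of U_P, so the
    # identifiable comparison projects the planted effect onto that subspace
    U_P = model.gene_decomp.U
    true_proj = (true_gene_effect @ U_P) @ U_P.T
    tf, ef = true_proj.ravel(), est_gene_effect.ravel()
    corr = float(np.corrcoef(tf, ef)[0, 1])
    nz = np.abs(tf) > 1e-12
    sign_agree = float(np.mean(np.sign(tf[nz]) == np.sign(ef[nz]))) if nz.any() else float("nan")

    probs = predict_matrix(model)
    y_true = (truth.logits > truth.intercept).astype(int).ravel()
    auc = float("nan")
    if np.unique(y_true).size == 2:
        auc = float(roc_auc_score(y_true, probs.ravel()))

    out = {
        "gene_effect_correlation": corr,
        "gene_effect_sign_agreement": sign_agree,
        "auc_vs_truth": auc,
    }
    if genome_result is not None:
        support_per_drug = np.abs(true_gene_effect) > 1e-12
        sig = significant_genes(genome_result, alpha)
        gene_pos = {g: k for k, g in enumerate(genome_result.gene_ids)}
        precisions, recalls = [], []
        for i, drug in enumerate(genome_result.drug_ids):
            called = {gene_pos[g] for g in sig[drug]}
            planted = set(np.flatnonzero(support_per_drug[i]).tolist())
            if called:
                precisions.append(len(called & planted) / len(called))
            if planted:
                recalls.append(len(called & planted) / len(planted))
        out["significant_gene_precision"] = (
            float(np.mean(precisions)) if precisions else float("nan")
        )
        out["significant_gene_recall"] = (
            float(np.mean(recalls)) if recalls else float("nan")
        )
    return out
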