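"""Target-gene enrichment and the disease-gene overlap drug network.

Two downstream analyses of the per-drug significant disease-gene sets:

* **Target enrichment** — for each molecular target (a set of >= 3 drugs)
  and each disease gene associated with at least one of those drugs, an
  upper-tail hypergeometric test asks whether drugs sharing the target are
  over-represented among drugs associated with that gene, adjusted by
  Benjamini-Hochberg within each target. A calibration permutes the
  assignment of drugs to targets (preserving target sizes) and compares the
  per-target minimum p-value against its permuted distribution.

* **Drug-drug network** — drugs are connected when their disease-gene sets
  overlap more than expected under a weighted resampling null: one drug's
  set is redrawn without replacement, genes sampled in proportion to how
  many drugs they are significantly associated with, and the overlap with
  the other drug's (fixed) set is recounted. Maximal cliques of at least
  three drugs give an exploratory drug categorization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

#: Targets must be shared by at least this many drugs to enter enrichment.
MIN_DRUGS_PER_TARGET = 3


@dataclass
class TargetMap:
    """Mapping target id -> set of drug ids."""

    targets: dict[str, set[str]]

    def filtered(self, min_drugs: int = MIN_DRUGS_PER_TARGET) -> "TargetMap":
        return TargetMap(
            {t: set(d) for t, d in self.targets.items() if len(d) >= min_drugs}
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TargetMap":
        """Two-column TSV (target, drug), with or without a header line."""
        df = pd.read_csv(path, sep="\t", header=None, names=["target", "drug"], dtype=str)
        if list(df.iloc[0]) == ["target", "drug"]:
            df = df.iloc[1:]
        out: dict[str, set[str]] = {}
        for t, d in zip(df["target"], df["drug"]):
            out.setdefault(str(t), set()).add(str(d))
        return cls(out)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("target\tdrug\n")
            for t in sorted(self.targets):
                for d in sorted(self.targets[t]):
                    fh.write(f"{t}\t{d}\n")


@dataclass
class DrugGeneSets:
    """Per-drug significant disease-gene sets and derived gene weights."""

    sets: dict[str, set[str]]

    @property
    def gene_weight(self) -> dict[str, int]:
        """Number of drugs each gene is significantly associated with."""
        w: dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                w[g] = w.get(g, 0) + 1
        return w

    @property
    def universe(self) -> list[str]:
        return sorted(self.gene_weight)


@dataclass
class DrugNetwork:
    """Drug-drug overlap network with per-edge (overlap, p) annotations."""

    graph: nx.Graph
    p_threshold: float
    cliques: list[list[str]] = field(default_factory=list)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"drug_a": a, "drug_b": b, "overlap": d["overlap"], "p": d["p"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["drug_a", "drug_b", "overlap", "p"])


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) drawing ``n`` from a population
    of ``N`` containing ``K`` successes."""
    if k > min(n, K):
        raise InvalidInputError(f"observed overlap {k} exceeds min(n={n}, K={K})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def target_gene_enrichment(
    targets: TargetMap,
    sets: DrugGeneSets,
    n_drugs_total: int,
    *,
    min_drugs_per_target: int = MIN_DRUGS_PER_TARGET,
) -> pd.DataFrame:
    """Hypergeometric target-gene enrichment table.

    For each retained target and each gene associated with >= 1 of the
    target's drugs: population ``N`` = all drugs in the model, successes
    ``K`` = drugs associated with the gene, draws ``n`` = drugs with the
    target, observed ``k`` = their overlap. ``q`` is BH-adjusted within
    each target across its tested genes.
    """
    drug_genes = sets.sets
    gene_drugs: dict[str, set[str]] = {}
    for d, genes in drug_genes.items():
        for g in genes:
            gene_drugs.setdefault(g, set()).add(d)
    rows = []
    for target, t_drugs in sorted(targets.filtered(min_drugs_per_target).targets.items()):
        tested = sorted({g for d in t_drugs for g in drug_genes.get(d, ())})
        for gene in tested:
            K_drugs = gene_drugs[gene]
            k = len(K_drugs & t_drugs)
            p = hypergeom_pvalue(k, n_drugs_total, len(K_drugs), len(t_drugs))
            rows.append(
                {
                    "target": target,
                    "gene": gene,
                    "k": k,
                    "n": len(t_drugs),
                    "K": len(K_drugs),
                    "N": n_drugs_total,
                    "p": p,
                }
            )
    table = pd.DataFrame(
        rows, columns=["target", "gene", "k", "n", "K", "N", "p"]
    )
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        return table
    table["q"] = np.nan
    for target, idx in table.groupby("target").groups.items():
        table.loc[idx, "q"] = multipletests(
            table.loc[idx, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return table


def permuted_target_calibration(
    targets: TargetMap,
    sets: DrugGeneSets,
    n_drugs_total: int,
    n_perm: int = 100,
    seed: int = 0,
    *,
    min_drugs_per_target: int = MIN_DRUGS_PER_TARGET,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Per-target minimum enrichment p-value, true vs permuted assignments.

    Each permutation redraws every target's drug set uniformly from the
    drugs with computed gene sets, preserving the target's size, and
    recomputes the most significant gene association. Returns
    ``(true_min_p, null_min_p)`` keyed by target id; targets whose permuted
    drugs share no genes get min-p 1.0 for that permutation.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    filt = targets.filtered(min_drugs_per_target)
    true_table = target_gene_enrichment(
        filt, sets, n_drugs_total, min_drugs_per_target=min_drugs_per_target
    )
    true_min: dict[str, float] = {t: 1.0 for t in filt.targets}
    if not true_table.empty:
        for t, sub in true_table.groupby("target"):
            true_min[str(t)] = float(sub["p"].min())
    drug_pool = sorted(sets.sets)
    rng = np.random.default_rng(seed)
    null_min: dict[str, list[float]] = {t: [] for t in filt.targets}
    for _ in range(n_perm):
        perm_targets = TargetMap(
            {
                t: set(rng.choice(drug_pool, size=len(d), replace=False))
                for t, d in filt.targets.items()
            }
        )
        perm_table = target_gene_enrichment(
            perm_targets, sets, n_drugs_total, min_drugs_per_target=min_drugs_per_target
        )
        mins = (
            perm_table.groupby("target")["p"].min().to_dict()
            if not perm_table.empty
            else {}
        )
        for t in filt.targets:
            null_min[t].append(float(mins.get(t, 1.0)))
    return true_min, {t: np.asarray(v) for t, v in null_min.items()}


def _weighted_sample_without_replacement(
    items: list[str], weights: np.ndarray, k: int, rng: np.random.Generator
) -> set[str]:
    """Successive draws proportional to weight, renormalizing after each."""
    idx = rng.choice(len(items), size=k, replace=False, p=weights / weights.sum())
    return {items[i] for i in idx}


def _pair_rng(seed: int, id_a: str, id_b: str) -> np.random.Generator:
    """Deterministic per-pair stream derived from the sorted pair ids, so
    the network is invariant to drug input order and parallel scheduling."""
    a, b = sorted((id_a, id_b))
    digest = hashlib.sha256(f"{a}\x00{b}".encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


def pair_overlap_test(
    genes_a: set[str],
    genes_b: set[str],
    gene_weight: dict[str, int],
    universe: list[str],
    n_sim: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[int, float]:
    """Monte-Carlo overlap test of two drugs' disease-gene sets.

    Drug A's set is resampled ``n_sim`` times (without replacement, genes
    weighted by their drug counts); drug B's set stays fixed. Returns the
    observed overlap and ``p = (1 + #{sim overlap >= observed}) / (n_sim + 1)``.
    """
    universe = list(universe)
    if len(genes_a) > len(universe):
        raise InvalidInputError("drug set larger than gene universe")
    if not set(genes_a) <= set(universe) or not set(genes_b) <= set(universe):
        raise InvalidInputError("gene sets must be contained in the universe")
    weights = np.array([gene_weight[g] for g in universe], dtype=float)
    if (weights <= 0).any():
        raise InvalidInputError("gene weights must be positive on the universe")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = len(genes_a & genes_b)
    exceed = 0
    for _ in range(n_sim):
        sim = _weighted_sample_without_replacement(universe, weights, len(genes_a), rng)
        if len(sim & genes_b) >= observed:
            exceed += 1
    return observed, (1.0 + exceed) / (n_sim + 1.0)


def build_network(
    sets: DrugGeneSets,
    p_threshold: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
    *,
    resample: str = "smaller",
    min_clique_size: int = 3,
) -> DrugNetwork:
    """Connect drugs whose gene-set overlap beats the weighted null.

    Only pairs with non-zero overlap are tested (zero overlap gives p = 1
    by construction). ``resample`` picks which drug of the pair is redrawn:
    the one with the ``smaller`` set (default), or ``both`` taking the
    larger (more conservative) of the two directional p-values.
    """
    drugs = sorted(d for d, g in sets.sets.items() if g)
    if len(drugs) < 2:
        raise InvalidInputError("need at least two drugs with non-empty gene sets")
    weight = sets.gene_weight
    universe = sets.universe
    graph = nx.Graph()
    graph.add_nodes_from(drugs)
    for a, b in combinations(drugs, 2):
        ga, gb = sets.sets[a], sets.sets[b]
        overlap = len(ga & gb)
        if overlap == 0:
            continue
        rng = _pair_rng(seed, a, b)
        small, big = (ga, gb) if len(ga) <= len(gb) else (gb, ga)
        _, p = pair_overlap_test(small, big, weight, universe, n_sim, rng=rng)
        if resample == "both":
            _, p2 = pair_overlap_test(big, small, weight, universe, n_sim, rng=rng)
            p = max(p, p2)
        elif resample != "smaller":
            raise InvalidInputError(f"unknown resample rule {resample!r}")
        if p < p_threshold:
            graph.add_edge(a, b, overlap=overlap, p=p)
    net = DrugNetwork(graph=graph, p_threshold=p_threshold)
    net.cliques = find_cliques(net, min_size=min_clique_size)
    return net


def find_cliques(network: DrugNetwork, min_size: int = 3) -> list[list[str]]:
    """All maximal cliques with at least ``min_size`` drugs, each sorted by
    drug id, the list sorted lexicographically."""
    cliques = [
        sorted(c) for c in nx.find_cliques(network.graph) if len(c) >= min_size
    ]
    return sorted(cliques)


def viz_gene_filter(
    sets: DrugGeneSets,
    enrichment_table: pd.DataFrame,
    max_drugs_per_gene: int = 15,
    q_threshold: float = 0.01,
) -> set[str]:
    """Genes worth drawing: significantly enriched for >= 1 target
    (q < ``q_threshold``) and associated with fewer than
    ``max_drugs_per_gene`` drugs (strict)."""
    if enrichment_table.empty:
        return set()
    sig = set(enrichment_table.loc[enrichment_table["q"] < q_threshold, "gene"])
    weight = sets.gene_weight
    return {g for g in sig if weight.get(g, 0) < max_drugs_per_gene}


def export_network(net: DrugNetwork, outdir: str | Path) -> None:
    """Write the edge list TSV, GraphML, and one-clique-per-line TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    net.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False)
    nx.write_graphml(net.graph, out / "network.graphml")
    with (out / "cliques.tsv").open("w") as fh:
        for clique in net.cliques:
            fh.write("\t".join(clique) + "\n")
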