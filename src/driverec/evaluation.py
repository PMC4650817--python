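"""Evaluation battery for ranked driver-gene predictions.

Covers the comparison criteria used to judge a ranked gene list: positive
predictive value of the top-k against a cancer-gene annotation catalog,
surrogate sensitivity/specificity from known positive/negative gene sets,
hypergeometric (one-sided Fisher exact) enrichment of the top-k in a
catalog, cross-method agreement counts, overlap with reference candidate
lists, rank-sum meta-ranking of methods, and generic gene-set
over-representation with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .feature_engine import normalize_gene

__all__ = [
    "AnnotationCatalog",
    "EvaluationReport",
    "ppv_at_k",
    "surrogate_rates",
    "enrichment_p",
    "criterion_agreement",
    "criterion_overlap",
    "rank_methods",
    "geneset_enrichment",
    "read_gmt",
]


@dataclass
class AnnotationCatalog:
    """A named set of annotated genes (e.g. the CGC/OMIM/NCG union)."""

    name: str
    genes: set[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.genes = {normalize_gene(g) for g in self.genes}
        if not self.genes:
            raise ValueError(f"annotation catalog {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EvaluationReport:
    ppv: float
    surrogate_sensitivity: float
    surrogate_specificity: float
    enrichment_p: float
    criterion_i_count: int
    criterion_ii_count: int
    method_ranking: pd.DataFrame | None = None
    overall_rank_score: int | None = None

    def to_json_dict(self) -> dict:
        out = {
            "ppv": self.ppv,
            "surrogate_sensitivity": self.surrogate_sensitivity,
            "surrogate_specificity": self.surrogate_specificity,
            "enrichment_p": self.enrichment_p,
            "criterion_i_count": self.criterion_i_count,
            "criterion_ii_count": self.criterion_ii_count,
        }
        if self.overall_rank_score is not None:
            out["overall_rank_score"] = self.overall_rank_score
        return out


def ppv_at_k(
    predictions: Sequence[str], catalog: AnnotationCatalog, k: int = 50
) -> float:
    """Fraction of the top-k predictions present in the catalog
    (true positives / number of calls)."""
    if k <= 0:
        raise IndexError("k must be positive")
    if len(predictions) < k:
        raise IndexError(f"need at least {k} predictions, got {len(predictions)}")
    top = {normalize_gene(g) for g in predictions[:k]}
    return len(top & catalog.genes) / k


def surrogate_rates(
    top_k: Sequence[str], positives: Iterable[str], negatives: Iterable[str]
) -> tuple[float, float]:
    """Surrogate sensitivity and specificity for a thresholdless method.

    Sensitivity: fraction of known positives inside the top-k list.
    Specificity: fraction of known negatives outside it.
    """
    pos = {normalize_gene(g) for g in positives}
    neg = {normalize_gene(g) for g in negatives}
    if pos & neg:
        raise ValueError("positive and negative sets overlap")
    if not pos or not neg:
        raise ValueError("positive and negative sets must be non-empty")
    top = {normalize_gene(g) for g in top_k}
    sensitivity = len(top & pos) / len(pos)
    specificity = len(neg - top) / len(neg)
    return sensitivity, specificity


def enrichment_p(hits: int, k: int, catalog_size: int, universe_size: int) -> float:
    """Hypergeometric upper-tail P(X >= hits) for k draws from a universe
    containing ``catalog_size`` annotated genes; identical to the one-sided
    Fisher exact P of the 2x2 table."""
    if not (0 <= hits <= k <= universe_size and 0 <= catalog_size <= universe_size):
        raise ValueError(
            f"inconsistent counts: hits={hits}, k={k}, "
            f"catalog={catalog_size}, universe={universe_size}"
        )
    if hits > catalog_size:
        raise ValueError(f"hits={hits} exceeds catalog size {catalog_size}")
    return float(hypergeom.sf(hits - 1, universe_size, catalog_size, k))


def criterion_agreement(
    top_k: Sequence[str],
    per_method_top_k: Sequence[Sequence[str]],
    threshold: int = 5,
) -> int:
    """Number of top-k genes also called by at least ``threshold`` of the
    individual methods' top lists."""
    method_sets = [{normalize_gene(g) for g in lst} for lst in per_method_top_k]
    count = 0
    for gene in top_k:
        gene = normalize_gene(gene)
        if sum(gene in s for s in method_sets) >= threshold:
            count += 1
    return count


def criterion_overlap(top_k: Sequence[str], reference: AnnotationCatalog) -> int:
    """Number of top-k genes present in a reference candidate-driver list."""
    return len({normalize_gene(g) for g in top_k} & reference.genes)


def rank_methods(
    per_method_scores: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    """Rank-sum meta-ranking of methods over two criteria.

    Each criterion is ranked descending (1 = best; ties share the better
    rank), the overall score is the sum of the two ranks, and methods are
    ordered by ascending score (lower is better).
    """
    if len(per_method_scores) < 2:
        raise ValueError("need at least 2 methods to rank")
    methods = sorted(per_method_scores)
    c1 = np.array([per_method_scores[m][0] for m in methods], dtype=float)
    c2 = np.array([per_method_scores[m][1] for m in methods], dtype=float)
    r1 = rankdata(-c1, method="min").astype(int)
    r2 = rankdata(-c2, method="min").astype(int)
    df = pd.DataFrame(
        {
            "method": methods,
            "criterion_i": c1,
            "criterion_ii": c2,
            "rank_i": r1,
            "rank_ii": r2,
            "overall_score": r1 + r2,
        }
    )
    df = df.sort_values(["overall_score", "method"], kind="mergesort")
    df["overall_rank"] = rankdata(df["overall_score"], method="min").astype(int)
    return df.reset_index(drop=True)


def geneset_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Gene-set over-representation: one-sided Fisher exact per set with
    Benjamini–Hochberg FDR, sorted by ascending FDR."""
    universe_set = {normalize_gene(g) for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = {normalize_gene(g) for g in query}
    if not query_set <= universe_set:
        raise ValueError("query genes must be a subset of the universe")

    rows = []
    for name in sorted(gene_sets):
        members = {normalize_gene(g) for g in gene_sets[name]} & universe_set
        overlap = query_set & members
        p = enrichment_p(len(overlap), len(query_set), len(members), len(universe_set))
        rows.append((name, len(overlap), sorted(overlap), p))
    df = pd.DataFrame(rows, columns=["set", "count", "genes", "p"])
    if len(df):
        _, fdr, _, _ = multipletests(df["p"], method="fdr_bh")
        df["fdr"] = fdr
        df["significant"] = df["fdr"] < fdr_threshold
        df = df.sort_values(["fdr", "p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: set_name <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {normalize_gene(g) for g in parts[2:] if g}
    return sets
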