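"""Encode heterogeneous driver-detection method outputs as per-gene features.

Ten upstream methods contribute one numeric feature each. Gene-level methods
(OncodriveFM, OncodriveCLUST, MutSig, ActiveDriver, Simon) report a P-value
per gene; network/module-level methods (FLN, NetBox, MEMo, Dendrix, FLNP)
report modules or ranked gene lists over a weighted gene network, from which
a connectivity-based feature is derived. A gene missing from a method's
output receives the method's "no evidence" default: P = 1 for P-value
methods, weight 0 for network/module methods. Stacking the ten features over
a gene universe yields the matrix the ensemble classifier is trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethodOutput",
    "FeatureMatrix",
    "gene_pvalue_feature",
    "fln_topk_feature",
    "module_count_feature",
    "module_avg_weight_feature",
    "build_feature_matrix",
    "read_pvalue_table",
    "read_module_file",
    "read_edge_list",
    "read_gene_list",
]

GENE_PVALUE = "gene_pvalue"
RANKED_LIST = "ranked_list"
MODULE_COUNT = "module_count"
MODULE_WEIGHTED = "module_weighted"

_KINDS = (GENE_PVALUE, RANKED_LIST, MODULE_COUNT, MODULE_WEIGHTED)

#: per-kind default for genes absent from a method's output
KIND_DEFAULT = {
    GENE_PVALUE: 1.0,
    RANKED_LIST: 0.0,
    MODULE_COUNT: 0.0,
    MODULE_WEIGHTED: 0.0,
}


def normalize_gene(gene: str) -> str:
    """Case-normalize a gene symbol (upper-case, stripped)."""
    return str(gene).strip().upper()


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    a, b = normalize_gene(a), normalize_gene(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class MethodOutput:
    """One upstream method's evidence.

    Parameters
    ----------
    method_id : str
        Short method name (e.g. ``"mutsig"``, ``"netbox"``).
    kind : str
        ``"gene_pvalue"`` — per-gene P-values; ``"ranked_list"`` — a ranked
        top-gene list plus a weighted network (FLN style); ``"module_count"``
        — modules plus an interaction network, feature = weighted link count;
        ``"module_weighted"`` — modules plus a weighted network, feature =
        mean edge weight into the module.
    pvalues : mapping gene -> P, for ``gene_pvalue`` only.
    modules : list of gene-id sets, for module kinds.
    network : iterable of (gene_a, gene_b, weight) edges, module/ranked kinds.
    top_genes : ordered gene list, ``ranked_list`` only.
    """

    method_id: str
    kind: str
    pvalues: dict[str, float] = field(default_factory=dict)
    modules: list[set[str]] = field(default_factory=list)
    network: dict[tuple[str, str], float] = field(default_factory=dict)
    top_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(
                f"method {self.method_id!r}: unknown kind {self.kind!r}; "
                f"expected one of {_KINDS}"
            )
        self.pvalues = {normalize_gene(g): float(p) for g, p in self.pvalues.items()}
        for gene, p in self.pvalues.items():
            if not (0.0 <= p <= 1.0) or not np.isfinite(p):
                raise ValueError(
                    f"method {self.method_id!r}: P-value {p!r} for gene "
                    f"{gene!r} outside [0, 1]"
                )
        self.modules = [
            {normalize_gene(g) for g in module} for module in self.modules
        ]
        for module in self.modules:
            if not module:
                raise ValueError(f"method {self.method_id!r}: empty module set")
        edges: dict[tuple[str, str], float] = {}
        items: Iterable
        if isinstance(self.network, Mapping):
            items = ((a, b, w) for (a, b), w in self.network.items())
        else:
            items = self.network
        for a, b, w in items:
            w = float(w)
            if w < 0 or not np.isfinite(w):
                raise ValueError(
                    f"method {self.method_id!r}: negative or non-finite edge "
                    f"weight {w!r} on ({a}, {b})"
                )
            key = _canonical_edge(a, b)
            if key in edges and edges[key] != w:
                raise ValueError(
                    f"method {self.method_id!r}: duplicate edge {key} with "
                    f"conflicting weights"
                )
            edges[key] = w
        self.network = edges
        self.top_genes = [normalize_gene(g) for g in self.top_genes]
        # adjacency cache, built lazily
        self._adj: dict[str, dict[str, float]] | None = None

    # -- network helpers ---------------------------------------------------

    @property
    def adjacency(self) -> dict[str, dict[str, float]]:
        if self._adj is None:
            adj: dict[str, dict[str, float]] = {}
            for (a, b), w in self.network.items():
                adj.setdefault(a, {})[b] = w
                adj.setdefault(b, {})[a] = w
            self._adj = adj
        return self._adj

    def edge_weight(self, a: str, b: str) -> float:
        return self.adjacency.get(normalize_gene(a), {}).get(normalize_gene(b), 0.0)

    @property
    def interior_genes(self) -> set[str]:
        """Union of all module members for this method."""
        out: set[str] = set()
        for module in self.modules:
            out |= module
        return out

    def covers(self, gene: str) -> bool:
        """Whether the method reports any evidence for *gene* (non-default)."""
        gene = normalize_gene(gene)
        if self.kind == GENE_PVALUE:
            return gene in self.pvalues
        return gene in self.adjacency


@dataclass
class FeatureMatrix:
    """Genes x methods feature matrix with no missing cells.

    ``imputed_mask[i, j]`` is True where gene *i* was absent from method *j*'s
    output and received the kind default (1 for P-value methods, 0 for
    module/network methods).
    """

    genes: list[str]
    methods: list[str]
    values: np.ndarray
    imputed_mask: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        n, m = self.values.shape
        if len(self.genes) != n or len(self.methods) != m:
            raise ValueError("feature matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing/non-finite cells")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[normalize_gene(gene)]]

    def subset(self, genes: Sequence[str]) -> "FeatureMatrix":
        idx = [self._index[normalize_gene(g)] for g in genes]
        return FeatureMatrix(
            genes=[self.genes[i] for i in idx],
            methods=list(self.methods),
            values=self.values[idx],
            imputed_mask=self.imputed_mask[idx],
            kinds=list(self.kinds),
        )

    def binary_candidate_matrix(self, pvalue_threshold: float = 0.05) -> np.ndarray:
        """0/1 candidate-call matrix: P < threshold for P-value methods,
        non-default (module membership / nonzero linkage) otherwise."""
        calls = np.zeros_like(self.values, dtype=int)
        for j, kind in enumerate(self.kinds):
            if kind == GENE_PVALUE:
                calls[:, j] = (self.values[:, j] < pvalue_threshold).astype(int)
            else:
                calls[:, j] = (self.values[:, j] > 0).astype(int)
        return calls

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.methods)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


# -- single-feature operations --------------------------------------------


def gene_pvalue_feature(output: MethodOutput, gene: str) -> float:
    """The method's P-value for *gene*; 1.0 when the gene is absent."""
    if output.kind != GENE_PVALUE:
        raise ValueError(
            f"method {output.method_id!r} has kind {output.kind!r}, "
            "expected gene_pvalue"
        )
    return output.pvalues.get(normalize_gene(gene), 1.0)


def fln_topk_feature(output: MethodOutput, gene: str, k: int = 100) -> float:
    """Mean network weight between *gene* and the method's top-``k`` genes.

    Non-edges contribute 0 and the mean is taken over all ``k`` top genes
    (or over all available when the ranked list is shorter). A gene absent
    from the network scores 0.
    """
    if not output.top_genes:
        raise ValueError(
            f"method {output.method_id!r}: ranked top-gene list is empty"
        )
    top = output.top_genes[:k]
    gene = normalize_gene(gene)
    neighbors = output.adjacency.get(gene)
    if not neighbors:
        return 0.0
    return sum(neighbors.get(t, 0.0) for t in top) / len(top)


def module_count_feature(output: MethodOutput, gene: str) -> float:
    """Weighted count of links between *gene* and module-interior genes.

    L = number of network links from *gene* to genes interior to the method's
    modules (union over modules). Interior target genes score 2·L, exterior
    ones 1·L; genes absent from the network score 0.
    """
    if output.kind != MODULE_COUNT:
        raise ValueError(
            f"method {output.method_id!r} has kind {output.kind!r}, "
            "expected module_count"
        )
    gene = normalize_gene(gene)
    neighbors = output.adjacency.get(gene)
    if not neighbors:
        return 0.0
    interior = output.interior_genes
    links = sum(1 for nb in neighbors if nb in interior and nb != gene)
    multiplier = 2.0 if gene in interior else 1.0
    return multiplier * links


def module_avg_weight_feature(output: MethodOutput, gene: str) -> float:
    """Mean network weight between *gene* and all module-interior genes.

    Non-edges contribute 0; the divisor is the number of interior genes other
    than the target itself. A gene absent from the network scores 0.
    """
    if output.kind != MODULE_WEIGHTED:
        raise ValueError(
            f"method {output.method_id!r} has kind {output.kind!r}, "
            "expected module_weighted"
        )
    if not output.modules:
        raise ValueError(f"method {output.method_id!r}: no modules supplied")
    gene = normalize_gene(gene)
    neighbors = output.adjacency.get(gene)
    if not neighbors:
        return 0.0
    interior = output.interior_genes - {gene}
    if not interior:
        return 0.0
    return sum(neighbors.get(g, 0.0) for g in interior) / len(interior)


def method_feature(output: MethodOutput, gene: str, k: int = 100) -> float:
    """Dispatch to the kind-appropriate single-feature operation."""
    if output.kind == GENE_PVALUE:
        return gene_pvalue_feature(output, gene)
    if output.kind == RANKED_LIST:
        return fln_topk_feature(output, gene, k=k)
    if output.kind == MODULE_COUNT:
        return module_count_feature(output, gene)
    return module_avg_weight_feature(output, gene)


def build_feature_matrix(
    outputs: Sequence[MethodOutput],
    universe: Sequence[str],
    n_methods: int = 10,
    topk: int = 100,
) -> FeatureMatrix:
    """Assemble the genes x methods feature matrix over a gene universe.

    One row per universe gene, one column per method, each cell produced by
    the kind-appropriate feature operation; absent genes get the kind default
    and are flagged in ``imputed_mask``.
    """
    if len(outputs) != n_methods:
        raise ValueError(f"expected {n_methods} method outputs, got {len(outputs)}")
    ids = [o.method_id for o in outputs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate method_ids: {ids}")
    genes = [normalize_gene(g) for g in universe]
    if not genes:
        raise ValueError("gene universe is empty")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in universe")

    values = np.empty((len(genes), len(outputs)), dtype=float)
    mask = np.zeros_like(values, dtype=bool)
    for j, out in enumerate(outputs):
        for i, gene in enumerate(genes):
            if out.covers(gene):
                values[i, j] = method_feature(out, gene, k=topk)
            else:
                values[i, j] = KIND_DEFAULT[out.kind]
                mask[i, j] = True
    return FeatureMatrix(
        genes=genes,
        methods=ids,
        values=values,
        imputed_mask=mask,
        kinds=[o.kind for o in outputs],
    )


# -- file dialects ---------------------------------------------------------


def read_pvalue_table(path: str | Path) -> dict[str, float]:
    """Read a ``gene<TAB>pvalue`` table (no header, '#' comments allowed)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene", "pvalue"]
    )
    return {normalize_gene(g): float(p) for g, p in zip(df["gene"], df["pvalue"])}


def read_module_file(path: str | Path) -> list[set[str]]:
    """Read ``module_id<TAB>gene`` rows into a list of gene sets."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["module_id", "gene"]
    )
    modules: dict[str, set[str]] = {}
    for mid, gene in zip(df["module_id"], df["gene"]):
        modules.setdefault(str(mid), set()).add(normalize_gene(gene))
    return list(modules.values())


def read_edge_list(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a ``gene_a<TAB>gene_b<TAB>weight`` undirected edge list."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["gene_a", "gene_b", "weight"],
    )
    edges: dict[tuple[str, str], float] = {}
    for a, b, w in zip(df["gene_a"], df["gene_b"], df["weight"]):
        edges[_canonical_edge(a, b)] = float(w)
    return edges


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list ('#' comments allowed)."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(normalize_gene(line))
    return out
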