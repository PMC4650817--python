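"""Synthetic cohorts with planted drivers for end-to-end testing.

Emulates the statistical structure the ensemble classifier relies on: a
small set of driver genes scores well on several — not all — of ten
upstream methods, while passengers show only noise. Five gene-level methods
report P-values (drivers concentrated near 0 via a Beta(shape, 1) draw,
passengers uniform); five network/module methods are built over planted
module graphs in which drivers are preferentially co-modular. A cohort MAF
gives drivers an elevated per-sample mutation probability. Everything is
deterministic given the seed.

The generator emulates driver/passenger signal separation, not mutational
realism: no trinucleotide context, signatures, CNV or expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .feature_engine import (
    GENE_PVALUE,
    MODULE_COUNT,
    MODULE_WEIGHTED,
    RANKED_LIST,
    MethodOutput,
    build_feature_matrix,
)
from .mutation_io import MutationTable, negative_candidates, write_maf
from .trials import TrainingSet

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "rare_driver_scenario",
    "cohort_training_set",
    "write_cohort",
]

GENE_METHODS = ("oncodrivefm", "oncodriveclust", "mutsig", "activedriver", "simon")
MODULE_METHODS = ("fln", "netbox", "memo", "dendrix", "flnp")


@dataclass
class SyntheticConfig:
    """Knobs of the planted-driver generator.

    driver_pvalue_shape : Beta(shape, 1) concentration of driver P-values
        near 0 (smaller = stronger signal; shape < 1 required for a mode
        at 0).
    detection_prob : probability a gene-level method reports a given gene.
    module_recall : probability a driver joins a module method's module.
    network_density : background (non-module) edge probability.
    driver/passenger_mutation_rate : per-sample mutation probabilities.
    """

    n_genes: int = 2000
    n_drivers: int = 40
    n_samples: int = 500
    driver_pvalue_shape: float = 0.1
    detection_prob: float = 0.8
    module_recall: float = 0.8
    network_density: float = 0.005
    driver_mutation_rate: float = 0.05
    passenger_mutation_rate: float = 0.002
    silent_fraction: float = 0.15
    module_size: int = 10
    drivers_per_module: int = 4
    #: probability a passenger filler is retained in a method's module;
    #: kept well below module_recall so module membership enriches for drivers
    filler_retention: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        probs = dict(
            detection_prob=self.detection_prob,
            module_recall=self.module_recall,
            network_density=self.network_density,
            driver_mutation_rate=self.driver_mutation_rate,
            passenger_mutation_rate=self.passenger_mutation_rate,
            silent_fraction=self.silent_fraction,
        )
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_drivers >= self.n_genes:
            raise ValueError(
                f"n_drivers ({self.n_drivers}) must be < n_genes ({self.n_genes})"
            )
        if self.driver_pvalue_shape <= 0:
            raise ValueError("driver_pvalue_shape must be > 0")

    @property
    def planted_separability(self) -> float:
        """Expected fraction of drivers visible to at least one method.

        A driver is invisible only if every gene-level method fails to
        report it and it joins no module; with independent per-method
        draws this is (1-detection)^5 * (1-recall)^5.
        """
        invisible = (1.0 - self.detection_prob) ** len(GENE_METHODS) * (
            1.0 - self.module_recall
        ) ** len(MODULE_METHODS)
        return 1.0 - invisible


@dataclass
class SyntheticCohort:
    """One simulated study: method outputs, MAF, truth and universe."""

    config: SyntheticConfig
    outputs: list[MethodOutput]
    maf: MutationTable
    universe: list[str]
    drivers: set[str]
    rare_drivers: set[str] = field(default_factory=set)

    @property
    def truth(self) -> dict[str, int]:
        return {g: int(g in self.drivers) for g in self.universe}

    @property
    def known_drivers(self) -> set[str]:
        """Drivers usable as training positives (rare ones are held out to
        emulate not-yet-annotated drivers)."""
        return self.drivers - self.rare_drivers


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _planted_modules(
    cfg: SyntheticConfig, drivers: list[str], passengers: list[str],
    rng: np.random.Generator,
) -> list[list[str]]:
    """Partition drivers into modules and pad each with passenger genes."""
    k = cfg.drivers_per_module
    modules = []
    filler_pool = list(passengers)
    rng.shuffle(filler_pool)
    cursor = 0
    for start in range(0, len(drivers), k):
        members = list(drivers[start:start + k])
        n_fill = max(cfg.module_size - len(members), 0)
        members += filler_pool[cursor:cursor + n_fill]
        cursor += n_fill
        modules.append(members)
    return modules


def _module_network(
    cfg: SyntheticConfig,
    universe: list[str],
    modules: list[list[str]],
    drivers: set[str],
    rng: np.random.Generator,
) -> dict[tuple[str, str], float]:
    """Planted-partition weighted graph on a sparse weak background.

    Driver-driver intra-module edges are frequent and heavy; intra-module
    edges touching a passenger filler are sparser and lighter, so network
    linkage — like module membership — enriches for drivers rather than for
    anything that happens to sit in a module.
    """
    edges: dict[tuple[str, str], float] = {}
    n = len(universe)
    n_background = rng.binomial(n * (n - 1) // 2, cfg.network_density)
    for _ in range(n_background):
        i, j = rng.choice(n, size=2, replace=False)
        a, b = universe[i], universe[j]
        key = (a, b) if a <= b else (b, a)
        edges[key] = float(rng.uniform(0.01, 0.3))
    for module in modules:
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                a, b = module[i], module[j]
                if a in drivers and b in drivers:
                    prob, low, high = 0.9, 0.7, 1.0
                else:
                    prob, low, high = 0.4, 0.2, 0.6
                if rng.random() < prob:
                    key = (a, b) if a <= b else (b, a)
                    edges[key] = float(rng.uniform(low, high))
    return edges


def _gene_pvalue_output(
    method_id: str,
    cfg: SyntheticConfig,
    universe: list[str],
    drivers: set[str],
    weak_genes: set[str],
    rng: np.random.Generator,
) -> MethodOutput:
    pvalues = {}
    for g in universe:
        if rng.random() >= cfg.detection_prob:
            continue
        if g in weak_genes:
            # rarely mutated true drivers: non-significant at gene level
            pvalues[g] = float(rng.uniform(0.3, 1.0))
        elif g in drivers:
            pvalues[g] = float(rng.beta(cfg.driver_pvalue_shape, 1.0))
        else:
            pvalues[g] = float(rng.uniform(0.0, 1.0))
    return MethodOutput(method_id=method_id, kind=GENE_PVALUE, pvalues=pvalues)


def _simulate_maf(
    cfg: SyntheticConfig,
    universe: list[str],
    drivers: set[str],
    rare: set[str],
    rng: np.random.Generator,
) -> MutationTable:
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    records: list[tuple[str, str, str]] = []
    for g in universe:
        if g in rare:
            rate = cfg.passenger_mutation_rate
        elif g in drivers:
            rate = cfg.driver_mutation_rate
        else:
            rate = cfg.passenger_mutation_rate
        if rate <= 0:
            continue
        n_mut = rng.binomial(cfg.n_samples, rate)
        if n_mut == 0:
            continue
        hit = rng.choice(cfg.n_samples, size=n_mut, replace=False)
        for s in sorted(hit):
            if rng.random() < cfg.silent_fraction:
                vc = "Silent"
            elif rng.random() < 0.1:
                vc = "Nonsense_Mutation"
            else:
                vc = "Missense_Mutation"
            records.append((g, samples[s], vc))
    return MutationTable(records=records, cohort_size=cfg.n_samples)


def simulate_cohort(
    cfg: SyntheticConfig, _rare: set[str] | None = None
) -> SyntheticCohort:
    """Generate a full synthetic study for a configuration.

    Returns ten method outputs (5 gene-level P-value tables; an FLN-style
    ranked list; 3 module methods over an interaction network; a weighted
    module method over the FLN), a cohort MAF and truth labels.
    """
    rng = np.random.default_rng(cfg.seed)
    universe = _gene_ids(cfg.n_genes)
    driver_idx = rng.choice(cfg.n_genes, size=cfg.n_drivers, replace=False)
    drivers_list = sorted(universe[i] for i in driver_idx)
    drivers = set(drivers_list)
    rare = set(_rare or set())
    passengers = [g for g in universe if g not in drivers]

    outputs: list[MethodOutput] = []
    for mid in GENE_METHODS:
        outputs.append(
            _gene_pvalue_output(mid, cfg, universe, drivers, rare, rng)
        )

    modules = _planted_modules(cfg, drivers_list, passengers, rng)
    fln = _module_network(cfg, universe, modules, drivers, rng)
    hin = _module_network(cfg, universe, modules, drivers, rng)

    def _retained(gene: str) -> bool:
        if gene in rare:
            return True
        p = cfg.module_recall if gene in drivers else cfg.filler_retention
        return bool(rng.random() < p)

    # FLN-style ranked list: genes ordered by total FLN weight to drivers
    adj: dict[str, dict[str, float]] = {}
    for (a, b), w in fln.items():
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w
    linkage = {
        g: sum(w for nb, w in adj.get(g, {}).items() if nb in drivers)
        for g in universe
    }
    top100 = sorted(universe, key=lambda g: (-linkage[g], g))[:100]
    outputs.append(
        MethodOutput(
            method_id="fln",
            kind=RANKED_LIST,
            network=fln,
            top_genes=top100,
        )
    )

    def method_view() -> list[set[str]]:
        view = [{g for g in module if _retained(g)} for module in modules]
        return [m for m in view if m]

    for mid in ("netbox", "memo", "dendrix"):
        outputs.append(
            MethodOutput(
                method_id=mid, kind=MODULE_COUNT, modules=method_view(), network=hin
            )
        )
    outputs.append(
        MethodOutput(
            method_id="flnp", kind=MODULE_WEIGHTED, modules=method_view(), network=fln
        )
    )

    maf = _simulate_maf(cfg, universe, drivers, rare, rng)
    return SyntheticCohort(
        config=cfg,
        outputs=outputs,
        maf=maf,
        universe=universe,
        drivers=drivers,
        rare_drivers=rare & drivers,
    )


def rare_driver_scenario(cfg: SyntheticConfig, n_rare: int = 5) -> SyntheticCohort:
    """Cohort in which a subset of drivers is nearly invisible at gene level.

    Rare drivers mutate at the passenger rate, draw non-significant
    P-values from the gene-level methods, but always join their modules —
    the regime in which integrating module evidence should recover drivers
    the per-gene statistics miss. Rare drivers are excluded from
    ``known_drivers`` (the training positives), emulating true drivers that
    are absent from annotation catalogs.
    """
    if n_rare < 0 or n_rare > cfg.n_drivers:
        raise ValueError(f"n_rare must lie in [0, {cfg.n_drivers}]")
    if n_rare == 0:
        return simulate_cohort(cfg)
    pre_rng = np.random.default_rng(cfg.seed)
    driver_idx = pre_rng.choice(cfg.n_genes, size=cfg.n_drivers, replace=False)
    universe = _gene_ids(cfg.n_genes)
    drivers_list = sorted(universe[i] for i in driver_idx)
    # rare drivers are spread across modules (one per module of the planted
    # partition) so module evidence stays informative for each
    rare = set(drivers_list[:: max(1, cfg.n_drivers // n_rare)][:n_rare])
    return simulate_cohort(cfg, _rare=rare)


def cohort_training_set(
    cohort: SyntheticCohort,
    annotated: set[str] | None = None,
) -> TrainingSet:
    """Build the labeled training set the way the real pipeline would.

    Positives are the known (annotated) drivers; the negative pool applies
    the ≤1-mutated-sample rule to the cohort MAF, excluding every annotated
    gene. By default the annotation catalog is the full truth driver set,
    so unknown (rare) drivers can never be sampled as training negatives.
    """
    if annotated is None:
        annotated = set(cohort.drivers)
    features = build_feature_matrix(cohort.outputs, cohort.universe)
    pool = negative_candidates(
        cohort.maf, annotated=annotated, universe=cohort.universe
    )
    return TrainingSet(
        positives=set(cohort.known_drivers),
        negatives_pool=pool,
        features=features,
    )


# -- file output (the dialects the other modules read) ---------------------


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write all cohort files in the formats the readers expect, plus a
    ``methods.yaml`` manifest mapping method ids to kinds and files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for out in cohort.outputs:
        entry: dict[str, str] = {"kind": out.kind}
        if out.kind == GENE_PVALUE:
            path = outdir / f"{out.method_id}.pvalues.tsv"
            with open(path, "w") as fh:
                for g in sorted(out.pvalues):
                    fh.write(f"{g}\t{out.pvalues[g]:.6g}\n")
            entry["pvalues"] = path.name
        else:
            npath = outdir / f"{out.method_id}.network.tsv"
            with open(npath, "w") as fh:
                for (a, b), w in sorted(out.network.items()):
                    fh.write(f"{a}\t{b}\t{w:.6g}\n")
            entry["network"] = npath.name
            if out.kind == RANKED_LIST:
                tpath = outdir / f"{out.method_id}.top.txt"
                tpath.write_text("\n".join(out.top_genes) + "\n")
                entry["top_genes"] = tpath.name
            else:
                mpath = outdir / f"{out.method_id}.modules.tsv"
                with open(mpath, "w") as fh:
                    for i, module in enumerate(out.modules, start=1):
                        for g in sorted(module):
                            fh.write(f"M{i:03d}\t{g}\n")
                entry["modules"] = mpath.name
        manifest[out.method_id] = entry

    write_maf(cohort.maf, outdir / "cohort.maf")
    (outdir / "universe.txt").write_text("\n".join(cohort.universe) + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\tis_driver\tis_rare\n")
        for g in cohort.universe:
            fh.write(
                f"{g}\t{int(g in cohort.drivers)}\t{int(g in cohort.rare_drivers)}\n"
            )
    payload = {
        "config": cohort.config.__dict__,
        "cohort_size": cohort.maf.cohort_size,
        "methods": manifest,
    }
    (outdir / "methods.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))


def load_cohort_outputs(indir: str | Path) -> tuple[list[MethodOutput], list[str]]:
    """Read back method outputs and the gene universe written by
    :func:`write_cohort` (or hand-prepared files in the same layout)."""
    from .feature_engine import (
        read_edge_list,
        read_gene_list,
        read_module_file,
        read_pvalue_table,
    )

    indir = Path(indir)
    payload = yaml.safe_load((indir / "methods.yaml").read_text())
    outputs = []
    for mid, entry in payload["methods"].items():
        kind = entry["kind"]
        kwargs: dict = {}
        if kind == GENE_PVALUE:
            kwargs["pvalues"] = read_pvalue_table(indir / entry["pvalues"])
        else:
            kwargs["network"] = [
                (a, b, w) for (a, b), w in read_edge_list(indir / entry["network"]).items()
            ]
            if kind == RANKED_LIST:
                kwargs["top_genes"] = read_gene_list(indir / entry["top_genes"])
            else:
                kwargs["modules"] = read_module_file(indir / entry["modules"])
        outputs.append(MethodOutput(method_id=mid, kind=kind, **kwargs))
    universe = read_gene_list(indir / "universe.txt")
    return outputs, universe
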