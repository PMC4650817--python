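"""MAF-style somatic mutation tables: parsing, per-gene statistics, and the
rarely-mutated negative-candidate rule.

Only three MAF columns matter here: Hugo_Symbol, Tumor_Sample_Barcode and
Variant_Classification. A mutation is *silent* iff its classification is
``Silent``; everything else (missense, nonsense, splice, indels, ...) counts
as non-silent. Per-gene mutation rates are the fraction of cohort samples
carrying at least one non-silent mutation in the gene; the cohort size is an
explicit parameter (the number of sequenced patients, which may exceed the
number of samples with any mutation) and is never inferred silently.

Negative training candidates are genes mutated in at most one sample across
the cohort and not annotated as cancer-related in any catalog — genes almost
certainly too rarely hit to be drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .feature_engine import normalize_gene

__all__ = [
    "MutationTable",
    "GeneMutationStats",
    "read_maf",
    "write_maf",
    "gene_stats",
    "negative_candidates",
]

REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")
SILENT = "Silent"


@dataclass
class MutationTable:
    """Somatic mutation records (gene, sample, variant classification)."""

    records: list[tuple[str, str, str]]
    cohort_size: int

    def __post_init__(self) -> None:
        self.records = [
            (normalize_gene(g), str(s), str(vc)) for g, s, vc in self.records
        ]
        for g, s, vc in self.records:
            if not vc:
                raise ValueError(f"empty Variant_Classification for gene {g!r}")
        n_samples = len({s for _, s, _ in self.records})
        if self.cohort_size < n_samples:
            raise ValueError(
                f"cohort_size {self.cohort_size} smaller than the "
                f"{n_samples} distinct samples present"
            )

    @property
    def genes(self) -> set[str]:
        return {g for g, _, _ in self.records}

    @property
    def samples(self) -> set[str]:
        return {s for _, s, _ in self.records}

    def mutated_sample_counts(self) -> dict[str, int]:
        """Distinct mutated samples per gene (any classification)."""
        seen: dict[str, set[str]] = {}
        for g, s, _ in self.records:
            seen.setdefault(g, set()).add(s)
        return {g: len(ss) for g, ss in seen.items()}

    def record_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g, _, _ in self.records:
            out[g] = out.get(g, 0) + 1
        return out


@dataclass
class GeneMutationStats:
    gene: str
    mutated_samples: int
    nonsilent_count: int
    silent_count: int
    rate: float

    @property
    def rate_display(self) -> float:
        """Rate rounded to 4 decimals, as printed in reports."""
        return round(self.rate, 4)


def read_maf(path: str | Path, cohort_size: int | None = None) -> MutationTable:
    """Parse a TCGA-dialect MAF (tab-separated, '#' comment lines).

    Only the three required columns are used; extra columns are ignored.
    ``cohort_size`` defaults to the number of distinct samples in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"MAF {path} is missing required column(s): {', '.join(missing)}"
        )
    records = list(
        zip(
            df["Hugo_Symbol"].astype(str),
            df["Tumor_Sample_Barcode"].astype(str),
            df["Variant_Classification"].astype(str),
        )
    )
    if cohort_size is None:
        cohort_size = len({s for _, s, _ in records})
    return MutationTable(records=records, cohort_size=cohort_size)


def write_maf(table: MutationTable, path: str | Path) -> None:
    """Serialize the three required columns, record for record."""
    df = pd.DataFrame(table.records, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def gene_stats(
    table: MutationTable, gene: str, cohort_size: int | None = None
) -> GeneMutationStats:
    """Per-gene mutation statistics.

    ``rate`` is the fraction of cohort samples carrying at least one
    non-silent mutation in the gene. An unknown gene yields all-zero stats.
    """
    if cohort_size is None:
        cohort_size = table.cohort_size
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    gene = normalize_gene(gene)
    silent = 0
    nonsilent = 0
    samples: set[str] = set()
    nonsilent_samples: set[str] = set()
    for g, s, vc in table.records:
        if g != gene:
            continue
        samples.add(s)
        if vc == SILENT:
            silent += 1
        else:
            nonsilent += 1
            nonsilent_samples.add(s)
    return GeneMutationStats(
        gene=gene,
        mutated_samples=len(samples),
        nonsilent_count=nonsilent,
        silent_count=silent,
        rate=len(nonsilent_samples) / cohort_size,
    )


def negative_candidates(
    table: MutationTable,
    annotated: Iterable[str],
    universe: Sequence[str],
    max_mutated: int = 1,
    require_observed: bool = True,
    count_records: bool = False,
) -> set[str]:
    """Universe genes mutated in at most ``max_mutated`` samples and absent
    from every cancer-gene annotation catalog.

    By default only genes with at least one MAF record qualify (they are
    demonstrably sequenced); set ``require_observed=False`` to also admit
    universe genes with no mutations at all. ``count_records=True`` switches
    the rule from distinct mutated samples to raw record counts.
    """
    if not universe:
        raise ValueError("gene universe is empty")
    annotated_set = {normalize_gene(g) for g in annotated}
    counts = (
        table.record_counts() if count_records else table.mutated_sample_counts()
    )
    out: set[str] = set()
    for gene in universe:
        gene = normalize_gene(gene)
        n = counts.get(gene, 0)
        if require_observed and gene not in counts:
            continue
        if n <= max_mutated and gene not in annotated_set:
            out.add(gene)
    return out
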