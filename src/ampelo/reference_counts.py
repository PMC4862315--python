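"""Published summary counts for the grapevine compendium build.

These are the printed per-platform sample counts and dense-platform design
figures reported for the public grapevine (*Vitis vinifera*) expression
compendium this package models its pipeline on.  They serve as arithmetic
cross-checks: the platform table must sum to the reported compendium size,
and the dense oligo platform's probe and gene-prediction counts must
reproduce its reported coverage and probes-per-gene figures.
"""

from __future__ import annotations

# (platform name, technology, number of samples)
PLATFORM_SAMPLE_COUNTS: list[tuple[str, str, int]] = [
    ("NimbleGen 090918 vitus vinifera exp HX12", "microarray", 583),
    ("Affymetrix V. vinifera (grape) genome array", "microarray", 502),
    ("Affymetrix GrapeGen V. vinifera GrapeGena520510F", "microarray", 219),
    ("INRA V. vinifera oligo array 15K v3", "microarray", 100),
    ("Combimatrix GrapeArray 1.2", "microarray", 69),
    ("Illumina HiSeq 1000", "rna-seq", 60),
    ("Illumina HiSeq 2500", "rna-seq", 36),
    ("AB 5500 xl genetic analyzer", "rna-seq", 20),
    ("Illumina HiSeq 2000", "rna-seq", 12),
    ("Illumina genome analyzer IIx", "rna-seq", 7),
]

# Dense 60-mer oligo platform design: probe count, gene predictions it
# measures, and the total gene predictions in the reference annotation.
NIMBLEGEN_N_PROBES = 118015
NIMBLEGEN_GENES_MEASURED = 29549
ANNOTATION_GENE_PREDICTIONS = 29971


def total_samples(
    table: list[tuple[str, str, int]] | None = None
) -> int:
    """Total samples across all platforms (microarray + sequencing)."""
    rows = PLATFORM_SAMPLE_COUNTS if table is None else table
    return sum(n for _, _, n in rows)


def microarray_sample_fraction(
    table: list[tuple[str, str, int]] | None = None
) -> float:
    """Fraction of samples measured on microarray platforms."""
    rows = PLATFORM_SAMPLE_COUNTS if table is None else table
    micro = sum(n for _, kind, n in rows if kind == "microarray")
    return micro / total_samples(rows)


def gene_coverage_pct(
    measured: int = NIMBLEGEN_GENES_MEASURED,
    total: int = ANNOTATION_GENE_PREDICTIONS,
) -> float:
    """Percent of annotated gene predictions the platform measures."""
    return 100.0 * measured / total


def probes_per_gene(
    n_probes: int = NIMBLEGEN_N_PROBES,
    genes_measured: int = NIMBLEGEN_GENES_MEASURED,
) -> float:
    """Average probes per measured gene prediction."""
    return n_probes / genes_measured
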