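"""Probe-to-transcript alignment and two-tier mapping decisions.

Short oligonucleotide probes are aligned against an up-to-date transcript
set and filtered in two tiers:

* a *strong* (restrictive) tier keeps near-perfect hits — the probe can in
  principle measure that gene;
* a *weak* (relaxed) tier keeps hits with a few more substitutions — the
  probe cannot measure that gene reliably, but may pick up its signal
  through cross-hybridization.

A probe whose surviving hits touch a single gene at the strong tier, and no
other gene at either tier, maps *uniquely*.  A probe touching two or more
genes is *ambiguous*: it measures none of them individually.  Probes with no
strong hit at all are *unmapped*.  Ambiguity is defined at the gene level —
multiple placements within one gene never make a probe ambiguous.

Alignments can either be parsed from a 12-column tabular report (the
standard BLAST ``outfmt 6`` dialect) produced by an external aligner, or
computed by the built-in full-length ungapped aligner
(:func:`kmismatch_align`), which is exact and sufficient for short probes
against small transcript sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentFormatError(ValueError):
    """A tabular alignment record could not be parsed."""


@dataclass(frozen=True)
class ProbeRecord:
    """One microarray probe: identifier, platform and sequence."""

    probe_id: str
    platform_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(
                f"probe {self.probe_id}: sequence shorter than 15 nt"
            )
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"probe {self.probe_id}: non-nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped local alignment of a probe against a transcript.

    Coordinates are 1-based inclusive on the transcript; ``strand`` is '-'
    when the probe matches the reverse complement of the region.
    """

    probe_id: str
    gene_id: str
    mismatches: int
    aligned_length: int
    probe_length: int
    strand: str
    gene_start: int
    gene_end: int
    identity_pct: float

    def __post_init__(self) -> None:
        if self.aligned_length > self.probe_length:
            raise ValueError(
                f"hit {self.probe_id}->{self.gene_id}: aligned_length "
                f"{self.aligned_length} exceeds probe_length {self.probe_length}"
            )
        if self.gene_start > self.gene_end:
            raise ValueError(
                f"hit {self.probe_id}->{self.gene_id}: gene_start > gene_end"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TierThresholds:
    """Mismatch and coverage cut-offs for the two filtering tiers.

    Defaults mirror the three mismatch classes used when diagnosing probe
    sharing on dense oligo platforms: perfect/one-mismatch hits are strong,
    two-or-three-mismatch hits are weak (cross-hybridization candidates),
    anything beyond is discarded.  All values are per-platform configurable;
    the weak tier is a substitution-count surrogate for whatever relaxed
    score an external aligner would use.
    """

    strong_max_mismatch: int = 1
    weak_max_mismatch: int = 3
    min_coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.strong_max_mismatch > self.weak_max_mismatch:
            raise ValueError(
                "strong_max_mismatch must not exceed weak_max_mismatch"
            )
        if not 0.0 < self.min_coverage_fraction <= 1.0:
            raise ValueError("min_coverage_fraction must be in (0, 1]")


@dataclass(frozen=True)
class MappingDecision:
    """Final per-probe call: unmapped, unique, or ambiguous.

    ``strong_genes`` are genes hit at the strong tier; ``weak_genes`` are
    genes hit *only* at the weak tier.
    """

    probe_id: str
    status: str  # unmapped | unique | ambiguous
    strong_genes: frozenset[str] = field(default_factory=frozenset)
    weak_genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def gene_ids(self) -> frozenset[str]:
        """All genes the probe may report on (strong plus weak)."""
        return self.strong_genes | self.weak_genes


def parse_alignment_table(lines: Iterable[str]) -> list[AlignmentHit]:
    """Parse 12-column tabular alignment records into :class:`AlignmentHit`.

    Columns: query, subject, identity%, aligned length, mismatches, gap
    opens, qstart, qend, sstart, send, evalue, bitscore.  Strand is inferred
    from the subject coordinate order; hits containing gap opens are dropped
    (tier filtering is substitution-only).  ``probe_length`` is taken as the
    largest query coordinate seen for the probe, a lower bound that is exact
    for full-length hits.

    Raises :class:`AlignmentFormatError` naming the offending line on a
    wrong field count or a non-numeric numeric field.
    """
    raw: list[tuple] = []
    max_qpos: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate space-separated tables
            fields = line.split()
        if len(fields) != 12:
            raise AlignmentFormatError(
                f"line {lineno}: expected 12 fields, got {len(fields)}"
            )
        try:
            query, subject = fields[0], fields[1]
            identity = float(fields[2])
            length = int(fields[3])
            mismatches = int(fields[4])
            gapopen = int(fields[5])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
        except ValueError as exc:
            raise AlignmentFormatError(
                f"line {lineno}: non-numeric value in numeric field ({exc})"
            ) from None
        max_qpos[query] = max(max_qpos.get(query, 0), qstart, qend)
        if gapopen > 0:
            continue
        raw.append((query, subject, identity, length, mismatches, sstart, send))

    hits = []
    for query, subject, identity, length, mismatches, sstart, send in raw:
        strand = "+" if sstart <= send else "-"
        start, end = min(sstart, send), max(sstart, send)
        hits.append(
            AlignmentHit(
                probe_id=query,
                gene_id=subject,
                mismatches=mismatches,
                aligned_length=length,
                probe_length=max(max_qpos[query], length),
                strand=strand,
                gene_start=start,
                gene_end=end,
                identity_pct=identity,
            )
        )
    return hits


def format_alignment_table(hits: Iterable[AlignmentHit]) -> str:
    """Render hits back to the 12-column tabular dialect (one line each)."""
    out = []
    for h in hits:
        if h.strand == "+":
            sstart, send = h.gene_start, h.gene_end
        else:
            sstart, send = h.gene_end, h.gene_start
        out.append(
            "\t".join(
                [
                    h.probe_id,
                    h.gene_id,
                    f"{h.identity_pct:.2f}",
                    str(h.aligned_length),
                    str(h.mismatches),
                    "0",
                    "1",
                    str(h.aligned_length),
                    str(sstart),
                    str(send),
                    "0.0",
                    "0.0",
                ]
            )
        )
    return "\n".join(out) + ("\n" if out else "")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def kmismatch_align(
    probe: ProbeRecord,
    transcripts: Mapping[str, str],
    max_mismatch: int,
) -> list[AlignmentHit]:
    """Exact full-length ungapped alignment of a probe against transcripts.

    Returns every placement of the whole probe, on either strand, with
    Hamming distance ≤ ``max_mismatch``.  ``N`` matches nothing, including
    another ``N``.  Probes longer than a transcript simply yield no hit on
    it.  Hits are ordered by gene id, then transcript start, then strand.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not transcripts:
        raise ValueError("transcripts must be non-empty")

    plen = len(probe.sequence)
    fwd = _encode(probe.sequence)
    rev = _encode(reverse_complement(probe.sequence))
    n_code = ord("N")
    hits: list[AlignmentHit] = []
    for gene_id in sorted(transcripts):
        tseq = _encode(transcripts[gene_id])
        tlen = len(tseq)
        if plen > tlen:
            continue
        # all windows of length plen as a (n_windows, plen) strided view
        windows = np.lib.stride_tricks.sliding_window_view(tseq, plen)
        for strand, query in (("+", fwd), ("-", rev)):
            mism = (windows != query) | (windows == n_code) | (query == n_code)
            counts = mism.sum(axis=1)
            for offset in np.flatnonzero(counts <= max_mismatch):
                mm = int(counts[offset])
                hits.append(
                    AlignmentHit(
                        probe_id=probe.probe_id,
                        gene_id=gene_id,
                        mismatches=mm,
                        aligned_length=plen,
                        probe_length=plen,
                        strand=strand,
                        gene_start=int(offset) + 1,
                        gene_end=int(offset) + plen,
                        identity_pct=100.0 * (plen - mm) / plen,
                    )
                )
    hits.sort(key=lambda h: (h.gene_id, h.gene_start, h.strand))
    return hits


def tier_hits(
    hits: Iterable[AlignmentHit],
    thresholds: TierThresholds = TierThresholds(),
) -> dict[str, tuple[list[AlignmentHit], list[AlignmentHit]]]:
    """Split each probe's hits into (strong, weak) tiers.

    A hit must cover at least ``min_coverage_fraction`` of the probe to
    survive at all; it is strong when ``mismatches <= strong_max_mismatch``,
    weak when it only satisfies the relaxed ``weak_max_mismatch`` bound, and
    discarded otherwise.  Per probe and gene only the best hit is kept
    (fewest mismatches, ties broken by smallest transcript start), so
    repeated placements within one gene collapse to a single tiered hit.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        if hit.mismatches > thresholds.weak_max_mismatch:
            continue
        if hit.aligned_length < thresholds.min_coverage_fraction * hit.probe_length:
            continue
        key = (hit.probe_id, hit.gene_id)
        prev = best.get(key)
        if prev is None or (hit.mismatches, hit.gene_start) < (
            prev.mismatches,
            prev.gene_start,
        ):
            best[key] = hit

    tiered: dict[str, tuple[list[AlignmentHit], list[AlignmentHit]]] = {}
    for (probe_id, _), hit in sorted(
        best.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        strong, weak = tiered.setdefault(probe_id, ([], []))
        if hit.mismatches <= thresholds.strong_max_mismatch:
            strong.append(hit)
        else:
            weak.append(hit)
    return tiered


def decide_mapping(
    tiered: Mapping[str, tuple[list[AlignmentHit], list[AlignmentHit]]],
    all_probe_ids: Iterable[str] | None = None,
) -> list[MappingDecision]:
    """Turn tiered hit sets into one mapping decision per probe.

    * no strong gene → ``unmapped`` (weak-only probes cannot measure
      anything reliably and are not kept as ambiguous);
    * exactly one strong gene and no *other* weak gene → ``unique``;
    * two or more genes overall (≥2 strong, or one strong plus a distinct
      weak cross-hybridization target) → ``ambiguous``.

    ``all_probe_ids``, when given, adds explicit ``unmapped`` decisions for
    probes absent from ``tiered`` so that statuses partition the probe set.
    """
    decisions: dict[str, MappingDecision] = {}
    for probe_id in sorted(tiered):
        strong_hits, weak_hits = tiered[probe_id]
        strong = frozenset(h.gene_id for h in strong_hits)
        weak = frozenset(h.gene_id for h in weak_hits) - strong
        if not strong:
            decisions[probe_id] = MappingDecision(probe_id, "unmapped")
        elif len(strong) == 1 and not weak:
            decisions[probe_id] = MappingDecision(probe_id, "unique", strong)
        else:
            decisions[probe_id] = MappingDecision(
                probe_id, "ambiguous", strong, weak
            )
    if all_probe_ids is not None:
        for probe_id in all_probe_ids:
            if probe_id not in decisions:
                decisions[probe_id] = MappingDecision(probe_id, "unmapped")
    return [decisions[p] for p in sorted(decisions)]


def write_decisions_tsv(decisions: Iterable[MappingDecision]) -> str:
    """Serialize decisions as TSV: probe_id, status, strong and weak genes."""
    lines = ["probe_id\tstatus\tstrong_genes\tweak_genes"]
    for d in decisions:
        lines.append(
            "\t".join(
                [
                    d.probe_id,
                    d.status,
                    ";".join(sorted(d.strong_genes)),
                    ";".join(sorted(d.weak_genes)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_decisions_tsv(text: str) -> list[MappingDecision]:
    """Inverse of :func:`write_decisions_tsv`."""
    decisions = []
    lines = text.splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        probe_id, status, strong, weak = line.split("\t")
        decisions.append(
            MappingDecision(
                probe_id,
                status,
                frozenset(g for g in strong.split(";") if g),
                frozenset(g for g in weak.split(";") if g),
            )
        )
    return decisions
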