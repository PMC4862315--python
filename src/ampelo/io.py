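"""File ingestion helpers shared by the CLI: FASTA and probe tables."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from ampelo.probe_alignment import ProbeRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_probes_tsv(path: str | Path) -> list[ProbeRecord]:
    """Read probes from TSV with columns probe_id, platform_id, sequence."""
    probes: list[ProbeRecord] = []
    seen: set[tuple[str, str]] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("probe_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"probe rows need 3 fields, got {len(parts)}: {line!r}")
        probe_id, platform_id, seq = parts
        key = (platform_id, probe_id)
        if key in seen:
            raise ValueError(f"duplicate probe id {probe_id!r} on {platform_id!r}")
        seen.add(key)
        probes.append(ProbeRecord(probe_id, platform_id, seq))
    return probes


def read_probes_fasta(path: str | Path, platform_id: str) -> list[ProbeRecord]:
    """Read probes from FASTA; all records get the given platform id."""
    return [
        ProbeRecord(pid, platform_id, seq)
        for pid, seq in read_fasta(path).items()
    ]
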