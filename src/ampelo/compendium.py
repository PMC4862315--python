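"""Sample summarization, log2 contrasts and the multi-platform matrix.

Inputs are assumed to be normalized log2 signals (microarray intensities
after within-platform normalization, or precomputed per-gene log2
abundances for sequencing samples); normalization and quality control
themselves are delegated upstream.  Probe signals are summarized to
measurable-transcript level, test and reference samples of the same
experiment are combined into log2-ratio *contrasts* (positive = up in
test), and the contrasts of all platforms are assembled column-wise into
one matrix with explicit missing values wherever a platform cannot measure
a transcript.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ampelo.gene_clusters import MeasurableTranscript
from ampelo.probe_alignment import MappingDecision

logger = logging.getLogger(__name__)


@dataclass
class SampleProfile:
    """Per-sample log2 signal for every measurable the platform can see."""

    sample_id: str
    platform_id: str
    values: dict[str, float]  # measurable_id -> log2 signal; absent = missing


@dataclass
class Contrast:
    """log2(test/reference) vector for one test/reference sample pair."""

    contrast_id: str
    test_sample_id: str
    reference_sample_id: str
    M: dict[str, float]  # measurable_id -> log2 ratio; absent = missing
    platform_id: str = ""


@dataclass
class Compendium:
    """Measurables x contrasts matrix with missing entries.

    ``matrix`` is a float DataFrame (NaN = missing) whose rows follow the
    measurable list and whose columns follow contrast input order;
    ``platforms`` tags each contrast column with its platform.
    """

    matrix: pd.DataFrame
    platforms: dict[str, str] = field(default_factory=dict)

    @property
    def missing_fraction(self) -> float:
        total = self.matrix.size
        if total == 0:
            return 0.0
        return float(self.matrix.isna().to_numpy().sum()) / total

    @property
    def measurable_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def contrast_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def to_tsv(self) -> str:
        """TSV matrix with 'NA' for missing cells (round-trip exact)."""
        buf = StringIO()
        out = self.matrix.copy()
        out.index.name = "measurable_id"
        out.to_csv(buf, sep="\t", na_rep="NA", float_format="%.10g")
        return buf.getvalue()

    def sidecar_json(self) -> str:
        """JSON sidecar: platform per contrast and the missing fraction."""
        return json.dumps(
            {
                "platforms": {c: self.platforms.get(c, "") for c in self.contrast_ids},
                "missing_fraction": self.missing_fraction,
                "n_measurables": len(self.measurable_ids),
                "n_contrasts": len(self.contrast_ids),
            },
            indent=2,
            sort_keys=True,
        ) + "\n"

    @classmethod
    def from_tsv(
        cls, text: str, platforms: Mapping[str, str] | None = None
    ) -> "Compendium":
        df = pd.read_csv(
            StringIO(text), sep="\t", index_col=0, na_values=["NA"],
            keep_default_na=False,
        )
        df = df.astype(float)
        df.index.name = None
        return cls(df, dict(platforms or {}))


def summarize_sample(
    probe_values: Mapping[str, float],
    decisions: Iterable[MappingDecision],
    measurables: Sequence[MeasurableTranscript],
    method: str = "median",
    sample_id: str = "",
    platform_id: str = "",
) -> SampleProfile:
    """Collapse probe-level log2 signals to measurable-transcript level.

    A singleton measurable takes the ``method`` (median by default, mean
    optional) of its uniquely mapping probes.  A cluster measurable takes
    the method over *all* probes — unique or ambiguous — whose entire gene
    set lies within the cluster: shared probes are kept as a measurement of
    the cluster as a whole instead of being discarded.  Ambiguous probes
    whose gene set straddles measurables contribute nowhere (logged), as do
    probe ids absent from the decisions.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown summarization method {method!r}")
    reduce = np.median if method == "median" else np.mean

    gene_to_measurable = {
        gene: m.measurable_id for m in measurables for gene in m.member_gene_ids
    }
    decision_by_probe = {d.probe_id: d for d in decisions}

    contributions: dict[str, list[float]] = {}
    for probe_id in sorted(probe_values):
        d = decision_by_probe.get(probe_id)
        if d is None:
            logger.warning("probe %s not in mapping decisions; ignored", probe_id)
            continue
        if d.status == "unmapped":
            continue
        targets = {gene_to_measurable.get(g) for g in d.gene_ids}
        if len(targets) != 1 or None in targets:
            logger.warning(
                "probe %s spans multiple measurables; contributes nowhere",
                probe_id,
            )
            continue
        (target,) = targets
        contributions.setdefault(target, []).append(float(probe_values[probe_id]))

    values = {
        m.measurable_id: float(reduce(contributions[m.measurable_id]))
        for m in measurables
        if m.measurable_id in contributions
    }
    return SampleProfile(sample_id=sample_id, platform_id=platform_id, values=values)


def make_contrast(
    test: SampleProfile,
    reference: SampleProfile,
    contrast_id: str,
) -> Contrast:
    """Form the log2 ratio vector M = test − reference (both already log2).

    Entries missing in either profile are missing in M.  Positive values
    mean up-regulation in the test sample.
    """
    if test.sample_id == reference.sample_id:
        raise ValueError(
            f"contrast {contrast_id}: test and reference are the same sample "
            f"({test.sample_id})"
        )
    shared = sorted(test.values.keys() & reference.values.keys())
    M = {m: test.values[m] - reference.values[m] for m in shared}
    return Contrast(
        contrast_id=contrast_id,
        test_sample_id=test.sample_id,
        reference_sample_id=reference.sample_id,
        M=M,
        platform_id=test.platform_id,
    )


def antisymmetry_check(
    test: SampleProfile, reference: SampleProfile, tol: float = 0.0
) -> bool:
    """Whether swapping test and reference exactly negates the contrast."""
    fwd = make_contrast(test, reference, "fwd").M
    rev = make_contrast(reference, test, "rev").M
    if fwd.keys() != rev.keys():
        return False
    return all(abs(fwd[m] + rev[m]) <= tol for m in fwd)


def assemble_compendium(
    contrasts: Sequence[Contrast],
    measurables: Sequence[MeasurableTranscript],
) -> Compendium:
    """Stack contrast columns into the full measurables x contrasts matrix.

    Rows follow the measurable list, columns follow input order; any cell a
    contrast's platform did not measure is NaN.  Duplicate contrast ids are
    an error.
    """
    ids = [c.contrast_id for c in contrasts]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate contrast ids: {sorted(dupes)}")
    index = [m.measurable_id for m in measurables]
    if len(set(index)) != len(index):
        raise ValueError("duplicate measurable ids")

    matrix = pd.DataFrame(np.nan, index=index, columns=ids, dtype=float)
    for c in contrasts:
        col = pd.Series(c.M, dtype=float).reindex(index)
        matrix[c.contrast_id] = col
    platforms = {c.contrast_id: c.platform_id for c in contrasts}
    return Compendium(matrix, platforms)


def read_probe_values_tsv(text: str) -> dict[str, float]:
    """Parse a per-sample probe value TSV (probe_id, value; header optional)."""
    values: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        probe_id, raw = line.split("\t")[:2]
        if probe_id == "probe_id":
            continue
        values[probe_id] = float(raw)
    return values


def write_probe_values_tsv(values: Mapping[str, float]) -> str:
    lines = ["probe_id\tvalue"]
    for probe_id in sorted(values):
        v = values[probe_id]
        lines.append(f"{probe_id}\t{v:.10g}" if math.isfinite(v) else f"{probe_id}\tNA")
    return "\n".join(lines) + "\n"


def read_pairings_tsv(text: str) -> list[tuple[str, str, str, str]]:
    """Parse contrast pairings: contrast_id, test, reference, experiment."""
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("contrast_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(
                f"pairing rows need 4 tab-separated fields, got {len(parts)}: "
                f"{line!r}"
            )
        rows.append((parts[0], parts[1], parts[2], parts[3]))
    return rows


def write_pairings_tsv(rows: Iterable[tuple[str, str, str, str]]) -> str:
    lines = ["contrast_id\ttest_sample\treference_sample\texperiment_id"]
    for r in rows:
        lines.append("\t".join(r))
    return "\n".join(lines) + "\n"
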