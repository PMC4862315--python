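"""Synthetic platforms and expression data with known ground truth.

The generator emulates the structure a probe-remapping pipeline faces on a
real crop-species platform: a transcript set containing *gene families*
(mutated copies of a common ancestor, the source of shared probes and hence
of ambiguity clusters), a dense short-oligo design of four 60-mer probes
per gene drawn from the sense strand (a configurable fraction stored
reverse-complemented), and test/reference sample pairs whose log2 signals
carry planted condition-specific effects on known gene sets plus
independent probe-level Gaussian noise.

Ground truth is computed by an intentionally simple, separate route — a
positional Hamming scan over both strands plus union-find transitive
closure — so pipeline results can be checked against it rather than
against the pipeline itself.

Everything is driven by a mandatory seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ampelo.probe_alignment import (
    AlignmentHit,
    ProbeRecord,
    TierThresholds,
    reverse_complement,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedModule:
    """A known co-expression signal: gene ids x contrast ids, log2 effect."""

    gene_ids: tuple[str, ...]
    contrast_ids: tuple[str, ...]
    effect: float


@dataclass
class FixtureConfig:
    """Parameters of one synthetic platform + expression study.

    Defaults emulate a dense grapevine-style oligo design: 60 nt probes,
    four per gene, 1 kb transcripts.  ``families`` plants groups of
    near-identical genes ((size, per-site substitution rate) each) that
    should be recovered as ambiguity clusters; remaining genes are
    independent random sequences and stay singletons.
    """

    n_genes: int = 24
    gene_length: int = 1000
    families: list[tuple[int, float]] = field(default_factory=list)
    probes_per_gene: int = 4
    probe_length: int = 60
    n_conditions: int = 10
    planted_modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    revcomp_fraction: float = 0.25
    seed: int = 0
    thresholds: TierThresholds = field(default_factory=TierThresholds)
    platform_id: str = "synth1"

    def __post_init__(self) -> None:
        if self.probe_length > self.gene_length:
            raise ValueError("probe_length exceeds gene_length")
        for size, rate in self.families:
            if size < 2:
                raise ValueError("family size must be >= 2")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("substitution rate must be in [0, 1]")
        if sum(size for size, _ in self.families) > self.n_genes:
            raise ValueError("families exceed n_genes")
        for name in ("n_genes", "gene_length", "probes_per_gene",
                     "probe_length", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.revcomp_fraction <= 1.0:
            raise ValueError("revcomp_fraction must be in [0, 1]")

    def gene_id(self, i: int) -> str:
        return f"g{i:04d}"

    def contrast_id(self, j: int) -> str:
        return f"c{j:04d}"


@dataclass
class SyntheticPlatform:
    transcripts: dict[str, str]
    probes: list[ProbeRecord]
    probe_source_gene: dict[str, str]
    true_partition: list[frozenset[str]]  # full partition incl. singletons

    @property
    def true_clusters(self) -> list[frozenset[str]]:
        return [p for p in self.true_partition if len(p) > 1]


@dataclass
class SyntheticExpression:
    sample_values: dict[str, dict[str, float]]  # sample -> probe -> log2
    pairings: list[tuple[str, str, str, str]]  # contrast, test, ref, expt
    planted_modules: list[PlantedModule]
    gene_effects: dict[tuple[str, str], float]  # (gene, contrast) -> effect


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, rate: float
) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = BASES[BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _hamming_profile(tseq: str, probe: str) -> np.ndarray:
    """Mismatch count of the probe at every offset of the transcript.

    Deliberately simple positional scan (one vector comparison per probe
    position), independent of the window-matrix aligner it cross-checks.
    """
    t = np.frombuffer(tseq.upper().encode(), dtype=np.uint8)
    p = np.frombuffer(probe.upper().encode(), dtype=np.uint8)
    n_off = len(t) - len(p) + 1
    if n_off <= 0:
        return np.empty(0, dtype=int)
    counts = np.zeros(n_off, dtype=int)
    for k in range(len(p)):
        counts += t[k:k + n_off] != p[k]
    return counts


def brute_force_gene_hits(
    probe_seq: str,
    transcripts: Mapping[str, str],
    max_mismatch: int,
) -> dict[str, int]:
    """gene -> best Hamming distance (both strands), kept if <= max_mismatch."""
    best: dict[str, int] = {}
    rc = reverse_complement(probe_seq)
    for gene, tseq in transcripts.items():
        dists = []
        for query in (probe_seq, rc):
            prof = _hamming_profile(tseq, query)
            if prof.size:
                dists.append(int(prof.min()))
        if dists and min(dists) <= max_mismatch:
            best[gene] = min(dists)
    return best


class _UnionFind:
    def __init__(self, items: Sequence[str]) -> None:
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def true_partition_from_hits(
    probe_hits: Mapping[str, Mapping[str, int]],
    gene_ids: Sequence[str],
    thresholds: TierThresholds,
) -> list[frozenset[str]]:
    """Transitive closure of shared-probe ambiguity into a gene partition.

    A probe links genes when it has at least one strong-tier hit and at
    least two target genes overall (the same mapped/ambiguous semantics the
    pipeline applies, re-derived here from raw distances).
    """
    uf = _UnionFind(list(gene_ids))
    for hits in probe_hits.values():
        genes = sorted(hits)
        strong = [g for g in genes if hits[g] <= thresholds.strong_max_mismatch]
        if strong and len(genes) >= 2:
            for g in genes[1:]:
                uf.union(genes[0], g)
    groups: dict[str, set[str]] = {}
    for g in gene_ids:
        groups.setdefault(uf.find(g), set()).add(g)
    return sorted(
        (frozenset(v) for v in groups.values()), key=lambda s: min(s)
    )


def generate_platform(config: FixtureConfig) -> SyntheticPlatform:
    """Generate transcripts, probes and the ground-truth cluster partition."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [config.gene_id(i) for i in range(config.n_genes)]

    transcripts: dict[str, str] = {}
    idx = 0
    for size, rate in config.families:
        ancestor = _random_seq(rng, config.gene_length)
        for _ in range(size):
            seq = _mutate(rng, ancestor, rate)
            transcripts[gene_ids[idx]] = seq.tobytes().decode()
            idx += 1
    while idx < config.n_genes:
        transcripts[gene_ids[idx]] = _random_seq(
            rng, config.gene_length
        ).tobytes().decode()
        idx += 1

    probes: list[ProbeRecord] = []
    probe_source: dict[str, str] = {}
    for gene in gene_ids:
        seq = transcripts[gene]
        for k in range(config.probes_per_gene):
            offset = int(
                rng.integers(0, config.gene_length - config.probe_length + 1)
            )
            psec = seq[offset:offset + config.probe_length]
            if rng.random() < config.revcomp_fraction:
                psec = reverse_complement(psec)
            pid = f"{gene}_p{k + 1}"
            probes.append(ProbeRecord(pid, config.platform_id, psec))
            probe_source[pid] = gene

    probe_hits = {
        p.probe_id: brute_force_gene_hits(
            p.sequence, transcripts, config.thresholds.weak_max_mismatch
        )
        for p in probes
    }
    partition = true_partition_from_hits(
        probe_hits, gene_ids, config.thresholds
    )
    return SyntheticPlatform(transcripts, probes, probe_source, partition)


def simulate_expression(
    config: FixtureConfig,
    platform: SyntheticPlatform,
) -> SyntheticExpression:
    """Simulate probe-level log2 signals for paired test/reference samples.

    Each gene has a fixed log2 baseline; a contrast's reference sample
    reads baseline + noise at every probe, and the test sample additionally
    carries the planted per-gene effect on the planted contrasts.  Probes
    of one gene share the gene's latent value and differ only by
    independent Gaussian probe-level noise.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7])
    )
    gene_ids = [config.gene_id(i) for i in range(config.n_genes)]
    baseline = {
        g: config.baseline_mean + config.baseline_sd * rng.standard_normal()
        for g in gene_ids
    }
    effects: dict[tuple[str, str], float] = {}
    for mod in config.planted_modules:
        for g in mod.gene_ids:
            for c in mod.contrast_ids:
                effects[(g, c)] = effects.get((g, c), 0.0) + mod.effect

    sample_values: dict[str, dict[str, float]] = {}
    pairings: list[tuple[str, str, str, str]] = []
    for j in range(config.n_conditions):
        cid = config.contrast_id(j)
        test_id, ref_id = f"s{j:04d}t", f"s{j:04d}r"
        for sample_id, is_test in ((test_id, True), (ref_id, False)):
            values: dict[str, float] = {}
            for p in platform.probes:
                gene = platform.probe_source_gene[p.probe_id]
                latent = baseline[gene]
                if is_test:
                    latent += effects.get((gene, cid), 0.0)
                noise = (
                    config.noise_sd * rng.standard_normal()
                    if config.noise_sd > 0
                    else 0.0
                )
                values[p.probe_id] = latent + noise
            sample_values[sample_id] = values
        pairings.append((cid, test_id, ref_id, "expt1"))
    return SyntheticExpression(
        sample_values, pairings, list(config.planted_modules), effects
    )


# ---------------------------------------------------------------------------
# A hand-built four-gene cluster fixture.
#
# Four tandem gene-family members measured by four probes each; three
# probes align to a single gene without mismatch, every other probe also
# hits at least one further family member with 0-3 substitutions.  Run
# through the pipeline this must yield exactly three uniquely mapping
# probes and one four-gene cluster (mean probes per gene: 4).

_CLUSTER170_GENES = ("gA", "gB", "gC", "gD")
_CLUSTER170_HITS: list[tuple[str, str, int]] = [
    # probe, gene, mismatches
    ("pA1", "gA", 0),                      # unique
    ("pA2", "gA", 0), ("pA2", "gB", 0),
    ("pA3", "gA", 0), ("pA3", "gC", 1),
    ("pA4", "gA", 0), ("pA4", "gD", 2),
    ("pB1", "gB", 0),                      # unique
    ("pB2", "gB", 0), ("pB2", "gA", 1),
    ("pB3", "gB", 0), ("pB3", "gC", 0),
    ("pB4", "gB", 0), ("pB4", "gD", 3),
    ("pC1", "gC", 0),                      # unique
    ("pC2", "gC", 0), ("pC2", "gD", 0),
    ("pC3", "gC", 0), ("pC3", "gA", 2),
    ("pC4", "gC", 0), ("pC4", "gB", 1),
    ("pD1", "gD", 0), ("pD1", "gA", 0),
    ("pD2", "gD", 0), ("pD2", "gB", 2),
    ("pD3", "gD", 0), ("pD3", "gC", 3),
    ("pD4", "gD", 0), ("pD4", "gA", 3),
]
_CLUSTER170_PROBE_LEN = 60


@dataclass
class Cluster170Fixture:
    gene_ids: tuple[str, ...]
    probe_ids: tuple[str, ...]
    hits: list[AlignmentHit]


def cluster170_fixture() -> Cluster170Fixture:
    """Fixed 4-gene / 16-probe tandem-family ambiguity fixture."""
    hits = []
    for i, (probe, gene, mm) in enumerate(_CLUSTER170_HITS):
        plen = _CLUSTER170_PROBE_LEN
        start = 1 + 10 * i  # arbitrary but fixed placements
        hits.append(
            AlignmentHit(
                probe_id=probe,
                gene_id=gene,
                mismatches=mm,
                aligned_length=plen,
                probe_length=plen,
                strand="+",
                gene_start=start,
                gene_end=start + plen - 1,
                identity_pct=100.0 * (plen - mm) / plen,
            )
        )
    probe_ids = tuple(dict.fromkeys(p for p, _, _ in _CLUSTER170_HITS))
    return Cluster170Fixture(_CLUSTER170_GENES, probe_ids, hits)


# ---------------------------------------------------------------------------
# File emission: the exact text formats the pipeline consumes.


def write_fixture_bundle(
    config: FixtureConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Generate a platform + expression study and write all input files.

    Emits transcript FASTA, probe TSV, per-sample probe-value TSVs, the
    contrast pairing TSV, a small vocabulary TSV, sample annotation JSON,
    and ground-truth files (cluster partition, planted modules).  Returns
    the paths keyed by role.  Byte-reproducible for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    platform = generate_platform(config)
    expr = simulate_expression(config, platform)

    paths: dict[str, Path] = {}

    fasta = outdir / "transcripts.fasta"
    with open(fasta, "w") as fh:
        for gene in sorted(platform.transcripts):
            fh.write(f">{gene}\n")
            seq = platform.transcripts[gene]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["transcripts"] = fasta

    probes = outdir / "probes.tsv"
    with open(probes, "w") as fh:
        fh.write("probe_id\tplatform_id\tsequence\n")
        for p in platform.probes:
            fh.write(f"{p.probe_id}\t{p.platform_id}\t{p.sequence}\n")
    paths["probes"] = probes

    samples_dir = outdir / "samples"
    samples_dir.mkdir(exist_ok=True)
    from ampelo.compendium import write_pairings_tsv, write_probe_values_tsv

    for sample_id in sorted(expr.sample_values):
        path = samples_dir / f"{sample_id}.tsv"
        path.write_text(write_probe_values_tsv(expr.sample_values[sample_id]))
    paths["samples_dir"] = samples_dir

    pairings = outdir / "pairings.tsv"
    pairings.write_text(write_pairings_tsv(expr.pairings))
    paths["pairings"] = pairings

    vocab = outdir / "vocabulary.tsv"
    vocab.write_text(
        "term\tparent\n"
        "development\t\n"
        "developmental stage\tdevelopment\n"
        "tissue\t\n"
        "leaf\ttissue\n"
        "berry\ttissue\n"
        "abiotic treatment\t\n"
        "salt stress\tabiotic treatment\n"
        "biotic treatment\t\n"
        "infection\tbiotic treatment\n"
        "genotype\t\n"
        "cultivar\tgenotype\n"
    )
    paths["vocabulary"] = vocab

    planted_cids = {
        c for m in config.planted_modules for c in m.contrast_ids
    }
    annotations: dict[str, list] = {}
    for cid, test_id, ref_id, _ in expr.pairings:
        base = [["tissue", None], ["leaf", None], ["cultivar", "PN40024"]]
        ref_entries = base + [["developmental stage", 33]]
        if cid in planted_cids:
            test_entries = base + [
                ["developmental stage", 33],
                ["salt stress", "150 mM NaCl"],
            ]
        else:
            test_entries = base + [["developmental stage", 38]]
        annotations[test_id] = test_entries
        annotations[ref_id] = ref_entries
    ann_path = outdir / "annotations.json"
    ann_path.write_text(
        json.dumps(annotations, indent=2, sort_keys=True) + "\n"
    )
    paths["annotations"] = ann_path

    truth = outdir / "truth_partition.tsv"
    with open(truth, "w") as fh:
        fh.write("group_id\tgene_ids\n")
        for i, part in enumerate(platform.true_partition, start=1):
            fh.write(f"t{i:04d}\t{';'.join(sorted(part))}\n")
    paths["truth_partition"] = truth

    modules = outdir / "truth_modules.json"
    modules.write_text(
        json.dumps(
            [
                {
                    "gene_ids": list(m.gene_ids),
                    "contrast_ids": list(m.contrast_ids),
                    "effect": m.effect,
                }
                for m in config.planted_modules
            ],
            indent=2,
        )
        + "\n"
    )
    paths["truth_modules"] = modules
    return paths


# ---------------------------------------------------------------------------
# Planted-signal recovery study.


def planted_recovery_study(
    seed: int,
    n_replicates: int = 100,
    n_genes: int = 60,
    n_conditions: int = 50,
    effect: float = 2.0,
    noise_sd: float = 0.25,
    n_module_genes: int = 6,
    n_planted_contrasts: int = 5,
    top_k_check: int = 1,
) -> dict[str, int]:
    """Measure recovery of a planted module over seeded replicates.

    One synthetic platform (no families, so every gene is its own
    measurable) is generated from ``seed`` and reused; each replicate
    simulates fresh expression noise, builds the compendium through the
    full summarize/contrast/assemble path, and checks two retrievals:

    * *quicksearch*: querying the planted genes must rank a planted
      contrast first;
    * *co-expression*: a module seeded with half the planted genes (over
      all contrasts) must place every remaining planted partner within the
      top decile of the ranked candidate genes.

    Returns counts of successful replicates for both checks.
    """
    import dataclasses

    from ampelo.compendium import (
        assemble_compendium,
        make_contrast,
        summarize_sample,
    )
    from ampelo.gene_clusters import (
        build_ambiguity_graph,
        define_measurables,
        find_gene_clusters,
    )
    from ampelo.module_query import (
        make_module,
        quicksearch,
        rank_coexpressed_genes,
    )
    from ampelo.probe_alignment import decide_mapping, kmismatch_align, tier_hits

    planted_genes = tuple(f"g{i:04d}" for i in range(n_module_genes))
    planted_contrasts = tuple(f"c{j:04d}" for j in range(n_planted_contrasts))
    config = FixtureConfig(
        n_genes=n_genes,
        gene_length=300,
        n_conditions=n_conditions,
        noise_sd=noise_sd,
        planted_modules=[PlantedModule(planted_genes, planted_contrasts, effect)],
        seed=seed,
    )
    platform = generate_platform(config)
    hits = []
    for p in platform.probes:
        hits.extend(
            kmismatch_align(
                p, platform.transcripts, config.thresholds.weak_max_mismatch
            )
        )
    tiered = tier_hits(hits, config.thresholds)
    decisions = decide_mapping(tiered, [p.probe_id for p in platform.probes])
    clusters = find_gene_clusters(build_ambiguity_graph(decisions, tiered))
    measurables = define_measurables(sorted(platform.transcripts), clusters)

    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    quicksearch_hits = 0
    coexpression_hits = 0
    half = n_module_genes // 2
    for rep_seed in seeds:
        rep_config = dataclasses.replace(config, seed=int(rep_seed % 2**31))
        expr = simulate_expression(rep_config, platform)
        profiles = {
            s: summarize_sample(v, decisions, measurables, sample_id=s,
                                platform_id=config.platform_id)
            for s, v in expr.sample_values.items()
        }
        contrasts = [
            make_contrast(profiles[t], profiles[r], cid)
            for cid, t, r, _ in expr.pairings
        ]
        compendium = assemble_compendium(contrasts, measurables)

        top = quicksearch(
            compendium, list(planted_genes), top_k=top_k_check,
            measurables=measurables,
        )
        if any(c in planted_contrasts for c in top.contrast_ids):
            quicksearch_hits += 1

        module = make_module(
            compendium, list(planted_genes[:half]), compendium.contrast_ids
        )
        ranked = rank_coexpressed_genes(compendium, module)
        decile = max(1, int(0.1 * len(ranked)))
        positions = {g: i for i, (g, _) in enumerate(ranked)}
        partners = planted_genes[half:]
        if all(positions.get(g, len(ranked)) < decile for g in partners):
            coexpression_hits += 1
    return {
        "n_replicates": n_replicates,
        "quicksearch_top1": quicksearch_hits,
        "coexpression_top_decile": coexpression_hits,
    }
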