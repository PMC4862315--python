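import numpy as np
import pytest

from ampelo.gene_clusters import (
    build_ambiguity_graph,
    define_measurables,
    find_gene_clusters,
)
from ampelo.probe_alignment import (
    AlignmentHit,
    TierThresholds,
    decide_mapping,
    kmismatch_align,
    tier_hits,
)
from ampelo.synthetic import cluster170_fixture


def make_hit(probe, gene, mismatches=0, plen=60, start=1, strand="+"):
    """Convenience constructor for full-length test hits."""
    return AlignmentHit(
        probe_id=probe,
        gene_id=gene,
        mismatches=mismatches,
        aligned_length=plen,
        probe_length=plen,
        strand=strand,
        gene_start=start,
        gene_end=start + plen - 1,
        identity_pct=100.0 * (plen - mismatches) / plen,
    )


def run_mapping(hits, probe_ids=None, thresholds=TierThresholds()):
    """hits -> (tiered, decisions, graph, clusters)."""
    tiered = tier_hits(hits, thresholds)
    decisions = decide_mapping(tiered, probe_ids)
    graph = build_ambiguity_graph(decisions, tiered)
    clusters = find_gene_clusters(graph)
    return tiered, decisions, graph, clusters


@pytest.fixture
def cluster170():
    """The hand-built 4-gene / 16-probe tandem-family fixture, mapped."""
    fx = cluster170_fixture()
    tiered, decisions, graph, clusters = run_mapping(fx.hits, fx.probe_ids)
    return fx, tiered, decisions, graph, clusters


@pytest.fixture
def rng():
    return np.random.default_rng(20160510)


def random_profile_vectors(rng, n, length, missing_frac=0.2):
    """Pairs of random log-ratio vectors with NaN holes."""
    out = []
    for _ in range(n):
        x = rng.normal(0, 1.5, size=length)
        y = rng.normal(0, 1.5, size=length)
        for v in (x, y):
            holes = rng.random(length) < missing_frac
            v[holes] = np.nan
        out.append((x, y))
    return out
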