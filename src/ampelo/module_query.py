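"""Exploration engine: expression modules and the operations on them.

An *expression module* is a user-chosen submatrix of the compendium (a set
of measurable rows x a set of contrast columns).  Starting from a gene or
contrast list, modules are grown and shrunk by expression similarity rather
than sequence similarity:

* ``quicksearch`` retrieves the contrasts in which the query genes are most
  strongly modulated (largest mean absolute log-ratio);
* ``rank_coexpressed_genes`` / ``rank_similar_contrasts`` score candidate
  rows/columns against the module's mean profile by uncentered Pearson
  correlation — the natural similarity for log-ratio data, where the zero
  point (no change) is meaningful and must not be re-centered away;
* ``correlation_network`` thresholds all pairwise gene correlations;
* ``enrich_terms`` performs one-sided hypergeometric annotation-term
  enrichment with step-up (Benjamini–Hochberg) FDR control;
* ``order_by_expression`` arranges rows and columns by average-linkage
  clustering on correlation distance for heatmap display.

All correlations are computed over pairwise-complete positions and are
*undefined* (never silently zero) below a minimum overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ampelo.compendium import Compendium
from ampelo.gene_clusters import MeasurableTranscript

DEFAULT_MIN_OVERLAP = 10


@dataclass(frozen=True)
class CorrelationScore:
    """Uncentered Pearson correlation, or undefined (value=None)."""

    value: float | None
    n_overlap: int


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # module genes carrying the term
    K: int  # background genes carrying the term
    n: int  # module size
    N: int  # background size
    p_value: float
    fdr: float


@dataclass
class ExpressionModule:
    """A genes x contrasts submatrix view of a compendium."""

    gene_ids: list[str]
    contrast_ids: list[str]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in module")
        if len(set(self.contrast_ids)) != len(self.contrast_ids):
            raise ValueError("duplicate contrast ids in module")

    def mean_gene_profile(self) -> pd.Series:
        """Per-contrast mean over module genes, ignoring missing entries."""
        return self.values.mean(axis=0, skipna=True)

    def mean_contrast_profile(self) -> pd.Series:
        """Per-gene mean over module contrasts, ignoring missing entries."""
        return self.values.mean(axis=1, skipna=True)


def make_module(
    compendium: Compendium,
    gene_ids: Sequence[str],
    contrast_ids: Sequence[str],
) -> ExpressionModule:
    """Cut a module out of the compendium, validating ids."""
    missing_g = [g for g in gene_ids if g not in compendium.matrix.index]
    missing_c = [c for c in contrast_ids if c not in compendium.matrix.columns]
    if missing_g or missing_c:
        raise KeyError(
            f"unknown ids — genes: {missing_g}, contrasts: {missing_c}"
        )
    sub = compendium.matrix.loc[list(gene_ids), list(contrast_ids)]
    return ExpressionModule(list(gene_ids), list(contrast_ids), sub)


def extend_module(
    compendium: Compendium,
    module: ExpressionModule,
    genes: Sequence[str] = (),
    contrasts: Sequence[str] = (),
) -> ExpressionModule:
    """Return a new module with extra rows/columns appended (dedup, stable)."""
    g = module.gene_ids + [x for x in genes if x not in module.gene_ids]
    c = module.contrast_ids + [x for x in contrasts if x not in module.contrast_ids]
    return make_module(compendium, g, c)


def shrink_module(
    compendium: Compendium,
    module: ExpressionModule,
    genes: Sequence[str] = (),
    contrasts: Sequence[str] = (),
) -> ExpressionModule:
    """Return a new module with the named rows/columns removed."""
    g = [x for x in module.gene_ids if x not in set(genes)]
    c = [x for x in module.contrast_ids if x not in set(contrasts)]
    return make_module(compendium, g, c)


def uncentered_pearson(
    x: Sequence[float],
    y: Sequence[float],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CorrelationScore:
    """Uncentered Pearson r = Σxy / sqrt(Σx² · Σy²) over shared positions.

    Missing entries (NaN) are allowed in either vector; only pairwise
    complete positions contribute.  The score is undefined when fewer than
    ``min_overlap`` positions overlap or either vector is all-zero on the
    overlap.  Unlike the centered statistic, r keeps the origin fixed, so
    two profiles agreeing on *which* conditions deviate from no-change score
    highly even if their baselines differ.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    mask = ~(np.isnan(xa) | np.isnan(ya))
    n = int(mask.sum())
    if n < min_overlap:
        return CorrelationScore(None, n)
    xs, ys = xa[mask], ya[mask]
    sxx = float(np.dot(xs, xs))
    syy = float(np.dot(ys, ys))
    if sxx == 0.0 or syy == 0.0:
        return CorrelationScore(None, n)
    r = float(np.dot(xs, ys) / math.sqrt(sxx * syy))
    return CorrelationScore(max(-1.0, min(1.0, r)), n)


def resolve_genes_to_measurables(
    gene_ids: Sequence[str],
    compendium: Compendium,
    measurables: Sequence[MeasurableTranscript] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Map query gene ids to the measurable rows that carry them.

    A gene inside a cluster resolves to its cluster measurable; the
    returned notices dict records such redirections.  Unresolvable ids
    raise ``KeyError``.
    """
    rows = set(compendium.matrix.index)
    member_map: dict[str, str] = {}
    if measurables is not None:
        member_map = {
            g: m.measurable_id for m in measurables for g in m.member_gene_ids
        }
    resolved: list[str] = []
    notices: dict[str, str] = {}
    unknown: list[str] = []
    for g in gene_ids:
        if g in rows:
            target = g
        elif g in member_map and member_map[g] in rows:
            target = member_map[g]
            notices[g] = target
        else:
            unknown.append(g)
            continue
        if target not in resolved:
            resolved.append(target)
    if unknown:
        raise KeyError(f"query genes not resolvable to measurables: {unknown}")
    return resolved, notices


def quicksearch(
    compendium: Compendium,
    query_gene_ids: Sequence[str],
    top_k: int = 20,
    measurables: Sequence[MeasurableTranscript] | None = None,
    min_query_coverage: float = 0.5,
) -> ExpressionModule:
    """Retrieve the contrasts where the query genes are most modulated.

    Each contrast is scored by the mean absolute log-ratio over the query
    measurables with defined values; contrasts where fewer than
    ``min_query_coverage`` of the query measurables are defined are
    skipped.  The top ``top_k`` contrasts (ties broken by lexicographic
    contrast id) form the returned module together with the resolved query
    rows.
    """
    resolved, _ = resolve_genes_to_measurables(
        query_gene_ids, compendium, measurables
    )
    sub = compendium.matrix.loc[resolved]
    absM = sub.abs()
    defined = absM.notna().sum(axis=0)
    scores = absM.mean(axis=0, skipna=True)
    ok = defined >= min_query_coverage * len(resolved)
    candidates = [
        (-(scores[c]), c) for c in compendium.matrix.columns
        if ok[c] and not np.isnan(scores[c])
    ]
    candidates.sort()
    chosen = [c for _, c in candidates[:top_k]]
    return make_module(compendium, resolved, chosen)


def _rank(
    scored: list[tuple[str, float, int]],
    mode: str,
) -> list[tuple[str, float]]:
    if mode not in ("correlated", "anticorrelated", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    keyfn = {
        "correlated": lambda r: -r,
        "anticorrelated": lambda r: r,
        "both": lambda r: -abs(r),
    }[mode]
    scored.sort(key=lambda t: (keyfn(t[1]), t[0]))
    return [(name, r) for name, r, _ in scored]


def rank_coexpressed_genes(
    compendium: Compendium,
    module: ExpressionModule,
    candidates: Sequence[str] | None = None,
    mode: str = "correlated",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    against: str = "mean",
) -> list[tuple[str, float]]:
    """Rank candidate genes by correlation with the module's expression.

    Each candidate row, restricted to the module's contrasts, is scored by
    uncentered Pearson against the module's mean gene profile (``against=
    'mean'``) or its best single member (``against='best_member'``).
    Candidates with undefined scores are excluded.  Modes: ``correlated``
    (descending r), ``anticorrelated`` (ascending r), ``both`` (descending
    |r|); ties broken by gene id.
    """
    if not module.contrast_ids:
        raise ValueError("module has no contrasts to correlate over")
    if candidates is None:
        candidates = [
            g for g in compendium.matrix.index if g not in set(module.gene_ids)
        ]
    profile = module.mean_gene_profile().to_numpy()
    member_rows = module.values.to_numpy()
    scored = []
    for g in candidates:
        row = compendium.matrix.loc[g, module.contrast_ids].to_numpy(dtype=float)
        if against == "mean":
            score = uncentered_pearson(row, profile, min_overlap)
        elif against == "best_member":
            best = None
            for mrow in member_rows:
                s = uncentered_pearson(row, mrow, min_overlap)
                if s.value is not None and (best is None or s.value > best.value):
                    best = s
            score = best if best is not None else CorrelationScore(None, 0)
        else:
            raise ValueError(f"unknown against {against!r}")
        if score.value is not None:
            scored.append((g, score.value, score.n_overlap))
    return _rank(scored, mode)


def rank_similar_contrasts(
    compendium: Compendium,
    module: ExpressionModule,
    candidates: Sequence[str] | None = None,
    mode: str = "correlated",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[tuple[str, float]]:
    """Rank candidate contrasts against the module's mean column profile.

    Symmetric to :func:`rank_coexpressed_genes`: candidate columns are
    restricted to the module's genes and scored against the per-gene mean
    over module contrasts.  All-missing candidates are excluded.
    """
    if not module.gene_ids:
        raise ValueError("module has no genes to correlate over")
    if candidates is None:
        candidates = [
            c for c in compendium.matrix.columns
            if c not in set(module.contrast_ids)
        ]
    profile = module.mean_contrast_profile().to_numpy()
    scored = []
    for c in candidates:
        col = compendium.matrix.loc[module.gene_ids, c].to_numpy(dtype=float)
        score = uncentered_pearson(col, profile, min_overlap)
        if score.value is not None:
            scored.append((c, score.value, score.n_overlap))
    return _rank(scored, mode)


def correlation_network(
    module: ExpressionModule,
    threshold: float,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[tuple[str, str, float]]:
    """All gene pairs with |uncentered Pearson| ≥ threshold.

    Returns a sorted, symmetric-free edge list (g < h lexicographically) of
    (gene, gene, r); pairs with undefined correlation are omitted, and
    there are no self edges.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    genes = sorted(module.gene_ids)
    rows = {g: module.values.loc[g].to_numpy(dtype=float) for g in genes}
    edges = []
    for i, g in enumerate(genes):
        for h in genes[i + 1:]:
            score = uncentered_pearson(rows[g], rows[h], min_overlap)
            if score.value is not None and abs(score.value) >= threshold:
                edges.append((g, h, score.value))
    return edges


def expand_to_genes(
    ids: Iterable[str],
    measurables: Sequence[MeasurableTranscript] | None,
) -> set[str]:
    """Expand measurable ids to their member genes (identity when no map)."""
    if measurables is None:
        return set(ids)
    by_id = {m.measurable_id: m for m in measurables}
    out: set[str] = set()
    for i in ids:
        if i in by_id:
            out |= by_id[i].member_gene_ids
        else:
            out.add(i)
    return out


def enrich_terms(
    module_gene_set: Iterable[str],
    background_gene_set: Iterable[str],
    gene_terms: Mapping[str, Iterable[str]],
    measurables: Sequence[MeasurableTranscript] | None = None,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric term enrichment with BH step-up FDR.

    Cluster measurables contribute every member gene's terms.  For each
    term present in the module (k ≥ 1), the p-value is the upper tail
    P(X ≥ k) of the hypergeometric distribution with population N
    (background genes), K carriers, and n draws (module genes); the FDR is
    the Benjamini–Hochberg step-up adjustment across all tested terms.
    Results are sorted by p-value then term.
    """
    module = expand_to_genes(module_gene_set, measurables)
    background = expand_to_genes(background_gene_set, measurables)
    if not background:
        raise ValueError("background gene set is empty")
    if not module <= background:
        raise ValueError(
            f"module genes outside background: {sorted(module - background)[:5]}"
        )
    N, n = len(background), len(module)
    K_counts: dict[str, int] = {}
    k_counts: dict[str, int] = {}
    for gene in background:
        for term in set(gene_terms.get(gene, ())):
            K_counts[term] = K_counts.get(term, 0) + 1
            if gene in module:
                k_counts[term] = k_counts.get(term, 0) + 1

    tested = sorted(t for t, k in k_counts.items() if k >= 1)
    if not tested:
        return []
    pvals = np.array(
        [hypergeom.sf(k_counts[t] - 1, N, K_counts[t], n) for t in tested]
    )
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=t,
            k=k_counts[t],
            K=K_counts[t],
            n=n,
            N=N,
            p_value=float(p),
            fdr=float(f),
        )
        for t, p, f in zip(tested, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def _deterministic_leaf_order(Z: np.ndarray, labels: list[str]) -> list[str]:
    """Leaf order with the smaller-lexicographic-minimum subtree first."""
    n = len(labels)
    # node -> (min label, leaf list); leaves are 0..n-1, merges n..2n-2
    memo: dict[int, tuple[str, list[str]]] = {
        i: (labels[i], [labels[i]]) for i in range(n)
    }
    for i, (a, b, _, _) in enumerate(Z):
        left = memo[int(a)]
        right = memo[int(b)]
        if right[0] < left[0]:
            left, right = right, left
        memo[n + i] = (left[0], left[1] + right[1])
    return memo[2 * n - 2][1] if n > 1 else list(labels)


def _correlation_distance_matrix(
    mat: np.ndarray, min_overlap: int
) -> np.ndarray:
    """Pairwise 1 − uncentered-Pearson distances; undefined pairs get 1.0."""
    m = mat.shape[0]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            score = uncentered_pearson(mat[i], mat[j], min_overlap)
            d = 1.0 if score.value is None else 1.0 - score.value
            D[i, j] = D[j, i] = d
    return D


def order_by_expression(
    module: ExpressionModule,
    min_overlap: int = 3,
) -> tuple[list[str], list[str]]:
    """Row and column orders for heatmap display.

    Rows and columns are clustered independently by average-linkage
    agglomeration on distance 1 − uncentered Pearson (missing-aware; pairs
    with undefined correlation sit at the neutral distance 1).  Leaf order
    is made deterministic by always placing the subtree containing the
    lexicographically smallest id first, so the result is invariant to the
    module's input ordering.  A default ``min_overlap`` of 3 (rather than
    the search default) keeps small display modules orderable.
    """
    if module.values.size == 0:
        raise ValueError("cannot order an empty module")

    def order_axis(labels: list[str], mat: np.ndarray) -> list[str]:
        if len(labels) == 1:
            return list(labels)
        # canonical (sorted) input order makes linkage permutation-invariant
        perm = np.argsort(labels)
        labels_sorted = [labels[i] for i in perm]
        D = _correlation_distance_matrix(mat[perm], min_overlap)
        Z = linkage(squareform(D, checks=False), method="average")
        ordered = _deterministic_leaf_order(Z, labels_sorted)
        return ordered

    vals = module.values.to_numpy(dtype=float)
    row_order = order_axis(list(module.gene_ids), vals)
    col_order = order_axis(list(module.contrast_ids), vals.T)
    return row_order, col_order


def module_to_tsv(module: ExpressionModule) -> str:
    buf_df = module.values.copy()
    buf_df.index.name = "gene_id"
    from io import StringIO

    buf = StringIO()
    buf_df.to_csv(buf, sep="\t", na_rep="NA", float_format="%.10g")
    return buf.getvalue()


def read_gene_sets_gmt(text: str) -> dict[str, set[str]]:
    """Parse tabular gene sets (term, description, genes...) per line.

    Returns term -> gene set.  The second column (description) is ignored.
    """
    sets: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"gene-set line needs >= 3 fields: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def gene_terms_from_sets(sets: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    """Invert term -> genes into gene -> terms."""
    out: dict[str, set[str]] = {}
    for term, genes in sets.items():
        for g in genes:
            out.setdefault(g, set()).add(term)
    return out
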