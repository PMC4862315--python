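"""Controlled-vocabulary sample annotation and contrast-level diffs.

Samples are annotated with qualitative and quantitative terms drawn from a
hierarchical controlled vocabulary (a forest of terms; top-level roots act
as broad condition categories such as development, tissue, or treatment
type).  Because every contrast compares a test against a reference sample,
diffing the two annotations exposes which conditions actually changed — the
candidate drivers of the observed expression response — and tallying the
touched categories across all contrasts summarizes what a compendium's
experiments actually probed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Value = str | float | int | None


def canonical_value(v: Value) -> Value:
    """Normalize an annotation value: numbers numeric, strings stripped.

    Numeric strings compare equal to their numbers ("33" == 33.0); None
    means the term is purely qualitative.
    """
    if v is None:
        return None
    if isinstance(v, bool):
        return float(v)
    if isinstance(v, (int, float)):
        return float(v)
    s = str(v).strip()
    try:
        return float(s)
    except ValueError:
        return s


class VocabularyError(ValueError):
    """Structural problem in the vocabulary (cycle, unknown parent/term)."""


@dataclass(frozen=True)
class VocabularyTerm:
    term: str
    parent: str | None
    category_root: str


@dataclass
class Vocabulary:
    """A forest of controlled-vocabulary terms keyed by term string."""

    terms: dict[str, VocabularyTerm] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def category_root(self, term: str) -> str:
        if term not in self.terms:
            raise VocabularyError(f"term not in vocabulary: {term!r}")
        return self.terms[term].category_root

    @property
    def roots(self) -> list[str]:
        return sorted(
            t.term for t in self.terms.values() if t.parent is None
        )


@dataclass
class SampleAnnotation:
    """Set of (term, value) entries describing one sample's conditions."""

    sample_id: str
    entries: dict[str, Value] = field(default_factory=dict)

    def validate(self, vocab: Vocabulary) -> None:
        unknown = sorted(set(self.entries) - set(vocab.terms))
        if unknown:
            raise VocabularyError(
                f"sample {self.sample_id}: terms not in vocabulary: {unknown}"
            )


@dataclass
class ContrastAnnotation:
    """Annotation diff between a contrast's test and reference samples.

    ``shared`` holds (term, value) entries equal on both sides; ``changed``
    holds (term, test_value, reference_value) for terms differing in value
    or present on only one side (the absent side's value is None and the
    term is still counted as changed).  ``changed_categories`` are the
    category roots touched by any changed term.
    """

    contrast_id: str
    shared: list[tuple[str, Value]]
    changed: list[tuple[str, Value, Value]]
    changed_categories: frozenset[str]


def load_vocabulary(rows: Iterable[tuple[str, str | None]]) -> Vocabulary:
    """Build the vocabulary forest from (term, parent) rows.

    Parentless rows (empty/None parent) become category roots.  Raises
    :class:`VocabularyError` naming the offending terms on an unknown
    parent or a parent cycle.
    """
    parents: dict[str, str | None] = {}
    for term, parent in rows:
        term = term.strip()
        parent = parent.strip() if isinstance(parent, str) else parent
        if not term:
            raise VocabularyError("empty term")
        if term in parents:
            raise VocabularyError(f"duplicate term: {term!r}")
        parents[term] = parent or None

    for term, parent in parents.items():
        if parent is not None and parent not in parents:
            raise VocabularyError(
                f"term {term!r} has unknown parent {parent!r}"
            )

    roots: dict[str, str] = {}

    def resolve_root(term: str) -> str:
        path = []
        cur: str | None = term
        while cur is not None and cur not in roots:
            if cur in path:
                cycle = path[path.index(cur):] + [cur]
                raise VocabularyError(f"parent cycle: {' -> '.join(cycle)}")
            path.append(cur)
            cur = parents[cur]
        root = roots[cur] if cur is not None else path[-1]
        for t in path:
            roots[t] = root
        return root

    terms = {
        term: VocabularyTerm(term, parents[term], resolve_root(term))
        for term in parents
    }
    return Vocabulary(terms)


def read_vocabulary_tsv(text: str) -> Vocabulary:
    """Parse a vocabulary TSV with columns term, parent (empty = root)."""
    rows: list[tuple[str, str | None]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("term\t") or line == "term":
            continue
        parts = line.split("\t")
        term = parts[0]
        parent = parts[1] if len(parts) > 1 and parts[1] else None
        rows.append((term, parent))
    return load_vocabulary(rows)


def read_annotations_json(text: str) -> dict[str, SampleAnnotation]:
    """Parse sample annotations: {sample_id: [[term, value], ...]}."""
    data = json.loads(text)
    out = {}
    for sample_id, entries in data.items():
        d: dict[str, Value] = {}
        for entry in entries:
            if isinstance(entry, str):
                term, value = entry, None
            else:
                term = entry[0]
                value = entry[1] if len(entry) > 1 else None
            d[term] = canonical_value(value)
        out[sample_id] = SampleAnnotation(sample_id, d)
    return out


def write_annotations_json(
    annotations: Mapping[str, SampleAnnotation]
) -> str:
    data = {
        sid: [[t, ann.entries[t]] for t in sorted(ann.entries)]
        for sid, ann in sorted(annotations.items())
    }
    return json.dumps(data, indent=2, sort_keys=True) + "\n"


def diff_annotations(
    test: SampleAnnotation,
    reference: SampleAnnotation,
    vocab: Vocabulary,
    contrast_id: str = "",
    numeric_tol: float = 0.0,
) -> ContrastAnnotation:
    """Split a contrast's test/reference annotations into shared vs changed.

    Values compare after canonical normalization; numeric values may be
    given a tolerance.  Output entries are ordered lexicographically by
    term so diffs are deterministic.
    """
    test.validate(vocab)
    reference.validate(vocab)

    def equal(a: Value, b: Value) -> bool:
        a, b = canonical_value(a), canonical_value(b)
        if isinstance(a, float) and isinstance(b, float):
            return abs(a - b) <= numeric_tol
        return a == b

    shared: list[tuple[str, Value]] = []
    changed: list[tuple[str, Value, Value]] = []
    for term in sorted(set(test.entries) | set(reference.entries)):
        in_t, in_r = term in test.entries, term in reference.entries
        tv = canonical_value(test.entries[term]) if in_t else None
        rv = canonical_value(reference.entries[term]) if in_r else None
        if in_t and in_r and equal(tv, rv):
            shared.append((term, tv))
        else:
            changed.append((term, tv, rv))
    categories = frozenset(vocab.category_root(t) for t, _, _ in changed)
    return ContrastAnnotation(contrast_id, shared, changed, categories)


def tally_categories(
    contrast_annotations: Sequence[ContrastAnnotation],
    category_roots: Sequence[str] = (
        "development",
        "tissue",
        "biotic treatment",
        "abiotic treatment",
        "genotype",
    ),
) -> dict[str, tuple[int, int]]:
    """Per-category (unique, shared) counts of contrasts touching it.

    A contrast whose changed terms touch exactly one of the given category
    roots increments that category's *unique* count; a contrast touching
    two or more increments the *shared* count of every touched category
    (so shared counts intentionally double-count multi-category
    contrasts).  Categories outside ``category_roots`` are ignored.
    """
    tallies = {c: [0, 0] for c in category_roots}
    wanted = set(category_roots)
    for ann in contrast_annotations:
        touched = sorted(ann.changed_categories & wanted)
        if len(touched) == 1:
            tallies[touched[0]][0] += 1
        elif len(touched) >= 2:
            for c in touched:
                tallies[c][1] += 1
    return {c: (u, s) for c, (u, s) in tallies.items()}


def write_tally_tsv(tallies: Mapping[str, tuple[int, int]]) -> str:
    lines = ["category\tunique\tshared"]
    for cat in sorted(tallies):
        u, s = tallies[cat]
        lines.append(f"{cat}\t{u}\t{s}")
    return "\n".join(lines) + "\n"
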