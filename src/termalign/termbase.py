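"""Terminology-base data model, readers/writers, validation, and seed handling.

A terminology base is a directed acyclic graph of medical concepts.  Three
relation kinds are modelled: hierarchy triples ``(child, h, parent)``,
attribute triples ``(subject, label, object)``, and synonym triples, which
are folded into :attr:`Concept.synonyms` rather than kept as graph nodes
(names and synonyms feed the text encoder, not the graph views).

Supported serializations: a TSV triple dialect, a JSON mirror of the same
model, and a small OBO flat-file subset (``id``, ``name``, ``is_a``,
``synonym`` tags) read through :mod:`obonet`.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Concept",
    "TerminologyBase",
    "AlignmentSeeds",
    "TermbaseError",
    "ParseError",
    "CycleError",
    "DanglingIdError",
    "load_termbase",
    "write_termbase",
    "load_seeds",
    "write_seeds",
    "split_seeds",
]


class TermbaseError(ValueError):
    """Base class for terminology-base validation and parse failures."""


class ParseError(TermbaseError):
    """Malformed input file; carries the offending line number."""


class CycleError(TermbaseError):
    """The hierarchy relation is not acyclic; names one offending edge."""


class DanglingIdError(TermbaseError):
    """A triple references a concept id that is not declared."""


@dataclass(frozen=True)
class Concept:
    """A single terminology concept: opaque id, preferred name, synonyms."""

    id: str
    name: str
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise TermbaseError(f"concept {self.id!r} has an empty name")


@dataclass
class TerminologyBase:
    """A DAG of concepts with hierarchy and attribute triples.

    ``hierarchy`` holds ``(child_id, parent_id)`` pairs — a concept may have
    multiple parents.  ``attributes`` holds ``(subject_id, label, object_id)``
    triples between concepts.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    hierarchy: set[tuple[str, str]] = field(default_factory=set)
    attributes: set[tuple[str, str, str]] = field(default_factory=set)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def ids(self) -> list[str]:
        return sorted(self.concepts)

    def name(self, concept_id: str) -> str:
        try:
            return self.concepts[concept_id].name
        except KeyError:
            raise DanglingIdError(f"unknown concept id {concept_id!r}") from None

    def parents(self, concept_id: str) -> list[str]:
        return sorted(p for c, p in self.hierarchy if c == concept_id)

    def children(self, concept_id: str) -> list[str]:
        return sorted(c for c, p in self.hierarchy if p == concept_id)

    def attribute_neighbors(self, concept_id: str) -> list[str]:
        out = {o for s, _, o in self.attributes if s == concept_id}
        out |= {s for s, _, o in self.attributes if o == concept_id}
        out.discard(concept_id)
        return sorted(out)

    def roots(self) -> list[str]:
        has_parent = {c for c, _ in self.hierarchy}
        linked = has_parent | {p for _, p in self.hierarchy}
        return sorted(i for i in self.concepts if i in linked and i not in has_parent)

    def isolated(self) -> list[str]:
        linked = {c for c, _ in self.hierarchy} | {p for _, p in self.hierarchy}
        return sorted(i for i in self.concepts if i not in linked)

    def hierarchy_graph(self) -> "nx.DiGraph":
        """Hierarchy as a digraph with child→parent edge direction."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(self.hierarchy)
        return g

    def validate(self) -> "TerminologyBase":
        """Check referential integrity and acyclicity; return self."""
        for c, p in self.hierarchy:
            for i in (c, p):
                if i not in self.concepts:
                    raise DanglingIdError(
                        f"hierarchy edge ({c!r}, {p!r}) references unknown id {i!r}"
                    )
        for s, r, o in self.attributes:
            for i in (s, o):
                if i not in self.concepts:
                    raise DanglingIdError(
                        f"attribute triple ({s!r}, {r!r}, {o!r}) references unknown id {i!r}"
                    )
        g = self.hierarchy_graph()
        if not nx.is_directed_acyclic_graph(g):
            edge = nx.find_cycle(g)[0]
            raise CycleError(
                f"hierarchy contains a cycle through edge ({edge[0]!r} -> {edge[1]!r})"
            )
        return self

    def triples(self) -> set[tuple[str, str, str]]:
        """Order-insensitive triple view (h / syn / attribute) for round-trips."""
        out: set[tuple[str, str, str]] = set()
        out |= {(c, "h", p) for c, p in self.hierarchy}
        out |= set(self.attributes)
        for c in self.concepts.values():
            out |= {(c.id, "syn", s) for s in c.synonyms}
        return out


@dataclass
class AlignmentSeeds:
    """Gold equivalent-concept pairs, optionally split into train/validation."""

    pairs: list[tuple[str, str]]
    labels: list[str] | None = None  # per-pair: "train" | "validation"

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.pairs):
            raise TermbaseError("labels length must match pairs length")

    def __len__(self) -> int:
        return len(self.pairs)

    def _by_label(self, label: str) -> list[tuple[str, str]]:
        if self.labels is None:
            raise TermbaseError("seeds are not split; call split_seeds first")
        return [p for p, l in zip(self.pairs, self.labels) if l == label]

    @property
    def train(self) -> list[tuple[str, str]]:
        return self._by_label("train")

    @property
    def validation(self) -> list[tuple[str, str]]:
        return self._by_label("validation")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def validate(self, source: TerminologyBase, target: TerminologyBase) -> "AlignmentSeeds":
        seen_s: set[str] = set()
        seen_t: set[str] = set()
        for s, t in self.pairs:
            if s not in source:
                raise DanglingIdError(f"seed source id {s!r} not in source base")
            if t not in target:
                raise DanglingIdError(f"seed target id {t!r} not in target base")
            if s in seen_s:
                raise TermbaseError(f"duplicate source id {s!r} in gold seeds")
            if t in seen_t:
                raise TermbaseError(f"duplicate target id {t!r} in gold seeds")
            seen_s.add(s)
            seen_t.add(t)
        return self


def split_seeds(
    seeds: AlignmentSeeds,
    train_fraction: float = 0.3,
    cap: int = 15_000,
    rng_seed: int = 0,
) -> AlignmentSeeds:
    """Subsample to at most ``cap`` pairs and split into train/validation.

    ``round(train_fraction * retained)`` pairs become the training set and the
    rest validation (the conventional 30/70 split caps seed alignments at
    15 000 pairs).  Deterministic for a given ``rng_seed``.
    """
    if not seeds.pairs:
        raise TermbaseError("cannot split an empty seed set")
    if cap < 1:
        raise TermbaseError(f"cap must be >= 1, got {cap}")
    if not 0.0 < train_fraction < 1.0:
        raise TermbaseError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(rng_seed)
    pairs = list(seeds.pairs)
    if len(pairs) > cap:
        keep = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    order = rng.permutation(len(pairs))
    n_train = int(round(train_fraction * len(pairs)))
    train_idx = set(order[:n_train].tolist())
    labels = ["train" if i in train_idx else "validation" for i in range(len(pairs))]
    return AlignmentSeeds(pairs=pairs, labels=labels)


# ---------------------------------------------------------------------------
# TSV triple dialect
#
#   [concepts]
#   <id>\t<name>
#   [triples]
#   <subject>\t<relation>\t<object>
#
# relation "h" is a hierarchy edge (subject = child), "syn" carries a synonym
# literal in the object column, anything else is an attribute label.
# ---------------------------------------------------------------------------


def _parse_tsv(text: str) -> TerminologyBase:
    names: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    hierarchy: set[tuple[str, str]] = set()
    attributes: set[tuple[str, str, str]] = set()
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() in ("[concepts]", "[triples]"):
            section = line.strip()
            continue
        cols = line.split("\t")
        if section == "[concepts]":
            if len(cols) != 2:
                raise ParseError(f"line {lineno}: expected 'id<TAB>name', got {line!r}")
            cid, name = cols
            if cid in names:
                raise ParseError(f"line {lineno}: duplicate concept id {cid!r}")
            names[cid] = name
        elif section == "[triples]":
            if len(cols) != 3:
                raise ParseError(
                    f"line {lineno}: expected 'subject<TAB>relation<TAB>object', got {line!r}"
                )
            s, r, o = cols
            if r == "h":
                hierarchy.add((s, o))
            elif r == "syn":
                synonyms.setdefault(s, set()).add(o)
            else:
                attributes.add((s, r, o))
        else:
            raise ParseError(f"line {lineno}: content before a section header")
    concepts = {
        cid: Concept(cid, name, frozenset(synonyms.get(cid, ())))
        for cid, name in names.items()
    }
    for cid in synonyms:
        if cid not in concepts:
            raise DanglingIdError(f"synonym triple references unknown id {cid!r}")
    return TerminologyBase(concepts, hierarchy, attributes)


def _write_tsv(tb: TerminologyBase) -> str:
    buf = io.StringIO()
    buf.write("[concepts]\n")
    for cid in tb.ids():
        buf.write(f"{cid}\t{tb.concepts[cid].name}\n")
    buf.write("[triples]\n")
    for c, p in sorted(tb.hierarchy):
        buf.write(f"{c}\th\t{p}\n")
    for cid in tb.ids():
        for syn in sorted(tb.concepts[cid].synonyms):
            buf.write(f"{cid}\tsyn\t{syn}\n")
    for s, r, o in sorted(tb.attributes):
        buf.write(f"{s}\t{r}\t{o}\n")
    return buf.getvalue()


def _parse_json(text: str) -> TerminologyBase:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"line {exc.lineno}: {exc.msg}") from exc
    concepts = {
        c["id"]: Concept(c["id"], c["name"], frozenset(c.get("synonyms", ())))
        for c in doc.get("concepts", ())
    }
    hierarchy = {(c, p) for c, p in doc.get("hierarchy", ())}
    attributes = {(s, r, o) for s, r, o in doc.get("attributes", ())}
    return TerminologyBase(concepts, hierarchy, attributes)


def _write_json(tb: TerminologyBase) -> str:
    doc = {
        "concepts": [
            {
                "id": cid,
                "name": tb.concepts[cid].name,
                "synonyms": sorted(tb.concepts[cid].synonyms),
            }
            for cid in tb.ids()
        ],
        "hierarchy": sorted(list(e) for e in tb.hierarchy),
        "attributes": sorted(list(t) for t in tb.attributes),
    }
    return json.dumps(doc, indent=1, sort_keys=True)


_OBO_SYN_RE = re.compile(r'^"(.*)"')


def _parse_obo(path: Path) -> TerminologyBase:
    import obonet

    graph = obonet.read_obo(str(path))
    concepts: dict[str, Concept] = {}
    hierarchy: set[tuple[str, str]] = set()
    for node, data in graph.nodes(data=True):
        name = data.get("name", "")
        syns: set[str] = set()
        for raw in data.get("synonym", ()):  # e.g. '"belly ache" EXACT []'
            m = _OBO_SYN_RE.match(raw)
            if m:
                syns.add(m.group(1))
        concepts[node] = Concept(node, name or node, frozenset(syns))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            hierarchy.add((child, parent))
    return TerminologyBase(concepts, hierarchy, set())


Format = Literal["tsv-triples", "json", "obo"]

_SUFFIX_FORMAT: dict[str, Format] = {
    ".tsv": "tsv-triples",
    ".json": "json",
    ".obo": "obo",
}


def load_termbase(path: str | Path, format: Format | None = None) -> TerminologyBase:
    """Read and validate a terminology base from ``path``.

    ``format`` defaults to the file suffix (.tsv / .json / .obo).  The
    returned base has passed referential-integrity and acyclicity checks;
    synonym triples are folded into :attr:`Concept.synonyms`.
    """
    path = Path(path)
    fmt = format or _SUFFIX_FORMAT.get(path.suffix)
    if fmt is None:
        raise TermbaseError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "obo":
        tb = _parse_obo(path)
    else:
        text = path.read_text(encoding="utf-8")
        tb = _parse_tsv(text) if fmt == "tsv-triples" else _parse_json(text)
    return tb.validate()


def write_termbase(tb: TerminologyBase, path: str | Path, format: Format | None = None) -> None:
    path = Path(path)
    fmt = format or _SUFFIX_FORMAT.get(path.suffix)
    if fmt == "tsv-triples":
        path.write_text(_write_tsv(tb), encoding="utf-8")
    elif fmt == "json":
        path.write_text(_write_json(tb), encoding="utf-8")
    else:
        raise TermbaseError(f"unsupported output format {fmt!r}")


def load_seeds(path: str | Path) -> AlignmentSeeds:
    """Read a two-column TSV of (source_id, target_id) pairs."""
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"line {lineno}: expected 'source<TAB>target', got {raw!r}")
        pairs.append((cols[0], cols[1]))
    return AlignmentSeeds(pairs)


def write_seeds(seeds: AlignmentSeeds, path: str | Path) -> None:
    lines = [f"{s}\t{t}" for s, t in seeds.pairs]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
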