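"""Synthetic paired-terminology generator with gold alignments.

Emulates the structural heterogeneity seen between real coding systems
(ICD-10 vs ICD-11 style revisions): a rooted concept DAG with compositional
clinical names is copied and perturbed by

* *parent reassignment* — a concept's hierarchy edge moves to a sibling of
  its original parent, so the two versions disagree on the parent while
  still sharing a common ancestor;
* *intermediate insertion* — a new category node is spliced into a
  hierarchy edge of the copy, shifting depths and neighborhoods;
* *synonym replacement* — a fraction of names is rewritten token-by-token
  from a built-in clinical synonym table ("pain" → "ache", "cardiac" →
  "heart", ...), so the text encoder sees genuinely different strings while
  the hierarchy stays put.

The gold alignment is the identity over concepts present in both copies;
inserted intermediates have no counterpart.  Everything is deterministic
for a given seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .termbase import AlignmentSeeds, Concept, TermbaseError, TerminologyBase

__all__ = ["SynthConfig", "SynthPair", "generate_base", "perturb", "generate_pair",
           "CATEGORIES", "QUALIFIERS", "HEADS", "SYNONYMS"]

CATEGORIES = (
    "cardiac", "renal", "hepatic", "pulmonary", "neural",
    "gastric", "dermal", "skeletal", "vascular", "ocular",
)
QUALIFIERS = (
    "acute", "chronic", "benign", "malignant", "congenital", "recurrent",
    "focal", "diffuse", "primary", "secondary", "mild", "severe",
    "proximal", "distal", "lateral", "medial", "early", "late",
    "partial", "complete", "atypical", "refractory",
)
HEADS = (
    "pain", "lesion", "disorder", "stenosis", "rupture", "inflammation",
    "atrophy", "fibrosis", "edema", "necrosis", "cyst", "ulcer",
)

# Token-level substitution table; every category and head token has an entry
# so any generated name can be rewritten into a genuinely different string.
SYNONYMS = {
    "cardiac": "heart", "renal": "kidney", "hepatic": "liver",
    "pulmonary": "lung", "neural": "nerve", "gastric": "stomach",
    "dermal": "skin", "skeletal": "bone", "vascular": "vessel",
    "ocular": "eye",
    "pain": "ache", "lesion": "abnormality", "disorder": "disease",
    "stenosis": "narrowing", "rupture": "tear", "inflammation": "swelling",
    "atrophy": "wasting", "fibrosis": "scarring", "edema": "fluid retention",
    "necrosis": "tissue death", "cyst": "sac", "ulcer": "sore",
    "acute": "sudden", "chronic": "persistent", "benign": "harmless",
    "malignant": "aggressive", "congenital": "inborn", "recurrent": "relapsing",
    "focal": "localized", "diffuse": "widespread", "severe": "extreme",
    "mild": "slight",
}


@dataclass(frozen=True)
class SynthConfig:
    n_concepts: int = 200
    max_depth: int = 4
    branching: tuple[int, int] = (2, 4)  # inclusive child-capacity range
    p_reassign: float = 0.0
    p_insert: float = 0.0
    p_synonym: float = 0.0
    p_extra_parent: float = 0.08  # fraction of non-roots given a second parent
    n_attributes: int | None = None  # default: n_concepts // 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 5:
            raise TermbaseError(f"n_concepts must be >= 5, got {self.n_concepts}")
        for name in ("p_reassign", "p_insert", "p_synonym", "p_extra_parent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TermbaseError(f"{name} must lie in [0, 1], got {v}")
        if self.max_depth < 1:
            raise TermbaseError("max_depth must be >= 1")


@dataclass
class SynthPair:
    source: TerminologyBase
    target: TerminologyBase
    gold: AlignmentSeeds
    log: list[dict] = field(default_factory=list)


def generate_base(cfg: SynthConfig) -> TerminologyBase:
    """Rooted DAG with compositional clinical names, deterministic per seed.

    Root names pair a category token with a head noun; each child prepends a
    qualifier to its parent's name, so every name embeds its top-level
    category token and names are globally unique.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_roots = min(len(CATEGORIES), max(2, cfg.n_concepts // 25))
    names: dict[str, str] = {}
    used_names: set[str] = set()
    depth: dict[str, int] = {}
    capacity: dict[str, int] = {}
    children_of: dict[str, list[str]] = {}
    hierarchy: set[tuple[str, str]] = set()
    order: list[str] = []

    def new_id() -> str:
        return f"C{len(order) + 1:04d}"

    for r in range(n_roots):
        cid = new_id()
        name = f"{CATEGORIES[r]} {HEADS[int(rng.integers(len(HEADS)))]}"
        names[cid] = name
        used_names.add(name)
        depth[cid] = 1
        capacity[cid] = int(rng.integers(cfg.branching[0], cfg.branching[1] + 1))
        children_of[cid] = []
        order.append(cid)

    while len(order) < cfg.n_concepts:
        eligible = [
            c
            for c in order
            if depth[c] < cfg.max_depth and len(children_of[c]) < capacity[c]
        ]
        if not eligible:
            # Relax capacities before giving up: depth is the hard limit.
            eligible = [c for c in order if depth[c] < cfg.max_depth]
            if not eligible:
                raise TermbaseError(
                    "infeasible config: depth/branching cannot host n_concepts"
                )
        parent = eligible[int(rng.integers(len(eligible)))]
        quals = list(QUALIFIERS)
        rng.shuffle(quals)
        name = None
        for q in quals:
            cand = f"{q} {names[parent]}"
            if cand not in used_names:
                name = cand
                break
        if name is None:
            continue  # all qualifiers taken for this parent; try another
        cid = new_id()
        names[cid] = name
        used_names.add(name)
        depth[cid] = depth[parent] + 1
        capacity[cid] = int(rng.integers(cfg.branching[0], cfg.branching[1] + 1))
        children_of[cid] = []
        children_of[parent].append(cid)
        hierarchy.add((cid, parent))
        order.append(cid)

    # Occasional second parents make the hierarchy a genuine DAG: any node
    # strictly shallower than the child keeps the graph acyclic.
    non_roots = [c for c in order if depth[c] > 1]
    n_extra = int(round(cfg.p_extra_parent * len(non_roots)))
    if n_extra:
        picks = rng.choice(len(non_roots), size=n_extra, replace=False)
        for i in sorted(picks):
            child = non_roots[i]
            shallower = [c for c in order if depth[c] < depth[child] and (child, c) not in hierarchy]
            if shallower:
                extra = shallower[int(rng.integers(len(shallower)))]
                hierarchy.add((child, extra))
                children_of[extra].append(child)

    attributes: set[tuple[str, str, str]] = set()
    n_attr = cfg.n_attributes if cfg.n_attributes is not None else cfg.n_concepts // 10
    for _ in range(n_attr):
        s, o = rng.choice(len(order), size=2, replace=False)
        attributes.add((order[int(s)], "associated_with", order[int(o)]))

    tb = TerminologyBase(
        concepts={c: Concept(c, names[c]) for c in order},
        hierarchy=hierarchy,
        attributes=attributes,
    )
    return tb.validate()


def _replace_tokens(name: str) -> str:
    return " ".join(SYNONYMS.get(tok, tok) for tok in name.split())


def _descendants(tb: TerminologyBase, root: str) -> set[str]:
    out: set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for c in tb.children(node):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def perturb(tb: TerminologyBase, cfg: SynthConfig) -> SynthPair:
    """Copy ``tb`` and apply reassignment, insertion, and synonym edits.

    Returns the source/target pair, the identity gold alignment over the
    original concepts, and a log recording every edit.
    """
    rng = np.random.default_rng(cfg.rng_seed + 101)
    target = copy.deepcopy(tb)
    log: list[dict] = []
    original_ids = tb.ids()

    # --- parent reassignment: move one hierarchy edge to a sibling of the
    # original parent (siblinghood judged in the source), so old and new
    # parent share an ancestor there by construction.
    candidates = []
    for c in original_ids:
        for p in tb.parents(c):
            for gp in tb.parents(p):
                siblings = [s for s in tb.children(gp) if s != p and s != c]
                if siblings:
                    candidates.append(c)
                    break
            else:
                continue
            break
    n_re = int(round(cfg.p_reassign * len(candidates)))
    if n_re:
        picks = rng.choice(len(candidates), size=n_re, replace=False)
        for i in sorted(picks):
            c = candidates[i]
            moves = []
            for p in tb.parents(c):
                for gp in tb.parents(p):
                    for s in tb.children(gp):
                        if s != p and s != c:
                            moves.append((p, s, gp))
            if not moves:
                continue
            below = _descendants(target, c)
            moves = [m for m in moves if m[1] not in below]
            if not moves:
                continue
            p, s, gp = moves[int(rng.integers(len(moves)))]
            target.hierarchy.discard((c, p))
            target.hierarchy.add((c, s))
            log.append(
                {"op": "reassign", "concept": c, "old_parent": p, "new_parent": s,
                 "common_ancestor": gp}
            )

    # --- intermediate insertion: splice a new category node into an edge.
    edges = sorted(target.hierarchy)
    n_ins = int(round(cfg.p_insert * len(edges)))
    if n_ins:
        picks = rng.choice(len(edges), size=n_ins, replace=False)
        used_names = {c.name for c in target.concepts.values()}
        for j, i in enumerate(sorted(picks)):
            child, parent = edges[i]
            nid = f"X{j + 1:04d}"
            name = f"{target.concepts[child].name} category"
            while name in used_names:
                name = "sub " + name
            used_names.add(name)
            target.concepts[nid] = Concept(nid, name)
            target.hierarchy.discard((child, parent))
            target.hierarchy.add((child, nid))
            target.hierarchy.add((nid, parent))
            log.append({"op": "insert", "between": [child, parent], "new": nid})

    # --- synonym replacement on names of the copy.
    n_syn = int(round(cfg.p_synonym * len(original_ids)))
    if n_syn:
        replaceable = [
            c for c in original_ids if _replace_tokens(tb.concepts[c].name) != tb.concepts[c].name
        ]
        n_syn = min(n_syn, len(replaceable))
        picks = rng.choice(len(replaceable), size=n_syn, replace=False)
        for i in sorted(picks):
            c = replaceable[i]
            old = target.concepts[c].name
            new = _replace_tokens(old)
            target.concepts[c] = Concept(c, new, target.concepts[c].synonyms)
            log.append({"op": "rename", "concept": c, "old": old, "new": new})

    target.validate()
    gold = AlignmentSeeds(pairs=[(c, c) for c in original_ids])
    return SynthPair(source=tb, target=target, gold=gold, log=log)


def generate_pair(cfg: SynthConfig) -> SynthPair:
    """Generate a base and its perturbed copy with gold alignment."""
    return perturb(generate_base(cfg), cfg)
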