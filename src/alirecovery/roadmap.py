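"""Search-term roadmaps: parsing, normalization, diffing, adjudication.

A *roadmap* is the algorithm's clinical knowledge base: per ALI component, a
set of multi-word search terms used to find auxiliary ICD-10 diagnoses that
imply an unhealthy value when the biomarker itself is unmeasured.  Roadmaps
come in several flavours (the clinicians' original, model-expanded variants,
and a clinician-endorsed final), distinguished by per-term provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .data_model import ComponentId, SchemaError, logger

PROVENANCES = ("original", "proposed", "endorsed", "rejected")

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def tokenize(raw: str) -> tuple[str, ...]:
    """Lowercase, replace every non-alphanumeric character with whitespace,
    split on whitespace.  Deterministic and idempotent on the joined result."""
    return tuple(t for t in _NON_ALNUM.split(raw.lower()) if t)


@dataclass(frozen=True)
class SearchTerm:
    raw: str
    tokens: tuple[str, ...]

    @classmethod
    def from_raw(cls, raw: str) -> "SearchTerm":
        tokens = tokenize(raw)
        if not tokens:
            raise ValueError(f"term {raw!r} normalizes to no tokens")
        return cls(raw=raw, tokens=tokens)

    @property
    def normalized(self) -> str:
        return " ".join(self.tokens)


@dataclass
class Roadmap:
    """Per-component search-term sets with provenance and code exclusions.

    ``terms`` maps every ComponentId to a dict keyed by normalized term text
    (so duplicates collapse); values are SearchTerm objects.  ``provenance``
    is keyed the same way.  ``code_exclusions`` holds ICD-10 codes struck by
    code-level adjudication, applied after matching.
    """

    name: str = "custom"
    terms: dict[ComponentId, dict[str, SearchTerm]] = field(
        default_factory=lambda: {c: {} for c in ComponentId}
    )
    provenance: dict[ComponentId, dict[str, str]] = field(
        default_factory=lambda: {c: {} for c in ComponentId}
    )
    code_exclusions: set[str] = field(default_factory=set)

    def add_term(self, component: ComponentId, raw: str, provenance: str = "original") -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        term = SearchTerm.from_raw(raw)
        self.terms.setdefault(component, {})
        self.provenance.setdefault(component, {})
        if term.normalized not in self.terms[component]:
            self.terms[component][term.normalized] = term
        self.provenance[component][term.normalized] = provenance

    def component_terms(self, component: ComponentId) -> set[SearchTerm]:
        return set(self.terms.get(component, {}).values())

    def n_terms(self) -> int:
        return sum(len(v) for v in self.terms.values())

    def term_set(self, component: ComponentId) -> set[str]:
        return set(self.terms.get(component, {}))

    def copy(self, name: str | None = None) -> "Roadmap":
        return Roadmap(
            name=name or self.name,
            terms={c: dict(d) for c, d in self.terms.items()},
            provenance={c: dict(d) for c, d in self.provenance.items()},
            code_exclusions=set(self.code_exclusions),
        )

    def union(self, other: "Roadmap", name: str = "custom") -> "Roadmap":
        out = self.copy(name=name)
        for comp, terms in other.terms.items():
            for key, term in terms.items():
                if key not in out.terms.setdefault(comp, {}):
                    out.terms[comp][key] = term
                    out.provenance.setdefault(comp, {})[key] = other.provenance[comp].get(
                        key, "proposed"
                    )
        out.code_exclusions |= other.code_exclusions
        return out


_GRADE_RE = re.compile(
    r"\b([IVXivx]+|\d+)\s*,\s*([IVXivx]+|\d+)\s*,\s*or\s+([IVXivx]+|\d+)\b"
)


def expand_grade_terms(raw: str) -> list[str]:
    """Expand an enumerated "I, II, or III" (or "1, 2, or 3") construction
    into one term per grade; anything else passes through as a singleton.

    "Grade I, II, or III obesity" -> ["Grade I obesity", "Grade II obesity",
    "Grade III obesity"].
    """
    m = _GRADE_RE.search(raw)
    if not m:
        return [raw]
    return [raw[: m.start()] + g + raw[m.end():] for g in m.groups()]


def parse_roadmap(path: str | Path, name: str = "custom") -> Roadmap:
    """Read ``roadmap.csv`` (component, term[, provenance]); normalize terms,
    expand grade enumerations, and collapse duplicates within a component."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("component", "term"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    rm = Roadmap(name=name)
    for i, row in df.iterrows():
        try:
            comp = ComponentId(row["component"].strip().upper())
        except ValueError:
            raise SchemaError(
                f"{path}: line {i + 2}: unknown component label {row['component']!r}"
            ) from None
        prov = (row.get("provenance", "") or "original").strip().lower() or "original"
        for piece in expand_grade_terms(row["term"]):
            rm.add_term(comp, piece, provenance=prov)
    return rm


def write_roadmap(roadmap: Roadmap, path: str | Path) -> None:
    rows = []
    for comp in ComponentId:
        for key in sorted(roadmap.terms.get(comp, {})):
            rows.append(
                {
                    "component": comp.value,
                    "term": roadmap.terms[comp][key].raw,
                    "provenance": roadmap.provenance[comp].get(key, "original"),
                }
            )
    pd.DataFrame(rows, columns=["component", "term", "provenance"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjudicationEntry:
    item_type: str  # "term" or "code"
    item: str       # normalized term text, or ICD-10 code
    component: ComponentId | None
    reviewer: str
    verdict: str    # "endorse" or "reject"


@dataclass
class AdjudicationLedger:
    entries: list[AdjudicationEntry] = field(default_factory=list)

    def add(self, item_type: str, item: str, component: ComponentId | None,
            reviewer: str, verdict: str) -> None:
        if item_type not in ("term", "code"):
            raise ValueError(f"unknown item_type {item_type!r}")
        if verdict not in ("endorse", "reject"):
            raise ValueError(f"unknown verdict {verdict!r}")
        self.entries.append(AdjudicationEntry(item_type, item, component, reviewer, verdict))


def read_ledger(path: str | Path) -> AdjudicationLedger:
    """Read ``ledger.csv`` (item_type, item, component, reviewer, verdict)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("item_type", "item", "component", "reviewer", "verdict"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    ledger = AdjudicationLedger()
    for _, row in df.iterrows():
        comp = ComponentId(row["component"].strip().upper()) if row["component"].strip() else None
        ledger.add(row["item_type"].strip().lower(), row["item"],
                   comp, row["reviewer"], row["verdict"].strip().lower())
    return ledger


def adjudicate(roadmap: Roadmap, ledger: AdjudicationLedger) -> Roadmap:
    """Keep exactly the items endorsed by at least one reviewer.

    Term-level verdicts filter the term sets: a term survives iff >=1
    ``endorse`` verdict targets it (so an empty ledger yields an empty
    roadmap).  Code-level verdicts operate on matched ICD-10 codes: codes
    with no endorsement are added to the exclusion list, applied after
    matching.  Verdicts on items not in the roadmap are warned about and
    ignored.  Contractive and idempotent.
    """
    endorsed_terms: set[tuple[ComponentId | None, str]] = set()
    seen_terms: set[tuple[ComponentId | None, str]] = set()
    code_verdicts: dict[str, bool] = {}  # code -> any endorsement
    for e in ledger.entries:
        if e.item_type == "term":
            key = (e.component, " ".join(tokenize(e.item)))
            seen_terms.add(key)
            if e.verdict == "endorse":
                endorsed_terms.add(key)
        else:
            code_verdicts[e.item] = code_verdicts.get(e.item, False) or e.verdict == "endorse"

    known = {(comp, key) for comp, terms in roadmap.terms.items() for key in terms}
    for comp, key in seen_terms:
        if comp is not None and (comp, key) not in known:
            logger.warning("adjudication verdict on unknown term %r (%s); ignored", key,
                           comp.value)

    out = Roadmap(name=roadmap.name, terms={c: {} for c in ComponentId},
                  provenance={c: {} for c in ComponentId},
                  code_exclusions=set(roadmap.code_exclusions))
    for comp, terms in roadmap.terms.items():
        for key, term in terms.items():
            hit = (comp, key) in endorsed_terms or (None, key) in endorsed_terms
            if hit:
                out.terms.setdefault(comp, {})[key] = term
                out.provenance.setdefault(comp, {})[key] = "endorsed"
    for code, any_endorse in code_verdicts.items():
        if not any_endorse:
            out.code_exclusions.add(code)
    return out


# ---------------------------------------------------------------------------
# Diff
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoadmapDiff:
    """Per-component partition of the union of two roadmaps' terms."""

    added: Mapping[ComponentId, frozenset[str]]    # in b, not a
    removed: Mapping[ComponentId, frozenset[str]]  # in a, not b
    shared: Mapping[ComponentId, frozenset[str]]


def diff_roadmaps(a: Roadmap, b: Roadmap) -> RoadmapDiff:
    added, removed, shared = {}, {}, {}
    for comp in ComponentId:
        sa, sb = a.term_set(comp), b.term_set(comp)
        added[comp] = frozenset(sb - sa)
        removed[comp] = frozenset(sa - sb)
        shared[comp] = frozenset(sa & sb)
    return RoadmapDiff(added=added, removed=removed, shared=shared)


# ---------------------------------------------------------------------------
# Shipped clinicians' original roadmap
# ---------------------------------------------------------------------------

def load_original_roadmap() -> Roadmap:
    """The clinicians' original roadmap shipped with the package
    (20 component-term entries after grade expansion; serum albumin has none)."""
    from importlib.resources import files

    path = files("alirecovery").joinpath("data/original_roadmap.csv")
    return parse_roadmap(str(path), name="original")
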