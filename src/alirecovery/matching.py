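"""The core merging algorithm: term vs ICD-10 description matching.

A search term matches a code when *every* word of the term appears somewhere
in the code's description (AND across tokens); a component's matched-code
set is the union over its terms (OR across terms).  Matching is
component-scoped and deterministic.  Two modes are exposed:

* ``token`` (default) -- each term token must occur as a whole token of the
  normalized description; avoids clinically absurd hits like "art" matching
  "Heart failure".
* ``substring`` -- each term token must occur as a substring of the
  normalized description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .data_model import ComponentId, DiagnosisRecord, ICD10Catalog
from .roadmap import Roadmap, SearchTerm, tokenize

MatchMode = Literal["token", "substring"]


def term_matches(term: SearchTerm, description: str, mode: MatchMode = "token") -> bool:
    """True iff every token of ``term`` appears in the normalized description.

    ``token`` mode requires whole-token occurrence; ``substring`` mode
    requires occurrence as a substring of the whitespace-joined normalized
    description.
    """
    desc_tokens = tokenize(description)
    if mode == "token":
        desc_set = set(desc_tokens)
        return all(tok in desc_set for tok in term.tokens)
    elif mode == "substring":
        joined = " ".join(desc_tokens)
        return all(tok in joined for tok in term.tokens)
    raise ValueError(f"unknown match mode {mode!r}")


@dataclass(frozen=True)
class MatchResult:
    component: ComponentId
    term: SearchTerm
    code: str
    description: str


@dataclass
class MatchUniverse:
    """Matched-code sets per component for one (roadmap, catalog, mode) run."""

    roadmap_name: str
    mode: MatchMode
    codes: dict[ComponentId, set[str]] = field(
        default_factory=lambda: {c: set() for c in ComponentId}
    )
    # code -> terms that justified it, per component (evidence for audits)
    evidence: dict[ComponentId, dict[str, set[str]]] = field(
        default_factory=lambda: {c: {} for c in ComponentId}
    )
    in_sample_codes: dict[ComponentId, set[str]] | None = None

    def component_codes(self, component: ComponentId) -> set[str]:
        return self.codes.get(component, set())

    @property
    def overall_count(self) -> int:
        """Distinct matched codes across all components."""
        return len(set().union(*self.codes.values())) if self.codes else 0

    @property
    def in_sample_count(self) -> int | None:
        if self.in_sample_codes is None:
            return None
        return len(set().union(*self.in_sample_codes.values()))


def expand_roadmap(
    roadmap: Roadmap,
    catalog: ICD10Catalog,
    exclusions: set[str] | None = None,
    mode: MatchMode = "token",
) -> MatchUniverse:
    """Match every roadmap term against every catalog description.

    Per component: the set of codes whose description matches at least one
    of the component's terms, minus ``exclusions`` and the roadmap's own
    ``code_exclusions``.  Monotone in terms, anti-monotone in exclusions,
    deterministic for fixed inputs.
    """
    excluded = set(exclusions or ()) | roadmap.code_exclusions
    universe = MatchUniverse(roadmap_name=roadmap.name, mode=mode)
    for comp in ComponentId:
        terms = roadmap.component_terms(comp)
        if not terms:
            continue
        for entry in catalog:
            if entry.code in excluded:
                continue
            hits = [t for t in terms if term_matches(t, entry.description, mode)]
            if hits:
                universe.codes[comp].add(entry.code)
                universe.evidence[comp].setdefault(entry.code, set()).update(
                    t.normalized for t in hits
                )
    return universe


def in_sample_counts(
    universe: MatchUniverse, diagnoses: Iterable[DiagnosisRecord]
) -> tuple[int, int]:
    """(overall, in_sample) distinct matched-code counts.

    ``in_sample`` counts matched codes carried by at least one patient in
    the supplied diagnosis records; the per-component breakdown is cached on
    the universe.  in_sample <= overall always.
    """
    carried = {d.code for d in diagnoses}
    universe.in_sample_codes = {
        comp: codes & carried for comp, codes in universe.codes.items()
    }
    return universe.overall_count, universe.in_sample_count


def write_match_report(
    universe: MatchUniverse, path: str | Path, indent: int = 2
) -> None:
    """Machine-readable analogue of a matched-codes summary table."""
    report = {
        "roadmap": universe.roadmap_name,
        "mode": universe.mode,
        "overall_matched": universe.overall_count,
        "in_sample_matched": universe.in_sample_count,
        "components": {
            comp.value: {
                "matched_codes": sorted(universe.codes[comp]),
                "in_sample_codes": (
                    sorted(universe.in_sample_codes[comp])
                    if universe.in_sample_codes is not None
                    else None
                ),
            }
            for comp in ComponentId
        },
    }
    Path(path).write_text(json.dumps(report, indent=indent))
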