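"""Model-assisted roadmap expansion with self-consistency aggregation.

A *proposer* is any callable following :class:`ProposerContract`: given
per-component metadata (and, in ``context`` mode, the seed examples from the
clinicians' roadmap), it returns candidate search terms per component.  The
expansion loop invokes the proposer across many independent iterations
(fresh session each time, so earlier answers cannot skew later ones) and
aggregates the *superset*: every term proposed at least once.  Saturation
diagnostics track the cumulative count of unique matched ICD-10 codes as
iterations accumulate.

Live API adapters are deliberately outside the tested surface; the shipped
:class:`MockProposer` (seeded sampling from a fixed pool) and
:class:`RecordedProposer` (replays stored proposal CSVs) make the whole path
testable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .data_model import ComponentId, ICD10Catalog, logger
from .matching import MatchMode, expand_roadmap
from .roadmap import Roadmap

#: component -> list of raw term texts
Proposal = dict[ComponentId, list[str]]


class ProposerContract(Protocol):
    """One independent proposal round.

    ``seed_examples`` is None in baseline mode and the clinicians' example
    terms per component in context mode (which the proposer is expected to
    echo back alongside its own additions).  ``iteration`` identifies the
    round so stateless proposers can still vary deterministically.
    """

    def __call__(
        self, iteration: int, seed_examples: Mapping[ComponentId, Sequence[str]] | None
    ) -> Proposal: ...


class MockProposer:
    """Deterministic stand-in proposer drawing from a fixed per-component pool.

    Each invocation samples ``n_per_iteration`` terms (without replacement)
    from the pool using a seeded generator keyed on (seed, iteration), and in
    context mode echoes the seed examples first.  Fixed seed => the full
    expansion run is bit-reproducible.
    """

    def __init__(
        self,
        pool: Mapping[ComponentId, Sequence[str]],
        n_per_iteration: int = 5,
        seed: int = 0,
    ):
        self.pool = {c: list(v) for c, v in pool.items()}
        self.n_per_iteration = n_per_iteration
        self.seed = seed

    def __call__(
        self, iteration: int, seed_examples: Mapping[ComponentId, Sequence[str]] | None
    ) -> Proposal:
        rng = np.random.default_rng([self.seed, iteration])
        proposal: Proposal = {}
        for comp in ComponentId:
            terms: list[str] = []
            if seed_examples is not None:
                terms.extend(seed_examples.get(comp, []))
            pool = self.pool.get(comp, [])
            if pool:
                k = min(self.n_per_iteration, len(pool))
                idx = rng.choice(len(pool), size=k, replace=False)
                terms.extend(pool[i] for i in sorted(idx))
            proposal[comp] = terms
        return proposal


class RecordedProposer:
    """Replays stored proposals: one CSV per iteration (component, term)."""

    def __init__(self, paths: Sequence[str | Path]):
        self.paths = [Path(p) for p in paths]

    def __call__(
        self, iteration: int, seed_examples: Mapping[ComponentId, Sequence[str]] | None
    ) -> Proposal:
        if iteration >= len(self.paths):
            raise IndexError(f"no recorded proposal for iteration {iteration}")
        df = pd.read_csv(self.paths[iteration], dtype=str, keep_default_na=False)
        proposal: Proposal = {c: [] for c in ComponentId}
        for _, row in df.iterrows():
            proposal[ComponentId(row["component"].strip().upper())].append(row["term"])
        return proposal


@dataclass
class ExpansionRun:
    mode: str  # baseline | context
    n_iterations: int
    proposals: list[Proposal]
    aggregate: Roadmap  # superset: union of all iterations' proposals
    saturation: list[int]  # cumulative unique matched-code counts per iteration
    proposer: str = ""
    failed_iterations: list[int] = field(default_factory=list)


def run_expansion(
    proposer: ProposerContract,
    mode: str,
    n_iterations: int = 20,
    seed_roadmap: Roadmap | None = None,
    catalog: ICD10Catalog | None = None,
    match_mode: MatchMode = "token",
    name: str | None = None,
) -> ExpansionRun:
    """Self-consistency loop: n independent proposals, superset aggregation.

    ``context`` mode passes the seed roadmap's raw terms to the proposer each
    iteration.  The saturation curve records, after each iteration, how many
    unique catalog codes the union-so-far matches (all zeros when no catalog
    is supplied).  A proposer failure skips that iteration with a warning;
    the run fails only if every iteration fails.
    """
    if mode not in ("baseline", "context"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    if mode == "context" and seed_roadmap is None:
        raise ValueError("context mode requires a seed roadmap")
    seed_examples = None
    if mode == "context":
        seed_examples = {
            comp: [t.raw for t in sorted(seed_roadmap.component_terms(comp),
                                         key=lambda t: t.normalized)]
            for comp in ComponentId
        }

    aggregate = Roadmap(name=name or f"llm_{mode}")
    proposals: list[Proposal] = []
    saturation: list[int] = []
    failed: list[int] = []
    for i in range(n_iterations):
        try:
            proposal = proposer(i, seed_examples)
        except Exception as exc:  # proposer contract: failures are skippable
            logger.warning("proposer failed on iteration %d: %s", i, exc)
            failed.append(i)
            proposals.append({})
            saturation.append(saturation[-1] if saturation else 0)
            continue
        proposals.append(proposal)
        for comp, terms in proposal.items():
            for raw in terms:
                if raw and raw.strip():
                    aggregate.add_term(comp, raw, provenance="proposed")
        if catalog is not None:
            universe = expand_roadmap(aggregate, catalog, mode=match_mode)
            saturation.append(universe.overall_count)
        else:
            saturation.append(0)
    if len(failed) == n_iterations and n_iterations > 0:
        raise RuntimeError("expansion failed: every proposer iteration raised")
    return ExpansionRun(
        mode=mode,
        n_iterations=n_iterations,
        proposals=proposals,
        aggregate=aggregate,
        saturation=saturation,
        proposer=type(proposer).__name__,
        failed_iterations=failed,
    )


def saturation_plateau(run: ExpansionRun, tolerance: int = 0) -> int:
    """Smallest 1-based iteration index after which the cumulative matched-code
    count never grows by more than ``tolerance``; n_iterations if it never
    plateaus."""
    if run.n_iterations < 2:
        raise ValueError("plateau detection needs at least 2 iterations")
    sat = run.saturation
    for i in range(1, len(sat) + 1):
        if all(sat[j] - sat[j - 1] <= tolerance for j in range(i, len(sat))):
            return i
    return run.n_iterations


def write_expansion_run(run: ExpansionRun, path: str | Path) -> None:
    payload = {
        "mode": run.mode,
        "proposer": run.proposer,
        "n_iterations": run.n_iterations,
        "failed_iterations": run.failed_iterations,
        "saturation": run.saturation,
        "proposals": [
            {c.value: terms for c, terms in p.items()} for p in run.proposals
        ],
        "aggregate": {
            c.value: sorted(run.aggregate.term_set(c)) for c in ComponentId
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
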