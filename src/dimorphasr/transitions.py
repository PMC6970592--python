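"""Counting independent evolutionary transitions from a reconstruction.

Each internal node takes its MAP state (tips their observed state); every
edge whose parent and child states differ is one independent event,
classified by direction:

* monomorphic -> male_enlarged   : ``gain_male``
* monomorphic -> female_enlarged : ``gain_female``
* monomorphic -> dimorphic       : ``gain``  (binary mode, sex unknown)
* any dimorphic -> monomorphic   : ``reversion``
* male_enlarged <-> female_enlarged : ``conversion``

A Sankoff parsimony score on the same tip states is computed as an
independent lower-bound cross-check (the MAP-state tally can never beat
the minimum number of changes the tips require).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mk import ASRResult
from .phylo import PhyloTree

MONO = "monomorphic"
DIMORPHIC_STATES = ("dimorphic", "male_enlarged", "female_enlarged")

CLASSES = ("gain_male", "gain_female", "gain", "reversion", "conversion")
GAIN_CLASSES = ("gain_male", "gain_female", "gain")


def classify_transition(from_state: str, to_state: str) -> str:
    """Pure function of the ordered state pair."""
    if from_state == to_state:
        raise ValueError("not a transition")
    if from_state == MONO:
        return {"male_enlarged": "gain_male",
                "female_enlarged": "gain_female",
                "dimorphic": "gain"}[to_state]
    if to_state == MONO:
        return "reversion"
    return "conversion"


@dataclass
class TransitionEvent:
    parent_id: int
    child_id: int
    child_label: Optional[str]  # leaf label when the event is on a terminal edge
    from_state: str
    to_state: str
    klass: str
    ambiguous: bool = False     # MAP tie was broken on one endpoint


@dataclass
class TransitionSummary:
    muscle: str
    events: list[TransitionEvent]
    parsimony_score: int

    @property
    def totals(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for e in self.events:
            out[e.klass] += 1
        return out

    @property
    def grand_total(self) -> int:
        return len(self.events)

    @property
    def n_gains(self) -> int:
        return sum(self.totals[c] for c in GAIN_CLASSES)


def sankoff_parsimony(tree: PhyloTree, tips: Mapping[str, str],
                      states: Sequence[str]) -> int:
    """Minimum number of state changes under unit costs (exact for
    polytomies, unlike plain Fitch)."""
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = np.full(k, np.inf)
            c[index[tips[node.label]]] = 0.0
        else:
            c = np.zeros(k)
            for child in node.children:
                cc = cost[child.id]
                # keeping the child in the parent's state costs cc[i];
                # switching to the cheapest other state costs min_j cc[j] + 1
                c = c + np.minimum(cc, cc.min() + 1.0)
        cost[node.id] = c
    return int(cost[tree.root.id].min())


def count_transitions(asr: ASRResult, tips: Mapping[str, str],
                      tree: PhyloTree, *, muscle: str = "") -> TransitionSummary:
    """Tally edge events from MAP states.

    MAP ties (posteriors within 1e-9) are broken toward the parent's state
    — minimizing spurious events — and any event with a tie-broken endpoint
    is marked ambiguous.
    """
    state_of: dict[int, str] = {}
    ambiguous: set[int] = set(asr.tied_nodes)
    for node in tree.preorder():
        if node.is_leaf:
            state_of[node.id] = tips[node.label]
            continue
        if node.id in ambiguous and node.parent is not None:
            parent_state = state_of[node.parent.id]
            probs = asr.node_probs[node.id]
            top = probs.max()
            idx = asr.model.state_index(parent_state)
            if top - probs[idx] <= 1e-9:
                state_of[node.id] = parent_state
                continue
        state_of[node.id] = asr.map_states[node.id]

    events: list[TransitionEvent] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        a, b = state_of[node.parent.id], state_of[node.id]
        if a == b:
            continue
        events.append(TransitionEvent(
            parent_id=node.parent.id, child_id=node.id,
            child_label=node.label if node.is_leaf else None,
            from_state=a, to_state=b, klass=classify_transition(a, b),
            ambiguous=(node.parent.id in ambiguous or node.id in ambiguous)))
    score = sankoff_parsimony(tree, tips, asr.model.states)
    return TransitionSummary(muscle=muscle, events=events, parsimony_score=score)


def summarize_across_muscles(summaries: Sequence[TransitionSummary]) -> pd.DataFrame:
    """Pooled per-class totals over muscles, plus a grand-total row.

    Also reports each muscle's parsimony score so MAP-based tallies can be
    sanity-checked against the tip-state lower bound.
    """
    rows = []
    for s in summaries:
        rows.append({"muscle": s.muscle, **s.totals, "gains": s.n_gains,
                     "total": s.grand_total, "parsimony_score": s.parsimony_score})
    pooled = {"muscle": "ALL"}
    for c in CLASSES:
        pooled[c] = sum(r[c] for r in rows)
    pooled["gains"] = sum(r["gains"] for r in rows)
    pooled["total"] = sum(r["total"] for r in rows)
    pooled["parsimony_score"] = sum(r["parsimony_score"] for r in rows)
    rows.append(pooled)
    return pd.DataFrame(rows, columns=["muscle", *CLASSES, "gains", "total",
                                       "parsimony_score"])


def state_grid(tip_maps: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Species x muscle grid of classified states (summary-figure style)."""
    species = sorted({sp for m in tip_maps.values() for sp in m})
    rows = [{"species": sp, **{m: tip_maps[m].get(sp, "NA") for m in tip_maps}}
            for sp in species]
    return pd.DataFrame(rows, columns=["species", *tip_maps.keys()])
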