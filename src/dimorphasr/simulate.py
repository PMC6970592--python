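"""Synthetic data with the statistical structure the analysis assumes.

Three generators, composable into an end-to-end fixture:

* ``simulate_tree`` — seeded Yule (pure-birth) ultrametric species trees;
* ``simulate_mk_history`` — exact CTMC simulation of a discrete dimorphism
  character along the tree, with every realized jump recorded so that
  reconstruction accuracy can be scored against known truth;
* ``simulate_volumes`` — per-specimen raw muscle volumes: species- and
  sex-specific body scale x mean muscle fraction x lognormal noise, with
  the enlarged sex's hg fraction shifted so the *expected* Cohen's d of
  normalized volumes hits a configurable target (the shift is calibrated
  numerically, because normalization couples the seven fractions).

Defaults mirror the comparative design being emulated: 19 species, two
long-branch outgroups, >= 10 hemithoraces per sex per species, |d| = 2.5
for dimorphic cells, lognormal CV 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .io_data import HG_MUSCLES, MUSCLES, VolumeRecord, VolumeTable
from .mk import BINARY_STATES, TERNARY_STATES, MkModel
from .phylo import Node, PhyloTree

#: plausible mean fractions of the seven-muscle total (hg muscles are the
#: small ones; b1 and the tergopleurals dominate); must sum to 1
DEFAULT_BASELINE_FRACS = {
    "hg1": 0.10, "hg2": 0.06, "hg3": 0.05, "hg4": 0.04,
    "b1": 0.30, "d-Tp": 0.25, "v-Tp": 0.20,
}


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions emulated."""

    n_species: int = 19
    birth_rate: float = 1.0
    mk_q: float = 0.1               # true ER rate per unit branch length
    k_states: int = 2
    d_target: dict = field(default_factory=lambda: {
        "male_enlarged": 2.5, "female_enlarged": -2.5, "monomorphic": 0.0,
        "dimorphic": 2.5})
    n_per_sex: int = 10
    noise_cv: float = 0.15
    baseline_fracs: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FRACS))
    body_scale_sd: float = 0.3      # log-SD of the species body-size factor
    female_body_factor: float = 1.15  # females are the larger sex
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2 or self.birth_rate <= 0 or self.n_per_sex < 2:
            raise ValueError("counts and rates must be positive (n >= 2)")
        total = sum(self.baseline_fracs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"baseline fractions must sum to 1, got {total}")


@dataclass
class SimTruth:
    """Ground truth for one simulated character history."""

    tree: PhyloTree
    true_node_states: dict          # node id -> state (every node, tips included)
    true_events: list               # (child node id, from_state, to_state)
    realized_d: dict = field(default_factory=dict)  # species -> generative d


# -- trees --------------------------------------------------------------------

def yule_tip_count(duration: float, birth_rate: float,
                   rng: np.random.Generator) -> int:
    """Lineage count of a pure-birth process started from one lineage and
    run for a fixed time (E[count] = exp(birth_rate * duration))."""
    n, t = 1, 0.0
    while True:
        t += rng.exponential(1.0 / (birth_rate * n))
        if t > duration:
            return n
        n += 1


def simulate_tree(n_species: int, birth_rate: float,
                  rng: np.random.Generator) -> PhyloTree:
    """Yule tree grown from one lineage to ``n_species`` tips, then extended
    by one more censored waiting time so no terminal branch is zero; the
    result is ultrametric with depth O(log n / birth_rate)."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    counter = [0]

    def new_node() -> Node:
        node = Node(counter[0])
        counter[0] += 1
        return node

    root = new_node()
    birth_time = {root.id: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        parent.length = None  # set below
        split_time = t
        parent_birth = birth_time[parent.id]
        parent.length = split_time - parent_birth
        for _ in range(2):
            child = parent.add_child(new_node())
            birth_time[child.id] = split_time
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(active):
        leaf.length = t - birth_time[leaf.id]
    root.length = None
    for i, leaf in enumerate(sorted(active, key=lambda n: n.id)):
        leaf.label = f"sp{i + 1:02d}"
    return PhyloTree(root)


def tree_depth(tree: PhyloTree) -> float:
    return max(tree.depths().values())


# -- character histories ------------------------------------------------------

def simulate_mk_history(tree: PhyloTree, model: MkModel,
                        rng: np.random.Generator, *,
                        root_state: Optional[str] = None) -> SimTruth:
    """Exact CTMC path simulation: exponential waiting times at rate -Q_ii
    along every branch, every realized jump recorded as an event."""
    Q = model.Q()
    states = model.states
    if root_state is None:
        root_idx = int(rng.choice(model.k, p=model.prior_vector()))
    else:
        root_idx = model.state_index(root_state)
    node_state: dict[int, int] = {tree.root.id: root_idx}
    events: list[tuple[int, str, str]] = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = node_state[node.parent.id]
        remaining = node.length or 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                break
            remaining -= wait
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            nxt = int(rng.choice(model.k, p=probs / probs.sum()))
            events.append((node.id, states[s], states[nxt]))
            s = nxt
        node_state[node.id] = s
    return SimTruth(tree=tree,
                    true_node_states={nid: states[i]
                                      for nid, i in node_state.items()},
                    true_events=events)


# -- volumes ------------------------------------------------------------------

def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv * cv)))


@lru_cache(maxsize=256)
def _calibrated_shift(muscle: str, d_abs: float, cv: float,
                      fracs_key: tuple) -> float:
    """Fractional enlargement of one muscle's mean fraction such that the
    expected Cohen's d of its *normalized* volume between the shifted and
    baseline sex equals ``d_abs``.

    Solved by root-finding on a large common-random-numbers Monte-Carlo
    estimate of d(shift); normalization makes the seven fractions
    interdependent, so no closed form is attempted.
    """
    if d_abs == 0.0:
        return 0.0
    fracs = dict(fracs_key)
    order = list(fracs)
    base = np.array([fracs[m] for m in order])
    mi = order.index(muscle)
    sigma = _lognormal_sigma(cv)
    rng = np.random.default_rng(20200117)  # internal, fixed: calibration only
    n = 20000
    eps_a = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=(n, len(order))))
    eps_b = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=(n, len(order))))

    def realized_d(shift: float) -> float:
        fa = base.copy()
        fa[mi] *= 1.0 + shift
        va = fa * eps_a
        vb = base * eps_b
        xa = va[:, mi] / va.sum(axis=1)
        xb = vb[:, mi] / vb.sum(axis=1)
        sp = np.sqrt((xa.var(ddof=1) + xb.var(ddof=1)) / 2.0)
        return (xa.mean() - xb.mean()) / sp

    return float(brentq(lambda s: realized_d(s) - d_abs, 0.0, 5.0,
                        xtol=1e-6))


def simulate_volumes(species_states: Mapping[str, Mapping[str, str]],
                     config: SimConfig,
                     rng: np.random.Generator) -> VolumeTable:
    """Per-specimen raw volumes for every species and sex.

    ``species_states`` maps muscle -> (species -> state).  A
    ``male_enlarged`` (or binary ``dimorphic``) state shifts the male's mean
    fraction of that muscle; ``female_enlarged`` shifts the female's.
    Raw volume = body_scale(species, sex) x fraction x lognormal noise;
    body scale cancels out of normalized values, so dimorphism in overall
    body size never masquerades as muscle dimorphism.
    """
    species = sorted({sp for m in species_states.values() for sp in m})
    fracs_key = tuple(sorted(config.baseline_fracs.items()))
    sigma = _lognormal_sigma(config.noise_cv)
    records: list[VolumeRecord] = []
    for sp in species:
        species_scale = float(np.exp(rng.normal(0.0, config.body_scale_sd)))
        for sex in ("female", "male"):
            scale = species_scale * (config.female_body_factor
                                     if sex == "female" else 1.0)
            fracs = dict(config.baseline_fracs)
            for muscle, states in species_states.items():
                state = states.get(sp, "monomorphic")
                d = config.d_target.get(state, 0.0)
                if d == 0.0:
                    continue
                enlarged_sex = "female" if state == "female_enlarged" else "male"
                if sex == enlarged_sex:
                    shift = _calibrated_shift(muscle, abs(d),
                                              config.noise_cv, fracs_key)
                    fracs[muscle] = fracs[muscle] * (1.0 + shift)
            base = np.array([fracs[m] for m in MUSCLES])
            noise = np.exp(rng.normal(-sigma * sigma / 2.0, sigma,
                                      size=(config.n_per_sex, len(MUSCLES))))
            vols = scale * base * noise
            for i in range(config.n_per_sex):
                records.append(VolumeRecord(
                    species=sp, sex=sex, specimen_id=f"s{i + 1:02d}",
                    volumes={m: float(v) for m, v in zip(MUSCLES, vols[i])}))
    table = VolumeTable(records=records, provenance="synthetic")
    table.validate()
    return table


# -- end-to-end fixture -------------------------------------------------------

@dataclass
class FixtureBundle:
    table: VolumeTable
    tree: PhyloTree
    truths: dict  # muscle -> SimTruth
    config: SimConfig


def _attach_outgroups(ingroup: PhyloTree, depth: float,
                      n_out: int = 2) -> PhyloTree:
    """Nest the ingroup under a new root with long-branch outgroup tips,
    mimicking the distant outgroup species of a comparative design."""
    root = Node(0)
    stem = depth  # ingroup stem as long as the ingroup is deep
    out_len = 2.0 * depth + stem
    old_root = ingroup.root
    old_root.length = stem
    root.add_child(old_root)
    if n_out == 1:
        tip = root.add_child(Node(0, label="out1", length=out_len))
    else:
        joint = root.add_child(Node(0, length=depth))
        for i in range(n_out):
            joint.add_child(Node(0, label=f"out{i + 1}",
                                 length=out_len - depth))
    return PhyloTree(root)


def end_to_end_fixture(config: SimConfig) -> FixtureBundle:
    """A complete seeded bundle: 19-species tree (two outgroup-like long
    branches), four hg-muscle histories with distinct dynamics — one binary,
    two ternary, and one held monomorphic everywhere (the conserved-muscle
    control) — plus the matching per-specimen volume table."""
    rng = np.random.default_rng(config.seed)
    n_in = config.n_species - 2
    ingroup = simulate_tree(n_in, config.birth_rate, rng)
    tree = _attach_outgroups(ingroup, tree_depth(ingroup))

    q = config.mk_q
    model2 = MkModel(states=BINARY_STATES, rates=(q,))
    model3 = MkModel(states=TERNARY_STATES, rates=(q / 2.0,))
    truths: dict[str, SimTruth] = {}
    truths["hg1"] = simulate_mk_history(tree, model2, rng,
                                        root_state="monomorphic")
    for muscle in ("hg2", "hg3"):
        truths[muscle] = simulate_mk_history(tree, model3, rng,
                                             root_state="monomorphic")
    # hg4: the conserved muscle — monomorphic at every node, no events
    truths["hg4"] = SimTruth(
        tree=tree,
        true_node_states={n.id: "monomorphic" for n in tree.postorder()},
        true_events=[])

    leaf_label = {leaf.id: leaf.label for leaf in tree.leaves()}
    species_states = {
        muscle: {leaf_label[nid]: s
                 for nid, s in truth.true_node_states.items()
                 if nid in leaf_label}
        for muscle, truth in truths.items()}
    for muscle, truth in truths.items():
        truth.realized_d = {sp: config.d_target.get(state, 0.0)
                            for sp, state in species_states[muscle].items()}
    table = simulate_volumes(species_states, config, rng)
    return FixtureBundle(table=table, tree=tree, truths=truths, config=config)
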