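"""Two-round pooled-ligand screening ("ligand fishing") and its decoder.

A panel of candidate molecules is partitioned into pools.  Round 1
exposes each pool to the lysate and asks, per stabilized target protein,
which pools stabilize it.  Round 2 re-screens the members of every
positive pool one molecule at a time.  A molecule is assigned to a target
when both its pool and its singleton assay read positive — the simple
adaptive group-testing scheme that resolves a panel of n molecules in
(#pools + members of positive pools) assays instead of n.

The canonical worked example is the nine major Danhong-injection
ingredients split into three groups of three, which resolves salvianolic
acid A as the binder of adenosine kinase (ADK) and protocatechualdehyde
as the binder of ALDH1B1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: The nine major DHI ingredients in canonical pool order: consecutive
#: blocks of three reproduce screening groups (a), (b), (c).
DHI_INGREDIENTS = (
    "salvianolic acid A",
    "salvianolic acid B",
    "salvianic acid A",
    "rosmarinic acid",
    "hydroxysafflor yellow A",
    "protocatechualdehyde",
    "lithospermic acid",
    "caffeic acid",
    "ferulic acid",
)

#: The experimentally confirmed molecule -> target edges for that panel.
DHI_CONFIRMED_EDGES = frozenset(
    {("salvianolic acid A", "ADK"), ("protocatechualdehyde", "ALDH1B1")}
)


@dataclass(frozen=True)
class BindingMap:
    """Ground-truth bipartite molecule -> target edge set."""

    edges: frozenset[tuple[str, str]]

    @property
    def molecules(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    def binds(self, molecule: str, target: str) -> bool:
        return (molecule, target) in self.edges


@dataclass(frozen=True)
class PoolDesign:
    """Ordered partition of the molecule panel into consecutive blocks."""

    molecules: tuple[str, ...]
    pool_size: int
    pools: tuple[tuple[str, ...], ...]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def pool_of(self, molecule: str) -> int:
        for i, pool in enumerate(self.pools):
            if molecule in pool:
                return i
        raise KeyError(molecule)


@dataclass(frozen=True)
class ScreenOutcome:
    """Observed stabilized/not readouts for one screening round.

    ``readouts`` maps (unit, target) -> bool where a unit is a pool index
    (round 1) or a molecule id (round 2).
    """

    round: int
    units: tuple[object, ...]
    targets: tuple[str, ...]
    readouts: Mapping[tuple[object, str], bool]

    def positive_units(self, target: str) -> list[object]:
        return [u for u in self.units if self.readouts.get((u, target), False)]


@dataclass(frozen=True)
class BindingAssignment:
    """Decoded screen: unambiguous pairs, ambiguous targets, unresolved targets."""

    assignments: frozenset[tuple[str, str]]
    ambiguities: dict[str, tuple[str, ...]] = field(default_factory=dict)
    unresolved: frozenset[str] = frozenset()
    assay_count: int = 0


def make_pool_design(molecules: Sequence[str], pool_size: int = 3) -> PoolDesign:
    """Partition the panel into consecutive blocks of ``pool_size`` (last may be short)."""
    if not molecules:
        raise ValueError("molecule list must be nonempty")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    mols = tuple(molecules)
    pools = tuple(mols[i : i + pool_size] for i in range(0, len(mols), pool_size))
    return PoolDesign(mols, pool_size, pools)


def _observe(truly_positive: bool, fpr: float, fnr: float, rng: np.random.Generator) -> bool:
    flip = rng.random() < (fnr if truly_positive else fpr)
    return (not truly_positive) if flip else truly_positive


def simulate_pool_screen(
    design: PoolDesign,
    truth: BindingMap,
    targets: Sequence[str] | None = None,
    fpr: float = 0.0,
    fnr: float = 0.0,
    seed: int = 0,
) -> ScreenOutcome:
    """Round-1 readouts: pool x target, true-positive iff the pool holds a binder.

    Observed readouts flip true negatives with probability ``fpr`` and
    true positives with probability ``fnr``, independently per assay.
    """
    if not (0 <= fpr < 1 and 0 <= fnr < 1):
        raise ValueError("fpr and fnr must be in [0, 1)")
    target_panel = tuple(targets) if targets is not None else tuple(sorted(truth.targets))
    rng = np.random.default_rng(seed)
    readouts: dict[tuple[object, str], bool] = {}
    for pool_idx, pool in enumerate(design.pools):
        for t in target_panel:
            true_pos = any(truth.binds(m, t) for m in pool)
            readouts[(pool_idx, t)] = _observe(true_pos, fpr, fnr, rng)
    return ScreenOutcome(1, tuple(range(design.n_pools)), target_panel, readouts)


def simulate_singleton_screen(
    molecules: Sequence[str],
    truth: BindingMap,
    targets: Sequence[str] | None = None,
    fpr: float = 0.0,
    fnr: float = 0.0,
    seed: int = 0,
) -> ScreenOutcome:
    """Round-2 readouts: one assay per (molecule, target)."""
    if not (0 <= fpr < 1 and 0 <= fnr < 1):
        raise ValueError("fpr and fnr must be in [0, 1)")
    target_panel = tuple(targets) if targets is not None else tuple(sorted(truth.targets))
    rng = np.random.default_rng(seed)
    readouts: dict[tuple[object, str], bool] = {}
    for m in molecules:
        for t in target_panel:
            readouts[(m, t)] = _observe(truth.binds(m, t), fpr, fnr, rng)
    return ScreenOutcome(2, tuple(molecules), target_panel, readouts)


def round2_candidates(r1: ScreenOutcome, design: PoolDesign) -> tuple[str, ...]:
    """Molecules advanced to round 2: members of any round-1-positive pool."""
    mols: list[str] = []
    for pool_idx, pool in enumerate(design.pools):
        if any(r1.readouts.get((pool_idx, t), False) for t in r1.targets):
            mols.extend(pool)
    return tuple(mols)


def decode_two_round(
    r1: ScreenOutcome,
    r2: ScreenOutcome,
    design: PoolDesign,
) -> BindingAssignment:
    """Assign molecules to targets from the two screening rounds.

    (m, t) is supported when m's pool read positive for t in round 1 and
    m itself read positive for t in round 2.  A target with exactly one
    supported molecule yields an assignment; with several, the target is
    reported ambiguous (all supported molecules listed, never
    auto-resolved); a round-1-positive target with no supported molecule
    is unresolved.
    """
    advanced = set(round2_candidates(r1, design))
    stray = [m for m in r2.units if m not in advanced]
    if stray:
        raise ValueError(f"round-2 molecules outside any round-1-positive pool: {stray}")

    assignments: set[tuple[str, str]] = set()
    ambiguities: dict[str, tuple[str, ...]] = {}
    unresolved: set[str] = set()
    for t in r1.targets:
        pos_pools = set(r1.positive_units(t))
        if not pos_pools:
            continue
        supported = [
            m
            for m in r2.units
            if design.pool_of(m) in pos_pools and r2.readouts.get((m, t), False)
        ]
        if len(supported) == 1:
            assignments.add((supported[0], t))
        elif len(supported) > 1:
            ambiguities[t] = tuple(supported)
        else:
            unresolved.add(t)
    assay_count = design.n_pools + len(advanced)
    return BindingAssignment(frozenset(assignments), ambiguities, frozenset(unresolved), assay_count)


def evaluate_recovery(pred: BindingAssignment, truth: BindingMap) -> dict[str, object]:
    """Edge-wise confusion metrics; precision/recall None when their denominator is 0."""
    tp = len(pred.assignments & truth.edges)
    fp = len(pred.assignments - truth.edges)
    fn = len(truth.edges - pred.assignments)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "assay_count": pred.assay_count,
    }
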