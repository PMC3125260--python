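"""Synthetic binary drug profiles with planted correlated components.

Each planted component is a small set of substructure columns and a small
set of side-effect columns that co-occur on a random subset of drugs: the
carriers get 1s on both supports, every planted bit flips with a small
probability, and all remaining cells are independent Bernoulli background.
This emulates the structure the method is built to find — correlated sets
of chemical fragments and side-effects shared by overlapping drug groups —
while keeping the ground truth available for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import BinaryProfileMatrix

__all__ = [
    "PlantedComponent",
    "PlantedGroundTruth",
    "generate_planted_dataset",
    "generate_null_dataset",
    "default_planted_components",
]


@dataclass
class PlantedComponent:
    sub_support: frozenset[int]
    se_support: frozenset[int]
    drug_frac: float = 0.2
    flip_noise: float = 0.05

    def __post_init__(self) -> None:
        self.sub_support = frozenset(self.sub_support)
        self.se_support = frozenset(self.se_support)
        if not self.sub_support or not self.se_support:
            raise ValueError("component supports must be non-empty")
        if not 0 < self.drug_frac < 1:
            raise ValueError("drug_frac must be in (0, 1)")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")


@dataclass
class PlantedGroundTruth:
    components: list[PlantedComponent]
    member_drugs: list[frozenset[int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "sub_support": sorted(c.sub_support),
                "se_support": sorted(c.se_support),
                "drug_frac": c.drug_frac,
                "flip_noise": c.flip_noise,
                "member_drugs": sorted(m),
            }
            for c, m in zip(self.components, self.member_drugs)
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


def default_planted_components(
    p: int = 50, q: int = 40, n_components: int = 2, support_size: int = 5
) -> list[PlantedComponent]:
    """Two disjoint components with 5-feature supports, 20% carriers, 5% flips."""
    comps = []
    for k in range(n_components):
        comps.append(
            PlantedComponent(
                sub_support=frozenset(range(k * support_size, (k + 1) * support_size)),
                se_support=frozenset(range(k * support_size, (k + 1) * support_size)),
            )
        )
    if comps and max(max(c.sub_support) for c in comps) >= p:
        raise ValueError("substructure supports do not fit inside p columns")
    if comps and max(max(c.se_support) for c in comps) >= q:
        raise ValueError("side-effect supports do not fit inside q columns")
    return comps


def _check_disjoint(supports: list[frozenset[int]], what: str) -> None:
    seen: set[int] = set()
    for s in supports:
        if seen & s:
            raise ValueError(f"overlapping {what} supports across components")
        seen |= s


def generate_planted_dataset(
    n: int,
    p: int,
    q: int,
    components: list[PlantedComponent],
    background_rate: float = 0.05,
    seed: int = 0,
) -> tuple[BinaryProfileMatrix, BinaryProfileMatrix, PlantedGroundTruth]:
    """Plant component blocks into otherwise-independent Bernoulli background.

    Carrier subsets are drawn without replacement per component (components
    may share drugs).  Flip noise acts only on planted cells; background
    noise only on unplanted cells, so the two generative roles stay
    separable.  Fully reproducible from ``seed``.
    """
    if not 0 <= background_rate < 0.5:
        raise ValueError("background_rate must be in [0, 0.5)")
    _check_disjoint([c.sub_support for c in components], "substructure")
    _check_disjoint([c.se_support for c in components], "side-effect")
    for c in components:
        if max(c.sub_support) >= p or max(c.se_support) >= q:
            raise ValueError("component support outside matrix dimensions")

    rng = np.random.default_rng(seed)
    X = np.zeros((n, p), dtype=np.int8)
    Y = np.zeros((n, q), dtype=np.int8)
    planted_x = np.zeros((n, p), dtype=bool)
    planted_y = np.zeros((n, q), dtype=bool)
    members: list[frozenset[int]] = []

    for comp in components:
        size = int(round(comp.drug_frac * n))
        carriers = rng.choice(n, size=size, replace=False)
        members.append(frozenset(int(i) for i in carriers))
        sub = sorted(comp.sub_support)
        se = sorted(comp.se_support)
        block_x = np.ones((size, len(sub)), dtype=np.int8)
        block_y = np.ones((size, len(se)), dtype=np.int8)
        if comp.flip_noise > 0:
            block_x ^= rng.random(block_x.shape) < comp.flip_noise
            block_y ^= rng.random(block_y.shape) < comp.flip_noise
        X[np.ix_(carriers, sub)] = block_x
        Y[np.ix_(carriers, se)] = block_y
        planted_x[np.ix_(carriers, sub)] = True
        planted_y[np.ix_(carriers, se)] = True

    if background_rate > 0:
        bg_x = (rng.random((n, p)) < background_rate) & ~planted_x
        bg_y = (rng.random((n, q)) < background_rate) & ~planted_y
        X[bg_x] = 1
        Y[bg_y] = 1

    ids = [f"D{i:05d}" for i in range(n)]
    Xm = BinaryProfileMatrix(ids, [f"sub{j:04d}" for j in range(p)], X)
    Ym = BinaryProfileMatrix(ids, [f"se{j:04d}" for j in range(q)], Y)
    return Xm, Ym, PlantedGroundTruth(components=list(components), member_drugs=members)


def generate_null_dataset(
    n: int, p: int, q: int, rate: float = 0.1, seed: int = 0
) -> tuple[BinaryProfileMatrix, BinaryProfileMatrix]:
    """Independent i.i.d. Bernoulli(rate) X and Y with no planted structure."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < rate).astype(np.int8)
    Y = (rng.random((n, q)) < rate).astype(np.int8)
    ids = [f"D{i:05d}" for i in range(n)]
    return (
        BinaryProfileMatrix(ids, [f"sub{j:04d}" for j in range(p)], X),
        BinaryProfileMatrix(ids, [f"se{j:04d}" for j in range(q)], Y),
    )
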