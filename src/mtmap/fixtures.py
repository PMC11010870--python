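"""Seeded synthetic Boolean networks with known ground truth.

The conflict fixture emulates the canonical adaptive-resistance topology:
a constitutively active drug target sustains an undesired (prosurvival)
positive-feedback motif and suppresses a desired (apoptotic) motif; the two
motifs inhibit each other mutually, one direction relayed through an
interconnecting node.  Pinning the drug target alone triggers a race
(competitive stabilization) whose outcome is heterogeneous; additionally
pinning the interconnecting node resolves the conflict toward the desired
marker state.

Every generated fixture ships with a machine-checkable annotation (motif
node sets, interconnecting node, intended optimal pair) that the test suite
verifies against the motif detector, the merged-transition-map ranking and
the exhaustive perturbation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolnet import BooleanNetwork, PhenotypeSpec, parse_bnet
from .errors import ModelError

__all__ = [
    "FixtureSpec",
    "ConflictFixture",
    "make_toggle",
    "make_conflict_network",
    "make_exemplar_network",
    "make_random_boolean_network",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes of the two mutually inhibiting motifs, relay depth and seed."""

    motif_sizes: tuple[int, int] = (2, 2)
    interconnect_depth: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.motif_sizes) < 2:
            raise ModelError("motif sizes must be >= 2")
        if self.interconnect_depth < 1:
            raise ModelError("interconnect depth must be >= 1")


@dataclass
class ConflictFixture:
    network: BooleanNetwork
    phenotype: PhenotypeSpec
    target: str
    target_pin: int
    motif_yellow: tuple[str, ...]
    motif_green: tuple[str, ...]
    interconnect: str
    optimal_pair: dict[str, int]  # intended SPS-optimal combined pin set

    def annotation(self) -> dict:
        return {
            "target": self.target,
            "target_pin": self.target_pin,
            "motif_yellow": list(self.motif_yellow),
            "motif_green": list(self.motif_green),
            "interconnect": self.interconnect,
            "optimal_pair": dict(self.optimal_pair),
            "markers": dict(self.phenotype.markers),
        }


def make_toggle() -> BooleanNetwork:
    """Minimal bistable unit: A = !B, B = !A."""
    return parse_bnet("A, !B\nB, !A")


def _motif_chain(prefix: str, size: int, drive: str, inhibitor: str) -> list[str]:
    """Positive-feedback ring ``prefix1 .. prefixN``: the hub node
    ``prefix1`` is activated by the ring or by ``drive`` and inhibited by
    ``inhibitor``; the remaining nodes relay the hub around the ring."""
    rules = [f"{prefix}1, ({prefix}{size} | {drive}) & !{inhibitor}"]
    for i in range(2, size + 1):
        rules.append(f"{prefix}{i}, {prefix}{i - 1}")
    return rules


def make_conflict_network(spec: FixtureSpec = FixtureSpec()) -> ConflictFixture:
    """Two-motif conflict fixture with ground-truth annotation.

    Core wiring (sizes (2, 2), depth 1):

        T,  0                      drug node, OFF until treatment pins it ON
        y1, (y2 | T) & !i1         desired motif hub, relay-inhibited
        y2, y1
        g1, (g2 | T) & !y1         undesired motif hub, directly inhibited
        g2, g1
        i1, g1                     interconnecting relay (green -| yellow)
        Ma, y1 & !g1               antisurvival marker (weight +1)
        Mp, g1                     prosurvival marker (weight -1)

    The treatment pins T ON, activating both motifs at once; their mutual
    inhibition then races (competitive stabilization), so the pinned
    network stabilizes heterogeneously in either the desired or the
    undesired outcome.  The annotated optimal pair additionally pins the
    interconnect OFF, blocking the undesired motif's channel into the
    desired one and making the desired marker state the unique response.
    """
    ny, ng = spec.motif_sizes
    depth = spec.interconnect_depth
    relays = []
    relay_in = "g1"
    for d in range(1, depth + 1):
        relays.append(f"i{d}, {relay_in}")
        relay_in = f"i{d}"
    interconnect = f"i{depth}"
    rules = ["T, 0"]
    rules += _motif_chain("y", ny, "T", interconnect)
    rules += _motif_chain("g", ng, "T", "y1")
    rules += relays
    rules += ["Ma, y1 & !g1", "Mp, g1"]
    net = parse_bnet("\n".join(rules))
    pheno = PhenotypeSpec({"Ma": 1.0, "Mp": -1.0})
    return ConflictFixture(
        network=net,
        phenotype=pheno,
        target="T",
        target_pin=1,
        motif_yellow=tuple(f"y{i}" for i in range(1, ny + 1)),
        motif_green=tuple(f"g{i}" for i in range(1, ng + 1)),
        interconnect=interconnect,
        optimal_pair={"T": 1, interconnect: 0},
    )


def make_exemplar_network() -> ConflictFixture:
    """Four-motif exemplar: the conflict core plus two side motifs.

    On top of the mutually inhibiting pair, a "purple" bistable motif is
    driven directly by the perturbation (it saturates ON under the pin
    without touching the others), and a "blue" bistable motif is untouched
    by the perturbation node but shut down by the desired motif.  With the
    target pinned ON the network therefore converges to exactly three
    attractors: the desired outcome (blue forced off) and the two undesired
    outcomes in which blue retains either of its stable states.
    """
    base = make_conflict_network()
    text = [
        "T, 0",
        "y1, (y2 | T) & !i1",
        "y2, y1",
        "g1, (g2 | T) & !y1",
        "g2, g1",
        "i1, g1",
        "p1, p2 | T",
        "p2, p1",
        "b1, b2 & !y1",
        "b2, b1",
        "Ma, y1 & !g1",
        "Mp, g1",
    ]
    net = parse_bnet("\n".join(text))
    return ConflictFixture(
        network=net,
        phenotype=base.phenotype,
        target="T",
        target_pin=1,
        motif_yellow=("y1", "y2"),
        motif_green=("g1", "g2"),
        interconnect="i1",
        optimal_pair={"T": 1, "i1": 0},
    )


def make_random_boolean_network(
    n: int, mean_degree: float = 2.0, bias: float = 0.5, seed: int | None = None
) -> BooleanNetwork:
    """Random truth-table network for property testing.

    Each node draws an in-degree around ``mean_degree`` (clipped to
    [1, min(n, 4)]), distinct regulators, and a random truth table with ON
    bias ``bias``, rendered as a DNF rule (or a constant).  Deterministic
    for a fixed seed.
    """
    if n < 2:
        raise ModelError("random network needs n >= 2")
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n)]
    lines = []
    kmax = min(n, 4)
    for i, name in enumerate(names):
        k = int(np.clip(rng.poisson(mean_degree), 1, kmax))
        regs = [names[j] for j in rng.choice(n, size=k, replace=False)]
        table = rng.random(1 << k) < bias
        terms = []
        for mask in range(1 << k):
            if table[mask]:
                lits = [(r if (mask >> j) & 1 else f"!{r}") for j, r in enumerate(regs)]
                terms.append("(" + " & ".join(lits) + ")")
        if not terms:
            lines.append(f"{name}, 0")
        elif len(terms) == 1 << k:
            lines.append(f"{name}, 1")
        else:
            lines.append(f"{name}, " + " | ".join(terms))
    return parse_bnet("\n".join(lines))
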