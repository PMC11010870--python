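"""Report and graph export helpers (SIF, GraphML, JSON/CSV tables)."""

from __future__ import annotations

import json
from typing import Sequence

import networkx as nx
import pandas as pd

from .boolnet import BooleanNetwork, SignedGraph
from .dynamics import Attractor
from .transition_map import MergedTransitionMap, TargetScore


def signed_graph_to_sif(graph: SignedGraph) -> str:
    """Three-column SIF: source, interaction (+1/-1), target."""
    lines = [f"{u}\t{s:+d}\t{v}" for u, v, s in sorted(graph.edges)]
    return "\n".join(lines) + "\n"


def write_signed_graph_graphml(graph: SignedGraph, path: str) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def attractor_report(net: BooleanNetwork, attractors: Sequence[Attractor]) -> list[dict]:
    return [
        {
            "id": a.id,
            "kind": a.kind,
            "states": sorted(net.state_to_str(s) for s in a.states),
            "basin_fraction": a.basin_fraction,
            "preference": a.preference,
        }
        for a in attractors
    ]


def attractor_table(net: BooleanNetwork, attractors: Sequence[Attractor]) -> pd.DataFrame:
    return pd.DataFrame(attractor_report(net, attractors)).assign(
        states=lambda d: d["states"].map(lambda xs: ";".join(xs))
    )


def scores_table(scores: Sequence[TargetScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node": s.node,
                "conflict_score": s.conflict_score,
                "wff": s.wff,
                "desired_mass": s.desired_mass,
                "undesired_mass": s.undesired_mass,
                "control_type": s.control_type,
            }
            for s in scores
        ]
    )


def mtm_to_graphml(mtm: MergedTransitionMap, path: str) -> None:
    """Export the merged map: states as nodes (0/1 strings), edges labeled
    with segment label, source attractor and branch probability."""
    g = nx.MultiDiGraph()
    for seg in mtm.segments:
        for s, outs in seg.succ.items():
            name = mtm.net.state_to_str(s)
            g.add_node(name, absorbing=s in seg.absorbing)
            if s in seg.absorbing or not outs:
                continue
            p = 1.0 / len(outs)
            for t in outs:
                g.add_edge(
                    name,
                    mtm.net.state_to_str(t),
                    label=seg.label,
                    source_attractor=seg.source.id,
                    probability=p,
                )
    nx.write_graphml(g, path)


def dump_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
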