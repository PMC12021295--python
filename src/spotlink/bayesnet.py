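"""Minimal discrete Bayesian network with exact enumeration inference.

The connectivity network used for tracklet linking is small (seven nodes,
two or three states each), so inference is done by exact enumeration over
joint assignments — no sampling, no approximations.  The class is generic:
nodes form a DAG, each node carries a CPT ``P(node | parents)``, evidence is
a partial assignment, and queries return exact posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["DiscreteBayesNet"]


@dataclass
class _Node:
    name: str
    n_states: int
    parents: list[str]
    cpt: np.ndarray  # shape (*parent_cards, n_states); rows sum to 1


@dataclass
class DiscreteBayesNet:
    nodes: dict[str, _Node] = field(default_factory=dict)

    def add_node(
        self, name: str, n_states: int, parents: list[str] | None = None,
        cpt: np.ndarray | list | None = None,
    ) -> None:
        parents = list(parents or [])
        for p in parents:
            if p not in self.nodes:
                raise ValueError(f"parent {p!r} of {name!r} not defined yet")
        cpt = np.asarray(cpt, dtype=float)
        expected = tuple(self.nodes[p].n_states for p in parents) + (n_states,)
        if cpt.shape != expected:
            raise ValueError(
                f"CPT for {name!r} has shape {cpt.shape}, expected {expected}"
            )
        if not np.allclose(cpt.sum(axis=-1), 1.0):
            raise ValueError(f"CPT rows for {name!r} must sum to 1")
        self.nodes[name] = _Node(name, n_states, parents, cpt)

    def _joint(self, assignment: dict[str, int], names: list[str]) -> float:
        p = 1.0
        for name in names:
            node = self.nodes[name]
            idx = tuple(assignment[par] for par in node.parents)
            p *= float(node.cpt[idx + (assignment[node.name],)])
        return p

    def posterior(self, query: str, evidence: dict[str, int]) -> np.ndarray:
        """Exact P(query | evidence) by enumeration over hidden nodes.

        Barren hidden nodes (no path to query or evidence) marginalize to 1
        and are pruned before enumeration; the result is unchanged.
        """
        if query not in self.nodes:
            raise KeyError(query)
        for name, state in evidence.items():
            if not 0 <= state < self.nodes[name].n_states:
                raise ValueError(f"evidence {name}={state} out of range")
        relevant = set(evidence) | {query}
        changed = True
        while changed:  # close over ancestors of query/evidence
            changed = False
            for node in self.nodes.values():
                if node.name in relevant:
                    for p in node.parents:
                        if p not in relevant:
                            relevant.add(p)
                            changed = True
        names = [n for n in self.nodes if n in relevant]
        hidden = [n for n in names if n not in evidence and n != query]
        card = self.nodes[query].n_states
        scores = np.zeros(card)
        for q in range(card):
            assignment = dict(evidence, **{query: q})
            total = 0.0
            for states in product(*(range(self.nodes[h].n_states) for h in hidden)):
                assignment.update(zip(hidden, states))
                total += self._joint(assignment, names)
            scores[q] = total
        z = scores.sum()
        if z == 0:
            raise ValueError("evidence has zero probability under the model")
        return scores / z
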