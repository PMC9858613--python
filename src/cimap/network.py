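"""Ground-truth Bayesian network over cohort variables and ancestral sampling.

A :class:`GroundTruthNetwork` couples a variable dictionary with one
conditional probability table (CPT) per variable; the directed edge set is
implied by CPT parents and must be acyclic. Sampling draws each variable
after its parents in a lexicographic topological order using a named,
seedable generator (NumPy PCG64), so identical (network, n, seed) yields
identical cohorts byte-for-byte when written to CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, VariableDictionary
from .errors import DomainError, SchemaError

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class CPT:
    """Conditional probability table of one variable given its parents.

    ``table`` has shape (*parent level counts, child level count); each row
    (distribution over child levels for one parent-level combination) sums
    to 1 within 1e-12.
    """

    child: str
    parents: tuple
    table: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(self.parents))
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if table.ndim != len(self.parents) + 1:
            raise SchemaError(
                f"{self.child}: CPT has {table.ndim} axes for "
                f"{len(self.parents)} parents"
            )
        if table.min() < 0.0 or table.max() > 1.0 + 1e-12:
            raise SchemaError(f"{self.child}: CPT entries must lie in [0, 1]")
        rows = table.reshape(-1, table.shape[-1])
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise SchemaError(f"{self.child}: CPT rows must sum to 1")

    @property
    def n_child_levels(self) -> int:
        return self.table.shape[-1]


@dataclass
class GroundTruthNetwork:
    """DAG + CPTs used for ancestral sampling of synthetic cohorts.

    ``metadata`` records calibration provenance (target MI per edge, which
    marginals/strengths are unpublished defaults rather than published
    values).
    """

    dictionary: VariableDictionary
    cpts: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        names = set(self.dictionary.names)
        if set(self.cpts) != names:
            raise SchemaError("every variable needs exactly one CPT")
        for name, cpt in self.cpts.items():
            if cpt.child != name:
                raise SchemaError(f"CPT for {name!r} declares child {cpt.child!r}")
            for p in cpt.parents:
                if p not in names:
                    raise SchemaError(f"{name}: unknown parent {p!r}")
            spec = self.dictionary[name]
            if cpt.n_child_levels != spec.n_levels:
                raise SchemaError(
                    f"{name}: CPT has {cpt.n_child_levels} child levels, "
                    f"dictionary declares {spec.n_levels}"
                )
            expected_shape = tuple(
                self.dictionary[p].n_levels for p in cpt.parents
            ) + (spec.n_levels,)
            if cpt.table.shape != expected_shape:
                raise SchemaError(
                    f"{name}: CPT shape {cpt.table.shape} != {expected_shape}"
                )
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise SchemaError("network edges must form a DAG")

    @property
    def edges(self) -> list:
        """Directed (parent, child) pairs implied by the CPTs."""
        out = []
        for name in self.dictionary.names:
            for p in self.cpts[name].parents:
                out.append((p, name))
        return out

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.dictionary.names)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list:
        return list(nx.lexicographical_topological_sort(self.graph()))

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rng_algorithm": RNG_ALGORITHM,
            "variables": self.dictionary.to_dict()["variables"],
            "cpts": [
                {
                    "child": c.child,
                    "parents": list(c.parents),
                    "table": c.table.tolist(),
                }
                for c in (self.cpts[n] for n in self.dictionary.names)
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruthNetwork":
        dictionary = VariableDictionary.from_dict(payload)
        cpts = {
            e["child"]: CPT(e["child"], tuple(e["parents"]), np.array(e["table"]))
            for e in payload["cpts"]
        }
        return cls(dictionary, cpts, payload.get("metadata", {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthNetwork":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def simulate_cohort(network: GroundTruthNetwork, n: int, seed: int) -> Cohort:
    """Draw n records from the network by ancestral sampling.

    Variables are sampled in lexicographic topological order; each record's
    value is drawn from the CPT row selected by its already-sampled parents.
    Deterministic for fixed (network, n, seed).
    """
    if n < 0:
        raise DomainError("n must be non-negative")
    rng = np.random.default_rng(seed)
    codes: dict = {}
    for name in network.topological_order():
        cpt = network.cpts[name]
        k = cpt.n_child_levels
        if cpt.parents:
            sizes = [network.dictionary[p].n_levels for p in cpt.parents]
            flat = np.zeros(n, dtype=np.int64)
            for p, size in zip(cpt.parents, sizes):
                flat = flat * size + codes[p]
            rows = cpt.table.reshape(-1, k)[flat]
        else:
            rows = np.broadcast_to(cpt.table, (n, k))
        cum = np.cumsum(rows, axis=1)
        u = rng.random(n)
        codes[name] = np.minimum((cum < u[:, None]).sum(axis=1), k - 1)
    data = {}
    for name in network.dictionary.names:
        levels = np.asarray(network.dictionary[name].levels, dtype=object)
        data[name] = levels[codes[name]] if n else np.array([], dtype=object)
    return Cohort(pd.DataFrame(data, dtype=object), network.dictionary)
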