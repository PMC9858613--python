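"""Structure learning: significance-pruned skeleton, orientation, acyclicity.

The pipeline mirrors constraint-based discovery on discrete data:

1. ``learn_skeleton`` starts from the complete undirected graph and, for
   conditioning-set sizes 0..max_cond, tests each surviving pair for
   (conditional) independence given every subset of that size drawn from
   the union of the pair's neighbourhoods *frozen at the start of the size
   level* (the "stable" variant, making the result invariant to variable
   ordering). An edge is removed at the first non-rejection; retained edges
   carry their marginal MI and the maximum p-value observed.
2. ``orientation_score`` quantifies directional asymmetry as the maximum
   total-variation distance between the conditional distributions of one
   endpoint across levels of the other; the edge points toward the endpoint
   whose distribution shifts more.
3. ``orient_and_acyclify`` orients edges in decreasing MI order and
   resolves directed cycles deterministically (reverse the offending edge;
   if both directions close cycles, leave it unoriented and flagged), so
   the final map is acyclic.

Exhaustively conditioning on *all* other variables — the idealised test —
is hopeless for ~30 discrete variables at cohort sizes in the hundreds
(strata become exponentially sparse), hence the bounded conditioning order
(default 2) exposed as a parameter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .association import (
    DEFAULT_N_PERM,
    _cmi_bits,
    _cochran_ok,
    _counts_3d,
    _g_and_df,
    _permutation_pvalue,
    AssociationResult,
)
from .cohort import Cohort
from .errors import DomainError
from scipy.stats import chi2 as chi2_dist

_LN2 = np.log(2.0)


@dataclass
class Edge:
    """A retained association with its weight, p-value and orientation."""

    source: str
    target: str
    mi: float
    p: float
    oriented: bool = True
    orientation_score_forward: float | None = None
    orientation_score_reverse: float | None = None

    @property
    def pair(self) -> tuple:
        return tuple(sorted((self.source, self.target)))


@dataclass
class CIMap:
    """Conditional-independence map: MI-weighted edges, acyclic when oriented."""

    variables: list
    edges: list
    alpha: float
    provenance: dict = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                mi=float(e.mi),
                p=float(e.p),
                oriented=bool(e.oriented),
            )
        return g

    def directed_view(self) -> nx.DiGraph:
        """Oriented edges only (the subgraph required to be acyclic)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.source, e.target) for e in self.edges if e.oriented)
        return g

    def undirected_view(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.directed_view())

    def edge_pairs(self) -> set:
        return {e.pair for e in self.edges}

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self, path) -> None:
        lines = ["digraph cimap {"]
        for v in self.variables:
            lines.append(f'  "{v}";')
        for e in self.edges:
            style = "" if e.oriented else ", dir=none"
            lines.append(
                f'  "{e.source}" -> "{e.target}" '
                f'[label="{e.mi:.3f}", mi={e.mi:.6f}, p={e.p:.3g}{style}];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "mi": e.mi,
                    "p": e.p,
                    "oriented": e.oriented,
                    "score_forward": e.orientation_score_forward,
                    "score_reverse": e.orientation_score_reverse,
                }
                for e in self.edges
            ],
            columns=[
                "source", "target", "mi", "p", "oriented",
                "score_forward", "score_reverse",
            ],
        )


@dataclass
class SkeletonEdge:
    mi: float
    p_marginal: float
    p_max: float


@dataclass
class Skeleton:
    """Undirected pruning result with per-edge statistics and sep-sets."""

    variables: list
    edges: dict  # pair tuple -> SkeletonEdge
    sepsets: dict  # pair tuple -> tuple of conditioning variables
    alpha: float
    alpha_effective: float
    n_tests: int


class _CodedCohort:
    """Integer-coded view of a cohort for fast repeated testing."""

    def __init__(self, cohort: Cohort, names):
        self.names = list(names)
        self.index = {n: j for j, n in enumerate(self.names)}
        self.codes = cohort.codes(self.names)
        self.sizes = [cohort.dictionary[n].n_levels for n in self.names]

    def test(self, x, y, given, n_perm=DEFAULT_N_PERM, seed=0):
        """CI test on codes; G-test with permutation fallback on sparse strata."""
        cols = [self.index[x], self.index[y]] + [self.index[s] for s in given]
        sub = self.codes[:, cols]
        sub = sub[(sub >= 0).all(axis=1)]
        n = sub.shape[0]
        kx, ky = self.sizes[self.index[x]], self.sizes[self.index[y]]
        if n == 0:
            return AssociationResult(0.0, 0.0, 0, 1.0, 0, "empty")
        if given:
            zc = np.zeros(n, dtype=np.int64)
            kz = 1
            for j, s in enumerate(given):
                size = self.sizes[self.index[s]]
                zc = zc * size + sub[:, 2 + j]
                kz *= size
        else:
            zc = np.zeros(n, dtype=np.int64)
            kz = 1
        counts = _counts_3d(sub[:, 0], sub[:, 1], zc, kx, ky, kz)
        if _cochran_ok(counts.astype(float)):
            g, df = _g_and_df(counts.astype(float))
            if df >= 1:
                return AssociationResult(
                    mi=g / (2.0 * n * _LN2),
                    g=g,
                    df=df,
                    p=float(chi2_dist.sf(g, df)),
                    n_effective=n,
                    method="g-test",
                )
        obs = _cmi_bits(counts.astype(float))
        p = _permutation_pvalue(counts, n_perm, np.random.default_rng(seed))
        return AssociationResult(
            mi=obs,
            g=2.0 * n * _LN2 * obs,
            df=0,
            p=p,
            n_effective=n,
            method="permutation",
        )


def learn_skeleton(
    cohort: Cohort,
    alpha: float = 0.05,
    max_cond: int = 2,
    seed: int = 0,
    correction: str | None = None,
    n_perm: int = DEFAULT_N_PERM,
) -> Skeleton:
    """Significance-pruned undirected skeleton over all variable pairs.

    Parameters
    ----------
    alpha : float
        Retention significance level (uncorrected by default, matching the
        study's p < 0.05 convention).
    max_cond : int
        Maximum conditioning-set size (clamped to n_variables - 2 with a
        warning). Conditioning sets are drawn from the union of the pair's
        neighbourhoods frozen at the start of each size level.
    correction : {None, "bonferroni", "bh"}
        ``bonferroni`` divides alpha by the number of variable pairs at
        every stage; ``bh`` applies Benjamini-Hochberg to the marginal
        screen only (later conditional tests run at raw alpha).
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    if max_cond < 0:
        raise DomainError("max_cond must be non-negative")
    names = sorted(cohort.dictionary.names)
    k = len(names)
    if k < 2:
        return Skeleton(names, {}, {}, alpha, alpha, 0)
    if max_cond > k - 2:
        warnings.warn(
            f"max_cond={max_cond} clamped to {k - 2} for {k} variables",
            stacklevel=2,
        )
        max_cond = k - 2
    coded = _CodedCohort(cohort, names)
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    alpha_eff = alpha / n_pairs if correction == "bonferroni" else alpha
    adj = {v: set(names) - {v} for v in names}
    edges: dict = {}
    sepsets: dict = {}
    n_tests = 0

    # marginal screen (conditioning size 0)
    marginal = {}
    for x, y in pairs:
        res = coded.test(x, y, (), n_perm=n_perm, seed=seed)
        n_tests += 1
        marginal[(x, y)] = res
    if correction == "bh":
        ps = np.array([marginal[p].p for p in pairs])
        order = np.argsort(ps, kind="stable")
        m = len(ps)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = ps[order] <= thresh
        k_max = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
        rejected = {pairs[i] for i in order[:k_max]}
        keep = {p: (p in rejected) for p in pairs}
    else:
        keep = {p: (marginal[p].p <= alpha_eff) for p in pairs}
    for x, y in pairs:
        res = marginal[(x, y)]
        if keep[(x, y)]:
            edges[(x, y)] = SkeletonEdge(mi=res.mi, p_marginal=res.p, p_max=res.p)
        else:
            adj[x].discard(y)
            adj[y].discard(x)
            sepsets[(x, y)] = ()

    for size in range(1, max_cond + 1):
        frozen = {v: set(adj[v]) for v in names}
        for x, y in pairs:
            if (x, y) not in edges:
                continue
            candidates = sorted((frozen[x] | frozen[y]) - {x, y})
            if len(candidates) < size:
                continue
            removed = False
            for subset in itertools.combinations(candidates, size):
                res = coded.test(x, y, subset, n_perm=n_perm, seed=seed)
                n_tests += 1
                rec = edges[(x, y)]
                rec.p_max = max(rec.p_max, res.p)
                if res.p > alpha_eff:
                    removed = True
                    sepsets[(x, y)] = subset
                    break
            if removed:
                del edges[(x, y)]
                adj[x].discard(y)
                adj[y].discard(x)

    return Skeleton(names, edges, sepsets, alpha, alpha_eff, n_tests)


def orientation_score(cohort: Cohort, x: str, y: str) -> tuple:
    """Directional asymmetry scores (score(x->y), score(y->x)).

    score(x->y) is the maximum, over pairs of x levels with non-zero
    counts, of the total-variation distance between the empirical
    conditional distributions of y given those levels; level pairs with an
    undefined conditional are skipped. Returns None for a score with no
    valid level pair.
    """
    codes = cohort.codes([x, y])
    codes = codes[(codes >= 0).all(axis=1)]
    kx = cohort.dictionary[x].n_levels
    ky = cohort.dictionary[y].n_levels
    counts = _counts_3d(
        codes[:, 0], codes[:, 1], np.zeros(codes.shape[0], dtype=np.int64),
        kx, ky, 1,
    )[0].astype(float)

    def score(table):  # rows condition, columns respond
        margins = table.sum(axis=1)
        valid = np.flatnonzero(margins > 0)
        best = None
        for i, j in itertools.combinations(valid, 2):
            tv = 0.5 * float(
                np.abs(table[i] / margins[i] - table[j] / margins[j]).sum()
            )
            best = tv if best is None else max(best, tv)
        return best

    return score(counts), score(counts.T)


def orient_and_acyclify(skeleton: Skeleton, scores: dict) -> CIMap:
    """Deterministically orient skeleton edges and remove directed cycles.

    Edges are processed in decreasing MI (ties broken lexicographically).
    Each edge's preferred direction follows its asymmetry scores (ties:
    lexicographically smaller endpoint becomes the source). A preferred
    direction that would close a directed cycle is reversed; if both
    directions close cycles the edge is kept unoriented and flagged.
    """
    ordered = sorted(
        skeleton.edges.items(), key=lambda kv: (-kv[1].mi, kv[0][0], kv[0][1])
    )
    g = nx.DiGraph()
    g.add_nodes_from(skeleton.variables)
    out_edges = []
    for (u, v), rec in ordered:
        fwd, rev = scores.get((u, v), (None, None))
        if fwd is None or rev is None:
            # undefined conditionals on every level pair: leave unoriented
            out_edges.append(
                Edge(u, v, rec.mi, rec.p_max, oriented=False,
                     orientation_score_forward=fwd,
                     orientation_score_reverse=rev)
            )
            continue
        if np.isclose(fwd, rev):
            preferred = (u, v)  # lexicographic source on ties
        elif fwd > rev:
            preferred = (u, v)
        else:
            preferred = (v, u)
        chosen = None
        for s, t in (preferred, preferred[::-1]):
            if not (g.has_node(t) and g.has_node(s) and nx.has_path(g, t, s)):
                chosen = (s, t)
                break
        if chosen is None:
            out_edges.append(
                Edge(u, v, rec.mi, rec.p_max, oriented=False,
                     orientation_score_forward=fwd, orientation_score_reverse=rev)
            )
            continue
        g.add_edge(*chosen)
        s, t = chosen
        sf, sr = (fwd, rev) if (s, t) == (u, v) else (rev, fwd)
        out_edges.append(
            Edge(s, t, rec.mi, rec.p_max, oriented=True,
                 orientation_score_forward=sf, orientation_score_reverse=sr)
        )
    return CIMap(
        variables=list(skeleton.variables),
        edges=out_edges,
        alpha=skeleton.alpha,
        provenance={"alpha_effective": skeleton.alpha_effective,
                    "n_tests": skeleton.n_tests},
    )


def build_cimap(
    cohort: Cohort,
    alpha: float = 0.05,
    max_cond: int = 2,
    seed: int = 0,
    correction: str | None = None,
    n_perm: int = DEFAULT_N_PERM,
) -> CIMap:
    """Full pipeline: skeleton, per-edge orientation scores, acyclic map."""
    skeleton = learn_skeleton(
        cohort, alpha=alpha, max_cond=max_cond, seed=seed,
        correction=correction, n_perm=n_perm,
    )
    scores = {
        pair: orientation_score(cohort, *pair) for pair in skeleton.edges
    }
    cimap = orient_and_acyclify(skeleton, scores)
    cimap.provenance.update(
        {
            "alpha": alpha,
            "max_cond": max_cond,
            "seed": seed,
            "correction": correction,
            "n_records": cohort.n,
        }
    )
    return cimap


def components(cimap: CIMap) -> list:
    """Connected components of the undirected view, largest first.

    Ties are broken by the lexicographically smallest member; members are
    sorted within each component.
    """
    comps = [sorted(c) for c in nx.connected_components(cimap.undirected_view())]
    return sorted(comps, key=lambda c: (-len(c), c[0]))
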