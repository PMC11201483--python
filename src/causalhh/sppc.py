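"""Constraint phase: search-space restriction and v-structure priors.

Three stages, all driven by partial-correlation CI tests:

1. **Markov random field.**  Connect every pair whose *full* partial
   correlation (conditioning on all other variables) is significant.
   Under faithfulness this graph approximates the moral graph; it becomes
   both the global search space (GSS) and the initial local one (LSS).

2. **Local d-separation search.**  Moralisation turns every v-structure
   into a triangle, so some MRF edges are spurious spouse links.  For
   each MRF edge a greedy search looks for a separating set, starting
   from the smaller of the two endpoint neighbourhoods and repeatedly
   removing the conditioning node with an *open simple path* (OSP) whose
   removal leaves the fewest OSP nodes behind.  Separated edges are
   dropped from the LSS (only).

3. **V-structure identification.**  For each separated pair, a common
   neighbour excluded from the separating set that re-opens the path when
   conditioned on is an unshielded collider; both parent edges enter the
   prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from causalhh.model_core import (
    DataMatrix,
    SearchSpaces,
    SepSetRecord,
    UndirectedGraph,
    VStructurePrior,
    creates_cycle,
)
from causalhh.partial_correlation import CITester

logger = logging.getLogger(__name__)


@dataclass
class SppcResult:
    spaces: SearchSpaces
    priors: VStructurePrior
    sepsets: list[SepSetRecord] = field(default_factory=list)

    @property
    def mrf(self) -> UndirectedGraph:
        return self.spaces.gss


def _as_tester(data, k: float) -> CITester:
    if isinstance(data, CITester):
        return data
    if isinstance(data, DataMatrix):
        return CITester.from_data(data, k)
    raise TypeError(f"expected DataMatrix or CITester, got {type(data).__name__}")


def build_mrf(data, k: float = 0.01) -> UndirectedGraph:
    """Stage 1: edge {i, j} iff the full partial correlation is significant."""
    tester = _as_tester(data, k)
    rho = tester.full_partials()
    g = UndirectedGraph.empty(tester.n)
    for i in range(tester.n):
        for j in range(i + 1, tester.n):
            if tester.decide(float(rho[i, j])).dependent:
                g.add_edge(i, j)
    return g


def osp_members(data, i: int, j: int, Z, k: float = 0.01) -> set[int]:
    """Conditioning-set members with an open simple path to the pair.

    Zm qualifies when both rho_{i,Zm | Z+{j}-{Zm}} and
    rho_{j,Zm | Z+{i}-{Zm}} are significant.
    """
    tester = _as_tester(data, k)
    Zs = set(Z)
    out = set()
    for zm in sorted(Zs):
        rest = Zs - {zm}
        if tester.dependent(i, zm, rest | {j}) and tester.dependent(j, zm, rest | {i}):
            out.add(zm)
    return out


def find_dsep(data, i: int, j: int, mrf: UndirectedGraph, k: float = 0.01) -> SepSetRecord:
    """Stage 2 greedy search for a separating set for the MRF edge {i, j}.

    The initial conditioning set is the smaller of the two endpoint
    neighbourhoods (either full neighbourhood suffices when a separator
    exists at all); each round removes the OSP node minimising the number
    of OSP nodes left, ties to the lowest index, until independence is
    reached or no OSP node remains.
    """
    tester = _as_tester(data, k)
    mb_i = set(mrf.neighbors(i).tolist()) - {j}
    mb_j = set(mrf.neighbors(j).tolist()) - {i}
    Z = set(mb_i if len(mb_i) <= len(mb_j) else mb_j)
    removed: list[int] = []
    while True:
        if not tester.dependent(i, j, Z):
            return SepSetRecord(i=i, j=j, found=True, Z=frozenset(Z), removed=tuple(removed))
        osp = osp_members(tester, i, j, Z, k)
        if not osp:
            return SepSetRecord(i=i, j=j, found=False, Z=frozenset(Z), removed=tuple(removed))
        best, best_count = None, None
        for zm in sorted(osp):
            count = len(osp_members(tester, i, j, Z - {zm}, k))
            if best_count is None or count < best_count:
                best, best_count = zm, count
        Z.remove(best)
        removed.append(best)


def identify_vstructures(
    data, records: list[SepSetRecord], mrf: UndirectedGraph, k: float = 0.01
) -> VStructurePrior:
    """Stage 3: unshielded-collider detection on the separated pairs.

    For a separated pair (i, j), a common MRF neighbour U outside the
    final separating set is a collider iff conditioning on it restores
    dependence; then i -> U and j -> U enter the prior.  A pair whose
    insertion would make the prior edge set cyclic is dropped.
    """
    tester = _as_tester(data, k)
    prior = VStructurePrior()
    adj = prior.as_adjacency(tester.n)
    for rec in records:
        if not rec.found:
            continue
        common = set(mrf.neighbors(rec.i).tolist()) & set(mrf.neighbors(rec.j).tolist())
        for u in sorted(common - set(rec.Z) - {rec.i, rec.j}):
            if not tester.dependent(rec.i, rec.j, set(rec.Z) | {u}):
                continue
            e1, e2 = (rec.i, u), (rec.j, u)
            new = [e for e in (e1, e2) if e not in prior.edges]
            ok = True
            for p, c in new:
                if creates_cycle(adj, p, c):
                    ok = False
                    break
                adj[p, c] = True
            if ok:
                prior.edges.update((e1, e2))
            else:
                for p, c in new:
                    adj[p, c] = False
                logger.warning(
                    "dropping collider edges %s, %s: would make the prior cyclic", e1, e2
                )
    return prior


def run_sppc(data, k: float = 0.01) -> SppcResult:
    """The full three-stage constraint phase."""
    tester = _as_tester(data, k)
    mrf = build_mrf(tester, k)
    gss = mrf.copy()
    lss = mrf.copy()
    records = []
    for i, j in mrf.edges():
        rec = find_dsep(tester, i, j, mrf, k)
        records.append(rec)
        if rec.found:
            lss.remove_edge(i, j)
    priors = identify_vstructures(tester, records, mrf, k)
    logger.info(
        "SPPC: %d MRF edges, %d separated, %d prior edges",
        mrf.edge_count(),
        sum(r.found for r in records),
        len(priors),
    )
    return SppcResult(
        spaces=SearchSpaces(gss=gss, lss=lss), priors=priors, sepsets=records
    )
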