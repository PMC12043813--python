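"""Incremental cost-effectiveness analysis: NMB, dominance, ICER chain.

Strategies are compared on total discounted cost and QALYs.  The fully
incremental analysis sorts by cost, removes strictly dominated strategies
(at least as costly and no more effective than another), then iteratively
removes extendedly dominated ones (those whose ICER versus the previous
frontier point exceeds the next ICER along the chain, meaning a mix of
two other strategies would deliver more QALYs at lower cost).  ICERs are
reported along the surviving chain; net monetary benefit (NMB) at a
willingness-to-pay threshold lambda is ``qalys * lambda - cost``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["nmb", "FrontierEntry", "FrontierResult", "incremental_frontier",
           "rank_by_nmb"]

ON_FRONTIER = "on-frontier"
REFERENCE = "reference"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly dominated"


def nmb(cost: float, qalys: float, threshold: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    return qalys * threshold - cost


@dataclass
class FrontierEntry:
    name: str
    cost: float
    qalys: float
    label: str
    icer: float | None = None  # vs previous frontier strategy; None for reference
    nmb: float | None = None


@dataclass
class FrontierResult:
    entries: list[FrontierEntry]

    @property
    def frontier(self) -> list[FrontierEntry]:
        return [e for e in self.entries
                if e.label in (REFERENCE, ON_FRONTIER)]

    def entry(self, name: str) -> FrontierEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def incremental_frontier(results: list[tuple[str, float, float]],
                         threshold: float | None = None) -> FrontierResult:
    """Fully incremental analysis over (name, cost, qalys) triples.

    Equal-cost strategies are treated as one comparison group: only the
    highest-QALY one can stay on the frontier.  Strategies equal in both
    cost and QALYs are all retained on the frontier and share an ICER.
    ICERs are computed from unrounded inputs; rounding is a display
    concern.
    """
    names = [r[0] for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    if not results:
        raise ValueError("at least one strategy required")

    order = sorted(results, key=lambda r: (r[1], -r[2]))
    labels: dict[str, str] = {}

    # strict dominance: another strategy costs no more and yields no fewer
    # QALYs, with at least one strict inequality
    for name, cost, q in order:
        for oname, ocost, oq in order:
            if oname == name:
                continue
            if ocost <= cost and oq >= q and (ocost < cost or oq > q):
                labels[name] = DOMINATED
                break

    chain = [r for r in order if r[0] not in labels]

    # extended dominance: remove interior points with non-increasing ICERs
    removed = True
    while removed and len(chain) > 2:
        removed = False
        for i in range(1, len(chain) - 1):
            lo, mid, hi = chain[i - 1], chain[i], chain[i + 1]
            icer_mid = _icer(lo, mid)
            icer_hi = _icer(mid, hi)
            if icer_mid is not None and icer_hi is not None and icer_mid >= icer_hi:
                labels[mid[0]] = EXTENDEDLY_DOMINATED
                del chain[i]
                removed = True
                break

    entries = []
    chain_names = [r[0] for r in chain]
    for name, cost, q in order:
        label = labels.get(name)
        icer = None
        if label is None:
            idx = chain_names.index(name)
            if idx == 0:
                label = REFERENCE
            else:
                label = ON_FRONTIER
                icer = _icer(chain[idx - 1], chain[idx])
        entries.append(FrontierEntry(
            name=name, cost=cost, qalys=q, label=label, icer=icer,
            nmb=None if threshold is None else nmb(cost, q, threshold),
        ))
    return FrontierResult(entries=entries)


def _icer(lo: tuple[str, float, float], hi: tuple[str, float, float]) -> float | None:
    dq = hi[2] - lo[2]
    dc = hi[1] - lo[1]
    if dq == 0.0:
        return None  # equal effectiveness: no meaningful ratio
    return dc / dq


def rank_by_nmb(results: list[tuple[str, float, float]],
                threshold: float) -> list[tuple[str, float]]:
    """Strategies in descending NMB order (stable for ties)."""
    scored = [(name, nmb(cost, q, threshold)) for name, cost, q in results]
    return sorted(scored, key=lambda x: -x[1])
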