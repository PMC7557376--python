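"""Per-community top-t b/d selection, confirmation bookkeeping, and hints.

Within each community the drugs with the highest betweenness/degree are the
most promising repurposing candidates: a high b/d node bridges communities
while having few documented links of its own.  Drugs with b/d = 0 are never
reported.  Ranks are grouped: drugs tied on b/d share a rank cell, and the
top ``t`` rank groups are returned, so a tie at the cut never silently
drops a drug.

A selected drug is *confirmed* when one of its annotation tags matches a
dominant tag of its community (case-insensitive exact match) with DATABASE
or LITERATURE evidence; the remaining selected drugs are the repurposing
hints B_x^h = B_x^t \\ B_x^c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

from ddsn.community import CommunityLabel, Partition
from ddsn.io import AnnotationTable, Evidence

Node = Hashable

CONFIRMED_DB = "confirmed_db"
CONFIRMED_LIT = "confirmed_lit"
HINT = "hint"


@dataclass(frozen=True)
class HintEntry:
    drug: str
    bd: float
    rank: int
    status: str  # confirmed_db | confirmed_lit | hint


@dataclass
class CommunityHints:
    community: int
    label_tags: dict[str, float]
    unresolved: bool
    top: list[HintEntry] = field(default_factory=list)

    @property
    def confirmed(self) -> list[HintEntry]:
        return [e for e in self.top if e.status != HINT]

    @property
    def hints(self) -> list[HintEntry]:
        return [e for e in self.top if e.status == HINT]


@dataclass
class HintReport:
    t: int
    communities: list[CommunityHints] = field(default_factory=list)

    @property
    def all_hints(self) -> list[HintEntry]:
        return [e for c in self.communities for e in c.hints]


def top_bd(
    partition: Partition, centrality, t: int = 5
) -> dict[int, list[tuple[str, float]]]:
    """Top-t rank groups by b/d per community (zeros excluded, ties grouped).

    ``centrality`` is the DataFrame from :func:`ddsn.centrality.centrality_table`
    (indexed by drug id with a ``bd`` column).  Returns, per community index,
    a list of (drug, bd) sorted by bd descending then drug id.
    """
    if t < 1:
        raise ValueError("t must be a positive integer")
    bd = centrality["bd"]
    missing = {str(n) for n in partition.membership} - set(bd.index.astype(str))
    if missing:
        raise ValueError(f"centrality table lacks nodes: {sorted(missing)[:5]}")
    out: dict[int, list[tuple[str, float]]] = {}
    for i, members in enumerate(partition.communities, start=1):
        scored = sorted(
            ((str(n), float(bd.loc[str(n)])) for n in members if float(bd.loc[str(n)]) > 0),
            key=lambda p: (-p[1], p[0]),
        )
        values_seen: list[float] = []
        selected: list[tuple[str, float]] = []
        for drug, value in scored:
            if not values_seen or value < values_seen[-1]:
                if len(values_seen) == t:
                    break
                values_seen.append(value)
            selected.append((drug, value))
        out[i] = selected
    return out


def _status(drug: str, dominant: set[str], ann: AnnotationTable) -> str:
    match = {tag for tag in ann.tags_of(drug) if tag.lower() in dominant}
    if not match:
        return HINT
    sources = {ann.evidence_of(drug, tag) for tag in match}
    if Evidence.DATABASE in sources:
        return CONFIRMED_DB
    if Evidence.LITERATURE in sources:
        return CONFIRMED_LIT
    return HINT  # annotated but without usable evidence


def select_hints(
    tops: dict[int, list[tuple[str, float]]],
    labels: list[CommunityLabel],
    ann: AnnotationTable,
    t: int = 5,
) -> HintReport:
    """Split each community's top-b/d list into confirmed drugs and hints.

    Communities whose label is UNRESOLVED emit their whole list as hints,
    flagged ``unresolved=True``.
    """
    by_index = {lab.community: lab for lab in labels}
    report = HintReport(t=t)
    for community in sorted(tops):
        lab = by_index.get(community, CommunityLabel(community=community))
        dominant = {tag.lower() for tag in lab.dominant_tags}
        entries = []
        rank, last = 0, None
        for drug, bd in tops[community]:
            if last is None or bd < last:
                rank += 1
                last = bd
            entries.append(
                HintEntry(drug=drug, bd=bd, rank=rank, status=_status(drug, dominant, ann))
            )
        report.communities.append(
            CommunityHints(
                community=community,
                label_tags=dict(lab.dominant_tags),
                unresolved=not lab.resolved,
                top=entries,
            )
        )
    return report


def confirmation_summary(
    partition: Partition, labels: list[CommunityLabel], ann: AnnotationTable
):
    """Per-community confirmation percentages plus the overall rate.

    For each community: the percentage of members whose annotations match a
    dominant tag with DATABASE evidence, with (at best) LITERATURE evidence,
    and the unconfirmed remainder; the three sum to 100.  Returns
    ``(DataFrame, overall_rate_percent)`` where the overall rate is
    sum_x |confirmed in C_x| / sum_x |C_x| in percent.
    """
    import pandas as pd

    by_index = {lab.community: lab for lab in labels}
    rows = []
    confirmed_total = 0
    member_total = 0
    for i, members in enumerate(partition.communities, start=1):
        lab = by_index.get(i, CommunityLabel(community=i))
        dominant = {tag.lower() for tag in lab.dominant_tags}
        n = len(members)
        db = lit = 0
        for node in members:
            status = _status(str(node), dominant, ann)
            if status == CONFIRMED_DB:
                db += 1
            elif status == CONFIRMED_LIT:
                lit += 1
        confirmed_total += db + lit
        member_total += n
        rows.append(
            {
                "community": i,
                "size": n,
                "database_pct": 100.0 * db / n,
                "literature_pct": 100.0 * lit / n,
                "not_confirmed_pct": 100.0 * (n - db - lit) / n,
            }
        )
    overall = 100.0 * confirmed_total / member_total if member_total else 0.0
    return pd.DataFrame(rows).set_index("community"), overall
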