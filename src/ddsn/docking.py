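"""Docking work-order construction for repurposing-hint verification.

For a pharmacological property phi, the tested drugs (the hinted drugs plus
negative controls unlikely to carry phi) are paired with *every* relevant
target — the Cartesian product D_t x T — while reference drugs (documented
carriers of phi, inside and outside the hint's community) are paired only
with targets they are already known to interact with.  The output is a
plain pair table ready for external docking software; running the docking
is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

ROLE_TESTED = "tested"
ROLE_REF_IN = "ref_in"
ROLE_REF_OUT = "ref_out"


@dataclass
class DockingPlan:
    """Drug/target sets and the role-labelled drug-target pair table."""

    property_tag: str
    hinted: list[str]
    negatives: list[str]
    refs_in: list[str]
    refs_out: list[str]
    targets_in: list[str]
    targets_out: list[str]
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def tested_drugs(self) -> list[str]:
        return sorted(set(self.hinted) | set(self.negatives))

    @property
    def targets(self) -> list[str]:
        return sorted(set(self.targets_in) | set(self.targets_out))

    @property
    def n_tested_pairs(self) -> int:
        return int((self.pairs["role"] == ROLE_TESTED).sum())


def build_plan(
    property_tag: str,
    hints: Iterable[str],
    refs_in: Iterable[str],
    refs_out: Iterable[str],
    negatives: Iterable[str],
    targets_in: Iterable[str],
    targets_out: Iterable[str],
    known: Iterable[tuple[str, str]] = (),
) -> DockingPlan:
    """Build the docking pair lists for property ``property_tag``.

    * tested pairs: every (drug, target) with drug in hints+negatives and
      target in targets_in+targets_out (full Cartesian product);
    * reference pairs: (drug, target) restricted to pairs present in
      ``known`` — in-community references against in-community targets,
      out-of-community references against the remaining targets.

    Raises on an empty hint set or an empty target set; hinted and negative
    drugs must be disjoint.
    """
    hints = sorted(set(hints))
    negatives = sorted(set(negatives))
    refs_in = sorted(set(refs_in))
    refs_out = sorted(set(refs_out))
    targets_in = sorted(set(targets_in))
    targets_out = sorted(set(targets_out))
    known = set(known)

    if not hints:
        raise ValueError("docking plan needs at least one hinted drug")
    targets = sorted(set(targets_in) | set(targets_out))
    if not targets:
        raise ValueError("docking plan needs at least one target")
    overlap = set(hints) & set(negatives)
    if overlap:
        raise ValueError(f"hinted and negative drugs overlap: {sorted(overlap)}")

    tested = sorted(set(hints) | set(negatives))
    rows = [
        {"drug": d, "target": t, "role": ROLE_TESTED} for d in tested for t in targets
    ]
    rows += [
        {"drug": d, "target": t, "role": ROLE_REF_IN}
        for d in refs_in
        for t in targets_in
        if (d, t) in known
    ]
    rows += [
        {"drug": d, "target": t, "role": ROLE_REF_OUT}
        for d in refs_out
        for t in targets_out
        if (d, t) in known
    ]
    pairs = pd.DataFrame(rows, columns=["drug", "target", "role"])
    return DockingPlan(
        property_tag=property_tag,
        hinted=hints,
        negatives=negatives,
        refs_in=refs_in,
        refs_out=refs_out,
        targets_in=targets_in,
        targets_out=targets_out,
        pairs=pairs,
    )
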