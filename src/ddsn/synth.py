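"""Synthetic typed drug-target interaction tables with planted communities.

The generator plants a block structure: drugs and targets are partitioned
into the same number of blocks, a drug interacts with a target of its own
block with probability ``p_in`` and with a foreign target with probability
``p_out``.  Each target carries a base action type (agonist or antagonist);
every interacting drug inherits that type except with a small flip
probability.  Same-block drugs therefore accumulate shared same-type
targets, and the projected similarity network has recoverable communities
whenever ``p_in`` clearly exceeds ``p_out``.  Annotations give every drug
its block's property tag with probability ``dominance`` and a random
foreign tag otherwise, mimicking a property-coherent community with a few
mislabeled (repurposable) members.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ddsn.io import Action, AnnotationTable, Evidence, InteractionRecord, InteractionTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 60
    n_targets: int = 30
    n_blocks: int = 3
    p_in: float = 0.6
    p_out: float = 0.05
    agonist_fraction: float = 0.5
    action_noise: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_targets, self.n_blocks) < 1:
            raise ValueError("counts must be positive")
        if self.n_blocks > min(self.n_drugs, self.n_targets):
            raise ValueError("need at least one drug and one target per block")
        for p in (self.p_in, self.p_out, self.agonist_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.action_noise < 1.0:
            raise ValueError("action_noise must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted block of each drug and the property tag of each block."""

    block_of: dict[str, int]
    property_of_block: dict[int, str]

    def property_of(self, drug_id: str) -> str:
        return self.property_of_block[self.block_of[drug_id]]


def _block_assign(n: int, n_blocks: int, prefix: str) -> dict[str, int]:
    ids = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    return {ids[i]: (i * n_blocks) // n + 1 for i in range(n)}


def generate_interactions(spec: SyntheticSpec) -> tuple[InteractionTable, GroundTruth]:
    """Generate a typed interaction table with planted block structure."""
    rng = np.random.default_rng(spec.seed)
    drug_block = _block_assign(spec.n_drugs, spec.n_blocks, "D")
    target_block = _block_assign(spec.n_targets, spec.n_blocks, "T")

    base_action = {
        t: (Action.AGONIST if rng.random() < spec.agonist_fraction else Action.ANTAGONIST)
        for t in sorted(target_block)
    }
    flip = {Action.AGONIST: Action.ANTAGONIST, Action.ANTAGONIST: Action.AGONIST}

    records = []
    for drug in sorted(drug_block):
        for target in sorted(target_block):
            p = spec.p_in if drug_block[drug] == target_block[target] else spec.p_out
            if rng.random() < p:
                action = base_action[target]
                if spec.action_noise and rng.random() < spec.action_noise:
                    action = flip[action]
                records.append(
                    InteractionRecord(
                        drug_id=drug,
                        target_id=target,
                        action=action,
                        drug_name=f"drug-{drug[1:]}",
                        target_name=f"target-{target[1:]}",
                    )
                )
    truth = GroundTruth(
        block_of=drug_block,
        property_of_block={b: f"property-{b}" for b in range(1, spec.n_blocks + 1)},
    )
    return InteractionTable(records=records), truth


def generate_annotations(
    truth: GroundTruth,
    dominance: float = 0.8,
    database_fraction: float = 0.7,
    seed: int = 1,
) -> AnnotationTable:
    """Annotate each drug with its block property (probability = dominance).

    With probability ``1 - dominance`` the drug instead receives a random
    *other* block's property — a planted non-compliant member.  Evidence is
    DATABASE with probability ``database_fraction``, LITERATURE otherwise.
    Requires ``dominance > 0.5`` so planted labels can resolve.
    """
    if not 0.5 < dominance <= 1.0:
        raise ValueError("dominance must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    properties = [truth.property_of_block[b] for b in sorted(truth.property_of_block)]
    table = AnnotationTable()
    for drug in sorted(truth.block_of):
        own = truth.property_of(drug)
        if rng.random() < dominance or len(properties) == 1:
            tag = own
        else:
            others = [p for p in properties if p != own]
            tag = others[rng.integers(len(others))]
        source = Evidence.DATABASE if rng.random() < database_fraction else Evidence.LITERATURE
        table.add(drug, tag, source)
    return table


def write_fixture(
    spec: SyntheticSpec,
    out_prefix: str | Path,
    dominance: float = 0.8,
    database_fraction: float = 0.7,
) -> tuple[Path, Path, Path]:
    """Write <prefix>.interactions.tsv / .annotations.tsv / .truth.tsv."""
    table, truth = generate_interactions(spec)
    ann = generate_annotations(
        truth, dominance=dominance, database_fraction=database_fraction, seed=spec.seed
    )
    p_int = Path(f"{out_prefix}.interactions.tsv")
    p_ann = Path(f"{out_prefix}.annotations.tsv")
    p_truth = Path(f"{out_prefix}.truth.tsv")
    with open(p_int, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdrug_name\ttarget_id\ttarget_name\taction\n")
        for r in table.records:
            fh.write(f"{r.drug_id}\t{r.drug_name}\t{r.target_id}\t{r.target_name}\t{r.action.value}\n")
    with open(p_ann, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tproperties\tsource\n")
        for drug in sorted(ann.tags):
            for tag in sorted(ann.tags[drug]):
                fh.write(f"{drug}\t{tag}\t{ann.evidence_of(drug, tag).value}\n")
    with open(p_truth, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tblock\tproperty\n")
        for drug in sorted(truth.block_of):
            fh.write(f"{drug}\t{truth.block_of[drug]}\t{truth.property_of(drug)}\n")
    return p_int, p_ann, p_truth
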