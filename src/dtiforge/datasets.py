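"""Gold-standard interaction datasets.

The benchmark DTI datasets (enzymes, ion channels, GPCRs, nuclear
receptors) are bipartite networks: a set of drugs, a set of target
proteins, and a list of experimentally known interacting pairs, all of
which serve as positive examples.  Because only positives are
deposited, a balanced negative set is constructed by sampling
uniformly, without replacement, from the unlabeled remainder of the
drug x target cross-product.

IDs are opaque case-sensitive strings (KEGG D-numbers / hsa-numbers in
the deposited data, but no format is enforced).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .errors import (
    EmptyDatasetError,
    ParseError,
    SamplingInfeasibleError,
    UndefinedSparsityError,
)

__all__ = [
    "GoldStandardDataset",
    "InteractionPair",
    "DatasetSummary",
    "load_gold_standard",
    "summarize",
    "sample_negatives",
]


@dataclass(frozen=True)
class InteractionPair:
    """One (drug, target) pair with a binary interaction label."""

    drug_id: str
    target_id: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class GoldStandardDataset:
    """Bipartite drug/target universe with the known-positive pair set.

    ``drug_ids`` and ``target_ids`` keep first-observation order;
    ``positives`` is a set of (drug_id, target_id) tuples.
    """

    name: str
    drug_ids: list[str]
    target_ids: list[str]
    positives: set[tuple[str, str]]

    def __post_init__(self):
        drugs, targets = set(self.drug_ids), set(self.target_ids)
        if len(drugs) != len(self.drug_ids) or len(targets) != len(self.target_ids):
            raise ValueError("duplicate IDs in drug or target universe")
        for d, t in self.positives:
            if d not in drugs:
                raise ValueError(f"positive pair references unknown drug {d!r}")
            if t not in targets:
                raise ValueError(f"positive pair references unknown target {t!r}")
        if self.positives and (not self.drug_ids or not self.target_ids):
            raise ValueError("non-empty positives require non-empty universes")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass(frozen=True)
class DatasetSummary:
    """Size statistics; sparsity = positives / (targets * drugs)."""

    n_targets: int
    n_drugs: int
    n_interactions: int
    sparsity: float

    def to_dict(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "n_drugs": self.n_drugs,
            "n_interactions": self.n_interactions,
            "sparsity": self.sparsity,
        }


def load_gold_standard(pair_file: str | Path, name: str = "") -> GoldStandardDataset:
    """Load a tab/whitespace-separated drug-target pair list.

    Each non-empty, non-comment ("#"-prefixed) line must hold exactly
    two tokens: drug ID then target ID.  Duplicate lines collapse to a
    single positive pair; the drug and target universes are the
    distinct IDs in order of first appearance.

    Raises
    ------
    ParseError
        If a line does not split into exactly two tokens (the message
        names the 1-based line number).
    EmptyDatasetError
        If no pairs remain after filtering.
    """
    pair_file = Path(pair_file)
    drug_ids: list[str] = []
    target_ids: list[str] = []
    seen_drugs: set[str] = set()
    seen_targets: set[str] = set()
    positives: set[tuple[str, str]] = set()

    with open(pair_file, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ParseError(
                    f"{pair_file}: line {lineno}: expected 2 tokens, got {len(tokens)}"
                )
            drug, target = tokens
            if drug not in seen_drugs:
                seen_drugs.add(drug)
                drug_ids.append(drug)
            if target not in seen_targets:
                seen_targets.add(target)
                target_ids.append(target)
            positives.add((drug, target))

    if not positives:
        raise EmptyDatasetError(f"{pair_file}: no interaction pairs found")

    return GoldStandardDataset(
        name=name or pair_file.stem,
        drug_ids=drug_ids,
        target_ids=target_ids,
        positives=positives,
    )


def summarize(ds: GoldStandardDataset) -> DatasetSummary:
    """Counts plus sparsity at full floating-point precision.

    Rounding (the benchmark tables print 4 decimals) is left to
    presentation.
    """
    if ds.n_drugs == 0 or ds.n_targets == 0:
        raise UndefinedSparsityError(
            f"dataset {ds.name!r}: sparsity undefined with zero drugs or targets"
        )
    return DatasetSummary(
        n_targets=ds.n_targets,
        n_drugs=ds.n_drugs,
        n_interactions=len(ds.positives),
        sparsity=len(ds.positives) / (ds.n_targets * ds.n_drugs),
    )


def sample_negatives(ds: GoldStandardDataset, seed: int) -> list[InteractionPair]:
    """Draw a balanced negative set.

    Exactly ``len(ds.positives)`` pairs are sampled uniformly without
    replacement from the cross-product minus the positives, labeled 0.
    The draw enumerates candidate cell indices of the drugs x targets
    grid, permutes them with a seeded PCG64 generator, and takes the
    first ``k`` — fully reproducible for a given seed across platforms.
    """
    n_needed = len(ds.positives)
    n_cells = ds.n_drugs * ds.n_targets
    n_candidates = n_cells - n_needed
    if n_candidates < n_needed:
        raise SamplingInfeasibleError(
            f"need {n_needed} negatives but only {n_candidates} "
            f"non-positive pairs exist"
        )

    # Positive cells as flat indices drug_index * n_targets + target_index.
    drug_index = {d: i for i, d in enumerate(ds.drug_ids)}
    target_index = {t: j for j, t in enumerate(ds.target_ids)}
    pos_flat = np.fromiter(
        (drug_index[d] * ds.n_targets + target_index[t] for d, t in ds.positives),
        dtype=np.int64,
        count=n_needed,
    )
    mask = np.ones(n_cells, dtype=bool)
    mask[pos_flat] = False
    candidates = np.nonzero(mask)[0]

    rng = np.random.default_rng(seed)
    chosen = candidates[rng.permutation(candidates.size)[:n_needed]]

    out = []
    for flat in chosen:
        d = ds.drug_ids[int(flat) // ds.n_targets]
        t = ds.target_ids[int(flat) % ds.n_targets]
        out.append(InteractionPair(drug_id=d, target_id=t, label=0))
    return out


def positive_pairs(ds: GoldStandardDataset) -> list[InteractionPair]:
    """Positives as labeled pairs, in deterministic sorted order."""
    return [
        InteractionPair(drug_id=d, target_id=t, label=1)
        for d, t in sorted(ds.positives)
    ]
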