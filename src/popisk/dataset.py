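"""Labeled peptide datasets: the unit of training and evaluation.

A :class:`LabeledDataset` is a list of equal-length peptides with binary
immunogenicity labels, +1 for immunogenic (elicits a T-cell response) and
-1 for non-immunogenic.  Duplicate sequences carrying contradictory labels
collapse to immunogenic: a peptide recognised by any TCR in any assay is
treated as an epitope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernel import validate_peptide

logger = logging.getLogger("popisk")


@dataclass
class LabeledDataset:
    """Equal-length peptides with labels in {-1, +1}."""

    peptides: list[str]
    labels: np.ndarray
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.peptides) == 0:
            raise ValueError("dataset must contain at least one peptide")
        length = len(self.peptides[0])
        self.peptides = [validate_peptide(p, length=length) for p in self.peptides]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.peptides),):
            raise ValueError(
                f"{len(self.peptides)} peptides but label vector of shape "
                f"{self.labels.shape}"
            )
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, +1}}, found {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def length(self) -> int:
        """Peptide length L (9 for the canonical HLA-A2 task)."""
        return len(self.peptides[0])

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == -1))

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            [self.peptides[i] for i in idx],
            self.labels[idx],
            name=self.name,
            metadata=dict(self.metadata),
        )

    def positives(self) -> list[str]:
        return [p for p, y in zip(self.peptides, self.labels) if y == 1]

    def negatives(self) -> list[str]:
        return [p for p, y in zip(self.peptides, self.labels) if y == -1]

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError(
                "both classes must be present "
                f"(got {self.n_positive} positive, {self.n_negative} negative)"
            )


def deduplicate(peptides: list[str], labels) -> LabeledDataset:
    """Collapse duplicate sequences, resolving contradictions to immunogenic.

    Exact duplicates (same sequence, same label) are reduced to one record;
    a sequence seen with both labels becomes a single +1 record.  Counts of
    both events are logged and recorded in the result's metadata.  First-seen
    order of sequences is preserved.
    """
    labels = np.asarray(labels, dtype=int)
    seen: dict[str, int] = {}
    order: list[str] = []
    n_exact = 0
    contradictory: set[str] = set()
    for pep, y in zip(peptides, labels):
        if pep not in seen:
            seen[pep] = int(y)
            order.append(pep)
        elif seen[pep] == y:
            n_exact += 1
        else:
            contradictory.add(pep)
            seen[pep] = 1
    if n_exact:
        logger.warning("removed %d exact duplicate records", n_exact)
    if contradictory:
        logger.warning(
            "%d peptide(s) had contradictory labels; regarded as immunogenic",
            len(contradictory),
        )
    return LabeledDataset(
        order,
        np.array([seen[p] for p in order]),
        metadata={
            "n_exact_duplicates": n_exact,
            "n_contradictory": len(contradictory),
        },
    )
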