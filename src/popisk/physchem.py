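"""Physicochemical property tables, mean-property encoding, feature usage.

Amino-acid scales are read and written in the AAindex1 flat-file dialect
(``H`` accession, ``D`` description, ``I`` header followed by two rows of
ten values in the canonical A R N D C Q E G H I / L K M F P S T W Y V
order, ``NA`` marking missing values, ``//`` terminating a record).
Records with any missing residue value are parsed but flagged incomplete
and excluded from encoding and analysis.

A peptide of length L is encoded, per property, as the arithmetic mean of
the property over its L residues — a deliberately position-blind
representation.  Properties are ranked by *feature usage*: after growing a
binary information-gain decision tree on the mean-property vectors, a
property's usage is the percentage of training peptides whose root-to-leaf
path passes through at least one node testing that property.  This mirrors
the feature-usage accounting of the C5.0 family of tree learners; the tree
here is a plain entropy-gain CART-style tree with deterministic
lowest-feature-index tie-breaking.
"""

from __future__ import annotations

import importlib.resources
import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernel import AMINO_ACIDS, validate_peptide

#: Residue order of the AAindex value matrix.
AAINDEX_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

# Scalar tables used for the three-letter S/M/L recoding of peptides
# (see popisk.positions.recode_alphabet).  Thresholds 2.0 / 6.0 trisect
# the normalized van der Waals volume scale; thresholds 0.5 / 2.5 trisect
# the hydrophobicity scale.

#: Normalized van der Waals volume per residue (standard scale; glycine 0,
#: tryptophan 8.08).  S/M/L class boundaries at 2.0 and 6.0.
NORMALIZED_VDW_VOLUME: dict[str, float] = {
    "A": 1.00, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43,
    "Q": 3.95, "E": 3.78, "G": 0.00, "H": 4.66, "I": 4.00,
    "L": 4.00, "K": 4.77, "M": 4.43, "F": 5.89, "P": 2.72,
    "S": 1.60, "T": 2.60, "W": 8.08, "Y": 6.47, "V": 3.00,
}

#: Synthetic hydrophobicity scale constructed so that the thresholds
#: 0.5 / 2.5 reproduce the standard polar (S) / neutral (M) /
#: hydrophobic (L) trisection of the 20 residues used in
#: composition-transition-distribution encodings.
HYDROPHOBICITY: dict[str, float] = {
    "R": 0.00, "K": 0.05, "D": 0.10, "E": 0.15, "N": 0.25, "Q": 0.30,
    "S": 0.60, "T": 0.80, "G": 1.00, "A": 1.20, "P": 1.50, "H": 1.80,
    "Y": 2.20,
    "C": 2.60, "M": 2.90, "V": 3.20, "I": 3.60, "L": 3.80, "F": 4.20,
    "W": 4.50,
}

#: Kyte-Doolittle hydropathy index (AAindex accession KYTJ820101).
KD_HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class AAindexParseError(ValueError):
    """Malformed AAindex record."""


@dataclass(frozen=True)
class PropertyRecord:
    """One amino-acid scale: accession, description, 20 scalar values."""

    accession: str
    description: str
    values: dict[str, float | None]

    @property
    def complete(self) -> bool:
        return all(self.values.get(aa) is not None for aa in AMINO_ACIDS)

    def value(self, residue: str) -> float:
        v = self.values.get(residue)
        if v is None:
            raise KeyError(
                f"property {self.accession} has no value for residue {residue!r}"
            )
        return v


@dataclass
class PropertyTable:
    """An ordered collection of property records with unique accessions."""

    records: list[PropertyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        acc = [r.accession for r in self.records]
        dup = {a for a in acc if acc.count(a) > 1}
        if dup:
            raise AAindexParseError(f"duplicate accession(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, accession: str) -> PropertyRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def complete_records(self) -> "PropertyTable":
        """Subset of records with no missing values (the analysable set)."""
        return PropertyTable([r for r in self.records if r.complete])

    def subset(self, accessions: list[str]) -> "PropertyTable":
        return PropertyTable([self[a] for a in accessions])


def load_aaindex(source) -> PropertyTable:
    """Parse an AAindex1 flat file (path, text stream, or string content)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
    records: list[PropertyRecord] = []
    accession = None
    description_parts: list[str] = []
    value_lines: list[str] = []
    in_values = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tag, _, rest = line.partition(" ")
        if line.startswith("//"):
            if accession is None:
                raise AAindexParseError(f"line {lineno}: record end without H line")
            records.append(
                _finish_record(accession, " ".join(description_parts), value_lines)
            )
            accession, description_parts, value_lines = None, [], []
            in_values = False
        elif tag == "H":
            if accession is not None:
                raise AAindexParseError(
                    f"line {lineno}: new H line inside record {accession}"
                )
            accession = rest.strip()
            if not accession:
                raise AAindexParseError(f"line {lineno}: empty accession")
        elif tag == "D":
            description_parts.append(rest.strip())
            in_values = False
        elif tag == "I":
            in_values = True
        elif line.startswith(" ") and in_values:
            value_lines.append(line)
        elif tag in {"R", "A", "T", "J", "C", "*"}:
            in_values = False
        elif line.startswith(" ") and description_parts and not in_values:
            description_parts.append(line.strip())  # wrapped D line
        else:
            raise AAindexParseError(
                f"line {lineno}: unrecognised content {line!r}"
                + (f" in record {accession}" if accession else "")
            )
    if accession is not None:
        raise AAindexParseError(f"record {accession} not terminated by //")
    return PropertyTable(records)


def _finish_record(accession, description, value_lines) -> PropertyRecord:
    tokens: list[str] = []
    for line in value_lines:
        tokens.extend(line.split())
    if len(tokens) != 20:
        raise AAindexParseError(
            f"record {accession}: expected 20 values, got {len(tokens)}"
        )
    values: dict[str, float | None] = {}
    for aa, tok in zip(AAINDEX_ORDER, tokens):
        values[aa] = None if tok.upper() == "NA" else float(tok)
    return PropertyRecord(accession, description, values)


def write_aaindex(table: PropertyTable, stream) -> None:
    """Write a table in the AAindex1 dialect; round-trips values exactly."""
    own = isinstance(stream, str)
    fh = open(stream, "w") if own else stream
    try:
        for rec in table.records:
            fh.write(f"H {rec.accession}\n")
            fh.write(f"D {rec.description}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S"
                     "     E/T     G/W     H/Y     I/V\n")
            vals = [rec.values[aa] for aa in AAINDEX_ORDER]
            for half in (vals[:10], vals[10:]):
                fh.write("   " + "  ".join(
                    "NA" if v is None else format(v, ".6g") for v in half
                ) + "\n")
            fh.write("//\n")
    finally:
        if own:
            fh.close()


def table_from_dicts(scales: dict[str, tuple[str, dict[str, float]]]) -> PropertyTable:
    """Build a PropertyTable from {accession: (description, residue->value)}."""
    records = [
        PropertyRecord(acc, desc, {aa: vals.get(aa) for aa in AMINO_ACIDS})
        for acc, (desc, vals) in scales.items()
    ]
    return PropertyTable(records)


def builtin_table() -> PropertyTable:
    """The bundled fixture table (~12 scales), parsed from package data.

    Contains well-known literature scales (Kyte-Doolittle hydropathy,
    normalized van der Waals volume, residue molecular weight) alongside
    synthetic scales under SYN* accessions, including one deliberately
    incomplete record exercising the NA-handling path.
    """
    ref = importlib.resources.files("popisk").joinpath("data/aaindex_fixture.txt")
    return load_aaindex(_io.StringIO(ref.read_text()))


# -- mean-property encoding ------------------------------------------------

def encode_mean_properties(peptides: list[str], table: PropertyTable) -> pd.DataFrame:
    """Encode peptides as per-property means over their residues.

    Only complete records are used; the result has one row per peptide and
    one column per property accession, column order bound to the table.
    """
    complete = table.complete_records()
    if len(complete) == 0:
        raise ValueError("no complete property records to encode with")
    peptides = [validate_peptide(p) for p in peptides]
    mats = np.empty((len(peptides), len(complete)))
    lookup = {
        rec.accession: np.array([rec.values[aa] for aa in AMINO_ACIDS])
        for rec in complete.records
    }
    from .kernel import encode_peptides

    codes = encode_peptides(peptides)
    for j, acc in enumerate(complete.accessions):
        mats[:, j] = lookup[acc][codes].mean(axis=1)
    return pd.DataFrame(mats, columns=complete.accessions)


# -- information-gain tree and feature usage -------------------------------

def _entropy(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0 or n_pos == 0 or n_neg == 0:
        return 0.0
    p = n_pos / n
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


@dataclass
class _TreeNode:
    feature: int | None = None      # None => leaf
    threshold: float = 0.0          # left: x <= threshold
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    n_samples: int = 0
    prediction: int = 0


def _best_split(X, y, idx, min_leaf):
    """(gain, feature, threshold) maximising information gain, or None.

    Ties break to the lowest feature index, then the lowest threshold.
    """
    n = len(idx)
    n_pos = int(np.sum(y[idx] == 1))
    parent = _entropy(n_pos, n - n_pos)
    best = None
    for f in range(X.shape[1]):
        xv = X[idx, f]
        order = np.argsort(xv, kind="stable")
        xs, ys = xv[order], (y[idx][order] == 1).astype(int)
        cum_pos = np.cumsum(ys)
        for cut in range(min_leaf, n - min_leaf + 1):
            if cut < 1 or cut >= n or xs[cut - 1] == xs[cut]:
                continue
            lp, ln = int(cum_pos[cut - 1]), cut - int(cum_pos[cut - 1])
            rp, rn = n_pos - lp, (n - cut) - (n_pos - lp)
            gain = parent - (cut / n) * _entropy(lp, ln) \
                - ((n - cut) / n) * _entropy(rp, rn)
            thr = 0.5 * (xs[cut - 1] + xs[cut])
            if best is None or gain > best[0] + 1e-12:
                best = (gain, f, thr)
    if best is None or best[0] <= 1e-12:
        return None
    return best


def _grow(X, y, idx, min_leaf, depth, max_depth) -> _TreeNode:
    n_pos = int(np.sum(y[idx] == 1))
    node = _TreeNode(n_samples=len(idx),
                     prediction=1 if n_pos * 2 >= len(idx) else -1)
    if n_pos in (0, len(idx)) or len(idx) < 2 * min_leaf or depth >= max_depth:
        return node
    split = _best_split(X, y, idx, min_leaf)
    if split is None:
        return node
    _, f, thr = split
    mask = X[idx, f] <= thr
    node.feature, node.threshold = f, thr
    node.left = _grow(X, y, idx[mask], min_leaf, depth + 1, max_depth)
    node.right = _grow(X, y, idx[~mask], min_leaf, depth + 1, max_depth)
    return node


@dataclass
class FeatureUsageReport:
    """Per-property usage percentages with ranking, plus a tree summary."""

    table: pd.DataFrame          # accession, description, usage, rank
    n_nodes: int
    depth: int
    training_accuracy: float

    def top(self, k: int) -> list[str]:
        return list(self.table["accession"].head(k))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def feature_usage_ranking(
    encoding: pd.DataFrame,
    labels,
    min_leaf: int = 5,
    max_depth: int = 30,
    descriptions: dict[str, str] | None = None,
) -> FeatureUsageReport:
    """Rank properties by decision-tree feature usage.

    A binary information-gain tree is grown on the mean-property matrix
    (no pruning; leaves hold at least ``min_leaf`` cases).  The usage of a
    property is the percentage of training cases whose path traverses at
    least one node testing it; the root feature of any non-trivial tree
    therefore scores 100%.
    """
    if isinstance(encoding, pd.DataFrame):
        X = encoding.to_numpy(dtype=float)
        names = list(encoding.columns)
    else:
        X = np.asarray(encoding, dtype=float)
        names = [f"feature_{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature_usage_ranking requires both classes")
    idx = np.arange(len(y))
    root = _grow(X, y, idx, min_leaf, 0, max_depth)

    usage_counts = np.zeros(X.shape[1])
    correct = 0
    n_nodes = 0
    depth_seen = 0

    def _walk_count(node, depth):
        nonlocal n_nodes, depth_seen
        n_nodes += 1
        depth_seen = max(depth_seen, depth)
        if node.feature is not None:
            _walk_count(node.left, depth + 1)
            _walk_count(node.right, depth + 1)

    _walk_count(root, 0)
    for i in idx:
        node = root
        seen: set[int] = set()
        while node.feature is not None:
            seen.add(node.feature)
            node = node.left if X[i, node.feature] <= node.threshold else node.right
        for f in seen:
            usage_counts[f] += 1
        correct += int(node.prediction == y[i])

    usage = 100.0 * usage_counts / len(y)
    rows = pd.DataFrame({
        "accession": names,
        "description": [(descriptions or {}).get(n, "") for n in names],
        "usage": usage,
    })
    rows = rows.sort_values(
        ["usage", "accession"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    return FeatureUsageReport(
        table=rows,
        n_nodes=n_nodes,
        depth=depth_seen,
        training_accuracy=correct / len(y),
    )
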