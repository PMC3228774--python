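"""Reading and writing labeled peptide datasets.

Two on-disk dialects are supported:

* **TSV** — one record per line, column 1 the peptide sequence, column 2
  the label (``1``/``0``, ``+1``/``-1``, or the words ``immunogenic`` /
  ``non-immunogenic``); an optional header line is skipped when its first
  field is not a valid peptide.
* **FASTA** — standard FASTA with the label carried in a ``label=`` key of
  the description line.

On reading, sequences are normalised and validated, exact duplicates are
dropped, and duplicates with contradictory labels collapse to immunogenic
(+1), each with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .dataset import LabeledDataset, deduplicate
from .kernel import InvalidPeptideError, validate_peptide

logger = logging.getLogger("popisk")

_LABEL_MAP = {
    "1": 1, "+1": 1, "immunogenic": 1, "pos": 1, "positive": 1, "true": 1,
    "0": -1, "-1": -1, "non-immunogenic": -1, "nonimmunogenic": -1,
    "neg": -1, "negative": -1, "false": -1,
}


class DatasetFormatError(ValueError):
    """A dataset file fails to parse; the message carries the line number."""


def _parse_label(token: str, where: str) -> int:
    label = _LABEL_MAP.get(token.strip().lower())
    if label is None:
        raise DatasetFormatError(f"{where}: unmappable label {token!r}")
    return label


def read_dataset(path, format: str = "auto") -> LabeledDataset:
    """Read and normalise a labeled dataset from TSV or FASTA.

    ``format="auto"`` sniffs FASTA by a leading ``>``.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise DatasetFormatError(f"{path}: empty dataset file")
    if format == "auto":
        format = "fasta" if text.lstrip().startswith(">") else "tsv"
    if format == "tsv":
        peptides, labels = _parse_tsv(text, str(path))
    elif format == "fasta":
        peptides, labels = _parse_fasta(text, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not peptides:
        raise DatasetFormatError(f"{path}: no records found")
    data = deduplicate(peptides, labels)
    data.name = path.stem
    return data


def _parse_tsv(text: str, where: str) -> tuple[list[str], list[int]]:
    peptides, labels = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise DatasetFormatError(
                f"{where}, line {lineno}: expected 2 columns, got {len(fields)}"
            )
        seq_tok, label_tok = fields[0], fields[1]
        try:
            seq = validate_peptide(seq_tok)
        except InvalidPeptideError as exc:
            if lineno == 1:  # tolerate a header line
                continue
            raise DatasetFormatError(f"{where}, line {lineno}: {exc}") from exc
        peptides.append(seq)
        labels.append(_parse_label(label_tok, f"{where}, line {lineno}"))
    _check_lengths(peptides, where)
    return peptides, labels


def _parse_fasta(text: str, where: str) -> tuple[list[str], list[int]]:
    peptides, labels = [], []
    header, seq_parts, header_line = None, [], 0

    def _flush(lineno):
        if header is None:
            return
        seq = "".join(seq_parts)
        try:
            peptides.append(validate_peptide(seq))
        except InvalidPeptideError as exc:
            raise DatasetFormatError(
                f"{where}, record ending line {lineno}: {exc}"
            ) from exc
        label_tok = None
        for tok in header.split():
            if tok.lower().startswith("label="):
                label_tok = tok.split("=", 1)[1]
        if label_tok is None:
            raise DatasetFormatError(
                f"{where}, line {header_line}: no label= key in FASTA header"
            )
        labels.append(_parse_label(label_tok, f"{where}, line {header_line}"))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush(lineno - 1)
            header, seq_parts, header_line = line[1:], [], lineno
        else:
            if header is None:
                raise DatasetFormatError(
                    f"{where}, line {lineno}: sequence before first header"
                )
            seq_parts.append(line)
    _flush(len(text.splitlines()))
    _check_lengths(peptides, where)
    return peptides, labels


def _check_lengths(peptides: list[str], where: str) -> None:
    if peptides:
        lengths = {len(p) for p in peptides}
        if len(lengths) > 1:
            raise DatasetFormatError(
                f"{where}: ragged peptide lengths {sorted(lengths)}"
            )


def write_dataset(data: LabeledDataset, path, format: str = "tsv") -> None:
    """Write a dataset in the TSV or FASTA dialect (reading it back
    reproduces the in-memory dataset exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "tsv":
            for pep, y in zip(data.peptides, data.labels):
                fh.write(f"{pep}\t{1 if y == 1 else 0}\n")
        elif format == "fasta":
            for i, (pep, y) in enumerate(zip(data.peptides, data.labels), start=1):
                word = "immunogenic" if y == 1 else "non-immunogenic"
                fh.write(f">pep{i} label={word}\n{pep}\n")
        else:
            raise ValueError(f"unknown format {format!r}")
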