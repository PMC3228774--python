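"""Identification of TCR-recognition positions.

Two complementary analyses locate the peptide positions that drive
T-cell reactivity:

* **Position-deletion importance** — excise one position from every
  peptide, re-run the full nested cross-validation on the shortened
  dataset (with the degree grid capped at the remaining length), and
  record the drop in MCC relative to the intact dataset.  The larger the
  drop, the more the classifier depended on that position.

* **Two-sample logo** — for every (position, symbol) pair, compare the
  0/1 occupancy indicator between the immunogenic and non-immunogenic
  sets with a two-sample t-test (Welch by default) and flag symbols whose
  raw p-value survives Bonferroni correction over all L x |alphabet|
  tests.  Direction is the sign of the frequency difference
  (over- vs under-represented in the immunogenic set).

The same logo machinery runs on peptides recoded to a three-letter
S/M/L (small/medium/large) alphabet under a scalar physicochemical
property — hydrophobicity (class boundaries 0.5 and 2.5) or normalized
van der Waals volume (boundaries 2.0 and 6.0) — exposing
position-specific property preferences.

All positions are reported 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import LabeledDataset
from .evaluation import CVReport, GridSpec, nested_cv
from .kernel import AMINO_ACIDS
from .physchem import HYDROPHOBICITY, NORMALIZED_VDW_VOLUME

#: (scalar table, low threshold, high threshold) per recodable property.
RECODING_PROPERTIES: dict[str, tuple[dict[str, float], float, float]] = {
    "hydrophobicity": (HYDROPHOBICITY, 0.5, 2.5),
    "vdw_volume": (NORMALIZED_VDW_VOLUME, 2.0, 6.0),
}

SML_ALPHABET = ("S", "M", "L")


# -- position deletion -----------------------------------------------------

def delete_position(data: LabeledDataset, pos: int) -> LabeledDataset:
    """Excise 1-based position ``pos`` from every peptide; labels unchanged."""
    if not 1 <= pos <= data.length:
        raise ValueError(f"position {pos} out of range 1..{data.length}")
    i = pos - 1
    return LabeledDataset(
        [p[:i] + p[i + 1:] for p in data.peptides],
        data.labels.copy(),
        name=f"{data.name}-del{pos}" if data.name else f"del{pos}",
    )


@dataclass
class PositionImportanceReport:
    """Per-position drop in nested-CV MCC when the position is deleted."""

    table: pd.DataFrame   # position, baseline_mcc, deleted_mcc, deleted_sd, delta_mcc, important
    baseline: CVReport
    n_runs: int
    seed: int

    @property
    def ranking(self) -> list[int]:
        """Positions ordered from most to least important (largest delta first)."""
        return list(
            self.table.sort_values("delta_mcc", ascending=False)["position"]
        )

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def position_importance(
    data: LabeledDataset,
    n_runs: int = 20,
    seed: int = 0,
    grid: GridSpec | None = None,
    n_outer: int = 10,
    n_inner: int = 10,
) -> PositionImportanceReport:
    """Rank positions by the MCC drop their deletion causes.

    The baseline nested CV uses the degree grid capped at the peptide
    length; every deleted run caps it at L-1 (the remaining length).
    Baseline and deleted runs share the same seed, so fold randomisation
    is matched across conditions.  A position is flagged important when
    its MCC drop exceeds twice the across-run sd of the deleted MCC.
    """
    if data.length < 2:
        raise ValueError("peptides must have length >= 2")
    grid = grid or GridSpec()
    kw = dict(n_runs=n_runs, seed=seed, n_outer=n_outer, n_inner=n_inner)
    baseline = nested_cv(data, grid.capped(data.length), **kw)
    base_mcc = baseline.summary["mean"]["MCC"]
    rows = []
    for pos in range(1, data.length + 1):
        deleted = delete_position(data, pos)
        rep = nested_cv(deleted, grid.capped(deleted.length), **kw)
        mcc = rep.summary["mean"]["MCC"]
        sd = rep.summary["sd"]["MCC"]
        delta = base_mcc - mcc
        rows.append({
            "position": pos,
            "baseline_mcc": base_mcc,
            "deleted_mcc": mcc,
            "deleted_sd": sd,
            "delta_mcc": delta,
            "important": bool(delta > 2.0 * sd),
        })
    return PositionImportanceReport(
        table=pd.DataFrame(rows), baseline=baseline, n_runs=n_runs, seed=seed
    )


# -- two-sample logo -------------------------------------------------------

@dataclass
class LogoReport:
    """Per-(position, symbol) enrichment statistics between two peptide sets."""

    table: pd.DataFrame  # position, symbol, freq_pos, freq_neg, t, p_raw, significant, direction
    alpha: float
    n_tests: int         # Bonferroni divisor m
    correction: str
    alphabet: tuple[str, ...]

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def two_sample_logo(
    pos_set: list[str],
    neg_set: list[str],
    alpha: float = 0.05,
    correction: str = "bonferroni",
    alphabet: tuple[str, ...] | str | None = None,
    equal_var: bool = False,
) -> LogoReport:
    """Position-wise residue enrichment between two equal-length peptide sets.

    For each position and symbol, the per-peptide occupancy indicator
    (1 if the symbol sits at the position) is compared between the sets
    with a two-sample t-test — Welch's by default, pooled-variance when
    ``equal_var`` is True.  A symbol is flagged significant only when its
    raw p-value is below ``alpha / m`` (``correction="bonferroni"``,
    m = L x |alphabet|) or below ``alpha`` (``correction="none"``).
    """
    if len(pos_set) == 0 or len(neg_set) == 0:
        raise ValueError("both peptide sets must be non-empty")
    length = len(pos_set[0])
    for p in list(pos_set) + list(neg_set):
        if len(p) != length:
            raise ValueError("all peptides must have equal length")
    if correction not in {"bonferroni", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    if alphabet is None:
        alphabet = tuple(AMINO_ACIDS)
    alphabet = tuple(alphabet)

    a = np.array([list(p) for p in pos_set])
    b = np.array([list(p) for p in neg_set])
    m = length * len(alphabet)
    threshold = alpha / m if correction == "bonferroni" else alpha
    rows = []
    for j in range(length):
        for sym in alphabet:
            xa = (a[:, j] == sym).astype(float)
            xb = (b[:, j] == sym).astype(float)
            fa, fb = float(xa.mean()), float(xb.mean())
            if xa.std() == 0 and xb.std() == 0:
                # constant indicator in both sets: no evidence either way
                t, p = 0.0, 1.0
                if fa != fb:  # constant but different (all vs none)
                    t = np.inf if fa > fb else -np.inf
                    p = 0.0
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
                t, p = float(t), float(p)
            rows.append({
                "position": j + 1,
                "symbol": sym,
                "freq_pos": fa,
                "freq_neg": fb,
                "t": t,
                "p_raw": p,
                "significant": bool(p < threshold and fa != fb),
                "direction": "over" if fa > fb else ("under" if fa < fb else "none"),
            })
    return LogoReport(
        table=pd.DataFrame(rows),
        alpha=alpha,
        n_tests=m,
        correction=correction,
        alphabet=alphabet,
    )


# -- S/M/L property recoding ----------------------------------------------

@dataclass
class RecodedDataset:
    """A dataset recoded to the S/M/L alphabet under a scalar property."""

    data: LabeledDataset      # sequences over {S, M, L}; validation bypassed
    property_name: str
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        pass


def _recode_sequence(seq: str, table: dict[str, float], low: float, high: float) -> str:
    out = []
    for aa in seq:
        if aa not in table:
            raise KeyError(f"residue {aa!r} missing from the property table")
        v = table[aa]
        out.append("S" if v < low else ("M" if v < high else "L"))
    return "".join(out)


@dataclass
class _SMLDataset:
    """Lightweight container: S/M/L strings are not canonical peptides."""

    peptides: list[str]
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def length(self) -> int:
        return len(self.peptides[0])

    def positives(self) -> list[str]:
        return [p for p, y in zip(self.peptides, self.labels) if y == 1]

    def negatives(self) -> list[str]:
        return [p for p, y in zip(self.peptides, self.labels) if y == -1]


def recode_alphabet(data: LabeledDataset, property: str) -> RecodedDataset:
    """Recode every residue to S/M/L by thresholding a scalar property.

    ``property`` is ``"hydrophobicity"`` (boundaries 0.5 / 2.5) or
    ``"vdw_volume"`` (boundaries 2.0 / 6.0); a residue maps to 'S' below
    the low boundary, 'M' in between, 'L' at or above the high boundary.
    """
    if property not in RECODING_PROPERTIES:
        raise ValueError(
            f"unknown property {property!r}; choose from {sorted(RECODING_PROPERTIES)}"
        )
    table, low, high = RECODING_PROPERTIES[property]
    recoded = [_recode_sequence(p, table, low, high) for p in data.peptides]
    return RecodedDataset(
        data=_SMLDataset(recoded, data.labels.copy()),  # type: ignore[arg-type]
        property_name=property,
        thresholds=(low, high),
    )


def property_logo(
    data: LabeledDataset,
    property: str,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> LogoReport:
    """Two-sample logo over the S/M/L alphabet (m = L x 3 tests)."""
    rec = recode_alphabet(data, property)
    return two_sample_logo(
        rec.data.positives(),
        rec.data.negatives(),
        alpha=alpha,
        correction=correction,
        alphabet=SML_ALPHABET,
    )


# -- rendering -------------------------------------------------------------

def render_logo(report: LogoReport, path, title: str = "") -> None:
    """Draw a two-sample logo: significant symbols stacked per position.

    Letter heights are proportional to the frequency difference;
    over-represented symbols stack upward, under-represented downward.
    Plain matplotlib text glyphs — the numbers live in the LogoReport.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flagged = report.flagged()
    length = int(report.table["position"].max())
    fig, ax = plt.subplots(figsize=(max(4, length), 4))
    for pos in range(1, length + 1):
        sub = flagged[flagged["position"] == pos]
        up, down = 0.0, 0.0
        for _, row in sub.sort_values("freq_pos", ascending=False).iterrows():
            diff = row["freq_pos"] - row["freq_neg"]
            h = abs(diff)
            if diff > 0:
                y0, up = up, up + h
                ax.text(pos, y0 + h / 2, row["symbol"], ha="center", va="center",
                        fontsize=10 + 40 * h, color="tab:green", fontweight="bold")
            else:
                down -= h
                ax.text(pos, down + h / 2, row["symbol"], ha="center", va="center",
                        fontsize=10 + 40 * h, color="tab:red", fontweight="bold")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlim(0.5, length + 0.5)
    ax.set_xticks(range(1, length + 1))
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("position")
    ax.set_ylabel("frequency difference (immunogenic - non-immunogenic)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
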