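"""Position-deletion importance, two-sample logos, S/M/L recoding."""

import numpy as np
import pytest
from scipy import stats

from popisk import (
    GridSpec,
    LabeledDataset,
    delete_position,
    enrichment_dataset,
    planted_rule_dataset,
    position_importance,
    property_logo,
    recode_alphabet,
    render_logo,
    shuffled_null_dataset,
    two_sample_logo,
)
from popisk.physchem import HYDROPHOBICITY, NORMALIZED_VDW_VOLUME
from conftest import random_peptides


def make_planted_sets(n, f_pos, f_neg, rng, position=4, residue="G"):
    """Two peptide sets with the residue planted at the given per-set rates."""
    def build(freq):
        peps = []
        for _ in range(n):
            p = "".join(rng.choice(list("ACDEFHIKLMNPQRSTVWY"), size=9))
            if rng.random() < freq:
                p = p[:position - 1] + residue + p[position:]
            peps.append(p)
        return peps
    return build(f_pos), build(f_neg)


class TestDeletePosition:
    def test_excision_worked_example(self):
        data = LabeledDataset(["LLFGYPVYV"], np.array([1]))
        assert delete_position(data, 6).peptides == ["LLFGYVYV"]

    def test_repeated_deletion_shortens_twice(self):
        data = LabeledDataset(["LLFGYPVYV", "GILGFVFTL"], np.array([1, -1]))
        twice = delete_position(delete_position(data, 1), 1)
        assert twice.length == 7
        assert twice.peptides[0] == "FGYPVYV"

    def test_size_and_labels_preserved(self):
        data = planted_rule_dataset(10, 10, seed=0)
        out = delete_position(data, 9)
        assert len(out) == len(data)
        assert np.array_equal(out.labels, data.labels)

    @pytest.mark.parametrize("pos", [0, 10, -1])
    def test_out_of_range_rejected(self, pos):
        data = LabeledDataset(["LLFGYPVYV"], np.array([1]))
        with pytest.raises(ValueError):
            delete_position(data, pos)


class TestTwoSampleLogo:
    def test_identical_sets_no_flags(self, rng):
        peps = random_peptides(rng, 40)
        report = two_sample_logo(peps, list(peps))
        assert report.flagged().empty
        assert report.n_tests == 9 * 20

    def test_planted_enrichment_flagged(self, rng):
        pos, neg = make_planted_sets(200, 0.8, 0.05, rng)
        report = two_sample_logo(pos, neg)
        flagged = report.flagged()
        hit = flagged[(flagged["position"] == 4) & (flagged["symbol"] == "G")]
        assert len(hit) == 1
        assert hit["direction"].item() == "over"
        # Bonferroni divisor for 9-mers over 20 residues
        assert report.n_tests == 180

    def test_antisymmetry_under_set_swap(self, rng):
        pos, neg = make_planted_sets(80, 0.6, 0.1, rng)
        fwd = two_sample_logo(pos, neg).table
        rev = two_sample_logo(neg, pos).table
        assert np.allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12, equal_nan=True)
        swap = {"over": "under", "under": "over", "none": "none"}
        assert (rev["direction"] == fwd["direction"].map(swap)).all()
        assert np.allclose(fwd["t"], -rev["t"], atol=1e-12)

    def test_flag_monotone_in_sample_size(self, rng):
        outcomes = []
        for n in (50, 100, 200):
            pos, neg = make_planted_sets(n, 0.8, 0.05,
                                         np.random.default_rng(77))
            rep = two_sample_logo(pos, neg)
            f = rep.flagged()
            outcomes.append(
                len(f[(f["position"] == 4) & (f["symbol"] == "G")]) == 1)
        # once flagged at some n, flagged at every larger n
        assert outcomes == sorted(outcomes)
        assert outcomes[-1]

    def test_welch_matches_textbook_computation(self, rng):
        """Small sets: t and p agree with a from-scratch Welch computation."""
        pos, neg = make_planted_sets(8, 0.7, 0.2, rng)
        rep = two_sample_logo(pos, neg).table
        for _, row in rep.sample(20, random_state=1).iterrows():
            xa = np.array([1.0 if p[row["position"] - 1] == row["symbol"] else 0.0
                           for p in pos])
            xb = np.array([1.0 if p[row["position"] - 1] == row["symbol"] else 0.0
                           for p in neg])
            if xa.std() == 0 and xb.std() == 0:
                continue
            va, vb = xa.var(ddof=1), xb.var(ddof=1)
            na, nb = len(xa), len(xb)
            t = (xa.mean() - xb.mean()) / np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = 2 * stats.t.sf(abs(t), df)
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["p_raw"] == pytest.approx(p, abs=1e-10)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            two_sample_logo([], random_peptides(rng, 5))

    def test_bonferroni_threshold_applied(self, rng):
        """A symbol significant uncorrected but not after correction."""
        pos, neg = make_planted_sets(60, 0.30, 0.10, np.random.default_rng(5))
        raw = two_sample_logo(pos, neg, correction="none").table
        cor = two_sample_logo(pos, neg, correction="bonferroni").table
        assert cor["significant"].sum() <= raw["significant"].sum()


class TestRecoding:
    def test_length_and_alphabet_preserved(self):
        data = LabeledDataset(["LLFGYPVYV"], np.array([1]))
        rec = recode_alphabet(data, "hydrophobicity")
        assert len(rec.data.peptides[0]) == 9
        assert set(rec.data.peptides[0]) <= {"S", "M", "L"}

    def test_hydrophobicity_threshold_rule(self):
        # every residue below 0.5 maps to S, 0.5..2.5 to M, >= 2.5 to L
        data = LabeledDataset(["RGWRGWRGW"], np.array([1]))
        rec = recode_alphabet(data, "hydrophobicity")
        assert HYDROPHOBICITY["R"] < 0.5
        assert 0.5 <= HYDROPHOBICITY["G"] < 2.5
        assert HYDROPHOBICITY["W"] >= 2.5
        assert rec.data.peptides[0] == "SML" * 3

    def test_glycine_small_under_vdw_volume(self):
        data = LabeledDataset(["GGGGGGGGG"], np.array([1]))
        rec = recode_alphabet(data, "vdw_volume")
        assert NORMALIZED_VDW_VOLUME["G"] < 2.0
        assert rec.data.peptides[0] == "SSSSSSSSS"
        assert rec.thresholds == (2.0, 6.0)

    def test_unknown_property_rejected(self):
        data = LabeledDataset(["GGGGGGGGG"], np.array([1]))
        with pytest.raises(ValueError):
            recode_alphabet(data, "charge")


class TestPropertyLogo:
    def test_identical_classes_no_flags(self, rng):
        peps = random_peptides(rng, 30) * 2
        labels = np.array([1] * 30 + [-1] * 30)
        rep = property_logo(LabeledDataset(peps, labels), "hydrophobicity")
        assert rep.flagged().empty
        assert rep.n_tests == 27  # 9 positions x {S, M, L}

    def test_planted_small_class_flagged(self, rng):
        """Positives carry an S-class (polar) residue at position 5."""
        peps, labels = [], []
        polar = list("RKDENQ")          # hydrophobicity < 0.5 -> 'S'
        hydrophobic = list("CLVIMFW")   # >= 2.5 -> 'L'
        for i in range(150):
            p = random_peptides(rng, 1)[0]
            if i % 2 == 0:
                p = p[:4] + str(rng.choice(polar)) + p[5:]
                labels.append(1)
            else:
                p = p[:4] + str(rng.choice(hydrophobic)) + p[5:]
                labels.append(-1)
            peps.append(p)
        rep = property_logo(LabeledDataset(peps, np.array(labels)), "hydrophobicity")
        hit = rep.flagged()
        hit = hit[(hit["position"] == 5) & (hit["symbol"] == "S")]
        assert len(hit) == 1 and hit["direction"].item() == "over"

    def test_flags_depend_only_on_class_frequencies(self, rng):
        """Swapping which concrete residue realises a class leaves the
        S/M/L logo unchanged."""
        base = random_peptides(rng, 60)
        pos_a = [p[:3] + "D" + p[4:] for p in base[:30]]   # D: S-class
        pos_b = [p[:3] + "E" + p[4:] for p in base[:30]]   # E: also S-class
        neg = [p[:3] + "L" + p[4:] for p in base[30:]]     # L-class
        labels = np.array([1] * 30 + [-1] * 30)
        rep_a = property_logo(LabeledDataset(pos_a + neg, labels), "hydrophobicity")
        rep_b = property_logo(LabeledDataset(pos_b + neg, labels), "hydrophobicity")
        assert rep_a.table["significant"].equals(rep_b.table["significant"])


class TestPositionImportance:
    GRID = GridSpec(Cs=(1.0,), ds=(1, 5, 9))

    def test_planted_position_dominates(self):
        data = planted_rule_dataset(60, 60, seed=31)
        rep = position_importance(data, n_runs=1, seed=3, grid=self.GRID,
                                  n_outer=5, n_inner=5)
        t = rep.table
        assert t["position"].tolist() == list(range(1, 10))
        best = t.loc[t["delta_mcc"].idxmax(), "position"]
        assert best == 4
        others = t[t["position"] != 4]["delta_mcc"]
        assert t["delta_mcc"].max() - others.max() >= 0.2

    def test_null_dataset_small_deltas(self):
        null = shuffled_null_dataset(50, 50, seed=41)
        rep = position_importance(null, n_runs=1, seed=3,
                                  grid=GridSpec(Cs=(1.0,), ds=(5,)),
                                  n_outer=5, n_inner=5)
        assert (rep.table["delta_mcc"].abs() <= 0.25).all()

    def test_single_run_matches_restricted_general_routine(self):
        data = planted_rule_dataset(40, 40, seed=8)
        r1 = position_importance(data, n_runs=1, seed=6,
                                 grid=GridSpec(Cs=(1.0,), ds=(5,)),
                                 n_outer=5, n_inner=5)
        r2 = position_importance(data, n_runs=1, seed=6,
                                 grid=GridSpec(Cs=(1.0,), ds=(5,)),
                                 n_outer=5, n_inner=5)
        assert r1.table.equals(r2.table)


def test_render_logo_writes_image(tmp_path, rng):
    data = enrichment_dataset(60, 60, seed=5)
    rep = two_sample_logo(data.positives(), data.negatives())
    out = tmp_path / "logo.svg"
    render_logo(rep, out, title="synthetic enrichment")
    assert out.exists() and out.stat().st_size > 0
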