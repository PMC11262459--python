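"""Interpretability: HAS statistic vs quantile oracle, attention
aggregation, enrichment, homolog cross-tabs, entropy, structure mapping."""

import numpy as np
import pytest

from thermadapt.encoder import AttentionTensorSet
from thermadapt.interpret import (
    AttentionProfile,
    aggregate_attention,
    column_entropy,
    compare_homologs,
    compare_models,
    enrichment,
    has_mask,
    has_threshold,
    residue_attention,
    write_bfactor_pdb,
)
from thermadapt.seqio import SequenceRecord, tokenize


def quantile_oracle(values, p):
    """Independent linear-interpolation quantile at position (n-1)p."""
    s = sorted(values)
    pos = (len(s) - 1) * p
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return s[lo] + (s[hi] - s[lo]) * (pos - lo)


def profile(scores, sid="x", agg="received_mean"):
    return AttentionProfile(sequence_id=sid, scores=np.asarray(scores, float), aggregation=agg)


class TestHasThreshold:
    def test_constant_scores_and_empty_mask(self):
        assert has_threshold([2.0, 2.0, 2.0]) == 2.0
        assert has_mask(profile([2.0, 2.0, 2.0])).positions == frozenset()

    def test_single_outlier_hand_case(self):
        scores = [1, 1, 1, 1, 10]
        assert has_threshold(scores) == 1.0
        assert has_mask(profile(scores)).positions == frozenset({4})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            has_threshold([])

    def test_matches_quantile_oracle_on_1000_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 513))
            scores = rng.gamma(2.0, 1.0, n)
            q1 = quantile_oracle(scores, 0.25)
            q3 = quantile_oracle(scores, 0.75)
            expected = q3 + 1.5 * (q3 - q1)
            assert has_threshold(scores) == pytest.approx(expected, rel=1e-12)
            mask = has_mask(profile(scores))
            assert mask.positions == frozenset(np.flatnonzero(scores > expected))

    def test_mask_positions_strictly_exceed_threshold(self):
        rng = np.random.default_rng(1)
        scores = rng.random(64)
        mask = has_mask(profile(scores))
        assert all(scores[i] > mask.threshold for i in mask.positions)


class TestAggregation:
    def _toy_attention(self):
        """2 layers, 1 head, sequence 'AC' -> 4 tokens (CLS, A, C, SEP)."""
        tokens = tokenize("AC")
        m = np.zeros((2, 1, 4, 4))
        # layer 0: every token attends uniformly
        m[0, 0] = 0.25
        # layer 1: everything attends to token 1 ('A')
        m[1, 0, :, 1] = 1.0
        return AttentionTensorSet(matrices=m, tokens=tokens)

    def test_received_mean_matches_hand_computation(self):
        att = self._toy_attention()
        scores = aggregate_attention(att, "received_mean")
        # residue submatrix (tokens 1,2): layer0 rows (.25,.25); layer1
        # rows (1,0) -> means over layers+rows: A: (0.25+0.25+1+1)/4,
        # C: (0.25+0.25+0+0)/4
        np.testing.assert_allclose(scores, [0.625, 0.125])

    def test_cls_row_last_layer(self):
        att = self._toy_attention()
        np.testing.assert_allclose(
            aggregate_attention(att, "cls_row_last_layer"), [1.0, 0.0]
        )

    def test_uniform_attention_gives_equal_scores(self, tiny_classifier_model):
        record = SequenceRecord(id="r", sequence="ACDEFGHIKL")
        att = tiny_classifier_model.capture_attention(tokenize(record.sequence))
        uniform = AttentionTensorSet(
            matrices=np.full_like(att.matrices, 1.0 / att.matrices.shape[-1]),
            tokens=att.tokens,
        )
        scores = aggregate_attention(uniform, "received_mean")
        assert np.allclose(scores, scores[0])

    def test_model_profiles_finite_nonnegative(self, tiny_classifier_model):
        record = SequenceRecord(id="r", sequence="ACDEFGHIKLMNPQR")
        p = residue_attention(tiny_classifier_model, record)
        assert len(p) == 15
        assert np.all(p.scores >= 0) and np.all(np.isfinite(p.scores))

    def test_unknown_aggregation_rejected(self, tiny_classifier_model):
        record = SequenceRecord(id="r", sequence="ACDEF" * 6)
        with pytest.raises(ValueError, match="aggregation"):
            residue_attention(tiny_classifier_model, record, "bogus")


class TestEnrichment:
    def test_full_coverage_masks_reproduce_background(self):
        records = [
            SequenceRecord(id="a", sequence="AACDE", thermal_class="thermophilic"),
            SequenceRecord(id="b", sequence="AAKKL", thermal_class="thermophilic"),
        ]
        masks = {
            r.id: has_mask(profile(np.zeros(len(r.sequence)) + 1.0, r.id))
            for r in records
        }
        # force full coverage
        from thermadapt.interpret import HASMask

        masks = {r.id: HASMask(0.0, frozenset(range(len(r.sequence)))) for r in records}
        table = enrichment(records, masks)
        assert np.allclose(table.background_freq, table.has_freq)
        assert np.allclose(table.ratio, 1.0)

    def test_frequencies_sum_to_one_per_class(self, motif_run):
        from thermadapt.interpret import has_mask as hm

        records = motif_run["test_records"][:30]
        masks = {
            r.id: hm(residue_attention(motif_run["model"], r)) for r in records
        }
        table = enrichment(records, masks)
        for cls, sub in table.groupby("thermal_class"):
            assert sub.background_freq.sum() == pytest.approx(1.0)
            if sub.has_freq.sum() > 0:
                assert sub.has_freq.sum() == pytest.approx(1.0)


class TestCompareModels:
    def test_model_compared_to_itself_is_identical(self, tiny_classifier_model):
        records = [
            SequenceRecord(id=f"r{i}", sequence="ACDEFGHIKLMNPQRSTVWY" * 2)
            for i in range(3)
        ]
        table = compare_models(tiny_classifier_model, tiny_classifier_model, records)
        np.testing.assert_allclose(table.freq_a, table.freq_b)
        if len(table):
            assert table.freq_a.sum() == pytest.approx(1.0)

    def test_finetuning_raises_signal_residue_has_frequency(self, motif_run):
        """After fine-tuning on the shifted+motif corpus, the HAS frequency
        of the up-shifted signal residues exceeds the untrained backbone's,
        under the class-token aggregation."""
        from thermadapt.encoder import TINY, AdapterConfig, EncoderModel, HeadConfig

        untrained = EncoderModel(TINY, AdapterConfig(2), HeadConfig("classifier"), seed=0)
        thermo = [r for r in motif_run["test_records"] if r.thermal_class == "thermophilic"][:40]
        table = compare_models(untrained, motif_run["model"], thermo,
                               aggregation="cls_row_last_layer")
        signal = set("RELV")
        sub = table[table.amino_acid.isin(signal)]
        assert sub.freq_b.sum() > sub.freq_a.sum()


class TestCompareHomologs:
    def test_identical_sequences_all_conserved(self):
        seq = "ACDEFGHIKLMNP"
        p = profile(np.linspace(0, 1, len(seq)))
        cmp = compare_homologs(p, p, seq, seq)
        assert all(c.label == "conserved" for c in cmp.columns)
        assert cmp.identity == 1.0

    def test_insert_block_labeled_as_insertions(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = a[:10] + "WWWWW" + a[10:]
        cmp = compare_homologs(
            profile(np.ones(len(a))), profile(np.ones(len(b))), a, b
        )
        labels = [c.label for c in cmp.columns]
        assert labels.count("insertion") == 5
        assert len(labels) == 25

    def test_labels_partition_alignment_and_order_invariance(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        from thermadapt.synthgen import mutate_to_identity

        b = mutate_to_identity(SequenceRecord(id="p", sequence=a), 0.7, seed=1).sequence
        pa, pb = profile(rng.random(len(a)), "a"), profile(rng.random(len(b)), "b")
        cmp_ab = compare_homologs(pa, pb, a, b)
        cmp_ba = compare_homologs(pb, pa, b, a)
        from collections import Counter

        counts_ab = Counter(c.label for c in cmp_ab.columns)
        counts_ba = Counter(c.label for c in cmp_ba.columns)
        assert sum(counts_ab.values()) == len(cmp_ab.columns)
        assert counts_ab == counts_ba
        assert cmp_ab.identity == cmp_ba.identity


class TestColumnEntropy:
    def test_hand_cases_and_oracle(self):
        assert column_entropy([["A", "A", "A", "A"]]) == [0.0]
        assert column_entropy([["A", "C", "D", "E"]])[0] == pytest.approx(2.0)
        assert column_entropy([["-", "-"]]) == [None]
        rng = np.random.default_rng(0)
        for _ in range(20):
            col = list(rng.choice(list("ACDEFG-"), 12))
            out = column_entropy([col])[0]
            residues = [c for c in col if c != "-"]
            if not residues:
                assert out is None
                continue
            from collections import Counter

            p = np.array(list(Counter(residues).values())) / len(residues)
            assert out == pytest.approx(float(-(p * np.log2(p)).sum()))


class TestStructureMapping:
    @staticmethod
    def _synthetic_pdb(tmp_path, sequence: str, chain="A"):
        """Synthetic one-chain C-alpha trace for the given sequence."""
        import biotite.structure as struc
        from biotite.sequence import ProteinSequence
        from biotite.structure.io.pdb import PDBFile

        n = len(sequence)
        atoms = struc.AtomArray(n)
        atoms.coord = np.stack(
            [np.arange(n) * 3.8, np.zeros(n), np.zeros(n)], axis=1
        )
        atoms.chain_id = np.full(n, chain)
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.array(
            [ProteinSequence.convert_letter_1to3(c).upper() for c in sequence]
        )
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        atoms.hetero = np.zeros(n, bool)
        pdb = PDBFile()
        pdb.set_structure(atoms)
        path = tmp_path / "synthetic.pdb"
        pdb.write(str(path))
        return path

    def test_scores_round_trip_through_bfactor_column(self, tmp_path):
        from biotite.structure.io.pdb import PDBFile

        seq = "ACDEFGHIKLMNPQRSTVWY"
        path = self._synthetic_pdb(tmp_path, seq)
        scores = np.linspace(0.2, 1.4, len(seq))
        out = write_bfactor_pdb(path, "A", profile(scores), seq, tmp_path / "out.pdb")
        atoms = PDBFile.read(str(out)).get_structure(model=1, extra_fields=["b_factor"])
        scaled = (scores - scores.min()) / (scores.max() - scores.min()) * 100
        np.testing.assert_allclose(atoms.b_factor, scaled, atol=0.005)
        # coordinates unchanged
        orig = PDBFile.read(str(path)).get_structure(model=1)
        np.testing.assert_allclose(atoms.coord, orig.coord, atol=1e-3)

    def test_constant_profile_maps_to_zero(self, tmp_path):
        from biotite.structure.io.pdb import PDBFile

        seq = "ACDEFGHIKL"
        path = self._synthetic_pdb(tmp_path, seq)
        out = write_bfactor_pdb(
            path, "A", profile(np.ones(len(seq))), seq, tmp_path / "out.pdb"
        )
        atoms = PDBFile.read(str(out)).get_structure(model=1, extra_fields=["b_factor"])
        assert np.all(atoms.b_factor == 0.0)

    def test_missing_chain_and_low_identity_warning(self, tmp_path):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        path = self._synthetic_pdb(tmp_path, seq)
        with pytest.raises(ValueError, match="chain"):
            write_bfactor_pdb(path, "B", profile(np.ones(len(seq))), seq,
                              tmp_path / "o.pdb")
        other = "WYWYWYWYWYWYWYWYWYWY"
        with pytest.warns(UserWarning, match="identity"):
            write_bfactor_pdb(path, "A", profile(np.ones(len(other))), other,
                              tmp_path / "o2.pdb")
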