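"""CMRT table I/O, filters, RTv consistency, similarity grouping."""

import numpy as np
import pytest

from chirsep.cmrt_data import (
    MoleculeRecord,
    chrom_equation_error,
    filter_records,
    load_cmrt,
    rtv,
    similarity_groups,
    write_cmrt,
)
from chirsep.errors import ContractError, SchemaError


def _rec(**kw):
    base = dict(
        smiles="C[C@H](O)c1ccccc1", column_name="ADH", elution_proportion=0.05,
        flow_rate=1.0, rt=10.0,
    )
    base.update(kw)
    return MoleculeRecord(**base)


class TestRtv:
    def test_unit_flow_identity(self):
        assert rtv(12.0, 1.0) == 12.0

    def test_product(self):
        assert rtv(20.0, 0.5) == 10.0

    def test_inverse_relation_exact(self):
        assert rtv(20.0, 0.5) / 0.5 == 20.0
        for rt, v in [(7.3, 0.7), (41.2, 0.85)]:
            assert abs(rtv(rt, v) / v - rt) <= 1e-12 * rt

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ContractError):
            rtv(0.0, 1.0)
        with pytest.raises(ContractError):
            rtv(10.0, -1.0)


class TestLoadWrite:
    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "fixture.csv"
        path.write_text(
            "smiles,column_name,elution_proportion,flow_rate,rt\n"
            "CCO,ADH,0.05,1.0,10.0\n"
            "C[C@H](N)C(=O)O,ODH,98/02,0.5,20.0\n"
            "c1ccccc1,IC,0.1,1.0,5.5\n"
        )
        result = load_cmrt(path)
        assert len(result.records) == 3
        assert result.rejects.empty
        assert result.records[1].elution_proportion == 0.02  # "98/02" normalized

    def test_invalid_rows_go_to_rejects_with_reason(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "smiles,column_name,elution_proportion,flow_rate,rt\n"
            "CCO,ADH,0.05,1.0,-3.0\n"
            "CCO,ADH,0.05,1.0,12.0\n"
        )
        result = load_cmrt(path)
        assert len(result.records) == 1
        assert len(result.rejects) == 1
        assert "positive" in result.rejects.iloc[0]["reason"]

    def test_missing_column_names_schema_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("smiles,rt\nCCO,10\n")
        with pytest.raises(SchemaError, match="column_name"):
            load_cmrt(path)

    def test_roundtrip_lossless(self, tmp_path):
        records = [
            _rec(pair_id="p1", handedness_label="major", source_id="doi:x"),
            _rec(smiles="C[C@@H](O)c1ccccc1", pair_id="p1", handedness_label="minor"),
            _rec(rt=33.3, flow_rate=0.7),
        ]
        path = tmp_path / "round.csv"
        write_cmrt(records, path)
        back = load_cmrt(path).records
        for a, b in zip(records, back):
            for f in ("smiles", "column_name", "elution_proportion", "flow_rate",
                      "rt", "handedness_label", "pair_id", "source_id"):
                assert getattr(a, f) == getattr(b, f)


class TestFilters:
    def test_rtv_threshold_is_strict(self):
        at = _rec(rt=60.0, flow_rate=1.0)       # RTv exactly 60: kept
        above = _rec(rt=61.0, flow_rate=1.0)    # RTv 61: dropped
        result = filter_records([at, above])
        assert at in result.kept
        assert [r for r, _ in result.removed] == [above]

    def test_stereocenter_bound_configurable(self):
        two_centers = _rec(smiles="C[C@H](O)[C@H](N)C(=O)O")
        assert filter_records([two_centers]).kept == []
        assert filter_records([two_centers], max_stereocenters=2).kept == [two_centers]

    def test_surviving_partner_flagged_unpaired(self):
        a = _rec(pair_id="p1", rt=10.0)
        b = _rec(smiles="C[C@@H](O)c1ccccc1", pair_id="p1", rt=61.0)  # dropped
        result = filter_records([a, b])
        assert result.kept == [a]
        assert a.unpaired is True
        assert result.flagged_unpaired == [a]


class TestChromEquationError:
    def test_identical_rtv_gives_zero_error(self):
        recs = [_rec(flow_rate=0.5, rt=20.0), _rec(flow_rate=1.0, rt=10.0)]
        summary = chrom_equation_error(recs)
        assert summary.n_groups == 1
        np.testing.assert_array_equal(summary.errors, [0.0])

    def test_hand_computed_median(self):
        recs = [_rec(flow_rate=0.5, rt=20.0), _rec(flow_rate=1.0, rt=12.0)]
        summary = chrom_equation_error(recs)
        assert summary.median == pytest.approx(2.0)

    def test_out_of_range_flow_excluded(self):
        recs = [_rec(flow_rate=0.1, rt=20.0), _rec(flow_rate=1.0, rt=10.0)]
        with pytest.warns(UserWarning):
            summary = chrom_equation_error(recs)
        assert summary.n_groups == 0

    def test_record_order_invariant(self, rng):
        recs = [
            _rec(flow_rate=0.5, rt=20.0), _rec(flow_rate=0.8, rt=13.0),
            _rec(flow_rate=1.0, rt=11.0),
            _rec(smiles="CC[C@H](C)O", flow_rate=0.5, rt=30.0),
            _rec(smiles="CC[C@H](C)O", flow_rate=1.0, rt=14.0),
        ]
        s1 = chrom_equation_error(recs)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        s2 = chrom_equation_error(shuffled)
        assert s1.median == s2.median
        np.testing.assert_array_equal(s1.errors, s2.errors)


class TestSimilarityGroups:
    def test_identical_molecule_in_every_group(self):
        test = [_rec()]
        train = [_rec(), _rec(smiles="CCCCCCCCCC")]
        sg = similarity_groups(test, train)
        assert all(0 in members for members in sg.members.values())

    def test_groups_nested_as_threshold_drops(self, rng):
        pool = [
            "C[C@H](O)c1ccccc1", "C[C@H](O)c1ccc(C)cc1", "CC[C@H](C)O",
            "N[C@H](C(=O)O)Cc1ccccc1", "c1ccc2ccccc2c1", "OCC(O)CO",
        ]
        test = [_rec(smiles=s) for s in pool]
        train = [_rec(smiles=s) for s in ["C[C@H](O)c1ccccc1", "CCO", "c1ccccc1"]]
        sg = similarity_groups(test, train, thresholds=(95, 80, 60, 40, 20))
        sizes = [len(sg.members[t]) for t in (95, 80, 60, 40, 20)]
        assert sizes == sorted(sizes)  # nondecreasing as threshold falls

    def test_disjoint_scaffolds_empty_at_50(self):
        """Deliberately unrelated structures: brute-force max similarity < 50%."""
        from rdkit import Chem, DataStructs
        from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

        test = [_rec(smiles="FC(F)(F)C(F)(F)F")]
        train = [_rec(smiles="c1ccc2ccccc2c1"), _rec(smiles="OCC(O)C(O)C(O)CO")]
        gen = GetMorganGenerator(radius=2, fpSize=2048)
        fp_t = gen.GetFingerprint(Chem.MolFromSmiles(test[0].smiles))
        sims = [
            DataStructs.TanimotoSimilarity(fp_t, gen.GetFingerprint(Chem.MolFromSmiles(r.smiles)))
            for r in train
        ]
        assert max(sims) < 0.5  # oracle guarding the fixture
        sg = similarity_groups(test, train, thresholds=(95, 80, 50))
        assert all(len(m) == 0 for m in sg.members.values())
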