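"""Curation: filters, deduplication, binarization, conservation."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npjury.chem import canonical_smiles
from npjury.curation import (
    ActivityRecord,
    binarize,
    curate,
    deduplicate,
    filter_records,
    read_activity_table,
    write_activity_table,
)
from npjury.errors import EmptyDatasetError, FormatError, InputError


def rec(
    smiles="CCO",
    type_="IC50",
    relation="=",
    value=500.0,
    units="nM",
    mol_id="M1",
    unparseable=False,
):
    return ActivityRecord(
        molecule_id=mol_id,
        smiles=smiles,
        standard_type=type_,
        standard_relation=relation,
        standard_value=value,
        standard_units=units,
        value_unparseable=unparseable,
    )


class TestReadWrite:
    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "molecule_id,smiles,standard_type,standard_relation,standard_value,standard_units\n"
        )
        assert read_activity_table(path) == []

    def test_roundtrip_is_byte_stable(self, tmp_path):
        records = [rec(mol_id=f"M{i}", value=100.0 * (i + 1)) for i in range(3)]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_activity_table(records, p1)
        write_activity_table(read_activity_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_column_names_reported(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("molecule_id,smiles,standard_type\nM1,CCO,IC50\n")
        with pytest.raises(FormatError, match="standard_value"):
            read_activity_table(path)

    def test_unparseable_value_flagged_and_counted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "molecule_id,smiles,standard_type,standard_relation,standard_value,standard_units\n"
            "M1,CCO,IC50,=,abc,nM\n"
        )
        (record,) = read_activity_table(path)
        assert record.value_unparseable and record.standard_value is None
        _, drops = filter_records([record])
        assert drops == {"unparseable_value": 1}

    def test_tsv_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "molecule_id\tsmiles\tstandard_type\tstandard_relation\tstandard_value\tstandard_units\n"
            "M1\tCCO\tIC50\t=\t500\tnM\n"
        )
        (record,) = read_activity_table(path)
        assert record.standard_value == 500.0


class TestFilters:
    @pytest.mark.parametrize("type_", ["IC50", "Kd", "Ki", "kd", "ic50"])
    def test_exact_nanomolar_measurements_kept(self, type_):
        kept, drops = filter_records([rec(type_=type_)])
        assert len(kept) == 1 and not drops

    @pytest.mark.parametrize(
        "record,reason",
        [
            (rec(type_="EC50"), "type"),
            (rec(relation=">"), "relation"),
            (rec(relation="~"), "relation"),
            (rec(relation=""), "relation"),
            (rec(value=0.5, units="uM"), "units"),
            (rec(units="ug.mL-1"), "units"),
            (rec(value=-3.0), "value"),
            (rec(smiles="not_a_smiles"), "smiles"),
        ],
    )
    def test_drop_reason_is_first_failing_criterion(self, record, reason):
        kept, drops = filter_records([record])
        assert not kept and drops == {reason: 1}

    def test_multiple_failures_charged_to_first_in_order(self):
        # fails type AND relation AND units: counted under "type" only
        _, drops = filter_records([rec(type_="EC50", relation=">", units="uM")])
        assert drops == {"type": 1}


class TestDeduplicate:
    def test_median_of_replicates(self):
        entries = deduplicate([rec(value=100.0), rec(value=400.0)])
        assert len(entries) == 1
        assert entries["value_nM"].iloc[0] == 250.0
        assert entries["n_replicates"].iloc[0] == 2

    def test_single_record_passes_through(self):
        entries = deduplicate([rec(value=42.0)])
        assert entries["value_nM"].tolist() == [42.0]

    def test_equivalent_smiles_merge(self):
        entries = deduplicate([rec(smiles="CCO", value=100.0), rec(smiles="OCC", value=300.0)])
        assert len(entries) == 1
        assert entries["value_nM"].iloc[0] == 200.0

    def test_salt_stripping_keeps_largest_organic_fragment(self):
        assert canonical_smiles("CCO.Cl") == canonical_smiles("CCO")
        assert canonical_smiles("CC(=O)[O-].[Na+]") == canonical_smiles("CC(=O)[O-]")


class TestBinarize:
    @pytest.mark.parametrize("value,label", [(500.0, 1), (1000.0, 0), (999.999, 1), (5000.0, 0)])
    def test_strict_threshold(self, value, label):
        assert binarize(value) == label

    def test_nonpositive_value_rejected(self):
        with pytest.raises(InputError):
            binarize(-1.0)


class TestCurate:
    def test_mixed_table_provenance_sums_to_input(self):
        records = [
            rec(mol_id="A", value=100.0),
            rec(mol_id="B", value=2000.0),
            rec(mol_id="C", smiles="c1ccccc1O", value=50.0),
            rec(mol_id="D", smiles="c1ccccc1O", value=150.0),
            rec(mol_id="E", relation=">"),
            rec(mol_id="F", units="uM", value=0.2),
            rec(mol_id="G", type_="EC50"),
            rec(mol_id="H", smiles="xx"),
            rec(mol_id="I", value=-1.0),
            rec(mol_id="J", relation="~"),
        ]
        dataset = curate(records)
        dropped = sum(v for k, v in dataset.provenance.items() if k != "retained_records")
        assert dropped + dataset.provenance["retained_records"] == len(records)
        assert len(dataset.entries) <= 4
        # label consistency invariant
        expect = (dataset.entries["value_nM"] < dataset.threshold_nM).astype(int)
        assert (dataset.entries["label"] == expect).all()
        assert dataset.entries["canonical_smiles"].is_unique

    def test_all_records_failing_raises_empty_dataset(self):
        with pytest.raises(EmptyDatasetError):
            curate([rec(relation=">"), rec(units="uM")])

    def test_idempotent_on_entry_set(self):
        records = [rec(mol_id=str(i), smiles=s, value=v) for i, (s, v) in
                   enumerate([("CCO", 100.0), ("OCC", 900.0), ("c1ccccc1", 3000.0)])]
        once = curate(records)
        again = curate(
            [
                rec(mol_id=str(i), smiles=row.canonical_smiles, value=row.value_nM)
                for i, row in enumerate(once.entries.itertuples())
            ]
        )
        columns = ["canonical_smiles", "value_nM", "label"]
        pd.testing.assert_frame_equal(
            once.entries[columns].reset_index(drop=True),
            again.entries[columns].reset_index(drop=True),
        )

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["IC50", "Kd", "EC50"]),
                st.sampled_from(["=", ">", "<"]),
                st.floats(min_value=1.0, max_value=1e6, allow_nan=False),
                st.sampled_from(["nM", "uM"]),
            ),
            min_size=0,
            max_size=30,
        )
    )
    def test_conservation_always_holds(self, rows):
        records = [
            rec(mol_id=str(i), type_=t, relation=r, value=v, units=u)
            for i, (t, r, v, u) in enumerate(rows)
        ]
        kept, drops = filter_records(records)
        assert len(kept) + sum(drops.values()) == len(records)
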