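import numpy as np
import pytest

from mmdrp.core_data import OmicMatrix, OmicType, ResponseRecord
from mmdrp.splitters import SCHEMES, complete_profile_filter, split


def make_records(n_cells, n_drugs, rng, n_lineages=3):
    records = []
    for c in range(n_cells):
        for d in range(n_drugs):
            records.append(ResponseRecord(f"CL{c}", f"D{d}",
                                          float(rng.random()),
                                          f"LIN{c % n_lineages}"))
    return records


def scaffold_map_for(n_drugs, n_scaffolds):
    return {f"D{d}": f"S{d % n_scaffolds}" for d in range(n_drugs)}


class TestSchemes:
    def test_cell_line_partition(self, rng):
        records = make_records(10, 4, rng)
        folds = split(records, "cell_line", 5, seed=0)
        seen = []
        for f in folds:
            val_cells = {records[i].cell_line for i in f.validation_indices}
            train_cells = {records[i].cell_line for i in f.train_indices}
            assert not val_cells & train_cells
            seen += sorted(val_cells)
        assert sorted(seen) == sorted({r.cell_line for r in records})

    def test_drug_scaffold_no_scaffold_on_both_sides(self, rng):
        records = make_records(6, 10, rng)
        smap = scaffold_map_for(10, 5)
        folds = split(records, "drug_scaffold", 5, seed=1, scaffold_map=smap)
        for f in folds:
            val_sc = {smap[records[i].drug] for i in f.validation_indices}
            train_sc = {smap[records[i].drug] for i in f.train_indices}
            assert not val_sc & train_sc
            assert len(val_sc) == 1  # 5 scaffolds over 5 folds

    def test_both_scheme_grid_hand_enumeration(self, rng):
        """4 cell lines x 4 scaffolds, k=2: fold 0 validates on (cell group 0
        x scaffold group 0), trains on the opposite quadrant, discards the
        two mixed quadrants."""
        records = make_records(4, 4, rng)
        smap = scaffold_map_for(4, 4)
        folds = split(records, "both", 2, seed=3, scaffold_map=smap)
        for f in folds:
            n = len(f.validation_indices) + len(f.train_indices) + len(f.discarded_indices)
            assert n == len(records)
            val_cells = {records[i].cell_line for i in f.validation_indices}
            val_sc = {smap[records[i].drug] for i in f.validation_indices}
            for i in f.train_indices:
                assert records[i].cell_line not in val_cells
                assert smap[records[i].drug] not in val_sc
            # mixed quadrants: exactly one of (cell, scaffold) in validation groups
            for i in f.discarded_indices:
                in_cell = records[i].cell_line in val_cells
                in_sc = smap[records[i].drug] in val_sc
                assert in_cell != in_sc

    def test_cancer_type_uses_lineage(self, rng):
        records = make_records(9, 3, rng, n_lineages=3)
        folds = split(records, "cancer_type", 3, seed=2)
        for f in folds:
            val_lin = {records[i].lineage for i in f.validation_indices}
            train_lin = {records[i].lineage for i in f.train_indices}
            assert not val_lin & train_lin

    def test_validation_sets_partition_records(self, rng):
        records = make_records(8, 5, rng)
        for scheme in ("cell_line", "cancer_type"):
            folds = split(records, scheme, 3, seed=4)
            covered = sorted(i for f in folds for i in f.validation_indices)
            assert covered == list(range(len(records)))

    def test_seed_determinism_and_sensitivity(self, rng):
        records = make_records(10, 4, rng)
        a = split(records, "cell_line", 5, seed=7)
        b = split(records, "cell_line", 5, seed=7)
        assert [f.validation_indices for f in a] == [f.validation_indices for f in b]
        c = split(records, "cell_line", 5, seed=8)
        assert any(f1.validation_indices != f2.validation_indices
                   for f1, f2 in zip(a, c))

    def test_too_few_groups_rejected(self, rng):
        records = make_records(3, 2, rng)
        with pytest.raises(ValueError, match="folds"):
            split(records, "cell_line", 5, seed=0)

    def test_unresolvable_scaffold_rejected(self, rng):
        records = make_records(3, 3, rng)
        with pytest.raises(ValueError, match="scaffold"):
            split(records, "drug_scaffold", 2, seed=0, scaffold_map={})

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError):
            split(make_records(4, 2, rng), "random", 2, seed=0)

    def test_leakage_suite_random_fixtures(self):
        """Across many random fixtures and all four schemes, the grouping key
        never appears on both sides of a fold and the validation sets
        partition the non-discarded records."""
        rng = np.random.default_rng(12345)
        for trial in range(1000):
            n_cells = int(rng.integers(4, 9))
            n_drugs = int(rng.integers(4, 9))
            n_sc = int(rng.integers(2, n_drugs + 1))
            records = make_records(n_cells, n_drugs, rng,
                                   n_lineages=int(rng.integers(2, 5)))
            smap = scaffold_map_for(n_drugs, n_sc)
            scheme = SCHEMES[trial % 4]
            groups = {"cell_line": lambda r: r.cell_line,
                      "drug_scaffold": lambda r: smap[r.drug],
                      "cancer_type": lambda r: r.lineage}
            k = 2
            folds = split(records, scheme, k, seed=trial, scaffold_map=smap)
            covered = []
            for f in folds:
                if scheme == "both":
                    keys = [lambda r: r.cell_line, lambda r: smap[r.drug]]
                else:
                    keys = [groups[scheme]]
                for key in keys:
                    val = {key(records[i]) for i in f.validation_indices}
                    train = {key(records[i]) for i in f.train_indices}
                    assert not val & train, (scheme, trial)
                covered += f.validation_indices
            assert sorted(covered) == sorted(set(covered))
            if scheme != "both":
                assert sorted(covered) == list(range(len(records)))


class TestCompleteProfileFilter:
    def matrix(self, cells, omic=OmicType.EXP):
        return OmicMatrix(omic, cells, ["g"], np.zeros((len(cells), 1)))

    def test_incomplete_cell_line_dropped(self, rng):
        records = make_records(3, 2, rng)
        mats = [self.matrix(["CL0", "CL1", "CL2"]),
                self.matrix(["CL0", "CL1"], OmicType.CNV)]
        kept, summary = complete_profile_filter(records, mats)
        assert {r.cell_line for r in kept} == {"CL0", "CL1"}

    def test_all_complete_unchanged(self, rng):
        records = make_records(3, 2, rng)
        mats = [self.matrix(["CL0", "CL1", "CL2"])]
        kept, summary = complete_profile_filter(records, mats)
        assert kept == records
        assert summary["pct_records_kept"] == 100.0

    def test_summary_percentages(self, rng):
        records = make_records(10, 1, rng)
        complete = [f"CL{i}" for i in range(4)]
        every = [f"CL{i}" for i in range(10)]
        mats = [self.matrix(every), self.matrix(complete, OmicType.CNV)]
        kept, summary = complete_profile_filter(records, mats)
        assert summary["n_cell_lines_complete"] == 4
        assert summary["pct_cell_lines_kept"] == pytest.approx(40.0)

    def test_no_matrices_rejected(self, rng):
        with pytest.raises(ValueError):
            complete_profile_filter(make_records(2, 2, rng), [])
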