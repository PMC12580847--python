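"""Reaction-core extraction and the three splitting strategies."""

import copy

import numpy as np
import pytest

from tsflow.errors import EmptyCoreError, SplitError, SplitWarning
from tsflow.fixtures import FixtureSpec, make_fixture_dataset
from tsflow.reaction_io import parse_reaction
from tsflow.splits import (extract_core, split_by_barrier, split_by_core,
                           split_random)


def _assert_partition(assignment, ids):
    parts = [assignment.train, assignment.val, assignment.test]
    assert set().union(*parts) == set(ids)
    assert sum(len(p) for p in parts) == len(ids)


class TestExtractCore:
    def test_single_bond_break_core_atoms(self):
        r = parse_reaction("[H:3][C:1]([H:4])=[O:2]>>[H:3][C:1]=[O:2].[H:4]")
        core = extract_core(r)
        assert core.core_atoms == {1, 4}

    def test_map_renumbering_gives_identical_key(self):
        a = parse_reaction("[H:3][C:1]([H:4])=[O:2]>>[H:3][C:1]=[O:2].[H:4]")
        s = "[H:1][C:4]([H:2])=[O:3]>>[H:1][C:4]=[O:3].[H:2]"
        b = parse_reaction(s)
        assert extract_core(a).core_key == extract_core(b).core_key

    def test_distinct_transformations_give_distinct_keys(self):
        ch = parse_reaction("[H:3][C:1]([H:4])=[O:2]>>[H:3][C:1]=[O:2].[H:4]")
        co = parse_reaction("[H:3][C:1]([H:4])=[O:2]>>[H:3][C:1][H:4].[O:2]")
        assert extract_core(ch).core_key != extract_core(co).core_key

    def test_two_changed_bonds_union_core(self):
        # C=C demoted to single AND a C-H bond formed elsewhere (H shift)
        r = parse_reaction(
            "[H:3][C:1]([H:4])=[C:2]([H:5])[H:6]>>"
            "[H:4][C:1]([H:3])[C:2]([H:5])([H:6])")
        core = extract_core(r)
        assert {1, 2}.issubset(core.core_atoms)

    def test_null_reaction_has_no_core(self):
        r = parse_reaction("[H:1][H:2]>>[H:1][H:2]")
        with pytest.raises(EmptyCoreError):
            extract_core(r)

    def test_fixture_core_count_matches_template_count(self):
        ds = make_fixture_dataset(FixtureSpec(n_reactions=9, seed=5, n_cores=3,
                                              n_heavy_range=(3, 4)))
        keys = {extract_core(r).core_key for r in ds}
        assert len(keys) == 3


class TestSplitRandom:
    def test_100_ids_default_fractions(self):
        ids = [f"r{i:03d}" for i in range(100)]
        a = split_random(ids, seed=1)
        assert (len(a.train), len(a.val), len(a.test)) == (80, 10, 10)
        _assert_partition(a, ids)

    def test_same_seed_identical(self):
        ids = [f"r{i}" for i in range(30)]
        assert split_random(ids, seed=4).as_dict() == split_random(ids, seed=4).as_dict()

    def test_different_seeds_differ(self):
        ids = [f"r{i}" for i in range(50)]
        base = split_random(ids, seed=0).test
        assert any(split_random(ids, seed=s).test != base for s in range(1, 6))

    def test_too_few_ids_rejected(self):
        with pytest.raises(SplitError):
            split_random(["a", "b"], seed=0)


class TestSplitByCore:
    def test_no_core_key_crosses_sets(self, tiny_dataset):
        a = split_by_core(tiny_dataset, seed=2)
        _assert_partition(a, [r.rxn_id for r in tiny_dataset])
        keysets = []
        by_id = {r.rxn_id: r for r in tiny_dataset}
        for part in (a.train, a.val, a.test):
            keysets.append({extract_core(by_id[i]).core_key for i in part})
        assert not (keysets[0] & keysets[1])
        assert not (keysets[0] & keysets[2])
        assert not (keysets[1] & keysets[2])

    def test_singleton_cores_fill_val_and_test(self):
        ds = make_fixture_dataset(FixtureSpec(n_reactions=10, seed=8, n_cores=3,
                                              n_heavy_range=(3, 4)))
        sizes = {}
        for r in ds:
            k = extract_core(r).core_key
            sizes[k] = sizes.get(k, 0) + 1
        assert sorted(sizes.values(), reverse=True) == [8, 1, 1]
        a = split_by_core(ds, seed=0)
        assert len(a.val) == 1 and len(a.test) == 1 and len(a.train) == 8

    def test_single_shared_core_warns_and_degenerates(self, tiny_dataset):
        clones = []
        for i in range(4):
            c = copy.copy(tiny_dataset[0])
            c.rxn_id = f"c{i}"
            clones.append(c)
        with pytest.warns(SplitWarning):
            a = split_by_core(clones, seed=0)
        nonempty = [p for p in (a.train, a.val, a.test) if p]
        assert len(nonempty) == 1 and len(nonempty[0]) == 4


class TestSplitByBarrier:
    def _with_barriers(self, dataset, barriers):
        out = []
        for r, b in zip(dataset, barriers):
            c = copy.copy(r)
            c.barrier_height = float(b)
            out.append(c)
        return out

    def _hundred(self, tiny_dataset):
        base = []
        for i in range(100):
            c = copy.copy(tiny_dataset[i % len(tiny_dataset)])
            c.rxn_id = f"b{i:03d}"
            c.barrier_height = float(i + 1)
            base.append(c)
        return base

    def test_barriers_1_to_100_train_is_inner_80(self, tiny_dataset):
        ds = self._hundred(tiny_dataset)
        a = split_by_barrier(ds, seed=0)
        train_barriers = {int(r.barrier_height) for r in ds if r.rxn_id in a.train}
        assert train_barriers == set(range(11, 91))
        _assert_partition(a, [r.rxn_id for r in ds])

    def test_train_range_is_contiguous_inner_interval(self, tiny_dataset):
        ds = self._hundred(tiny_dataset)
        a = split_by_barrier(ds, seed=3)
        by_id = {r.rxn_id: r.barrier_height for r in ds}
        train_vals = [by_id[i] for i in a.train]
        tail_vals = [by_id[i] for i in a.val | a.test]
        low = [v for v in tail_vals if v < min(train_vals)]
        high = [v for v in tail_vals if v > max(train_vals)]
        assert len(low) + len(high) == len(tail_vals)

    def test_missing_barrier_lists_ids(self, tiny_dataset):
        ds = self._with_barriers(tiny_dataset, range(len(tiny_dataset)))
        ds[2].barrier_height = None
        with pytest.raises(SplitError, match=ds[2].rxn_id):
            split_by_barrier(ds, seed=0)


class TestAllStrategiesPartition:
    def test_partitions_on_fixture_dataset(self, tiny_dataset):
        ids = [r.rxn_id for r in tiny_dataset]
        _assert_partition(split_random(ids, seed=0), ids)
        _assert_partition(split_by_core(tiny_dataset, seed=0), ids)
        _assert_partition(split_by_barrier(tiny_dataset, seed=0), ids)
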