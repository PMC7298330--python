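"""Item-model tests: inventories, incidentals, distractor balance, determinism."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from figmem.stimulus import (
    ERASABLE_FRAMES,
    ItemSpec,
    assign_distractors,
    build_emblem_inventory,
    build_frame_inventory,
    generate_item,
    generate_parallel_set,
    option_orders,
)


class TestInventories:
    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_sizes_and_distinctness(self, level):
        emblems = build_emblem_inventory(level)
        frames = build_frame_inventory(level)
        assert len(emblems) == 20 and len({e.key for e in emblems}) == 20
        assert len(frames) == 20 and len({f.key for f in frames}) == 20

    def test_levels_1_and_2_share_original_emblems(self):
        assert {e.key for e in build_emblem_inventory(1)} == {
            e.key for e in build_emblem_inventory(2)
        }
        assert all(e.orientation_deg == 0 and e.gap_position == "none"
                   for e in build_emblem_inventory(1))

    def test_level3_emblems_are_rotations_plus_gapped_rings(self):
        inv = build_emblem_inventory(3)
        rotated = [e for e in inv if e.gap_position == "none"]
        rings = [e for e in inv if e.gap_position != "none"]
        assert len(rotated) == 16 and len(rings) == 4
        assert {e.orientation_deg for e in rotated} == {0, 90, 180, 270}
        assert len({e.shape_id for e in rotated}) == 4
        assert {e.gap_position for e in rings} == {"top", "right", "bottom", "left"}

    def test_level1_frames_complete_level23_erased_variants(self):
        assert all(f.missing_line == 0 for f in build_frame_inventory(1))
        lvl2 = build_frame_inventory(2)
        assert {f.base_shape for f in lvl2} == set(ERASABLE_FRAMES)
        by_shape = Counter(f.base_shape for f in lvl2)
        assert set(by_shape.values()) == {5}  # complete + 4 erased variants
        assert {f.key for f in lvl2} == {f.key for f in build_frame_inventory(3)}

    @pytest.mark.parametrize("level", [0, 4, -1])
    def test_invalid_level_raises(self, level):
        with pytest.raises(ValueError, match="1, 2, 3"):
            build_emblem_inventory(level)
        with pytest.raises(ValueError, match="1, 2, 3"):
            build_frame_inventory(level)


class TestDistractorAssignment:
    def test_balance_and_exclusion(self):
        inv = build_frame_inventory(1)
        rng = np.random.default_rng(0)
        correct = list(inv)
        triples = assign_distractors(correct, inv, rng)
        counts = Counter(d.key for t in triples for d in t)
        assert set(counts.values()) == {3} and len(counts) == 20
        for cf, t in zip(correct, triples):
            keys = {d.key for d in t}
            assert len(keys) == 3 and cf.key not in keys

    def test_deterministic_in_rng_state(self):
        inv = build_frame_inventory(2)
        t1 = assign_distractors(inv, inv, np.random.default_rng(5))
        t2 = assign_distractors(inv, inv, np.random.default_rng(5))
        assert t1 == t2

    def test_infeasible_balance_raises(self):
        inv = build_frame_inventory(1)
        with pytest.raises(ValueError, match="divisible"):
            assign_distractors(inv[:7], inv, np.random.default_rng(0))


class TestGenerateItem:
    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_invariants_across_seeds(self, level):
        # distractor balance, bijection and permutation invariants over many
        # seeds at every radical level
        for seed in range(70):
            item = generate_item(level, seed)
            item.validate()
            counts = Counter(d.key for u in item.units for d in u.distractors)
            assert set(counts.values()) == {3} and len(counts) == 20
            inv_keys = {f.key for f in build_frame_inventory(level)}
            assert {u.correct_frame.key for u in item.units} == inv_keys

    def test_determinism_byte_identity(self):
        a = generate_item(2, 123).to_json()
        b = generate_item(2, 123).to_json()
        assert a == b

    def test_distinct_seeds_give_distinct_bijections(self):
        # collision probability 1/20! per pair under uniform permutations
        seen = set()
        for seed in range(100):
            item = generate_item(1, seed)
            bij = tuple(
                u.correct_frame.key
                for u in sorted(item.units, key=lambda u: u.emblem.key)
            )
            assert bij not in seen
            seen.add(bij)

    @pytest.mark.parametrize("n_units", [4, 10, 19])
    def test_reduced_n_units(self, n_units):
        item = generate_item(1, 3, n_units=n_units)
        item.validate()
        counts = Counter(d.key for u in item.units for d in u.distractors)
        assert set(counts.values()) == {3} and len(counts) == n_units

    @pytest.mark.parametrize("bad", [3, 21, 0])
    def test_invalid_n_units(self, bad):
        with pytest.raises(ValueError, match="n_units"):
            generate_item(1, 1, n_units=bad)

    def test_json_round_trip(self):
        item = generate_item(3, 77)
        again = ItemSpec.from_json(item.to_json())
        assert again.to_json() == item.to_json()

    def test_option_orders_are_permutations(self):
        item = generate_item(1, 8)
        orders = option_orders(item)
        assert len(orders) == 20
        assert all(sorted(o) == [0, 1, 2, 3] for o in orders)
        assert orders == option_orders(item)


class TestParallelSet:
    def test_same_level_distinct_items(self):
        items = generate_parallel_set(2, 3, master_seed=7)
        assert len(items) == 3
        assert all(it.radical_level == 2 for it in items)
        bijections = {
            tuple(u.correct_frame.key
                  for u in sorted(it.units, key=lambda u: u.emblem.key))
            for it in items
        }
        assert len(bijections) == 3

    def test_reproducible(self):
        a = [it.to_json() for it in generate_parallel_set(1, 3, 42)]
        b = [it.to_json() for it in generate_parallel_set(1, 3, 42)]
        assert a == b

    def test_study_layout_three_by_three(self):
        # the 3 x 3 study layout: three isomorphs per radical level
        table = {lev: generate_parallel_set(lev, 3, 11) for lev in (1, 2, 3)}
        for lev, items in table.items():
            assert [it.radical_level for it in items] == [lev] * 3


@settings(max_examples=30, deadline=None)
@given(
    level=st.sampled_from([1, 2, 3]),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_property_generated_items_always_valid(level, seed):
    item = generate_item(level, seed)
    item.validate()
    counts = Counter(d.key for u in item.units for d in u.distractors)
    assert set(counts.values()) == {3}
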