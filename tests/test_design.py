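"""Design enumeration, zoning, randomization and fingerprints."""

import pytest

from rtscreen.design import (
    ALL_WELLS,
    BarcodePool,
    CapacityError,
    Condition,
    ControlRules,
    DesignError,
    FactorLevels,
    PlateLayout,
    assign_barcodes,
    build_replicate_layouts,
    build_zone_plans,
    default_interleaving,
    enumerate_conditions,
    layout_fingerprint,
    pcr_cycles,
    randomize_layout,
)


def _one_enzyme(levels):
    return [c for c in enumerate_conditions(levels) if c.enzyme == levels.enzymes[0]]


class TestEnumerateConditions:
    def test_default_grid_has_648_combinations(self, levels):
        assert len(enumerate_conditions(levels)) == 648

    def test_single_level_per_factor(self):
        lv = FactorLevels((10,), (1,), (100,), ("E",))
        conds = enumerate_conditions(lv)
        assert len(conds) == 1
        assert not conds[0].is_control

    def test_nested_order_enzyme_outermost(self):
        lv = FactorLevels((1, 2), (3, 4), (5,), ("E",))
        got = [(c.tso, c.rtp) for c in enumerate_conditions(lv)]
        assert got == [(1, 3), (1, 4), (2, 3), (2, 4)]

    def test_empty_levels_rejected(self):
        with pytest.raises(DesignError):
            FactorLevels(tso_molarities=())

    def test_nonincreasing_levels_rejected(self):
        with pytest.raises(DesignError):
            FactorLevels(rtp_molarities=(4, 2, 1))


class TestZonePlans:
    def test_six_zones_of_64(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        assert len(plans) == 6
        assert all(len(p.members) == 64 for p in plans)

    def test_control_counts_per_zone(self, levels):
        for plan in build_zone_plans(_one_enzyme(levels), levels):
            assert plan.n_no_rtp == 9
            assert plan.n_no_rna == 1

    def test_zone_covers_grid_once(self, levels):
        plan = build_zone_plans(_one_enzyme(levels), levels)[0]
        grid = {(m.tso, m.rtp) for m in plan.members if not m.is_control}
        assert len(grid) == 54
        assert grid == {
            (t, p) for t in levels.tso_molarities for p in levels.rtp_molarities
        }

    def test_oversized_grid_raises_capacity_error(self):
        lv = FactorLevels(
            tso_molarities=tuple(float(i) for i in range(1, 11)),  # 10 TSO levels
            rtp_molarities=(1, 2, 4, 8, 16, 24),
            rna_masses=(1,),
            enzymes=("E",),
        )
        with pytest.raises(CapacityError):
            build_zone_plans(_one_enzyme(lv), lv, zone_size=64)


class TestRandomization:
    def test_same_seed_is_bit_identical(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        a = randomize_layout(plans, "p", seed=42)
        b = randomize_layout(plans, "p", seed=42)
        assert a.wells == b.wells

    def test_randomization_is_permutation_within_zone(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        layout = randomize_layout(plans, "p", seed=5)
        interleave = default_interleaving()
        for plan in plans:
            placed = sorted(
                [
                    (layout.wells[w][0].tso, layout.wells[w][0].rtp, layout.wells[w][0].rna)
                    for w in interleave[plan.zone_id]
                ],
                key=str,
            )
            expected = sorted(((m.tso, m.rtp, m.rna) for m in plan.members), key=str)
            assert placed == expected

    def test_zone_well_sets_are_fixed_interleaved_columns(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        layout = randomize_layout(plans, "p", seed=7)
        for well in ALL_WELLS:
            col = int(well[1:])
            assert layout.zone(well) == ((col - 1) % 6) + 1

    def test_distinct_seeds_give_distinct_fingerprints(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        fps = {
            layout_fingerprint(randomize_layout(plans, "p", seed=s))
            for s in (1, 2, 3, 4)
        }
        assert len(fps) == 4


class TestBarcodes:
    def test_64_distinct_barcodes_from_pool_of_70(self, levels, pool):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        layout = assign_barcodes(randomize_layout(plans, "p", seed=1), pool)
        assert len(pool) == 70
        assert len(layout.barcode_seqs) == 64

    def test_barcodes_unique_within_each_zone(self, one_plate):
        per_zone = {}
        for w, (cond, z) in one_plate.wells.items():
            per_zone.setdefault(z, []).append(one_plate.barcodes[w])
        for z, bcs in per_zone.items():
            assert len(set(bcs)) == 64

    def test_same_barcode_set_reused_across_zones(self, one_plate):
        sets = {}
        for w, (_, z) in one_plate.wells.items():
            sets.setdefault(z, set()).add(one_plate.barcodes[w])
        assert len({frozenset(s) for s in sets.values()}) == 1

    def test_undersized_pool_rejected(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        layout = randomize_layout(plans, "p", seed=1)
        small = BarcodePool.random_pool(size=63, seed=0)
        with pytest.raises(DesignError):
            assign_barcodes(layout, small)

    def test_pool_enforces_distinct_same_length_sequences(self):
        with pytest.raises(DesignError):
            BarcodePool({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(DesignError):
            BarcodePool({"a": "ACGT", "b": "ACG"})


class TestFingerprint:
    def test_fingerprint_deterministic_and_row_major(self, one_plate):
        fp = layout_fingerprint(one_plate)
        assert fp == layout_fingerprint(one_plate)
        wells = [w for w, _ in fp]
        assert wells == sorted(wells, key=ALL_WELLS.index)
        assert len(fp) == 60

    def test_swapping_control_with_experimental_changes_fingerprint(self, levels):
        plans = build_zone_plans(_one_enzyme(levels), levels)
        layout = randomize_layout(plans, "p", seed=3)
        fp = layout_fingerprint(layout)
        ctrl = next(w for w in ALL_WELLS if layout.wells[w][0].is_control)
        z = layout.wells[ctrl][1]
        exp = next(
            w for w in ALL_WELLS
            if not layout.wells[w][0].is_control and layout.wells[w][1] == z
        )
        layout.wells[ctrl], layout.wells[exp] = layout.wells[exp], layout.wells[ctrl]
        assert layout_fingerprint(layout) != fp

    def test_eight_replicate_layouts_have_distinct_fingerprints(self, screen_layouts):
        assert len({layout_fingerprint(l) for l in screen_layouts}) == 8


class TestScreenArithmetic:
    def test_per_plate_condition_and_control_counts(self, screen_layouts):
        plate = screen_layouts[0].to_frame()
        exp = plate[plate.control_type == "none"]
        assert len({tuple(r) for r in exp[["tso_uM", "rtp_uM", "rna_pg"]].values}) == 324
        assert (plate.control_type != "none").sum() == 60

    def test_demux_key_collision_free_per_pool(self, screen_layouts):
        # one pool per enzyme: 4 plates x 6 zones x 64 barcodes = 1536 keys
        for enzyme in ("SSIII", "SSIV"):
            keys = set()
            for layout in screen_layouts:
                if layout.enzyme != enzyme:
                    continue
                df = layout.to_frame()
                keys.update(zip(df.index_label, df.barcode_id))
            assert len(keys) == 1536


class TestLayoutIO:
    def test_csv_round_trip(self, one_plate, tmp_path):
        path = tmp_path / "layout.csv"
        one_plate.to_csv(path)
        back = PlateLayout.from_csv(path)
        assert back.wells == one_plate.wells
        assert back.barcodes == one_plate.barcodes
        assert back.index_labels == one_plate.index_labels


class TestPcrCycles:
    def test_printed_schedule(self, levels):
        got = {m: pcr_cycles(m) for m in levels.rna_masses}
        assert got == {100_000: 18, 10_000: 21, 1_000: 24, 100: 27, 10: 30, 1: 33}

    def test_unknown_mass_rejected(self):
        with pytest.raises(DesignError):
            pcr_cycles(7.0)


def test_condition_must_keep_one_of_rtp_rna():
    with pytest.raises(DesignError):
        Condition(tso=1.0, rtp=None, rna=None, enzyme="E")
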