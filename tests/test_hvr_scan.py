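"""Sliding-window profiles and hypervariable-region delimitation."""

import random

import pytest

import ctrlregion as cr
from ctrlregion.diversity import GapPolicy
from conftest import make_alignment
import _oracles as orc


def _random_rows(rng, n, L):
    base = [rng.choice("ACGT") for _ in range(L)]
    return [
        "".join(rng.choice("ACGT") if rng.random() < 0.1 else base[c]
                for c in range(L))
        for _ in range(n)
    ]


class TestWindowProfile:
    def test_window_count_formula(self):
        rng = random.Random(0)
        aln = make_alignment(_random_rows(rng, 3, 1022))
        prof = cr.window_profile(aln, window_length=100, step=25)
        assert prof.n_windows == (1022 - 100) // 25 + 1 == 37

    def test_monomorphic_profile_is_flat_zero(self):
        aln = make_alignment(["ACGT" * 50] * 4)
        prof = cr.window_profile(aln, 50, 10)
        assert all(p.pi_window == 0 for p in prof.points)

    def test_variation_localised_to_left_end(self):
        rng = random.Random(3)
        L = 120
        rows = []
        base = [rng.choice("ACGT") for _ in range(L)]
        for i in range(4):
            row = base.copy()
            for c in range(20):  # all variation in columns 1-20
                if rng.random() < 0.5:
                    row[c] = rng.choice("ACGT")
            rows.append("".join(row))
        aln = make_alignment(rows)
        prof = cr.window_profile(aln, 40, 5)
        pis = [p.pi_window for p in prof.points]
        assert max(range(len(pis)), key=pis.__getitem__) == 0
        for p in prof.points:
            if p.start > 20:  # windows past the variable stretch
                assert p.pi_window == 0

    def test_each_window_matches_oracle(self):
        rng = random.Random(11)
        rows = _random_rows(rng, 5, 200)
        aln = make_alignment(rows)
        prof = cr.window_profile(aln, 60, 20)
        for p in prof.points:
            S, mean_d, n_an = orc.window_stats(rows, p.start - 1, 60,
                                               "complete_deletion")
            assert p.s_window == S
            assert p.n_analyzed == n_an
            assert p.pi_window == pytest.approx(mean_d / n_an if n_an else 0.0)

    def test_window_longer_than_alignment_rejected(self, toy_aln):
        with pytest.raises(ValueError):
            cr.window_profile(toy_aln, window_length=100)

    def test_profile_invariant_to_record_order(self, default_panel):
        aln, _ = default_panel
        rev = cr.Alignment(list(reversed(aln.records)))
        a = cr.window_profile(aln)
        b = cr.window_profile(rev)
        assert [p.pi_window for p in a.points] == [p.pi_window for p in b.points]

    def test_disjoint_windows_sum_to_total_differences(self):
        rng = random.Random(5)
        rows = _random_rows(rng, 6, 200)  # gap-free: all columns analysed
        aln = make_alignment(rows)
        prof = cr.window_profile(aln, 50, 50)
        total = sum(p.pi_window * p.n_analyzed for p in prof.points)
        assert total == pytest.approx(cr.mean_pairwise_differences(aln))


class TestConservationThreshold:
    def test_uniform_scatter_arithmetic(self):
        assert cr.expected_sites_per_window(186, 1000, 100) == pytest.approx(18.6)

    def test_no_variation_gives_zero(self):
        aln = make_alignment(["ACGT" * 30] * 3)
        assert cr.conservation_threshold(aln, 40) == 0.0

    def test_saturation_equals_window_length(self):
        assert cr.expected_sites_per_window(500, 500, 75) == 75.0


class TestDelimitRegions:
    def test_monomorphic_alignment_single_conserved_interval(self):
        aln = make_alignment(["ACGT" * 50] * 4)
        prof = cr.window_profile(aln, 50, 10)
        regions = cr.delimit_regions(prof, aln)
        assert regions.hypervariable == []
        [only] = regions.intervals
        assert (only.start, only.label) == (1, "conserved")

    def test_planted_block_recovered_within_one_step(self):
        hits = 0
        for seed in range(25):
            aln, truth = cr.generate(cr.SyntheticConfig(seed=seed))
            regions = cr.delimit_regions(cr.window_profile(aln), aln)
            hvr1 = regions.hvr1
            (bs, be, _), = truth.blocks
            if hvr1 and abs(hvr1.start - bs) <= 25 and abs(hvr1.end - be) <= 25:
                hits += 1
        assert hits >= 23

    def test_intervals_partition_covered_columns(self, bornean_panel):
        aln, _ = bornean_panel
        prof = cr.window_profile(aln)
        regions = cr.delimit_regions(prof, aln)
        covered_end = prof.points[-1].start + prof.window_length - 1
        cursor = 1
        last_label = None
        for r in regions.intervals:
            assert r.start == cursor
            assert r.label != last_label  # labels alternate where adjacent
            cursor = r.end + 1
            last_label = r.label
        assert cursor == covered_end + 1

    def test_finer_step_moves_boundaries_by_less_than_old_step(self):
        aln, _ = cr.generate(cr.SyntheticConfig(seed=2))
        coarse = cr.delimit_regions(cr.window_profile(aln, 100, 25), aln)
        fine = cr.delimit_regions(cr.window_profile(aln, 100, 5), aln)
        c1, f1 = coarse.hvr1, fine.hvr1
        assert c1 is not None and f1 is not None
        assert abs(c1.start - f1.start) <= 25
        assert abs(c1.end - f1.end) <= 25

    def test_secondary_blocks_differ_between_panel_styles(
        self, bornean_panel, sumatran_panel
    ):
        """Panel-specific hotspot placement yields different secondary regions.

        Polymorphism density is elevated in every planted block (three hot
        stretches in the Bornean-style panel vs two in the Sumatran-style
        one), and a sensitised scan (multiplier 0.6, surfacing stretches that
        are apparent but below the HVRI threshold) detects intervals at
        panel-specific positions, each overlapping a planted block.
        """
        out = {}
        for name, (aln, truth) in (
            ("bornean", bornean_panel), ("sumatran", sumatran_panel),
        ):
            ingroup = aln.subset(
                [i for i in aln.ids if i not in truth.outgroup_ids]
            )
            _, _, sites = cr.segregating_sites(ingroup)
            in_block = {
                c for bs, be, _ in truth.blocks for c in range(bs, be + 1)
            }
            n_out_cols = ingroup.n_cols - len(in_block)
            dens_out = sum(1 for c in sites if c not in in_block) / n_out_cols
            for bs, be, _ in truth.blocks:
                dens = sum(1 for c in sites if bs <= c <= be) / (be - bs + 1)
                assert dens > 2 * dens_out
            regions = cr.delimit_regions(
                cr.window_profile(ingroup), ingroup, threshold_multiplier=0.6
            )
            ivs = [(r.start, r.end) for r in regions.hypervariable]
            assert len(ivs) == len(truth.blocks)
            for (s, e), (bs, be, _) in zip(ivs, truth.blocks):
                assert s <= be and e >= bs  # each detection overlaps its block
            out[name] = ivs
        assert len(out["bornean"]) == 3
        assert len(out["sumatran"]) == 2
        assert out["bornean"][1:] != out["sumatran"][1:]

    def test_region_export_to_reference_coordinates(self, sumatran_panel):
        aln, _ = sumatran_panel
        regions = cr.delimit_regions(cr.window_profile(aln), aln)
        cmap = cr.build_coordinate_map(aln, aln.ids[0], ref_start=15484)
        refs = regions.to_reference(cmap)
        assert len(refs) == len(regions.intervals)
        assert refs[0][0] == 15484

    def test_profile_and_region_tables(self, default_panel, tmp_path):
        aln, _ = default_panel
        prof = cr.window_profile(aln)
        regions = cr.delimit_regions(prof, aln)
        pt = cr.profile_table(prof)
        rt = cr.regions_table(regions)
        assert len(pt) == prof.n_windows
        assert set(rt["label"]) <= {"conserved", "hypervariable"}
        cr.plot_profile(prof, tmp_path / "profile.png", regions)
        assert (tmp_path / "profile.png").stat().st_size > 0
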