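"""Single-cell copy-number profiling, QC and clonality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecell import cna, synthetic
from rarecell.cna import (
    Alteration,
    ClonalityRule,
    CNProfile,
    QCThresholds,
    QS_SENTINEL,
    call_clonality,
    call_integers,
    extract_alterations,
    normalize,
    profile_from_counts,
    qc,
    quality_score,
    segment,
)


class TestNormalize:
    def test_flat_counts_give_unit_ratios(self):
        np.testing.assert_allclose(normalize(np.full(10, 37.0)), 1.0)

    def test_arithmetic(self):
        np.testing.assert_allclose(
            normalize(np.array([100.0, 50.0, 100.0, 150.0])), [1.0, 0.5, 1.0, 1.5]
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=1e6))
    def test_scale_invariance(self, scale):
        counts = np.array([10.0, 20.0, 5.0, 40.0, 25.0])
        np.testing.assert_allclose(normalize(counts * scale), normalize(counts))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            normalize(np.zeros(5))

    def test_mean_of_ratios_is_one(self, rng):
        r = normalize(rng.poisson(100, 500).astype(float))
        assert r.mean() == pytest.approx(1.0, abs=1e-9)


class TestQualityScore:
    def test_noiseless_flat_gives_sentinel(self):
        assert quality_score(np.ones(100)) == QS_SENTINEL

    def test_alternating_ratios_exactly_at_threshold(self):
        """Ratios alternating 0.8/1.2: MAPD = 0.4, QS = 2.5 (inclusive pass)."""
        ratios = np.tile([0.8, 1.2], 50)
        qs = quality_score(ratios)
        assert qs == pytest.approx(2.5)
        assert qs >= QCThresholds().min_qs

    def test_poisson_noise_crosses_threshold_with_depth(self):
        """Low depth (3 reads/bin) fails QS >= 2.5; high depth (200) passes.

        At m reads/bin the adjacent-ratio difference has SD ~ sqrt(2/m), so
        MAPD ~ 0.674*sqrt(2/m): well above 0.4 at m=3, ~0.067 at m=200.
        """
        rng = np.random.default_rng(0)
        low = normalize(rng.poisson(3, 2200).astype(float) + 1e-9)
        high = normalize(rng.poisson(200, 2200).astype(float))
        assert quality_score(low) < 2.5
        assert quality_score(high) > 2.5

    def test_diffs_do_not_cross_chromosomes(self):
        ratios = np.array([1.0, 1.0, 5.0, 5.0])
        chroms = np.array(["a", "a", "b", "b"])
        assert quality_score(ratios, chroms) == QS_SENTINEL  # the 1->5 jump spans chroms

    def test_single_bin_chromosomes_raise(self):
        with pytest.raises(ValueError):
            quality_score(np.array([1.0, 2.0]), np.array(["a", "b"]))


class TestSegmentation:
    def test_flat_profile_single_segment_per_chromosome(self):
        ratios = np.ones(200)
        chroms = np.repeat(["chr1", "chr2"], 100)
        segs = segment(ratios, chroms, n_perm=100)
        assert len(segs) == 2
        assert list(segs["n_bins"]) == [100, 100]

    def test_noiseless_step_breakpoint_exact(self):
        ratios = np.concatenate([np.ones(50), np.full(50, 0.5)])
        segs = segment(ratios, np.full(100, "chr1"))
        assert len(segs) == 2
        assert segs.iloc[0]["end_bin"] == 49 and segs.iloc[1]["start_bin"] == 50
        assert segs.iloc[0]["mean_ratio"] == pytest.approx(1.0)
        assert segs.iloc[1]["mean_ratio"] == pytest.approx(0.5)

    def test_poisson_breakpoint_recovery(self):
        """CN {2,1,2,3} blocks of 50 bins at 200 reads/bin: breakpoints
        within +/-2 bins in >=9/10 seeds."""
        cn = np.repeat([2, 1, 2, 3], 50)
        expected_bp = {50, 100, 150}
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(200 * cn / 2).astype(float)
            segs = segment(normalize(counts), np.full(200, "chr1"), n_perm=200, seed=seed)
            found = set(segs["start_bin"]) - {0}
            ok = len(found) == 3 and all(
                min(abs(f - b) for f in found) <= 2 for b in expected_bp
            )
            hits += ok
        assert hits >= 9

    def test_idempotence_on_piecewise_constant_input(self):
        ratios = np.concatenate([np.ones(30), np.full(40, 1.5), np.full(30, 0.5)])
        segs1 = segment(ratios, np.full(100, "chr1"))
        expanded = np.repeat(segs1["mean_ratio"].to_numpy(), segs1["n_bins"].to_numpy())
        segs2 = segment(expanded, np.full(100, "chr1"))
        pd.testing.assert_frame_equal(segs1, segs2)

    def test_seed_determinism(self, rng):
        counts = rng.poisson(50, 300).astype(float)
        r = normalize(counts)
        a = segment(r, np.full(300, "chr1"), seed=9)
        b = segment(r, np.full(300, "chr1"), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestIntegerCalling:
    def _segs(self, ratios, n_bins):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start_bin": np.cumsum([0] + list(n_bins[:-1])),
                "end_bin": np.cumsum(n_bins) - 1,
                "n_bins": n_bins,
                "mean_ratio": ratios,
            }
        )

    def test_single_diploid_segment(self):
        segs, ploidy = call_integers(self._segs([1.0], [100]))
        assert ploidy == pytest.approx(2.0)
        assert list(segs["cn"]) == [2]

    def test_exact_integer_ratios(self):
        segs, ploidy = call_integers(self._segs([1.0, 0.5, 1.5], [50, 50, 50]))
        assert ploidy == pytest.approx(2.0)
        assert list(segs["cn"]) == [2, 1, 3]

    def test_tetraploid_consistent_ratios(self):
        """Ratios {1.0, 0.75, 1.25} fit only P=4 exactly: CN {4,3,5}."""
        segs, ploidy = call_integers(self._segs([1.0, 0.75, 1.25], [50, 50, 50]))
        assert ploidy == pytest.approx(4.0)
        assert list(segs["cn"]) == [4, 3, 5]

    def test_empty_segments_raise(self):
        with pytest.raises(ValueError):
            call_integers(pd.DataFrame(columns=["mean_ratio", "n_bins"]))


def _flat_profile(cell_id="c0", n=100, value=1.0):
    return CNProfile(
        cell_id=cell_id,
        chroms=np.full(n, "chr1"),
        ratios=np.full(n, value),
        segments=pd.DataFrame(
            {"chrom": ["chr1"], "start_bin": [0], "end_bin": [n - 1], "n_bins": [n], "mean_ratio": [value], "cn": [2]}
        ),
    )


class TestQC:
    def test_reads_just_below_threshold_fails(self):
        res = qc(_flat_profile(), total_reads=49_000, alignment_rate=0.9)
        assert not res.passed and "total_reads" in res.failed_criteria

    def test_boundary_pass_qs_inclusive(self):
        res = qc(_flat_profile(), total_reads=50_001, alignment_rate=0.51)
        assert res.passed and res.failed_criteria == []

    def test_toy_table_three_of_five_pass(self):
        """Hand-evaluated rule on five tabulated cells: exactly 3 survive."""
        cases = [
            (60_000, 0.9, 1.0, True),    # all good
            (49_000, 0.9, 1.0, False),   # reads too low
            (60_000, 0.6, 0.5, False),   # genome coverage gap
            (200_000, 0.8, 1.0, True),   # all good
            (51_000, 0.51, 0.96, True),  # boundary pass
        ]
        results = []
        for reads, align, cov, expect in cases:
            prof = _flat_profile()
            n = len(prof.ratios)
            counts = np.full(n, reads / n)
            counts[: int(n * (1 - cov))] = 0.0
            res = qc(prof, reads, align, counts=counts)
            results.append((res.passed, expect))
        assert all(got == want for got, want in results)
        assert sum(got for got, _ in results) == 3

    def test_missing_metadata_raises(self):
        with pytest.raises(ValueError):
            qc(_flat_profile(), total_reads=None, alignment_rate=0.9)

    def test_low_quality_score_fails(self, rng):
        counts = rng.poisson(3, 2200).astype(float) + 1e-9
        prof = CNProfile(
            cell_id="noisy",
            chroms=np.full(2200, "chr1"),
            ratios=normalize(counts),
            segments=pd.DataFrame(),
        )
        res = qc(prof, 200_000, 0.9, counts=counts)
        assert "quality_score" in res.failed_criteria


class TestAlterations:
    def _profile_from_cn(self, cn):
        """Profile whose segments are the maximal constant-CN runs."""
        cn = np.asarray(cn)
        edges = np.flatnonzero(np.diff(cn)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges - 1, [len(cn) - 1]])
        segs = pd.DataFrame(
            {
                "chrom": "chr1",
                "start_bin": starts,
                "end_bin": ends,
                "n_bins": ends - starts + 1,
                "mean_ratio": cn[starts] / 2.0,
                "cn": cn[starts],
            }
        )
        return CNProfile("c0", np.full(len(cn), "chr1"), cn / 2.0, segs)

    def test_all_diploid_empty(self):
        assert extract_alterations(self._profile_from_cn([2] * 50)) == []

    def test_single_loss(self):
        alts = extract_alterations(self._profile_from_cn([2] * 20 + [1] * 10 + [2] * 20))
        assert alts == [Alteration("chr1", 20, 29, 1)]
        assert alts[0].direction == "loss"

    def test_no_bridging_across_diploid_bin(self):
        cn = [2] * 10 + [1] * 6 + [2] + [1] * 6 + [2] * 10
        alts = extract_alterations(self._profile_from_cn(cn))
        assert len(alts) == 2
        assert [a.n_bins for a in alts] == [6, 6]

    def test_short_runs_filtered_by_min_bins(self):
        cn = [2] * 10 + [3] * 4 + [2] * 10
        assert extract_alterations(self._profile_from_cn(cn), min_bins=5) == []
        assert len(extract_alterations(self._profile_from_cn(cn), min_bins=4)) == 1

    def test_adjacent_same_cn_segments_merged(self):
        segs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start_bin": [0, 10],
                "end_bin": [9, 19],
                "n_bins": [10, 10],
                "mean_ratio": [0.5, 0.5],
                "cn": [1, 1],
            }
        )
        prof = CNProfile("c0", np.full(20, "chr1"), np.full(20, 0.5), segs)
        alts = extract_alterations(prof)
        assert alts == [Alteration("chr1", 0, 19, 1)]


LOSSES = [
    Alteration("chr13", 40, 59, 1),
    Alteration("chr17", 0, 19, 1),
    Alteration("chr10", 60, 79, 1),
]


class TestClonality:
    def test_two_cells_sharing_five_not_a_group(self):
        five = LOSSES + [Alteration("chr2", 0, 19, 3), Alteration("chr5", 0, 19, 3)]
        call = call_clonality({"a": five, "b": five})
        assert call.groups == [] and not call.cells["clonal"].any()

    def test_three_cells_sharing_three_alterations(self):
        call = call_clonality({c: list(LOSSES) for c in "abc"})
        assert len(call.groups) == 1 and call.cells["clonal"].all()

    def test_two_shared_alterations_insufficient(self):
        call = call_clonality({c: LOSSES[:2] for c in "abc"})
        assert call.groups == []

    def test_monotone_in_adding_concordant_cell(self):
        base = {c: list(LOSSES) for c in "abc"}
        call3 = call_clonality(base)
        base["d"] = list(LOSSES)
        call4 = call_clonality(base)
        assert call3.clonal_cell_ids <= call4.clonal_cell_ids
        assert len(call4.groups[0]) == 4

    def test_order_invariance(self):
        alts = {f"cell{i}": list(LOSSES) for i in range(5)}
        alts["flat1"], alts["flat2"] = [], []
        forward = call_clonality(alts)
        backward = call_clonality(dict(reversed(list(alts.items()))))
        assert forward.clonal_cell_ids == backward.clonal_cell_ids

    def test_reciprocal_overlap_gate(self):
        shifted = [Alteration(a.chrom, a.start_bin + 15, a.end_bin + 15, a.cn) for a in LOSSES]
        # 5/20 bins overlap: below the 0.5 reciprocal threshold
        call = call_clonality({"a": LOSSES, "b": LOSSES, "c": shifted})
        assert call.groups == []

    def test_direction_must_match(self):
        gains = [Alteration(a.chrom, a.start_bin, a.end_bin, 3) for a in LOSSES]
        call = call_clonality({"a": LOSSES, "b": LOSSES, "c": gains})
        assert call.groups == []

    def test_intersection_semantics_stricter(self):
        # chain: a~b and b~c but a and c share nothing
        a = LOSSES
        c = [Alteration("chr2", 0, 19, 1), Alteration("chr4", 0, 19, 1), Alteration("chr6", 0, 19, 1)]
        b = a + c
        pairwise = call_clonality({"a": a, "b": b, "c": c})
        strict = call_clonality({"a": a, "b": b, "c": c}, ClonalityRule(semantics="intersection"))
        assert len(pairwise.groups) == 1
        assert strict.groups == []

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ClonalityRule(min_group_size=2)
        with pytest.raises(ValueError):
            ClonalityRule(reciprocal_overlap=0.0)


class TestEndToEnd:
    def test_noiseless_exact_recovery(self):
        """Noiseless synthetic genomes are recovered with zero error:
        segmentation, ploidy, integer CN and alterations all match truth."""
        gspec = synthetic.GenomeSpec(noise_model="noiseless")
        cells = pd.DataFrame(
            {"cell_id": ["t0"], "sample_id": ["S1"], "group_true": ["CK"]}
        )
        coupling = synthetic.PhenoGenoCoupling(p_clonal_by_group={"CK": 1.0}, exact_allocation=True)
        bins, truth = synthetic.generate_genomes(gspec, cells, coupling, seed=0)
        sub = bins[bins["cell_id"] == "t0"]
        prof = profile_from_counts("t0", sub["count"].to_numpy(), sub["chrom"].to_numpy())
        assert prof.ploidy == pytest.approx(2.0)
        alts = extract_alterations(prof)
        expected = {
            (a.chrom, a.start_bin, a.end_bin, a.cn) for a in gspec.alteration_template
        }
        assert {(a.chrom, a.start_bin, a.end_bin, a.cn) for a in alts} == expected

    def test_scale_invariance_of_profile(self):
        gspec = synthetic.GenomeSpec(noise_model="noiseless", chromosomes=[("chr1", 60)],
                                     alteration_template=[Alteration("chr1", 20, 39, 3)])
        cells = pd.DataFrame({"cell_id": ["c0"], "sample_id": ["S1"], "group_true": ["CK"]})
        coupling = synthetic.PhenoGenoCoupling(p_clonal_by_group={"CK": 1.0}, exact_allocation=True)
        bins, _ = synthetic.generate_genomes(gspec, cells, coupling, seed=0)
        counts = bins["count"].to_numpy()
        chroms = bins["chrom"].to_numpy()
        p1 = profile_from_counts("c0", counts, chroms)
        p2 = profile_from_counts("c0", counts * 17.0, chroms)
        pd.testing.assert_frame_equal(p1.segments, p2.segments)
        assert p1.ploidy == p2.ploidy

    def test_flat_wbc_controls_never_clonal_under_noise(self):
        """Diploid controls at realistic depth produce no clonal group."""
        rng = np.random.default_rng(7)
        chroms = np.repeat([f"chr{i}" for i in range(1, 12)], 100)
        alts_by_cell = {}
        for i in range(6):
            counts = rng.poisson(200, len(chroms)).astype(float)
            prof = profile_from_counts(f"w{i}", counts, chroms, seed=i)
            alts_by_cell[f"w{i}"] = extract_alterations(prof)
        call = call_clonality(alts_by_cell)
        assert call.groups == [] and not call.cells["clonal"].any()
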