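"""Union and intersection-union combination strategies."""

import pytest

from cnvensemble import (
    ConfigError,
    Genotype,
    InputError,
    StrategyConfig,
    apply_genotypes,
    combine_intersection_union,
    combine_union,
    intersect_pair,
    reciprocal_overlap,
    run_strategy,
    simulate_cohort,
)

from .conftest import mk, mkset, random_callset


def caller_set(caller, calls, sample="s1"):
    return mkset(
        [mk(c.interval.chrom, c.interval.start, c.interval.end, c.svtype.value,
            sample=sample, caller=caller, id=f"{caller}_{i}")
         for i, c in enumerate(calls)],
        origin=caller, sample=sample,
    )


class TestIntersectPair:
    def test_pair_takes_priority_coordinates(self):
        delly = caller_set("delly", [mk(1, 0, 1000, "DEL")])
        manta = caller_set("manta", [mk(1, 100, 1100, "DEL")])
        out = intersect_pair(delly, manta, 0.75)
        assert len(out) == 1
        call = out[0]
        # Manta outranks Delly by default: its coordinates win
        assert (call.interval.start, call.interval.end) == (100, 1100)
        assert set(call.source_callers) == {"delly", "manta"}
        assert len(call.sources) == 2

    def test_type_mismatch_empty(self):
        a = caller_set("delly", [mk(1, 0, 1000, "DEL")])
        b = caller_set("manta", [mk(1, 0, 1000, "DUP")])
        assert len(intersect_pair(a, b, 0.75)) == 0

    def test_low_ro_empty(self):
        a = caller_set("delly", [mk(1, 0, 1000, "DEL")])
        b = caller_set("manta", [mk(1, 700, 1700, "DEL")])
        assert len(intersect_pair(a, b, 0.75)) == 0

    def test_sample_mismatch_hard_error(self):
        a = caller_set("delly", [mk(1, 0, 1000)], sample="s1")
        b = caller_set("manta", [mk(1, 0, 1000, sample="s2")], sample="s2")
        with pytest.raises(InputError):
            intersect_pair(a, b, 0.75)

    def test_commutative_pair_selection(self, rng):
        a = random_callset(rng, 60, "delly")
        b = random_callset(rng, 60, "manta")
        ab = intersect_pair(a, b, 0.75)
        ba = intersect_pair(b, a, 0.75)
        key = lambda cs: sorted(
            (c.interval.chrom, c.interval.start, c.interval.end, c.svtype.value,
             tuple(sorted(c.source_callers)))
            for c in cs
        )
        assert key(ab) == key(ba)

    def test_quality_fields_carried(self):
        a = caller_set("delly", [mk(1, 0, 1000, "DEL")])
        import dataclasses

        a = a.subset([dataclasses.replace(a[0], pe_support_fraction=0.8)])
        b = caller_set("cnvnator", [mk(1, 0, 1000, "DEL")])
        b = b.subset([dataclasses.replace(b[0], adjusted_p=0.01)])
        out = intersect_pair(a, b, 0.75)
        assert out[0].pe_support_fraction == pytest.approx(0.8)
        assert out[0].adjusted_p == pytest.approx(0.01)


class TestCombineUnion:
    def test_single_set_identity(self):
        a = caller_set("delly", [mk(1, 0, 1000), mk(2, 0, 1000)])
        out = combine_union([a])
        assert [(c.interval, c.sources) for c in out] == [
            (c.interval, c.sources) for c in a
        ]

    def test_empty_input(self):
        assert len(combine_union([])) == 0

    def test_four_caller_collapse(self):
        sets = [
            caller_set(c, [mk(1, 1000 + 10 * i, 2000 + 10 * i, "DEL")])
            for i, c in enumerate(["delly", "manta", "erds", "cnvnator"])
        ]
        out = combine_union(sets, 0.5)
        assert len(out) == 1
        assert set(out[0].source_callers) == {"delly", "manta", "erds", "cnvnator"}
        # representative coordinates from the highest-priority caller (manta)
        assert (out[0].interval.start, out[0].interval.end) == (1010, 2010)

    def test_provenance_connected_to_representative(self, rng):
        # every source interval of an output record matches the
        # representative at >= dedup_ro (post-hoc oracle scan)
        dedup_ro = 0.5
        sets = [random_callset(rng, 80, c) for c in ["delly", "manta", "erds", "cnvnator"]]
        out = combine_union(sets, dedup_ro)
        for call in out:
            for _, src in call.sources:
                assert reciprocal_overlap(call.interval, src) >= dedup_ro
        # conservation: every input call appears in exactly one output record
        n_sources = sum(len(c.sources) for c in out)
        assert n_sources == sum(len(s) for s in sets)


class TestIntersectionUnion:
    def _quad(self, cells):
        callers = ["delly", "manta", "erds", "cnvnator"]
        return {c: caller_set(c, cells.get(c, [])) for c in callers}

    def test_pe_only_call_survives(self):
        quad = self._quad(
            {"delly": [mk(1, 0, 1000, "DEL")], "manta": [mk(1, 100, 1100, "DEL")]}
        )
        out, _ = combine_intersection_union(
            quad["delly"], quad["manta"], quad["erds"], quad["cnvnator"]
        )
        assert len(out) == 1

    def test_single_caller_call_dropped(self):
        quad = self._quad({"delly": [mk(1, 0, 1000, "DEL")]})
        out, _ = combine_intersection_union(
            quad["delly"], quad["manta"], quad["erds"], quad["cnvnator"]
        )
        assert len(out) == 0

    def test_all_four_collapse_to_one(self):
        quad = self._quad(
            {c: [mk(1, 1000, 11000, "DEL")] for c in ["delly", "manta", "erds", "cnvnator"]}
        )
        out, _ = combine_intersection_union(
            quad["delly"], quad["manta"], quad["erds"], quad["cnvnator"]
        )
        assert len(out) == 1
        assert set(out[0].source_callers) == {"delly", "manta", "erds", "cnvnator"}

    def test_delamp_applied_before_intersection(self):
        # opposite-type twin kills the PE deletion before the pair intersect
        quad = self._quad(
            {
                "delly": [mk(1, 0, 1000, "DEL"), mk(1, 10, 1010, "DUP")],
                "manta": [mk(1, 0, 1000, "DEL")],
            }
        )
        out, reports = combine_intersection_union(
            quad["delly"], quad["manta"], quad["erds"], quad["cnvnator"]
        )
        assert len(out) == 0
        assert reports[0].n_removed == 2  # delly delamp removed both members


class TestRunStrategy:
    def test_union_matches_combine_union(self, small_sim_cfg):
        cohort = simulate_cohort(small_sim_cfg)
        res = run_strategy("union", cohort.callsets)
        direct = combine_union(list(cohort.callsets.values()), 0.5)
        assert res.calls.ids() == direct.ids()

    def test_intersection_union_contained_in_union(self, small_sim_cfg):
        cohort = simulate_cohort(small_sim_cfg)
        cfg = StrategyConfig()
        union = run_strategy("union", cohort.callsets, cfg).calls
        iu = run_strategy("intersection_union", cohort.callsets, cfg).calls
        union_sources = {
            (caller, s.chrom, s.start, s.end) for c in union for caller, s in c.sources
        }
        for call in iu:
            assert any(
                (caller, s.chrom, s.start, s.end) in union_sources
                for caller, s in call.sources
            )

    def test_sv2_requires_genotypes(self, small_sim_cfg):
        cohort = simulate_cohort(small_sim_cfg)
        with pytest.raises(ConfigError, match="regenotyped"):
            run_strategy("union_sv2", cohort.callsets)

    def test_sv2_all_homref_empty(self):
        quad = {
            c: caller_set(c, [mk(1, 1000, 11000, "DEL")])
            for c in ["delly", "manta", "erds", "cnvnator"]
        }
        candidates = run_strategy("union", quad).calls
        import dataclasses

        genotyped = candidates.subset(
            [dataclasses.replace(c, genotype=Genotype.HOM_REF) for c in candidates]
        )
        res = run_strategy("union_sv2", quad, genotyped=genotyped)
        assert len(res.calls) == 0

    def test_sv2_contractive(self, small_sim_cfg, rng):
        cohort = simulate_cohort(small_sim_cfg)
        iu = run_strategy("intersection_union", cohort.callsets).calls
        import dataclasses

        gts = [Genotype.HET, Genotype.HOM_REF, Genotype.MISSING]
        genotyped = iu.subset(
            [dataclasses.replace(c, genotype=gts[int(rng.integers(0, 3))]) for c in iu]
        )
        res = run_strategy("intersection_union_sv2", cohort.callsets, genotyped=genotyped)
        assert res.calls.ids() <= iu.ids()
        assert all(c.genotype.non_reference for c in res.calls)

    def test_unknown_strategy(self):
        with pytest.raises(ConfigError):
            run_strategy("majority_vote", {})

    def test_missing_caller_config_error(self, small_sim_cfg):
        cohort = simulate_cohort(small_sim_cfg)
        inputs = dict(cohort.callsets)
        inputs.pop("manta")
        with pytest.raises(ConfigError, match="missing"):
            run_strategy("intersection_union", inputs)


class TestApplyGenotypes:
    def test_id_then_coordinate_matching(self):
        cand = mkset([mk(1, 100, 1100, id="a"), mk(1, 5000, 9000, id="b"),
                      mk(2, 100, 1100, id="c")])
        genotyped = mkset(
            [
                mk(1, 100, 1100, id="a", genotype=Genotype.HET),
                mk(1, 5000, 9000, id="other-id", genotype=Genotype.HOM_ALT),
            ]
        )
        out = apply_genotypes(cand, genotyped)
        gts = {c.id: c.genotype for c in out}
        assert gts == {
            "a": Genotype.HET,
            "b": Genotype.HOM_ALT,   # exact-coordinate fallback
            "c": Genotype.MISSING,   # no genotyped record
        }


class TestStrategyConfig:
    def test_duplicate_callers_rejected(self):
        with pytest.raises(ConfigError):
            StrategyConfig(pe_pair=("delly", "delly"))

    def test_priority_must_cover_callers(self):
        with pytest.raises(ConfigError):
            StrategyConfig(priority=("manta", "delly"))

    def test_bad_threshold(self):
        with pytest.raises(ConfigError):
            StrategyConfig(intersect_ro=1.5)
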