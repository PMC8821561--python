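"""Per-call-set filters: rules, missing-field conventions, filter algebra."""

import math

import pytest

from cnvensemble import (
    ConfigError,
    Genotype,
    InputError,
    SizeTypeRule,
    SvType,
    Track,
    TrackRecord,
    filter_adjusted_p,
    filter_delamp,
    filter_frequency,
    filter_genotype_nonref,
    filter_region,
    filter_same_signal_confirmation,
    filter_size_and_type,
    filter_support_fraction,
    reciprocal_overlap,
)

from .conftest import mk, mkset, random_callset


class TestDelamp:
    def test_both_members_removed(self):
        calls = mkset([mk(1, 1000, 2000, "DEL"), mk(1, 1050, 2050, "DUP")])
        out, report = filter_delamp(calls, 0.75)
        assert len(out) == 0
        assert report.n_removed == 2

    def test_low_overlap_retained(self):
        calls = mkset([mk(1, 1000, 2000, "DEL"), mk(1, 1700, 2700, "DUP")])
        out, _ = filter_delamp(calls, 0.75)
        assert len(out) == 2

    def test_single_type_unchanged(self):
        calls = mkset([mk(1, 1000, 2000, "DEL"), mk(1, 5000, 6000, "DEL")])
        out, report = filter_delamp(calls)
        assert out.ids() == calls.ids()
        assert report.n_removed == 0

    def test_postcondition_no_cross_type_pair(self, rng):
        for seed in range(10):
            calls = random_callset(rng, 150, f"r{seed}", span=100_000)
            out, _ = filter_delamp(calls, 0.75)
            for a in out:
                for b in out:
                    if a.svtype is not b.svtype:
                        assert reciprocal_overlap(a.interval, b.interval) < 0.75


class TestSupportFraction:
    @pytest.mark.parametrize(
        "pe, sr, kept",
        [
            (0.4, 0.1, True),   # one channel above 0.3 suffices
            (0.2, 0.25, False),
            (0.31, None, True),
            (None, 0.3, False),  # strictly above, as printed
        ],
    )
    def test_rule(self, pe, sr, kept):
        calls = mkset([mk(1, 100, 1000, pe_support_fraction=pe, sr_support_fraction=sr)])
        out, _ = filter_support_fraction(calls, 0.3)
        assert (len(out) == 1) is kept

    def test_missing_fields_retained_flagged(self):
        calls = mkset([mk(1, 100, 1000, id="na")])
        out, report = filter_support_fraction(calls)
        assert len(out) == 1
        assert report.not_applicable == ["na"]


class TestAdjustedP:
    @pytest.mark.parametrize("p, kept", [(0.01, True), (0.49, True), (0.5, False), (0.7, False)])
    def test_rule(self, p, kept):
        calls = mkset([mk(1, 100, 1000, adjusted_p=p)])
        out, _ = filter_adjusted_p(calls, 0.5)
        assert (len(out) == 1) is kept

    def test_missing_retained_flagged(self):
        out, report = filter_adjusted_p(mkset([mk(1, 100, 1000, id="na")]))
        assert len(out) == 1 and report.not_applicable == ["na"]


class TestSameSignalConfirmation:
    def test_confirmed_retained(self):
        delly = mkset([mk(1, 0, 1000, caller="delly")], origin="delly")
        manta = mkset([mk(1, 100, 1100, caller="manta")], origin="manta")
        out, _ = filter_same_signal_confirmation(delly, manta, 0.75)
        assert len(out) == 1  # ro = 900/1100 ~ 0.818

    def test_unconfirmed_removed(self):
        delly = mkset([mk(1, 0, 1000, caller="delly")], origin="delly")
        manta = mkset([mk(2, 0, 1000, caller="manta")], origin="manta")
        out, report = filter_same_signal_confirmation(delly, manta, 0.5)
        assert len(out) == 0 and report.n_removed == 1

    def test_threshold_monotone(self, rng):
        for _ in range(10):
            a = random_callset(rng, 80, "a")
            b = random_callset(rng, 80, "b")
            out50, _ = filter_same_signal_confirmation(a, b, 0.5)
            out75, _ = filter_same_signal_confirmation(a, b, 0.75)
            assert out75.ids() <= out50.ids()

    def test_cross_signal_warns(self):
        a = mkset([mk(1, 0, 1000)], origin="delly")
        b = mkset([mk(1, 0, 1000)], origin="cnvnator")
        with pytest.warns(UserWarning):
            filter_same_signal_confirmation(a, b, 0.5, partner_signal_matches=False)


class TestGenotypeNonref:
    def test_rules(self):
        calls = mkset(
            [
                mk(1, 100, 1000, genotype=Genotype.HET, id="het"),
                mk(1, 2000, 3000, genotype=Genotype.HOM_ALT, id="hom"),
                mk(1, 4000, 5000, genotype=Genotype.HOM_REF, id="ref"),
                mk(1, 6000, 7000, genotype=Genotype.MISSING, id="mis"),
            ]
        )
        out, report = filter_genotype_nonref(calls)
        assert out.ids() == {"het", "hom"}
        reasons = dict(report.removed)
        assert reasons["ref"] == "genotype:hom-ref"
        assert reasons["mis"] == "genotype:missing"

    def test_ungenotyped_hard_error(self):
        with pytest.raises(InputError, match="genotype"):
            filter_genotype_nonref(mkset([mk(1, 100, 1000)]))

    def test_wrong_sample_hard_error(self):
        calls = mkset([mk(1, 100, 1000, genotype=Genotype.HET)])
        with pytest.raises(InputError, match="sample"):
            filter_genotype_nonref(calls, sample="other")


def pop_track(*recs):
    return Track(
        [
            TrackRecord(mk(c, s, e).interval, svtype=SvType(t), af=af)
            for c, s, e, t, af in recs
        ],
        name="pop",
    )


class TestFrequency:
    def test_common_call_removed(self):
        calls = mkset([mk(1, 10000, 20000, "DEL")])
        pop = pop_track((1, 10500, 20500, "DEL", 0.06))
        out, _ = filter_frequency(calls, pop, af_max=0.05, ro_min=0.5)
        assert len(out) == 0

    def test_rare_and_unmatched_retained(self):
        calls = mkset([mk(1, 10000, 20000, "DEL"), mk(2, 10000, 20000, "DEL")])
        pop = pop_track((1, 10500, 20500, "DEL", 0.01))
        out, _ = filter_frequency(calls, pop, af_max=0.05)
        assert len(out) == 2

    def test_type_mismatch_ignored_when_same_type(self):
        calls = mkset([mk(1, 10000, 20000, "DEL")])
        pop = pop_track((1, 10000, 20000, "DUP", 0.9))
        out, _ = filter_frequency(calls, pop, af_max=0.05, same_type=True)
        assert len(out) == 1
        out2, _ = filter_frequency(calls, pop, af_max=0.05, same_type=False)
        assert len(out2) == 0

    def test_af_max_monotone(self, rng):
        calls = random_callset(rng, 100, "c", span=200_000)
        pop = Track(
            [
                TrackRecord(c.interval, svtype=c.svtype, af=float(rng.random()))
                for c in random_callset(rng, 150, "p", span=200_000)
            ]
        )
        prev = None
        for af_max in (0.5, 0.2, 0.1, 0.02):
            out, _ = filter_frequency(calls, pop, af_max=af_max)
            if prev is not None:
                assert out.ids() <= prev  # stricter af_max never retains more
            prev = out.ids()


class TestSizeAndType:
    def test_drop_large_gains(self):
        rule = SizeTypeRule(SvType.DUP, 50_000, math.inf, keep=False)
        calls = mkset([mk(1, 0, 60_000, "DUP"), mk(1, 100_000, 110_000, "DUP"),
                       mk(1, 200_000, 300_000, "DEL")])
        out, _ = filter_size_and_type(calls, [rule])
        assert {c.length for c in out} == {10_000, 100_000}

    def test_empty_rules_identity(self):
        calls = mkset([mk(1, 0, 60_000, "DUP")])
        out, _ = filter_size_and_type(calls, [])
        assert out.ids() == calls.ids()

    def test_bad_rule_rejected(self):
        with pytest.raises(ConfigError):
            SizeTypeRule(SvType.DEL, 5000, 5000, keep=True)

    def test_first_rule_wins(self):
        rules = [
            SizeTypeRule(None, 0, 10_000, keep=True),
            SizeTypeRule(None, 0, math.inf, keep=False),
        ]
        calls = mkset([mk(1, 0, 5_000), mk(1, 10_000, 40_000)])
        out, _ = filter_size_and_type(calls, rules)
        assert len(out) == 1 and out[0].length == 5_000


class TestRegion:
    track = Track([TrackRecord(mk(1, 1000, 2000).interval)], name="bl")

    def test_exclude(self):
        calls = mkset([mk(1, 1500, 2500), mk(1, 5000, 6000)])
        out, _ = filter_region(calls, self.track, "exclude_overlapping")
        assert len(out) == 1 and out[0].interval.start == 5000

    def test_require(self):
        calls = mkset([mk(1, 1500, 2500), mk(1, 5000, 6000)])
        out, _ = filter_region(calls, self.track, "require_overlapping")
        assert len(out) == 1 and out[0].interval.start == 1500

    def test_empty_track_exclude_identity(self):
        calls = mkset([mk(1, 1500, 2500)])
        out, _ = filter_region(calls, Track([], name="empty"), "exclude_overlapping")
        assert out.ids() == calls.ids()

    def test_min_bp(self):
        calls = mkset([mk(1, 1990, 3000)])  # 10 bp inside the track interval
        out, _ = filter_region(calls, self.track, "exclude_overlapping", min_bp=11)
        assert len(out) == 1
        out2, _ = filter_region(calls, self.track, "exclude_overlapping", min_bp=10)
        assert len(out2) == 0

    def test_bad_mode(self):
        with pytest.raises(ConfigError):
            filter_region(mkset([]), self.track, "bogus")


class TestFilterAlgebra:
    """Contractivity, idempotence and report conservation for every filter."""

    @staticmethod
    def _all_filters(rng):
        pop = Track(
            [
                TrackRecord(c.interval, svtype=c.svtype, af=float(rng.random()))
                for c in random_callset(rng, 80, "p", span=200_000)
            ]
        )
        partner = random_callset(rng, 100, "partner", span=200_000)
        region = Track([TrackRecord(mk(1, 0, 50_000).interval)], name="bl")
        return [
            lambda cs: filter_delamp(cs, 0.75),
            lambda cs: filter_support_fraction(cs, 0.3),
            lambda cs: filter_adjusted_p(cs, 0.5),
            lambda cs: filter_same_signal_confirmation(cs, partner, 0.5),
            lambda cs: filter_frequency(cs, pop, 0.05),
            lambda cs: filter_size_and_type(
                cs, [SizeTypeRule(SvType.DUP, 10_000, math.inf, keep=False)]
            ),
            lambda cs: filter_region(cs, region, "exclude_overlapping"),
        ]

    def test_contractive_idempotent_conserving(self, rng):
        base = random_callset(rng, 120, "c", span=200_000)
        # give some calls quality fields so those filters have raw material
        import dataclasses

        calls = []
        for i, c in enumerate(base):
            if i % 3 == 0:
                c = dataclasses.replace(
                    c,
                    pe_support_fraction=float(rng.random()),
                    adjusted_p=float(rng.random()),
                )
            calls.append(c)
        cs = base.subset(calls)
        for f in self._all_filters(rng):
            out, report = f(cs)
            assert out.ids() <= cs.ids()  # contractive
            assert report.n_retained + report.n_removed == report.n_input == len(cs)
            out2, report2 = f(out)
            assert out2.ids() == out.ids()  # idempotent
            assert report2.n_removed == 0
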