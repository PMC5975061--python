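"""Simulator unit and property tests: map building, meiosis, pedigree advance,
trial generation, and the determinism contract."""

import numpy as np
import pandas as pd
import pytest

from masbreed.simulate import (
    DONOR,
    RECIPIENT,
    EffectModel,
    TrialDesign,
    advance,
    build_map,
    f1_line,
    founder,
    format_generation,
    genotype_codes,
    grow_to_size,
    haldane,
    make_gamete,
    parse_generation,
    qtl_dosages,
    simulate_trial,
)

from conftest import make_qtl, simulate_f3_trial


class TestGenerationLabels:
    @pytest.mark.parametrize(
        "label,expected",
        [("F1", (0, 1)), ("F8", (0, 8)), ("BC1F3", (1, 3)), ("BC2F8", (2, 8))],
    )
    def test_roundtrip(self, label, expected):
        assert parse_generation(label) == expected
        assert format_generation(*expected) == label

    @pytest.mark.parametrize("bad", ["F0", "bc1F3", "BC0F3", "F3x", "BCF3", "f3", ""])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_generation(bad)


class TestBuildMap:
    def test_three_qtls_spacing_five(self, three_qtls):
        gmap = build_map(three_qtls, spacing_cM=5.0)
        assert len(gmap) == 15
        by_name = {l.name: l for l in gmap.loci}
        for q in three_qtls:
            peak = by_name[q.peak_marker].position_cM
            assert by_name[q.left_flanks[0]].position_cM == peak - 5
            assert by_name[q.left_flanks[1]].position_cM == peak - 10
            assert by_name[q.right_flanks[0]].position_cM == peak + 5
            assert by_name[q.right_flanks[1]].position_cM == peak + 10

    def test_zero_spacing_coincident(self):
        gmap = build_map([make_qtl("qDTY12.1", "12")], spacing_cM=0.0)
        assert len(gmap) == 5
        assert len({l.position_cM for l in gmap.loci}) == 1

    def test_six_qtls_thirty_loci(self):
        defs = [make_qtl(f"qDTY{c}.1", str(c)) for c in (1, 2, 3, 4, 10, 12)]
        assert len(build_map(defs)) == 30

    def test_same_chromosome_qtls_do_not_interleave(self):
        defs = [make_qtl("qDTY1.1", "1"), make_qtl("qDTY1.2", "1")]
        gmap = build_map(defs, spacing_cM=5.0)
        pos = {l.name: l.position_cM for l in gmap.loci}
        first_right = max(pos[m] for m in defs[0].markers)
        second_left = min(pos[m] for m in defs[1].markers)
        assert second_left > first_right

    def test_duplicate_marker_rejected(self):
        a = make_qtl("qDTY1.1", "1")
        b = make_qtl("qDTY2.1", "2")
        b = type(b)(
            name=b.name, chromosome=b.chromosome, peak_marker=a.peak_marker,
            left_flanks=b.left_flanks, right_flanks=b.right_flanks,
        )
        with pytest.raises(ValueError, match="qDTY1.1_PK"):
            build_map([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_map([])


class TestMeiosis:
    def test_homozygous_parent_gamete_identical(self, three_qtls):
        gmap = build_map(three_qtls)
        rng = np.random.default_rng(0)
        for allele in (DONOR, RECIPIENT):
            parent = founder("p", gmap, allele)
            g = make_gamete(parent, gmap, rng)
            assert np.array_equal(g, parent.maternal)

    def test_haldane_zero_distance(self):
        assert haldane(0.0) == 0.0
        gmap = build_map([make_qtl("qDTY1.1", "1")], spacing_cM=0.0)
        rng = np.random.default_rng(1)
        parent = f1_line(gmap)
        for _ in range(200):
            g = make_gamete(parent, gmap, rng)
            assert len(set(g)) == 1  # complete linkage: no recombinants ever

    def test_haldane_monte_carlo_10cM(self):
        # closed form: r = (1 - exp(-0.2))/2 = 0.090635
        r_expected = 0.5 * (1.0 - np.exp(-0.2))
        gmap = build_map([make_qtl("qDTY1.1", "1")], spacing_cM=10.0)
        i, j = gmap.index["qDTY1.1_PK"], gmap.index["qDTY1.1_R1"]
        parent = f1_line(gmap)
        rng = np.random.default_rng(2)
        n = 20_000
        rec = 0
        for _ in range(n):
            g = make_gamete(parent, gmap, rng)
            rec += g[i] != g[j]
        sd = np.sqrt(r_expected * (1 - r_expected) / n)
        assert abs(rec / n - r_expected) < 3 * sd

    def test_allele_conservation(self, two_qtls):
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(3)
        pop = grow_to_size([f1_line(gmap)], "selfing", 50, gmap, rng)
        for line in pop:
            assert set(np.unique(line.maternal)) <= {DONOR, RECIPIENT}
            assert set(np.unique(line.paternal)) <= {DONOR, RECIPIENT}


class TestAdvance:
    def test_selfing_heterozygosity_decay(self, two_qtls):
        # expected heterozygosity after t selfing generations from F1: (1/2)^t
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(4)
        n = 5000
        pop = [f1_line(gmap, f"F1-{i}") for i in range(n)]
        locus = gmap.index["qDTY2.2_PK"]
        for t in range(1, 5):
            pop = advance(pop, "selfing", 1, 1, gmap, rng)
            het = np.mean([l.maternal[locus] != l.paternal[locus] for l in pop])
            expected = 0.5**t
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(het - expected) < 3 * se, f"t={t}"

    def test_backcross_donor_frequency(self, two_qtls):
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(5)
        recurrent = founder("rp", gmap, RECIPIENT)
        bc1 = advance([f1_line(gmap)], "backcross", 1, 5000, gmap, rng, recurrent=recurrent)
        assert bc1[0].generation == "BC1F1"
        locus = gmap.index["qDTY4.1_PK"]
        freq = np.mean([(l.maternal[locus] + l.paternal[locus]) / 2 for l in bc1])
        se = 0.25 / np.sqrt(len(bc1))
        assert abs(freq - 0.25) < 3 * se

    def test_f2_segregation_1_2_1(self, two_qtls):
        from scipy.stats import chisquare

        gmap = build_map(two_qtls)
        rng = np.random.default_rng(6)
        f2 = advance([f1_line(gmap)], "selfing", 1, 10_000, gmap, rng)
        locus = gmap.index["qDTY2.2_PK"]
        totals = np.array([l.maternal[locus] + l.paternal[locus] for l in f2])
        observed = [(totals == 2).sum(), (totals == 1).sum(), (totals == 0).sum()]
        _, p = chisquare(observed, f_exp=[len(f2) / 4, len(f2) / 2, len(f2) / 4])
        assert p > 0.001

    def test_label_bookkeeping(self, two_qtls):
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(7)
        recurrent = founder("rp", gmap, RECIPIENT)
        pop = advance([f1_line(gmap)], "backcross", 2, 1, gmap, rng, recurrent=recurrent)
        assert pop[0].generation == "BC2F1"
        pop = advance(pop, "selfing", 3, 1, gmap, rng)
        assert pop[0].generation == "BC2F4"

    def test_backcross_requires_recurrent(self, two_qtls):
        gmap = build_map(two_qtls)
        with pytest.raises(ValueError, match="recurrent"):
            advance([f1_line(gmap)], "backcross", 1, 1, gmap, np.random.default_rng(0))


class TestSimulateTrial:
    def test_zero_effects_gives_exact_baselines(self, two_qtls):
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(8)
        pop = [founder(f"p{i}", gmap, DONOR, "F3") for i in range(4)]
        effects = EffectModel(
            baseline_ns=5000.0, baseline_rs=2500.0, additive={},
            line_effect_sd=0.0, residual_sd=1e-12, replicate_sd=0.0, block_sd=0.0,
        )
        ph = simulate_trial(pop, two_qtls, effects, TrialDesign(), gmap, rng)
        assert np.allclose(ph.loc[ph.environment == "NS", "grain_yield_kg_ha"], 5000.0)
        assert np.allclose(ph.loc[ph.environment == "RS", "grain_yield_kg_ha"], 2500.0)

    def test_injected_effect_recovery(self):
        # one QTL with a(RS)=400: donor-vs-recipient class mean difference
        qtl = make_qtl("qDTY12.1", "12")
        gmap = build_map([qtl])
        rng = np.random.default_rng(9)
        n_half = 1000
        pop = [founder(f"d{i}", gmap, DONOR, "F3") for i in range(n_half)]
        pop += [founder(f"r{i}", gmap, RECIPIENT, "F3") for i in range(n_half)]
        effects = EffectModel(additive={"qDTY12.1": (120.0, 400.0)})
        design = TrialDesign(environments=("RS",), n_replicates=2)
        ph = simulate_trial(pop, [qtl], effects, design, gmap, rng)
        means = ph.groupby(ph.line_id.str[0])["grain_yield_kg_ha"].mean()
        diff = means["d"] - means["r"]
        # var of a line mean: line_sd^2 + residual_sd^2 / n_reps
        var_line = effects.line_effect_sd**2 + effects.residual_sd**2 / 2
        se = np.sqrt(2 * var_line / n_half)
        assert abs(diff - 400.0) < 3 * se

    def test_stress_reduction_calibration(self, two_qtls):
        # default baselines reproduce a ~47% RS trial-mean reduction
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(10)
        pop = [founder(f"x{i}", gmap, RECIPIENT, "F3") for i in range(200)]
        effects = EffectModel(additive={})
        ph = simulate_trial(pop, two_qtls, effects, TrialDesign(), gmap, rng)
        tm = ph.groupby("environment")["grain_yield_kg_ha"].mean()
        reduction = 100 * (1 - tm["RS"] / tm["NS"])
        assert reduction == pytest.approx(100 * (1 - 2691 / 5077), abs=6.0)

    def test_empty_population_rejected(self, two_qtls):
        gmap = build_map(two_qtls)
        with pytest.raises(ValueError):
            simulate_trial([], two_qtls, EffectModel(), TrialDesign(), gmap, np.random.default_rng(0))

    def test_interaction_term_enters_yield(self, two_qtls):
        gmap = build_map(two_qtls)
        rng = np.random.default_rng(11)
        pop = [founder("both", gmap, DONOR, "F3"), founder("none", gmap, RECIPIENT, "F3")]
        effects = EffectModel(
            additive={"qDTY2.2": (0.0, 300.0), "qDTY4.1": (0.0, 300.0)},
            interaction={frozenset(["qDTY2.2", "qDTY4.1"]): (0.0, -200.0)},
            line_effect_sd=0.0, residual_sd=1e-12, replicate_sd=0.0, block_sd=0.0,
        )
        ph = simulate_trial(pop, two_qtls, effects, TrialDesign(environments=("RS",), n_replicates=1), gmap, rng)
        y = ph.set_index("line_id")["grain_yield_kg_ha"]
        assert y["both"] == pytest.approx(2691 + 600 - 200, abs=1e-6)
        assert y["none"] == pytest.approx(2691, abs=1e-6)


class TestLinkageAndDeterminism:
    def test_flanks_cosegregate_at_zero_spacing(self, two_qtls):
        _, genos, _, _, gmap = simulate_f3_trial(two_qtls, seed=12, n_f2=120, spacing=0.0)
        for q in two_qtls:
            for m in q.markers:
                assert (genos[m] == genos[q.peak_marker]).all()

    def test_flank_correlation_increases_as_spacing_shrinks(self, two_qtls):
        def peak_flank_agreement(spacing, seed=13):
            _, genos, _, _, _ = simulate_f3_trial(two_qtls, seed=seed, n_f2=300, spacing=spacing)
            q = two_qtls[0]
            return (genos[q.left_flanks[0]] == genos[q.peak_marker]).mean()

        assert peak_flank_agreement(0.0) >= peak_flank_agreement(10.0) >= peak_flank_agreement(40.0)

    def test_same_seed_same_output(self, two_qtls):
        out = [simulate_f3_trial(two_qtls, seed=99, n_f2=60) for _ in range(2)]
        (_, g1, a1, p1, _), (_, g2, a2, p2, _) = out
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_effect_model_validation(self):
        with pytest.raises(ValueError):
            EffectModel(baseline_ns=2000.0, baseline_rs=3000.0)  # stress above control
        with pytest.raises(ValueError):
            EffectModel(residual_sd=0.0)
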