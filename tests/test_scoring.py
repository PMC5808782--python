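import math

import numpy as np
import pytest

from tissuescore import (
    CalibrationFunction,
    EnrichmentCurve,
    SigmoidFit,
    ValidationError,
    apply_stars,
    calibrate_stars,
    eval_sigmoid,
    expected_fraction,
    fit_sigmoid,
    fold_enrichment_curve,
    integrate_channels,
    score_dataset,
)
from tissuescore.scoring import EnrichmentBin

from conftest import make_channel, make_dataset, make_gold


def brute_force_curve(ds, gs, window, step):
    """Direct-count oracle: explicit pair list, explicit sort, explicit count."""
    gs_genes = {g for g, _ in gs.pairs}
    gs_tissues = {t for _, t in gs.pairs}
    genes = sorted(set(ds.genes) & gs_genes)
    tissues = sorted(set(ds.tissues) & gs_tissues)
    pairs = [
        (float(ds.values.loc[g, t]), g, t) for g in genes for t in tissues
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    restricted = [(g, t) for g, t in gs.pairs if g in set(genes) and t in set(tissues)]
    expected = len(restricted) / (len(genes) * len(tissues))
    bins = []
    for start in range(0, len(pairs) - window + 1, step):
        chunk = pairs[start : start + window]
        hits = sum(1 for _r, g, t in chunk if (g, t) in gs.pairs)
        x = sum(r for r, _g, _t in chunk) / window
        bins.append((x, (hits / window) / expected))
    return bins


class TestExpectedFraction:
    def test_direct_arithmetic(self):
        gs = make_gold({("G0", "T0"), ("G1", "T1")})
        assert expected_fraction(gs, {"G0", "G1", "G2", "G3"}, {"T0", "T1"}) == 0.25

    def test_saturation(self):
        genes, tissues = {"G0", "G1"}, {"T0"}
        gs = make_gold({(g, t) for g in genes for t in tissues})
        assert expected_fraction(gs, genes, tissues) == 1.0

    def test_zero_restricted_errors(self):
        gs = make_gold({("GX", "TX")})
        with pytest.raises(ValidationError):
            expected_fraction(gs, {"G0"}, {"T0"})

    def test_enumeration_oracle_50x10(self):
        rng = np.random.default_rng(0)
        genes = {f"G{i}" for i in range(50)}
        tissues = {f"T{j}" for j in range(10)}
        gs_pairs = {
            (f"G{rng.integers(0, 60)}", f"T{rng.integers(0, 12)}") for _ in range(150)
        }
        gs = make_gold(gs_pairs)
        direct = sum(1 for g in genes for t in tissues if (g, t) in gs_pairs) / 500
        assert expected_fraction(gs, genes, tissues) == pytest.approx(direct)


class TestFoldEnrichmentCurve:
    def test_gs_all_pairs_saturates_at_one(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.lognormal(0, 1, size=(20, 5)))
        gs = make_gold({(g, t) for g in ds.genes for t in ds.tissues})
        curve = fold_enrichment_curve(ds, gs, window=10, step=10)
        assert np.allclose(curve.e, 1.0)

    def test_window_without_gs_pairs_is_zero(self):
        # two genes: G0 highly expressed and annotated, G1 low and unannotated
        vals = np.vstack([np.full(5, 100.0), np.full(5, 1.0)])
        ds = make_dataset(vals)
        gs = make_gold({("G0", t) for t in ds.tissues} | {("G1", "T_elsewhere")})
        curve = fold_enrichment_curve(ds, gs, window=5, step=5)
        assert curve.bins[-1].e == 0.0

    def test_too_few_pairs_errors(self):
        ds = make_dataset([[1.0, 2.0]])
        gs = make_gold({("G0", "T0")})
        with pytest.raises(ValidationError, match="window"):
            fold_enrichment_curve(ds, gs, window=100)

    @pytest.mark.parametrize("seed", range(5))
    def test_400_pair_direct_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ds = make_dataset(rng.lognormal(1, 1, size=(40, 10)))
        gs_pairs = {
            (f"G{rng.integers(0, 40)}", f"T{rng.integers(0, 10)}") for _ in range(120)
        }
        # ensure every gene and tissue is represented so all 400 pairs survive
        gs_pairs |= {(f"G{i}", f"T{i % 10}") for i in range(40)}
        gs = make_gold(gs_pairs)
        curve = fold_enrichment_curve(ds, gs, window=100, step=100)
        oracle = brute_force_curve(ds, gs, window=100, step=100)
        assert len(curve.bins) == len(oracle) == 4
        for b, (x, e) in zip(curve.bins, oracle):
            assert b.x == pytest.approx(x)
            assert b.e == pytest.approx(e)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0, 1, size=(30, 6))
        ds = make_dataset(vals)
        perm = rng.permutation(30)
        ds2 = make_dataset(vals[perm], genes=[f"G{i}" for i in perm], tissues=ds.tissues)
        gs = make_gold(
            {(f"G{rng.integers(0, 30)}", f"T{rng.integers(0, 6)}") for _ in range(50)}
        )
        c1 = fold_enrichment_curve(ds, gs, window=20, step=20)
        c2 = fold_enrichment_curve(ds2, gs, window=20, step=20)
        assert np.allclose(c1.x, c2.x) and np.allclose(c1.e, c2.e)

    def test_conservation_of_overall_hit_fraction(self):
        # mean(e) over non-overlapping bins covering all pairs, times the
        # expected fraction, equals the overall gs hit fraction
        rng = np.random.default_rng(8)
        ds = make_dataset(rng.lognormal(0, 1, size=(20, 5)))
        pairs = {(f"G{rng.integers(0, 20)}", f"T{rng.integers(0, 5)}") for _ in range(40)}
        pairs |= {(f"G{i}", f"T{i % 5}") for i in range(20)}  # cover the universe
        gs = make_gold(pairs)
        curve = fold_enrichment_curve(ds, gs, window=10, step=10)
        exp_frac = expected_fraction(gs, set(ds.genes), set(ds.tissues))
        overall = sum(1 for g in ds.genes for t in ds.tissues if (g, t) in gs.pairs) / 100
        assert float(np.mean(curve.e)) * exp_frac == pytest.approx(overall)


class TestEvalSigmoid:
    def test_midpoint(self):
        fit = SigmoidFit(a0=0.5, a1=3.5, a2=1.3, a3=0.7)
        assert eval_sigmoid(fit, 10**0.7) == pytest.approx(2.0)

    def test_flat_limit_a2_zero(self):
        fit = SigmoidFit(a0=1.0, a1=3.0, a2=0.0, a3=0.0)
        for x in (0.01, 1.0, 100.0):
            assert eval_sigmoid(fit, x) == pytest.approx(2.0)

    def test_closed_form_value(self):
        fit = SigmoidFit(a0=0.0, a1=4.0, a2=1.0, a3=0.0)
        assert eval_sigmoid(fit, 10.0) == pytest.approx(4.0 / (1.0 + math.exp(-1.0)))

    def test_monotone_and_bounded(self):
        fit = SigmoidFit(a0=0.2, a1=4.2, a2=2.0, a3=0.5)
        xs = np.logspace(-6, 6, 200)
        ys = eval_sigmoid(fit, xs)
        assert np.all(np.diff(ys) >= 0)
        assert np.all(ys >= fit.a0 - 1e-12) and np.all(ys <= fit.a1 + 1e-12)

    def test_nonpositive_x_rejected(self):
        fit = SigmoidFit(a0=0, a1=1, a2=1, a3=0)
        with pytest.raises(ValidationError):
            eval_sigmoid(fit, 0.0)


def synthetic_curve(a0, a1, a2, a3, lx, noise=0.0, rng=None):
    fit = SigmoidFit(a0=a0, a1=a1, a2=a2, a3=a3)
    e = np.asarray(eval_sigmoid(fit, 10.0**lx))
    if noise:
        e = np.clip(e + rng.normal(0, noise, size=e.shape), 0, None)
    bins = [EnrichmentBin(x=float(10.0**l), e=float(v), n=100) for l, v in zip(lx, e)]
    return EnrichmentCurve(bins=bins, window=100, step=100)


class TestFitSigmoid:
    TRUE = (0.5, 4.0, 1.2, 0.8)

    def test_noiseless_recovery(self):
        lx = np.linspace(-2.5, 4.0, 50)
        curve = synthetic_curve(*self.TRUE, lx)
        fit = fit_sigmoid(curve)
        assert fit.a0 == pytest.approx(self.TRUE[0], abs=1e-3)
        assert fit.a1 == pytest.approx(self.TRUE[1], abs=1e-3)
        assert fit.a2 == pytest.approx(self.TRUE[2], abs=1e-3)
        assert fit.a3 == pytest.approx(self.TRUE[3], abs=1e-3)

    def test_constant_curve_flat_fit(self):
        lx = np.linspace(-1, 2, 10)
        bins = [EnrichmentBin(x=float(10.0**l), e=2.0, n=100) for l in lx]
        fit = fit_sigmoid(EnrichmentCurve(bins=bins, window=100, step=100))
        for x in (0.1, 1.0, 50.0):
            assert eval_sigmoid(fit, x) == pytest.approx(2.0, abs=1e-4)

    def test_too_few_bins_errors(self):
        bins = [EnrichmentBin(x=1.0, e=1.0, n=100)] * 3
        with pytest.raises(ValidationError):
            fit_sigmoid(EnrichmentCurve(bins=bins, window=100, step=100))

    def test_noisy_recovery_18_of_20(self):
        lx = np.linspace(-2.5, 4.0, 50)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            curve = synthetic_curve(*self.TRUE, lx, noise=0.1, rng=rng)
            fit = fit_sigmoid(curve)
            if (
                abs(fit.a1 - self.TRUE[1]) <= 0.1 * self.TRUE[1]
                and abs(fit.a3 - self.TRUE[3]) <= 0.1 * abs(self.TRUE[3])
            ):
                ok += 1
        assert ok >= 18


class TestScoreDataset:
    def test_midpoint_confidence(self):
        fit = SigmoidFit(a0=0.0, a1=4.0, a2=1.0, a3=1.0)
        ds = make_dataset([[10.0]])
        ch = score_dataset(ds, fit)
        assert ch.associations[0].confidence == pytest.approx(2.0)

    def test_monotone_in_raw(self):
        fit = SigmoidFit(a0=0.0, a1=4.0, a2=1.5, a3=0.0)
        ds = make_dataset([[1.0, 5.0, 25.0]])
        ch = score_dataset(ds, fit)
        confs = [a.confidence for a in ch.associations]
        assert confs == sorted(confs)

    def test_pointwise_oracle(self):
        rng = np.random.default_rng(6)
        fit = SigmoidFit(a0=0.3, a1=3.3, a2=1.1, a3=0.4)
        ds = make_dataset(rng.lognormal(0, 1, size=(15, 4)))
        ch = score_dataset(ds, fit)
        for a in ch.associations:
            assert a.confidence == pytest.approx(eval_sigmoid(fit, a.raw))

    def test_zero_raw_uses_pseudo_floor(self):
        fit = SigmoidFit(a0=0.0, a1=4.0, a2=1.0, a3=0.0)
        vals = np.array([[0.0, 2.0]])
        ds = make_dataset(vals)
        ch = score_dataset(ds, fit)
        floor_conf = eval_sigmoid(fit, 1.0)  # floor = 2.0 * 0.5
        got = {a.raw: a.confidence for a in ch.associations}
        assert got[0.0] == pytest.approx(floor_conf)


class TestCalibration:
    def test_uniform_linear_map(self):
        rng = np.random.default_rng(0)
        ref = make_channel(
            [("G", f"T{i}", None, float(v), None) for i, v in enumerate(rng.random(2000))]
        )
        cal = calibrate_stars(ref, anchors=((0.0, 0.0), (1.0, 5.0)))
        for c in (0.1, 0.5, 0.9):
            assert cal(c) == pytest.approx(5.0 * c, abs=0.05)

    def test_degenerate_equal_confidences_step(self):
        ref = make_channel([("G", f"T{i}", None, 2.0, None) for i in range(10)])
        cal = calibrate_stars(ref, anchors=((0.0, 1.0), (1.0, 3.0)))
        assert cal(2.0) >= 1.0
        assert cal(1.0) == 1.0  # below the step: lowest anchor stars
        assert cal(3.0) == 3.0

    def test_anchor_quantiles_reproduced(self):
        rng = np.random.default_rng(5)
        confs = rng.lognormal(0, 1, size=500)
        ref = make_channel(
            [("G", f"T{i}", None, float(v), None) for i, v in enumerate(confs)]
        )
        anchors = ((0.0, 0.0), (0.25, 1.0), (0.5, 2.0), (1.0, 5.0))
        cal = calibrate_stars(ref, anchors=anchors)
        for q, s in anchors:
            assert cal(float(np.quantile(confs, q))) == pytest.approx(s, abs=1e-9)

    def test_non_monotone_anchors_error(self):
        ref = make_channel([("G", "T", None, 1.0, None)])
        with pytest.raises(ValidationError):
            calibrate_stars(ref, anchors=((0.0, 2.0), (1.0, 1.0)))

    def test_empty_reference_errors(self):
        with pytest.raises(ValidationError):
            calibrate_stars(make_channel([]))


class TestApplyStars:
    CAL = CalibrationFunction(breakpoints=[(1.0, 0.0), (2.0, 2.0), (3.0, 5.0)])

    def test_below_zero_breakpoint_removed(self):
        ch = make_channel([("G", "T", None, 0.2, None)])  # pre-clamp negative
        out = apply_stars(ch, self.CAL)
        assert len(out) == 0

    def test_equal_confidence_equal_stars(self):
        ch = make_channel(
            [("G1", "T", None, 2.5, None), ("G2", "T", None, 2.5, None)]
        )
        out = apply_stars(ch, self.CAL)
        assert out.associations[0].stars == out.associations[1].stars

    def test_clamped_at_star_max(self):
        ch = make_channel([("G", "T", None, 100.0, None)])
        out = apply_stars(ch, self.CAL)
        assert out.associations[0].stars == 5.0

    def test_survivor_count_matches_direct_filter(self):
        rng = np.random.default_rng(12)
        confs = rng.normal(2.0, 1.5, size=500)
        ch = make_channel(
            [("G", f"T{i}", None, float(c), None) for i, c in enumerate(confs)]
        )
        out = apply_stars(ch, self.CAL)
        direct = sum(1 for c in confs if self.CAL.pre_clamp(float(c)) >= 0)
        assert len(out) == direct
        assert all(a.stars is not None and a.stars >= 0 for a in out.associations)

    def test_never_increases_count(self):
        rng = np.random.default_rng(13)
        ch = make_channel(
            [("G", f"T{i}", None, float(c), None) for i, c in enumerate(rng.normal(size=50))]
        )
        assert len(apply_stars(ch, self.CAL)) <= len(ch)


class TestIntegrateChannels:
    def test_max_wins(self):
        kn = make_channel([("G", "T", None, None, 4.0)], channel="knowledge")
        ex = make_channel([("G", "T", None, None, 2.0)], channel="experiments")
        out = integrate_channels([kn, ex])
        assert out.associations[0].stars == 4.0
        assert out.sources[("G", "T")] == ("knowledge", "experiments")

    def test_single_channel_passthrough(self):
        ex = make_channel([("G", "T", None, None, 2.0)], channel="experiments")
        out = integrate_channels([ex])
        assert len(out) == 1 and out.associations[0].stars == 2.0

    def test_duplicate_pair_within_channel_errors(self):
        ch = make_channel(
            [("G", "T", None, None, 1.0), ("G", "T", None, None, 2.0)]
        )
        with pytest.raises(ValidationError, match="duplicate"):
            integrate_channels([ch])

    def test_three_channel_brute_force(self):
        rng = np.random.default_rng(21)
        chans = []
        for name in ("knowledge", "experiments", "textmining"):
            entries = {
                (f"G{rng.integers(0, 10)}", f"T{rng.integers(0, 4)}"): float(
                    np.round(rng.random() * 5, 3)
                )
                for _ in range(20)
            }
            chans.append(
                make_channel(
                    [(g, t, None, None, s) for (g, t), s in entries.items()],
                    channel=name,
                )
            )
        out = integrate_channels(chans)
        expected: dict = {}
        for ch in chans:
            for a in ch.associations:
                key = (a.gene, a.tissue)
                expected[key] = max(expected.get(key, -1), a.stars)
        got = {(a.gene, a.tissue): a.stars for a in out.associations}
        assert got == expected
        assert max(len(c) for c in chans) <= len(out) <= sum(len(c) for c in chans)

    def test_mixed_organisms_error(self):
        a = make_channel([("G", "T", None, None, 1.0)], organism="human")
        b = make_channel([("G", "T", None, None, 1.0)], organism="mouse")
        with pytest.raises(ValidationError):
            integrate_channels([a, b])
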