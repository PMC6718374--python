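"""Agreement statistics against hand-coded oracles and known identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perfquant.agreement import (
    AHA16_TERRITORIES,
    PairedMeasurements,
    SegmentTable,
    agreement_report,
    bland_altman,
    icc,
    pearson,
    territory_aggregate,
)
from perfquant.curves import InvalidInputError


def icc21_anova_oracle(x, y):
    """Explicit two-way ANOVA table for ICC(2,1), coded independently."""
    data = np.array([x, y], dtype=float).T  # n subjects x 2 raters
    n, k = data.shape
    mean_subj = [np.mean(row) for row in data]
    mean_rater = [np.mean(col) for col in data.T]
    grand = float(np.mean(data))
    ssr = sum(k * (m - grand) ** 2 for m in mean_subj)
    ssc = sum(n * (m - grand) ** 2 for m in mean_rater)
    sst = sum((v - grand) ** 2 for row in data for v in row)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestBlandAltman:
    def test_perfect_agreement(self):
        p = PairedMeasurements((), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        ba = bland_altman(p)
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_hand_example(self):
        """x=(1,2,3), y=(2,2,2): differences (-1,0,1) -> bias 0, LoA +/-1.96."""
        ba = bland_altman(PairedMeasurements((), [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]))
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(12), rng.random(12)
        a = bland_altman(PairedMeasurements((), x, y))
        b = bland_altman(PairedMeasurements((), x + 0.7, y))
        assert b.bias == pytest.approx(a.bias + 0.7, rel=1e-12)
        assert (b.loa_high - b.loa_low) == pytest.approx(a.loa_high - a.loa_low, rel=1e-12)

    def test_symmetry_invariant(self):
        rng = np.random.default_rng(9)
        ba = bland_altman(PairedMeasurements((), rng.random(8), rng.random(8)))
        assert ba.loa_high - ba.bias == pytest.approx(ba.bias - ba.loa_low, rel=1e-10)


class TestICC:
    def test_identity_pairs(self):
        assert icc(PairedMeasurements((), [1.0, 2, 3, 4], [1.0, 2, 3, 4])) == pytest.approx(1.0)

    def test_systematic_offset_penalized_below_pearson(self):
        p = PairedMeasurements((), [1.0, 2, 3, 4], [2.0, 3, 4, 5])
        r, _ = pearson(p)
        assert r == pytest.approx(1.0)
        assert icc(p) < 1.0
        assert icc(p) == pytest.approx(icc21_anova_oracle(p.x, p.y), abs=1e-12)

    def test_matches_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for n in (2, 3, 5, 10):
            for _ in range(20):
                x = rng.normal(2.0, 1.0, n)
                y = rng.normal(2.0, 1.0, n)
                assert icc(PairedMeasurements((), x, y)) == pytest.approx(
                    icc21_anova_oracle(x, y), abs=1e-12)

    def test_matches_pingouin_reference(self):
        """Cross-check against the published ICC2 implementation."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(23)
        x, y = rng.normal(2.5, 0.8, 9), rng.normal(2.5, 0.8, 9)
        df = pd.DataFrame({
            "subject": list(range(9)) * 2,
            "rater": ["a"] * 9 + ["b"] * 9,
            "score": np.concatenate([x, y]),
        })
        # absolute-agreement, single-rater row (McGraw-Wong A,1 == Shrout-Fleiss 2,1)
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score").set_index("Type").loc["ICC(A,1)", "ICC"]
        assert icc(PairedMeasurements((), x, y)) == pytest.approx(float(ref), abs=1e-10)

    def test_independent_draws_center_near_zero(self):
        rng = np.random.default_rng(31)
        vals = [icc(PairedMeasurements((), rng.normal(0, 1, 10), rng.normal(0, 1, 10)))
                for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.1


class TestPearson:
    def test_exact_linear(self):
        r, p = pearson(PairedMeasurements((), [0.0, 1, 2, 3], [1.0, 3, 5, 7]))
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_hand_example(self):
        p = PairedMeasurements((), [1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        r, _ = pearson(p)
        assert r == pytest.approx(0.5)

    def test_sign_flip(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(10), rng.random(10)
        r_pos, _ = pearson(PairedMeasurements((), x, y))
        r_neg, _ = pearson(PairedMeasurements((), x, -y))
        assert r_neg == pytest.approx(-r_pos, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson(PairedMeasurements((), [1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestPairedMeasurements:
    def test_missing_pairs_dropped_and_counted(self):
        p = PairedMeasurements(("a", "b", "c"), [1.0, np.nan, 3.0], [1.0, 2.0, 3.0])
        assert len(p) == 2
        assert p.n_dropped == 1
        assert p.labels == ("a", "c")

    def test_too_few_pairs(self):
        with pytest.raises(InvalidInputError):
            PairedMeasurements((), [1.0, np.nan], [1.0, 2.0])


class TestTerritoryAggregate:
    @staticmethod
    def _table(values):
        return SegmentTable(np.arange(1, 17), np.asarray(values, float))

    def test_uniform_table(self):
        out = territory_aggregate(self._table([2.5] * 16))
        assert all(v == pytest.approx(2.5) for v in out.values())

    def test_lad_elevated_hand_arithmetic(self):
        vals = [3.0 if s in AHA16_TERRITORIES["LAD"] else 1.0 for s in range(1, 17)]
        out = territory_aggregate(self._table(vals))
        assert out["LAD"] == pytest.approx(3.0)
        assert out["RCA"] == pytest.approx(1.0)
        assert out["global"] == pytest.approx((6 * 3.0 + 10 * 1.0) / 16)

    def test_default_mapping_partitions_16_segments(self):
        claimed = sorted(s for segs in AHA16_TERRITORIES.values() for s in segs)
        assert claimed == list(range(1, 17))

    def test_missing_segments_named(self):
        table = SegmentTable(np.arange(1, 15), np.ones(14))
        with pytest.raises(InvalidInputError, match=r"\[15, 16\]"):
            territory_aggregate(table)

    def test_duplicate_segment_rejected(self):
        with pytest.raises(InvalidInputError, match="unique"):
            SegmentTable([1, 1, 2], [1.0, 2.0, 3.0])


class TestSimulatedCohort:
    def test_end_to_end_cohort_report_is_internally_consistent(self):
        """Synthetic per-territory flows near stress levels through both arms:
        the report machinery must produce symmetric LoA, bounded r and ICC,
        and a bias whose sign matches the known inter-modality offset
        (the CMR arm reads low)."""
        from perfquant.phantom import PhantomConfig, simulate_protocol
        from perfquant.pipeline import quantify_cmr_phantom, quantify_pet_phantom

        rng = np.random.default_rng(101)
        flows = np.clip(rng.normal(2.6, 0.4, 6), 1.5, 4.0)
        cmr, pet = [], []
        for i, f in enumerate(flows):
            ds = simulate_protocol(PhantomConfig(flow=float(f), seed=500 + i))
            cmr.append(quantify_cmr_phantom(ds).mbf)
            pet.append(quantify_pet_phantom(ds).mbf)
        rep = agreement_report(PairedMeasurements((), np.array(cmr), np.array(pet)))
        assert -1 <= rep.pearson_r <= 1
        assert rep.icc <= 1
        assert rep.loa_high - rep.bias == pytest.approx(rep.bias - rep.loa_low, rel=1e-9)
        assert rep.bias < 0  # CMR underestimates PET

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_report_invariants_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        x = rng.normal(2.5, 0.7, n)
        y = x + rng.normal(-0.3, 0.2, n)
        rep = agreement_report(PairedMeasurements((), x, y))
        assert -1 <= rep.pearson_r <= 1
        assert rep.icc <= 1
        assert rep.loa_low <= rep.bias <= rep.loa_high
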