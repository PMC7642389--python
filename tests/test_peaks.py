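"""Peak calling: noise quantile, S/N filter, merging, annotation, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulonscope.config import RunConfig
from regulonscope.models import GeneFeature, Peak, StrandedCoverage
from regulonscope.peaks import (
    annotate_peaks,
    call_peaks,
    compute_noise_level,
    merge_replicates,
    smoothed_track,
)
from conftest import make_coverage


def brute_force_peaks(cov: StrandedCoverage, cfg: RunConfig, border_offset: int,
                      require_pair: bool = True) -> list[tuple[int, float]]:
    """Independent enumerator: test every position as a candidate summit.

    Implements the caller's verbal definition with plain loops; returns
    (summit, signal) pairs.
    """
    combined = (cov.plus + cov.minus).tolist()
    n = len(combined)
    b = border_offset
    # noise: boundary of top fraction of nonzero values
    nonzero = sorted(v for v in combined if v > 0)
    import math

    k = max(1, math.ceil(cfg.noise_top_fraction * len(nonzero)))
    noise = nonzero[-k]
    # moving sum with zero padding
    sm = []
    for i in range(n):
        sm.append(sum(combined[max(0, i - b): min(n, i + b + 1)]))
    out = []
    for i in range(n):
        if sm[i] <= 0:
            continue
        left = [sm[j] for j in range(max(0, i - b), i)]
        right = [sm[j] for j in range(i + 1, min(n, i + b + 1))]
        if any(v >= sm[i] for v in left) or any(v > sm[i] for v in right):
            continue
        lo, hi = max(0, i - b), min(n, i + b + 1)
        if require_pair:
            if sum(cov.plus[lo: i + 1]) == 0 or sum(cov.minus[i:hi]) == 0:
                continue
        signal = max(combined[lo:hi])
        if signal / noise < cfg.sn_threshold:
            continue
        out.append((i, float(signal)))
    return out


class TestNoiseLevel:
    def test_rank_boundary_of_1_to_100(self):
        cov = make_coverage(200, plus_spikes={i: i + 1 for i in range(100)})
        assert compute_noise_level(cov, 0.05) == 96.0

    def test_constant_signal_returns_constant(self):
        cov = make_coverage(50, plus_spikes={i: 7 for i in range(50)})
        assert compute_noise_level(cov, 0.05) == 7.0

    def test_two_level_signal(self):
        spikes = {i: 1 for i in range(95)}
        spikes.update({100 + i: 10 for i in range(5)})
        cov = make_coverage(200, plus_spikes=spikes)
        assert compute_noise_level(cov, 0.05) == 10.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no signal"):
            compute_noise_level(make_coverage(100))

    @given(
        values=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=200),
        frac=st.floats(min_value=0.01, max_value=0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_noise_is_a_quantile_boundary(self, values, frac):
        """The noise level is attained, and at most frac of nonzero values exceed it."""
        if not any(v > 0 for v in values):
            values = values + [1]
        cov = make_coverage(len(values), plus_spikes=dict(enumerate(values)))
        noise = compute_noise_level(cov, frac)
        nonzero = [v for v in values if v > 0]
        assert noise in nonzero
        import math

        k = max(1, math.ceil(frac * len(nonzero)))
        assert sum(v > noise for v in nonzero) < k
        assert sum(v >= noise for v in nonzero) >= k


class TestCallPeaks:
    def _background(self, n0=95, n10=5, offset=2000):
        spikes = {offset + 25 * i: 1 for i in range(n0)}
        spikes.update({offset + 4000 + 25 * i: 10 for i in range(n10)})
        return spikes

    def test_flat_background_no_pairs_gives_empty(self):
        cov = make_coverage(8000, plus_spikes=self._background())
        assert call_peaks(cov, RunConfig(), border_offset=10) == []

    def test_single_site_sn_three(self):
        # noise 10 from background; paired spikes of 30 -> S/N 3.0
        cov = make_coverage(
            8000,
            plus_spikes={**self._background(), 990: 30},
            minus_spikes={1010: 30},
        )
        peaks = call_peaks(cov, RunConfig(), border_offset=10)
        assert len(peaks) == 1
        assert peaks[0].summit == 1000
        assert peaks[0].signal == 30.0
        assert peaks[0].sn_ratio == pytest.approx(3.0)

    def test_weak_site_removed_at_threshold(self):
        # paired spikes of 12 over noise 10 -> S/N 1.2 < 1.5: removed
        cov = make_coverage(
            8000,
            plus_spikes={**self._background(), 990: 12},
            minus_spikes={1010: 12},
        )
        assert call_peaks(cov, RunConfig(), border_offset=10) == []

    def test_sn_threshold_monotonicity(self):
        rng = np.random.default_rng(12)
        cov = StrandedCoverage(
            "toy", plus=rng.poisson(0.05, 5000), minus=rng.poisson(0.05, 5000)
        )
        cov.plus[990] += 40
        cov.minus[1010] += 40
        counts = [
            len(call_peaks(cov, RunConfig(sn_threshold=t), border_offset=10))
            for t in (0.5, 1.0, 1.5, 2.0, 5.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_oracle_on_random_tracks(self):
        cfg = RunConfig()
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(500, 2000))
            plus = rng.poisson(0.05, n)
            minus = rng.poisson(0.05, n)
            # a few planted paired spikes
            for _k in range(rng.integers(0, 4)):
                c = int(rng.integers(50, n - 50))
                plus[c - 10] += rng.integers(5, 40)
                minus[c + 10] += rng.integers(5, 40)
            if not (plus + minus).any():
                plus[n // 2] = 1
            cov = StrandedCoverage("toy", plus=plus, minus=minus)
            fast = [(p.summit, p.signal) for p in call_peaks(cov, cfg, border_offset=10)]
            assert fast == brute_force_peaks(cov, cfg, border_offset=10)

    def test_planted_site_recovery_on_default_scenario(self, default_dataset):
        """>=95% of planted sites with S/N >= 2 recovered within the border offset."""
        ds = default_dataset
        cfg = RunConfig()
        b = ds.scenario.border_offset
        noise = compute_noise_level(ds.coverage[0], cfg.noise_top_fraction)
        peaks = call_peaks(ds.coverage[0], cfg, border_offset=b)
        strong = [
            s for s in ds.sites
            if s.occupancy * ds.scenario.reads_per_occupancy / 2 >= 2 * noise
        ]
        hits = sum(
            1 for s in strong if any(abs(p.summit - s.center) <= b for p in peaks)
        )
        assert hits / len(strong) >= 0.95
        # the S/N filter leaves nothing below threshold by construction
        assert all(p.sn_ratio >= cfg.sn_threshold for p in peaks)


class TestMergeReplicates:
    def _peak(self, summit, signal, pid="p"):
        return Peak(pid, summit - 10, summit + 11, summit, signal, signal / 10.0)

    def test_identical_lists_all_support_two(self):
        peaks = [self._peak(100, 20), self._peak(500, 30)]
        merged = merge_replicates(peaks, [self._peak(100, 20), self._peak(500, 30)], 10)
        assert len(merged) == 2
        assert all(p.replicate_support == 2 for p in merged)

    def test_disjoint_lists_union_support_one(self):
        merged = merge_replicates([self._peak(100, 20)], [self._peak(500, 30)], 10)
        assert len(merged) == 2
        assert all(p.replicate_support == 1 for p in merged)

    def test_weighted_summit(self):
        merged = merge_replicates(
            [self._peak(1000, 10)], [self._peak(1005, 30)], max_dist=10
        )
        assert len(merged) == 1
        assert merged[0].summit == 1004  # (1000*10 + 1005*30) / 40 = 1003.75 -> 1004
        assert merged[0].signal == 20.0
        assert merged[0].replicate_support == 2


class TestAnnotatePeaks:
    GENES = [
        GeneFeature("A", 100, 200, "+"),
        GeneFeature("B", 500, 700, "+"),
    ]

    def _peak(self, summit):
        return Peak("p", summit - 5, summit + 6, summit, 10.0, 2.0)

    def test_summit_inside_gene_is_intragenic(self):
        [p] = annotate_peaks([self._peak(150)], self.GENES)
        assert p.location_class == "intragenic"
        assert p.nearest_gene == "A"

    def test_intergenic_nearest_by_boundary_distance(self):
        # 450: 251 bp from A's last base (199), 50 bp from B's start
        [p] = annotate_peaks([self._peak(450)], self.GENES)
        assert p.location_class == "intergenic"
        assert p.nearest_gene == "B"

    def test_equidistant_tie_prefers_downstream_gene(self):
        # summit 349: 150 from A (199), 151 from B; summit 350: 151 vs 150
        genes = [GeneFeature("A", 100, 200, "+"), GeneFeature("B", 500, 700, "+")]
        # construct an exact tie: A ends at 200 (last base 199), B starts 500
        # midpoint of [199, 500] at 349.5 -> use genes at symmetric distance
        sym = [GeneFeature("A", 100, 200, "+"), GeneFeature("B", 499, 700, "+")]
        [p] = annotate_peaks([self._peak(349)], sym)  # 150 bp to each
        assert p.nearest_gene == "B"

    def test_empty_annotation_all_intergenic(self):
        [p] = annotate_peaks([self._peak(150)], [])
        assert p.location_class == "intergenic"
        assert p.nearest_gene is None

    def test_location_classes_partition_peaks(self, default_dataset):
        ds = default_dataset
        peaks = call_peaks(ds.coverage[0], RunConfig(), border_offset=ds.scenario.border_offset)
        annotated = annotate_peaks(peaks, ds.genes)
        n_intra = sum(1 for p in annotated if p.location_class == "intragenic")
        n_inter = sum(1 for p in annotated if p.location_class == "intergenic")
        assert n_intra + n_inter == len(annotated)
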