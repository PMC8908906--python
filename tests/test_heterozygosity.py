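import numpy as np
import pytest

from hetdom.heterozygosity import (
    LocusStats,
    RohetParams,
    classify_run_lengths,
    detect_rohet,
    homozygosity_by_locus,
    locus_stats,
    observed_heterozygosity,
    rank_correlation,
    subset_measures,
)
from hetdom.io_formats import GenotypeMatrix, SNPInfo

from conftest import make_genotypes


def one_animal(calls, pos=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8).reshape(1, -1)
    m = calls.shape[1]
    pos = pos if pos is not None else [(j + 1) * 1000 for j in range(m)]
    snps = [SNPInfo(f"s{j}", chrom, int(pos[j])) for j in range(m)]
    return GenotypeMatrix(["x"], snps, calls)


def rohet_oracle(row, pos, params: RohetParams):
    """Naive enumerate-every-window reimplementation of the run rule."""
    m = len(row)
    w = params.window
    if m < w:
        return []
    window_ok = []
    for s in range(m - w + 1):
        win = row[s : s + w]
        n_miss = sum(1 for c in win if c == -1)
        n_hom = sum(1 for c in win if c in (0, 2))
        window_ok.append(
            n_miss <= params.max_missing_per_window
            and n_hom <= params.max_hom_per_window
        )
    flagged = []
    for j in range(m):
        covering = [s for s in range(len(window_ok)) if s <= j <= s + w - 1]
        n_ok = sum(window_ok[s] for s in covering)
        if params.require_all_windows:
            flagged.append(n_ok == len(covering))
        else:
            flagged.append(n_ok / len(covering) > params.snp_in_run_threshold)
    runs = []
    j = 0
    while j < m:
        if not flagged[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and flagged[k + 1] and pos[k + 1] - pos[k] <= params.max_gap_bp:
            k += 1
        het = [i for i in range(j, k + 1) if row[i] == 1]
        if het:
            lo, hi = het[0], het[-1]
            length = pos[hi] - pos[lo] + 1
            n_snps = hi - lo + 1
            if length >= params.min_length_bp and n_snps / length >= params.min_density:
                runs.append((int(pos[lo]), int(pos[hi]), n_snps))
        j = k + 1
    return runs


class TestLocusStats:
    def test_expected_het_values(self):
        # column frequencies 0.5, 0.9 and 0 across four animals
        dosage = np.array(
            [[1, 2, 0], [1, 2, 0], [2, 2, 0], [0, 1, 0]], dtype=np.int8
        )
        g = GenotypeMatrix(
            ["a", "b", "c", "d"],
            [SNPInfo(f"s{j}", "1", j + 1) for j in range(3)],
            dosage,
        )
        st = locus_stats(g)
        np.testing.assert_allclose(st.freq_b, [0.5, 0.875, 0.0])
        np.testing.assert_allclose(st.expected_het[0], 0.5)
        np.testing.assert_allclose(st.expected_het[2], 0.0)
        # p = 0.9 gives E = 1 - 0.81 - 0.01 = 0.18
        p = 0.9
        assert 1 - p**2 - (1 - p) ** 2 == pytest.approx(0.18)

    def test_all_missing_snp_named_in_error(self):
        g = one_animal([-1, 1])
        with pytest.raises(ValueError, match="s0"):
            locus_stats(g)


class TestObservedHeterozygosity:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            ([0, 1, 2, 1, -1], 0.5),
            ([0, 0, 2, 2], 0.0),
            ([1, 1, 1], 1.0),
        ],
    )
    def test_values(self, calls, expected):
        assert observed_heterozygosity(one_animal(calls), "x") == expected

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            observed_heterozygosity(one_animal([-1, -1]), "x")


class TestHomozygosityByLocus:
    def test_extremes(self):
        stats = LocusStats(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert homozygosity_by_locus(one_animal([1, 1]), stats, "x") == 0.0
        assert homozygosity_by_locus(one_animal([0, 2]), stats, "x") == 1.0

    def test_weighted_hand_example(self):
        stats = LocusStats(np.array([0.5, 0.9]), np.array([0.5, 0.18]))
        got = homozygosity_by_locus(one_animal([0, 1]), stats, "x")
        assert got == pytest.approx(0.5 / 0.68)

    def test_missing_locus_excluded(self):
        stats = LocusStats(np.array([0.5, 0.9, 0.5]), np.array([0.5, 0.18, 0.5]))
        got = homozygosity_by_locus(one_animal([0, 1, -1]), stats, "x")
        assert got == pytest.approx(0.5 / 0.68)


class TestRohetDetector:
    def test_long_heterozygous_chromosome_single_run(self):
        g = one_animal([1] * 200)
        runs = detect_rohet(g, "x")
        assert len(runs) == 1
        assert (runs[0].start_bp, runs[0].end_bp, runs[0].n_snps) == (1000, 200_000, 200)

    def test_all_homozygous_no_runs(self, rng):
        g = one_animal(rng.choice([0, 2], size=300))
        assert detect_rohet(g, "x") == []

    def test_tolerates_one_hom_not_two(self):
        flank = [0] * 100
        stretch = [1] * 60
        stretch_1hom = list(stretch)
        stretch_1hom[30] = 0
        g = one_animal(flank + stretch_1hom + flank)
        runs = detect_rohet(g, "x")
        assert len(runs) == 1
        # two homozygous calls in every window of the stretch kill it
        stretch_2hom = list(stretch)
        stretch_2hom[20] = 0
        stretch_2hom[40] = 0  # every 50-window over the 60 contains both
        g2 = one_animal(flank + stretch_2hom + flank)
        assert detect_rohet(g2, "x") == []

    def test_short_chromosome_skipped_by_default(self):
        g = one_animal([1] * 30)
        assert detect_rohet(g, "x") == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_window_oracle_on_random_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        params = RohetParams()
        for _ in range(20):
            m = int(rng.integers(60, 300))
            row = rng.choice([0, 1, 2, -1], size=m, p=[0.15, 0.72, 0.08, 0.05])
            pos = np.cumsum(rng.integers(100, 5_000, size=m))
            g = one_animal(row, pos=pos)
            got = [(r.start_bp, r.end_bp, r.n_snps) for r in detect_rohet(g, "x", params)]
            assert got == rohet_oracle(list(row), list(pos), params)

    def test_invariant_to_snp_order_scrambling(self, rng):
        m = 150
        row = rng.choice([0, 1, 2], size=m, p=[0.1, 0.8, 0.1]).astype(np.int8)
        pos = np.cumsum(rng.integers(500, 2_000, size=m))
        g = one_animal(row, pos=pos)
        perm = rng.permutation(m)
        snps = [SNPInfo(f"s{j}", "1", int(pos[j])) for j in perm]
        g_scrambled = GenotypeMatrix(["x"], snps, row[perm].reshape(1, -1))
        a = [(r.start_bp, r.end_bp) for r in detect_rohet(g, "x")]
        b = [(r.start_bp, r.end_bp) for r in detect_rohet(g_scrambled, "x")]
        assert a == b

    def test_runs_never_span_chromosomes(self, rng):
        row = np.ones(200, dtype=np.int8)
        snps = [SNPInfo(f"a{j}", "1", (j + 1) * 1000) for j in range(100)] + [
            SNPInfo(f"b{j}", "2", (j + 1) * 1000) for j in range(100)
        ]
        g = GenotypeMatrix(["x"], snps, row.reshape(1, -1))
        runs = detect_rohet(g, "x")
        assert {r.chrom for r in runs} == {"1", "2"}
        assert all(r.end_bp <= 100_000 for r in runs)

    def test_length_classes_partition_count(self, rng):
        bm_runs = detect_rohet(one_animal([1] * 400), "x")
        counts = classify_run_lengths(bm_runs)
        assert sum(counts.values()) == len(bm_runs)


class TestSubsetMeasures:
    def test_full_subset_equals_global(self, small_genotypes):
        g = small_genotypes
        st = locus_stats(g)
        sub = subset_measures(g, st, np.arange(g.n_snps))
        for _, row in sub.iterrows():
            assert row["oh"] == observed_heterozygosity(g, row["animal_id"])
            assert row["hl"] == homozygosity_by_locus(g, st, row["animal_id"])

    def test_het_counts_additive_across_split(self, small_genotypes):
        g = small_genotypes
        st = locus_stats(g)
        half = g.n_snps // 2
        full = subset_measures(g, st, np.arange(g.n_snps))
        left = subset_measures(g, st, np.arange(half))
        right = subset_measures(g, st, np.arange(half, g.n_snps))
        # counts of het calls add up: oh * n_called is additive
        n1, n2 = half, g.n_snps - half
        np.testing.assert_allclose(
            full["oh"] * g.n_snps, left["oh"] * n1 + right["oh"] * n2, atol=1e-9
        )

    def test_rohet_exclusion_lowers_oh(self):
        row = [0, 2, 0] * 20 + [1] * 100 + [2, 0, 2] * 20
        g = one_animal(row)
        st_ = locus_stats(
            GenotypeMatrix(
                ["x", "y"],
                g.snps,
                np.vstack([g.dosage, np.ones_like(g.dosage)]),
            )
        )
        runs = detect_rohet(g, "x")
        assert runs
        pos = np.array([s.pos_bp for s in g.snps])
        in_run = np.zeros(g.n_snps, dtype=bool)
        for r in runs:
            in_run |= (pos >= r.start_bp) & (pos <= r.end_bp)
        sub = subset_measures(g, st_, {"x": ~in_run})
        assert sub.iloc[0]["oh"] <= observed_heterozygosity(g, "x")

    def test_empty_subset_rejected(self, small_genotypes):
        st = locus_stats(small_genotypes)
        with pytest.raises(ValueError):
            subset_measures(small_genotypes, st, np.array([], dtype=int))


class TestRankCorrelation:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert rank_correlation(x, 3 * x + 1) == pytest.approx(1.0)
        assert rank_correlation(x, -x) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            sv = v[order]
            i = 0
            r = np.arange(1.0, len(v) + 1)
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                r[i : j + 1] = (i + 1 + j + 1) / 2.0
                i = j + 1
            out = np.empty(len(v))
            out[order] = r
            return out

        for _ in range(10):
            x = rng.integers(0, 5, size=30).astype(float)
            y = rng.integers(0, 5, size=30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            oracle = np.corrcoef(avg_ranks(x), avg_ranks(y))[0, 1]
            assert rank_correlation(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation(np.ones(5), np.arange(5.0))
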