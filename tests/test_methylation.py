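import numpy as np
import pytest

from d4z4kit import (MethModel, UnitCoords, acf_missing_aware, anchor_calls,
                     length_methylation_correlation, methylation_acf,
                     read_meth_tsv, region_stats, smooth_profile)
from d4z4kit.methylation import (AlleleMethylome, acf_peak_lag, percent_vector,
                                 unit_intervals_from_reference, write_bedmethyl)
from d4z4kit.simulate import (AlleleSpec, build_allele_sequence,
                              simulate_methylation, simulate_reads,
                              truth_site_rates, write_meth_tsv)


def simulated_methylome(bundle, params, rng, coverage=10, model=None,
                        err=(0, 0, 0), **spec_kwargs):
    spec = AlleleSpec(**spec_kwargs)
    allele = build_allele_sequence(spec, bundle, rng)
    reads = simulate_reads([allele], coverage, rng, error_rates=err,
                           all_spanning=True)
    model = model or MethModel()
    calls, truth = simulate_methylation(reads, [allele], model, rng)
    methylome = anchor_calls(calls, {r.read_id: r.seq for r in reads},
                             [r.read_id for r in reads], allele.seq, bundle,
                             params, allele_key=spec.name)
    return allele, methylome, calls, truth


class TestAnchorCalls:
    def test_threshold_arithmetic_at_one_site(self, bundle, params, rng):
        # four reads with probabilities {0.9, 0.9, 0.1, 0.7} at one CpG:
        # threshold 0.5 gives 3 methylated / 1 unmethylated, fraction 0.75
        spec = AlleleSpec(name="a", chrom="4q", ab="A", subtype="AS", structure=(2,))
        allele = build_allele_sequence(spec, bundle, rng)
        ref = allele.seq
        site = int(np.flatnonzero([ref[i:i + 2] == "CG"
                                   for i in range(8000, 9000)])[0]) + 8000
        reads = {f"r{i}": ref for i in range(4)}
        calls = {f"r{i}": [(site, "+", p)] for i, p in enumerate((0.9, 0.9, 0.1, 0.7))}
        mm = anchor_calls(calls, reads, list(reads), ref, bundle, params)
        idx = int(np.searchsorted(mm.sites, site))
        assert mm.sites[idx] == site
        assert (mm.n_meth[idx], mm.n_unmeth[idx]) == (3, 1)
        assert mm.fraction_modified[idx] == 0.75

    def test_probability_exactly_at_threshold_counts_methylated(self, bundle, params):
        ref = bundle.p13e11_seq + bundle.unit_seq + bundle.plam_seq
        site = next(i for i in range(len(ref) - 1) if ref[i:i + 2] == "CG")
        mm = anchor_calls({"r": [(site, "+", 0.5)]}, {"r": ref}, ["r"], ref,
                          bundle, params)
        idx = int(np.searchsorted(mm.sites, site))
        assert mm.n_meth[idx] == 1

    def test_low_coverage_site_excluded_from_profile(self, bundle, params, rng):
        _, mm, _, _ = simulated_methylome(bundle, params, rng, coverage=4,
                                          name="lo", chrom="4q", ab="A",
                                          subtype="AS", structure=(2,))
        vec = percent_vector(mm, min_coverage=5)
        assert np.all(np.isnan(vec))          # nothing passes coverage >= 5
        assert mm.pooled_rate() == mm.pooled_rate()  # pooled counts still usable

    def test_reverse_strand_reads_project_to_same_sites(self, bundle, params, rng):
        spec = AlleleSpec(name="rc", chrom="4q", ab="A", subtype="AS", structure=(2,))
        allele = build_allele_sequence(spec, bundle, rng)
        reads = simulate_reads([allele], 12, rng, error_rates=(0, 0, 0),
                               all_spanning=True)
        assert {r.strand for r in reads} == {"+", "-"}
        calls, _ = simulate_methylation(reads, [allele], MethModel(), rng)
        mm = anchor_calls(calls, {r.read_id: r.seq for r in reads},
                          [r.read_id for r in reads], allele.seq, bundle, params)
        assert int(mm.coverage.max()) == 12  # both strands pooled per site

    def test_simulation_recovers_truth_within_binomial_ci(self, bundle, params, rng):
        _, mm, _, truth = simulated_methylome(bundle, params, rng, coverage=20,
                                              name="ci", chrom="4q", ab="A",
                                              subtype="AS", structure=(8,))
        rates = truth["ci"]
        keep = mm.passing(5)
        obs = mm.fraction_modified[keep]
        exp = rates[mm.sites[keep]]
        # per-site binomial(20) 99.9% envelope; allow a small outlier share
        se = np.sqrt(exp * (1 - exp) / mm.coverage[keep])
        frac_outside = np.mean(np.abs(obs - exp) > 3.29 * se + 1e-9)
        assert frac_outside < 0.01

    def test_missing_reads_are_counted_skipped(self, bundle, params, rng):
        spec = AlleleSpec(name="sk", chrom="4q", ab="A", subtype="AS", structure=(2,))
        allele = build_allele_sequence(spec, bundle, rng)
        mm = anchor_calls({"ghost": [(10, "+", 0.9)]}, {}, ["ghost"],
                          allele.seq, bundle, params)
        assert mm.n_skipped_reads == 1


class TestRegionStats:
    def test_uniform_full_methylation(self, bundle, params, rng):
        model = MethModel(base_rate=0.99, gradient_low=0.99, dr1_depression=0,
                         tss_elevation=0, nucleosome_amplitude=0,
                         contracted_threshold=0)
        allele, mm, _, _ = simulated_methylome(bundle, params, rng, coverage=8,
                                               model=model, name="u", chrom="4q",
                                               ab="A", subtype="AS", structure=(3,))
        units = unit_intervals_from_reference(allele.seq, bundle, params)
        st = region_stats(mm, units)
        assert st.ru_count == 3
        assert st.global_rate > 0.97 and st.final_unit_rate > 0.97

    def test_pooled_rate_identity_with_naive_count(self, bundle, params, rng):
        # oracle: count threshold-crossing calls directly from the raw call
        # table (error-free reads, so read position == reference position)
        allele, mm, calls, _ = simulated_methylome(bundle, params, rng,
                                                   coverage=6, name="n",
                                                   chrom="4q", ab="A",
                                                   subtype="AS", structure=(3,))
        units = unit_intervals_from_reference(allele.seq, bundle, params)
        st = region_stats(mm, units)
        span = (units[0][0], units[-1][1])
        n_meth = n_tot = 0
        for rid, rows in calls.items():
            for pos, strand, prob in rows:
                # reconstruct reference position for error-free reads
                L = len(allele.seq)
                ref_pos = pos if strand == "+" else L - 2 - pos
                if span[0] <= ref_pos < span[1]:
                    n_tot += 1
                    n_meth += prob >= 0.5
        assert n_tot > 0
        assert st.global_rate == pytest.approx(n_meth / n_tot, abs=1e-12)

    def test_contracted_allele_recovers_low_rate(self, bundle, params, rng):
        allele, mm, _, _ = simulated_methylome(bundle, params, rng, coverage=20,
                                               name="fshd1", chrom="4q", ab="A",
                                               subtype="AS", structure=(2,))
        units = unit_intervals_from_reference(allele.seq, bundle, params)
        st = region_stats(mm, units)
        n_calls = mm.coverage.sum()
        se = np.sqrt(0.08 * 0.92 / n_calls)
        assert abs(st.global_rate - 0.08) < max(4 * se, 0.01)
        assert abs(st.final_unit_rate - 0.08) < 0.03

    def test_empty_region_is_nan_not_zero(self, bundle, params, rng):
        allele, mm, _, _ = simulated_methylome(bundle, params, rng, coverage=4,
                                               name="e", chrom="4q", ab="A",
                                               subtype="AS", structure=(2,))
        assert np.isnan(mm.pooled_rate(0, 10))

    def test_dr1_below_tss_in_nearly_all_units(self, bundle, params, rng):
        allele, mm, _, _ = simulated_methylome(bundle, params, rng, coverage=20,
                                               name="osc", chrom="4q", ab="A",
                                               subtype="AS", structure=(12,))
        units = unit_intervals_from_reference(allele.seq, bundle, params)
        st = region_stats(mm, units)
        pairs = [(d, t) for d, t in zip(st.dr1_means, st.tss_means)
                 if not (np.isnan(d) or np.isnan(t))]
        frac = np.mean([d < t for d, t in pairs])
        assert frac >= 0.95


class TestSmoothProfile:
    def _methylome_from_vector(self, fractions, positions, ref_len, cov=10):
        n_meth = np.round(np.asarray(fractions) * cov).astype(np.int64)
        return AlleleMethylome(allele_key="v", ref_len=ref_len,
                               sites=np.asarray(positions, dtype=np.int64),
                               n_meth=n_meth,
                               n_unmeth=cov - n_meth)

    def test_constant_profile_stays_constant(self):
        pos = np.arange(100, 5000, 25)
        mm = self._methylome_from_vector([0.7] * len(pos), pos, 6000)
        track = smooth_profile(mm, window=2000, min_coverage=5)
        assert np.allclose(track["smoothed"], 0.7)

    def test_step_profile_becomes_monotone_ramp(self):
        pos = np.arange(0, 8000, 20)
        frac = np.where(pos < 4000, 0.0, 1.0)
        mm = self._methylome_from_vector(frac, pos, 8000)
        track = smooth_profile(mm, window=2000, min_coverage=5)
        sm = track["smoothed"].to_numpy()
        assert np.all(np.diff(sm) >= -1e-12)
        mid = sm[(track["pos"] > 3000) & (track["pos"] < 5000)]
        assert mid.min() > 0.0 and mid.max() < 1.0
        # closed-form windowed mean at the step: ramps linearly over +-1 kb
        at_3500 = sm[np.argmin(np.abs(track["pos"].to_numpy() - 3500))]
        assert at_3500 == pytest.approx(0.25, abs=0.02)

    def test_unit_scale_oscillation_survives_2kb_window(self):
        pos = np.arange(0, 33000, 25)
        frac = 0.5 + 0.4 * np.sin(2 * np.pi * pos / 3300.0)
        mm = self._methylome_from_vector(frac, pos, 33000)
        track = smooth_profile(mm, window=2000, min_coverage=5)
        sm = track["smoothed"].to_numpy()
        assert sm.max() - sm.min() > 0.2   # window 2000 < unit 3300 keeps it

    def test_loess_option_runs(self):
        pos = np.arange(0, 5000, 50)
        frac = 0.5 + 0.3 * np.sin(2 * np.pi * pos / 1000)
        mm = self._methylome_from_vector(frac, pos, 5000)
        track = smooth_profile(mm, loess=True, span=0.2, min_coverage=5)
        assert np.isfinite(track["smoothed"]).all()


class TestAcf:
    def _acf_oracle(self, x, max_lag):
        """Independent O(n*lag) oracle with explicit loops."""
        obs = [v for v in x if not np.isnan(v)]
        mu = sum(obs) / len(obs)
        var = sum((v - mu) ** 2 for v in obs) / len(obs)
        out = [1.0]
        for lag in range(1, max_lag + 1):
            acc, n = 0.0, 0
            for i in range(len(x) - lag):
                a, b = x[i], x[i + lag]
                if not (np.isnan(a) or np.isnan(b)):
                    acc += (a - mu) * (b - mu)
                    n += 1
            out.append(acc / n / var if n else np.nan)
        return np.array(out)

    def test_matches_brute_force_oracle(self, rng):
        x = np.full(4000, np.nan)
        sites = np.sort(rng.choice(4000, size=300, replace=False))
        x[sites] = 0.5 + 0.4 * np.cos(2 * np.pi * sites / 330.0) \
            + rng.normal(0, 0.05, size=300)
        ours = acf_missing_aware(x, 600)
        oracle = self._acf_oracle(x, 600)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_square_wave_peak_at_unit_period(self, rng):
        n = 19800  # 6 unit periods, <= 20 kb
        pos = np.sort(rng.choice(n, size=1500, replace=False))
        x = np.full(n, np.nan)
        x[pos] = ((pos % 3300) < 1650).astype(float)
        acf, cnt = acf_missing_aware(x, 4500, return_counts=True)
        peak = acf_peak_lag(acf, 2500, 4500, pair_counts=cnt)
        assert abs(peak - 3300) <= 50

    def test_white_noise_stays_small(self, rng):
        n = 5000
        x = rng.normal(0, 1, size=n)
        acf = acf_missing_aware(x, 400)
        bound = 3 / np.sqrt(n)
        assert np.mean(np.abs(acf[1:]) <= bound) >= 0.99

    def test_acf_zero_is_one_and_degenerate_inputs_raise(self):
        x = np.array([0.1, np.nan, 0.5, 0.9])
        assert acf_missing_aware(x, 2)[0] == 1.0
        with pytest.raises(ValueError):
            acf_missing_aware(np.array([np.nan, 0.4]), 2)
        with pytest.raises(ValueError):
            acf_missing_aware(np.array([0.4, 0.4, 0.4]), 2)

    def test_nucleosome_period_recovered(self, dense_bundle, params, rng):
        model = MethModel(dr1_depression=0, tss_elevation=0,
                          nucleosome_amplitude=0.3)
        # 6 units cover the 3-unit phase cycle of the 180 bp modulation
        # (unit length mod period = 60) twice, giving stable pair support
        allele, mm, _, _ = simulated_methylome(dense_bundle, params, rng,
                                               coverage=40, model=model,
                                               name="nuc", chrom="4q", ab="A",
                                               subtype="AS", structure=(6,))
        acf, cnt = methylation_acf(mm, 500, min_coverage=5, return_counts=True)
        peak = acf_peak_lag(acf, 100, 300, pair_counts=cnt)
        assert abs(peak - 180) <= 15


class TestCorrelationAndIO:
    def test_perfect_linear_cohort(self):
        from d4z4kit.methylation import RegionStats
        stats = [RegionStats(f"a{i}", ru, 0.02 * ru + 0.1, 0.015 * ru + 0.1, [], [])
                 for i, ru in enumerate((5, 10, 20, 30, 40))]
        table = length_methylation_correlation(stats)
        assert table.loc[0, "pearson_global"] == pytest.approx(1.0)
        assert table.loc[0, "spearman_global"] == pytest.approx(1.0)

    def test_degenerate_variance_gives_nan(self):
        from d4z4kit.methylation import RegionStats
        stats = [RegionStats(f"a{i}", 10, 0.5, 0.5, [], []) for i in range(4)]
        table = length_methylation_correlation(stats)
        assert np.isnan(table.loc[0, "pearson_global"])

    def test_meth_tsv_round_trip(self, tmp_path):
        calls = {"r1": [(5, "+", 0.91), (40, "-", 0.02)]}
        write_meth_tsv(calls, tmp_path / "m.tsv")
        back = read_meth_tsv(tmp_path / "m.tsv")
        assert back["r1"][0][0] == 5 and back["r1"][1][1] == "-"

    def test_bedmethyl_format(self, bundle, params, rng, tmp_path):
        _, mm, _, _ = simulated_methylome(bundle, params, rng, coverage=6,
                                          name="bm", chrom="4q", ab="A",
                                          subtype="AS", structure=(2,))
        path = tmp_path / "out.bed"
        write_bedmethyl(mm, path)
        first = path.read_text().splitlines()[0].split("\t")
        assert int(first[2]) - int(first[1]) == 2       # 0-based half-open CpG
        assert 0.0 <= float(first[10]) <= 100.0          # percent
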