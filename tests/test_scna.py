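"""Copy-number pipeline: DP segmentation vs exhaustive search, purity/ploidy
recovery, arm-interval arithmetic, mirrored allelic imbalance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from papevo import scna, simdata


def probe_frame(n, chrom="chr1"):
    idx = [f"p{i}" for i in range(n)]
    return pd.DataFrame({"chrom": chrom, "pos": np.arange(n) * 1000}, index=idx)


class TestNormalize:
    def test_single_region_is_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"R1": rng.normal(0, 0.1, 200)})
        out = scna.normalize_logr(df, winsor_k=50)  # huge k: no clipping
        np.testing.assert_allclose(out["R1"], df["R1"])

    def test_outlier_clipped_to_mad_bound(self):
        vals = np.zeros(101)
        vals[50] = 10.0
        noise = np.sin(np.arange(101)) * 0.01  # non-degenerate MAD
        df = pd.DataFrame({"R1": vals + noise})
        out = scna.normalize_logr(df, winsor_k=2.5)
        assert out["R1"].iloc[50] < 1.0  # clipped far below the outlier

    def test_permuted_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.2, 300)
        perm = rng.permutation(300)
        df = pd.DataFrame({"R1": x, "R2": x[perm]})
        out = scna.normalize_logr(df, winsor_k=50)
        np.testing.assert_allclose(
            np.sort(out["R1"].values), np.sort(out["R2"].values)
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            scna.normalize_logr(pd.DataFrame({"R1": [0.0, np.inf]}))


def dp_objective(y, cuts, gamma):
    bounds = [0] + sorted(cuts) + [len(y)]
    sse = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = y[a:b]
        sse += float(((seg - seg.mean(axis=0)) ** 2).sum())
    return sse + gamma * len(cuts)


class TestJointSegment:
    def test_flat_signal_single_segment(self):
        info = probe_frame(80)
        mat = pd.DataFrame({"R1": np.zeros(80), "R2": np.zeros(80)}, index=info.index)
        prof = scna.joint_segment(mat, info, scna.SegmentationParams(gamma=1.0))
        assert len(prof["R1"].segments) == 1

    def test_noiseless_step_breakpoint_at_step(self):
        info = probe_frame(100)
        y = np.concatenate([np.zeros(50), np.ones(50)])
        # SSE saved by the cut is 25 per region; gamma below that -> cut
        mat = pd.DataFrame({"R1": y}, index=info.index)
        prof = scna.joint_segment(mat, info, scna.SegmentationParams(gamma=20.0))
        seg = prof["R1"].segments
        assert len(seg) == 2
        assert seg.iloc[0].n_probes == 50 and seg.iloc[1].n_probes == 50
        # gamma above the saved SSE -> no cut
        prof2 = scna.joint_segment(mat, info, scna.SegmentationParams(gamma=30.0))
        assert len(prof2["R1"].segments) == 1

    def test_matches_exhaustive_search_small_instances(self):
        """<=12 probes: the DP objective equals brute force over all
        breakpoint subsets, across random signals and penalties."""
        rng = np.random.default_rng(5)
        for trial in range(40):
            n = int(rng.integers(2, 13))
            n_reg = int(rng.integers(1, 4))
            y = rng.normal(0, 1, (n, n_reg)).round(2)
            gamma = float(rng.choice([0.1, 0.5, 2.0, 8.0]))
            info = probe_frame(n)
            mat = pd.DataFrame(y, index=info.index,
                               columns=[f"R{j}" for j in range(n_reg)])
            prof = scna.joint_segment(mat, info, scna.SegmentationParams(gamma=gamma))
            seg = prof["R0"].segments
            dp_cuts = np.cumsum(seg["n_probes"].values)[:-1].tolist()
            best = min(
                dp_objective(y, list(cuts), gamma)
                for k in range(n)
                for cuts in itertools.combinations(range(1, n), k)
            )
            assert dp_objective(y, dp_cuts, gamma) == pytest.approx(best, abs=1e-9)

    def test_shared_breakpoints_across_regions(self):
        info = probe_frame(60)
        y1 = np.concatenate([np.zeros(30), np.ones(30)])
        mat = pd.DataFrame({"R1": y1, "R2": np.zeros(60)}, index=info.index)
        prof = scna.joint_segment(mat, info, scna.SegmentationParams(gamma=5.0))
        assert list(prof["R1"].segments["start"]) == list(prof["R2"].segments["start"])

    def test_unsorted_probes_rejected(self):
        info = probe_frame(10)
        info.loc["p3", "pos"] = 999999
        mat = pd.DataFrame({"R1": np.zeros(10)}, index=info.index)
        with pytest.raises(ValueError, match="sorted"):
            scna.joint_segment(mat, info)


def simulate_ratio_profile(alpha, tau, qs, noise_sd, rng, n_probes=50):
    # probe-level noise sd; a segment mean of n probes has sd noise_sd/sqrt(n)
    denom = alpha * tau + 2 * (1 - alpha)
    logr = np.log2((alpha * np.asarray(qs) + 2 * (1 - alpha)) / denom)
    logr = logr + rng.normal(0, noise_sd / np.sqrt(n_probes), len(qs))
    k = len(qs)
    return scna.SegmentProfile(
        "R1",
        pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(k) * 10_000_000,
            "end": (np.arange(k) + 1) * 10_000_000,
            "n_probes": n_probes,
            "logR": logr,
        }),
    )


class TestPurityPloidy:
    def test_diploid_noiseless(self):
        rng = np.random.default_rng(0)
        prof = simulate_ratio_profile(1.0, 2.0, [2] * 8, 0.0, rng)
        sols = scna.fit_purity_ploidy(prof, prior_ploidy=2.0)
        assert np.allclose(prof.segments["logR"], 0.0)
        assert (sols[0].modal_cn == 2).all()

    def test_topk_contract(self):
        rng = np.random.default_rng(1)
        prof = simulate_ratio_profile(0.6, 2.0, [1, 2, 3, 2, 4], 0.05, rng)
        sols = scna.fit_purity_ploidy(prof, prior_ploidy=2.0, top_k=5)
        assert len(sols) <= 5
        lls = [s.log_likelihood for s in sols]
        assert lls == sorted(lls, reverse=True)

    def test_parameter_recovery(self):
        """alpha within 0.05 and tau within 0.1 on simulated profiles."""
        rng = np.random.default_rng(2)
        hits = 0
        n_trials = 12
        for _ in range(n_trials):
            alpha = float(rng.uniform(0.35, 0.9))
            tau = 2.0
            qs = rng.choice([1, 2, 2, 2, 3, 3, 4], size=12)
            prof = simulate_ratio_profile(alpha, tau, qs, 0.05, rng)
            best = scna.fit_purity_ploidy(prof, prior_ploidy=2.0)[0]
            if abs(best.purity - alpha) <= 0.05 and abs(best.ploidy - tau) <= 0.1:
                hits += 1
        assert hits >= 0.9 * n_trials

    def test_empty_profile_rejected(self):
        prof = scna.SegmentProfile("R1", pd.DataFrame(
            columns=["chrom", "start", "end", "n_probes", "logR"]))
        with pytest.raises(ValueError):
            scna.fit_purity_ploidy(prof)


class TestHarmonize:
    def _solution(self, purity, ploidy, ll, cn):
        return scna.PurityPloidySolution(purity, ploidy, ll, np.array(cn))

    def test_decoy_doubled_solutions_rejected(self):
        # truth: diploid; decoy: genome-doubled with slightly higher ll in R2
        true_cn = [2, 2, 3, 2]
        doubled = [4, 4, 6, 4]
        per_region = {
            "R1": [self._solution(0.7, 2.0, -10.0, true_cn),
                   self._solution(0.35, 4.0, -11.0, doubled)],
            "R2": [self._solution(0.6, 4.0, -9.5, doubled),
                   self._solution(0.6, 2.0, -10.0, true_cn)],
            "R3": [self._solution(0.8, 2.0, -10.0, true_cn),
                   self._solution(0.4, 4.0, -10.5, doubled)],
        }
        choice = scna.harmonize_solutions(per_region)["choice"]
        for r in ("R1", "R2", "R3"):
            assert choice[r].ploidy == 2.0

    def test_single_region_returns_top_likelihood(self):
        per_region = {"R1": [self._solution(0.5, 2.0, -5.0, [2, 2]),
                             self._solution(0.9, 2.0, -3.0, [2, 3])]}
        choice = scna.harmonize_solutions(per_region)["choice"]
        assert choice["R1"].log_likelihood == -3.0

    def test_lambda_zero_gives_independent_ml(self):
        per_region = {
            "R1": [self._solution(0.5, 2.0, -5.0, [2, 2]),
                   self._solution(0.9, 2.0, -3.0, [4, 4])],
            "R2": [self._solution(0.5, 2.0, -4.0, [2, 2]),
                   self._solution(0.9, 2.0, -6.0, [4, 4])],
        }
        choice = scna.harmonize_solutions(per_region, lam=0.0)["choice"]
        assert choice["R1"].log_likelihood == -3.0
        assert choice["R2"].log_likelihood == -4.0


def brute_force_arm_fractions(segments, arm_table):
    """Per-arm affected length by direct interval arithmetic."""
    out = {}
    for _, arm in arm_table.iterrows():
        for direction, cond in (("gain", lambda q: q > 2), ("loss", lambda q: q < 2)):
            length = 0
            for s in segments.itertuples():
                if s.chrom != arm.chrom or not cond(s.q):
                    continue
                length += max(0, min(s.end, arm.end) - max(s.start, arm.start))
            out[(arm.chrom, arm.arm, direction)] = length / (arm.end - arm.start)
    return out


class TestArmEvents:
    arm_table = pd.DataFrame(
        [("chr7", "p", 0, 60_000_000), ("chr7", "q", 60_000_000, 160_000_000),
         ("chr17", "p", 0, 25_000_000), ("chr17", "q", 25_000_000, 81_000_000)],
        columns=["chrom", "arm", "start", "end"],
    )

    def _profile(self, rows):
        return scna.SegmentProfile("S", pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_probes", "logR", "q"]))

    def test_whole_chromosome_gain(self):
        prof = self._profile([("chr7", 0, 160_000_000, 500, 0.3, 3)])
        events = scna.call_arm_events(prof, self.arm_table)
        assert len(events) == 1
        e = events[0]
        assert (e.arm, e.direction) == ("7", "gain")
        assert e.fraction == pytest.approx(1.0)

    def test_below_threshold_not_called(self):
        # 29% of 17q gained
        prof = self._profile([
            ("chr17", 25_000_000, 25_000_000 + int(0.29 * 56_000_000), 100, 0.3, 3),
            ("chr17", 25_000_000 + int(0.29 * 56_000_000), 81_000_000, 100, 0.0, 2),
            ("chr17", 0, 25_000_000, 100, 0.0, 2),
        ])
        assert scna.call_arm_events(prof, self.arm_table) == []

    def test_fractions_match_interval_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            rows = []
            for chrom, cstart, cend in (("chr7", 0, 160_000_000), ("chr17", 0, 81_000_000)):
                cuts = np.sort(rng.choice(
                    np.arange(cstart + 1, cend, 1_000_000), size=4, replace=False))
                bounds = [cstart, *cuts.tolist(), cend]
                for a, b in zip(bounds[:-1], bounds[1:]):
                    rows.append((chrom, a, b, 10, 0.0, int(rng.choice([1, 2, 2, 3]))))
            prof = self._profile(rows)
            events = scna.call_arm_events(prof, self.arm_table, threshold=0.30)
            oracle = brute_force_arm_fractions(prof.segments, self.arm_table)
            called = {}
            for e in events:
                for arm_label in e.arms_involved:
                    chrom = "chr" + arm_label.rstrip("pq")
                    called[(chrom, arm_label[-1], e.direction)] = True
            for key, frac in oracle.items():
                assert ((frac > 0.30) == called.get(key, False)), (key, frac)

    def test_affected_length_conserved(self):
        # sum of per-arm affected lengths equals sum over aberrant segments
        prof = self._profile([
            ("chr7", 0, 100_000_000, 100, 0.3, 3),
            ("chr7", 100_000_000, 160_000_000, 100, 0.0, 2),
            ("chr17", 0, 50_000_000, 100, -0.4, 1),
        ])
        oracle = brute_force_arm_fractions(prof.segments, self.arm_table)
        arm_len = {(r.chrom, r.arm): r.end - r.start for r in self.arm_table.itertuples()}
        total_by_arms = sum(
            frac * arm_len[(c, a)] for (c, a, d), frac in oracle.items()
        )
        total_by_segments = sum(
            s.end - s.start for s in prof.segments.itertuples() if s.q != 2
        )
        assert total_by_arms == pytest.approx(total_by_segments)

    def test_missing_cn_rejected(self):
        prof = scna.SegmentProfile("S", pd.DataFrame(
            [("chr7", 0, 1000, 5, 0.0)],
            columns=["chrom", "start", "end", "n_probes", "logR"]))
        with pytest.raises(ValueError):
            scna.call_arm_events(prof, self.arm_table)


class TestCohortSummaryAndCooccurrence:
    def test_empty_cohort_zeros(self):
        s = scna.summarize_cohort_scna({})
        assert s["total_events"] == 0 and s["median_per_sample"] == 0.0

    def test_involvement_semantics(self):
        events = {
            "S1": [scna.ArmEvent("S1", "7", "gain")],       # whole chromosome
            "S2": [scna.ArmEvent("S2", "7q", "gain")],
            "S3": [scna.ArmEvent("S3", "7p", "loss")],
        }
        s = scna.summarize_cohort_scna(events)
        assert s["recurrence"]["7:gain"] == 2       # S1 + S2
        assert s["recurrence"]["7q:gain"] == 2      # whole-chrom involves 7q
        assert s["recurrence"]["7p:gain"] == 1      # only the whole-chrom event
        assert s["recurrence"]["7p:loss"] == 1

    def test_perfect_cooccurrence_significant(self):
        events = {}
        for i in range(10):
            events[f"S{i}"] = [scna.ArmEvent(f"S{i}", "7", "gain"),
                               scna.ArmEvent(f"S{i}", "17q", "gain")]
        for i in range(10, 20):
            events[f"S{i}"] = []
        res = scna.cooccurrence_test(events, {"7", "17q"}, n_samples=20)
        assert res["observed"] == 10
        assert res["p"] < 0.05

    def test_no_cooccurrence_p_one(self):
        events = {"S1": [scna.ArmEvent("S1", "7", "gain")], "S2": []}
        res = scna.cooccurrence_test(events, {"7", "17q"}, n_samples=2)
        assert res["p"] == 1.0

    def test_null_calibration(self):
        """Independent gains: the test should not be anticonservative."""
        rng = np.random.default_rng(9)
        arms = ["7", "12", "16", "17q"]
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            events = {}
            for i in range(23):
                evts = [scna.ArmEvent(f"S{i}", a, "gain")
                        for a in arms if rng.random() < 0.4]
                events[f"S{i}"] = evts
            res = scna.cooccurrence_test(events, set(arms), n_samples=23)
            if res["p"] < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10


class TestFocal:
    def _profile(self, rows):
        return scna.SegmentProfile("S", pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_probes", "logR", "q"]))

    def test_reported_and_filtered(self):
        prof = self._profile([
            ("chr9", 21_000_000, 21_900_000, 20, -1.0, 1),   # 0.9 Mb deletion
            ("chr9", 30_000_000, 30_900_000, 20, -1.0, 1),   # covered by CNV
            ("chr9", 40_000_000, 45_000_000, 20, -1.0, 1),   # too large
        ])
        cnvs = [("chr9", 30_000_000, 30_540_000)]  # 60% of second segment
        res = scna.detect_focal_scna(prof, cnvs)
        assert list(res["start"]) == [21_000_000]

    def test_matches_overlap_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            s0 = int(rng.integers(0, 50_000_000))
            size = int(rng.integers(100_000, 1_500_000))
            q = int(rng.choice([1, 2, 3]))
            c0 = int(rng.integers(0, 50_000_000))
            csize = int(rng.integers(100_000, 1_500_000))
            prof = self._profile([("chr1", s0, s0 + size, 10, 0.0, q)])
            cnvs = [("chr1", c0, c0 + csize)]
            res = scna.detect_focal_scna(prof, cnvs)
            ov = max(0, min(s0 + size, c0 + csize) - max(s0, c0))
            expect = q != 2 and size < 1_000_000 and ov / size <= 0.5
            assert (len(res) == 1) == expect


class TestHaplotypeConcordance:
    def _mirrored_probes(self, hap_r2, seed=31, noise=0.05, n=60):
        """One-clone, two-region tumour; chr1q gained on haplotype A in R1 and
        ``hap_r2`` in R2 (separate draws spliced into one table)."""
        def build(hap_pair):
            tree = simdata.simulate_clone_tree(1, 2, (0.7, 0.7), seed=seed)
            simdata.assign_scna_events(tree, [
                {"chrom": "chr1", "arm": "q", "direction": 1, "clone": 0,
                 "haplotype": hap_pair}])
            return simdata.simulate_snp_array(tree, n_probes_per_arm=n, noise_sd=noise)
        a = build("A")
        b = build(hap_r2)
        return pd.concat([a[a.region == "R1"], b[b.region == "R2"]])

    SPAN = (40_000_000, 100_000_000)

    def test_same_haplotype_concordant(self):
        probes = self._mirrored_probes("A")
        res = scna.haplotype_concordance(probes, "chr1", self.SPAN,
                                         ["R1", "R2"], "R1")
        assert res["R2"]["call"] == "concordant"

    def test_alternate_haplotype_inverted(self):
        probes = self._mirrored_probes("B")
        res = scna.haplotype_concordance(probes, "chr1", self.SPAN,
                                         ["R1", "R2"], "R1")
        assert res["R2"]["call"] == "inverted"

    def test_balanced_region_indeterminate(self):
        # event only in R1; R2 diploid-balanced -> flip fraction ~0.5
        tree = simdata.simulate_clone_tree(2, 2, (0.7, 0.7), seed=41)
        tree.clone_ccf[1] = np.array([1.0, 0.0])  # clone present only in R1
        simdata.assign_scna_events(tree, [
            {"chrom": "chr1", "arm": "q", "direction": 1, "clone": 1,
             "haplotype": "A"}])
        probes = simdata.simulate_snp_array(tree, n_probes_per_arm=60, noise_sd=0.05)
        res = scna.haplotype_concordance(probes, "chr1", self.SPAN,
                                         ["R1", "R2"], "R1")
        assert res["R2"]["call"] == "indeterminate"

    def test_too_few_probes_indeterminate(self):
        probes = self._mirrored_probes("B", n=10)
        res = scna.haplotype_concordance(probes, "chr1", self.SPAN,
                                         ["R1", "R2"], "R1", min_het_probes=20)
        assert res["R2"]["call"] == "indeterminate"
        assert res["R2"]["n_het"] < 20


class TestDnaIndex:
    def test_arithmetic(self):
        assert scna.dna_index(200, 200) == 1.0
        assert scna.dna_index(300, 200) == 1.5
        with pytest.raises(ValueError):
            scna.dna_index(0, 200)

    def test_simulated_triploid_population(self):
        rng = np.random.default_rng(7)
        diploid_peak = rng.normal(200, 2, 500).mean()
        triploid_peak = rng.normal(300, 2, 500).mean()
        assert scna.dna_index(triploid_peak, diploid_peak) == pytest.approx(1.5, abs=0.05)
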