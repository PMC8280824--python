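"""Beta-binomial differential test, rank statistics, clustering, cryptic sites."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from minorlens.annotation_io import Intron
from minorlens.differential_ir import (
    adjust_bh,
    betabin_test,
    cluster_retention,
    detect_cryptic,
    differential_table,
    estimate_common_rho,
    mann_whitney,
    summarize_by_subtype,
)


def binomial_lrt_oracle(r_c, n_c, r_t, n_t):
    """Independent closed-form binomial LRT used as a cross-check."""

    def ll(r, n):
        r, n = float(np.sum(r)), float(np.sum(n))
        out = 0.0
        if r > 0:
            out += r * np.log(r / n)
        if n - r > 0:
            out += (n - r) * np.log((n - r) / n)
        return out

    lrt = 2 * (
        ll(r_c, n_c)
        + ll(r_t, n_t)
        - ll(np.sum(r_c) + np.sum(r_t), np.sum(n_c) + np.sum(n_t))
    )
    return stats.chi2.sf(max(lrt, 0.0), 1)


class TestBetabinTest:
    def test_identical_counts_give_p_one(self):
        p, dpsi = betabin_test([10, 12], [40, 38], [10, 12], [40, 38])
        assert p == pytest.approx(1.0, abs=1e-6)
        assert dpsi == pytest.approx(0.0)

    def test_rho_zero_matches_binomial_lrt_oracle(self, rng):
        for _ in range(50):
            n_c = rng.integers(10, 80, size=3)
            n_t = rng.integers(10, 80, size=3)
            r_c = rng.binomial(n_c, 0.2)
            r_t = rng.binomial(n_t, 0.35)
            p, _ = betabin_test(r_c, n_c, r_t, n_t, fix_rho=0)
            assert p == pytest.approx(
                binomial_lrt_oracle(r_c, n_c, r_t, n_t), rel=1e-9
            )

    def test_single_replicate_equal_proportions(self):
        p, dpsi = betabin_test([10], [20], [10], [20])
        assert dpsi == 0.0
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_totals(self):
        p, dpsi = betabin_test([0], [0], [0], [0])
        assert p == 1.0
        assert np.isnan(dpsi)

    def test_large_shift_detected(self):
        p, dpsi = betabin_test([5, 6, 4], [50, 55, 45], [30, 28, 33], [50, 55, 45])
        assert p < 1e-3
        assert dpsi == pytest.approx(0.5, abs=0.1)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            betabin_test([10], [5], [1], [5])


class TestCommonRho:
    def test_recovers_planted_overdispersion(self, rng):
        for true_rho in (0.0, 0.05):
            groups = []
            for _ in range(800):
                n = rng.integers(40, 90, size=6).astype(float)
                if true_rho > 0:
                    a = 0.1 * (1 - true_rho) / true_rho
                    b = 0.9 * (1 - true_rho) / true_rho
                    pj = rng.beta(a, b, size=6)
                else:
                    pj = np.full(6, 0.1)
                r = rng.binomial(n.astype(int), pj).astype(float)
                groups.append([(r[:3], n[:3]), (r[3:], n[3:])])
            est = estimate_common_rho(groups)
            assert est == pytest.approx(true_rho, abs=0.015)


class TestAdjustBH:
    def test_hand_step_up_example(self):
        adjusted = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_unchanged(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37]) == pytest.approx([0.37])

    def test_never_decreases_and_monotone(self, rng):
        p = rng.random(40)
        adj = adjust_bh(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of arrangements."""
    x, y = list(x), list(y)
    n1 = len(x)
    combined = x + y
    ranks = stats.rankdata(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(combined)
    us = []
    for idx in itertools.combinations(range(n), n1):
        rx = sum(ranks[i] for i in idx)
        us.append(rx - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    mean_u = n1 * (n - n1) / 2
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_extreme_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_approximate_path(self):
        _, p = mann_whitney([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4)
        assert p == pytest.approx(1.0)

    def test_exact_agrees_with_enumeration_up_to_n8(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 5):
            for n2 in range(1, 5):
                if n1 + n2 > 8:
                    continue
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = vals[:n1], vals[n1:]
                u, p = mann_whitney(x, y)
                u_o, p_o = mw_enumeration_oracle(x, y)
                assert u == pytest.approx(u_o)
                assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_and_approximate_agree_moderate_n(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, p_exact = mann_whitney(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p_exact == pytest.approx(res.pvalue, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSummarizeBySubtype:
    def make_inputs(self, n_a=10, flagged_a=9):
        results = pd.DataFrame(
            {
                "intron_key": [f"i{k}" for k in range(n_a + 5)],
                "delta_psi": [0.3] * n_a + [0.01] * 5,
                "p": [0.001] * n_a + [0.9] * 5,
                "p_adj": [0.01] * flagged_a
                + [0.5] * (n_a - flagged_a)
                + [0.9] * 5,
            }
        )
        results["affected_ir"] = results["p_adj"] < 0.05
        results["affected_strict"] = results["affected_ir"] & (
            results["delta_psi"] > 0.1
        )
        cls = pd.DataFrame(
            {
                "intron_key": results["intron_key"],
                "spliceosome_type": ["minor"] * (n_a + 5),
                "subtype": ["A"] * n_a + ["G"] * 5,
            }
        )
        return results, cls

    def test_fraction_affected(self):
        results, cls = self.make_inputs()
        summary = summarize_by_subtype(results, cls)
        assert summary["subtypes"]["A"]["fraction_affected"] == pytest.approx(0.9)
        assert summary["subtypes"]["A"]["n"] == 10

    def test_zero_delta_psi_gives_p_one(self):
        results, cls = self.make_inputs()
        results["delta_psi"] = 0.0
        summary = summarize_by_subtype(results, cls)
        assert summary["subtypes"]["A"]["mean_delta_psi"] == 0.0
        assert summary["a_vs_g_mannwhitney"]["p"] == pytest.approx(1.0)

    def test_cryptic_union_mode(self):
        results, cls = self.make_inputs(n_a=10, flagged_a=5)
        cryptic = {"i5", "i6"}  # two unflagged A introns with cryptic events
        summary = summarize_by_subtype(results, cls, cryptic_by_intron=cryptic)
        assert summary["subtypes"]["A"]["fraction_affected"] == pytest.approx(0.7)

    def test_empty_subtype_flagged(self):
        results, cls = self.make_inputs()
        cls["subtype"] = "A"
        summary = summarize_by_subtype(results, cls)
        assert summary["subtypes"]["G"]["n"] == 0
        assert np.isnan(summary["subtypes"]["G"]["fraction_affected"])


def brute_force_average_linkage(points):
    """Independent average-linkage oracle returning merge member sets."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    nxt = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                ]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[nxt] = merged
        merges.append(frozenset(merged))
        nxt += 1
    return merges


class TestClusterRetention:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[0.1, 0.1], [0.1, 0.1], [0.9, 0.9]], index=["a", "b", "c"]
        )
        Z, order = cluster_retention(m)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {0, 1}
        assert order.index("c") in (0, 2)

    def test_matches_brute_force_on_random_points(self, rng):
        points = rng.normal(size=(8, 3))
        m = pd.DataFrame(points)
        Z, _ = cluster_retention(m)
        # reconstruct member sets of each scipy merge
        members = {i: [i] for i in range(len(points))}
        got = []
        for step, (a, b, _, _) in enumerate(Z):
            merged = members[int(a)] + members[int(b)]
            members[len(points) + step] = merged
            got.append(frozenset(merged))
        assert got == brute_force_average_linkage(points)

    def test_row_permutation_invariance(self, rng):
        points = rng.normal(size=(7, 2))
        m = pd.DataFrame(points, index=[f"r{i}" for i in range(7)])
        _, order_a = cluster_retention(m)
        perm = rng.permutation(7)
        _, order_b = cluster_retention(m.iloc[perm])
        # same tree up to relabeling: adjacent-pair structure is stable
        assert set(order_a) == set(order_b)
        Z_a, _ = cluster_retention(m)
        Z_b, _ = cluster_retention(m.iloc[perm])
        assert np.allclose(sorted(Z_a[:, 2]), sorted(Z_b[:, 2]))

    def test_missing_rows_dropped_with_warning(self):
        m = pd.DataFrame([[0.1, np.nan], [0.2, 0.3], [0.4, 0.5]])
        with pytest.warns(UserWarning, match="undefined psi"):
            _, order = cluster_retention(m)
        assert len(order) == 2

    def test_fewer_than_two_rows_trivial(self):
        m = pd.DataFrame([[0.1, 0.2]], index=["only"])
        Z, order = cluster_retention(m)
        assert Z.shape == (0, 4)
        assert order == ["only"]


def minor_intron(contig="c", start=100, end=250):
    return Intron(
        contig=contig, start=start, end=end, strand="+", host_gene="g",
        intron_index=1, donor_dinucleotide="AT", acceptor_dinucleotide="AC",
        terminal_label="AT-AC", donor_region_seq="ATATCCTTT",
        three_prime_region_seq="A" * 40,
    )


def junction_frame(canonical, alt, samples):
    rows = []
    for sample, (j_can, j_alt) in samples.items():
        rows.append(
            {"contig": "c", "start": canonical[0], "end": canonical[1],
             "sample": sample, "count": j_can}
        )
        rows.append(
            {"contig": "c", "start": alt[0], "end": alt[1],
             "sample": sample, "count": j_alt}
        )
    return pd.DataFrame(rows)


DESIGN = {
    "c1": "control", "c2": "control", "c3": "control",
    "t1": "treatment", "t2": "treatment", "t3": "treatment",
}


class TestDetectCryptic:
    def test_extreme_activation_detected(self):
        jc = junction_frame(
            (100, 250), (100, 230),
            {
                "c1": (50, 0), "c2": (50, 0), "c3": (50, 0),
                "t1": (10, 40), "t2": (10, 40), "t3": (10, 40),
            },
        )
        events = detect_cryptic(jc, [minor_intron()], DESIGN, "control", "treatment")
        assert len(events) == 1
        assert bool(events.iloc[0].activated)

    def test_unchanged_usage_not_activated(self):
        jc = junction_frame(
            (100, 250), (100, 230),
            {s: (40, 10) for s in DESIGN},
        )
        events = detect_cryptic(jc, [minor_intron()], DESIGN, "control", "treatment")
        assert len(events) == 1
        assert not bool(events.iloc[0].activated)

    def test_distant_junction_not_a_candidate(self):
        jc = junction_frame(
            (100, 250), (500, 700),
            {s: (40, 10) for s in DESIGN},
        )
        events = detect_cryptic(jc, [minor_intron()], DESIGN, "control", "treatment")
        assert events.empty

    def test_planted_usage_shift_simulation(self, rng):
        # alternative-donor usage rising from 5% to 50% at moderate depth
        samples = {}
        for s, cond in DESIGN.items():
            frac = 0.05 if cond == "control" else 0.5
            total = int(rng.integers(80, 120))
            alt = rng.binomial(total, frac)
            samples[s] = (total - alt, alt)
        jc = junction_frame((100, 250), (130, 250), samples)
        events = detect_cryptic(jc, [minor_intron()], DESIGN, "control", "treatment")
        assert len(events) == 1
        assert bool(events.iloc[0].activated)


class TestDifferentialTable:
    def test_null_data_rarely_flagged_and_shift_always_flagged(self, rng):
        rows = []
        for i in range(30):
            shifted = i < 10
            for j, (sample, cond) in enumerate(DESIGN.items()):
                psi = 0.1 + (0.36 if shifted and cond == "treatment" else 0.0)
                n = int(rng.integers(50, 90))
                r = rng.binomial(n, psi)
                rows.append(
                    {"intron_key": f"i{i:02d}", "sample": sample,
                     "J": n - r, "B": 2 * r, "R": 0}
                )
        counts = pd.DataFrame(rows)
        table = differential_table(counts, DESIGN, "control", "treatment")
        shifted_keys = {f"i{i:02d}" for i in range(10)}
        flagged = set(table[table.affected_strict].intron_key)
        assert shifted_keys <= flagged
        assert len(flagged - shifted_keys) <= 2
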