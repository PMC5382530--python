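"""Responsive-OTU filter, profile clustering, post-hoc tests, response classes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import microsucc as ms
from microsucc.io import SampleMetadata
from microsucc.succession import (
    bray_curtis_matrix,
    classify_taxon_response,
    cluster_response_groups,
    filter_responsive_otus,
    kruskal_posthoc,
    relativize_profiles,
    validate_subset_procrustes,
)

TIMES = (0, 1, 4, 10)
REPS = 3


def engineered_filter_fixture():
    """10-taxon table over 4 time points x 3 disturbed replicates in which
    exactly four engineered taxa pass all three responsiveness rules.

    Columns all sum to the same depth, so "flat in counts" really means
    flat in relative abundance. otu0-otu3 carry strong time trends whose
    proportions sum to 0.30 at every time point; otu4 is abundant but
    constant (fails the ANOVA rule), otu5 sits at 0.4% (fails the
    abundance rule), otu6 appears in only two samples (fails prevalence),
    otu7-otu9 are constant background.
    """
    rng = np.random.default_rng(77)
    depth = 2000
    responsive = {  # taxon -> per-time proportions, each column sums to 0.30
        "otu0": {0: 0.20, 1: 0.05, 4: 0.03, 10: 0.02},
        "otu1": {0: 0.02, 1: 0.02, 4: 0.02, 10: 0.14},
        "otu2": {0: 0.04, 1: 0.08, 4: 0.15, 10: 0.10},
        "otu3": {0: 0.04, 1: 0.15, 4: 0.10, 10: 0.04},
    }
    flat = {"otu4": 0.10, "otu5": 0.004, "otu7": 0.30, "otu8": 0.20, "otu9": 0.096}
    samples, meta_rows = [], []
    for t in TIMES:
        for r in range(REPS):
            sid = f"D{t:02d}R{r + 1}"
            samples.append(sid)
            meta_rows.append({"sample_id": sid, "time_days": t,
                              "treatment": "disturbed", "replicate": f"R{r + 1}"})
    counts = pd.DataFrame(0, index=[f"otu{i}" for i in range(10)], columns=samples)
    for j, sid in enumerate(samples):
        t = TIMES[j // REPS]
        for taxon, prof in responsive.items():
            counts.loc[taxon, sid] = int(round(depth * prof[t]))
        for taxon, p in flat.items():
            counts.loc[taxon, sid] = int(round(depth * p))
        if sid in samples[:2]:  # otu6 present in exactly two samples
            counts.loc["otu6", sid] = int(round(depth * 0.05))
            counts.loc["otu0", sid] -= int(round(depth * 0.05))
        # small replicate jitter on the responsive taxa, balanced against
        # the large flat background so column totals stay equal
        for taxon in responsive:
            j_ = int(rng.integers(0, 3))
            counts.loc[taxon, sid] += j_
            counts.loc["otu7", sid] -= j_
    table = ms.CommunityTable(counts)
    assert table.sample_totals().nunique() == 1
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, metadata


class TestFilter:
    def test_exactly_engineered_taxa_pass(self):
        table, metadata = engineered_filter_fixture()
        profiles = filter_responsive_otus(table, metadata)
        assert sorted(p.taxon_id for p in profiles) == ["otu0", "otu1", "otu2", "otu3"]
        for p in profiles:
            assert p.anova_p < 0.01
            assert p.relativized.max() == pytest.approx(1.0)

    def test_filter_is_monotone_in_thresholds(self):
        table, metadata = engineered_filter_fixture()
        base = {p.taxon_id for p in filter_responsive_otus(table, metadata)}
        stricter_ab = {p.taxon_id for p in
                       filter_responsive_otus(table, metadata, min_relabund=0.05)}
        stricter_alpha = {p.taxon_id for p in
                          filter_responsive_otus(table, metadata, alpha=1e-6)}
        assert stricter_ab <= base
        assert stricter_alpha <= base

    def test_no_survivors_warns(self):
        table, metadata = engineered_filter_fixture()
        with pytest.warns(UserWarning, match="no OTUs"):
            out = filter_responsive_otus(table, metadata, min_relabund=0.9)
        assert out == []


class TestRelativize:
    def test_arithmetic(self):
        frame = pd.DataFrame({0: [2.0], 1: [4.0], 2: [8.0]}, index=["t"])
        out = relativize_profiles(frame)
        assert out.loc["t"].tolist() == [0.25, 0.5, 1.0]

    def test_constant_profile_all_ones(self):
        frame = pd.DataFrame({0: [3.0], 1: [3.0]}, index=["t"])
        assert (relativize_profiles(frame) == 1.0).all().all()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.random((5, 4)))
        once = relativize_profiles(frame)
        twice = relativize_profiles(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_sum_mode(self):
        frame = pd.DataFrame({0: [2.0], 1: [6.0]}, index=["t"])
        out = relativize_profiles(frame, mode="sum")
        assert out.loc["t"].sum() == pytest.approx(1.0)


class TestClustering:
    @staticmethod
    def _planted(noise=0.05, per_group=10, seed=0):
        rng = np.random.default_rng(seed)
        archetypes = np.array([
            [1.0, 0.2, 0.1, 0.0, 0.0],  # early peak
            [0.1, 1.0, 0.3, 0.1, 0.0],  # primary-phase peak
            [0.0, 0.2, 1.0, 0.6, 0.3],  # mid peak
            [0.1, 0.0, 0.2, 0.7, 1.0],  # late rise
        ])
        rows, labels = [], []
        for g, base in enumerate(archetypes):
            for i in range(per_group):
                rows.append(np.clip(base + rng.normal(0, noise, 5), 0, None))
                labels.append(g)
        frame = pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))],
                             columns=[0, 1, 4, 10, 29])
        return frame, np.array(labels)

    def test_planted_archetypes_recovered_exactly(self):
        frame, truth = self._planted()
        res = cluster_response_groups(frame, k=4)
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0

    def test_groups_numbered_by_peak_time(self):
        frame, _ = self._planted()
        res = cluster_response_groups(frame, k=4)
        peaks = [res.group_profiles.loc[g].idxmax() for g in sorted(res.group_profiles.index)]
        assert peaks == sorted(peaks)

    def test_identical_profiles_share_group(self):
        frame = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.3, 1.0]],
            index=list("abcd"), columns=[0, 1],
        )
        res = cluster_response_groups(frame, k=2)
        assert res.assignments["a"] == res.assignments["b"]

    def test_k_one_and_k_too_large(self):
        frame, _ = self._planted(per_group=2)
        assert cluster_response_groups(frame, k=1).assignments.nunique() == 1
        with pytest.raises(ValueError):
            cluster_response_groups(frame, k=9)


class TestKruskalPosthoc:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        res = kruskal_posthoc([vals[:10], vals[10:20], vals[20:]])
        assert res.p_value > 0.05
        assert (res.posthoc_p.to_numpy() > 0.05).all()

    def test_exact_permutation_oracle_small_n(self):
        """Exact KW p equals exhaustive enumeration over rank assignments."""
        a = np.array([1.3, 2.7, 3.9, 5.2])
        b = np.array([6.1, 7.4, 8.8, 9.5])
        res = kruskal_posthoc([a, b], exact=True)
        # independent oracle: enumerate all C(8,4) splits of the pooled values
        from scipy.stats import kruskal
        pooled = np.concatenate([a, b])
        h_obs = kruskal(a, b).statistic
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            total += 1
            count += kruskal(pooled[mask], pooled[~mask]).statistic >= h_obs - 1e-12
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_ties_switch_to_chisq_branch(self):
        res = kruskal_posthoc([[1.0, 1.0, 2.0], [2.0, 3.0, 3.0]])
        assert res.posthoc_method == "chisq"
        res2 = kruskal_posthoc([[1.1, 1.9, 2.6], [3.2, 4.1, 5.3]])
        assert res2.posthoc_method == "tukey"

    def test_posthoc_symmetric_and_monotone(self):
        res = kruskal_posthoc({
            "t0": [10.0, 11.2, 12.1, 10.7],
            "t1": [1.0, 1.4, 2.1, 1.8],
            "t2": [9.8, 11.0, 10.2, 12.3],
        })
        pm = res.posthoc_p
        assert pm.loc["t0", "t1"] == pm.loc["t1", "t0"]
        # far-apart groups less plausible under H0 than similar ones
        assert pm.loc["t0", "t1"] < pm.loc["t0", "t2"]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_posthoc([[1.0, 2.0]])


class TestClassifyResponse:
    @staticmethod
    def _posthoc(sig_pairs, times=(0, 1, 4, 18, 49)):
        pm = pd.DataFrame(1.0, index=list(times), columns=list(times))
        for a, b in sig_pairs:
            pm.loc[a, b] = pm.loc[b, a] = 0.001
        return pm

    def test_drop_then_return_is_conventional(self):
        prof = {0: 0.10, 1: 0.01, 4: 0.02, 18: 0.06, 49: 0.09}
        pm = self._posthoc([(0, 1), (0, 4)])
        assert classify_taxon_response(prof, 0.10, pm) == "conventional_recovery"

    def test_spike_then_decay_is_stress_tolerant(self):
        # the post-shock bloom pattern of endospore formers
        prof = {0: 0.02, 1: 0.30, 4: 0.20, 18: 0.05, 49: 0.02}
        pm = self._posthoc([(0, 1), (0, 4)])
        assert classify_taxon_response(prof, 0.02, pm) == "stress_tolerant"

    def test_overshoot_is_positive_secondary(self):
        prof = {0: 0.05, 1: 0.01, 4: 0.02, 18: 0.12, 49: 0.11}
        pm = self._posthoc([(0, 1), (0, 18), (0, 49)])
        assert classify_taxon_response(prof, 0.05, pm) == "positive_secondary"

    def test_flat_profile_is_no_change(self):
        prof = {0: 0.05, 1: 0.05, 4: 0.05, 18: 0.05, 49: 0.05}
        assert classify_taxon_response(prof, 0.05, self._posthoc([])) == "no_change"

    def test_missing_time_rejected(self):
        prof = {0: 0.1, 1: 0.2, 4: 0.1, 18: 0.1}
        pm = self._posthoc([], times=(0, 1, 4))
        with pytest.raises(ValueError):
            classify_taxon_response(prof, 0.1, pm)


class TestSubsetValidation:
    @staticmethod
    def _structured_table(seed=0):
        """5 dominant taxa with two-regime dynamics + 25 tiny noise taxa."""
        rng = np.random.default_rng(seed)
        n_samp = 16
        dominants = np.empty((5, n_samp))
        for j in range(n_samp):
            base = np.array([50, 30, 5, 5, 10]) if j < 8 else np.array([5, 5, 40, 40, 10])
            dominants[:, j] = base * 40 + rng.integers(0, 20, 5)
        noise = rng.integers(0, 4, size=(25, n_samp))
        counts = pd.DataFrame(
            np.vstack([dominants, noise]).astype(int),
            index=[f"d{i}" for i in range(5)] + [f"n{i}" for i in range(25)],
            columns=[f"s{j}" for j in range(n_samp)],
        )
        return ms.CommunityTable(counts)

    def test_full_subset_is_identity(self):
        table = self._structured_table()
        res = validate_subset_procrustes(table, table.taxon_ids, n_perm=19, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-9)
        assert res.correlation == pytest.approx(1.0)

    def test_dominant_subset_highly_concordant(self):
        table = self._structured_table()
        res = validate_subset_procrustes(table, [f"d{i}" for i in range(5)],
                                         n_perm=199, seed=0)
        assert res.correlation > 0.9
        assert res.p_value == pytest.approx(1 / 200)

    def test_noise_subset_weakly_concordant(self):
        table = self._structured_table()
        strong = validate_subset_procrustes(table, [f"d{i}" for i in range(5)],
                                            n_perm=99, seed=0)
        weak = validate_subset_procrustes(table, [f"n{i}" for i in range(10)],
                                          n_perm=99, seed=0)
        assert weak.correlation < strong.correlation

    def test_bray_curtis_basics(self):
        table = self._structured_table()
        dm = bray_curtis_matrix(table)
        assert np.all(np.diag(dm.data) == 0)
        assert dm.data.max() <= 1.0 + 1e-12
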