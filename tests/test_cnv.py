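"""CNV caller: normalization, zero coverage, imbalance, integration, recovery."""

import numpy as np
import pandas as pd
import pytest

from otopanel.cnv import (
    BackgroundError,
    CnvParams,
    allelic_imbalance,
    call_cnv,
    detect_zero_coverage,
    normalize_depth,
)
from otopanel.simulate import CnvEvent, SimulationConfig, simulate_patient

PARAMS = CnvParams()


def _flat(n_targets=40, n_samples=8, value=500):
    idx = [f"t{i}" for i in range(n_targets)]
    bg = pd.DataFrame(value, index=idx, columns=[f"B{i}" for i in range(n_samples)])
    return pd.Series(value, index=idx, name="S"), bg


class TestNormalizeDepth:
    def test_identical_sample_gives_zero_everywhere(self):
        sample, bg = _flat()
        assert np.allclose(normalize_depth(sample, bg), 0.0)

    def test_too_small_background_rejected(self):
        sample, bg = _flat(n_samples=5)
        with pytest.raises(BackgroundError):
            normalize_depth(sample, bg)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        idx = [f"t{i}" for i in range(60)]
        bg = pd.DataFrame(rng.poisson(400, size=(60, 8)), index=idx,
                          columns=[f"B{i}" for i in range(8)])
        sample = pd.Series(rng.poisson(400, size=60), index=idx)
        base = normalize_depth(sample, bg)
        scaled = normalize_depth(sample * 7, bg)
        assert np.allclose(base, scaled, equal_nan=True)

    def test_halved_gene_near_minus_one(self):
        patient = simulate_patient(
            SimulationConfig(seed=2, mean_depth=500), events=[CnvEvent("G010", 1)]
        )
        log2r = normalize_depth(patient.counts, patient.background)
        in_gene = patient.targets["gene"] == "G010"
        assert abs(log2r[in_gene.to_numpy()].mean() - (-1.0)) < 0.1
        assert abs(log2r[~in_gene.to_numpy()].mean()) < 0.05

    def test_three_copy_gain_near_log2_three_halves(self):
        patient = simulate_patient(
            SimulationConfig(seed=3, mean_depth=500), events=[CnvEvent("G020", 3)]
        )
        log2r = normalize_depth(patient.counts, patient.background)
        in_gene = patient.targets["gene"] == "G020"
        assert abs(log2r[in_gene.to_numpy()].mean() - np.log2(1.5)) < 0.1

    def test_zero_median_background_target_masked(self):
        sample, bg = _flat()
        bg.iloc[0, :] = 0
        assert np.isnan(normalize_depth(sample, bg).iloc[0])


class TestZeroCoverage:
    def _targets(self, genes):
        return pd.DataFrame({"gene": genes}, index=[f"t{i}" for i in range(len(genes))])

    def test_whole_gene_zero_with_proper_background(self):
        sample, bg = _flat(n_targets=10)
        targets = self._targets(["STRClike"] * 10)
        sample[:] = 0
        cands = detect_zero_coverage(sample, bg, targets)
        assert len(cands) == 1
        assert cands[0].targets == tuple(f"t{i}" for i in range(10))

    def test_uncallable_when_background_also_empty(self):
        sample, bg = _flat(n_targets=5)
        targets = self._targets(["G"] * 5)
        sample[:] = 0
        bg.iloc[:, :] = 1  # background itself near zero: not a deletion signal
        assert detect_zero_coverage(sample, bg, targets) == []

    def test_single_interior_target(self):
        sample, bg = _flat(n_targets=9)
        targets = self._targets(["RDXlike"] * 9)
        sample["t2"] = 0
        cands = detect_zero_coverage(sample, bg, targets)
        assert len(cands) == 1 and cands[0].targets == ("t2",)


class TestAllelicImbalance:
    def test_balanced_snps(self):
        verdict = allelic_imbalance([0.50, 0.49, 0.51], [200, 200, 200])
        assert verdict.verdict == "balanced"

    def test_one_third_bafs_reject_half(self):
        verdict = allelic_imbalance([0.33, 0.34, 0.32], [200, 200, 200])
        assert verdict.verdict == "imbalanced"
        # binomial oracle: a single SNP at 66/200 already rejects at 0.01
        from scipy.stats import binomtest
        assert binomtest(66, 200, 0.5).pvalue < 0.01

    def test_no_hets_short_region_uninformative(self):
        assert allelic_imbalance([], []).verdict == "uninformative"

    def test_no_hets_long_region_supports_deletion(self):
        # expected hets: 0.8/target x 10 targets = 8; P(0 hets) = e^-8 ~ 3e-4
        verdict = allelic_imbalance([], [], n_targets=10, expected_hets_per_target=0.8)
        assert verdict.verdict == "supports_deletion"
        assert verdict.p_value == pytest.approx(np.exp(-8), rel=1e-6)


class TestCallCnv:
    def _pipeline(self, patient, params=PARAMS):
        log2r = normalize_depth(patient.counts, patient.background, params)
        zero = detect_zero_coverage(patient.counts, patient.background,
                                    patient.targets, params)
        return call_cnv(log2r, zero, patient.targets, params)

    def test_single_het_deletion_recovered(self):
        patient = simulate_patient(
            SimulationConfig(seed=11, mean_depth=500), events=[CnvEvent("G007", 1)]
        )
        calls = self._pipeline(patient)
        assert len(calls) == 1
        assert calls[0].gene == "G007" and calls[0].state == 1
        assert calls[0].n_targets == 10

    def test_flat_profile_yields_no_calls(self):
        for seed in range(100):
            patient = simulate_patient(SimulationConfig(seed=seed, mean_depth=500))
            assert self._pipeline(patient) == []

    def test_partial_interior_duplication(self):
        patient = simulate_patient(
            SimulationConfig(seed=13, mean_depth=500),
            events=[CnvEvent("G005", 3, first_target=2, last_target=6)],
        )
        calls = self._pipeline(patient)
        assert len(calls) == 1
        call = calls[0]
        assert (call.gene, call.state, call.n_targets) == ("G005", 3, 5)
        assert call.first_target == "G005_t2" and call.last_target == "G005_t6"

    def test_homozygous_deletion_uses_zero_coverage_evidence(self):
        patient = simulate_patient(
            SimulationConfig(seed=17, mean_depth=500), events=[CnvEvent("G002", 0)]
        )
        calls = self._pipeline(patient)
        assert len(calls) == 1
        assert calls[0].state == 0 and "zero_coverage" in calls[0].evidence

    def test_cn0_calls_subset_of_low_depth_targets(self):
        patient = simulate_patient(
            SimulationConfig(seed=19, mean_depth=500), events=[CnvEvent("G001", 0)]
        )
        calls = self._pipeline(patient)
        for call in calls:
            if call.state == 0:
                idx = patient.targets.index.get_indexer([call.first_target, call.last_target])
                span = patient.targets.index[idx[0] : idx[1] + 1]
                assert (patient.counts[span] <= PARAMS.hom_del_depth_max).all()

    def test_leave_one_out_background_stability(self):
        patient = simulate_patient(
            SimulationConfig(seed=23, mean_depth=500), n_background=9,
            events=[CnvEvent("G030", 1)],
        )
        full = self._pipeline(patient)
        for drop in patient.background.columns:
            reduced = patient.background.drop(columns=[drop])
            log2r = normalize_depth(patient.counts, reduced)
            zero = detect_zero_coverage(patient.counts, reduced, patient.targets)
            calls = call_cnv(log2r, zero, patient.targets)
            assert [(c.gene, c.state, c.n_targets) for c in calls] == [
                (c.gene, c.state, c.n_targets) for c in full
            ]

    def test_male_x_baseline_adjustment(self):
        """A male X gene at its constitutive single copy is not a deletion."""
        patient = simulate_patient(
            SimulationConfig(seed=29, mean_depth=500), events=[CnvEvent("G040", 1)]
        )
        log2r = normalize_depth(patient.counts, patient.background)
        expected = pd.Series(2.0, index=patient.targets.index)
        expected[patient.targets["gene"] == "G040"] = 1.0  # chrX in a male
        calls = call_cnv(log2r, [], patient.targets, expected_cn=expected)
        assert calls == []


class TestParameterRecovery:
    def test_recall_and_precision_over_seeded_simulations(self):
        """100 single-event simulations at depth >= 300: recall and
        precision both >= 0.95 at default parameters."""
        rng = np.random.default_rng(2024)
        tp = fp = fn = 0
        for seed in range(100):
            state = int(rng.choice([0, 1, 3]))
            first = int(rng.integers(0, 5))
            last = first + int(rng.integers(0, 6))  # 1-10 targets
            gene = f"G{int(rng.integers(1, 51)):03d}"
            event = CnvEvent(gene, state, first, last)
            patient = simulate_patient(
                SimulationConfig(seed=seed, mean_depth=350), events=[event]
            )
            log2r = normalize_depth(patient.counts, patient.background)
            zero = detect_zero_coverage(patient.counts, patient.background,
                                        patient.targets)
            calls = call_cnv(log2r, zero, patient.targets)
            matched = [
                c for c in calls
                if c.gene == gene and c.state == state
                and c.first_target == f"{gene}_t{first}"
                and c.last_target == f"{gene}_t{last}"
            ]
            tp += bool(matched)
            fn += not matched
            fp += len(calls) - len(matched)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95, (tp, fn, fp)
        assert precision >= 0.95, (tp, fn, fp)
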