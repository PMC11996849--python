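"""Marker-discovery tests: probe harmonisation, the three-criterion DMR
screen, the one-hot plasma transform, and logistic marker selection."""

import numpy as np
import pandas as pd
import pytest

from methpanel import (
    GenomicRegion,
    MethylMatrix,
    ProbeRecord,
    harmonize_probes,
    onehot_transform,
    screen_dmrs,
    select_markers,
)
from methpanel.core import ValidationError
from methpanel.discovery import dmr_table
from methpanel.simulate import DiscoverySpec, generate_discovery_data


def probe(pid, chrom, start, end, platform="450K"):
    return ProbeRecord(pid, platform, GenomicRegion(chrom, start, end))


class TestHarmonizeProbes:
    def test_gap_at_limit_matches(self):
        a = [probe("a1", "chr1", 100, 250)]
        b = [probe("b1", "chr1", 400, 500, "GG")]
        assert len(harmonize_probes(a, b, max_gap=150)) == 1

    def test_gap_over_limit_does_not_match(self):
        a = [probe("a1", "chr1", 100, 250)]
        b = [probe("b1", "chr1", 401, 500, "GG")]
        assert harmonize_probes(a, b, max_gap=150) == []

    def test_overlap_matches(self):
        a = [probe("a1", "chr1", 100, 250)]
        b = [probe("b1", "chr1", 200, 300, "GG")]
        assert len(harmonize_probes(a, b)) == 1

    def test_different_chromosomes_never_match(self):
        a = [probe("a1", "chr1", 100, 250)]
        b = [probe("b1", "chr2", 100, 250, "GG")]
        assert harmonize_probes(a, b) == []

    def test_symmetric_pair_set(self):
        rng = np.random.default_rng(4)
        a = [probe(f"a{i}", f"chr{rng.integers(1, 3)}",
                   int(s), int(s) + 100)
             for i, s in enumerate(rng.integers(0, 5000, size=25))]
        b = [probe(f"b{i}", f"chr{rng.integers(1, 3)}",
                   int(s), int(s) + 100, "GG")
             for i, s in enumerate(rng.integers(0, 5000, size=25))]
        ab = {(p.probe_id, q.probe_id) for p, q in harmonize_probes(a, b)}
        ba = {(q.probe_id, p.probe_id) for p, q in harmonize_probes(b, a)}
        assert ab == ba

    def test_probe_may_pair_repeatedly(self):
        a = [probe("a1", "chr1", 1000, 1100)]
        b = [probe(f"b{i}", "chr1", 1000 + 40 * i, 1090 + 40 * i, "GG")
             for i in range(3)]
        assert len(harmonize_probes(a, b)) == 3


def matrix_from_arrays(tumor, adjacent, wbc, seed=0):
    """Assemble a MethylMatrix from per-group region x sample arrays."""
    n_regions = tumor.shape[0]
    regions = [GenomicRegion("chr1", 1000 * i, 1000 * i + 150)
               for i in range(n_regions)]
    cols, groups = {}, {}
    for name, arr in (("tumor", tumor), ("adjacent", adjacent), ("wbc", wbc)):
        for j in range(arr.shape[1]):
            sid = f"{name}{j:02d}"
            cols[sid] = arr[:, j]
            groups[sid] = name
    values = pd.DataFrame(cols, index=[r.key for r in regions])
    return MethylMatrix(regions=regions, values=values, groups=groups)


class TestScreenDmrs:
    def test_null_data_passes_nothing(self):
        rng = np.random.default_rng(0)
        tumor = rng.beta(2, 18, size=(300, 20))
        adjacent = rng.beta(2, 18, size=(300, 20))
        wbc = rng.beta(1, 19, size=(300, 10))
        res = screen_dmrs(matrix_from_arrays(tumor, adjacent, wbc))
        assert sum(r.pass_overall for r in res) == 0

    def test_planted_region_passes_all_criteria(self, small_discovery):
        _, matrix, planted = small_discovery
        res = {r.region.key: r for r in screen_dmrs(matrix)}
        for key in planted:
            r = res[key]
            assert r.pass_p and r.pass_delta and r.pass_wbc
            assert r.p_adj < 1e-2

    def test_high_wbc_background_fails_wbc_criterion(self):
        rng = np.random.default_rng(1)
        tumor = rng.beta(10, 10, size=(50, 30))  # mean 0.5
        adjacent = rng.beta(2, 18, size=(50, 30))  # mean 0.1, delta 0.4
        wbc = rng.beta(4, 16, size=(50, 20))  # mean 0.2 > 0.1
        res = screen_dmrs(matrix_from_arrays(tumor, adjacent, wbc))
        assert all(r.pass_delta for r in res)
        assert not any(r.pass_wbc for r in res)
        assert not any(r.pass_overall for r in res)

    def test_adjusted_p_dominates_raw(self, small_discovery):
        _, matrix, _ = small_discovery
        for r in screen_dmrs(matrix):
            assert r.p_adj >= r.p_raw - 1e-12

    def test_pass_set_shrinks_with_stricter_thresholds(self, small_discovery):
        _, matrix, _ = small_discovery
        loose = {r.region.key for r in screen_dmrs(matrix, alpha=1e-2)
                 if r.pass_overall}
        tight_alpha = {r.region.key for r in screen_dmrs(matrix, alpha=1e-4)
                       if r.pass_overall}
        tight_delta = {r.region.key
                       for r in screen_dmrs(matrix, min_delta=0.3)
                       if r.pass_overall}
        assert tight_alpha <= loose
        assert tight_delta <= loose

    def test_sorted_by_adjusted_p(self, small_discovery):
        _, matrix, _ = small_discovery
        res = screen_dmrs(matrix)
        padj = [r.p_adj for r in res if not np.isnan(r.p_adj)]
        assert padj == sorted(padj)

    def test_missing_group_rejected(self):
        rng = np.random.default_rng(2)
        m = matrix_from_arrays(
            rng.beta(2, 18, size=(10, 5)),
            rng.beta(2, 18, size=(10, 5)),
            rng.beta(1, 19, size=(10, 3)),
        )
        groups = {s: ("tumor" if g == "tumor" else "wbc")
                  for s, g in m.groups.items()}
        with pytest.raises(ValidationError, match="adjacent"):
            screen_dmrs(m, groups=groups)

    def test_all_missing_region_flagged_not_adjusted(self):
        rng = np.random.default_rng(3)
        tumor = rng.beta(2, 18, size=(20, 6))
        adjacent = rng.beta(2, 18, size=(20, 6))
        wbc = rng.beta(1, 19, size=(20, 4))
        tumor[0, :] = np.nan
        adjacent[0, :] = np.nan
        res = screen_dmrs(matrix_from_arrays(tumor, adjacent, wbc))
        flagged = [r for r in res if r.excluded]
        assert len(flagged) == 1
        assert np.isnan(flagged[0].p_adj)

    def test_report_table_schema(self, small_discovery):
        _, matrix, _ = small_discovery
        table = dmr_table(screen_dmrs(matrix))
        assert list(table.columns) == [
            "region", "p_raw", "p_adj", "delta_t2n", "mean_wbc",
            "pass_p", "pass_delta", "pass_wbc", "pass_overall",
        ]


def plasma_matrix(case_values, control_values):
    """region x sample plasma matrix from two arrays."""
    n_regions = case_values.shape[0]
    regions = [GenomicRegion("chr2", 500 * i, 500 * i + 150)
               for i in range(n_regions)]
    cols, groups = {}, {}
    for j in range(case_values.shape[1]):
        cols[f"case{j:03d}"] = case_values[:, j]
        groups[f"case{j:03d}"] = "plasma_case"
    for j in range(control_values.shape[1]):
        cols[f"ctrl{j:03d}"] = control_values[:, j]
        groups[f"ctrl{j:03d}"] = "plasma_control"
    values = pd.DataFrame(cols, index=[r.key for r in regions])
    return MethylMatrix(regions=regions, values=values, groups=groups)


class TestOnehotTransform:
    def test_degenerate_constant_controls(self):
        controls = np.full((3, 25), 0.07)
        cases = np.array([[0.07], [0.05], [0.09]])
        m = plasma_matrix(cases, controls)
        oh = onehot_transform(m, [s for s in m.sample_ids if s.startswith("ctrl")])
        assert (oh.thresholds == 0.07).all()
        # at-threshold and below-threshold levels are not detected
        assert oh.signals["case000"].tolist() == [0.0, 0.0, 0.09]

    def test_linear_interpolation_percentile(self):
        # 100 evenly spread control values 0.01..0.10 -> 95th pct 0.0955
        controls = np.tile(np.linspace(0.01, 0.10, 100), (1, 1))
        cases = np.array([[0.15, 0.05]])
        m = plasma_matrix(cases, controls)
        oh = onehot_transform(m, [s for s in m.sample_ids if s.startswith("ctrl")])
        assert oh.thresholds.iloc[0] == pytest.approx(0.0955)
        assert oh.signals.loc[:, "case000"].iloc[0] == pytest.approx(0.15)
        assert oh.signals.loc[:, "case001"].iloc[0] == 0.0

    def test_control_detection_rate_bounded(self):
        rng = np.random.default_rng(8)
        n_controls = 60
        controls = rng.beta(1, 19, size=(40, n_controls))
        cases = rng.beta(1, 19, size=(40, 10))
        m = plasma_matrix(cases, controls)
        ctrl_ids = [s for s in m.sample_ids if s.startswith("ctrl")]
        oh = onehot_transform(m, ctrl_ids)
        rate = oh.detected[ctrl_ids].mean(axis=1)
        assert (rate <= 0.05 + 1 / n_controls + 1e-12).all()

    def test_detected_signal_is_verbatim_level(self, small_discovery):
        _, matrix, _ = small_discovery
        plasma_ids = [s for s in matrix.sample_ids
                      if matrix.groups[s].startswith("plasma")]
        plasma = MethylMatrix(
            regions=matrix.regions,
            values=matrix.values[plasma_ids],
            groups={s: matrix.groups[s] for s in plasma_ids},
        )
        controls = [s for s in plasma_ids
                    if matrix.groups[s] == "plasma_control"]
        oh = onehot_transform(plasma, controls)
        detected = oh.detected.to_numpy()
        assert np.array_equal(
            oh.signals.to_numpy()[detected],
            plasma.values.to_numpy()[detected],
        )
        assert (oh.signals.to_numpy()[~detected] == 0).all()

    def test_idempotent_on_nonzero_pattern(self):
        rng = np.random.default_rng(9)
        controls = rng.beta(1, 19, size=(30, 40))
        cases = rng.beta(2, 8, size=(30, 15))
        m = plasma_matrix(cases, controls)
        ctrl_ids = [s for s in m.sample_ids if s.startswith("ctrl")]
        oh1 = onehot_transform(m, ctrl_ids)
        m2 = MethylMatrix(regions=m.regions, values=oh1.signals, groups=m.groups)
        oh2 = onehot_transform(m2, ctrl_ids)
        case_ids = [s for s in m.sample_ids if s.startswith("case")]
        p1 = oh1.signals[case_ids].to_numpy() > 0
        p2 = oh2.signals[case_ids].to_numpy() > 0
        assert np.array_equal(p1 & p2, p2)  # never detects anew

    def test_empty_controls_rejected(self):
        m = plasma_matrix(np.array([[0.5]]), np.array([[0.1]]))
        with pytest.raises(ValidationError):
            onehot_transform(m, [])

    def test_few_controls_warn(self):
        m = plasma_matrix(np.full((2, 2), 0.5), np.full((2, 5), 0.1))
        with pytest.warns(UserWarning, match="controls"):
            onehot_transform(m, [s for s in m.sample_ids if s.startswith("ctrl")])


class TestSelectMarkers:
    def _onehot(self, matrix):
        plasma_ids = [s for s in matrix.sample_ids
                      if matrix.groups[s].startswith("plasma")]
        plasma = MethylMatrix(
            regions=matrix.regions,
            values=matrix.values[plasma_ids],
            groups={s: matrix.groups[s] for s in plasma_ids},
        )
        controls = [s for s in plasma_ids
                    if matrix.groups[s] == "plasma_control"]
        labels = {s: ("case" if matrix.groups[s] == "plasma_case" else "control")
                  for s in plasma_ids}
        return onehot_transform(plasma, controls), labels

    def test_perfect_separator_selected_first(self):
        rng = np.random.default_rng(10)
        controls = rng.beta(1, 19, size=(20, 30))
        cases = rng.beta(1, 19, size=(20, 30))
        cases[7, :] = 0.9  # one region separates perfectly
        m = plasma_matrix(cases, controls)
        oh, labels = self._onehot(m)
        model = select_markers(oh, labels, k=1)
        assert model.selected_regions == [m.regions[7].key]

    def test_planted_regions_dominate_selection(self, small_discovery):
        _, matrix, planted = small_discovery
        oh, labels = self._onehot(matrix)
        model = select_markers(oh, labels, k=5)
        assert len(set(model.selected_regions) & set(planted)) >= 4

    def test_shuffled_labels_give_chance_auc(self, small_discovery):
        """Selection on shuffled labels yields a model with held-out
        AUC ~ 0.5: train on half the samples, score the other half."""
        from sklearn.metrics import roc_auc_score

        _, matrix, _ = small_discovery
        oh, labels = self._onehot(matrix)
        rng = np.random.default_rng(0)
        ids = np.array(oh.signals.columns)
        y = np.array([1 if labels[s] == "case" else 0 for s in ids])
        aucs = []
        for _ in range(5):
            rng.shuffle(y)
            perm = rng.permutation(len(ids))
            train, test = perm[: len(ids) // 2], perm[len(ids) // 2:]
            from methpanel.discovery import OneHotMatrix

            oh_train = OneHotMatrix(
                thresholds=oh.thresholds,
                signals=oh.signals[ids[train]],
                detected=oh.detected[ids[train]],
            )
            shuffled = {s: ("case" if v else "control")
                        for s, v in zip(ids, y)}
            model = select_markers(oh_train, shuffled, k=5, seed=0)
            oh_test = OneHotMatrix(
                thresholds=oh.thresholds,
                signals=oh.signals[ids[test]],
                detected=oh.detected[ids[test]],
            )
            probs = model.predict_proba(oh_test)
            aucs.append(roc_auc_score(y[test], probs.to_numpy()))
        assert abs(np.median(aucs) - 0.5) <= 0.1

    def test_k_exceeding_candidates_rejected(self, small_discovery):
        _, matrix, _ = small_discovery
        oh, labels = self._onehot(matrix)
        with pytest.raises(ValidationError):
            select_markers(oh, labels, k=10, candidate_regions=list(oh.signals.index[:3]))

    def test_deterministic(self, small_discovery):
        _, matrix, _ = small_discovery
        oh, labels = self._onehot(matrix)
        m1 = select_markers(oh, labels, k=4, seed=1)
        m2 = select_markers(oh, labels, k=4, seed=1)
        assert m1.selected_regions == m2.selected_regions
        assert m1.coefficients == m2.coefficients


class TestFullChainNull:
    def test_null_spec_yields_uninformative_panel(self):
        """With no planted signal the selected panel cannot classify an
        independently simulated plasma cohort (held-out AUC <= 0.6)."""
        from sklearn.metrics import roc_auc_score

        def plasma_onehot(seed):
            spec = DiscoverySpec(
                n_regions=150, n_dmr=0, n_tumor=20, n_adjacent=20, n_wbc=20,
                n_plasma_case=40, n_plasma_control=40, delta_planted=0.0,
                seed=seed,
            )
            matrix, _ = generate_discovery_data(spec)
            plasma_ids = [s for s in matrix.sample_ids
                          if matrix.groups[s].startswith("plasma")]
            plasma = MethylMatrix(
                regions=matrix.regions,
                values=matrix.values[plasma_ids],
                groups={s: matrix.groups[s] for s in plasma_ids},
            )
            controls = [s for s in plasma_ids
                        if matrix.groups[s] == "plasma_control"]
            oh = onehot_transform(plasma, controls)
            labels = {
                s: ("case" if matrix.groups[s] == "plasma_case" else "control")
                for s in plasma_ids
            }
            return oh, labels

        # region coordinates differ across seeds but columns align by
        # position, so re-key the held-out signals to the training index
        oh_train, labels_train = plasma_onehot(21)
        oh_test, labels_test = plasma_onehot(22)
        model = select_markers(oh_train, labels_train, k=6)
        oh_test.signals.index = oh_train.signals.index
        probs = model.predict_proba(oh_test)
        y_test = np.array(
            [1 if labels_test[s] == "case" else 0 for s in probs.index]
        )
        auc = roc_auc_score(y_test, probs.to_numpy())
        assert auc <= 0.6
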