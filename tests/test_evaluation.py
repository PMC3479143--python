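import numpy as np
import pytest

from mrsisep import (
    ConfusionCounts,
    MetricsReport,
    ReferenceSpectra,
    SourceAssignment,
    TissueMask,
    UNDECIDED,
    VoxelGrid,
    classification_metrics,
    match_sources,
    rmse,
    source_fit,
    summarize,
)
from mrsisep.labeling import SourceLabelMap, pearson

rng = np.random.default_rng(5)

ASSIGN = SourceAssignment(tumor_source=0, nontumor_source=1)


def _label_map(labels, grid):
    labels = np.asarray(labels)
    return SourceLabelMap(grid=grid, labels=labels,
                          corr=np.zeros((labels.size, 2)))


def _case(n_tumor_correct, n_tumor, n_non_correct, n_non, n_excluded=0):
    """Build predicted/gold pairs realizing given per-class counts."""
    labels, gold = [], []
    for i in range(n_tumor):
        gold.append("T")
        labels.append(0 if i < n_tumor_correct else 1)
    for i in range(n_non):
        gold.append("N")
        labels.append(1 if i < n_non_correct else UNDECIDED)
    for _ in range(n_excluded):
        gold.append("X")
        labels.append(0)
    grid = VoxelGrid(1, len(gold))
    return (_label_map(labels, grid),
            TissueMask(grid=grid, labels=np.array(gold, dtype=object)))


class TestClassificationMetrics:
    def test_published_style_counts(self):
        # 41/41 gold-tumor and 28/30 gold-non-tumor voxels correct
        pred, gold = _case(41, 41, 28, 30)
        m = classification_metrics(pred, gold, ASSIGN)
        assert m.accuracy_tumor == pytest.approx(100.0)
        assert round(m.accuracy_nontumor, 1) == 93.3
        assert m.sensitivity == pytest.approx(1.00)
        assert round(m.specificity, 2) == 0.93
        assert (m.counts.tp, m.counts.fn, m.counts.tn, m.counts.fp) == (41, 0, 28, 2)

    def test_perfect_prediction(self):
        pred, gold = _case(10, 10, 5, 5)
        m = classification_metrics(pred, gold, ASSIGN)
        assert m.accuracy_tumor == 100.0 and m.accuracy_nontumor == 100.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_all_undecided_scores_zero(self):
        grid = VoxelGrid(1, 6)
        pred = _label_map([UNDECIDED] * 6, grid)
        gold = TissueMask(grid=grid, labels=np.array(list("TTTNNN"), dtype=object))
        m = classification_metrics(pred, gold, ASSIGN)
        assert m.accuracy_tumor == 0.0 and m.accuracy_nontumor == 0.0

    def test_excluded_voxels_never_counted(self):
        base_pred, base_gold = _case(7, 9, 4, 6)
        with_x_pred, with_x_gold = _case(7, 9, 4, 6, n_excluded=5)
        a = classification_metrics(base_pred, base_gold, ASSIGN)
        b = classification_metrics(with_x_pred, with_x_gold, ASSIGN)
        assert a == b

    def test_absent_class_reported_as_none(self):
        pred, gold = _case(5, 5, 0, 0)
        m = classification_metrics(pred, gold, ASSIGN)
        assert m.accuracy_nontumor is None and m.specificity is None

    def test_accuracy_and_rate_consistency(self):
        pred, gold = _case(13, 20, 9, 14)
        m = classification_metrics(pred, gold, ASSIGN)
        assert m.accuracy_tumor == pytest.approx(100 * m.sensitivity)
        assert m.accuracy_nontumor == pytest.approx(100 * m.specificity)


def _report(acc_t=None, acc_n=None):
    return MetricsReport(
        counts=ConfusionCounts(0, 0, 0, 0),
        accuracy_tumor=acc_t,
        accuracy_nontumor=acc_n,
        sensitivity=None if acc_t is None else acc_t / 100,
        specificity=None if acc_n is None else acc_n / 100,
    )


class TestSummarize:
    def test_accuracy_column_mean(self):
        # seven per-grid tumor accuracies averaging to 83.7 at 1 decimal
        values = [100, 91.9, 66.7, 100, 86.7, 69.8, 71.1]
        mean = summarize([_report(acc_t=v) for v in values]).accuracy_tumor
        assert round(mean, 1) == 83.7

    def test_specificity_mean_skips_absent(self):
        # six specificities (one grid has no usable non-tumor area)
        specs = [0.93, 0.92, 0.46, 0.50, 0.48, 0.47]
        reports = [_report(acc_t=80.0, acc_n=100 * s) for s in specs]
        reports.append(_report(acc_t=71.1, acc_n=None))
        mean = summarize(reports).specificity
        assert round(mean, 2) == 0.63

    def test_single_report_is_identity(self):
        r = _report(acc_t=77.0, acc_n=50.0)
        s = summarize([r])
        assert s.accuracy_tumor == 77.0 and s.accuracy_nontumor == 50.0

    def test_permutation_invariant(self):
        reports = [_report(acc_t=v, acc_n=100 - v) for v in (10.0, 50.0, 90.0)]
        a = summarize(reports)
        b = summarize(reports[::-1])
        assert a.accuracy_tumor == b.accuracy_tumor
        assert a.accuracy_nontumor == b.accuracy_nontumor

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            summarize([])


class TestSourceFit:
    def test_identical_source(self):
        ref = ReferenceSpectra(tumor_mean=np.sin(np.linspace(0, 2, 25)))
        W = np.column_stack([ref.tumor_mean, np.ones(25)])
        fit = source_fit(W, SourceAssignment(tumor_source=0), ref)
        assert fit.r_tumor == pytest.approx(1.0)
        assert fit.rmse_tumor == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset(self):
        base = np.sin(np.linspace(0, 2, 25))
        ref = ReferenceSpectra(tumor_mean=base)
        W = (base + 0.7).reshape(-1, 1)
        fit = source_fit(W, SourceAssignment(tumor_source=0), ref)
        assert fit.r_tumor == pytest.approx(1.0)
        assert fit.rmse_tumor == pytest.approx(0.7)

    def test_matches_definitions_on_random_pair(self):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        ref = ReferenceSpectra(tumor_mean=b)
        fit = source_fit(a.reshape(-1, 1), SourceAssignment(tumor_source=0), ref)
        r_brute = float(np.cov(a, b)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1)))
        assert fit.r_tumor == pytest.approx(r_brute, abs=1e-12)
        assert fit.rmse_tumor == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), abs=1e-12)

    def test_missing_nontumor_reference_omitted(self):
        ref = ReferenceSpectra(tumor_mean=np.arange(10.0))
        fit = source_fit(rng.normal(size=(10, 2)),
                         SourceAssignment(tumor_source=0, nontumor_source=1), ref)
        assert fit.r_nontumor is None and fit.rmse_nontumor is None


class TestHelpers:
    def test_pearson_matches_numpy(self):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        assert pearson(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_rmse_definition(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 0.0, 3.0])
        assert rmse(a, b) == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_match_sources_self_is_perfect(self):
        W = rng.normal(size=(30, 2))
        perm, score = match_sources(W, W)
        assert perm == (0, 1) and score == pytest.approx(1.0)

    def test_match_sources_detects_swap(self):
        W = rng.normal(size=(30, 2))
        perm, score = match_sources(W, W[:, ::-1])
        assert perm == (1, 0) and score == pytest.approx(1.0)
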