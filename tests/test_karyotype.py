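"""Karyotype inference: QC, normalization, scores, permutation null, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aneukit import (
    CountMatrix,
    QCFilterSpec,
    call_karyotypes,
    chromosome_scores,
    infer_karyotypes,
    noise_free_trisomy_matrix,
    normalize,
    per_chromosome_event_counts,
    permutation_null,
    qc_filter,
)
from aneukit.pipeline import call_metrics
from aneukit.synthetic import truth_frame


def _matrix(counts, chroms, cell_ids=None):
    counts = np.asarray(counts)
    gene_ids = [f"g{i}" for i in range(counts.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        gene_chromosome=pd.Series(list(chroms), index=gene_ids),
    )


class TestQCFilter:
    def test_gene_detection_threshold_is_strict(self):
        """A cell with 4999 detected genes is excluded at the 5000 cutoff."""
        n_genes = 5100
        counts = np.zeros((n_genes, 3), dtype=int)
        counts[:4999, 0] = 1   # 4999 detected -> excluded
        counts[:5000, 1] = 1   # exactly 5000 -> retained
        counts[:5100, 2] = 1
        m = _matrix(counts, ["1"] * n_genes)
        kept, report = qc_filter(m, QCFilterSpec())
        assert kept.cell_ids == ["c1", "c2"]
        assert report["cell_id"].tolist() == ["c0"]
        assert "genes_detected" in report["reason"].iloc[0]

    def test_mito_fraction_threshold(self):
        counts = np.array(
            [[50, 10], [50, 10], [10, 80]]  # third gene is mitochondrial
        )
        m = CountMatrix(
            counts=counts,
            gene_ids=["a", "b", "MT-x"],
            cell_ids=["ok", "bad"],
            gene_chromosome=pd.Series(["1", "2", "MT"], index=["a", "b", "MT-x"]),
        )
        spec = QCFilterSpec(min_genes_detected=0, max_mito_fraction=0.20)
        kept, report = qc_filter(m, spec)
        assert kept.cell_ids == ["ok"]        # mito 10/110 = 0.09
        assert report["cell_id"].tolist() == ["bad"]  # mito 80/100 = 0.8
        assert "mito_fraction" in report["reason"].iloc[0]

    def test_zero_mito_and_enough_genes_retained(self):
        counts = np.ones((10, 2), dtype=int)
        m = _matrix(counts, ["1"] * 10)
        kept, report = qc_filter(m, QCFilterSpec(min_genes_detected=5))
        assert kept.cell_ids == ["c0", "c1"]
        assert report.empty

    def test_planted_failing_cells_are_exactly_excluded(self, small_sim):
        _, matrix, _ = small_sim
        counts = matrix.counts.copy()
        bad = [0, 17, 63]
        for j in bad:
            counts[:, j] = 0
            counts[0, j] = 1  # 1 detected gene
        m = CountMatrix(
            counts=counts,
            gene_ids=list(matrix.gene_ids),
            cell_ids=list(matrix.cell_ids),
            gene_chromosome=matrix.gene_chromosome,
        )
        kept, report = qc_filter(m, QCFilterSpec(min_genes_detected=300))
        assert sorted(report["cell_id"]) == sorted(matrix.cell_ids[j] for j in bad)
        assert kept.n_cells == matrix.n_cells - 3

    def test_all_excluded_raises_with_spec_in_message(self):
        m = _matrix(np.ones((5, 2), dtype=int), ["1"] * 5)
        with pytest.raises(ValueError, match="min_genes_detected=5000"):
            qc_filter(m, QCFilterSpec())


class TestNormalize:
    def test_proportional_cells_become_identical(self):
        v = np.array([3, 1, 4, 1, 5])
        m = _matrix(np.column_stack([v, 2 * v, 7 * v]), ["1"] * 5)
        out = normalize(m)
        assert np.allclose(out.counts[:, 0], out.counts[:, 1])
        assert np.allclose(out.counts[:, 0], out.counts[:, 2])

    def test_single_cell_unchanged(self):
        m = _matrix(np.array([[5], [7]]), ["1", "2"])
        out = normalize(m)
        assert np.allclose(out.counts, m.counts)

    def test_totals_equal_median_library_size(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(0, 50, size=(30, 7)), ["1"] * 30)
        out = normalize(m)
        target = np.median(m.counts.sum(axis=0))
        assert np.allclose(out.counts.sum(axis=0), target)

    def test_zero_total_cell_rejected(self):
        m = _matrix(np.array([[1, 0], [1, 0]]), ["1", "1"])
        with pytest.raises(ValueError, match="zero total"):
            normalize(m)


class TestChromosomeScores:
    def test_identical_cells_have_unit_deviation(self):
        m = _matrix(np.tile([[4], [6], [2]], (1, 5)), ["1", "1", "2"])
        s = chromosome_scores(m, min_genes=1)
        assert np.allclose(s.deviation.to_numpy(), 1.0)

    def test_cell_permutation_symmetry(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, size=(40, 6))
        m = _matrix(counts, ["1"] * 20 + ["2"] * 20)
        perm = [3, 1, 5, 0, 2, 4]
        m_perm = _matrix(counts[:, perm], ["1"] * 20 + ["2"] * 20,
                         cell_ids=[f"c{j}" for j in perm])
        s = chromosome_scores(m, min_genes=1)
        s_perm = chromosome_scores(m_perm, min_genes=1)
        assert np.allclose(
            s.deviation.loc[[f"c{j}" for j in perm]].to_numpy(),
            s_perm.deviation.to_numpy(),
        )

    def test_small_chromosomes_flagged_low_confidence(self):
        m = _matrix(np.ones((30, 4), dtype=int), ["1"] * 26 + ["2"] * 4)
        s = chromosome_scores(m, min_genes=25)
        assert s.low_confidence == ["2"]
        assert "2" in s.deviation.columns  # flagged but reported

    def test_silent_chromosome_excluded_with_warning(self):
        counts = np.ones((10, 4), dtype=int)
        counts[8:] = 0  # chromosome "3" entirely silent
        m = _matrix(counts, ["1"] * 8 + ["3"] * 2)
        with pytest.warns(UserWarning, match="zero median"):
            s = chromosome_scores(m, min_genes=1)
        assert list(s.deviation.columns) == ["1"]

    def test_trisomy_deviation_matches_renormalization_closed_form(self):
        """Noise-free trisomy: r = 1.5 / (1 + 0.5 f_k) exactly."""
        m, f_k = noise_free_trisomy_matrix(
            n_cells=21, n_genes=1000, trisomy_chromosome="7",
            trisomy_cells=(0, 1), seed=3,
        )
        s = chromosome_scores(normalize(m))
        predicted = 1.5 / (1 + 0.5 * f_k)
        for cell in ("cell0000", "cell0001"):
            assert s.deviation.loc[cell, "7"] == pytest.approx(predicted, rel=1e-9)

    def test_deviation_strictly_increases_with_copy_number(self):
        """Monotonicity: more copies of a chromosome -> larger deviation."""
        m, _ = noise_free_trisomy_matrix(n_cells=21, n_genes=800, seed=4)
        chrom = m.gene_chromosome.to_numpy()
        mask = chrom == "5"
        devs = []
        for copies in (1, 2, 3, 4):
            counts = m.counts.copy()
            counts[mask, 0] = counts[mask, 0] / 1.0 * (copies / 2.0)
            m2 = CountMatrix(
                counts=counts, gene_ids=list(m.gene_ids),
                cell_ids=list(m.cell_ids), gene_chromosome=m.gene_chromosome,
            )
            devs.append(chromosome_scores(normalize(m2)).deviation.loc["cell0000", "5"])
        assert all(a < b for a, b in zip(devs, devs[1:]))


class TestPermutationNull:
    def test_matches_brute_force_recomputation_exactly(self):
        """5 cells x 3 chromosomes x 30 genes against an independent
        brute-force implementation sharing the permutation stream."""
        rng = np.random.default_rng(12)
        chroms = ["1"] * 12 + ["2"] * 10 + ["3"] * 8
        counts = rng.integers(1, 40, size=(30, 5))
        m = _matrix(counts, chroms)
        n_perm, seed = 199, 31
        p = permutation_null(m, n_perm=n_perm, seed=seed, exclude=())

        # brute force: python loops, same stream definition
        order = np.lexsort((np.arange(30), np.array(chroms)))
        sorted_chrom = np.array(chroms)[order]
        mat = counts[order].astype(float)
        uniq = sorted(set(chroms))

        def dev(x):
            out = {}
            for k in uniq:
                s = x[sorted_chrom == k].sum(axis=0)
                out[k] = s / np.median(s)
            return out

        obs = dev(mat)
        exceed = {k: np.zeros(5) for k in uniq}
        stream = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = stream.permutation(30)
            d = dev(mat[perm])
            for k in uniq:
                exceed[k] += np.abs(np.log(d[k])) >= np.abs(np.log(obs[k]))
        for k in uniq:
            expected = (1 + exceed[k]) / (1 + n_perm)
            assert np.allclose(p[k].to_numpy(), expected)

    def test_unit_deviation_has_p_one(self):
        m = _matrix(np.tile([[4], [6], [2], [9]], (1, 7)), ["1", "1", "2", "2"])
        p = permutation_null(m, n_perm=100, seed=0, exclude=())
        assert np.all(p.to_numpy() == 1.0)

    def test_minimum_attainable_p_is_smoothing_bound(self):
        m, _ = noise_free_trisomy_matrix(n_cells=21, n_genes=600, seed=6)
        p = permutation_null(normalize(m), n_perm=199, seed=1)
        assert p.loc["cell0000", "7"] == pytest.approx(1 / 200)
        assert p.to_numpy().min() >= 1 / 200

    def test_rejects_too_few_permutations(self):
        m = _matrix(np.ones((4, 3), dtype=int), ["1", "1", "2", "2"])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(m, n_perm=99)

    def test_null_pairs_uniformish_planted_pair_minimal(self):
        """Noise-free 50-cell matrix with one planted trisomy: the planted
        pair reaches the minimum p; null p-values look uniform (KS)."""
        m, _ = noise_free_trisomy_matrix(
            n_cells=49, n_genes=1000, trisomy_chromosome="3",
            trisomy_cells=(7,), seed=13,
        )
        rng = np.random.default_rng(13)
        noisy = CountMatrix(
            counts=rng.poisson(m.counts * 5),
            gene_ids=list(m.gene_ids),
            cell_ids=list(m.cell_ids),
            gene_chromosome=m.gene_chromosome,
        )
        p = permutation_null(normalize(noisy), n_perm=999, seed=17)
        assert p.loc["cell0007", "3"] == 1 / 1000
        null = p.drop(index="cell0007").to_numpy().ravel()
        ks = stats.kstest(null, "uniform")
        assert ks.pvalue > 0.01


class TestCalls:
    def _score_stub(self, dev: pd.DataFrame):
        from aneukit.karyotype import ChromosomeScoreMatrix

        return ChromosomeScoreMatrix(
            score=dev, deviation=dev,
            n_genes=pd.Series(100, index=dev.columns),
        )

    def test_unit_deviations_all_neutral_euploid(self):
        dev = pd.DataFrame(1.0, index=["a", "b"], columns=["1", "2", "3"])
        p = pd.DataFrame(1.0, index=["a", "b"], columns=["1", "2", "3"])
        calls = call_karyotypes(self._score_stub(dev), p)
        assert (calls.calls["call"] == "neutral").all()
        assert (calls.per_cell["ploidy_class"] == "euploid").all()

    def test_event_counts_drive_simple_and_complex_classes(self):
        chroms = [str(i) for i in range(1, 9)]
        dev = pd.DataFrame(1.0, index=["s", "x"], columns=chroms)
        p = pd.DataFrame(1.0, index=["s", "x"], columns=chroms)
        dev.loc["s", ["1", "2"]] = 1.6
        p.loc["s", ["1", "2"]] = 0.001
        dev.loc["x", ["1", "2", "3", "4"]] = 1.6
        dev.loc["x", "5"] = 0.4
        p.loc["x", ["1", "2", "3", "4", "5"]] = 0.001
        calls = call_karyotypes(self._score_stub(dev), p)
        assert calls.per_cell.loc["s", "n_aneuploid"] == 2
        assert calls.per_cell.loc["s", "ploidy_class"] == "simple"
        assert calls.per_cell.loc["x", "n_aneuploid"] == 5
        assert calls.per_cell.loc["x", "ploidy_class"] == "complex"
        assert (calls.calls["q"] >= calls.calls["p"]).all()

    def test_effect_size_gate_blocks_tiny_significant_deviations(self):
        dev = pd.DataFrame(
            [[1.1, 1.6]], index=["a"], columns=["1", "2"]
        )
        p = pd.DataFrame([[0.001, 0.001]], index=["a"], columns=["1", "2"])
        calls = call_karyotypes(self._score_stub(dev), p, gain_min=1.25)
        by_chrom = calls.calls.set_index("chromosome")["call"]
        assert by_chrom["1"] == "neutral"  # significant but below gain_min
        assert by_chrom["2"] == "gain"

    def test_invalid_thresholds_rejected(self):
        dev = pd.DataFrame([[1.0]], index=["a"], columns=["1"])
        p = pd.DataFrame([[1.0]], index=["a"], columns=["1"])
        with pytest.raises(ValueError):
            call_karyotypes(self._score_stub(dev), p, gain_min=0.9)
        with pytest.raises(ValueError):
            call_karyotypes(self._score_stub(dev), p, loss_max=1.2)

    def test_per_chromosome_event_counts(self):
        chroms = ["1", "7"]
        dev = pd.DataFrame(1.0, index=["a", "b"], columns=chroms)
        p = pd.DataFrame(1.0, index=["a", "b"], columns=chroms)
        dev.loc["a", "7"] = 1.8
        p.loc["a", "7"] = 0.001
        calls = call_karyotypes(self._score_stub(dev), p)
        tally = per_chromosome_event_counts(calls)
        assert tally.loc["7"].tolist() == [1, 0]
        assert tally.loc["1"].tolist() == [0, 0]
        with pytest.raises(ValueError, match="empty"):
            per_chromosome_event_counts(calls, cells=[])


class TestRecovery:
    def test_planted_aneuploidies_recovered(self, small_sim):
        """Calls on a 120-cell simulation recover the planted truth with
        high precision/recall and cell-class accuracy."""
        _, matrix, truths = small_sim
        calls, scores, _ = infer_karyotypes(
            matrix, qc=QCFilterSpec(min_genes_detected=300),
            n_perm=999, seed=5,
        )
        met = call_metrics(calls, truth_frame(truths))
        assert met["precision"] >= 0.90
        assert met["recall"] >= 0.90
        assert met["class_accuracy"] >= 0.90

    def test_all_euploid_matrix_rarely_called(self, euploid_sim):
        _, matrix, _ = euploid_sim
        calls, _, _ = infer_karyotypes(
            matrix, qc=None, n_perm=199, seed=3,
        )
        rate = (calls.calls["call"] != "neutral").mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(calls.calls))
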