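"""GRM construction, block structure, LOCO kernels and window enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import rhmscan as r


def _panel(dosages, pops=None, chroms=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                         "chrom": chroms if chroms is not None else [1] * m,
                         "bp": np.arange(1, m + 1) * 10})
    return r.GenotypePanel(dosages, np.array([f"a{i}" for i in range(n)]),
                           np.array(pops if pops is not None else ["P"] * n,
                                    dtype=object), snps)


def grm_oracle(dosages, pops, freqs_by_pop):
    """Naive double-loop VanRaden per population block (test oracle)."""
    n, m = dosages.shape
    G = np.zeros((n, n))
    for pop, p in freqs_by_pop.items():
        rows = [i for i in range(n) if pops[i] == pop]
        d = 2.0 * float(np.sum(p * (1 - p)))
        centered = np.empty((len(rows), m))
        for a, i in enumerate(rows):
            for j in range(m):
                x = dosages[i, j]
                if np.isnan(x):
                    x = 2.0 * p[j]
                centered[a, j] = x - 2.0 * p[j]
        for a, i in enumerate(rows):
            for b, k in enumerate(rows):
                G[i, k] = sum(centered[a, j] * centered[b, j]
                              for j in range(m)) / d
    return G


class TestGRM:
    def test_hand_example_two_animals(self):
        panel = _panel([[0, 2], [2, 0]])
        k = r.compute_grm(panel, freqs=[0.5, 0.5])
        assert np.allclose(k.matrix, [[2, -2], [-2, 2]], atol=1e-12)
        assert k.denominator == pytest.approx(1.0)

    def test_duplicate_animals_are_clones(self):
        rng = np.random.default_rng(4)
        row = rng.binomial(2, 0.4, 30).astype(float)
        other = rng.binomial(2, 0.4, (4, 30)).astype(float)
        panel = _panel(np.vstack([row, row, other]))
        k = r.compute_grm(panel)
        assert np.allclose(k.matrix[0], k.matrix[1], atol=1e-12)
        assert k.matrix[0, 1] == pytest.approx(k.matrix[0, 0], abs=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 1000)
        d = rng.binomial(2, p, size=(300, 1000)).astype(float)
        k = r.compute_grm(_panel(d))
        assert abs(np.mean(np.diag(k.matrix)) - 1.0) < 0.05

    def test_matches_double_loop_oracle_with_missing(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.4, (8, 15)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        pops = ["A"] * 4 + ["B"] * 4
        panel = _panel(d, pops=pops)
        k = r.compute_grm(panel)  # per-population scope
        freqs = {pop: panel.allele_freqs(rows=np.flatnonzero(
            panel.populations == pop)) for pop in ("A", "B")}
        oracle = grm_oracle(d, pops, freqs)
        # oracle builds within-population blocks; cross blocks are zero in both
        assert np.allclose(k.matrix, oracle, atol=1e-10)

    def test_pooled_additivity_over_disjoint_snp_sets(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.35, (12, 40)).astype(float)
        panel = _panel(d)
        a, b = np.arange(0, 25), np.arange(25, 40)
        ka = r.compute_grm(panel, snp_indices=a, freq_scope="pooled")
        kb = r.compute_grm(panel, snp_indices=b, freq_scope="pooled")
        kab = r.compute_grm(panel, freq_scope="pooled")
        assert np.allclose(kab.matrix * kab.denominator,
                           ka.matrix * ka.denominator
                           + kb.matrix * kb.denominator, atol=1e-10)

    def test_monomorphic_population_error_names_population(self):
        d = np.array([[0, 0], [0, 0], [1, 2], [2, 1]], dtype=float)
        panel = _panel(d, pops=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="'A'"):
            r.compute_grm(panel)

    def test_empty_subset_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            r.compute_grm(tiny_panel, snp_indices=np.array([], dtype=int))

    def test_symmetry_and_psd_after_stabilization(self, study):
        k = r.compute_grm(study["panel"])
        assert np.allclose(k.matrix, k.matrix.T, atol=1e-10)
        stabilized = k.matrix + 1e-8 * np.mean(np.diag(k.matrix)) * np.eye(
            len(k.animal_ids))
        evals = np.linalg.eigvalsh(stabilized)
        assert evals.min() > -1e-8


class TestBlockStructure:
    def test_single_population_unchanged(self, tiny_panel):
        k = r.compute_grm(tiny_panel, freq_scope="pooled")
        out = r.block_diagonalize(k, tiny_panel.populations)
        assert np.allclose(out.matrix, k.matrix)
        assert out.block_diagonal

    def test_cross_population_entries_exactly_zero(self, study):
        panel = study["panel"]
        k = r.compute_grm(panel, freq_scope="pooled")
        out = r.block_diagonalize(k, panel.populations)
        cross = panel.populations[:, None] != panel.populations[None, :]
        assert (out.matrix[cross] == 0.0).all()

    def test_frobenius_norm_equals_blockwise_norm(self, study):
        panel = study["panel"]
        k = r.block_diagonalize(r.compute_grm(panel, freq_scope="pooled"),
                                panel.populations)
        total = np.linalg.norm(k.matrix)
        blocks = 0.0
        for rows in panel.population_indices().values():
            blocks += np.linalg.norm(k.matrix[np.ix_(rows, rows)]) ** 2
        assert total == pytest.approx(np.sqrt(blocks), rel=1e-12)

    def test_per_population_scope_is_block_diagonal_by_construction(self, study):
        panel = study["panel"]
        k = r.compute_grm(panel)
        cross = panel.populations[:, None] != panel.populations[None, :]
        assert k.block_diagonal and (k.matrix[cross] == 0.0).all()


class TestLoco:
    def test_two_chromosome_complement_identity(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.4, (10, 20)).astype(float)
        panel = _panel(d, chroms=[1] * 12 + [2] * 8)
        loco = r.loco_kernel(panel, 1)
        direct = r.compute_grm(panel, snp_indices=np.arange(12, 20))
        assert np.allclose(loco.matrix, direct.matrix, atol=1e-12)
        assert loco.provenance == "loco(1)"

    def test_whole_equals_loco_plus_chromosome(self, study):
        # per-population additivity with the recorded per-block denominators
        panel = study["panel"]
        whole = r.compute_grm(panel)
        loco = r.loco_kernel(panel, 3)
        chrom = r.compute_grm(panel, snp_indices=panel.chrom_snp_indices(3))
        for pop, rows in panel.population_indices().items():
            ix = np.ix_(rows, rows)
            lhs = whole.matrix[ix] * whole.denominator[pop]
            rhs = (loco.matrix[ix] * loco.denominator[pop]
                   + chrom.matrix[ix] * chrom.denominator[pop])
            assert np.allclose(lhs, rhs, atol=1e-8)

    def test_loco_close_to_whole_when_excluded_chrom_is_small(self, study):
        panel = study["panel"]
        whole = r.compute_grm(panel)
        loco = r.loco_kernel(panel, 6)  # 300 of 1800 SNPs
        tri = np.triu_indices(panel.n_animals, k=1)
        mask = (panel.populations[tri[0]] == panel.populations[tri[1]])
        c = np.corrcoef(whole.matrix[tri][mask], loco.matrix[tri][mask])[0, 1]
        assert c > 0.9

    def test_six_distinct_kernels_with_correct_snp_counts(self, study):
        panel = study["panel"]
        for chrom in panel.chromosomes:
            k = r.loco_kernel(panel, chrom)
            assert k.n_snps == panel.n_snps - len(panel.chrom_snp_indices(chrom))

    def test_single_chromosome_rejected(self):
        d = np.random.default_rng(1).binomial(2, 0.5, (5, 6)).astype(float)
        panel = _panel(d)
        with pytest.raises(ValueError):
            r.loco_kernel(panel, 1)


class TestWindows:
    def _map(self, n_snps, chrom=1):
        return pd.DataFrame({"snp": [f"c{chrom}_{i}" for i in range(n_snps)],
                             "chrom": chrom, "bp": np.arange(1, n_snps + 1) * 100})

    def test_exact_window_size_single_window(self):
        ws = r.make_windows(self._map(100))
        assert len(ws) == 1 and (ws[0].start, ws[0].stop) == (0, 100)

    def test_250_snps_enumeration(self):
        spans = [(w.start, w.stop) for w in r.make_windows(self._map(250))]
        assert spans == [(0, 100), (50, 150), (100, 200), (150, 250)]

    def test_130_snps_tail_rule(self):
        spans = [(w.start, w.stop) for w in r.make_windows(self._map(130))]
        assert spans == [(0, 100), (50, 130)]

    def test_windows_never_span_chromosomes(self, study):
        snps = study["panel"].snps
        for w in r.make_windows(snps):
            chroms = snps["chrom"].iloc[w.start:w.stop].unique()
            assert list(chroms) == [w.chrom]

    @given(n_snps=st.integers(1, 700), window=st.integers(1, 120),
           step_frac=st.integers(1, 4))
    def test_window_cover_and_overlap_properties(self, n_snps, window, step_frac):
        step = max(1, window // step_frac)
        ws = r.make_windows(self._map(n_snps), window_size=window, step=step)
        covered = set()
        prev = None
        for w in ws:
            assert 1 <= w.n_snps <= window
            assert w.stop > (prev.stop if prev else 0)
            if prev is not None and prev.stop == prev.start + window:
                # full predecessor: overlap is window - step
                assert prev.stop - w.start == window - step
            covered.update(range(w.start, w.stop))
            prev = w
        assert covered == set(range(n_snps))

    def test_validation(self):
        with pytest.raises(ValueError):
            r.make_windows(self._map(10), window_size=0)
        with pytest.raises(ValueError):
            r.make_windows(self._map(10), window_size=10, step=20)

    def test_windows_table_layout(self, study):
        ws = r.make_windows(study["panel"].snps)
        table = r.windows_table(ws)
        assert len(table) == len(ws)
        assert list(table.columns) == ["chrom", "window", "first_snp",
                                       "last_snp", "start_bp", "end_bp",
                                       "n_snps"]

    def test_regional_kernel_is_block_diagonal(self, study):
        panel = study["panel"]
        w = r.make_windows(panel.snps)[0]
        k = r.regional_kernel(panel, w)
        cross = panel.populations[:, None] != panel.populations[None, :]
        assert k.block_diagonal and (k.matrix[cross] == 0.0).all()
        assert k.n_snps == w.n_snps
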