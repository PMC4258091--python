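"""Log transform, repeatability REML/BLUP, standardization and assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rhmscan as r
from rhmscan.reml import restricted_loglik

from conftest import seed_stream


def _records(values, animals, time_points=None, pop="P", **extra):
    n = len(values)
    df = pd.DataFrame({
        "animal_id": animals,
        "population": pop,
        "time_point": time_points if time_points is not None else [1] * n,
        "trait": "trait",
        "value": values,
    })
    for k, v in extra.items():
        df[k] = v
    return df


class TestLogTransform:
    @pytest.mark.parametrize("value,offset,expected", [
        (0.0, 1.0, 0.0),
        (np.e - 1.0, 1.0, 1.0),
        (9.0, 1.0, np.log(10.0)),
    ])
    def test_known_values(self, value, offset, expected):
        rec = _records([value], ["a1"])
        out = r.log_transform(rec, offset=offset)
        assert out["value"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_other_columns_untouched_and_negative_rejected(self):
        rec = _records([1.0, 2.0], ["a1", "a2"], sex=[1, 2])
        out = r.log_transform(rec)
        assert out["sex"].tolist() == [1, 2]
        with pytest.raises(ValueError):
            r.log_transform(_records([-1.0], ["a1"]))
        with pytest.raises(ValueError):
            r.log_transform(rec, offset=0.0)

    def test_reduces_skewness_of_lognormal_counts(self):
        for seed in seed_stream(31, 10):
            rng = np.random.default_rng(seed)
            raw = np.exp(rng.normal(3.0, 1.0, 400))
            rec = _records(raw, [f"a{i}" for i in range(400)])
            out = r.log_transform(rec)
            assert abs(stats.skew(out["value"])) < abs(stats.skew(raw))


class TestRepeatabilityModel:
    def _balanced(self, seed, n=60, m=3, sigma2_a=0.5, sigma2_e=0.5):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, np.sqrt(sigma2_a), n)
        y = (np.repeat(a, m) + rng.normal(0, np.sqrt(sigma2_e), n * m))
        animals = np.repeat([f"a{i}" for i in range(n)], m)
        return y, animals

    def test_null_variance_sits_on_boundary_with_zero_blups(self):
        # animals exchangeable with identical within-animal means: the
        # between-animal component must land on the zero boundary
        rng = np.random.default_rng(12)
        n, m = 200, 3
        e = rng.normal(0, 1, (n, m))
        y = (e - e.mean(axis=1, keepdims=True)).ravel() + 2.0
        animals = np.repeat([f"a{i}" for i in range(n)], m)
        model = r.RepeatabilityModel().fit(np.ones((n * m, 1)), y, animals)
        assert model.sigma2_animal_ < 1e-6
        assert np.abs(model.blup_).max() < 1e-4

    def test_balanced_design_blup_matches_closed_form(self):
        y, animals = self._balanced(13)
        n, m = 60, 3
        model = r.RepeatabilityModel().fit(np.ones((n * m, 1)), y, animals)
        sa, se = model.sigma2_animal_, model.sigma2_resid_
        lam = m * sa / (m * sa + se)
        ybar = pd.Series(y).groupby(np.asarray(animals)).mean()
        # GLS intercept in the balanced case is the grand mean
        expected = lam * (ybar - y.mean())
        assert np.allclose(model.blup_.loc[expected.index], expected, atol=1e-6)

    def test_reml_beats_grid_oracle(self):
        # small unbalanced instance: fitted restricted likelihood is at least
        # the best over a dense (sigma2_a, sigma2_e) grid
        rng = np.random.default_rng(14)
        animals = np.repeat([f"a{i}" for i in range(12)],
                            rng.integers(2, 6, 12))[:48]
        n = len(animals)
        a = dict(zip(sorted(set(animals)), rng.normal(0, 0.8, 12)))
        y = np.array([a[x] for x in animals]) + rng.normal(0, 0.7, n)
        X = np.ones((n, 1))
        model = r.RepeatabilityModel().fit(X, y, animals)
        _, idx = np.unique(animals, return_inverse=True)
        Z = np.eye(len(set(animals)))[idx]
        K = Z @ Z.T
        grid = np.linspace(0.05, 2.5, 50)
        best = max(restricted_loglik(y, X, [K], [sa], se)
                   for sa in grid for se in grid)
        assert model.loglik_ >= best - 1e-4
        # and the profiled likelihood agrees with the dense evaluation
        dense = restricted_loglik(y, X, [K], [model.sigma2_animal_],
                                  model.sigma2_resid_)
        assert model.loglik_ == pytest.approx(dense, abs=1e-8)

    def test_monte_carlo_recovery_of_repeatability(self):
        ests = []
        for seed in seed_stream(15, 10):
            y, animals = self._balanced(seed, n=500, m=4)
            model = r.RepeatabilityModel().fit(np.ones((2000, 1)), y, animals)
            ests.append(model.repeatability_)
        assert abs(np.mean(ests) - 0.5) < 0.05

    def test_adjusted_mean_estimator_is_unshrunk_balanced_mean(self):
        # sensitivity alternative to the BLUP: per-animal adjusted mean
        y, animals = self._balanced(16)
        rec = _records(y, animals, time_points=np.tile([1, 2, 3], 60))
        eff = r.fit_repeatability(rec, fixed_factors=(),
                                  estimator="adjusted_mean")
        ybar = pd.Series(y).groupby(np.asarray(animals)).mean()
        got = eff.table.set_index("animal_id")["effect"]
        assert np.allclose(got.loc[ybar.index], ybar - y.mean(), atol=1e-8)

    def test_zero_variance_and_confounding_raise(self):
        n = 30
        animals = np.repeat([f"a{i}" for i in range(10)], 3)
        with pytest.raises(ValueError, match="variance"):
            r.RepeatabilityModel().fit(np.ones((n, 1)), np.ones(n), animals)
        rng = np.random.default_rng(3)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), np.ones(n)])  # confounded column
        with pytest.raises(ValueError, match="rank"):
            r.RepeatabilityModel().fit(X, y, animals)


class TestStandardize:
    def _effects(self, values, pops):
        table = pd.DataFrame({"animal_id": [f"a{i}" for i in range(len(values))],
                              "population": pops, "effect": values,
                              "n_records": 1})
        return r.AnimalEffects(table=table, components={})

    def test_hand_computed_values(self):
        out = r.standardize(self._effects([1.0, 2.0, 3.0], ["P"] * 3))
        assert np.allclose(out.table["effect"],
                           [-1.2247448714, 0.0, 1.2247448714], atol=1e-9)

    def test_idempotent(self):
        once = r.standardize(self._effects([4.0, -1.0, 2.5, 0.1], ["P"] * 4))
        twice = r.standardize(once)
        assert np.allclose(once.table["effect"], twice.table["effect"],
                           atol=1e-12)

    def test_per_population_contract(self):
        out = r.standardize(self._effects([1, 2, 3, 10, 20, 30, 40],
                                          ["A"] * 3 + ["B"] * 4))
        for _, sub in out.table.groupby("population"):
            assert sub["effect"].mean() == pytest.approx(0.0, abs=1e-8)
            assert sub["effect"].std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_zero_spread_raises(self):
        with pytest.raises(ValueError):
            r.standardize(self._effects([1.0, 1.0], ["P", "P"]))


class TestAssembly:
    def _std_effects(self, pop_sizes, seed=99):
        tables = []
        rng = np.random.default_rng(seed)
        for pop, size in pop_sizes.items():
            vals = rng.normal(size=size)
            vals = (vals - vals.mean()) / vals.std()
            tables.append(pd.DataFrame({
                "animal_id": [f"{pop}_{i}" for i in range(size)],
                "population": pop, "effect": vals, "n_records": 4}))
        return r.AnimalEffects(table=pd.concat(tables, ignore_index=True),
                               components={}, standardized=True)

    def test_single_trait_equals_concatenation(self):
        eff = self._std_effects({"A": 5, "B": 4})
        order = eff.table["animal_id"].tolist()
        out = r.assemble_trait({"strongyles": eff},
                               {"A": "strongyles", "B": "strongyles"}, order)
        assert np.allclose(out.to_numpy(), eff.table["effect"].to_numpy())

    def test_remapping_changes_only_that_population(self):
        eff1 = self._std_effects({"A": 5, "B": 4})
        eff2 = self._std_effects({"A": 5, "B": 4}, seed=123)
        order = eff1.table["animal_id"].tolist()
        base = r.assemble_trait({"t1": eff1, "t2": eff2},
                                {"A": "t1", "B": "t1"}, order)
        swapped = r.assemble_trait({"t1": eff1, "t2": eff2},
                                   {"A": "t1", "B": "t2"}, order)
        a_rows = [i for i, x in enumerate(order) if x.startswith("A_")]
        b_rows = [i for i, x in enumerate(order) if x.startswith("B_")]
        assert np.allclose(base.iloc[a_rows], swapped.iloc[a_rows])
        assert not np.allclose(base.iloc[b_rows], swapped.iloc[b_rows])

    def test_output_length_matches_population_sizes(self):
        eff = self._std_effects({"A": 400, "B": 600, "C": 500})
        order = eff.table["animal_id"].tolist()
        out = r.assemble_trait({"t": eff}, {p: "t" for p in "ABC"}, order)
        assert len(out) == 1500

    def test_unmapped_population_raises(self):
        eff = self._std_effects({"A": 3, "B": 3})
        with pytest.raises(KeyError):
            r.assemble_trait({"t": eff}, {"A": "t"},
                             eff.table["animal_id"].tolist())


class TestPipeline:
    def test_pipeline_composes_the_fixed_stage_order(self):
        # log -> per-population repeatability fit -> standardize -> assemble
        rng = np.random.default_rng(7)
        rows = []
        for pop, n in (("A", 40), ("B", 30)):
            a = rng.normal(0, 0.7, n)
            for t in (1, 2, 3):
                latent = a + rng.normal(0, 0.7, n)
                for i in range(n):
                    rows.append((f"{pop}_{i}", pop, t, "trait",
                                 float(np.exp(3 + latent[i]))))
        records = pd.DataFrame(rows, columns=["animal_id", "population",
                                              "time_point", "trait", "value"])
        order = list(pd.unique(records["animal_id"]))
        out = r.animal_effect_pipeline(records, order)
        manual = r.assemble_trait(
            {"trait": r.standardize(r.fit_repeatability(r.log_transform(records)))},
            {"A": "trait", "B": "trait"}, order)
        assert np.allclose(out.to_numpy(), manual.to_numpy(), atol=1e-12)
        for pop in ("A", "B"):
            vals = out[[x.startswith(pop) for x in out.index]]
            assert vals.mean() == pytest.approx(0.0, abs=1e-8)
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-8)
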