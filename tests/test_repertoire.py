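"""BCR repertoire statistics: isotype calls, mutation loads, expansion."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from seroclone import (compare_mutation_rates, constant_region_proportions,
                       dominant_isotype, dominant_isotypes, expansion_or,
                       mutation_rate, mutation_rates)
from seroclone.repertoire import ISOTYPE_ORDER, haldane_or


class TestDominantIsotype:
    @pytest.mark.parametrize("expr, expected", [
        ({"IGHA1": 5, "IGHG1": 2}, "IGHA1"),
        ({}, "unassigned"),
        ({"IGHM": 0.0, "IGHA1": 0.0}, "unassigned"),
        ({"IGHM": 3, "IGHA1": 3}, "IGHM"),       # genomic-order tie-break
        ({"IGHA2": 1, "IGHE": 1}, "IGHE"),       # IGHE precedes IGHA2
    ])
    def test_argmax_with_tie_break(self, expr, expected):
        assert dominant_isotype(expr) == expected

    def test_vectorised_matches_scalar(self, rng):
        frame = pd.DataFrame(rng.integers(0, 4, size=(50, 9)),
                             columns=list(ISOTYPE_ORDER)).astype(float)
        vec = dominant_isotypes(frame)
        for i in range(len(frame)):
            assert vec.iloc[i] == dominant_isotype(frame.iloc[i].to_dict())


class TestMutationRate:
    def test_arithmetic(self):
        res = mutation_rate(33, 330)
        assert res["rate_per_kb"] == pytest.approx(100.0)
        assert res["log10_display"] == pytest.approx(2.0)

    def test_zero_mutations_floored_display(self):
        res = mutation_rate(0, 300)
        assert res["rate_per_kb"] == 0.0
        assert res["log10_display"] == pytest.approx(math.log10(0.5 / 0.3))

    def test_zero_length_error(self):
        with pytest.raises(ValueError):
            mutation_rate(3, 0)

    def test_vectorised_matches_scalar(self, rng):
        frame = pd.DataFrame({"v_mutation_count": rng.integers(0, 40, 30),
                              "v_length_nt": rng.integers(280, 380, 30)})
        out = mutation_rates(frame)
        for i in range(len(frame)):
            ref = mutation_rate(frame.v_mutation_count[i], frame.v_length_nt[i])
            assert out.rate_per_kb[i] == pytest.approx(ref["rate_per_kb"])
            assert out.log10_display[i] == pytest.approx(ref["log10_display"])


class TestCompareMutationRates:
    def _frame(self, a, b):
        return pd.DataFrame({
            "g": ["A"] * len(a) + ["B"] * len(b),
            "rate_per_kb": np.concatenate([a, b]),
        })

    def test_identical_groups(self, rng):
        x = rng.normal(10, 2, 40)
        out = compare_mutation_rates(self._frame(x, x), group_by="g")
        assert out.loc[0, "p"] == pytest.approx(1.0, abs=0.05)
        assert out.loc[0, "shift"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_recovered(self, rng):
        """Hodges–Lehmann estimate of a pure location shift equals the shift
        (median of pairwise differences oracle)."""
        b = rng.normal(10, 2, 60)
        a = b + 5.0
        out = compare_mutation_rates(self._frame(a, b), group_by="g")
        oracle = np.median((a[:, None] - b[None, :]).ravel())
        assert out.loc[0, "shift"] == pytest.approx(oracle) == pytest.approx(5.0)
        assert out.loc[0, "ci95_low"] <= 5.0 <= out.loc[0, "ci95_high"]

    def test_small_group_skipped_with_warning(self, rng):
        frame = self._frame(rng.normal(size=10), [1.0])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = compare_mutation_rates(frame, group_by="g")
        assert out.empty

    def test_isotype_contrast_detected_on_synthetic_cells(self, repertoire):
        """IgA1/2 cells carry heavier mutation loads than IgG1 cells."""
        cells = repertoire.cells.join(mutation_rates(repertoire.cells))
        out = compare_mutation_rates(cells, pairs=[("IGHA1", "IGHG1"),
                                                   ("IGHA2", "IGHG1")])
        assert (out["shift"] > 0).all()
        assert (out["p_adj"] < 0.05).all()


class TestExpansionOr:
    def test_worked_example_zero_cell(self):
        """A = {c1 x4, c2, c3}, B = 6 singletons -> [[4,2],[0,6]], OR inf,
        Haldane point (4.5*6.5)/(2.5*0.5) = 23.4."""
        a = ["c1"] * 4 + ["c2", "c3"]
        b = [f"s{i}" for i in range(6)]
        with pytest.warns(UserWarning, match="low-power"):
            res = expansion_or(a, b, n_downsamples=3, seed=0)
        assert math.isinf(res.or_point)
        assert res.haldane_or_full == pytest.approx(23.4)
        assert haldane_or(4, 2, 0, 6) == pytest.approx(23.4)

    def test_identical_tissues_or_one(self):
        clones = ["c1"] * 3 + ["c2"] * 2 + [f"s{i}" for i in range(15)]
        res = expansion_or(clones, list(clones), n_downsamples=5, seed=1)
        assert res.or_point == pytest.approx(1.0)
        assert res.ci95 == (pytest.approx(1.0), pytest.approx(1.0))

    def test_seeded_determinism(self, repertoire):
        cells = repertoire.cells
        tum = cells.loc[cells.tissue == "tumour", "clone_id"]
        blood = cells.loc[cells.tissue == "blood", "clone_id"]
        r1 = expansion_or(tum, blood, n_downsamples=50, seed=9, keep_samples=True)
        r2 = expansion_or(tum, blood, n_downsamples=50, seed=9, keep_samples=True)
        assert np.array_equal(r1.or_samples, r2.or_samples)
        assert r1.or_point == r2.or_point and r1.ci95 == r2.ci95

    def test_ci_width_narrows_with_more_downsamples(self, repertoire):
        """Percentile-CI width stabilises (does not blow up) as the number
        of downsamples grows."""
        cells = repertoire.cells
        tum = cells.loc[cells.tissue == "tumour", "clone_id"]
        blood = cells.loc[cells.tissue == "blood", "clone_id"]
        widths = []
        for n in (50, 400):
            res = expansion_or(tum, blood, n_downsamples=n, seed=2)
            widths.append(math.log(res.ci95[1]) - math.log(res.ci95[0]))
        assert widths[1] < widths[0] * 1.5

    def test_empty_tissue_error(self):
        with pytest.raises(ValueError):
            expansion_or([], ["c1"], n_downsamples=2, seed=0)

    def test_clonotype_unit(self):
        a = ["c1"] * 4 + ["c2", "c3"]
        b = [f"s{i}" for i in range(6)]
        with pytest.warns(UserWarning, match="low-power"):
            res = expansion_or(a, b, n_downsamples=3, seed=0, unit="clonotype")
        # clonotype table: [[1,2],[0,6]]
        assert res.haldane_or_full == pytest.approx((1.5 * 6.5) / (2.5 * 0.5))


class TestConstantRegionProportions:
    def _cells(self, calls):
        return pd.DataFrame({"dominant_isotype": calls})

    def test_extreme_proportions(self):
        out = constant_region_proportions(self._cells(["IGHM"] * 10))
        ighm = out.set_index("constant_region").loc["IGHM"]
        igha = out.set_index("constant_region").loc["IGHA1"]
        assert ighm["proportion"] == 1.0 and ighm["ci95_high"] == pytest.approx(1.0)
        assert igha["proportion"] == 0.0 and igha["ci95_low"] == pytest.approx(0.0)

    def test_wilson_closed_form(self):
        """50/100: Wilson score interval from its closed form."""
        out = constant_region_proportions(
            self._cells(["IGHA1"] * 50 + ["IGHG1"] * 50))
        row = out.set_index("constant_region").loc["IGHA1"]
        z = 1.959963984540054
        n, p = 100, 0.5
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        assert row["proportion"] == pytest.approx(0.5)
        assert row["ci95_low"] == pytest.approx(centre - half, abs=1e-9)
        assert row["ci95_high"] == pytest.approx(centre + half, abs=1e-9)

    def test_wilson_consistent_with_exact_binomial(self):
        """Wilson 95% bounds bracket probabilities whose exact binomial tail
        keeps the observation inside the central region."""
        k, n = 50, 100
        out = constant_region_proportions(
            self._cells(["IGHA1"] * k + ["IGHG1"] * (n - k)))
        row = out.set_index("constant_region").loc["IGHA1"]
        for bound in (row["ci95_low"], row["ci95_high"]):
            tail = min(binom.cdf(k, n, bound), binom.sf(k - 1, n, bound))
            assert 0.005 < tail < 0.10

    def test_proportions_sum_to_one(self, repertoire):
        out = constant_region_proportions(repertoire.cells)
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_unassigned_error(self):
        with pytest.raises(ValueError):
            constant_region_proportions(self._cells(["unassigned"] * 5))
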