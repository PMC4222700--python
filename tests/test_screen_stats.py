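"""Phenotype score, hit rule, cross-stress profiles and confirmation rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sgscreen import screen
from sgscreen.screen import (
    PhenotypeResult,
    StrainMeasurement,
    UndefinedScoreError,
    confirmation_rates,
    cross_stress_profile,
    phenotype_score,
    select_hits,
    strain_phenotype,
)


class TestPhenotypeScore:
    @pytest.mark.parametrize(
        "f_mut,f_wt,expected",
        [
            (0.0, 0.35, -100.0),   # mutant forms no SGs
            (0.175, 0.35, -50.0),  # half the wild-type fraction
            (0.70, 0.35, 100.0),   # twice the wild-type fraction
            (0.35, 0.35, 0.0),
        ],
    )
    def test_anchor_values(self, f_mut, f_wt, expected):
        assert phenotype_score(f_mut, f_wt) == pytest.approx(expected)

    def test_zero_wt_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            phenotype_score(0.1, 0.0)

    @given(
        f_mut=st.floats(0.0, 1.0),
        f_wt=st.floats(0.01, 1.0),
        c=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_free_and_monotone(self, f_mut, f_wt, c):
        s = phenotype_score(f_mut, f_wt)
        assert phenotype_score(c * f_mut, c * f_wt) == pytest.approx(s, abs=1e-9)
        assert phenotype_score(min(f_mut + 0.01, 1.0) , f_wt) >= s - 1e-12


class TestStrainPhenotype:
    def test_identical_samples_score_zero_p_one(self):
        wt = StrainMeasurement("wt", "2-DG", [0.35] * 10)
        mut = StrainMeasurement("m", "2-DG", [0.35] * 10)
        r = strain_phenotype(mut, wt)
        assert r.score == 0.0
        assert r.p_value == 1.0

    def test_zero_mutant_scores_minus_100(self):
        wt = StrainMeasurement("wt", "2-DG", [0.3, 0.35, 0.4])
        mut = StrainMeasurement("m", "2-DG", [0.0, 0.0, 0.0])
        r = strain_phenotype(mut, wt)
        assert r.score == pytest.approx(-100.0)

    def test_undefined_images_excluded(self):
        wt = StrainMeasurement("wt", "2-DG", [0.3, None, 0.4, np.nan])
        mut = StrainMeasurement("m", "2-DG", [0.35, 0.35, None])
        r = strain_phenotype(mut, wt)
        assert r.n_images == 2
        assert r.f_wt_mean == pytest.approx(0.35)

    def test_condition_mismatch_rejected(self):
        wt = StrainMeasurement("wt", "heat", [0.3, 0.4])
        mut = StrainMeasurement("m", "2-DG", [0.3, 0.4])
        with pytest.raises(ValueError, match="condition"):
            strain_phenotype(mut, wt)

    def test_score_recovery_from_binomial_sampling(self, rng):
        """True S = −50 recovered within ±2 SE from 25 reps of 80 cells."""
        wt_f, mut_f, reps, cells = 0.35, 0.175, 25, 80
        wt = StrainMeasurement(
            "wt", "2-DG", list(rng.binomial(cells, wt_f, reps) / cells)
        )
        mut = StrainMeasurement(
            "m", "2-DG", list(rng.binomial(cells, mut_f, reps) / cells)
        )
        r = strain_phenotype(mut, wt)
        assert abs(r.score - (-50.0)) <= 2 * r.score_se


class TestSelectHits:
    def _res(self, strain, s, p):
        return PhenotypeResult(strain, "2-DG", 0.0, 0.35, s, 1.0, p, 25)

    def test_threshold_semantics_are_strict(self):
        table = select_hits(
            [
                self._res("below", -19.9, 0.001),
                self._res("edge", -20.0, 0.001),
                self._res("edge_p", -30.0, 0.05),
                self._res("hit", -30.0, 0.01),
                self._res("up", 45.0, 0.001),
            ]
        )
        by = table.set_index("strain")
        assert not by.loc["below", "hit"]
        assert not by.loc["edge", "hit"]      # "exceeded 20%" is strict
        assert not by.loc["edge_p", "hit"]    # P < 0.05 is strict
        assert by.loc["hit", "hit"] and by.loc["hit", "direction"] == "decreased"
        assert by.loc["up", "hit"] and by.loc["up", "direction"] == "increased"

    def test_hit_set_monotone_in_min_abs(self, rng):
        results = [
            self._res(f"s{i}", rng.uniform(-80, 80), rng.uniform(0, 0.1))
            for i in range(100)
        ]
        n_hits = [
            int(select_hits(results, min_abs=m)["hit"].sum()) for m in (10, 20, 40, 60)
        ]
        assert n_hits == sorted(n_hits, reverse=True)

    def test_idempotent_on_hit_subset(self, rng):
        results = [
            self._res(f"s{i}", rng.uniform(-80, 80), rng.uniform(0, 0.1))
            for i in range(50)
        ]
        first = select_hits(results)
        hit_strains = set(first.loc[first["hit"], "strain"])
        again = select_hits([r for r in results if r.strain in hit_strains])
        assert set(again.loc[again["hit"], "strain"]) == hit_strains


class TestCrossStress:
    CONDS = ["2-DG", "heat", "KCl", "NaCl"]

    def _hit_table(self, cond, strains):
        rows = [
            {
                "strain": s, "condition": cond, "score": -50.0, "score_se": 5.0,
                "p_value": 0.001, "hit": True, "direction": "decreased",
            }
            for s in strains
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "strain", "condition", "score", "score_se", "p_value", "hit",
                "direction",
            ],
        )

    def test_all_condition_hit_labeled_with_full_set(self):
        tables = {c: self._hit_table(c, ["general"]) for c in self.CONDS}
        labels, counts = cross_stress_profile(tables)
        assert labels.iloc[0]["conditions"] == "+".join(sorted(self.CONDS))
        assert labels.iloc[0]["n_conditions"] == 4

    def test_nowhere_hit_excluded(self):
        tables = {c: self._hit_table(c, []) for c in self.CONDS}
        labels, counts = cross_stress_profile(tables)
        assert len(labels) == 0 and len(counts) == 0

    def test_planted_overlap_geometry_recovered(self):
        # 10 strains defective everywhere, 40 specific to the glucose stress
        general = [f"g{i}" for i in range(10)]
        specific = [f"u{i}" for i in range(40)]
        tables = {
            c: self._hit_table(c, general + (specific if c == "2-DG" else []))
            for c in self.CONDS
        }
        _, counts = cross_stress_profile(tables)
        by = counts.set_index("conditions")["n_strains"]
        assert by["2-DG"] == 40
        assert by["+".join(sorted(self.CONDS))] == 10

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cross_stress_profile({"2-DG": self._hit_table("2-DG", ["x"])})

    def test_mislabeled_table_rejected(self):
        tables = {
            "2-DG": self._hit_table("2-DG", ["x"]),
            "heat": self._hit_table("KCl", ["x"]),
        }
        with pytest.raises(ValueError, match="condition"):
            cross_stress_profile(tables)


class TestConfirmationRates:
    def test_reported_bin_rates(self):
        """Rate per bin rounds to the nearest integer percent."""
        scores, confirmed = [], []
        for center, n, k in [(-95, 8, 8), (-55, 17, 12), (-35, 21, 14)]:
            scores += [center] * n
            confirmed += [True] * k + [False] * (n - k)
        table = confirmation_rates(scores, confirmed)
        by = table.set_index("bin")
        assert by.loc["−90–−100", "rate_pct"] == 100
        assert by.loc["−50–−60", "rate_pct"] == 71
        assert by.loc["−30–−40", "rate_pct"] == 67

    def test_empty_bin_flagged(self):
        table = confirmation_rates([-95.0], [True])
        empty = table[table["n_mutants"] == 0]
        assert len(empty) > 0
        assert empty["rate_pct"].isna().all()

    def test_bins_half_open_top_closed(self):
        table = confirmation_rates([-40.0, -100.0], [True, True])
        by = table.set_index("bin")
        assert by.loc["−40–−50", "n_mutants"] == 1   # -40 belongs to [40,50)
        assert by.loc["−90–−100", "n_mutants"] == 1  # -100 included at the top
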