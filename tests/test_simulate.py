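"""Generator correctness: determinism, documented draw order, planted truth."""

import numpy as np
import pandas as pd
import pytest

from sgscreen import simulate
from sgscreen.simulate import (
    ImageSpec,
    MutabilityDesign,
    QpcrDesign,
    ScreenDesign,
    SequenceSpec,
)


class TestGenerateField:
    def test_blank_field_has_background_and_empty_truth(self):
        spec = ImageSpec(n_cells=0, seed=1)
        images, truth = simulate.generate_field(spec)
        assert truth.n_cells == 0
        assert len(truth.puncta) == 0
        assert truth.labels.max() == 0
        # background plus read noise only
        assert abs(images["SG"].mean() - spec.pixel_background) < 5

    def test_every_positive_cell_gets_exactly_one_punctum(self):
        spec = ImageSpec(
            n_cells=30, sg_positive_fraction=1.0, puncta_per_positive_cell=(1, 1),
            seed=2,
        )
        _, truth = simulate.generate_field(spec)
        counts = truth.puncta.groupby("cell_id").size()
        assert truth.n_sg_positive == 30
        assert (counts == 1).all() and len(counts) == 30

    def test_flag_count_matches_documented_stream_replay(self):
        """The SG-positive flags replay from the documented child stream."""
        spec = ImageSpec(n_cells=80, sg_positive_fraction=0.35, seed=123)
        _, truth = simulate.generate_field(spec)
        children = np.random.SeedSequence(123).spawn(5)
        replay = np.random.default_rng(children[1]).random(80) < 0.35
        assert truth.n_sg_positive == int(replay.sum())
        assert (truth.cells["sg_positive"].to_numpy() == replay).all()

    def test_equal_seeds_are_byte_identical(self):
        spec = ImageSpec(n_cells=20, seed=5, shot_noise=True,
                         second_channel=simulate.SecondChannelSpec())
        im1, t1 = simulate.generate_field(spec)
        im2, t2 = simulate.generate_field(spec)
        for ch in im1:
            assert np.array_equal(im1[ch], im2[ch])
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.puncta, t2.puncta)

    def test_puncta_inside_parent_cell_and_cells_disjoint(self):
        spec = ImageSpec(n_cells=40, sg_positive_fraction=1.0, seed=6)
        _, truth = simulate.generate_field(spec)
        cells = truth.cells.set_index("cell_id")
        for _, p in truth.puncta.iterrows():
            c = cells.loc[p["cell_id"]]
            d = np.hypot(p["row"] - c["row"], p["col"] - c["col"])
            assert d <= c["radius_px"]
        # pairwise: no two cell disks touch (1-px moat by construction)
        xy = cells[["row", "col"]].to_numpy()
        r = cells["radius_px"].to_numpy()
        dist = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        sep = r[:, None] + r[None, :] + 1
        np.fill_diagonal(dist, np.inf)
        assert (dist >= sep - 1e-9).all()

    def test_placement_failure_raises(self):
        spec = ImageSpec(width_px=64, height_px=64, n_cells=80, seed=0)
        with pytest.raises(simulate.FieldPlacementError, match="80"):
            simulate.generate_field(spec)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ImageSpec(sg_positive_fraction=1.5)


class TestGenerateScreen:
    def _design(self, strains, reps, seed=0):
        return ScreenDesign(
            strains=strains, conditions=["2-DG"], wt_name="wt",
            replicates_per_strain=reps, cells_per_image=80, seed=seed,
        )

    def test_layout_row_count(self):
        design = self._design({"wt": {"2-DG": 0.35}}, reps=3)
        layout = simulate.generate_screen(design)
        assert len(layout) == 3
        assert set(layout["strain"]) == {"wt"}

    def test_zero_fraction_mutant_has_zero_positives(self):
        design = self._design(
            {"wt": {"2-DG": 0.35}, "mutA": {"2-DG": 0.0}}, reps=5
        )
        layout = simulate.generate_screen(design)
        assert (layout.loc[layout["strain"] == "mutA", "n_true_positive"] == 0).all()

    def test_unknown_wt_is_configuration_error(self):
        with pytest.raises(ValueError, match="wild-type"):
            ScreenDesign(strains={"a": {"c": 0.1}}, conditions=["c"], wt_name="wt")

    def test_ground_truth_fraction_calibrated(self):
        """Law of large numbers: empirical fraction -> design fraction."""
        p = 0.35
        design = self._design({"wt": {"2-DG": p}}, reps=63, seed=3)  # 5040 cells
        layout = simulate.generate_screen(design)
        n_total = int(layout["n_cells"].sum())
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(layout["n_true_positive"].sum() / n_total - p) <= 3 * se

    def test_multi_strain_geometry(self):
        strains = {f"m{i}": {"2-DG": 0.2, "heat": 0.2} for i in range(9)}
        strains["wt"] = {"2-DG": 0.35, "heat": 0.35}
        design = ScreenDesign(
            strains=strains, conditions=["2-DG", "heat"], wt_name="wt",
            replicates_per_strain=25, seed=1,
        )
        layout = simulate.generate_screen(design)
        assert len(layout) == 10 * 2 * 25


class TestGenerateProteins:
    def test_planted_tract_at_recorded_coordinates(self):
        spec = SequenceSpec(
            n_proteins=1, length_range=(100, 100), lcr_tracts=[("Q", 30)], seed=4
        )
        seqs, tracts = simulate.generate_proteins(spec)
        assert len(tracts) == 1
        row = tracts.iloc[0]
        seq = seqs[row["protein_id"]]
        assert seq[row["start"] - 1 : row["end"]] == "Q" * 30

    def test_zero_tracts_gives_empty_table(self):
        seqs, tracts = simulate.generate_proteins(SequenceSpec(n_proteins=3, seed=0))
        assert len(tracts) == 0
        assert len(seqs) == 3
        assert all(set(s) <= set(simulate.AMINO_ACIDS) for s in seqs.values())

    def test_tract_table_row_geometry(self):
        # 54 proteins carrying 223 tracts total, the summary-table geometry
        spec = SequenceSpec(
            n_proteins=54,
            length_range=(400, 600),
            lcr_tracts=[("Q", 20)] * 223,
            seed=9,
        )
        _, tracts = simulate.generate_proteins(spec)
        assert len(tracts) == 223

    def test_tract_longer_than_protein_rejected(self):
        spec = SequenceSpec(
            n_proteins=1, length_range=(50, 50), lcr_tracts=[("Q", 60)], seed=0
        )
        with pytest.raises(ValueError, match="does not fit"):
            simulate.generate_proteins(spec)


class TestGenerateQpcr:
    def _design(self, folds, noise=0.0, e=2.0):
        return QpcrDesign(
            genes=["ACT1", "HSP12"], reference_gene="ACT1", strains=["wt"],
            timepoints=[0.0, 60.0],
            fold_changes={("HSP12", "wt", 0.0): 1.0, ("HSP12", "wt", 60.0): folds},
            efficiencies={"ACT1": e, "HSP12": e}, ct_noise_sd=noise, seed=1,
        )

    def test_twofold_dilution_steps_one_ct(self):
        design = QpcrDesign(
            genes=["g"], reference_gene="g", strains=["s"], timepoints=[0.0],
            fold_changes={}, efficiencies={"g": 2.0}, ct_noise_sd=0.0,
            dilution_series=(1 / 2, 1 / 4, 1 / 8, 1 / 16), replicates=1,
        )
        _, curve = simulate.generate_qpcr(design)
        ct = curve["ct"].to_numpy()
        assert np.allclose(np.diff(ct), 1.0)

    def test_planted_fold16_gives_delta_ct_4(self):
        ct, _ = simulate.generate_qpcr(self._design(16.0))
        hs = ct[ct["gene"] == "HSP12"].groupby("timepoint")["ct"].mean()
        assert hs[0.0] - hs[60.0] == pytest.approx(4.0)

    def test_reference_gene_flat(self):
        ct, _ = simulate.generate_qpcr(self._design(16.0))
        act = ct[ct["gene"] == "ACT1"].groupby("timepoint")["ct"].mean()
        assert act[0.0] == pytest.approx(act[60.0])

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            self._design(2.0, e=0.9)

    def test_nonmonotone_dilutions_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            QpcrDesign(
                genes=["g"], reference_gene="g", strains=["s"], timepoints=[0.0],
                fold_changes={}, efficiencies={"g": 2.0},
                dilution_series=(1 / 2, 1 / 2),
            )


class TestGenerateMutability:
    def test_zero_frequency_gives_zero_resistant(self):
        design = MutabilityDesign(
            frequencies={("wt", "control"): 0.0, ("wt", "heat"): 0.0}, seed=1
        )
        table = simulate.generate_mutability(design)
        assert (table["resistant_colonies"] == 0).all()

    def test_poisson_mean_recovered(self):
        # frequency 1e-6 on 1e7 plated cells -> resistant ~ Poisson(10)
        design = MutabilityDesign(
            frequencies={("wt", "control"): 1e-6, ("wt", "heat"): 1e-6},
            replicates=40, seed=2,
        )
        table = simulate.generate_mutability(design)
        mean = table["resistant_colonies"].mean()
        assert abs(mean - 10) <= 3 * np.sqrt(10 / len(table))

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            MutabilityDesign(frequencies={("wt", "control"): 1.5})
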