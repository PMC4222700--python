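#!/usr/bin/env python
"""Simulate a miniature deletion-mutant SG screen with known ground truth.

Nine strains (wild type plus eight mutants spanning true phenotype scores
from −100% to +100%) are imaged under glucose-starvation (2-DG) and heat
stress, 8 replicate fields of 40 cells each — a scaled-down version of the
full screen geometry (25 × ~80) that keeps this driver fast.  Images go to
scratch/fields (binary TIFFs); the layout and ground-truth tables go to
results/.
"""

from pathlib import Path

from sgscreen import io, simulate

ROOT = Path(__file__).resolve().parents[1]
FIELDS = ROOT / "scratch" / "fields"
RESULTS = ROOT / "results"

# true SG-positive fractions; wild type forms SGs in ~35% of cells
TRUE_FRACTIONS = {
    "wt": {"2-DG": 0.35, "heat": 0.35},
    "null-former": {"2-DG": 0.0, "heat": 0.0},        # S = -100 everywhere
    "half-former": {"2-DG": 0.175, "heat": 0.175},    # S = -50 everywhere
    "dg-specific": {"2-DG": 0.10, "heat": 0.35},      # defective in 2-DG only
    "heat-specific": {"2-DG": 0.35, "heat": 0.10},
    "mild-down": {"2-DG": 0.30, "heat": 0.30},        # S = -14, below the rule
    "neutral": {"2-DG": 0.35, "heat": 0.35},
    "over-former": {"2-DG": 0.70, "heat": 0.70},      # S = +100
    "mild-up": {"2-DG": 0.45, "heat": 0.45},
}


def main() -> None:
    design = simulate.ScreenDesign(
        strains=TRUE_FRACTIONS,
        conditions=["2-DG", "heat"],
        wt_name="wt",
        replicates_per_strain=8,
        cells_per_image=40,
        seed=2014,
    )
    layout = simulate.generate_screen(design)
    spec = simulate.ImageSpec(
        width_px=384, height_px=384, n_cells=40,
        read_noise_sd=20.0, puncta_per_positive_cell=(1, 2),
    )
    for row, images, _truth in simulate.iter_screen_fields(layout, spec):
        io.save_field(FIELDS, row["strain"], row["condition"], row["replicate"],
                      images)
    io.write_tsv(layout, RESULTS / "layout.tsv")
    n = len(layout)
    print(f"simulated {n} fields ({n // 16} strains x 2 conditions x 8 reps)")
    print(f"images in {FIELDS}, layout in {RESULTS / 'layout.tsv'}")


if __name__ == "__main__":
    main()
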