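"""Synthetic micrographs, screen designs, sequences and assay tables.

Everything downstream of this module (segmentation, punctum detection,
phenotype scoring, LCR detection, qPCR and mutability statistics) is tested
against data produced here, with full ground truth recorded.  The generator
emulates fixed-cell fluorescence fields of budding yeast: near-circular
cells rendered as soft-edged disks, diffraction-limited stress-granule
puncta as Gaussian spots, Gaussian read noise and optional Poisson shot
noise.

Randomness is drawn from per-purpose child streams of a single
``numpy.random.SeedSequence`` in a documented order (see
:func:`field_streams`), so any draw can be replayed independently — the
regenerated output is the oracle for detector tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageSpec",
    "SecondChannelSpec",
    "GroundTruth",
    "ScreenDesign",
    "SequenceSpec",
    "QpcrDesign",
    "MutabilityDesign",
    "FieldPlacementError",
    "field_streams",
    "render_cells",
    "render_puncta",
    "generate_field",
    "generate_screen",
    "iter_screen_fields",
    "generate_proteins",
    "generate_qpcr",
    "generate_mutability",
]

U16_MAX = 65535

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FieldPlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails within the retry budget."""


@dataclass(frozen=True)
class SecondChannelSpec:
    """Optional second fluorescence channel (e.g. Hsp104-GFP aggregates).

    ``coloc_prob`` is the probability that a focus in this channel is placed
    within 2 px of a first-channel punctum; the default 0 reflects spatially
    separated aggregate types.
    """

    punctum_amplitude: float = 3000.0
    punctum_sigma_px: float = 1.5
    focus_fraction: float = 0.3
    foci_per_positive_cell: tuple[int, int] = (1, 2)
    coloc_prob: float = 0.0


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic field.

    Intensities are in arbitrary camera units (a.u.); the rendered image is
    clipped to the unsigned 16-bit range.  ``sg_positive_count`` overrides
    ``sg_positive_fraction`` with an exact number of punctum-bearing cells
    (used when a screen design has already drawn the per-field truth);
    ``punctum_min_sep_px`` optionally enforces a minimum distance between
    puncta of the same cell so that well-separated oracle fields can be
    constructed.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_background: float = 400.0
    read_noise_sd: float = 20.0
    shot_noise: bool = False
    n_cells: int = 80
    cell_radius_px: tuple[float, float] = (6.0, 9.0)
    cytoplasm_intensity: float = 1200.0
    punctum_amplitude: float = 4000.0
    punctum_sigma_px: float = 1.5
    sg_positive_fraction: float = 0.35
    puncta_per_positive_cell: tuple[int, int] = (1, 2)
    second_channel: SecondChannelSpec | None = None
    seed: int = 0
    sg_positive_count: int | None = None
    punctum_min_sep_px: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sg_positive_fraction <= 1.0:
            raise ValueError("sg_positive_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        lo, hi = self.cell_radius_px
        if not 0 < lo <= hi:
            raise ValueError("cell_radius_px must satisfy 0 < min <= max")
        lo, hi = self.puncta_per_positive_cell
        if not 1 <= lo <= hi:
            raise ValueError("puncta_per_positive_cell must satisfy 1 <= min <= max")
        if self.sg_positive_count is not None and not (
            0 <= self.sg_positive_count <= self.n_cells
        ):
            raise ValueError("sg_positive_count must lie in [0, n_cells]")


@dataclass
class GroundTruth:
    """Per-cell and per-punctum truth of one generated field.

    ``cells`` columns: cell_id, row, col, radius_px, sg_positive.
    ``puncta`` columns: cell_id, channel, row, col, amplitude.
    ``labels`` is the true cell label map (0 = background).
    """

    cells: pd.DataFrame
    puncta: pd.DataFrame
    labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sg_positive(self) -> int:
        return int(self.cells["sg_positive"].sum())


# Order of child streams spawned from SeedSequence(seed); documented so tests
# can replay any single draw stage.
_STREAMS = ("placement", "flags", "puncta", "channel2", "noise")


def field_streams(seed: int) -> dict[str, np.random.Generator]:
    """Child generators for one field, keyed by draw stage.

    Stages, in spawn order: ``placement`` (cell radii and centres),
    ``flags`` (per-cell SG-positive Bernoulli draws), ``puncta`` (counts and
    positions in the SG channel), ``channel2`` (second-channel foci),
    ``noise`` (shot then read noise, per channel in output order).
    """
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _place_cells(
    spec: ImageSpec, rng: np.random.Generator, max_tries: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping (row, col) centres and radii."""
    lo, hi = spec.cell_radius_px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(spec.n_cells):
        placed = False
        for _attempt in range(max_tries):
            r = rng.uniform(lo, hi)
            row = rng.uniform(r + 1, spec.height_px - r - 1)
            col = rng.uniform(r + 1, spec.width_px - r - 1)
            ok = True
            for (pr, pc), prad in zip(centers, radii):
                # 3-px moat: masks never touch, and soft edges stay resolvable
                if (row - pr) ** 2 + (col - pc) ** 2 < (r + prad + 3.0) ** 2:
                    ok = False
                    break
            if ok:
                centers.append((row, col))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise FieldPlacementError(
                f"could not place {spec.n_cells} non-overlapping cells in a "
                f"{spec.height_px}x{spec.width_px} field"
            )
    return np.asarray(centers, dtype=float).reshape(-1, 2), np.asarray(radii)


def render_cells(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    intensity: float,
    edge_sigma_px: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render soft-edged disks; returns (float image, label map).

    Exposed separately so tests can construct deliberately overlapping blobs
    for the watershed-splitting path.
    """
    from scipy.ndimage import gaussian_filter

    img = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, ((row, col), r) in enumerate(zip(np.atleast_2d(centers), radii), start=1):
        mask = (rr - row) ** 2 + (cc - col) ** 2 <= r**2
        img[mask] = intensity
        labels[mask] = i
    if edge_sigma_px > 0:
        img = gaussian_filter(img, edge_sigma_px)
    return img, labels


def render_puncta(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Additive Gaussian spots at (row, col) positions."""
    img = np.zeros(shape, dtype=float)
    if len(positions) == 0:
        return img
    half = max(3, int(np.ceil(4 * sigma_px)))
    for (row, col), amp in zip(np.atleast_2d(positions), amplitudes):
        r0, r1 = int(row) - half, int(row) + half + 1
        c0, c1 = int(col) - half, int(col) + half + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, shape[0]), min(c1, shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma_px**2)
        )
    return img


def _sample_puncta_positions(
    center: tuple[float, float],
    radius: float,
    n: int,
    rng: np.random.Generator,
    min_sep: float | None,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform positions within 0.6×radius of the cell centre (inside the mask)."""
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(max_tries):
            rho = 0.6 * radius * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            p = (center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta))
            if min_sep is None or all(
                (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in pts
            ):
                pts.append(p)
                break
        else:  # fall back to last draw; separation is best-effort
            pts.append(p)
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def generate_field(spec: ImageSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Generate one field: ``{"SG": image, ...}`` plus full ground truth.

    The SG channel models Pab1-RFP; a second channel ("GFP") is added when
    ``spec.second_channel`` is set.  Identical seeds yield byte-identical
    output.
    """
    streams = field_streams(spec.seed)
    shape = (spec.height_px, spec.width_px)

    if spec.n_cells > 0:
        centers, radii = _place_cells(spec, streams["placement"])
    else:
        centers = np.empty((0, 2))
        radii = np.empty(0)

    if spec.sg_positive_count is not None:
        flags = np.zeros(spec.n_cells, dtype=bool)
        if spec.sg_positive_count > 0:
            idx = streams["flags"].choice(
                spec.n_cells, size=spec.sg_positive_count, replace=False
            )
            flags[idx] = True
    else:
        flags = streams["flags"].random(spec.n_cells) < spec.sg_positive_fraction

    rng_p = streams["puncta"]
    lo, hi = spec.puncta_per_positive_cell
    puncta_rows: list[tuple[int, str, float, float, float]] = []
    for i in np.flatnonzero(flags):
        n_p = int(rng_p.integers(lo, hi + 1))
        pts = _sample_puncta_positions(
            tuple(centers[i]), radii[i], n_p, rng_p, spec.punctum_min_sep_px
        )
        for row, col in pts:
            puncta_rows.append((int(i), "SG", row, col, spec.punctum_amplitude))

    ch2 = spec.second_channel
    if ch2 is not None:
        rng_2 = streams["channel2"]
        sg_pts = np.asarray(
            [(r, c) for _, _, r, c, _ in puncta_rows], dtype=float
        ).reshape(-1, 2)
        for i in range(spec.n_cells):
            if rng_2.random() >= ch2.focus_fraction:
                continue
            n_f = int(rng_2.integers(ch2.foci_per_positive_cell[0],
                                     ch2.foci_per_positive_cell[1] + 1))
            for _ in range(n_f):
                if len(sg_pts) > 0 and rng_2.random() < ch2.coloc_prob:
                    base = sg_pts[rng_2.integers(len(sg_pts))]
                    offset = rng_2.uniform(-2, 2, size=2) / np.sqrt(2)
                    p = (base[0] + offset[0], base[1] + offset[1])
                else:
                    # keep chance foci clear of SG puncta (>2.5 px) so the
                    # planted colocalization probability stays recoverable
                    for _try in range(50):
                        rho = 0.6 * radii[i] * np.sqrt(rng_2.uniform())
                        theta = rng_2.uniform(0, 2 * np.pi)
                        p = (
                            centers[i, 0] + rho * np.sin(theta),
                            centers[i, 1] + rho * np.cos(theta),
                        )
                        if len(sg_pts) == 0 or (
                            ((sg_pts - p) ** 2).sum(axis=1).min() > 2.5**2
                        ):
                            break
                puncta_rows.append((i, "GFP", p[0], p[1], ch2.punctum_amplitude))

    puncta = pd.DataFrame(
        puncta_rows, columns=["cell_id", "channel", "row", "col", "amplitude"]
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "row": centers[:, 0] if spec.n_cells else np.empty(0),
            "col": centers[:, 1] if spec.n_cells else np.empty(0),
            "radius_px": radii,
            "sg_positive": flags,
        }
    )

    cell_img, labels = render_cells(shape, centers, radii, spec.cytoplasm_intensity)

    rng_noise = streams["noise"]
    images: dict[str, np.ndarray] = {}
    channel_names = ["SG"] + (["GFP"] if ch2 is not None else [])
    for name in channel_names:
        sub = puncta[puncta["channel"] == name]
        sigma = spec.punctum_sigma_px if name == "SG" else ch2.punctum_sigma_px
        signal = (
            spec.pixel_background
            + cell_img
            + render_puncta(
                shape,
                sub[["row", "col"]].to_numpy(),
                sub["amplitude"].to_numpy(),
                sigma,
            )
        )
        if spec.shot_noise:
            signal = rng_noise.poisson(np.clip(signal, 0, None)).astype(float)
        if spec.read_noise_sd > 0:
            signal = signal + rng_noise.normal(0, spec.read_noise_sd, shape)
        images[name] = np.clip(np.round(signal), 0, U16_MAX).astype(np.uint16)

    return images, GroundTruth(cells=cells, puncta=puncta, labels=labels)


# ---------------------------------------------------------------------------
# screen design


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a (synthetic) deletion-mutant screen.

    ``strains`` maps strain name -> {condition -> true SG-positive fraction}.
    Defaults mirror the screen geometry: 25 replicate images of ~80 cells per
    strain/condition.
    """

    strains: Mapping[str, Mapping[str, float]]
    conditions: Sequence[str]
    wt_name: str
    replicates_per_strain: int = 25
    cells_per_image: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_name not in self.strains:
            raise ValueError(f"wild-type strain {self.wt_name!r} not in strain table")
        for strain, fracs in self.strains.items():
            for cond in self.conditions:
                f = fracs[cond]
                if not 0.0 <= f <= 1.0:
                    raise ValueError(
                        f"true fraction for {strain}/{cond} outside [0, 1]: {f}"
                    )


def generate_screen(
    design: ScreenDesign, image_spec: ImageSpec | None = None
) -> pd.DataFrame:
    """Draw per-field ground truth for a whole screen; returns the layout table.

    Columns: strain, condition, replicate, field_id, seed, n_cells,
    true_fraction, n_true_positive, true_f (= n_true_positive / n_cells).
    Each field's positive-cell count is a binomial draw from the strain's
    true fraction.  Images are rendered lazily by :func:`iter_screen_fields`
    so calibration-scale designs stay cheap.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0xFACE)))
    rows = []
    fid = 0
    for strain in design.strains:
        for cond in design.conditions:
            p = design.strains[strain][cond]
            for rep in range(design.replicates_per_strain):
                k = int(rng.binomial(design.cells_per_image, p))
                rows.append(
                    {
                        "strain": strain,
                        "condition": cond,
                        "replicate": rep,
                        "field_id": fid,
                        "seed": int(rng.integers(0, 2**31 - 1)),
                        "n_cells": design.cells_per_image,
                        "true_fraction": p,
                        "n_true_positive": k,
                        "true_f": k / design.cells_per_image,
                    }
                )
                fid += 1
    return pd.DataFrame(rows)


def iter_screen_fields(
    layout: pd.DataFrame, image_spec: ImageSpec
) -> Iterator[tuple[pd.Series, dict[str, np.ndarray], GroundTruth]]:
    """Render the fields of a layout one at a time."""
    for _, row in layout.iterrows():
        spec = dataclasses.replace(
            image_spec,
            n_cells=int(row["n_cells"]),
            seed=int(row["seed"]),
            sg_positive_count=int(row["n_true_positive"]),
        )
        images, truth = generate_field(spec)
        yield row, images, truth


# ---------------------------------------------------------------------------
# protein sequences with planted low-complexity tracts


@dataclass(frozen=True)
class SequenceSpec:
    """Synthetic proteome with planted low-complexity tracts.

    ``lcr_tracts`` lists (composition alphabet, tract length) pairs to plant,
    distributed round-robin over the proteins; filler is near-uniform over
    the 20 amino acids (maximal complexity).
    """

    n_proteins: int = 10
    length_range: tuple[int, int] = (300, 600)
    lcr_tracts: Sequence[tuple[str, int]] = ()
    high_complexity_filler: bool = True
    seed: int = 0


def generate_proteins(spec: SequenceSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Return {protein id -> sequence} and the planted-tract table.

    Tract table columns: protein_id, start, end (1-based inclusive),
    alphabet, length.  A tract longer than its host protein is a
    specification error.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xAC1D)))
    aa = np.array(list(AMINO_ACIDS))
    lengths = rng.integers(
        spec.length_range[0], spec.length_range[1] + 1, size=spec.n_proteins
    )
    seqs: dict[str, list[str]] = {}
    ids = [f"P{i:04d}" for i in range(spec.n_proteins)]
    for pid, L in zip(ids, lengths):
        seqs[pid] = list(aa[rng.integers(0, 20, size=int(L))])

    tract_rows = []
    for t_idx, (alphabet, t_len) in enumerate(spec.lcr_tracts):
        pid = ids[t_idx % spec.n_proteins]
        L = len(seqs[pid])
        if t_len > L:
            raise ValueError(
                f"tract of length {t_len} does not fit protein {pid} (length {L})"
            )
        start0 = int(rng.integers(0, L - t_len + 1))
        letters = np.array(list(alphabet))
        tract = letters[rng.integers(0, len(letters), size=t_len)]
        seqs[pid][start0 : start0 + t_len] = list(tract)
        tract_rows.append(
            {
                "protein_id": pid,
                "start": start0 + 1,
                "end": start0 + t_len,
                "alphabet": alphabet,
                "length": t_len,
            }
        )
    tracts = pd.DataFrame(
        tract_rows, columns=["protein_id", "start", "end", "alphabet", "length"]
    )
    return {pid: "".join(s) for pid, s in seqs.items()}, tracts


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrDesign:
    """Synthetic real-time PCR experiment.

    ``fold_changes[(gene, strain, timepoint)]`` is the true mRNA quantity
    relative to the calibrator sample (wild type at the first timepoint);
    the reference gene must have fold 1 everywhere.  Ct values follow
    Ct = Ct0 − log(quantity)/log(E) + N(0, ct_noise_sd); the standard curve
    uses the classic dilution ladder 1/2 … 1/500.
    """

    genes: Sequence[str]
    reference_gene: str
    strains: Sequence[str]
    timepoints: Sequence[float]
    fold_changes: Mapping[tuple[str, str, float], float]
    efficiencies: Mapping[str, float]
    ct0: Mapping[str, float] | None = None
    ct_noise_sd: float = 0.1
    dilution_series: Sequence[float] = (
        1 / 2, 1 / 5, 1 / 10, 1 / 25, 1 / 50, 1 / 100, 1 / 500,
    )
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"amplification efficiency for {gene} not in (1, 2]: {e}")
        dil = list(self.dilution_series)
        if any(d <= 0 for d in dil) or any(
            b >= a for a, b in zip(dil, dil[1:])
        ):
            raise ValueError("dilution series must be positive and strictly decreasing")


def generate_qpcr(design: QpcrDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (Ct table, standard-curve table).

    Ct table columns: gene, strain, timepoint, replicate, ct.
    Standard-curve columns: gene, dilution, replicate, ct.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0xC7)))
    ct0 = dict(design.ct0 or {g: 20.0 for g in design.genes})
    rows = []
    for gene in design.genes:
        e = design.efficiencies[gene]
        for strain in design.strains:
            for t in design.timepoints:
                if gene == design.reference_gene:
                    q = 1.0
                else:
                    q = design.fold_changes[(gene, strain, t)]
                base = ct0[gene] - np.log(q) / np.log(e)
                for rep in range(design.replicates):
                    noise = rng.normal(0, design.ct_noise_sd) if design.ct_noise_sd else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "strain": strain,
                            "timepoint": t,
                            "replicate": rep,
                            "ct": base + noise,
                        }
                    )
    curve_rows = []
    for gene in design.genes:
        e = design.efficiencies[gene]
        for d in design.dilution_series:
            base = ct0[gene] - np.log(d) / np.log(e)
            for rep in range(design.replicates):
                noise = rng.normal(0, design.ct_noise_sd) if design.ct_noise_sd else 0.0
                curve_rows.append(
                    {"gene": gene, "dilution": d, "replicate": rep, "ct": base + noise}
                )
    return pd.DataFrame(rows), pd.DataFrame(curve_rows)


# ---------------------------------------------------------------------------
# mutability plating


@dataclass(frozen=True)
class MutabilityDesign:
    """Forward-mutation plating experiment (canavanine-resistance style).

    ``frequencies[(strain, treatment)]`` is the true per-cell mutation
    frequency; resistant and viable colony counts are Poisson draws from
    frequency × cells plated (after dilution).
    """

    frequencies: Mapping[tuple[str, str], float]
    treatments: Sequence[str] = ("control", "heat")
    cells_plated_selective: float = 1e7
    cells_plated_nonselective: float = 1e7
    selective_dilution_factor: float = 1.0
    nonselective_dilution_factor: float = 1e5
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for key, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mutation frequency for {key} outside [0, 1]: {f}")


def generate_mutability(design: MutabilityDesign) -> pd.DataFrame:
    """Colony-count table; frequency is recomputable from counts and dilutions.

    Columns: strain, treatment, replicate, resistant_colonies,
    selective_dilution_factor, viable_colonies, nonselective_dilution_factor.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0xCA1)))
    strains = sorted({s for s, _ in design.frequencies})
    rows = []
    for strain in strains:
        for treatment in design.treatments:
            f = design.frequencies[(strain, treatment)]
            lam_res = f * design.cells_plated_selective / design.selective_dilution_factor
            lam_via = design.cells_plated_nonselective / design.nonselective_dilution_factor
            for rep in range(design.replicates):
                rows.append(
                    {
                        "strain": strain,
                        "treatment": treatment,
                        "replicate": rep,
                        "resistant_colonies": int(rng.poisson(lam_res)),
                        "selective_dilution_factor": design.selective_dilution_factor,
                        "viable_colonies": int(rng.poisson(lam_via)),
                        "nonselective_dilution_factor": design.nonselective_dilution_factor,
                    }
                )
    return pd.DataFrame(rows)
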