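"""Statistics for the downstream assays: forward mutability and qPCR.

Mutability: the per-cell mutation frequency is estimated from selective
(canavanine) vs non-selective plating, frequency = (resistant colonies ×
selective dilution) / (viable colonies × non-selective dilution); stress
induction is the replicate-averaged fold over the untreated control, and
mutant-vs-wild-type comparisons use a two-sided Student's t-test on
log-transformed folds (logs stabilize ratio variance).

qPCR: amplification efficiency E per primer pair is fitted from a serial
dilution standard curve (Ct vs log10 dilution; E = 10^(−1/slope)), relative
expression is efficiency-corrected (Pfaffl) against a reference gene, and
time courses are reported as percent of the wild-type maximum with
per-timepoint t-tests (* p<0.05, ** p<0.01).  With E = 2 for both genes
the Pfaffl ratio reduces to plain ΔΔCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlatingRecord",
    "MutabilityResult",
    "mutation_frequency",
    "fold_induction",
    "mutability_test",
    "mutability_table",
    "pcr_efficiency",
    "relative_expression",
    "expression_table",
    "percent_of_wt_max",
]


@dataclass(frozen=True)
class PlatingRecord:
    """One replicate of a selective/non-selective plating pair."""

    strain: str
    treatment: str
    replicate: int
    resistant_colonies: int
    selective_dilution_factor: float
    viable_colonies: int
    nonselective_dilution_factor: float

    def __post_init__(self) -> None:
        if self.resistant_colonies < 0 or self.viable_colonies < 0:
            raise ValueError("colony counts must be >= 0")
        if self.selective_dilution_factor <= 0 or self.nonselective_dilution_factor <= 0:
            raise ValueError("dilution factors must be > 0")


@dataclass
class MutabilityResult:
    """Per-strain frequencies, stress/control fold and P vs wild type."""

    strain: str
    frequency_control: float
    frequency_stress: float
    fold: float
    fold_se: float
    p_vs_wt: float | None


def mutation_frequency(rec: PlatingRecord) -> float:
    """Mutants per viable cell from one plating pair.

    frequency = (resistant × selective dilution) / (viable × non-selective
    dilution); undefined (error) when no viable colonies were counted.
    """
    if rec.viable_colonies == 0:
        raise ValueError(
            f"{rec.strain}/{rec.treatment} rep {rec.replicate}: no viable colonies"
        )
    return (rec.resistant_colonies * rec.selective_dilution_factor) / (
        rec.viable_colonies * rec.nonselective_dilution_factor
    )


def fold_induction(freq_stress: float, freq_control: float) -> float:
    """Stress/control frequency ratio; undefined when the control is 0."""
    if freq_control <= 0:
        raise ValueError("control frequency is 0; fold induction undefined")
    if freq_stress < 0:
        raise ValueError("frequencies must be >= 0")
    return freq_stress / freq_control


def mutability_test(
    folds_mut: "list[float]", folds_wt: "list[float]"
) -> float:
    """Two-sided Student's t on log-transformed replicate folds.

    Non-positive folds are excluded with a warning; fewer than 2 usable
    replicates per group is an error (no degrees of freedom).
    """
    def clean(folds: list[float], name: str) -> np.ndarray:
        arr = np.asarray(folds, dtype=float)
        bad = arr <= 0
        if bad.any():
            warnings.warn(
                f"excluding {int(bad.sum())} non-positive fold(s) from {name}",
                stacklevel=2,
            )
        return np.log(arr[~bad])

    a = clean(folds_mut, "mutant")
    b = clean(folds_wt, "wild type")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 positive replicate folds per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def mutability_table(
    plating: pd.DataFrame,
    wt_name: str,
    control: str = "control",
    stress: str = "heat",
) -> pd.DataFrame:
    """Per-strain frequency, fold and P vs wild type from a plating table.

    Expects the column layout written by the mutability generator.  Folds
    are computed per replicate (stress/control pairing by replicate index)
    and averaged; P compares each mutant's replicate folds to the wild
    type's on the log scale.
    """
    def replicate_folds(strain: str) -> np.ndarray:
        folds = []
        sub = plating[plating["strain"] == strain]
        for rep in sorted(sub["replicate"].unique()):
            pair = {}
            for treatment in (control, stress):
                row = sub[(sub["treatment"] == treatment) & (sub["replicate"] == rep)]
                if len(row) != 1:
                    continue
                pair[treatment] = mutation_frequency(
                    PlatingRecord(**row.iloc[0].to_dict())
                )
            if control in pair and stress in pair and pair[control] > 0:
                folds.append(pair[stress] / pair[control])
        return np.asarray(folds)

    wt_folds = replicate_folds(wt_name)
    rows = []
    for strain in plating["strain"].unique():
        sub = plating[plating["strain"] == strain]
        freqs = {
            t: np.mean(
                [
                    mutation_frequency(PlatingRecord(**r.to_dict()))
                    for _, r in sub[sub["treatment"] == t].iterrows()
                ]
            )
            for t in (control, stress)
        }
        folds = replicate_folds(strain)
        p = (
            mutability_test(list(folds), list(wt_folds))
            if strain != wt_name and len(folds) >= 2 and len(wt_folds) >= 2
            else None
        )
        rows.append(
            {
                "strain": strain,
                "frequency_control": freqs[control],
                "frequency_stress": freqs[stress],
                "fold": folds.mean() if len(folds) else np.nan,
                "fold_se": folds.std(ddof=1) / np.sqrt(len(folds))
                if len(folds) > 1
                else np.nan,
                "p_vs_wt": p,
            }
        )
    return pd.DataFrame(rows)


def pcr_efficiency(
    standard_curve: "list[tuple[float, float]] | pd.DataFrame",
) -> tuple[float, float, float]:
    """Fit (E, slope, R²) from (dilution, Ct) pairs.

    Least-squares line of Ct vs log10(dilution); E = 10^(−1/slope).  A
    perfect two-fold ladder has slope −3.3219 and E = 2.  Needs >= 3
    dilutions spanning at least one decade.
    """
    if isinstance(standard_curve, pd.DataFrame):
        pairs = list(zip(standard_curve["dilution"], standard_curve["ct"]))
    else:
        pairs = list(standard_curve)
    dil = np.asarray([d for d, _ in pairs], dtype=float)
    ct = np.asarray([c for _, c in pairs], dtype=float)
    if (dil <= 0).any():
        raise ValueError("dilutions must be > 0")
    if len(np.unique(dil)) < 3:
        raise ValueError("need >= 3 distinct dilutions")
    x = np.log10(dil)
    if x.max() - x.min() < 1.0:
        raise ValueError("dilution series must span at least one log10 decade")
    fit = stats.linregress(x, ct)
    slope = float(fit.slope)
    return 10 ** (-1.0 / slope), slope, float(fit.rvalue**2)


def relative_expression(
    ct_target: float,
    ct_reference: float,
    e_target: float,
    e_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Efficiency-corrected (Pfaffl) expression ratio vs the calibrator.

    ratio = E_t^(ΔCt_t) / E_r^(ΔCt_r) with ΔCt = calibrator − sample.
    """
    if e_target <= 1 or e_reference <= 1:
        raise ValueError("amplification efficiencies must be > 1")
    d_t = ct_target_calibrator - ct_target
    d_r = ct_reference_calibrator - ct_reference
    return (e_target**d_t) / (e_reference**d_r)


def expression_table(
    ct: pd.DataFrame,
    reference_gene: str,
    efficiencies: "dict[str, float]",
    wt_name: str,
    calibrator_timepoint: float | None = None,
) -> pd.DataFrame:
    """Reference-normalized relative levels per replicate.

    The calibrator is the wild type at ``calibrator_timepoint`` (default:
    the earliest timepoint), using replicate-mean Cts.  Samples missing a
    reference-gene Ct are skipped with a warning.  Columns: gene, strain,
    timepoint, replicate, rel_level.
    """
    tps = sorted(ct["timepoint"].unique())
    cal_tp = calibrator_timepoint if calibrator_timepoint is not None else tps[0]
    e_ref = efficiencies[reference_gene]

    def mean_ct(gene: str, strain: str, tp: float) -> float:
        sub = ct[
            (ct["gene"] == gene) & (ct["strain"] == strain) & (ct["timepoint"] == tp)
        ]
        return float(sub["ct"].mean()) if len(sub) else np.nan

    rows = []
    for gene in ct["gene"].unique():
        if gene == reference_gene:
            continue
        cal_t = mean_ct(gene, wt_name, cal_tp)
        cal_r = mean_ct(reference_gene, wt_name, cal_tp)
        for strain in ct["strain"].unique():
            for tp in tps:
                sub = ct[
                    (ct["gene"] == gene)
                    & (ct["strain"] == strain)
                    & (ct["timepoint"] == tp)
                ]
                for _, r in sub.iterrows():
                    ref = ct[
                        (ct["gene"] == reference_gene)
                        & (ct["strain"] == strain)
                        & (ct["timepoint"] == tp)
                        & (ct["replicate"] == r["replicate"])
                    ]
                    if len(ref) != 1:
                        warnings.warn(
                            f"missing reference Ct for {gene}/{strain}/t={tp} "
                            f"rep {r['replicate']}; record skipped",
                            stacklevel=2,
                        )
                        continue
                    rows.append(
                        {
                            "gene": gene,
                            "strain": strain,
                            "timepoint": tp,
                            "replicate": r["replicate"],
                            "rel_level": relative_expression(
                                r["ct"],
                                float(ref["ct"].iloc[0]),
                                efficiencies[gene],
                                e_ref,
                                cal_t,
                                cal_r,
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def percent_of_wt_max(
    expression: pd.DataFrame, wt_name: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each gene's series to percent of the wild-type maximum.

    The wild-type maximum is the largest replicate-mean level across
    timepoints; the wild type's own maximum timepoint therefore reads
    exactly 100.  Returns (scaled table with ``pct_of_wt_max``, per-
    timepoint t-tests wt vs each mutant with significance stars:
    "*" p<0.05, "**" p<0.01).
    """
    scaled_parts = []
    test_rows = []
    for gene in expression["gene"].unique():
        sub = expression[expression["gene"] == gene].copy()
        wt = sub[sub["strain"] == wt_name]
        if not len(wt):
            raise ValueError(f"no wild-type series for gene {gene!r}")
        wt_means = wt.groupby("timepoint")["rel_level"].mean()
        wt_max = float(wt_means.max())
        if wt_max <= 0:
            raise ValueError(f"wild-type maximum for {gene!r} is 0; cannot scale")
        sub["pct_of_wt_max"] = 100.0 * sub["rel_level"] / wt_max
        scaled_parts.append(sub)
        for strain in sub["strain"].unique():
            if strain == wt_name:
                continue
            for tp in sorted(sub["timepoint"].unique()):
                a = sub[(sub["strain"] == strain) & (sub["timepoint"] == tp)][
                    "rel_level"
                ].to_numpy()
                b = wt[wt["timepoint"] == tp]["rel_level"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    p = np.nan
                elif np.ptp(a) == 0 and np.ptp(b) == 0:
                    p = 1.0 if a.mean() == b.mean() else 0.0
                else:
                    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
                test_rows.append(
                    {
                        "gene": gene,
                        "strain": strain,
                        "timepoint": tp,
                        "p_value": p,
                        "stars": stars,
                    }
                )
    scaled = pd.concat(scaled_parts, ignore_index=True)
    tests = pd.DataFrame(
        test_rows, columns=["gene", "strain", "timepoint", "p_value", "stars"]
    )
    return scaled, tests
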