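"""Normalized SG phenotype score, hit selection and cross-stress profiling.

The screen's central statistic is the phenotype score

    S = (f_mut − f_wt) / f_wt × 100  [percent]

where f is the per-image fraction of SG-positive cells averaged over
replicate images.  S = 0 means wild-type level, −100 means the mutant forms
no SGs at all, +100 means twice the wild-type fraction.  A strain is a hit
when |S| strictly exceeds 20% and a two-sided two-sample Student's t-test
on the per-image fractions gives P < 0.05 (no multiple-testing correction
at the screen stage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedScoreError",
    "StrainMeasurement",
    "PhenotypeResult",
    "phenotype_score",
    "strain_phenotype",
    "select_hits",
    "cross_stress_profile",
    "confirmation_rates",
]


class UndefinedScoreError(ValueError):
    """Wild-type formed no SGs under this condition; the score is undefined."""


@dataclass(frozen=True)
class StrainMeasurement:
    """Per-image SG-positive fractions for one strain under one condition."""

    strain: str
    condition: str
    fractions: Sequence[float | None]

    def usable(self) -> np.ndarray:
        """Fractions with undefined (None/NaN) images excluded."""
        vals = np.asarray(
            [f for f in self.fractions if f is not None], dtype=float
        )
        vals = vals[np.isfinite(vals)]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"fractions outside [0, 1] for {self.strain}")
        return vals


@dataclass
class PhenotypeResult:
    """Score, uncertainty and significance of one strain vs wild type."""

    strain: str
    condition: str
    f_mut_mean: float
    f_wt_mean: float
    score: float
    score_se: float
    p_value: float
    n_images: int


def phenotype_score(f_mut: float, f_wt: float) -> float:
    """S = (f_mut − f_wt)/f_wt × 100, in percent.

    Anchors: (0, f_wt) → −100 (mutant forms no SGs); (f_wt/2, f_wt) → −50;
    (2·f_wt, f_wt) → +100 (twice the wild-type fraction).
    """
    if f_wt <= 0:
        raise UndefinedScoreError(
            "wild-type SG-positive fraction is 0; score undefined"
        )
    if f_mut < 0:
        raise ValueError("f_mut must be >= 0")
    return (f_mut - f_wt) / f_wt * 100.0


def _ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided two-sample Student's t; identical constant samples give P=1."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def strain_phenotype(
    mut: StrainMeasurement, wt: StrainMeasurement
) -> PhenotypeResult:
    """Score a mutant against its wild-type reference for one condition.

    The score is computed from the replicate means; its standard error by
    first-order propagation of the standard errors of the two means; P by a
    two-sided two-sample Student's t-test on per-image fractions.
    """
    if mut.condition != wt.condition:
        raise ValueError(
            f"condition mismatch: {mut.condition!r} vs {wt.condition!r}"
        )
    fm = mut.usable()
    fw = wt.usable()
    if len(fm) < 2 or len(fw) < 2:
        raise ValueError("need >= 2 usable images per strain")
    m, w = fm.mean(), fw.mean()
    s = phenotype_score(m, w)
    se_m = fm.std(ddof=1) / np.sqrt(len(fm))
    se_w = fw.std(ddof=1) / np.sqrt(len(fw))
    se_s = 100.0 / w * np.sqrt(se_m**2 + (m / w) ** 2 * se_w**2)
    return PhenotypeResult(
        strain=mut.strain,
        condition=mut.condition,
        f_mut_mean=float(m),
        f_wt_mean=float(w),
        score=float(s),
        score_se=float(se_s),
        p_value=_ttest(fm, fw),
        n_images=len(fm),
    )


def select_hits(
    results: Iterable[PhenotypeResult],
    min_abs: float = 20.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hit table: hit ⇔ |S| > min_abs (strict) and P < alpha (strict).

    Columns: strain, condition, score, score_se, p_value, hit, direction
    (decreased/increased by the sign of S).
    """
    rows = []
    for r in results:
        hit = abs(r.score) > min_abs and r.p_value < alpha
        rows.append(
            {
                "strain": r.strain,
                "condition": r.condition,
                "score": r.score,
                "score_se": r.score_se,
                "p_value": r.p_value,
                "hit": hit,
                "direction": "decreased" if r.score < 0 else "increased",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain", "condition", "score", "score_se", "p_value", "hit", "direction",
        ],
    )


def cross_stress_profile(
    hit_tables: Mapping[str, pd.DataFrame],
    direction: str = "decreased",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each strain with the set of conditions where it is a hit.

    ``hit_tables`` maps condition label -> hit table from
    :func:`select_hits`.  Returns (per-strain labels, overlap counts):
    labels has columns strain/conditions (a "+"-joined sorted label) and
    n_conditions; counts aggregates strains per exact condition set, the
    numbers behind a Venn diagram.  Strains that are hits nowhere are
    excluded.  Requires >= 2 conditions; a table whose ``condition`` column
    disagrees with its key is a configuration error.
    """
    if len(hit_tables) < 2:
        raise ValueError("cross-stress profiling needs >= 2 conditions")
    memberships: dict[str, set[str]] = {}
    for cond, table in hit_tables.items():
        if len(table) and not (table["condition"] == cond).all():
            raise ValueError(f"hit table for {cond!r} carries other condition labels")
        sub = table[(table["hit"]) & (table["direction"] == direction)]
        for strain in sub["strain"]:
            memberships.setdefault(strain, set()).add(cond)
    rows = [
        {
            "strain": strain,
            "conditions": "+".join(sorted(conds)),
            "n_conditions": len(conds),
        }
        for strain, conds in sorted(memberships.items())
    ]
    labels = pd.DataFrame(rows, columns=["strain", "conditions", "n_conditions"])
    counts = (
        labels.groupby("conditions").size().rename("n_strains").reset_index()
        if len(labels)
        else pd.DataFrame(columns=["conditions", "n_strains"])
    )
    return labels, counts


def confirmation_rates(
    scores: Sequence[float],
    confirmed: Sequence[bool],
    bin_width: float = 10.0,
    bin_range: tuple[float, float] = (-100.0, -30.0),
) -> pd.DataFrame:
    """Manual-confirmation rate per phenotype-score bin.

    Bins are half-open on |S| ([30, 40), …) with the most extreme bin closed
    at 100, labeled from the extreme end like "−90–−100".  Rate is
    round(100 × confirmed/total) to the nearest integer; an empty bin gets a
    row with rate NaN (flagged undefined).
    """
    if len(scores) != len(confirmed):
        raise ValueError("scores and confirmed flags differ in length")
    scores = np.asarray(scores, dtype=float)
    confirmed = np.asarray(confirmed, dtype=bool)
    lo, hi = sorted(abs(b) for b in bin_range)  # |S| range, e.g. (30, 100)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rows = []
    for a, b in reversed(list(zip(edges[:-1], edges[1:]))):
        top = b >= hi
        mask = (np.abs(scores) >= a) & (
            np.abs(scores) <= b if top else np.abs(scores) < b
        )
        n = int(mask.sum())
        n_conf = int(confirmed[mask].sum())
        rows.append(
            {
                "bin": f"−{a:.0f}–−{b:.0f}",
                "n_mutants": n,
                "n_confirmed": n_conf,
                "rate_pct": float(round(100 * n_conf / n)) if n else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["bin", "n_mutants", "n_confirmed", "rate_pct"])
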