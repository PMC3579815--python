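"""Sensitivity-anchored benchmarking of splice-effect predictors.

Given a variants x predictors matrix of signed percent differences (natural
site, mutated vs wild-type sequence; missing cells mean the predictor did
not recognize the natural site) and per-variant in vitro truth labels, the
procedure is:

1. **informativeness** -- per predictor, the fraction of variants with a
   non-missing cell; only predictors with no missing cell are *fully
   informative*.
2. **calibration** -- per predictor, the threshold is the smallest absolute
   percent *decrease* observed for a true spliceogenic variant; by
   construction the calibrated classifier has 100% sensitivity on the
   calibration set (the comparison is inclusive so the calibrating cell
   itself is called spliceogenic).
3. **classification** -- a cell is called S (spliceogenic) iff it is a
   decrease with magnitude >= the threshold; increases and sub-threshold
   decreases are NS; missing cells stay missing.  Concordance is C/D
   against the in vitro label.
4. **specificity** -- the false-positive rate is the fraction of S calls
   among informative true-non-spliceogenic variants.

Calibrating and evaluating on the same variant set mirrors how such
benchmarks are typically reported on small clinical series; it is a
documented optimistic bias, and a leave-one-out mode is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

S_CALL = "S"
NS_CALL = "NS"
CONCORDANT = "C"
DISCORDANT = "D"


@dataclass
class PredictionMatrix:
    """Signed percent differences (variants x predictors) plus truth labels."""

    values: pd.DataFrame  # float, NaN = missing
    truth: pd.Series  # bool, indexed like values

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        missing = self.values.index.difference(self.truth.index)
        if len(missing):
            raise ValueError(f"variants without a truth label: {list(missing)}")
        self.truth = self.truth.reindex(self.values.index).astype(bool)

    @property
    def variants(self) -> list[str]:
        return list(self.values.index)

    @property
    def predictors(self) -> list[str]:
        return list(self.values.columns)


def informativeness(matrix: PredictionMatrix) -> tuple[pd.Series, list[str]]:
    """Recognized fraction per predictor and the fully informative set."""
    if len(matrix.predictors) == 0:
        raise ValueError("prediction matrix has no predictors")
    frac = matrix.values.notna().mean(axis=0)
    fully = [p for p in matrix.predictors if frac[p] == 1.0]
    return frac, fully


@dataclass
class CalibrationResult:
    """Per-predictor thresholds and benchmark bookkeeping."""

    thresholds: pd.Series  # absolute minimal spliceogenic decrease, % (NaN undefined)
    undefined: list[str] = field(default_factory=list)
    informative_fraction: pd.Series | None = None
    fully_informative: list[str] = field(default_factory=list)


def calibrate_thresholds(matrix: PredictionMatrix) -> CalibrationResult:
    """Minimal spliceogenic percent decrease per predictor (100% sensitivity).

    Predictors with no informative spliceogenic decrease get an undefined
    (NaN) threshold and are flagged.
    """
    spl = matrix.values.loc[matrix.truth]
    decreases = spl.where(spl < 0)
    thresholds = decreases.abs().min(axis=0)
    undefined = [p for p in matrix.predictors if np.isnan(thresholds[p])]
    frac, fully = informativeness(matrix)
    return CalibrationResult(
        thresholds=thresholds,
        undefined=undefined,
        informative_fraction=frac,
        fully_informative=fully,
    )


def classify(
    matrix: PredictionMatrix, thresholds: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell S/NS calls and C/D concordance against the truth labels.

    S iff the cell is a decrease with ``|value| >= threshold`` (inclusive,
    so the calibrating cell is itself S).  Score increases are never called
    spliceogenic.  Missing cells and undefined thresholds stay missing.
    """
    calls = pd.DataFrame(
        np.where(matrix.values.isna(), None, NS_CALL),
        index=matrix.values.index,
        columns=matrix.values.columns,
        dtype=object,
    )
    for p in matrix.predictors:
        thr = thresholds.get(p, np.nan)
        if np.isnan(thr):
            calls[p] = None
            continue
        col = matrix.values[p]
        is_s = (col < 0) & (col.abs() >= thr)
        calls.loc[is_s, p] = S_CALL
    truth = matrix.truth
    concordance = calls.copy()
    for p in matrix.predictors:
        col = calls[p]
        conc = np.where(
            col.isna(),
            None,
            np.where((col == S_CALL) == truth, CONCORDANT, DISCORDANT),
        )
        concordance[p] = conc
    return calls, concordance


def sensitivity(calls: pd.DataFrame, truth: pd.Series) -> pd.Series:
    """Fraction of informative true spliceogenic variants called S."""
    spl = calls.loc[truth]
    return (spl == S_CALL).sum() / spl.notna().sum()


def false_positive_rates(calls: pd.DataFrame, truth: pd.Series) -> pd.DataFrame:
    """Per-predictor FP rate among informative true non-spliceogenic variants.

    Returns columns ``rate`` (%), ``fp_num`` and ``fp_den``; the rate is NaN
    when no informative non-spliceogenic analysis exists.
    """
    neg = calls.loc[~truth.reindex(calls.index).astype(bool)]
    num = (neg == S_CALL).sum()
    den = neg.notna().sum()
    rate = 100.0 * num / den.replace(0, np.nan)
    return pd.DataFrame({"rate": rate, "fp_num": num.astype(int), "fp_den": den.astype(int)})


@dataclass
class BenchmarkResult:
    calibration: CalibrationResult
    calls: pd.DataFrame
    concordance: pd.DataFrame
    fp_rates: pd.DataFrame


def benchmark(matrix: PredictionMatrix) -> BenchmarkResult:
    """Full pipeline: calibrate, classify, measure false-positive rates."""
    calibration = calibrate_thresholds(matrix)
    calls, concordance = classify(matrix, calibration.thresholds)
    fp = false_positive_rates(calls, matrix.truth)
    return BenchmarkResult(calibration, calls, concordance, fp)


def benchmark_loo(matrix: PredictionMatrix) -> pd.DataFrame:
    """Leave-one-out variant calls: each variant is classified with
    thresholds calibrated on the remaining variants.  Diagnostic only."""
    out = {}
    for v in matrix.variants:
        rest = PredictionMatrix(matrix.values.drop(index=v), matrix.truth.drop(index=v))
        thr = calibrate_thresholds(rest).thresholds
        row = PredictionMatrix(matrix.values.loc[[v]], matrix.truth.loc[[v]])
        calls, _ = classify(row, thr)
        out[v] = calls.loc[v]
    return pd.DataFrame(out).T.reindex(matrix.values.index)


@dataclass(frozen=True)
class SiteRank:
    """Ranks of an in vitro used alternative junction among candidates."""

    junction: int
    predicted: bool
    score_rank: int | None
    distance_rank: int | None


def rank_alternative_sites(
    candidates, used_junctions: list[int], scorer: str = "cv"
) -> list[SiteRank]:
    """Rank each used junction among predicted candidates.

    ``candidates`` are alternative sites (see
    :func:`splicebench.variant_effects.find_alternative_sites`) carrying a
    ``position``, a scored ``site`` and a signed ``distance``.  Ties share
    the better (minimum) rank.  A used junction absent from the candidates
    is reported as not predicted.
    """
    if used_junctions and not candidates:
        raise ValueError("no candidates supplied for the used junctions")
    positions = [c.position for c in candidates]
    scores = np.array([c.site.score(scorer) for c in candidates])
    distances = np.abs([c.distance for c in candidates])
    score_ranks = rankdata(-scores, method="min") if candidates else np.array([])
    dist_ranks = rankdata(distances, method="min") if candidates else np.array([])
    out = []
    for j in used_junctions:
        if j not in positions:
            out.append(SiteRank(j, predicted=False, score_rank=None, distance_rank=None))
        else:
            i = positions.index(j)
            out.append(
                SiteRank(
                    j,
                    predicted=True,
                    score_rank=int(score_ranks[i]),
                    distance_rank=int(dist_ranks[i]),
                )
            )
    return out
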