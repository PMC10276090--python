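"""Polygenic transmission disequilibrium test (pTDT) on complete trios.

Each proband's composite PGS is compared with the mid-parent PGS — the
within-family expectation under Mendelian transmission. Deviations
(child − mid-parent), standardized by the SD of the mid-parent distribution
of the analyzed trios, are tested against zero with a one-sample two-sided
t-test. Because every child is compared to their own parents, the test is
immune to population stratification and other between-family confounding.
Cohorts are combined by pooling their (within-cohort standardized)
deviations and re-testing the pooled vector.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .sumstats_io import GenotypePanel

log = logging.getLogger(__name__)


@dataclass
class TrioDeviationSet:
    """Per-trio composite scores and standardized mid-parent deviations.

    ``trios`` columns: family_id, child_id, child_score, father_score,
    mother_score, midparent, deviation. Only complete trios with one proband
    per family are present.
    """

    trios: pd.DataFrame
    cohort_label: str = "cohort1"
    tie_break_seed: int = 0

    @property
    def deviations(self) -> np.ndarray:
        return self.trios["deviation"].to_numpy()

    def __len__(self) -> int:
        return len(self.trios)


@dataclass
class PTDTResult:
    n_trios: int
    mean_deviation: float
    se_deviation: float
    t_statistic: float
    pvalue: float
    cohort_label: str = ""
    fdr_pvalue: float | None = None


def select_trios(
    panel: GenotypePanel,
    composite: pd.Series,
    cohort_label: str = "cohort1",
    tie_break_seed: int = 0,
) -> TrioDeviationSet:
    """Assemble complete trios and compute standardized mid-parent deviations.

    A trio is complete when the proband and both parents have composite
    scores. Families with several probands contribute one child, chosen
    uniformly with ``tie_break_seed`` (recorded on the result so the choice
    is reproducible). Deviations are (child − midparent) / SD(midparent),
    with the sample SD taken over the retained trios.
    """
    s = panel.samples
    scores = composite.dropna()
    probands = s[(s["role"] == "proband") & s["complete_trio"]]
    rows = []
    for r in probands.itertuples():
        if r.sample_id in scores.index and r.father_id in scores.index and r.mother_id in scores.index:
            rows.append((r.family_id, r.sample_id,
                         scores[r.sample_id], scores[r.father_id], scores[r.mother_id]))
    if not rows:
        raise ValueError("no complete trios with scores for all three members")
    df = pd.DataFrame(rows, columns=["family_id", "child_id", "child_score",
                                     "father_score", "mother_score"])
    # one child per family, seeded uniform tie-break
    keep = (
        df.sample(frac=1.0, random_state=np.random.RandomState(tie_break_seed))
        .groupby("family_id", sort=True)
        .head(1)
        .sort_index()
    )
    n_dropped = len(df) - len(keep)
    if n_dropped:
        log.info("dropped %d extra probands from multi-proband families (seed %d)",
                 n_dropped, tie_break_seed)
    df = keep.reset_index(drop=True)

    df["midparent"] = (df["father_score"] + df["mother_score"]) / 2.0
    sd_mp = df["midparent"].std(ddof=1)
    if not np.isfinite(sd_mp) or sd_mp == 0:
        raise ValueError("mid-parent score SD is zero; scores are degenerate")
    df["deviation"] = (df["child_score"] - df["midparent"]) / sd_mp
    return TrioDeviationSet(trios=df, cohort_label=cohort_label, tie_break_seed=tie_break_seed)


def ptdt_test(devs: TrioDeviationSet) -> PTDTResult:
    """One-sample two-sided t-test of the mean standardized deviation against 0."""
    d = devs.deviations
    return _ttest(d, devs.cohort_label)


def combined_ptdt(devsets: list[TrioDeviationSet]) -> PTDTResult:
    """Pool per-cohort standardized deviations and re-test the combined vector.

    Each cohort's deviations keep their own mid-parent-SD standardization and
    composite scaling, so the pooled vector is unit-comparable across
    cohorts; n is the total trio count.
    """
    if len(devsets) < 2:
        raise ValueError("combined pTDT needs at least two cohorts")
    pooled = np.concatenate([ds.deviations for ds in devsets])
    label = "+".join(ds.cohort_label for ds in devsets)
    return _ttest(pooled, label)


def _ttest(d: np.ndarray, label: str) -> PTDTResult:
    n = len(d)
    if n < 2:
        raise ValueError(f"pTDT needs >= 2 trios, got {n}")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("all deviations identical; t-test undefined")
    mean = float(np.mean(d))
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PTDTResult(n_trios=n, mean_deviation=mean, se_deviation=se,
                      t_statistic=t, pvalue=p, cohort_label=label)


def ptdt_battery(results: dict[str, PTDTResult]) -> pd.DataFrame:
    """Tabulate pTDT results for a panel of scores with BH-FDR across the panel."""
    names = list(results)
    pvals = np.array([results[k].pvalue for k in names])
    fdr = bh_fdr(pvals)
    rows = []
    for name, q in zip(names, fdr):
        r = results[name]
        r.fdr_pvalue = float(q)
        rows.append({
            "pgs": name, "cohort": r.cohort_label, "n_trios": r.n_trios,
            "mean_deviation": r.mean_deviation, "se": r.se_deviation,
            "t": r.t_statistic, "p": r.pvalue, "p_fdr": r.fdr_pvalue,
        })
    return pd.DataFrame(rows)
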