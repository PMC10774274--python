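"""Quantification of the validation assays: splicing, qPCR, densitometry.

PSI (percent spliced-in) is computed from junction counts with effective
length normalization, PSI = (I/l_I) / (I/l_I + S/l_S); the group-level
difference dPSI follows the convention that positive values mean higher
inclusion in the control group.  The three-primer PCR assay reduces to the
ratio A/(A+B) of band intensities, the restriction-digest assay to the
cleaved fraction, qPCR to ddCt fold changes, and neurite outgrowth to
length-per-nucleus normalized within replicate to the wild-type group.
Group comparisons at the tiny sample sizes of these assays use an exact
Mann-Whitney U test by full enumeration, or one/two-tailed t tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpliceEvent",
    "psi",
    "delta_psi",
    "inclusion_ratio",
    "digest_isoform_fraction",
    "ddct_fold_change",
    "neurite_summary",
    "mann_whitney_exact",
    "group_test",
]


@dataclass
class SpliceEvent:
    """Inclusion/skipping junction counts with effective lengths."""

    event_id: str
    inclusion: int
    skipping: int
    inclusion_len: int
    skipping_len: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.inclusion < 0 or self.skipping < 0:
            raise ValueError("counts must be >= 0")
        if self.inclusion_len <= 0 or self.skipping_len <= 0:
            raise ValueError("effective lengths must be > 0")


def psi(event: SpliceEvent) -> float:
    """Length-normalized inclusion fraction in [0, 1]."""
    if event.inclusion + event.skipping == 0:
        raise ValueError(f"{event.event_id}: zero total junction counts")
    inc = event.inclusion / event.inclusion_len
    skp = event.skipping / event.skipping_len
    return inc / (inc + skp)


def delta_psi(group_ctrl: Sequence[SpliceEvent],
              group_case: Sequence[SpliceEvent]) -> float:
    """Mean PSI(control) - mean PSI(case); positive means higher inclusion
    in controls."""
    if not group_ctrl or not group_case:
        raise ValueError("both groups must be non-empty")
    return (float(np.mean([psi(e) for e in group_ctrl]))
            - float(np.mean([psi(e) for e in group_case])))


def inclusion_ratio(product_a: float, product_b: float) -> float:
    """Relative inclusion of the alternative exon from a two-band PCR:
    A/(A+B)."""
    if product_a < 0 or product_b < 0:
        raise ValueError("band intensities must be >= 0")
    if product_a + product_b == 0:
        raise ValueError("both band intensities are zero")
    return product_a / (product_a + product_b)


def digest_isoform_fraction(uncut: float, cut_1: float, cut_2: float) -> float:
    """Fraction of the restriction-cleaved isoform: (cut1+cut2)/total.

    The uncleaved band is the isoform lacking the restriction site; the
    cleaved doublet quantifies the isoform carrying it.
    """
    if min(uncut, cut_1, cut_2) < 0:
        raise ValueError("band intensities must be >= 0")
    total = uncut + cut_1 + cut_2
    if total == 0:
        raise ValueError("all bands are zero")
    return (cut_1 + cut_2) / total


def ddct_fold_change(ct: pd.DataFrame, calibrator_group: str,
                     target_col: str = "ct_target",
                     reference_col: str = "ct_reference",
                     group_col: str = "group") -> pd.DataFrame:
    """Per-sample ddCt fold change relative to a calibrator group.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - mean dCt of the
    calibrator group (arithmetic mean of dCt, a documented convention);
    fold = 2^(-ddCt).  The calibrator group's fold changes have geometric
    mean exactly 1.
    """
    for col in (target_col, reference_col, group_col):
        if col not in ct.columns:
            raise ValueError(f"missing column {col!r}")
    if ct[[target_col, reference_col]].isna().any().any():
        raise ValueError("missing Ct values")
    cal = ct[ct[group_col] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    out = ct.copy()
    out["dct"] = out[target_col] - out[reference_col]
    baseline = float(cal[target_col].mean() - cal[reference_col].mean())
    out["ddct"] = out["dct"] - baseline
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def neurite_summary(images: pd.DataFrame, wt_group: str,
                    group_col: str = "group",
                    replicate_col: str = "replicate",
                    length_col: str = "total_length_um",
                    nuclei_col: str = "nuclei"
                    ) -> tuple[pd.DataFrame, int]:
    """Neurite length per nucleus, normalized to wild type per replicate.

    Per image: average length = total neurite length / nuclei count (images
    with zero nuclei are excluded and counted).  Per replicate and group:
    mean of image averages.  Each group is then expressed as percent of the
    matched wild-type replicate.  Returns (summary frame, n excluded).
    """
    n_excluded = int((images[nuclei_col] <= 0).sum())
    ok = images[images[nuclei_col] > 0].copy()
    if ok.empty:
        raise ValueError("no image with a positive nuclei count")
    ok["avg_length"] = ok[length_col] / ok[nuclei_col]
    per_rep = (ok.groupby([replicate_col, group_col])["avg_length"]
               .mean().reset_index())
    wt = per_rep[per_rep[group_col] == wt_group].set_index(replicate_col)[
        "avg_length"]
    if wt.empty:
        raise ValueError(f"wild-type group {wt_group!r} absent")
    per_rep["pct_of_wt"] = [
        100.0 * row.avg_length / wt[getattr(row, replicate_col)]
        if getattr(row, replicate_col) in wt.index else float("nan")
        for row in per_rep.itertuples(index=False)
    ]
    return per_rep, n_excluded


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _u_statistic(ranks_a: Sequence[float], n1: int) -> float:
    return sum(ranks_a) - n1 * (n1 + 1) / 2


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]
                       ) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    All C(n1+n2, n1) assignments of the pooled (mid)ranks to group a are
    enumerated; the two-sided p-value is the probability, under that uniform
    null, of a U statistic at least as far from its mean n1*n2/2 as the one
    observed.  Midranks make the enumeration valid under ties (the p-value
    is then conditional on the observed tie pattern).  Restricted to
    combined n <= 20.  For complete separation at n1=3, n2=5 this gives
    p = 2/56 ~ 0.0357.
    """
    a, b = list(map(float, a)), list(map(float, b))
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("groups must be non-empty")
    if n1 + n2 > 20:
        raise ValueError("exact enumeration restricted to combined n <= 20")
    pooled = a + b
    ranks = stats.rankdata(pooled)          # midranks under ties
    u_obs = _u_statistic(ranks[:n1], n1)
    center = n1 * n2 / 2
    d_obs = abs(u_obs - center)

    total = math.comb(n1 + n2, n1)
    hits = 0
    offset = n1 * (n1 + 1) / 2
    for combo in combinations(ranks, n1):
        u = sum(combo) - offset
        if abs(u - center) >= d_obs - 1e-9:
            hits += 1
    return float(u_obs), hits / total


def group_test(values_a: Iterable[float], values_b: Iterable[float],
               test: str = "mann_whitney_exact_two_sided",
               equal_var: bool = False,
               alternative: str = "greater") -> tuple[float, float]:
    """Dispatch the small-sample group comparisons used in the figures.

    ``mann_whitney_exact_two_sided`` enumerates all arrangements (n <= 20);
    ``t_one_tailed`` / ``t_two_tailed`` run a t test, Welch by default
    (``equal_var=True`` for the pooled-variance variant).  For the one-tailed
    test ``alternative='greater'`` tests mean(a) > mean(b).
    """
    a = list(values_a)
    b = list(values_b)
    if not a or not b:
        raise ValueError("groups must be non-empty")
    if test == "mann_whitney_exact_two_sided":
        return mann_whitney_exact(a, b)
    if test == "t_one_tailed":
        res = stats.ttest_ind(a, b, equal_var=equal_var,
                              alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if test == "t_two_tailed":
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
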