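"""Intronic Retention Score (IRS) per gene and condition comparisons.

With per-feature read-depth sums, the intron density sum
I = sum(intronic coverage / intronic length) and the exon density sum
E = sum(exonic coverage / exonic length) define

    IRS = 2 * I / (E + I)

which is algebraically bounded in [0, 2] (0 = no intronic signal,
1 = equal intron/exon densities, 2 = purely intronic signal) and
invariant to rescaling all coverages. Condition ratios are taken on
epsilon-regularized scores, flags at 2 standard deviations of the
log-ratio, and the increase/decrease balance is tested with an exact
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "GeneCoverage",
    "irs",
    "irs_table",
    "irs_response",
    "ShiftReport",
    "shift_test",
]


@dataclass(frozen=True)
class GeneCoverage:
    """Per-feature lengths and summed read depths for one gene/condition."""

    gene_id: str
    exon_lengths: tuple[int, ...]
    exon_coverage: tuple[float, ...]
    intron_lengths: tuple[int, ...]
    intron_coverage: tuple[float, ...]
    condition: str = ""

    def __post_init__(self):
        if len(self.exon_lengths) != len(self.exon_coverage):
            raise ValueError(f"{self.gene_id}: exon length/coverage mismatch")
        if len(self.intron_lengths) != len(self.intron_coverage):
            raise ValueError(f"{self.gene_id}: intron length/coverage mismatch")
        if any(l <= 0 for l in self.exon_lengths + self.intron_lengths):
            raise ValueError(f"{self.gene_id}: non-positive feature length")
        if any(c < 0 for c in self.exon_coverage + self.intron_coverage):
            raise ValueError(f"{self.gene_id}: negative coverage")


class IrsUndefinedError(ValueError):
    """IRS is undefined for this gene (no introns, or no signal at all)."""


def irs(coverage: GeneCoverage) -> float:
    """Intronic Retention Score 2I/(E+I) for one gene."""
    if not coverage.exon_lengths:
        raise IrsUndefinedError(f"{coverage.gene_id}: no exons")
    if not coverage.intron_lengths:
        raise IrsUndefinedError(f"{coverage.gene_id}: intron-less gene")
    E = float(sum(c / l for c, l in zip(coverage.exon_coverage, coverage.exon_lengths)))
    I = float(sum(c / l for c, l in zip(coverage.intron_coverage, coverage.intron_lengths)))
    if E + I == 0:
        raise IrsUndefinedError(f"{coverage.gene_id}: zero exonic and intronic signal")
    return 2.0 * I / (E + I)


def irs_table(coverages: Sequence[GeneCoverage]) -> pd.DataFrame:
    """IRS per gene with exclusion bookkeeping.

    Returns a table indexed by gene_id with columns ``irs`` and
    ``excluded_reason`` (empty string when scored); excluded + scored
    always equals the number of input genes.
    """
    rows = []
    for cov in coverages:
        try:
            rows.append({"gene_id": cov.gene_id, "irs": irs(cov), "excluded_reason": ""})
        except IrsUndefinedError as exc:
            rows.append({"gene_id": cov.gene_id, "irs": np.nan,
                         "excluded_reason": str(exc)})
    return pd.DataFrame(rows).set_index("gene_id")


def irs_response(
    records_control: pd.DataFrame,
    records_treated: pd.DataFrame,
    epsilon: float = 0.01,
    n_sd: float = 2.0,
    min_genes: int = 50,
) -> pd.DataFrame:
    """Per-gene IRS condition ratios with extreme-change flags.

    ``records_*`` are :func:`irs_table` outputs (or any frames with an
    ``irs`` column indexed by gene). Ratio = (treated + eps)/(control +
    eps); genes are flagged ``increased``/``decreased`` when their
    log-ratio departs from the sample mean by more than ``n_sd``
    standard deviations, symmetric on the log scale.
    """
    shared = records_control.index.intersection(records_treated.index)
    c = records_control.loc[shared, "irs"]
    t = records_treated.loc[shared, "irs"]
    ok = c.notna() & t.notna()
    c, t = c[ok], t[ok]
    if len(c) < min_genes:
        raise ValueError(
            f"only {len(c)} shared scored genes (< {min_genes}); "
            "standard deviation is unstable"
        )
    ratio = (t + epsilon) / (c + epsilon)
    logr = np.log(ratio)
    mu, sd = float(logr.mean()), float(logr.std(ddof=1))
    flag = np.where(
        logr > mu + n_sd * sd, "increased",
        np.where(logr < mu - n_sd * sd, "decreased", "none"),
    )
    out = pd.DataFrame(
        {"irs_control": c, "irs_treated": t, "ratio": ratio, "log_ratio": logr,
         "flag": flag}
    )
    out.attrs["log_ratio_mean"] = mu
    out.attrs["log_ratio_sd"] = sd
    return out


@dataclass
class ShiftReport:
    n_increased: int
    n_decreased: int
    p_value: float | None
    systematic_shift: bool
    verdict: str

    def to_dict(self) -> dict:
        return {
            "n_increased": self.n_increased,
            "n_decreased": self.n_decreased,
            "p_value": self.p_value,
            "systematic_shift": self.systematic_shift,
            "verdict": self.verdict,
        }


def shift_test(response: pd.DataFrame, alpha: float = 0.05) -> ShiftReport:
    """Exact binomial symmetry test of increased vs decreased flags.

    Zero flagged genes is a valid "no flags" outcome, not an error.
    """
    n_inc = int((response["flag"] == "increased").sum())
    n_dec = int((response["flag"] == "decreased").sum())
    if n_inc + n_dec == 0:
        return ShiftReport(0, 0, None, False, "no flags")
    res = binomtest(n_inc, n_inc + n_dec, 0.5, alternative="two-sided")
    p = float(res.pvalue)
    shift = p < alpha
    verdict = (
        "systematic shift detected" if shift else "no systematic shift"
    )
    return ShiftReport(n_inc, n_dec, p, shift, verdict)
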