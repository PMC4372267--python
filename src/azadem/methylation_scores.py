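"""Global (LUMA) and per-site (HpaII/MspI angle) DNA methylation scores.

LUMA estimates global percent methylation from pyrosequencing
incorporation values after methylation-sensitive (HpaII) and insensitive
(MspI) digestion, each normalized by an EcoRI co-digestion:

    meth% = 100 * (1 - (HpaII_CG / HpaII_norm) / (MspI_CG / MspI_norm))

The per-site angle score compares HpaII and MspI read counts at a CCGG
site on library-size-normalized scales:

    score = 100 * (2/pi) * arctan(h / m),  h = hpaii/H, m = mspi/M

and ranges 0-100 with HIGHER scores meaning LESS methylation (a fully
methylated site yields no HpaII signal, score 0; h == m gives 50).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import SiteCounts

__all__ = [
    "LumaRun",
    "AssayError",
    "luma_methylation",
    "luma_mean",
    "angle_score",
    "angle_track",
    "dose_response",
]


class AssayError(ValueError):
    """The assay run carries no usable signal (e.g. zero MspI reference)."""


@dataclass(frozen=True)
class LumaRun:
    """One LUMA pyrosequencing reaction pair.

    ``*_cg`` are (C+G) incorporation values after HpaII+EcoRI or
    MspI+EcoRI digestion; ``*_norm`` are the EcoRI normalizers (A+C)/2
    of the same reactions.
    """

    hpaii_cg: float
    hpaii_norm: float
    mspi_cg: float
    mspi_norm: float

    def __post_init__(self):
        if min(self.hpaii_cg, self.mspi_cg) < 0:
            raise ValueError("incorporation values must be >= 0")
        if min(self.hpaii_norm, self.mspi_norm) <= 0:
            raise ValueError("EcoRI normalizers must be > 0")


def luma_methylation(run: LumaRun) -> float:
    """Percent global methylation from one LUMA run, clamped to [0, 100].

    Raises :class:`AssayError` when the MspI reaction shows no
    incorporation: without the methylation-insensitive reference the
    ratio is undefined.
    """
    if run.mspi_cg == 0:
        raise AssayError("MspI (C+G) incorporation is zero; no unmethylated reference")
    ratio = (run.hpaii_cg / run.hpaii_norm) / (run.mspi_cg / run.mspi_norm)
    return float(min(100.0, max(0.0, 100.0 * (1.0 - ratio))))


def luma_mean(runs: Sequence[LumaRun]) -> float:
    """Average percent methylation over replicate runs.

    Each replicate is normalized and converted on its own (per-reaction
    normalization), then the percentages are averaged.
    """
    if not runs:
        raise ValueError("no LUMA runs given")
    return float(np.mean([luma_methylation(r) for r in runs]))


def angle_score(
    site: SiteCounts,
    hpaii_libsize: float,
    mspi_libsize: float,
    min_mspi: int = 1,
) -> float:
    """Angle methylation score of one CCGG site, in [0, 100].

    Returns ``nan`` when the MspI count is below ``min_mspi``: such a
    site carries no reference signal and is *filtered*, which is distinct
    from a true score of 0 (fully methylated).
    """
    if hpaii_libsize <= 0 or mspi_libsize <= 0:
        raise ValueError("library sizes must be positive")
    if site.mspi_count < min_mspi:
        return math.nan
    h = site.hpaii_count / hpaii_libsize
    m = site.mspi_count / mspi_libsize
    return 100.0 * (2.0 / math.pi) * math.atan2(h, m)


def angle_track(
    sites: pd.DataFrame,
    hpaii_libsize: float | None = None,
    mspi_libsize: float | None = None,
    min_mspi: int = 1,
) -> tuple[pd.DataFrame, int]:
    """Vectorized angle scores for a site-count table.

    ``sites`` needs columns ``chrom, pos, hpaii_count, mspi_count``.
    Library sizes default to the column totals. Returns the scored track
    (``chrom, pos, score``; filtered sites absent, not zero) and the
    number of sites removed by the ``min_mspi`` filter.
    """
    H = float(sites["hpaii_count"].sum()) if hpaii_libsize is None else float(hpaii_libsize)
    M = float(sites["mspi_count"].sum()) if mspi_libsize is None else float(mspi_libsize)
    if H <= 0 or M <= 0:
        raise ValueError("library sizes must be positive")
    keep = sites["mspi_count"] >= min_mspi
    n_filtered = int((~keep).sum())
    kept = sites.loc[keep]
    h = kept["hpaii_count"].to_numpy(float) / H
    m = kept["mspi_count"].to_numpy(float) / M
    score = 100.0 * (2.0 / math.pi) * np.arctan2(h, m)
    track = pd.DataFrame(
        {"chrom": kept["chrom"].to_numpy(), "pos": kept["pos"].to_numpy(), "score": score}
    ).reset_index(drop=True)
    return track, n_filtered


def _global_methylation(obj) -> float:
    """Global percent-methylation-like value of one condition's data.

    LUMA runs are converted directly; an angle track (DataFrame with a
    ``score`` column) is summarized as ``100 - mean(score)`` so that the
    value increases with methylation in both representations.
    """
    if isinstance(obj, LumaRun):
        return luma_methylation(obj)
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], LumaRun):
        return luma_mean(obj)
    if isinstance(obj, pd.DataFrame):
        if "score" not in obj.columns:
            raise ValueError("angle track needs a 'score' column")
        return float(100.0 - obj["score"].mean())
    raise TypeError(f"cannot summarize {type(obj).__name__} as global methylation")


def dose_response(by_dose: Mapping[float, object] | Iterable[tuple[float, object]]) -> pd.DataFrame:
    """Global methylation versus dose, with monotonicity flags.

    ``by_dose`` maps dose to either LUMA run(s) or an angle track.
    Returns a table sorted by dose with per-dose global methylation and a
    boolean ``violates_monotone_decrease`` column flagging doses whose
    methylation exceeds that of the previous (lower) dose.
    """
    pairs = list(by_dose.items()) if isinstance(by_dose, Mapping) else list(by_dose)
    doses = [d for d, _ in pairs]
    if len(set(doses)) != len(doses):
        raise ValueError(f"duplicate dose labels in {doses}")
    if len(pairs) < 2:
        raise ValueError("dose_response needs at least 2 doses")
    pairs.sort(key=lambda p: p[0])
    values = [_global_methylation(obj) for _, obj in pairs]
    flags = [False] + [values[i] > values[i - 1] for i in range(1, len(values))]
    return pd.DataFrame(
        {"dose": [d for d, _ in pairs], "global_methylation": values,
         "violates_monotone_decrease": flags}
    )
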