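"""Zero removal and adaptive interquartile-range outlier exclusion.

Raw o/e samples contain artifacts: exact zeros (short sequences, or no
occurrence of the dinucleotide) and extreme values.  Cleaning first drops
all zeros, then removes every value outside the closed interval
``[Q25 - k*IQR, Q75 + k*IQR]``, where the integer multiplier ``k`` is the
smallest value in {2, 3, 4, 5} that removes at most 1% of the zero-free
sample (k = 5 if none qualifies).  Quantiles use linear interpolation of
order statistics, with quantile p at rank 1 + (n - 1) p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ratios import RatioSample

__all__ = [
    "CleaningReport",
    "LowSampleWarning",
    "remove_zeros",
    "select_iqr_multiplier",
    "clean",
    "CANDIDATE_K",
    "MAX_REMOVAL_PCT",
    "MIN_RELIABLE_N",
]

#: Candidate IQR multipliers, tried smallest first.
CANDIDATE_K = (2, 3, 4, 5)
#: A multiplier qualifies if it removes at most this percentage.
MAX_REMOVAL_PCT = 1.0
#: Below this many cleaned values the KDE parametrization is unreliable.
MIN_RELIABLE_N = 500


class LowSampleWarning(UserWarning):
    """Fewer cleaned values than the empirical reliability guideline."""


@dataclass
class CleaningReport:
    """Exclusion statistics for one cleaned sample.

    ``prop_zero`` is the fraction of the raw sample removed as zeros;
    ``prop_out_k`` maps each candidate multiplier to the percentage
    (0-100) it would remove from the zero-free sample; ``used_k`` is the
    multiplier actually applied.
    """

    name: str
    prop_zero: float
    prop_out_k: dict[int, float]
    used_k: int
    n_raw: int
    n_nozero: int
    n_clean: int
    q25: float
    q75: float
    iqr: float
    median: float
    low_sample: bool = False

    # exact output column names of the cleaning table
    COLUMNS = (
        "Name",
        "prop.zero",
        "prop.out.2iqr",
        "prop.out.3iqr",
        "prop.out.4iqr",
        "prop.out.5iqr",
        "used",
        "no.obs.raw",
        "no.obs.nozero",
        "no.obs.clean",
    )

    def to_row(self) -> dict:
        row = {
            "Name": self.name,
            "prop.zero": self.prop_zero,
            "used": self.used_k,
            "no.obs.raw": self.n_raw,
            "no.obs.nozero": self.n_nozero,
            "no.obs.clean": self.n_clean,
        }
        for k in CANDIDATE_K:
            row[f"prop.out.{k}iqr"] = self.prop_out_k[k]
        return {c: row[c] for c in self.COLUMNS}


def remove_zeros(sample: RatioSample) -> tuple[RatioSample, float]:
    """Drop all values equal to zero; return the fraction removed."""
    values = sample.values
    if values.size == 0:
        raise ValueError("empty sample")
    keep = values > 0
    if not keep.any():
        raise ValueError("all values are zero; nothing to analyze")
    frac = 1.0 - keep.sum() / values.size
    out = RatioSample(
        values=values[keep],
        ids=[i for i, k in zip(sample.ids, keep) if k],
        dinucleotide=sample.dinucleotide,
        formula=sample.formula,
        n_input=sample.n_input,
        n_too_short=sample.n_too_short,
        name=sample.name,
    )
    return out, float(frac)


def _interval(values: np.ndarray, k: float) -> tuple[float, float, float, float]:
    q25, q75 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q75 - q25
    return q25, q75, q25 - k * iqr, q75 + k * iqr


def select_iqr_multiplier(
    values: np.ndarray,
    candidates: tuple[int, ...] = CANDIDATE_K,
    max_removal_pct: float = MAX_REMOVAL_PCT,
) -> tuple[int, dict[int, float]]:
    """Smallest multiplier removing at most ``max_removal_pct`` percent.

    Returns the chosen k and the removal percentage for every candidate
    (percentages are relative to the zero-free sample).  Falls back to
    the largest candidate when none qualifies.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to select an IQR multiplier")
    pct: dict[int, float] = {}
    for k in candidates:
        _, _, lo, hi = _interval(values, k)
        outside = np.count_nonzero((values < lo) | (values > hi))
        pct[k] = 100.0 * outside / values.size
    for k in candidates:
        if pct[k] <= max_removal_pct:
            return k, pct
    return candidates[-1], pct


def clean(
    sample: RatioSample, k: int | None = None
) -> tuple[RatioSample, CleaningReport]:
    """Remove zeros, then outliers outside ``[Q25 - k*IQR, Q75 + k*IQR]``.

    ``k`` is selected adaptively unless forced.  Boundary values are
    retained (closed interval).  Emits :class:`LowSampleWarning` when
    fewer than 500 values survive, the empirical minimum for a reliable
    density estimate.
    """
    nozero, prop_zero = remove_zeros(sample)
    auto_k, pct = select_iqr_multiplier(nozero.values)
    used_k = auto_k if k is None else int(k)
    q25, q75, lo, hi = _interval(nozero.values, used_k)
    keep = (nozero.values >= lo) & (nozero.values <= hi)
    cleaned = RatioSample(
        values=nozero.values[keep],
        ids=[i for i, m in zip(nozero.ids, keep) if m],
        dinucleotide=sample.dinucleotide,
        formula=sample.formula,
        n_input=sample.n_input,
        n_too_short=sample.n_too_short,
        name=sample.name,
    )
    report = CleaningReport(
        name=sample.name,
        prop_zero=prop_zero,
        prop_out_k=pct,
        used_k=used_k,
        n_raw=len(sample),
        n_nozero=len(nozero),
        n_clean=len(cleaned),
        q25=float(q25),
        q75=float(q75),
        iqr=float(q75 - q25),
        median=float(np.quantile(nozero.values, 0.5, method="linear")),
        low_sample=len(cleaned) < MIN_RELIABLE_N,
    )
    if report.low_sample:
        warnings.warn(
            f"only {report.n_clean} values after cleaning; at least about "
            f"{MIN_RELIABLE_N} are needed for a reliable density estimate",
            LowSampleWarning,
            stacklevel=2,
        )
    return cleaned, report
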