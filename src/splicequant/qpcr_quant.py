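"""Standard-curve relative quantification of qPCR data.

A dilution series of pooled cDNA yields, per target, a linear fit of Cq on
log10(relative template amount); a sample's relative quantity is then
interpolated as ``10 ** ((Cq - intercept) / slope)``.  Amplification
efficiency is ``10 ** (-1/slope) - 1`` (a perfect doubling per cycle gives
slope -3.321928 and efficiency 1.0).  Target quantities are normalized to
the geometric mean of reference-gene quantities (e.g. GAPDH and HPRT1)
within each sample, and isoform ratios (4R/3R) are reported as percentages
of normalized quantities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DilutionPoint",
    "StandardCurve",
    "SampleQuantity",
    "fit_standard_curve",
    "interpolate_quantity",
    "summarize_replicates",
    "normalize_to_references",
    "qpcr_ratio",
    "check_negative_controls",
    "read_cq_table",
    "run_qpcr_pipeline",
]

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.321928...: exact doubling chemistry


@dataclass(frozen=True)
class DilutionPoint:
    dilution_factor: float  # relative template amount (1, 0.5, 0.25, ...)
    cq: float

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")
        if not math.isfinite(self.cq):
            raise ValueError("cq must be finite")


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # Cq per log10(amount)
    intercept: float  # Cq at log10(amount) == 0
    r_squared: float
    efficiency: float | None  # 10**(-1/slope) - 1; None for degenerate slope
    valid: bool  # slope < 0


@dataclass
class SampleQuantity:
    sample_id: str
    target: str
    cq_mean: float
    cq_sd: float | None
    n_replicates: int
    quantity: float
    normalized_quantity: float | None = None


def fit_standard_curve(points: Sequence[DilutionPoint]) -> StandardCurve:
    """Least-squares fit of Cq on log10(dilution factor).

    Requires at least three distinct dilution factors.  A non-negative slope
    yields an invalid curve (warned, not raised): constant Cq across
    dilutions means the chemistry is uninformative about template amount.
    """
    distinct = {p.dilution_factor for p in points}
    if len(distinct) < 3:
        raise ValueError(
            f"need >= 3 distinct dilution factors, got {len(distinct)}"
        )
    x = np.log10([p.dilution_factor for p in points])
    y = np.array([p.cq for p in points])
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r_squared = float(fit.rvalue) ** 2
    if slope >= 0:
        logger.warning(
            "standard curve slope %.4f is non-negative; curve flagged invalid",
            slope,
        )
        efficiency = None if slope == 0 else 10.0 ** (-1.0 / slope) - 1.0
        return StandardCurve(slope, intercept, r_squared, efficiency, False)
    return StandardCurve(
        slope, intercept, r_squared, 10.0 ** (-1.0 / slope) - 1.0, True
    )


def interpolate_quantity(cq: float, curve: StandardCurve) -> float:
    """Relative template amount at a given Cq: 10**((Cq - b) / m)."""
    if not curve.valid:
        raise ValueError("cannot interpolate on an invalid (slope >= 0) curve")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def summarize_replicates(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to mean/sd Cq per sample x target."""
    grouped = cq_table.groupby(["sample_id", "target"])["cq"]
    out = grouped.agg(cq_mean="mean", cq_sd="std", n_replicates="size")
    return out.reset_index()


def normalize_to_references(
    samples: Sequence[SampleQuantity], reference_targets: Iterable[str]
) -> list[SampleQuantity]:
    """Divide each quantity by the geometric mean of that sample's references."""
    refs = set(reference_targets)
    by_sample: dict[str, dict[str, float]] = {}
    for s in samples:
        by_sample.setdefault(s.sample_id, {})[s.target] = s.quantity
    out = []
    for s in samples:
        have = by_sample[s.sample_id]
        missing = refs - set(have)
        if missing:
            raise ValueError(
                f"sample {s.sample_id}: missing reference target(s) "
                f"{sorted(missing)}"
            )
        geomean = float(stats.gmean([have[r] for r in sorted(refs)]))
        out.append(replace(s, normalized_quantity=s.quantity / geomean))
    return out


def qpcr_ratio(num: SampleQuantity, den: SampleQuantity) -> float | None:
    """100 * normalized(num) / normalized(den); None when undefined."""
    if num.sample_id != den.sample_id:
        raise ValueError("numerator and denominator are from different samples")
    if num.normalized_quantity is None or den.normalized_quantity is None:
        raise ValueError("normalize quantities before forming ratios")
    if den.normalized_quantity == 0:
        return None
    return 100.0 * num.normalized_quantity / den.normalized_quantity


def check_negative_controls(
    cq_table: pd.DataFrame,
    control_samples: Iterable[str] = ("NRT", "NTC", "water"),
    cq_threshold: float = 38.0,
) -> pd.DataFrame:
    """Flag no-RT/water controls: pass = no Cq or Cq beyond the threshold."""
    ctl = cq_table[cq_table["sample_id"].isin(set(control_samples))].copy()
    ctl["passed"] = ctl["cq"].isna() | (ctl["cq"] > cq_threshold)
    return ctl


def read_cq_table(path: str | Path, *, dilution: bool = False) -> pd.DataFrame:
    """Read a long-format Cq TSV.

    Sample tables have columns ``sample_id  target  replicate  cq``;
    dilution tables have ``target  dilution_factor  replicate  cq``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = (
        {"target", "dilution_factor", "replicate", "cq"}
        if dilution
        else {"sample_id", "target", "replicate", "cq"}
    )
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def run_qpcr_pipeline(
    sample_cq: pd.DataFrame,
    dilution_cq: pd.DataFrame,
    *,
    reference_targets: Iterable[str] = ("GAPDH", "HPRT1"),
    numerator: str = "4R",
    denominator: str = "3R",
) -> tuple[dict[str, StandardCurve], list[SampleQuantity], pd.DataFrame]:
    """Full standard-curve workflow: fit curves, interpolate, normalize, ratio.

    Returns per-target curves, per-sample-x-target quantities, and a ratio
    table (one row per sample) with the numerator/denominator percentage.
    """
    curves: dict[str, StandardCurve] = {}
    for target, sub in dilution_cq.groupby("target"):
        points = [
            DilutionPoint(float(r.dilution_factor), float(r.cq))
            for r in sub.itertuples()
        ]
        curves[target] = fit_standard_curve(points)
    quantities: list[SampleQuantity] = []
    for row in summarize_replicates(sample_cq).itertuples():
        if row.target not in curves:
            raise ValueError(f"no standard curve for target {row.target!r}")
        q = interpolate_quantity(float(row.cq_mean), curves[row.target])
        quantities.append(
            SampleQuantity(
                row.sample_id,
                row.target,
                float(row.cq_mean),
                None if pd.isna(row.cq_sd) else float(row.cq_sd),
                int(row.n_replicates),
                q,
            )
        )
    quantities = normalize_to_references(quantities, reference_targets)
    by_sample: dict[str, dict[str, SampleQuantity]] = {}
    for q in quantities:
        by_sample.setdefault(q.sample_id, {})[q.target] = q
    rows = []
    for sample_id, targets in sorted(by_sample.items()):
        if numerator in targets and denominator in targets:
            ratio = qpcr_ratio(targets[numerator], targets[denominator])
            rows.append(
                {
                    "sample_id": sample_id,
                    "numerator": numerator,
                    "denominator": denominator,
                    "ratio_percent": ratio,
                    "defined": ratio is not None,
                }
            )
    return curves, quantities, pd.DataFrame(rows)
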