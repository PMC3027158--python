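"""Bisulfite-trace and HPLC methylation quantification.

Direct sequencing of bisulfite-converted PCR products yields, at every
CpG site, a C peak (methylated molecules, protected from conversion) and
a T peak (unmethylated, converted); the C/(C+T) area proportion is a
semi-quantitative per-site methylation percentage. Non-CpG cytosines
must read as T — their conversion rate is the bisulfite QC. Global 5mC
levels come from HPLC mononucleotide peak areas as the 5mdC share of
total cytosine signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chip import welch_test

__all__ = [
    "Site",
    "BisulfiteTrace",
    "HplcProfile",
    "site_methylation",
    "region_methylation",
    "conversion_qc",
    "compare_regions",
    "classify_region",
    "global_methylation_percent",
    "fold_difference",
    "read_traces",
    "write_traces",
    "read_hplc",
    "write_hplc",
]


@dataclass(frozen=True)
class Site:
    position: int
    c_area: float
    t_area: float

    def __post_init__(self) -> None:
        if self.c_area < 0 or self.t_area < 0:
            raise ValueError("peak areas must be >= 0")

    @property
    def missing(self) -> bool:
        return self.c_area + self.t_area == 0


@dataclass
class BisulfiteTrace:
    region_id: str
    sample_id: str
    group: str
    cpg_sites: list[Site]
    non_cpg_sites: list[Site] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cpg_sites:
            raise ValueError("trace must contain at least one CpG site")
        pos = [s.position for s in self.cpg_sites]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("CpG site positions must be strictly increasing")


HPLC_PEAKS = ("dC", "5mdC", "dG", "dA", "dT", "U")


@dataclass
class HplcProfile:
    areas: dict[str, float]
    response_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("peak areas must be >= 0")

    def corrected(self, peak: str) -> float:
        return self.areas.get(peak, 0.0) / self.response_factors.get(peak, 1.0)


# ---------------------------------------------------------------------------
# Trace quantification

def site_methylation(c_area: float, t_area: float) -> float:
    """Percent methylation at one CpG site: 100 * C / (C + T)."""
    total = c_area + t_area
    if total <= 0:
        raise ValueError("site has no signal (both areas 0)")
    return 100.0 * c_area / total


def _site_percents(trace: BisulfiteTrace) -> list[float]:
    return [site_methylation(s.c_area, s.t_area) for s in trace.cpg_sites if not s.missing]


def region_methylation(trace: BisulfiteTrace) -> float:
    """Unweighted mean of per-site percentages over non-missing CpG sites."""
    pct = _site_percents(trace)
    if not pct:
        raise ValueError(f"region {trace.region_id}: all CpG sites missing")
    return float(np.mean(pct))


def conversion_qc(trace: BisulfiteTrace, threshold: float = 0.98) -> tuple[float | None, bool | None]:
    """Bisulfite conversion rate from non-CpG cytosines.

    Returns ``(rate, passed)``; ``(None, None)`` when the trace has no
    non-CpG cytosine sites (QC unavailable, not a pass).
    """
    if not trace.non_cpg_sites:
        return None, None
    c = sum(s.c_area for s in trace.non_cpg_sites)
    t = sum(s.t_area for s in trace.non_cpg_sites)
    if c + t == 0:
        return None, None
    rate = t / (c + t)
    return rate, rate >= threshold


def compare_regions(
    tumor_traces: list[BisulfiteTrace], control_traces: list[BisulfiteTrace]
) -> dict[str, float | str]:
    """Welch comparison of pooled per-site percentages, tumor vs control.

    Site percentages are pooled across replicate samples within each
    group ("combined for all measured CpGs"); the reported difference is
    tumor mean minus control mean.
    """
    tumor = [p for tr in tumor_traces for p in _site_percents(tr)]
    control = [p for tr in control_traces for p in _site_percents(tr)]
    if len(tumor) < 2 or len(control) < 2:
        raise ValueError("need >= 2 site measurements per group")
    t, df, p = welch_test(tumor, control)
    diff = float(np.mean(tumor) - np.mean(control))
    direction = "hyper" if diff > 0 else ("hypo" if diff < 0 else "none")
    return {"mean_difference": diff, "t": t, "df": df, "p": p, "direction": direction}


def classify_region(percent: float, low_cut: float = 10.0, high_cut: float = 90.0) -> str:
    """Classify a region percentage as unmethylated / partial / methylated."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    if percent <= low_cut:
        return "unmethylated"
    if percent >= high_cut:
        return "methylated"
    return "partial"


# ---------------------------------------------------------------------------
# HPLC

def global_methylation_percent(profile: HplcProfile) -> float:
    """Global 5mC percent: 100 * 5mdC / (5mdC + dC), response-corrected.

    A warning is emitted when the uracil peak is nonzero (RNA
    contamination).
    """
    if profile.corrected("U") > 0:
        warnings.warn("nonzero uracil peak: sample may be contaminated with RNA", stacklevel=2)
    c = profile.corrected("dC")
    mc = profile.corrected("5mdC")
    if c + mc <= 0:
        raise ValueError("no cytosine signal (dC + 5mdC is zero)")
    return 100.0 * mc / (mc + c)


def fold_difference(a: float, b: float) -> float:
    """Ratio a/b of two methylation percentages."""
    if b == 0:
        raise ValueError("denominator percentage is zero")
    return a / b


# ---------------------------------------------------------------------------
# IO

_TRACE_COLS = ["region_id", "sample_id", "group", "position", "site_type", "c_area", "t_area"]


def write_traces(traces: list[BisulfiteTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for s in tr.cpg_sites:
            rows.append([tr.region_id, tr.sample_id, tr.group, s.position, "cpg", s.c_area, s.t_area])
        for s in tr.non_cpg_sites:
            rows.append([tr.region_id, tr.sample_id, tr.group, s.position, "non_cpg_c", s.c_area, s.t_area])
    pd.DataFrame(rows, columns=_TRACE_COLS).to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path) -> list[BisulfiteTrace]:
    df = pd.read_csv(path, sep="\t")
    traces = []
    for (region, sample, group), sub in df.groupby(["region_id", "sample_id", "group"], sort=True):
        sub = sub.sort_values("position")
        cpg = [Site(int(r.position), float(r.c_area), float(r.t_area))
               for r in sub[sub.site_type == "cpg"].itertuples()]
        non = [Site(int(r.position), float(r.c_area), float(r.t_area))
               for r in sub[sub.site_type == "non_cpg_c"].itertuples()]
        traces.append(BisulfiteTrace(str(region), str(sample), str(group), cpg, non))
    return traces


def write_hplc(profile: HplcProfile, path: str | Path) -> None:
    rows = [
        {"peak": p, "area": profile.areas.get(p, 0.0),
         "response_factor": profile.response_factors.get(p, 1.0)}
        for p in HPLC_PEAKS
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hplc(path: str | Path) -> HplcProfile:
    df = pd.read_csv(path, sep="\t")
    areas = dict(zip(df["peak"], df["area"].astype(float)))
    factors = (
        dict(zip(df["peak"], df["response_factor"].astype(float)))
        if "response_factor" in df.columns
        else {}
    )
    return HplcProfile(areas=areas, response_factors=factors)
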