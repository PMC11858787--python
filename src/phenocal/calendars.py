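"""Phenological calendars and synchrony summaries.

A calendar describes the annual distribution of flowering for one pooled
unit — a climatic region, a region–zone combination, or one species
within a region–zone — as monthly record counts plus the circular model
chosen by the consensus procedure, with environmental overlays: dry
months (monthly precipitation below 100 mm) and months of locally peak
irradiance, flagged when a flowering peak falls within one month of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circstats import (MODEL_SPECS, CircularSample, ConsensusResult,
                        angle_to_month_day, circular_separation, peaks_from_fit,
                        run_consensus)

__all__ = [
    "Calendar",
    "SynchronySummary",
    "pool_records",
    "build_calendar",
    "dry_months",
    "irradiance_peak_months",
    "coincidence",
    "normalized_proportions",
    "summarize_synchrony",
    "compare_across_regions",
    "calendars_to_frame",
]

MONTH_ABBR = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
              "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


@dataclass
class Calendar:
    context: dict[str, object]  # e.g. {"scope": "region", "region": 2}
    n: int
    monthly_counts: list[int]
    consensus: ConsensusResult
    pattern: str  # uniform | unimodal | bimodal
    peak_angles: list[float]
    peak_dates: list[tuple[int, int]]  # (month, day)
    dry_months: set[int] = field(default_factory=set)
    irradiance_peak_months: set[int] | None = None
    drought_coincidence: list[bool] = field(default_factory=list)
    irradiance_coincidence: list[bool] | None = None

    @property
    def label(self) -> str:
        return "|".join(f"{k}={v}" for k, v in self.context.items())


def _angle_month(angle: float) -> int:
    return min(int((angle % 360.0) // 30.0) + 1, 12)


def pool_records(
    records: pd.DataFrame,
    scope: str,
    min_n: int = 20,
) -> tuple[list[CircularSample], pd.DataFrame]:
    """Group predicted-flowering records into circular samples.

    ``records`` needs columns ``angle`` plus the stratum columns used by
    ``scope``: "region", "region_zone" or "species_region_zone".  Units
    with fewer than ``min_n`` records are excluded and reported.
    """
    keys = {
        "region": ["region"],
        "region_zone": ["region", "zone"],
        "species_region_zone": ["species", "region", "zone"],
    }.get(scope)
    if keys is None:
        raise ValueError(f"unknown scope {scope!r}")
    df = records.dropna(subset=keys + ["angle"])
    samples, excluded = [], []
    for key_vals, grp in df.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        ctx = dict(zip(keys, key_vals))
        if len(grp) < min_n:
            excluded.append({**ctx, "n": len(grp)})
            continue
        sample = CircularSample(grp["angle"].to_numpy(float),
                                context="|".join(f"{k}={v}" for k, v in ctx.items()))
        sample.context_dict = {"scope": scope, **ctx}
        samples.append(sample)
    return samples, pd.DataFrame(excluded, columns=keys + ["n"])


def dry_months(precip: Sequence[float], threshold_mm: float = 100.0) -> set[int]:
    """Months with precipitation strictly below the threshold (default 100 mm)."""
    p = np.asarray(precip, dtype=float)
    if p.size != 12:
        raise ValueError("need 12 monthly precipitation values")
    return {m for m in range(1, 13) if p[m - 1] < threshold_mm}


def irradiance_peak_months(series: Sequence[float]) -> set[int]:
    """Circular local maxima of a monthly series; plateaus count their
    first month; a constant series has no peaks."""
    v = np.asarray(series, dtype=float)
    if v.size != 12:
        raise ValueError("need 12 monthly values")
    peaks: set[int] = set()
    for start in range(12):
        if v[start] == v[start - 1]:
            continue  # not the first month of its plateau
        end = start
        while v[(end + 1) % 12] == v[start] and end - start < 11:
            end += 1
        before = v[start - 1]
        after = v[(end + 1) % 12]
        if v[start] > before and v[start] > after:
            peaks.add(start + 1)
    return peaks


def coincidence(
    peak_months: Iterable[int], month_set: set[int], window: int = 1
) -> list[bool]:
    """Whether each peak month falls in the set or circularly within
    ``window`` months of it."""
    out = []
    for pm in peak_months:
        hit = any(min((pm - m) % 12, (m - pm) % 12) <= window for m in month_set)
        out.append(bool(month_set) and hit)
    return out


def build_calendar(
    sample: CircularSample,
    precip: Sequence[float] | None = None,
    irradiance: Sequence[float] | None = None,
    seed: int = 0,
    runs: int = 100,
    threshold: int = 75,
    n_starts: int = 5,
    coincidence_window: int = 1,
    dry_mm: float = 100.0,
) -> Calendar:
    """Run the consensus model selection for one pooled sample and attach
    monthly counts, peak dates and environmental-coincidence flags."""
    consensus = run_consensus(sample, runs=runs, threshold=threshold,
                              seed=seed, n_starts=n_starts)
    fit = consensus.final_fit
    pattern = MODEL_SPECS[consensus.final_model].family
    peaks = peaks_from_fit(fit) if pattern != "uniform" else []
    months = [_angle_month(a) for a in sample.angles]
    counts = [months.count(m) for m in range(1, 13)]
    dry = dry_months(precip, dry_mm) if precip is not None else set()
    irr = irradiance_peak_months(irradiance) if irradiance is not None else None
    peak_months = [_angle_month(a) for a in peaks]
    cal = Calendar(
        context=getattr(sample, "context_dict", {"scope": "sample",
                                                 "context": sample.context}),
        n=sample.n,
        monthly_counts=counts,
        consensus=consensus,
        pattern=pattern,
        peak_angles=[round(a, 3) for a in peaks],
        peak_dates=[angle_to_month_day(a) for a in peaks],
        dry_months=dry,
        irradiance_peak_months=irr,
        drought_coincidence=coincidence(peak_months, dry, coincidence_window),
        irradiance_coincidence=(coincidence(peak_months, irr, coincidence_window)
                                if irr is not None else None),
    )
    return cal


def normalized_proportions(unit_counts: Mapping[str, int]) -> dict[str, float]:
    """Per-unit record counts normalized by the best-covered unit (=1.0)."""
    if not unit_counts:
        raise ValueError("no units")
    top = max(unit_counts.values())
    if top <= 0:
        raise ValueError("all unit counts are zero")
    return {u: c / top for u, c in unit_counts.items()}


@dataclass
class SynchronySummary:
    n_calendars: int
    pattern_counts: dict[str, int]
    peak_month_histogram: dict[int, int]
    bimodal_irradiance_fraction: float | None

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({
            "n_calendars": self.n_calendars,
            "pattern_counts": self.pattern_counts,
            "peak_month_histogram": {str(k): v for k, v in
                                     sorted(self.peak_month_histogram.items())},
            "bimodal_irradiance_fraction": self.bimodal_irradiance_fraction,
        }, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def summarize_synchrony(calendars: Sequence[Calendar]) -> SynchronySummary:
    """Tabulate pattern classes, peak months, and — among bimodal calendars
    with irradiance data — the fraction whose peaks all coincide with
    irradiance peaks."""
    if not calendars:
        raise ValueError("no calendars to summarize")
    patterns: dict[str, int] = {"uniform": 0, "unimodal": 0, "bimodal": 0}
    hist: dict[int, int] = {}
    bi_total = bi_coinc = 0
    for cal in calendars:
        patterns[cal.pattern] += 1
        for (m, _d) in cal.peak_dates:
            hist[m] = hist.get(m, 0) + 1
        if cal.pattern == "bimodal" and cal.irradiance_coincidence is not None:
            bi_total += 1
            bi_coinc += all(cal.irradiance_coincidence)
    frac = (bi_coinc / bi_total) if bi_total else None
    return SynchronySummary(
        n_calendars=len(calendars),
        pattern_counts=patterns,
        peak_month_histogram=hist,
        bimodal_irradiance_fraction=frac,
    )


def _match_peaks(a: Sequence[float], b: Sequence[float]) -> float:
    """Largest circular separation under the better of the two pairings."""
    if len(a) != len(b) or not a:
        return float("inf") if a or b else 0.0
    if len(a) == 1:
        return circular_separation(a[0], b[0])
    d_straight = max(circular_separation(a[0], b[0]), circular_separation(a[1], b[1]))
    d_crossed = max(circular_separation(a[0], b[1]), circular_separation(a[1], b[0]))
    return min(d_straight, d_crossed)


def compare_across_regions(
    calendars: Sequence[Calendar], max_separation_deg: float = 30.0
) -> dict:
    """Intraspecific comparison across ≥2 regions.

    "consistent" requires a shared pattern class and all pairwise peak
    separations within one month (30°); anything else is "variable".
    """
    if len(calendars) < 2:
        raise ValueError("need calendars from at least two regions")
    patterns = {c.pattern for c in calendars}
    pairs = []
    max_sep = 0.0
    for i in range(len(calendars)):
        for j in range(i + 1, len(calendars)):
            sep = _match_peaks(calendars[i].peak_angles, calendars[j].peak_angles)
            pairs.append({"a": calendars[i].label, "b": calendars[j].label,
                          "separation_deg": None if sep == float("inf") else round(sep, 3)})
            max_sep = max(max_sep, sep)
    consistent = len(patterns) == 1 and max_sep <= max_separation_deg
    return {
        "verdict": "consistent" if consistent else "variable",
        "patterns": sorted(patterns),
        "max_peak_separation_deg": None if max_sep == float("inf") else round(max_sep, 3),
        "pairwise": pairs,
    }


def calendars_to_frame(calendars: Sequence[Calendar]) -> pd.DataFrame:
    """One row per calendar, suitable for CSV export."""
    rows = []
    for cal in calendars:
        fit = cal.consensus.final_fit
        rows.append({
            **cal.context,
            "n": cal.n,
            "pattern": cal.pattern,
            "model": cal.consensus.final_model,
            "consistent": cal.consensus.consistent,
            "fallback_used": cal.consensus.fallback_used,
            "mu1": round(fit.mu1, 3),
            "k1": round(fit.k1, 4),
            "mu2": None if fit.mu2 is None else round(fit.mu2, 3),
            "k2": None if fit.k2 is None else round(fit.k2, 4),
            "lam": None if fit.lam is None else round(fit.lam, 4),
            "AIC": round(fit.AIC, 4),
            "peak_dates": ";".join(f"{MONTH_ABBR[m-1]}-{d:02d}"
                                   for m, d in cal.peak_dates),
            "dry_months": ";".join(str(m) for m in sorted(cal.dry_months)),
            "irradiance_peaks": ("" if cal.irradiance_peak_months is None else
                                 ";".join(str(m) for m in
                                          sorted(cal.irradiance_peak_months))),
            "drought_coincidence": ";".join(str(b) for b in cal.drought_coincidence),
            "irradiance_coincidence": ("" if cal.irradiance_coincidence is None else
                                       ";".join(str(b) for b in
                                                cal.irradiance_coincidence)),
            **{f"count_{m:02d}": c for m, c in
               zip(range(1, 13), cal.monthly_counts)},
        })
    return pd.DataFrame(rows)
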