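"""Pseudo individual-patient data from digitized Kaplan-Meier coordinates.

Published KM figures carry more information than the handful of summary
statistics a paper prints.  Given digitized (time, survival) coordinates
and, optionally, the numbers-at-risk row printed under the figure, the
interval-wise reconstruction algorithm of Guyot et al. recovers a pseudo
patient-level dataset whose KM estimate reproduces the digitized curve.
The reconstructed records can then be fitted with any parametric family
(see :mod:`hcc_cea.distributions`).

Censoring within a risk-table interval is placed at uniformly spaced
times, so the reconstruction is fully deterministic (no seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .distributions import IPDRecord

__all__ = [
    "CurvePoint",
    "RiskTableEntry",
    "ReconstructionError",
    "clean_curve",
    "reconstruct_ipd",
    "km_estimate",
]


@dataclass(frozen=True)
class CurvePoint:
    time: float
    survival: float


@dataclass(frozen=True)
class RiskTableEntry:
    time: float
    n_at_risk: int


class ReconstructionError(ValueError):
    pass


def clean_curve(points: Sequence[CurvePoint]) -> list[CurvePoint]:
    """Repair digitization noise: sort, clamp to [0, 1], enforce monotone
    non-increase by clipping each value at its predecessor, prepend (0, 1)."""
    if len(points) < 2:
        raise ValueError(f"need at least 2 curve points, got {len(points)}")
    pts = sorted(points, key=lambda p: p.time)
    if pts[0].time < 0:
        raise ValueError("curve times must be non-negative")
    out: list[CurvePoint] = [CurvePoint(0.0, 1.0)]
    prev = 1.0
    for p in pts:
        if p.time == 0:
            continue  # the origin is pinned at S(0) = 1
        s = min(max(p.survival, 0.0), 1.0)
        s = min(s, prev)
        out.append(CurvePoint(float(p.time), s))
        prev = s
    return out


def km_estimate(data: Sequence[IPDRecord]) -> list[CurvePoint]:
    """Product-limit estimate of the input records; steps only at event times."""
    if not data:
        raise ValueError("no records")
    times = [r.time for r in data]
    events = [r.event for r in data]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    out = [CurvePoint(float(t), float(s)) for t, s in zip(sf.index, sf.iloc[:, 0])]
    if not out or out[0].time > 0:
        out.insert(0, CurvePoint(0.0, 1.0))
    return out


def _validate_risk_table(risk_table: Sequence[RiskTableEntry]) -> list[RiskTableEntry]:
    if not risk_table:
        raise ReconstructionError("risk table needs at least one entry")
    rt = sorted(risk_table, key=lambda e: e.time)
    for prev, cur in zip(rt, rt[1:]):
        if cur.n_at_risk > prev.n_at_risk:
            raise ReconstructionError(
                f"numbers at risk increase in the interval starting at t={cur.time:g} "
                f"({prev.n_at_risk} -> {cur.n_at_risk})"
            )
    return rt


def reconstruct_ipd(
    points: Sequence[CurvePoint],
    risk_table: Sequence[RiskTableEntry],
    total_events: int | None = None,
) -> list[IPDRecord]:
    """Interval-wise reconstruction of pseudo-IPD from a digitized curve.

    Within each risk-table interval the number of censorings is chosen so
    that the implied number at risk at the start of the next interval
    matches the printed one; event counts then follow from the digitized
    survival drops through the KM recursion.  With a single risk-table
    entry (initial n only), censoring is assumed absent and events follow
    the drops directly; ``total_events``, when given, adjusts the final
    interval (the published total event count is usually reported).
    """
    curve = clean_curve(points)
    rt = _validate_risk_table(risk_table)
    t = np.array([p.time for p in curve])
    s = np.array([p.survival for p in curve])

    # interval boundaries: risk-table times, last interval extends past the curve
    bounds = [e.time for e in rt] + [t[-1] + 1e-9]
    n_init = rt[0].n_at_risk

    records: list[IPDRecord] = []
    n_risk = float(n_init)  # patients still at risk entering the current point
    s_km = 1.0  # running KM estimate of the reconstruction

    for i in range(len(rt)):
        lo, hi = bounds[i], bounds[i + 1]
        mask = (t >= lo) & (t < hi) & (t > 0)
        idx = np.where(mask)[0]
        target_next = rt[i + 1].n_at_risk if i + 1 < len(rt) else None

        # events implied by the digitized drops, at the current n at risk,
        # for a candidate number of censorings c spread uniformly over the
        # interval.  Solve for c so that n at risk at the next boundary
        # matches the printed value (Guyot's iteration, deterministic).
        def simulate(c: int, commit: bool = False):
            nonlocal n_risk, s_km
            nr, sk = n_risk, s_km
            cens_times = (
                lo + (np.arange(1, c + 1) - 0.5) * (min(hi, t[-1]) - lo) / c
                if c > 0
                else np.array([])
            )
            cens_used = 0
            new_records: list[IPDRecord] = []
            for j in idx:
                # censor everyone scheduled before this curve point
                while cens_used < c and cens_times[cens_used] < t[j]:
                    if nr > 0:
                        new_records.append(
                            IPDRecord(float(cens_times[cens_used]), False)
                        )
                        nr -= 1
                    cens_used += 1
                if nr <= 0 or sk <= 0:
                    break
                d = int(round(nr * (1.0 - s[j] / sk)))
                d = max(0, min(d, int(nr)))
                if d > 0:
                    new_records.extend(IPDRecord(float(t[j]), True) for _ in range(d))
                    sk *= 1.0 - d / nr
                    nr -= d
            while cens_used < c and nr > 0:
                new_records.append(IPDRecord(float(cens_times[cens_used]), False))
                nr -= 1
                cens_used += 1
            if commit:
                n_risk, s_km = nr, sk
                records.extend(new_records)
            return nr

        if target_next is None:
            c_best = 0
            if total_events is not None:
                # choose c so events in this interval hit the printed total
                want = max(0, total_events - sum(r.event for r in records))
                best = None
                for c in range(int(n_risk) + 1):
                    got = _count_events_under(
                        c, idx, t, s, n_risk, s_km, lo, min(hi, t[-1])
                    )
                    diff = abs(got - want)
                    if best is None or diff < best[0]:
                        best = (diff, c)
                    if diff == 0:
                        break
                c_best = best[1]
        else:
            # bisect-ish scan: n at risk after the interval is monotone
            # decreasing in c, so walk c upward until the target is met
            best = None
            for c in range(int(n_risk) + 1):
                nr_after = simulate(c)
                diff = abs(nr_after - target_next)
                if best is None or diff < best[0]:
                    best = (diff, c)
                if nr_after <= target_next:
                    break
            if best[0] > 0 and target_next > n_risk:
                raise ReconstructionError(
                    f"risk table inconsistent in the interval starting at t={lo:g}: "
                    f"{target_next} at risk exceeds the {int(n_risk)} survivors available"
                )
            c_best = best[1]
        simulate(c_best, commit=True)

    # anyone still at risk at the end of the curve is administratively censored
    n_left = int(round(n_risk))
    records.extend(IPDRecord(float(t[-1]), False) for _ in range(n_left))
    return sorted(records, key=lambda r: (r.time, not r.event))


def _count_events_under(c, idx, t, s, n_risk, s_km, lo, hi):
    """Number of events the KM recursion implies in one interval for c censorings."""
    nr, sk = n_risk, s_km
    cens_times = (
        lo + (np.arange(1, c + 1) - 0.5) * (hi - lo) / c if c > 0 else np.array([])
    )
    cens_used = 0
    events = 0
    for j in idx:
        while cens_used < c and cens_times[cens_used] < t[j]:
            if nr > 0:
                nr -= 1
            cens_used += 1
        if nr <= 0 or sk <= 0:
            break
        d = int(round(nr * (1.0 - s[j] / sk)))
        d = max(0, min(d, int(nr)))
        if d > 0:
            sk *= 1.0 - d / nr
            nr -= d
            events += d
    return events
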