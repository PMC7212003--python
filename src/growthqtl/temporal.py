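"""Temporal QTL: day-by-day scans, clustering, trajectories, co-localization.

Running the additive scan on every imputed day (1..85 DAS) yields one LOD
profile per day.  Daily QTL calls are consolidated into *temporal QTL* by
single-linkage clustering of peak positions on the same chromosome within
a window (default 10 cM).  Each temporal QTL carries its full-season
LOD / additive-effect / PVE trajectories (including sub-threshold days),
an activity window (onset/offset = first/last significant day), a
sign-switch flag (the additive effect crossing zero between two
significant days), and optional candidate-gene proximity.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import GenotypeProbabilities, call_qtl, icim_scan, interval_mapping_scan

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalQTL",
    "scan_all_days",
    "cluster_temporal",
    "detect_sign_switch",
    "colocalize",
    "candidate_gene_distance",
    "bin_gene_distances",
]


@dataclass
class TemporalQTL:
    """One clustered temporal QTL with its full-season trajectories."""

    name: str
    chrom: str
    peak_cm: float            # LOD-weighted consensus of daily peak positions
    onset_das: int
    offset_das: int
    peak_das: int             # day of maximum LOD among member calls
    max_lod: float
    max_pve: float
    effect_at_peak: float
    sign_switch: bool
    switch_day: int | None
    member_days: list[int] = field(default_factory=list)
    trajectory: pd.DataFrame | None = None  # das, lod, additive, pve

    def to_row(self) -> dict:
        return {
            "name": self.name, "chrom": self.chrom, "peak_cm": self.peak_cm,
            "onset_das": self.onset_das, "offset_das": self.offset_das,
            "peak_das": self.peak_das, "max_lod": self.max_lod,
            "max_pve": self.max_pve, "effect_at_peak": self.effect_at_peak,
            "sign_switch": self.sign_switch, "switch_day": self.switch_day,
            "n_days": len(self.member_days),
        }


def scan_all_days(
    daily_matrix: pd.DataFrame,
    gp: GenotypeProbabilities,
    geno: pd.DataFrame | None = None,
    pin: float = 0.001,
    use_icim: bool = True,
    lod_min: float = 2.0,
    pve_min: float = 0.03,
    min_lines: int = 20,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Run the scan for every day column of ``daily_matrix``.

    ``daily_matrix`` holds one row per entry and one column per DAS
    (integer column labels).  Returns ``(profiles, daily_calls)`` where
    *profiles* maps DAS to its LOD profile and *daily_calls* stacks the
    per-day QTL calls with a ``das`` column.
    """
    profiles: dict[int, pd.DataFrame] = {}
    call_frames = []
    for day in daily_matrix.columns:
        t0 = time.perf_counter()
        y = daily_matrix[day]
        if use_icim:
            if geno is None:
                raise ValueError("ICIM needs the marker matrix")
            prof = icim_scan(y, gp, geno, pin=pin, min_lines=min_lines)
        else:
            prof = interval_mapping_scan(y, gp, min_lines=min_lines)
        profiles[int(day)] = prof
        calls = call_qtl(prof, lod_min=lod_min, pve_min=pve_min)
        calls.insert(0, "das", int(day))
        if not calls.empty:
            call_frames.append(calls)
        logger.debug("scan DAS %s: %.3f s, %d calls",
                     day, time.perf_counter() - t0, len(calls))
    if call_frames:
        daily_calls = pd.concat(call_frames, ignore_index=True)
    else:
        daily_calls = pd.DataFrame(columns=["das", "name", "chrom", "peak_cm",
                                            "lod", "pve", "additive"])
    return profiles, daily_calls


def cluster_temporal(
    daily_calls: pd.DataFrame,
    profiles: dict[int, pd.DataFrame] | None = None,
    window_cm: float = 10.0,
    lod_min: float = 2.0,
) -> list[TemporalQTL]:
    """Single-linkage clustering of daily peaks into temporal QTL.

    Calls on the same chromosome whose peak positions chain together
    within ``window_cm`` form one cluster; the consensus position is the
    LOD-weighted mean of member peaks.  Onset/offset are the first/last
    member day (short detection gaps are thereby bridged).  When
    *profiles* are given, each cluster carries full-season trajectories
    sampled at the scan position nearest its consensus peak.
    """
    out: list[TemporalQTL] = []
    if daily_calls.empty:
        return out
    for chrom, sub in daily_calls.groupby("chrom", sort=False):
        sub = sub.sort_values(["peak_cm", "das"]).reset_index(drop=True)
        pos = sub["peak_cm"].to_numpy()
        # single linkage in 1-D: break where the gap exceeds the window
        breaks = np.flatnonzero(np.diff(pos) > window_cm)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            members = sub.iloc[s:e + 1]
            w = members["lod"].to_numpy()
            consensus = float(np.average(members["peak_cm"], weights=w))
            peak_row = members.iloc[int(np.argmax(w))]
            days = sorted(members["das"].astype(int).unique())
            traj = None
            if profiles is not None:
                traj = _trajectory(profiles, chrom, consensus)
            switch, switch_day = detect_sign_switch_series(
                traj if traj is not None else members.rename(
                    columns={"additive": "additive"}),
                lod_min=lod_min,
            )
            out.append(TemporalQTL(
                name=f"q{chrom}_{int(round(consensus))}",
                chrom=chrom,
                peak_cm=consensus,
                onset_das=days[0],
                offset_das=days[-1],
                peak_das=int(peak_row["das"]),
                max_lod=float(peak_row["lod"]),
                max_pve=float(members["pve"].max()),
                effect_at_peak=float(peak_row["additive"]),
                sign_switch=switch,
                switch_day=switch_day,
                member_days=[int(d) for d in days],
                trajectory=traj,
            ))
    out.sort(key=lambda q: (str(q.chrom), q.peak_cm))
    return out


def _trajectory(profiles: dict[int, pd.DataFrame], chrom, cm_val: float) -> pd.DataFrame:
    rows = []
    for day in sorted(profiles):
        prof = profiles[day]
        sub = prof[prof["chrom"] == chrom]
        i = (sub["cm"] - cm_val).abs().idxmin()
        rows.append({
            "das": day,
            "lod": float(sub.loc[i, "lod"]),
            "additive": float(sub.loc[i, "additive"]),
            "pve": float(sub.loc[i, "pve"]),
        })
    return pd.DataFrame(rows)


def detect_sign_switch_series(
    traj: pd.DataFrame, lod_min: float = 2.0
) -> tuple[bool, int | None]:
    """Sign switch on a (das, lod, additive) series.

    Flagged when the additive effect has opposite signs on two successive
    significant days (LOD > ``lod_min``); the switch day is the first
    significant day carrying the new sign.  Sign changes occurring only
    while the locus is sub-threshold are ignored.
    """
    sig = traj[traj["lod"] > lod_min].sort_values("das")
    eff = sig["additive"].to_numpy()
    days = sig["das"].to_numpy()
    signs = np.sign(eff)
    nz = signs != 0
    signs, days = signs[nz], days[nz]
    for k in range(1, len(signs)):
        if signs[k] != signs[k - 1]:
            return True, int(days[k])
    return False, None


def detect_sign_switch(qtl: TemporalQTL, lod_min: float = 2.0) -> tuple[bool, int | None]:
    """Sign-switch flag for a clustered temporal QTL (uses its trajectory)."""
    if qtl.trajectory is None:
        raise ValueError("temporal QTL has no trajectory")
    return detect_sign_switch_series(qtl.trajectory, lod_min=lod_min)


# ---------------------------------------------------------------------------
# cross-trait co-localization and candidate genes
# ---------------------------------------------------------------------------

def colocalize(
    qtl_by_trait: dict[str, pd.DataFrame],
    window_cm: float = 10.0,
) -> pd.DataFrame:
    """All cross-trait QTL pairs on one chromosome within ``window_cm``.

    Each input frame needs columns ``name, chrom, peak_cm`` (and
    optionally ``ci_lo_bp, ci_hi_bp`` for a physical-overlap flag).
    """
    traits = list(qtl_by_trait)
    rows = []
    for a_i in range(len(traits)):
        for b_i in range(a_i + 1, len(traits)):
            ta, tb = traits[a_i], traits[b_i]
            A, B = qtl_by_trait[ta], qtl_by_trait[tb]
            for _, qa in A.iterrows():
                for _, qb in B.iterrows():
                    if qa["chrom"] != qb["chrom"]:
                        continue
                    d = abs(float(qa["peak_cm"]) - float(qb["peak_cm"]))
                    if d > window_cm:
                        continue
                    overlap = np.nan
                    if {"ci_lo_bp", "ci_hi_bp"}.issubset(qa.index) and \
                       {"ci_lo_bp", "ci_hi_bp"}.issubset(qb.index):
                        overlap = bool(
                            qa["ci_lo_bp"] <= qb["ci_hi_bp"]
                            and qb["ci_lo_bp"] <= qa["ci_hi_bp"]
                        )
                    rows.append({
                        "trait_a": ta, "qtl_a": qa["name"],
                        "trait_b": tb, "qtl_b": qb["name"],
                        "chrom": qa["chrom"], "distance_cm": d,
                        "physical_overlap": overlap,
                    })
    return pd.DataFrame(rows, columns=[
        "trait_a", "qtl_a", "trait_b", "qtl_b", "chrom",
        "distance_cm", "physical_overlap",
    ])


def candidate_gene_distance(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Nearest candidate gene per QTL by distance from the interval center.

    ``genes`` is BED-like: columns ``chrom, start, end, name`` with
    0-based half-open spans.  The distance is 0 when the center of the
    QTL support interval (mean of ``ci_lo_bp``/``ci_hi_bp``) lies inside
    a gene span, else the bp gap to the nearer edge.  QTL on chromosomes
    with no gene get a missing sentinel (NaN distance).
    """
    rows = []
    for _, q in calls.iterrows():
        center = 0.5 * (float(q["ci_lo_bp"]) + float(q["ci_hi_bp"]))
        sub = genes[genes["chrom"].astype(str) == str(q["chrom"])]
        if sub.empty:
            rows.append({"name": q["name"], "chrom": q["chrom"],
                         "center_bp": center, "nearest_gene": None,
                         "distance_bp": float("nan")})
            continue
        start = sub["start"].to_numpy(dtype=float)
        end = sub["end"].to_numpy(dtype=float)
        inside = (center >= start) & (center < end)
        dist = np.where(inside, 0.0,
                        np.minimum(np.abs(center - start), np.abs(center - end)))
        j = int(np.argmin(dist))
        rows.append({"name": q["name"], "chrom": q["chrom"],
                     "center_bp": center,
                     "nearest_gene": sub["name"].iloc[j],
                     "distance_bp": float(dist[j])})
    return pd.DataFrame(rows)


def bin_gene_distances(distances: pd.DataFrame) -> dict[str, int]:
    """Counts of QTL within 1 Mbp, and additionally within 5 Mbp, of a gene."""
    d = distances["distance_bp"].to_numpy(dtype=float)
    finite = np.isfinite(d)
    return {
        "lt_1mbp": int((d[finite] < 1e6).sum()),
        "1_to_5mbp": int(((d[finite] >= 1e6) & (d[finite] < 5e6)).sum()),
        "ge_5mbp": int((d[finite] >= 5e6).sum()),
        "no_gene": int((~finite).sum()),
    }
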