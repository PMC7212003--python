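"""Genotype QC and genetic-map construction for selfed RIL populations.

Genotypes are held in a pandas DataFrame (rows = lines, columns = markers)
with integer calls: 0 = parent-A homozygote, 2 = parent-B homozygote,
1 = heterozygote, -1 = missing.  A marker map is a DataFrame with columns
``marker, chrom, bp, cm`` (bp 1-based, strictly increasing within a
chromosome; cm non-decreasing).

The processing chain mirrors standard bi-parental linkage-map workflows:

1. drop lines/markers with too much missing data,
2. set residual heterozygous calls to missing (lines are F6+, so the two
   homozygous classes carry all the mapping information),
3. clean double recombinants by absorbing genotype runs shorter than a
   minimum region into their flanking runs,
4. collapse redundant (identical-pattern) markers to one representative,
5. estimate adjacent-marker recombination fractions under the selfed-RIL
   expectation R = 2r/(1+2r) and accumulate Kosambi distances into a map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "kosambi_cm",
    "kosambi_r",
    "ril_R_from_r",
    "ril_r_from_R",
    "filter_missing",
    "set_het_missing",
    "clean_double_recombinants",
    "bin_redundant_markers",
    "estimate_recombination",
    "build_map",
    "validate_genotypes",
    "validate_map",
]

MISSING = -1
_VALID_CALLS = frozenset({-1, 0, 1, 2})
#: recombination fractions are capped strictly below 1/2 so the Kosambi
#: distance stays finite; flagged intervals carry this cap
R_CAP = 0.4999


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance d = 25*ln((1+2r)/(1-2r)) in cM for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_r(cm):
    """Inverse Kosambi: r = tanh(d/50)/2; exact round-trip with kosambi_cm."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(cm / 50.0)
    return float(out) if out.ndim == 0 else out


def ril_R_from_r(r):
    """Selfed-RIL (F-infinity) recombinant fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def ril_r_from_R(R):
    """Invert R = 2r/(1+2r): r = R/(2-2R)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 1.0):
        raise ValueError("RIL recombinant fraction must lie in [0, 1)")
    out = R / (2.0 - 2.0 * R)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_genotypes(geno: pd.DataFrame) -> None:
    vals = set(np.unique(geno.to_numpy()))
    bad = vals - _VALID_CALLS
    if bad:
        raise ValueError(f"invalid genotype calls: {sorted(bad)}")


def validate_map(mmap: pd.DataFrame) -> None:
    required = {"marker", "chrom", "bp", "cm"}
    if not required.issubset(mmap.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}")
    if mmap["marker"].duplicated().any():
        raise ValueError("duplicate marker names in map")
    for chrom, sub in mmap.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy()
        cm = sub["cm"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"cm decreasing on chromosome {chrom}")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_missing(
    geno: pd.DataFrame,
    max_line_missing: float = 0.10,
    max_marker_missing: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Drop lines and markers whose missing fraction strictly exceeds the cut.

    Lines are screened first on the full matrix, then markers on the
    surviving lines; the strict ``>`` keeps entities at exactly the
    threshold.  Returns the filtered matrix and a report dict.
    """
    if not (0 <= max_line_missing <= 1 and 0 <= max_marker_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = geno.to_numpy() == MISSING
    line_frac = miss.mean(axis=1)
    keep_lines = line_frac <= max_line_missing
    marker_frac = miss[keep_lines].mean(axis=0) if keep_lines.any() else miss.mean(axis=0)
    keep_markers = marker_frac <= max_marker_missing
    if not keep_lines.any() or not keep_markers.any():
        raise ValueError("missing-data filter removed everything")
    out = geno.loc[keep_lines, keep_markers]
    report = {
        "lines_in": geno.shape[0],
        "markers_in": geno.shape[1],
        "lines_dropped": int((~keep_lines).sum()),
        "markers_dropped": int((~keep_markers).sum()),
        "dropped_lines": list(geno.index[~keep_lines]),
        "dropped_markers": list(geno.columns[~keep_markers]),
    }
    return out, report


def set_het_missing(geno: pd.DataFrame) -> pd.DataFrame:
    """Recode heterozygous calls (1) as missing (-1); 0/2/-1 untouched."""
    out = geno.copy()
    arr = out.to_numpy()
    arr[arr == 1] = MISSING
    out.loc[:, :] = arr
    return out


# ---------------------------------------------------------------------------
# double-recombinant cleaning
# ---------------------------------------------------------------------------

@dataclass
class _Run:
    allele: int
    idx: list = field(default_factory=list)  # positions into the informative arrays


def _absorb_runs(runs, bp, min_region_bp, min_run_markers):
    """Iteratively merge runs violating the size constraints into neighbours.

    A run's size is the physical region it owns between crosspoints: from
    the midpoint to the previous run's last marker up to the midpoint to
    the next run's first marker (chromosome ends truncate at the outermost
    markers).  Isolated wrong calls in dense data own a tiny region and are
    absorbed; at coarse marker spacing a single-marker run still owns a
    large region and is left alone.
    """
    def span(i):
        run = runs[i]
        left = (0.5 * (bp[runs[i - 1].idx[-1]] + bp[run.idx[0]])
                if i > 0 else bp[run.idx[0]])
        right = (0.5 * (bp[run.idx[-1]] + bp[runs[i + 1].idx[0]])
                 if i < len(runs) - 1 else bp[run.idx[-1]])
        return right - left

    while len(runs) > 1:
        viol = [
            i for i, run in enumerate(runs)
            if span(i) < min_region_bp or len(run.idx) < min_run_markers
        ]
        if not viol:
            break
        # absorb the smallest offender first for determinism
        i = min(viol, key=lambda j: (span(j), len(runs[j].idx), j))
        run = runs[i]
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i < len(runs) - 1 else None
        if left is not None and right is not None and left.allele == right.allele:
            left.idx.extend(run.idx)
            left.idx.extend(right.idx)
            del runs[i:i + 2]
        else:
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                # assign to the physically longer neighbour, tie -> left
                target = left if span(i - 1) >= span(i + 1) else right
            if target is left:
                left.idx.extend(run.idx)
            else:
                target.idx = run.idx + target.idx
            del runs[i]
    return runs


def clean_double_recombinants(
    geno: pd.DataFrame,
    mmap: pd.DataFrame,
    min_region_frac: float = 0.001,
    min_run_markers: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Absorb genotype runs too short to be credible into flanking runs.

    Genotyping errors in dense RIL data show up as isolated calls (or very
    short runs) of the opposite homozygote inside an otherwise uniform
    region, implying impossible double crossovers.  Per line and chromosome
    the homozygous calls are segmented into runs; any run whose region
    between crosspoints covers less than ``min_region_frac`` of the
    chromosome's physical size (or that holds fewer than
    ``min_run_markers`` markers) is merged into its flanking runs, and its
    calls corrected to the absorbing allele.  The region rule only bites
    when markers are dense relative to the threshold, which is exactly
    when an isolated opposite call is implausible; raise
    ``min_run_markers`` for stricter smoothing.

    Returns ``(cleaned, breakpoints, report)`` where *breakpoints* has one
    row per retained run boundary (midpoint between bounding markers).
    """
    if not (0 < min_region_frac < 0.1):
        raise ValueError("min_region_frac must lie in (0, 0.1)")
    unmapped = set(geno.columns) - set(mmap["marker"])
    if unmapped:
        raise ValueError(f"markers missing from map: {sorted(unmapped)[:5]} ...")
    cleaned = geno.copy()
    arr = cleaned.to_numpy()
    mpos = mmap.set_index("marker")
    bkp_rows = []
    corrected = 0
    for chrom, sub in mmap[mmap["marker"].isin(geno.columns)].groupby("chrom", sort=False):
        sub = sub.sort_values("bp")
        markers = sub["marker"].to_list()
        cols = [geno.columns.get_loc(m) for m in markers]
        bp_all = sub["bp"].to_numpy(dtype=float)
        cm_all = sub["cm"].to_numpy(dtype=float)
        chrom_size = bp_all[-1] - bp_all[0]
        min_region_bp = min_region_frac * chrom_size
        for li in range(arr.shape[0]):
            calls = arr[li, cols]
            inf = np.flatnonzero((calls == 0) | (calls == 2))
            if inf.size == 0:
                continue
            bp = bp_all[inf]
            cm = cm_all[inf]
            alleles = calls[inf]
            runs: list[_Run] = []
            for k, a in enumerate(alleles):
                if runs and runs[-1].allele == a:
                    runs[-1].idx.append(k)
                else:
                    runs.append(_Run(int(a), [k]))
            runs = _absorb_runs(runs, bp, min_region_bp, min_run_markers)
            for run in runs:
                run.idx.sort()
                for k in run.idx:
                    if alleles[k] != run.allele:
                        arr[li, cols[inf[k]]] = run.allele
                        corrected += 1
            for ra, rb in zip(runs[:-1], runs[1:]):
                a_last, b_first = ra.idx[-1], rb.idx[0]
                bkp_rows.append({
                    "line": geno.index[li],
                    "chrom": chrom,
                    "pos_bp": 0.5 * (bp[a_last] + bp[b_first]),
                    "pos_cm": 0.5 * (cm[a_last] + cm[b_first]),
                    "left_marker": markers[inf[a_last]],
                    "right_marker": markers[inf[b_first]],
                })
    cleaned.loc[:, :] = arr
    breakpoints = pd.DataFrame(
        bkp_rows,
        columns=["line", "chrom", "pos_bp", "pos_cm", "left_marker", "right_marker"],
    )
    report = {"calls_corrected": corrected, "breakpoints": len(bkp_rows)}
    return cleaned, breakpoints, report


# ---------------------------------------------------------------------------
# marker binning
# ---------------------------------------------------------------------------

def bin_redundant_markers(
    geno: pd.DataFrame, mmap: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group markers with identical call patterns; keep one representative.

    Two markers on the same chromosome are redundant when their calls agree
    on every line where both are non-missing (and they share at least one
    such line).  The representative of each bin is the member with the
    fewest missing calls, ties broken by smallest bp.  Markers are compared
    greedily in physical order against existing bin representatives, which
    is deterministic.

    Returns ``(binned_geno, binned_map, membership)``.
    """
    mm = mmap[mmap["marker"].isin(geno.columns)].sort_values(["chrom", "bp"])
    X = geno.to_numpy()
    col_of = {m: geno.columns.get_loc(m) for m in geno.columns}
    rows = []
    kept: list[str] = []
    bin_id = 0
    for chrom, sub in mm.groupby("chrom", sort=False):
        bins: list[dict] = []  # each: rep marker, rep col, members
        for _, rec in sub.iterrows():
            m = rec["marker"]
            cm_col = X[:, col_of[m]]
            placed = False
            for b in bins:
                rep = X[:, b["rep_col"]]
                both = (cm_col != MISSING) & (rep != MISSING)
                if both.any() and np.array_equal(cm_col[both], rep[both]):
                    b["members"].append(m)
                    # representative: fewest missing, tie -> smallest bp (the
                    # incumbent, being earlier in bp order, wins ties)
                    if (cm_col == MISSING).sum() < (rep == MISSING).sum():
                        b["rep"] = m
                        b["rep_col"] = col_of[m]
                    placed = True
                    break
            if not placed:
                bins.append({"rep": m, "rep_col": col_of[m], "members": [m]})
        for b in bins:
            kept.append(b["rep"])
            for m in b["members"]:
                rows.append({
                    "marker": m,
                    "chrom": chrom,
                    "bin": bin_id,
                    "representative": m == b["rep"],
                })
            bin_id += 1
    membership = pd.DataFrame(rows, columns=["marker", "chrom", "bin", "representative"])
    keep_order = [m for m in geno.columns if m in set(kept)]
    binned_geno = geno[keep_order]
    binned_map = mmap[mmap["marker"].isin(keep_order)].reset_index(drop=True)
    return binned_geno, binned_map, membership


# ---------------------------------------------------------------------------
# recombination and map building
# ---------------------------------------------------------------------------

def estimate_recombination(
    geno: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    min_informative: int = 20,
) -> tuple[float, float, int]:
    """Adjacent-pair recombination from homozygous-informative lines.

    Returns ``(R, r, n_informative)`` where R is the observed recombinant
    line fraction (capped at 0.4999) and r the meiotic fraction from the
    selfed-RIL inversion r = R/(2-2R).
    """
    a = geno[marker_a].to_numpy()
    b = geno[marker_b].to_numpy()
    inf = ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
    n = int(inf.sum())
    if n < min_informative:
        raise ValueError(
            f"only {n} informative lines for {marker_a}/{marker_b} "
            f"(need >= {min_informative})"
        )
    R = float((a[inf] != b[inf]).mean())
    R = min(R, R_CAP)
    return R, ril_r_from_R(R), n


def build_map(
    geno: pd.DataFrame,
    phys_map: pd.DataFrame,
    min_informative: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct a Kosambi genetic map over the physical marker order.

    Marker order is taken from physical bp within each chromosome (no de
    novo ordering); interval distances are Kosambi cM of the meiotic r
    inferred from the adjacent-pair RIL recombinant fraction.  Intervals
    whose R hit the cap are flagged.

    Returns ``(marker_map, intervals)``; *marker_map* has estimated ``cm``.
    """
    mm = phys_map[phys_map["marker"].isin(geno.columns)].sort_values(["chrom", "bp"])
    map_rows, interval_rows = [], []
    for chrom, sub in mm.groupby("chrom", sort=False):
        markers = sub["marker"].to_list()
        if len(markers) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 markers")
        cm = 0.0
        map_rows.append({"marker": markers[0], "chrom": chrom,
                         "bp": int(sub["bp"].iloc[0]), "cm": 0.0})
        for i in range(1, len(markers)):
            R, r, n = estimate_recombination(
                geno, markers[i - 1], markers[i], min_informative
            )
            d = kosambi_cm(r)
            capped = R >= R_CAP
            interval_rows.append({
                "chrom": chrom, "left": markers[i - 1], "right": markers[i],
                "R": R, "r": r, "d_cm": d, "n_informative": n, "capped": capped,
            })
            cm += d
            map_rows.append({"marker": markers[i], "chrom": chrom,
                             "bp": int(sub["bp"].iloc[i]), "cm": cm})
    return pd.DataFrame(map_rows), pd.DataFrame(interval_rows)


def map_lengths(marker_map: pd.DataFrame) -> pd.Series:
    """Total genetic length (cM) per chromosome."""
    return marker_map.groupby("chrom", sort=False)["cm"].max()
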