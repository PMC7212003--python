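"""Additive QTL genome scans for RIL populations on a 1 cM grid.

The scan chain follows inclusive composite interval mapping for additive
effects (ICIM-ADD):

1. conditional QTL-genotype probabilities at every grid position from the
   flanking observed markers, under selfed-RIL transition probabilities
   R = 2r/(1+2r) with r the Kosambi inverse of the cM distance;
2. a stepwise (forward-backward) marker regression with a strict entry
   threshold (PIN, default 0.001) picks background cofactors;
3. at each position the phenotype, adjusted for all selected cofactors
   except the flanking markers of the current interval, is regressed on
   the expected additive genotype score P(BB) - P(AA) (Haley-Knott);
   LOD = (n/2) log10(RSS0/RSS1), the additive effect is the slope (half
   the difference between homozygous class means), and PVE is the
   variance fraction explained;
4. peaks with LOD > 2.0 and PVE >= 3% (the study's liberal thresholds)
   become QTL calls with 1-LOD support intervals, named
   ``q{chrom}_{peak cM}``.

Positive additive effects always mean the parent-B (call 2) allele
increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import kosambi_r, ril_R_from_r

__all__ = [
    "GenotypeProbabilities",
    "genotype_probabilities",
    "interval_mapping_scan",
    "stepwise_select",
    "icim_scan",
    "call_qtl",
]


@dataclass
class GenotypeProbabilities:
    """Per-line conditional probabilities of the two homozygous classes.

    ``pB[i, j]`` is P(line i is the parent-B homozygote at scan position
    j); P(parent-A) is its complement.  ``positions`` records chromosome,
    cM, and the structural flanking markers of each position.
    """

    lines: pd.Index
    positions: pd.DataFrame  # chrom, cm, is_marker, left_marker, right_marker
    pB: np.ndarray

    @property
    def score(self) -> np.ndarray:
        """Expected additive score P(BB) - P(AA), in [-1, 1]."""
        return 2.0 * self.pB - 1.0


def genotype_probabilities(
    geno: pd.DataFrame,
    mmap: pd.DataFrame,
    step_cm: float = 1.0,
) -> GenotypeProbabilities:
    """Conditional homozygous-class probabilities on a cM grid.

    The grid holds every multiple of ``step_cm`` within each chromosome
    plus all marker positions.  A line observed at a marker gets
    probability 1 on its observed class there; between markers the
    probabilities condition on the nearest non-missing flanking calls via
    the RIL transition probability; lines missing both flanks get (.5, .5).
    Heterozygous calls are treated as missing.
    """
    mm = mmap[mmap["marker"].isin(geno.columns)].sort_values(["chrom", "cm"])
    pos_frames = []
    pB_blocks = []
    n = geno.shape[0]
    for chrom, sub in mm.groupby("chrom", sort=False):
        mpos = sub["cm"].to_numpy(dtype=float)
        markers = sub["marker"].to_list()
        grid = np.arange(mpos[0], mpos[-1] + 0.5 * step_cm, step_cm)
        pos = np.unique(np.round(np.concatenate([grid, mpos]), 6))
        li_idx = np.searchsorted(mpos, pos, side="right") - 1  # left marker
        ri_idx = np.searchsorted(mpos, pos, side="left")       # right marker
        li_idx = np.clip(li_idx, 0, len(mpos) - 1)
        ri_idx = np.clip(ri_idx, 0, len(mpos) - 1)
        calls = geno[markers].to_numpy()
        obs = (calls == 0) | (calls == 2)
        state = (calls == 2).astype(float)  # 1 = parent-B class
        pB = np.full((n, pos.size), 0.5)
        for i in range(n):
            inf = np.flatnonzero(obs[i])
            if inf.size == 0:
                continue
            ipos = mpos[inf]
            istate = state[i, inf]
            left = np.searchsorted(ipos, pos, side="right") - 1
            right = np.searchsorted(ipos, pos, side="left")
            has_l = left >= 0
            has_r = right < inf.size
            wA = np.ones(pos.size)
            wB = np.ones(pos.size)
            for has, idx, dist_sign in ((has_l, left, 1), (has_r, right, -1)):
                d = np.zeros(pos.size)
                s = np.zeros(pos.size)
                d[has] = np.abs(pos[has] - ipos[np.clip(idx[has], 0, inf.size - 1)])
                s[has] = istate[np.clip(idx[has], 0, inf.size - 1)]
                R = ril_R_from_r(kosambi_r(d))
                # weight of each class given the observed flank state
                wB_side = np.where(has, np.where(s == 1, 1.0 - R, R), 0.5)
                wA_side = np.where(has, np.where(s == 1, R, 1.0 - R), 0.5)
                wA *= wA_side
                wB *= wB_side
            tot = wA + wB
            pB[i] = np.where(tot > 0, wB / tot, 0.5)
        pos_frames.append(pd.DataFrame({
            "chrom": chrom,
            "cm": pos,
            "is_marker": np.isin(np.round(pos, 6), np.round(mpos, 6)),
            "left_marker": [markers[j] for j in li_idx],
            "right_marker": [markers[j] for j in ri_idx],
        }))
        pB_blocks.append(pB)
    positions = pd.concat(pos_frames, ignore_index=True)
    return GenotypeProbabilities(
        lines=geno.index, positions=positions, pB=np.hstack(pB_blocks)
    )


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _regress_on_scores(yc: np.ndarray, X: np.ndarray):
    """Simple regression of centered y on each column of X (with intercept).

    Returns (slope, rss1, tss) arrays; monomorphic columns get slope 0.
    """
    n = yc.size
    Xc = X - X.mean(axis=0, keepdims=True)
    sxx = (Xc ** 2).sum(axis=0)
    sxy = yc @ Xc
    tss = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 1e-12, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = tss - slope * sxy
    rss1 = np.maximum(rss1, 1e-300)
    return slope, rss1, tss


def _profile_frame(gp, lod, slope, pve, n):
    prof = gp.positions.copy()
    prof["lod"] = lod
    prof["additive"] = slope
    prof["pve"] = pve
    prof["n"] = n
    return prof


def interval_mapping_scan(
    phenotype: pd.Series,
    gp: GenotypeProbabilities,
    min_lines: int = 20,
) -> pd.DataFrame:
    """Plain interval mapping: regress phenotype on the expected score.

    Returns a profile DataFrame with columns
    ``chrom, cm, lod, additive, pve, n``.  A zero-variance phenotype
    yields an all-zero profile with ``attrs['zero_variance'] = True``.
    """
    common = gp.lines.intersection(phenotype.index)
    if len(common) < min_lines:
        raise ValueError(f"only {len(common)} informative lines (need >= {min_lines})")
    sel = gp.lines.get_indexer(common)
    y = phenotype.loc[common].to_numpy(dtype=float)
    X = gp.score[sel]
    n = y.size
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        prof = _profile_frame(gp, 0.0, 0.0, 0.0, n)
        prof.attrs["zero_variance"] = True
        return prof
    slope, rss1, tss = _regress_on_scores(yc, X)
    lod = 0.5 * n * np.log10(tss / rss1)
    pve = 1.0 - rss1 / tss
    prof = _profile_frame(gp, lod, slope, pve, n)
    prof.attrs["zero_variance"] = False
    return prof


# ---------------------------------------------------------------------------
# ICIM background selection
# ---------------------------------------------------------------------------

def _marker_scores(geno: pd.DataFrame) -> np.ndarray:
    """Additive scores -1/+1 with missing and het calls mean-imputed."""
    calls = geno.to_numpy(dtype=float)
    score = np.where(calls == 2, 1.0, np.where(calls == 0, -1.0, np.nan))
    col_mean = np.nanmean(np.where(np.isnan(score), np.nan, score), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(score))
    score[idx] = col_mean[idx[1]]
    return score


def stepwise_select(
    y: np.ndarray,
    M: np.ndarray,
    pin: float = 0.001,
    pout: float | None = None,
    max_steps: int = 200,
) -> tuple[list[int], np.ndarray]:
    """Forward-backward stepwise regression of y on marker columns.

    A marker enters when its partial-F p-value is the smallest and
    <= ``pin``; after each entry, selected markers with p > ``pout``
    (default 2*pin) leave.  Returns the selected column indices and the
    joint least-squares coefficients (intercept excluded).
    """
    pout = 2.0 * pin if pout is None else pout
    n, m = M.shape
    selected: list[int] = []
    for _ in range(max_steps):
        changed = False
        X = np.column_stack([np.ones(n)] + [M[:, j] for j in selected])
        Q, _ = np.linalg.qr(X)
        ry = y - Q @ (Q.T @ y)
        k = X.shape[1]
        if n - k - 1 >= 1:
            RM = M - Q @ (Q.T @ M)
            denom = np.sqrt((ry @ ry) * (RM ** 2).sum(axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(denom > 1e-12, (ry @ RM) / np.where(denom > 0, denom, 1.0), 0.0)
            r = np.clip(r, -0.999999999, 0.999999999)
            r[selected] = 0.0
            F = r ** 2 * (n - k - 1) / (1.0 - r ** 2)
            p = stats.f.sf(F, 1, n - k - 1)
            j = int(np.argmin(p))
            if p[j] <= pin and j not in selected:
                selected.append(j)
                changed = True
        # backward elimination
        while selected:
            X = np.column_stack([np.ones(n)] + [M[:, j] for j in selected])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dfres = n - X.shape[1]
            if dfres < 1:
                selected.pop()
                changed = True
                continue
            s2 = resid @ resid / dfres
            XtX_inv = np.linalg.pinv(X.T @ X)
            se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
            tvals = beta / se
            pvals = 2.0 * stats.t.sf(np.abs(tvals), dfres)
            worst = int(np.argmax(pvals[1:])) if len(selected) else 0
            if len(selected) and pvals[1 + worst] > pout:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        return [], np.zeros(0)
    X = np.column_stack([np.ones(n)] + [M[:, j] for j in selected])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return selected, beta[1:]


def icim_scan(
    phenotype: pd.Series,
    gp: GenotypeProbabilities,
    geno: pd.DataFrame,
    pin: float = 0.001,
    pout: float | None = None,
    min_lines: int = 20,
) -> pd.DataFrame:
    """ICIM-ADD: background-adjusted interval scan.

    For every scan position the phenotype is adjusted by subtracting the
    fitted contributions of all stepwise-selected markers except the
    flanking markers of the position's interval, then regressed on the
    expected genotype score.  With no selected markers this reduces to
    plain interval mapping.  PVE is reported against the unadjusted
    phenotypic variance.
    """
    common = gp.lines.intersection(phenotype.index)
    if len(common) < min_lines:
        raise ValueError(f"only {len(common)} informative lines (need >= {min_lines})")
    sel_idx = gp.lines.get_indexer(common)
    y = phenotype.loc[common].to_numpy(dtype=float)
    n = y.size
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        prof = _profile_frame(gp, 0.0, 0.0, 0.0, n)
        prof.attrs["zero_variance"] = True
        return prof
    geno_l = geno.loc[common]
    M = _marker_scores(geno_l)
    selected, coefs = stepwise_select(yc, M, pin=pin, pout=pout)
    if len(selected) >= n / 2:
        raise RuntimeError(
            f"stepwise selected {len(selected)} markers for n={n}; "
            "background model is oversaturated"
        )
    marker_names = list(geno_l.columns)
    sel_names = {marker_names[j]: (j, c) for j, c in zip(selected, coefs)}
    y_base = yc.copy()
    for j, c in zip(selected, coefs):
        y_base -= c * M[:, j]
    Xscore = gp.score[sel_idx]
    P = Xscore.shape[1]
    lod = np.zeros(P)
    slope = np.zeros(P)
    pve = np.zeros(P)
    # group positions by their set of selected flanking markers
    keys = []
    for lm, rm in zip(gp.positions["left_marker"], gp.positions["right_marker"]):
        keys.append(tuple(sorted({m for m in (lm, rm) if m in sel_names})))
    keys = pd.Series(keys)
    for key in keys.unique():
        mask = (keys == key).to_numpy()
        y_adj = y_base.copy()
        for mname in key:
            j, c = sel_names[mname]
            y_adj += c * M[:, j]
        y_adj = y_adj - y_adj.mean()
        rss0 = float(y_adj @ y_adj)
        if rss0 <= 0:
            continue
        sl, rss1, _ = _regress_on_scores(y_adj, Xscore[:, mask])
        lod[mask] = 0.5 * n * np.log10(rss0 / rss1)
        slope[mask] = sl
        pve[mask] = (rss0 - rss1) / tss
    prof = _profile_frame(gp, lod, slope, np.clip(pve, 0.0, 1.0), n)
    prof.attrs["zero_variance"] = False
    prof.attrs["selected_markers"] = [marker_names[j] for j in selected]
    return prof


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

def call_qtl(
    profile: pd.DataFrame,
    lod_min: float = 2.0,
    pve_min: float = 0.03,
    peak_sep_cm: float = 20.0,
    mmap: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Turn a LOD profile into QTL calls.

    Local maxima above both thresholds become calls; two maxima on one
    chromosome are distinct when separated by a dip below ``lod_min`` or
    by at least ``peak_sep_cm``.  The support interval is the contiguous
    region within 1 LOD of the peak; names follow ``q{chrom}_{peak cM}``.
    """
    calls = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.sort_values("cm").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        cm = sub["cm"].to_numpy()
        above = lod > lod_min
        if not above.any():
            continue
        # contiguous segments above the threshold
        seg_starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
        seg_ends = np.flatnonzero(above & ~np.r_[above[1:], False])
        accepted = []
        for s, e in zip(seg_starts, seg_ends):
            seg = np.arange(s, e + 1)
            # local maxima within segment, highest first
            is_max = np.ones(seg.size, dtype=bool)
            if seg.size > 1:
                l = np.r_[True, lod[seg][1:] >= lod[seg][:-1]]
                r = np.r_[lod[seg][:-1] >= lod[seg][1:], True]
                is_max = l & r
            cand = seg[is_max]
            # a dip below the calling threshold already separates segments;
            # within one segment a second maximum counts as distinct only
            # when it is far enough away AND the profile drops at least
            # 1 LOD below the smaller maximum in between (otherwise it is
            # a noise shoulder of the same peak)
            seg_accept = []
            for i in cand[np.argsort(-lod[cand], kind="stable")]:
                distinct = True
                for j in seg_accept:
                    if abs(cm[i] - cm[j]) < peak_sep_cm:
                        distinct = False
                        break
                    lo_, hi_ = sorted((i, j))
                    valley = lod[lo_:hi_ + 1].min()
                    if valley > min(lod[i], lod[j]) - 1.0:
                        distinct = False
                        break
                if distinct:
                    seg_accept.append(i)
            accepted.extend(seg_accept)
        for i in sorted(accepted):
            if sub["pve"].iloc[i] < pve_min:
                continue
            # 1-LOD support interval
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - 1.0:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] >= lod[i] - 1.0:
                hi += 1
            rec = {
                "name": f"q{chrom}_{int(round(cm[i]))}",
                "chrom": chrom,
                "peak_cm": float(cm[i]),
                "lod": float(lod[i]),
                "pve": float(sub["pve"].iloc[i]),
                "additive": float(sub["additive"].iloc[i]),
                "ci_lo_cm": float(cm[lo]),
                "ci_hi_cm": float(cm[hi]),
                "left_marker": sub["left_marker"].iloc[i],
                "right_marker": sub["right_marker"].iloc[i],
                "n": int(sub["n"].iloc[i]),
            }
            if mmap is not None:
                rec["ci_lo_bp"] = _cm_to_bp(mmap, chrom, cm[lo])
                rec["ci_hi_bp"] = _cm_to_bp(mmap, chrom, cm[hi])
            calls.append(rec)
    cols = ["name", "chrom", "peak_cm", "lod", "pve", "additive",
            "ci_lo_cm", "ci_hi_cm", "left_marker", "right_marker", "n"]
    if mmap is not None:
        cols += ["ci_lo_bp", "ci_hi_bp"]
    return pd.DataFrame(calls, columns=cols)


def _cm_to_bp(mmap: pd.DataFrame, chrom, cm_val: float) -> float:
    sub = mmap[mmap["chrom"] == chrom].sort_values("cm")
    return float(np.interp(cm_val, sub["cm"], sub["bp"]))
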