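"""Synthetic RIL genotypes, trait architectures, and field-trial phenotypes.

The generator emulates a multi-environment UAS height-phenotyping study on
biparental recombinant inbred line (RIL) populations:

* genotypes arise from a Markov chain along each chromosome with the
  selfed-RIL (F-infinity) transition probability R = 2r/(1+2r), where the
  meiotic fraction r between adjacent markers is the Kosambi inverse of
  their cM spacing; residual heterozygosity is injected at a configurable
  rate (default 3%, roughly (1/2)^5 for F6 material);
* each entry carries true Weibull growth parameters (L, x0, b) built from
  population means, additive QTL effects on the parameters, and polygenic
  (normal) deviations; optional QTL act directly on height inside a DAS
  window to mimic transient, environment-triggered loci;
* plot heights follow the randomized-complete-block model
  Y = mu + G + Rep + Range + Row + eps, with the genetic value given by
  the entry's Weibull curve at the flight date, and independent Gaussian
  rep/range/row/residual effects;
* a ground-truth record of every draw supports recovery testing.

Defaults mirror the study conditions: three populations of 102/237/178
lines, 10 chromosomes, two environments x two replicates, eight usable
flights at DAS {35, 43, 57, 62, 65, 69, 100, 117}, flight noise 0.03 m,
and parameter means (L, x0, b) = (1.10 m, 58 DAS, 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import kosambi_r, ril_R_from_r

__all__ = [
    "MapSpec",
    "QTLEffect",
    "TraitArchitecture",
    "TrialDesign",
    "SyntheticTruth",
    "default_map_spec",
    "default_population_sizes",
    "simulate_ril_population",
    "entry_parameters",
    "daily_genetic_values",
    "simulate_trial",
    "make_plot_rectangles",
    "simulate_point_cloud_field",
    "DEFAULT_FLIGHT_DAS",
    "PARAM_MEANS",
]

DEFAULT_FLIGHT_DAS = (35, 43, 57, 62, 65, 69, 100, 117)
PARAM_MEANS = {"L": 1.10, "x0": 58.0, "b": 7.0}
#: population (polygenic + QTL) spread of the growth parameters; chosen so
#: that entry curves differ visibly mid-season but stay within the ranges
#: typical of maize inbred trials
PARAM_POLYGENIC_SD = {"L": 0.06, "x0": 2.5, "b": 0.8}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class MapSpec:
    """Chromosome layout: (name, length in cM, number of markers) triples.

    Markers are evenly spaced from 0 to the chromosome length; physical
    positions scale linearly at ``bp_per_cm`` (default 1.5 Mb/cM, the
    genome-wide average for maize).
    """

    chromosomes: list[tuple[str, float, int]]
    bp_per_cm: float = 1.5e6

    def __post_init__(self):
        for name, length, n in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
            if n < 2:
                raise ValueError(f"chromosome {name}: need >= 2 markers")

    def marker_map(self) -> pd.DataFrame:
        rows = []
        for name, length, n in self.chromosomes:
            cms = np.linspace(0.0, length, n)
            for i, cm in enumerate(cms):
                rows.append({
                    "marker": f"m{name}_{i + 1:03d}",
                    "chrom": name,
                    "bp": int(round(cm * self.bp_per_cm)) + 1,
                    "cm": float(cm),
                })
        return pd.DataFrame(rows)


def default_map_spec(n_chrom: int = 10, length_cm: float = 130.0,
                     markers_per_chrom: int = 27) -> MapSpec:
    """Ten ~130 cM chromosomes, markers every 5 cM by default."""
    return MapSpec([(str(c + 1), length_cm, markers_per_chrom)
                    for c in range(n_chrom)])


def default_population_sizes() -> dict[str, int]:
    """The three RIL population sizes of the emulated study."""
    return {"POP1": 102, "POP2": 237, "POP3": 178}


@dataclass
class QTLEffect:
    """One additive QTL: acts on a Weibull parameter, or directly on height
    within a DAS window (``param='height'`` with ``window=(on, off)``)."""

    chrom: str
    pos_cm: float
    param: str                      # 'L' | 'x0' | 'b' | 'height'
    effect: float                   # additive effect in parameter units
    window: tuple[int, int] | None = None  # DAS activity window for 'height'

    def __post_init__(self):
        if self.param not in ("L", "x0", "b", "height"):
            raise ValueError(f"unknown target parameter {self.param!r}")
        if self.param == "height" and self.window is None:
            raise ValueError("direct height QTL needs an activity window")
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")


@dataclass
class TraitArchitecture:
    """Genetic architecture of the growth curve."""

    qtl: list[QTLEffect] = field(default_factory=list)
    polygenic_sd: dict[str, float] = field(
        default_factory=lambda: dict(PARAM_POLYGENIC_SD))
    means: dict[str, float] = field(default_factory=lambda: dict(PARAM_MEANS))

    def __post_init__(self):
        for p, m in self.means.items():
            if m <= 0:
                raise ValueError(f"parameter mean {p} must be positive")


@dataclass
class TrialDesign:
    """RCBD layout, flight schedule, and noise model.

    Every entry appears once per replicate; plots fill a ranges-by-rows
    grid (replicates stacked along ranges).  Environment shifts move the
    population-mean growth parameters (e.g. water stress delaying x0).
    """

    environments: tuple[str, ...] = ("irrigated", "non_irrigated")
    n_reps: int = 2
    n_rows: int = 17
    flight_das: tuple[int, ...] = DEFAULT_FLIGHT_DAS
    resid_sd: float = 0.03   # per-flight measurement noise, m
    rep_sd: float = 0.01     # replicate effect sd, m
    range_sd: float = 0.015  # range (spatial) effect sd, m
    row_sd: float = 0.015    # row (spatial) effect sd, m
    env_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"irrigated": {},
                                 "non_irrigated": {"x0": 2.0, "L": -0.04}})

    def __post_init__(self):
        if any(d <= 0 for d in self.flight_das):
            raise ValueError("flight DAS must be positive")
        for sd in (self.resid_sd, self.rep_sd, self.range_sd, self.row_sd):
            if sd < 0:
                raise ValueError("noise sds must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside observations, for recovery tests."""

    entry_params: pd.DataFrame        # entry, env, L, x0, b
    qtl: pd.DataFrame                 # chrom, pos_cm, param, effect, window
    variance_components: pd.DataFrame  # env, das, component, value
    effects: dict                     # env -> dict of rep/range/row draws
    breakpoints: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_ril_population(
    map_spec: MapSpec,
    n_lines: int,
    het_rate: float = 0.03,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw RIL genotypes as a Markov chain along each chromosome.

    Between adjacent markers spaced d cM apart, the chain switches
    homozygous class with probability R = 2r/(1+2r) where r is the Kosambi
    inverse of d — the fixation probability of a recombinant chromatid
    under repeated selfing.  Heterozygous calls (1) overwrite homozygous
    calls independently at ``het_rate``.

    Returns ``(genotypes, marker_map, breakpoints)``; breakpoints are the
    true switch positions (interval midpoints, cM and bp) per line.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not (0 <= het_rate < 0.5):
        raise ValueError("het_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mmap = map_spec.marker_map()
    line_ids = [f"L{i + 1:04d}" for i in range(n_lines)]
    blocks = []
    bkp_rows = []
    for chrom, sub in mmap.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy()
        bp = sub["bp"].to_numpy()
        m = cm.size
        R = ril_R_from_r(kosambi_r(np.diff(cm)))
        start = rng.integers(0, 2, size=n_lines)
        switches = rng.random((n_lines, m - 1)) < R
        state = np.empty((n_lines, m), dtype=np.int8)
        state[:, 0] = start
        cum = np.cumsum(switches, axis=1) % 2
        state[:, 1:] = (start[:, None] + cum) % 2
        calls = state * 2  # 0 / 2
        for li in range(n_lines):
            for j in np.flatnonzero(switches[li]):
                bkp_rows.append({
                    "line": line_ids[li], "chrom": chrom,
                    "pos_cm": 0.5 * (cm[j] + cm[j + 1]),
                    "pos_bp": 0.5 * (bp[j] + bp[j + 1]),
                })
        blocks.append(pd.DataFrame(calls, index=line_ids, columns=sub["marker"]))
    geno = pd.concat(blocks, axis=1).astype(np.int8)
    if het_rate > 0:
        het = rng.random(geno.shape) < het_rate
        arr = geno.to_numpy()
        arr[het] = 1
        geno.loc[:, :] = arr
    breakpoints = pd.DataFrame(bkp_rows, columns=["line", "chrom", "pos_cm", "pos_bp"])
    return geno, mmap, breakpoints


# ---------------------------------------------------------------------------
# trait architecture -> entry parameters and genetic values
# ---------------------------------------------------------------------------

def _qtl_scores(geno: pd.DataFrame, mmap: pd.DataFrame, qtl: QTLEffect) -> np.ndarray:
    """Additive score (-1/0/+1) at the marker nearest the QTL position."""
    sub = mmap[mmap["chrom"] == qtl.chrom]
    if sub.empty:
        raise ValueError(f"QTL chromosome {qtl.chrom!r} not in map")
    if not (sub["cm"].min() <= qtl.pos_cm <= sub["cm"].max()):
        raise ValueError(f"QTL position {qtl.pos_cm} outside chromosome {qtl.chrom}")
    nearest = sub.iloc[(sub["cm"] - qtl.pos_cm).abs().argmin()]["marker"]
    calls = geno[nearest].to_numpy()
    score = np.where(calls == 2, 1.0, np.where(calls == 0, -1.0, 0.0))
    return score


def entry_parameters(
    geno: pd.DataFrame,
    mmap: pd.DataFrame,
    arch: TraitArchitecture,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True (L, x0, b) per entry: means + QTL effects + polygenic draws."""
    n = geno.shape[0]
    params = {p: np.full(n, arch.means[p]) for p in ("L", "x0", "b")}
    for q in arch.qtl:
        if q.param == "height":
            continue
        params[q.param] = params[q.param] + q.effect * _qtl_scores(geno, mmap, q)
    for p in ("L", "x0", "b"):
        sd = arch.polygenic_sd.get(p, 0.0)
        if sd > 0:
            params[p] = params[p] + rng.normal(0.0, sd, size=n)
        params[p] = np.maximum(params[p], 1e-3)  # keep parameters positive
    return pd.DataFrame({"entry": geno.index, **params})


def daily_genetic_values(
    geno: pd.DataFrame,
    mmap: pd.DataFrame,
    arch: TraitArchitecture,
    days: np.ndarray,
    rng: np.random.Generator | None = None,
    entry_params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genetic value (m) of every entry on each day, incl. windowed QTL.

    The deterministic part of the phenotype: the entry's Weibull curve
    plus any direct height QTL active on that day.  Used as the oracle in
    temporal-recovery tests and by the trial simulator.
    """
    days = np.asarray(days)
    if entry_params is None:
        if rng is None:
            rng = np.random.default_rng(0)
        entry_params = entry_parameters(geno, mmap, arch, rng)
    L = entry_params["L"].to_numpy()[:, None]
    x0 = entry_params["x0"].to_numpy()[:, None]
    b = entry_params["b"].to_numpy()[:, None]
    t = days.astype(float)[None, :]
    g = L * (1.0 - np.exp(-((t / x0) ** b)))
    for q in arch.qtl:
        if q.param != "height":
            continue
        score = _qtl_scores(geno, mmap, q)
        active = (days >= q.window[0]) & (days <= q.window[1])
        g[:, active] += np.outer(score, np.full(active.sum(), q.effect))
    return pd.DataFrame(g, index=geno.index, columns=days)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _layout(entries: list[str], design: TrialDesign, env: str,
            rng: np.random.Generator) -> pd.DataFrame:
    """RCBD plot layout for one environment: entry -> (rep, range, row)."""
    rows = []
    range_offset = 0
    for rep in range(1, design.n_reps + 1):
        order = rng.permutation(len(entries))
        for k, ei in enumerate(order):
            rows.append({
                "entry": entries[ei], "env": env, "rep": rep,
                "range": range_offset + k // design.n_rows + 1,
                "row": k % design.n_rows + 1,
            })
        range_offset += (len(entries) + design.n_rows - 1) // design.n_rows
    return pd.DataFrame(rows)


def simulate_trial(
    geno: pd.DataFrame,
    mmap: pd.DataFrame,
    arch: TraitArchitecture,
    design: TrialDesign,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit noisy multi-flight plot heights plus the full ground truth.

    Each plot x flight yields one height observation
    ``weibull(entry params shifted by env, DAS) + windowed QTL + Rep +
    Range + Row + eps`` with independent Gaussian effects at the design's
    standard deviations.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    entries = list(geno.index)
    base_params = entry_parameters(geno, mmap, arch, rng)
    days = np.asarray(design.flight_das)
    obs_rows = []
    truth_params = []
    effects: dict[str, dict] = {}
    vc_rows = []
    for env in design.environments:
        shift = design.env_shifts.get(env, {})
        ep = base_params.copy()
        for p, dv in shift.items():
            ep[p] = np.maximum(ep[p] + dv, 1e-3)
        ep.insert(1, "env", env)
        truth_params.append(ep)
        gvals = daily_genetic_values(geno, mmap, arch, days, entry_params=ep)
        layout = _layout(entries, design, env, rng)
        n_ranges = int(layout["range"].max())
        n_rows_used = int(layout["row"].max())
        rep_eff = rng.normal(0.0, design.rep_sd, size=design.n_reps)
        range_eff = rng.normal(0.0, design.range_sd, size=n_ranges)
        row_eff = rng.normal(0.0, design.row_sd, size=n_rows_used)
        effects[env] = {"rep": rep_eff, "range": range_eff, "row": row_eff}
        entry_pos = {e: i for i, e in enumerate(entries)}
        for _, plot in layout.iterrows():
            gi = entry_pos[plot["entry"]]
            eps = rng.normal(0.0, design.resid_sd, size=days.size)
            heights = (
                gvals.iloc[gi].to_numpy()
                + rep_eff[plot["rep"] - 1]
                + range_eff[plot["range"] - 1]
                + row_eff[plot["row"] - 1]
                + eps
            )
            for d, h in zip(days, heights):
                obs_rows.append({
                    "entry": plot["entry"], "env": env, "rep": plot["rep"],
                    "range": plot["range"], "row": plot["row"],
                    "das": int(d), "height_m": h,
                })
        gvar = gvals.var(axis=0, ddof=1)
        for d in days:
            vc_rows.append({"env": env, "das": int(d), "component": "G",
                            "value": float(gvar[d])})
            for comp, sd in (("Rep", design.rep_sd), ("Range", design.range_sd),
                             ("Row", design.row_sd), ("Residual", design.resid_sd)):
                vc_rows.append({"env": env, "das": int(d), "component": comp,
                                "value": sd ** 2})
    observations = pd.DataFrame(obs_rows)
    truth = SyntheticTruth(
        entry_params=pd.concat(truth_params, ignore_index=True),
        qtl=pd.DataFrame([{
            "chrom": q.chrom, "pos_cm": q.pos_cm, "param": q.param,
            "effect": q.effect,
            "window_on": q.window[0] if q.window else np.nan,
            "window_off": q.window[1] if q.window else np.nan,
        } for q in arch.qtl]),
        variance_components=pd.DataFrame(vc_rows),
        effects=effects,
    )
    return observations, truth


# ---------------------------------------------------------------------------
# point-cloud fixtures
# ---------------------------------------------------------------------------

def make_plot_rectangles(
    n_ranges: int,
    n_rows: int,
    row_spacing: float = 0.76,
    plot_length: float = 3.81,
) -> pd.DataFrame:
    """Axis-aligned plot rectangles on the standard field grid.

    Rows advance along x at ``row_spacing`` (0.76 m) and ranges along y at
    ``plot_length`` (3.81 m).
    """
    rows = []
    for rg in range(n_ranges):
        for rw in range(n_rows):
            rows.append({
                "plot_id": f"R{rg + 1:02d}C{rw + 1:02d}",
                "x_min": rw * row_spacing, "y_min": rg * plot_length,
                "x_max": (rw + 1) * row_spacing, "y_max": (rg + 1) * plot_length,
            })
    return pd.DataFrame(rows)


def simulate_point_cloud_field(
    rectangles: pd.DataFrame,
    plot_heights: dict[str, float],
    ground: tuple[float, float, float] = (0.0, 0.0, 0.0),
    density: float = 50.0,
    seed: int | np.random.Generator = 0,
    ground_margin: float = 1.0,
) -> tuple[np.ndarray, list[str]]:
    """Synthetic XYZ cloud: planar ground plus uniform canopy per plot.

    ``ground`` holds plane coefficients (a, b, c) with z = a*x + b*y + c.
    Canopy points fall uniformly in [0, plant height] above the ground
    inside each plot footprint at ``density`` points/m^2; ground points
    cover the field bounding box (plus a margin) at the same density.
    Returns ``(points, empty_plots)`` where *empty_plots* lists plot ids
    that received zero canopy points.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    r = rectangles
    widths = r["x_max"] - r["x_min"]
    if (widths <= 0).any() or ((r["y_max"] - r["y_min"]) <= 0).any():
        raise ValueError("degenerate plot rectangle")
    for i in range(len(r)):
        a = r.iloc[i]
        overlap = (
            (r["x_min"] < a["x_max"]) & (r["x_max"] > a["x_min"])
            & (r["y_min"] < a["y_max"]) & (r["y_max"] > a["y_min"])
        )
        if overlap.sum() > 1:
            raise ValueError("overlapping plot rectangles")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ga, gb, gc = ground
    x0, x1 = r["x_min"].min() - ground_margin, r["x_max"].max() + ground_margin
    y0, y1 = r["y_min"].min() - ground_margin, r["y_max"].max() + ground_margin
    n_ground = max(int(density * (x1 - x0) * (y1 - y0)), 3)
    gx = rng.uniform(x0, x1, n_ground)
    gy = rng.uniform(y0, y1, n_ground)
    gz = ga * gx + gb * gy + gc
    pts = [np.column_stack([gx, gy, gz])]
    empty = []
    for _, rec in r.iterrows():
        h = float(plot_heights.get(rec["plot_id"], 0.0))
        area = (rec["x_max"] - rec["x_min"]) * (rec["y_max"] - rec["y_min"])
        n = int(density * area) if h > 0 else 0
        if n == 0:
            empty.append(rec["plot_id"])
            continue
        cx = rng.uniform(rec["x_min"], rec["x_max"], n)
        cy = rng.uniform(rec["y_min"], rec["y_max"], n)
        cz = ga * cx + gb * cy + gc + rng.uniform(0.0, h, n)
        pts.append(np.column_stack([cx, cy, cz]))
    return np.vstack(pts), empty
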