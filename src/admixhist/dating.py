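"""Simulation-calibrated dating of admixture events from wavelet centers.

The wavelet center of a two-population ancestry signal decreases
monotonically with the age of the admixture event (older events leave
narrower blocks, pushing spectral energy to finer scales).  A calibration
table of center means over a (generations, admixture rate) grid, built from
single-pulse simulations matched to the observed data (same genome, window
grid, population size, sample size, and the same masked window positions),
lets the observed center be inverted into a point estimate of generations
since admixture by linear interpolation along the g axis at the admixture
rate nearest the observed one.  Confidence intervals come from resampling
chromosomes with replacement and re-pooling the spectrum.

Multiple events are dated sequentially, most recent first: the most recent
ancestry (per the inferred arrival order) is dated against the union of all
older ancestries, then masked; the next event is dated on the remaining
genome against a calibration table carrying the identical cumulative mask.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .ahg import AHGResult
from .io import MASKED, GeneticMap, LocalAncestryPanel, QMatrix, WindowGrid
from .simulate import AdmixtureHistorySpec, simulate_history
from .tracts import (
    POP1,
    POP2,
    SignalError,
    WaveletSummary,
    center_from_energies,
    encode_signal,
    mask_ancestry,
    merge_ancestries,
    wavelet_center,
)

__all__ = [
    "CalibrationTable",
    "DateEstimate",
    "DatingConfig",
    "CalibrationRangeError",
    "build_calibration",
    "estimate_generations",
    "date_events",
    "generations_to_years",
    "mask_key",
]

DEFAULT_G_GRID = tuple(range(5, 201, 5))
DEFAULT_M_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


class CalibrationRangeError(ValueError):
    """Observed center falls outside the calibrated range: the date is beyond
    the resolution the calibration covers."""


def mask_key(mask: np.ndarray | None) -> str | None:
    """Stable fingerprint of a boolean mask (provenance matching)."""
    if mask is None or not np.any(mask):
        return None
    return hashlib.sha1(np.packbits(mask.astype(bool)).tobytes()).hexdigest()[:16]


def generations_to_years(g: float, generation_time: float = 29.0) -> float:
    """Calendar-year depth of an event ``g`` generations ago."""
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    return g * generation_time


@dataclass
class DatingSimConfig:
    """Simulation conditions shared by calibration and validation runs."""

    gmap: GeneticMap
    grid: WindowGrid
    population_size: int = 500
    sample_haplotypes: int = 40


@dataclass
class CalibrationTable:
    """Mean (and spread of) wavelet centers over a (g, m) simulation grid."""

    g_grid: np.ndarray
    m_grid: np.ndarray
    center_mean: np.ndarray  # (len(g_grid), len(m_grid))
    center_sd: np.ndarray
    n_replicates: int
    metadata: dict = field(default_factory=dict)
    nonmonotone: list[tuple[float, float]] = field(default_factory=list)

    def m_column(self, m_obs: float) -> int:
        return int(np.argmin(np.abs(self.m_grid - m_obs)))

    def to_dict(self) -> dict:
        return {
            "g_grid": self.g_grid.tolist(),
            "m_grid": self.m_grid.tolist(),
            "center_mean": self.center_mean.tolist(),
            "center_sd": self.center_sd.tolist(),
            "n_replicates": self.n_replicates,
            "metadata": self.metadata,
            "nonmonotone": [list(c) for c in self.nonmonotone],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        return cls(
            np.asarray(d["g_grid"], dtype=float),
            np.asarray(d["m_grid"], dtype=float),
            np.asarray(d["center_mean"], dtype=float),
            np.asarray(d["center_sd"], dtype=float),
            int(d["n_replicates"]),
            dict(d.get("metadata", {})),
            [tuple(c) for c in d.get("nonmonotone", [])],
        )

    def to_frame(self):
        """Tidy long-format view: one row per (g, m) cell."""
        import pandas as pd

        rows = [
            {
                "g": float(g), "m": float(m),
                "center_mean": float(self.center_mean[i, j]),
                "center_sd": float(self.center_sd[i, j]),
                "n_replicates": self.n_replicates,
                "nonmonotone": (float(g), float(m)) in self.nonmonotone,
            }
            for i, g in enumerate(self.g_grid)
            for j, m in enumerate(self.m_grid)
        ]
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        """Write the table as JSON plus a TSV sibling (same stem)."""
        path = str(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        stem = path[:-5] if path.endswith(".json") else path
        self.to_frame().to_csv(stem + ".tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _single_pulse_center(
    g: int,
    m: float,
    sim: DatingSimConfig,
    mask: np.ndarray | None,
    seed: int,
) -> float:
    spec = AdmixtureHistorySpec(
        founding_generation=int(g),
        founding_components=(POP1, POP2),
        founding_m=1.0 - m,  # m is the proportion of population 2
        population_size=sim.population_size,
        sample_size=sim.sample_haplotypes,
    )
    sample = simulate_history(spec, sim.gmap, sim.grid, seed=seed, build_tracts=False)
    signal = encode_signal(sample.panel, sim.grid)
    if mask is not None:
        signal = signal.copy()
        signal[mask] = 0.0
    return wavelet_center(signal, sim.grid).center


def build_calibration(
    g_grid: Sequence[float] = DEFAULT_G_GRID,
    m_grid: Sequence[float] = DEFAULT_M_GRID,
    mask: np.ndarray | None = None,
    sim_config: DatingSimConfig | None = None,
    R: int = 20,
    seed: int = 0,
) -> CalibrationTable:
    """Simulate R single-pulse replicates per (g, m) cell and record the mean
    and spread of the wavelet center, with the given mask positions applied
    to every simulated signal.

    The g column means should decrease with g at each m; non-monotone cells
    (simulation noise) are flagged in the table.
    """
    if R < 20:
        raise ValueError("need at least 20 replicates per cell")
    g_grid = np.asarray(sorted(g_grid), dtype=float)
    m_grid = np.asarray(sorted(m_grid), dtype=float)
    if np.any(np.diff(g_grid) <= 0) or g_grid[0] < 1:
        raise ValueError("g_grid must be ascending, >= 1")
    sim = sim_config or DatingSimConfig(*_default_genome())
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        expected = (sim.sample_haplotypes, sim.grid.total_windows)
        if mask.shape != expected:
            raise ValueError(
                f"mask shape {mask.shape} does not match simulated panels {expected}"
            )
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(len(g_grid), len(m_grid), R))
    mean = np.empty((len(g_grid), len(m_grid)))
    sd = np.empty_like(mean)
    for j, m in enumerate(m_grid):
        for i, g in enumerate(g_grid):
            centers = [
                _single_pulse_center(int(g), float(m), sim, mask, int(seeds[i, j, r]))
                for r in range(R)
            ]
            mean[i, j] = np.mean(centers)
            sd[i, j] = np.std(centers, ddof=1)
    nonmono = []
    for j, m in enumerate(m_grid):
        bad = np.nonzero(np.diff(mean[:, j]) > 0)[0]
        for i in bad:
            nonmono.append((float(g_grid[i + 1]), float(m)))
    meta = {
        "population_size": sim.population_size,
        "sample_haplotypes": sim.sample_haplotypes,
        "chromosomes": list(sim.grid.chromosomes),
        "window_counts": dict(sim.grid.window_counts),
        "mask_key": mask_key(mask),
        "masked_fraction": float(mask.mean()) if mask is not None else 0.0,
        "seed": seed,
        "R": R,
    }
    return CalibrationTable(g_grid, m_grid, mean, sd, R, meta, nonmono)


def _default_genome():
    from .simulate import desk_genome

    return desk_genome()


@dataclass
class DateEstimate:
    """One dated admixture event."""

    event: str
    generations: float | None
    ci_generations: tuple[float, float] | None
    years: float | None
    m_used: float
    m_observed: float
    masked_fraction: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "event": self.event,
            "generations": self.generations,
            "ci_generations": list(self.ci_generations) if self.ci_generations else None,
            "years": self.years,
            "m_used": self.m_used,
            "m_observed": self.m_observed,
            "masked_fraction": self.masked_fraction,
            "warnings": list(self.warnings),
        }


def _monotone_inverse(g_grid: np.ndarray, centers: np.ndarray):
    """Fit a non-increasing center(g) curve and return an inverse usable with
    np.interp, plus the invertible center range."""
    iso = IsotonicRegression(increasing=False)
    fit = iso.fit_transform(g_grid, centers)
    # collapse plateaus: mean g per distinct fitted center
    xs, ys = [], []
    i = 0
    while i < len(fit):
        j = i
        while j + 1 < len(fit) and fit[j + 1] == fit[i]:
            j += 1
        xs.append(fit[i])
        ys.append(float(np.mean(g_grid[i:j + 1])))
        i = j + 1
    xs = np.array(xs)[::-1]  # ascending centers
    ys = np.array(ys)[::-1]
    return xs, ys, (float(fit.min()), float(fit.max()))


def estimate_generations(
    summary: WaveletSummary,
    m_obs: float,
    table: CalibrationTable,
    generation_time: float = 29.0,
    n_bootstrap: int = 200,
    seed: int = 0,
    event: str = "admixture",
) -> DateEstimate:
    """Invert an observed wavelet center into generations since admixture.

    Uses the calibration column with the admixture rate nearest ``m_obs``;
    the center->g relation is made monotone (isotonic fit) and inverted by
    linear interpolation.  The CI resamples chromosomes with replacement,
    re-pools the spectrum and re-inverts (clipped to the calibrated range).
    """
    warnings_: list[str] = []
    if table.metadata.get("mask_key") != summary.mask_key:
        warnings_.append(
            "calibration mask provenance differs from the summary's mask"
        )
    if len(table.m_grid) > 1:
        step = float(np.max(np.diff(table.m_grid)))
    else:
        step = float(table.metadata.get("m_step", 0.05))
    col = table.m_column(m_obs)
    m_used = float(table.m_grid[col])
    if abs(m_used - m_obs) > step:
        raise ValueError(
            f"observed admixture rate {m_obs:.3f} outside the calibrated m grid"
        )
    xs, ys, (cmin, cmax) = _monotone_inverse(table.g_grid, table.center_mean[:, col])
    if not cmin <= summary.center <= cmax:
        raise CalibrationRangeError(
            f"center {summary.center:.3f} outside calibrated range "
            f"[{cmin:.3f}, {cmax:.3f}]: date beyond calibrated range"
        )
    point = float(np.interp(summary.center, xs, ys))
    rng = np.random.default_rng(seed)
    chroms = list(summary.chrom_energies)
    boots = []
    for _ in range(n_bootstrap):
        pick = rng.integers(0, len(chroms), size=len(chroms))
        pooled = np.sum([summary.chrom_energies[chroms[i]] for i in pick], axis=0)
        try:
            c = center_from_energies(pooled, summary.scale_axis)
        except SignalError:
            continue
        boots.append(float(np.interp(np.clip(c, cmin, cmax), xs, ys)))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), point), max(float(hi), point))
    else:
        ci = (point, point)
    return DateEstimate(
        event=event,
        generations=point,
        ci_generations=ci,
        years=generations_to_years(point, generation_time),
        m_used=m_used,
        m_observed=float(m_obs),
        masked_fraction=1.0 - summary.callable_fraction,
        warnings=warnings_,
    )


@dataclass
class DatingConfig:
    """Options for sequential dating of an inferred arrival order."""

    sim: DatingSimConfig
    g_grid: tuple = DEFAULT_G_GRID
    m_grid: tuple = DEFAULT_M_GRID
    replicates: int = 20
    generation_time: float = 29.0
    n_bootstrap: int = 200
    seed: int = 0
    max_masked_fraction: float = 0.8
    mask_mode: str = "positions"  # or "length": randomized mask placement
    table_cache: dict = field(default_factory=dict)


def _randomize_mask(mask: np.ndarray, grid: WindowGrid, rng) -> np.ndarray:
    """Length-matched random mask: circularly shift each haplotype-chromosome
    mask row by a random offset, preserving run-length structure."""
    out = mask.copy()
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        for h in range(out.shape[0]):
            out[h, sl] = np.roll(out[h, sl], int(rng.integers(0, sl.stop - sl.start)))
    return out


def _step_table(
    config: DatingConfig, mask: np.ndarray | None, m_obs: float, seed: int
) -> CalibrationTable:
    """Build (or fetch) a single-m-column calibration table for one step."""
    m_grid = np.asarray(config.m_grid, dtype=float)
    m_sel = float(m_grid[np.argmin(np.abs(m_grid - m_obs))])
    key = (mask_key(mask), m_sel)
    if key in config.table_cache:
        return config.table_cache[key]
    table = build_calibration(
        g_grid=config.g_grid,
        m_grid=[m_sel],
        mask=mask,
        sim_config=config.sim,
        R=config.replicates,
        seed=seed,
    )
    # tolerance for m matching follows the configured (full) m grid
    if len(m_grid) > 1:
        table.metadata["m_step"] = float(np.max(np.diff(np.sort(m_grid))))
    config.table_cache[key] = table
    return table


def _observed_m(panel: LocalAncestryPanel) -> float:
    """Mean proportion of population 2 among callable windows."""
    callable_ = panel.callable_mask()
    n = callable_.sum()
    if n == 0:
        raise SignalError("no callable windows left")
    return float((panel.calls == 1).sum() / n)


def date_events(
    panel: LocalAncestryPanel,
    q: QMatrix,
    graph: AHGResult,
    config: DatingConfig,
) -> list[DateEstimate]:
    """Date every admixture event of an inferred arrival order, newest first.

    Each step merges all older components into population 1 and the newest
    remaining component into population 2, estimates the date with a
    calibration table carrying the cumulative mask, then masks the newest
    component's blocks.  The founding pair is dated against each other under
    the cumulative mask (the lower-proportion member is population 2).
    Events whose center falls outside the calibrated range are reported
    undatable; dating stops once more than ``max_masked_fraction`` of the
    genome is masked.
    """
    pair = list(graph.arrival_order[0])
    later = list(graph.arrival_order[1:])
    missing = [c for c in pair + later if c not in panel.labels]
    if missing:
        raise SignalError(f"graph components missing from panel: {missing}")
    rng = np.random.default_rng(config.seed)
    grid = panel.grid
    estimates: list[DateEstimate] = []
    work = panel
    pre_warnings: list[str] = []
    # components excluded from the graph (e.g. below min_prop) cannot be
    # dated; their blocks are masked out before the sequential analysis
    for lab in panel.labels:
        if lab not in pair + later and (work.calls == panel.labels.index(lab)).any():
            work, _, frac = mask_ancestry(work, lab)
            pre_warnings.append(
                f"label {lab} not in the arrival order; its blocks "
                f"({frac:.1%} of the genome) were masked before dating"
            )
    steps: list[tuple[str, set[str], str]] = []
    remaining = pair + later
    for comp in reversed(later):
        older = set(remaining) - {comp}
        steps.append((f"{comp} arrival", older, comp))
        remaining = [c for c in remaining if c != comp]
    # founding pair: population 2 is the lower-proportion member
    a, b = pair
    if q.column(a).mean() < q.column(b).mean():
        a, b = b, a
    steps.append((f"founding {a}+{b}", {a}, b))

    for i, (name, older, recent) in enumerate(steps):
        cum_mask = work.calls == MASKED
        masked_frac = float(cum_mask.mean())
        if masked_frac > config.max_masked_fraction:
            estimates.append(
                DateEstimate(
                    event=name, generations=None, ci_generations=None, years=None,
                    m_used=np.nan, m_observed=np.nan, masked_fraction=masked_frac,
                    warnings=["insufficient genome remains (masked fraction "
                              f"{masked_frac:.2f} > {config.max_masked_fraction})"],
                )
            )
            break
        binary = merge_ancestries(work, older, recent)
        signal = encode_signal(binary, grid)
        m_obs = _observed_m(binary)
        mask = (~binary.callable_mask())
        mask_for_cal = mask if mask.any() else None
        if mask_for_cal is not None and config.mask_mode == "length":
            mask_for_cal = _randomize_mask(mask_for_cal, grid, rng)
        step_seed = int(rng.integers(0, 2**31 - 1))
        table = _step_table(config, mask_for_cal, m_obs, step_seed)
        summary = wavelet_center(signal, grid, mask_key=mask_key(mask_for_cal))
        try:
            est = estimate_generations(
                summary, m_obs, table,
                generation_time=config.generation_time,
                n_bootstrap=config.n_bootstrap,
                seed=int(rng.integers(0, 2**31 - 1)),
                event=name,
            )
        except CalibrationRangeError as exc:
            est = DateEstimate(
                event=name, generations=None, ci_generations=None, years=None,
                m_used=float(table.m_grid[table.m_column(m_obs)]),
                m_observed=m_obs, masked_fraction=masked_frac,
                warnings=[str(exc)],
            )
        estimates.append(est)
        if i < len(steps) - 1:
            work, _, _ = mask_ancestry(work, recent)
    if pre_warnings and estimates:
        estimates[0].warnings = pre_warnings + estimates[0].warnings
    return estimates
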