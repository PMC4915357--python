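"""Forward-in-time simulation of multi-pulse / continuous admixture.

The model: a founding admixed population of N diploids is created g0
generations before the present from two unadmixed sources, then evolves by
discrete non-overlapping generations of random mating with replacement.
Each later admixture event injects unadmixed migrant individuals (a fixed
fraction of the generation being formed); continuous gene flow is a run of
equal per-generation pulses.  Meioses draw Poisson(L) crossovers uniformly on
the genetic map (no interference), so all tract lengths are in genetic
units.  The sampled present-day haplotypes are returned as continuous tracts,
as a window-rasterized local-ancestry panel, and as a per-individual Q matrix
of genetic-length-weighted ancestry fractions.

Defaults emulate the desk-scale study genome used throughout the test suite:
8 chromosomes x 128 cM with 256 windows (0.5 cM) each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _wf
from .io import (
    MASKED,
    UNRESOLVED,
    GeneticMap,
    LocalAncestryPanel,
    QMatrix,
    TractList,
    WindowGrid,
)

__all__ = [
    "Pulse",
    "ContinuousFlow",
    "AdmixtureHistorySpec",
    "SimulatedSample",
    "simulate_history",
    "expected_tract_length",
    "apply_call_noise",
    "desk_genome",
]


def desk_genome(
    n_chromosomes: int = 8, length_cm: float = 128.0, windows: int = 256
) -> tuple[GeneticMap, WindowGrid]:
    """The default validation genome: uniform map plus matching window grid."""
    gmap = GeneticMap.uniform(n_chromosomes, length_cm)
    grid = WindowGrid.uniform(n_chromosomes, length_cm, windows)
    return gmap, grid


@dataclass(frozen=True)
class Pulse:
    """Single-generation gene flow: fraction ``m`` of the generation formed
    ``g`` generations before present are unadmixed ``source`` migrants."""

    g: int
    source: str
    m: float


@dataclass(frozen=True)
class ContinuousFlow:
    """Equal per-generation pulses of ``m_per_generation`` over the closed
    generation interval [g_end, g_start] (g_start is the older bound)."""

    g_start: int
    g_end: int
    source: str
    m_per_generation: float

    def as_pulses(self) -> list[Pulse]:
        return [
            Pulse(g, self.source, self.m_per_generation)
            for g in range(self.g_start, self.g_end - 1, -1)
        ]


@dataclass
class AdmixtureHistorySpec:
    """An ordered admixture history driving the simulator.

    founding_generation: generations before present of the founding mixture
    of ``founding_components`` (A, B) at proportion ``founding_m`` of A.
    ``events`` lists later pulses / continuous intervals, strictly more
    recent than the founding and in decreasing age order.
    """

    founding_generation: int
    founding_components: tuple[str, str]
    founding_m: float
    events: list[Pulse | ContinuousFlow] = field(default_factory=list)
    population_size: int = 500
    sample_size: int = 50  # haplotypes
    generation_time: float = 29.0

    def __post_init__(self) -> None:
        if self.founding_generation < 1:
            raise ValueError("founding event must be at least 1 generation ago")
        if not 0 < self.founding_m < 1:
            raise ValueError("founding proportion must be in (0, 1)")
        if self.sample_size % 2:
            raise ValueError("sample_size counts haplotypes and must be even")
        if self.population_size < self.sample_size / 2:
            raise ValueError("sample larger than the population (need N >= sample/2)")
        last = self.founding_generation
        for ev in self.events:
            if isinstance(ev, ContinuousFlow):
                if ev.g_start < ev.g_end:
                    raise ValueError("continuous interval needs g_start >= g_end")
                if not 0 < ev.m_per_generation < 1:
                    raise ValueError("per-generation proportion must be in (0, 1)")
                hi, lo = ev.g_start, ev.g_end
            else:
                if not 0 < ev.m < 1:
                    raise ValueError("pulse proportion must be in (0, 1)")
                hi = lo = ev.g
            if hi >= last:
                raise ValueError("event generations must be strictly decreasing")
            if lo < 1:
                raise ValueError("events must be at least 1 generation before present")
            last = lo
        exp = self.expected_proportions()
        if any(v < 0 for v in exp.values()):
            raise ValueError("expected cumulative proportion of a component is negative")

    @property
    def components(self) -> list[str]:
        out = list(self.founding_components)
        for ev in self.events:
            if ev.source not in out:
                out.append(ev.source)
        return out

    def pulses(self) -> list[Pulse]:
        """The history flattened to one pulse per event generation."""
        out: list[Pulse] = []
        for ev in self.events:
            out.extend(ev.as_pulses() if isinstance(ev, ContinuousFlow) else [ev])
        return out

    def expected_proportions(self) -> dict[str, float]:
        """Expected final ancestry fractions (infinite-N limit)."""
        a, b = self.founding_components
        props = {a: self.founding_m, b: 1.0 - self.founding_m}
        for p in self.pulses():
            props = {k: v * (1.0 - p.m) for k, v in props.items()}
            props[p.source] = props.get(p.source, 0.0) + p.m
        return props

    @classmethod
    def from_dict(cls, d: dict) -> "AdmixtureHistorySpec":
        f = d["founding"]
        events: list[Pulse | ContinuousFlow] = []
        for ev in d.get("events", []):
            if "g_start" in ev:
                events.append(
                    ContinuousFlow(
                        int(ev["g_start"]), int(ev["g_end"]), str(ev["source"]),
                        float(ev["m_per_generation"]),
                    )
                )
            else:
                events.append(Pulse(int(ev["g"]), str(ev["source"]), float(ev["m"])))
        return cls(
            founding_generation=int(f["g"]),
            founding_components=(str(f["components"][0]), str(f["components"][1])),
            founding_m=float(f["m"]),
            events=events,
            population_size=int(d.get("population_size", 500)),
            sample_size=int(d.get("sample_size", 50)),
            generation_time=float(d.get("generation_time", 29.0)),
        )

    def to_dict(self) -> dict:
        events = []
        for ev in self.events:
            if isinstance(ev, ContinuousFlow):
                events.append(
                    {"g_start": ev.g_start, "g_end": ev.g_end, "source": ev.source,
                     "m_per_generation": ev.m_per_generation}
                )
            else:
                events.append({"g": ev.g, "source": ev.source, "m": ev.m})
        return {
            "founding": {
                "g": self.founding_generation,
                "components": list(self.founding_components),
                "m": self.founding_m,
            },
            "events": events,
            "population_size": self.population_size,
            "sample_size": self.sample_size,
            "generation_time": self.generation_time,
        }


@dataclass
class SimulatedSample:
    """Simulator output: matched tracts, panel and Q for one sampled cohort."""

    tracts: TractList | None
    panel: LocalAncestryPanel | None
    q: QMatrix
    history: AdmixtureHistorySpec
    seed: int


def expected_tract_length(g: float, m: float) -> float:
    """Expected tract length (cM) of an ancestry at proportion ``m``
    introduced by a single pulse ``g`` generations ago (large-N Markovian
    limit): 100 / (g * (1 - m))."""
    if g < 1:
        raise ValueError("g must be >= 1")
    if not 0 < m < 1:
        raise ValueError("m must be in (0, 1)")
    return 100.0 / (g * (1.0 - m))


def _chrom_bounds(gmap: GeneticMap) -> np.ndarray:
    lengths = [gmap.total_length_cm(c) for c in gmap.names]
    return np.concatenate([[0.0], np.cumsum(lengths)])


def simulate_history(
    spec: AdmixtureHistorySpec,
    gmap: GeneticMap,
    grid: WindowGrid | None,
    seed: int,
    rasterize: bool = True,
    build_tracts: bool = True,
) -> SimulatedSample:
    """Run the forward simulation and sample ``spec.sample_size`` haplotypes.

    ``grid`` may be None (with ``rasterize=False``) when only tracts and Q
    are needed; ``build_tracts=False`` skips the tract table (validation and
    calibration runs that only consume the panel/Q).  Deterministic for a
    fixed seed.
    """
    if grid is not None and list(grid.chromosomes) != list(gmap.names):
        raise ValueError("grid chromosomes do not match the genetic map")
    comps = spec.components
    code = {c: i for i, c in enumerate(comps)}
    n = spec.population_size
    pulses = spec.pulses()
    ev_gens = np.array([p.g for p in pulses], dtype=np.int64)
    ev_srcs = np.array([code[p.source] for p in pulses], dtype=np.int8)
    ev_ndip = np.array([int(round(p.m * n)) for p in pulses], dtype=np.int64)
    bounds = _chrom_bounds(gmap)

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    ends, labels, offs = _wf.evolve_population(
        kernel_seed,
        n,
        spec.founding_generation,
        bounds,
        int(round(spec.founding_m * n)),
        np.int8(code[spec.founding_components[0]]),
        np.int8(code[spec.founding_components[1]]),
        ev_gens,
        ev_srcs,
        ev_ndip,
    )

    k_ind = spec.sample_size // 2
    individuals = np.sort(rng.choice(n, size=k_ind, replace=False))
    hap_ids = []
    rows = []
    G = bounds[-1]
    q = np.zeros((k_ind, len(comps)))
    calls = (
        np.full((spec.sample_size, grid.total_windows), UNRESOLVED, dtype=np.int16)
        if (rasterize and grid is not None)
        else None
    )
    for ii, ind in enumerate(individuals):
        for which in (0, 1):
            h = 2 * int(ind) + which
            hap_id = f"ind{ii}_h{which}"
            hap_ids.append(hap_id)
            e = ends[offs[h]:offs[h + 1]]
            lab = labels[offs[h]:offs[h + 1]]
            starts = np.concatenate([[0.0], e[:-1]])
            # per-individual genetic-length-weighted ancestry fractions
            np.add.at(q[ii], lab.astype(int), (e - starts) / (2.0 * G))
            # split the concatenated axis back into chromosomes
            for ci, chrom in enumerate(gmap.names):
                lo, hi = bounds[ci], bounds[ci + 1]
                if build_tracts:
                    j0 = np.searchsorted(e, lo, side="right")
                    j1 = np.searchsorted(e, hi, side="left")
                    for j in range(j0, j1 + 1):
                        s = max(starts[j], lo) - lo
                        t = min(e[j], hi) - lo
                        if t > s:
                            rows.append((hap_id, chrom, s, t, comps[int(lab[j])]))
                if calls is not None:
                    mids = grid.midpoints(chrom) + lo
                    idx = np.searchsorted(e, mids, side="right")
                    calls[len(hap_ids) - 1, grid.chrom_slice(chrom)] = lab[idx]
    if build_tracts:
        frame = pd.DataFrame(
            rows, columns=["haplotype", "chromosome", "start_cm", "end_cm", "ancestry"]
        )
        tracts = TractList(frame, gmap.lengths_cm)
    else:
        tracts = None
    panel = LocalAncestryPanel(hap_ids, grid, comps, calls) if calls is not None else None
    ids = [f"ind{i}" for i in range(k_ind)]
    qmat = QMatrix(ids, comps, q)
    return SimulatedSample(tracts, panel, qmat, spec, seed)


def apply_call_noise(
    panel: LocalAncestryPanel, error_rate: float, seed: int
) -> LocalAncestryPanel:
    """Reassign each callable window to a uniformly random *different* label
    with probability ``error_rate``; MASKED/UNRESOLVED windows untouched."""
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    out = panel.copy()
    if error_rate == 0 or len(panel.labels) < 2:
        return out
    rng = np.random.default_rng(seed)
    callable_ = out.callable_mask()
    flip = callable_ & (rng.random(out.calls.shape) < error_rate)
    k = len(out.labels)
    offsets = rng.integers(1, k, size=int(flip.sum()))
    out.calls[flip] = (out.calls[flip] + offsets) % k
    return out
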