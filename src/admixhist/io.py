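"""Readers, writers and domain containers for admixture-history analyses.

The on-disk dialects supported here are the ones produced by the standard
upstream tools of a local-ancestry workflow:

* ADMIXTURE ``.Q`` matrices (whitespace-delimited ancestry proportions, one
  row per individual) with a companion label file (2-column ID/population
  TSV or 6-column pedigree file, auto-detected);
* HapMap-style genetic maps (``chromosome  position(bp)  rate(cM/Mb)  map(cM)``);
* windowed per-haplotype local-ancestry calls (5-column TSV with header) and
  BED-like ancestry tract intervals (5 columns, 0-based half-open, in cM).

Coordinates are genetic (centimorgan) throughout; window grids partition each
chromosome into 2**n equal-width half-open windows, the layout required by the
Haar wavelet analysis downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneticMap",
    "WindowGrid",
    "QMatrix",
    "LocalAncestryPanel",
    "TractList",
    "UNRESOLVED",
    "MASKED",
    "read_q_matrix",
    "read_genetic_map",
    "build_window_grid",
    "human_default_scheme",
    "read_local_ancestry",
    "write_local_ancestry",
    "select_parentals",
]

#: call codes for windows without an accepted ancestry label
UNRESOLVED = -1
MASKED = -2

_UNRESOLVED_TOKEN = "UNRESOLVED"
_MASKED_TOKEN = "MASKED"

_Q_ROW_SUM_TOL = 1e-3
_CHROM_RE = re.compile(r"^(chr)?([0-9]+|[XY])$", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear map from physical (bp) to genetic (cM)
    position.

    ``chromosomes`` maps chromosome name to ``(positions_bp, positions_cm)``
    arrays; both are non-decreasing and each chromosome has at least two
    points.  Genetic length of a chromosome is the last cM value.
    """

    chromosomes: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for name, (bp, cm) in self.chromosomes.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise FormatError(f"chromosome {name}: need at least 2 map points")
            if np.any(np.diff(bp) < 0) or np.any(np.diff(cm) < 0):
                raise FormatError(f"chromosome {name}: map positions must be non-decreasing")
            if np.any(cm < 0):
                raise FormatError(f"chromosome {name}: genetic positions must be >= 0")
            self.chromosomes[name] = (bp, cm)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def total_length_cm(self, chromosome: str) -> float:
        bp, cm = self.chromosomes[chromosome]
        return float(cm[-1] - cm[0])

    @property
    def lengths_cm(self) -> dict[str, float]:
        return {c: self.total_length_cm(c) for c in self.chromosomes}

    def interpolate(self, chromosome: str, position_bp: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of genetic position at physical position(s)."""
        bp, cm = self.chromosomes[chromosome]
        return np.interp(position_bp, bp, cm)

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 8,
        length_cm: float = 128.0,
        rate_cm_per_mb: float = 1.0,
    ) -> "GeneticMap":
        """A synthetic constant-rate map: chromosomes named "1".."n"."""
        length_bp = length_cm / rate_cm_per_mb * 1e6
        chroms = {
            str(i + 1): (np.array([0.0, length_bp]), np.array([0.0, length_cm]))
            for i in range(n_chromosomes)
        }
        return cls(chroms)


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-dialect genetic map (4 columns with header)."""
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 columns (chromosome, position, rate, map)")
    chrom_col = df.iloc[:, 0].astype(str)
    try:
        pos = df.iloc[:, 1].astype(float).to_numpy()
        cm = df.iloc[:, 3].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric position or map value ({exc})") from None
    chroms: dict[str, tuple[list, list]] = {}
    for line_no, (c, p, g) in enumerate(zip(chrom_col, pos, cm), start=2):
        if not _CHROM_RE.match(c):
            raise FormatError(f"{path}: unknown chromosome token {c!r} at line {line_no}")
        bp_list, cm_list = chroms.setdefault(c, ([], []))
        if cm_list and (g < cm_list[-1] or p < bp_list[-1]):
            raise FormatError(f"{path}: decreasing map position at line {line_no}")
        bp_list.append(p)
        cm_list.append(g)
    return GeneticMap({c: (np.array(b), np.array(g)) for c, (b, g) in chroms.items()})


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------


def _is_power_of_two(k: int) -> bool:
    return k >= 2 and (k & (k - 1)) == 0


@dataclass
class WindowGrid:
    """Equal-genetic-width window partition of each chromosome.

    Window counts are powers of two (2**n, n >= 1); windows are half-open
    ``[i*w, (i+1)*w)`` intervals covering ``[0, length_cm)`` exactly.
    """

    chromosomes: list[str]
    window_counts: dict[str, int]
    lengths_cm: dict[str, float]

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            k = self.window_counts[c]
            if not _is_power_of_two(int(k)):
                raise FormatError(f"chromosome {c}: window count {k} is not a power of two >= 2")
            if self.lengths_cm[c] <= 0:
                raise FormatError(f"chromosome {c}: non-positive length")

    @property
    def widths_cm(self) -> dict[str, float]:
        return {c: self.lengths_cm[c] / self.window_counts[c] for c in self.chromosomes}

    @property
    def total_windows(self) -> int:
        return int(sum(self.window_counts[c] for c in self.chromosomes))

    @property
    def offsets(self) -> dict[str, int]:
        """Start index of each chromosome's windows in the flattened layout."""
        out, acc = {}, 0
        for c in self.chromosomes:
            out[c] = acc
            acc += self.window_counts[c]
        return out

    def n_scales(self, chromosome: str) -> int:
        return int(np.log2(self.window_counts[chromosome]))

    def boundaries(self, chromosome: str) -> np.ndarray:
        k = self.window_counts[chromosome]
        return np.linspace(0.0, self.lengths_cm[chromosome], k + 1)

    def midpoints(self, chromosome: str) -> np.ndarray:
        b = self.boundaries(chromosome)
        return 0.5 * (b[:-1] + b[1:])

    def chrom_slice(self, chromosome: str) -> slice:
        o = self.offsets[chromosome]
        return slice(o, o + self.window_counts[chromosome])

    @classmethod
    def uniform(
        cls, n_chromosomes: int = 8, length_cm: float = 128.0, windows: int = 256
    ) -> "WindowGrid":
        names = [str(i + 1) for i in range(n_chromosomes)]
        return cls(names, {c: windows for c in names}, {c: length_cm for c in names})


def human_default_scheme(chromosomes: Iterable[str]) -> dict[str, int]:
    """The human window layout: 1024 windows on chromosomes 1-8, 512 on
    9-18 and 20, 256 on 19, 21 and 22."""
    scheme = {}
    for c in chromosomes:
        num = c[3:] if c.lower().startswith("chr") else c
        try:
            i = int(num)
        except ValueError:
            raise FormatError(f"no default window count for chromosome {c!r}") from None
        if 1 <= i <= 8:
            scheme[c] = 1024
        elif i in (19, 21, 22):
            scheme[c] = 256
        elif 9 <= i <= 20:
            scheme[c] = 512
        else:
            raise FormatError(f"no default window count for chromosome {c!r}")
    return scheme


def build_window_grid(gmap: GeneticMap, scheme: Mapping[str, int]) -> WindowGrid:
    """Partition every chromosome of ``gmap`` into ``scheme[chrom]`` windows.

    ``scheme`` maps chromosome name to a power-of-two window count (use
    :func:`human_default_scheme` for the standard 1024/512/256 layout).
    """
    missing = [c for c in gmap.names if c not in scheme]
    if missing:
        raise FormatError(f"scheme missing chromosomes: {missing}")
    counts = {}
    for c in gmap.names:
        k = int(scheme[c])
        if not _is_power_of_two(k):
            raise FormatError(f"chromosome {c}: requested {k} windows, not a power of two")
        counts[c] = k
    return WindowGrid(list(gmap.names), counts, gmap.lengths_cm)


# ---------------------------------------------------------------------------
# Q matrix
# ---------------------------------------------------------------------------


@dataclass
class QMatrix:
    """Individual ancestry proportions: ``n_individuals x K``, rows sum to 1."""

    individual_ids: list[str]
    component_names: list[str]
    proportions: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        n, k = self.proportions.shape
        if k < 2:
            raise FormatError("QMatrix needs K >= 2 components")
        if len(self.individual_ids) != n:
            raise FormatError(
                f"{len(self.individual_ids)} ids for {n} proportion rows"
            )
        if len(self.component_names) != k:
            raise FormatError("component_names length does not match K")
        if np.any(self.proportions < 0):
            raise FormatError("negative ancestry proportion")

    @property
    def n_individuals(self) -> int:
        return self.proportions.shape[0]

    @property
    def k(self) -> int:
        return self.proportions.shape[1]

    def column(self, component: str) -> np.ndarray:
        return self.proportions[:, self.component_names.index(component)]

    def means(self) -> dict[str, float]:
        return {
            c: float(self.proportions[:, i].mean())
            for i, c in enumerate(self.component_names)
        }

    def subset_components(self, keep: Sequence[str]) -> "QMatrix":
        idx = [self.component_names.index(c) for c in keep]
        return QMatrix(
            list(self.individual_ids),
            list(keep),
            self.proportions[:, idx].copy(),
            self.populations,
        )


def _default_components(k: int) -> list[str]:
    if k <= 26:
        return [chr(ord("A") + i) for i in range(k)]
    return [f"K{i + 1}" for i in range(k)]


def read_q_matrix(q_path, labels_path, component_names: Sequence[str] | None = None) -> QMatrix:
    """Read an ADMIXTURE ``.Q`` file and its companion label file.

    Rows whose sum deviates from 1 by <= 1e-3 are renormalized (ADMIXTURE
    output is rounded text); larger deviations are rejected with the row
    index.  The label file dialect (2-column ID/population or 6-column
    pedigree) is auto-detected from its column count.
    """
    try:
        q = np.loadtxt(q_path, ndmin=2, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{q_path}: non-numeric value in Q matrix ({exc})") from None
    labels = pd.read_csv(labels_path, sep=r"\s+", header=None, dtype=str)
    if labels.shape[1] == 2:
        ids = labels.iloc[:, 0].tolist()
        pops = labels.iloc[:, 1].tolist()
    elif labels.shape[1] == 6:
        # pedigree dialect: family, individual, father, mother, sex, phenotype
        ids = labels.iloc[:, 1].tolist()
        pops = labels.iloc[:, 0].tolist()
    else:
        raise FormatError(
            f"{labels_path}: expected 2 or 6 columns, found {labels.shape[1]}"
        )
    if len(ids) != q.shape[0]:
        raise FormatError(
            f"label/Q row mismatch: {len(ids)} labels for {q.shape[0]} Q rows"
        )
    sums = q.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > _Q_ROW_SUM_TOL)[0]
    if bad.size:
        raise FormatError(
            f"{q_path}: row {bad[0]} sums to {sums[bad[0]]:.6f}, "
            f"outside 1 +/- {_Q_ROW_SUM_TOL}"
        )
    q = q / sums[:, None]
    names = list(component_names) if component_names else _default_components(q.shape[1])
    return QMatrix(ids, names, q, pops)


def select_parentals(q: QMatrix, component: str, max_admixture: float) -> list[str]:
    """Individuals usable as a parental panel for ``component``: those whose
    total proportion of all *other* components is <= ``max_admixture``.

    Returns an empty list with a warning when nobody qualifies; callers may
    then relax the threshold (as is common for heavily admixed proxies).
    """
    if component not in q.component_names:
        raise FormatError(f"unknown component {component!r}")
    if not 0 < max_admixture < 1:
        raise FormatError("max_admixture must be in (0, 1)")
    other = 1.0 - q.column(component)
    keep = [i for i, v in zip(q.individual_ids, other) if v <= max_admixture]
    if not keep:
        warnings.warn(
            f"no individual has <= {max_admixture:.0%} non-{component} admixture; "
            "consider raising the threshold",
            stacklevel=2,
        )
    return keep


# ---------------------------------------------------------------------------
# Local ancestry panel and tracts
# ---------------------------------------------------------------------------


@dataclass
class LocalAncestryPanel:
    """Per-haplotype, per-window ancestry calls on a window grid.

    ``calls`` is an ``(n_haplotypes, total_windows)`` int16 array holding an
    index into ``labels``, or :data:`UNRESOLVED` (-1) / :data:`MASKED` (-2).
    ``posterior`` optionally carries the per-call assignment confidence.
    """

    haplotype_ids: list[str]
    grid: WindowGrid
    labels: list[str]
    calls: np.ndarray
    posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        expected = (len(self.haplotype_ids), self.grid.total_windows)
        if self.calls.shape != expected:
            raise FormatError(f"calls shape {self.calls.shape} != {expected}")
        if self.calls.max(initial=-2) >= len(self.labels) or self.calls.min(initial=0) < MASKED:
            raise FormatError("call code outside label set")
        if self.posterior is not None:
            self.posterior = np.asarray(self.posterior, dtype=float)
            if self.posterior.shape != expected:
                raise FormatError("posterior shape does not match calls")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    def callable_mask(self) -> np.ndarray:
        return self.calls >= 0

    @property
    def masked_fraction(self) -> float:
        return float((self.calls == MASKED).mean()) if self.calls.size else 0.0

    def label_fractions(self) -> dict[str, float]:
        """Genome fraction of each label among callable windows."""
        callable_ = self.callable_mask()
        total = callable_.sum()
        out = {}
        for i, lab in enumerate(self.labels):
            out[lab] = float((self.calls == i).sum() / total) if total else 0.0
        return out

    def copy(self) -> "LocalAncestryPanel":
        return LocalAncestryPanel(
            list(self.haplotype_ids),
            self.grid,
            list(self.labels),
            self.calls.copy(),
            None if self.posterior is None else self.posterior.copy(),
        )


@dataclass
class TractList:
    """Continuous-coordinate ancestry tracts, one row per tract.

    ``frame`` columns: haplotype, chromosome, start_cm, end_cm, ancestry.
    Within a haplotype-chromosome the half-open intervals are non-overlapping
    and contiguous from 0 to the chromosome's genetic length.
    """

    frame: pd.DataFrame
    lengths_cm: dict[str, float]

    _COLS = ("haplotype", "chromosome", "start_cm", "end_cm", "ancestry")

    def __post_init__(self) -> None:
        if tuple(self.frame.columns) != self._COLS:
            self.frame = self.frame[list(self._COLS)]
        for (hap, chrom), g in self.frame.groupby(["haplotype", "chromosome"], sort=False):
            starts = g["start_cm"].to_numpy()
            ends = g["end_cm"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            if starts[0] != 0.0 or not np.allclose(ends[-1], self.lengths_cm[str(chrom)]):
                raise FormatError(f"tracts on {hap}/{chrom} do not cover the chromosome")
            if np.any(starts[1:] < ends[:-1]) :
                raise FormatError(f"overlapping tracts on {hap}/{chrom}")
            if np.any(starts[1:] > ends[:-1]):
                raise FormatError(f"gap between tracts on {hap}/{chrom}")

    def tract_lengths(self, ancestry: str) -> np.ndarray:
        sel = self.frame[self.frame["ancestry"] == ancestry]
        return (sel["end_cm"] - sel["start_cm"]).to_numpy()


# -- serialization -----------------------------------------------------------

_WINDOWED_HEADER = "haplotype\tchromosome\twindow\tlabel\tposterior"


def _code_to_token(code: int, labels: Sequence[str]) -> str:
    if code == UNRESOLVED:
        return _UNRESOLVED_TOKEN
    if code == MASKED:
        return _MASKED_TOKEN
    return labels[code]


def read_local_ancestry(
    path,
    dialect: str,
    grid: WindowGrid,
    posterior_threshold: float = 0.9,
    labels: Sequence[str] | None = None,
) -> LocalAncestryPanel:
    """Read local-ancestry calls into a grid-aligned panel.

    ``dialect`` is ``"windowed_tsv"`` (haplotype, chromosome, window, label,
    posterior; header line) or ``"tract_bed"`` (chromosome, start, end,
    haplotype, label; cM, 0-based half-open, no header).  Tracts are
    rasterized by the label at each window midpoint.  Labeled calls with a
    posterior below ``posterior_threshold`` become UNRESOLVED.
    """
    if dialect == "windowed_tsv":
        return _read_windowed(path, grid, posterior_threshold, labels)
    if dialect == "tract_bed":
        return _read_tract_bed(path, grid, labels)
    raise FormatError(f"unknown dialect {dialect!r}")


def _label_index(labels: list[str], token: str, frozen: bool) -> int:
    if token == _UNRESOLVED_TOKEN:
        return UNRESOLVED
    if token == _MASKED_TOKEN:
        return MASKED
    if token not in labels:
        if frozen:
            raise FormatError(f"label {token!r} not in declared label set {labels}")
        labels.append(token)
    return labels.index(token)


def _read_windowed(path, grid, posterior_threshold, declared_labels):
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 5:
        raise FormatError(f"{path}: windowed dialect needs 5 columns")
    labels: list[str] = list(declared_labels) if declared_labels else []
    frozen = declared_labels is not None
    haps: list[str] = []
    hap_idx: dict[str, int] = {}
    offsets = grid.offsets
    rows = []
    for hap, chrom, win, lab, post in df.itertuples(index=False):
        if hap not in hap_idx:
            hap_idx[hap] = len(haps)
            haps.append(hap)
        if chrom not in offsets:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        w = int(win)
        if not 0 <= w < grid.window_counts[chrom]:
            raise FormatError(
                f"{path}: window index {w} out of range for chromosome {chrom}"
            )
        code = _label_index(labels, lab, frozen)
        p = np.nan if (pd.isna(post) or post == ".") else float(post)
        rows.append((hap_idx[hap], offsets[chrom] + w, code, p))
    n = len(haps)
    calls = np.full((n, grid.total_windows), UNRESOLVED, dtype=np.int16)
    posterior = np.full((n, grid.total_windows), np.nan)
    for h, w, code, p in rows:
        calls[h, w] = code
        posterior[h, w] = p
    low = (calls >= 0) & ~np.isnan(posterior) & (posterior < posterior_threshold)
    calls[low] = UNRESOLVED
    if np.all(np.isnan(posterior)):
        posterior = None
    return LocalAncestryPanel(haps, grid, labels, calls, posterior)


def _read_tract_bed(path, grid, declared_labels):
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 5:
        raise FormatError(f"{path}: tract dialect needs 5 columns")
    df.columns = ["chromosome", "start", "end", "haplotype", "label"]
    df["start"] = df["start"].astype(float)
    df["end"] = df["end"].astype(float)
    labels: list[str] = list(declared_labels) if declared_labels else []
    frozen = declared_labels is not None
    haps: list[str] = []
    for hap in df["haplotype"]:
        if hap not in haps:
            haps.append(hap)
    calls = np.full((len(haps), grid.total_windows), UNRESOLVED, dtype=np.int16)
    for (hap, chrom), g in df.groupby(["haplotype", "chromosome"], sort=False):
        if chrom not in grid.offsets:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        g = g.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"{path}: overlapping tracts on {hap}/{chrom}")
        h = haps.index(hap)
        mids = grid.midpoints(chrom)
        sl = grid.chrom_slice(chrom)
        codes = np.array([_label_index(labels, t, frozen) for t in g["label"]], dtype=np.int16)
        # midpoint rasterization: window takes the label of the tract
        # containing its midpoint; uncovered midpoints stay UNRESOLVED
        idx = np.searchsorted(ends, mids, side="right")
        inside = (idx < len(starts)) & (mids >= starts[np.minimum(idx, len(starts) - 1)])
        row = calls[h, sl]
        row[inside] = codes[idx[inside]]
        calls[h, sl] = row
    return LocalAncestryPanel(haps, grid, labels, calls, None)


def write_local_ancestry(panel: LocalAncestryPanel, path, dialect: str = "windowed_tsv") -> None:
    """Serialize a panel; the windowed dialect round-trips losslessly
    (labels, masks and posteriors), the tract dialect drops posteriors."""
    if dialect == "windowed_tsv":
        _write_windowed(panel, path)
    elif dialect == "tract_bed":
        _write_tract_bed(panel, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def _write_windowed(panel: LocalAncestryPanel, path) -> None:
    grid = panel.grid
    with open(path, "w") as fh:
        fh.write(_WINDOWED_HEADER + "\n")
        for h, hap in enumerate(panel.haplotype_ids):
            for chrom in grid.chromosomes:
                sl = grid.chrom_slice(chrom)
                codes = panel.calls[h, sl]
                posts = None if panel.posterior is None else panel.posterior[h, sl]
                for w, code in enumerate(codes):
                    tok = _code_to_token(int(code), panel.labels)
                    if posts is None or np.isnan(posts[w]):
                        p = "."
                    else:
                        p = repr(float(posts[w]))
                    fh.write(f"{hap}\t{chrom}\t{w}\t{tok}\t{p}\n")


def _write_tract_bed(panel: LocalAncestryPanel, path) -> None:
    grid = panel.grid
    with open(path, "w") as fh:
        for h, hap in enumerate(panel.haplotype_ids):
            for chrom in grid.chromosomes:
                sl = grid.chrom_slice(chrom)
                codes = panel.calls[h, sl]
                bounds = grid.boundaries(chrom)
                start = 0
                for w in range(1, len(codes) + 1):
                    if w == len(codes) or codes[w] != codes[start]:
                        tok = _code_to_token(int(codes[start]), panel.labels)
                        fh.write(
                            f"{chrom}\t{bounds[start]!r}\t{bounds[w]!r}\t{hap}\t{tok}\n"
                        )
                        start = w
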