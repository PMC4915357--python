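"""Ancestry-block signals: merging, masking, Haar spectra and block lengths.

For dating, a multi-way local-ancestry panel is reduced to a two-population
signal: all blocks contributed by the *older* admixture participants count as
population 1 (encoded -1), the most recent contributor as population 2 (+1),
and MASKED/UNRESOLVED windows as 0.  The orthonormal Haar transform of each
2**n-window chromosome splits the signal variance across dyadic scales; wide
ancestry blocks (recent admixture) put the energy at coarse scales, narrow
blocks (old admixture) at fine scales.  The single summary used for dating is
the *wavelet center*: the energy-weighted mean scale of the pooled spectrum,
with chromosome spectra aligned on the genetic block-width axis (window
width x 2**j cM) so that mixed window schemes pool coherently.

Sequential dating masks the blocks of each dated ancestry before analyzing
the next-older event; masked windows encode as 0 and the identical mask is
applied to the calibration simulations, which is how the reduction in
usable genome size is taken into account.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pywt

from .io import MASKED, UNRESOLVED, LocalAncestryPanel, WindowGrid

__all__ = [
    "WaveletSummary",
    "BlockLengthSummary",
    "merge_ancestries",
    "encode_signal",
    "haar_power",
    "wavelet_center",
    "block_lengths",
    "mask_ancestry",
]

POP1 = "pop1"
POP2 = "pop2"


class SignalError(ValueError):
    """The panel cannot be converted into a usable two-population signal."""


def merge_ancestries(
    panel: LocalAncestryPanel, older: Iterable[str], recent: str
) -> LocalAncestryPanel:
    """Collapse a multi-way panel to two populations: every label in
    ``older`` becomes population 1, ``recent`` becomes population 2;
    MASKED/UNRESOLVED windows are preserved.  Any other label present in the
    calls is an error."""
    older = set(older)
    if recent in older:
        raise SignalError(f"recent label {recent!r} also listed as older")
    unknown = (older | {recent}) - set(panel.labels)
    if unknown:
        raise SignalError(f"labels not in panel: {sorted(unknown)}")
    mapping = np.full(len(panel.labels), -100, dtype=np.int16)
    for i, lab in enumerate(panel.labels):
        if lab in older:
            mapping[i] = 0
        elif lab == recent:
            mapping[i] = 1
    present = np.unique(panel.calls[panel.calls >= 0])
    stray = [panel.labels[i] for i in present if mapping[i] == -100]
    if stray:
        raise SignalError(
            f"panel contains label(s) {stray} outside older + recent sets"
        )
    calls = panel.calls.copy()
    pos = calls >= 0
    calls[pos] = mapping[calls[pos]]
    return LocalAncestryPanel(
        list(panel.haplotype_ids), panel.grid, [POP1, POP2], calls, None
    )


def encode_signal(panel: LocalAncestryPanel, grid: WindowGrid | None = None) -> np.ndarray:
    """Encode a binary panel as a (n_haplotypes, total_windows) float signal:
    population 1 -> -1, population 2 -> +1, MASKED/UNRESOLVED -> 0."""
    grid = grid or panel.grid
    if len(panel.labels) != 2:
        raise SignalError(
            f"panel has {len(panel.labels)} labels; merge to two populations first"
        )
    if panel.calls.shape[1] != grid.total_windows:
        raise SignalError("panel does not match the window grid")
    signal = np.zeros(panel.calls.shape, dtype=np.float64)
    signal[panel.calls == 0] = -1.0
    signal[panel.calls == 1] = 1.0
    return signal


def haar_power(signal: np.ndarray) -> np.ndarray:
    """Per-scale power of a length-2**n signal under the orthonormal Haar
    transform: power_j = mean squared detail coefficient at scale j
    (j = 1 finest ... n coarsest).

    The orthonormal convention gives a Parseval identity: the coefficient-
    count-weighted sum of the powers equals the (population) signal variance.
    A constant signal yields all-zero power ("no admixture signal").
    """
    x = np.asarray(signal, dtype=float)
    n_win = x.shape[-1]
    n = int(np.log2(n_win))
    if 2**n != n_win or n < 1:
        raise SignalError(f"signal length {n_win} is not 2**n with n >= 1")
    coeffs = pywt.wavedec(x, "haar", mode="periodization", level=n, axis=-1)
    # coeffs = [cA_n, cD_n, ..., cD_1]; detail at level j is scale j
    details = coeffs[:0:-1]  # cD_1 ... cD_n
    return np.array([float(np.mean(d**2)) for d in details])


def _scale_energies(signals: np.ndarray) -> np.ndarray:
    """Total squared detail coefficients per scale, summed over rows."""
    n = int(np.log2(signals.shape[-1]))
    coeffs = pywt.wavedec(signals, "haar", mode="periodization", level=n, axis=-1)
    details = coeffs[:0:-1]
    return np.array([float(np.sum(d**2)) for d in details])


@dataclass
class WaveletSummary:
    """Pooled Haar spectrum of a two-population ancestry signal.

    ``scale_widths_cm`` is the pooled genetic block-width axis; ``powers``
    the normalized pooled spectrum (sums to 1); ``center`` the power-weighted
    mean scale, expressed in dyadic steps above the finest window width
    (identical to sum(j * p_j) when all chromosomes share one window width).
    ``chrom_energies`` keeps per-chromosome raw energies on the same axis for
    chromosome-level resampling.
    """

    scale_widths_cm: np.ndarray
    scale_axis: np.ndarray
    powers: np.ndarray
    center: float
    callable_fraction: float
    per_chromosome: dict[str, np.ndarray]
    chrom_energies: dict[str, np.ndarray]
    mask_key: str | None = None


def center_from_energies(energies: np.ndarray, scale_axis: np.ndarray) -> float:
    total = energies.sum()
    if total <= 0:
        raise SignalError("cannot date: single ancestry (no signal energy)")
    p = energies / total
    return float(np.sum(scale_axis * p))


def wavelet_center(
    signals: np.ndarray, grid: WindowGrid, mask_key: str | None = None
) -> WaveletSummary:
    """Pool per-chromosome Haar spectra into one genome-wide summary.

    Energies are pooled on the genetic block-width axis (window width x 2**j
    cM), so chromosomes with different window counts combine coherently; the
    center is the energy-weighted mean dyadic scale of the pooled spectrum.
    Errors when every signal is constant (a single ancestry cannot be dated).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != grid.total_windows:
        raise SignalError("signal width does not match the grid")
    widths = grid.widths_cm
    keyed: dict[float, float] = {}
    per_chrom_raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in grid.chromosomes:
        block = signals[:, grid.chrom_slice(chrom)]
        e = _scale_energies(block)
        w = widths[chrom] * 2.0 ** np.arange(1, len(e) + 1)
        per_chrom_raw[chrom] = (w, e)
        for wi, ei in zip(w, e):
            key = round(float(np.log2(wi)), 9)
            keyed[key] = keyed.get(key, 0.0) + float(ei)
    axis_keys = sorted(keyed)
    pooled_w = np.array([2.0**k for k in axis_keys])
    pooled_e = np.array([keyed[k] for k in axis_keys])
    w_min = min(widths.values())
    scale_axis = np.log2(pooled_w / w_min)
    center = center_from_energies(pooled_e, scale_axis)
    total = pooled_e.sum()
    chrom_energies = {}
    per_chromosome = {}
    for chrom, (w, e) in per_chrom_raw.items():
        vec = np.zeros(len(axis_keys))
        for wi, ei in zip(w, e):
            vec[axis_keys.index(round(float(np.log2(wi)), 9))] = ei
        chrom_energies[chrom] = vec
        per_chromosome[chrom] = e / e.sum() if e.sum() > 0 else e
    return WaveletSummary(
        scale_widths_cm=pooled_w,
        scale_axis=scale_axis,
        powers=pooled_e / total,
        center=center,
        callable_fraction=float(np.mean(signals != 0.0)),
        per_chromosome=per_chromosome,
        chrom_energies=chrom_energies,
        mask_key=mask_key,
    )


@dataclass
class BlockLengthSummary:
    """Genetic lengths (cM) of maximal same-ancestry runs, per ancestry."""

    lengths: dict[str, np.ndarray]

    def mean(self, ancestry: str) -> float:
        return float(self.lengths[ancestry].mean())

    def variance(self, ancestry: str) -> float:
        v = self.lengths[ancestry]
        return float(v.var(ddof=1)) if v.size > 1 else 0.0

    def cdf(self, ancestry: str) -> tuple[np.ndarray, np.ndarray]:
        x = np.sort(self.lengths[ancestry])
        return x, np.arange(1, x.size + 1) / x.size

    def to_records(self) -> list[dict]:
        return [
            {
                "ancestry": a,
                "n_blocks": int(v.size),
                "mean_cm": self.mean(a),
                "variance_cm2": self.variance(a),
            }
            for a, v in self.lengths.items()
        ]


def block_lengths(
    panel: LocalAncestryPanel,
    grid: WindowGrid | None = None,
    ancestries: Sequence[str] | None = None,
) -> BlockLengthSummary:
    """Maximal runs of identical ancestry labels on the rasterized grid,
    converted to genetic lengths.  Runs are split by MASKED (and UNRESOLVED)
    windows; lengths are quantized to the window width."""
    grid = grid or panel.grid
    want = list(ancestries) if ancestries else list(panel.labels)
    codes = {panel.labels.index(a): a for a in want}
    out: dict[str, list[float]] = {a: [] for a in want}
    widths = grid.widths_cm
    for chrom in grid.chromosomes:
        w = widths[chrom]
        block = panel.calls[:, grid.chrom_slice(chrom)]
        for row in block:
            # run-length encode
            change = np.nonzero(np.diff(row))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [row.size]])
            for s, e in zip(starts, ends):
                code = int(row[s])
                if code in codes:
                    out[codes[code]].append((e - s) * w)
    return BlockLengthSummary({a: np.array(v) for a, v in out.items()})


def mask_ancestry(
    panel: LocalAncestryPanel, label: str
) -> tuple[LocalAncestryPanel, np.ndarray, float]:
    """Mask every window carrying ``label``.

    Returns (masked panel, boolean mask positions, fraction of the genome
    newly masked).  Errors when the label is absent from the calls.
    """
    if label not in panel.labels:
        raise SignalError(f"label {label!r} not in panel")
    code = panel.labels.index(label)
    positions = panel.calls == code
    if not positions.any():
        raise SignalError(f"label {label!r} has no windows to mask")
    out = panel.copy()
    out.calls[positions] = MASKED
    return out, positions, float(positions.mean())
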