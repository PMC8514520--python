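"""5'-end overlap distance spectra, overlap Z-scores, ping-pong statistics,
and the footprint-phasing periodogram.

Offset convention: there is no offset 0.  Offset 1 means exact 5'-end
coincidence; offsets 2..window mean the A-read 5' end lies 1..window-1 nt
downstream of the B-read 5' end; offsets -1..-window mean 1..window nt
upstream.  The window therefore spans 2*window positions (window upstream +
coincidence + window-1 downstream).

The Z score at the coincidence position uses all other offsets as background
with the sample (n-1) standard deviation; p-values are one-sided upper-tail
normal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DegenerateBackgroundError, EmptySetError
from .transcripts import ReadSet

__all__ = [
    "DistanceSpectrum",
    "OverlapZ",
    "PingPongResult",
    "PeriodogramResult",
    "distance_spectrum",
    "overlap_z",
    "pingpong",
    "periodogram",
    "phasing_periodogram",
]


@dataclass
class DistanceSpectrum:
    """Averaged fraction of Set-A 5' ends at each signed offset around Set-B 5' ends."""

    offsets: np.ndarray  # [-window..-1, 1..window]
    values: np.ndarray  # mean per-b fraction at each offset
    pair_counts: np.ndarray  # raw count-weighted tallies
    n_b_total: float  # count-weighted size of Set B (averaging denominator)
    window: int = 50

    def value(self, offset: int) -> float:
        return float(self.values[self._index(offset)])

    def _index(self, offset: int) -> int:
        if offset == 0 or not -self.window <= offset <= self.window:
            raise ConfigError(f"offset {offset} outside [-{self.window}..-1, 1..{self.window}]")
        return offset + self.window if offset < 0 else offset + self.window - 1

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def downstream_series(self) -> np.ndarray:
        """Values at offsets 1..window, ordered."""
        return self.values[self.window :].copy()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "pair_count": self.pair_counts}
        )


@dataclass
class OverlapZ:
    z: float
    focal_value: float
    bg_mean: float
    bg_sd: float
    p_one_sided: float
    focal_offset: int = 1


@dataclass
class PingPongResult:
    overlap_lengths: np.ndarray  # 1..max_overlap
    pair_counts: np.ndarray  # count-weighted pair tallies
    z10: float
    p_one_sided: float

    @property
    def argmax_overlap(self) -> int:
        return int(self.overlap_lengths[int(np.argmax(self.pair_counts))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"overlap": self.overlap_lengths, "pair_count": self.pair_counts})


@dataclass
class PeriodogramResult:
    frequencies: np.ndarray  # cycles per nt, Fourier grid k/n
    density: np.ndarray  # classical periodogram |DFT|^2 / n
    relative_density: np.ndarray  # normalized to the first reported frequency
    is_constant: bool = False

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.density))])

    @property
    def peak_period(self) -> float:
        f = self.peak_frequency
        return float("nan") if self.is_constant or f == 0 else 1.0 / f

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frequency": self.frequencies,
                "density": self.density,
                "relative_density": self.relative_density,
            }
        )


def _group_positions(reads: ReadSet) -> dict[tuple[str, str], dict[int, float]]:
    groups: dict[tuple[str, str], dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for r in reads.records:
        groups[(r.ref_id, r.strand)][r.five_prime] += r.count
    return groups


def distance_spectrum(
    a: ReadSet, b: ReadSet, window: int = 50, exclude_self: bool = False
) -> DistanceSpectrum:
    """Distance spectrum of Set-A 5' ends around Set-B 5' ends.

    For each b read, A reads with 5' ends within ``window`` nt upstream through
    ``window - 1`` nt downstream (in the read's own orientation) form the
    per-b spectrum: the fraction of those A 5' ends at each offset.  Per-b
    spectra are summed and divided by the count-weighted total of Set B, so
    b reads with no A read in their window contribute zero.

    ``exclude_self`` removes each read's trivial pairing with itself, for
    self-spectra (phasing analysis).
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    if not b.records:
        raise EmptySetError("Set B is empty")
    n_positions = 2 * window
    values = np.zeros(n_positions)
    pair_counts = np.zeros(n_positions)
    n_b_total = float(b.total_count)

    a_groups = _group_positions(a)
    b_groups = _group_positions(b)
    for key, b_pos in b_groups.items():
        a_pos = a_groups.get(key)
        if not a_pos:
            continue
        _, strand = key
        a_positions = np.fromiter(a_pos.keys(), dtype=np.int64, count=len(a_pos))
        a_counts = np.fromiter(a_pos.values(), dtype=np.float64, count=len(a_pos))
        b_positions = np.fromiter(b_pos.keys(), dtype=np.int64, count=len(b_pos))
        b_counts = np.fromiter(b_pos.values(), dtype=np.float64, count=len(b_pos))

        lo = int(min(a_positions.min(), b_positions.min())) - window
        hi = int(max(a_positions.max(), b_positions.max())) + window + 1
        arr = np.zeros(hi - lo)
        np.add.at(arr, a_positions - lo, a_counts)

        win = sliding_window_view(arr, n_positions)
        if strand == "+":
            # row starting at p-lo-window covers a5 = p-window .. p+window-1,
            # i.e. d = a5 - p ascending over [-window, window-1]
            rows = win[b_positions - lo - window]
        else:
            # d = p - a5: take the window ending at p+window and reverse
            rows = win[b_positions - lo - (window - 1)][:, ::-1]
        rows = np.array(rows, dtype=np.float64)
        if exclude_self:
            rows[:, window] = np.maximum(rows[:, window] - 1.0, 0.0)
        totals = rows.sum(axis=1)
        nz = totals > 0
        if np.any(nz):
            values += ((rows[nz] / totals[nz, None]) * b_counts[nz, None]).sum(axis=0)
        pair_counts += (rows * b_counts[:, None]).sum(axis=0)

    values /= n_b_total
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    return DistanceSpectrum(offsets, values, pair_counts, n_b_total, window)


def overlap_z(spectrum: DistanceSpectrum) -> OverlapZ:
    """Z score of the coincidence offset against all other offsets as background."""
    focal_idx = spectrum._index(1)
    focal = float(spectrum.values[focal_idx])
    bg = np.delete(spectrum.values, focal_idx)
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std(ddof=1))
    eps = 1e-12 * max(abs(bg_mean), float(np.abs(spectrum.values).max()), 1e-300)
    if bg_sd <= eps:
        if abs(focal - bg_mean) <= eps:  # flat spectrum: no excess by definition
            return OverlapZ(0.0, focal, bg_mean, 0.0, 0.5)
        raise DegenerateBackgroundError("background standard deviation is zero")
    z = (focal - bg_mean) / bg_sd
    return OverlapZ(z, focal, bg_mean, bg_sd, float(scipy.stats.norm.sf(z)))


def pingpong(plus: ReadSet, minus: ReadSet, max_overlap: int = 50) -> PingPongResult:
    """Opposite-strand 5'-5' overlap pair counts and the Z score at overlap 10.

    Minus-read ``five_prime`` must be the plus-strand coordinate of the
    5'-most template base.  Overlap g pairs a plus read p with a minus read q
    when ``q.five_prime - p.five_prime + 1 == g``; tallies are products of
    the two counts.
    """
    if not plus.records or not minus.records:
        raise EmptySetError("ping-pong requires non-empty plus and minus sets")
    if max_overlap < 11:
        raise ConfigError("max_overlap must be >= 11 to score overlap 10")
    pair_counts = np.zeros(max_overlap)

    plus_by_ref: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    minus_by_ref: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for r in plus.records:
        plus_by_ref[r.ref_id][r.five_prime] += r.count
    for r in minus.records:
        minus_by_ref[r.ref_id][r.five_prime] += r.count

    for ref, p_pos in plus_by_ref.items():
        m_pos = minus_by_ref.get(ref)
        if not m_pos:
            continue
        p_positions = np.fromiter(p_pos.keys(), dtype=np.int64, count=len(p_pos))
        p_counts = np.fromiter(p_pos.values(), dtype=np.float64, count=len(p_pos))
        m_positions = np.fromiter(m_pos.keys(), dtype=np.int64, count=len(m_pos))
        m_counts = np.fromiter(m_pos.values(), dtype=np.float64, count=len(m_pos))
        lo = int(p_positions.min())
        hi = int(max(p_positions.max(), m_positions.max())) + max_overlap + 1
        arr = np.zeros(hi - lo)
        keep = m_positions >= lo
        np.add.at(arr, m_positions[keep] - lo, m_counts[keep])
        win = sliding_window_view(arr, max_overlap)  # row at i covers q5 = i..i+max-1
        rows = win[p_positions - lo]  # g = q5 - p5 + 1 in 1..max_overlap
        pair_counts += (rows * p_counts[:, None]).sum(axis=0)

    idx10 = 9
    bg = np.delete(pair_counts, idx10)
    bg_sd = float(bg.std(ddof=1))
    if bg_sd == 0:
        z10 = 0.0 if pair_counts[idx10] == bg.mean() else float("inf")
        p = 0.5 if z10 == 0.0 else 0.0
    else:
        z10 = float((pair_counts[idx10] - bg.mean()) / bg_sd)
        p = float(scipy.stats.norm.sf(z10))
    return PingPongResult(np.arange(1, max_overlap + 1), pair_counts, z10, p)


def periodogram(series) -> PeriodogramResult:
    """Classical (Schuster) periodogram of a mean-centered series.

    I(f_k) = |DFT(x)|^2 / n at the Fourier frequencies f_k = k/n for
    k = 1..floor(n/2).  The relative density is normalized so the first
    reported frequency equals 1; a constant input yields all-zero power and
    is flagged rather than raised.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 6:
        raise ConfigError("series must be 1-D with length >= 6")
    n = x.size
    x = x - x.mean()
    spectrum = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    density = (np.abs(spectrum[k]) ** 2) / n
    freqs = k / n
    is_constant = bool(np.allclose(density, 0.0))
    if is_constant:
        relative = np.zeros_like(density)
    elif density[0] > 0:
        relative = density / density[0]
    else:
        relative = np.full_like(density, np.nan)
    return PeriodogramResult(freqs, density, relative, is_constant)


def phasing_periodogram(reads: ReadSet, window: int = 50, codon_aligned: bool = True) -> PeriodogramResult:
    """Periodogram of the downstream half of a read set's self distance spectrum.

    The self spectrum excludes each read's trivial self pair.  With
    ``codon_aligned`` the series is truncated to a multiple of 3 so the
    codon frequency 1/3 lies exactly on the Fourier grid.
    """
    spec = distance_spectrum(reads, reads, window=window, exclude_self=True)
    series = spec.downstream_series()
    if codon_aligned:
        n = 3 * (series.size // 3)
        series = series[:n]
    return periodogram(series)
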