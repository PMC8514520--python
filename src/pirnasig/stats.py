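"""Coupling statistics, 2x2 chi-square helper, normal-tail p-values, and
3'UTR precursor (uppl) calling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .errors import ConfigError
from .quant import AbundanceRecord
from .transcripts import ORF, UTR3, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int
    residuals_x: np.ndarray
    residuals_y: np.ndarray


def partial_correlation(x, y, z) -> PartialCorrResult:
    """Partial correlation of x and y conditional on z, via residuals.

    x and y are each regressed on z (with intercept); r is the Pearson
    correlation of the residual vectors and equals the closed form
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).  The two-sided
    p-value comes from t = r sqrt((n-3)/(1-r^2)) with n-3 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ConfigError("x, y, z must have equal lengths")
    if n < 4:
        raise ConfigError("need n >= 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ConfigError("inputs must be finite")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ConfigError(f"{name} has zero variance")
    design = np.column_stack([np.ones(n), z])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    res_x = x - design @ beta_x
    res_y = y - design @ beta_y
    r = float(np.corrcoef(res_x, res_y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 3))
    return PartialCorrResult(r, p, n, res_x, res_y)


@dataclass
class Chi2Result:
    chi2: float
    p: float
    df: int = 1
    yates: bool = True


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> Chi2Result:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Yates continuity correction is applied by default; all marginals must be
    positive.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ConfigError("cell counts must be nonnegative integers")
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ConfigError("all row and column marginals must be > 0")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(table, correction=yates)
    return Chi2Result(float(chi2), float(p), int(dof), yates)


def normal_upper_p(z: float) -> float:
    """One-sided upper-tail standard-normal p-value, 1 - Phi(z)."""
    if not np.isfinite(z):
        raise ConfigError("z must be finite")
    return float(scipy.stats.norm.sf(z))


@dataclass
class PrecursorCall:
    transcript_id: str
    pirna_ppm: float
    frac_utr3: float
    rpf_orf_ppm: float
    is_uppl: bool
    failed_criteria: list[str] = field(default_factory=list)


DEFAULT_UPPL_THRESHOLDS = {"ppm": 100.0, "frac": 0.90, "rpf_ppm": 1.0}


def call_uppl(
    pirna: Sequence[AbundanceRecord],
    rpf: Sequence[AbundanceRecord],
    models: Sequence[TranscriptModel],
    thresholds: Mapping[str, float] | None = None,
) -> list[PrecursorCall]:
    """Call 3'UTR piRNA-producing precursor transcripts.

    A transcript passes with piRNA abundance strictly > ``ppm`` ppm, a 3'UTR
    piRNA fraction >= ``frac``, and ORF RPF abundance >= ``rpf_ppm`` ppm.
    Abundance-table transcripts absent from ``models`` are skipped (logged).
    """
    th = dict(DEFAULT_UPPL_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    model_ids = {m.transcript_id for m in models if m.is_coding}
    pirna_whole: dict[str, float] = {}
    pirna_utr3: dict[str, float] = {}
    pirna_raw_whole: dict[str, float] = {}
    pirna_raw_utr3: dict[str, float] = {}
    rpf_orf: dict[str, float] = {}
    for rec in pirna:
        if rec.transcript_id not in model_ids:
            logger.info("call_uppl: %s not in models; skipped", rec.transcript_id)
            continue
        if rec.region == "whole":
            pirna_whole[rec.transcript_id] = rec.ppm
            pirna_raw_whole[rec.transcript_id] = rec.raw_count
        elif rec.region == UTR3:
            pirna_utr3[rec.transcript_id] = rec.ppm
            pirna_raw_utr3[rec.transcript_id] = rec.raw_count
    for rec in rpf:
        if rec.transcript_id not in model_ids:
            continue
        if rec.region == ORF:
            rpf_orf[rec.transcript_id] = rec.ppm
    calls = []
    for tid in sorted(model_ids):
        ppm = pirna_whole.get(tid, 0.0)
        raw_whole = pirna_raw_whole.get(tid, 0.0)
        frac = (pirna_raw_utr3.get(tid, 0.0) / raw_whole) if raw_whole > 0 else 0.0
        orf_ppm = rpf_orf.get(tid, 0.0)
        failed = []
        if not ppm > th["ppm"]:
            failed.append("pirna_ppm")
        if not frac >= th["frac"]:
            failed.append("frac_utr3")
        if not orf_ppm >= th["rpf_ppm"]:
            failed.append("rpf_orf_ppm")
        calls.append(PrecursorCall(tid, ppm, frac, orf_ppm, not failed, failed))
    return calls
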