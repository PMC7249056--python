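"""SDR/SIR/SAR source-separation metrics.

The estimate is decomposed into a target part (orthogonal projection onto the
true source), an interference part (projection onto the span of all true
sources, minus the target), and an artifact residual.  In this mono
two-source setting there is no spatial image, so the spatial error term is
identically zero.  The projections use time-invariant gains (no
allowed-distortion filter), which realizes the printed energy-ratio
definitions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_frontend import AudioSignal

__all__ = ["ErrorDecomposition", "BssScores", "decompose", "scores", "evaluate_pair"]

SCORE_CEILING_DB = 120.0


@dataclass
class ErrorDecomposition:
    """Orthogonal error decomposition of an estimated source signal."""

    target: np.ndarray
    e_interf: np.ndarray
    e_artif: np.ndarray
    e_spatial: np.ndarray

    def total(self) -> np.ndarray:
        return self.target + self.e_interf + self.e_artif + self.e_spatial


@dataclass
class BssScores:
    """Source-to-distortion/interference/artifact ratios in dB."""

    sdr: float
    sir: float
    sar: float
    source_role: str = ""
    raw: tuple[float, float, float] | None = None  # uncapped values


def _as_array(x) -> np.ndarray:
    if isinstance(x, AudioSignal):
        return x.samples
    return np.asarray(x, dtype=np.float64)


def decompose(estimate, true_sources: list, target_index: int = 0) -> ErrorDecomposition:
    """Decompose an estimate against the true sources.

    target   = projection of the estimate onto span{s_target}
    e_interf = projection onto span{all true sources} minus target
    e_artif  = remainder
    e_spatial = 0 (mono, no spatial image)
    """
    est = _as_array(estimate)
    sources = np.stack([_as_array(s) for s in true_sources])  # n_src x n
    if sources.shape[1] != est.shape[0]:
        raise ValueError("estimate and sources must have equal length")
    energies = np.sum(sources**2, axis=1)
    if np.any(energies == 0):
        raise ValueError("zero-energy true source")
    s_t = sources[target_index]
    target = (est @ s_t) / (s_t @ s_t) * s_t
    # least-squares projection onto the span of all sources
    coeffs, *_ = np.linalg.lstsq(sources.T, est, rcond=None)
    p_all = sources.T @ coeffs
    e_interf = p_all - target
    e_artif = est - p_all
    return ErrorDecomposition(
        target=target,
        e_interf=e_interf,
        e_artif=e_artif,
        e_spatial=np.zeros_like(est),
    )


def _ratio_db(num: float, den: float) -> float:
    if den == 0.0:
        return np.inf
    return 10.0 * np.log10(num / den) if num > 0 else -np.inf


def scores(
    decomp: ErrorDecomposition,
    source_role: str = "",
    ceiling_db: float = SCORE_CEILING_DB,
) -> BssScores:
    """Energy-ratio scores of a decomposition, capped at ``ceiling_db``."""
    t = float(np.sum(decomp.target**2))
    err = decomp.e_interf + decomp.e_artif + decomp.e_spatial
    sdr = _ratio_db(t, float(np.sum(err**2)))
    sir = _ratio_db(t, float(np.sum(decomp.e_interf**2)))
    num_sar = decomp.target + decomp.e_interf + decomp.e_spatial
    sar = _ratio_db(float(np.sum(num_sar**2)), float(np.sum(decomp.e_artif**2)))
    raw = (sdr, sir, sar)
    capped = tuple(min(v, ceiling_db) for v in raw)
    return BssScores(*capped, source_role=source_role, raw=raw)


def evaluate_pair(result, truth_wheeze, truth_respiratory) -> tuple[BssScores, BssScores, dict]:
    """Score both separated sources against their ground truths.

    ``result`` is a SeparationResult (or any object with ``wheeze_signal``
    and ``respiratory_signal``).  Signals are trimmed to the common interior
    length before scoring.  Returns (wheeze scores, respiratory scores,
    means) where means holds sdr/sir/sar averaged over the two roles.
    """
    est_w = _as_array(result.wheeze_signal)
    est_r = _as_array(result.respiratory_signal)
    s_w = _as_array(truth_wheeze)
    s_r = _as_array(truth_respiratory)
    n = min(len(est_w), len(est_r), len(s_w), len(s_r))
    est_w, est_r, s_w, s_r = est_w[:n], est_r[:n], s_w[:n], s_r[:n]
    sources = [s_w, s_r]
    wheeze = scores(decompose(est_w, sources, 0), source_role="wheeze")
    resp = scores(decompose(est_r, sources, 1), source_role="respiratory")
    means = {
        "sdr": (wheeze.sdr + resp.sdr) / 2.0,
        "sir": (wheeze.sir + resp.sir) / 2.0,
        "sar": (wheeze.sar + resp.sar) / 2.0,
    }
    return wheeze, resp, means
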