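"""Benchmark runner: method ladder over synthetic suites, per-case scores.

Shared by the test suite and the reproduction script.  Sizes here are the
desk-scale defaults (8 s recordings, a 16 s training signal); the generator
itself defaults to the full-scale conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import BaselineConfig, baseline_separate, build_wheeze_template
from .bss_eval import evaluate_pair
from .separation_pipeline import SegmentAnnotation
from .signal_frontend import StftConfig
from .synthetic_data import MixtureCase, build_benchmark, generate_training_y

__all__ = ["annotation_for_case", "run_suite", "SUITE_SNR"]

SUITE_SNR = {"t1h": 5.0, "t1m": 0.0, "t1l": -5.0}

LADDER = ("nmf", "snmf", "ssnmf", "nmpcf_1s", "nmpcf_t", "nmpcf_st", "iis0", "iis")


def annotation_for_case(case: MixtureCase, config: StftConfig) -> SegmentAnnotation:
    """Ground-truth stage annotation of a generated case, in frames."""
    n_frames = (len(case.mixture.samples) - config.window_length) // config.hop + 1
    return SegmentAnnotation.from_sample_boundaries(
        case.stage_edges, case.labels, config, n_frames
    )


def run_suite(
    snr_db: float,
    n_cases: int = 16,
    seed: int = 0,
    methods: tuple[str, ...] = LADDER,
    max_iter: int = 50,
    training_duration: float = 24.0,
    training_stages: int = 12,
    stage_duration: float = 2.0,
    extra_schemes: dict | None = None,
    n_runs: int = 1,
) -> pd.DataFrame:
    """Run every method over one SNR suite; one row per (case, method, run).

    ``extra_schemes`` maps a name to a (HyperParams, WeightScheme) pair run
    through the informed core in addition to the named methods (used for the
    equal-weight comparison).  Replicate r of a case adds r to the method
    seed.  Columns: case, method, run, sdr_w, sir_w, sar_w, sdr_r, sir_r,
    sar_r.
    """
    from .nmpcf_core import HyperParams, WeightScheme  # noqa: F401 (doc types)
    from .separation_pipeline import separate

    config = StftConfig()
    y = generate_training_y(
        total_duration=training_duration, n_stages=training_stages,
        seed=999_000 + seed,
    )
    z = build_wheeze_template()
    cases = build_benchmark(
        n_cases=n_cases, snr_db=snr_db, seed=seed, stage_duration=stage_duration
    )
    rows = []
    for ci, case in enumerate(cases):
        ann = annotation_for_case(case, config)
        for run in range(n_runs):
            run_seed = 100 * seed + ci + 7919 * run
            for m in methods:
                cfg = BaselineConfig.for_method(m, seed=run_seed, max_iter=max_iter)
                res = baseline_separate(case.mixture, cfg, ann=ann, y=y, z=z, config=config)
                sw, sr, _ = evaluate_pair(res, case.wheeze, case.respiratory)
                rows.append(
                    dict(case=ci, method=m, run=run, sdr_w=sw.sdr, sir_w=sw.sir,
                         sar_w=sw.sar, sdr_r=sr.sdr, sir_r=sr.sir, sar_r=sr.sar)
                )
            for name, (hp, scheme) in (extra_schemes or {}).items():
                hp = type(hp)(k_r=hp.k_r, k_w=hp.k_w, max_iter=hp.max_iter,
                              seed=run_seed, eps=hp.eps)
                res = separate(case.mixture, ann=ann, y=y, hp=hp, w=scheme, config=config)
                sw, sr, _ = evaluate_pair(res, case.wheeze, case.respiratory)
                rows.append(
                    dict(case=ci, method=name, run=run, sdr_w=sw.sdr, sir_w=sw.sir,
                         sar_w=sw.sar, sdr_r=sr.sdr, sir_r=sr.sir, sar_r=sr.sar)
                )
    return pd.DataFrame(rows)
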