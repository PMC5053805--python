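"""End-to-end analysis pipeline over a session bundle.

Runs validate -> rate maps -> sequence statistics -> sample information ->
population decoding -> GLM tests, writing one tidy CSV per stage plus a JSON
report.  A master seed fans out to named per-stage substreams, so toggling
one stage never changes another stage's randomness, and re-running with the
same bundle and config reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import rate_maps, sample_info, sequence_stats
from .population_decoder import error_trial_trace, loo_accuracy_trace
from .glm_selectivity import bin_response, build_design, glm_unit_tests
from .session_model import Session, read_session

__all__ = ["PipelineConfig", "run_pipeline", "dissociation_summary"]

log = logging.getLogger(__name__)

STAGES = ("validate", "ratemaps", "sequences", "info", "decode", "glm")


@dataclass
class PipelineConfig:
    """Stage toggles and parameters (defaults match the analysis conventions)."""

    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seed: int = 0
    delays: tuple = (10.0,)
    align_event: str = "sample_press"
    bin_width_s: float = 0.05
    sigma_s: float = 1.0 / 6.0
    ridge_shifts: int = 1000
    info_stride_s: float = 0.25
    info_n_mc: int = 500
    info_shuffles: int = 200
    decode_stride_s: float = 0.25
    n_pseudo: int = 500
    alpha: float = 0.01

    def substream(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), STAGES.index(stage)])
        )


def dissociation_summary(info_traces: list, rate_peaks: dict) -> tuple[pd.DataFrame, dict]:
    """Per significant unit, rate-peak vs information-peak times, with the
    population correlation and earlier-information signed-rank test."""
    rows = [
        {
            "unit_id": tr.unit_id,
            "rate_peak_s": float(rate_peaks[tr.unit_id]),
            "info_peak_s": tr.peak_time_s,
            "info_peak_bits": tr.peak_bits,
        }
        for tr in info_traces
        if tr.significant
    ]
    table = pd.DataFrame(rows, columns=["unit_id", "rate_peak_s", "info_peak_s", "info_peak_bits"])
    stats: dict = {"n_significant": len(table)}
    if len(table) >= 3:
        r, p_corr, p_signed = sample_info.info_vs_rate_peak_comparison(
            table["info_peak_s"].to_numpy(), table["rate_peak_s"].to_numpy()
        )
        stats.update(pearson_r=r, p_corr=p_corr, wilcoxon_signed_rank_p=p_signed)
    return table, stats


def run_pipeline(
    bundle: str | Path | Session, config: PipelineConfig | None = None, out_dir: str | Path = "."
) -> dict:
    """Run all enabled stages; returns (and writes) the JSON report."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("seqdecode")
    root.addHandler(handler)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    report: dict = {"stages": {}, "seed": config.seed}
    failed = False
    t_start = time.time()

    session = bundle if isinstance(bundle, Session) else read_session(bundle, validate=False)
    delay = float(max(config.delays))
    ratemap = None
    info_traces: list = []
    try:
        for stage in STAGES:
            if not config.stages.get(stage, False):
                report["stages"][stage] = {"status": "skipped"}
                continue
            if failed and stage in ("info", "decode", "glm"):
                report["stages"][stage] = {"status": "skipped (upstream failure)"}
                continue
            t0 = time.time()
            try:
                if stage == "validate":
                    session.validate()
                    report["n_units"] = len(session.units)
                    report["n_trials"] = len(session.trials)
                elif stage == "ratemaps":
                    ratemap = rate_maps.estimate_rates(
                        session,
                        align_event=config.align_event,
                        window=(-2.0, delay + 2.0),
                        bin_width_s=config.bin_width_s,
                        delays=config.delays,
                    )
                    sm = rate_maps.smooth_rates(ratemap, config.sigma_s)
                    z = rate_maps.zscore_rates(sm)
                    peaks = rate_maps.peak_times(sm, (-1.0, delay + 1.0))
                    long = []
                    for i, u in enumerate(sm.unit_ids):
                        for j, c in enumerate(sm.bin_centers):
                            long.append((u, c, sm.rates[i, j], z.rates[i, j]))
                    pd.DataFrame(long, columns=["unit", "bin_center_s", "rate_hz", "z"]).to_csv(
                        out / "ratemaps.csv", index=False
                    )
                    report["rate_peaks"] = dict(zip(sm.unit_ids, map(float, peaks)))
                elif stage == "sequences":
                    rng = config.substream("sequences")
                    mean_ratio, p_pop, results = sequence_stats.population_ridge_test(
                        session, delays=config.delays, n_shifts=config.ridge_shifts, rng=rng
                    )
                    pd.DataFrame(
                        {
                            "unit": session.unit_ids,
                            "ratio": [r.ratio for r in results],
                            "p": [r.p for r in results],
                            "peak_time_s": [r.peak_time_s for r in results],
                        }
                    ).to_csv(out / "ridge.csv", index=False)
                    report["sequences"] = {
                        "mean_ridge_ratio": mean_ratio,
                        "population_p": p_pop,
                        "frac_significant": float(
                            np.mean([r.p < config.alpha for r in results])
                        ),
                    }
                elif stage == "info":
                    rng = config.substream("info")
                    rows = []
                    for u in session.unit_ids:
                        tr = sample_info.shuffle_significance(
                            session,
                            u,
                            n_shuffles=config.info_shuffles,
                            rng=rng,
                            delays=config.delays,
                            stride_s=config.info_stride_s,
                            n_mc=config.info_n_mc,
                        )
                        info_traces.append(tr)
                        for c, m, s in zip(tr.window_centers_s, tr.mi_bits, tr.mc_se):
                            rows.append((u, c, m, s, tr.null_peak_99, tr.significant))
                    pd.DataFrame(
                        rows,
                        columns=["unit", "t_center", "mi_bits", "mc_se", "null99", "significant"],
                    ).to_csv(out / "info.csv", index=False)
                    report["info"] = {
                        "frac_significant": float(
                            np.mean([tr.significant for tr in info_traces])
                        ),
                        "mean_peak_bits_significant": float(
                            np.mean([tr.peak_bits for tr in info_traces if tr.significant])
                        )
                        if any(tr.significant for tr in info_traces)
                        else float("nan"),
                    }
                    if info_traces and "rate_peaks" in report:
                        table, stats = dissociation_summary(info_traces, report["rate_peaks"])
                        table.to_csv(out / "dissociation.csv", index=False)
                        report["dissociation"] = stats
                elif stage == "decode":
                    rng = config.substream("decode")
                    trace = loo_accuracy_trace(
                        session,
                        delays=config.delays,
                        stride_s=config.decode_stride_s,
                        n_pseudo=config.n_pseudo,
                        rng=rng,
                    )
                    frames = [
                        pd.DataFrame(
                            {
                                "t_center": trace.window_centers_s,
                                "accuracy": trace.accuracy,
                                "sem_upper": trace.sem_upper,
                                "eval": trace.eval_set,
                            }
                        )
                    ]
                    report["decode"] = {
                        "loo_mean_accuracy": float(trace.accuracy.mean()),
                        "loo_first_window_accuracy": float(trace.accuracy[0]),
                        "n_min": trace.n_min,
                    }
                    try:
                        err = error_trial_trace(
                            session,
                            delays=config.delays,
                            stride_s=config.decode_stride_s,
                            n_pseudo=config.n_pseudo,
                            rng=rng,
                        )
                        frames.append(
                            pd.DataFrame(
                                {
                                    "t_center": err.window_centers_s,
                                    "accuracy": err.accuracy,
                                    "sem_upper": err.sem_upper,
                                    "eval": err.eval_set,
                                }
                            )
                        )
                        report["decode"]["error_mean_accuracy"] = float(err.accuracy.mean())
                    except ValueError as exc:
                        report["decode"]["error_trials"] = f"skipped: {exc}"
                    pd.concat(frames).to_csv(out / "decode.csv", index=False)
                elif stage == "glm":
                    design = build_design(session)
                    rows = []
                    for u in session.unit_ids:
                        y = bin_response(design, session.unit(u).spike_times_s)
                        res = glm_unit_tests(design, y)
                        rows.append((u, res["p_time"], res["p_sample"]))
                    glm_df = pd.DataFrame(rows, columns=["unit", "p_time", "p_sample"])
                    glm_df.to_csv(out / "glm.csv", index=False)
                    report["glm"] = {
                        "frac_time_significant": float(
                            np.nanmean(glm_df["p_time"] < config.alpha)
                        ),
                        "frac_sample_significant": float(
                            np.nanmean(glm_df["p_sample"] < config.alpha)
                        ),
                    }
                report["stages"][stage] = {
                    "status": "ok",
                    "seconds": round(time.time() - t0, 3),
                }
                log.info("stage %s finished in %.1fs", stage, time.time() - t0)
            except Exception as exc:
                log.exception("stage %s failed", stage)
                report["stages"][stage] = {"status": f"failed: {exc}"}
                failed = True
        report["total_seconds"] = round(time.time() - t_start, 3)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    finally:
        root.removeHandler(handler)
        handler.close()
    return report
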