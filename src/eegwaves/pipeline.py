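"""Full study analysis: preprocess → quantify → aggregate → statistics.

Produces, for a :class:`~eegwaves.core_io.StudyDataset`, the standard analysis
products: pre/post block summaries with group tests, minute-by-minute series
with FDR-corrected tests against zero, per-subject forward/backward coupling
correlations, rating and VAS correlations, peak-frequency band histograms and
per-frequency wave spectra.  Deterministic given the master seed.

Time conventions: minute bin ``b`` covers ``t_start ∈ [60(b−1), 60b)`` seconds
relative to injection, so post-injection bins are 1, 2, ... and bin 0 is the
last pre-injection minute; a window belongs to the bin containing its start.
The pre and post blocks are the ``block_minutes`` immediately before and after
injection.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (MIDLINE, ElectrodeArray, RatingsTable,
                      StudyDataset, write_results_table)
from .preprocessing import WindowSpec, preprocess
from .stats import bh_fdr, fw_bw_coupling, one_sample_t, paired_t, pearson
from .wave_quant import (DEFAULT_BAND, BandDefinition, SurrogateSpec,
                         WaveEstimate, estimates_frame, quantify_recording)

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Everything the study analysis needs beyond the data itself."""

    array: ElectrodeArray = MIDLINE
    window: WindowSpec = WindowSpec()
    n_shuffles: int = 100
    bands: BandDefinition = BandDefinition()
    band: tuple = DEFAULT_BAND
    low_hz: float = 1.0
    high_hz: float = 45.0
    apply_preprocessing: bool = True
    fdr_q: float = 0.05
    coupling_minutes: tuple = (2.0, 5.0)
    block_minutes: float = 5.0
    per_frequency: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if not self.coupling_minutes[0] < self.coupling_minutes[1]:
            raise ValueError("empty coupling range")
        if self.block_minutes <= 0:
            raise ValueError("block_minutes must be positive")


@dataclasses.dataclass
class StudyResults:
    """All tables produced by :func:`run_study` (one DataFrame each)."""

    windows: pd.DataFrame
    block_summary: pd.DataFrame
    block_tests: pd.DataFrame
    minute_series: pd.DataFrame
    coupling: pd.DataFrame
    coupling_tests: pd.DataFrame
    rating_timecourse: pd.DataFrame
    rating_per_minute: pd.DataFrame
    vas_correlations: pd.DataFrame
    band_histogram: pd.DataFrame
    per_frequency: pd.DataFrame | None

    def write(self, outdir: "str | Path") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, value in dataclasses.asdict(self).items():
            if isinstance(value, pd.DataFrame) and not value.empty:
                write_results_table(value, outdir / f"{name}.tsv")


def minute_of(t_start: "float | np.ndarray") -> "int | np.ndarray":
    """Minute bin of a window start time (bin b covers [60(b-1), 60b))."""
    return np.floor_divide(np.asarray(t_start) / 60.0, 1).astype(int) + 1


def _session_seed(master_seed: int, subject_i: int, cond_i: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), subject_i, cond_i])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def quantify_study(dataset: StudyDataset, config: AnalysisConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Window-level wave estimates for every session of the study.

    Returns ``(windows, per_frequency)``: one row per window with subject,
    condition and all WaveEstimate fields; and (optionally) per-frequency
    mean dB per subject × condition × block.
    """
    frames, freq_rows = [], []
    for si, subject in enumerate(dataset.subjects):
        for ci, condition in enumerate(("placebo", "dmt")):
            try:
                rec = dataset.get_recording(subject, condition)
                if config.apply_preprocessing:
                    rec = preprocess(rec, config.low_hz, config.high_hz)
                spec = SurrogateSpec(config.n_shuffles,
                                     seed=_session_seed(config.seed, si, ci))
                out = quantify_recording(
                    rec, config.array, config.window, spec, config.band,
                    per_frequency=config.per_frequency)
            except Exception as exc:
                raise RuntimeError(
                    f"wave quantification failed for subject {subject!r}, "
                    f"session {condition!r}: {exc}") from exc
            if config.per_frequency:
                ests, freqs, fw_f, bw_f = out
            else:
                ests = out
            frame = estimates_frame(ests)
            frame.insert(0, "subject", subject)
            frame.insert(1, "condition", condition)
            frames.append(frame)
            logger.info("quantified %s/%s: %d windows", subject, condition,
                        len(ests))
            if config.per_frequency:
                t = frame["t_start"].to_numpy()
                for block, mask in _block_masks(t, config.block_minutes).items():
                    if not mask.any():
                        continue
                    for direction, mat in (("FW", fw_f), ("BW", bw_f)):
                        for j, f in enumerate(freqs):
                            freq_rows.append({
                                "subject": subject, "condition": condition,
                                "block": block, "direction": direction,
                                "freq_hz": float(f),
                                "mean_db": float(mat[mask, j].mean()),
                            })
    windows = pd.concat(frames, ignore_index=True)
    per_freq = pd.DataFrame(freq_rows) if freq_rows else None
    return windows, per_freq


def _block_masks(t_start: np.ndarray, block_minutes: float) -> dict:
    span = 60.0 * block_minutes
    return {"pre": (t_start >= -span) & (t_start < 0),
            "post": (t_start >= 0) & (t_start < span)}


def block_summary(windows: pd.DataFrame, block_minutes: float = 5.0
                  ) -> pd.DataFrame:
    """Per subject × condition × {pre, post} block mean FW/BW dB."""
    rows = []
    for (subject, condition), grp in windows.groupby(["subject", "condition"]):
        t = grp["t_start"].to_numpy()
        for block, mask in _block_masks(t, block_minutes).items():
            if not mask.any():
                continue
            rows.append({
                "subject": subject, "condition": condition, "block": block,
                "fw_db": grp.loc[mask, "fw_db"].mean(),
                "bw_db": grp.loc[mask, "bw_db"].mean(),
            })
    return pd.DataFrame(rows)


def block_tests(summary: pd.DataFrame, with_bf: bool = True) -> pd.DataFrame:
    """Group tests on block means: each cell against zero, post-block drug
    versus placebo (paired), and post versus pre within condition."""
    rows = []
    piv = summary.pivot_table(index="subject", columns=["condition", "block"],
                              values=["fw_db", "bw_db"])
    for direction in ("fw_db", "bw_db"):
        for condition in ("placebo", "dmt"):
            for block in ("pre", "post"):
                vals = piv[(direction, condition, block)].dropna().to_numpy()
                res = one_sample_t(vals, 0.0, with_bf=with_bf)
                rows.append({"direction": direction, "comparison":
                             f"{condition}_{block}_vs_zero",
                             "estimate": res.estimate, "t": res.statistic,
                             "df": res.df, "p": res.p_value,
                             "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "bf10": res.bf10})
        for label, a, b in (
                ("dmt_post_vs_placebo_post", ("dmt", "post"), ("placebo", "post")),
                ("dmt_post_vs_dmt_pre", ("dmt", "post"), ("dmt", "pre")),
                ("placebo_post_vs_placebo_pre", ("placebo", "post"),
                 ("placebo", "pre"))):
            res = paired_t(piv[(direction, *a)].to_numpy(),
                           piv[(direction, *b)].to_numpy(), with_bf=with_bf)
            rows.append({"direction": direction, "comparison": label,
                         "estimate": res.estimate, "t": res.statistic,
                         "df": res.df, "p": res.p_value,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "bf10": res.bf10})
    return pd.DataFrame(rows)


def minute_series(windows: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Minute-by-minute group series with FDR-corrected tests against zero.

    FDR correction is applied across the minute bins within each
    condition × direction series separately.
    """
    if windows["subject"].nunique() < 2:
        raise ValueError("minute series needs at least 2 subjects")
    work = windows.copy()
    work["minute"] = minute_of(work["t_start"].to_numpy())
    rows = []
    for (condition, direction), col in (
            (("placebo", "FW"), "fw_db"), (("placebo", "BW"), "bw_db"),
            (("dmt", "FW"), "fw_db"), (("dmt", "BW"), "bw_db")):
        sub = work[work["condition"] == condition]
        per_subj = sub.groupby(["minute", "subject"])[col].mean().reset_index()
        series = []
        for minute, grp in per_subj.groupby("minute"):
            vals = grp[col].to_numpy()
            res = one_sample_t(vals, 0.0)
            series.append({"condition": condition, "direction": direction,
                           "minute": int(minute), "mean_db": res.estimate,
                           "se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                           "t": res.statistic, "p": res.p_value})
        fdr = bh_fdr([r["p"] for r in series], q)
        for r, adj, rej in zip(series, fdr.adjusted, fdr.rejected):
            r["p_adj"] = float(adj)
            r["significant"] = bool(rej)
        rows.extend(series)
    return pd.DataFrame(rows)


def coupling_table(windows: pd.DataFrame,
                   coupling_minutes: tuple = (2.0, 5.0),
                   block_minutes: float = 5.0) -> pd.DataFrame:
    """Per-subject window-by-window FW–BW correlation, pre and post.

    "post" uses the coupling window (minutes where both wave types are
    expected present); "pre" uses the pre-injection block.
    """
    rows = []
    pre_range = (-block_minutes, 0.0)
    for (subject, condition), grp in windows.groupby(["subject", "condition"]):
        ests = [WaveEstimate(**r) for r in
                grp.drop(columns=["subject", "condition"]).to_dict("records")]
        for phase, t_range in (("pre", pre_range), ("post", coupling_minutes)):
            try:
                r, p = fw_bw_coupling(ests, t_range)
            except ValueError:
                continue
            rows.append({"subject": subject, "condition": condition,
                         "phase": phase, "r": r, "p": p})
    return pd.DataFrame(rows)


def coupling_tests(coupling: pd.DataFrame) -> pd.DataFrame:
    """One-sample tests of the per-subject coupling r against zero."""
    rows = []
    for (condition, phase), grp in coupling.groupby(["condition", "phase"]):
        res = one_sample_t(grp["r"].to_numpy(), 0.0, with_bf=True)
        rows.append({"condition": condition, "phase": phase,
                     "mean_r": res.estimate, "t": res.statistic,
                     "df": res.df, "p": res.p_value, "bf10": res.bf10})
    return pd.DataFrame(rows)


def rating_correlations(windows: pd.DataFrame, ratings: RatingsTable,
                        coupling_minutes: tuple = (2.0, 5.0),
                        q: float = 0.05):
    """Correlations between wave amounts and subjective intensity/VAS scores.

    Returns three tables: (a) time-course — group-mean intensity versus
    group-mean wave dB across post-injection minutes, per direction;
    (b) per-minute across-subject correlations (uncorrected and BH-adjusted
    p-values, as none are expected to survive correction at this sample
    size); (c) per-VAS-item across-subject correlations with the mean wave
    amount over the coupling window.
    """
    drug = windows[windows["condition"] == "dmt"].copy()
    drug["minute"] = minute_of(drug["t_start"].to_numpy())
    post = drug[drug["minute"] >= 1]
    per_subj = post.groupby(["minute", "subject"])[["fw_db", "bw_db"]].mean()
    intensity = ratings.intensity.set_index(["minute", "subject"])["intensity"]

    # (a) time-course across minutes
    merged = per_subj.join(intensity, how="inner").reset_index()
    by_minute = merged.groupby("minute")[["fw_db", "bw_db", "intensity"]].mean()
    tc_rows = []
    for direction, col in (("FW", "fw_db"), ("BW", "bw_db")):
        try:
            r, p = pearson(by_minute["intensity"], by_minute[col])
        except ValueError:  # fewer than 3 minutes (or degenerate series)
            r = p = float("nan")
        tc_rows.append({"direction": direction, "r": r, "p": p,
                        "n_minutes": len(by_minute)})
    timecourse = pd.DataFrame(tc_rows)

    # (b) across subjects at each minute
    pm_rows = []
    for direction, col in (("FW", "fw_db"), ("BW", "bw_db")):
        series = []
        for minute, grp in merged.groupby("minute"):
            if len(grp) < 3:
                continue
            r, p = pearson(grp["intensity"], grp[col])
            series.append({"direction": direction, "minute": int(minute),
                           "r": r, "p": p, "n": len(grp)})
        if series:
            fdr = bh_fdr([s["p"] for s in series], q)
            for s, adj in zip(series, fdr.adjusted):
                s["p_adj"] = float(adj)
        pm_rows.extend(series)
    per_minute = pd.DataFrame(pm_rows)

    # (c) VAS items versus mean wave amount over the coupling window
    low, high = (60.0 * m for m in coupling_minutes)
    window_mask = (drug["t_start"] >= low) & (drug["t_start"] < high)
    subj_mean = drug[window_mask].groupby("subject")[["fw_db", "bw_db"]].mean()
    vas_rows = []
    for item, grp in ratings.vas.groupby("item"):
        scores = grp.set_index("subject")["score"]
        joined = subj_mean.join(scores, how="inner").dropna()
        for direction, col in (("FW", "fw_db"), ("BW", "bw_db")):
            try:
                r, p = pearson(joined["score"], joined[col])
            except ValueError:
                r = p = float("nan")
            vas_rows.append({"item": item, "direction": direction,
                             "r": r, "p": p, "n": len(joined)})
    vas = pd.DataFrame(vas_rows)
    return timecourse, per_minute, vas


def band_histogram(windows: pd.DataFrame, bands: BandDefinition,
                   block_minutes: float = 5.0) -> pd.DataFrame:
    """Peak-frequency band counts per subject × condition × block × direction."""
    rows = []
    for (subject, condition), grp in windows.groupby(["subject", "condition"]):
        t = grp["t_start"].to_numpy()
        for block, mask in _block_masks(t, block_minutes).items():
            sub = grp.loc[mask]
            if sub.empty:
                continue
            for direction, col in (("FW", "fw_peak_hz"), ("BW", "bw_peak_hz")):
                counts = {name: 0 for name in bands.names}
                for f in sub[col]:
                    name = bands.classify(float(f))
                    if name is not None:
                        counts[name] += 1
                for name, count in counts.items():
                    rows.append({"subject": subject, "condition": condition,
                                 "block": block, "direction": direction,
                                 "band": name, "count": count,
                                 "n_windows": len(sub)})
    return pd.DataFrame(rows)


def run_study(dataset: StudyDataset, config: AnalysisConfig = AnalysisConfig()
              ) -> StudyResults:
    """Run the complete analysis over a study dataset."""
    logger.info("run_study: %d subjects, seed=%d, %d shuffles",
                len(dataset.subjects), config.seed, config.n_shuffles)
    windows, per_freq = quantify_study(dataset, config)
    summary = block_summary(windows, config.block_minutes)
    tests = block_tests(summary)
    minutes = minute_series(windows, config.fdr_q)
    coupling = coupling_table(windows, config.coupling_minutes,
                              config.block_minutes)
    ctests = coupling_tests(coupling)
    if dataset.ratings is not None:
        timecourse, per_minute, vas = rating_correlations(
            windows, dataset.ratings, config.coupling_minutes, config.fdr_q)
    else:
        timecourse = per_minute = vas = pd.DataFrame()
    hist = band_histogram(windows, config.bands, config.block_minutes)
    return StudyResults(
        windows=windows, block_summary=summary, block_tests=tests,
        minute_series=minutes, coupling=coupling, coupling_tests=ctests,
        rating_timecourse=timecourse, rating_per_minute=per_minute,
        vas_correlations=vas, band_histogram=hist, per_frequency=per_freq,
    )
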