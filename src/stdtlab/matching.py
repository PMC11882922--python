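"""Visuo-tactile matching task: trial engine and percept/report dissociation.

The matching task decouples the percept (one vs. two pulses) from the overt
report: on each trial a visual cue (fixation disk turning white = "two", dark
= "one") is drawn independently of the stimulus, and the participant reports
whether their somatosensory experience *matches* the cue. The same percept
therefore maps onto both possible reports with equal probability, so percept
and report are statistically independent by construction — the property the
dissociation table and its Bayes factor quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ISIDesign, PsychometricFit
from .observers import Observer, psychometric_p

__all__ = [
    "SessionConfig",
    "evaluate_match",
    "build_session",
    "simulate_session",
    "select_stdt_trials",
    "dissociation_table",
    "events_to_tsv",
]

CUE_TWO = "white"
CUE_ONE = "dark"


@dataclass(frozen=True)
class SessionConfig:
    """Main-experiment session parameters.

    Defaults reproduce the reported session: 7 runs of 200 trials (some
    participants completed 6), intertrial intervals jittered in 0.7-1.3 s, a
    2.1% missed-trial rate, and log-normal reaction times with equal
    parameters for both percepts (no reaction-time difference was found;
    an asymmetry can be configured for power analyses). ``report_error_rate``
    is the probability of reporting the wrong match/mismatch answer (0 models
    participants who passed the 90%-accuracy training screen).
    """

    n_runs: int = 7
    trials_per_run: int = 200
    iti_min: float = 0.7
    iti_max: float = 1.3
    miss_rate: float = 0.021
    report_error_rate: float = 0.0
    rt_mu_one: float = float(np.log(0.307))
    rt_sigma_one: float = 0.15
    rt_mu_two: float = float(np.log(0.307))
    rt_sigma_two: float = 0.15
    rt_deadline: float = 0.9
    stim_duration: float = 0.0002


def evaluate_match(percept: str, cue: str) -> str:
    """Truth table of the matching task.

    (two, white) and (one, dark) are matches; (two, dark) and (one, white) are
    mismatches.
    """
    if percept not in ("one", "two"):
        raise ValueError(f"invalid percept {percept!r}")
    if cue not in (CUE_ONE, CUE_TWO):
        raise ValueError(f"invalid cue {cue!r}")
    cue_means_two = cue == CUE_TWO
    return "match" if (percept == "two") == cue_means_two else "mismatch"


def build_session(
    design: ISIDesign, cfg: SessionConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomized trial skeletons for a full session.

    Each run contains exactly ``design.counts_per_run`` trials per ISI level in
    randomized order; cues are drawn 50/50 independently of the ISI; response
    sides are counterbalanced within run and shuffled. Onsets accrue from the
    jittered intertrial intervals.
    """
    rows = []
    onset = 0.0
    trial_index = 0
    for run in range(1, cfg.n_runs + 1):
        levels = np.repeat(np.arange(1, 11), design.counts_per_run)
        rng.shuffle(levels)
        n = levels.size
        cues = np.where(rng.random(n) < 0.5, CUE_TWO, CUE_ONE)
        sides = np.array(["left", "right"]).repeat([n - n // 2, n // 2])
        rng.shuffle(sides)
        itis = rng.uniform(cfg.iti_min, cfg.iti_max, size=n)
        for i in range(n):
            onset += itis[i]
            rows.append(
                {
                    "trial_index": trial_index,
                    "run": run,
                    "isi_level": int(levels[i]),
                    "isi_ms": float(design.levels[levels[i] - 1]),
                    "cue": cues[i],
                    "response_side": sides[i],
                    "onset": onset,
                }
            )
            trial_index += 1
    return pd.DataFrame(rows)


def simulate_session(
    obs: Observer,
    skeletons: pd.DataFrame,
    cfg: SessionConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fill trial skeletons with percepts, reports, reaction times, misses.

    Percepts are Bernoulli draws from the observer's psychometric function at
    the trial ISI; the report equals the match truth except with probability
    ``report_error_rate``; reaction times are percept-conditional log-normal;
    missed trials (rate ``miss_rate``) carry no report and no reaction time.
    """
    df = skeletons.copy()
    n = len(df)
    p_two = psychometric_p(df["isi_ms"].to_numpy(), obs)
    felt_two = rng.random(n) < p_two
    df["percept"] = np.where(felt_two, "two", "one")
    cue_means_two = df["cue"].to_numpy() == CUE_TWO
    is_match = felt_two == cue_means_two
    df["match_truth"] = np.where(is_match, "match", "mismatch")
    flip = rng.random(n) < cfg.report_error_rate
    df["report"] = np.where(
        flip ^ is_match, "match", "mismatch"
    )
    mu = np.where(felt_two, cfg.rt_mu_two, cfg.rt_mu_one)
    sigma = np.where(felt_two, cfg.rt_sigma_two, cfg.rt_sigma_one)
    rt = np.exp(rng.normal(mu, sigma))
    rt = np.minimum(rt, cfg.rt_deadline - 1e-3)  # non-missed responses beat the deadline
    missed = rng.random(n) < cfg.miss_rate
    df["rt"] = np.where(missed, np.nan, rt)
    df["missed"] = missed
    df.loc[missed, "report"] = pd.NA
    return df


def select_stdt_trials(
    trials: pd.DataFrame, run_fits: dict[int, PsychometricFit]
) -> pd.DataFrame:
    """Near-threshold ("STDT") trial selection.

    For each run, keeps the trials of the ISI level whose interval is closest
    to that run's fitted inflection point (ties broken toward the lower
    level); missed trials are excluded.
    """
    out = []
    for run, sub in trials.groupby("run"):
        if run not in run_fits:
            raise KeyError(f"no psychometric fit provided for run {run}")
        t50 = run_fits[run].t50
        levels = sub[["isi_level", "isi_ms"]].drop_duplicates().sort_values("isi_level")
        dist = np.abs(levels["isi_ms"].to_numpy() - t50)
        best = levels["isi_level"].to_numpy()[np.argmin(dist)]  # argmin takes first == lower level
        keep = sub[(sub["isi_level"] == best) & (~sub["missed"])]
        out.append(keep)
    return pd.concat(out, ignore_index=True)


def dissociation_table(trials: pd.DataFrame) -> np.ndarray:
    """2x2 percept-by-report contingency counts (missed trials excluded).

    Rows: percept one/two; columns: report match/mismatch.
    """
    ok = trials[~trials["missed"]]
    if len(ok) == 0:
        raise ValueError("no non-missed trials")
    table = np.zeros((2, 2), dtype=int)
    for i, percept in enumerate(("one", "two")):
        for j, report in enumerate(("match", "mismatch")):
            table[i, j] = int(((ok["percept"] == percept) & (ok["report"] == report)).sum())
    return table


def events_to_tsv(trials: pd.DataFrame, path) -> None:
    """Write a BIDS-events-like TSV (onset/duration first)."""
    df = trials.copy()
    if "duration" not in df:
        df["duration"] = 0.0002
    lead = ["onset", "duration"]
    cols = lead + [c for c in df.columns if c not in lead]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")
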