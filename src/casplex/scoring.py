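"""Genotype scores from kinetic traces.

A replicate's raw statistic is the maximum slope between consecutive
background-subtracted fluorescence measurements within 5-60 min. Each
replicate's max slope is normalized to the mean max slope of the
target-allele standard replicates for that channel (sG1G1 for FAM/TEX,
sG2G2 for HEX), and the sample score is the mean over technical
replicates. Because the standard shares the batch's multiplicative scale,
the score is invariant to day/reader/prep scale effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alleles import CHANNELS
from .io import KineticTrace, PlateSet

#: guard against normalizing to a failed standard
STANDARD_EPS = 1e-9

DEFAULT_WINDOW = (5.0, 60.0)


def background_subtract(trace: KineticTrace, mode: str = "ntc",
                        ntc_traces: list[KineticTrace] | None = None) -> KineticTrace:
    """Subtract background from a trace.

    mode='ntc': subtract the timepoint-wise mean of the channel's NTC
    wells (they must share the trace's time base). mode='first-point':
    subtract the trace's own first reading.
    """
    if mode == "first-point":
        return trace.copy_with(trace.rfus - trace.rfus[0])
    if mode == "ntc":
        if not ntc_traces:
            raise ValueError("background mode 'ntc' requires NTC traces for the channel")
        ref = np.mean([t.rfus for t in ntc_traces], axis=0)
        if ref.shape != trace.rfus.shape:
            raise ValueError("NTC traces do not share the sample trace's time base")
        return trace.copy_with(trace.rfus - ref)
    raise ValueError(f"unknown background mode {mode!r}; expected 'ntc' or 'first-point'")


def max_slope(trace: KineticTrace, window: tuple[float, float] = DEFAULT_WINDOW) -> float:
    """Maximum consecutive-measurement slope (RFU/min) within the window.

    Only pairs with both endpoints inside the closed window count.
    Negative slopes participate in the max (no flooring here).
    """
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    t = trace.times[mask]
    r = trace.rfus[mask]
    if t.size < 2:
        raise ValueError(f"trace {trace.well}/{trace.channel}: fewer than 2 timepoints "
                         f"in window [{lo},{hi}] min")
    return float(np.max(np.diff(r) / np.diff(t)))


def genotype_score(sample_slopes, standard_slopes, eps: float = STANDARD_EPS):
    """Normalize replicate max slopes to the standard's mean max slope.

    Returns (per-replicate scores, sample mean score). Raises if the
    standard's mean slope is <= eps (a failed standard must not silently
    become a divisor).
    """
    sample_slopes = np.asarray(sample_slopes, dtype=float)
    standard_slopes = np.asarray(standard_slopes, dtype=float)
    if standard_slopes.size < 1:
        raise ValueError("need at least one standard replicate slope")
    denom = float(np.mean(standard_slopes))
    if denom <= eps:
        raise ValueError(
            f"standard mean max slope {denom:.3g} RFU/min <= {eps:.0e}: assay failure, "
            "cannot normalize")
    scores = sample_slopes / denom
    return scores, float(np.mean(scores))


@dataclass
class GenotypeScore:
    """Per-channel normalized scores for one sample."""

    sample_id: str
    scores: dict[str, float]                 # channel -> mean score, floored at 0
    raw_scores: dict[str, float] = field(default_factory=dict)   # unfloored means
    replicate_slopes: dict[str, np.ndarray] = field(default_factory=dict)
    standard_mean_slope: dict[str, float] = field(default_factory=dict)


def _resolve_mode(plate: PlateSet, mode: str, channel: str, batch: str) -> str:
    if mode == "auto":
        return "ntc" if plate.ntc(channel, batch) else "first-point"
    return mode


def score_plate(plate: PlateSet, background_mode: str = "auto",
                window: tuple[float, float] = DEFAULT_WINDOW) -> list[GenotypeScore]:
    """Score every sample on a plate, per batch.

    Standards and NTC wells of a sample's own batch are used. The default
    background mode subtracts the NTC mean where NTC wells exist and falls
    back to first-point subtraction otherwise.
    """
    # per (batch, channel): background-subtracted standard slopes
    std_mean: dict[tuple[str, str], float] = {}
    modes: dict[tuple[str, str], str] = {}
    for batch in plate.batches():
        for ch in plate.channels_with_samples():
            stds = plate.standards(ch, batch)
            if not stds:
                continue
            m = _resolve_mode(plate, background_mode, ch, batch)
            modes[(batch, ch)] = m
            ntc = plate.ntc(ch, batch) if m == "ntc" else None
            slopes = [max_slope(background_subtract(t, m, ntc), window) for t in stds]
            _, mean_score = genotype_score(slopes, slopes)   # validates the standard
            std_mean[(batch, ch)] = float(np.mean(slopes))

    out: list[GenotypeScore] = []
    for sid in plate.sample_ids():
        scores: dict[str, float] = {}
        raw: dict[str, float] = {}
        rep_slopes: dict[str, np.ndarray] = {}
        std_used: dict[str, float] = {}
        for ch in CHANNELS:
            reps = plate.sample_traces(sid, ch)
            if not reps:
                continue
            batch = reps[0].batch
            key = (batch, ch)
            if key not in std_mean:
                raise ValueError(f"no {ch} standard wells in batch {batch} for sample {sid}")
            m = modes[key]
            ntc = plate.ntc(ch, batch) if m == "ntc" else None
            slopes = np.array([max_slope(background_subtract(t, m, ntc), window)
                               for t in reps])
            rep_scores, mean_score = genotype_score(slopes, [std_mean[key]])
            raw[ch] = mean_score
            scores[ch] = max(0.0, mean_score)   # floored for reporting/calling
            rep_slopes[ch] = slopes
            std_used[ch] = std_mean[key]
        out.append(GenotypeScore(sample_id=sid, scores=scores, raw_scores=raw,
                                 replicate_slopes=rep_slopes, standard_mean_slope=std_used))
    return out


def scores_frame(scores: list[GenotypeScore]):
    """GenotypeScore list as a tidy DataFrame (one row per sample)."""
    import pandas as pd

    rows = [{"sample_id": s.sample_id,
             "score_fam": s.scores.get("FAM", np.nan),
             "score_hex": s.scores.get("HEX", np.nan),
             "score_tex": s.scores.get("TEX", np.nan)} for s in scores]
    return pd.DataFrame(rows, columns=["sample_id", "score_fam", "score_hex", "score_tex"])
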