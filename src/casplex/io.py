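"""Plate-reader kinetics I/O and call tables.

Kinetic exports are accepted in two delimited-text dialects:

* long — one row per (well, timepoint):
  ``well, sample_id, role, batch, channel, time_min, rfu``
* wide — one row per well with the same leading metadata columns followed
  by one column per timepoint whose header is the time in minutes.

Calls are written as TSV with the scores, the call, a QC flag, the
thresholds used and the software version, so a call file is a complete
record of how it was produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alleles import CHANNELS, ROLES, STANDARD_FOR_CHANNEL

_META_COLS = ["well", "sample_id", "role", "batch", "channel"]
_LONG_COLS = _META_COLS + ["time_min", "rfu"]

#: relative tolerance on uniform sampling spacing
_SPACING_RTOL = 0.01


def canonical_channel(name: str) -> str:
    """Map channel names case-insensitively onto FAM/HEX/TEX."""
    key = str(name).strip().upper()
    if key in ("TEXAS RED", "TEXASRED", "TXRD", "TEXRED"):
        key = "TEX"
    if key not in CHANNELS:
        raise ValueError(f"unknown channel {name!r}; expected one of {CHANNELS}")
    return key


@dataclass
class KineticTrace:
    """One well's RFU time series in one channel."""

    well: str
    sample_id: str
    role: str
    batch: str
    channel: str
    times: np.ndarray
    rfus: np.ndarray

    def __post_init__(self) -> None:
        self.channel = canonical_channel(self.channel)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.times = np.asarray(self.times, dtype=float)
        self.rfus = np.asarray(self.rfus, dtype=float)
        if self.times.size < 2:
            raise ValueError(f"trace {self.well}/{self.channel}: need >=2 timepoints")
        if self.times.size != self.rfus.size:
            raise ValueError(f"trace {self.well}/{self.channel}: times/rfus length mismatch")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError(f"trace {self.well}/{self.channel}: times not strictly increasing")
        if np.any(np.abs(dt - dt[0]) > _SPACING_RTOL * dt[0]):
            raise ValueError(f"trace {self.well}/{self.channel}: non-uniform sampling spacing")
        if not np.all(np.isfinite(self.rfus)):
            raise ValueError(f"trace {self.well}/{self.channel}: non-finite RFU values")

    def copy_with(self, rfus: np.ndarray) -> "KineticTrace":
        return KineticTrace(self.well, self.sample_id, self.role, self.batch,
                            self.channel, self.times.copy(), np.asarray(rfus, dtype=float))


@dataclass
class PlateSet:
    """Validated collection of traces with standard/NTC indexes.

    Every channel with at least one sample trace must carry at least one
    trace of its matching target-allele standard (sG1G1 for FAM/TEX,
    sG2G2 for HEX) so scores can be normalized between experiments.
    """

    traces: list[KineticTrace]
    _by_sample: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_sample = {}
        for tr in self.traces:
            self._by_sample.setdefault((tr.sample_id, tr.channel), []).append(tr)
        for ch in self.channels_with_samples():
            std = STANDARD_FOR_CHANNEL[ch]
            if not any(t.role == std and t.channel == ch for t in self.traces):
                raise ValueError(
                    f"channel {ch} has sample wells but no {std} standard wells"
                )

    # -- queries -----------------------------------------------------------
    def channels_with_samples(self) -> list[str]:
        return sorted({t.channel for t in self.traces if t.role == "sample"})

    def batches(self) -> list[str]:
        return sorted({t.batch for t in self.traces})

    def sample_ids(self) -> list[str]:
        return sorted({t.sample_id for t in self.traces if t.role == "sample"})

    def sample_traces(self, sample_id: str, channel: str) -> list[KineticTrace]:
        return self._by_sample.get((sample_id, canonical_channel(channel)), [])

    def standards(self, channel: str, batch: str | None = None) -> list[KineticTrace]:
        ch = canonical_channel(channel)
        role = STANDARD_FOR_CHANNEL[ch]
        return [t for t in self.traces
                if t.role == role and t.channel == ch
                and (batch is None or t.batch == batch)]

    def ntc(self, channel: str, batch: str | None = None) -> list[KineticTrace]:
        ch = canonical_channel(channel)
        return [t for t in self.traces
                if t.role == "ntc" and t.channel == ch
                and (batch is None or t.batch == batch)]

    def replicate_counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self._by_sample.items()}


# ---------------------------------------------------------------------------
# kinetics reading / writing


def _traces_from_long(df: pd.DataFrame) -> list[KineticTrace]:
    missing_rfu = df.index[df["rfu"].isna()]
    if len(missing_rfu):
        rows = ", ".join(str(i) for i in missing_rfu[:10])
        raise ValueError(f"missing RFU values at data rows: {rows}"
                         + (" ..." if len(missing_rfu) > 10 else ""))
    traces = []
    for (well, ch), grp in df.groupby(["well", "channel"], sort=True):
        grp = grp.sort_values("time_min")
        meta = grp.iloc[0]
        traces.append(KineticTrace(
            well=str(well), sample_id=str(meta["sample_id"]), role=str(meta["role"]),
            batch=str(meta["batch"]), channel=str(ch),
            times=grp["time_min"].to_numpy(dtype=float),
            rfus=grp["rfu"].to_numpy(dtype=float),
        ))
    return traces


def _melt_wide(df: pd.DataFrame) -> pd.DataFrame:
    time_cols = [c for c in df.columns if c not in _META_COLS]
    bad = [c for c in time_cols if not _is_number(c)]
    if bad:
        raise ValueError(f"wide dialect: non-numeric time columns {bad}")
    long = df.melt(id_vars=_META_COLS, value_vars=time_cols,
                   var_name="time_min", value_name="rfu")
    long["time_min"] = long["time_min"].astype(float)
    return long


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_kinetics(path: str | Path, dialect: str = "auto") -> PlateSet:
    """Read a kinetics export (long or wide CSV) into a validated PlateSet.

    ``dialect='auto'`` sniffs the header: presence of both ``time_min`` and
    ``rfu`` columns means long format, otherwise wide.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"kinetics file {path} lacks required columns {missing}")
    if dialect == "auto":
        dialect = "long" if {"time_min", "rfu"} <= set(df.columns) else "wide"
    if dialect == "wide":
        df = _melt_wide(df)
    elif dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}; expected long/wide/auto")
    df["channel"] = df["channel"].map(canonical_channel)
    return PlateSet(_traces_from_long(df))


def kinetics_frame(traces: Iterable[KineticTrace]) -> pd.DataFrame:
    """Long-format DataFrame for a trace collection."""
    recs = []
    for t in traces:
        for tm, r in zip(t.times, t.rfus):
            recs.append((t.well, t.sample_id, t.role, t.batch, t.channel, tm, r))
    return pd.DataFrame(recs, columns=_LONG_COLS)


def write_kinetics(traces: Iterable[KineticTrace], path: str | Path,
                   header_comment: str | None = None) -> None:
    """Write traces as long-format CSV (optionally with a provenance comment)."""
    df = kinetics_frame(traces)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# call tables

_CALL_COLS = ["sample_id", "score_fam", "score_hex", "score_tex",
              "call", "qc_flag", "fam_lo", "fam_hi", "hex_lo", "tex_lo", "version"]

#: decimal places for serialized scores (thresholds are specified at 2)
SCORE_DECIMALS = 4


def write_calls(calls: Sequence, path: str | Path, thresholds=None,
                version: str | None = None, header_comment: str | None = None) -> None:
    """Write genotype calls as TSV.

    ``calls`` are :class:`casplex.genotyping.GenotypeCall` objects (anything
    with sample_id, scores, call, qc_flag attributes works). An empty call
    list produces a header-only file.
    """
    from . import __version__
    from .genotyping import ThresholdSet

    th = thresholds if thresholds is not None else ThresholdSet()
    ver = version or __version__
    rows = []
    for c in calls:
        s = c.scores
        rows.append({
            "sample_id": c.sample_id,
            "score_fam": f"{s['FAM']:.{SCORE_DECIMALS}f}",
            "score_hex": f"{s['HEX']:.{SCORE_DECIMALS}f}",
            "score_tex": f"{s['TEX']:.{SCORE_DECIMALS}f}",
            "call": c.call,
            "qc_flag": c.qc_flag,
            "fam_lo": th.fam_lo, "fam_hi": th.fam_hi,
            "hex_lo": th.hex_lo, "tex_lo": th.tex_lo,
            "version": ver,
        })
    df = pd.DataFrame(rows, columns=_CALL_COLS)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _CALL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"call table {path} lacks columns {missing}")
    return df
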