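"""Live/dead flow-cytometry gating and viability quantification.

Cells suspended in diluted bioink are stained with calcein-AM (green
fluorescence in live cells) and propidium iodide (red fluorescence in cells
with a compromised membrane).  Viability analysis proceeds in two steps:

1. a rectangular scatter gate on forward/side scatter removes debris (low
   scatter) and agglomerates (very high scatter);
2. the remaining events are classified by the green and red channels —
   live iff green above its threshold and red at or below its threshold,
   dead iff red above its threshold.  Double-positive events count as dead
   (PI entry indicates a compromised membrane); double-negative events are
   left unclassified and excluded from the viability denominator.

Viability is the number of live cells divided by the number of classified
cells (live plus dead).  The red threshold can be derived from a
fixed-and-permeabilized (all-dead) control sample as a low quantile of its
red distribution, so that at least 99% of known-dead events classify as dead.

Events load from FCS 3.0/3.1 list-mode files (the reader/writer here covers
the plain linear float/double list-mode subset) or from a CSV fallback with
columns ``fsc, ssc, green, red``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GatingConfig",
    "GatedEvents",
    "ViabilityResult",
    "read_events",
    "write_fcs",
    "derive_dead_threshold",
    "gate",
    "viability",
    "DEFAULT_CHANNEL_MAP",
]

CHANNELS = ("fsc", "ssc", "green", "red")

# canonical channel -> typical instrument channel names ($PnN / CSV headers)
DEFAULT_CHANNEL_MAP: dict[str, tuple[str, ...]] = {
    "fsc": ("fsc", "FSC", "FSC-A", "FSC-H"),
    "ssc": ("ssc", "SSC", "SSC-A", "SSC-H"),
    "green": ("green", "FITC", "FITC-A", "FL1-A", "B1", "GRN-B-HLin"),
    "red": ("red", "PI", "PE-A", "FL2-A", "FL3-A", "B3", "RED-B-HLin"),
}


@dataclass(frozen=True)
class EventTable:
    """List-mode events with canonical columns ``fsc, ssc, green, red``."""

    data: pd.DataFrame
    channel_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"channel not found: {missing}")
        if len(self.data) == 0:
            raise ValueError("invalid events: empty table")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GatingConfig:
    """Rectangular scatter gate plus per-channel fluorescence thresholds."""

    fsc_bounds: tuple[float, float] = (1e4, 1.5e5)
    ssc_bounds: tuple[float, float] = (0.0, 1.5e5)
    green_threshold: float = 1e3
    red_threshold: float = 1e3
    double_positive: str = "dead"  # how green+/red+ events are counted

    def __post_init__(self) -> None:
        for lo, hi in (self.fsc_bounds, self.ssc_bounds):
            if not lo < hi:
                raise ValueError("invalid gate: lower bound must be below upper bound")
        if not (self.green_threshold > 0 and self.red_threshold > 0):
            raise ValueError("invalid gate: thresholds must be positive")
        if self.double_positive not in ("dead", "live"):
            raise ValueError("double_positive must be 'dead' or 'live'")

    @classmethod
    def from_scatter_percentiles(
        cls, events: EventTable, lo: float = 1.0, hi: float = 99.0, **kw
    ) -> "GatingConfig":
        """Scatter gate at pooled-percentile bounds (no instrument units needed)."""
        f = np.percentile(events.data["fsc"], [lo, hi])
        s = np.percentile(events.data["ssc"], [lo, hi])
        return cls(fsc_bounds=(float(f[0]), float(f[1])), ssc_bounds=(float(s[0]), float(s[1])), **kw)


@dataclass(frozen=True)
class GatedEvents:
    """Scatter-gated events with a ``label`` column (live/dead/unclassified)."""

    data: pd.DataFrame
    n_input: int
    n_scatter_excluded: int
    config: GatingConfig

    @property
    def fraction_excluded(self) -> float:
        return self.n_scatter_excluded / self.n_input


@dataclass(frozen=True)
class ViabilityResult:
    n_live: int
    n_dead: int
    viability: float
    fraction_excluded: float


# --------------------------------------------------------------------------
# FCS 3.0 / 3.1 list-mode input/output (linear float/double data)


def write_fcs(path, events: EventTable) -> None:
    """Write events as a minimal FCS 3.1 list-mode file (float32, linear)."""
    df = events.data[list(CHANNELS)]
    n_par = len(CHANNELS)
    tot = len(df)
    data = df.to_numpy(dtype="<f4").tobytes()
    pairs = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(tot),
        "$NEXTDATA": "0",
    }
    for i, ch in enumerate(CHANNELS, start=1):
        pairs[f"$P{i}N"] = ch
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(max(float(df[ch].max()), 1.0)) + 1)
    delim = "/"
    # iterate: text offsets depend on the text length
    header_len = 58
    text = b""
    for _ in range(3):
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_start + len(text)
        data_end = data_start + len(data) - 1
        pairs["$BEGINDATA"] = str(data_start)
        pairs["$ENDDATA"] = str(data_end)
        text = (delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim).encode()
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_start:>8d}".encode() if data_start <= 99999999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99999999 else b"       0")
        + b"       0"
        + b"       0"
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _read_fcs(path) -> tuple[pd.DataFrame, dict]:
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError("parse error: not an FCS 3.0/3.1 file")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ValueError("parse error: malformed FCS header") from exc
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].rstrip(delim).split(delim)
    kw = {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}
    try:
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError:
        data_start = data_end = 0
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    n_par = int(kw["$PAR"])
    tot = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].strip().upper()
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise ValueError("parse error: only list-mode FCS is supported")
    if dtype_code not in ("F", "D"):
        raise ValueError("parse error: only float/double FCS data are supported")
    little = kw.get("$BYTEORD", "1,2,3,4").strip().startswith("1")
    base = "f4" if dtype_code == "F" else "f8"
    dt = ("<" if little else ">") + base
    arr = np.frombuffer(raw[data_start : data_end + 1], dtype=dt)
    if arr.size != n_par * tot:
        raise ValueError("parse error: data segment size mismatch")
    names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    return pd.DataFrame(arr.reshape(tot, n_par), columns=names), kw


def _map_channels(df: pd.DataFrame, channel_map: dict | None) -> pd.DataFrame:
    out = {}
    for canon in CHANNELS:
        if channel_map and canon in channel_map:
            candidates = (channel_map[canon],)
        else:
            candidates = DEFAULT_CHANNEL_MAP[canon]
        col = next((c for c in candidates if c in df.columns), None)
        if col is None:
            raise ValueError(f"channel not found: {canon!r} (tried {candidates})")
        out[canon] = df[col].to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_events(path, channel_map: dict | None = None) -> EventTable:
    """Load events from FCS 3.0/3.1 or CSV.

    ``channel_map`` maps canonical names (``fsc, ssc, green, red``) to the
    column / $PnN names used in the file; common instrument names are tried
    automatically when no map is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".csv", ".txt", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:
            raise ValueError(f"parse error: {exc}") from exc
    else:
        df, _ = _read_fcs(path)
    return EventTable(data=_map_channels(df, channel_map), channel_map=channel_map or {})


# --------------------------------------------------------------------------
# gating and viability


def derive_dead_threshold(
    control: EventTable, quantile: float = 0.01, config: GatingConfig | None = None
) -> float:
    """Red-channel threshold from an all-dead (fixed/permeabilized) control.

    The threshold is the given lower quantile of the control's red signal
    after scatter gating, so at least ``1 - quantile`` of known-dead events
    classify as dead.  ``quantile=0`` returns the control minimum.
    """
    if len(control) < 100:
        raise ValueError("insufficient control: need at least 100 events")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    cfg = config or GatingConfig.from_scatter_percentiles(control)
    d = control.data
    inside = (
        d["fsc"].between(*cfg.fsc_bounds) & d["ssc"].between(*cfg.ssc_bounds)
    )
    red = d.loc[inside, "red"]
    if len(red) == 0:
        raise ValueError("all events excluded")
    # threshold sits just below the quantile so boundary events stay dead
    return float(np.quantile(red, quantile)) * (1.0 - 1e-12)


def gate(events: EventTable, config: GatingConfig) -> GatedEvents:
    """Scatter-gate events and classify the remainder as live/dead.

    Classification: live iff ``green > green_threshold`` and
    ``red <= red_threshold``; dead iff ``red > red_threshold`` (including
    double positives when ``double_positive='dead'``); everything else is
    unclassified.
    """
    d = events.data
    inside = d["fsc"].between(*config.fsc_bounds) & d["ssc"].between(*config.ssc_bounds)
    kept = d[inside].copy()
    if len(kept) == 0:
        raise ValueError("all events excluded")
    green_pos = kept["green"] > config.green_threshold
    red_pos = kept["red"] > config.red_threshold
    if config.double_positive == "dead":
        label = np.where(red_pos, "dead", np.where(green_pos, "live", "unclassified"))
    else:
        label = np.where(green_pos, "live", np.where(red_pos, "dead", "unclassified"))
    kept["label"] = label
    return GatedEvents(
        data=kept,
        n_input=len(d),
        n_scatter_excluded=int((~inside).sum()),
        config=config,
    )


def viability(gated: GatedEvents) -> ViabilityResult:
    """Live fraction among classified cells: ``n_live / (n_live + n_dead)``."""
    counts = gated.data["label"].value_counts()
    n_live = int(counts.get("live", 0))
    n_dead = int(counts.get("dead", 0))
    if n_live + n_dead == 0:
        raise ValueError("no cells after gating")
    return ViabilityResult(
        n_live=n_live,
        n_dead=n_dead,
        viability=n_live / (n_live + n_dead),
        fraction_excluded=gated.fraction_excluded,
    )
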