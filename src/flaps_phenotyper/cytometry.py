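"""Flow-cytometry gating of FLAPS-positive events.

Cells that have accumulated fluorescently labeled polysaccharide (FLAPS) in
their periplasm carry elevated green fluorescence (FL1-H, 530/30 nm under
488 nm excitation).  Gating proceeds in two steps, mirroring instrument
practice:

1. an "electric" forward-scatter threshold (default FSC-H >= 17,000) removes
   sub-cellular debris and electronic noise;
2. an FL1-H threshold derived from a negative control (unamended community,
   or a fixed-and-inactivated sample with FLAPS added) separates
   FLAPS-positive from FLAPS-negative events.

The control threshold is the nearest-rank quantile (default 0.999) of the
control's FL1-H among events surviving the scatter threshold; a sample event
is positive when its FL1-H strictly exceeds that threshold, so a control
gated against its own threshold yields ~1 - quantile positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ControlInsufficiencyError, FormatError, GatingError

__all__ = [
    "EventTable",
    "GateResult",
    "control_threshold",
    "gate_flaps_positive",
    "DEFAULT_FSC_THRESHOLD",
    "DEFAULT_CONTROL_QUANTILE",
]

#: Instrument electric threshold on forward-scatter pulse height.
DEFAULT_FSC_THRESHOLD = 17_000.0
#: Quantile of control FL1-H used to place the positive gate.
DEFAULT_CONTROL_QUANTILE = 0.999

_REQUIRED = ("FSC-H", "FL1-H")


@dataclass(frozen=True)
class EventTable:
    """Per-event cytometry measurements.

    ``data`` must carry at least FSC-H and FL1-H columns (SSC-H is kept when
    present); one row per detected event.  An empty table is valid — gating
    against it raises, reading it does not.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"event table lacks required columns: {missing}")
        for col in self.data.columns:
            if len(self.data) and not np.issubdtype(self.data[col].dtype, np.number):
                raise FormatError(f"event column {col!r} is not numeric")

    @property
    def n_events(self) -> int:
        return int(len(self.data))

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class GateResult:
    """Outcome of gating one sample against a control-derived threshold."""

    fsc_threshold: float
    fl1_threshold: float
    n_events_total: int
    n_after_fsc: int
    n_positive: int
    frac_positive: float
    ci95: tuple[float, float]


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (inverse-CDF) sample quantile: x_(ceil(q*n))."""
    srt = np.sort(values)
    k = min(max(math.ceil(q * srt.size), 1), srt.size)
    return float(srt[k - 1])


def control_threshold(
    control: EventTable,
    quantile: float = DEFAULT_CONTROL_QUANTILE,
    fsc_threshold: float = DEFAULT_FSC_THRESHOLD,
    min_events: int = 100,
) -> float:
    """FL1-H gate position from a negative-control event table.

    Returns the nearest-rank ``quantile`` of control FL1-H among events with
    FSC-H >= ``fsc_threshold``.  Raises
    :class:`~flaps_phenotyper.errors.ControlInsufficiencyError` when fewer
    than ``min_events`` control events survive the scatter threshold.
    """
    if not 0.0 < quantile <= 1.0:
        raise GatingError("quantile must lie in (0, 1]")
    fl1 = control.column("FL1-H")[control.column("FSC-H") >= fsc_threshold]
    if fl1.size < min_events:
        raise ControlInsufficiencyError(
            f"only {fl1.size} control events survive FSC-H >= {fsc_threshold}; "
            f"need {min_events}"
        )
    return _nearest_rank_quantile(fl1, quantile)


def gate_flaps_positive(
    sample: EventTable,
    fl1_threshold: float,
    fsc_threshold: float = DEFAULT_FSC_THRESHOLD,
) -> GateResult:
    """Count FLAPS-positive events in a sample.

    Events are retained when FSC-H >= ``fsc_threshold`` and called positive
    when FL1-H > ``fl1_threshold`` (strict).  The positive fraction is
    reported over retained events with a Wilson 95% confidence interval.
    """
    if sample.n_events == 0:
        raise GatingError("cannot gate an empty event table")
    fsc = sample.column("FSC-H")
    fl1 = sample.column("FL1-H")
    keep = fsc >= fsc_threshold
    n_after = int(keep.sum())
    if n_after == 0:
        raise GatingError("no events survive the forward-scatter threshold")
    n_pos = int((fl1[keep] > fl1_threshold).sum())
    frac = n_pos / n_after
    lo, hi = proportion_confint(n_pos, n_after, alpha=0.05, method="wilson")
    return GateResult(
        fsc_threshold=float(fsc_threshold),
        fl1_threshold=float(fl1_threshold),
        n_events_total=sample.n_events,
        n_after_fsc=n_after,
        n_positive=n_pos,
        frac_positive=float(frac),
        ci95=(float(lo), float(hi)),
    )
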