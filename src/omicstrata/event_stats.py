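"""Per-sample CNV/methylation event tallies and their pairwise concordance.

Events are called with strict inequalities: copy-number gain at value > 0.3,
loss at < -0.3, hypermethylation at beta > 0.8 and hypomethylation at
beta < 0.2. Per-sample tallies of the four event types are then correlated
(Pearson, two-sided t-transform p) across all six unordered pairs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._stats import pearson_with_p
from .errors import InvalidInputError
from .matrix import OmicsMatrix

EVENT_NAMES = ("gain", "loss", "hyper", "hypo")


@dataclass(frozen=True)
class EventThresholds:
    cnv_gain: float = 0.3
    cnv_loss: float = -0.3
    beta_hyper: float = 0.8
    beta_hypo: float = 0.2

    def __post_init__(self) -> None:
        if self.cnv_loss >= self.cnv_gain:
            raise InvalidInputError("cnv_loss must be < cnv_gain")
        if not (0.0 <= self.beta_hypo < self.beta_hyper <= 1.0):
            raise InvalidInputError("beta thresholds must satisfy 0 <= hypo < hyper <= 1")


@dataclass(frozen=True)
class EventCounts:
    sample: str
    n_gain: int
    n_loss: int
    n_hyper: int
    n_hypo: int


@dataclass(frozen=True)
class PairCorrelation:
    pair: str
    r: float
    p: float
    n: int

    @property
    def significance(self) -> str:
        """Sign label at p < 0.01, mirroring the reporting rule used downstream."""
        if not np.isfinite(self.p) or self.p >= 0.01:
            return "ns"
        return "positive" if self.r > 0 else "negative"


def classify_events(
    cnv: OmicsMatrix,
    beta: OmicsMatrix,
    thresholds: EventThresholds = EventThresholds(),
) -> list[EventCounts]:
    """Count strict-threshold events per sample. Missing entries never count."""
    shared = [s for s in cnv.samples if s in set(beta.samples)]
    if not shared:
        raise InvalidInputError("cnv and beta matrices share no samples")
    c = cnv.values[shared].to_numpy(dtype=float)
    b = beta.values[shared].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        n_gain = np.nansum(c > thresholds.cnv_gain, axis=0)
        n_loss = np.nansum(c < thresholds.cnv_loss, axis=0)
        n_hyper = np.nansum(b > thresholds.beta_hyper, axis=0)
        n_hypo = np.nansum(b < thresholds.beta_hypo, axis=0)
    return [
        EventCounts(s, int(n_gain[i]), int(n_loss[i]), int(n_hyper[i]), int(n_hypo[i]))
        for i, s in enumerate(shared)
    ]


def event_counts_frame(counts: list[EventCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in counts],
            "n_gain": [c.n_gain for c in counts],
            "n_loss": [c.n_loss for c in counts],
            "n_hyper": [c.n_hyper for c in counts],
            "n_hypo": [c.n_hypo for c in counts],
        }
    ).set_index("sample")


def event_frequency_correlations(counts: list[EventCounts]) -> list[PairCorrelation]:
    """Pearson r + p for all six unordered pairs of event tallies."""
    if len(counts) < 3:
        raise InvalidInputError("need at least 3 samples for correlations")
    frame = event_counts_frame(counts)
    vectors = {name: frame[f"n_{name}"].to_numpy(dtype=float) for name in EVENT_NAMES}
    out = []
    for a, b in combinations(EVENT_NAMES, 2):
        r, p, n = pearson_with_p(vectors[a], vectors[b])
        if not np.isfinite(r):
            warnings.warn(f"pair {a}~{b}: constant vector, correlation undefined")
        out.append(PairCorrelation(f"{a}~{b}", r, p, n))
    return out


def correlations_frame(correlations: list[PairCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [c.pair for c in correlations],
            "r": [c.r for c in correlations],
            "p": [c.p for c in correlations],
            "n": [c.n for c in correlations],
            "significance": [c.significance for c in correlations],
        }
    )
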