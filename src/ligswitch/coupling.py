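"""State-coupling statistics: chain mode × rotamer association and distance gating.

The central scientific claim these statistics operationalize is that the
ligand chain's +anticlinal (I-shape) pose and the g+ chi1 rotamer of the
6.51 side chain occur together: frames are cross-tabulated by (chain mode,
rotamer state) and the association is quantified with three standard
effect-size measures — the odds ratio (with the Haldane–Anscombe +0.5
correction when a cell is empty, since trajectories commonly never visit
one joint state), Cramér's V, and mutual information in bits.

Frames are treated as exchangeable for counting; no autocorrelation
correction is applied, so these are descriptive effect sizes, not
significance tests.

``distance_gate`` conditions a distance series (e.g. ligand terminal carbon
to the Phe 3.36 ring centroid) on the chain mode and reports, per state,
the fraction of frames below a threshold (default 5 Å — the contact
criterion separating the engaged I-shape pose from the disengaged L-shape).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats.contingency import association

from .errors import ConfigError
from .geometry import DistanceSeries
from .states import StateSeries

__all__ = [
    "CouplingSummary",
    "contingency",
    "association_stats",
    "distance_gate",
    "coupling_summary",
]

DEFAULT_GATE_THRESHOLD = 5.0  # Å


@dataclass
class CouplingSummary:
    """Contingency table plus association and distance-gate statistics."""

    table: pd.DataFrame
    odds_ratio: float | None = None
    cramers_v: float | None = None
    mutual_information: float | None = None
    per_state_distance: dict[str, dict[str, float | None]] = field(default_factory=dict)
    below_threshold_fraction: dict[str, float | None] = field(default_factory=dict)
    gate_threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "table": {
                "index": list(self.table.index),
                "columns": list(self.table.columns),
                "counts": self.table.to_numpy().tolist(),
            },
            "odds_ratio": self.odds_ratio,
            "cramers_v": self.cramers_v,
            "mutual_information_bits": self.mutual_information,
            "per_state_distance": self.per_state_distance,
            "below_threshold_fraction": self.below_threshold_fraction,
            "gate_threshold": self.gate_threshold,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def contingency(chain: StateSeries, rotamer: StateSeries) -> CouplingSummary:
    """Cross-tabulate frames by (chain mode, rotamer state).

    Rows and columns cover each scheme's full alphabet, so never-visited
    joint states appear as explicit zero cells.
    """
    if len(chain) != len(rotamer):
        raise ConfigError(
            f"series lengths differ: chain {len(chain)} vs rotamer {len(rotamer)}"
        )
    if chain.replica_id != rotamer.replica_id:
        raise ConfigError(
            f"series from different replicas: {chain.replica_id} vs "
            f"{rotamer.replica_id}"
        )
    table = pd.DataFrame(
        0, index=list(chain.alphabet), columns=list(rotamer.alphabet), dtype=int
    )
    joint = pd.crosstab(pd.Series(chain.labels), pd.Series(rotamer.labels))
    for r in joint.index:
        for c in joint.columns:
            table.loc[r, c] = int(joint.loc[r, c])
    return CouplingSummary(table=table)


def _mutual_information_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pr * pc))
    return float(np.nansum(terms))


def association_stats(
    table: pd.DataFrame | np.ndarray,
) -> tuple[float | None, float, float]:
    """Odds ratio, Cramér's V, and mutual information (bits) for a table.

    The odds ratio is defined for effectively 2×2 tables (after dropping
    all-zero rows/columns) and uses the Haldane–Anscombe +0.5 correction
    whenever any cell is zero; for larger tables it is returned as None.
    V and MI are computed on the reduced table; both are zero exactly when
    the table factorizes into its margins.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ConfigError("association_stats expects a 2-D table")
    if counts.sum() == 0:
        raise ConfigError("all-zero contingency table")
    if np.any(counts < 0):
        raise ConfigError("negative counts in contingency table")
    # drop never-visited states before computing effect sizes
    reduced = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]

    odds_ratio: float | None = None
    if reduced.shape == (2, 2):
        cells = reduced + 0.5 if np.any(reduced == 0) else reduced
        odds_ratio = float((cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0]))

    if 1 in reduced.shape:
        cramers_v = 0.0  # a degenerate margin carries no association
    else:
        cramers_v = float(association(reduced.astype(int), method="cramer"))
    mutual_information = _mutual_information_bits(reduced)
    return odds_ratio, cramers_v, mutual_information


def distance_gate(
    distances: DistanceSeries,
    chain: StateSeries,
    threshold: float = DEFAULT_GATE_THRESHOLD,
) -> tuple[dict[str, float | None], dict[str, dict[str, float | None]]]:
    """Per-chain-state distance summaries and below-threshold fractions.

    Returns ``(below_threshold_fraction, per_state_distance)`` keyed by
    chain state. A state with no frames reports None (missing), never 0 —
    absence of evidence is not a zero fraction.
    """
    if threshold <= 0:
        raise ConfigError("gate threshold must be positive")
    if len(distances) != len(chain):
        raise ConfigError(
            f"series lengths differ: distances {len(distances)} vs chain {len(chain)}"
        )
    fractions: dict[str, float | None] = {}
    summaries: dict[str, dict[str, float | None]] = {}
    for state in chain.alphabet:
        mask = chain.labels == state
        if not np.any(mask):
            fractions[state] = None
            summaries[state] = {"mean": None, "min": None, "max": None, "n": 0}
            continue
        vals = distances.values[mask]
        fractions[state] = float(np.mean(vals < threshold))
        summaries[state] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(vals.size),
        }
    return fractions, summaries


def coupling_summary(
    chain: StateSeries,
    rotamer: StateSeries,
    distances: DistanceSeries | None = None,
    threshold: float = DEFAULT_GATE_THRESHOLD,
) -> CouplingSummary:
    """Full coupling analysis: table, association stats, optional distance gate."""
    summary = contingency(chain, rotamer)
    odds, v, mi = association_stats(summary.table)
    summary.odds_ratio = odds
    summary.cramers_v = v
    summary.mutual_information = mi
    if distances is not None:
        fractions, per_state = distance_gate(distances, chain, threshold)
        summary.below_threshold_fraction = fractions
        summary.per_state_distance = per_state
        summary.gate_threshold = threshold
    return summary
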