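"""Discrete-state classification of torsion series and state summaries.

Two classification schemes are defined:

``chain_mode``
    The ligand alkyl-chain binding mode, split purely on the sign of the
    chain dihedral 1-2-3-4: ``MINUS_AC`` (−anticlinal, around −90°, the
    L-shape pose, chain bent toward the TM3/TM5 cavity) for angles < 0°,
    ``PLUS_AC`` (+anticlinal, around +90°, the I-shape pose, chain extended
    into the intracellular TM3/TM6 cavity) for angles > 0°.  Exactly 0° is
    assigned ``PLUS_AC`` so the rule is total (documented tie-break).

``rotamer``
    The chi1 rotamer of a side chain, using the standard 120°-wide staggered
    windows: ``T`` (trans/anti, centered 180°), ``GPLUS`` (gauche+, centered
    −60°), ``GMINUS`` (gauche−, centered +60°).  The windows tile the circle
    exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError
from .geometry import TorsionSeries

__all__ = [
    "CHAIN_STATES",
    "ROTAMER_STATES",
    "SCHEMES",
    "StateSeries",
    "StateSummary",
    "HistogramMatrix",
    "classify_chain_mode",
    "classify_rotamer",
    "filter_min_dwell",
    "summarize_states",
    "circular_histogram",
    "state_heatmap",
]

CHAIN_STATES = ("MINUS_AC", "PLUS_AC")
ROTAMER_STATES = ("T", "GPLUS", "GMINUS")
SCHEMES = {"chain_mode": CHAIN_STATES, "rotamer": ROTAMER_STATES}


@dataclass
class StateSeries:
    """Per-frame categorical labels under a named scheme."""

    labels: np.ndarray
    scheme: str
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; known: {sorted(SCHEMES)}")
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D array")
        alphabet = set(SCHEMES[self.scheme])
        bad = set(self.labels) - alphabet
        if bad:
            raise ValueError(
                f"labels {sorted(bad)} not in scheme {self.scheme!r} "
                f"alphabet {SCHEMES[self.scheme]}"
            )

    @property
    def alphabet(self) -> tuple[str, ...]:
        return SCHEMES[self.scheme]

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class StateSummary:
    """Occupancies, kinetic counts, and circular statistics per state."""

    occupancy: dict[str, float]
    n_transitions: int
    mean_dwell: dict[str, float]
    circular_mean: dict[str, float]
    circular_resultant: dict[str, float]
    n_frames: int = 0

    def to_dict(self) -> dict:
        return {
            "occupancy": self.occupancy,
            "n_transitions": self.n_transitions,
            "mean_dwell": self.mean_dwell,
            "circular_mean": self.circular_mean,
            "circular_resultant": self.circular_resultant,
            "n_frames": self.n_frames,
        }


@dataclass
class HistogramMatrix:
    """Counts over equal-width circular bins on (−180, 180]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    def normalize(self) -> "HistogramMatrix":
        total = self.counts.sum()
        if total == 0:
            raise ConfigError("cannot normalize an empty histogram")
        return HistogramMatrix(
            bin_edges=self.bin_edges, counts=self.counts / total, normalized=True
        )


def classify_chain_mode(series: TorsionSeries) -> StateSeries:
    """Label each frame MINUS_AC (angle < 0°) or PLUS_AC (angle ≥ 0°)."""
    labels = np.where(series.values < 0.0, CHAIN_STATES[0], CHAIN_STATES[1])
    return StateSeries(
        labels=labels.astype(object), scheme="chain_mode", replica_id=series.replica_id
    )


def classify_rotamer(series: TorsionSeries) -> StateSeries:
    """Label chi1 frames T / GPLUS / GMINUS by 120° staggered windows.

    GPLUS covers [−120°, 0°), GMINUS covers [0°, +120°), T covers the rest
    of the circle including the ±180° seam.
    """
    v = series.values
    labels = np.full(v.shape, "T", dtype=object)
    labels[(v >= -120.0) & (v < 0.0)] = "GPLUS"
    labels[(v >= 0.0) & (v < 120.0)] = "GMINUS"
    return StateSeries(labels=labels, scheme="rotamer", replica_id=series.replica_id)


def filter_min_dwell(states: StateSeries, min_frames: int) -> StateSeries:
    """Suppress runs shorter than ``min_frames`` by extending the previous run.

    Off by default in the pipeline: an optional guard against single-frame
    classification flicker near state boundaries. The first run is never
    rewritten (there is no previous state to extend).
    """
    if min_frames < 1:
        raise ConfigError("min_frames must be >= 1")
    labels = states.labels.copy()
    out = labels.copy()
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if i > 0 and (j - i) < min_frames:
            out[i:j] = out[i - 1]
        i = j
    return StateSeries(labels=out, scheme=states.scheme, replica_id=states.replica_id)


def _run_lengths(labels: np.ndarray) -> dict[str, list[int]]:
    runs: dict[str, list[int]] = {}
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.setdefault(labels[i], []).append(j - i)
        i = j
    return runs


def summarize_states(states: StateSeries, angles: TorsionSeries) -> StateSummary:
    """Occupancy, transition count, mean dwell and circular stats per state.

    Circular means use the resultant-vector method, so angles straddling the
    ±180° seam average correctly (e.g. {170°, −170°} → 180°). The resultant
    length R ∈ [0, 1] measures concentration (1 = all frames identical).
    States never visited are omitted from the per-state dictionaries.
    """
    if len(states) != len(angles):
        raise ConfigError(
            f"state series ({len(states)}) and angle series ({len(angles)}) "
            "differ in length"
        )
    n = len(states)
    occupancy = {
        s: float(np.mean(states.labels == s))
        for s in states.alphabet
        if np.any(states.labels == s)
    }
    n_transitions = int(np.sum(states.labels[1:] != states.labels[:-1]))
    mean_dwell = {
        s: float(np.mean(lengths)) for s, lengths in _run_lengths(states.labels).items()
    }
    circular_mean: dict[str, float] = {}
    circular_resultant: dict[str, float] = {}
    for s in occupancy:
        rad = np.radians(angles.values[states.labels == s])
        mean = float(np.degrees(stats.circmean(rad, high=np.pi, low=-np.pi)))
        if mean <= -180.0:
            mean += 360.0
        circular_mean[s] = mean
        circular_resultant[s] = float(np.abs(np.mean(np.exp(1j * rad))))
    return StateSummary(
        occupancy=occupancy,
        n_transitions=n_transitions,
        mean_dwell=mean_dwell,
        circular_mean=circular_mean,
        circular_resultant=circular_resultant,
        n_frames=n,
    )


def circular_histogram(series: TorsionSeries, n_bins: int = 72) -> HistogramMatrix:
    """Histogram of a torsion series over equal circular bins on (−180, 180].

    The default 72 bins give 5° resolution. The count total always equals
    the frame count (no value falls off the seam).
    """
    if n_bins < 2:
        raise ConfigError("circular histogram needs at least 2 bins")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # bins are half-open (left, right], matching the angle range (−180, 180];
    # np.histogram bins are [left, right), so count the negated values and flip
    counts, _ = np.histogram(-series.values, bins=edges)
    counts = counts[::-1].copy()
    return HistogramMatrix(bin_edges=edges, counts=counts, normalized=False)


def state_heatmap(
    replicas: list[StateSeries], downsample: int = 1
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Replica × time matrix of integer state codes, for heatmap rendering.

    Rows follow replica order; columns are windows of ``downsample`` frames
    reduced to the modal label (ties go to the earliest-occurring label in
    the window). Returns the matrix and the alphabet whose position defines
    each code. Replicas shorter than the longest one are right-padded with −1.
    """
    if not replicas:
        raise ConfigError("state_heatmap needs at least one replica")
    schemes = {s.scheme for s in replicas}
    if len(schemes) > 1:
        raise ConfigError(f"replicas mix schemes {sorted(schemes)}")
    if downsample < 1:
        raise ConfigError("downsample must be >= 1")
    alphabet = replicas[0].alphabet
    code = {s: i for i, s in enumerate(alphabet)}
    rows = []
    for rep in replicas:
        labels = rep.labels
        row = []
        for start in range(0, len(labels), downsample):
            window = labels[start : start + downsample]
            uniq = list(dict.fromkeys(window))  # earliest-first
            counts = {u: int(np.sum(window == u)) for u in uniq}
            best = max(uniq, key=lambda u: counts[u])  # ties → earliest
            row.append(code[best])
        rows.append(row)
    width = max(len(r) for r in rows)
    matrix = np.full((len(rows), width), -1, dtype=int)
    for i, r in enumerate(rows):
        matrix[i, : len(r)] = r
    return matrix, alphabet
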