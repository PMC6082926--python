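"""Electrode geometry of the 10–20 system and the sensor-adjacency graph.

The montage carries three things: an ordered list of electrode labels, a
2-D head-plane position per electrode (azimuthal-equidistant projection of
the template spherical positions, head radius = 1 at the circumferential
ring level is *not* imposed — units are arbitrary), and a symmetric,
irreflexive adjacency relation over the scalp ("analysis") channels.
Adjacency is what the cluster-forming step of the permutation statistics
consumes, and what the synthetic generator uses to place spatial effects.

The template ships with the package: the 20 scalp electrodes used in the
recording (the classic 19-channel 10–20 set plus Oz) and the A1/A2 ear
references, which carry no analysis adjacency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "build_default_montage",
    "neighbors",
    "ANALYSIS_CHANNELS",
    "REFERENCE_CHANNELS",
    "DEFAULT_ADJACENCY_THRESHOLD",
]

# Template spherical positions: (inclination from vertex, azimuth) in degrees.
# Azimuth is measured from the nasion (front) midline, positive towards the
# right ear.  The circumferential 10% ring sits at 72 deg inclination, the
# mid rings at 36/48 deg, Cz at the vertex.  Ear references sit below the
# ring (inclination > 90 deg).
_TEMPLATE_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (72.0, -18.0), "Fp2": (72.0, 18.0),
    "F7": (72.0, -54.0), "F8": (72.0, 54.0),
    "T7": (72.0, -90.0), "T8": (72.0, 90.0),
    "P7": (72.0, -126.0), "P8": (72.0, 126.0),
    "O1": (72.0, -162.0), "O2": (72.0, 162.0),
    "Oz": (72.0, 180.0),
    "F3": (48.0, -29.0), "F4": (48.0, 29.0),
    "P3": (48.0, -151.0), "P4": (48.0, 151.0),
    "Fz": (36.0, 0.0), "Pz": (36.0, 180.0),
    "C3": (36.0, -90.0), "C4": (36.0, 90.0),
    "Cz": (0.0, 0.0),
    "A1": (112.0, -100.0), "A2": (112.0, 100.0),
}

#: Scalp channels entering every analysis stage, in montage order.
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Ear references, recorded but excluded from analysis and adjacency.
REFERENCE_CHANNELS: tuple[str, ...] = ("A1", "A2")

#: Euclidean distance cutoff (head-plane units, vertex-to-ring distance
#: = 0.8) below which two scalp electrodes count as spatial neighbors.
#: Chosen so each interior electrode has 4–5 neighbors and the scalp
#: graph is a single connected component.
DEFAULT_ADJACENCY_THRESHOLD: float = 0.5


def _project(inclination_deg: float, azimuth_deg: float) -> tuple[float, float]:
    """Azimuthal-equidistant projection onto the head plane (x right, y front)."""
    r = inclination_deg / 90.0
    az = math.radians(azimuth_deg)
    return (r * math.sin(az), r * math.cos(az))


@dataclass(frozen=True)
class Montage:
    """Electrode labels, 2-D template coordinates and the adjacency graph.

    ``adjacency`` maps each analysis channel to the frozenset of its
    neighbors; reference channels map to an empty set.  The relation is
    symmetric and irreflexive by construction.
    """

    labels: tuple[str, ...]
    coords: dict[str, tuple[float, float]]
    adjacency: dict[str, frozenset[str]]
    threshold: float = DEFAULT_ADJACENCY_THRESHOLD
    analysis_channels: tuple[str, ...] = field(default=ANALYSIS_CHANNELS)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        for a, nbrs in self.adjacency.items():
            if a in nbrs:
                raise ValueError(f"self-adjacency at {a}")
            for b in nbrs:
                if a not in self.adjacency.get(b, frozenset()):
                    raise ValueError(f"adjacency not symmetric: {a}-{b}")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    def analysis_indices(self) -> np.ndarray:
        """Positions of the analysis channels within ``labels``."""
        return np.array([self.labels.index(c) for c in self.analysis_channels])

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean neighbor matrix over the analysis channels (in order)."""
        chans = self.analysis_channels
        n = len(chans)
        mat = np.zeros((n, n), dtype=bool)
        for i, a in enumerate(chans):
            for j, b in enumerate(chans):
                if b in self.adjacency[a]:
                    mat[i, j] = True
        return mat

    # -- serialization --------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["label\tx\ty"]
        for lab in self.labels:
            x, y = self.coords[lab]
            lines.append(f"{lab}\t{x:.6f}\t{y:.6f}")
        return "\n".join(lines) + "\n"

    def adjacency_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "adjacency": {a: sorted(nbrs) for a, nbrs in self.adjacency.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _distance_adjacency(
    coords: dict[str, tuple[float, float]],
    channels: tuple[str, ...],
    threshold: float,
) -> dict[str, frozenset[str]]:
    adj: dict[str, set[str]] = {c: set() for c in coords}
    for i, a in enumerate(channels):
        ax, ay = coords[a]
        for b in channels[i + 1:]:
            bx, by = coords[b]
            if math.hypot(ax - bx, ay - by) <= threshold:
                adj[a].add(b)
                adj[b].add(a)
    return {c: frozenset(s) for c, s in adj.items()}


def build_default_montage(threshold: float = DEFAULT_ADJACENCY_THRESHOLD) -> Montage:
    """Build the 10–20 montage with template coordinates and distance adjacency.

    Parameters
    ----------
    threshold
        Euclidean head-plane distance at or below which two scalp
        electrodes are neighbors.  Reference channels A1/A2 never acquire
        adjacency.  Deterministic: same threshold, same montage.
    """
    labels = ANALYSIS_CHANNELS + REFERENCE_CHANNELS
    coords = {lab: _project(*_TEMPLATE_ANGLES[lab]) for lab in labels}
    adjacency = _distance_adjacency(coords, ANALYSIS_CHANNELS, threshold)
    return Montage(labels=labels, coords=coords, adjacency=adjacency,
                   threshold=threshold)


def neighbors(montage: Montage, label: str) -> frozenset[str]:
    """All channels spatially adjacent to ``label``.

    Raises ``KeyError`` naming the label when it is not in the montage.
    Reference channels return the empty set.
    """
    if label not in montage.labels:
        raise KeyError(f"unknown electrode label: {label!r}")
    return montage.adjacency.get(label, frozenset())
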