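"""Numeric sequence descriptors: nucleotide counts, motif-distance
descriptors, and rigid-body features of a 2D graphical sequence embedding.

Motif-distance descriptors
--------------------------
For a motif with 1-based occurrence starts p1 < p2 < p3 (first three
occurrences, overlaps allowed), the three descriptors are

    d2_1 = p2 - p1 + n,   d3_1 = p3 - p1 + n,   d3_2 = p3 - p2 + n,

where n is the number of nucleotides before the *latter* occurrence of the
pair (i.e. its start minus one). The n term pins the pair to its absolute
location, so two ODNs whose occurrences are equally spaced but shifted get
different descriptor values. When the required occurrence does not exist
the whole descriptor is 0.

Graphical features
------------------
Each base takes one unit step in the plane — A: (0,+1), T: (0,−1),
G: (+1,0), C: (−1,0) — and the positions after each step are unit point
masses of a rigid body. Features are the center of mass (Mu_x, Mu_y), the
principal moments of inertia PMI1 ≥ PMI2 of the planar inertia tensor, and
the radius of gyration Rg = sqrt((PMI1 + PMI2) / N).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .motifs import FingerprintDictionary, encode_fingerprint
from .records import OdnRecord

#: Motifs whose distance descriptors are computed by default.
DEFAULT_DISTANCE_MOTIFS = ("CG", "AG", "GG", "CC", "TCT", "TTC", "TGT")

GRAPH_FEATURE_NAMES = ("PMI1", "PMI2", "Mu_x", "Mu_y", "Rg")

_STEPS = {"A": (0.0, 1.0), "T": (0.0, -1.0), "G": (1.0, 0.0), "C": (-1.0, 0.0)}


class NucleotideCounts(NamedTuple):
    A: int
    T: int
    G: int
    C: int


class GraphFeatures(NamedTuple):
    mu_x: float
    mu_y: float
    I11: float
    I22: float
    Rg: float


def count_nucleotides(sequence: str) -> NucleotideCounts:
    """Per-letter tallies of A/T/G/C; any other character (ambiguity codes,
    gaps) is ignored rather than rejected."""
    return NucleotideCounts(
        A=sequence.count("A"),
        T=sequence.count("T"),
        G=sequence.count("G"),
        C=sequence.count("C"),
    )


def motif_positions(sequence: str, motif: str) -> list[int]:
    """All 1-based start positions of (possibly overlapping) occurrences."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        positions.append(i + 1)
        i = sequence.find(motif, i + 1)
    return positions


def distance_descriptors(sequence: str, motif: str) -> tuple[int, int, int]:
    """(d2_1, d3_1, d3_2) for ``motif`` in ``sequence``; 0 where the needed
    occurrence is absent."""
    p = motif_positions(sequence, motif)
    d2_1 = p[1] - p[0] + (p[1] - 1) if len(p) >= 2 else 0
    d3_1 = p[2] - p[0] + (p[2] - 1) if len(p) >= 3 else 0
    d3_2 = p[2] - p[1] + (p[2] - 1) if len(p) >= 3 else 0
    return d2_1, d3_1, d3_2


def graph_embed(sequence: str) -> np.ndarray:
    """Cumulative 2D walk of the sequence; row i is the position after base i."""
    if not sequence:
        return np.empty((0, 2), dtype=float)
    steps = np.array([_STEPS[b] for b in sequence], dtype=float)
    return np.cumsum(steps, axis=0)


def graph_features(points: np.ndarray) -> GraphFeatures:
    """Center of mass, principal moments of inertia and radius of gyration
    of unit point masses at ``points``.

    The planar inertia tensor about the center of mass is
    Ixx = Σ(y−μy)², Iyy = Σ(x−μx)², Ixy = −Σ(x−μx)(y−μy); PMI1 ≥ PMI2 are
    its eigenvalues, and Rg² · N = PMI1 + PMI2 (trace invariance).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("graph_features needs a non-empty (N, 2) point array")
    mu = pts.mean(axis=0)
    dx = pts[:, 0] - mu[0]
    dy = pts[:, 1] - mu[1]
    ixx = float(np.sum(dy * dy))
    iyy = float(np.sum(dx * dx))
    ixy = -float(np.sum(dx * dy))
    eig = np.linalg.eigvalsh(np.array([[ixx, ixy], [ixy, iyy]]))
    i22, i11 = float(max(eig[0], 0.0)), float(eig[1])
    rg = float(np.sqrt((i11 + i22) / pts.shape[0]))
    return GraphFeatures(mu_x=float(mu[0]), mu_y=float(mu[1]), I11=i11, I22=i22, Rg=rg)


def distance_feature_names(motifs: Sequence[str] = DEFAULT_DISTANCE_MOTIFS) -> list[str]:
    return [f"d_{m}{suffix}" for m in motifs for suffix in ("2_1", "3_1", "3_2")]


def feature_names(
    dictionary: FingerprintDictionary | None = None,
    distance_motifs: Sequence[str] = DEFAULT_DISTANCE_MOTIFS,
) -> list[str]:
    """Full feature-matrix header for the given configuration."""
    names = ["A", "T", "G", "C"]
    names += distance_feature_names(distance_motifs)
    names += list(GRAPH_FEATURE_NAMES)
    if dictionary is not None:
        names += dictionary.names
    return names


def fingerprint_column_names(dictionary: FingerprintDictionary | None) -> list[str]:
    """Names of the binary columns in a matrix built with ``featurize``."""
    return dictionary.names if dictionary is not None else []


def featurize(
    records: Sequence[OdnRecord],
    dictionary: FingerprintDictionary | None = None,
    distance_motifs: Sequence[str] = DEFAULT_DISTANCE_MOTIFS,
) -> pd.DataFrame:
    """One feature row per ODN, indexed by record id.

    Columns, in order: nucleotide counts A/T/G/C; distance descriptors
    d_<motif>2_1 / 3_1 / 3_2 per configured motif; graph features
    PMI1, PMI2, Mu_x, Mu_y, Rg; then one binary column per dictionary token
    (names like CG1, GT18). An empty record list yields a 0-row frame with
    the full header.
    """
    cols = feature_names(dictionary, distance_motifs)
    rows = []
    for rec in records:
        seq = rec.sequence
        c = count_nucleotides(seq)
        row: list[float] = [c.A, c.T, c.G, c.C]
        for m in distance_motifs:
            row.extend(distance_descriptors(seq, m))
        g = graph_features(graph_embed(seq))
        row.extend([g.I11, g.I22, g.mu_x, g.mu_y, g.Rg])
        if dictionary is not None:
            row.extend(encode_fingerprint(seq, dictionary).tolist())
        rows.append(row)
    index = pd.Index([rec.id for rec in records], name="id")
    return pd.DataFrame(rows, index=index, columns=cols, dtype=float)
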