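"""Per-residue aggregation/amyloidogenicity predictors and their consensus.

Four local, fully specified methods stand in for a web-based multi-predictor
consensus:

* ``aggrescan`` — windowed mean of the AGGRESCAN a3v aggregation-propensity
  scale with hot-spot calling (threshold -0.02, minimum run 5, prolines break
  runs), after Conchillo-Sole et al. 2007.
* ``pattern`` — the six-position amyloidogenic hexapeptide residue-class
  pattern of Lopez de la Paz & Serrano 2004 (canonical match: STVIIE).
* ``packing`` — windowed mean of the expected packing-density (contact
  number) scale of Galzitskaya et al. 2006, hot spots above 21.4.
* ``beta`` — windowed mean of Chou-Fasman beta-sheet propensities, hot spots
  above 1.0 (the scale's database average; residues favouring beta strands).

A residue is a *consensus hit* when at least ``threshold`` methods flag it
(default: majority). Because the method set differs from any particular web
consensus, absolute scores are comparable only within this package; analyses
built on top use rank order and classification, not raw score equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .records import ProteinSequence

# Method defaults (config-overridable in every entry point).
AGGRESCAN_WINDOW = 5
AGGRESCAN_HOTSPOT_THRESHOLD = -0.02
PACKING_WINDOW = 5
PACKING_THRESHOLD = 21.4
BETA_WINDOW = 5
BETA_THRESHOLD = 1.0
MIN_HOTSPOT_LEN = 5

METHOD_IDS = ("aggrescan", "pattern", "packing", "beta")


@lru_cache(maxsize=None)
def load_scale(name: str) -> dict[str, float]:
    """Load one of the shipped residue scales (``aggrescan_a3v``,
    ``packing_density``, ``beta_propensity``)."""
    text = resources.files("splicescout.data").joinpath(f"{name}.tsv").read_text()
    scale = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split("\t")
        scale[aa] = float(val)
    if len(scale) != 20:
        raise ValueError(f"scale {name!r} does not cover all 20 residues")
    return scale


@dataclass(frozen=True)
class ResidueTrack:
    """One method's per-residue values and thresholded hit calls."""

    method_id: str
    values: np.ndarray
    hits: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.hits):
            raise ValueError("values/hits length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ConsensusTrack:
    """Per-residue count of methods flagging each residue, and the
    thresholded consensus mask."""

    counts: np.ndarray
    hits: np.ndarray
    n_methods: int
    threshold: int

    def __len__(self) -> int:
        return len(self.counts)


def window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window mean, truncated symmetrically at the termini.

    At position i the mean runs over ``[i-h, i+h]`` clipped to the sequence,
    so the output has the same length as the input and terminal values
    average over fewer residues.
    """
    n = len(values)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _runs_above(
    values: np.ndarray,
    threshold: float,
    min_len: int,
    forbidden_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Boolean mask of residues inside maximal runs of length >= min_len with
    value > threshold, optionally broken by forbidden residues."""
    ok = values > threshold
    if forbidden_mask is not None:
        ok &= ~forbidden_mask
    hits = np.zeros(len(values), dtype=bool)
    i = 0
    n = len(values)
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_len:
                hits[i:j] = True
            i = j
        else:
            i += 1
    return hits


def _scale_track(
    seq: ProteinSequence,
    scale_name: str,
    method_id: str,
    window: int,
    threshold: float,
    min_hotspot_len: int,
    proline_breaks: bool,
) -> ResidueTrack:
    scale = load_scale(scale_name)
    raw = np.array([scale[aa] for aa in seq.residues])
    values = window_mean(raw, window)
    forbidden = None
    if proline_breaks:
        forbidden = np.array([aa == "P" for aa in seq.residues])
    hits = _runs_above(values, threshold, min_hotspot_len, forbidden)
    return ResidueTrack(method_id=method_id, values=values, hits=hits)


def aggrescan_track(
    seq: ProteinSequence,
    window: int = AGGRESCAN_WINDOW,
    hotspot_threshold: float = AGGRESCAN_HOTSPOT_THRESHOLD,
    min_hotspot_len: int = MIN_HOTSPOT_LEN,
) -> ResidueTrack:
    """AGGRESCAN-style track: windowed a3v mean with hot-spot calling.

    A hot spot is a proline-free run of at least ``min_hotspot_len`` residues
    whose windowed value exceeds ``hotspot_threshold``.
    """
    return _scale_track(
        seq, "aggrescan_a3v", "aggrescan", window, hotspot_threshold,
        min_hotspot_len, proline_breaks=True,
    )


def packing_density_track(
    seq: ProteinSequence,
    window: int = PACKING_WINDOW,
    threshold: float = PACKING_THRESHOLD,
    min_hotspot_len: int = MIN_HOTSPOT_LEN,
) -> ResidueTrack:
    """Mean-packing-density track: residues in dense (contact-rich) runs are
    amyloidogenic candidates."""
    return _scale_track(
        seq, "packing_density", "packing", window, threshold,
        min_hotspot_len, proline_breaks=False,
    )


def beta_propensity_track(
    seq: ProteinSequence,
    window: int = BETA_WINDOW,
    threshold: float = BETA_THRESHOLD,
    min_hotspot_len: int = MIN_HOTSPOT_LEN,
) -> ResidueTrack:
    """Beta-sheet-propensity track: runs of strong beta formers."""
    return _scale_track(
        seq, "beta_propensity", "beta", window, threshold,
        min_hotspot_len, proline_breaks=False,
    )


# Six-position residue-class pattern for de novo amyloid hexapeptides
# (canonical positive: STVIIE). Position classes: {not P}, {not P/K/R/H/W},
# [VLSCWFNQE], [ILTYWFNE], [FIY], {not P/K/R/H}.
_HEXA_CLASSES = (
    frozenset("ACDEFGHIKLMNQRSTVWY"),            # not P
    frozenset("ACDEFGILMNQSTVY"),                # not P,K,R,H,W
    frozenset("VLSCWFNQE"),
    frozenset("ILTYWFNE"),
    frozenset("FIY"),
    frozenset("ACDEFGILMNQSTVWY"),               # not P,K,R,H
)


def amyloidogenic_pattern_track(seq: ProteinSequence) -> ResidueTrack:
    """Hexapeptide amyloidogenic-pattern track.

    Every 6-residue window matching the residue-class pattern marks all six
    positions as hits (values 1 inside matches, 0 elsewhere). Sequences
    shorter than 6 residues yield an all-false track.
    """
    n = len(seq)
    hits = np.zeros(n, dtype=bool)
    for i in range(n - 5):
        window = seq.residues[i : i + 6]
        if all(window[j] in _HEXA_CLASSES[j] for j in range(6)):
            hits[i : i + 6] = True
    return ResidueTrack(
        method_id="pattern", values=hits.astype(float), hits=hits
    )


def compute_tracks(
    seq: ProteinSequence, methods: Sequence[str] = METHOD_IDS, **overrides
) -> list[ResidueTrack]:
    """Compute the requested method tracks with default parameters.

    ``overrides`` may carry per-method keyword dicts, e.g.
    ``compute_tracks(seq, aggrescan={"window": 7})``.
    """
    funcs = {
        "aggrescan": aggrescan_track,
        "pattern": amyloidogenic_pattern_track,
        "packing": packing_density_track,
        "beta": beta_propensity_track,
    }
    tracks = []
    for m in methods:
        if m not in funcs:
            raise ValueError(f"unknown method {m!r}; choose from {METHOD_IDS}")
        tracks.append(funcs[m](seq, **overrides.get(m, {})))
    return tracks


def consensus(
    tracks: Sequence[ResidueTrack], threshold: Optional[int] = None
) -> ConsensusTrack:
    """Combine method hit masks into a consensus track.

    ``counts[i]`` is the number of methods flagging residue i; residues with
    ``counts >= threshold`` are consensus hits. The default threshold is a
    majority, ``ceil(n_methods / 2)``. Threshold 1 is the union of the
    methods, threshold ``n_methods`` their intersection.
    """
    if not tracks:
        raise ValueError("no tracks given")
    n = len(tracks[0])
    if any(len(t) != n for t in tracks):
        raise ValueError("tracks have mixed lengths")
    m = len(tracks)
    if threshold is None:
        threshold = math.ceil(m / 2)
    if not 1 <= threshold <= m:
        raise ValueError(f"threshold {threshold} outside [1, {m}]")
    counts = np.sum([t.hits for t in tracks], axis=0).astype(int)
    return ConsensusTrack(
        counts=counts, hits=counts >= threshold, n_methods=m, threshold=threshold
    )


def score_sequence(
    seq: ProteinSequence,
    methods: Sequence[str] = METHOD_IDS,
    consensus_threshold: Optional[int] = None,
    **overrides,
) -> ConsensusTrack:
    """Convenience: per-method tracks plus majority consensus in one call."""
    return consensus(compute_tracks(seq, methods, **overrides), consensus_threshold)


def tracks_to_dataframe(
    seq: ProteinSequence,
    tracks: Sequence[ResidueTrack],
    cons: ConsensusTrack,
):
    """Tabulate tracks for TSV export (position, residue, per-method value
    and hit columns, consensus count and hit) — the per-residue profile
    behind aggregation-landscape plots."""
    import pandas as pd

    data = {"position": np.arange(len(seq)), "residue": list(seq.residues)}
    for t in tracks:
        data[f"{t.method_id}_value"] = t.values
        data[f"{t.method_id}_hit"] = t.hits.astype(int)
    data["consensus_count"] = cons.counts
    data["consensus_hit"] = cons.hits.astype(int)
    return pd.DataFrame(data)
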