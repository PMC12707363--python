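"""N1/N2 lobe partitioning and the N2/N1 aggregation-score ratio.

Before association with its Int^C partner, an Int^N fragment comprises two
folding regions: a molten-globule-like N-terminal lobe (N1) and a disordered,
highly charged C-terminal lobe (N2). Aggregation driven by the N2 lobe is a
known cause of incomplete trans-splicing, so the per-residue aggregation
score of N2 relative to N1 — the ratio r = s_N2 / s_N1 — is used as a
sequence-only predictor: r < 1 predicts an efficient splicer, r > 1 an
aggregation-prone one.

The N1/N2 boundary of a candidate is obtained by transferring an annotated
boundary from a reference intein through deterministic global pairwise
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .predictors import ConsensusTrack
from .records import ProteinSequence

EFFICIENT = "efficient_predicted"
AGGREGATION_PRONE = "aggregation_prone_predicted"
INDETERMINATE = "indeterminate"

DEFAULT_IDENTITY_FLOOR = 0.15


@dataclass(frozen=True)
class LobePartition:
    """Boundary index b partitioning an Int^N of length L into
    N1 = [0, b) and N2 = [b, L); both lobes must be non-empty."""

    boundary: int
    length: int
    source: str = "explicit"  # "explicit" | "reference_transfer"

    def __post_init__(self) -> None:
        if not 0 < self.boundary < self.length:
            raise ValueError(
                f"boundary {self.boundary} must satisfy 0 < b < L={self.length}"
            )


@dataclass(frozen=True)
class LobeScores:
    """Per-residue aggregation scores of the two lobes and the full fragment.

    ``s_total`` equals the length-weighted mean of the lobe scores exactly.
    ``ratio`` is undefined (None) when s_N1 = 0, in which case the
    classification is indeterminate.
    """

    s_n1: float
    s_n2: float
    s_total: float
    ratio: Optional[float]
    classification: str
    boundary: int
    length: int
    score_mode: str


class LowIdentityError(ValueError):
    """Alignment identity below the floor: transfer the boundary manually."""


def _aligner(open_gap: float = -10.0, extend_gap: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def transfer_boundary(
    candidate: ProteinSequence,
    reference: ProteinSequence,
    reference_boundary: int,
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
    min_identity: float = DEFAULT_IDENTITY_FLOOR,
) -> LobePartition:
    """Map a reference N1/N2 boundary onto a candidate by global alignment.

    The candidate position aligned with reference position
    ``reference_boundary`` becomes the candidate boundary; if that reference
    column aligns to a gap, the boundary maps to the nearest *following*
    candidate residue (N2 begins at the first residue of the transferred
    region). BLOSUM62 with affine gaps; of co-optimal tracebacks the
    aligner's first (match preferred over insertion over deletion) is used,
    making the result deterministic.

    Raises :class:`LowIdentityError` when the fraction of identical aligned
    residue pairs, relative to the longer sequence, falls below
    ``min_identity`` (default 15%) — below that, automatic transfer is not
    trustworthy and a manual boundary should be supplied.
    """
    if not 0 < reference_boundary < len(reference):
        raise ValueError("reference boundary outside (0, len(reference))")
    aln = _aligner(open_gap, extend_gap).align(
        candidate.residues, reference.residues
    )[0]
    cand_idx, ref_idx = aln.indices  # -1 where gapped
    matches = sum(
        1
        for c, r in zip(cand_idx, ref_idx)
        if c >= 0 and r >= 0 and candidate.residues[c] == reference.residues[r]
    )
    identity = matches / max(len(candidate), len(reference))
    if identity < min_identity:
        raise LowIdentityError(
            f"alignment identity {identity:.1%} below floor {min_identity:.0%}; "
            "supply an explicit boundary"
        )
    col = int(np.nonzero(ref_idx == reference_boundary)[0][0])
    for c in range(col, len(cand_idx)):
        if cand_idx[c] >= 0:
            boundary = int(cand_idx[c])
            break
    else:
        raise ValueError(
            "reference boundary maps past the candidate C-terminus; "
            "no residues remain for the N2 lobe"
        )
    return LobePartition(
        boundary=boundary, length=len(candidate), source="reference_transfer"
    )


def classify_ratio(ratio: float, cutoff: float = 1.0) -> str:
    """Classify an N2/N1 score ratio against the efficiency cutoff.

    Ratios below the cutoff predict efficient splicing; above it,
    aggregation-prone behaviour; exactly at the cutoff, indeterminate.
    """
    if ratio < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio}")
    if ratio < cutoff:
        return EFFICIENT
    if ratio > cutoff:
        return AGGREGATION_PRONE
    return INDETERMINATE


def lobe_scores(
    track: ConsensusTrack,
    partition: LobePartition,
    score_mode: str = "hit_fraction",
    cutoff: float = 1.0,
) -> LobeScores:
    """Per-lobe aggregation scores from a consensus track.

    ``hit_fraction`` (default): fraction of lobe residues that are consensus
    hits. ``mean_count``: mean of counts / n_methods over the lobe. Both are
    per-residue normalised, so s_total is exactly the length-weighted mean
    of s_N1 and s_N2.
    """
    if len(track) != partition.length:
        raise ValueError(
            f"track length {len(track)} != partition length {partition.length}"
        )
    b, length = partition.boundary, partition.length
    if score_mode == "hit_fraction":
        per_residue = track.hits.astype(float)
    elif score_mode == "mean_count":
        per_residue = track.counts / track.n_methods
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")
    s_n1 = float(per_residue[:b].mean())
    s_n2 = float(per_residue[b:].mean())
    s_total = (b * s_n1 + (length - b) * s_n2) / length
    if s_n1 > 0:
        ratio = s_n2 / s_n1
        classification = classify_ratio(ratio, cutoff)
    else:
        ratio = None
        classification = INDETERMINATE
        warnings.warn(
            "s_N1 = 0: N2/N1 ratio undefined, classification indeterminate",
            stacklevel=2,
        )
    return LobeScores(
        s_n1=s_n1,
        s_n2=s_n2,
        s_total=s_total,
        ratio=ratio,
        classification=classification,
        boundary=b,
        length=length,
        score_mode=score_mode,
    )
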