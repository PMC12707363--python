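"""Synthetic intein-like sequences and kinetics traces with known ground
truth.

The generators emulate the composition contrast between the two Int^N
lobes — an order-promoting, hydrophobic-leaning N1 and a charged, disordered
N2 — and seed amyloidogenic hexapeptides (STVIIE) into chosen lobes so that
lobe scores and ratio orderings have a known expected direction. They are
test fixtures: residue pools are named constants chosen for their scale
properties, not claims about real intein sequences. All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lobes import LobePartition
from .records import InteinRecord, ProteinSequence

# Pool for N1 (molten-globule-like lobe): order-promoting hydrophobics
# diluted 4:1 with small/polar neutrals, so the baseline aggregation score is
# moderate and responds to seeded hexapeptide inserts; no Cys (fixtures are
# cysteine-less) and no Pro (order-breaking).
N1_POOL = "AAGGTTSSQQNNVLF"
# Disorder-promoting, non-charged pool for N2; the charged fraction is drawn
# separately from D/E/K/R. Pro included: it breaks aggregation hot spots,
# keeping the disordered background score low.
N2_NEUTRAL_POOL = "GQSPAN"
N2_CHARGED_POOL = "DEKR"
# Generic pool for Int^C fragments.
INTC_POOL = "GSTNDEKRAQ"

AMYLOID_HEXAPEPTIDE = "STVIIE"


@dataclass(frozen=True)
class SyntheticInteinSpec:
    """Recipe for one synthetic split-intein candidate.

    ``n2_charge_fraction`` is the D/E/K/R fraction of the N2 lobe (disorder
    proxy); ``n_amyloid_inserts_*`` count non-overlapping STVIIE hexapeptides
    written into each lobe.
    """

    n1_length: int = 60
    n2_length: int = 60
    n2_charge_fraction: float = 0.5
    n_amyloid_inserts_n1: int = 0
    n_amyloid_inserts_n2: int = 0
    seed: int = 0
    intc_length: int = 36

    def __post_init__(self) -> None:
        if self.n1_length < 10 or self.n2_length < 10:
            raise ValueError("lobe lengths must be >= 10")
        if not 0.0 <= self.n2_charge_fraction <= 1.0:
            raise ValueError("charge fraction must be in [0, 1]")
        if self.n_amyloid_inserts_n1 < 0 or self.n_amyloid_inserts_n2 < 0:
            raise ValueError("insert counts must be non-negative")


def _insert_hexapeptides(
    lobe: list[str], count: int, rng: np.random.Generator, label: str
) -> None:
    """Overwrite ``count`` non-overlapping 6-mers with the amyloid
    hexapeptide, at seeded block positions. Length-preserving."""
    k = len(AMYLOID_HEXAPEPTIDE)
    capacity = len(lobe) // k
    if count > capacity:
        raise ValueError(
            f"{count} inserts exceed capacity {capacity} of the {label} lobe"
        )
    if count == 0:
        return
    blocks = rng.choice(capacity, size=count, replace=False)
    for b in sorted(blocks):
        lobe[b * k : (b + 1) * k] = list(AMYLOID_HEXAPEPTIDE)


def make_intein(
    spec: SyntheticInteinSpec, name: Optional[str] = None
) -> tuple[InteinRecord, LobePartition, dict]:
    """Generate a synthetic cysteine-less split-intein record.

    Returns the record, the true N1/N2 partition (boundary = n1_length), and
    a ground-truth dict with the insert counts and the expected ratio
    ordering key (more N2 inserts relative to N1 inserts => larger expected
    N2/N1 ratio). Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = list(rng.choice(list(N1_POOL), size=spec.n1_length))
    n_charged = int(round(spec.n2_charge_fraction * spec.n2_length))
    n2_res = list(rng.choice(list(N2_CHARGED_POOL), size=n_charged)) + list(
        rng.choice(list(N2_NEUTRAL_POOL), size=spec.n2_length - n_charged)
    )
    n2 = list(rng.permutation(n2_res))
    _insert_hexapeptides(n1, spec.n_amyloid_inserts_n1, rng, "N1")
    _insert_hexapeptides(n2, spec.n_amyloid_inserts_n2, rng, "N2")
    n1[0] = "S"  # catalytic position 1
    intc = list(rng.choice(list(INTC_POOL), size=spec.intc_length - 1)) + ["N"]
    if name is None:
        name = f"syn-{spec.seed}"
    rec = InteinRecord(
        name=name,
        intN=ProteinSequence(id=f"{name}_intN", residues="".join(n1 + n2)),
        intC=ProteinSequence(id=f"{name}_intC", residues="".join(intc)),
        plus1="S",
    )
    partition = LobePartition(
        boundary=spec.n1_length,
        length=spec.n1_length + spec.n2_length,
        source="explicit",
    )
    ground_truth = {
        "n_inserts_n1": spec.n_amyloid_inserts_n1,
        "n_inserts_n2": spec.n_amyloid_inserts_n2,
        "ratio_rank_key": spec.n_amyloid_inserts_n2 - spec.n_amyloid_inserts_n1,
    }
    return rec, partition, ground_truth


def make_timecourse(
    k: float,
    sp_max: float,
    sigma: float,
    n_points: int,
    t_max: float,
    seed: int = 0,
    pn0: Optional[float] = None,
):
    """Generate a noisy one-phase exponential splice time course.

    Times are log-spaced over (0, t_max] (front-loaded, since fast reactions
    complete within the first few half-lives); sp = sp_max (1 - e^{-kt}) plus
    Gaussian noise of sd ``sigma``, clipped at 0. Deterministic per seed.
    """
    from .kinetics import SpliceTimeCourse

    if k <= 0:
        raise ValueError("k must be positive")
    if n_points < 4:
        raise ValueError("need >= 4 points")
    if sigma < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.geomspace(t_max / 100.0, t_max, n_points)
    sp = sp_max * (1.0 - np.exp(-k * times))
    if sigma > 0:
        sp = np.clip(sp + rng.normal(0.0, sigma, size=n_points), 0.0, None)
    return SpliceTimeCourse(times=times, sp=sp, pn0=pn0)


MAX_PANEL_INSERTS = 6


def make_panel(
    n_inteins: int, anticorrelation: float, seed: int = 0
) -> tuple[list[tuple[InteinRecord, LobePartition, dict]], dict]:
    """Generate a panel of synthetic inteins with negatively coupled
    N1/N2 amyloid-insert counts.

    For each intein the N2 insert count is uniform on {0..6}; with
    probability |anticorrelation| the N1 count is set to its complement
    (6 - n2), otherwise drawn independently — so the expected insert-count
    correlation is about ``anticorrelation``. Returns the per-intein
    (record, partition, ground_truth) triples and a panel-level ground-truth
    dict (requested coupling and realised insert-count correlation).
    """
    if n_inteins < 5:
        raise ValueError("need >= 5 inteins")
    if not -1.0 <= anticorrelation <= 0.0:
        raise ValueError("anticorrelation must lie in [-1, 0]")
    rng = np.random.default_rng(seed)
    triples = []
    n1_counts, n2_counts = [], []
    for i in range(n_inteins):
        n2c = int(rng.integers(0, MAX_PANEL_INSERTS + 1))
        if rng.random() < abs(anticorrelation):
            n1c = MAX_PANEL_INSERTS - n2c
        else:
            n1c = int(rng.integers(0, MAX_PANEL_INSERTS + 1))
        spec = SyntheticInteinSpec(
            n_amyloid_inserts_n1=n1c,
            n_amyloid_inserts_n2=n2c,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        triples.append(make_intein(spec, name=f"syn-panel-{i}"))
        n1_counts.append(n1c)
        n2_counts.append(n2c)
    n1a, n2a = np.array(n1_counts, float), np.array(n2_counts, float)
    realised = (
        float(np.corrcoef(n1a, n2a)[0, 1])
        if n1a.std() > 0 and n2a.std() > 0
        else math.nan
    )
    ground_truth = {
        "requested_anticorrelation": anticorrelation,
        "realised_insert_correlation": realised,
        "n1_insert_counts": n1_counts,
        "n2_insert_counts": n2_counts,
    }
    return triples, ground_truth


def make_reference_intein(seed: int = 2024) -> tuple[InteinRecord, LobePartition]:
    """A synthetic stand-in for a boundary-annotated reference intein.

    Real reference inteins with a published N1/N2 border are not shipped;
    this record exists so boundary transfer can be demonstrated and tested.
    """
    rec, partition, _ = make_intein(
        SyntheticInteinSpec(seed=seed), name="synthetic-reference"
    )
    return rec, partition
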