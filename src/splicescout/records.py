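"""Sequence records and split-intein candidate models.

A split intein is expressed as two complementary fragments: a larger
N-terminal fragment (Int^N, typically 100-120 aa) and a short C-terminal
fragment (Int^C, ~35-45 aa). Splicing chemistry is anchored by the residue
at intein position 1 (first residue of Int^N) and the +1 residue (first
residue of the C-extein). Cysteine-less inteins carry Ser/Thr at both
positions and are therefore independent of thiol chemistry and redox state.

Coordinates are 0-based with half-open intervals throughout; 1-based numbers
appear only in human-facing mutation labels such as ``C24S``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

CATALYTIC_POS1 = frozenset("CST")
CATALYTIC_PLUS1 = frozenset("CST")

CYSTEINE_LESS = "cysteine_less"
CYSTEINE_DEPENDENT = "cysteine_dependent"


class SequenceAlphabetError(ValueError):
    """A residue outside the 20-letter amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with an identifier.

    Residues are upper-case and restricted to the 20 standard amino acids.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(self.residues):
            if ch not in AMINO_ACIDS:
                raise SequenceAlphabetError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _normalise_cys_positions(
    positions: Iterable,
) -> tuple[tuple[str, int], ...]:
    """Normalise cysteine positions to ``(fragment, position)`` pairs.

    Plain integers are interpreted as Int^N positions (the common case).
    """
    out = []
    for p in positions:
        if isinstance(p, int):
            out.append(("intN", p))
        else:
            frag, pos = p
            if frag not in ("intN", "intC"):
                raise ValueError(f"unknown fragment {frag!r} (expected intN/intC)")
            out.append((frag, int(pos)))
    return tuple(out)


@dataclass(frozen=True)
class InteinRecord:
    """A split-intein candidate.

    ``pos1`` (the catalytic position-1 residue) is the first residue of
    ``intN``. ``plus1`` — the first C-extein residue — is stored explicitly
    because Int^C FASTA files usually exclude extein context.
    ``nonconserved_cys`` lists 0-based positions of non-conserved cysteines
    as ``(fragment, position)`` pairs (bare ints mean Int^N).
    """

    name: str
    intN: ProteinSequence
    intC: ProteinSequence
    plus1: str
    nonconserved_cys: tuple[tuple[str, int], ...] = ()
    extein_context_N: str = ""
    extein_context_C: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "nonconserved_cys", _normalise_cys_positions(self.nonconserved_cys)
        )
        if self.pos1 not in CATALYTIC_POS1:
            raise ValueError(
                f"{self.name}: position-1 residue {self.pos1!r} not in C/S/T"
            )
        if self.plus1 not in CATALYTIC_PLUS1:
            raise ValueError(f"{self.name}: +1 residue {self.plus1!r} not in C/S/T")
        if self.intC.residues[-1] != "N":
            warnings.warn(
                f"{self.name}: Int^C does not end in the conserved Asn "
                f"(found {self.intC.residues[-1]!r})",
                stacklevel=2,
            )
        for frag, pos in self.nonconserved_cys:
            seq = self.intN if frag == "intN" else self.intC
            if not 0 <= pos < len(seq):
                raise ValueError(
                    f"{self.name}: cysteine position {pos} out of range for {frag}"
                )

    @property
    def pos1(self) -> str:
        return self.intN.residues[0]


def classify_catalytic_chemistry(rec: InteinRecord) -> str:
    """Classify splicing chemistry by the catalytic 1 / +1 residues.

    Returns ``"cysteine_less"`` iff both are Ser or Thr, else
    ``"cysteine_dependent"``.
    """
    if rec.pos1 in "ST" and rec.plus1 in "ST":
        return CYSTEINE_LESS
    return CYSTEINE_DEPENDENT


def substitute_nonconserved_cys(rec: InteinRecord) -> InteinRecord:
    """Return a new record with every listed non-conserved Cys mutated to Ser.

    The record name gains 1-based mutation labels (e.g. ``"C24S"`` for the
    cysteine at 0-based Int^N position 23). The input record is unchanged;
    applying the function twice is a no-op (the returned record has an empty
    substitution list).
    """
    if not rec.nonconserved_cys:
        return replace(rec, nonconserved_cys=())
    new_seqs = {"intN": list(rec.intN.residues), "intC": list(rec.intC.residues)}
    labels = []
    for frag, pos in rec.nonconserved_cys:
        if new_seqs[frag][pos] != "C":
            raise ValueError(
                f"{rec.name}: listed position {pos} in {frag} holds "
                f"{new_seqs[frag][pos]!r}, not C"
            )
        new_seqs[frag][pos] = "S"
        labels.append(f"C{pos + 1}S")
    suffix = "(" + ",".join(labels) + ")"
    return replace(
        rec,
        name=rec.name + suffix,
        intN=replace(rec.intN, residues="".join(new_seqs["intN"])),
        intC=replace(rec.intC, residues="".join(new_seqs["intC"])),
        nonconserved_cys=(),
    )


# --- FASTA I/O -------------------------------------------------------------


def read_fasta(path) -> list[ProteinSequence]:
    """Read a protein FASTA file into :class:`ProteinSequence` records.

    Sequences are upper-cased. Raises on an empty file, on duplicate record
    ids, and on residues outside the standard alphabet (naming the record
    and 0-based position).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate record ids: {', '.join(dups)}")
    out = []
    for r in records:
        desc = r.description[len(r.id):].strip() if r.description else ""
        out.append(ProteinSequence(id=r.id, residues=str(r.seq), description=desc))
    return out


def write_fasta(seqs: Sequence[ProteinSequence], path) -> None:
    """Write records to FASTA; round-trips ids and residues exactly."""
    bio = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    SeqIO.write(bio, str(path), "fasta")


# --- Motif annotation ------------------------------------------------------

VALID_MOTIF_IDS = frozenset({"A", "B", "F", "G", "NX"})


@dataclass(frozen=True)
class MotifHit:
    """A motif match on one fragment, 0-based half-open."""

    motif_id: str
    target: str  # "intN" or "intC"
    start: int
    end: int
    pattern: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid motif interval")


@dataclass(frozen=True)
class MotifPattern:
    motif_id: str
    target: str
    pattern: str
    anchor: Optional[str] = None  # "start" | "end" | None
    window: Optional[tuple[float, float]] = None  # fractional [lo, hi)


_PATTERN_TOKEN = re.compile(r"\[([A-Z]+)\]|\{([A-Z]+)\}|([A-Zx])")


def _compile_pattern(pattern: str) -> list[frozenset]:
    """Compile a residue-class pattern into per-position allowed sets.

    Syntax: literal residue; ``[XYZ]`` allowed class; ``{XYZ}`` excluded
    class; ``x`` wildcard.
    """
    sets = []
    pos = 0
    for m in _PATTERN_TOKEN.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"bad motif pattern {pattern!r} near index {pos}")
        allowed, excluded, single = m.groups()
        if allowed:
            sets.append(frozenset(allowed))
        elif excluded:
            sets.append(AMINO_ACIDS - frozenset(excluded))
        elif single == "x":
            sets.append(AMINO_ACIDS)
        else:
            sets.append(frozenset(single))
        pos = m.end()
    if pos != len(pattern):
        raise ValueError(f"bad motif pattern {pattern!r} near index {pos}")
    return sets


def default_motif_config() -> list[MotifPattern]:
    """Load the shipped default motif patterns (advisory placeholders)."""
    raw = json.loads(
        resources.files("splicescout.data").joinpath("motifs.json").read_text()
    )
    return [
        MotifPattern(
            motif_id=m["motif_id"],
            target=m["target"],
            pattern=m["pattern"],
            anchor=m.get("anchor"),
            window=tuple(m["window"]) if m.get("window") else None,
        )
        for m in raw["motifs"]
    ]


def scan_motifs(
    rec: InteinRecord, motif_config: Optional[Sequence[MotifPattern]] = None
) -> list[MotifHit]:
    """Annotate conserved sequence blocks (A/B/F/G and the NX motif).

    The NX motif — a conserved histidine-containing motif found only in
    cysteine-independent inteins — and the classic blocks are matched with
    config-supplied degenerate patterns. Matching is deterministic: all
    matches of a pattern score equally, so non-overlapping hits are taken
    left to right (leftmost tie-break). Annotations are advisory and never
    filter records.
    """
    if motif_config is None:
        motif_config = default_motif_config()
    hits: list[MotifHit] = []
    for mp in motif_config:
        if mp.motif_id not in VALID_MOTIF_IDS:
            raise ValueError(f"unknown motif id {mp.motif_id!r}")
        seq = (rec.intN if mp.target == "intN" else rec.intC).residues
        sets = _compile_pattern(mp.pattern)
        k = len(sets)
        if k > len(seq):
            continue
        if mp.anchor == "start":
            starts: Iterable[int] = [0]
        elif mp.anchor == "end":
            starts = [len(seq) - k]
        else:
            lo, hi = 0, len(seq) - k
            if mp.window is not None:
                lo = int(mp.window[0] * len(seq))
                hi = min(hi, int(mp.window[1] * len(seq)) - k)
            starts = range(lo, hi + 1)
        taken_until = -1
        for s in starts:
            if s <= taken_until:
                continue
            window = seq[s : s + k]
            if all(window[j] in sets[j] for j in range(k)):
                hits.append(
                    MotifHit(
                        motif_id=mp.motif_id,
                        target=mp.target,
                        start=s,
                        end=s + k,
                        pattern=mp.pattern,
                    )
                )
                taken_until = s + k - 1
    return hits


# --- JSON I/O --------------------------------------------------------------


def record_to_dict(rec: InteinRecord, motif_hits: Optional[list[MotifHit]] = None) -> dict:
    d = {
        "name": rec.name,
        "intN": {"id": rec.intN.id, "residues": rec.intN.residues},
        "intC": {"id": rec.intC.id, "residues": rec.intC.residues},
        "pos1": rec.pos1,
        "plus1": rec.plus1,
        "nonconserved_cys": [list(p) for p in rec.nonconserved_cys],
        "extein_context_N": rec.extein_context_N,
        "extein_context_C": rec.extein_context_C,
        "catalytic_chemistry": classify_catalytic_chemistry(rec),
    }
    if motif_hits is not None:
        d["motif_hits"] = [
            {
                "motif_id": h.motif_id,
                "target": h.target,
                "start": h.start,
                "end": h.end,
                "pattern": h.pattern,
            }
            for h in motif_hits
        ]
    return d


def record_from_dict(d: dict) -> InteinRecord:
    return InteinRecord(
        name=d["name"],
        intN=ProteinSequence(id=d["intN"]["id"], residues=d["intN"]["residues"]),
        intC=ProteinSequence(id=d["intC"]["id"], residues=d["intC"]["residues"]),
        plus1=d["plus1"],
        nonconserved_cys=tuple(tuple(p) for p in d.get("nonconserved_cys", [])),
        extein_context_N=d.get("extein_context_N", ""),
        extein_context_C=d.get("extein_context_C", ""),
    )


def save_records(records_with_hits: Sequence[tuple], path) -> None:
    """Write ``(InteinRecord, motif_hits)`` pairs to a JSON document."""
    docs = [record_to_dict(rec, hits) for rec, hits in records_with_hits]
    Path(path).write_text(json.dumps(docs, indent=2) + "\n")


def load_records(path) -> list[InteinRecord]:
    docs = json.loads(Path(path).read_text())
    return [record_from_dict(d) for d in docs]
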