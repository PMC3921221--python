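"""Scanning DNA for short recombination-hotspot motifs on both strands.

The built-in catalogue covers the hotspot-associated motifs reported in
intragenic-recombination work: the E. coli chi octamer GCTGGTGG and its
single-mismatch "chi-like" variants (e.g. GCTGGTGC, GCTGGTGA, which can
partially overlap into a 14-mer GCTGGTGCTGGTGA), the S. pombe CRE/M26
nonamer ATGACGTCA and its "CRE-like" variants (e.g. ATGAAGTCA), the human
hotspot heptamer CCTCCCT — whose T-to-C change at position 3 is the known
"suppressor" variant — and the S. pombe-associated CCAAT pentamer.

"Variant"/"-like" is formalised as Hamming distance exactly 1 from the
consensus (indels are not considered), and exact hits are reported under the
exact class only, so the exact and variant classes never double count.
Coordinates in all outputs are 1-based inclusive on the forward sequence;
minus-strand hits carry the forward-coordinate start of their window and the
matched text as read 5'-to-3' on the minus strand.  ``N`` matches nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


class SequenceError(ValueError):
    """Invalid DNA input (bad characters, empty records)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass(frozen=True)
class PositionRule:
    """Annotate a hit whose matched text carries ``base`` at 1-based ``position``."""

    position: int
    base: str
    label: str


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    max_mismatches: int = 0
    exclude_exact: bool = False  # variant classes report Hamming >= 1 only
    family: str = ""
    rules: tuple[PositionRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError(f"consensus must be non-empty over ACGT: {self.consensus!r}")
        if not 0 <= self.max_mismatches < len(self.consensus):
            raise ValueError("max_mismatches must be < consensus length")
        if not self.family:
            object.__setattr__(self, "family", self.name)

    def annotation_for(self, matched_text: str) -> Union[str, None]:
        labels = [
            r.label for r in self.rules if matched_text[r.position - 1] == r.base
        ]
        return ";".join(labels) if labels else None


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start`` is 1-based inclusive on the forward strand."""

    sequence_id: str
    motif_name: str
    start: int
    strand: str  # "+" | "-"
    matched_text: str
    n_mismatches: int
    family: str = ""
    annotation: Union[str, None] = None

    @property
    def end(self) -> int:
        """1-based inclusive end of the window on the forward sequence."""
        return self.start + len(self.matched_text) - 1


@dataclass(frozen=True)
class OverlapEvent:
    """Two same-family, same-strand hits whose windows intersect."""

    sequence_id: str
    hits: tuple[MotifHit, MotifHit]
    span: tuple[int, int]  # 1-based inclusive interval covered by both


def builtin_motifs() -> list[MotifDefinition]:
    """The hotspot-motif catalogue: chi, CRE/M26, CCTCCCT, CCAAT and variants."""
    return [
        MotifDefinition("chi", "GCTGGTGG", 0, family="chi"),
        MotifDefinition("chi-like", "GCTGGTGG", 1, exclude_exact=True, family="chi"),
        MotifDefinition("CRE", "ATGACGTCA", 0, family="CRE"),
        MotifDefinition("CRE-like", "ATGACGTCA", 1, exclude_exact=True, family="CRE"),
        MotifDefinition("CCTCCCT", "CCTCCCT", 0, family="CCTCCCT"),
        MotifDefinition(
            "CCTCCCT-variant",
            "CCTCCCT",
            1,
            exclude_exact=True,
            family="CCTCCCT",
            rules=(PositionRule(position=3, base="C", label="suppressor"),),
        ),
        MotifDefinition("CCAAT", "CCAAT", 0, family="CCAAT"),
    ]


def _validate_sequence(sequence_id: str, sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(
            f"sequence {sequence_id!r} contains invalid characters {sorted(bad)!r}"
        )
    return seq


def scan_sequence(
    sequence_id: str,
    sequence: str,
    motifs: Union[Iterable[MotifDefinition], None] = None,
    strands: str = "both",
) -> list[MotifHit]:
    """Report every motif window within its mismatch budget, on the requested strands.

    Overlapping and nested hits are all reported.  Hits are ordered by
    forward start, then motif name, then strand.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    seq = _validate_sequence(sequence_id, sequence)
    if motifs is None:
        motifs = builtin_motifs()
    hits: list[MotifHit] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for motif in motifs:
        k = len(motif.consensus)
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:  # N matches nothing; masked windows yield no hit
                continue
            for strand in strand_list:
                text = window if strand == "+" else reverse_complement(window)
                d = hamming(text, motif.consensus)
                if d > motif.max_mismatches:
                    continue
                if motif.exclude_exact and d == 0:
                    continue
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        motif_name=motif.name,
                        start=i + 1,
                        strand=strand,
                        matched_text=text,
                        n_mismatches=d,
                        family=motif.family,
                        annotation=motif.annotation_for(text),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def find_overlaps(hits: Iterable[MotifHit]) -> list[OverlapEvent]:
    """All unordered pairs of same-family, same-strand hits with intersecting windows."""
    hits = list(hits)
    if len({h.sequence_id for h in hits}) > 1:
        raise ValueError("find_overlaps expects hits from a single sequence")
    events: list[OverlapEvent] = []
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            if a.family != b.family or a.strand != b.strand:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo <= hi:
                first, second = sorted((a, b), key=lambda h: (h.start, h.motif_name))
                events.append(
                    OverlapEvent(
                        sequence_id=a.sequence_id, hits=(first, second), span=(lo, hi)
                    )
                )
    events.sort(key=lambda e: e.span)
    return events


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, line-wrapped) FASTA; sequences upper-cased."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    for rec_id, seq in records:
        if not seq:
            raise SequenceError(f"{path}: record {rec_id!r} has an empty sequence")
    return records


BED_HEADER = [
    "sequence_id",
    "start",
    "end",
    "motif_name",
    "n_mismatches",
    "strand",
    "matched_text",
    "annotation",
]


def hits_to_bed(hits: Iterable[MotifHit]) -> str:
    """BED-like TSV: 0-based half-open start/end, plus match details."""
    out = StringIO()
    out.write("\t".join(BED_HEADER) + "\n")
    for h in hits:
        out.write(
            "\t".join(
                [
                    h.sequence_id,
                    str(h.start - 1),
                    str(h.end),
                    h.motif_name,
                    str(h.n_mismatches),
                    h.strand,
                    h.matched_text,
                    h.annotation or ".",
                ]
            )
            + "\n"
        )
    return out.getvalue()


def summarize_hits(hits: Iterable[MotifHit], overlaps: Iterable[OverlapEvent]) -> str:
    """Human-readable per-family summary of hits and overlap events."""
    hits = list(hits)
    overlaps = list(overlaps)
    out = StringIO()
    out.write("Motif scan summary\n")
    families: dict[str, list[MotifHit]] = {}
    for h in hits:
        families.setdefault(h.family, []).append(h)
    for family in sorted(families):
        fam_hits = families[family]
        out.write(f"\n{family}: {len(fam_hits)} hit(s)\n")
        for h in fam_hits:
            ann = f" [{h.annotation}]" if h.annotation else ""
            out.write(
                f"  {h.sequence_id}:{h.start}-{h.end} ({h.strand}) "
                f"{h.motif_name} {h.matched_text} mm={h.n_mismatches}{ann}\n"
            )
    out.write(f"\nOverlap events: {len(overlaps)}\n")
    for ev in overlaps:
        a, b = ev.hits
        out.write(
            f"  {ev.sequence_id}: {a.motif_name}@{a.start} x {b.motif_name}@{b.start} "
            f"span {ev.span[0]}-{ev.span[1]} ({a.strand})\n"
        )
    return out.getvalue()
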