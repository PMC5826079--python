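"""Marker presence/absence calling from tabular homology hits.

A marker is called present in a bin when at least one hit is near full length
(alignment longer than a fraction of the shortest reference sequence, 0.9 by
default, strict inequality) and at least as significant as the e-value cutoff
(1e-20 by default).  Calls supported only by contaminant-flagged contigs are
screened out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from magtrace.errors import HitParseError, InputError

PRESENT = "+"
ABSENT = "-"
SCREENED = "screened"

DEFAULT_MIN_LENGTH_FRACTION = 0.9
DEFAULT_MAX_EVALUE = 1e-20

# standard BLAST outfmt-6 columns
_OUTFMT6 = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class HomologyHit:
    query_marker: str
    bin_id: str
    contig_id: str
    alignment_length: int
    e_value: float
    bit_score: float
    subject_length: int | None = None

    def __post_init__(self):
        if self.e_value < 0:
            raise InputError(f"negative e-value: {self.e_value}")
        if self.alignment_length < 1:
            raise InputError(
                f"alignment length must be >= 1, got {self.alignment_length}"
            )


@dataclass(frozen=True)
class ReferenceSet:
    """Reference protein lengths (from isolate genomes) for one marker."""

    marker: str
    reference_lengths: tuple[int, ...]

    def __post_init__(self):
        if not self.reference_lengths:
            raise InputError(f"reference set for {self.marker} is empty")
        if any(l < 1 for l in self.reference_lengths):
            raise InputError(f"reference lengths for {self.marker} must be >= 1")

    @property
    def min_length(self) -> int:
        return min(self.reference_lengths)

    @classmethod
    def from_fasta(cls, marker: str, path) -> "ReferenceSet":
        lengths = tuple(len(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
        return cls(marker=marker, reference_lengths=lengths)


@dataclass(frozen=True)
class MarkerCall:
    bin_id: str
    marker: str
    status: str
    supporting_contigs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.status not in (PRESENT, ABSENT, SCREENED):
            raise InputError(f"bad status {self.status!r}")
        if self.status == PRESENT and not self.supporting_contigs:
            raise InputError("present call needs >= 1 supporting contig")
        object.__setattr__(
            self, "supporting_contigs", tuple(self.supporting_contigs)
        )


def read_hits_outfmt6(path, bin_id: str) -> list[HomologyHit]:
    """Parse BLAST tabular (outfmt 6) hits, optional 13th column = slen.

    qseqid is taken as the marker name and sseqid as the contig id.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise HitParseError(
                    f"expected >= 12 tab-separated columns, got {len(parts)}",
                    line=lineno,
                )
            try:
                hits.append(
                    HomologyHit(
                        query_marker=parts[0],
                        bin_id=bin_id,
                        contig_id=parts[1],
                        alignment_length=int(parts[3]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                        subject_length=int(parts[12]) if len(parts) > 12 else None,
                    )
                )
            except (ValueError, InputError) as exc:
                raise HitParseError(str(exc), line=lineno) from exc
    return hits


def read_reference_lengths_tsv(path) -> dict[str, ReferenceSet]:
    """Two-column TSV (marker, length), one row per reference sequence."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"marker", "length"} <= set(df.columns):
        raise InputError("reference length table needs columns marker, length")
    out = {}
    for marker, sub in df.groupby("marker", sort=True):
        out[str(marker)] = ReferenceSet(
            marker=str(marker), reference_lengths=tuple(int(v) for v in sub["length"])
        )
    return out


def _hit_length(hit: HomologyHit, length_basis: str) -> int:
    if length_basis == "alignment":
        return hit.alignment_length
    if length_basis == "subject":
        # full ORF length of the hit, when the extended column is present
        return hit.subject_length if hit.subject_length else hit.alignment_length
    raise InputError(f"unknown length_basis {length_basis!r}")


def call_marker(
    hits: Sequence[HomologyHit],
    refs: ReferenceSet,
    *,
    bin_id: str | None = None,
    min_length_fraction: float = DEFAULT_MIN_LENGTH_FRACTION,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    length_basis: str = "alignment",
) -> MarkerCall:
    """Call a marker present iff some hit passes both acceptance criteria.

    A hit qualifies when its length is strictly greater than
    ``min_length_fraction`` times the shortest reference length and its
    e-value is at most ``max_evalue``.  Support is the deduplicated, sorted
    set of qualifying contigs (markers may legitimately span several contigs
    in fragmented bins).
    """
    if bin_id is None:
        if not hits:
            raise InputError("bin_id required when the hit list is empty")
        bin_id = hits[0].bin_id
    cutoff = min_length_fraction * refs.min_length
    contigs = sorted(
        {
            h.contig_id
            for h in hits
            if h.query_marker == refs.marker
            and _hit_length(h, length_basis) > cutoff
            and h.e_value <= max_evalue
        }
    )
    if contigs:
        return MarkerCall(bin_id, refs.marker, PRESENT, tuple(contigs))
    return MarkerCall(bin_id, refs.marker, ABSENT)


def screen_contaminant_contigs(
    calls: Iterable[MarkerCall], outlier_contigs: set[str]
) -> list[MarkerCall]:
    """Drop support on contaminant-flagged contigs.

    A present call loses its flagged contigs; if none remain the call becomes
    ``screened``.  Idempotent; absent calls pass through unchanged.
    """
    outlier_contigs = set(outlier_contigs)
    out = []
    for call in calls:
        if call.status != PRESENT:
            out.append(call)
            continue
        clean = tuple(c for c in call.supporting_contigs if c not in outlier_contigs)
        if clean:
            out.append(replace(call, supporting_contigs=clean))
        else:
            out.append(MarkerCall(call.bin_id, call.marker, SCREENED))
    return out


def read_outlier_contigs(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def build_marker_matrix(
    calls: Iterable[MarkerCall],
    bins: Sequence[str],
    markers: Sequence[str],
) -> pd.DataFrame:
    """Dense presence/absence matrix, rows=bins, cols=markers, in given order.

    Cells hold '+', '-' or 'screened'; unmentioned cells default to '-'.
    """
    df = pd.DataFrame(ABSENT, index=list(bins), columns=list(markers))
    seen: dict[tuple[str, str], str] = {}
    for call in calls:
        if call.bin_id not in df.index:
            raise InputError(f"call references unknown bin {call.bin_id!r}")
        if call.marker not in df.columns:
            raise InputError(f"call references unknown marker {call.marker!r}")
        key = (call.bin_id, call.marker)
        if key in seen and seen[key] != call.status:
            raise InputError(
                f"conflicting duplicate calls for bin {call.bin_id!r}, "
                f"marker {call.marker!r}: {seen[key]!r} vs {call.status!r}"
            )
        seen[key] = call.status
        df.loc[call.bin_id, call.marker] = call.status
    return df
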