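"""Pairwise alternative-splicing event classification.

Given two isoforms of one gene, assign the event type distinguishing them:
skipped exon (SE), retained intron (RI), alternative 3'/5' splice site
(A3/A5), alternative first/last exon (AF/AL) or mutually exclusive exons
(MX).  Donor/acceptor and first/last are interpreted relative to the
direction of transcription, so the same coordinate difference yields swapped
A3/A5 (and AF/AL) labels on opposite strands.  Pairs whose chains differ in
a way none of the seven patterns describes are reported as ``complex`` so
the classifier is total; equal chains are ``identical``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import TranscriptModel, ValidationError

EVENT_TYPES = ("SE", "RI", "A3", "A5", "AF", "AL", "MX", "complex", "identical")


@dataclass(frozen=True)
class SpliceEvent:
    """The classified relation between two isoforms of one gene.

    ``event_coords`` holds the distinguishing genomic interval(s), 0-based
    half-open: the skipped exon for SE, the retained intron for RI, the
    region between the two alternative splice sites for A3/A5, the two
    alternative exons for MX and AF/AL.  Empty iff the chains are identical.
    """

    gene_id: str
    isoform_a: str
    isoform_b: str
    event_type: str
    event_coords: tuple[tuple[int, int], ...]
    chrom: str = ""
    strand: str = "+"


def _one_interval(x: int, y: int) -> tuple[tuple[int, int], ...]:
    return ((min(x, y), max(x, y)),)


def _same_length_event(
    A: list[tuple[int, int]], B: list[tuple[int, int]], strand: str
) -> tuple[str, tuple[tuple[int, int], ...]]:
    diffs = [i for i, (x, y) in enumerate(zip(A, B)) if x != y]
    if len(diffs) != 1:
        return "complex", ()
    i = diffs[0]
    x, y = A[i], B[i]
    n = len(A)
    if n >= 2 and (i == 0 or i == n - 1):
        # terminal exon differs, remaining chain shared
        is_first = (i == 0) == (strand == "+")
        coords = tuple(sorted((x, y)))
        return ("AF" if is_first else "AL"), coords
    if n == 1:
        return "complex", ()
    # internal exon differs
    if x[1] <= y[0] or y[1] <= x[0]:
        return "MX", tuple(sorted((x, y)))
    if x[0] == y[0] and x[1] != y[1]:
        # genomic end (right edge) differs: donor on '+', acceptor on '-'
        return ("A5" if strand == "+" else "A3"), _one_interval(x[1], y[1])
    if x[1] == y[1] and x[0] != y[0]:
        # genomic start (left edge) differs: acceptor on '+', donor on '-'
        return ("A3" if strand == "+" else "A5"), _one_interval(x[0], y[0])
    return "complex", ()


def _off_by_one_event(
    L: list[tuple[int, int]], S: list[tuple[int, int]], strand: str
) -> tuple[str, tuple[tuple[int, int], ...]]:
    # one exon of L absent from S, all remaining exons identical
    for i in range(len(L)):
        if L[:i] + L[i + 1 :] == S:
            if 0 < i < len(L) - 1:
                return "SE", (L[i],)
            # terminal-exon skip reads as alternative first/last exon
            if len(S) == 0:
                return "complex", ()
            is_first = (i == 0) == (strand == "+")
            return ("AF" if is_first else "AL"), (L[i],)
    # two adjacent exons of L fused (intron retained) in S
    for i in range(len(L) - 1):
        merged = L[:i] + [(L[i][0], L[i + 1][1])] + L[i + 2 :]
        if merged == S:
            return "RI", ((L[i][1], L[i + 1][0]),)
    return "complex", ()


def classify_event(a: TranscriptModel, b: TranscriptModel) -> SpliceEvent:
    """Classify the alternative-splicing event relating isoforms ``a``, ``b``.

    The result is symmetric in its arguments: swapping ``a`` and ``b``
    returns the same event type and coordinates.
    """
    if a.gene_id != b.gene_id:
        raise ValidationError(f"isoforms of different genes: {a.gene_id} vs {b.gene_id}")
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValidationError(
            f"{a.transcript_id}/{b.transcript_id}: chromosomes or strands differ"
        )
    A, B = list(a.exons), list(b.exons)
    if A == B:
        etype, coords = "identical", ()
    elif len(A) == len(B):
        etype, coords = _same_length_event(A, B, a.strand)
    elif abs(len(A) - len(B)) == 1:
        L, S = (A, B) if len(A) > len(B) else (B, A)
        etype, coords = _off_by_one_event(L, S, a.strand)
    else:
        etype, coords = "complex", ()
    return SpliceEvent(
        gene_id=a.gene_id,
        isoform_a=a.transcript_id,
        isoform_b=b.transcript_id,
        event_type=etype,
        event_coords=coords,
        chrom=a.chrom,
        strand=a.strand,
    )


def event_table(pairs: list[tuple[TranscriptModel, TranscriptModel]]):
    """Classify isoform pairs into a tidy table (1-based inclusive coords)."""
    import pandas as pd

    rows = []
    for a, b in pairs:
        ev = classify_event(a, b)
        coord_s = ";".join(f"{s + 1}-{e}" for s, e in ev.event_coords)
        rows.append(
            {
                "gene_id": ev.gene_id,
                "isoform_a": ev.isoform_a,
                "isoform_b": ev.isoform_b,
                "event_type": ev.event_type,
                "coords": coord_s,
                "chrom": ev.chrom,
                "strand": ev.strand,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "isoform_a", "isoform_b", "event_type", "coords", "chrom", "strand"],
    )
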