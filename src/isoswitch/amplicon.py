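"""In-silico RT-PCR: predicted amplicon sizes on transcript sequences.

A primer pair discriminates two isoforms when the region between its
binding sites contains the alternatively spliced sequence: the predicted
product lengths then differ by exactly the cassette length, which is how a
single gel lane distinguishes exon-included from exon-skipped transcripts.

Product length spans the first base of the forward site through the last
base of the reverse-complement site, i.e. it includes both primers — the
convention in which gel band sizes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .core_io import PrimerPair, logger


@dataclass
class AmpliconPrediction:
    """Predicted PCR product for one transcript.

    ``forward_pos`` / ``reverse_pos`` are 0-based offsets of the forward
    site and of the reverse primer's reverse-complement site on the sense
    strand; ``product_length`` is None when either site is absent.
    """

    transcript_id: str
    product_length: int | None
    forward_pos: int | None
    reverse_pos: int | None
    mismatches: int = 0


def _find_sites(seq: str, pattern: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where pattern matches within tolerance."""
    if max_mismatches == 0:
        sites, start = [], 0
        while (i := seq.find(pattern, start)) != -1:
            sites.append((i, 0))
            start = i + 1
        return sites
    k = len(pattern)
    sites = []
    for i in range(len(seq) - k + 1):
        mm = sum(a != b for a, b in zip(seq[i : i + k], pattern))
        if mm <= max_mismatches:
            sites.append((i, mm))
    return sites


def predict_amplicon(
    transcript_seq: str,
    primers: PrimerPair,
    max_mismatches: int = 0,
    transcript_id: str = "",
) -> AmpliconPrediction:
    """Predict the PCR product of a primer pair on a sense-strand cDNA.

    The forward primer is matched directly; the reverse primer as its
    reverse complement downstream of the forward site.  With multiple
    forward sites the leftmost is used (warned); the nearest downstream
    reverse site is chosen.  Matching is case-insensitive.
    """
    seq = transcript_seq.upper()
    fwd = primers.forward
    rc_rev = str(Seq(primers.reverse).reverse_complement())
    fwd_sites = _find_sites(seq, fwd, max_mismatches)
    if not fwd_sites:
        return AmpliconPrediction(transcript_id, None, None, None)
    if len(fwd_sites) > 1:
        logger.warning(
            "%s: multiple forward primer sites at %s; using leftmost",
            transcript_id or "<sequence>",
            [i for i, _ in fwd_sites],
        )
    fpos, fmm = fwd_sites[0]
    rev_sites = [
        (i, mm) for i, mm in _find_sites(seq, rc_rev, max_mismatches) if i >= fpos + len(fwd)
    ]
    if not rev_sites:
        return AmpliconPrediction(transcript_id, None, fpos, None, mismatches=fmm)
    rpos, rmm = rev_sites[0]
    product = rpos + len(rc_rev) - fpos
    return AmpliconPrediction(transcript_id, product, fpos, rpos, mismatches=fmm + rmm)


def predict_for_fasta(
    sequences: dict[str, str], primers: PrimerPair, max_mismatches: int = 0
) -> pd.DataFrame:
    """Predict amplicons for every sequence in a FASTA mapping."""
    rows = []
    for tid, seq in sequences.items():
        pred = predict_amplicon(seq, primers, max_mismatches, transcript_id=tid)
        rows.append(
            {
                "transcript_id": tid,
                "product_length": pred.product_length,
                "forward_pos": pred.forward_pos,
                "reverse_pos": pred.reverse_pos,
                "mismatches": pred.mismatches,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "product_length", "forward_pos", "reverse_pos", "mismatches"],
    )
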