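"""Abundance normalization and percent-spliced-in (PSI) quantification.

Two complementary inclusion measures are provided:

* ``isoform_fractions`` — the TPM-ratio form: each transcript's share of its
  gene's total TPM, per sample.
* ``compute_psi`` — the junction-read form: length-normalized inclusion
  junction support over total junction support for one cassette event.

Undefined values (gene not expressed; no junction reads) propagate as
missing, never as zero — a zero would fabricate anti-correlation for
unexpressed genes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError, logger


@dataclass
class PsiRecord:
    """Percent-spliced-in of one cassette event in one sample.

    ``psi`` is ``None`` when there is no junction evidence at all (both
    normalized counts zero); otherwise it lies in [0, 1].
    """

    event_id: str
    sample_id: str
    inclusion_count: int
    exclusion_count: int
    inclusion_norm_len: int = 2
    exclusion_norm_len: int = 1
    psi: float | None = None


def tpm_normalize(
    counts: ExpressionMatrix, effective_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert a count matrix to TPM.

    Per sample: ``TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6``.  Columns
    sum to 1e6; a sample with zero total counts stays all-zero and is
    reported with a warning.
    """
    if counts.unit != "count":
        raise ValidationError(f"expected a count matrix, got unit {counts.unit!r}")
    lengths = np.empty(len(counts.values.index))
    for i, fid in enumerate(counts.values.index):
        if fid not in effective_lengths:
            raise ValidationError(f"no effective length for feature {fid!r}")
        length = effective_lengths[fid]
        if length < 1:
            raise ValidationError(f"effective length of {fid!r} must be >= 1")
        lengths[i] = length
    rate = counts.values.to_numpy(dtype=float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        for col in counts.values.columns[zero]:
            logger.warning("sample %s has zero total counts; TPM left all-zero", col)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(zero[None, :], 0.0, rate / np.where(zero, 1.0, colsum) * 1e6)
    values = pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(
        values, unit="TPM", feature_level=counts.feature_level, gene_of=counts.gene_of
    )


def isoform_fractions(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene per-sample relative isoform frequencies from transcript TPM.

    fraction = transcript TPM / gene TPM sum.  Where a gene's TPM sum is
    zero in a sample its fractions are missing (NaN) for that sample.
    """
    if tpm.feature_level != "transcript":
        raise ValidationError("isoform fractions need a transcript-level matrix")
    gene_sums = tpm.values.groupby(tpm.gene_of).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = tpm.values / gene_sums
    frac = frac.where(gene_sums > 0)
    return ExpressionMatrix(frac, unit="fraction", feature_level="transcript", gene_of=tpm.gene_of)


def compute_psi(
    inclusion_count: int,
    exclusion_count: int,
    inclusion_norm_len: int = 2,
    exclusion_norm_len: int = 1,
    event_id: str = "",
    sample_id: str = "",
) -> PsiRecord:
    """PSI from junction counts with length normalization.

    psi = (I/L_I) / (I/L_I + E/L_E).  The defaults L_I=2, L_E=1 reflect that
    a cassette exon is supported by two flanking inclusion junctions but a
    single skipping junction.  With equal lengths this reduces to I/(I+E).
    Zero evidence on both sides leaves psi undefined (None), not zero.
    """
    if inclusion_count < 0 or exclusion_count < 0:
        raise ValidationError("junction counts must be non-negative")
    if inclusion_norm_len < 1 or exclusion_norm_len < 1:
        raise ValidationError("normalization lengths must be >= 1")
    rec = PsiRecord(
        event_id=event_id,
        sample_id=sample_id,
        inclusion_count=inclusion_count,
        exclusion_count=exclusion_count,
        inclusion_norm_len=inclusion_norm_len,
        exclusion_norm_len=exclusion_norm_len,
    )
    inc = inclusion_count / inclusion_norm_len
    exc = exclusion_count / exclusion_norm_len
    if inc + exc > 0:
        rec.psi = inc / (inc + exc)
    return rec


def psi_table(
    junctions: pd.DataFrame,
    inclusion_norm_len: int = 2,
    exclusion_norm_len: int = 1,
) -> pd.DataFrame:
    """Apply :func:`compute_psi` to a junction count table.

    Expects columns event_id, sample_id, inclusion, exclusion; returns the
    same rows with a psi column (NaN where undefined).
    """
    records = [
        compute_psi(
            int(row.inclusion),
            int(row.exclusion),
            inclusion_norm_len,
            exclusion_norm_len,
            event_id=str(row.event_id),
            sample_id=str(row.sample_id),
        )
        for row in junctions.itertuples(index=False)
    ]
    out = junctions.copy()
    out["psi"] = [r.psi if r.psi is not None else np.nan for r in records]
    return out
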