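"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a small bulk RNA-seq cell-line panel conditioned on
one splicing regulator:

* a regulator gene whose TPM follows a log-normal gradient across samples;
* switch genes with two isoforms differing by exactly one cassette exon,
  whose inclusion-isoform fraction follows a logistic link
  ``f1 = logistic(beta * (z - center))`` in the standardized log regulator
  ``z`` — the minimal bounded monotone association;
* null genes with the same two-isoform structure but a constant fraction
  drawn once per gene from U(0.2, 0.8);
* negative-binomial transcript counts (shared dispersion) whose means are
  gene level x isoform fraction x transcript-length factor, so TPM ratios
  recover the fractions;
* binomial junction counts for each cassette event at the true inclusion
  fraction;
* a separate paired tumor/normal cohort with exponential survival times and
  a hazard multiplier for patients whose tumor/normal ratio clears a fold
  threshold.

One global seed drives counter-based per-gene substreams
(``SeedSequence((seed, kind, index))``), so enlarging the cohort never
reshuffles the genes already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    PrimerPair,
    SampleInfo,
    TranscriptModel,
    ValidationError,
    sample_table,
    write_gtf,
)

# substream kinds for counter-based seeding
_KIND_SAMPLES = 0
_KIND_SWITCH = 1
_KIND_NULL = 2
_KIND_REGULATOR = 3

#: cassette exon length used for every simulated switch pair (bp)
CASSETTE_LEN = 90
_EXON1 = 200
_EXON3 = 300
_GENE_SPACING = 10_000


@dataclass
class CohortConfig:
    """Study-design parameters for :func:`simulate_cohort`.

    Defaults follow the emulated design: an 18-sample panel with 20 switch
    genes among 2000 total, logistic slope 4 centered on the cohort mean.
    Expression scales are log-normal (natural-log mean/sd); ``nb_dispersion``
    is the negative-binomial alpha (variance = m + alpha * m^2).
    """

    n_samples: int = 18
    n_switch_genes: int = 20
    n_null_genes: int = 1980
    regulator_log_mean: float = 3.0
    regulator_log_sd: float = 1.0
    switch_slope: float = 4.0
    switch_center: float = 0.0
    gene_expression_log_mean: float = 5.5
    gene_expression_log_sd: float = 0.8
    nb_dispersion: float = 0.1
    junction_depth_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        if self.n_switch_genes < 0 or self.n_null_genes < 0:
            raise ValidationError("gene counts must be >= 0")
        if self.n_switch_genes + self.n_null_genes == 0:
            raise ValidationError("cohort must contain at least one gene")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")


@dataclass
class GroundTruth:
    """What was planted: switch genes, link parameters, true fractions."""

    switch_gene_ids: set[str]
    gene_params: dict[str, dict]
    fractions: pd.DataFrame  # genes x samples, true inclusion-isoform fraction
    regulator_tpm: pd.Series
    survival_hazard_ratio: float | None = None

    def __post_init__(self) -> None:
        if not self.switch_gene_ids <= set(self.fractions.index):
            raise ValidationError("switch gene ids not a subset of generated genes")
        arr = self.fractions.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValidationError("true fractions must lie in [0, 1]")


def _rng(seed: int, kind: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, kind, index)))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance m + dispersion * m^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + np.where(mean > 0, mean, 1.0))
    draws = rng.negative_binomial(n, p)
    return np.where(mean > 0, draws, 0)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gene_models(gene_id: str, index: int) -> tuple[TranscriptModel, TranscriptModel]:
    o = _GENE_SPACING * (index + 1)
    e1 = (o, o + _EXON1)
    cassette = (o + _EXON1 + 100, o + _EXON1 + 100 + CASSETTE_LEN)
    e3 = (o + _EXON1 + 100 + CASSETTE_LEN + 110, o + _EXON1 + 100 + CASSETTE_LEN + 110 + _EXON3)
    inc = TranscriptModel(gene_id, f"{gene_id}.inc", "chr1", "+", (e1, cassette, e3))
    skp = TranscriptModel(gene_id, f"{gene_id}.skp", "chr1", "+", (e1, e3))
    return inc, skp


def simulate_cohort(
    config: CohortConfig,
) -> tuple[
    ExpressionMatrix, list[TranscriptModel], pd.DataFrame, list[SampleInfo], GroundTruth
]:
    """Generate one cohort; bit-identical under a fixed config."""
    S = config.n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(S)]

    srng = _rng(config.seed, _KIND_SAMPLES, 0)
    log_reg = srng.normal(config.regulator_log_mean, config.regulator_log_sd, size=S)
    reg_tpm = np.exp(log_reg)
    z = (log_reg - log_reg.mean()) / log_reg.std()

    models: list[TranscriptModel] = []
    rows: dict[str, np.ndarray] = {}
    gene_of: dict[str, str] = {}
    junc_rows: list[dict] = []
    gene_params: dict[str, dict] = {}
    true_fracs: dict[str, np.ndarray] = {}

    reg_model = TranscriptModel("REG", "REG.t1", "chr1", "+", ((0, 1000),))
    models.append(reg_model)
    gene_of["REG.t1"] = "REG"
    rrng = _rng(config.seed, _KIND_REGULATOR, 0)
    rows["REG.t1"] = _nb_draw(rrng, reg_tpm, config.nb_dispersion)

    n_total = config.n_switch_genes + config.n_null_genes
    width = max(4, len(str(n_total)))
    switch_ids: set[str] = set()

    def emit_gene(gene_id: str, index: int, f1: np.ndarray, rng: np.random.Generator) -> None:
        inc, skp = _gene_models(gene_id, index)
        models.extend([inc, skp])
        gene_of[inc.transcript_id] = gene_id
        gene_of[skp.transcript_id] = gene_id
        level = rng.lognormal(config.gene_expression_log_mean, config.gene_expression_log_sd)
        mean_inc = level * f1 * (inc.length / 1000.0)
        mean_skp = level * (1.0 - f1) * (skp.length / 1000.0)
        rows[inc.transcript_id] = _nb_draw(rng, mean_inc, config.nb_dispersion)
        rows[skp.transcript_id] = _nb_draw(rng, mean_skp, config.nb_dispersion)
        depth = rng.poisson(config.junction_depth_mean, size=len(f1))
        inclusion = rng.binomial(depth, f1)
        for s_idx, sid in enumerate(sample_ids):
            junc_rows.append(
                {
                    "event_id": f"{gene_id}.SE",
                    "sample_id": sid,
                    "inclusion": int(inclusion[s_idx]),
                    "exclusion": int(depth[s_idx] - inclusion[s_idx]),
                }
            )
        true_fracs[gene_id] = f1

    for j in range(config.n_switch_genes):
        gene_id = f"SW{j + 1:0{width}d}"
        rng = _rng(config.seed, _KIND_SWITCH, j)
        f1 = _logistic(config.switch_slope * (z - config.switch_center))
        gene_params[gene_id] = {
            "kind": "switch",
            "beta": config.switch_slope,
            "center": config.switch_center,
        }
        switch_ids.add(gene_id)
        emit_gene(gene_id, j, f1, rng)

    for j in range(config.n_null_genes):
        gene_id = f"NL{j + 1:0{width}d}"
        rng = _rng(config.seed, _KIND_NULL, j)
        f1_const = rng.uniform(0.2, 0.8)
        f1 = np.full(S, f1_const)
        gene_params[gene_id] = {"kind": "null", "f1": float(f1_const)}
        emit_gene(gene_id, config.n_switch_genes + j, f1, rng)

    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids).astype(float)
    counts = ExpressionMatrix(
        values,
        unit="count",
        feature_level="transcript",
        gene_of=pd.Series(gene_of).reindex(values.index),
    )
    junctions = pd.DataFrame(junc_rows, columns=["event_id", "sample_id", "inclusion", "exclusion"])
    samples = [SampleInfo(sample_id=s) for s in sample_ids]
    truth = GroundTruth(
        switch_gene_ids=switch_ids,
        gene_params=gene_params,
        fractions=pd.DataFrame.from_dict(true_fracs, orient="index", columns=sample_ids),
        regulator_tpm=pd.Series(reg_tpm, index=sample_ids, name="REG"),
    )
    return counts, models, junctions, samples, truth


def effective_lengths(models: list[TranscriptModel]) -> dict[str, int]:
    """Annotated exonic length per transcript (no fragment-length correction)."""
    return {m.transcript_id: m.length for m in models}


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------


def simulate_survival_cohort(
    n_patients: int = 37,
    fold_threshold: float = 2.0,
    hazard_ratio: float = 3.0,
    seed: int = 0,
    baseline_median_months: float = 20.0,
    censor_max_months: float | None = 60.0,
    log2_fold_mean: float = 0.2,
    log2_fold_sd: float = 1.2,
) -> pd.DataFrame:
    """Paired tumor/normal expression of one feature with survival outcomes.

    Each patient's normal-tissue expression is log-normal; the tumor value
    multiplies it by ``2**N(log2_fold_mean, log2_fold_sd)``.  Event times
    are exponential with median ``baseline_median_months``; patients whose
    tumor/normal ratio is at least ``fold_threshold`` have their hazard
    multiplied by ``hazard_ratio``.  Censoring is independent uniform on
    (0, ``censor_max_months``); ``None`` disables censoring.  Returns the
    survival input table (patient_id, time, event, tumor_expr, normal_expr).
    """
    if n_patients < 2:
        raise ValidationError("need at least 2 patients")
    if hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4, 0)))
    normal = rng.lognormal(3.0, 0.5, size=n_patients)
    fold = 2.0 ** rng.normal(log2_fold_mean, log2_fold_sd, size=n_patients)
    tumor = normal * fold
    lam0 = np.log(2.0) / baseline_median_months
    lam = np.where(fold >= fold_threshold, lam0 * hazard_ratio, lam0)
    event_time = rng.exponential(1.0 / lam)
    if censor_max_months is None:
        time, event = event_time, np.ones(n_patients, dtype=int)
    else:
        censor = rng.uniform(0.0, censor_max_months, size=n_patients)
        event = (event_time <= censor).astype(int)
        time = np.minimum(event_time, censor)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n_patients)],
            "time": time,
            "event": event,
            "tumor_expr": tumor,
            "normal_expr": normal,
        }
    )


# ---------------------------------------------------------------------------
# two-condition DE matrix
# ---------------------------------------------------------------------------


def simulate_de_matrix(
    n_genes: int = 2000,
    n_planted: int = 50,
    fold: float = 4.0,
    n_reps: int = 4,
    noise_sd: float = 0.05,
    base_log2_mean: float = 6.0,
    base_log2_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Two-condition expression matrix with planted fold changes.

    The first ``n_planted`` genes are multiplied by ``fold`` in condition B;
    every gene gets log-normal replicate noise of ``noise_sd`` on the log2
    scale.  Returns (matrix, condition labels, planted gene ids).
    """
    if n_planted > n_genes:
        raise ValidationError("cannot plant more genes than exist")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5, 0)))
    base = rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    planted = set(genes[:n_planted])
    cols, data = [], []
    for cond, shift in (("A", 0.0), ("B", np.log2(fold))):
        for r in range(n_reps):
            cols.append(f"{cond}{r + 1}")
            log2_mean = base + np.where(np.isin(genes, list(planted)), shift if cond == "B" else 0.0, 0.0)
            data.append(2.0 ** (log2_mean + rng.normal(0.0, noise_sd, size=n_genes)))
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    condition = pd.Series([c[0] for c in cols], index=cols)
    return matrix, condition, planted


# ---------------------------------------------------------------------------
# synthetic amplicon fixture
# ---------------------------------------------------------------------------


def synthetic_primer_isoform_pair(
    primers: PrimerPair,
    short_product: int = 222,
    cassette_length: int = 72,
    flank: int = 30,
    seed: int = 0,
) -> dict[str, str]:
    """Synthetic exon-skipped / exon-included cDNA pair for a primer pair.

    Builds two sense-strand sequences around the given primers such that
    the skipped form yields a product of ``short_product`` bp and the
    included form inserts a ``cassette_length``-nt exon strictly between
    the primer sites.  Fillers are random and re-drawn until neither primer
    matches anywhere unintended.  Purely synthetic stand-ins for real
    transcript records — only the arithmetic of the construction is meant
    to be faithful.
    """
    from Bio.Seq import Seq

    fwd = primers.forward
    rc_rev = str(Seq(primers.reverse).reverse_complement())
    inner_len = short_product - len(fwd) - len(rc_rev)
    if inner_len < cassette_length or inner_len < 2:
        raise ValidationError("short_product too small for the primers")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6, 0)))

    def random_nt(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    for _ in range(100):
        left, right = random_nt(flank), random_nt(flank)
        inner = random_nt(inner_len)
        cassette = random_nt(cassette_length)
        cut = inner_len // 2
        skipped = left + fwd + inner + rc_rev + right
        included = left + fwd + inner[:cut] + cassette + inner[cut:] + rc_rev + right
        ok = all(
            seq.count(fwd) == 1 and seq.count(rc_rev) == 1 and primers.reverse not in seq
            for seq in (skipped, included)
        )
        if ok:
            return {"exon_skipped": skipped, "exon_included": included}
    raise RuntimeError("could not construct collision-free synthetic sequences")


# ---------------------------------------------------------------------------
# cohort writer (CLI `simulate`)
# ---------------------------------------------------------------------------


def write_cohort(config: CohortConfig, out_dir: str | Path) -> list[Path]:
    """Simulate a cohort and write it in the formats core_io reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, models, junctions, samples, truth = simulate_cohort(config)
    counts.to_tsv(out_dir / "transcript_counts.tsv")
    write_gtf(models, out_dir / "transcripts.gtf")
    junctions.to_csv(out_dir / "junction_counts.tsv", sep="\t", index=False)
    sample_table(samples).to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    truth_json = {
        "switch_gene_ids": sorted(truth.switch_gene_ids),
        "gene_params": truth.gene_params,
        "regulator_tpm": truth.regulator_tpm.round(6).to_dict(),
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
    return sorted(out_dir.iterdir())
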