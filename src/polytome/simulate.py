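"""Synthetic polysome-profiling cohorts with planted translational regulation.

The generator emulates a fraction-resolved RNA-seq experiment: 8 library
types (total RNA + monosome/light/heavy polysome pools x low/high glucose)
x replicates.  Baseline gene expression is log-normal; a planted per-gene
fold-change triple delta = (d_mono, d_light, d_heavy) multiplies the
polysome-fraction means in the high-glucose condition only, so total RNA is
condition-invariant by default — the regime where regulation is purely
translational.  Counts are negative binomial with Var = mu + phi*mu^2;
phi = 0 degenerates to deterministic rounding of the expected mean, giving
bit-identical null libraries.

The default cluster layout plants six translation behaviours with sizes
(73, 90, 79, 37, 21, 102): a mono->polysome shift, light+heavy gain,
mono+light gain, light loss, heavy loss, and a mono->heavy shift.

Transcript sequences are generated alongside with controllable UTR/CDS
lengths and GC, a 5'-terminal oligopyrimidine tract planted on the two
shift-up clusters and uORFs on the two down-regulated clusters, so the
sequence-feature stages have ground truth too.

Randomness: one global seed; three child streams are spawned from it in a
fixed, documented order — (1) transcripts, (2) baseline expression,
(3) counts (libraries drawn fraction-major: total, mono, light, heavy;
low before high; replicates in order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import tpm_from_counts
from .seqfeatures import SENSE_CODONS, TranscriptRecord

__all__ = [
    "ClusterSpec",
    "TranscriptSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "DEFAULT_CLUSTER_SPECS",
    "simulate_cohort",
    "simulate_counts",
    "simulate_transcripts",
]

FRACTIONS = ("total", "mono", "light", "heavy")
CONDITIONS = ("low", "high")
POLYSOME_INDEX = {"mono": 0, "light": 1, "heavy": 2}


@dataclass(frozen=True)
class ClusterSpec:
    """A planted translation behaviour: per-fraction log2 fold-changes."""

    cluster_id: int
    n_genes: int
    delta: tuple[float, float, float]  # (mono, light, heavy)


#: The six default planted behaviours and their cardinalities.
DEFAULT_CLUSTER_SPECS: tuple[ClusterSpec, ...] = (
    ClusterSpec(1, 73, (-1.0, 1.0, 1.0)),   # mono -> light+heavy shift
    ClusterSpec(2, 90, (0.0, 1.0, 1.0)),    # light+heavy gain
    ClusterSpec(3, 79, (1.0, 1.0, 0.0)),    # mono+light gain
    ClusterSpec(4, 37, (0.0, -1.0, 0.0)),   # light loss
    ClusterSpec(5, 21, (0.0, 0.0, -1.0)),   # heavy loss
    ClusterSpec(6, 102, (-1.0, 0.0, 1.0)),  # mono -> heavy shift
)


@dataclass(frozen=True)
class TranscriptSpec:
    """Distributions for transcript region lengths, GC and planted motifs.

    Lengths are log-normal around the given medians (human-like defaults:
    5'UTR ~170 nt, CDS ~430 codons, 3'UTR ~450 nt); a ``fixed_*`` value
    overrides the draw.  Transcripts of genes in ``top_clusters`` start
    with a C + pyrimidine tract of ``top_tract_len``; genes in
    ``uorf_clusters`` carry ``n_uorf`` planted uORFs of ``uorf_codons``
    codons in the 5'UTR.
    """

    utr5_len_median: float = 170.0
    utr5_len_log_sd: float = 0.45
    cds_codons_median: float = 430.0
    cds_codons_log_sd: float = 0.45
    utr3_len_median: float = 450.0
    utr3_len_log_sd: float = 0.6
    gc_utr5: float = 0.60
    gc_utr3: float = 0.45
    gc_sd: float = 0.02
    top_tract_len: int = 8
    top_clusters: tuple[int, ...] = (1, 6)
    n_uorf: int = 2
    uorf_codons: int = 10
    uorf_clusters: tuple[int, ...] = (4, 5)
    fixed_utr5_len: int | None = None
    fixed_cds_codons: int | None = None
    fixed_utr3_len: int | None = None

    def validate(self) -> None:
        for name in ("utr5_len_median", "cds_codons_median", "utr3_len_median"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("gc_utr5", "gc_utr3"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.top_tract_len < 0:
            raise ConfigurationError("top_tract_len must be >= 0")
        if self.n_uorf < 0 or self.uorf_codons < 2:
            raise ConfigurationError("need n_uorf >= 0 and uorf_codons >= 2")

    def required_utr5(self, planted_top: bool, planted_uorfs: bool) -> int:
        need = 2
        if planted_top:
            need += self.top_tract_len
        if planted_uorfs:
            need += self.n_uorf * (3 * self.uorf_codons + 3)
        return need


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic cohort."""

    n_genes: int = 10000
    n_replicates: int = 3
    lib_size: float = 1e7
    dispersion: float = 0.01
    cluster_specs: tuple[ClusterSpec, ...] = DEFAULT_CLUSTER_SPECS
    seed: int = 0
    transcript_spec: TranscriptSpec = field(default_factory=TranscriptSpec)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    #: genes whose *total-RNA* abundance also changes (gene index -> log2 FC);
    #: empty by default: steady-state mRNA levels are condition-invariant.
    total_affected: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.lib_size <= 0:
            raise ConfigurationError("lib_size must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        planted = sum(c.n_genes for c in self.cluster_specs)
        if planted > self.n_genes:
            raise ConfigurationError(
                f"cluster specs plant {planted} genes but n_genes={self.n_genes}"
            )
        ids = [c.cluster_id for c in self.cluster_specs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate cluster_id in cluster_specs")
        self.transcript_spec.validate()

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def cluster_assignment(self) -> pd.Series:
        """Gene -> planted cluster id (pd.NA for null genes); genes are
        assigned in spec order, planted clusters first."""
        labels: list = []
        for spec in self.cluster_specs:
            labels.extend([spec.cluster_id] * spec.n_genes)
        labels.extend([pd.NA] * (self.n_genes - len(labels)))
        return pd.Series(labels, index=self.gene_ids, dtype="Int64", name="cluster")

    def delta_matrix(self) -> pd.DataFrame:
        delta = np.zeros((self.n_genes, 3))
        row = 0
        for spec in self.cluster_specs:
            delta[row : row + spec.n_genes] = spec.delta
            row += spec.n_genes
        return pd.DataFrame(
            delta, index=self.gene_ids, columns=["delta_mono", "delta_light", "delta_heavy"]
        )


@dataclass
class SyntheticCohort:
    """A generated cohort: counts/TPM, truth table and transcripts."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    transcripts: list[TranscriptRecord]
    config: SimulationConfig


def _streams(cfg: SimulationConfig) -> tuple[np.random.Generator, ...]:
    # documented sub-stream order: transcripts, baseline, counts
    return tuple(np.random.default_rng(cfg.seed).spawn(3))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    gc = float(np.clip(gc, 0.02, 0.98))
    probs = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("GCAT")), size=n, p=probs)


def _draw_length(rng, median: float, log_sd: float, minimum: int) -> int:
    if log_sd == 0:
        return max(minimum, int(round(median)))
    return max(minimum, int(round(np.exp(rng.normal(np.log(median), log_sd)))))


_NON_ATG_SENSE = tuple(c for c in SENSE_CODONS if c != "ATG")


def simulate_transcripts(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TranscriptRecord]:
    """Generate one well-formed transcript per gene.

    The CDS starts with ATG, ends with a stop and has no internal in-frame
    stop; planted TOP tracts occupy the first nucleotides of the 5'UTR and
    planted uORFs are fully contained in it.
    """
    if rng is None:
        rng = _streams(cfg)[0]
    spec = cfg.transcript_spec
    clusters = cfg.cluster_assignment()
    records: list[TranscriptRecord] = []
    for gene_id in cfg.gene_ids:
        cl = clusters[gene_id]
        has_top = (cl is not pd.NA) and int(cl) in spec.top_clusters
        has_uorf = (cl is not pd.NA) and int(cl) in spec.uorf_clusters
        need5 = spec.required_utr5(has_top, has_uorf)
        if spec.fixed_utr5_len is not None:
            if spec.fixed_utr5_len < need5:
                raise ConfigurationError(
                    f"5'UTR length {spec.fixed_utr5_len} cannot hold the "
                    f"requested motifs (need >= {need5})"
                )
            len5 = spec.fixed_utr5_len
        else:
            len5 = max(
                _draw_length(rng, spec.utr5_len_median, spec.utr5_len_log_sd, 20), need5
            )
        n_codons = (
            spec.fixed_cds_codons
            if spec.fixed_cds_codons is not None
            else _draw_length(rng, spec.cds_codons_median, spec.cds_codons_log_sd, 10)
        )
        len3 = (
            spec.fixed_utr3_len
            if spec.fixed_utr3_len is not None
            else _draw_length(rng, spec.utr3_len_median, spec.utr3_len_log_sd, 10)
        )

        gc5 = rng.normal(spec.gc_utr5, spec.gc_sd)
        gc3 = rng.normal(spec.gc_utr3, spec.gc_sd)
        utr5 = list(_random_bases(rng, len5, gc5))
        if has_top and spec.top_tract_len > 0:
            utr5[0] = "C"
            tract = rng.choice(np.array(list("CT")), size=spec.top_tract_len - 1)
            utr5[1 : spec.top_tract_len] = list(tract)
        if has_uorf:
            pos = spec.top_tract_len + 1 if has_top else 1
            for _ in range(spec.n_uorf):
                body = rng.choice(np.array(_NON_ATG_SENSE), size=spec.uorf_codons - 2)
                orf = "ATG" + "".join(body) + "TAA"
                utr5[pos : pos + len(orf)] = list(orf)
                pos += len(orf)
        cds = "ATG" + "".join(
            rng.choice(np.array(_NON_ATG_SENSE), size=n_codons - 2)
        ) + "TAA"
        utr3 = "".join(_random_bases(rng, len3, gc3))
        records.append(
            TranscriptRecord(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                utr5="".join(utr5),
                cds=cds,
                utr3=utr3,
            )
        )
    return records


def sample_table(cfg: SimulationConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{frac}_{cond}_{rep}",
            "condition": cond,
            "fraction": frac,
            "replicate": rep,
        }
        for frac in FRACTIONS
        for cond in CONDITIONS
        for rep in range(1, cfg.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def _draw_lengths_only(cfg: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Vectorised transcript total lengths (no sequences): same marginal
    distributions as :func:`simulate_transcripts`, different draw order."""
    spec = cfg.transcript_spec
    n = cfg.n_genes

    def draw(median, log_sd, minimum, fixed):
        if fixed is not None:
            return np.full(n, fixed)
        if log_sd == 0:
            return np.full(n, max(minimum, int(round(median))))
        vals = np.rint(np.exp(rng.normal(np.log(median), log_sd, n)))
        return np.maximum(vals, minimum).astype(int)

    total = (
        draw(spec.utr5_len_median, spec.utr5_len_log_sd, 20, spec.fixed_utr5_len)
        + 3 * draw(spec.cds_codons_median, spec.cds_codons_log_sd, 10, spec.fixed_cds_codons)
        + draw(spec.utr3_len_median, spec.utr3_len_log_sd, 10, spec.fixed_utr3_len)
    )
    return pd.Series(total, index=cfg.gene_ids, name="length")


def simulate_counts(
    cfg: SimulationConfig,
    transcripts: Sequence[TranscriptRecord] | None = None,
    with_sequences: bool = True,
) -> SyntheticCohort:
    """Generate the full cohort (counts, TPM, truth, transcripts).

    ``with_sequences=False`` skips sequence generation (transcript lengths
    are still drawn for TPM) — useful for purely count-level studies.
    """
    t_rng, b_rng, c_rng = _streams(cfg)
    lengths = None
    if transcripts is None:
        if with_sequences:
            transcripts = simulate_transcripts(cfg, t_rng)
        else:
            transcripts = []
            lengths = _draw_lengths_only(cfg, t_rng)
    baseline = 2.0 ** b_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    scale = cfg.lib_size / baseline.sum()
    delta = cfg.delta_matrix().to_numpy()
    sheet = sample_table(cfg)
    phi = cfg.dispersion
    columns = {}
    total_lfc = np.zeros(cfg.n_genes)
    if cfg.total_affected:
        idx = {g: i for i, g in enumerate(cfg.gene_ids)}
        for g, lfc in cfg.total_affected.items():
            total_lfc[idx[g]] = lfc
    for _, row in sheet.iterrows():
        if row["condition"] == "high":
            if row["fraction"] == "total":
                lfc = total_lfc
            else:
                lfc = delta[:, POLYSOME_INDEX[row["fraction"]]]
        else:
            lfc = 0.0
        mu = baseline * scale * np.exp2(lfc)
        if phi == 0:
            counts = np.rint(mu).astype(np.int64)
        else:
            r = 1.0 / phi
            counts = c_rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
        columns[row["sample_id"]] = counts
    counts_df = pd.DataFrame(columns, index=cfg.gene_ids)
    if lengths is None:
        lengths = pd.Series(
            {t.gene_id: len(t.sequence) for t in transcripts}, name="length"
        )
    tpm = tpm_from_counts(counts_df, lengths)
    truth = pd.concat([cfg.cluster_assignment(), cfg.delta_matrix()], axis=1)
    truth["baseline"] = baseline
    return SyntheticCohort(
        counts=counts_df,
        tpm=tpm,
        sample_sheet=sheet,
        truth=truth,
        transcripts=list(transcripts),
        config=cfg,
    )


def simulate_cohort(
    cfg: SimulationConfig | None = None, with_sequences: bool = True, **overrides
) -> SyntheticCohort:
    """Convenience entry point: build a config (defaults + overrides) and
    generate the cohort."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    return simulate_counts(cfg, with_sequences=with_sequences)
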