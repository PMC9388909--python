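"""Per-transcript mRNA sequence/structure features and grouped statistics.

For every gene a representative transcript is chosen (most expressed, or best
annotated), and a row of features is computed on its 5'UTR / CDS / 3'UTR:
region lengths, UTR GC content, folding energy per nucleotide, codon
adaptation index (CAI), a 5'-terminal oligopyrimidine (TOP) local score, a
TOP-motif flag, and the number of upstream open reading frames (uORFs).
Feature distributions are then compared between translation-behaviour groups
with the Kruskal-Wallis H-test and Dunn's pairwise post-hoc test.

Folding backends
----------------
``engine="nussinov"`` (default) scores a sequence by base-pair maximisation
(Watson-Crick plus G:U wobble, minimum hairpin loop of 3 unpaired
nucleotides) at -1 per pair, normalised by length: a self-contained
structural-complexity score with the same orientation as a thermodynamic
MFE/nt (more negative = more paired).  ``engine="rnafold"`` shells out to the
ViennaRNA ``RNAfold`` binary and parses the thermodynamic MFE (kcal/mol),
normalised by length.  The engine used is recorded in the feature table.
"""

from __future__ import annotations

import re
import subprocess
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from numba import njit
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = [
    "TranscriptRecord",
    "select_representative_transcript",
    "gc_content",
    "nussinov_max_pairs",
    "fold_mfe_per_bp",
    "cai",
    "load_human_codon_usage",
    "top_local_score",
    "detect_top_motif",
    "detect_uorfs",
    "feature_table",
    "feature_group_stats",
    "top_rna_overlap",
    "TOP_SCORE_VERSION",
]

#: Version tag of the TOP local-score definition, recorded in every output so
#: scores are only ever compared within one definition.
TOP_SCORE_VERSION = "anchored-kadane-v1"

PYRIMIDINES = frozenset("CTU")
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))


@dataclass
class TranscriptRecord:
    """A representative transcript split into its three mRNA regions.

    Sequences are DNA alphabet (A/C/G/T/N), transcript orientation (5'->3').
    ``annotation_level`` follows the GENCODE/Ensembl convention: lower is
    better supported.  ``abundance`` is the mean TPM used for representative
    selection (``None`` when unknown).
    """

    transcript_id: str
    gene_id: str
    utr5: str = ""
    cds: str = ""
    utr3: str = ""
    annotation_level: int = 1
    abundance: float | None = None

    def __post_init__(self) -> None:
        alphabet = set("ACGTN")
        for name in ("utr5", "cds", "utr3"):
            seq = getattr(self, name).upper().replace("U", "T")
            if set(seq) - alphabet:
                raise DataError(
                    f"{self.transcript_id}.{name}: non-ACGTN characters "
                    f"{sorted(set(seq) - alphabet)}"
                )
            setattr(self, name, seq)

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_complete(self) -> bool:
        c = self.cds
        return (
            len(c) >= 6
            and len(c) % 3 == 0
            and c.startswith("ATG")
            and c[-3:] in STOP_CODONS
        )


def select_representative_transcript(
    transcripts: Sequence[TranscriptRecord],
    abundance: Mapping[str, float] | None = None,
) -> TranscriptRecord:
    """Pick one transcript to represent a gene.

    With an abundance table: highest mean TPM, ties broken by longest CDS
    then lexicographically smallest transcript ID.  Without: best (lowest)
    annotation level, then longest CDS, then ID.
    """
    if not transcripts:
        raise DataError("no transcripts to select from")
    if abundance is not None:
        key = lambda t: (-float(abundance.get(t.transcript_id, 0.0)),
                         -len(t.cds), t.transcript_id)
    else:
        key = lambda t: (t.annotation_level, -len(t.cds), t.transcript_id)
    return min(transcripts, key=key)


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N is excluded from the denominator.

    Returns NaN for empty or all-N input.
    """
    seq = seq.upper().replace("U", "T")
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / total


# ---------------------------------------------------------------------------
# Folding


@njit(cache=True)
def _nussinov_dp(pairable: np.ndarray, n: int, min_loop: int) -> int:
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable[i, k]:
                    left = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = left + 1 + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp[0, n - 1]


_PAIR_SET = frozenset({"AT", "TA", "GC", "CG", "GT", "TG"})


def nussinov_max_pairs(seq: str, min_loop: int = 3, wobble: bool = True) -> int:
    """Maximum number of nested base pairs (Nussinov base-pair maximisation).

    Watson-Crick pairs plus, when ``wobble``, G:U; a hairpin loop must
    enclose at least ``min_loop`` unpaired nucleotides.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return 0
    pairs = _PAIR_SET if wobble else frozenset({"AT", "TA", "GC", "CG"})
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    pairable = np.zeros((n, n), dtype=np.bool_)
    for a, b in pairs:
        pairable |= (enc[:, None] == ord(a)) & (enc[None, :] == ord(b))
    return int(_nussinov_dp(pairable, n, min_loop))


def _rnafold_mfe(seq: str) -> float:
    rna = seq.upper().replace("T", "U")
    try:
        out = subprocess.run(
            ["RNAfold", "--noPS"],
            input=rna + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        raise ConfigurationError(
            "RNAfold backend unavailable; rerun with engine='nussinov'"
        ) from exc
    m = re.search(r"\(\s*(-?\d+\.?\d*)\s*\)\s*$", out.strip())
    if m is None:
        raise DataError(f"could not parse RNAfold output: {out!r}")
    return float(m.group(1))


def fold_mfe_per_bp(seq: str, engine: str = "nussinov") -> float:
    """Folding score divided by sequence length (<= 0).

    ``nussinov``: -(max base pairs)/length.  ``rnafold``: thermodynamic MFE
    in kcal/mol per nt from the external ViennaRNA binary.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < 4:
        raise DataError(f"sequence too short to fold (length {len(seq)} < 4)")
    if engine == "nussinov":
        return -nussinov_max_pairs(seq) / len(seq)
    if engine == "rnafold":
        return min(_rnafold_mfe(seq), 0.0) / len(seq)
    raise ConfigurationError(f"unknown folding engine {engine!r}")


# ---------------------------------------------------------------------------
# Codon adaptation index


def load_human_codon_usage() -> dict[str, float]:
    """Packaged human codon usage frequencies (per 1000 codons).

    Standard human codon usage as tabulated from GenBank coding sequences
    (Kazusa codon-usage database, Homo sapiens).  Override by passing any
    codon->frequency mapping to :func:`cai`.
    """
    from importlib.resources import files

    path = files("polytome.resources").joinpath("human_codon_usage.tsv")
    usage: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        codon, freq = line.split("\t")
        usage[codon] = float(freq)
    return usage


def _relative_adaptiveness(usage: Mapping[str, float]) -> dict[str, float]:
    families: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        families.setdefault(aa, []).append(codon)
    w: dict[str, float] = {}
    for aa, codons in families.items():
        freqs = {c: float(usage.get(c, 0.0)) for c in codons}
        fmax = max(freqs.values())
        if fmax <= 0:
            continue
        for c, f in freqs.items():
            # zero observed usage is floored so one rare codon cannot
            # annihilate the geometric mean
            w[c] = max(f, 0.01 * fmax) / fmax
    return w


def cai(cds: str, usage: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness w.

    w_c = f_c / max f over synonymous codons.  ATG and TGG (single-codon
    amino acids) and stop codons are excluded.  Codons after an internal
    in-frame stop are not scored (a warning is issued).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 6:
        raise DataError("CDS too short for CAI")
    w = _relative_adaptiveness(usage)
    logs: list[float] = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            if i < len(cds) - 3:
                warnings.warn(
                    f"internal stop codon at position {i}; "
                    "CAI computed on upstream codons only",
                    stacklevel=2,
                )
            break
        if codon in ("ATG", "TGG") or codon not in w:
            continue
        logs.append(np.log(w[codon]))
    if not logs:
        return 1.0
    return float(np.exp(np.mean(logs)))


# ---------------------------------------------------------------------------
# 5' end motifs


def top_local_score(seq: str, anchor_max: int = 5, window: int = 50) -> int:
    """Local pyrimidine-tract score of a transcript 5' end.

    Each nucleotide scores +1 if pyrimidine (C/T) and -1 otherwise.  The
    score is the maximum contiguous-window sum over windows that start
    within the first ``anchor_max`` positions and end within the first
    ``window`` nucleotides (a start-anchored variant of Kadane's maximum
    subarray), floored at 0.  Definition version: ``TOP_SCORE_VERSION``.
    """
    seq = seq.upper().replace("U", "T")[:window]
    if not seq:
        raise DataError("empty sequence for TOP scoring")
    vals = np.where(np.isin(list(seq), list("CT")), 1, -1)
    csum = np.concatenate([[0], np.cumsum(vals)])
    best = 0
    for s in range(min(anchor_max, len(seq))):
        best = max(best, int(np.max(csum[s + 1 :] - csum[s])))
    return best


def detect_top_motif(utr5: str, min_run: int = 5) -> bool:
    """Classic 5'TOP motif: a C at position 1 followed by pyrimidines.

    True iff the first nucleotide is C and the 5'-terminal pyrimidine run is
    at least ``min_run`` long (C included).
    """
    seq = utr5.upper().replace("U", "T")
    if not seq or seq[0] != "C":
        return False
    run = 0
    for b in seq:
        if b in "CT":
            run += 1
        else:
            break
    return run >= min_run


def detect_uorfs(utr5: str, min_codons: int = 3) -> list[tuple[int, int]]:
    """Upstream ORFs fully contained in the 5'UTR, any frame.

    An uORF is an ATG followed by an in-frame stop codon within the UTR,
    spanning at least ``min_codons`` codons (start and stop included).
    Overlapping uORFs are reported separately.  Coordinates are 0-based
    half-open on the given sequence.
    """
    if min_codons < 2:
        raise ConfigurationError("min_codons must be >= 2 (ATG + stop)")
    seq = utr5.upper().replace("U", "T")
    found: list[tuple[int, int]] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                if (j + 3 - i) // 3 >= min_codons:
                    found.append((i, j + 3))
                break
    return found


# ---------------------------------------------------------------------------
# Feature table and grouped statistics

FEATURE_COLUMNS = [
    "len5", "len_cds", "len3", "gc5", "gc3",
    "mfe5_bp", "mfe3_bp", "cai", "top_local_score", "n_uorf",
]


def feature_table(
    records: Iterable[TranscriptRecord],
    usage: Mapping[str, float] | None = None,
    engine: str = "nussinov",
    ires_genes: Iterable[str] | None = None,
    top_min_run: int = 5,
    uorf_min_codons: int = 3,
) -> pd.DataFrame:
    """One feature row per representative transcript, indexed by gene."""
    if usage is None:
        usage = load_human_codon_usage()
    ires = set(ires_genes) if ires_genes is not None else set()
    rows = []
    for rec in records:
        row = {
            "gene_id": rec.gene_id,
            "transcript_id": rec.transcript_id,
            "len5": len(rec.utr5),
            "len_cds": len(rec.cds),
            "len3": len(rec.utr3),
            "gc5": gc_content(rec.utr5) if rec.utr5 else np.nan,
            "gc3": gc_content(rec.utr3) if rec.utr3 else np.nan,
            "mfe5_bp": fold_mfe_per_bp(rec.utr5, engine) if len(rec.utr5) >= 4 else np.nan,
            "mfe3_bp": fold_mfe_per_bp(rec.utr3, engine) if len(rec.utr3) >= 4 else np.nan,
            "cai": cai(rec.cds, usage) if len(rec.cds) >= 6 else np.nan,
            "top_local_score": top_local_score(rec.utr5 + rec.cds[:3])
            if rec.utr5 or rec.cds else 0,
            "n_uorf": len(detect_uorfs(rec.utr5, uorf_min_codons)),
            "has_top_motif": detect_top_motif(rec.utr5, top_min_run),
            "has_ires": rec.gene_id in ires,
            "engine": engine,
            "top_score_version": TOP_SCORE_VERSION,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("no transcript records supplied")
    return df.set_index("gene_id")


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's post-hoc z statistics on pooled ranks with tie correction."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    groups = np.unique(labels)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a_idx in range(len(groups)):
        for b_idx in range(a_idx + 1, len(groups)):
            a, b = groups[a_idx], groups[b_idx]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"group1": a, "group2": b, "z": z, "p": p})
    return pd.DataFrame(rows)


def feature_group_stats(
    features: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    feature_cols: Sequence[str] | None = None,
    p_adjust: str = "holm",
) -> dict[str, pd.DataFrame]:
    """Kruskal-Wallis H per feature across groups plus Dunn pairwise tests.

    ``groups`` maps gene -> group label; genes absent from it are ignored.
    Pairwise p-values are corrected per feature (Holm by default).  Returns
    ``{"overall": ..., "pairwise": ...}``.
    """
    from statsmodels.stats.multitest import multipletests

    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    common = features.index.intersection(groups.index)
    sub = features.loc[common]
    labels = groups.loc[common].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise DataError("need >= 2 groups with >= 2 members each")
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_COLUMNS if c in sub.columns]
    overall_rows, pairwise_frames = [], []
    for col in feature_cols:
        vals = sub[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        v, lab = vals[ok], labels[ok]
        row: dict = {"feature": col}
        for g in uniq:
            row[f"median_{g}"] = float(np.median(v[lab == g])) if (lab == g).any() else np.nan
        samples = [v[lab == g] for g in uniq if (lab == g).sum() >= 2]
        if len(samples) < 2 or np.all(v == v[0]):
            row.update({"H": np.nan, "p": np.nan})
            overall_rows.append(row)
            continue
        H, p = stats.kruskal(*samples)
        row.update({"H": float(H), "p": float(p)})
        overall_rows.append(row)
        pw = _dunn_pairwise(v, lab)
        pw.insert(0, "feature", col)
        finite = pw["p"].notna()
        padj = np.full(len(pw), np.nan)
        if finite.any():
            padj[finite.to_numpy()] = multipletests(
                pw.loc[finite, "p"], method=p_adjust
            )[1]
        pw["p_adj"] = padj
        pairwise_frames.append(pw)
    pairwise = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame(columns=["feature", "group1", "group2", "z", "p", "p_adj"])
    )
    return {"overall": pd.DataFrame(overall_rows), "pairwise": pairwise}


def top_rna_overlap(
    cluster_sets: Mapping[str | int, Iterable[str]],
    known_top: Iterable[str],
    scores: Mapping[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Overlap of each cluster with a published TOP-RNA gene list.

    Returns a per-cluster table (counts and fractions of the known list) and
    the non-listed genes of each cluster ranked by TOP local score — the
    candidate new TOP-RNAs.
    """
    known = set(known_top)
    if not known:
        raise ConfigurationError("known TOP-RNA list is empty")
    rows, cand_rows = [], []
    for name, members in cluster_sets.items():
        members = set(members)
        overlap = members & known
        rows.append(
            {
                "cluster": name,
                "n_genes": len(members),
                "n_known_top": len(overlap),
                "fraction_of_known": len(overlap) / len(known),
                "fraction_of_cluster": len(overlap) / len(members) if members else 0.0,
            }
        )
        for g in sorted(members - known):
            cand_rows.append(
                {
                    "cluster": name,
                    "gene_id": g,
                    "top_local_score": float(scores[g])
                    if scores is not None and g in scores
                    else np.nan,
                }
            )
    candidates = pd.DataFrame(cand_rows)
    if not candidates.empty:
        candidates = candidates.sort_values(
            ["cluster", "top_local_score"], ascending=[True, False]
        ).reset_index(drop=True)
    return {"table": pd.DataFrame(rows), "candidates": candidates}
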