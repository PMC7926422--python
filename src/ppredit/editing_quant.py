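"""Quantification and differential testing of C-to-U RNA editing.

Editing extent at a site is the fraction of reads carrying the edited base
among edited + unedited reads: on a forward-strand transcript a genomic C
is read as T when edited, so extent = T / (C + T); on a reverse-strand
transcript the forward-reference G position is read as A when edited, so
extent = A / (G + A).  Other bases at the position are treated as
sequencing noise and excluded from the denominator (configurable).

Differential editing between two genotypes is tested per position with a
two-sided Fisher exact test on the (edited, unedited) x (genotype) table,
corrected for multiple testing with the Simes-Hochberg step-up procedure
over all positions showing C/U variation.  Effect sizes are odds ratios
with a pseudocount of 0.5 added to every cell so they stay finite.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["sample_id", "position", "ref", "A", "C", "G", "T"]

#: Relative tolerance used when deciding whether an outcome's probability
#: is "no larger" than the observed table's in the two-sided Fisher test;
#: absorbs floating-point noise among exactly tied probabilities.
_FISHER_TIE_RTOL = 1e-7


# ---------------------------------------------------------------------------
# Count matrices


class SiteCountMatrix:
    """Per-(sample, position) A/C/G/T read counts over a reference.

    Positions are 1-based on the forward reference strand; ``ref`` is the
    forward-strand reference base.  Strand of the annotated transcript is
    supplied separately when computing extents.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table is missing columns: {missing}")
        df = df.loc[:, COUNT_COLUMNS].copy()
        for i, col in enumerate(["A", "C", "G", "T"]):
            try:
                df[col] = df[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-integer count in column {col}: {exc}") from exc
            if (df[col] < 0).any():
                row = int(df.index[df[col] < 0][0])
                raise ValueError(f"negative count in column {col} at row {row}")
        df["position"] = df["position"].astype(int)
        df["ref"] = df["ref"].astype(str).str.upper()
        dupes = df.duplicated(subset=["sample_id", "position"])
        if dupes.any():
            logger.warning(
                "summing %d duplicate (sample, position) count rows", int(dupes.sum())
            )
            df = (
                df.groupby(["sample_id", "position", "ref"], as_index=False, sort=False)[
                    ["A", "C", "G", "T"]
                ].sum()
            )[COUNT_COLUMNS]
        self.df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))

    def positions(self, sample_id: Optional[str] = None) -> set[int]:
        df = self.df if sample_id is None else self.df[self.df["sample_id"] == sample_id]
        return set(df["position"].tolist())

    def counts_at(self, sample_id: str, position: int) -> Optional[dict]:
        sel = self.df[(self.df["sample_id"] == sample_id) & (self.df["position"] == position)]
        if sel.empty:
            return None
        row = sel.iloc[0]
        return {
            "ref": row["ref"],
            "A": int(row["A"]),
            "C": int(row["C"]),
            "G": int(row["G"]),
            "T": int(row["T"]),
        }

    def write(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def count_from_pileup(
    source: Union[pd.DataFrame, str, Path, io.IOBase],
) -> SiteCountMatrix:
    """Ingest a per-position nucleotide count table (pileup-style TSV).

    Expected columns: ``sample_id, position, ref, A, C, G, T``; ``#``
    comment lines are ignored.  Duplicate (sample, position) rows are
    summed with a logged warning.
    """
    if isinstance(source, pd.DataFrame):
        return SiteCountMatrix(source)
    try:
        df = pd.read_csv(source, sep="\t", comment="#", dtype={"sample_id": str})
    except Exception as exc:  # surface the parser's line context
        raise ValueError(f"malformed count table {source}: {exc}") from exc
    return SiteCountMatrix(df)


def count_from_alignment(
    alignment_path: Union[str, Path],
    reference: Mapping[str, str],
    sample_id: str,
    min_mapping_quality: int = 10,
    min_base_quality: int = 20,
) -> SiteCountMatrix:
    """Count bases per reference position from a coordinate-sorted SAM/BAM.

    ``reference`` maps contig name to sequence (e.g. from
    ``Bio.SeqIO.to_dict``); contigs present in the alignment header but
    absent from the reference are a hard error.  Reads below the mapping-
    quality threshold and bases below the base-quality threshold are
    excluded; the filter values used are logged.
    """
    import pysam  # optional adapter; imported lazily

    logger.info(
        "pileup filters: mapping quality >= %d, base quality >= %d",
        min_mapping_quality,
        min_base_quality,
    )
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(str(alignment_path)) as af:
        for contig, length in zip(af.references, af.lengths):
            if contig not in reference:
                raise ValueError(
                    f"alignment contig {contig!r} not present in the supplied reference"
                )
            counts[contig] = np.zeros((4, length), dtype=np.int64)
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            grid = counts[read.reference_name]
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                idx = base_index.get(seq[qpos].upper())
                if idx is not None and rpos < grid.shape[1]:
                    grid[idx, rpos] += 1
    rows = []
    for contig, grid in counts.items():
        ref_seq = str(reference[contig]).upper()
        for pos0 in np.nonzero(grid.sum(axis=0))[0]:
            rows.append(
                dict(
                    sample_id=sample_id,
                    position=int(pos0) + 1,
                    ref=ref_seq[pos0] if pos0 < len(ref_seq) else "N",
                    A=int(grid[0, pos0]),
                    C=int(grid[1, pos0]),
                    G=int(grid[2, pos0]),
                    T=int(grid[3, pos0]),
                )
            )
    return SiteCountMatrix(pd.DataFrame(rows, columns=COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# Editing extent


@dataclass(frozen=True)
class EditingObservation:
    """Edited/total read counts at one site.

    ``total`` is edited + unedited reads, i.e. the reads carrying either
    the genomic or the edited base; other bases are excluded as noise.
    """

    edited: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.edited <= self.total:
            raise ValueError(
                f"need 0 <= edited <= total, got edited={self.edited} total={self.total}"
            )

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def unedited(self) -> int:
        return self.total - self.edited

    @property
    def extent(self) -> Optional[float]:
        """Editing extent in [0, 1]; ``None`` (undefined) when total is 0."""
        if self.total == 0:
            return None
        return self.edited / self.total

    @property
    def percent(self) -> Optional[float]:
        return None if self.extent is None else 100.0 * self.extent


def editing_extent(
    counts: Mapping[str, int],
    strand: str = "+",
    all_bases_denominator: bool = False,
) -> EditingObservation:
    """Editing extent at one position from A/C/G/T counts.

    On the forward strand (transcript reads C, edited to U/T):
    edited = T, unedited = C.  On the reverse strand (forward reference
    shows G, edited reads appear as A): edited = A, unedited = G.  With
    ``all_bases_denominator`` the total includes all four bases instead of
    just the edited/unedited pair.
    """
    if strand == "+":
        edited, unedited = int(counts["T"]), int(counts["C"])
    elif strand == "-":
        edited, unedited = int(counts["A"]), int(counts["G"])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if all_bases_denominator:
        total = sum(int(counts[b]) for b in "ACGT")
    else:
        total = edited + unedited
    return EditingObservation(edited=edited, total=total)


# ---------------------------------------------------------------------------
# Statistics


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Exact hypergeometric computation in log space (no approximation):
    with margins fixed, the p-value sums the probabilities of every
    outcome whose probability does not exceed the observed table's
    (the minimum-likelihood two-sided convention).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # a degenerate margin admits only one outcome
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = _log_binom(n, c1)
    log_pmf = np.array(
        [_log_binom(r1, x) + _log_binom(r2, c1 - x) - denom for x in range(lo, hi + 1)]
    )
    log_obs = log_pmf[a - lo]
    included = log_pmf[log_pmf <= log_obs + math.log1p(_FISHER_TIE_RTOL)]
    shift = included.max()
    p = math.exp(shift) * float(np.exp(included - shift).sum())
    return min(1.0, p)


def fisher_differential(obs_a: EditingObservation, obs_b: EditingObservation) -> float:
    """Two-sided Fisher exact p comparing editing between two samples."""
    if not (obs_a.defined and obs_b.defined):
        raise ValueError("Fisher test requires total > 0 in both samples")
    return fisher_exact_two_sided(obs_a.edited, obs_a.unedited, obs_b.edited, obs_b.unedited)


def adjust_pvalues(p_raw: Sequence[float]) -> np.ndarray:
    """Simes-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def odds_ratio(
    obs_a: EditingObservation, obs_b: EditingObservation, pseudocount: float = 0.5
) -> float:
    """Pseudocounted odds ratio of editing in sample A relative to sample B.

    ``pseudocount`` (default 0.5) is added to every cell so the ratio is
    finite and positive even with zero cells.
    """
    k = pseudocount
    return ((obs_a.edited + k) * (obs_b.unedited + k)) / (
        (obs_a.unedited + k) * (obs_b.edited + k)
    )


# ---------------------------------------------------------------------------
# Differential calling


@dataclass(frozen=True)
class DifferentialResult:
    """Per-site differential-editing test result (sample A vs sample B)."""

    position: int
    annotation: str
    obs_a: EditingObservation
    obs_b: EditingObservation
    p_raw: float
    p_adj: float
    odds_ratio: float
    direction: int
    significant: bool
    call: str

    @property
    def delta_extent(self) -> float:
        return (self.obs_b.extent or 0.0) - (self.obs_a.extent or 0.0)


def call_differential_sites(
    matrix_a: SiteCountMatrix,
    matrix_b: SiteCountMatrix,
    alpha: float = 0.05,
    min_total: int = 10,
    delta_min: float = 0.10,
    or_pseudocount: float = 0.5,
    lost_ratio: float = 0.05,
    sample_a: Optional[str] = None,
    sample_b: Optional[str] = None,
    strands: Optional[Mapping[int, str]] = None,
    annotations: Optional[Mapping[int, str]] = None,
) -> list[DifferentialResult]:
    """Call differentially edited positions between two count matrices.

    Candidate positions are those whose reference base is C on the
    transcript strand (G on the forward reference for ``-`` transcripts)
    and that show C/U variation — edited reads in at least one sample.
    Positions covered in only one sample are excluded with a logged
    reason; positions below ``min_total`` in either sample are excluded
    from the test family.

    A position is flagged significant when its Simes-Hochberg adjusted p
    is <= ``alpha`` and the absolute extent change is >= ``delta_min``.
    Significant decreases where the extent in B collapses to at most
    ``lost_ratio`` x the extent in A are classified ``"lost"`` (editing
    effectively abolished); other significant positions are
    ``"significant"``; the rest ``"ns"``.
    """
    if sample_a is None:
        sample_a = _only_sample(matrix_a, "matrix_a")
    if sample_b is None:
        sample_b = _only_sample(matrix_b, "matrix_b")
    strands = strands or {}
    annotations = annotations or {}

    pos_a = matrix_a.positions(sample_a)
    pos_b = matrix_b.positions(sample_b)
    if not pos_a & pos_b:
        raise ValueError("count matrices share no positions")
    for pos in sorted((pos_a | pos_b) - (pos_a & pos_b)):
        logger.info("position %d covered in only one sample; excluded", pos)

    candidates: list[tuple[int, EditingObservation, EditingObservation]] = []
    for pos in sorted(pos_a & pos_b):
        counts_a = matrix_a.counts_at(sample_a, pos)
        counts_b = matrix_b.counts_at(sample_b, pos)
        strand = strands.get(pos, "+")
        ref = counts_a["ref"]
        expected_ref = "C" if strand == "+" else "G"
        if ref not in (expected_ref, "N"):
            continue  # not a C on the transcript strand
        obs_a = editing_extent(counts_a, strand)
        obs_b = editing_extent(counts_b, strand)
        if obs_a.edited == 0 and obs_b.edited == 0:
            continue  # no C/U variation anywhere
        if not (obs_a.defined and obs_b.defined):
            logger.info("position %d has zero informative coverage in one sample", pos)
            continue
        if obs_a.total < min_total or obs_b.total < min_total:
            continue
        candidates.append((pos, obs_a, obs_b))

    p_raw = [fisher_differential(oa, ob) for _, oa, ob in candidates]
    p_adj = adjust_pvalues(p_raw)

    results = []
    for (pos, oa, ob), praw, padj in zip(candidates, p_raw, p_adj):
        delta = ob.extent - oa.extent
        significant = bool(padj <= alpha and abs(delta) >= delta_min)
        if significant and delta < 0 and ob.extent <= lost_ratio * oa.extent:
            call = "lost"
        elif significant:
            call = "significant"
        else:
            call = "ns"
        results.append(
            DifferentialResult(
                position=pos,
                annotation=annotations.get(pos, ""),
                obs_a=oa,
                obs_b=ob,
                p_raw=float(praw),
                p_adj=float(padj),
                odds_ratio=odds_ratio(oa, ob, or_pseudocount),
                direction=int(np.sign(delta)),
                significant=significant,
                call=call,
            )
        )
    return results


def _only_sample(matrix: SiteCountMatrix, name: str) -> str:
    samples = matrix.samples
    if len(samples) != 1:
        raise ValueError(
            f"{name} contains {len(samples)} samples; pass sample_a/sample_b explicitly"
        )
    return samples[0]


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Differential results as a flat table (percentages to 2 dp, p to 3 sf)."""
    rows = []
    for r in results:
        rows.append(
            dict(
                position=r.position,
                annotation=r.annotation,
                edited_a=r.obs_a.edited,
                total_a=r.obs_a.total,
                pct_a=float(f"{r.obs_a.percent:.2f}") if r.obs_a.defined else np.nan,
                edited_b=r.obs_b.edited,
                total_b=r.obs_b.total,
                pct_b=float(f"{r.obs_b.percent:.2f}") if r.obs_b.defined else np.nan,
                p_raw=float(f"{r.p_raw:.3g}"),
                p_adj=float(f"{r.p_adj:.3g}"),
                odds_ratio=float(f"{r.odds_ratio:.3g}"),
                call=r.call,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "annotation",
            "edited_a",
            "total_a",
            "pct_a",
            "edited_b",
            "total_b",
            "pct_b",
            "p_raw",
            "p_adj",
            "odds_ratio",
            "call",
        ],
    )


# ---------------------------------------------------------------------------
# Codon consequences


@dataclass(frozen=True)
class CodonEffect:
    ref_codon: str
    ref_aa: str
    edited_codon: str
    edited_aa: str
    synonymous: bool


def codon_effect(cds: str, edit_position: int) -> CodonEffect:
    """Consequence of C-to-U editing at a 1-based position within a CDS.

    The CDS must be in frame from its first base; the base at
    ``edit_position`` must be C.  Codons are reported in DNA letters
    (edited C shown as T), translated with the standard genetic code.
    """
    cds = str(cds).upper().replace("U", "T")
    if not 1 <= edit_position <= len(cds):
        raise ValueError(f"edit position {edit_position} outside CDS of length {len(cds)}")
    if cds[edit_position - 1] != "C":
        raise ValueError(
            f"base at CDS position {edit_position} is {cds[edit_position - 1]!r}, not C"
        )
    codon_start = 3 * ((edit_position - 1) // 3)
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"edit position {edit_position} falls in an incomplete codon")
    within = (edit_position - 1) % 3
    edited_codon = ref_codon[:within] + "T" + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    edited_aa = str(Seq(edited_codon).translate())
    return CodonEffect(
        ref_codon=ref_codon,
        ref_aa=ref_aa,
        edited_codon=edited_codon,
        edited_aa=edited_aa,
        synonymous=(ref_aa == edited_aa),
    )
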