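"""PPR-RNA recognition-code scoring.

The recognition code is trained from alignments of known editing factors
to their target sites: for each motif type, the frequency with which each
(5th, last) amino-acid pair aligns with A, C, G or U is tallied and
converted to a log-ratio score

    score = ln((k + observed) / (k + expected)),

with pseudocount ``k = 10`` by default.  ``expected`` is the two-way
independence expectation within the motif type — (pair row total) ×
(nucleotide column total) / grand total — i.e. the count expected from
overall amino-acid and nucleotide frequencies if pair and base were
unassociated.  A protein-site alignment is then scored by summing the
per-motif lookups.

Alignment convention: the edited C is the last base of the site window,
the E2 motif is anchored two positions upstream of it (E1 at -3, the
C-terminal-most P/L/S motif at -4), and each motif toward the N-terminus
steps one base further 5'.  Proteins without an E2 motif anchor their
C-terminal-most motif at a configurable offset (default -4).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from ppredit.ppr_model import (
    COARSEN_MAP,
    AminoAcidPair,
    PPRMotif,
    PPRProtein,
)

NUCLEOTIDES = ("A", "C", "G", "U")
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: Window-position offset (relative to the edited C at -1) at which the E2
#: motif is anchored.
E2_ANCHOR_OFFSET = -2

#: Fallback anchor offset for the C-terminal-most motif of proteins that
#: lack an E2 motif.
NO_E2_ANCHOR_OFFSET = -4


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map T to U."""
    return str(seq).upper().replace("T", "U")


def _check_rna(seq: str, what: str = "sequence") -> str:
    seq = normalize_rna(seq)
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class AlignmentObservation:
    """One training observation: a motif (type + code pair) aligned to a base.

    ``weight`` carries a count, so a tallied frequency table can be fed in
    as one observation per cell.
    """

    motif_type: str
    pair: AminoAcidPair
    nucleotide: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleotide", normalize_rna(self.nucleotide))
        if self.nucleotide not in NUCLEOTIDES:
            raise ValueError(f"nucleotide must be one of {NUCLEOTIDES}, got {self.nucleotide!r}")
        if self.weight < 0:
            raise ValueError(f"observation weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class EditingSite:
    """A candidate editing site: the edited position plus its 5' context.

    The window is the RNA ending at the edited C (the site base is always
    the window's last character).  For non-editable orthologue positions
    the last base is the genomic pre-mutation base (usually U) instead of
    C; pass ``require_c=False`` for those.
    """

    site_id: str
    window: str
    genome_position: int = 0
    strand: str = "+"
    require_c: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "window", _check_rna(self.window, f"window of {self.site_id}"))
        if not self.window:
            raise ValueError(f"site {self.site_id}: window must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-'")
        if self.require_c and self.window[-1] != "C":
            raise ValueError(
                f"site {self.site_id}: window must end at the edited C, "
                f"got {self.window[-1]!r}"
            )

    @property
    def edited_offset(self) -> int:
        """0-based index of the edited base within the window (always last)."""
        return len(self.window) - 1

    @property
    def site_base(self) -> str:
        return self.window[-1]


@dataclass(frozen=True)
class SiteScore:
    """Score of one protein against one site, with the per-motif breakdown.

    ``per_motif`` holds ``(motif_index, offset, score)`` triples where
    ``offset`` is the aligned window position relative to the edited C
    (-2 = two bases upstream) or ``None`` for motifs falling 5' of the
    window.
    """

    protein_id: str
    site_id: str
    total: float
    per_motif: tuple[tuple[int, Optional[int], float], ...]

    @property
    def n_off_window(self) -> int:
        return sum(1 for _, off, _ in self.per_motif if off is None)


class ScoringTableSet:
    """Per-motif-type lookup tables from (aa5, aa_last, base) to a score.

    Unseen (pair, base) combinations obey the same log-ratio formula with
    an observed count of 0; a pair never seen for a motif type has
    expected 0 in every column, so all four of its scores are exactly 0.
    """

    def __init__(
        self,
        scores: Mapping[str, Mapping[tuple[str, str], np.ndarray]],
        pseudocount: float = 10.0,
        n_observations: Optional[Mapping[str, float]] = None,
        coarsened: bool = False,
    ) -> None:
        if pseudocount <= 0:
            raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
        self._scores = {
            mt: {pair: np.asarray(v, dtype=float) for pair, v in table.items()}
            for mt, table in scores.items()
        }
        for mt, table in self._scores.items():
            for pair, v in table.items():
                if v.shape != (4,) or not np.all(np.isfinite(v)):
                    raise ValueError(f"invalid score vector for {mt}/{pair}: {v}")
        self.pseudocount = float(pseudocount)
        self.n_observations = dict(n_observations or {})
        self.coarsened = bool(coarsened)

    @property
    def motif_types(self) -> tuple[str, ...]:
        return tuple(sorted(self._scores))

    def _resolve_type(self, motif_type: str) -> Optional[str]:
        if motif_type in self._scores:
            return motif_type
        if self.coarsened:
            coarse = COARSEN_MAP.get(motif_type)
            if coarse in self._scores:
                return coarse
        return None

    def has_motif_type(self, motif_type: str) -> bool:
        return self._resolve_type(motif_type) is not None

    def lookup(self, motif_type: str, pair: AminoAcidPair, nucleotide: str) -> float:
        """Score for one motif-base alignment; 0 for anything unseen or gapped."""
        nucleotide = normalize_rna(nucleotide)
        if nucleotide not in _NUC_INDEX:
            raise ValueError(f"nucleotide must be one of {NUCLEOTIDES}, got {nucleotide!r}")
        if not pair.scorable:
            return 0.0
        mt = self._resolve_type(motif_type)
        if mt is None:
            return 0.0
        vec = self._scores[mt].get(pair.as_tuple())
        if vec is None:
            return 0.0
        return float(vec[_NUC_INDEX[nucleotide]])

    def frame(self, motif_type: str) -> pd.DataFrame:
        """One motif type's table as a DataFrame (aa5, aa_last, A, C, G, U)."""
        table = self._scores[motif_type]
        rows = [
            dict(aa5=aa5, aa_last=aal, **dict(zip(NUCLEOTIDES, vec)))
            for (aa5, aal), vec in sorted(table.items())
        ]
        return pd.DataFrame(rows, columns=["aa5", "aa_last", *NUCLEOTIDES])

    def write(self, directory: Union[str, Path]) -> None:
        """Write one TSV per motif type into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for mt in self.motif_types:
            self.frame(mt).to_csv(directory / f"{mt}.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: Union[str, Path], pseudocount: float = 10.0) -> "ScoringTableSet":
        """Read a table set written by :meth:`write` (one TSV per motif type)."""
        directory = Path(directory)
        scores: dict[str, dict[tuple[str, str], np.ndarray]] = {}
        paths = sorted(directory.glob("*.tsv"))
        if not paths:
            raise FileNotFoundError(f"no scoring-table TSVs found in {directory}")
        for path in paths:
            df = pd.read_csv(path, sep="\t", dtype={"aa5": str, "aa_last": str})
            scores[path.stem] = {
                (row.aa5, row.aa_last): np.array([getattr(row, n) for n in NUCLEOTIDES])
                for row in df.itertuples(index=False)
            }
        return cls(scores, pseudocount=pseudocount)


def expected_counts(observed: pd.DataFrame) -> pd.DataFrame:
    """Two-way independence expectation for a pair-by-nucleotide count table.

    ``expected[pair, base] = row_total(pair) * col_total(base) / grand_total``.
    This is the count expected from the overall amino-acid-pair and
    nucleotide frequencies if the two were unassociated.  Isolated here so
    an alternative null (e.g. an external nucleotide composition) can be
    swapped in.
    """
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    grand = float(observed.values.sum())
    if grand == 0:
        return observed * 0.0
    return pd.DataFrame(
        np.outer(row.values, col.values) / grand,
        index=observed.index,
        columns=observed.columns,
    )


def build_scoring_tables(
    observations: Iterable[AlignmentObservation],
    pseudocount: float = 10.0,
    coarsen: bool = False,
) -> ScoringTableSet:
    """Train per-motif-type scoring tables from factor-target alignments.

    Parameters
    ----------
    observations:
        Motif-base alignment observations (weights act as counts).
    pseudocount:
        Stabilising constant added to both observed and expected counts.
    coarsen:
        Pool fine motif labels (P1, P2 -> P, etc.) before tallying; the
        resulting table set also coarsens labels at lookup time.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    observations = list(observations)
    if not observations:
        raise ValueError("cannot build scoring tables from an empty observation set")

    tallies: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for obs in observations:
        mt = COARSEN_MAP.get(obs.motif_type, obs.motif_type) if coarsen else obs.motif_type
        table = tallies.setdefault(mt, {})
        vec = table.setdefault(obs.pair.as_tuple(), np.zeros(4))
        vec[_NUC_INDEX[obs.nucleotide]] += obs.weight

    scores: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    n_obs: dict[str, float] = {}
    for mt, table in tallies.items():
        obs_df = pd.DataFrame.from_dict(table, orient="index", columns=list(NUCLEOTIDES))
        exp = expected_counts(obs_df).values
        score_mat = np.log((pseudocount + obs_df.values) / (pseudocount + exp))
        scores[mt] = {
            pair: score_mat[i].astype(float) for i, pair in enumerate(obs_df.index)
        }
        n_obs[mt] = float(obs_df.values.sum())
    return ScoringTableSet(
        scores, pseudocount=pseudocount, n_observations=n_obs, coarsened=coarsen
    )


def align_motifs_to_site(
    protein: PPRProtein,
    site: EditingSite,
    no_e2_anchor: int = NO_E2_ANCHOR_OFFSET,
) -> list[tuple[PPRMotif, Optional[int]]]:
    """Align a protein's motifs to a site window, one base per motif.

    The E2 motif is placed at offset -2 relative to the edited C (the
    window's last base is offset -1) and each motif toward the N-terminus
    occupies the next base 5'.  Proteins lacking E2 anchor their
    C-terminal-most motif at ``no_e2_anchor``.  Motifs extending 5' of the
    window are reported with offset ``None``.
    """
    if not protein.motifs:
        raise ValueError(f"protein {protein.protein_id} has no motifs to align")
    motifs = protein.motifs
    anchor_idx = None
    for i, m in enumerate(motifs):
        if m.motif_type == "E2":
            anchor_idx = i
            anchor_offset = E2_ANCHOR_OFFSET
    if anchor_idx is None:
        anchor_idx = len(motifs) - 1
        anchor_offset = no_e2_anchor

    out: list[tuple[PPRMotif, Optional[int]]] = []
    for i, m in enumerate(motifs):
        offset = anchor_offset - (anchor_idx - i)
        out.append((m, offset if offset >= -len(site.window) else None))
    return out


def score_protein_site(
    protein: PPRProtein,
    site: EditingSite,
    tables: ScoringTableSet,
    score_terminal_motifs: bool = False,
    no_e2_anchor: int = NO_E2_ANCHOR_OFFSET,
) -> SiteScore:
    """Score one protein against one site by summing per-motif lookups.

    Gap residues, motifs aligned 5' of the window, and motif types absent
    from the table set all contribute exactly 0.  E1/E2 motifs are scored
    only when ``score_terminal_motifs`` is set (and their types are in the
    tables); by default they serve purely as alignment anchors.
    """
    alignment = align_motifs_to_site(protein, site, no_e2_anchor=no_e2_anchor)
    per_motif: list[tuple[int, Optional[int], float]] = []
    total = 0.0
    for motif, offset in alignment:
        if offset is None:
            per_motif.append((motif.index, None, 0.0))
            continue
        if motif.is_terminal and not score_terminal_motifs:
            per_motif.append((motif.index, offset, 0.0))
            continue
        base = site.window[len(site.window) + offset]
        s = tables.lookup(motif.motif_type, motif.pair, base)
        per_motif.append((motif.index, offset, s))
        total += s
    return SiteScore(
        protein_id=protein.protein_id,
        site_id=site.site_id,
        total=total,
        per_motif=tuple(per_motif),
    )


def rank_candidates(
    site: EditingSite,
    proteins: Sequence[PPRProtein],
    tables: ScoringTableSet,
    **score_kwargs,
) -> list[tuple[str, float, int]]:
    """Rank candidate factors for one site by descending total score.

    Competition ranking: a protein outscored by ``k`` others has rank
    ``k + 1``; exact ties share the smaller rank.
    """
    if not proteins:
        raise ValueError("rank_candidates requires at least one protein")
    totals = [
        (p.protein_id, score_protein_site(p, site, tables, **score_kwargs).total)
        for p in proteins
    ]
    values = np.array([t for _, t in totals])
    order = np.argsort(-values, kind="stable")
    ranked = []
    for pos in order:
        pid, total = totals[pos]
        rank = int(np.sum(values > total)) + 1
        ranked.append((pid, float(total), rank))
    return ranked


def score_distribution(
    site: EditingSite,
    proteins: Sequence[PPRProtein],
    tables: ScoringTableSet,
    named_protein: Optional[str] = None,
    **score_kwargs,
) -> dict:
    """Summary of the candidate-score distribution for one site.

    Mirrors the usual presentation of a target-prediction scan: the range
    and quartiles of scores over a candidate set, plus where a named
    protein of interest falls.  ``named`` is ``None`` (with ``found``
    False) when the requested protein is not in the candidate set.
    """
    ranked = rank_candidates(site, proteins, tables, **score_kwargs)
    values = np.array([t for _, t, _ in ranked])
    summary = {
        "site_id": site.site_id,
        "n": len(ranked),
        "min": float(values.min()),
        "max": float(values.max()),
        "q25": float(np.quantile(values, 0.25)),
        "median": float(np.quantile(values, 0.5)),
        "q75": float(np.quantile(values, 0.75)),
        "named": None,
        "found": False,
    }
    if named_protein is not None:
        for pid, total, rank in ranked:
            if pid == named_protein:
                summary["named"] = {"protein_id": pid, "total": total, "rank": rank}
                summary["found"] = True
                break
    return summary


# ---------------------------------------------------------------------------
# I/O helpers


def read_observations_tsv(path: Union[str, Path]) -> list[AlignmentObservation]:
    """Read training observations (motif_type, aa5, aa_last, nucleotide, weight)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"aa5": str, "aa_last": str})
    weight = df["weight"] if "weight" in df.columns else pd.Series(1.0, index=df.index)
    return [
        AlignmentObservation(
            motif_type=str(row.motif_type),
            pair=AminoAcidPair(row.aa5, row.aa_last),
            nucleotide=str(row.nucleotide),
            weight=float(w),
        )
        for row, w in zip(df.itertuples(index=False), weight)
    ]


def write_observations_tsv(
    observations: Sequence[AlignmentObservation], path: Union[str, Path]
) -> None:
    pd.DataFrame(
        [
            dict(
                motif_type=o.motif_type,
                aa5=o.pair.aa5,
                aa_last=o.pair.aa_last,
                nucleotide=o.nucleotide,
                weight=o.weight,
            )
            for o in observations
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: Union[str, Path], require_c: bool = True) -> list[EditingSite]:
    """Read editing sites (site_id, position, strand, window)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        EditingSite(
            site_id=str(row.site_id),
            genome_position=int(row.position),
            strand=str(row.strand),
            window=str(row.window),
            require_c=require_c,
        )
        for row in df.itertuples(index=False)
    ]


def write_sites_tsv(sites: Sequence[EditingSite], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            dict(
                site_id=s.site_id,
                position=s.genome_position,
                strand=s.strand,
                window=s.window,
            )
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_site_windows_fasta(
    path: Union[str, Path], require_c: bool = True
) -> list[EditingSite]:
    """Read site windows from FASTA; the record id is the site id."""
    return [
        EditingSite(site_id=rec.id, window=str(rec.seq), require_c=require_c)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
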