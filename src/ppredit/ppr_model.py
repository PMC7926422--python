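"""Domain model for PLS-subfamily PPR proteins.

A PPR editing factor is an ordered array of ~35-aa helical repeats.  Each
motif contacts one ribonucleotide, and the amino acids at the motif's 5th
and last positions largely determine which base is preferred (the "PPR
code").  PLS-subfamily arrays alternate P, L and S motif variants and are
usually capped by E1/E2 motifs and, in DYW-class factors, a
cytidine-deaminase-like DYW domain.

Motif boundaries are taken from prior annotation; this module only parses,
validates and manipulates such annotations — it does not detect motifs
from protein sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

#: Canonical one-letter amino-acid alphabet.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Symbol for an unannotatable (gapped) code residue.  Gap residues are
#: representable but non-scorable: they contribute 0 to alignment scores.
GAP = "-"

#: Default motif label vocabulary.  Both coarse (P, L, S) and fine
#: (P1, P2, L1, L2, S1, S2, SS) labels are accepted; scoring tables are
#: keyed by the label as given unless a coarsening map is applied.
MOTIF_LABELS = frozenset(
    {"P", "L", "S", "SS", "P1", "P2", "L1", "L2", "S1", "S2", "E1", "E2"}
)

#: Map from fine motif labels to coarse ones (used when a scoring-table
#: set was built with ``coarsen=True``).
COARSEN_MAP = {
    "P1": "P",
    "P2": "P",
    "L1": "L",
    "L2": "L",
    "S1": "S",
    "S2": "S",
    "SS": "S",
}

#: Labels of the C-terminal PPR-like motifs that anchor the alignment.
TERMINAL_LABELS = frozenset({"E1", "E2"})

ANNOTATION_COLUMNS = ["protein_id", "motif_index", "motif_type", "aa5", "aa_last"]


def _check_residue(aa: str, what: str) -> str:
    aa = str(aa).upper()
    if aa != GAP and aa not in AA_ALPHABET:
        raise ValueError(f"{what} {aa!r} is not an amino acid or the gap symbol {GAP!r}")
    return aa


@dataclass(frozen=True)
class AminoAcidPair:
    """The (5th, last) code-residue pair of one PPR motif."""

    aa5: str
    aa_last: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "aa5", _check_residue(self.aa5, "aa5"))
        object.__setattr__(self, "aa_last", _check_residue(self.aa_last, "aa_last"))

    @property
    def scorable(self) -> bool:
        """False when either residue is a gap; such pairs score 0."""
        return GAP not in (self.aa5, self.aa_last)

    def as_tuple(self) -> tuple[str, str]:
        return (self.aa5, self.aa_last)


@dataclass(frozen=True)
class PPRMotif:
    """One PPR motif: its 1-based array index, type label and code residues."""

    index: int
    motif_type: str
    aa5: str
    aa_last: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"motif index must be >= 1, got {self.index}")
        if self.motif_type not in MOTIF_LABELS:
            raise ValueError(
                f"unknown motif type {self.motif_type!r}; expected one of "
                f"{sorted(MOTIF_LABELS)}"
            )
        object.__setattr__(self, "aa5", _check_residue(self.aa5, "aa5"))
        object.__setattr__(self, "aa_last", _check_residue(self.aa_last, "aa_last"))

    @property
    def is_terminal(self) -> bool:
        return self.motif_type in TERMINAL_LABELS

    @property
    def pair(self) -> AminoAcidPair:
        return AminoAcidPair(self.aa5, self.aa_last)


@dataclass(frozen=True)
class PPRProtein:
    """An ordered PPR motif array with optional E1/E2 cap and DYW domain."""

    protein_id: str
    motifs: tuple[PPRMotif, ...]
    has_dyw: bool = False

    def __post_init__(self) -> None:
        motifs = tuple(self.motifs)
        object.__setattr__(self, "motifs", motifs)
        indices = [m.index for m in motifs]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(
                f"{self.protein_id}: motif indices must be strictly increasing, got {indices}"
            )
        e1 = [i for i, m in enumerate(motifs) if m.motif_type == "E1"]
        e2 = [i for i, m in enumerate(motifs) if m.motif_type == "E2"]
        if len(e1) > 1 or len(e2) > 1:
            raise ValueError(f"{self.protein_id}: at most one E1 and one E2 motif allowed")
        last_pls = max(
            (i for i, m in enumerate(motifs) if not m.is_terminal), default=-1
        )
        if e1 and (e1[0] < last_pls):
            raise ValueError(f"{self.protein_id}: E1 must follow all P/L/S motifs")
        if e2 and (e2[0] < last_pls):
            raise ValueError(f"{self.protein_id}: E2 must follow all P/L/S motifs")
        if e1 and e2 and e1[0] > e2[0]:
            raise ValueError(f"{self.protein_id}: E1 must precede E2")

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def has_e1(self) -> bool:
        return any(m.motif_type == "E1" for m in self.motifs)

    @property
    def has_e2(self) -> bool:
        return any(m.motif_type == "E2" for m in self.motifs)

    @property
    def pls_motifs(self) -> tuple[PPRMotif, ...]:
        return tuple(m for m in self.motifs if not m.is_terminal)

    @property
    def cterm(self) -> str:
        """C-terminal architecture label, e.g. ``E1-E2-DYW`` or ``none``."""
        parts = []
        if self.has_e1:
            parts.append("E1")
        if self.has_e2:
            parts.append("E2")
        if self.has_dyw:
            parts.append("DYW")
        return "-".join(parts) if parts else "none"


def code_residues(motif: PPRMotif) -> AminoAcidPair:
    """Return the (5th, last) amino-acid pair used for scoring lookups."""
    return motif.pair


def truncate_protein(protein: PPRProtein, stop_motif_index: int) -> PPRProtein:
    """Model a premature stop codon falling inside motif ``stop_motif_index``.

    The motif containing the stop and everything downstream — including
    E1/E2 and any DYW domain — is removed; only motifs with a strictly
    smaller array index survive.

    Parameters
    ----------
    protein:
        The full-length protein.
    stop_motif_index:
        1-based array index of the motif in which translation terminates.
        Must satisfy ``1 <= stop_motif_index <= len(protein)``.
    """
    if not 1 <= stop_motif_index <= len(protein.motifs):
        raise ValueError(
            f"stop_motif_index {stop_motif_index} out of range 1..{len(protein.motifs)}"
        )
    kept = tuple(m for m in protein.motifs if m.index < stop_motif_index)
    return replace(protein, motifs=kept, has_dyw=False)


def _coerce_annotation_frame(
    records: Union[pd.DataFrame, str, Path, io.IOBase, Iterable[dict]],
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    elif isinstance(records, (str, Path, io.IOBase)):
        df = pd.read_csv(records, sep="\t", comment="#", dtype=str)
    else:
        df = pd.DataFrame(list(records))
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motif annotation is missing columns: {missing}")
    return df


def parse_ppr_annotation(
    records: Union[pd.DataFrame, str, Path, io.IOBase, Iterable[dict]],
) -> list[PPRProtein]:
    """Parse a tabular PPR motif annotation into :class:`PPRProtein` objects.

    Accepts a TSV path/handle (``#`` comment lines ignored), a DataFrame,
    or an iterable of dicts with columns ``protein_id``, ``motif_index``,
    ``motif_type``, ``aa5``, ``aa_last``.  An optional ``DYW`` row per
    protein (any motif index after the array) marks the presence of the
    catalytic domain; it is recorded as metadata, not as a motif.

    Rows for one protein may be interleaved with other proteins'; they are
    sorted by motif index.  Duplicate ``(protein_id, motif_index)`` rows
    are a hard error, as is any unknown motif label or non-amino-acid
    residue.
    """
    df = _coerce_annotation_frame(records)
    if df.empty:
        return []
    df = df.assign(motif_index=df["motif_index"].astype(int))
    dupes = df.duplicated(subset=["protein_id", "motif_index"])
    if dupes.any():
        bad = df.loc[dupes, ["protein_id", "motif_index"]].iloc[0]
        raise ValueError(
            f"duplicate motif annotation for protein {bad['protein_id']!r} "
            f"index {bad['motif_index']}"
        )
    proteins: list[PPRProtein] = []
    # Preserve first-appearance order of proteins; sort motifs within each.
    for protein_id, group in df.groupby("protein_id", sort=False):
        group = group.sort_values("motif_index")
        motifs = []
        has_dyw = False
        for row in group.itertuples(index=False):
            if str(row.motif_type).upper() == "DYW":
                has_dyw = True
                continue
            motifs.append(
                PPRMotif(
                    index=int(row.motif_index),
                    motif_type=str(row.motif_type),
                    aa5=str(row.aa5),
                    aa_last=str(row.aa_last),
                )
            )
        proteins.append(
            PPRProtein(protein_id=str(protein_id), motifs=tuple(motifs), has_dyw=has_dyw)
        )
    return proteins


def annotation_frame(proteins: Sequence[PPRProtein]) -> pd.DataFrame:
    """Serialise proteins back to the tabular annotation schema (round-trip)."""
    rows = []
    for p in proteins:
        for m in p.motifs:
            rows.append(
                dict(
                    protein_id=p.protein_id,
                    motif_index=m.index,
                    motif_type=m.motif_type,
                    aa5=m.aa5,
                    aa_last=m.aa_last,
                )
            )
        if p.has_dyw:
            next_index = (p.motifs[-1].index + 1) if p.motifs else 1
            rows.append(
                dict(
                    protein_id=p.protein_id,
                    motif_index=next_index,
                    motif_type="DYW",
                    aa5=GAP,
                    aa_last=GAP,
                )
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_ppr_annotation(proteins: Sequence[PPRProtein], path: Union[str, Path]) -> None:
    annotation_frame(proteins).to_csv(path, sep="\t", index=False)
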