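"""Cross-species comparison of editing-factor binding-site scores.

When a plant lineage loses the need to edit a site (typically because the
genomic C has mutated to T, already encoding the edited state), the
upstream sequence is no longer constrained to bind the editing factor and
tends to diverge.  This module scores putative orthologues of a factor
against the homologous site sequence in each species and tests, per site,
whether species in which the site is editable (genomic C) score higher
than species in which it is not (genomic T, rarely A or G).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ppredit.code_scoring import (
    EditingSite,
    ScoringTableSet,
    normalize_rna,
    score_protein_site,
)
from ppredit.ppr_model import PPRProtein

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesSiteRecord:
    """One species' putative orthologue and its homologous site sequence.

    ``window`` ends at the homologous position; the site is editable when
    its genomic base there is C.
    """

    species: str
    site_id: str
    window: str
    protein: PPRProtein

    def __post_init__(self) -> None:
        object.__setattr__(self, "window", normalize_rna(self.window))

    @property
    def site_base(self) -> str:
        return self.window[-1]

    @property
    def editable(self) -> bool:
        return self.site_base == "C"

    def as_site(self) -> EditingSite:
        return EditingSite(
            site_id=self.site_id,
            window=self.window,
            require_c=False,
        )


@dataclass(frozen=True)
class GroupComparison:
    """Editable-vs-non-editable score comparison for one site.

    ``p_one_sided`` tests the alternative that editable-species scores
    have the higher mean (equivalently, that non-editable sites score
    lower).  ``testable`` is False when either group has fewer than two
    observations; the statistic and p are then NaN.
    """

    site_id: str
    scores_editable: tuple[float, ...]
    scores_noneditable: tuple[float, ...]
    t_statistic: float
    p_one_sided: float
    testable: bool

    @property
    def mean_editable(self) -> float:
        return float(np.mean(self.scores_editable)) if self.scores_editable else np.nan

    @property
    def mean_noneditable(self) -> float:
        return float(np.mean(self.scores_noneditable)) if self.scores_noneditable else np.nan


def score_orthologue_set(
    records: Sequence[SpeciesSiteRecord],
    tables: ScoringTableSet,
    **score_kwargs,
) -> pd.DataFrame:
    """Score each species' orthologue against its own site sequence.

    Returns a DataFrame with columns ``species, site_id, editable, score``.
    Scoring failures are re-raised with the species/site attached so a bad
    record in a large panel is identifiable.
    """
    rows = []
    for rec in records:
        try:
            result = score_protein_site(rec.protein, rec.as_site(), tables, **score_kwargs)
        except Exception as exc:
            raise type(exc)(
                f"scoring failed for species {rec.species!r} site {rec.site_id!r}: {exc}"
            ) from exc
        rows.append(
            dict(
                species=rec.species,
                site_id=rec.site_id,
                editable=rec.editable,
                score=result.total,
            )
        )
    return pd.DataFrame(rows, columns=["species", "site_id", "editable", "score"])


def editable_vs_noneditable_test(
    site_id: str,
    scores_editable: Sequence[float],
    scores_noneditable: Sequence[float],
    equal_var: bool = False,
) -> GroupComparison:
    """One-sided two-sample t-test: do editable sites score higher?

    Welch's unequal-variance form by default (species panels are
    unbalanced); set ``equal_var`` for the pooled-variance test.  With
    fewer than two observations in either group the comparison is flagged
    untestable rather than raising.  The degenerate case of two constant
    groups is resolved analytically (p = 0.5 on equal means).
    """
    ed = np.asarray(list(scores_editable), dtype=float)
    ne = np.asarray(list(scores_noneditable), dtype=float)
    if len(ed) < 2 or len(ne) < 2:
        logger.info("site %s: a group has <2 observations; comparison untestable", site_id)
        return GroupComparison(
            site_id=site_id,
            scores_editable=tuple(ed),
            scores_noneditable=tuple(ne),
            t_statistic=float("nan"),
            p_one_sided=float("nan"),
            testable=False,
        )
    if np.ptp(ed) == 0 and np.ptp(ne) == 0:
        # both groups constant: no within-group variance to scale by
        if ed[0] == ne[0]:
            t, p = 0.0, 0.5
        else:
            t = float("inf") if ed[0] > ne[0] else float("-inf")
            p = 0.0 if ed[0] > ne[0] else 1.0
    else:
        t, p = stats.ttest_ind(ed, ne, equal_var=equal_var, alternative="greater")
    return GroupComparison(
        site_id=site_id,
        scores_editable=tuple(ed),
        scores_noneditable=tuple(ne),
        t_statistic=float(t),
        p_one_sided=float(p),
        testable=True,
    )


def compare_orthologue_panel(
    records: Sequence[SpeciesSiteRecord],
    tables: ScoringTableSet,
    equal_var: bool = False,
    **score_kwargs,
) -> list[GroupComparison]:
    """Score a species panel and run the per-site editable/non-editable test."""
    scored = score_orthologue_set(records, tables, **score_kwargs)
    comparisons = []
    for site_id, group in scored.groupby("site_id", sort=True):
        comparisons.append(
            editable_vs_noneditable_test(
                site_id=str(site_id),
                scores_editable=group.loc[group["editable"], "score"].tolist(),
                scores_noneditable=group.loc[~group["editable"], "score"].tolist(),
                equal_var=equal_var,
            )
        )
    return comparisons


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Per-site summary table: group means, sizes, t, one-sided p."""
    return pd.DataFrame(
        [
            dict(
                site_id=c.site_id,
                n_editable=len(c.scores_editable),
                n_noneditable=len(c.scores_noneditable),
                mean_editable=c.mean_editable,
                mean_noneditable=c.mean_noneditable,
                t_statistic=c.t_statistic,
                p_one_sided=c.p_one_sided,
                testable=c.testable,
            )
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# I/O


def read_orthologue_tsv(
    path: Union[str, Path], proteins: Mapping[str, PPRProtein]
) -> list[SpeciesSiteRecord]:
    """Read a species panel TSV (species, site_id, site_base, window, protein_id).

    ``proteins`` maps protein_id to the parsed orthologue (from the motif
    annotation TSV).  Records whose protein is missing are dropped with a
    logged reason; a site_base column inconsistent with the window's last
    base is a hard error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        protein = proteins.get(str(row.protein_id))
        if protein is None:
            logger.warning(
                "species %s site %s: orthologue %r missing from annotation; dropped",
                row.species,
                row.site_id,
                row.protein_id,
            )
            continue
        window = normalize_rna(str(row.window))
        if hasattr(row, "site_base"):
            declared = normalize_rna(str(row.site_base))
            if declared != window[-1]:
                raise ValueError(
                    f"species {row.species} site {row.site_id}: site_base "
                    f"{declared!r} disagrees with window end {window[-1]!r}"
                )
        records.append(
            SpeciesSiteRecord(
                species=str(row.species),
                site_id=str(row.site_id),
                window=window,
                protein=protein,
            )
        )
    return records


def write_orthologue_tsv(
    records: Sequence[SpeciesSiteRecord], path: Union[str, Path]
) -> None:
    pd.DataFrame(
        [
            dict(
                species=r.species,
                site_id=r.site_id,
                site_base=r.site_base,
                window=r.window,
                protein_id=r.protein.protein_id,
            )
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
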