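"""Reference data for the mef100 mitochondrial editing study.

Published read counts at the seven mitochondrial positions that are
differentially edited between wild-type Arabidopsis (Col-0) and the
*mef100* mutant, in which a premature stop codon truncates the editing
factor MEF100 inside its second PPR motif.  Four major sites (*nad1*-493,
*nad4*-403, *nad7*-698, *ccmF_N2*-356) lose editing almost completely in
the mutant; three minor sites on the same transcripts show smaller
decreases.

These counts serve as worked-example inputs for
:func:`ppredit.editing_quant.editing_extent` and
:func:`ppredit.editing_quant.codon_effect`, and as the coverage/extent
profile the synthetic count generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ppredit.editing_quant import EditingObservation

#: Representative codon used for the synonymous site, whose report gives no
#: codon identity.  Any third-position C-to-T change is synonymous under
#: the standard code, so the choice does not affect the consequence call.
SYNONYMOUS_PLACEHOLDER_CODON = "GGC"


@dataclass(frozen=True)
class StudySite:
    """One differentially edited site with its published read counts."""

    position: int  # 1-based position in the mitochondrial genome
    site: str  # gene-relative site name, e.g. nad1-493
    annotation: str  # codon-consequence annotation as reported
    cds_position: int  # 1-based edited position within the CDS
    codon: Optional[str]  # reference codon (None where only "synonymous" is reported)
    col0: EditingObservation
    mef100: EditingObservation
    major: bool  # True for the four sites whose editing requires MEF100

    @property
    def codon_offset(self) -> int:
        """1-based position of the edited C within its codon."""
        return (self.cds_position - 1) % 3 + 1


MEF100_STUDY_SITES: tuple[StudySite, ...] = (
    StudySite(
        position=59314,
        site="nad1-493",
        annotation="nad1 CGT(R) to TGT(C)",
        cds_position=493,
        codon="CGT",
        col0=EditingObservation(413, 433),
        mef100=EditingObservation(381, 6304),
        major=True,
    ),
    StudySite(
        position=59321,
        site="nad1-500",
        annotation="nad1 TCG(S) to TTG(L)",
        cds_position=500,
        codon="TCG",
        col0=EditingObservation(1002, 1130),
        mef100=EditingObservation(13358, 16837),
        major=False,
    ),
    StudySite(
        position=291935,
        site="ccmFN2-356",
        annotation="ccmFN2 TCA(S) to TTA(L)",
        cds_position=356,
        codon="TCA",
        col0=EditingObservation(38, 40),
        mef100=EditingObservation(0, 712),
        major=True,
    ),
    StudySite(
        position=215160,
        site="nad4-403",
        annotation="nad4 CGC(R) to TGC(C)",
        cds_position=403,
        codon="CGC",
        col0=EditingObservation(291, 301),
        mef100=EditingObservation(13, 5429),
        major=True,
    ),
    StudySite(
        position=215468,
        site="nad4-95",
        annotation="nad4 TCA(S) to TTA(L)",
        cds_position=95,
        codon="TCA",
        col0=EditingObservation(32, 716),
        mef100=EditingObservation(254, 14186),
        major=False,
    ),
    StudySite(
        position=215479,
        site="nad4-84",
        annotation="nad4 synonymous",
        cds_position=84,
        codon=None,
        col0=EditingObservation(197, 524),
        mef100=EditingObservation(1606, 8731),
        major=False,
    ),
    StudySite(
        position=241553,
        site="nad7-698",
        annotation="nad7 TCG(S) to TTG(L)",
        cds_position=698,
        codon="TCG",
        col0=EditingObservation(813, 918),
        mef100=EditingObservation(20, 15966),
        major=True,
    ),
)


def study_sites_frame() -> pd.DataFrame:
    """The study sites as a flat table (one row per site)."""
    return pd.DataFrame(
        [
            dict(
                position=s.position,
                site=s.site,
                annotation=s.annotation,
                edited_col0=s.col0.edited,
                total_col0=s.col0.total,
                edited_mef100=s.mef100.edited,
                total_mef100=s.mef100.total,
                major=s.major,
            )
            for s in MEF100_STUDY_SITES
        ]
    )
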