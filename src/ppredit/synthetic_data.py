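"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of a real organellar editing study:

* a PPR-code training set — per motif type, amino-acid pairs with a
  planted nucleotide preference, observed counts drawn from a multinomial
  whose preferred base has probability proportional to exp(contrast);
* a planted editing factor whose code residues match its target window
  base-for-base, plus random decoy proteins (a nuclear PLS-PPR panel);
* per-position read count matrices for two genotypes, with binomially
  sampled edited/unedited reads at specified extents and coverages and a
  low symmetric miscall rate on the other bases;
* an orthologue panel in which species that no longer edit the site carry
  T (rarely A/G) at the site and drift freely across the binding window,
  while editable species remain constrained.

All generators are pure functions of :class:`GeneratorConfig`: the same
seed yields identical outputs, and each generator draws from its own
substream so adding one does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from ppredit import datasets
from ppredit.code_scoring import (
    NUCLEOTIDES,
    AlignmentObservation,
    EditingSite,
)
from ppredit.editing_quant import COUNT_COLUMNS, SiteCountMatrix
from ppredit.ortho_compare import SpeciesSiteRecord
from ppredit.ppr_model import AA_ALPHABET, AminoAcidPair, PPRMotif, PPRProtein

_AA = tuple(sorted(AA_ALPHABET))
_PLS_CYCLE = ("P", "L", "S")

# Fixed substream keys: adding a generator must not shift existing ones.
_STREAMS = {"training": 0, "protein": 1, "counts": 2, "ortho": 3}


def _default_editing_rates() -> tuple[tuple[float, float], ...]:
    """Per-site (wild-type, mutant) extents emulating the study profile.

    Four sites lose editing outright (0.95 -> 0.0), three show the minor
    decreases observed at the secondary sites, and the remaining 197
    background sites are unchanged at extents cycling over a realistic
    range of organellar editing levels.
    """
    lost = (((0.95, 0.0),) * 4)
    minor = ((0.8867, 0.7934), (0.0447, 0.0179), (0.3760, 0.1839))
    cycle = (0.30, 0.50, 0.70, 0.80, 0.90, 0.95, 0.99)
    background = tuple((cycle[i % len(cycle)], cycle[i % len(cycle)]) for i in range(197))
    return lost + minor + background


def _default_site_coverages() -> tuple[Optional[tuple[int, int]], ...]:
    """Coverages for the seven planted sites follow the study's read depths;
    background sites draw from ``coverage_range``."""
    study = datasets.MEF100_STUDY_SITES
    # same ordering as _default_editing_rates: 4 major sites, 3 minor, background
    majors = [s for s in study if s.major]
    minors = [s for s in study if not s.major]
    planted = tuple((s.col0.total, s.mef100.total) for s in majors + minors)
    return planted + (None,) * 197


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs for the synthetic generators (one seed, substreamed)."""

    seed: int = 0
    # --- PPR-code training set ---
    motif_types: tuple[str, ...] = ("P", "L", "S", "SS")
    n_pairs_per_type: int = 24
    n_obs_per_pair: int = 40
    contrast: float = 3.0
    # --- factor/decoy panel ---
    n_proteins: int = 205
    n_motifs: int = 17
    n_motifs_range: tuple[int, int] = (10, 18)
    window_pad: int = 2
    # --- count matrices ---
    editing_rates: tuple[tuple[float, float], ...] = field(
        default_factory=_default_editing_rates
    )
    site_coverages: tuple[Optional[tuple[int, int]], ...] = field(
        default_factory=_default_site_coverages
    )
    coverage_range: tuple[int, int] = (500, 2000)
    error_rate: float = 0.001
    first_position: int = 1001
    # --- orthologue panel ---
    n_species: int = 40
    site_editability: Optional[tuple[bool, ...]] = None
    divergence_rate: float = 0.3
    editable_drift_factor: float = 0.1

    def __post_init__(self) -> None:
        for rate_pair in self.editing_rates:
            if not all(0.0 <= r <= 1.0 for r in rate_pair):
                raise ValueError(f"editing rates must lie in [0, 1], got {rate_pair}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate must lie in [0, 1], got {self.error_rate}")
        if not 0.0 <= self.divergence_rate <= 1.0:
            raise ValueError(f"divergence_rate must lie in [0, 1]")
        if self.contrast < 0:
            raise ValueError(f"contrast must be >= 0, got {self.contrast}")
        if self.coverage_range[0] < 0:
            raise ValueError("coverage must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named substream of the global seed."""
        seq = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(seq)

    def editability(self) -> tuple[bool, ...]:
        if self.site_editability is not None:
            if len(self.site_editability) != self.n_species:
                raise ValueError("site_editability must have one entry per species")
            return tuple(self.site_editability)
        half = (self.n_species + 1) // 2
        return (True,) * half + (False,) * (self.n_species - half)


# ---------------------------------------------------------------------------
# Training observations


def simulate_training_observations(
    config: GeneratorConfig,
) -> tuple[list[AlignmentObservation], dict[tuple[str, tuple[str, str]], str]]:
    """Draw factor-target alignment counts with planted base preferences.

    Per motif type, ``n_pairs_per_type`` distinct amino-acid pairs each
    receive a preferred nucleotide (the first four pairs cover A, C, G, U
    so every base is representable) and ``n_obs_per_pair`` aligned-base
    draws from a multinomial where the preferred base's probability is
    proportional to exp(contrast) and the others to 1.

    Returns the observations and the planted (motif_type, pair) ->
    preferred-base truth map.
    """
    rng = config.rng("training")
    w_pref = float(np.exp(config.contrast))
    probs_by_pref = {
        n: np.array([w_pref if m == n else 1.0 for m in NUCLEOTIDES])
        / (w_pref + 3.0)
        for n in NUCLEOTIDES
    }

    observations: list[AlignmentObservation] = []
    truth: dict[tuple[str, tuple[str, str]], str] = {}
    for motif_type in config.motif_types:
        pairs: list[tuple[str, str]] = []
        seen = set()
        while len(pairs) < config.n_pairs_per_type:
            pair = (str(rng.choice(_AA)), str(rng.choice(_AA)))
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
        for i, pair in enumerate(pairs):
            preferred = NUCLEOTIDES[i % 4] if i < 4 else str(rng.choice(NUCLEOTIDES))
            truth[(motif_type, pair)] = preferred
            counts = rng.multinomial(config.n_obs_per_pair, probs_by_pref[preferred])
            for nuc, count in zip(NUCLEOTIDES, counts):
                if count > 0:
                    observations.append(
                        AlignmentObservation(
                            motif_type=motif_type,
                            pair=AminoAcidPair(*pair),
                            nucleotide=nuc,
                            weight=float(count),
                        )
                    )
    return observations, truth


# ---------------------------------------------------------------------------
# Planted factor and decoy panel


def _random_window(rng: np.random.Generator, length: int) -> str:
    bases = [str(rng.choice(NUCLEOTIDES)) for _ in range(length - 1)]
    return "".join(bases) + "C"


def _pairs_by_type_and_base(
    truth: dict[tuple[str, tuple[str, str]], str],
) -> dict[str, dict[str, list[tuple[str, str]]]]:
    out: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for (motif_type, pair), base in sorted(truth.items()):
        out.setdefault(motif_type, {}).setdefault(base, []).append(pair)
    return out


def _append_terminal_motifs(
    motifs: list[PPRMotif], rng: np.random.Generator
) -> list[PPRMotif]:
    next_index = motifs[-1].index + 1 if motifs else 1
    for i, label in enumerate(("E1", "E2")):
        motifs.append(
            PPRMotif(
                index=next_index + i,
                motif_type=label,
                aa5=str(rng.choice(_AA)),
                aa_last=str(rng.choice(_AA)),
            )
        )
    return motifs


def simulate_protein_with_target(
    config: GeneratorConfig,
    truth: Optional[dict[tuple[str, tuple[str, str]], str]] = None,
) -> tuple[PPRProtein, EditingSite, list[PPRProtein]]:
    """Build a factor that matches a random target window base-for-base.

    The planted protein's P/L/S motifs (types cycling P, L, S) each carry
    a code pair whose planted preference equals the window base the motif
    aligns to under the E2-at--2 convention; decoys carry random pairs
    from the same pair pool.  Returns (planted protein, target site,
    decoys); there are ``n_proteins - 1`` decoys.
    """
    if truth is None:
        _, truth = simulate_training_observations(config)
    rng = config.rng("protein")
    by_type = _pairs_by_type_and_base(truth)
    pls_types = [t for t in _PLS_CYCLE if t in by_type] or sorted(by_type)

    window_len = config.n_motifs + 3 + config.window_pad
    window = _random_window(rng, window_len)

    # P/L/S motif k (1-based, N- to C-terminal) aligns at offset
    # -(n_motifs + 3) + (k - 1); E1 and E2 then sit at -3 and -2.
    motifs: list[PPRMotif] = []
    for k in range(1, config.n_motifs + 1):
        offset = -(config.n_motifs + 3) + (k - 1)
        base = window[len(window) + offset]
        motif_type = pls_types[(k - 1) % len(pls_types)]
        candidates = by_type[motif_type].get(base)
        if not candidates:  # ensured by training coverage of all four bases
            raise RuntimeError(f"no planted pair prefers {base} for type {motif_type}")
        pair = candidates[int(rng.integers(len(candidates)))]
        motifs.append(PPRMotif(index=k, motif_type=motif_type, aa5=pair[0], aa_last=pair[1]))
    planted = PPRProtein(
        protein_id="planted_factor",
        motifs=tuple(_append_terminal_motifs(motifs, rng)),
        has_dyw=True,
    )

    site = EditingSite(
        site_id="site-planted", window=window, genome_position=1, strand="+"
    )

    decoys = []
    all_pairs = {t: sorted({p for ps in by_type[t].values() for p in ps}) for t in by_type}
    for i in range(config.n_proteins - 1):
        n = int(rng.integers(config.n_motifs_range[0], config.n_motifs_range[1] + 1))
        dmotifs = []
        for k in range(1, n + 1):
            motif_type = pls_types[(k - 1) % len(pls_types)]
            pool = all_pairs[motif_type]
            pair = pool[int(rng.integers(len(pool)))]
            dmotifs.append(
                PPRMotif(index=k, motif_type=motif_type, aa5=pair[0], aa_last=pair[1])
            )
        decoys.append(
            PPRProtein(
                protein_id=f"decoy_{i:03d}",
                motifs=tuple(_append_terminal_motifs(dmotifs, rng)),
                has_dyw=True,
            )
        )
    return planted, site, decoys


# ---------------------------------------------------------------------------
# Count matrices


def simulate_count_matrices(
    config: GeneratorConfig,
    sample_a: str = "wildtype",
    sample_b: str = "mutant",
) -> tuple[SiteCountMatrix, SiteCountMatrix, pd.DataFrame]:
    """Binomially sampled edited/unedited counts for two genotypes.

    Site ``i`` sits at ``first_position + i`` on the forward strand with
    reference base C.  Edited reads appear as T, unedited as C; A and G
    receive independent binomial miscalls at ``error_rate``.  The truth
    table records the planted extents and whether each site is truly
    "lost" (mutant extent <= 5% of the wild-type extent, with a real
    decrease).
    """
    rng = config.rng("counts")
    coverages = config.site_coverages
    if len(coverages) < len(config.editing_rates):
        coverages = tuple(coverages) + (None,) * (len(config.editing_rates) - len(coverages))

    rows_a, rows_b, truth_rows = [], [], []
    for i, (rate_a, rate_b) in enumerate(config.editing_rates):
        position = config.first_position + i
        fixed = coverages[i]
        for sample, rate, rows, which in (
            (sample_a, rate_a, rows_a, 0),
            (sample_b, rate_b, rows_b, 1),
        ):
            if fixed is not None:
                cov = int(fixed[which])
            else:
                cov = int(rng.integers(config.coverage_range[0], config.coverage_range[1] + 1))
            edited = int(rng.binomial(cov, rate)) if cov > 0 else 0
            noise_a = int(rng.binomial(cov, config.error_rate)) if cov > 0 else 0
            noise_g = int(rng.binomial(cov, config.error_rate)) if cov > 0 else 0
            rows.append(
                dict(
                    sample_id=sample,
                    position=position,
                    ref="C",
                    A=noise_a,
                    C=cov - edited,
                    G=noise_g,
                    T=edited,
                )
            )
        lost = rate_a > 0 and rate_b <= 0.05 * rate_a
        truth_rows.append(
            dict(position=position, rate_a=rate_a, rate_b=rate_b, lost=lost,
                 changed=rate_a != rate_b)
        )
    matrix_a = SiteCountMatrix(pd.DataFrame(rows_a, columns=COUNT_COLUMNS))
    matrix_b = SiteCountMatrix(pd.DataFrame(rows_b, columns=COUNT_COLUMNS))
    return matrix_a, matrix_b, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Orthologue panel


def _drift(window: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for base in window[:-1]:
        if rng.random() < rate:
            others = [n for n in NUCLEOTIDES if n != base]
            out.append(str(rng.choice(others)))
        else:
            out.append(base)
    return "".join(out) + window[-1]


def simulate_orthologue_panel(
    config: GeneratorConfig,
    truth: Optional[dict[tuple[str, tuple[str, str]], str]] = None,
) -> list[SpeciesSiteRecord]:
    """Species panel with controlled conservation of a planted binding site.

    Every species carries the planted factor as its orthologue.  In
    editable species the site base stays C and the window drifts slowly
    (``divergence_rate * editable_drift_factor`` per position, emulating
    binding-site constraint); in non-editable species the site base
    mutates to T (rarely A or G) and the window drifts at the full
    ``divergence_rate``.
    """
    planted, site, _ = simulate_protein_with_target(config, truth)
    rng = config.rng("ortho")
    records = []
    for i, editable in enumerate(config.editability()):
        species = f"species_{i:02d}"
        if editable:
            window = _drift(site.window, config.divergence_rate * config.editable_drift_factor, rng)
        else:
            drifted = _drift(site.window, config.divergence_rate, rng)
            site_base = "U" if rng.random() < 0.8 else str(rng.choice(["A", "G"]))
            window = drifted[:-1] + site_base
        records.append(
            SpeciesSiteRecord(
                species=species,
                site_id=site.site_id,
                window=window,
                protein=replace(planted, protein_id=f"orth_{species}"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Fixture directory (used by the CLI `simulate` subcommand)


def write_fixture_directory(config: GeneratorConfig, outdir: Union[str, Path]) -> dict:
    """Generate every pipeline input into ``outdir``; returns written paths."""
    from ppredit.code_scoring import write_observations_tsv, write_sites_tsv
    from ppredit.ortho_compare import write_orthologue_tsv
    from ppredit.ppr_model import write_ppr_annotation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    observations, truth = simulate_training_observations(config)
    planted, site, decoys = simulate_protein_with_target(config, truth)
    matrix_a, matrix_b, count_truth = simulate_count_matrices(config)
    panel = simulate_orthologue_panel(config, truth)

    paths = {
        "training_observations": outdir / "training_observations.tsv",
        "proteins": outdir / "proteins.tsv",
        "sites": outdir / "sites.tsv",
        "counts_wildtype": outdir / "counts_wildtype.tsv",
        "counts_mutant": outdir / "counts_mutant.tsv",
        "count_truth": outdir / "count_truth.tsv",
        "orthologues": outdir / "orthologues.tsv",
        "orthologue_proteins": outdir / "orthologue_proteins.tsv",
    }
    write_observations_tsv(observations, paths["training_observations"])
    write_ppr_annotation([planted, *decoys], paths["proteins"])
    write_sites_tsv([site], paths["sites"])
    matrix_a.write(paths["counts_wildtype"])
    matrix_b.write(paths["counts_mutant"])
    count_truth.to_csv(paths["count_truth"], sep="\t", index=False)
    write_orthologue_tsv(panel, paths["orthologues"])
    write_ppr_annotation(
        sorted({r.protein.protein_id: r.protein for r in panel}.values(),
               key=lambda p: p.protein_id),
        paths["orthologue_proteins"],
    )
    return {k: str(v) for k, v in paths.items()}
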