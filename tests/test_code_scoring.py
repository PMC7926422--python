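"""Scoring-table construction, motif-site alignment and candidate ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import worked_observations
from ppredit.code_scoring import (
    AlignmentObservation,
    EditingSite,
    ScoringTableSet,
    align_motifs_to_site,
    build_scoring_tables,
    rank_candidates,
    read_sites_tsv,
    score_distribution,
    score_protein_site,
    write_sites_tsv,
)
from ppredit.ppr_model import AminoAcidPair, PPRMotif, PPRProtein, truncate_protein

LN_50_20 = math.log(50 / 20)
LN_10_20 = math.log(10 / 20)


def _protein(types_and_pairs, protein_id="X", with_terminal=True):
    motifs = [
        PPRMotif(i + 1, mt, aa5, aa_last)
        for i, (mt, aa5, aa_last) in enumerate(types_and_pairs)
    ]
    if with_terminal:
        n = len(motifs)
        motifs.append(PPRMotif(n + 1, "E1", "T", "N"))
        motifs.append(PPRMotif(n + 2, "E2", "T", "N"))
    return PPRProtein(protein_id, tuple(motifs))


class TestBuildScoringTables:
    def test_worked_fixture_matches_hand_computation(self):
        pairs, obs = worked_observations()
        tables = build_scoring_tables(obs, pseudocount=10.0)
        for pair, base in zip(pairs[:4], "ACGU"):
            ap = AminoAcidPair(*pair)
            assert tables.lookup("P", ap, base) == pytest.approx(LN_50_20, abs=1e-12)
            for other in set("ACGU") - {base}:
                assert tables.lookup("P", ap, other) == pytest.approx(LN_10_20, abs=1e-12)
        # balanced pair: observed == expected == 10 -> exactly 0
        for base in "ACGU":
            assert tables.lookup("P", AminoAcidPair(*pairs[4]), base) == 0.0

    def test_unseen_pair_scores_zero_for_all_bases(self):
        _, obs = worked_observations()
        tables = build_scoring_tables(obs)
        for base in "ACGU":
            assert tables.lookup("P", AminoAcidPair("W", "W"), base) == 0.0

    def test_invalid_pseudocount_and_empty_observations_rejected(self):
        _, obs = worked_observations()
        with pytest.raises(ValueError, match="pseudocount"):
            build_scoring_tables(obs, pseudocount=0.0)
        with pytest.raises(ValueError, match="empty"):
            build_scoring_tables([])

    def test_scores_match_formula_recomputed_independently(self, training):
        """Cross-check every table cell against a pandas pivot + formula."""
        observations, _ = training
        tables = build_scoring_tables(observations)
        df = pd.DataFrame(
            [
                dict(mt=o.motif_type, pair=o.pair.as_tuple(), nuc=o.nucleotide, w=o.weight)
                for o in observations
            ]
        )
        for mt, group in df.groupby("mt"):
            counts = group.pivot_table(
                index="pair", columns="nuc", values="w", aggfunc="sum", fill_value=0.0
            ).reindex(columns=list("ACGU"), fill_value=0.0)
            expected = (
                np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.values.sum()
            )
            ref = np.log((10.0 + counts.values) / (10.0 + expected))
            for i, pair in enumerate(counts.index):
                for j, nuc in enumerate("ACGU"):
                    assert tables.lookup(mt, AminoAcidPair(*pair), nuc) == pytest.approx(
                        ref[i, j], abs=1e-12
                    )

    def test_formula_monotone_in_observed_count(self):
        # fixed expected, increasing observed -> strictly increasing score
        scores = [math.log((10 + o) / (10 + 12.5)) for o in range(0, 50, 5)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_coarsening_pools_fine_labels(self):
        obs = [
            AlignmentObservation("P1", AminoAcidPair("T", "N"), "A", 30),
            AlignmentObservation("P2", AminoAcidPair("T", "N"), "A", 30),
            AlignmentObservation("P1", AminoAcidPair("S", "D"), "U", 30),
        ]
        tables = build_scoring_tables(obs, coarsen=True)
        assert tables.motif_types == ("P",)
        # lookups by fine label resolve through the coarsening map
        assert tables.lookup("P2", AminoAcidPair("T", "N"), "A") == tables.lookup(
            "P", AminoAcidPair("T", "N"), "A"
        )

    def test_table_tsv_round_trip(self, tmp_path, tables):
        tables.write(tmp_path / "tables")
        again = ScoringTableSet.read(tmp_path / "tables")
        assert again.motif_types == tables.motif_types
        for mt in tables.motif_types:
            pd.testing.assert_frame_equal(again.frame(mt), tables.frame(mt))


class TestAlignment:
    def test_e2_anchored_layout_on_17_motif_protein(self):
        types = [("P", "T", "N")] * 17
        protein = _protein(types)
        site = EditingSite(site_id="s", window="A" * 20 + "C")
        aligned = dict(
            (motif.index, off) for motif, off in align_motifs_to_site(protein, site)
        )
        assert aligned[19] == -2  # E2
        assert aligned[18] == -3  # E1
        assert aligned[17] == -4  # C-terminal-most P/L/S motif
        assert aligned[1] == -20  # N-terminal motif

    def test_single_motif_protein_occupies_three_positions(self):
        protein = _protein([("P", "T", "N")])
        site = EditingSite(site_id="s", window="ACGUC")
        offsets = [off for _, off in align_motifs_to_site(protein, site)]
        assert offsets == [-4, -3, -2]

    def test_motifs_past_window_start_get_null_positions(self):
        protein = _protein([("P", "T", "N")] * 10)
        site = EditingSite(site_id="s", window="ACGUC")  # too short for 10 motifs
        offsets = [off for _, off in align_motifs_to_site(protein, site)]
        # E2 at -2, E1 at -3, motifs 10 and 9 at -4/-5; motifs 1-8 overflow
        assert offsets.count(None) == 8

    def test_no_e2_protein_anchors_cterminal_motif(self):
        protein = _protein([("P", "T", "N")] * 3, with_terminal=False)
        site = EditingSite(site_id="s", window="ACGAUGC")
        offsets = [off for _, off in align_motifs_to_site(protein, site)]
        assert offsets == [-6, -5, -4]

    def test_window_must_end_at_edited_c(self):
        with pytest.raises(ValueError, match="edited C"):
            EditingSite(site_id="s", window="ACGUA")

    def test_zero_motif_protein_cannot_align(self):
        protein = PPRProtein("empty", ())
        site = EditingSite(site_id="s", window="AC")
        with pytest.raises(ValueError, match="no motifs"):
            align_motifs_to_site(protein, site)


def _planted_ones_tables(pairs=(("T", "N"),)):
    return ScoringTableSet(
        {mt: {p: np.ones(4) for p in pairs} for mt in ("P", "L", "S")}
    )


class TestScoring:
    def test_planted_unit_scores_sum_to_motif_count(self):
        protein = _protein([("P", "T", "N"), ("L", "T", "N"), ("S", "T", "N")] * 6 + [("P", "T", "N")])
        assert len(protein.pls_motifs) == 19
        site = EditingSite(site_id="s", window="A" * 22 + "C")
        result = score_protein_site(protein, site, _planted_ones_tables())
        assert result.total == pytest.approx(19.0)
        assert result.total == pytest.approx(sum(s for _, _, s in result.per_motif))

    def test_zero_scorable_motifs_scores_zero(self):
        protein = _protein([("P", "T", "N")] * 3)
        truncated = truncate_protein(protein, 1)  # keeps nothing
        site = EditingSite(site_id="s", window="AAAC")
        with pytest.raises(ValueError):
            score_protein_site(truncated, site, _planted_ones_tables())
        # a protein whose pairs are all gaps is alignable but scores 0
        gappy = _protein([("P", "-", "-")] * 3)
        assert score_protein_site(gappy, site, _planted_ones_tables()).total == 0.0

    def test_terminal_motifs_scored_only_on_request(self):
        protein = _protein([("P", "T", "N")])
        site = EditingSite(site_id="s", window="AAAAC")
        tables = ScoringTableSet(
            {mt: {("T", "N"): np.ones(4)} for mt in ("P", "E1", "E2")}
        )
        assert score_protein_site(protein, site, tables).total == pytest.approx(1.0)
        assert score_protein_site(
            protein, site, tables, score_terminal_motifs=True
        ).total == pytest.approx(3.0)

    def test_permuting_motifs_with_different_bases_changes_total(self, tables, training):
        _, truth = training
        # two P-type pairs with different planted preferences
        p_pairs = [(pair, base) for (mt, pair), base in truth.items() if mt == "P"]
        (pair_a, base_a), (pair_b, base_b) = next(
            ((a, b) for a, b in itertools.combinations(p_pairs, 2) if a[1] != b[1])
        )
        window = "A" + base_a + base_b + "AAC"
        site = EditingSite(site_id="s", window=window)
        protein = _protein([("P", *pair_a), ("P", *pair_b)])
        permuted = _protein([("P", *pair_b), ("P", *pair_a)])
        t1 = score_protein_site(protein, site, tables).total
        t2 = score_protein_site(permuted, site, tables).total
        assert t1 != pytest.approx(t2)

    def test_additivity_over_motif_partitions(self, tables, planted):
        protein, site, _ = planted
        full = score_protein_site(protein, site, tables)
        per_motif = {idx: s for idx, _, s in full.per_motif}
        for split in (3, 8, len(protein.motifs) - 1):
            head = sum(s for idx, s in per_motif.items() if idx <= split)
            tail = sum(s for idx, s in per_motif.items() if idx > split)
            assert head + tail == pytest.approx(full.total)

    def test_translation_invariance(self, tables, planted):
        protein, site, _ = planted
        moved = EditingSite(
            site_id=site.site_id,
            window=site.window,
            genome_position=site.genome_position + 12345,
            strand=site.strand,
        )
        assert score_protein_site(protein, moved, tables).total == pytest.approx(
            score_protein_site(protein, site, tables).total
        )

    def test_exhaustive_oracle_on_small_windows(self, tables, training):
        """Totals for 3-motif proteins on 6-nt windows match a hand-rolled
        enumeration of table lookups over every window."""
        _, truth = training
        p_pair = next(pair for (mt, pair) in truth if mt == "P")
        l_pair = next(pair for (mt, pair) in truth if mt == "L")
        s_pair = next(pair for (mt, pair) in truth if mt == "S")
        protein = _protein([("P", *p_pair), ("L", *l_pair), ("S", *s_pair)])
        for bases in itertools.product("ACGU", repeat=4):
            window = "A" + "".join(bases) + "C"  # length 6, ends at the edited C
            site = EditingSite(site_id="w", window=window)
            # motifs at offsets -6, -5, -4 -> window indices 0, 1, 2
            expected = (
                tables.lookup("P", AminoAcidPair(*p_pair), window[0])
                + tables.lookup("L", AminoAcidPair(*l_pair), window[1])
                + tables.lookup("S", AminoAcidPair(*s_pair), window[2])
            )
            assert score_protein_site(protein, site, tables).total == pytest.approx(
                expected, abs=1e-12
            )


class TestRanking:
    def test_planted_best_match_ranks_first(self, tables, planted):
        protein, site, decoys = planted
        ranked = rank_candidates(site, [protein, *decoys], tables)
        by_id = {pid: rank for pid, _, rank in ranked}
        assert by_id["planted_factor"] == 1

    def test_single_protein_ranks_first(self, tables, planted):
        protein, site, _ = planted
        assert rank_candidates(site, [protein], tables)[0][2] == 1

    def test_identical_proteins_tie_at_rank_one(self, tables, planted):
        protein, site, _ = planted
        from dataclasses import replace

        twin = replace(protein, protein_id="twin")
        ranked = rank_candidates(site, [protein, twin], tables)
        assert [rank for _, _, rank in ranked] == [1, 1]

    def test_competition_ranking_counts_strictly_better(self):
        site = EditingSite(site_id="s", window="AAAAC")
        tables = _planted_ones_tables(pairs=(("T", "N"), ("W", "W")))
        # scored motif ("T","N") hits the table; ("W","W") is absent -> 0
        strong = _protein([("P", "T", "N")], protein_id="strong")
        weak1 = _protein([("P", "W", "F")], protein_id="weak1")
        weak2 = _protein([("P", "W", "F")], protein_id="weak2")
        ranked = rank_candidates(site, [weak1, strong, weak2], tables)
        assert [(pid, rank) for pid, _, rank in ranked] == [
            ("strong", 1), ("weak1", 2), ("weak2", 2),
        ]


class TestScoreDistribution:
    def test_summary_of_three_planted_totals(self, tables, planted):
        protein, site, decoys = planted
        summary = score_distribution(site, [protein, *decoys[:2]], tables,
                                     named_protein="planted_factor")
        assert summary["n"] == 3
        assert summary["found"] and summary["named"]["rank"] == 1
        assert summary["max"] == pytest.approx(summary["named"]["total"])
        assert summary["min"] <= summary["median"] <= summary["max"]

    def test_missing_named_protein_is_flagged_not_raised(self, tables, planted):
        protein, site, _ = planted
        summary = score_distribution(site, [protein], tables, named_protein="nope")
        assert summary["found"] is False and summary["named"] is None

    def test_max_equals_top_ranked_total(self, tables, planted):
        protein, site, decoys = planted
        summary = score_distribution(site, [protein, *decoys], tables)
        top = rank_candidates(site, [protein, *decoys], tables)[0]
        assert summary["max"] == pytest.approx(top[1])


def test_sites_tsv_round_trip(tmp_path, planted):
    _, site, _ = planted
    path = tmp_path / "sites.tsv"
    write_sites_tsv([site], path)
    (again,) = read_sites_tsv(path)
    assert (again.site_id, again.window, again.strand) == (
        site.site_id, site.window, site.strand,
    )
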