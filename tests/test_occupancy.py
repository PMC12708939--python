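import numpy as np
import pandas as pd
import pytest

from ribopause.footprints import FootprintAlignment, match_footprints
from ribopause.occupancy import (
    DEFAULT_GROUPS,
    CodonOccupancy,
    SiteSpec,
    count_by_codon_site,
    default_sites,
    differential_occupancy,
    group_counts,
    per_transcript_differential,
)
from ribopause.simulate import SimConfig, generate_transcriptome, simulate_footprints
from ribopause.transcripts import TranscriptModel, codon_at


def brute_force_codon_site(alignments, transcripts, sites, library_total):
    """Independent oracle: nested loop reading codons straight off sequences."""
    tmap = {t.transcript_id: t for t in transcripts}
    table = {}
    for a in alignments:
        t = tmap[a.transcript_id]
        for s in sites:
            pos = a.p_site + s.nt_offset
            if pos < t.cds_start or pos + 3 > t.cds_end:
                continue
            if (pos - t.cds_start) % 3 != 0:
                continue
            c = t.sequence[pos : pos + 3]
            table[c, s.name] = table.get((c, s.name), 0) + 1
    return table


class TestSites:
    def test_default_site_list(self):
        sites = default_sites()
        assert [(s.name, s.nt_offset) for s in sites] == [
            ("minus6", -6), ("E", -3), ("P", 0), ("A", 3), ("plus6", 6),
        ]

    def test_extra_site_allowed(self):
        assert SiteSpec("plus9", 9).nt_offset == 9

    def test_non_codon_aligned_offset_rejected(self):
        with pytest.raises(ValueError, match="codon-aligned"):
            SiteSpec("bad", 4)


class TestCountByCodonSite:
    def test_direct_addressing(self, tiny_transcript):
        # P site on AAA: E reads ATG, A reads GAA, +6 reads the stop, -6 outside
        aln = FootprintAlignment("r1", "t1", -9, 28, 3, 0)
        csc = count_by_codon_site([aln], [tiny_transcript], library_total=1)
        t = csc.table.set_index(["codon", "site"])["raw"]
        assert t["AAA", "P"] == 1
        assert t["GAA", "A"] == 1
        assert t["ATG", "E"] == 1
        assert t["TAA", "plus6"] == 1
        assert t.sum() == 4  # minus6 fell outside the CDS

    def test_boundary_at_start_codon(self, tiny_transcript):
        aln = FootprintAlignment("r1", "t1", -12, 28, 0, 0)
        csc = count_by_codon_site([aln], [tiny_transcript], library_total=1)
        t = csc.table.set_index(["codon", "site"])["raw"]
        assert t["ATG", "P"] == 1 and t["AAA", "A"] == 1
        assert t.xs("E", level="site").sum() == 0
        assert t.xs("minus6", level="site").sum() == 0

    def test_out_of_frame_p_site_contributes_nowhere(self, tiny_transcript):
        aln = FootprintAlignment("r1", "t1", -8, 28, 4, 1)
        csc = count_by_codon_site([aln], [tiny_transcript], library_total=1)
        assert csc.table["raw"].sum() == 0

    def test_matches_brute_force_oracle(self):
        cfg = SimConfig(n_transcripts=5, cds_length_range=(150, 300),
                        depth=1000, seed=13)
        ts = generate_transcriptome(cfg)
        reads, _ = simulate_footprints(ts, cfg, "mut")
        alns, _ = match_footprints(reads, ts)
        sites = default_sites()
        csc = count_by_codon_site(alns, ts, sites, len(alns))
        got = {
            (r.codon, r.site): r.raw for r in csc.table.itertuples() if r.raw
        }
        assert got == brute_force_codon_site(alns, ts, sites, len(alns))

    def test_per_site_totals_bounded_by_alignments(self, small_transcriptome, small_cfg):
        reads, _ = simulate_footprints(small_transcriptome, small_cfg, "wt")
        alns, _ = match_footprints(reads, small_transcriptome)
        csc = count_by_codon_site(alns, small_transcriptome)
        per_site = csc.table.groupby("site")["raw"].sum()
        assert (per_site <= len(alns)).all()
        assert per_site["P"] == len(alns)  # every in-frame P site is a CDS codon


class TestGrouping:
    def test_group_sums(self, tiny_transcript):
        alns = [
            FootprintAlignment("r1", "t1", -9, 28, 3, 0),
            FootprintAlignment("r2", "t1", -9, 28, 3, 0),
        ]
        csc = count_by_codon_site(alns, [tiny_transcript], library_total=2)
        g = group_counts(csc).table.set_index(["group", "site"])
        assert g.loc[("NAA", "P"), "raw"] == 2  # AAA at P
        assert g.loc[("NAA", "A"), "raw"] == 2  # GAA at A
        assert g.loc[("NGA", "A"), "raw"] == 0

    def test_overlapping_groups_rejected(self, tiny_transcript):
        csc = count_by_codon_site([], [tiny_transcript], library_total=1)
        with pytest.raises(ValueError, match="overlap"):
            group_counts(csc, {"a": {"AAA"}, "b": {"AAA", "GGG"}})

    def test_empty_table_gives_zero_groups(self, tiny_transcript):
        csc = count_by_codon_site([], [tiny_transcript], library_total=1)
        g = group_counts(csc).table
        assert (g["raw"] == 0).all() and (g["normalized"] == 0).all()


class TestDifferential:
    def _grouped(self, seed, cond):
        cfg = SimConfig(n_transcripts=5, cds_length_range=(150, 300),
                        depth=2000, seed=seed)
        ts = generate_transcriptome(cfg)
        reads, _ = simulate_footprints(ts, cfg, cond)
        alns, _ = match_footprints(reads, ts)
        return group_counts(count_by_codon_site(alns, ts, None, len(alns), cond))

    def test_identical_inputs_give_zero(self):
        g = self._grouped(1, "wt")
        d = differential_occupancy(g, g)
        assert (d.table["diff_normalized"] == 0).all()

    def test_antisymmetry_under_condition_swap(self):
        gw, gm = self._grouped(1, "wt"), self._grouped(1, "mut")
        d1 = differential_occupancy(gm, gw).table
        d2 = differential_occupancy(gw, gm).table
        assert np.allclose(d1["diff_normalized"], -d2["diff_normalized"])
        assert np.allclose(d1["se_normalized"], d2["se_normalized"])

    def test_mismatched_keys_rejected(self, tiny_transcript):
        csc = count_by_codon_site([], [tiny_transcript], library_total=1)
        g1 = group_counts(csc, {"NAA": {"AAA"}})
        g2 = group_counts(csc, {"NGG": {"GGG"}})
        with pytest.raises(ValueError, match="mismatched"):
            differential_occupancy(g1, g2)

    def test_pause_signal_and_compositional_dilution(self):
        """A 3x A-site dwell on NAA makes (NAA, A) the dominant entry; under
        per-million normalization the library is a closed composition, so the
        A-site cells of unboosted groups are diluted by ~the inverse mean
        dwell while non-A cells stay at 0 within counting noise."""
        cfg = SimConfig(seed=101)
        ts = generate_transcriptome(cfg)
        from ribopause.footprints import FootprintMatcher

        matcher = FootprintMatcher(ts)
        alns = {
            c: matcher.match(simulate_footprints(ts, cfg, c)[0])[0]
            for c in ("wt", "mut")
        }
        res = CodonOccupancy(ts, alns).fit()
        d = res.differential("mut", "wt").table.set_index(["group", "site"])
        assert d["diff_normalized"].idxmax() == ("NAA", "A")
        # non-A-site control cells: no signal beyond counting noise
        ctrl = d.loc[(["NGA", "NGG"], ["minus6", "E", "P", "plus6"]), :]
        assert (ctrl["diff_normalized"].abs() <= 4 * ctrl["se_normalized"]).all()
        # A-site control cells: match the predicted compositional dilution
        wt = res.grouped["wt"].table.set_index(["group", "site"])
        naa_share = wt.loc[("NAA", "A"), "normalized"] / 1e6
        dilution = 1.0 / (1.0 + 2.0 * naa_share) - 1.0  # mean dwell = 1 + 2*share
        for grp in ("NGA", "NGG"):
            expected = dilution * wt.loc[(grp, "A"), "normalized"]
            se = d.loc[(grp, "A"), "se_normalized"]
            assert d.loc[(grp, "A"), "diff_normalized"] == pytest.approx(
                expected, abs=4 * se
            )


class TestPerTranscript:
    def _setup(self):
        cfg = SimConfig(n_transcripts=5, cds_length_range=(150, 300),
                        depth=4000, seed=21)
        ts = generate_transcriptome(cfg)
        from ribopause.footprints import FootprintMatcher

        matcher = FootprintMatcher(ts)
        alns = {
            c: matcher.match(simulate_footprints(ts, cfg, c)[0])[0]
            for c in ("wt", "mut")
        }
        totals = {c: len(a) for c, a in alns.items()}
        return ts, alns, totals

    def test_additivity_over_transcripts(self):
        ts, alns, totals = self._setup()
        whole = differential_occupancy(
            group_counts(count_by_codon_site(alns["mut"], ts, None, totals["mut"], "mut")),
            group_counts(count_by_codon_site(alns["wt"], ts, None, totals["wt"], "wt")),
        ).table.set_index(["group", "site"])["diff_normalized"]
        summed = sum(
            per_transcript_differential(alns, t, library_totals=totals)
            .table.set_index(["group", "site"])["diff_normalized"]
            for t in ts
        )
        pd.testing.assert_series_equal(whole, summed, check_names=False)

    def test_absent_transcript_is_an_error(self):
        ts, alns, totals = self._setup()
        ghost = TranscriptModel("ghost", "A" * 30 + "ATGAAATAA" + "A" * 30, 30, 39)
        with pytest.raises(ValueError, match="ghost"):
            per_transcript_differential(alns, ghost, library_totals=totals)

    def test_transcript_without_group_codons_scores_zero(self):
        t = TranscriptModel("t1", ("N" * 0) + "ATGCTGCTGCTGTAA", 0, 15)
        # build alignments directly: P sites on the CTG codons
        alns = {
            "wt": [FootprintAlignment("w1", "t1", -9, 28, 3, 0)],
            "mut": [FootprintAlignment("m1", "t1", -9, 28, 3, 0)],
        }
        d = per_transcript_differential(alns, t, library_totals={"wt": 1, "mut": 1})
        naa = d.table[d.table.group == "NAA"]
        assert (naa["diff_normalized"] == 0).all()
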