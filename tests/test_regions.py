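"""Transcript parsing, scan-window geometry and region filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ironspot import regions as rg


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestReadAnnotation:
    def test_refgene_field_mapping(self, tmp_path):
        row = "\t".join(
            ["0", "NM_1", "chr1", "+", "100", "400", "120", "380", "2",
             "100,300,", "200,400,", "0", "GENEA", "cmpl", "cmpl", "0,0,"]
        )
        path = _write(tmp_path, "a.txt", row + "\n")
        (model,) = rg.read_annotation(path, "refgene")
        assert model.exons == ((100, 200), (300, 400))
        assert model.cds_start == 120 and model.cds_end == 380
        assert model.gene_symbol == "GENEA"
        assert model.is_coding

    def test_noncoding_when_cds_empty(self, tmp_path):
        row = "\t".join(
            ["0", "NR_1", "chr1", "+", "100", "400", "400", "400", "2",
             "100,300,", "200,400,", "0", "GENEB", "none", "none", "-1,-1,"]
        )
        (model,) = rg.read_annotation(_write(tmp_path, "b.txt", row + "\n"), "refgene")
        assert not model.is_coding

    def test_gtf_matches_refgene_on_three_exon_gene(self, tmp_path):
        refgene_row = "\t".join(
            ["0", "T1", "chr2", "-", "10", "300", "10", "10", "3",
             "10,100,250,", "50,150,300,", "0", "G1", "none", "none", "-1,-1,-1,"]
        )
        gtf = "\n".join(
            f'chr2\tx\texon\t{s + 1}\t{e}\t.\t-\t.\tgene_name "G1"; transcript_id "T1";'
            for s, e in [(10, 50), (100, 150), (250, 300)]
        )
        (m_ref,) = rg.read_annotation(_write(tmp_path, "c.txt", refgene_row + "\n"), "refgene")
        (m_gtf,) = rg.read_annotation(_write(tmp_path, "c.gtf", gtf + "\n"), "gtf")
        assert m_gtf.exons == m_ref.exons
        assert not m_gtf.is_coding and not m_ref.is_coding

    def test_malformed_row_reports_line(self, tmp_path):
        path = _write(tmp_path, "bad.txt", "only\tthree\tcols\n")
        with pytest.raises(rg.AnnotationError, match="bad.txt:1"):
            rg.read_annotation(path, "refgene")

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        assert rg.read_annotation(_write(tmp_path, "e.txt", ""), "refgene") == []


class TestBuildRegions:
    def test_plus_strand_window_geometry(self, two_exon_plus):
        regions = rg.build_splice_site_regions([two_exon_plus])
        by_side = {r.side: r for r in regions}
        assert by_side["donor"].window == (197, 206)
        assert by_side["donor"].boundary == 200
        assert by_side["acceptor"].window == (294, 301)
        assert by_side["acceptor"].boundary == 300

    def test_minus_strand_windows_mirror(self, two_exon_minus):
        regions = rg.build_splice_site_regions([two_exon_minus])
        by_side = {r.side: r for r in regions}
        assert by_side["donor"].window == (294, 303)
        assert by_side["acceptor"].window == (199, 206)

    def test_three_exons_give_two_donors_two_acceptors(self):
        model = rg.TranscriptModel(
            "T", "G", "chr1", "+", ((0, 100), (200, 300), (400, 500)), 0, 0
        )
        regions = rg.build_splice_site_regions([model])
        sides = sorted(r.side for r in regions)
        assert sides == ["acceptor", "acceptor", "donor", "donor"]

    def test_window_lengths_on_simulated_annotation(self, planted_scene):
        for region in planted_scene.regions:
            expected = 9 if region.side == "donor" else 7
            assert region.window[1] - region.window[0] == expected

    def test_shared_boundary_merges_isoforms(self, two_exon_plus):
        iso2 = rg.TranscriptModel(
            "TXP2", "GP", "chr1", "+", ((50, 200), (300, 450)), 60, 440
        )
        regions = rg.build_splice_site_regions([two_exon_plus, iso2])
        donors = [r for r in regions if r.side == "donor"]
        assert len(donors) == 1
        assert set(donors[0].transcript_ids) == {"TXP", "TXP2"}

    def test_single_exon_model_yields_nothing(self):
        model = rg.TranscriptModel("T", "G", "chr1", "+", ((0, 100),), 0, 0)
        assert rg.build_splice_site_regions([model]) == []

    @given(shift=st.integers(0, 10_000), span=st.integers(1000, 5000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_strand_involution(self, shift, span):
        """Mirroring a gene through a coordinate reflection and flipping the
        strand yields mirrored windows."""
        exons = ((shift + 100, shift + 200), (shift + 300, shift + 400))
        plus = rg.TranscriptModel("T", "G", "c", "+", exons, shift + 100, shift + 100)
        hi = shift + span + 1000
        mirrored_exons = tuple(
            sorted((hi - e, hi - s) for s, e in exons)
        )
        minus = rg.TranscriptModel(
            "T", "G", "c", "-", mirrored_exons, hi - 200, hi - 200
        )
        plus_regions = rg.build_splice_site_regions([plus])
        minus_regions = rg.build_splice_site_regions([minus])
        plus_mirrored = sorted(
            (r.side, hi - r.window[1], hi - r.window[0]) for r in plus_regions
        )
        got = sorted((r.side, r.window[0], r.window[1]) for r in minus_regions)
        assert got == plus_mirrored


class TestExcludeExonOverlapped:
    def _donor(self, window=(197, 206), tids=("TXP",)):
        return rg.SpliceSiteRegion(
            "chr1", 200, "donor", "+", window, (200, 300), tids
        )

    def test_complete_containment_removes(self, two_exon_plus):
        other = rg.TranscriptModel("OT", "OG", "chr1", "+", ((150, 250),), 150, 150)
        kept = rg.exclude_exon_overlapped([self._donor()], [two_exon_plus, other])
        assert kept == []

    def test_partial_overlap_retained(self, two_exon_plus):
        other = rg.TranscriptModel("OT", "OG", "chr1", "+", ((200, 250),), 200, 200)
        kept = rg.exclude_exon_overlapped([self._donor()], [two_exon_plus, other])
        assert len(kept) == 1

    def test_own_transcript_containment_retained(self):
        weird = rg.TranscriptModel("TXP", "G", "chr1", "+", ((150, 250), (400, 500)), 150, 150)
        kept = rg.exclude_exon_overlapped([self._donor()], [weird])
        assert len(kept) == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            models = []
            for i in range(int(rng.integers(5, 30))):
                start = int(rng.integers(0, 2000))
                e1 = start + int(rng.integers(20, 200))
                s2 = e1 + int(rng.integers(50, 200))
                e2 = s2 + int(rng.integers(20, 200))
                models.append(
                    rg.TranscriptModel(
                        f"T{i}", f"G{i}", "chr1", "+" if i % 2 else "-",
                        ((start, e1), (s2, e2)), start, start,
                    )
                )
            regions = rg.build_splice_site_regions(models)
            kept = rg.exclude_exon_overlapped(regions, models)
            expected = []
            for region in regions:
                buried = any(
                    s <= region.window[0] and e >= region.window[1]
                    for m in models
                    if m.transcript_id not in region.transcript_ids
                    for s, e in m.exons
                )
                if not buried:
                    expected.append(region.key)
            assert [r.key for r in kept] == expected


class TestControlPanel:
    def _region(self):
        return rg.SpliceSiteRegion(
            "chr1", 200, "donor", "+", (197, 206), (200, 300), ("T",)
        )

    @pytest.mark.parametrize(
        "fracs, removed",
        [
            ([0.05] * 8 + [0.0] * 2, True),   # 8 of 10 at the threshold
            ([0.9] * 7 + [0.0] * 3, False),   # count below the sample threshold
            ([0.049] * 10, False),            # below the fraction threshold
        ],
    )
    def test_threshold_semantics(self, fracs, removed):
        region = self._region()
        kept = rg.filter_by_control_panel([region], {region.key: fracs})
        assert (kept == []) is removed

    def test_missing_region_kept_with_warning(self, caplog):
        region = self._region()
        kept = rg.filter_by_control_panel([region], {})
        assert kept == [region]

    @given(
        fracs=st.lists(st.floats(0, 1), min_size=10, max_size=10),
        d_frac=st.floats(0, 0.5),
        d_n=st.integers(0, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_monotone_in_both_thresholds(self, fracs, d_frac, d_n):
        region = self._region()
        profile = {region.key: fracs}
        base = rg.filter_by_control_panel([region], profile, 0.05, 8)
        looser = rg.filter_by_control_panel([region], profile, 0.05 + d_frac, 8 + d_n)
        assert len(looser) >= len(base)

    def test_profile_tsv_round_trip(self, tmp_path):
        region = self._region()
        profile = {region.key: [0.0, 0.25, 1.0]}
        path = tmp_path / "panel.tsv"
        rg.write_control_profile(profile, str(path))
        assert rg.read_control_profile(str(path)) == profile
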