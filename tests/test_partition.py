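import warnings

import pandas as pd
import pytest

from sirescan import (DomainHits, PartitionError, check_pol_anchor,
                      partition_pol, read_domain_hits)
from sirescan.partition import find_ilgd, find_rnase_motif, partition_to_frame


def build_pol(protease_len=120, integrase_len=300, rt_len=200,
              rnase_len=150, filler="L"):
    """Synthetic pol with anchors at analytically known coordinates.

    Layout (1-based): protease [1, protease_len]; GAG-pre-integrase starts
    at protease_len+1; PF07727 starts 30 aa into the RT segment (so the
    integrase/RT junction back-computes exactly); the ribonuclease
    D10-E48-D70 motif's first D sits 15 aa into the RNase segment.
    """
    rt_start_seg = protease_len + integrase_len + 1     # RT junction
    pf07727_start = rt_start_seg + 30
    pf07727_end = pf07727_start + 100
    rnase_start_seg = protease_len + integrase_len + rt_len + 1
    d_pos = rnase_start_seg + 15
    total = protease_len + integrase_len + rt_len + rnase_len
    seq = [filler] * total
    seq[d_pos - 1] = "D"
    seq[d_pos - 1 + 48] = "E"
    seq[d_pos - 1 + 70] = "D"
    # ADIFTK 3'-completeness anchor near the end
    anchor_at = total - 40
    seq[anchor_at - 1:anchor_at + 5] = list("ADIFTK")
    # ILGD a short distance upstream of the integrase 3' end
    seq[rt_start_seg - 60:rt_start_seg - 56] = list("ILGD")
    hits = DomainHits("pol1", (
        ("GAG-pre-integrase", protease_len + 1, protease_len + 40),
        ("PF07727-RT", pf07727_start, pf07727_end),
    ))
    expected = (
        ("protease", 1, protease_len),
        ("integrase", protease_len + 1, rt_start_seg - 1),
        ("reverse_transcriptase", rt_start_seg, d_pos - 16),
        ("ribonuclease", d_pos - 15, total),
    )
    return "".join(seq), hits, expected


class TestCheckPolAnchor:
    def test_motif_near_three_prime_end(self):
        protein, _, _ = build_pol()
        found, pos = check_pol_anchor(protein)
        assert found and protein[pos - 1:pos + 5] == "ADIFTK"
        assert len(protein) - pos < 50

    def test_motif_absent(self):
        assert check_pol_anchor("MKLLV" * 20) == (False, None)

    def test_motif_at_position_one(self):
        assert check_pol_anchor("ADIFTK") == (True, 1)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            check_pol_anchor("")


class TestPartitionPol:
    def test_segments_at_forced_coordinates(self):
        protein, hits, expected = build_pol()
        part = partition_pol(protein, hits)
        assert part.segments == expected
        assert part.complete

    def test_segments_tile_protein_exactly(self):
        protein, hits, _ = build_pol()
        segs = partition_pol(protein, hits).segments
        assert segs[0][1] == 1 and segs[-1][2] == len(protein)
        for (_, _, end), (_, start, _) in zip(segs, segs[1:]):
            assert start == end + 1

    def test_invariant_to_filler_content(self):
        p1, h1, _ = build_pol(filler="L")
        p2, h2, _ = build_pol(filler="G")
        assert partition_pol(p1, h1).segments == \
            partition_pol(p2, h2).segments

    def test_gag_domain_at_start_gives_empty_protease(self):
        protein, hits, _ = build_pol(protease_len=0)
        part = partition_pol(protein, hits)
        assert part.segments[0][0] == "integrase"
        assert any("protease" in w for w in part.warnings)

    def test_disordered_hits_rejected(self):
        protein, _, _ = build_pol()
        bad = DomainHits("x", (("GAG-pre-integrase", 500, 540),
                               ("PF07727-RT", 100, 200)))
        with pytest.raises(PartitionError, match="precede"):
            partition_pol(protein, bad)

    def test_missing_domain_rejected(self):
        protein, _, _ = build_pol()
        with pytest.raises(PartitionError, match="missing"):
            partition_pol(protein,
                          DomainHits("x", (("PF07727-RT", 100, 200),)))

    def test_missing_rnase_motif_gives_partial_partition(self):
        protein, hits, _ = build_pol()
        protein = protein.replace("E", "Q")  # break the D-E-D spacing
        with pytest.warns(UserWarning, match="unresolved"):
            part = partition_pol(protein, hits)
        assert not part.complete
        assert [g for g, _, _ in part.segments] == \
            ["protease", "integrase", "reverse_transcriptase"]
        assert part.segments[-1][2] == len(protein)

    def test_junction_offsets_are_tunable(self):
        protein, hits, _ = build_pol()
        part = partition_pol(protein, hits, rt_offset=20)
        rt = dict((g, (a, b)) for g, a, b in part.segments)
        default = dict((g, (a, b)) for g, a, b in
                       partition_pol(protein, hits).segments)
        assert rt["reverse_transcriptase"][0] == \
            default["reverse_transcriptase"][0] + 10


class TestMotifFinders:
    def test_ilgd_detected(self):
        protein, _, _ = build_pol()
        assert find_ilgd(protein) is not None
        assert protein[find_ilgd(protein) - 1:][:4] == "ILGD"

    def test_rnase_motif_tolerates_small_spacing_shifts(self):
        seq = ["A"] * 200
        seq[49] = "D"
        seq[49 + 46] = "E"   # 48 - 2, inside tolerance 3
        seq[49 + 72] = "D"   # 70 + 2
        assert find_rnase_motif("".join(seq), search_start=1) == 50

    def test_rnase_motif_window_respected(self):
        seq = ["A"] * 400
        seq[299] = "D"
        seq[299 + 48] = "E"
        seq[299 + 70] = "D"
        s = "".join(seq)
        assert find_rnase_motif(s, search_start=1, window=120) is None
        assert find_rnase_motif(s, search_start=250, window=120) == 300


class TestDomainHitsIO:
    def test_read_hits_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        pd.DataFrame({
            "element_id": ["pol1", "pol1"],
            "domain": ["GAG-pre-integrase", "PF07727-RT"],
            "start": [121, 451],
            "end": [160, 551],
        }).to_csv(p, sep="\t", index=False)
        hits = read_domain_hits(p)
        assert hits["pol1"].get("PF07727-RT") == (451, 551)

    def test_partition_frame_layout(self):
        protein, hits, _ = build_pol()
        df = partition_to_frame([partition_pol(protein, hits)])
        assert list(df.columns) == ["element_id", "gene", "start", "end",
                                    "complete"]
        assert len(df) == 4
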